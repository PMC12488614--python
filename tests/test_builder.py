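"""Discretization (d_λ rule), the single-compartment build, and morphology."""

import math

import numpy as np
import pytest

from calres.builder import (GradientSet, build_single_compartment, d_lambda_nseg,
                            discretize, lambda_100)
from calres.gradients import (LinearConductanceGradient,
                              SigmoidConductanceGradient)
from calres.morphology import Morphology, Section, read_swc, write_swc
from calres.synthetic import SyntheticTrunkSpec, make_trunk


def test_lambda_100_scaling_and_closed_form():
    base = lambda_100(2.0, 120.0, 1.0)
    assert lambda_100(8.0, 120.0, 1.0) == pytest.approx(2 * base)
    assert lambda_100(2.0, 480.0, 1.0) == pytest.approx(base / 2)
    # independent evaluation of the closed form
    d_cm, f, ra, cm = 2e-4, 100.0, 120.0, 1e-6
    expected = 0.5 * math.sqrt(d_cm / (math.pi * f * ra * cm)) * 1e4
    assert base == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        lambda_100(-1.0, 120.0, 1.0)


def test_single_compartment_passive_constants():
    m = build_single_compartment()
    area = m.area_cm2[0]
    assert area == pytest.approx(math.pi * 60e-4 * 60e-4)  # lateral, no end caps
    r_in_mohm = 11e3 / area / 1e6
    assert r_in_mohm == pytest.approx(97.3, rel=5e-3)      # printed: 97 MΩ
    assert m.rm[0] * m.cm[0] == pytest.approx(11.0)        # τ_m = 11 ms
    with pytest.raises(ValueError):
        build_single_compartment({"NotAChannel": 1e-3})


def test_short_cylinder_is_one_compartment():
    soma = Section(points=np.array([[0, 0, 0, 60.0], [60.0, 0, 0, 60.0]]),
                   stype="soma", parent=-1)
    model = discretize(Morphology(sections=[soma], identifier="cyl"))
    assert model.n == 1
    assert d_lambda_nseg(60.0, lambda_100(60.0, 100.0, 1.0)) == 1


def test_trunk_discretization_invariants():
    model = discretize(make_trunk())
    assert model.check_d_lambda(0.1)
    # path distance monotone from root to leaf
    for i in range(1, model.n):
        assert model.path_dist_um[i] >= model.path_dist_um[model.parent[i]] - 1e-9
    # bit-identical rebuild (no hidden randomness)
    again = discretize(make_trunk())
    for a, b in [(model.diam_um, again.diam_um), (model.rm, again.rm),
                 (model.dens["CaT"], again.dens["CaT"])]:
        assert np.array_equal(a, b)


def test_gradient_assignment_rules():
    spec = SyntheticTrunkSpec(basal_length_um=150.0, axon_length_um=80.0)
    model = discretize(make_trunk(spec))
    from calres.builder import STYPE_CODE
    apical = model.stype == STYPE_CODE["apical"]
    basal = model.stype == STYPE_CODE["basal"]
    axon = model.stype == STYPE_CODE["axon"]
    # axon: Na/KDR only
    assert np.all(model.dens["Na"][axon] > 0)
    assert np.all(model.dens["h"][axon] == 0)
    assert np.all(model.dens["CaT"][axon] == 0)
    # basal: somatic (x = 0) h/CaT values with the K_A distribution present
    from calres.gradients import H_GRADIENT
    assert np.allclose(model.dens["h"][basal], H_GRADIENT.value_at(0.0))
    assert np.all((model.dens["KA_prox"] + model.dens["KA_dist"])[basal] > 0)
    # apical CaT rises with distance; h V1/2 override follows the map
    x = model.path_dist_um[apical]
    order = np.argsort(x)
    assert np.all(np.diff(model.dens["CaT"][apical][order]) >= 0)
    shift = model.vhalf_shift[("h", "l")][apical][order]
    assert shift[0] == pytest.approx(0.0)
    assert shift[-1] == pytest.approx(-8.0)
    # proximal/distal A-type switch
    assert np.all(model.dens["KA_dist"][apical][x < 100] == 0)
    assert np.all(model.dens["KA_prox"][apical][x >= 100] == 0)


def _passive_gradients():
    return GradientSet(na_density=0.0, kdr_density=0.0,
                       ka=LinearConductanceGradient(0.0, 8.0),
                       h=SigmoidConductanceGradient(0.0, 12.0, 320.0, 50.0),
                       cat=SigmoidConductanceGradient(0.0, 30.0, 350.0, 50.0))


def test_trunk_input_resistance_matches_cable_oracle():
    """Somatic R_in of the discretized passive trunk vs the closed-form
    finite-cable (sealed end) + lumped-soma estimate, within 20%."""
    model = discretize(make_trunk(), _passive_gradients())
    n = model.n
    G = np.zeros((n, n))
    axg = model.axial_conductance()
    np.fill_diagonal(G, model.g_pas * model.area_cm2)
    for i in range(1, n):
        p = model.parent[i]
        G[i, i] += axg[i]
        G[p, p] += axg[i]
        G[i, p] -= axg[i]
        G[p, i] -= axg[i]
    rhs = np.zeros(n)
    rhs[0] = 1e-9  # 1 nA at the soma
    v = np.linalg.solve(G, rhs)
    r_model = v[0] / 1e-9  # Ω

    spec = SyntheticTrunkSpec()
    d_cm = 0.5 * (spec.proximal_diam_um + spec.distal_diam_um) * 1e-4
    rm, ra = 125e3, 120.0  # somatic Ω·cm² / Ω·cm
    lam = math.sqrt(rm * d_cm / (4.0 * ra))
    r_inf = math.sqrt(4.0 * rm * ra / (math.pi ** 2 * d_cm ** 3))
    r_cable = r_inf / math.tanh(spec.trunk_length_um * 1e-4 / lam)
    a_soma = math.pi * (20e-4) ** 2
    r_soma = 125e3 / a_soma
    r_oracle = 1.0 / (1.0 / r_soma + 1.0 / r_cable)
    assert r_model == pytest.approx(r_oracle, rel=0.20)


def test_swc_round_trip(tmp_path):
    morph = make_trunk(SyntheticTrunkSpec(basal_length_um=120.0))
    path = tmp_path / "trunk.swc"
    write_swc(morph, path)
    back = read_swc(path)
    assert back.total_apical_extent() == pytest.approx(425.0, abs=1e-6)
    types = sorted({s.stype for s in back.sections})
    assert types == ["apical", "basal", "soma"]
    # the reader merges unbranched same-type chains; geometry is preserved
    model = discretize(back)
    assert model.check_d_lambda(0.1)
    assert model.path_dist_um.max() == pytest.approx(
        discretize(morph).path_dist_um.max(), abs=25.0)
    # taper survives the round trip
    apical_pts = np.vstack([s.points for s in back.sections
                            if s.stype == "apical"])
    assert apical_pts[:, 3].min() == pytest.approx(1.0)
    assert apical_pts[:, 3].max() == pytest.approx(2.5)
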