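"""Neuronal morphologies: a tree of cylindrical/tapered sections, plus a plain
7-column SWC reader and writer.

A :class:`Section` is an unbranched run of 3D sample points (x, y, z in μm and
diameter in μm) with one type tag (soma/axon/basal/apical) and a parent link.
The soma is always section 0 and, following the equivalent-cylinder
convention, is collapsed to a single cylinder of the same surface area when
read from SWC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SWC_TYPES = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
SWC_CODES = {v: k for k, v in SWC_TYPES.items()}


@dataclass
class Section:
    """Unbranched cable section; ``points`` columns are x, y, z, diameter (μm)."""

    points: np.ndarray
    stype: str = "apical"
    parent: int = -1  # index of parent section, -1 for root

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise ValueError("points must be (n, 4): x, y, z, diameter")
        if np.any(self.points[:, 3] <= 0):
            raise ValueError("diameters must be positive")
        if self.length <= 0:
            raise ValueError("section length must be positive")

    @property
    def length(self) -> float:
        seg = np.diff(self.points[:, :3], axis=0)
        return float(np.sum(np.linalg.norm(seg, axis=1)))

    @property
    def arc(self) -> np.ndarray:
        """Cumulative arc length at each sample point (μm)."""
        seg = np.diff(self.points[:, :3], axis=0)
        return np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])

    def diam_at(self, s):
        """Diameter (μm) interpolated at arc length s along the section."""
        return np.interp(s, self.arc, self.points[:, 3])


@dataclass
class Morphology:
    """Tree of sections; section 0 is the soma root."""

    sections: list[Section] = field(default_factory=list)
    identifier: str = "cell"

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.sections:
            raise ValueError("morphology has no sections")
        if self.sections[0].parent != -1 or self.sections[0].stype != "soma":
            raise ValueError("section 0 must be the soma root")
        for i, sec in enumerate(self.sections[1:], start=1):
            if not (0 <= sec.parent < i):
                raise ValueError(
                    f"section {i}: parent {sec.parent} must precede it (acyclic, connected)")

    def path_distance_to_start(self, idx: int) -> float:
        """Path distance (μm) from the soma to the start of section idx.

        Distances are measured from the soma boundary: sections attached to
        the soma start at 0.
        """
        d = 0.0
        sec = self.sections[idx]
        while sec.parent > 0:
            sec = self.sections[sec.parent]
            d += sec.length
        return d

    def total_apical_extent(self) -> float:
        best = 0.0
        for i, sec in enumerate(self.sections):
            if sec.stype == "apical":
                best = max(best, self.path_distance_to_start(i) + sec.length)
        return best


def _soma_equivalent_cylinder(pts: np.ndarray) -> Section:
    """Collapse SWC soma samples to one cylinder of equal surface area, L = d."""
    if len(pts) == 1:
        area = 4.0 * np.pi * (pts[0, 3] / 2.0) ** 2  # sphere
    else:
        area = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            dl = np.linalg.norm(b[:3] - a[:3])
            rm = (a[3] + b[3]) / 4.0  # mean radius
            area += 2.0 * np.pi * rm * dl
        if area <= 0:
            area = 4.0 * np.pi * (pts[0, 3] / 2.0) ** 2
    d = float(np.sqrt(area / np.pi))  # solve pi d L = area with L = d
    c = pts[0, :3]
    points = np.array([[c[0] - d / 2.0, c[1], c[2], d],
                       [c[0] + d / 2.0, c[1], c[2], d]])
    return Section(points=points, stype="soma", parent=-1)


def read_swc(path, identifier: str | None = None) -> Morphology:
    """Read a standard 7-column SWC file (id type x y z radius parent)."""
    ids, rows = [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            nid, t = int(f[0]), int(f[1])
            x, y, z, r = (float(v) for v in f[2:6])
            par = int(f[6])
            rows[nid] = (t, np.array([x, y, z, 2.0 * r]), par)
            ids.append(nid)

    children: dict[int, list[int]] = {}
    root = None
    for nid in ids:
        t, _, par = rows[nid]
        if par == -1:
            root = nid
        else:
            children.setdefault(par, []).append(nid)
    if root is None:
        raise ValueError("SWC file has no root")

    soma_ids = [nid for nid in ids if rows[nid][0] == 1]
    if not soma_ids:
        raise ValueError("SWC file has no soma (type 1) samples")
    soma_pts = np.array([rows[nid][1] for nid in soma_ids])
    sections = [_soma_equivalent_cylinder(soma_pts)]
    soma_set = set(soma_ids)

    # non-soma trees: walk unbranched chains of one type
    sec_of_node: dict[int, int] = {nid: 0 for nid in soma_ids}
    stack = []
    for nid in soma_ids:
        for ch in children.get(nid, []):
            if ch not in soma_set:
                stack.append((ch, 0, rows[nid][1]))
    while stack:
        start, parent_sec, attach_pt = stack.pop()
        t = rows[start][0]
        chain = [start]
        cur = start
        while True:
            kids = [c for c in children.get(cur, []) if c not in soma_set]
            if len(kids) == 1 and rows[kids[0]][0] == t:
                cur = kids[0]
                chain.append(cur)
            else:
                break
        pts = np.vstack([attach_pt] + [rows[c][1] for c in chain])
        # attach point inherits the first child's diameter to avoid soma taper
        pts[0, 3] = pts[1, 3]
        sec = Section(points=pts, stype=SWC_TYPES.get(t, "apical"), parent=parent_sec)
        sections.append(sec)
        sec_idx = len(sections) - 1
        for c in chain:
            sec_of_node[c] = sec_idx
        for ch in children.get(cur, []):
            if ch not in soma_set:
                stack.append((ch, sec_idx, rows[cur][1]))
    return Morphology(sections=sections, identifier=identifier or str(path))


def write_swc(morph: Morphology, path):
    """Write a morphology as standard SWC (one sample row per section point)."""
    lines = ["# SWC written by calres"]
    nid = 0
    last_node_of_sec: dict[int, int] = {}
    last_pt_of_sec: dict[int, np.ndarray] = {}
    for si, sec in enumerate(morph.sections):
        t = SWC_CODES[sec.stype]
        parent_node = -1 if sec.parent < 0 else last_node_of_sec[sec.parent]
        pts = sec.points
        if sec.parent >= 0 and np.allclose(pts[0], last_pt_of_sec[sec.parent]):
            pts = pts[1:]  # shared attach sample, already written by the parent
        for p in pts:
            nid += 1
            lines.append(f"{nid} {t} {p[0]:.6g} {p[1]:.6g} {p[2]:.6g} {p[3] / 2.0:.6g} "
                         f"{parent_node}")
            parent_node = nid
        last_node_of_sec[si] = nid
        last_pt_of_sec[si] = sec.points[-1]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
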