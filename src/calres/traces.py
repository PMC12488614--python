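"""Time-aligned simulation traces and their on-disk formats.

A :class:`TraceSet` holds one time grid (ms), the injected oscillatory
current (pA), and per-site voltage (mV) and intracellular calcium (nM)
series.  Two formats are supported and round-trip bit-exactly:

* tabular text (CSV with ``#``-prefixed JSON metadata header), and
* a compact binary ``.npz`` container for long runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class TraceSet:
    time_ms: np.ndarray
    current_pA: np.ndarray
    sites: list[str]
    v_mV: np.ndarray              # (nsites, nt)
    ca_nM: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        nt = len(self.time_ms)
        if len(self.current_pA) != nt or self.v_mV.shape != (len(self.sites), nt):
            raise ValueError("all series must share the time grid")
        if self.ca_nM is not None and self.ca_nM.shape != self.v_mV.shape:
            raise ValueError("calcium series must match voltage shape")
        dt = np.diff(self.time_ms)
        if nt > 1 and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ValueError("time grid must be uniform with no gaps")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def site_index(self, site: str) -> int:
        return self.sites.index(site)

    def to_csv(self, path):
        cols = [self.time_ms, self.current_pA]
        names = ["time_ms", "current_pA"]
        for i, s in enumerate(self.sites):
            cols.append(self.v_mV[i])
            names.append(f"v_mV[{s}]")
        if self.ca_nM is not None:
            for i, s in enumerate(self.sites):
                cols.append(self.ca_nM[i])
                names.append(f"ca_nM[{s}]")
        header = "# meta " + json.dumps(self.meta, sort_keys=True) + "\n" + ",".join(names)
        np.savetxt(path, np.column_stack(cols), delimiter=",", fmt="%.17g",
                   header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# meta "):
                meta = json.loads(first[len("# meta "):])
                names = fh.readline().strip().split(",")
            else:
                names = first.strip().split(",")
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        cols = {n: data[:, i] for i, n in enumerate(names)}
        sites = [n[5:-1] for n in names if n.startswith("v_mV[")]
        v = np.vstack([cols[f"v_mV[{s}]"] for s in sites])
        ca = None
        if any(n.startswith("ca_nM[") for n in names):
            ca = np.vstack([cols[f"ca_nM[{s}]"] for s in sites])
        return cls(time_ms=cols["time_ms"], current_pA=cols["current_pA"],
                   sites=sites, v_mV=v, ca_nM=ca, meta=meta)

    def to_npz(self, path):
        np.savez_compressed(
            path, time_ms=self.time_ms, current_pA=self.current_pA,
            sites=np.array(self.sites), v_mV=self.v_mV,
            ca_nM=self.ca_nM if self.ca_nM is not None else np.empty(0),
            meta=json.dumps(self.meta, sort_keys=True))

    @classmethod
    def from_npz(cls, path) -> "TraceSet":
        with np.load(path, allow_pickle=False) as z:
            ca = z["ca_nM"]
            return cls(time_ms=z["time_ms"], current_pA=z["current_pA"],
                       sites=[str(s) for s in z["sites"]], v_mV=z["v_mV"],
                       ca_nM=None if ca.size == 0 else ca,
                       meta=json.loads(str(z["meta"])))
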