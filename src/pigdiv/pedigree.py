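"""Pedigree-based inbreeding (Wright's F) and pedigree-depth statistics.

F is the kinship of an animal's parents, computed by the tabular (recursive
kinship) method in topological order. Animals with unknown parents are
treated as unrelated, non-inbred base animals; an animal with one known
parent is a half-founder (the unknown side contributes zero relationship).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PedigreeTable


@dataclass
class InbreedingVector:
    """Per-animal inbreeding coefficients under one method ("pedigree"/"roh"/"snp")."""

    values: dict[str, float]
    method: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=f"F_{self.method}", dtype=float)


def wright_inbreeding(ped: PedigreeTable) -> InbreedingVector:
    """Wright's coefficient for every animal via the tabular kinship method.

    Builds the kinship matrix row by row in topological order:
    f(i, j) = (f(s, j) + f(d, j)) / 2 for j before i, and
    f(i, i) = (1 + f(s, d)) / 2, so F_i = f(sire_i, dam_i).
    """
    order = ped.topological_order()
    parents = ped.parents()
    n = len(order)
    idx = {a: k for k, a in enumerate(order)}
    kin = np.zeros((n, n))
    f_out: dict[str, float] = {}
    for k, animal in enumerate(order):
        sire, dam = parents[animal]
        si = idx.get(sire) if sire is not None else None
        di = idx.get(dam) if dam is not None else None
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * kin[si]
        if di is not None:
            row += 0.5 * kin[di]
        kin[k, :k] = row[:k]
        kin[:k, k] = row[:k]
        f_parents = kin[si, di] if (si is not None and di is not None) else 0.0
        kin[k, k] = 0.5 * (1.0 + f_parents)
        f_out[animal] = float(f_parents)
    return InbreedingVector(values=f_out, method="pedigree")


def pedigree_depth(ped: PedigreeTable) -> pd.DataFrame:
    """Equivalent complete generations and max generation count per animal.

    depth_equivalent(i) = sum over known ancestors of (1/2)^g with parents at
    g=1; computed by the recursion d(i) = sum over known parents of
    (1 + d(parent)) / 2. depth_max is the longest known ancestral path.
    """
    parents = ped.parents()
    order = ped.topological_order()
    d_eq: dict[str, float] = {}
    d_max: dict[str, int] = {}
    for animal in order:
        eq, mx = 0.0, 0
        for p in parents[animal]:
            if p is not None and p in d_eq:
                eq += 0.5 * (1.0 + d_eq[p])
                mx = max(mx, 1 + d_max[p])
            elif p is not None:
                # parent named but recordless: counts as one known ancestor
                eq += 0.5
                mx = max(mx, 1)
        d_eq[animal] = eq
        d_max[animal] = mx
    df = pd.DataFrame(
        {
            "animal": list(order),
            "depth_equivalent": [d_eq[a] for a in order],
            "depth_max": [d_max[a] for a in order],
        }
    )
    return df


def mean_pedigree_depth(ped: PedigreeTable) -> dict[str, float]:
    df = pedigree_depth(ped)
    return {
        "mean_depth_equivalent": float(df["depth_equivalent"].mean()),
        "mean_depth_max": float(df["depth_max"].mean()),
    }


@dataclass
class InbreedingComparison:
    r: float | None
    n: int
    method_a: str
    method_b: str
    reason: str = ""


def compare_inbreeding(a: InbreedingVector, b: InbreedingVector) -> InbreedingComparison:
    """Pearson correlation of two inbreeding vectors over their shared animals.

    Returns an undefined result (r=None with a reason) if fewer than three
    animals are shared or either vector has zero variance - never a silent 0.
    """
    shared = sorted(set(a.values) & set(b.values))
    n = len(shared)
    if n < 3:
        return InbreedingComparison(None, n, a.method, b.method, reason="fewer than 3 shared animals")
    x = np.array([a.values[k] for k in shared])
    y = np.array([b.values[k] for k in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return InbreedingComparison(None, n, a.method, b.method, reason="zero variance")
    r, _ = stats.pearsonr(x, y)
    return InbreedingComparison(float(r), n, a.method, b.method)
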