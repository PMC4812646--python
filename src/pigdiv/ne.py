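"""LD-based historical effective population size via the Sved relationship.

E(r2) = 1 / (4 c Ne + 1) links expected r2 to Ne at genetic distance c
(Morgan); LD at distance c reflects Ne about t = 1/(2c) generations ago, so
Ne_t = (1 - r2) / (4 c r2) for 0 < r2 < 1. Physical distances are converted
at 1 cM ~ 1 Mb by default. The generation grid runs t = 1..10 by 1,
15..100 by 5 and 150..1000 by 50; each t selects pairs whose c falls in a
window whose ends come from the midpoints to the neighboring grid values
(reproducing the worked t=1 window c in (1/3, 1] Morgan).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import defaults


@dataclass(frozen=True)
class NePoint:
    """One point of the Ne trajectory (undefined Ne carries a reason)."""

    t: int
    c_lo: float
    c_hi: float
    mean_r2: float
    n_pairs: int
    ne: float
    reason: str = ""


@dataclass(frozen=True)
class GenerationGrid:
    """Ordered generations-in-the-past at which Ne is evaluated."""

    t_values: tuple[int, ...]

    def __post_init__(self):
        ts = self.t_values
        if len(ts) == 0:
            raise ValueError("generation grid must not be empty")
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])) or ts[0] <= 0:
            raise ValueError("grid must be strictly increasing positive integers")


def default_generation_grid() -> GenerationGrid:
    """t = 1..10 step 1, 15..100 step 5, 150..1000 step 50 (46 points)."""
    ts = (
        list(range(1, defaults.GRID_STEP1_MAX + 1))
        + list(range(15, defaults.GRID_STEP5_MAX + 1, 5))
        + list(range(150, defaults.GRID_STEP50_MAX + 1, 50))
    )
    return GenerationGrid(tuple(ts))


def bp_to_morgan(distance_bp: float, cm_per_mb: float = defaults.CM_PER_MB) -> float:
    """Convert a physical distance to Morgan (Mb -> cM at ``cm_per_mb`` -> M)."""
    if distance_bp <= 0:
        raise ValueError("distance must be positive")
    return distance_bp * cm_per_mb / 1e8


def sved_expected_r2(ne: float, c: float) -> float:
    """Expected r2 at genetic distance ``c`` (Morgan) under drift with size ``ne``."""
    if ne <= 0 or c <= 0:
        raise ValueError("Ne and c must be positive")
    return 1.0 / (4.0 * c * ne + 1.0)


def ne_from_r2(r2: float, c: float) -> float:
    """Invert the Sved relationship: Ne = (1 - r2) / (4 c r2)."""
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must lie strictly inside (0, 1) for Ne estimation")
    if c <= 0:
        raise ValueError("c must be positive")
    return (1.0 - r2) / (4.0 * c * r2)


def c_window_for_t(grid: GenerationGrid, t: int) -> tuple[float, float]:
    """Half-open Morgan window (c_lo, c_hi] of SNP-pair distances probing generation t.

    Window ends are t-midpoints to the neighboring grid values: t_lo =
    (t_prev + t)/2 (or t/2 for the first point), t_hi = (t + t_next)/2 (or
    t + (t - t_prev)/2 for the last); then c = 1/(2 t) maps them to Morgan.
    """
    ts = grid.t_values
    if t not in ts:
        raise ValueError(f"t={t} is not on the generation grid")
    k = ts.index(t)
    t_lo = t / 2.0 if k == 0 else (ts[k - 1] + t) / 2.0
    t_hi = t + (t - ts[k - 1]) / 2.0 if k == len(ts) - 1 else (t + ts[k + 1]) / 2.0
    return 1.0 / (2.0 * t_hi), 1.0 / (2.0 * t_lo)


def ne_trajectory(
    pairs: pd.DataFrame,
    grid: GenerationGrid | None = None,
    cm_per_mb: float = defaults.CM_PER_MB,
    r2_offset: float = 0.0,
    c_representative: str = "half_t",
    alpha: float = 1.0,
) -> list[NePoint]:
    """Ne at every grid generation from a pair table (chromosome, distance_bp, r2).

    Per grid point: select pairs with c in the window, drop r2 exactly 0 or 1
    (outside the stated domain), average r2 per chromosome and then unweighted
    across chromosomes, and invert Sved at the window's representative
    c = 1/(2t). Points with no pairs or a mean r2 outside (0,1) are emitted
    with NaN Ne and a reason.

    ``r2_offset`` is an optional sampling-inflation correction subtracted
    from each window's mean r2 before inversion (e.g. 1/n for EM-based r2
    from n unphased diploids, 1/(2n) for phased haplotypes). Default 0: no
    correction. ``c_representative`` picks the c at which the window is
    inverted: "half_t" (the defining c = 1/(2t); default) or "pair_mean"
    (mean genetic distance of the selected pairs). ``alpha`` generalizes the
    inversion to Ne = (1/r2 - alpha)/(4c); alpha=1 is the default relation,
    alpha=2 the mutation-adjusted variant. Both variants are off by default.
    """
    if grid is None:
        grid = default_generation_grid()
    if c_representative not in ("half_t", "pair_mean"):
        raise ValueError("c_representative must be 'half_t' or 'pair_mean'")
    c = pairs["distance_bp"].to_numpy() * cm_per_mb / 1e8
    r2 = pairs["r2"].to_numpy()
    chrom = pairs["chromosome"].to_numpy()
    interior = (r2 > 0.0) & (r2 < 1.0)
    out = []
    for t in grid.t_values:
        c_lo, c_hi = c_window_for_t(grid, t)
        sel = (c > c_lo) & (c <= c_hi) & interior
        n = int(sel.sum())
        if n == 0:
            out.append(NePoint(t, c_lo, c_hi, float("nan"), 0, float("nan"), reason="no pairs in window"))
            continue
        sub = pd.DataFrame({"chromosome": chrom[sel], "r2": r2[sel]})
        mean_r2 = float(sub.groupby("chromosome")["r2"].mean().mean()) - r2_offset
        if not (0.0 < mean_r2 < 1.0):
            out.append(NePoint(t, c_lo, c_hi, mean_r2, n, float("nan"), reason="mean r2 outside (0,1)"))
            continue
        c_rep = float(c[sel].mean()) if c_representative == "pair_mean" else 1.0 / (2.0 * t)
        ne_val = (1.0 / mean_r2 - alpha) / (4.0 * c_rep)
        if ne_val <= 0:
            out.append(NePoint(t, c_lo, c_hi, mean_r2, n, float("nan"), reason="non-positive Ne"))
            continue
        out.append(NePoint(t, c_lo, c_hi, mean_r2, n, ne_val))
    return out


def trajectory_to_frame(points: list[NePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.t, p.c_lo, p.c_hi, p.n_pairs, p.mean_r2, p.ne, p.reason) for p in points],
        columns=["t", "c_lo_morgan", "c_hi_morgan", "n_pairs", "mean_r2", "ne", "reason"],
    )
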