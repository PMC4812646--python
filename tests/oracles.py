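"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written the slow, literal way (explicit
loops, exact rational arithmetic, grid search) so it shares no code path
with the package implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# HWE exact test (exact rational arithmetic)
# ---------------------------------------------------------------------------

def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Full-enumeration exact HWE p-value using Fractions (no shared code)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    probs = {}
    denom = 0
    for het in range(min(n_a, n_b) + 1):
        if (n_a - het) % 2 != 0:
            continue
        hom_a = (n_a - het) // 2
        hom_b = (n_b - het) // 2
        if hom_a < 0 or hom_b < 0:
            continue
        # multinomial count of genotype configurations x 2^het phase choices
        ways = Fraction(comb(n, hom_a) * comb(n - hom_a, het) * (2 ** het))
        probs[het] = ways
        denom += ways
    p_obs = probs[n_ab]
    total = sum(w for w in probs.values() if w <= p_obs)
    return float(Fraction(total, denom))


# ---------------------------------------------------------------------------
# ROH detection (direct against the every-interior-window definition)
# ---------------------------------------------------------------------------

def roh_oracle(
    genotypes,
    positions,
    min_snps: int,
    min_length_kb: float,
    window: int,
    max_het: int,
    max_missing: int,
) -> list[tuple[int, int]]:
    """Maximal valid runs as inclusive SNP index pairs, then length-filtered.

    A window starting at k is re-counted with explicit loops; a run [s, e]
    is valid iff every window wholly inside passes; maximality is checked by
    the invalidity of both one-SNP extensions.
    """
    g = list(genotypes)
    n = len(g)
    if n < window:
        return []

    def window_ok(k: int) -> bool:
        het = miss = 0
        for v in g[k:k + window]:
            if v == 1:
                het += 1
            elif v == MISSING:
                miss += 1
        return het <= max_het and miss <= max_missing

    ok = [window_ok(k) for k in range(n - window + 1)]

    def valid(s: int, e: int) -> bool:
        if e - s + 1 < window:
            return True  # vacuous: no window fits inside
        for k in range(s, e - window + 2):
            if not ok[k]:
                return False
        return True

    segs = []
    for s in range(0, n - window + 1):
        if not valid(s, s + window - 1):
            continue
        e = s + window - 1
        while e + 1 <= n - 1 and valid(s, e + 1):
            e += 1
        if s == 0 or not valid(s - 1, e):
            segs.append((s, e))
    out = []
    for s, e in segs:
        if e - s + 1 >= min_snps and positions[e] - positions[s] + 1 >= min_length_kb * 1000:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Wright's F by literal path counting
# ---------------------------------------------------------------------------

def wright_path_oracle(parents: dict[str, tuple[str | None, str | None]]) -> dict[str, float]:
    """F per animal from Wright's sum over non-intersecting ancestor path pairs."""
    path_cache: dict[str, list[tuple[str, tuple[str, ...]]]] = {}

    def paths_up(x: str) -> list[tuple[str, tuple[str, ...]]]:
        if x in path_cache:
            return path_cache[x]
        out = [(x, (x,))]
        sire, dam = parents.get(x, (None, None))
        for p in (sire, dam):
            if p is not None and p in parents:
                for anc, path in paths_up(p):
                    out.append((anc, (x,) + path))
        path_cache[x] = out
        return out

    # topological order by repeated sweeps (slow but simple)
    order: list[str] = []
    placed: set[str] = set()
    pending = set(parents)
    while pending:
        progressed = False
        for a in sorted(pending):
            s, d = parents[a]
            if (s is None or s not in parents or s in placed) and (
                d is None or d not in parents or d in placed
            ):
                order.append(a)
                placed.add(a)
                pending.discard(a)
                progressed = True
        if not progressed:
            raise ValueError("cycle in pedigree")

    F: dict[str, float] = {}
    for x in order:
        sire, dam = parents[x]
        if sire is None or dam is None or sire not in parents or dam not in parents:
            F[x] = 0.0
            continue
        total = 0.0
        for anc1, p1 in paths_up(sire):
            for anc2, p2 in paths_up(dam):
                if anc1 != anc2:
                    continue
                if set(p1) & set(p2) != {anc1}:
                    continue
                n1 = len(p1) - 1
                n2 = len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + F[anc1])
        F[x] = total
    return F


# ---------------------------------------------------------------------------
# Two-locus likelihood grid search
# ---------------------------------------------------------------------------

def grid_max_loglik(counts33: np.ndarray, n_grid: int = 999) -> float:
    """Max log-likelihood over a pAB grid with margins fixed at allele freqs."""
    n = np.asarray(counts33, dtype=float)
    tot = 2.0 * n.sum()
    p_a = (2 * n[2, :].sum() + n[1, :].sum()) / tot
    p_b = (2 * n[:, 2].sum() + n[:, 1].sum()) / tot
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.linspace(lo, hi, n_grid)
    best = -np.inf
    for x in grid:
        best = max(best, loglik_from_hapfreqs(n, x, p_a, p_b))
    return best


def loglik_from_hapfreqs(counts33: np.ndarray, p_ab: float, p_a: float, p_b: float) -> float:
    """Log-likelihood of a genotype table under HWE given haplotype freqs."""
    f = {
        "AB": p_ab,
        "Ab": p_a - p_ab,
        "aB": p_b - p_ab,
        "ab": 1.0 - p_a - p_b + p_ab,
    }
    geno_prob = np.zeros((3, 3))
    hap_dose = {"AB": (1, 1), "Ab": (1, 0), "aB": (0, 1), "ab": (0, 0)}
    for h1, f1 in f.items():
        for h2, f2 in f.items():
            gi = hap_dose[h1][0] + hap_dose[h2][0]
            gj = hap_dose[h1][1] + hap_dose[h2][1]
            geno_prob[gi, gj] += f1 * f2
    ll = 0.0
    for a in range(3):
        for b in range(3):
            if counts33[a][b] > 0:
                p = geno_prob[a, b]
                if p <= 0:
                    return -np.inf
                ll += counts33[a][b] * np.log(p)
    return float(ll)


# ---------------------------------------------------------------------------
# Misc small oracles
# ---------------------------------------------------------------------------

def autozygosity_interval_oracle(m0, m1) -> float:
    """Shared-founder length of two gamete mosaics by fine-grained sweep."""
    b0, i0 = m0
    b1, i1 = m1
    length = float(b0[-1])
    xs = np.linspace(0, length, 20001)[:-1] + length / 40002.0
    same = 0
    for x in xs:
        f0 = i0[np.searchsorted(b0, x, side="right") - 1]
        f1 = i1[np.searchsorted(b1, x, side="right") - 1]
        same += f0 == f1
    return same / len(xs) * length
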