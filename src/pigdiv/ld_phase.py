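"""Pairwise LD from unphased genotypes, LD decay, and linkage-phase correlation.

Haplotype frequencies for each SNP pair are estimated by EM over the
double-heterozygote phase ambiguity (maximum likelihood under random
mating), with pairwise deletion of missing genotypes. When a pair has no
double heterozygotes the EM reduces to direct haplotype counting in a
single step. Signed r = D / sqrt(pA pa pB pb) and r2 = r**2.

Cross-chromosome LD summaries are the unweighted mean of per-chromosome
bin means; the pooled-pair mean is emitted alongside for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .io_formats import MISSING, GenotypeDataset, chrom_sort_key

log = logging.getLogger(__name__)


@dataclass
class PairLd:
    """LD estimate for one SNP pair (i < j on the same chromosome)."""

    snp_i: int
    snp_j: int
    distance_bp: int
    hap_freqs: tuple[float, float, float, float]  # (pAB, pAb, paB, pab)
    d: float
    r_signed: float
    r2: float
    reason: str = ""  # non-empty when the pair is excluded (e.g. monomorphic)


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts (A1-dosage indexed), missing-excluded pairwise."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    for a in range(3):
        for b in range(3):
            counts[a, b] = int(((g1 == a) & (g2 == b) & ok).sum())
    return counts


def em_hap_freqs(
    counts: np.ndarray,
    tol: float = defaults.EM_TOL,
    max_iter: int = defaults.EM_MAX_ITER,
) -> np.ndarray:
    """ML haplotype frequencies (pAB, pAb, paB, pab) from 3x3 genotype counts.

    Initialized at linkage equilibrium (products of allele frequencies) with
    a tiny D>0 nudge so the symmetric double-root case resolves to the D>=0
    solution deterministically. Convergence: max frequency change < ``tol``
    or ``max_iter`` iterations.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.sum() < 1:
        raise ValueError("at least one individual non-missing at both loci is required")
    cAB, cAb, caB, cab, ndh, tot = _known_hap_counts(counts[None, :, :])
    pAB, pAb, paB, pab, _ = _em_batch(cAB, cAb, caB, cab, ndh, tot, tol, max_iter)
    return np.array([pAB[0], pAb[0], paB[0], pab[0]])


def _known_hap_counts(counts9: np.ndarray):
    """Unambiguous haplotype counts + double-het count from (m,3,3) tables."""
    n = counts9
    cAB = 2 * n[:, 2, 2] + n[:, 2, 1] + n[:, 1, 2]
    cAb = 2 * n[:, 2, 0] + n[:, 2, 1] + n[:, 1, 0]
    caB = 2 * n[:, 0, 2] + n[:, 0, 1] + n[:, 1, 2]
    cab = 2 * n[:, 0, 0] + n[:, 0, 1] + n[:, 1, 0]
    ndh = n[:, 1, 1]
    tot = 2.0 * n.sum(axis=(1, 2))
    return cAB.astype(float), cAb.astype(float), caB.astype(float), cab.astype(float), ndh.astype(float), tot


def _em_batch(cAB, cAb, caB, cab, ndh, tot, tol=defaults.EM_TOL, max_iter=defaults.EM_MAX_ITER):
    """Vectorized EM over many pairs (active-set loop); returns hap freqs + n_iter.

    Converged pairs drop out of the iteration, so a few slow-mixing pairs do
    not force full-array passes; pairs without double heterozygotes converge
    on the first iteration (direct counting).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = (cAB + cAb + ndh) / tot
        pB = (cAB + caB + ndh) / tot
    pAB = _ml_pab_init(cAB, cAb, caB, cab, ndh, tot, pA, pB)
    pAb = pA - pAB
    paB = pB - pAB
    pab = 1.0 - pA - pB + pAB
    active = np.arange(len(pAB))
    it = 0
    for it in range(1, max_iter + 1):
        if len(active) == 0:
            break
        a = active
        num = pAB[a] * pab[a]
        den = num + pAb[a] * paB[a]
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        nAB = (cAB[a] + w * ndh[a]) / tot[a]
        nAb = (cAb[a] + (1.0 - w) * ndh[a]) / tot[a]
        naB = (caB[a] + (1.0 - w) * ndh[a]) / tot[a]
        nab = (cab[a] + w * ndh[a]) / tot[a]
        delta = np.maximum(
            np.maximum(np.abs(nAB - pAB[a]), np.abs(nAb - pAb[a])),
            np.maximum(np.abs(naB - paB[a]), np.abs(nab - pab[a])),
        )
        pAB[a], pAb[a], paB[a], pab[a] = nAB, nAb, naB, nab
        active = a[delta >= tol]
    return pAB, pAb, paB, pab, it


def _ml_pab_init(cAB, cAb, caB, cab, ndh, tot, pA, pB):
    """Starting pAB for EM: the likelihood-maximizing root of the EM fixed-point cubic.

    The EM stationary condition x = (cAB + w(x) ndh) / tot expands to
    2T x^3 + (bT - 2cAB - ndh) x^2 + (cT - b cAB - ndh(1-pA-pB)) x - c cAB = 0
    with b = 1 - 2pA - 2pB and c = pA pB. All (up to three) real roots are
    clipped to the feasible interval and scored by the observed-data
    log-likelihood; ties resolve toward larger x, i.e. D >= 0. EM then
    refines from this start, so a mis-picked root only costs iterations.
    """
    n = len(pA)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = 1.0 - 2.0 * pA - 2.0 * pB
        c = pA * pB
        a3 = np.where(tot != 0, 2.0 * tot, 1.0)
        p_ = (b * tot - 2.0 * cAB - ndh) / a3
        q_ = (c * tot - b * cAB - ndh * (1.0 - pA - pB)) / a3
        r_ = (-c * cAB) / a3
        pp = q_ - p_ * p_ / 3.0
        qq = 2.0 * p_**3 / 27.0 - p_ * q_ / 3.0 + r_
        shift = -p_ / 3.0
        disc = (qq / 2.0) ** 2 + (pp / 3.0) ** 3
        lo = np.maximum(0.0, pA + pB - 1.0)
        hi = np.minimum(pA, pB)
        margin = 1e-12

        best = np.full(n, np.nan)
        best_ll = np.full(n, -np.inf)

        def consider(idx, x):
            x = np.minimum(np.maximum(x, lo[idx] + margin), np.maximum(hi[idx] - margin, lo[idx] + margin))
            ll = _loglik_pab(x, cAB[idx], cAb[idx], caB[idx], cab[idx], ndh[idx], pA[idx], pB[idx])
            # prefer higher likelihood; on ties prefer larger x (D >= 0 rule)
            better = (ll > best_ll[idx] + 1e-9) | (
                (ll > best_ll[idx] - 1e-9) & (x > best[idx])
            ) | ~np.isfinite(best[idx])
            upd = idx[better]
            best[upd] = x[better]
            best_ll[upd] = ll[better]

        one = np.flatnonzero(disc >= 0)
        if len(one):
            sq = np.sqrt(disc[one])
            consider(one, np.cbrt(-qq[one] / 2.0 + sq) + np.cbrt(-qq[one] / 2.0 - sq) + shift[one])
        three = np.flatnonzero(disc < 0)
        if len(three):
            m = np.sqrt(-pp[three] / 3.0)
            arg = np.clip(3.0 * qq[three] / (2.0 * pp[three] * m), -1.0, 1.0)
            phi = np.arccos(arg)
            for k in range(3):
                consider(three, 2.0 * m * np.cos((phi - 2.0 * np.pi * k) / 3.0) + shift[three])
        # interval ends are ML candidates only when their vanishing haplotype
        # class is unobserved (otherwise the log-likelihood there is -inf)
        hi_ok = np.flatnonzero(((hi == pA) & (cAb == 0)) | ((hi == pB) & (caB == 0)))
        if len(hi_ok):
            consider(hi_ok, hi[hi_ok])
        lo_ok = np.flatnonzero(((lo == 0.0) & (cAB == 0)) | ((lo > 0.0) & (cab == 0)))
        if len(lo_ok):
            consider(lo_ok, lo[lo_ok])
        fallback = np.minimum(np.maximum(c, lo), hi)  # linkage equilibrium
        return np.where(np.isfinite(best), best, fallback)


def _loglik_pab(x, cAB, cAb, caB, cab, ndh, pA, pB):
    """Observed-data log-likelihood of pAB = x with margins fixed (up to const)."""
    # zero counts contribute 0 * log(tiny) = 0, so no masking is needed
    ll = cAB * np.log(np.maximum(x, 1e-300))
    ll += cAb * np.log(np.maximum(pA - x, 1e-300))
    ll += caB * np.log(np.maximum(pB - x, 1e-300))
    ll += cab * np.log(np.maximum(1.0 - pA - pB + x, 1e-300))
    dh = x * (1.0 - pA - pB + x) + (pA - x) * (pB - x)
    ll += ndh * np.log(np.maximum(dh, 1e-300))
    return ll


def _ld_from_freqs(pAB, pAb, paB, pab):
    """(D, r_signed, r2, valid) arrays from haplotype frequency arrays."""
    pA = pAB + pAb
    pB = pAB + paB
    d = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    valid = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(valid, d / np.sqrt(np.where(valid, denom, 1.0)), np.nan)
    r = np.clip(r, -1.0, 1.0)
    return d, r, r * r, valid


def pair_ld(ds: GenotypeDataset, i: int, j: int) -> PairLd:
    """LD between SNPs at dataset indices ``i`` and ``j`` (same chromosome)."""
    if ds.chromosomes[i] != ds.chromosomes[j]:
        raise ValueError("pair_ld requires SNPs on the same chromosome")
    if i == j:
        raise ValueError("pair_ld requires two distinct SNPs")
    if i > j:
        i, j = j, i
    counts = genotype_pair_counts(ds.calls[:, i], ds.calls[:, j])
    freqs = em_hap_freqs(counts)
    d, r, r2, valid = _ld_from_freqs(*(np.array([v]) for v in freqs))
    reason = "" if valid[0] else "monomorphic locus"
    return PairLd(
        snp_i=int(i),
        snp_j=int(j),
        distance_bp=int(ds.positions[j] - ds.positions[i]),
        hap_freqs=tuple(float(v) for v in freqs),
        d=float(d[0]),
        r_signed=float(r[0]) if valid[0] else float("nan"),
        r2=float(r2[0]) if valid[0] else float("nan"),
        reason=reason,
    )


def pair_ld_from_hap_counts(n_ab: float, n_a_b: float, n_a_bb: float, n_ab_2: float) -> tuple[float, float, float]:
    """(D, r_signed, r2) from direct haplotype counts (AB, Ab, aB, ab).

    The phased-input path: with haplotypes observed, counting is exact and
    no EM is involved. Raises on monomorphic input.
    """
    counts = np.array([n_ab, n_a_b, n_a_bb, n_ab_2], dtype=float)
    tot = counts.sum()
    if tot <= 0:
        raise ValueError("at least one haplotype is required")
    pAB, pAb, paB, pab = counts / tot
    d, r, r2, valid = _ld_from_freqs(*(np.array([v]) for v in (pAB, pAb, paB, pab)))
    if not valid[0]:
        raise ValueError("monomorphic locus: r undefined")
    return float(d[0]), float(r[0]), float(r2[0])


def pair_ld_phased(haplotypes: np.ndarray, i: int, j: int) -> tuple[float, float, float]:
    """(D, r_signed, r2) for two loci from a (2n, m) phased 0/1 haplotype matrix."""
    hi = haplotypes[:, i].astype(bool)
    hj = haplotypes[:, j].astype(bool)
    return pair_ld_from_hap_counts(
        int((hi & hj).sum()), int((hi & ~hj).sum()),
        int((~hi & hj).sum()), int((~hi & ~hj).sum()),
    )


# ---------------------------------------------------------------------------
# Batch pair LD across a dataset
# ---------------------------------------------------------------------------

def _chrom_indices(ds: GenotypeDataset):
    chroms = ds.chromosomes
    for chrom in sorted(dict.fromkeys(chroms), key=chrom_sort_key):
        yield str(chrom), np.flatnonzero(chroms == chrom)


def _pairs_within(pos: np.ndarray, max_dist_bp: int | None):
    """Index pairs (ii, jj), ii < jj, with pos[jj]-pos[ii] <= max_dist (or all)."""
    m = len(pos)
    if m < 2:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    if max_dist_bp is None:
        ii, jj = np.triu_indices(m, k=1)
        return ii.astype(np.intp), jj.astype(np.intp)
    hi = np.searchsorted(pos, pos + max_dist_bp, side="right")
    counts = np.maximum(hi - np.arange(m) - 1, 0)
    ii = np.repeat(np.arange(m), counts)
    jj = np.concatenate([np.arange(i + 1, h) for i, h in enumerate(hi) if h > i + 1]) if counts.sum() else np.array([], dtype=np.intp)
    return ii.astype(np.intp), jj.astype(np.intp)


def _pair_ld_arrays(calls: np.ndarray, ii: np.ndarray, jj: np.ndarray):
    """(r_signed, r2, valid) for the given column pairs of ``calls`` via batch EM."""
    ind = [(calls == g).astype(np.float32) for g in (0, 1, 2)]

    def cnt(a: int, b: int) -> np.ndarray:
        return (ind[a].T @ ind[b])[ii, jj].astype(np.float64)

    n11 = cnt(1, 1)
    n12 = cnt(1, 2)
    n21 = cnt(2, 1)
    n22 = cnt(2, 2)
    if (calls == MISSING).any():
        n10 = cnt(1, 0)
        n20 = cnt(2, 0)
        n01 = cnt(0, 1)
        n02 = cnt(0, 2)
        n00 = cnt(0, 0)
    else:
        # complete data: remaining cells follow from per-SNP genotype counts
        c1 = ind[1].sum(axis=0).astype(np.float64)
        c2 = ind[2].sum(axis=0).astype(np.float64)
        n10 = c1[ii] - n11 - n12
        n20 = c2[ii] - n21 - n22
        n01 = c1[jj] - n11 - n21
        n02 = c2[jj] - n12 - n22
        n00 = calls.shape[0] - (n11 + n12 + n21 + n22 + n10 + n20 + n01 + n02)
    cAB = 2 * n22 + n21 + n12
    cAb = 2 * n20 + n21 + n10
    caB = 2 * n02 + n01 + n12
    cab = 2 * n00 + n01 + n10
    ndh = n11
    tot = 2.0 * (n00 + n01 + n02 + n10 + n11 + n12 + n20 + n21 + n22)
    ok = tot > 0
    r = np.full(len(ii), np.nan)
    r2 = np.full(len(ii), np.nan)
    valid = np.zeros(len(ii), dtype=bool)
    if ok.any():
        pAB, pAb, paB, pab, _ = _em_batch(cAB[ok], cAb[ok], caB[ok], cab[ok], ndh[ok], tot[ok])
        _, r_ok, r2_ok, valid_ok = _ld_from_freqs(pAB, pAb, paB, pab)
        r[ok], r2[ok], valid[np.flatnonzero(ok)[valid_ok]] = r_ok, r2_ok, True
    return r, r2, valid


def ld_pairs(
    ds: GenotypeDataset,
    max_dist_bp: int | None = defaults.LD_MAX_DIST_BP,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to ``max_dist_bp`` with r/r2.

    Returns a DataFrame with columns chromosome, i, j (dataset SNP indices),
    distance_bp, r_signed, r2; pairs with an undefined r (monomorphic locus)
    are excluded, with the exclusion count logged.
    """
    frames = []
    n_excluded = 0
    for chrom, vi in _chrom_indices(ds):
        pos = ds.positions[vi]
        ii, jj = _pairs_within(pos, max_dist_bp)
        if len(ii) == 0:
            continue
        r, r2, valid = _pair_ld_arrays(ds.calls[:, vi], ii, jj)
        n_excluded += int((~valid).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "i": vi[ii[valid]],
                    "j": vi[jj[valid]],
                    "distance_bp": (pos[jj] - pos[ii])[valid].astype(np.int64),
                    "r_signed": r[valid],
                    "r2": r2[valid],
                }
            )
        )
    if n_excluded:
        log.info("ld_pairs: %d pairs excluded (monomorphic locus)", n_excluded)
    if not frames:
        return pd.DataFrame(columns=["chromosome", "i", "j", "distance_bp", "r_signed", "r2"])
    return pd.concat(frames, ignore_index=True)


def ld_decay(
    ds: GenotypeDataset | pd.DataFrame,
    max_dist_bp: int = defaults.LD_MAX_DIST_BP,
    bin_bp: int = defaults.LD_BIN_BP,
) -> pd.DataFrame:
    """Mean r2 by physical-distance class ([lo, hi) bins of ``bin_bp``).

    ``mean_r2`` is the unweighted mean over chromosomes of the per-chromosome
    bin means (empty per-chromosome bins excluded); ``pooled_r2`` is the
    plain mean over all pairs in the bin; ``n_pairs`` the pooled pair count.
    Accepts a dataset or a precomputed :func:`ld_pairs` frame.
    """
    pairs = ds if isinstance(ds, pd.DataFrame) else ld_pairs(ds, max_dist_bp)
    pairs = pairs[pairs["distance_bp"] < max_dist_bp]
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    out = pd.DataFrame(
        {
            "bin_lo_bp": np.arange(n_bins, dtype=np.int64) * bin_bp,
            "bin_hi_bp": (np.arange(n_bins, dtype=np.int64) + 1) * bin_bp,
        }
    )
    if len(pairs) == 0:
        out["mean_r2"] = np.nan
        out["pooled_r2"] = np.nan
        out["n_pairs"] = 0
        return out
    b = (pairs["distance_bp"] // bin_bp).astype(int)
    per_chrom = pairs.groupby([pairs["chromosome"], b])["r2"].mean()
    cross = per_chrom.groupby(level=1).mean()
    pooled = pairs.groupby(b)["r2"].mean()
    n = pairs.groupby(b)["r2"].size()
    out["mean_r2"] = out.index.map(cross).astype(float)
    out["pooled_r2"] = out.index.map(pooled).astype(float)
    out["n_pairs"] = out.index.map(n).fillna(0).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Adjacent / thinned LD
# ---------------------------------------------------------------------------

@dataclass
class AdjacentLdSummary:
    """Summary of LD between consecutive informative SNP pairs."""

    mean_r2: float
    frac_above: dict[float, float]
    mean_distance_bp: float
    n_pairs_informative: int
    n_pairs_total: int
    pairs: pd.DataFrame = field(repr=False, default=None)


def adjacent_ld(
    ds: GenotypeDataset,
    thresholds: tuple[float, ...] = defaults.ADJACENT_R2_THRESHOLDS,
) -> AdjacentLdSummary:
    """Mean r2 over consecutive SNP pairs within chromosomes.

    Fractions above each threshold are strict (>) and computed among
    informative pairs (r defined); the mean adjacent distance is over all
    consecutive pairs. Chromosomes with < 2 SNPs contribute nothing.
    """
    rows = []
    for chrom, vi in _chrom_indices(ds):
        if len(vi) < 2:
            continue
        pos = ds.positions[vi]
        ii = np.arange(len(vi) - 1)
        jj = ii + 1
        r, r2, valid = _pair_ld_arrays(ds.calls[:, vi], ii, jj)
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "distance_bp": (pos[jj] - pos[ii]).astype(np.int64),
                    "r_signed": r,
                    "r2": r2,
                    "informative": valid,
                }
            )
        )
    if not rows:
        return AdjacentLdSummary(float("nan"), {t: float("nan") for t in thresholds}, float("nan"), 0, 0,
                                 pairs=pd.DataFrame())
    pairs = pd.concat(rows, ignore_index=True)
    info = pairs[pairs["informative"]]
    mean_r2 = float(info["r2"].mean()) if len(info) else float("nan")
    frac = {
        float(t): (float((info["r2"] > t).mean()) if len(info) else float("nan"))
        for t in thresholds
    }
    return AdjacentLdSummary(
        mean_r2=mean_r2,
        frac_above=frac,
        mean_distance_bp=float(pairs["distance_bp"].mean()),
        n_pairs_informative=int(len(info)),
        n_pairs_total=int(len(pairs)),
        pairs=pairs,
    )


def thin_dataset(ds: GenotypeDataset, keep_every: int) -> GenotypeDataset:
    """Keep SNPs at ordinal positions 0, k, 2k, ... within each chromosome."""
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    keep = []
    for _, vi in _chrom_indices(ds):
        keep.extend(vi[::keep_every].tolist())
    return ds.subset(snp_idx=np.array(sorted(keep), dtype=np.intp))


def thinned_ld(
    ds: GenotypeDataset,
    keep_every: int = defaults.THIN_KEEP_EVERY,
    thresholds: tuple[float, ...] = defaults.ADJACENT_R2_THRESHOLDS,
) -> AdjacentLdSummary:
    """:func:`adjacent_ld` on a map thinned to every ``keep_every``-th SNP."""
    return adjacent_ld(thin_dataset(ds, keep_every), thresholds=thresholds)


# ---------------------------------------------------------------------------
# Correlation of linkage phase between two populations
# ---------------------------------------------------------------------------

@dataclass
class PhaseCorrResult:
    bins: pd.DataFrame
    headline_corr: float
    headline_n: int
    headline_dist_bp: int
    n_shared_snps: int


def phase_correlation(
    ds_pop1: GenotypeDataset,
    ds_pop2: GenotypeDataset,
    max_dist_bp: int = defaults.LD_MAX_DIST_BP,
    bin_bp: int = defaults.LD_BIN_BP,
    headline_dist_bp: int = defaults.PHASE_HEADLINE_DIST_BP,
) -> PhaseCorrResult:
    """Correlation of signed r between two populations by distance class.

    SNPs are matched by id (requiring equal chromosome and position) and
    alleles harmonized to population 1's A1 before computing r; pairs
    monomorphic in either population are excluded. Each distance class
    reports the Pearson correlation across shared pairs of (r1, r2); bins
    with < 2 shared pairs get an undefined (NaN) correlation. The headline
    value pools all shared pairs at distance <= ``headline_dist_bp``.
    """
    m1 = ds_pop1.snps.reset_index().rename(columns={"index": "i1"})
    m2 = ds_pop2.snps.reset_index().rename(columns={"index": "i2"})
    merged = m1.merge(m2, on="snp_id", suffixes=("_1", "_2"))
    merged = merged[
        (merged["chromosome_1"] == merged["chromosome_2"])
        & (merged["position_bp_1"] == merged["position_bp_2"])
    ]
    same = (merged["allele_a1_1"] == merged["allele_a1_2"]) & (
        merged["allele_a2_1"] == merged["allele_a2_2"]
    )
    flipped = (merged["allele_a1_1"] == merged["allele_a2_2"]) & (
        merged["allele_a2_1"] == merged["allele_a1_2"]
    )
    merged = merged[same | flipped]
    sign = np.where(merged["allele_a1_1"] == merged["allele_a1_2"], 1.0, -1.0)
    idx1 = merged["i1"].to_numpy(dtype=np.intp)
    idx2 = merged["i2"].to_numpy(dtype=np.intp)
    chrom_arr = merged["chromosome_1"].to_numpy()
    pos_arr = merged["position_bp_1"].to_numpy()

    rows = []
    for chrom in sorted(dict.fromkeys(chrom_arr), key=chrom_sort_key):
        sel = np.flatnonzero(chrom_arr == chrom)
        sel = sel[np.argsort(pos_arr[sel], kind="stable")]
        pos = pos_arr[sel]
        ii, jj = _pairs_within(pos, max_dist_bp)
        if len(ii) == 0:
            continue
        r1, _, v1 = _pair_ld_arrays(ds_pop1.calls[:, idx1[sel]], ii, jj)
        r2_, _, v2 = _pair_ld_arrays(ds_pop2.calls[:, idx2[sel]], ii, jj)
        s = sign[sel]
        r2_adj = r2_ * s[ii] * s[jj]
        ok = v1 & v2
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "distance_bp": (pos[jj] - pos[ii])[ok].astype(np.int64),
                    "r1": r1[ok],
                    "r2": r2_adj[ok],
                }
            )
        )
    pairs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chromosome", "distance_bp", "r1", "r2"])
    )
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    bins = pd.DataFrame(
        {
            "bin_lo_bp": np.arange(n_bins, dtype=np.int64) * bin_bp,
            "bin_hi_bp": (np.arange(n_bins, dtype=np.int64) + 1) * bin_bp,
            "phase_corr": np.nan,
            "n_pairs": 0,
        }
    )
    if len(pairs):
        b = (pairs["distance_bp"] // bin_bp).astype(int)
        for k, sub in pairs.groupby(b):
            if k >= n_bins:
                continue
            bins.loc[k, "n_pairs"] = len(sub)
            if len(sub) >= 2 and sub["r1"].nunique() > 1 and sub["r2"].nunique() > 1:
                bins.loc[k, "phase_corr"] = float(np.corrcoef(sub["r1"], sub["r2"])[0, 1])
    head = pairs[pairs["distance_bp"] <= headline_dist_bp]
    if len(head) >= 2 and head["r1"].nunique() > 1 and head["r2"].nunique() > 1:
        headline = float(np.corrcoef(head["r1"], head["r2"])[0, 1])
    else:
        headline = float("nan")
    return PhaseCorrResult(
        bins=bins,
        headline_corr=headline,
        headline_n=int(len(head)),
        headline_dist_bp=int(headline_dist_bp),
        n_shared_snps=int(len(merged)),
    )
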