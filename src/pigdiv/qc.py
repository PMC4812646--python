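"""Sample- and SNP-level quality control for SNP-chip genotype datasets.

Two preset profiles mirror the two-stage filtering used for inbreeding
versus LD/Ne analyses:

* ``inbreeding`` - sample call rate >= 0.90, drop unknown-position and
  sex-chromosome SNPs, no MAF/HWE filter, SNP call rate 0.90;
* ``ld`` - within-population: SNP call rate 0.98, MAF 0.03, HWE p 1e-6.

All thresholds are strict inequalities on the "bad" side: a sample with call
rate exactly 0.90 or a SNP with MAF exactly 0.03 is retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .io_formats import MISSING, GenotypeDataset, PedigreeTable

log = logging.getLogger(__name__)


@dataclass
class QcProfile:
    """Threshold bundle for one QC pass. ``None`` disables a filter."""

    name: str
    sample_call_rate_min: float | None = defaults.SAMPLE_CALL_RATE_MIN
    het_sd: float | None = defaults.HET_SD
    het_two_sided: bool = False
    dup_match_min: float | None = defaults.DUP_MATCH_MIN
    snp_call_rate_min: float | None = defaults.SNP_CALL_RATE_MIN
    maf_min: float | None = defaults.MAF_MIN
    hwe_p_min: float | None = defaults.HWE_P_MIN
    drop_unknown_pos: bool = False
    drop_sex_chroms: bool = False
    autosomes: tuple[str, ...] = defaults.AUTOSOMES


INBREEDING_PROFILE = QcProfile(
    name="inbreeding",
    snp_call_rate_min=0.90,
    maf_min=None,
    hwe_p_min=None,
    drop_unknown_pos=True,
    drop_sex_chroms=True,
)
LD_PROFILE = QcProfile(
    name="ld",
    snp_call_rate_min=defaults.SNP_CALL_RATE_MIN,
    maf_min=defaults.MAF_MIN,
    hwe_p_min=defaults.HWE_P_MIN,
    drop_unknown_pos=True,
    drop_sex_chroms=True,
)

PROFILES = {"inbreeding": INBREEDING_PROFILE, "ld": LD_PROFILE}


@dataclass
class SampleQcReport:
    """Per-sample statistics and removal flags (``table`` one row per sample)."""

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def dropped_ids(self) -> list[str]:
        return self.table.loc[self.table["drop"], "sample_id"].tolist()


@dataclass
class SnpQcReport:
    """Per-SNP statistics and removal flags (``table`` one row per SNP)."""

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def dropped_ids(self) -> list[str]:
        return self.table.loc[self.table["drop"], "snp_id"].tolist()


@dataclass
class IbdEstimate:
    """Method-of-moments IBD estimate for one sample pair."""

    id1: str
    id2: str
    ibs0: int
    ibs1: int
    ibs2: int
    pi_hat: float
    relationship: str = ""
    expected_pi_hat: float | None = None
    flagged: bool = False


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def sample_qc(
    ds: GenotypeDataset,
    call_rate_min: float = defaults.SAMPLE_CALL_RATE_MIN,
    het_sd: float = defaults.HET_SD,
    dup_match_min: float = defaults.DUP_MATCH_MIN,
    het_two_sided: bool = False,
) -> SampleQcReport:
    """Flag samples with low call rate, outlying heterozygosity or a duplicate.

    Duplicate detection compares pairwise genotype concordance (identical
    non-missing calls / SNPs co-called in both samples); both members of a
    pair above ``dup_match_min`` are flagged but only the lower-call-rate
    member is marked for removal.
    """
    if ds.n_snps == 0:
        raise ValueError("sample_qc requires at least one SNP")
    if ds.n_samples < 2:
        raise ValueError("sample_qc requires at least two samples (het z-scores)")
    calls = ds.calls
    nonmiss = calls != MISSING
    n_called = nonmiss.sum(axis=1)
    call_rate = n_called / ds.n_snps
    het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)

    mean = float(np.nanmean(het_rate))
    sd = float(np.nanstd(het_rate, ddof=0))
    if sd == 0.0:
        log.warning("heterozygosity SD is 0; no heterozygosity outliers can be flagged")
        z = np.zeros(ds.n_samples)
        het_flag = np.zeros(ds.n_samples, dtype=bool)
    else:
        z = (het_rate - mean) / sd
        het_flag = (np.abs(z) > het_sd) if het_two_sided else (z > het_sd)

    # pairwise concordance via per-code indicator matmuls
    conc, co_called = _pairwise_concordance(calls)
    dup_partner = [""] * ds.n_samples
    dup_flag = np.zeros(ds.n_samples, dtype=bool)
    dup_drop = np.zeros(ds.n_samples, dtype=bool)
    iu, ju = np.triu_indices(ds.n_samples, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(co_called[iu, ju] > 0, conc[iu, ju] / np.maximum(co_called[iu, ju], 1), 0.0)
    for i, j, f in zip(iu[frac > dup_match_min], ju[frac > dup_match_min], frac[frac > dup_match_min]):
        dup_flag[i] = dup_flag[j] = True
        dup_partner[i] = str(ds.sample_ids[j])
        dup_partner[j] = str(ds.sample_ids[i])
        victim = i if call_rate[i] <= call_rate[j] else j
        dup_drop[victim] = True
        log.info(
            "duplicate pair %s / %s concordance %.4f; dropping %s",
            ds.sample_ids[i], ds.sample_ids[j], f, ds.sample_ids[victim],
        )

    low_cr = call_rate < call_rate_min
    table = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "call_rate": call_rate,
            "heterozygosity_rate": het_rate,
            "het_z_score": z,
            "duplicate_partner": dup_partner,
            "low_call_rate": low_cr,
            "het_outlier": het_flag,
            "duplicate": dup_flag,
            "drop": low_cr | het_flag | dup_drop,
        }
    )
    for sid in table.loc[table["drop"], "sample_id"]:
        log.info("sample %s flagged for removal", sid)
    return SampleQcReport(
        table=table,
        thresholds={"call_rate_min": call_rate_min, "het_sd": het_sd, "dup_match_min": dup_match_min},
    )


def _pairwise_concordance(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (n identical non-missing calls, n co-called) for all sample pairs."""
    conc = np.zeros((calls.shape[0],) * 2, dtype=np.float64)
    for g in (0, 1, 2):
        ind = (calls == g).astype(np.float32)
        conc += ind @ ind.T
    nm = (calls != MISSING).astype(np.float32)
    co_called = nm @ nm.T
    return conc, co_called


# ---------------------------------------------------------------------------
# IBD / pedigree check
# ---------------------------------------------------------------------------

def ibd_check(
    ds: GenotypeDataset,
    ped: PedigreeTable | None = None,
    pairs: list[tuple[str, str]] | None = None,
    pi_hat_tol: float = defaults.PI_HAT_TOL,
) -> list[IbdEstimate]:
    """Method-of-moments IBD for sample pairs; flags discordant parent-offspring.

    With ``pairs=None`` the recorded parent-offspring pairs present in the
    dataset are evaluated. ``pi_hat = P(IBD=2) + 0.5 P(IBD=1)`` estimated from
    IBS counts and allele frequencies; recorded parent-offspring pairs whose
    pi_hat deviates from 0.5 by more than ``pi_hat_tol`` are flagged.
    """
    ids = {sid: k for k, sid in enumerate(ds.sample_ids)}
    relationships: dict[tuple[str, str], str] = {}
    if pairs is None:
        pairs = []
        if ped is not None:
            for animal, (sire, dam) in ped.parents().items():
                for parent in (sire, dam):
                    if parent is not None and animal in ids and parent in ids:
                        pairs.append((parent, animal))
                        relationships[(parent, animal)] = "parent-offspring"
    calls = ds.calls
    nonmiss = calls != MISSING
    p = _allele_freq_a1(calls)
    valid_snp = ~np.isnan(p)
    q = 1.0 - p
    # expected per-SNP IBS probabilities given IBD state (no small-sample correction)
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    out = []
    for id1, id2 in pairs:
        i, j = ids[id1], ids[id2]
        both = nonmiss[i] & nonmiss[j] & valid_snp
        n = int(both.sum())
        if n == 0:
            log.warning("pair (%s, %s) has no co-called SNPs; skipped", id1, id2)
            continue
        gi, gj = calls[i, both], calls[j, both]
        diff = np.abs(gi - gj)
        ibs0, ibs1, ibs2 = int((diff == 2).sum()), int((diff == 1).sum()), int((diff == 0).sum())
        E0_0, E1_0 = float(e0_ibs0[both].sum()), float(e0_ibs1[both].sum())
        E1_1 = float(e1_ibs1[both].sum())
        E2_0, E2_1 = float(e0_ibs2[both].sum()), float(e1_ibs2[both].sum())
        p0 = ibs0 / E0_0 if E0_0 > 0 else 0.0
        p1 = (ibs1 - p0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
        p2 = (ibs2 - p0 * E2_0 - p1 * E2_1) / n
        # clamp to the simplex
        p0, p1, p2 = (max(0.0, v) for v in (p0, p1, p2))
        s = p0 + p1 + p2
        if s > 0:
            p0, p1, p2 = p0 / s, p1 / s, p2 / s
        pi_hat = min(1.0, p2 + 0.5 * p1)
        rel = relationships.get((id1, id2), "")
        expected = defaults.PARENT_OFFSPRING_PI_HAT if rel == "parent-offspring" else None
        flagged = expected is not None and abs(pi_hat - expected) > pi_hat_tol
        if flagged:
            log.info("pedigree_error: pair (%s, %s) pi_hat %.3f vs expected %.2f", id1, id2, pi_hat, expected)
        out.append(
            IbdEstimate(id1=id1, id2=id2, ibs0=ibs0, ibs1=ibs1, ibs2=ibs2,
                        pi_hat=pi_hat, relationship=rel, expected_pi_hat=expected, flagged=flagged)
        )
    return out


def _allele_freq_a1(calls: np.ndarray) -> np.ndarray:
    """A1 allele frequency per SNP over non-missing calls (NaN if none)."""
    nonmiss = calls != MISSING
    n2 = 2.0 * nonmiss.sum(axis=0)
    dose = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n2 > 0, dose / n2, np.nan)


# ---------------------------------------------------------------------------
# Sex check
# ---------------------------------------------------------------------------

def sex_check(
    ds: GenotypeDataset,
    f_female_max: float = defaults.SEX_F_FEMALE_MAX,
    f_male_min: float = defaults.SEX_F_MALE_MIN,
    x_label: str = "X",
) -> pd.DataFrame:
    """Infer sex from X-chromosome homozygosity F and flag mismatches.

    F = (O_hom - E_hom) / (N - E_hom) with E_hom from X allele frequencies
    estimated on declared females (males are hemizygous and typed homozygous).
    Returns one row per sample: x_f, inferred_sex, declared_sex, sex_mismatch.
    """
    on_x = ds.chromosomes == x_label
    if not on_x.any():
        log.warning("sex_check: no SNPs on chromosome %r; returning empty result", x_label)
        return pd.DataFrame(columns=["sample_id", "x_f", "inferred_sex", "declared_sex", "sex_mismatch"])
    x_calls = ds.calls[:, on_x]
    declared = ds.samples["sex"].to_numpy()
    females = declared == 2
    freq_source = x_calls[females] if females.any() else x_calls
    p = _allele_freq_a1(freq_source)
    valid = ~np.isnan(p)
    x_calls = x_calls[:, valid]
    p = p[valid]
    e_het = 2 * p * (1 - p)
    nonmiss = x_calls != MISSING
    n = nonmiss.sum(axis=1).astype(float)
    o_hom = ((x_calls == 0) | (x_calls == 2)).sum(axis=1).astype(float)
    e_hom = (nonmiss * (1.0 - e_het)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n - e_hom != 0, (o_hom - e_hom) / (n - e_hom), np.nan)
    inferred = np.zeros(ds.n_samples, dtype=np.int8)
    inferred[f < f_female_max] = 2
    inferred[f > f_male_min] = 1
    mismatch = (declared != 0) & (inferred != 0) & (declared != inferred)
    for sid in ds.sample_ids[mismatch]:
        log.info("sex_mismatch flagged for sample %s", sid)
    return pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "x_f": f,
            "inferred_sex": inferred,
            "declared_sex": declared,
            "sex_mismatch": mismatch,
        }
    )


def merge_sample_reports(
    report: SampleQcReport,
    sex_table: pd.DataFrame | None = None,
    ibd_estimates: list[IbdEstimate] | None = None,
) -> SampleQcReport:
    """Fold sex-check and IBD pedigree-check flags into a sample QC report.

    Adds ``x_f``/``sex_mismatch`` columns from :func:`sex_check` output and a
    ``pedigree_error`` column (True for any sample in a flagged
    parent-offspring pair); both flags join the ``drop`` decision.
    """
    t = report.table.copy()
    if sex_table is not None and len(sex_table):
        sx = sex_table.set_index("sample_id")
        t["x_f"] = t["sample_id"].map(sx["x_f"])
        mapped = t["sample_id"].map(sx["sex_mismatch"])
        t["sex_mismatch"] = mapped.notna() & mapped.eq(True)
    else:
        t["sex_mismatch"] = False
    flagged_ids = set()
    for est in ibd_estimates or []:
        if est.flagged:
            flagged_ids.update((est.id1, est.id2))
    t["pedigree_error"] = t["sample_id"].isin(flagged_ids)
    t["drop"] = t["drop"] | t["sex_mismatch"] | t["pedigree_error"]
    return SampleQcReport(table=t, thresholds=dict(report.thresholds))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic genotype table.

    Sums the conditional probabilities (given allele counts) of every
    heterozygote count with probability <= that of the observed count.
    Computed in exact integer arithmetic, so ties are handled exactly; a
    monomorphic table returns 1.0.
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype call is required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # possible heterozygote counts share the parity of the rare allele count
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        na2 = (n_a - h) // 2
        nb2 = (n_b - h) // 2
        if na2 < 0 or nb2 < 0:
            continue
        # P(h) proportional to n! / (na2! h! nb2!) * 2^h  (exact integer weight)
        w = math.factorial(n) // (math.factorial(na2) * math.factorial(h) * math.factorial(nb2))
        weights[h] = w * (1 << h)
    total = sum(weights.values())
    w_obs = weights[n_ab]
    p_num = sum(w for w in weights.values() if w <= w_obs)
    return p_num / total


def _hwe_pval_fast(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Floating-point HWE exact p for bulk SNP QC (log-gamma weights).

    Same test as :func:`hwe_exact_test` but in floats for speed; agrees with
    the exact integer version to ~1e-12 relative, far below any sensible
    p-value threshold. Ties are compared with a 1+1e-9 relative guard.
    """
    from scipy.special import gammaln

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    h = np.arange(rare % 2, rare + 1, 2)
    na2 = (n_a - h) // 2
    nb2 = (n_b - h) // 2
    ok = (na2 >= 0) & (nb2 >= 0)
    h, na2, nb2 = h[ok], na2[ok], nb2[ok]
    logw = -gammaln(na2 + 1) - gammaln(h + 1) - gammaln(nb2 + 1) + h * np.log(2.0)
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[h == n_ab][0]
    return float(w[w <= w_obs * (1.0 + 1e-9)].sum() / w.sum())


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------

def snp_qc(
    ds: GenotypeDataset,
    call_rate_min: float | None = defaults.SNP_CALL_RATE_MIN,
    maf_min: float | None = defaults.MAF_MIN,
    hwe_p_min: float | None = defaults.HWE_P_MIN,
    drop_unknown_pos: bool = False,
    drop_sex_chroms: bool = False,
    autosomes: tuple[str, ...] = defaults.AUTOSOMES,
) -> SnpQcReport:
    """Per-SNP call rate / MAF / HWE / position / chromosome flags.

    Each flag is recorded independently; a SNP may carry several. ``None``
    disables the corresponding filter (statistic still reported).
    """
    calls = ds.calls
    nonmiss = calls != MISSING
    n_called = nonmiss.sum(axis=0)
    call_rate = n_called / max(ds.n_samples, 1)
    p = _allele_freq_a1(calls)
    maf = np.where(np.isnan(p), np.nan, np.minimum(p, 1 - p))
    hwe_p = np.ones(ds.n_snps)
    if hwe_p_min is not None:
        n_bb_arr = (calls == 0).sum(axis=0)
        n_ab_arr = (calls == 1).sum(axis=0)
        n_aa_arr = (calls == 2).sum(axis=0)
        for k in range(ds.n_snps):
            if n_called[k] > 0:
                hwe_p[k] = _hwe_pval_fast(int(n_aa_arr[k]), int(n_ab_arr[k]), int(n_bb_arr[k]))

    low_cr = (call_rate < call_rate_min) if call_rate_min is not None else np.zeros(ds.n_snps, bool)
    low_maf = (np.nan_to_num(maf, nan=0.0) < maf_min) if maf_min is not None else np.zeros(ds.n_snps, bool)
    hwe_fail = (hwe_p < hwe_p_min) if hwe_p_min is not None else np.zeros(ds.n_snps, bool)
    unknown_pos = (ds.positions == 0) | (ds.chromosomes == "0")
    sex_chrom = ~np.isin(ds.chromosomes, list(autosomes)) & (ds.chromosomes != "0")
    drop = low_cr | low_maf | hwe_fail
    if drop_unknown_pos:
        drop = drop | unknown_pos
    if drop_sex_chroms:
        drop = drop | sex_chrom
    table = pd.DataFrame(
        {
            "snp_id": ds.snps["snp_id"].to_numpy(),
            "chromosome": ds.chromosomes,
            "position_bp": ds.positions,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "low_call_rate": low_cr,
            "low_maf": low_maf,
            "hwe_fail": hwe_fail,
            "unknown_position": unknown_pos,
            "sex_chromosome": sex_chrom,
            "drop": drop,
        }
    )
    return SnpQcReport(
        table=table,
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "drop_unknown_pos": drop_unknown_pos,
            "drop_sex_chroms": drop_sex_chroms,
        },
    )


def run_profile_snp_qc(ds: GenotypeDataset, profile: QcProfile) -> SnpQcReport:
    return snp_qc(
        ds,
        call_rate_min=profile.snp_call_rate_min,
        maf_min=profile.maf_min,
        hwe_p_min=profile.hwe_p_min,
        drop_unknown_pos=profile.drop_unknown_pos,
        drop_sex_chroms=profile.drop_sex_chroms,
        autosomes=profile.autosomes,
    )


# ---------------------------------------------------------------------------
# Apply
# ---------------------------------------------------------------------------

def apply_qc(
    ds: GenotypeDataset,
    sample_report: SampleQcReport | None = None,
    snp_report: SnpQcReport | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop flagged samples/SNPs; return the filtered dataset and reason tallies.

    A SNP (or sample) removed for several reasons counts once in the
    removed/retained totals and once per reason in the reason tallies.
    """
    keep_s = np.ones(ds.n_samples, dtype=bool)
    keep_v = np.ones(ds.n_snps, dtype=bool)
    rows = []
    if sample_report is not None:
        t = sample_report.table
        if len(t) != ds.n_samples or not (t["sample_id"].to_numpy() == ds.sample_ids).all():
            raise ValueError("sample report does not match dataset")
        keep_s = ~t["drop"].to_numpy()
        for reason in ("low_call_rate", "het_outlier", "duplicate"):
            rows.append(("sample", reason, int(t[reason].sum())))
        rows.append(("sample", "removed_total", int((~keep_s).sum())))
        rows.append(("sample", "retained", int(keep_s.sum())))
    if snp_report is not None:
        t = snp_report.table
        if len(t) != ds.n_snps or not (t["snp_id"].to_numpy() == ds.snps["snp_id"].to_numpy()).all():
            raise ValueError("snp report does not match dataset")
        keep_v = ~t["drop"].to_numpy()
        for reason in ("low_call_rate", "low_maf", "hwe_fail", "unknown_position", "sex_chromosome"):
            rows.append(("snp", reason, int(t[reason].sum())))
        rows.append(("snp", "removed_total", int((~keep_v).sum())))
        rows.append(("snp", "retained", int(keep_v.sum())))
    if not keep_s.any():
        raise ValueError("QC removed every sample")
    if not keep_v.any():
        raise ValueError("QC removed every SNP")
    counts = pd.DataFrame(rows, columns=["level", "reason", "count"])
    return ds.subset(np.flatnonzero(keep_s), np.flatnonzero(keep_v)), counts
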