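"""Runs of homozygosity: detection, F_ROH / F_SNP, sharing and consensus regions.

A ROH is a maximal run of consecutive SNPs on one chromosome such that every
contiguous window of ``window`` SNPs lying wholly inside the run contains at
most ``max_het_per_window`` heterozygous and ``max_missing_per_window``
missing calls; runs with fewer than ``min_snps`` SNPs or spanning less than
``min_length_kb`` are discarded. This every-interior-window rule is exactly
specifiable (and oracle-testable); it is NOT PLINK's proportion-based
window-overlap algorithm - see README for the divergence note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .io_formats import MISSING, GenotypeDataset, chrom_sort_key
from .pedigree import InbreedingVector

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run in one individual (1-based inclusive bp span)."""

    sample_id: str
    chromosome: str
    start_snp_index: int
    end_snp_index: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SharedRegion:
    """A homozygous region carried by several animals (possibly across populations)."""

    chromosome: str
    start_bp: int
    end_bp: int
    carriers: dict[str, list[str]]           # population -> carrier sample ids
    carrier_fraction: dict[str, float]       # population -> carriers / pop size
    mean_incidence: float | None = None


def detect_roh(
    ds: GenotypeDataset,
    min_snps: int = defaults.ROH_MIN_SNPS,
    min_length_kb: float = defaults.ROH_MIN_LENGTH_KB,
    window: int = defaults.ROH_WINDOW,
    max_het_per_window: int = defaults.ROH_MAX_HET_PER_WINDOW,
    max_missing_per_window: int = defaults.ROH_MAX_MISSING_PER_WINDOW,
    autosomes: tuple[str, ...] | None = defaults.AUTOSOMES,
) -> list[RohSegment]:
    """Call ROH per sample on autosomal SNPs sorted by position.

    Output is deterministic, ordered by (sample order, chromosome, start).
    Chromosomes with fewer than ``window`` SNPs yield no calls (logged).
    """
    if min(min_snps, window, max_het_per_window + 1, max_missing_per_window + 1) <= 0:
        raise ValueError("ROH parameters must be positive")
    if window > min_snps:
        raise ValueError(f"window ({window}) must be <= min_snps ({min_snps})")
    min_length_bp = min_length_kb * 1000.0
    segments: list[RohSegment] = []
    chroms = ds.chromosomes
    for chrom in _ordered_chromosomes(ds, autosomes):
        snp_idx = np.flatnonzero(chroms == chrom)
        pos = ds.positions[snp_idx]
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"SNPs on chromosome {chrom} are not sorted by position")
        m = len(snp_idx)
        if m < window:
            log.info("chromosome %s has %d < window=%d SNPs; no ROH called", chrom, m, window)
            continue
        calls = ds.calls[:, snp_idx]
        is_het = calls == 1
        is_miss = calls == MISSING
        het_c = np.concatenate([np.zeros((ds.n_samples, 1), int), np.cumsum(is_het, axis=1)], axis=1)
        miss_c = np.concatenate([np.zeros((ds.n_samples, 1), int), np.cumsum(is_miss, axis=1)], axis=1)
        # window starting at k is "good" if its het and missing counts pass
        het_w = het_c[:, window:] - het_c[:, :-window]
        miss_w = miss_c[:, window:] - miss_c[:, :-window]
        good = (het_w <= max_het_per_window) & (miss_w <= max_missing_per_window)
        for i in range(ds.n_samples):
            for a, b in _true_runs(good[i]):
                s, e = a, b + window - 1  # SNP span covered by the good window run
                n = e - s + 1
                length = pos[e] - pos[s] + 1
                if n < min_snps or length < min_length_bp:
                    continue
                segments.append(
                    RohSegment(
                        sample_id=str(ds.sample_ids[i]),
                        chromosome=str(chrom),
                        start_snp_index=int(s),
                        end_snp_index=int(e),
                        start_bp=int(pos[s]),
                        end_bp=int(pos[e]),
                        n_snps=int(n),
                        n_het=int(het_c[i, e + 1] - het_c[i, s]),
                        n_missing=int(miss_c[i, e + 1] - miss_c[i, s]),
                    )
                )
    sample_rank = {str(sid): k for k, sid in enumerate(ds.sample_ids)}
    segments.sort(key=lambda r: (sample_rank[r.sample_id], chrom_sort_key(r.chromosome), r.start_bp))
    return segments


def _ordered_chromosomes(ds: GenotypeDataset, autosomes) -> list[str]:
    seen = list(dict.fromkeys(ds.chromosomes))
    if autosomes is not None:
        seen = [c for c in seen if c in autosomes]
    return sorted(seen, key=chrom_sort_key)


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def apply_roh_post_filters(
    segments: list[RohSegment],
    ds: GenotypeDataset,
    max_gap_kb: float | None = None,
    min_snps_per_100kb: float | None = None,
) -> list[RohSegment]:
    """Optional post-hoc filters mirroring PLINK's gap/density options.

    Neither is applied by default anywhere in the pipeline. ``max_gap_kb``
    drops segments containing an inter-SNP gap larger than the bound;
    ``min_snps_per_100kb`` drops segments whose SNP density falls below it.
    """
    out = []
    chroms = ds.chromosomes
    pos_by_chrom = {
        str(c): ds.positions[np.flatnonzero(chroms == c)] for c in dict.fromkeys(chroms)
    }
    for seg in segments:
        if min_snps_per_100kb is not None:
            density = seg.n_snps / (seg.length_bp / 100_000.0)
            if density < min_snps_per_100kb:
                continue
        if max_gap_kb is not None:
            pos = pos_by_chrom[seg.chromosome]
            inside = pos[(pos >= seg.start_bp) & (pos <= seg.end_bp)]
            if len(inside) > 1 and np.diff(inside).max() > max_gap_kb * 1000.0:
                continue
        out.append(seg)
    return out


def f_roh(
    segments: list[RohSegment],
    sample_ids: list[str],
    genome_length_kb: float = defaults.GENOME_LENGTH_KB,
) -> InbreedingVector:
    """F_ROH = total ROH length / genome length, per sample (0 when no ROH)."""
    if genome_length_kb <= 0:
        raise ValueError("genome_length_kb must be positive")
    total = {str(s): 0.0 for s in sample_ids}
    for seg in segments:
        total[seg.sample_id] = total.get(seg.sample_id, 0.0) + seg.length_bp
    genome_bp = genome_length_kb * 1000.0
    values = {}
    for sid, t in total.items():
        if t > genome_bp:
            raise ValueError(
                f"sample {sid}: total ROH length {t:.0f} bp exceeds genome length "
                f"{genome_bp:.0f} bp (inconsistent units?)"
            )
        values[sid] = t / genome_bp
    return InbreedingVector(values=values, method="roh")


def f_snp(ds: GenotypeDataset) -> InbreedingVector:
    """Observed homozygous fraction per sample (NaN for all-missing samples)."""
    nonmiss = ds.calls != MISSING
    n = nonmiss.sum(axis=1)
    hom = ((ds.calls == 0) | (ds.calls == 2)).sum(axis=1)
    values = {}
    for sid, h, k in zip(ds.sample_ids, hom, n):
        values[str(sid)] = float(h / k) if k > 0 else float("nan")
        if k == 0:
            log.warning("sample %s has no non-missing calls; F_SNP undefined", sid)
    return InbreedingVector(values=values, method="snp")


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_snps,
             s.length_bp, s.n_het, s.n_missing)
            for s in segments
        ],
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps",
                 "length_bp", "n_het", "n_missing"],
    )


def summarize_roh(
    segments: list[RohSegment],
    sample_ids: list[str],
    populations: dict[str, str] | None = None,
    genome_length_kb: float = defaults.GENOME_LENGTH_KB,
    short_mb: float = defaults.SHORT_ROH_MB,
) -> dict:
    """Per-sample and per-population ROH summary.

    The short/long partition is per segment at ``short_mb`` (strictly
    shorter = short). Includes the Pearson correlation between a sample's
    segment count and its mean segment length, and both per-segment and
    per-animal-total length distributions.
    """
    if not segments:
        log.warning("summarize_roh called with no segments; all-zero summary")
    df = segments_to_frame(segments)
    per_sample = pd.DataFrame({"sample_id": [str(s) for s in sample_ids]})
    if len(df):
        agg = df.groupby("sample_id")["length_bp"].agg(n_roh="count", total_length_bp="sum", mean_length_bp="mean")
        per_sample = per_sample.merge(agg, on="sample_id", how="left")
    else:
        per_sample[["n_roh", "total_length_bp", "mean_length_bp"]] = 0.0
    per_sample[["n_roh", "total_length_bp"]] = per_sample[["n_roh", "total_length_bp"]].fillna(0)
    fr = f_roh(segments, list(per_sample["sample_id"]), genome_length_kb)
    per_sample["f_roh"] = per_sample["sample_id"].map(fr.values)
    per_sample["population"] = per_sample["sample_id"].map(populations) if populations else "pop"

    short_bp = short_mb * 1e6
    n_short = int((df["length_bp"] < short_bp).sum()) if len(df) else 0
    n_long = int(len(df) - n_short)
    valid = per_sample[per_sample["n_roh"] > 1].dropna(subset=["mean_length_bp"])
    if len(valid) >= 3 and valid["n_roh"].nunique() > 1 and valid["mean_length_bp"].nunique() > 1:
        corr = float(stats.pearsonr(valid["n_roh"], valid["mean_length_bp"])[0])
    else:
        corr = float("nan")
    pop_stats = (
        per_sample.groupby("population")
        .agg(
            n_samples=("sample_id", "count"),
            mean_n_roh=("n_roh", "mean"),
            min_n_roh=("n_roh", "min"),
            max_n_roh=("n_roh", "max"),
            mean_total_length_bp=("total_length_bp", "mean"),
            min_total_length_bp=("total_length_bp", "min"),
            max_total_length_bp=("total_length_bp", "max"),
            mean_f_roh=("f_roh", "mean"),
            min_f_roh=("f_roh", "min"),
            max_f_roh=("f_roh", "max"),
        )
        .reset_index()
    )
    return {
        "per_sample": per_sample,
        "per_population": pop_stats,
        "n_segments_short": n_short,
        "n_segments_long": n_long,
        "segment_length_mean_bp": float(df["length_bp"].mean()) if len(df) else 0.0,
        "corr_n_vs_mean_length": corr,
    }


def shared_roh(
    segments_by_pop: dict[str, list[RohSegment]],
    pop_sizes: dict[str, int],
    mode: str = "within",
    match: str = "exact",
    min_overlap_bp: float = defaults.SHARED_ROH_MIN_OVERLAP_BP,
    populations: tuple[str, str] | None = None,
) -> tuple[list[SharedRegion], pd.DataFrame]:
    """Find homozygous segments shared by several animals.

    ``match="exact"`` groups segments with identical (chromosome, start, end);
    ``match="overlap"`` groups segments whose pairwise overlap is at least
    ``min_overlap_bp`` (connected components). ``mode="within"`` requires >= 2
    carriers in one population; ``mode="between"`` requires >= 1 carrier in
    each of the two named populations. Also returns a per-chromosome count
    table of the shared regions.
    """
    if mode not in ("within", "between"):
        raise ValueError(f"unknown mode {mode!r}")
    if match not in ("exact", "overlap"):
        raise ValueError(f"unknown match {match!r}")
    for p in populations or ():
        if p not in segments_by_pop:
            raise ValueError(f"unknown population label {p!r}")
    if mode == "between":
        if populations is None:
            if len(segments_by_pop) != 2:
                raise ValueError("between-mode needs exactly two populations")
            populations = tuple(segments_by_pop)  # type: ignore[assignment]
        pops = list(populations)
    else:
        pops = list(segments_by_pop)

    rows = []  # (chrom, start, end, pop, sample)
    for pop in pops:
        for seg in segments_by_pop[pop]:
            rows.append((seg.chromosome, seg.start_bp, seg.end_bp, pop, seg.sample_id))
    regions: list[SharedRegion] = []
    if match == "exact":
        groups: dict[tuple, list[tuple[str, str]]] = {}
        for chrom, s, e, pop, sid in rows:
            groups.setdefault((chrom, s, e), []).append((pop, sid))
        for (chrom, s, e), members in sorted(groups.items(), key=lambda kv: (chrom_sort_key(kv[0][0]), kv[0][1])):
            region = _make_region(chrom, s, e, members, pop_sizes)
            if _qualifies(region, mode, pops):
                regions.append(region)
    else:
        by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
        for chrom, s, e, pop, sid in rows:
            by_chrom.setdefault(chrom, []).append((s, e, pop, sid))
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            for comp in _overlap_components(by_chrom[chrom], min_overlap_bp):
                s = min(x[0] for x in comp)
                e = max(x[1] for x in comp)
                members = [(x[2], x[3]) for x in comp]
                region = _make_region(chrom, s, e, members, pop_sizes)
                if _qualifies(region, mode, pops):
                    regions.append(region)

    counts = (
        pd.Series([r.chromosome for r in regions]).value_counts().rename("n_shared_regions")
        if regions
        else pd.Series([], name="n_shared_regions", dtype=int)
    )
    table = counts.rename_axis("chromosome").reset_index()
    table = table.sort_values("chromosome", key=lambda s: s.map(chrom_sort_key)).reset_index(drop=True)
    total = pd.DataFrame([{"chromosome": "Total", "n_shared_regions": int(table["n_shared_regions"].sum())}])
    table = pd.concat([table, total], ignore_index=True)
    return regions, table


def _make_region(chrom, s, e, members, pop_sizes) -> SharedRegion:
    carriers: dict[str, list[str]] = {}
    for pop, sid in members:
        carriers.setdefault(pop, [])
        if sid not in carriers[pop]:
            carriers[pop].append(sid)
    frac = {p: len(c) / pop_sizes[p] for p, c in carriers.items() if pop_sizes.get(p)}
    return SharedRegion(chromosome=str(chrom), start_bp=int(s), end_bp=int(e),
                        carriers=carriers, carrier_fraction=frac)


def _qualifies(region: SharedRegion, mode: str, pops: list[str]) -> bool:
    if mode == "within":
        return any(len(region.carriers.get(p, [])) >= 2 for p in pops)
    return all(len(region.carriers.get(p, [])) >= 1 for p in pops)


def _overlap_components(items: list[tuple[int, int, str, str]], min_overlap_bp: float):
    """Connected components under 'pairwise overlap >= min_overlap_bp' (sweep)."""
    items = sorted(items)
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        si, ei = items[i][0], items[i][1]
        for j in range(i + 1, n):
            sj, ej = items[j][0], items[j][1]
            if sj > ei - min_overlap_bp + 1:
                break
            if min(ei, ej) - max(si, sj) + 1 >= min_overlap_bp:
                union(i, j)
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i])
    return [comps[k] for k in sorted(comps)]


def consensus_regions(
    segments: list[RohSegment],
    ds: GenotypeDataset,
    population_ids: list[str],
    incidence_min: float,
) -> list[SharedRegion]:
    """Maximal runs of consecutive SNPs whose ROH incidence >= incidence_min.

    Incidence at a SNP is the fraction of ``population_ids`` whose ROH covers
    the SNP. Regions are reported with the bp bounds of their terminal SNPs
    and the mean incidence across their SNPs.
    """
    if not (0 < incidence_min):
        raise ValueError("incidence_min must be positive")
    pop_set = set(map(str, population_ids))
    n_pop = len(pop_set)
    out: list[SharedRegion] = []
    chroms = ds.chromosomes
    for chrom in _ordered_chromosomes(ds, None):
        snp_idx = np.flatnonzero(chroms == chrom)
        pos = ds.positions[snp_idx]
        cover = np.zeros(len(snp_idx), dtype=np.int64)
        carriers_at: list[set] = [set() for _ in range(len(snp_idx))]
        for seg in segments:
            if seg.chromosome != chrom or seg.sample_id not in pop_set:
                continue
            lo = np.searchsorted(pos, seg.start_bp, side="left")
            hi = np.searchsorted(pos, seg.end_bp, side="right")
            cover[lo:hi] += 1
            for k in range(lo, hi):
                carriers_at[k].add(seg.sample_id)
        incidence = cover / n_pop
        for a, b in _true_runs(incidence >= incidence_min):
            carr = set.union(*carriers_at[a:b + 1]) if b >= a else set()
            members = [("pop", sid) for sid in sorted(carr)]
            region = _make_region(chrom, pos[a], pos[b], members, {"pop": n_pop})
            region.mean_incidence = float(incidence[a:b + 1].mean())
            out.append(region)
    return out


def regions_to_bed(regions: list[SharedRegion], path) -> None:
    """Write regions as BED (0-based half-open on disk; internal is 1-based inclusive)."""
    with open(path, "w") as fh:
        for r in regions:
            name = ";".join(f"{p}:{len(c)}" for p, c in sorted(r.carriers.items()))
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")
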