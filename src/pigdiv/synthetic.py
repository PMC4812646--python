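"""Forward Wright-Fisher diploid simulator with recombination and truth tracking.

Founders carry 2N distinct haplotype ids; every gamete is a recombinant
mosaic of its parent's two gametes (crossovers Poisson per Morgan, uniform
positions, no interference), and the founder-haplotype mosaic of every
gamete is recorded. True autozygosity of an individual is the fraction of
the genome where its two gametes carry the same founder haplotype id -
the ground truth against which F_ROH and pedigree F are validated.

SNP positions are deterministic and equally spaced; physical coordinates
use 1 Morgan = 100 Mb (1 cM ~ 1 Mb), matching the Ne module default.
Everything is driven by a single seeded generator: same seed, same output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset, PedigreeTable, make_dataset, make_pedigree

log = logging.getLogger(__name__)

BP_PER_MORGAN = 100_000_000

Mosaic = tuple[np.ndarray, np.ndarray]  # (breakpoints[k+1] in Morgan, founder ids[k])


@dataclass(frozen=True)
class SplitSpec:
    """Split the population into two isolated daughters at ``generation``."""

    generation: int
    sizes: tuple[int, int]


@dataclass
class SimConfig:
    seed: int
    n_generations: int
    pop_size: int | Sequence[int]
    n_chromosomes: int = 1
    chrom_length_morgan: float | Sequence[float] = 1.0
    n_snps: int | Sequence[int] = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    mating: str = "random_monogamous"
    split: SplitSpec | None = None
    missing_rate: float = 0.0
    error_rate: float = 0.0
    export: str = "final"  # "final" or "all"
    export_haplotypes: bool = False  # keep phased haplotypes of exported animals in SimTruth

    def size_at(self, generation: int) -> int:
        if isinstance(self.pop_size, int):
            return self.pop_size
        sizes = list(self.pop_size)
        return sizes[min(generation, len(sizes) - 1)]

    def chrom_lengths(self) -> list[float]:
        if isinstance(self.chrom_length_morgan, (int, float)):
            return [float(self.chrom_length_morgan)] * self.n_chromosomes
        return [float(v) for v in self.chrom_length_morgan]

    def snps_per_chrom(self) -> list[int]:
        if isinstance(self.n_snps, int):
            return [self.n_snps] * self.n_chromosomes
        return [int(v) for v in self.n_snps]

    def validate(self) -> None:
        if self.n_generations < 0 or self.n_chromosomes < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.missing_rate < 1 and 0 <= self.error_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.mating not in ("random_monogamous", "random_polygamous"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.split is not None:
            if not (0 < self.split.generation <= self.n_generations):
                raise ValueError("split generation must lie in 1..n_generations")
            parent_n = self.size_at(self.split.generation - 1)
            if max(self.split.sizes) > parent_n:
                raise ValueError("daughter sizes exceeding parent N")
        if self.export not in ("final", "all"):
            raise ValueError("export must be 'final' or 'all'")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    pedigree: PedigreeTable
    mosaics: dict[str, list[tuple[Mosaic, Mosaic]]]  # animal -> per-chrom gamete pair
    chrom_lengths: list[float]
    ne_history: list[int]
    split_generation: int | None
    populations: dict[str, str]  # animal -> population label
    generation_of: dict[str, int]
    haplotypes: dict[str, np.ndarray] | None = None  # animal -> (2, n_snps) phased alleles


class _Indiv:
    __slots__ = ("animal_id", "sex", "sire", "dam", "pop", "haps", "mosaics")

    def __init__(self, animal_id, sex, sire, dam, pop, haps, mosaics):
        self.animal_id = animal_id
        self.sex = sex  # 1 male, 2 female
        self.sire = sire
        self.dam = dam
        self.pop = pop
        self.haps = haps        # per chromosome: [hap0 uint8[m], hap1 uint8[m]]
        self.mosaics = mosaics  # per chromosome: (Mosaic, Mosaic)


def _snp_positions_morgan(length: float, m: int) -> np.ndarray:
    return (np.arange(m) + 0.5) * (length / m)


def _splice(mosaics: tuple[Mosaic, Mosaic], cuts: np.ndarray, start: int, length: float) -> Mosaic:
    """Compose a recombinant mosaic from two parent mosaics and crossover cuts."""
    bounds = np.concatenate([[0.0], cuts, [length]])
    out_b = [0.0]
    out_i: list[int] = []
    for s, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        if hi <= lo:
            continue
        b, ids = mosaics[(start + s) % 2]
        k0 = int(np.searchsorted(b, lo, side="right")) - 1
        k1 = int(np.searchsorted(b, hi, side="left"))
        for k in range(k0, k1):
            seg_hi = min(float(b[k + 1]), float(hi))
            fid = int(ids[k])
            if out_i and out_i[-1] == fid:
                out_b[-1] = seg_hi
            else:
                out_b.append(seg_hi)
                out_i.append(fid)
    return np.array(out_b), np.array(out_i, dtype=np.int64)


def _make_gamete(rng, parent: _Indiv, chrom: int, snp_pos: np.ndarray, length: float):
    nco = rng.poisson(length)
    cuts = np.sort(rng.uniform(0.0, length, nco)) if nco else np.empty(0)
    start = int(rng.integers(2))
    choice = (start + np.searchsorted(cuts, snp_pos, side="right")) % 2
    h0, h1 = parent.haps[chrom]
    alleles = np.where(choice == 0, h0, h1).astype(np.uint8)
    mosaic = _splice(parent.mosaics[chrom], cuts, start, length)
    return alleles, mosaic


def _balanced_sexes(rng, n: int) -> np.ndarray:
    """Random permutation of an (almost) half-male, half-female sex vector."""
    sexes = np.array([1, 2] * (n // 2) + ([int(rng.integers(1, 3))] if n % 2 else []), dtype=np.int8)
    rng.shuffle(sexes)
    return sexes


def _choose_parents(rng, parents: list[_Indiv], n_off: int, mating: str):
    males = [p for p in parents if p.sex == 1]
    females = [p for p in parents if p.sex == 2]
    if not males or not females:
        raise ValueError("no valid mating pair: need at least one male and one female")
    if mating == "random_monogamous":
        mi = rng.permutation(len(males))
        fi = rng.permutation(len(females))
        couples = [(males[a], females[b]) for a, b in zip(mi, fi)]
        picks = rng.integers(0, len(couples), n_off)
        return [couples[k] for k in picks]
    si = rng.integers(0, len(males), n_off)
    di = rng.integers(0, len(females), n_off)
    return [(males[a], females[b]) for a, b in zip(si, di)]


def simulate(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Run the forward simulation; returns genotypes and full ground truth.

    With a :class:`SplitSpec`, daughters are labelled "pop1"/"pop2" and bred
    from the whole parent generation at the split, then kept isolated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = config.chrom_lengths()
    snps = config.snps_per_chrom()
    snp_pos = [_snp_positions_morgan(L, m) for L, m in zip(lengths, snps)]

    n0 = config.size_at(0)
    founders: list[_Indiv] = []
    founder_freqs = [rng.uniform(config.maf_range[0], config.maf_range[1], m) for m in snps]
    for k in range(n0):
        haps = []
        mos = []
        for c, m in enumerate(snps):
            h0 = (rng.random(m) < founder_freqs[c]).astype(np.uint8)
            h1 = (rng.random(m) < founder_freqs[c]).astype(np.uint8)
            haps.append([h0, h1])
            L = lengths[c]
            mos.append(
                (
                    (np.array([0.0, L]), np.array([2 * k], dtype=np.int64)),
                    (np.array([0.0, L]), np.array([2 * k + 1], dtype=np.int64)),
                )
            )
        sex = 1 if k % 2 == 0 else 2  # founders alternate male/female
        founders.append(_Indiv(f"G0_{k}", sex, None, None, "pop", haps, mos))

    ped_rows = []
    mosaics: dict[str, list] = {}
    populations: dict[str, int | str] = {}
    generation_of: dict[str, int] = {}
    ne_history = [n0]
    all_gens: list[list[_Indiv]] = [founders]

    def record(ind: _Indiv, gen: int):
        ped_rows.append((ind.animal_id, ind.sire or "0", ind.dam or "0", ind.sex, gen))
        mosaics[ind.animal_id] = ind.mosaics
        populations[ind.animal_id] = ind.pop
        generation_of[ind.animal_id] = gen

    for ind in founders:
        record(ind, 0)

    groups: dict[str, list[_Indiv]] = {"pop": founders}
    for g in range(1, config.n_generations + 1):
        split_now = config.split is not None and g == config.split.generation
        new_groups: dict[str, list[_Indiv]] = {}
        if split_now:
            parent_pool = [ind for grp in groups.values() for ind in grp]
            plan = [("pop1", config.split.sizes[0]), ("pop2", config.split.sizes[1])]
            pools = {"pop1": parent_pool, "pop2": parent_pool}
        elif config.split is not None and g > config.split.generation:
            plan = [("pop1", config.split.sizes[0]), ("pop2", config.split.sizes[1])]
            pools = dict(groups)
        else:
            plan = [("pop", config.size_at(g))]
            pools = {"pop": groups["pop"]}
        gen_indivs: list[_Indiv] = []
        for pop, n_off in plan:
            parents = pools[pop]
            matings = _choose_parents(rng, parents, n_off, config.mating)
            sexes = _balanced_sexes(rng, n_off)
            children = []
            for k, (sire, dam) in enumerate(matings):
                haps, mos = [], []
                for c in range(config.n_chromosomes):
                    a0, m0 = _make_gamete(rng, sire, c, snp_pos[c], lengths[c])
                    a1, m1 = _make_gamete(rng, dam, c, snp_pos[c], lengths[c])
                    haps.append([a0, a1])
                    mos.append((m0, m1))
                suffix = f"{pop}_" if pop != "pop" else ""
                child = _Indiv(
                    f"G{g}_{suffix}{k}", int(sexes[k]), sire.animal_id, dam.animal_id, pop, haps, mos
                )
                children.append(child)
                record(child, g)
            new_groups[pop] = children
            gen_indivs.extend(children)
        groups = new_groups
        ne_history.append(sum(len(v) for v in groups.values()))
        all_gens.append(gen_indivs)

    ped = make_pedigree(
        pd.DataFrame(ped_rows, columns=["animal", "sire", "dam", "sex", "birth_year"])
    )
    truth = SimTruth(
        pedigree=ped,
        mosaics=mosaics,
        chrom_lengths=lengths,
        ne_history=ne_history,
        split_generation=config.split.generation if config.split else None,
        populations={k: str(v) for k, v in populations.items()},
        generation_of=generation_of,
    )
    exported = (
        [ind for gen in all_gens for ind in gen] if config.export == "all"
        else [ind for grp in groups.values() for ind in grp]
    )
    if config.export_haplotypes:
        truth.haplotypes = {
            ind.animal_id: np.vstack(
                [
                    np.concatenate([ind.haps[c][0] for c in range(config.n_chromosomes)]),
                    np.concatenate([ind.haps[c][1] for c in range(config.n_chromosomes)]),
                ]
            )
            for ind in exported
        }
    ds = _export_dataset(exported, snp_pos, lengths)
    if config.missing_rate > 0 or config.error_rate > 0:
        ds = degrade(ds, config.missing_rate, config.error_rate, seed=int(rng.integers(2**31)))
    return ds, truth


def _export_dataset(indivs: list[_Indiv], snp_pos, lengths) -> GenotypeDataset:
    n_chrom = len(snp_pos)
    snp_rows = []
    for c in range(n_chrom):
        bp = np.round(snp_pos[c] * BP_PER_MORGAN).astype(np.int64)
        for k, p in enumerate(bp):
            snp_rows.append((f"c{c + 1}s{k}", str(c + 1), int(p), "A", "G"))
    snp_df = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position_bp", "allele_a1", "allele_a2"])
    calls = np.empty((len(indivs), len(snp_rows)), dtype=np.int8)
    for i, ind in enumerate(indivs):
        calls[i] = np.concatenate([ind.haps[c][0] + ind.haps[c][1] for c in range(n_chrom)])
    return make_dataset(
        sample_ids=[ind.animal_id for ind in indivs],
        snps=snp_df,
        calls=calls,
        populations=[ind.pop for ind in indivs],
        sexes=[ind.sex for ind in indivs],
    )


def split_populations(config: SimConfig) -> tuple[GenotypeDataset, GenotypeDataset, SimTruth]:
    """Simulate with a split spec and return the two daughter datasets."""
    if config.split is None:
        raise ValueError("split_populations requires config.split")
    ds, truth = simulate(config)
    pops = ds.samples["population"].to_numpy()
    ds1 = ds.subset(sample_idx=np.flatnonzero(pops == "pop1"))
    ds2 = ds.subset(sample_idx=np.flatnonzero(pops == "pop2"))
    return ds1, ds2, truth


def degrade(ds: GenotypeDataset, missing_rate: float, error_rate: float, seed: int) -> GenotypeDataset:
    """Inject missingness then uniform random genotype errors (seeded copy)."""
    if not (0 <= missing_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    if error_rate > 0:
        hit = (rng.random(calls.shape) < error_rate) & (calls != MISSING)
        # replace by a uniformly random *different* valid code
        shift = rng.integers(1, 3, size=calls.shape)
        calls[hit] = ((calls[hit] + shift[hit]) % 3).astype(np.int8)
    return GenotypeDataset(samples=ds.samples.copy(), snps=ds.snps.copy(), calls=calls)


def true_autozygosity(truth: SimTruth, animal_id: str) -> tuple[float, list[tuple[str, float, float]]]:
    """Fraction of the genome where both gametes carry the same founder haplotype.

    Returns (fraction, intervals) with intervals as (chromosome label,
    start_M, end_M), merged per chromosome.
    """
    if animal_id not in truth.mosaics:
        raise KeyError(f"unknown individual {animal_id!r}")
    total = sum(truth.chrom_lengths)
    auto = 0.0
    intervals: list[tuple[str, float, float]] = []
    for c, (m0, m1) in enumerate(truth.mosaics[animal_id]):
        b0, i0 = m0
        b1, i1 = m1
        bounds = np.union1d(b0, b1)
        cur_start = None
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mid = (lo + hi) / 2.0
            f0 = i0[np.searchsorted(b0, mid, side="right") - 1]
            f1 = i1[np.searchsorted(b1, mid, side="right") - 1]
            if f0 == f1:
                auto += hi - lo
                if cur_start is None:
                    cur_start = lo
            elif cur_start is not None:
                intervals.append((str(c + 1), float(cur_start), float(lo)))
                cur_start = None
        if cur_start is not None:
            intervals.append((str(c + 1), float(cur_start), float(bounds[-1])))
    return auto / total, intervals


def truth_autozygosity_frame(truth: SimTruth, animal_ids=None) -> pd.DataFrame:
    ids = animal_ids if animal_ids is not None else list(truth.mosaics)
    rows = [(a, true_autozygosity(truth, a)[0]) for a in ids]
    return pd.DataFrame(rows, columns=["animal", "true_autozygosity"])
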