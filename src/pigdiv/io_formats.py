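"""Readers and writers for PLINK-dialect genotype files and pedigree tables.

The in-memory model is :class:`GenotypeDataset`: a samples table, a SNP map
sorted by (chromosome, position) and an ``int8`` call matrix coding the
number of copies of the first allele (A1), with ``MISSING`` (-1) for no-calls.

Coordinates are 1-based inclusive base pairs throughout (PLINK convention);
position 0 means "unknown". Chromosomes are string labels ordered naturally
(numeric labels numerically, then alphabetic ones, with "0" last).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
GENOTYPE_CODES = (0, 1, 2, MISSING)
VALID_ALLELES = frozenset("ACGT012")
BED_MAGIC = b"\x6c\x1b"
SNP_MAJOR = b"\x01"

# .bed two-bit value -> A1 dosage (PLINK 1 encoding; value order is LSB-first)
_BED_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CODE_TO_BED = {2: 0, MISSING: 1, 1: 2, 0: 3}


class FormatError(ValueError):
    """A genotype file violates the expected PLINK dialect."""


class PedigreeError(ValueError):
    """A pedigree table is structurally invalid (cycle, duplicate id...)."""


def plink_path(prefix, ext: str) -> Path:
    """PLINK companion file path: append ``ext`` to the prefix verbatim.

    Unlike ``Path.with_suffix`` this never swallows dots already in the
    prefix name (e.g. ``pop1.inbreeding`` + ``.bed`` -> ``pop1.inbreeding.bed``).
    """
    prefix = Path(prefix)
    return prefix.parent / (prefix.name + ext)


def chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Natural ordering for chromosome labels: 1..n numeric, then X/Y..., then "0"."""
    s = str(label)
    if s == "0":
        return (2, 0, "")
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass(frozen=True)
class SnpRecord:
    """One SNP on the map: id, chromosome label, 1-based bp position, alleles."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a1: str
    allele_a2: str


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix with A1-dosage coding.

    Attributes
    ----------
    samples : DataFrame with columns ``sample_id``, ``population``, ``sex``
        (sex 1=male, 2=female, 0=unknown).
    snps : DataFrame with columns ``snp_id``, ``chromosome``, ``position_bp``,
        ``allele_a1``, ``allele_a2``, sorted by (chromosome, position_bp).
    calls : int8 array of shape (n_samples, n_snps); values in {0,1,2,-1}.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.snps["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.snps["position_bp"].to_numpy()

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if self.calls.shape != (self.n_samples, self.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({self.n_samples}, {self.n_snps})"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))[:5]}")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()]
            raise ValueError(f"duplicate snp ids: {sorted(set(dup))[:5]}")
        bad = ~np.isin(self.calls, GENOTYPE_CODES)
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")
        for chrom, sub in self.snps.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            pos = pos[pos > 0]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    def sorted_by_map(self) -> "GenotypeDataset":
        """Return a copy with SNPs (and call columns) sorted by (chromosome, position)."""
        keys = [chrom_sort_key(c) for c in self.snps["chromosome"]]
        order = np.array(
            sorted(range(self.n_snps), key=lambda i: (keys[i], int(self.snps["position_bp"].iat[i]))),
            dtype=np.intp,
        )
        return GenotypeDataset(
            samples=self.samples.reset_index(drop=True),
            snps=self.snps.iloc[order].reset_index(drop=True),
            calls=np.ascontiguousarray(self.calls[:, order]),
        )

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Restrict to the given positional sample/SNP indices (order preserved)."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            samples=self.samples.iloc[si].reset_index(drop=True),
            snps=self.snps.iloc[vi].reset_index(drop=True),
            calls=np.ascontiguousarray(self.calls[np.ix_(si, vi)]),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


def make_dataset(
    sample_ids: Sequence[str],
    snps: Iterable[SnpRecord] | pd.DataFrame,
    calls: np.ndarray,
    populations: Sequence[str] | None = None,
    sexes: Sequence[int] | None = None,
    sort: bool = True,
) -> GenotypeDataset:
    """Assemble and validate a :class:`GenotypeDataset` from plain pieces."""
    samples = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "population": list(populations) if populations is not None else ["pop"] * len(sample_ids),
            "sex": np.asarray(sexes, dtype=np.int8) if sexes is not None else np.zeros(len(sample_ids), np.int8),
        }
    )
    if isinstance(snps, pd.DataFrame):
        snp_df = snps.reset_index(drop=True).copy()
    else:
        snp_df = pd.DataFrame(
            [(r.snp_id, r.chromosome, r.position_bp, r.allele_a1, r.allele_a2) for r in snps],
            columns=["snp_id", "chromosome", "position_bp", "allele_a1", "allele_a2"],
        )
    snp_df["chromosome"] = snp_df["chromosome"].astype(str)
    snp_df["position_bp"] = snp_df["position_bp"].astype(np.int64)
    ds = GenotypeDataset(samples=samples, snps=snp_df, calls=np.asarray(calls, dtype=np.int8))
    if sort:
        ds = ds.sorted_by_map()
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# PLINK text dialect (.ped / .map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a .ped/.map pair into a :class:`GenotypeDataset`.

    A1 of each SNP is the first allele symbol encountered scanning samples in
    file order (the text dialect carries no allele metadata); "0 0" pairs are
    missing. SNPs are re-sorted by (chromosome, position) on return.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)

    sample_rows = []
    geno_rows = []
    # per-SNP observed alleles, in first-seen order
    seen: list[list[str]] = [[] for _ in range(n_snps)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns, got {len(parts)}"
                )
            fid, iid, _pat, _mat, sex, _pheno = parts[:6]
            alleles = parts[6:]
            pair_rows = []
            for k in range(n_snps):
                a, b = alleles[2 * k], alleles[2 * k + 1]
                for al in (a, b):
                    if al not in VALID_ALLELES:
                        raise FormatError(
                            f"{ped_path}:{lineno}: invalid allele symbol {al!r} at SNP #{k + 1}"
                        )
                    if al != "0" and al not in seen[k]:
                        seen[k].append(al)
                pair_rows.append((a, b))
            sample_rows.append((iid, fid, int(sex) if sex in ("0", "1", "2") else 0))
            geno_rows.append(pair_rows)

    calls = np.full((len(sample_rows), n_snps), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    for k in range(n_snps):
        obs = seen[k]
        a1 = obs[0] if obs else "0"
        a2 = obs[1] if len(obs) > 1 else "0"
        a1s.append(a1)
        a2s.append(a2)
        for i, pair_rows in enumerate(geno_rows):
            a, b = pair_rows[k]
            if a == "0" or b == "0":
                continue
            calls[i, k] = (a == a1) + (b == a1)
    snp_df = pd.DataFrame(
        {
            "snp_id": [r[1] for r in map_rows],
            "chromosome": [r[0] for r in map_rows],
            "position_bp": np.array([r[2] for r in map_rows], dtype=np.int64),
            "allele_a1": a1s,
            "allele_a2": a2s,
        }
    )
    return make_dataset(
        sample_ids=[r[0] for r in sample_rows],
        snps=snp_df,
        calls=calls,
        populations=[r[1] for r in sample_rows],
        sexes=[r[2] for r in sample_rows],
    )


def write_plink_text(ds: GenotypeDataset, prefix) -> tuple[Path, Path]:
    """Write a .ped/.map pair (readable back by :func:`read_plink_text`)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = plink_path(prefix, ".map")
    ped_path = plink_path(prefix, ".ped")
    with open(map_path, "w") as fh:
        for r in ds.snps.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(ds.samples.itertuples(index=False)):
            cols = [str(s.population), str(s.sample_id), "0", "0", str(int(s.sex)), "-9"]
            for k in range(ds.n_snps):
                g = ds.calls[i, k]
                a1 = ds.snps["allele_a1"].iat[k]
                a2 = ds.snps["allele_a2"].iat[k]
                if g == MISSING:
                    cols += ["0", "0"]
                elif g == 2:
                    cols += [a1, a1]
                elif g == 1:
                    cols += [a1, a2]
                else:
                    cols += [a2, a2]
            fh.write(" ".join(cols) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# PLINK binary dialect (.bed / .bim / .fam), SNP-major
# ---------------------------------------------------------------------------

def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a SNP-major .bed/.bim/.fam triplet; same contract as the text reader."""
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele_a1", "allele_a2"],
        dtype={"chromosome": str, "snp_id": str, "allele_a1": str, "allele_a2": str},
    )
    n_samples, n_snps = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not a PLINK .bed file)")
    if raw[2:3] != SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n_samples + 3) // 4
    expect = 3 + bytes_per_snp * n_snps
    if len(raw) != expect:
        raise FormatError(f"{bed_path}: expected {expect} bytes, found {len(raw)} (truncated?)")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    # unpack two-bit codes, LSB-first within each byte
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    calls = _BED_TO_CODE[codes[:, :n_samples]].T  # (n_samples, n_snps)
    return make_dataset(
        sample_ids=fam["iid"].tolist(),
        snps=bim[["snp_id", "chromosome", "position_bp", "allele_a1", "allele_a2"]],
        calls=np.ascontiguousarray(calls),
        populations=fam["fid"].tolist(),
        sexes=[int(s) if s in ("0", "1", "2") else 0 for s in fam["sex"]],
    )


def write_plink_binary(ds: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write a SNP-major .bed/.bim/.fam triplet readable by stock PLINK."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = plink_path(prefix, ".bed")
    bim_path = plink_path(prefix, ".bim")
    fam_path = plink_path(prefix, ".fam")
    with open(fam_path, "w") as fh:
        for s in ds.samples.itertuples(index=False):
            fh.write(f"{s.population}\t{s.sample_id}\t0\t0\t{int(s.sex)}\t-9\n")
    with open(bim_path, "w") as fh:
        for r in ds.snps.itertuples(index=False):
            fh.write(
                f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\t{r.allele_a1}\t{r.allele_a2}\n"
            )
    n_samples = ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    two_bits = np.empty(ds.calls.shape, dtype=np.uint8)
    for code, tb in _CODE_TO_BED.items():
        two_bits[ds.calls == code] = tb
    padded = np.full((ds.n_snps, bytes_per_snp * 4), _CODE_TO_BED[0], dtype=np.uint8)
    padded[:, :n_samples] = two_bits.T
    # PLINK pads trailing sample slots with zeros (hom A1 two-bit 00)
    padded[:, n_samples:] = 0
    out = np.zeros((ds.n_snps, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        out |= padded[:, shift::4] << (2 * shift)
    with open(bed_path, "wb") as fh:
        fh.write(BED_MAGIC + SNP_MAJOR)
        fh.write(out.tobytes())
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeTable:
    """Pedigree records with a single unknown-parent sentinel.

    ``table`` has columns animal, sire, dam, sex, birth_year (all ids as str).
    """

    table: pd.DataFrame
    sentinel: str = "0"
    _order: list[str] = field(default_factory=list, repr=False)

    @property
    def animals(self) -> list[str]:
        return self.table["animal"].tolist()

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        """animal -> (sire, dam), with None for the sentinel or absent parent."""
        out = {}
        for r in self.table.itertuples(index=False):
            sire = None if r.sire == self.sentinel else r.sire
            dam = None if r.dam == self.sentinel else r.dam
            out[r.animal] = (sire, dam)
        return out

    def topological_order(self) -> list[str]:
        """Animals ordered parents-before-offspring (computed at load time)."""
        return list(self._order)


def _toposort(parents: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Kahn's algorithm over parent->offspring edges; raises on a cycle."""
    known = set(parents)
    indeg = {a: sum(1 for p in ps if p is not None and p in known) for a, ps in parents.items()}
    children: dict[str, list[str]] = {a: [] for a in parents}
    for a, ps in parents.items():
        for p in ps:
            if p is not None and p in known:
                children[p].append(a)
    queue = sorted(a for a, d in indeg.items() if d == 0)
    order = []
    while queue:
        a = queue.pop()
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(parents):
        cycle = _find_cycle(parents, set(parents) - set(order))
        raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
    return order


def _find_cycle(parents, candidates) -> list[str]:
    start = sorted(candidates)[0]
    seen: dict[str, int] = {}
    path = []
    node = start
    while node is not None and node not in seen:
        seen[node] = len(path)
        path.append(node)
        sire, dam = parents.get(node, (None, None))
        node = sire if sire in candidates else (dam if dam in candidates else None)
    if node is None:  # pragma: no cover - defensive
        return [start]
    return path[seen[node]:] + [node]


def read_pedigree(path, sentinel: str = "0") -> PedigreeTable:
    """Read a delimited pedigree with header animal,sire,dam,sex,birth_year.

    Acyclicity is verified eagerly; parents named without a record of their own
    are accepted (treated as base animals by downstream consumers).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["animal", "sire", "dam", "sex", "birth_year"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PedigreeError(f"{path}: missing pedigree columns {missing_cols}")
    df = df[required].copy()
    return make_pedigree(df, sentinel=sentinel)


def make_pedigree(df: pd.DataFrame, sentinel: str = "0") -> PedigreeTable:
    """Validate a pedigree frame (unique ids, acyclic) and freeze a topological order."""
    df = df.copy()
    for col in ("animal", "sire", "dam"):
        df[col] = df[col].astype(str)
    if df["animal"].duplicated().any():
        dup = df["animal"][df["animal"].duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup!r}")
    ped = PedigreeTable(table=df.reset_index(drop=True), sentinel=sentinel)
    ped._order = _toposort(ped.parents())
    return ped


def write_pedigree(ped: PedigreeTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ped.table.to_csv(path, sep="\t", index=False)
    return path
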