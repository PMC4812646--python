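from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pigdiv.io_formats import GenotypeDataset, make_dataset, make_pedigree


def build_dataset(
    calls,
    chromosomes=None,
    positions=None,
    populations=None,
    sexes=None,
    a1="A",
    a2="G",
):
    """Small-dataset builder: calls is an (n_samples, n_snps) array-like."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chromosomes is None:
        chromosomes = ["1"] * m
    if positions is None:
        positions = [(k + 1) * 1000 for k in range(m)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{k}" for k in range(m)],
            "chromosome": [str(c) for c in chromosomes],
            "position_bp": positions,
            "allele_a1": [a1] * m,
            "allele_a2": [a2] * m,
        }
    )
    return make_dataset(
        sample_ids=[f"s{i}" for i in range(n)],
        snps=snps,
        calls=calls,
        populations=populations,
        sexes=sexes,
    )


def build_pedigree(rows):
    """rows: iterable of (animal, sire, dam) or (animal, sire, dam, sex, year)."""
    full = []
    for r in rows:
        if len(r) == 3:
            full.append((*r, 0, 2000))
        else:
            full.append(tuple(r))
    df = pd.DataFrame(full, columns=["animal", "sire", "dam", "sex", "birth_year"])
    return make_pedigree(df)


def random_pedigree(rng, n_generations=4, per_generation=8):
    """Generation-structured random pedigree (parents from previous generation)."""
    rows = []
    prev: list[tuple[str, int]] = []
    idx = 0
    for g in range(n_generations + 1):
        cur = []
        for k in range(per_generation):
            aid = f"a{idx}"
            idx += 1
            sex = 1 if k % 2 == 0 else 2
            if g == 0:
                rows.append((aid, "0", "0", sex, g))
            else:
                males = [a for a, s in prev if s == 1]
                females = [a for a, s in prev if s == 2]
                rows.append((aid, males[rng.integers(len(males))], females[rng.integers(len(females))], sex, g))
            cur.append((aid, sex))
        prev = cur
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "birth_year"])
    return make_pedigree(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def small_sim():
    """A small cached Wright-Fisher run shared by several tests."""
    from pigdiv import synthetic

    cfg = synthetic.SimConfig(
        seed=11, n_generations=8, pop_size=24, n_chromosomes=2,
        chrom_length_morgan=0.5, n_snps=400,
    )
    return synthetic.simulate(cfg)
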