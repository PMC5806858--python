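"""Shared fixtures: programmatic panel builders (no stored data files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chickld.genotype_io import BIM_COLUMNS, FAM_COLUMNS, MISSING, GenotypeDataset


def make_dataset(
    calls: np.ndarray,
    chroms: list[str] | None = None,
    bps: list[int] | None = None,
    fids: list[str] | None = None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from a raw calls matrix with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chroms = chroms or ["1"] * m
    bps = bps or list(range(1, m + 1))
    fids = fids or ["FAM"] * n
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "id": [f"v{j}" for j in range(m)],
            "cm": 0.0,
            "bp": bps,
            "allele1": "A",
            "allele2": "B",
        }
    )[BIM_COLUMNS]
    samples = pd.DataFrame(
        {
            "fid": fids,
            "iid": [f"s{i}" for i in range(n)],
            "father": "0",
            "mother": "0",
            "sex": 1,
            "phenotype": -9,
        }
    )[FAM_COLUMNS]
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


def random_dataset(
    n_samples: int,
    n_variants: int,
    seed: int,
    missing_rate: float = 0.0,
    n_chromosomes: int = 1,
) -> GenotypeDataset:
    """Random Hardy-Weinberg-ish panel for format and oracle round-trips."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, size=n_variants)
    calls = (rng.random((n_samples, n_variants)) < freqs).astype(np.int8) + (
        rng.random((n_samples, n_variants)) < freqs
    ).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n_samples, n_variants)) < missing_rate] = MISSING
    per = n_variants // n_chromosomes
    chroms = [str(1 + min(j // max(per, 1), n_chromosomes - 1)) for j in range(n_variants)]
    bps = []
    pos = 0
    prev = chroms[0]
    for c in chroms:
        pos = pos + rng.integers(1, 1000) if c == prev else rng.integers(1, 1000)
        prev = c
        bps.append(int(pos))
    return make_dataset(calls, chroms=chroms, bps=bps)


@pytest.fixture(scope="session")
def small_panel() -> GenotypeDataset:
    return random_dataset(20, 60, seed=11, missing_rate=0.05, n_chromosomes=3)
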