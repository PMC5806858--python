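"""Seeded Wright–Fisher forward simulator for multi-line SNP panels.

The simulator produces diploid biallelic panels whose within-chromosome LD
decays with genetic distance according to a known, constant true Ne — the
ground truth the LD → Ne pipeline is validated against.  The model is the
idealised population the Sved relationship assumes:

* discrete non-overlapping generations of N diploids;
* each offspring draws two parents uniformly with replacement;
* each gamete recombines the parent's two haplotypes with a
  Poisson(map length in Morgans) crossover count at uniform positions;
* no mutation: segregating sites are standing variation in the founder
  generation, with allele frequencies drawn from a uniform window (an
  array-ascertainment-like spectrum), and sites may later fix (QC removes
  monomorphic markers downstream, as it would on a real array).

Multi-line panels come from a shared base population drifted independently
per line, giving the divergence structure MDS/diversity analyses expect.
``inject_qc_defects`` plants call-rate, Hardy-Weinberg and rare-allele
failures at known indices for end-to-end QC accounting tests.

Determinism: one SeedSequence per run, with fixed-order spawned substreams
for the pedigree and each chromosome, so the same config and seed yield a
byte-identical panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chickld.genotype_io import MISSING, FAM_COLUMNS, BIM_COLUMNS, GenotypeDataset
from chickld.ne import GeneticMap
from chickld.qc import hwe_exact_pvalue


@dataclass
class SimConfig:
    """Wright–Fisher run parameters (defaults are the package's reference
    desk-scale conditions; see docs/methods.md for the rationale)."""

    true_ne: int = 100
    n_generations: int = 200
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    recomb_rate_cm_per_mb: float = 3.0
    n_snps_per_chrom: int = 200
    init_freq_low: float = 0.05
    init_freq_high: float = 0.5
    n_sampled_individuals: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.true_ne, self.n_generations, self.n_chromosomes,
               self.chrom_length_bp, self.n_snps_per_chrom,
               self.n_sampled_individuals) <= 0:
            raise ValueError("all counts must be positive")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be non-negative")
        if not 0 < self.init_freq_low <= self.init_freq_high <= 1:
            raise ValueError("founder frequency window must satisfy 0 < low ≤ high ≤ 1")
        if self.n_sampled_individuals > self.true_ne:
            raise ValueError("cannot sample more individuals than the population holds")

    @property
    def map_length_morgans(self) -> float:
        return self.chrom_length_bp / 1e6 * self.recomb_rate_cm_per_mb / 100.0


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    config: SimConfig
    genetic_map: GeneticMap
    founder_freqs: list[np.ndarray]
    positions: list[np.ndarray]
    per_line_ne: dict[str, float] = field(default_factory=dict)


def _spawn_streams(seed: int, n_chromosomes: int) -> tuple[np.random.Generator, list[np.random.Generator]]:
    """Pedigree stream + one stream per chromosome, in fixed spawn order."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chromosomes + 1)
    return (
        np.random.default_rng(children[0]),
        [np.random.default_rng(c) for c in children[1:]],
    )


def _founder_haplotypes(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(haplotypes (2N, m), positions (m,), founder freqs (m,)) for one chromosome."""
    m = cfg.n_snps_per_chrom
    pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp + 1), size=m, replace=False))
    freqs = rng.uniform(cfg.init_freq_low, cfg.init_freq_high, size=m)
    haps = (rng.random((2 * cfg.true_ne, m)) < freqs).astype(np.uint8)
    return haps, pos, freqs


def _recombine(
    haps: np.ndarray,
    parents: np.ndarray,
    pos: np.ndarray,
    map_len: float,
    chrom_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per row of ``parents`` (parent individual indices).

    Crossover counts are Poisson(map_len); positions uniform on the
    chromosome; the transmitted haplotype switches parity at each
    crossover, starting from a random parental haplotype.
    """
    g = len(parents)
    m = len(pos)
    start = rng.integers(0, 2, size=g)
    k = rng.poisson(map_len, size=g) if map_len > 0 else np.zeros(g, dtype=np.int64)
    max_k = int(k.max()) if g else 0
    if max_k == 0:
        phase = np.broadcast_to(start[:, None], (g, m))
    else:
        xpos = rng.uniform(0, chrom_len, size=(g, max_k))
        valid = np.arange(max_k)[None, :] < k[:, None]
        xpos = np.where(valid, xpos, np.inf)
        # crossovers strictly before each SNP flip the transmitted strand
        n_before = (xpos[:, :, None] < pos[None, None, :]).sum(axis=1)
        phase = (start[:, None] + n_before) % 2
    hap_a = haps[2 * parents]
    hap_b = haps[2 * parents + 1]
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def _drift(
    chrom_haps: list[np.ndarray],
    positions: list[np.ndarray],
    cfg: SimConfig,
    n_generations: int,
    ne: int,
    rng_ped: np.random.Generator,
    rng_chrom: list[np.random.Generator],
) -> list[np.ndarray]:
    """Evolve all chromosomes for ``n_generations`` at diploid size ``ne``.

    The pedigree (parent choices) is drawn once per generation from the
    pedigree stream and shared across chromosomes, so linkage between
    chromosomes reflects co-inheritance through individuals, exactly as in
    a real pedigree.
    """
    haps = [h.copy() for h in chrom_haps]
    current_n = haps[0].shape[0] // 2
    for _ in range(n_generations):
        mothers = rng_ped.integers(0, current_n, size=ne)
        fathers = rng_ped.integers(0, current_n, size=ne)
        for c, (h, pos) in enumerate(zip(haps, positions)):
            gam_m = _recombine(h, mothers, pos, cfg.map_length_morgans, cfg.chrom_length_bp, rng_chrom[c])
            gam_f = _recombine(h, fathers, pos, cfg.map_length_morgans, cfg.chrom_length_bp, rng_chrom[c])
            nxt = np.empty((2 * ne, h.shape[1]), dtype=np.uint8)
            nxt[0::2] = gam_m
            nxt[1::2] = gam_f
            haps[c] = nxt
        current_n = ne
    return haps


def _panel_from_haplotypes(
    chrom_haps: list[np.ndarray],
    positions: list[np.ndarray],
    cfg: SimConfig,
    sample_idx: np.ndarray,
    fid: str,
    iid_prefix: str,
) -> GenotypeDataset:
    calls = np.concatenate(
        [h[2 * sample_idx] + h[2 * sample_idx + 1] for h in chrom_haps], axis=1
    ).astype(np.int8)
    variants = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": str(c + 1),
                    "id": [f"snp_{c + 1}_{k + 1}" for k in range(len(pos))],
                    "cm": pos / 1e6 * cfg.recomb_rate_cm_per_mb,
                    "bp": pos,
                    "allele1": "A",
                    "allele2": "B",
                }
            )
            for c, pos in enumerate(positions)
        ],
        ignore_index=True,
    )
    samples = pd.DataFrame(
        {
            "fid": fid,
            "iid": [f"{iid_prefix}{i + 1}" for i in range(len(sample_idx))],
            "father": "0",
            "mother": "0",
            "sex": 1,
            "phenotype": -9,
        }
    )[FAM_COLUMNS]
    return GenotypeDataset(samples=samples, variants=variants[BIM_COLUMNS], calls=calls)


def _genetic_map(cfg: SimConfig) -> GeneticMap:
    cm = cfg.chrom_length_bp / 1e6 * cfg.recomb_rate_cm_per_mb
    return GeneticMap(
        chrom_lengths={str(c + 1): (cfg.chrom_length_bp, cm) for c in range(cfg.n_chromosomes)}
    )


def simulate_population(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Run the Wright–Fisher model and sample a genotyped panel.

    Returns the sampled panel (one line, fid "SIM") and the ground truth
    (true Ne, genetic map, founder frequencies, marker positions).
    """
    rng_ped, rng_chrom = _spawn_streams(cfg.seed, cfg.n_chromosomes)
    haps, positions, freqs = [], [], []
    for c in range(cfg.n_chromosomes):
        h, pos, f = _founder_haplotypes(cfg, rng_chrom[c])
        haps.append(h)
        positions.append(pos)
        freqs.append(f)
    haps = _drift(haps, positions, cfg, cfg.n_generations, cfg.true_ne, rng_ped, rng_chrom)
    sample_idx = np.sort(
        rng_ped.choice(cfg.true_ne, size=cfg.n_sampled_individuals, replace=False)
    )
    ds = _panel_from_haplotypes(haps, positions, cfg, sample_idx, "SIM", "ind")
    truth = SimTruth(
        config=cfg,
        genetic_map=_genetic_map(cfg),
        founder_freqs=freqs,
        positions=positions,
        per_line_ne={"SIM": float(cfg.true_ne)},
    )
    return ds.sort_variants(), truth


def diverge_lines(
    cfg: SimConfig,
    n_lines: int,
    divergence_generations: int,
    line_sizes: list[int] | None = None,
    line_ne: list[int] | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Multi-line panel: one base population drifted independently per line.

    Each line runs ``divergence_generations`` further Wright–Fisher
    generations at its own size (default: the base true_ne) from the state
    the base reached after ``cfg.n_generations``; ``line_sizes[i]``
    individuals are then sampled per line (default
    ``cfg.n_sampled_individuals``).  fids are "L01", "L02", ...
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    line_sizes = line_sizes or [cfg.n_sampled_individuals] * n_lines
    line_ne = line_ne or [cfg.true_ne] * n_lines
    if len(line_sizes) != n_lines or len(line_ne) != n_lines:
        raise ValueError("line_sizes / line_ne must have one entry per line")

    rng_ped, rng_chrom = _spawn_streams(cfg.seed, cfg.n_chromosomes)
    base, positions, freqs = [], [], []
    for c in range(cfg.n_chromosomes):
        h, pos, f = _founder_haplotypes(cfg, rng_chrom[c])
        base.append(h)
        positions.append(pos)
        freqs.append(f)
    base = _drift(base, positions, cfg, cfg.n_generations, cfg.true_ne, rng_ped, rng_chrom)

    parts: list[GenotypeDataset] = []
    truth_ne: dict[str, float] = {}
    for li in range(n_lines):
        label = f"L{li + 1:02d}"
        # fixed-order substreams per line keep the panel reproducible and
        # independent of how many lines follow
        ss = np.random.SeedSequence((cfg.seed, 7919, li))
        kids = ss.spawn(cfg.n_chromosomes + 1)
        l_ped = np.random.default_rng(kids[0])
        l_chrom = [np.random.default_rng(k) for k in kids[1:]]
        ne_i = int(line_ne[li])
        if divergence_generations > 0:
            line_haps = _drift(base, positions, cfg, divergence_generations, ne_i, l_ped, l_chrom)
        else:
            line_haps = base
        pool = line_haps[0].shape[0] // 2
        if line_sizes[li] > pool:
            raise ValueError(f"line {label}: cannot sample {line_sizes[li]} of {pool}")
        idx = np.sort(l_ped.choice(pool, size=line_sizes[li], replace=False))
        parts.append(_panel_from_haplotypes(line_haps, positions, cfg, idx, label, f"{label}_"))
        truth_ne[label] = float(ne_i)

    ds = GenotypeDataset(
        samples=pd.concat([p.samples for p in parts], ignore_index=True),
        variants=parts[0].variants,
        calls=np.concatenate([p.calls for p in parts], axis=0),
    )
    truth = SimTruth(
        config=cfg,
        genetic_map=_genetic_map(cfg),
        founder_freqs=freqs,
        positions=positions,
        per_line_ne=truth_ne,
    )
    return ds.sort_variants(), truth


@dataclass
class PlantedDefects:
    low_call_rate: np.ndarray
    hwe_violating: np.ndarray
    rare_allele: np.ndarray


def inject_qc_defects(
    ds: GenotypeDataset,
    n_low_callrate: int,
    n_hwe_violating: int,
    n_rare: int,
    seed: int,
) -> tuple[GenotypeDataset, PlantedDefects]:
    """Mutate disjoint random variants so each fails exactly one QC filter.

    * call-rate defects: genotypes rewritten to a perfect Hardy-Weinberg
      pattern, then just over 10% of samples masked (call rate < 0.90);
    * Hardy-Weinberg defects: every sample heterozygous (maximal
      heterozygote excess; requires enough samples for p < 1e-4);
    * rare-allele defects: at most one heterozygote, rest homozygous
      (MAF < 0.01).

    Returns the modified copy plus the planted index lists.
    """
    total = n_low_callrate + n_hwe_violating + n_rare
    if total > ds.n_variants:
        raise ValueError("more defects requested than variants available")
    n = ds.n_samples
    if n_hwe_violating and hwe_exact_pvalue(0, n, 0) >= 1e-4:
        raise ValueError(f"{n} samples cannot produce a Hardy-Weinberg exact p < 1e-4")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(ds.n_variants, size=total, replace=False)
    low_cr = np.sort(chosen[:n_low_callrate])
    hwe_bad = np.sort(chosen[n_low_callrate:n_low_callrate + n_hwe_violating])
    rare = np.sort(chosen[n_low_callrate + n_hwe_violating:])

    calls = ds.calls.copy()
    hwe_ok_pattern = np.resize(np.array([0, 1, 2, 1], dtype=np.int8), n)
    n_mask = int(np.floor(0.10 * n)) + 1  # strictly below the 0.90 threshold
    for v in low_cr:
        calls[:, v] = hwe_ok_pattern
        calls[rng.choice(n, size=n_mask, replace=False), v] = MISSING
    for v in hwe_bad:
        calls[:, v] = 1
    for v in rare:
        calls[:, v] = 0
        if 1 / (2 * n) < 0.01:  # keep the marker segregating when possible
            calls[rng.integers(0, n), v] = 1

    out = GenotypeDataset(samples=ds.samples, variants=ds.variants, calls=calls)
    return out, PlantedDefects(low_call_rate=low_cr, hwe_violating=hwe_bad, rare_allele=rare)
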