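"""Reference simulation experiments validating the LD → Ne pipeline.

These are the package's reproducible study designs: each function runs the
Wright–Fisher generator under fixed conditions, pushes the panels through
the same QC/LD/Ne code paths a real analysis uses, and returns the
quantities of interest.  The acceptance tests and the analysis drivers
both call these, so the numbers they report come from one implementation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from chickld.genotype_io import GenotypeDataset, split_by_line, subset
from chickld.ld import bin_ld_by_distance, pairwise_ld_scan
from chickld.ne import fit_ne_nls
from chickld.synthetic_data import SimConfig, diverge_lines, simulate_population

#: Reference recovery conditions: 50 sampled diploids, 200 SNPs on each of
#: 5 chromosomes, 200 generations of drift at the target Ne.
RECOVERY_CONFIG = SimConfig()


def fit_ne_from_panel(
    ds: GenotypeDataset,
    truth_rate_cm_per_mb: float,
    n_generations: int,
    max_dist_bp: float = 1_000_000,
    sample_correction: bool = True,
) -> float:
    """Fit a single Ne to a panel's pairwise r² decay.

    Pairs are converted to genetic distance with the simulation's uniform
    recombination rate and restricted to c ≥ 1/n_generations, i.e. to
    epochs t = 1/(2c) ≤ n_generations/2.  LD at distance c equilibrates
    with time constant ≈ 1/(2c + 1/(2Ne)); shorter-range pairs reflect
    history older than the simulation and sit below their equilibrium,
    which would inflate the fitted Ne.  The 1/(2n) sampling inflation
    enters the fitted model when ``sample_correction`` is on.
    """
    pairs = pairwise_ld_scan(ds, max_dist_bp=max_dist_bp)
    rate_m_per_bp = truth_rate_cm_per_mb / 100.0 / 1e6
    c = pairs["dist_bp"].to_numpy() * rate_m_per_bp
    r2 = pairs["r2"].to_numpy()
    ok = ~np.isnan(r2) & (c >= 1.0 / n_generations)
    n_corr = ds.n_samples if sample_correction else None
    ne_hat, _ = fit_ne_nls(c[ok], r2[ok], n_samples=n_corr)
    return ne_hat


def ne_recovery(
    true_ne: int,
    n_replicates: int,
    seed: int,
    base_config: SimConfig = RECOVERY_CONFIG,
) -> list[float]:
    """Fitted Ne per replicate under the reference recovery conditions."""
    out = []
    for rep in range(n_replicates):
        cfg = replace(base_config, true_ne=true_ne,
                      n_sampled_individuals=min(base_config.n_sampled_individuals, true_ne),
                      seed=(seed * 100_003 + true_ne * 131 + rep) % (2**31))
        ds, truth = simulate_population(cfg)
        out.append(fit_ne_from_panel(ds, cfg.recomb_rate_cm_per_mb, cfg.n_generations))
    return out


#: Two-line contrast conditions: a larger commercial-style line sampled at
#: n=23 versus a small conserved line (strong drift) sampled at n=6, as in
#: multi-line panels where conserved purebred lines show the most LD.
TWO_LINE_CONFIG = SimConfig(
    true_ne=300,
    n_generations=100,
    n_chromosomes=3,
    chrom_length_bp=2_000_000,
    n_snps_per_chrom=200,
    n_sampled_individuals=23,
)
TWO_LINE_NE = (300, 50)
TWO_LINE_SIZES = (23, 6)


def short_range_ld_contrast(seed: int, window_kb: float = 20.0) -> dict[str, dict]:
    """Mean EM-r² within ``window_kb`` for the two-line contrast panel.

    Returns per-line dicts with mean r², pair count, sample size, true Ne.
    """
    cfg = replace(TWO_LINE_CONFIG, seed=seed % (2**31))
    ds, truth = diverge_lines(
        cfg,
        n_lines=2,
        divergence_generations=50,
        line_sizes=list(TWO_LINE_SIZES),
        line_ne=list(TWO_LINE_NE),
    )
    out: dict[str, dict] = {}
    for line, part in split_by_line(ds).items():
        pairs = pairwise_ld_scan(part, max_dist_bp=window_kb * 1000)
        binned = bin_ld_by_distance(pairs, windows_kb=(window_kb,))
        row = binned.table.iloc[0]
        out[line] = {
            "mean_r2": float(row["mean_r2"]),
            "n_pairs": int(row["n_pairs"]),
            "n_samples": part.n_samples,
            "true_ne": truth.per_line_ne[line],
        }
    return out


def sample_size_inflation(
    seed: int,
    n_small: int = 6,
    n_large: int = 23,
    n_replicates: int = 10,
) -> pd.DataFrame:
    """Mean r² from small vs large subsamples of one population, replicated.

    Finite samples inflate observed r² by roughly 1/(2n), so the small
    subsample's mean should exceed the large one's in essentially every
    replicate.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = SimConfig(true_ne=100, n_generations=100, n_chromosomes=2,
                        chrom_length_bp=2_000_000, n_snps_per_chrom=120,
                        n_sampled_individuals=30,
                        seed=(seed * 99_991 + rep) % (2**31))
        ds, _ = simulate_population(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        idx = rng.permutation(ds.n_samples)
        means = {}
        for label, n in (("small", n_small), ("large", n_large)):
            part = subset(ds, keep_samples=np.sort(idx[:n]))
            pairs = pairwise_ld_scan(part, max_dist_bp=1_000_000)
            means[label] = float(pairs["r2"].mean())
        rows.append({"replicate": rep, "n_small": n_small, "n_large": n_large,
                     "mean_r2_small": means["small"], "mean_r2_large": means["large"]})
    return pd.DataFrame(rows)
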