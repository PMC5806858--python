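"""Pairwise linkage disequilibrium from EM haplotype frequencies.

For a pair of biallelic loci with unphased diploid genotypes, the four
haplotype frequencies p11, p12, p21, p22 (alleles A1/A2 × B1/B2) are not
directly observable: the double heterozygote is an equal-evidence mixture
of the coupling (A1B1 / A2B2) and repulsion (A1B2 / A2B1) phases.  The EM
algorithm resolves this by splitting double heterozygotes between the two
phases in the ratio p11·p22 : p12·p21 at the current estimate and
re-counting, iterated to a fixed point from the linkage-equilibrium start.

LD is then

    D  = p11·p22 − p12·p21
    r² = D² / (pA·(1−pA)·pB·(1−pB))

with pA = p11+p12, pB = p11+p21 the allele-1 frequencies.  r² is invariant
under allele relabelling at either locus and under swapping the loci.

The genome scan pairs every two syntenic markers within a bp window,
builds the 3×3 two-locus genotype table over pairwise-complete samples,
and runs the EM on all pairs at once (vectorised over pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from chickld.genotype_io import MISSING, GenotypeDataset

DEFAULT_WINDOWS_KB: tuple[float, ...] = (20, 50, 100, 200, 500, 1000)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class HaplotypeFrequencies:
    """Frequencies of the four two-locus haplotypes A1B1, A1B2, A2B1, A2B2."""

    p11: float
    p12: float
    p21: float
    p22: float
    n_iter: int = 0
    converged: bool = True

    @property
    def freq_a1(self) -> float:
        return self.p11 + self.p12

    @property
    def freq_b1(self) -> float:
        return self.p11 + self.p21

    @property
    def d(self) -> float:
        """Gametic disequilibrium coefficient D."""
        return self.p11 * self.p22 - self.p12 * self.p21

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p21, self.p22])


def two_locus_counts(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """3×3 table n[gA][gB] of samples by genotype pair, missing excluded."""
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    for ga, gb in zip(calls_a[ok], calls_b[ok]):
        table[ga, gb] += 1
    return table


def _known_haplotype_counts(n: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Determinate haplotype counts plus the double-heterozygote count.

    ``n`` has shape (..., 3, 3) indexed by copies of A1 × copies of B1.
    Every genotype class except (1,1) resolves unambiguously: e.g. an
    A1A1 × B1B2 individual carries one A1B1 and one A1B2.
    """
    c11 = 2 * n[..., 2, 2] + n[..., 2, 1] + n[..., 1, 2]
    c12 = 2 * n[..., 2, 0] + n[..., 2, 1] + n[..., 1, 0]
    c21 = 2 * n[..., 0, 2] + n[..., 0, 1] + n[..., 1, 2]
    c22 = 2 * n[..., 0, 0] + n[..., 0, 1] + n[..., 1, 0]
    n_dh = n[..., 1, 1]
    return c11, c12, c21, c22, n_dh


def _em_iterate(n: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over tables ``n`` of shape (..., 3, 3).

    Returns (p of shape (..., 4) in order p11,p12,p21,p22, iteration count,
    converged flag).  Initialisation is the linkage-equilibrium product of
    the observed allele frequencies, which makes the first E-step split
    double heterozygotes 50:50 when D=0 is consistent with the data.
    """
    c11, c12, c21, c22, n_dh = _known_haplotype_counts(n)
    total = n.sum(axis=(-2, -1))
    hap_total = np.maximum(2 * total, 1)

    pa = (c11 + c12 + n_dh) / hap_total  # freq(A1)
    pb = (c11 + c21 + n_dh) / hap_total  # freq(B1)
    p11 = pa * pb
    p12 = pa * (1 - pb)
    p21 = (1 - pa) * pb
    p22 = (1 - pa) * (1 - pb)
    # without double heterozygotes there is no latent data: the MLE is the
    # determinate haplotype count solution, no iteration needed
    closed = n_dh == 0
    p11 = np.where(closed, c11 / hap_total, p11)
    p12 = np.where(closed, c12 / hap_total, p12)
    p21 = np.where(closed, c21 / hap_total, p21)
    p22 = np.where(closed, c22 / hap_total, p22)

    n_iter = np.zeros(total.shape, dtype=np.int64)
    converged = np.ones(total.shape, dtype=bool)
    active = n_dh > 0  # tables without double heterozygotes are closed-form
    if np.any(active):
        converged = ~active
        for it in range(1, max_iter + 1):
            coupling = p11 * p22
            repulsion = p12 * p21
            denom = coupling + repulsion
            # stationary 50:50 split when both phase products vanish
            w = np.where(denom > 0, coupling / np.where(denom > 0, denom, 1.0), 0.5)
            q11 = (c11 + n_dh * w) / hap_total
            q12 = (c12 + n_dh * (1 - w)) / hap_total
            q21 = (c21 + n_dh * (1 - w)) / hap_total
            q22 = (c22 + n_dh * w) / hap_total
            delta = np.max(
                np.stack([abs(q11 - p11), abs(q12 - p12), abs(q21 - p21), abs(q22 - p22)]),
                axis=0,
            )
            p11, p12, p21, p22 = q11, q12, q21, q22
            newly = active & (delta < tol)
            n_iter[newly] = it
            converged |= newly
            active = active & ~newly
            if not np.any(active):
                break
        n_iter[active] = max_iter
    return np.stack([p11, p12, p21, p22], axis=-1), n_iter, converged


def em_haplotype_frequencies(
    counts: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> HaplotypeFrequencies:
    """Maximum-likelihood haplotype frequencies for one 3×3 genotype table.

    The EM fixed point maximises the multinomial likelihood of the nine
    genotype classes under random mating (Hardy-Weinberg pairing of
    haplotypes).  Non-convergence after ``max_iter`` returns the last
    iterate with ``converged=False``.
    """
    n = np.asarray(counts, dtype=np.int64)
    if n.shape != (3, 3):
        raise ValueError("counts must be a 3×3 genotype-pair table")
    if n.sum() < 2:
        raise ValueError("need at least 2 genotyped samples")
    p, n_iter, conv = _em_iterate(n[None, :, :], tol, max_iter)
    return HaplotypeFrequencies(
        p11=float(p[0, 0]),
        p12=float(p[0, 1]),
        p21=float(p[0, 2]),
        p22=float(p[0, 3]),
        n_iter=int(n_iter[0]),
        converged=bool(conv[0]),
    )


def em_log_likelihood(counts: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3×3 table under haplotype frequencies p.

    Genotype-class probabilities are Hardy-Weinberg products of haplotype
    pairs; the double heterozygote sums both phases:
    P(1,1) = 2·p11·p22 + 2·p12·p21.
    """
    p11, p12, p21, p22 = np.asarray(p, dtype=float)
    g = np.empty((3, 3))
    g[2, 2] = p11**2
    g[2, 1] = 2 * p11 * p12
    g[2, 0] = p12**2
    g[1, 2] = 2 * p11 * p21
    g[1, 1] = 2 * p11 * p22 + 2 * p12 * p21
    g[1, 0] = 2 * p12 * p22
    g[0, 2] = p21**2
    g[0, 1] = 2 * p21 * p22
    g[0, 0] = p22**2
    n = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(g), 0.0)
    return float(terms.sum())


def ld_r2(h: HaplotypeFrequencies) -> float:
    """r² = D² / (pA·(1−pA)·pB·(1−pB)); NaN if either locus is monomorphic."""
    pa, pb = h.freq_a1, h.freq_b1
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return float("nan")
    return float(min(1.0, h.d**2 / denom))


def _pair_tables(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """3×3 genotype-pair tables for column sets A × B via indicator matmuls.

    ``calls_a`` is (n_samples, mA), ``calls_b`` (n_samples, mB); returns
    int64 (mA, mB, 3, 3) with missing excluded pairwise.
    """
    ind_a = [(calls_a == g).astype(np.float64) for g in (0, 1, 2)]
    ind_b = [(calls_b == g).astype(np.float64) for g in (0, 1, 2)]
    out = np.empty((calls_a.shape[1], calls_b.shape[1], 3, 3), dtype=np.int64)
    for ga in range(3):
        for gb in range(3):
            out[:, :, ga, gb] = np.rint(ind_a[ga].T @ ind_b[gb]).astype(np.int64)
    return out


def pairwise_ld_scan(
    ds: GenotypeDataset,
    max_dist_bp: float = 1_000_000,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    block_size: int = 512,
) -> pd.DataFrame:
    """r² for every same-chromosome marker pair within ``max_dist_bp``.

    Returns one row per pair: chrom, i, j (positional indices), id_i, id_j,
    bp_i, bp_j, dist_bp, r2.  Pairs where either locus is monomorphic on
    the pairwise-complete samples carry r2 = NaN (skipped, not imputed).
    Variants must be position-sorted (as :func:`read_plink` guarantees).
    """
    frames: list[pd.DataFrame] = []
    variants = ds.variants
    for chrom in variants["chrom"].unique():
        v_idx = np.flatnonzero((variants["chrom"] == chrom).to_numpy())
        bp = variants["bp"].to_numpy()[v_idx]
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"variants on chromosome {chrom} are not position-sorted")
        m = len(v_idx)
        if m < 2:
            continue
        calls = ds.calls[:, v_idx]
        # block the upper triangle to bound memory at ~block_size² tables
        for a0 in range(0, m, block_size):
            a1 = min(a0 + block_size, m)
            # partners of block columns never sit further than max_dist_bp ahead
            b1 = int(np.searchsorted(bp, bp[a1 - 1] + max_dist_bp, side="right"))
            tables = _pair_tables(calls[:, a0:a1], calls[:, a0:b1])
            ii, jj = np.meshgrid(np.arange(a0, a1), np.arange(a0, b1), indexing="ij")
            dist = np.abs(bp[jj] - bp[ii]).astype(np.int64)
            keep = (jj > ii) & (dist <= max_dist_bp)
            if not keep.any():
                continue
            t = tables[keep]
            p, _, _ = _em_iterate(t, tol, max_iter)
            r2 = _r2_from_p(p)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "i": v_idx[ii[keep]],
                        "j": v_idx[jj[keep]],
                        "bp_i": bp[ii[keep]],
                        "bp_j": bp[jj[keep]],
                        "dist_bp": dist[keep],
                        "r2": r2,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "i", "j", "bp_i", "bp_j", "dist_bp", "r2", "id_i", "id_j"]
        )
    pairs = pd.concat(frames, ignore_index=True)
    ids = ds.variants["id"].to_numpy()
    pairs["id_i"] = ids[pairs["i"]]
    pairs["id_j"] = ids[pairs["j"]]
    return pairs


def _r2_from_p(p: np.ndarray) -> np.ndarray:
    """Vectorised r² from haplotype-frequency rows (..., 4)."""
    p11, p12, p21, p22 = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    pa = p11 + p12
    pb = p11 + p21
    d = p11 * p22 - p12 * p21
    denom = pa * (1 - pa) * pb * (1 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d**2 / np.where(denom > 0, denom, 1.0), np.nan)
    return np.minimum(r2, 1.0)


@dataclass
class BinnedLD:
    """Window-aggregated mean r².

    ``table`` has one row per window upper bound (kb): mean_r2, n_pairs.
    ``average`` is the unweighted mean of the per-window means (the
    "Average" column of line-by-window LD tables).  ``mode`` is
    "cumulative" (pairs with dist ≤ W) or "disjoint" ((W_prev, W]).
    """

    table: pd.DataFrame
    average: float
    mode: str


def bin_ld_by_distance(
    pairs: pd.DataFrame,
    windows_kb: tuple[float, ...] = DEFAULT_WINDOWS_KB,
    mode: str = "cumulative",
) -> BinnedLD:
    """Mean r² per distance window; NaN-r² (skipped) pairs are excluded."""
    if mode not in ("cumulative", "disjoint"):
        raise ValueError("mode must be 'cumulative' or 'disjoint'")
    if len(pairs) == 0:
        raise ValueError("no pairs to bin")
    windows = sorted(float(w) for w in windows_kb)
    ok = pairs["r2"].notna()
    dist_kb = pairs["dist_bp"].to_numpy() / 1000.0
    r2 = pairs["r2"].to_numpy()
    rows = []
    prev = 0.0
    for w in windows:
        if mode == "cumulative":
            sel = ok & (dist_kb <= w)
        else:
            sel = ok & (dist_kb > prev) & (dist_kb <= w)
            prev = w
        n = int(sel.sum())
        mean = float(r2[sel].mean()) if n else float("nan")
        rows.append((w, mean, n))
    table = pd.DataFrame(rows, columns=["window_kb", "mean_r2", "n_pairs"])
    means = table["mean_r2"].dropna()
    average = float(means.mean()) if len(means) else float("nan")
    return BinnedLD(table=table, average=average, mode=mode)


def decay_regression(pairs: pd.DataFrame):
    """OLS of r² on bp distance (the r² ~ distance decay model).

    Returns scipy's linregress result (slope per bp, intercept, rvalue,
    pvalue, stderr).
    """
    ok = pairs["r2"].notna()
    x = pairs.loc[ok, "dist_bp"].to_numpy(dtype=float)
    y = pairs.loc[ok, "r2"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("decay regression needs ≥2 distinct distances")
    return stats.linregress(x, y)


def ld_profile_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation of two populations' binned mean-r² profiles.

    Profiles must sit on the same distance grid with ≥3 points; a
    zero-variance profile makes the correlation undefined (NaN).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share one distance grid")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need ≥3 shared profile points")
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def composite_r2(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages (composite LD).

    Alternative to EM-based r² for sensitivity checks; equals the EM value
    when the sample is in Hardy-Weinberg phase equilibrium.
    """
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    a = calls_a[ok].astype(float)
    b = calls_b[ok].astype(float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)
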