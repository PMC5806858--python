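"""Identity-by-state distances and classical multidimensional scaling.

Per-locus IBS similarity between two diploids is (shared alleles)/2:
1 for identical genotypes, 0.5 when they differ by one allele copy, 0 for
opposite homozygotes.  The distance is 1 minus the mean similarity over
pairwise-complete loci.  Classical (metric) MDS double-centres the squared
distance matrix and embeds samples on the top-k eigenvectors scaled by the
square roots of their eigenvalues; negative eigenvalues (non-Euclidean
residual) are truncated and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chickld.genotype_io import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        self.values = v


@dataclass
class MDSResult:
    labels: list[str]
    coordinates: np.ndarray  # (n_samples, k), axes by decreasing eigenvalue
    eigenvalues: np.ndarray  # all n eigenvalues, decreasing
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        cols = {f"C{d + 1}": self.coordinates[:, d] for d in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample": self.labels, **cols})


def ibs_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise 1 − IBS distances over pairwise-complete variants.

    A sample pair sharing no non-missing variant has undefined distance
    (NaN).  Computed with per-genotype indicator matmuls, so cost is
    O(n² m) in matrix arithmetic rather than a Python pair loop.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    inds = [(ds.calls == g).astype(np.float64) for g in (0, 1, 2)]
    n_shared = np.zeros((ds.n_samples, ds.n_samples))
    dist_sum = np.zeros((ds.n_samples, ds.n_samples))
    for ga in range(3):
        for gb in range(3):
            cross = inds[ga] @ inds[gb].T
            n_shared += cross
            dist_sum += cross * (abs(ga - gb) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_shared > 0, dist_sum / np.maximum(n_shared, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    labels = [f"{f}:{i}" for f, i in zip(ds.samples["fid"], ds.samples["iid"])]
    return DistanceMatrix(labels=labels, values=d)


def classical_mds(dist: DistanceMatrix, k: int = 4) -> MDSResult:
    """Metric MDS by eigendecomposition of the double-centred Gram matrix.

    B = −½·J·D²·J with J = I − 11ᵀ/n; coordinates are the top-k
    eigenvectors of B scaled by sqrt(max(eigenvalue, 0)).  Requires
    k < n_samples.
    """
    d = dist.values
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = evals[:k]
    coords = evecs[:, :k] * np.sqrt(np.maximum(top, 0.0))
    return MDSResult(
        labels=dist.labels,
        coordinates=coords,
        eigenvalues=evals,
        n_negative=int((evals < -1e-9 * max(1.0, abs(evals[0]))).sum()),
    )
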