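"""Effective population size from LD via Sved's equation.

Under drift–recombination equilibrium in a closed random-mating population,
the expected squared allele-frequency correlation of two loci at genetic
distance c Morgans is

    E(r²) = 1 / (4·Ne·c + 1)

which inverts to the point estimate

    Ne = (1 / 4c) · (1/r² − 1).

Because LD at distance c equilibrates over roughly 1/(2c) generations, the
estimate at distance c is read as the effective size t = 1/(2c) generations
in the past: short distances probe ancient Ne, long distances recent Ne.
Finite samples inflate observed r² by about 1/(2n) for n diploids; the
correction is available but off by default so uncorrected tables match the
classical usage.

Physical distance converts to Morgans through a per-chromosome linkage map:
c = dist_bp · (map_cM / physical_bp) / 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from chickld.ld import BinnedLD

#: Window (kb) -> linkage distance (cM) preset used for replication-style
#: trajectory tables when no per-chromosome map is supplied.
TABLE_DISTANCE_PRESET_CM: dict[float, float] = {
    20: 0.01,
    50: 0.03,
    100: 0.07,
    200: 0.15,
    600: 0.4,
    800: 0.7,
    1000: 0.9,
}


@dataclass
class GeneticMap:
    """Per-chromosome physical length (bp) and linkage-map length (cM).

    ``preset_window_cm`` optionally maps a distance window (kb) straight to
    an average linkage distance (cM), bypassing per-chromosome ratios; an
    explicit per-chromosome map always takes precedence where both exist.
    """

    chrom_lengths: dict[str, tuple[float, float]] = field(default_factory=dict)
    preset_window_cm: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self.chrom_lengths.items():
            if bp <= 0 or cm < 0:
                raise ValueError(f"chromosome {chrom}: lengths must be positive")

    @classmethod
    def from_table_preset(cls) -> "GeneticMap":
        return cls(preset_window_cm=dict(TABLE_DISTANCE_PRESET_CM))

    def cm_per_mb(self, chrom: str) -> float:
        bp, cm = self.chrom_lengths[chrom]
        return cm / (bp / 1e6)

    def window_to_morgans(self, window_kb: float) -> float:
        """c for a distance window, in Morgans.

        A preset entry (kb → cM) wins; otherwise the window's upper bound
        converts through the mean cM/Mb ratio of the per-chromosome map.
        """
        if window_kb in self.preset_window_cm:
            return self.preset_window_cm[window_kb] / 100.0
        if self.chrom_lengths:
            mean_rate = float(np.mean([self.cm_per_mb(c) for c in self.chrom_lengths]))
            return window_kb / 1000.0 * mean_rate / 100.0
        raise KeyError(f"window {window_kb} kb has no preset linkage distance")


def bp_to_morgans(dist_bp: float, chrom: str, gmap: GeneticMap) -> float:
    """Genetic distance of a bp separation on ``chrom``, in Morgans."""
    if chrom not in gmap.chrom_lengths:
        raise KeyError(f"chromosome {chrom!r} not in genetic map")
    phys_bp, map_cm = gmap.chrom_lengths[chrom]
    return dist_bp * (map_cm / phys_bp) / 100.0


def sved_expected_r2(ne: float, c: float, n_samples: int | None = None) -> float:
    """E(r²) = 1/(4·Ne·c + 1) at genetic distance c Morgans.

    ``n_samples`` adds the finite-sample inflation 1/(2n) expected when r²
    is estimated from n diploid individuals.
    """
    if ne < 0:
        raise ValueError("Ne must be non-negative")
    if c <= 0:
        raise ValueError("genetic distance c must be positive")
    r2 = 1.0 / (4.0 * ne * c + 1.0)
    if n_samples is not None:
        r2 += 1.0 / (2.0 * n_samples)
    return r2


def ne_from_r2(r2: float, c: float) -> float:
    """Sved inversion Ne = (1/4c)·(1/r² − 1); infinite at r² = 0."""
    if c <= 0:
        raise ValueError("genetic distance c must be positive")
    if r2 > 1:
        raise ValueError("r² cannot exceed 1")
    if r2 <= 0:
        return float("inf")
    return (1.0 / (4.0 * c)) * (1.0 / r2 - 1.0)


def generations_ago(c: float) -> tuple[float, int]:
    """(raw, rounded) t = 1/(2c): the epoch an Ne-at-c estimate refers to."""
    if c <= 0:
        raise ValueError("genetic distance c must be positive")
    t = 1.0 / (2.0 * c)
    return t, int(round(t))


@dataclass
class NeEstimate:
    """One (distance window, c, mean r², Ne, t) point of a trajectory."""

    window_kb: float
    c_morgans: float
    r2: float
    ne: float
    t_raw: float
    t: int


@dataclass
class NeTrajectory:
    population: str
    estimates: list[NeEstimate]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "population": self.population,
                    "window_kb": e.window_kb,
                    "c_morgans": e.c_morgans,
                    "mean_r2": e.r2,
                    "ne": e.ne,
                    "t_raw": e.t_raw,
                    "t": e.t,
                }
                for e in self.estimates
            ]
        )


def ne_trajectory(
    binned: BinnedLD,
    gmap: GeneticMap,
    population: str = "",
    n_samples: int | None = None,
) -> NeTrajectory:
    """Per-window Ne estimates from binned mean r², ordered by decreasing t.

    Each window's c comes from the map preset (kb → cM).  ``n_samples``
    subtracts the 1/(2n) sampling inflation from the mean r² before the
    Sved inversion.  Windows with an undefined mean, or absent from the
    preset (the binner's 500-kb window has no preset linkage distance),
    are omitted.
    """
    estimates: list[NeEstimate] = []
    for _, row in binned.table.iterrows():
        w = float(row["window_kb"])
        r2 = float(row["mean_r2"])
        if np.isnan(r2):
            continue
        try:
            c = gmap.window_to_morgans(w)
        except KeyError:
            continue
        r2_adj = r2 - (1.0 / (2.0 * n_samples) if n_samples else 0.0)
        if r2_adj <= 0:
            continue
        t_raw, t = generations_ago(c)
        estimates.append(
            NeEstimate(
                window_kb=w,
                c_morgans=c,
                r2=r2,
                ne=ne_from_r2(min(1.0, r2_adj), c),
                t_raw=t_raw,
                t=t,
            )
        )
    estimates.sort(key=lambda e: -e.t_raw)
    return NeTrajectory(population=population, estimates=estimates)


def fit_ne_nls(
    c: np.ndarray,
    r2: np.ndarray,
    n_samples: int | None = None,
    ne_max: float = 1e7,
) -> tuple[float, dict]:
    """Non-linear least-squares fit of Ne to (c, r²) points.

    Minimises Σ (r²_obs − [1/(4·Ne·c+1) + 1/(2n)])² over Ne ≥ 0 by bounded
    scalar minimisation (the model is monotone in its single parameter, so
    the 1-D profile is well behaved).  Returns (Ne_hat, diagnostics).
    """
    c = np.asarray(c, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    ok = ~(np.isnan(c) | np.isnan(r2))
    c, r2 = c[ok], r2[ok]
    if len(np.unique(c)) < 1 or len(c) < 1:
        raise ValueError("need at least one (c, r²) point")
    offset = 1.0 / (2.0 * n_samples) if n_samples else 0.0

    def sse(ne: float) -> float:
        pred = 1.0 / (4.0 * ne * c + 1.0) + offset
        return float(((r2 - pred) ** 2).sum())

    # log-scale bracket keeps the bounded search well conditioned across
    # Ne spanning 1..1e7
    res = minimize_scalar(
        lambda x: sse(np.exp(x)),
        bounds=(np.log(1e-6), np.log(ne_max)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ne_hat = float(np.exp(res.x))
    # single-point data invert exactly
    if len(c) == 1:
        ne_hat = max(0.0, ne_from_r2(min(1.0, float(r2[0] - offset)), float(c[0]))) if r2[0] - offset > 0 else ne_hat
    return ne_hat, {"sse": sse(ne_hat), "converged": bool(res.success), "n_points": int(len(c))}
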