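"""Marker quality control: call rate, Hardy-Weinberg exact test, MAF.

The cascade mirrors standard SNP-array cleaning of a combined multi-line
panel: drop variants with call rate below 0.90, Hardy-Weinberg exact-test
p below 1e-4 and minor allele frequency below 0.01 (all strict "<", so a
variant sitting exactly on a threshold is retained), then restrict to the
autosome set.  Non-autosomal markers (sex chromosomes, unassigned linkage
groups) are counted separately from the three statistical filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from chickld.genotype_io import MISSING, GenotypeDataset, subset

#: Default autosome whitelist: the chicken karyotype's 28 assembled autosomes.
CHICKEN_AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 29))

#: Avian chromosome size classes.  The split is configurable; this default
#: uses GGA1-5 macro, GGA6-10 intermediate, GGA11-28 micro.
DEFAULT_CHROMOSOME_CLASSES: dict[str, str] = {
    **{str(i): "macro" for i in range(1, 6)},
    **{str(i): "intermediate" for i in range(6, 11)},
    **{str(i): "micro" for i in range(11, 29)},
}

FILTER_CALL_RATE = "call_rate"
FILTER_HWE = "hwe"
FILTER_MAF = "maf"


@dataclass
class QCConfig:
    """Thresholds and ordering for the marker-cleaning cascade.

    Removal is strict: a variant is dropped when its statistic is strictly
    below the threshold (call rate, MAF) or its p-value strictly below
    ``hwe_alpha``.  ``sequential=True`` counts each filter's removals among
    the survivors of the previous one; ``False`` evaluates every filter on
    the full input (counts may overlap) and removes the union.
    """

    min_call_rate: float = 0.90
    hwe_alpha: float = 1e-4
    min_maf: float = 0.01
    autosomes: frozenset[str] = CHICKEN_AUTOSOMES
    filter_order: tuple[str, ...] = (FILTER_CALL_RATE, FILTER_HWE, FILTER_MAF)
    sequential: bool = True

    def __post_init__(self) -> None:
        for name, v in (
            ("min_call_rate", self.min_call_rate),
            ("hwe_alpha", self.hwe_alpha),
            ("min_maf", self.min_maf),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if sorted(self.filter_order) != sorted(set(self.filter_order)):
            raise ValueError("filter_order contains duplicates")
        unknown = set(self.filter_order) - {FILTER_CALL_RATE, FILTER_HWE, FILTER_MAF}
        if unknown:
            raise ValueError(f"unknown filters: {unknown}")


@dataclass
class QCReport:
    """Per-filter removal accounting.  n_input − all removals = n_retained."""

    n_input: int
    removed_by_filter: dict[str, int]
    removed_sex_chromosome: int
    removed_linkage_group: int
    n_retained: int
    flagged_all_missing: int = 0

    def check_conservation(self) -> bool:
        total_removed = (
            sum(self.removed_by_filter.values())
            + self.removed_sex_chromosome
            + self.removed_linkage_group
        )
        return self.n_input - total_removed == self.n_retained

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input, self.n_input)]
        remaining = self.n_input
        for name, count in self.removed_by_filter.items():
            remaining -= count
            rows.append((name, count, remaining))
        remaining -= self.removed_sex_chromosome
        rows.append(("sex_chromosome", self.removed_sex_chromosome, remaining))
        remaining -= self.removed_linkage_group
        rows.append(("linkage_group", self.removed_linkage_group, remaining))
        return pd.DataFrame(rows, columns=["filter", "removed", "remaining"])


def call_rate(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing calls per variant, in [0, 1]."""
    if ds.n_samples == 0:
        raise ValueError("call rate undefined for a dataset with zero samples")
    return (ds.calls != MISSING).mean(axis=0)


def genotype_counts(ds: GenotypeDataset) -> np.ndarray:
    """(n_variants, 3) counts of calls 0, 1, 2 (missing excluded)."""
    return np.stack([(ds.calls == g).sum(axis=0) for g in (0, 1, 2)], axis=1)


def hwe_exact_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test conditioned on allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts (all share the parity of the rare-allele count) and sums the
    conditional probabilities of tables no more probable than the observed
    one.  No mid-p adjustment.  Returns a p-value in (0, 1].
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_hom1 + n_het  # copies of the first allele
    n_rare = min(n_a, 2 * n - n_a)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(het | allele counts) ∝ n! / (h1! het! h2!) * 2^het, with
    # h1 = (n_rare - het)/2 rare homs, h2 the rest.  Log-space for n ≤ 10^5.
    h1 = (n_rare - hets) // 2
    h2 = n - hets - h1
    logp = hets * np.log(2.0) - gammaln(h1 + 1) - gammaln(hets + 1) - gammaln(h2 + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_pvalues(ds: GenotypeDataset) -> np.ndarray:
    """Per-variant exact HWE p-values; NaN where all calls are missing."""
    counts = genotype_counts(ds)
    p = np.full(ds.n_variants, np.nan)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(ds.n_variants):
        key = (int(counts[j, 0]), int(counts[j, 1]), int(counts[j, 2]))
        if key[0] + key[1] + key[2] == 0:
            continue
        if key not in cache:
            cache[key] = hwe_exact_pvalue(key[2], key[1], key[0])
        p[j] = cache[key]
    return p


def minor_allele_frequency(ds: GenotypeDataset) -> np.ndarray:
    """Per-variant MAF among non-missing calls; NaN where all missing."""
    counts = genotype_counts(ds)
    n_called = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = (2 * counts[:, 2] + counts[:, 1]) / (2 * n_called)
    maf = np.minimum(freq1, 1 - freq1)
    maf[n_called == 0] = np.nan
    return maf


def _filter_fail_mask(ds: GenotypeDataset, name: str, cfg: QCConfig) -> np.ndarray:
    if name == FILTER_CALL_RATE:
        return call_rate(ds) < cfg.min_call_rate
    if name == FILTER_HWE:
        p = hwe_pvalues(ds)
        return np.where(np.isnan(p), False, p < cfg.hwe_alpha)
    if name == FILTER_MAF:
        maf = minor_allele_frequency(ds)
        return np.where(np.isnan(maf), False, maf < cfg.min_maf)
    raise ValueError(f"unknown filter {name!r}")


def classify_nonautosomal(chrom_labels: pd.Series, autosomes: frozenset[str]) -> pd.Series:
    """Label each variant 'autosome', 'sex_chromosome' or 'linkage_group'.

    Sex chromosomes are the avian Z/W (and mammalian X/Y/XY/MT codes);
    every other non-autosomal label counts as an unassigned linkage group.
    """
    sex_labels = {"Z", "W", "X", "Y", "XY", "MT", "23", "24", "25", "26"} - autosomes
    out = pd.Series("linkage_group", index=chrom_labels.index)
    out[chrom_labels.isin(autosomes)] = "autosome"
    out[chrom_labels.isin(sex_labels)] = "sex_chromosome"
    return out


def apply_qc(ds: GenotypeDataset, cfg: QCConfig | None = None) -> tuple[GenotypeDataset, QCReport]:
    """Run the cleaning cascade and return (filtered dataset, report).

    Sequential mode applies each filter to the survivors of the previous
    one, so removal counts depend on ``cfg.filter_order``; independent mode
    evaluates every filter on the full input and removes the union.
    Non-autosomal markers are excluded after the statistical filters and
    reported separately.  All-missing variants are flagged, not p-filtered.
    """
    cfg = cfg or QCConfig()
    n_input = ds.n_variants
    removed_by_filter: dict[str, int] = {}
    all_missing = int((call_rate(ds) == 0).sum()) if ds.n_samples else 0

    if cfg.sequential:
        survivors = ds
        for name in cfg.filter_order:
            fail = _filter_fail_mask(survivors, name, cfg)
            removed_by_filter[name] = int(fail.sum())
            survivors = subset(survivors, keep_variants=np.flatnonzero(~fail))
    else:
        masks = {name: _filter_fail_mask(ds, name, cfg) for name in cfg.filter_order}
        union = np.zeros(n_input, dtype=bool)
        for name in cfg.filter_order:
            removed_by_filter[name] = int(masks[name].sum())
            union |= masks[name]
        survivors = subset(ds, keep_variants=np.flatnonzero(~union))
        # independent counts overlap; conservation is restored via a
        # correction entry so the report still balances
        overlap = int(sum(m.sum() for m in masks.values()) - union.sum())
        if overlap:
            removed_by_filter["overlap_correction"] = -overlap

    kinds = classify_nonautosomal(survivors.variants["chrom"], cfg.autosomes)
    n_sex = int((kinds == "sex_chromosome").sum())
    n_lg = int((kinds == "linkage_group").sum())
    survivors = subset(
        survivors, keep_variants=np.flatnonzero((kinds == "autosome").to_numpy())
    )

    if survivors.n_variants == 0:
        warnings.warn("QC removed every variant", stacklevel=2)

    report = QCReport(
        n_input=n_input,
        removed_by_filter=removed_by_filter,
        removed_sex_chromosome=n_sex,
        removed_linkage_group=n_lg,
        n_retained=survivors.n_variants,
        flagged_all_missing=all_missing,
    )
    assert report.check_conservation()
    return survivors.sort_variants(), report


def classify_chromosomes(
    variants: pd.DataFrame, table: dict[str, str] | None = None
) -> dict[str, int]:
    """Per-size-class SNP counts (macro / intermediate / micro autosomes)."""
    table = table or DEFAULT_CHROMOSOME_CLASSES
    unknown = set(variants["chrom"]) - set(table)
    if unknown:
        raise KeyError(f"chromosome labels missing from class table: {sorted(unknown)}")
    counts: dict[str, int] = {cls: 0 for cls in dict.fromkeys(table.values())}
    for chrom, n in variants["chrom"].value_counts().items():
        counts[table[chrom]] += int(n)
    return counts
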