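"""End-to-end orchestration: QC → per-line LD → binning → Ne → MDS.

``run`` executes the full panel analysis deterministically and writes
tab-separated reports: a QC accounting table, per-line window-binned mean
r² (lines × windows + Average), per-line Ne trajectories (with linkage
distance and generations rows), and MDS coordinates.  Panel-level QC runs
first on the combined panel; within each line, pairs where a locus is
monomorphic are skipped by the LD scan rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chickld.diversity import classical_mds, ibs_matrix
from chickld.genotype_io import GenotypeDataset, read_plink, split_by_line, subset
from chickld.ld import DEFAULT_WINDOWS_KB, BinnedLD, bin_ld_by_distance, pairwise_ld_scan
from chickld.ne import GeneticMap, NeTrajectory, ne_trajectory
from chickld.qc import QCConfig, QCReport, apply_qc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_prefix: str | Path | None = None
    dataset: GenotypeDataset | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    windows_kb: tuple[float, ...] = DEFAULT_WINDOWS_KB
    bin_mode: str = "cumulative"
    max_dist_bp: float = 1_000_000
    genetic_map: GeneticMap | None = None
    mds_dimensions: int = 4
    min_line_samples: int = 2
    sample_size_correction: bool = False
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.input_prefix is None) == (self.dataset is None):
            raise ValueError("provide exactly one of input_prefix or dataset")
        if list(self.windows_kb) != sorted(set(self.windows_kb)):
            raise ValueError("windows must be strictly increasing")


@dataclass
class RunReport:
    qc_report: QCReport
    per_line_bins: dict[str, BinnedLD]
    per_line_trajectories: dict[str, NeTrajectory]
    mds: pd.DataFrame | None
    skipped_lines: list[str]

    def bins_frame(self) -> pd.DataFrame:
        """Lines × windows table of mean r² plus the Average column."""
        rows = {}
        for line, binned in self.per_line_bins.items():
            row = dict(zip(binned.table["window_kb"], binned.table["mean_r2"]))
            row["Average"] = binned.average
            rows[line] = row
        return pd.DataFrame(rows).T.sort_index()

    def trajectory_frame(self) -> pd.DataFrame:
        frames = [t.to_frame() for t in self.per_line_trajectories.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run(cfg: RunConfig) -> RunReport:
    """Execute QC → split-by-line → LD scan → bin → Ne → MDS.

    Lines with fewer than ``cfg.min_line_samples`` samples after QC are
    skipped and recorded.  Re-running with the same inputs reproduces
    identical outputs (nothing here is stochastic).
    """
    ds = cfg.dataset if cfg.dataset is not None else read_plink(cfg.input_prefix)
    logger.info("panel: %d samples × %d variants", ds.n_samples, ds.n_variants)

    clean, qc_report = apply_qc(ds, cfg.qc)
    logger.info("QC retained %d of %d variants", qc_report.n_retained, qc_report.n_input)

    per_line_bins: dict[str, BinnedLD] = {}
    per_line_traj: dict[str, NeTrajectory] = {}
    skipped: list[str] = []
    gmap = cfg.genetic_map or GeneticMap.from_table_preset()

    for line, part in sorted(split_by_line(clean).items()):
        if part.n_samples < cfg.min_line_samples:
            logger.warning("line %s: %d samples, skipped", line, part.n_samples)
            skipped.append(line)
            continue
        pairs = pairwise_ld_scan(part, max_dist_bp=cfg.max_dist_bp)
        if len(pairs) == 0:
            skipped.append(line)
            continue
        binned = bin_ld_by_distance(pairs, windows_kb=cfg.windows_kb, mode=cfg.bin_mode)
        per_line_bins[line] = binned
        n_corr = part.n_samples if cfg.sample_size_correction else None
        per_line_traj[line] = ne_trajectory(binned, gmap, population=line, n_samples=n_corr)

    mds_frame = None
    if clean.n_variants > 0 and clean.n_samples > cfg.mds_dimensions:
        dist = ibs_matrix(clean)
        if not np.isnan(dist.values).any():
            mds = classical_mds(dist, k=cfg.mds_dimensions)
            mds_frame = mds.to_frame()
            mds_frame.insert(1, "fid", clean.samples["fid"].to_numpy())

    report = RunReport(
        qc_report=qc_report,
        per_line_bins=per_line_bins,
        per_line_trajectories=per_line_traj,
        mds=mds_frame,
        skipped_lines=skipped,
    )
    if cfg.output_dir is not None:
        write_report(report, cfg.output_dir)
    return report


def write_report(report: RunReport, output_dir: str | Path) -> None:
    """Write qc_report.tsv, ld_bins.tsv, ne_trajectory.tsv, mds.tsv."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    report.bins_frame().to_csv(out / "ld_bins.tsv", sep="\t", index_label="line")
    report.trajectory_frame().to_csv(out / "ne_trajectory.tsv", sep="\t", index=False)
    if report.mds is not None:
        report.mds.to_csv(out / "mds.tsv", sep="\t", index=False)


def subsample_balanced(ds: GenotypeDataset, n_per_line: int, seed: int) -> GenotypeDataset:
    """Draw ``n_per_line`` samples per line, uniformly without replacement.

    Lines with fewer samples are dropped with a warning.  The draw is a
    deterministic function of (panel, n_per_line, seed).
    """
    if n_per_line <= 0:
        raise ValueError("n_per_line must be positive")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for fid in ds.samples["fid"].unique():
        idx = np.flatnonzero((ds.samples["fid"] == fid).to_numpy())
        if len(idx) < n_per_line:
            logger.warning("line %s has %d < %d samples; dropped", fid, len(idx), n_per_line)
            continue
        keep.append(np.sort(rng.choice(idx, size=n_per_line, replace=False)))
    if not keep:
        raise ValueError("no line has enough samples")
    return subset(ds, keep_samples=np.concatenate(keep))
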