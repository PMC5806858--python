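"""Build the reference multi-line panel the downstream analyses consume.

Simulates a 14-line panel shaped like a real conservation-flock study
(line sizes 6–23, shared base population, independent drift per line),
injects known QC defects, and writes the PLINK trio plus ground truth
under results/panel/.
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from chickld.genotype_io import write_plink
from chickld.synthetic_data import SimConfig, diverge_lines, inject_qc_defects

#: 8 commercial-style lines (sizes 7–23) and 6 conserved purebred lines
#: (sizes 6–7), the small conserved lines drifting at much smaller Ne.
LINE_SIZES = [7, 23, 23, 23, 23, 23, 23, 7, 6, 6, 6, 7, 6, 6]
LINE_NE = [80, 250, 250, 250, 250, 250, 250, 80, 40, 40, 40, 60, 40, 40]

PANEL_CONFIG = SimConfig(
    true_ne=250,
    n_generations=80,
    n_chromosomes=3,
    chrom_length_bp=2_000_000,
    n_snps_per_chrom=150,
    n_sampled_individuals=23,
)

N_DEFECTS = (12, 8, 10)  # low call rate, HWE-violating, rare-allele


def main(seed: int, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = replace(PANEL_CONFIG, seed=seed)
    ds, truth = diverge_lines(cfg, n_lines=14, divergence_generations=40,
                              line_sizes=LINE_SIZES, line_ne=LINE_NE)
    ds, planted = inject_qc_defects(ds, *N_DEFECTS, seed=seed + 1)
    prefix = outdir / "panel"
    write_plink(ds, prefix)
    pd.DataFrame(
        {"line": list(truth.per_line_ne), "true_ne": list(truth.per_line_ne.values()),
         "n_samples": LINE_SIZES}
    ).to_csv(outdir / "truth_lines.tsv", sep="\t", index=False)
    (outdir / "truth_defects.json").write_text(json.dumps({
        "low_call_rate": planted.low_call_rate.tolist(),
        "hwe_violating": planted.hwe_violating.tolist(),
        "rare_allele": planted.rare_allele.tolist(),
        "seed": seed,
    }, indent=2))
    print(f"panel: {ds.n_samples} samples × {ds.n_variants} SNPs, "
          f"14 lines, defects planted {N_DEFECTS} -> {prefix}.bed/.bim/.fam")
    return prefix


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/panel"))
    args = ap.parse_args()
    main(args.seed, args.out)
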