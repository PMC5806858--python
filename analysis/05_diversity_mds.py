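"""Line structure: 1 − IBS distances and a four-dimensional classical MDS.

Writes per-sample MDS coordinates (C1..C4 with line labels) and, when
matplotlib is available, a C1 × C2 scatter coloured by line.
"""

import argparse
from pathlib import Path

from chickld.diversity import classical_mds, ibs_matrix
from chickld.genotype_io import read_plink


def main(clean_prefix: Path, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    ds = read_plink(clean_prefix)
    dist = ibs_matrix(ds)
    res = classical_mds(dist, k=4)
    frame = res.to_frame()
    frame.insert(1, "fid", ds.samples["fid"].to_numpy())
    frame.to_csv(outdir / "mds.tsv", sep="\t", index=False)

    explained = res.eigenvalues[:4] / res.eigenvalues[res.eigenvalues > 0].sum()
    print("variance explained by C1..C4:",
          " ".join(f"{v:.1%}" for v in explained))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for line, grp in frame.groupby("fid"):
            ax.scatter(grp["C1"], grp["C2"], s=14, label=line)
        ax.set_xlabel("C1")
        ax.set_ylabel("C2")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(outdir / "mds_c1_c2.png", dpi=120)
        print(f"scatter -> {outdir / 'mds_c1_c2.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the scatter plot")
    return frame


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--clean", type=Path, default=Path("results/qc/panel_clean"))
    ap.add_argument("--out", type=Path, default=Path("results/diversity"))
    args = ap.parse_args()
    main(args.clean, args.out)
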