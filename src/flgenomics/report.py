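"""Static Markdown report with summary figures over pipeline outputs.

Renders from the saved TSVs only — no recomputation — so every number in
the report is traceable to a machine-readable output file.  Missing stage
outputs skip their section with a notice.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _rainfall(muts: pd.DataFrame, sample: str, path: Path) -> None:
    sub = muts[muts["sample"] == sample].sort_values(["chrom", "pos"])
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for chrom, grp in sub.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if len(pos) < 2:
            continue
        d = np.diff(pos)
        ax.scatter(pos[1:] + offset, d, s=4, label=chrom)
        offset += pos.max()
    ax.set_yscale("log")
    ax.set_xlabel("genomic position (concatenated chromosomes)")
    ax.set_ylabel("distance to previous mutation (bp)")
    ax.set_title(f"rainfall: {sample}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _exposure_bars(exposures: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    bottom = np.zeros(len(exposures))
    for sig in exposures.columns:
        ax.bar(range(len(exposures)), exposures[sig], bottom=bottom, label=sig)
        bottom += exposures[sig].to_numpy()
    ax.set_xticks(range(len(exposures)))
    ax.set_xticklabels(exposures.index, rotation=90, fontsize=6)
    ax.set_ylabel("attributed mutations")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _consensus_heatmap(matrix_path: Path, labels: pd.DataFrame, path: Path) -> None:
    labels = labels.sort_values("cluster")
    fig, ax = plt.subplots(figsize=(4, 4))
    m = pd.read_csv(matrix_path, sep="\t", index_col=0)
    order = [s for s in labels.index if s in m.index] or list(m.index)
    ax.imshow(m.loc[order], cmap="viridis", aspect="auto")
    ax.set_title("lesion matrix (cluster-ordered)" )
    ax.set_xlabel("markers")
    ax.set_ylabel("samples")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(outdir) -> Path:
    """Write ``report.md`` (plus PNG figures) summarising a pipeline run."""
    out = Path(outdir)
    lines = ["# flgenomics run report", ""]

    mpath = out / "mutations.tsv"
    if mpath.exists():
        muts = pd.read_csv(mpath, sep="\t")
        lines += [
            "## Cohort",
            f"- samples: {muts['sample'].nunique()}",
            f"- somatic SNVs: {len(muts)}",
            "",
        ]
        sample = muts["sample"].iloc[0]
        _rainfall(muts, sample, out / "rainfall.png")
        lines += [f"![rainfall](rainfall.png)", ""]
    else:
        lines += ["## Cohort", "_no mutation table found — section skipped_", ""]

    epath = out / "exposures.tsv"
    if epath.exists():
        expo = pd.read_csv(epath, sep="\t", index_col=0)
        _exposure_bars(expo, out / "exposures.png")
        lines += [
            "## Signature exposures",
            f"- signatures: {', '.join(expo.columns)}",
            f"![exposures](exposures.png)",
            "",
        ]
    else:
        lines += ["## Signature exposures", "_no exposures found — section skipped_", ""]

    kpath = out / "kataegis_events.tsv"
    if kpath.exists():
        ev = pd.read_csv(kpath, sep="\t")
        if len(ev) == 0:
            lines += ["## Kataegis", "zero kataegis events detected", ""]
        else:
            n_k1 = int((ev["dominance"] == "K1-dominant").sum())
            lines += [
                "## Kataegis",
                f"- events: {len(ev)} across {ev['sample'].nunique()} samples",
                f"- K1-dominant: {n_k1}, K2-dominant: {len(ev) - n_k1}",
                f"- median event size: {int(ev['n_mutations'].median())} mutations",
                "",
            ]
    else:
        lines += ["## Kataegis", "_no events table found — section skipped_", ""]

    cpath = out / "cluster_labels.tsv"
    if cpath.exists():
        labels = pd.read_csv(cpath, sep="\t", index_col=0)
        coph = pd.read_csv(out / "cophenetic.tsv", sep="\t", index_col=0)
        counts = labels.iloc[:, -1].value_counts().sort_index()
        lines += [
            "## Genetic subtypes",
            f"- selected K (max cophenetic): {int(coph['cophenetic'].idxmax())}",
            "- cluster sizes: "
            + ", ".join(f"C{c}: {n}" for c, n in counts.items()),
            "",
            "| K | cophenetic |",
            "|---|------------|",
        ]
        lines += [f"| {k} | {v:.4f} |" for k, v in coph["cophenetic"].items()]
        lines.append("")
        if (out / "lesion_matrix.tsv").exists():
            _consensus_heatmap(out / "lesion_matrix.tsv", labels, out / "lesion_matrix.png")
            lines += [f"![lesion matrix](lesion_matrix.png)", ""]
    else:
        lines += ["## Genetic subtypes", "_no clustering output found — section skipped_", ""]

    gpath = out / "comparisons.tsv"
    if gpath.exists():
        comp = pd.read_csv(gpath, sep="\t")
        lines += ["## Group comparisons", "", "```", comp.to_string(index=False), "```", ""]

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
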