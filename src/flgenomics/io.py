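"""File I/O: VCF, mutation TSV, BED annotation, lesion tables.

VCF output is minimal v4.2 (CHROM/POS/REF/ALT, one sample per file) with the
trinucleotide context and generating-signature origin preserved in INFO so
that a written cohort round-trips losslessly.  Reading uses cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .catalogs import validate_mutations

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CTX,Number=1,Type=String,Description="Reference-strand trinucleotide context">
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Generating signature (synthetic cohorts)">
"""


def write_vcf(muts: pd.DataFrame, path, sample: str | None = None) -> None:
    """Write one sample's SNVs as a VCF v4.2 text file (1-based positions)."""
    if len(muts) > 0:
        ids = muts["sample"].unique()
        if len(ids) > 1:
            raise ValueError("write_vcf expects mutations of a single sample")
        sample = sample or str(ids[0])
    if sample is None:
        raise ValueError("sample name required for an empty VCF")
    muts = muts.sort_values(["chrom", "pos"], kind="mergesort") if len(muts) else muts
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in sorted(muts["chrom"].unique()) if len(muts) else []:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"##SAMPLE=<ID={sample}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in muts.iterrows():
            info = []
            if "context" in muts.columns and isinstance(r.get("context"), str):
                info.append(f"CTX={r['context']}")
            if "origin" in muts.columns and isinstance(r.get("origin"), str):
                info.append(f"ORIGIN={r['origin']}")
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t"
                f"{';'.join(info) or '.'}\n"
            )


def read_mutations_vcf(paths, samples: list[str] | None = None) -> pd.DataFrame:
    """Read per-sample VCFs into a cohort mutation table.

    The sample id is taken from the ``##SAMPLE`` header line if present,
    else the file stem.  Returns the table sorted by (sample, chrom, pos).
    """
    from cyvcf2 import VCF

    if isinstance(paths, (str, Path)):
        paths = [paths]
    rows = []
    for i, p in enumerate(paths):
        p = Path(p)
        sample = samples[i] if samples else None
        if sample is None:
            with open(p) as fh:
                for line in fh:
                    if line.startswith("##SAMPLE=<ID="):
                        sample = line.strip()[len("##SAMPLE=<ID=") : -1]
                    if not line.startswith("##"):
                        break
        sample = sample or p.stem
        for v in VCF(str(p)):
            ctx = v.INFO.get("CTX")
            origin = v.INFO.get("ORIGIN")
            rows.append((sample, v.CHROM, v.POS, v.REF, v.ALT[0], ctx, origin))
    muts = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "context", "origin"]
    )
    if muts["context"].isna().all():
        muts = muts.drop(columns=["context"])
    if muts["origin"].isna().all():
        muts = muts.drop(columns=["origin"])
    return validate_mutations(muts) if len(muts) else muts


def read_mutations_tsv(path) -> pd.DataFrame:
    """Read a mutation TSV with columns sample, chrom, pos, ref, alt[, context]."""
    return validate_mutations(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def read_bed(path, expect_name: bool = False) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end[/name].

    Malformed lines raise with the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < (4 if expect_name else 3):
                raise ValueError(f"{path}:{lineno}: expected >= {4 if expect_name else 3} BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_tss_bed(path) -> pd.DataFrame:
    """Read a TSS BED (one anchor per gene) into chrom/pos (1-based)/gene."""
    bed = read_bed(path)
    return pd.DataFrame(
        {"chrom": bed["chrom"], "pos": bed["start"] + 1, "gene": bed["name"]}
    )


def read_lesion_calls(path) -> pd.DataFrame:
    """Read a lesion-call TSV (sample, marker, kind, detail)."""
    calls = pd.read_csv(path, sep="\t")
    missing = {"sample", "marker", "kind", "detail"} - set(calls.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    return calls


def read_marker_table(path) -> pd.DataFrame:
    """Read a marker metadata TSV (marker index, kind column)."""
    markers = pd.read_csv(path, sep="\t", index_col=0)
    if "kind" not in markers.columns:
        raise ValueError("marker table needs a 'kind' column")
    return markers
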