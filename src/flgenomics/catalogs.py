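"""Mutation tables and 96-channel substitution catalogs.

A *mutation set* is a :class:`pandas.DataFrame` with one row per somatic SNV
and columns

    sample   sample identifier (str)
    chrom    chromosome name (str)
    pos      1-based position (int)
    ref      reference-strand reference base
    alt      reference-strand alternate base
    context  optional reference-strand trinucleotide centered on the site

plus any extra columns (the simulator adds ``origin`` with the generating
signature).  ``validate_mutations`` normalises and sorts such a table; the
catalog builder turns it into a samples x 96 count matrix.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .channels import BASES, CHANNELS, channel_of

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ("sample", "chrom", "pos", "ref", "alt")


def validate_mutations(muts: pd.DataFrame) -> pd.DataFrame:
    """Check SNV invariants and return a copy sorted by (sample, chrom, pos).

    Enforces: required columns present; single-base ref/alt; ref != alt.
    """
    missing = [c for c in MUTATION_COLUMNS if c not in muts.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    out = muts.copy()
    out["pos"] = out["pos"].astype(np.int64)
    for col in ("ref", "alt"):
        out[col] = out[col].astype(str).str.upper()
    bad_len = (out["ref"].str.len() != 1) | (out["alt"].str.len() != 1)
    if bad_len.any():
        raise ValueError(f"{int(bad_len.sum())} records are not single-nucleotide substitutions")
    same = out["ref"] == out["alt"]
    if same.any():
        raise ValueError(f"{int(same.sum())} records have ref == alt")
    out = out.sort_values(["sample", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def _fetch_context(source, chrom: str, pos: int) -> str:
    """Trinucleotide (pos-1, pos, pos+1) from a FASTA handle or a dict of sequences."""
    if isinstance(source, Mapping):
        seq = source[chrom]
        if pos < 2 or pos > len(seq) - 1:
            return "N" * 3
        return str(seq[pos - 2 : pos + 1]).upper()
    # pyfaidx.Fasta-like: 0-based slicing on records
    rec = source[chrom]
    if pos < 2 or pos > len(rec) - 1:
        return "N" * 3
    return str(rec[pos - 2 : pos + 1]).upper()


def attach_contexts(muts: pd.DataFrame, context_source) -> pd.DataFrame:
    """Add/overwrite the ``context`` column by looking up the reference sequence.

    ``context_source`` may be a ``pyfaidx.Fasta`` or any mapping from
    chromosome name to sequence string.
    """
    out = muts.copy()
    out["context"] = [
        _fetch_context(context_source, c, p) for c, p in zip(out["chrom"], out["pos"])
    ]
    return out


def build_catalog(muts: pd.DataFrame, context_source=None) -> pd.DataFrame:
    """Build the samples x 96 substitution catalog.

    Every record needs a trinucleotide context, either already present in a
    ``context`` column or looked up from ``context_source``.  Purine-reference
    records are folded to the reverse-complement pyrimidine channel.  Records
    whose context contains an unknown base (N) are skipped with a logged
    count; a context whose middle base disagrees with ``ref`` is an error.

    Returns
    -------
    DataFrame indexed by sample with the 96 canonical channel labels as
    columns; row sums equal each sample's (non-skipped) SNV count.
    """
    muts = validate_mutations(muts)
    if "context" not in muts.columns or muts["context"].isna().any():
        if context_source is None:
            raise ValueError("mutation table has no context column and no context_source given")
        muts = attach_contexts(muts, context_source)
    contexts = muts["context"].astype(str).str.upper()

    mismatch = (contexts.str.len() == 3) & (contexts.str[1] != muts["ref"]) & ~contexts.str.contains("N")
    if mismatch.any():
        offending = muts.loc[mismatch, ["sample", "chrom", "pos", "ref", "context"]]
        raise ValueError(
            "context middle base != ref for records:\n" + offending.head(20).to_string()
        )
    has_n = ~contexts.str.fullmatch(f"[{BASES}]{{3}}")
    n_skipped = int(has_n.sum())
    if n_skipped:
        logger.warning("skipping %d records with ambiguous (non-ACGT) context", n_skipped)

    keep = muts.loc[~has_n]
    labels = [
        channel_of(r, a, c)
        for r, a, c in zip(keep["ref"], keep["alt"], contexts[~has_n])
    ]
    samples = pd.Index(muts["sample"].unique(), name="sample")
    counts = (
        pd.crosstab(keep["sample"], pd.Categorical(labels, categories=CHANNELS))
        .reindex(index=samples, columns=list(CHANNELS), fill_value=0)
        .astype(np.int64)
    )
    counts.columns.name = "channel"
    return counts


def read_catalog(path) -> pd.DataFrame:
    """Read a catalog TSV written by :func:`write_catalog` (channels as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS):
        raise ValueError(f"{path}: channel rows are not in the canonical 96-channel order")
    out = df.T
    out.index.name = "sample"
    out.columns.name = "channel"
    return out


def write_catalog(catalog: pd.DataFrame, path) -> None:
    """Write a catalog as TSV with the 96 channels as labeled rows."""
    catalog.T.to_csv(path, sep="\t", index_label="channel")
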