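"""The 96-channel single-base-substitution taxonomy.

Somatic single-nucleotide variants are classified by the substituted
pyrimidine (six substitution types: C>A, C>G, C>T, T>A, T>C, T>G) together
with the immediate 5' and 3' flanking bases, giving 6 x 4 x 4 = 96 channels.
Substitutions reported with a purine reference are folded onto the
reverse-complement strand so that the central base is always a pyrimidine.

Channel labels follow the widely used lexicographic convention
("A[C>A]A" ... "T[T>G]T"): substitution types in the order above, then the
5' base and the 3' base each in A, C, G, T order.  Files exchanged with
other tools must use this exact order.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = str.maketrans("ACGTN", "TGCAN")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMP)[::-1]


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map one substitution to its pyrimidine-centered channel label.

    Parameters
    ----------
    ref, alt
        Reference-strand reference and alternate base (single characters).
    context
        Reference-strand trinucleotide centered on the variant; its middle
        base must equal ``ref``.

    Raises
    ------
    ValueError
        If the record is not a simple SNV, the context middle base disagrees
        with ``ref``, or a base outside ACGT (e.g. N) is present.
    """
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError(f"not a contexted SNV: ref={ref!r} alt={alt!r} context={context!r}")
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if any(b not in BASES for b in (ref, alt)) or any(b not in BASES for b in context):
        raise ValueError(f"non-ACGT base in ref={ref!r} alt={alt!r} context={context!r}")
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = context[1]
        alt = alt.translate(_COMP)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def parse_channel(channel: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into ``("A", "C", "T", "G")`` (5', ref, alt, 3')."""
    if len(channel) != 7 or channel[1] != "[" or channel[3] != ">" or channel[5] != "]":
        raise ValueError(f"malformed channel label {channel!r}")
    return channel[0], channel[2], channel[4], channel[6]


def channel_context(channel: str) -> str:
    """Pyrimidine-strand trinucleotide context of a channel label."""
    five, ref, _, three = parse_channel(channel)
    return five + ref + three
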