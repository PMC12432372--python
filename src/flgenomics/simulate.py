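"""Synthetic cohort generation.

Generates somatic-SNV cohorts and lesion matrices with the statistical
structure the downstream analyses assume, so every stage is testable
without access to patient genomes:

* background mutations are placed uniformly per chromosome (then sorted),
  which makes adjacent intermutation distances approximately exponential —
  the null the kataegis detector tests against;
* each mutation's 96-channel identity is drawn from a per-sample mixture of
  signature profiles, and every record carries its generating signature in
  an ``origin`` column for recovery tests;
* kataegis is planted as runs of >= n mutations within a bounded span, with
  channel composition drawn from a designated source signature;
* the lesion simulator emits gene/CNV/SV calls for a planted cluster
  structure (each cluster's own markers lesioned with high probability,
  others at a background probability), with copy numbers sampled from every
  scoring tier so each encoding branch is exercised.

Two placement modes exist.  Without a genome, trinucleotide contexts are
synthesised directly from the sampled channel and stored on a random strand
(so purine-reference records exercise the pyrimidine folding path).  With a
reference genome (dict of sequences), positions are drawn from sites whose
reference trinucleotide matches the sampled channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, parse_channel, revcomp
from .catalogs import validate_mutations

DEFAULT_CHROM_LENGTHS = {"chr1": 12_000_000, "chr2": 8_000_000}

_COMP_TABLE = str.maketrans("ACGT", "TGCA")

# per-channel (ref, alt, context) on the pyrimidine strand and its purine mirror
_PYR = [(c[2], c[4], c[0] + c[2] + c[6]) for c in CHANNELS]
_PUR = [
    (revcomp(ctx)[1], alt.translate(_COMP_TABLE), revcomp(ctx)) for _, alt, ctx in _PYR
]


@dataclass(frozen=True)
class KataegisPlan:
    """One planted clustered-mutation run.

    ``source_signature`` names a column of the signature set the cluster's
    channels are drawn from; ``None`` draws channels from the sample's
    background mixture.  Placement: without a genome (or without a source
    signature) positions start at ``start`` with every adjacent gap drawn
    uniformly in ``[1, max_span_bp // (n_mutations - 1)]``, guaranteeing the
    span bound and a tight spacing; with a genome and a source signature,
    positions are context-matching sites inside ``[start, start +
    max_span_bp)``.
    """

    chrom: str
    start: int
    n_mutations: int = 10
    max_span_bp: int = 10_000
    source_signature: str | None = None


@dataclass
class CohortSpec:
    """Parameters of a synthetic SNV cohort."""

    n_samples: int = 10
    background_rate: float = 1000.0          # mean mutations per sample (Poisson)
    # weights over signature columns: 1-D (shared by all samples) or 2-D
    # (n_samples x n_signatures, one row per sample); None = uniform
    signature_mix: np.ndarray | list | None = None
    kataegis_plan: dict[str, list[KataegisPlan]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.signature_mix is not None:
            w = np.asarray(self.signature_mix, dtype=float)
            if (w < 0).any():
                raise ValueError("signature mixture weights must be non-negative")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


@dataclass
class ClusterSpec:
    """Parameters of a planted lesion-cluster structure."""

    n_clusters: int = 3
    samples_per_cluster: int = 40
    markers_per_cluster: int | tuple[int, ...] = 10   # scalar, or one count per cluster
    enrichment_own: float = 0.9       # P(own-cluster marker lesioned in a member)
    enrichment_other: float = 0.05    # P(foreign marker lesioned)
    marker_kinds: tuple[str, ...] = ("mutation", "cnv_gain_peak", "cnv_loss_peak", "sv")
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        counts = self.marker_counts()
        if len(counts) != self.n_clusters or any(c < 1 for c in counts):
            raise ValueError("markers_per_cluster must be >= 1 (one count per cluster)")
        for p in (self.enrichment_own, self.enrichment_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("enrichment probabilities must lie in [0, 1]")
        bad = set(self.marker_kinds) - {"mutation", "cnv_gain_peak", "cnv_loss_peak", "sv"}
        if bad:
            raise ValueError(f"unknown lesion kinds: {sorted(bad)}")

    def marker_counts(self) -> tuple[int, ...]:
        if isinstance(self.markers_per_cluster, int):
            return (self.markers_per_cluster,) * self.n_clusters
        return tuple(self.markers_per_cluster)


def random_genome(chrom_lengths: dict[str, int], seed: int = 0) -> dict[str, str]:
    """IID random reference sequences (equal base frequencies), one per chromosome."""
    rng = np.random.default_rng(seed)
    return {
        chrom: "".join(rng.choice(list("ACGT"), size=length))
        for chrom, length in chrom_lengths.items()
    }


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class ContextIndex:
    """Positions of each trinucleotide in a genome, for context-matched placement."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self.index: dict[str, dict[str, np.ndarray]] = {}
        bases = "ACGT"
        for chrom, seq in genome.items():
            arr = np.frombuffer(seq.upper().encode(), dtype="S1")
            codes = np.full(len(arr), -100, dtype=np.int64)
            for i, b in enumerate(b"ACGT"):
                codes[arr == bytes([b])] = i
            key = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
            order = np.argsort(key, kind="stable")
            sorted_key = key[order]
            tri = {}
            for k in range(64):
                lo = np.searchsorted(sorted_key, k, side="left")
                hi = np.searchsorted(sorted_key, k, side="right")
                t = bases[k // 16] + bases[(k // 4) % 4] + bases[k % 4]
                tri[t] = np.sort(order[lo:hi]) + 2  # 1-based center positions
            self.index[chrom] = tri

    def positions(self, chrom: str, trinuc: str) -> np.ndarray:
        return self.index[chrom][trinuc]


def simulate_mutations(
    spec: CohortSpec,
    signatures: pd.DataFrame,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Generate a cohort mutation table from a :class:`CohortSpec`.

    Returns a validated mutation table with columns sample, chrom, pos, ref,
    alt, context, origin; ``origin`` is the generating signature name
    (prefixed ``kataegis:`` for planted runs).  Duplicate positions within a
    sample are dropped (background yields *approximately*
    ``background_rate`` mutations).
    """
    if list(signatures.index) != list(CHANNELS):
        raise ValueError("signature set must use the canonical 96-channel order")
    rng = np.random.default_rng(spec.seed)
    k = signatures.shape[1]
    if spec.signature_mix is None:
        weight_rows = np.full((spec.n_samples, k), 1.0 / k)
    else:
        w = np.atleast_2d(np.asarray(spec.signature_mix, dtype=float))
        if w.shape[0] == 1:
            w = np.repeat(w, spec.n_samples, axis=0)
        if w.shape != (spec.n_samples, k):
            raise ValueError(
                f"signature_mix shape {w.shape} incompatible with "
                f"({spec.n_samples} samples, {k} signatures)"
            )
        sums = w.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("signature mixture weights sum to zero for some sample")
        weight_rows = w / sums[:, None]
    profiles = signatures.to_numpy(dtype=float)
    ctx_index = ContextIndex(genome) if genome is not None else None
    chroms = list(spec.chrom_lengths)
    chrom_p = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    for sample, plans in spec.kataegis_plan.items():
        for plan in plans:
            length = spec.chrom_lengths.get(plan.chrom)
            if length is None or plan.start < 2 or plan.start + plan.max_span_bp > length:
                raise ValueError(
                    f"kataegis locus {plan.chrom}:{plan.start} (+{plan.max_span_bp} bp) "
                    "outside genome bounds"
                )

    frames = []
    for si, sample in enumerate(spec.sample_ids()):
        weights = weight_rows[si]
        seen: set[tuple[str, int]] = set()
        planted = []
        for plan in spec.kataegis_plan.get(sample, []):
            planted.extend(
                _plant_kataegis(sample, plan, signatures, profiles, weights, ctx_index, rng, seen)
            )
        n_bg = int(rng.poisson(spec.background_rate))
        bg = _background_mutations(
            sample, n_bg, profiles, weights, signatures.columns, chroms, chrom_p,
            spec.chrom_lengths, ctx_index, rng,
        )
        frame = pd.DataFrame(
            planted + bg, columns=["sample", "chrom", "pos", "ref", "alt", "context", "origin"]
        )
        frame = frame.drop_duplicates(subset=["chrom", "pos"], keep="first")
        frames.append(frame)
    return validate_mutations(pd.concat(frames, ignore_index=True))


def _background_mutations(
    sample, n_bg, profiles, weights, sig_names, chroms, chrom_p, chrom_lengths, ctx_index, rng
) -> list[tuple]:
    if n_bg == 0:
        return []
    sig_idx = rng.choice(len(weights), size=n_bg, p=weights)
    channel_idx = np.empty(n_bg, dtype=np.int64)
    for j in np.unique(sig_idx):
        mask = sig_idx == j
        channel_idx[mask] = rng.choice(96, size=int(mask.sum()), p=profiles[:, j])
    chrom_idx = rng.choice(len(chroms), size=n_bg, p=chrom_p)
    records: list[tuple] = []
    if ctx_index is None:
        purine = rng.random(n_bg) < 0.5
        pos = np.empty(n_bg, dtype=np.int64)
        for ci, chrom in enumerate(chroms):
            mask = chrom_idx == ci
            pos[mask] = rng.integers(2, chrom_lengths[chrom], size=int(mask.sum()))
        for k in range(n_bg):
            ref, alt, ctx = (_PUR if purine[k] else _PYR)[channel_idx[k]]
            records.append(
                (sample, chroms[chrom_idx[k]], int(pos[k]), ref, alt, ctx,
                 str(sig_names[sig_idx[k]]))
            )
    else:
        for k in range(n_bg):
            rec = _context_matched_site(
                chroms[chrom_idx[k]], channel_idx[k], ctx_index, rng, window=None
            )
            if rec is None:
                continue
            records.append((sample, *rec, str(sig_names[sig_idx[k]])))
    return records


def _context_matched_site(chrom, channel_i, ctx_index, rng, window):
    """A genome position whose reference trinucleotide matches the channel."""
    ref, alt, ctx = _PYR[channel_i]
    fwd = ctx_index.positions(chrom, ctx)
    rc = ctx_index.positions(chrom, revcomp(ctx))
    if window is not None:
        lo, hi = window
        fwd = fwd[(fwd >= lo) & (fwd < hi)]
        rc = rc[(rc >= lo) & (rc < hi)]
    n_f, n_r = len(fwd), len(rc)
    if n_f + n_r == 0:
        return None
    k = int(rng.integers(0, n_f + n_r))
    if k < n_f:
        return chrom, int(fwd[k]), ref, alt, ctx
    p_ref, p_alt, p_ctx = _PUR[channel_i]
    return chrom, int(rc[k - n_f]), p_ref, p_alt, p_ctx


def _plant_kataegis(sample, plan, signatures, profiles, weights, ctx_index, rng, seen):
    """Place one planted cluster; returns record tuples and updates ``seen``."""
    n = plan.n_mutations
    if plan.source_signature is not None:
        if plan.source_signature not in signatures.columns:
            raise ValueError(f"unknown source signature {plan.source_signature!r}")
        p_channels = signatures[plan.source_signature].to_numpy(dtype=float)
        origin = f"kataegis:{plan.source_signature}"
    else:
        p_channels = profiles @ weights
        origin = "kataegis:background-mix"
    p_channels = p_channels / p_channels.sum()

    records = []
    if ctx_index is not None and plan.source_signature is not None:
        # context-matched placement within the window
        window = (plan.start, plan.start + plan.max_span_bp)
        for _ in range(n):
            for _attempt in range(500):
                ch = int(rng.choice(96, p=p_channels))
                rec = _context_matched_site(plan.chrom, ch, ctx_index, rng, window)
                if rec is not None and (rec[0], rec[1]) not in seen:
                    records.append((sample, *rec, origin))
                    seen.add((rec[0], rec[1]))
                    break
            else:
                raise ValueError(
                    f"cannot place {n} context-matched mutations in "
                    f"{plan.chrom}:{window[0]}-{window[1]}"
                )
        return records

    # geometric placement: bounded gaps guarantee the span (and spacing) bound
    max_gap = max(1, plan.max_span_bp // max(1, n - 1))
    while True:
        gaps = rng.integers(1, max_gap + 1, size=n - 1)
        positions = plan.start + np.concatenate([[0], np.cumsum(gaps)])
        if all((plan.chrom, int(p)) not in seen for p in positions):
            break
    channel_draws = rng.choice(96, size=n, p=p_channels)
    for pos, ch in zip(positions, channel_draws):
        pos = int(pos)
        if ctx_index is not None:
            # take ref/context from the genome; alt = channel's alt if compatible,
            # else a uniformly chosen non-reference base
            seq = ctx_index.genome[plan.chrom]
            ctx = seq[pos - 2 : pos + 1].upper()
            ref = ctx[1]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            records.append((sample, plan.chrom, pos, ref, alt, ctx, origin))
        else:
            ref, alt, ctx = (_PUR if rng.random() < 0.5 else _PYR)[ch]
            records.append((sample, plan.chrom, pos, ref, alt, ctx, origin))
        seen.add((plan.chrom, pos))
    return records


@dataclass
class SimulatedLesions:
    """Lesion calls plus ground truth from :func:`simulate_lesions`."""

    calls: pd.DataFrame        # sample, marker, kind, detail (long format, lesioned only)
    truth: pd.Series           # sample -> true cluster label (1..K)
    markers: pd.DataFrame      # marker -> kind, true_cluster


def simulate_lesions(spec: ClusterSpec) -> SimulatedLesions:
    """Generate lesion calls with planted cluster-specific marker enrichment.

    Copy numbers at CNV markers are sampled half from the high-grade and
    half from the low-grade tier so both scoring branches occur; mutation
    consequences are nonsilent/indel/synonymous at 0.7/0.15/0.15.
    """
    rng = np.random.default_rng(spec.seed)
    samples, truth = [], []
    for c in range(spec.n_clusters):
        for i in range(spec.samples_per_cluster):
            samples.append(f"S{c * spec.samples_per_cluster + i + 1:03d}")
            truth.append(c + 1)
    marker_rows = []
    for c, n_markers in enumerate(spec.marker_counts()):
        for m in range(n_markers):
            kind = spec.marker_kinds[m % len(spec.marker_kinds)]
            marker_rows.append((f"C{c + 1}_M{m + 1:02d}_{kind}", kind, c + 1))
    markers = (
        pd.DataFrame(marker_rows, columns=["marker", "kind", "true_cluster"])
        .set_index("marker")
    )

    calls = []
    for sample, cl in zip(samples, truth):
        for marker, row in markers.iterrows():
            p = spec.enrichment_own if row["true_cluster"] == cl else spec.enrichment_other
            if rng.random() >= p:
                continue
            kind = row["kind"]
            if kind == "mutation":
                detail = str(rng.choice(["nonsilent", "indel", "synonymous"], p=[0.7, 0.15, 0.15]))
            elif kind == "cnv_gain_peak":
                detail = float(rng.uniform(3.71, 6.0) if rng.random() < 0.5 else rng.uniform(2.4, 3.7))
            elif kind == "cnv_loss_peak":
                detail = float(rng.uniform(0.05, 0.80) if rng.random() < 0.5 else rng.uniform(0.81, 1.6))
            else:
                detail = 1
            calls.append((sample, marker, kind, detail))
    calls_df = pd.DataFrame(calls, columns=["sample", "marker", "kind", "detail"])
    truth_s = pd.Series(truth, index=pd.Index(samples, name="sample"), name="cluster")
    return SimulatedLesions(calls=calls_df, truth=truth_s, markers=markers)


def write_cohort(
    muts: pd.DataFrame,
    lesions: SimulatedLesions | None,
    outdir,
    all_samples: list[str] | None = None,
) -> dict[str, Path]:
    """Write one VCF v4.2 per sample plus lesion/truth/marker TSVs.

    ``all_samples`` may list samples without mutations; these still get a
    valid header-only VCF.  Round-trips losslessly (position, ref, alt,
    sample; context and origin travel in INFO) through
    :func:`flgenomics.io.read_mutations_vcf`.
    """
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    samples = sorted(set(muts["sample"]).union(all_samples or []))
    for sample in samples:
        grp = muts[muts["sample"] == sample]
        p = outdir / f"{sample}.vcf"
        fio.write_vcf(grp, p, sample=sample)
        paths[f"vcf:{sample}"] = p
    if lesions is not None:
        lp = outdir / "lesions.tsv"
        lesions.calls.to_csv(lp, sep="\t", index=False)
        tp = outdir / "truth.tsv"
        lesions.truth.to_frame().to_csv(tp, sep="\t")
        mp = outdir / "markers.tsv"
        lesions.markers.to_csv(mp, sep="\t")
        paths.update({"lesions": lp, "truth": tp, "markers": mp})
    return paths
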