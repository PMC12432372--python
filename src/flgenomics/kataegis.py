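"""Detection and characterisation of clustered somatic mutations (kataegis).

The detector follows the intermutation-distance scheme used for B-cell
lymphoma genomes:

1. Per sample, the *abnormal distance line* (ADL) is one-tenth of the mean
   distance between adjacent mutations (distances computed within, never
   across, chromosomes and pooled genome-wide).
2. Every run of ``window_n`` (default 10) consecutive same-chromosome
   mutations spanning at most ``max_span_bp`` (default 10 kb) forms a
   candidate window.  Its 9 internal adjacent distances are split into
   below-ADL vs above-ADL counts and compared with the sample-wide split by
   a one-tailed Fisher's exact test (enrichment of below-ADL distances).
3. Windows with p below the calling threshold (default 1e-4) are kataegis
   candidates; overlapping candidates are merged when the Fisher p
   recomputed on the merged run of mutations stays below the threshold.

Each event is then decomposed against fixed K1/K2 signature profiles by
non-negative least squares; the K1 contribution (K1 / (K1+K2) exposure)
classifies events as K1- or K2-dominant, and the per-sample mean
contribution split at the cohort median defines K1-high vs K1-low samples.

Conventions (degrees of freedom the scheme itself leaves open):

* a distance exactly equal to the ADL counts as *above* (strict ``<``
  defines clustered spacing) — conservative toward fewer calls;
* windows are all consecutive ``window_n``-mers (stride 1), their span
  measured first to last member inclusive;
* the sample-wide background table includes the window's own distances
  (set ``include_window_in_background=False`` to exclude them);
* merging is transitive: chains of pairwise-overlapping candidates are
  pooled once; if the pooled region fails the threshold the chain is split
  back greedily into maximal passing prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import catalogs, signatures as sigmod

DEFAULT_WINDOW_N = 10
DEFAULT_MAX_SPAN_BP = 10_000
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_PROXIMAL_BP = 2_000


@dataclass(frozen=True)
class AdlStatistic:
    """Sample-level intermutation-distance summary."""

    sample: str
    mean_distance: float      # mean adjacent intermutation distance, bp
    adl: float                # mean_distance / 10
    n_below: int              # adjacent distances strictly below the ADL
    n_above: int              # adjacent distances >= ADL


@dataclass(frozen=True)
class CandidateWindow:
    """One window of ``window_n`` consecutive mutations with its Fisher test."""

    chrom: str
    first: int                # index of the first member within the chromosome's sorted positions
    last: int                 # index of the last member (inclusive)
    start: int                # 1-based position of the first member
    end: int                  # 1-based position of the last member
    below: int
    above: int
    p: float


@dataclass
class KataegisEvent:
    """A called clustered-mutation region."""

    sample: str
    chrom: str
    start: int                # 1-based, inclusive span of member mutations
    end: int
    n_mutations: int
    p: float
    member_positions: tuple[int, ...]
    k1_contribution: float | None = None
    dominance: str | None = None          # "K1-dominant" / "K2-dominant"
    region_class: str | None = None
    degenerate: bool = False              # NNLS attributed zero to both signatures


def _positions_by_chrom(sample_muts: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in sample_muts.groupby("chrom", sort=True):
        out[chrom] = np.sort(grp["pos"].to_numpy(dtype=np.int64))
    return out


def compute_adl(sample_muts: pd.DataFrame) -> AdlStatistic:
    """ADL = one-tenth of the mean adjacent intermutation distance.

    Adjacent distances are taken within each chromosome and pooled across
    chromosomes; a distance equal to the ADL counts as above.  Raises if the
    sample has no chromosome with >= 2 mutations.
    """
    sample_ids = sample_muts["sample"].unique()
    if len(sample_ids) != 1:
        raise ValueError("compute_adl expects mutations of exactly one sample")
    dists = []
    for pos in _positions_by_chrom(sample_muts).values():
        if len(pos) >= 2:
            dists.append(np.diff(pos))
    if not dists:
        raise ValueError(f"insufficient mutations for ADL in sample {sample_ids[0]!r}")
    d = np.concatenate(dists)
    mean = float(d.mean())
    adl = mean / 10.0
    below = int((d < adl).sum())
    return AdlStatistic(
        sample=str(sample_ids[0]),
        mean_distance=mean,
        adl=adl,
        n_below=below,
        n_above=int(len(d) - below),
    )


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher's exact p for enrichment of the first cell.

    For the 2x2 table ``[[a, b], [c, d]]`` (window below/above vs background
    below/above) this is the exact hypergeometric upper tail
    ``P(X >= a)`` for ``X ~ Hypergeom(M=a+b+c+d, K=a+c, n=a+b)``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative count in 2x2 table ({a}, {b}, {c}, {d})")
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def scan_windows(
    sample_muts: pd.DataFrame,
    adl: AdlStatistic,
    window_n: int = DEFAULT_WINDOW_N,
    max_span_bp: int = DEFAULT_MAX_SPAN_BP,
    *,
    include_window_in_background: bool = True,
) -> list[CandidateWindow]:
    """All ``window_n``-mutation windows within ``max_span_bp`` with Fisher p-values.

    Samples with fewer than ``window_n`` mutations on every chromosome yield
    an empty list.  No p-value filtering happens here.
    """
    out: list[CandidateWindow] = []
    for chrom, pos in _positions_by_chrom(sample_muts).items():
        if len(pos) < window_n:
            continue
        d = np.diff(pos)
        below_mask = d < adl.adl
        below_cum = np.concatenate([[0], np.cumsum(below_mask)])
        spans = pos[window_n - 1 :] - pos[: len(pos) - window_n + 1]
        for i in np.flatnonzero(spans <= max_span_bp):
            w_below = int(below_cum[i + window_n - 1] - below_cum[i])
            w_above = (window_n - 1) - w_below
            bg_below, bg_above = adl.n_below, adl.n_above
            if not include_window_in_background:
                bg_below -= w_below
                bg_above -= w_above
            p = fisher_one_tailed(w_below, w_above, bg_below, bg_above)
            out.append(
                CandidateWindow(
                    chrom=chrom,
                    first=int(i),
                    last=int(i + window_n - 1),
                    start=int(pos[i]),
                    end=int(pos[i + window_n - 1]),
                    below=w_below,
                    above=w_above,
                    p=p,
                )
            )
    return out


def _pooled_candidate(
    chrom: str,
    first: int,
    last: int,
    pos: np.ndarray,
    below_mask: np.ndarray,
    adl: AdlStatistic,
    include_window_in_background: bool,
) -> CandidateWindow:
    w_below = int(below_mask[first:last].sum())
    w_above = (last - first) - w_below
    bg_below, bg_above = adl.n_below, adl.n_above
    if not include_window_in_background:
        bg_below -= w_below
        bg_above -= w_above
    p = fisher_one_tailed(w_below, w_above, bg_below, bg_above)
    return CandidateWindow(chrom, first, last, int(pos[first]), int(pos[last]), w_below, w_above, p)


def merge_events(
    sample_muts: pd.DataFrame,
    candidates: list[CandidateWindow],
    adl: AdlStatistic,
    threshold: float = DEFAULT_P_THRESHOLD,
    *,
    include_window_in_background: bool = True,
) -> list[KataegisEvent]:
    """Merge overlapping candidate windows into kataegis events.

    Candidates on the same chromosome that overlap (share a member mutation
    or at least one bp) are chained transitively; each chain's pooled run of
    mutations is re-tested and kept merged only if the recomputed Fisher p
    stays below ``threshold``, otherwise the chain is split back greedily
    into maximal passing prefixes.
    """
    sample = str(sample_muts["sample"].iloc[0]) if len(sample_muts) else ""
    passing = [c for c in candidates if c.p < threshold]
    by_chrom = _positions_by_chrom(sample_muts)
    events: list[KataegisEvent] = []
    for chrom in sorted({c.chrom for c in passing}):
        pos = by_chrom[chrom]
        below_mask = np.diff(pos) < adl.adl
        cands = sorted(
            (c for c in passing if c.chrom == chrom), key=lambda c: (c.first, c.last)
        )
        # transitive chains of overlapping candidates (consecutive-index or bp overlap)
        chains: list[list[CandidateWindow]] = []
        for c in cands:
            if chains and _overlaps(chains[-1][-1], chains[-1], c):
                chains[-1].append(c)
            else:
                chains.append([c])
        for chain in chains:
            i = 0
            while i < len(chain):
                # longest prefix chain[i:j+1] whose pooled region passes
                j_pass = i
                pooled_pass = _pooled_candidate(
                    chrom, chain[i].first, chain[i].last, pos, below_mask, adl,
                    include_window_in_background,
                )
                for j in range(i + 1, len(chain)):
                    pooled = _pooled_candidate(
                        chrom,
                        min(chain[k].first for k in range(i, j + 1)),
                        max(chain[k].last for k in range(i, j + 1)),
                        pos, below_mask, adl, include_window_in_background,
                    )
                    if pooled.p < threshold:
                        j_pass, pooled_pass = j, pooled
                    else:
                        break
                events.append(
                    KataegisEvent(
                        sample=sample,
                        chrom=chrom,
                        start=pooled_pass.start,
                        end=pooled_pass.end,
                        n_mutations=pooled_pass.last - pooled_pass.first + 1,
                        p=pooled_pass.p,
                        member_positions=tuple(
                            int(x) for x in pos[pooled_pass.first : pooled_pass.last + 1]
                        ),
                    )
                )
                i = j_pass + 1
    return events


def _overlaps(last_c: CandidateWindow, chain: list[CandidateWindow], c: CandidateWindow) -> bool:
    chain_last = max(x.last for x in chain)
    chain_end = max(x.end for x in chain)
    return c.first <= chain_last or c.start <= chain_end


def detect_kataegis(
    muts: pd.DataFrame,
    window_n: int = DEFAULT_WINDOW_N,
    max_span_bp: int = DEFAULT_MAX_SPAN_BP,
    threshold: float = DEFAULT_P_THRESHOLD,
    *,
    include_window_in_background: bool = True,
) -> list[KataegisEvent]:
    """Run ADL → window scan → merge for every sample of a cohort table."""
    muts = catalogs.validate_mutations(muts)
    events: list[KataegisEvent] = []
    for _, grp in muts.groupby("sample", sort=True):
        if len(grp) < 2:
            continue
        adl = compute_adl(grp)
        cands = scan_windows(
            grp, adl, window_n, max_span_bp,
            include_window_in_background=include_window_in_background,
        )
        events.extend(
            merge_events(
                grp, cands, adl, threshold,
                include_window_in_background=include_window_in_background,
            )
        )
    return events


def decompose_event(
    event: KataegisEvent,
    muts: pd.DataFrame,
    k_signatures: pd.DataFrame,
) -> KataegisEvent:
    """Attach the K1 contribution and dominance label to one event.

    Builds the event's 96-channel catalog from its member mutations (which
    must carry contexts) and refits it against the two fixed profiles (the
    first column is treated as K1) by NNLS; contribution = K1 / (K1 + K2).
    If both exposures are zero the contribution is undefined and the event
    is flagged ``degenerate``.
    """
    if k_signatures.shape[1] != 2:
        raise ValueError("decomposition needs exactly two fixed signatures (K1, K2)")
    members = muts[
        (muts["sample"] == event.sample)
        & (muts["chrom"] == event.chrom)
        & muts["pos"].isin(event.member_positions)
    ]
    cat = catalogs.build_catalog(members)
    expo, _ = sigmod.refit_exposures(cat, k_signatures)
    k1, k2 = float(expo.iloc[0, 0]), float(expo.iloc[0, 1])
    if k1 + k2 == 0:
        return replace(event, k1_contribution=None, dominance=None, degenerate=True)
    contrib = k1 / (k1 + k2)
    return replace(
        event,
        k1_contribution=contrib,
        dominance="K1-dominant" if contrib > 0.5 else "K2-dominant",
        degenerate=False,
    )


def decompose_events(
    events: list[KataegisEvent], muts: pd.DataFrame, k_signatures: pd.DataFrame
) -> list[KataegisEvent]:
    return [decompose_event(e, muts, k_signatures) for e in events]


def summarize_samples(
    events: list[KataegisEvent], all_samples: list[str]
) -> pd.DataFrame:
    """Per-sample kataegis summary and K1-high/K1-low grouping.

    The per-sample K1 contribution is the unweighted mean over that sample's
    events; the cohort is split at the median of these means (samples with
    at least one event only): strictly above the median → ``K1-high``, at or
    below → ``K1-low``; samples without events → ``no-kataegis``.
    """
    rows = {s: [] for s in all_samples}
    for e in events:
        if e.k1_contribution is not None:
            rows.setdefault(e.sample, []).append(e.k1_contribution)
    counts = {s: 0 for s in all_samples}
    for e in events:
        counts[e.sample] = counts.get(e.sample, 0) + 1
    means = {s: (float(np.mean(v)) if v else np.nan) for s, v in rows.items()}
    with_events = [s for s in all_samples if counts.get(s, 0) > 0 and not np.isnan(means[s])]
    median = float(np.median([means[s] for s in with_events])) if with_events else np.nan
    out = []
    for s in all_samples:
        if counts.get(s, 0) == 0:
            group = "no-kataegis"
        elif np.isnan(means[s]):
            group = "no-kataegis"
        else:
            group = "K1-high" if means[s] > median else "K1-low"
        out.append((s, counts.get(s, 0), means[s], group))
    df = pd.DataFrame(out, columns=["sample", "n_events", "mean_k1_contribution", "group"])
    df.attrs["median_k1_contribution"] = median
    return df


def annotate_events(
    events: list[KataegisEvent],
    ig_intervals: pd.DataFrame,
    tss: pd.DataFrame,
    proximal_bp: int = DEFAULT_PROXIMAL_BP,
) -> list[KataegisEvent]:
    """Classify each event as Ig:V / Ig:S / Ig:J&C or TSS-proximal/-distal.

    ``ig_intervals``: BED-derived frame with columns chrom, start (0-based),
    end (half-open), name (subclass in {V, S, J&C}).  ``tss``: frame with
    columns chrom, pos (1-based anchor per gene).  An event overlapping an
    Ig interval by >= 1 bp takes that interval's subclass (largest overlap
    wins); otherwise the distance from the event midpoint to the nearest TSS
    decides: <= ``proximal_bp`` → "TSS-proximal", else "TSS-distal".
    """
    out = []
    for e in events:
        cls = None
        best_overlap = 0
        for _, iv in ig_intervals[ig_intervals["chrom"] == e.chrom].iterrows():
            lo = max(e.start, int(iv["start"]) + 1)   # bed start is 0-based
            hi = min(e.end, int(iv["end"]))
            if hi - lo + 1 > best_overlap:
                best_overlap = hi - lo + 1
                cls = f"Ig:{iv['name']}"
        if cls is None:
            mid = (e.start + e.end) // 2
            near = tss[tss["chrom"] == e.chrom]["pos"]
            dist = int(np.min(np.abs(near.to_numpy() - mid))) if len(near) else None
            if dist is not None and dist <= proximal_bp:
                cls = "TSS-proximal"
            else:
                cls = "TSS-distal"
        out.append(replace(e, region_class=cls))
    return out


def events_to_frame(events: list[KataegisEvent]) -> pd.DataFrame:
    """BED-like table of events (start0 is 0-based for BED compatibility)."""
    rows = [
        (
            e.chrom, e.start - 1, e.end, e.sample, e.n_mutations, e.p,
            e.k1_contribution, e.dominance, e.region_class,
        )
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start0", "end", "sample", "n_mutations", "p",
            "k1_contribution", "dominance", "region_class",
        ],
    )
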