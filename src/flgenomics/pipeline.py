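"""End-to-end pipeline orchestration.

A :class:`RunConfig` (loadable from YAML/JSON) drives the full analysis:
simulate or load a cohort, build the 96-channel catalog, extract and refit
signatures, detect and decompose kataegis, encode lesions and run consensus
subtyping, then emit group-comparison statistics.  Every stage writes plain
TSV/JSON outputs plus a manifest with the seed and SHA-256 checksums;
rerunning the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalogs, io as fio, kataegis as kat, signatures as sigmod, simulate as sim
from . import stats, subtyping

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; the seed is mandatory (reproducibility)."""

    outdir: str = "flgenomics-out"
    seed: int | None = None
    # simulation block (used when no input paths are given)
    n_samples: int = 12
    background_rate: float = 1500.0
    n_kataegis_per_sample: int = 2
    cluster_spec: dict = field(default_factory=dict)
    # inputs (optional; override simulation)
    vcf_paths: list[str] = field(default_factory=list)
    mutations_tsv: str | None = None
    lesions_tsv: str | None = None
    markers_tsv: str | None = None
    ig_bed: str | None = None
    tss_bed: str | None = None
    k_signatures_tsv: str | None = None
    # analysis parameters
    window_n: int = kat.DEFAULT_WINDOW_N
    max_span_bp: int = kat.DEFAULT_MAX_SPAN_BP
    p_threshold: float = kat.DEFAULT_P_THRESHOLD
    proximal_bp: int = kat.DEFAULT_PROXIMAL_BP
    extract_k: int | None = 2
    extract_restarts: int = 30
    k_range: list[int] = field(default_factory=lambda: list(range(2, 7)))
    n_runs: int = 50

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set a seed (reproducibility is mandatory)")
        for name in ("window_n", "max_span_bp", "p_threshold", "proximal_bp", "n_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns the map of output names to paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ksig = (
        sigmod.read_signatures(config.k_signatures_tsv)
        if config.k_signatures_tsv
        else sigmod.kataegis_fixture_signatures()
    )
    outputs: dict[str, Path] = {}

    # --- stage: cohort -----------------------------------------------------
    try:
        if config.vcf_paths:
            muts = fio.read_mutations_vcf(config.vcf_paths)
            lesions = None
        elif config.mutations_tsv:
            muts = fio.read_mutations_tsv(config.mutations_tsv)
            lesions = None
        else:
            muts, lesions = _simulate_cohort(config, ksig, rng)
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    logger.info("cohort: %d mutations, %d samples", len(muts), muts["sample"].nunique())
    muts.to_csv(out / "mutations.tsv", sep="\t", index=False)
    outputs["mutations"] = out / "mutations.tsv"

    # --- stage: catalog ----------------------------------------------------
    catalog = catalogs.build_catalog(muts)
    catalogs.write_catalog(catalog, out / "catalog.tsv")
    outputs["catalog"] = out / "catalog.tsv"
    logger.info("catalog: %d samples x 96 channels", len(catalog))

    # --- stage: signatures -------------------------------------------------
    try:
        extraction = sigmod.extract_signatures(
            catalog,
            k_range=config.k_range,
            n_restarts=config.extract_restarts,
            seed=int(rng.integers(0, 2**31 - 1)),
            k=config.extract_k,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'signatures' failed: {exc}") from exc
    sigmod.write_signatures(extraction.signatures, out / "signatures.tsv")
    extraction.exposures.to_csv(out / "exposures.tsv", sep="\t")
    expo_prop = extraction.exposures.div(extraction.exposures.sum(axis=1), axis=0)
    expo_prop.to_csv(out / "exposures_proportions.tsv", sep="\t")
    match = sigmod.cosine_similarity_table(extraction.signatures, ksig)
    match.to_csv(out / "signature_match.tsv", sep="\t", index=False)
    outputs.update(
        {
            "signatures": out / "signatures.tsv",
            "exposures": out / "exposures.tsv",
            "signature_match": out / "signature_match.tsv",
        }
    )

    # --- stage: kataegis ---------------------------------------------------
    try:
        events = kat.detect_kataegis(
            muts, config.window_n, config.max_span_bp, config.p_threshold
        )
        if "context" in muts.columns:
            events = kat.decompose_events(events, muts, ksig)
        if config.ig_bed and config.tss_bed:
            events = kat.annotate_events(
                events,
                fio.read_bed(config.ig_bed, expect_name=True),
                fio.read_tss_bed(config.tss_bed),
                config.proximal_bp,
            )
        summary = kat.summarize_samples(events, sorted(muts["sample"].unique()))
    except Exception as exc:
        raise RuntimeError(f"stage 'kataegis' failed: {exc}") from exc
    kat.events_to_frame(events).to_csv(out / "kataegis_events.tsv", sep="\t", index=False)
    summary.to_csv(out / "kataegis_summary.tsv", sep="\t", index=False)
    outputs["kataegis_events"] = out / "kataegis_events.tsv"
    outputs["kataegis_summary"] = out / "kataegis_summary.tsv"
    logger.info("kataegis: %d events", len(events))

    # --- stage: subtyping --------------------------------------------------
    if config.lesions_tsv and config.markers_tsv:
        calls = fio.read_lesion_calls(config.lesions_tsv)
        markers = fio.read_marker_table(config.markers_tsv)
        truth = None
    elif lesions is not None:
        calls, markers, truth = lesions.calls, lesions.markers, lesions.truth
    else:
        calls = markers = truth = None
    if calls is not None:
        try:
            matrix = subtyping.encode_lesions(calls, markers)
            consensus = subtyping.nmf_consensus(
                matrix,
                k_range=config.k_range,
                n_runs=config.n_runs,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            marker_table = subtyping.cluster_markers(matrix, consensus.labels)
        except Exception as exc:
            raise RuntimeError(f"stage 'subtyping' failed: {exc}") from exc
        matrix.to_csv(out / "lesion_matrix.tsv", sep="\t")
        consensus.labels.to_frame().to_csv(out / "cluster_labels.tsv", sep="\t")
        pd.Series(consensus.cophenetic, name="cophenetic").rename_axis("k").to_csv(
            out / "cophenetic.tsv", sep="\t"
        )
        marker_table.to_csv(out / "cluster_markers.tsv", sep="\t", index=False)
        outputs.update(
            {
                "lesion_matrix": out / "lesion_matrix.tsv",
                "cluster_labels": out / "cluster_labels.tsv",
                "cophenetic": out / "cophenetic.tsv",
                "cluster_markers": out / "cluster_markers.tsv",
            }
        )
        logger.info("subtyping: selected K=%d", consensus.selected_k)

        # --- stage: comparisons -------------------------------------------
        comparisons = _group_comparisons(extraction.exposures, summary, consensus.labels, truth)
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        outputs["comparisons"] = out / "comparisons.tsv"

    manifest = {
        "package": "flgenomics",
        "version": pkg_version("flgenomics"),
        "seed": config.seed,
        "config": asdict(config),
        "checksums": {k: _sha256(p) for k, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = out / "manifest.json"
    return outputs


def _simulate_cohort(config: RunConfig, ksig: pd.DataFrame, rng) -> tuple:
    plan: dict[str, list[sim.KataegisPlan]] = {}
    spec = sim.CohortSpec(
        n_samples=config.n_samples,
        background_rate=config.background_rate,
        signature_mix=None,
        kataegis_plan=plan,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    chroms = list(spec.chrom_lengths)
    for i, sample in enumerate(spec.sample_ids()):
        plans = []
        for j in range(config.n_kataegis_per_sample):
            chrom = chroms[(i + j) % len(chroms)]
            start = int(rng.integers(10_000, spec.chrom_lengths[chrom] - 20_000))
            source = ksig.columns[int(rng.integers(0, ksig.shape[1]))]
            plans.append(
                sim.KataegisPlan(
                    chrom=chrom, start=start, n_mutations=int(rng.integers(10, 21)),
                    max_span_bp=5_000, source_signature=str(source),
                )
            )
        plan[sample] = plans
    muts = sim.simulate_mutations(spec, ksig)
    cspec = sim.ClusterSpec(seed=int(rng.integers(0, 2**31 - 1)), **config.cluster_spec)
    lesions = sim.simulate_lesions(cspec)
    return muts, lesions


def _group_comparisons(exposures, summary, cluster_labels, truth) -> pd.DataFrame:
    """Rank-sum/chi-square readouts over the cohort groupings."""
    rows = []
    grouped = summary[summary["group"].isin(["K1-high", "K1-low"])]
    if grouped["group"].nunique() == 2:
        for sig in exposures.columns:
            vals = exposures.loc[grouped["sample"], sig].to_numpy()
            cmp_ = stats.compare_groups(
                vals, grouped["group"].to_numpy(), variable=f"exposure:{sig}",
                grouping="K1-group", test="rank-sum",
            )
            rows.append(cmp_)
    if truth is not None:
        common = summary.set_index("sample").join(truth, how="inner")
        common = common[common["group"] != "no-kataegis"]
        if len(common) and common["cluster"].nunique() >= 2 and common["group"].nunique() >= 2:
            cmp_ = stats.compare_groups(
                common["group"].to_numpy(), common["cluster"].to_numpy(),
                variable="K1-group", grouping="true-cluster", test="chi-square",
            )
            rows.append(cmp_)
    return pd.DataFrame([asdict(r) for r in rows])
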