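"""Signature extraction, matching, and exposure refitting.

A *signature set* is a DataFrame of non-negative profiles over the 96
substitution channels (rows = canonical channel labels, columns = signature
names, each column summing to 1).  An *exposure matrix* is samples x
signatures with entries in mutation counts.

De-novo extraction runs non-negative matrix factorisation under the
generalised Kullback-Leibler divergence with multiplicative updates — the
convention of the mutational-signature literature — from many random
restarts; restart components are matched by cosine similarity and their
silhouette measures the stability of each factorisation rank.  Exposures
against a *fixed* signature set are obtained by per-sample non-negative
least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .channels import CHANNELS

NORMALIZATION_TOL = 1e-9


def validate_signatures(sig: pd.DataFrame) -> pd.DataFrame:
    """Check a signature set: canonical channel order, non-negative, columns sum to 1."""
    if list(sig.index) != list(CHANNELS):
        raise ValueError("signature matrix rows must be the 96 channels in canonical order")
    vals = sig.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("signature profiles must be non-negative")
    sums = vals.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = sig.columns[np.abs(sums - 1.0) > 1e-6].tolist()
        raise ValueError(f"signature columns not normalised to 1: {bad}")
    return sig


def normalize_signatures(profiles: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise non-negative profiles to sum 1 (zero columns rejected)."""
    sums = profiles.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("cannot normalise an all-zero signature column")
    return profiles / sums


def kataegis_fixture_signatures() -> pd.DataFrame:
    """Bundled K1-like / K2-like reference profiles for kataegis decomposition.

    The kataegis signatures attributed to AID (K1) and POLH (K2) activity are
    emulated with two synthetic profiles on disjoint channel support:

    * ``K1-like`` — C>T and C>G restricted to a 5' A/T flank (the W of the
      AID WRCY hotspot motif), C>T weighted 2:1 over C>G; 16 channels.
    * ``K2-like`` — T>N dominated (T>C 0.6, T>G 0.3, T>A 0.1, uniform within
      each substitution type), emulating POLH-driven A:T mutagenesis.

    Disjoint support (C>* vs T>*) makes the pair orthogonal, so mixture
    fractions refit by NNLS are identifiable exactly.
    """
    prof = pd.DataFrame(0.0, index=list(CHANNELS), columns=["K1-like", "K2-like"])
    for sub, w in (("C>T", 2.0), ("C>G", 1.0)):
        for five in "AT":
            for three in "ACGT":
                prof.loc[f"{five}[{sub}]{three}", "K1-like"] = w
    for sub, mass in (("T>C", 0.6), ("T>G", 0.3), ("T>A", 0.1)):
        for five in "ACGT":
            for three in "ACGT":
                prof.loc[f"{five}[{sub}]{three}", "K2-like"] = mass / 16.0
    prof.index.name = "channel"
    return validate_signatures(normalize_signatures(prof))


def cosine_similarity_table(extracted: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """All-pairs cosine similarity between two signature sets.

    Both sets must use the identical canonical channel order (a differing
    order is an error, never silently re-sorted).  Returns a long table with
    columns ``extracted, reference, cosine, best_match`` where ``best_match``
    flags, for each extracted signature, its highest-similarity reference.
    """
    if list(extracted.index) != list(reference.index):
        raise ValueError("channel order mismatch between signature sets")
    a = extracted.to_numpy(dtype=float)
    b = reference.to_numpy(dtype=float)
    an = np.linalg.norm(a, axis=0)
    bn = np.linalg.norm(b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (a.T @ b) / np.outer(an, bn)
    sim = np.nan_to_num(sim)
    rows = []
    for i, e in enumerate(extracted.columns):
        j_best = int(np.argmax(sim[i]))
        for j, r in enumerate(reference.columns):
            rows.append((e, r, float(sim[i, j]), j == j_best))
    return pd.DataFrame(rows, columns=["extracted", "reference", "cosine", "best_match"])


def refit_exposures(
    catalog: pd.DataFrame, fixed: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample non-negative least-squares refit against fixed signatures.

    Solves ``min ||x - S e||_2, e >= 0`` for each catalog row ``x`` with the
    96 x K signature matrix ``S``.  Returns (exposures, residual l2 norm per
    sample); exposures are in mutation counts attributed to each signature.
    """
    validate_signatures(fixed)
    if list(catalog.columns) != list(CHANNELS):
        raise ValueError("catalog columns must be the 96 channels in canonical order")
    S = fixed.to_numpy(dtype=float)
    expo = np.zeros((len(catalog), S.shape[1]))
    resid = np.zeros(len(catalog))
    for i, x in enumerate(catalog.to_numpy(dtype=float)):
        expo[i], resid[i] = nnls(S, x)
    exposures = pd.DataFrame(expo, index=catalog.index, columns=fixed.columns)
    return exposures, pd.Series(resid, index=catalog.index, name="residual")


@dataclass
class ExtractionResult:
    """Output of de-novo signature extraction."""

    signatures: pd.DataFrame          # 96 x k, column-normalised
    exposures: pd.DataFrame           # samples x k, counts
    selected_k: int
    stability: dict[int, float]       # mean silhouette of matched restart components
    reconstruction_error: dict[int, float]
    excluded_samples: list = field(default_factory=list)


def _nmf_once(X: np.ndarray, k: int, seed: int, beta_loss: str) -> tuple[float, np.ndarray, np.ndarray]:
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss=beta_loss,
        max_iter=600,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(X)
    return float(model.reconstruction_err_), W, model.components_


def extract_signatures(
    catalog: pd.DataFrame,
    k_range=range(2, 6),
    n_restarts: int = 100,
    seed: int = 0,
    *,
    beta_loss: str = "kullback-leibler",
    stability_threshold: float = 0.8,
    k: int | None = None,
) -> ExtractionResult:
    """Extract de-novo signatures from a catalog by restarted NMF.

    For each candidate rank the catalog ``X`` (samples x 96) is factorised
    ``n_restarts`` times from seeded random non-negative initialisations,
    minimising the generalised KL divergence with multiplicative updates
    (``beta_loss="frobenius"`` available as an option).  Each restart's
    components are matched to the best-error restart by cosine similarity
    (Hungarian assignment); the mean silhouette of the pooled, matched
    components (cosine metric) is the rank's stability.

    The selected rank is the largest one whose stability meets
    ``stability_threshold`` (falling back to the most stable rank if none
    does); pass ``k`` to override model selection entirely.

    All-zero catalog rows are excluded with a warning and reported in
    ``excluded_samples``; their exposures are zero.
    """
    if list(catalog.columns) != list(CHANNELS):
        raise ValueError("catalog columns must be the 96 channels in canonical order")
    ks = [k] if k is not None else list(k_range)
    if min(ks) < 1 or max(ks) > min(catalog.shape[0], 96):
        raise ValueError(f"requested rank(s) {ks} outside [1, min(n_samples, 96)]")

    zero = catalog.sum(axis=1) == 0
    excluded = catalog.index[zero].tolist()
    if excluded:
        warnings.warn(f"excluding {len(excluded)} all-zero samples from extraction")
    X = catalog.loc[~zero].to_numpy(dtype=float)
    if min(ks) > np.linalg.matrix_rank(X):
        raise ValueError("requested rank exceeds the numerical rank of the catalog")

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=(len(ks), n_restarts))

    stability: dict[int, float] = {}
    recon: dict[int, float] = {}
    best_runs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ki, kk in enumerate(ks):
        runs = [_nmf_once(X, kk, int(s), beta_loss) for s in run_seeds[ki]]
        errs = [r[0] for r in runs]
        ibest = int(np.argmin(errs))
        recon[kk] = errs[ibest]
        ref = _l2_normalise_rows(runs[ibest][2])
        comps, labels = [], []
        for _, _, H in runs:
            Hn = _l2_normalise_rows(H)
            # match this restart's components to the reference components
            cost = -(Hn @ ref.T)
            ri, ci = linear_sum_assignment(cost)
            order = np.empty(kk, dtype=int)
            order[ci] = ri
            comps.append(Hn[order])
            labels.extend(range(kk))
        pooled = np.vstack(comps)
        if kk == 1:
            stability[kk] = 1.0
        else:
            stability[kk] = float(silhouette_score(pooled, labels, metric="cosine"))
        best_runs[kk] = runs[ibest][1:]

    if k is not None:
        selected = k
    else:
        passing = [kk for kk in ks if stability[kk] >= stability_threshold]
        selected = max(passing) if passing else max(stability, key=stability.get)

    W, H = best_runs[selected]
    scale = H.sum(axis=1)
    signatures = pd.DataFrame(
        (H / scale[:, None]).T,
        index=list(CHANNELS),
        columns=[f"Sig{j + 1}" for j in range(selected)],
    )
    signatures.index.name = "channel"
    expo = pd.DataFrame(0.0, index=catalog.index, columns=signatures.columns)
    expo.loc[~zero] = W * scale[None, :]
    return ExtractionResult(
        signatures=validate_signatures(signatures),
        exposures=expo,
        selected_k=selected,
        stability=stability,
        reconstruction_error=recon,
        excluded_samples=excluded,
    )


def _l2_normalise_rows(H: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(H, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return H / n


def read_signatures(path) -> pd.DataFrame:
    """Read a signature TSV (channel rows in canonical order, one column per signature)."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signatures(sig)


def write_signatures(sig: pd.DataFrame, path) -> None:
    sig.to_csv(path, sep="\t", index_label="channel")
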