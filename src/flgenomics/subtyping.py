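"""Genetic-subtype discovery: lesion encoding and NMF consensus clustering.

Gene-level mutations, copy-number peaks, and structural variants are encoded
into an integer lesion matrix (samples x markers, scores 0-3):

=====================  =====
lesion                 score
=====================  =====
nonsilent / indel        2
synonymous               1
no mutation              0
CNV gain  > 3.7          2
CNV gain  2.4 - 3.7      1
CNV neutral              0
CNV loss  0.8 - 1.6      1
CNV loss  <= 0.8         2
SV present               3
=====================  =====

Gain peaks score only gains and loss peaks only losses; the boundary values
3.7 (low-grade gain) and 0.80 (high-grade loss) belong to the tiers shown.

The matrix is clustered by NMF consensus: for each candidate rank K, many
seeded NMF runs each assign every sample to its maximum-loading factor; the
fraction of runs co-assigning two samples forms the consensus matrix, whose
cophenetic coefficient (fit between 1-consensus and its average-linkage
dendrogram) selects K.  Cluster markers are then found per cluster by
Fisher's exact test on lesioned-vs-not contingency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from sklearn.decomposition import NMF

MUTATION_SCORES = {"nonsilent": 2, "indel": 2, "synonymous": 1, "none": 0}


def score_copy_number(cn: float, kind: str) -> int:
    """Score an absolute copy number at a gain or loss peak."""
    if cn < 0:
        raise ValueError(f"negative copy number {cn}")
    if kind == "cnv_gain_peak":
        if cn > 3.7:
            return 2
        if cn >= 2.4:
            return 1
        return 0
    if kind == "cnv_loss_peak":
        if cn <= 0.80:
            return 2
        if cn <= 1.6:
            return 1
        return 0
    raise ValueError(f"not a CNV marker kind: {kind!r}")


def encode_lesions(calls: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Encode lesion calls into the integer samples x markers matrix.

    ``calls``: long table (sample, marker, kind, detail) — detail is the
    consequence class for mutations, the absolute copy number for CNV
    peaks, and a 0/1 presence flag for SVs.  ``markers``: metadata frame
    indexed by marker with a ``kind`` column; defines the column set.
    Absent (sample, marker) pairs score 0.
    """
    unknown = set(calls["marker"]) - set(markers.index)
    if unknown:
        raise ValueError(f"calls reference markers not in the marker list: {sorted(unknown)[:5]}")
    samples = pd.Index(sorted(calls["sample"].unique()), name="sample")
    matrix = pd.DataFrame(0, index=samples, columns=markers.index, dtype=np.int64)
    for _, r in calls.iterrows():
        kind = markers.loc[r["marker"], "kind"]
        if kind == "mutation":
            cons = str(r["detail"])
            if cons not in MUTATION_SCORES:
                raise ValueError(f"unknown mutation consequence {cons!r}")
            score = MUTATION_SCORES[cons]
        elif kind in ("cnv_gain_peak", "cnv_loss_peak"):
            score = score_copy_number(float(r["detail"]), kind)
        elif kind == "sv":
            score = 3 if int(float(r["detail"])) else 0
        else:
            raise ValueError(f"unknown marker kind {kind!r}")
        # one record per (sample, marker) after collapsing; keep the max score
        prev = matrix.at[r["sample"], r["marker"]]
        matrix.at[r["sample"], r["marker"]] = max(prev, score)
    return matrix


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the 1-consensus distance matrix.

    Pearson correlation between the condensed distances and the cophenetic
    distances of their average-linkage dendrogram.  Degenerate cases: with
    fewer than 3 samples the dendrogram reproduces the single distance
    exactly (returns 1.0); if all distances are identical the correlation is
    undefined and NaN is returned.
    """
    consensus = np.asarray(consensus, dtype=float)
    if consensus.shape[0] != consensus.shape[1] or not np.allclose(consensus, consensus.T):
        raise ValueError("consensus matrix must be symmetric")
    if not np.allclose(np.diag(consensus), 1.0):
        raise ValueError("consensus matrix must have unit diagonal")
    n = consensus.shape[0]
    if n < 3:
        return 1.0
    dist = squareform(1.0 - consensus, checks=False)
    if np.ptp(dist) == 0:
        return float("nan")
    Z = linkage(dist, method="average")
    c, _ = cophenet(Z, dist)
    return float(c)


@dataclass
class ConsensusResult:
    """Consensus-clustering output across the candidate rank range."""

    consensus: dict[int, np.ndarray]
    cophenetic: dict[int, float]
    selected_k: int
    labels: pd.Series                  # sample -> cluster label in 1..K
    run_seeds: dict[int, list[int]] = field(default_factory=dict)
    zero_samples: list = field(default_factory=list)


def _nmf_assign(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    model = NMF(
        n_components=k, init="random", solver="mu", beta_loss="frobenius",
        max_iter=300, tol=1e-4, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(X)
    return np.argmax(W, axis=1)


def nmf_consensus(
    matrix: pd.DataFrame,
    k_range=range(2, 11),
    n_runs: int = 100,
    seed: int = 0,
) -> ConsensusResult:
    """NMF consensus clustering with cophenetic rank selection.

    For each K in ``k_range``, ``n_runs`` NMF factorisations from seeded
    random initialisations each assign samples to their maximum-loading
    factor; consensus(i, j) is the co-assignment fraction.  The K with the
    highest cophenetic coefficient wins (ties -> smaller K) and final labels
    come from average-linkage hierarchical clustering of 1-consensus cut at
    that K.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("lesion matrix must be non-negative")
    if np.ptp(X) == 0:
        raise ValueError("degenerate input: constant lesion matrix")
    ks = list(k_range)
    if len(matrix) < 2 * max(ks):
        raise ValueError(f"need >= {2 * max(ks)} samples for k_range up to {max(ks)}")
    zero_samples = matrix.index[X.sum(axis=1) == 0].tolist()

    master = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    coph: dict[int, float] = {}
    run_seeds: dict[int, list[int]] = {}
    n = len(matrix)
    for k in ks:
        seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_runs)]
        run_seeds[k] = seeds
        C = np.zeros((n, n))
        for s in seeds:
            a = _nmf_assign(X, k, s)
            C += (a[:, None] == a[None, :])
        C /= n_runs
        np.fill_diagonal(C, 1.0)
        consensus[k] = C
        coph[k] = cophenetic_coefficient(C)

    finite = {k: v for k, v in coph.items() if np.isfinite(v)}
    pick_from = finite if finite else coph
    best = max(pick_from.values())
    selected = min(k for k, v in pick_from.items() if v == best)

    dist = squareform(1.0 - consensus[selected], checks=False)
    Z = linkage(dist, method="average")
    raw = fcluster(Z, t=selected, criterion="maxclust")
    labels = pd.Series(raw, index=matrix.index, name="cluster")
    return ConsensusResult(
        consensus=consensus,
        cophenetic=coph,
        selected_k=selected,
        labels=labels,
        run_seeds=run_seeds,
        zero_samples=zero_samples,
    )


def cluster_markers(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher-exact marker discovery per (marker, cluster).

    A sample counts as lesioned at a marker when its score is > 0 (so a
    synonymous mutation counts).  For every marker and cluster, the 2x2
    table (lesioned/not x in-cluster/rest) is tested by Fisher's exact test
    (two-sided by default; pass ``alternative="greater"`` for one-sided
    enrichment); a marker is assigned to a cluster when p <= ``alpha`` and
    the in-cluster odds ratio exceeds 1.  The full table, including
    non-significant rows, is returned.
    """
    labels = labels.loc[matrix.index]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("marker discovery needs >= 2 clusters")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("empty cluster")
    lesioned = matrix.to_numpy() > 0
    rows = []
    for mi, marker in enumerate(matrix.columns):
        for cl in clusters:
            inc = (labels == cl).to_numpy()
            a = int((lesioned[:, mi] & inc).sum())        # lesioned, in cluster
            b = int((~lesioned[:, mi] & inc).sum())       # intact, in cluster
            c = int((lesioned[:, mi] & ~inc).sum())       # lesioned, rest
            d = int((~lesioned[:, mi] & ~inc).sum())      # intact, rest
            odds, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
            enriched = a * d > b * c
            rows.append((marker, cl, a, b, c, d, p, odds, bool(p <= alpha and enriched)))
    return pd.DataFrame(
        rows,
        columns=["marker", "cluster", "a", "b", "c", "d", "p", "odds_ratio", "assigned"],
    )


def classify_new_sample(
    row: pd.Series, training_matrix: pd.DataFrame, labels: pd.Series
) -> tuple[int, bool]:
    """Nearest-centroid (cosine) assignment of a new lesion-score row.

    Returns (cluster label, low_confidence flag).  An all-zero row has no
    direction in score space; it is assigned to the smallest-norm centroid
    and flagged low-confidence.
    """
    missing = [m for m in training_matrix.columns if m not in row.index]
    if missing:
        raise ValueError(f"sample is missing markers: {missing[:5]}")
    x = row.loc[training_matrix.columns].to_numpy(dtype=float)
    labels = labels.loc[training_matrix.index]
    centroids = {
        cl: training_matrix[labels == cl].mean(axis=0).to_numpy() for cl in sorted(labels.unique())
    }
    if np.linalg.norm(x) == 0:
        cl = min(centroids, key=lambda c: np.linalg.norm(centroids[c]))
        return int(cl), True
    best, best_sim = None, -np.inf
    for cl, mu in centroids.items():
        nm = np.linalg.norm(mu)
        sim = float(x @ mu / (np.linalg.norm(x) * nm)) if nm > 0 else -1.0
        if sim > best_sim:
            best, best_sim = cl, sim
    return int(best), False
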