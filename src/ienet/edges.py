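"""Edge networks and fourth-order (edge-pair) correlations.

An *edge* is an unordered taxon pair; the top-ranked edges (by correlation
strength) become the "nodes" of the edge-network. Each edge (i, j) has a
per-sample profile

    e(s) = z_i(s) * z_j(s),   z = (x - mu_ref) / sd_ref,

the product of reference-standardized abundances, i.e. a second-order
(pairwise) quantity. The *fourth-order* sPCC of an edge-pair (e1, e2) is the
single-sample perturbation of the Pearson correlation between the two edge
profiles — a correlation of two products of two variables, hence order four.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ReferenceNetwork

Edge = tuple[str, str]


def _canonical(i: str, j: str) -> Edge:
    return (i, j) if str(i) <= str(j) else (j, i)


@dataclass
class EdgeNetwork:
    """Ranked list of selected edges (taxon pairs) with selection scores."""

    edges: list[Edge]
    scores: list[float]
    ranking: str  # "max_spcc" or "reference_pcc"
    top_k: int
    truncated: bool = False  # True when k exceeded the available pairs

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("edge list contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_i": [e[0] for e in self.edges],
                "taxon_j": [e[1] for e in self.edges],
                "score": self.scores,
                "rank": np.arange(1, len(self.edges) + 1),
            }
        )


def default_top_k(n_pairs: int) -> int:
    """Default edge-network size: min(200, 10% of all pairs), at least 1."""
    return max(1, min(200, n_pairs // 10))


def _all_pairs(taxa: list[str]) -> list[Edge]:
    return [(taxa[a], taxa[b]) for a in range(len(taxa)) for b in range(a + 1, len(taxa))]


def select_top_edges(
    ref: ReferenceNetwork,
    X_query=None,
    k: int | None = None,
    ranking: str = "max_spcc",
) -> EdgeNetwork:
    """Select the top-k strongest edges as edge-network nodes.

    ranking="max_spcc" (default) scores each taxon pair by the maximum of
    |sPCC| over the query (non-reference) samples, capturing pairs strongly
    perturbed in any disease sample; ranking="reference_pcc" scores by
    |PCC_ref| instead. Ties break lexicographically on the taxon-id pair.
    """
    if ranking not in ("max_spcc", "reference_pcc"):
        raise ValueError(f"unknown ranking {ranking!r}")
    taxa = ref.taxa_
    pairs = _all_pairs(taxa)
    if k is None:
        k = default_top_k(len(pairs))
    if k < 1:
        raise ValueError("k must be >= 1")

    if ranking == "reference_pcc":
        score_mat = np.abs(ref.correlation_)
    else:
        if X_query is None:
            raise ValueError("ranking='max_spcc' requires query samples")
        frame = X_query if isinstance(X_query, pd.DataFrame) else pd.DataFrame(np.asarray(X_query, dtype=float), columns=ref.taxa_)
        score_mat = np.zeros_like(ref.correlation_)
        for _, row in frame.iterrows():
            score_mat = np.maximum(score_mat, np.abs(ref.spcc_matrix(row).to_numpy()))

    idx = {t: a for a, t in enumerate(taxa)}
    scored = [(float(score_mat[idx[i], idx[j]]), (i, j)) for i, j in pairs]
    scored.sort(key=lambda t: (-t[0], t[1]))
    truncated = k > len(scored)
    chosen = scored[: min(k, len(scored))]
    return EdgeNetwork(
        edges=[p for _, p in chosen],
        scores=[s for s, _ in chosen],
        ranking=ranking,
        top_k=k,
        truncated=truncated,
    )


def edge_profile(ref: ReferenceNetwork, X, edge: Edge) -> np.ndarray:
    """Per-sample edge variable z_i * z_j over the rows of X."""
    z = ref.zscores(X)
    a, b = ref._index_of(edge[0]), ref._index_of(edge[1])
    return z[:, a] * z[:, b]


def _profile_matrix(ref: ReferenceNetwork, values: np.ndarray, edges: list[Edge]) -> np.ndarray:
    """(n_samples, n_edges) matrix of edge profiles; ``values`` already retained-taxa ordered."""
    z = (values - ref.mean_) / ref.std_
    idx = {t: a for a, t in enumerate(ref.taxa_)}
    cols = [z[:, idx[i]] * z[:, idx[j]] for i, j in edges]
    return np.column_stack(cols)


@dataclass
class EdgePairScores:
    """Fourth-order sPCC for every pair of edges of one sample's edge-network.

    ``matrix`` is symmetric with zero diagonal over ``edges``; edges whose
    profile is constant across the reference carry no correlation and are
    flagged in ``degenerate_edges`` (their rows/columns are NaN).
    """

    sample_id: str
    edges: list[Edge]
    matrix: np.ndarray
    degenerate_edges: list[Edge] = field(default_factory=list)

    def score(self, e1: Edge, e2: Edge) -> float:
        a = self.edges.index(_canonical(*e1))
        b = self.edges.index(_canonical(*e2))
        if a == b:
            raise ValueError("edge-pair requires two distinct edges")
        return float(self.matrix[a, b])

    def pairs(self):
        """Iterate (e1, e2, score) over unordered non-degenerate edge pairs."""
        for a in range(len(self.edges)):
            for b in range(a + 1, len(self.edges)):
                v = self.matrix[a, b]
                if np.isfinite(v):
                    yield self.edges[a], self.edges[b], float(v)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"edge_1": f"{e1[0]}|{e1[1]}", "edge_2": f"{e2[0]}|{e2[1]}", "score": v}
            for e1, e2, v in self.pairs()
        ]
        return pd.DataFrame(rows)


def fourth_order_spcc_matrix(
    ref: ReferenceNetwork, sample, network: EdgeNetwork, sample_id: str = ""
) -> EdgePairScores:
    """All fourth-order sPCC scores for one sample over an edge-network.

    The perturbation form mirrors the node-level sPCC: Pearson correlation of
    the two edge profiles over (reference + sample) minus the correlation
    over the reference alone.
    """
    vec = ref._sample_vector(sample)
    edges = list(network.edges)
    prof_ref = _profile_matrix(ref, ref.reference_, edges)
    prof_s = _profile_matrix(ref, vec[None, :], edges)
    degenerate_mask = prof_ref.var(axis=0) == 0
    degenerate = [e for e, bad in zip(edges, degenerate_mask) if bad]

    with np.errstate(invalid="ignore", divide="ignore"):
        corr_ref = np.corrcoef(prof_ref, rowvar=False)
        corr_aug = np.corrcoef(np.vstack([prof_ref, prof_s]), rowvar=False)
    corr_ref = np.atleast_2d(corr_ref)
    corr_aug = np.atleast_2d(corr_aug)
    delta = corr_aug - corr_ref
    np.fill_diagonal(delta, 0.0)
    delta[degenerate_mask, :] = np.nan
    delta[:, degenerate_mask] = np.nan
    return EdgePairScores(sample_id=str(sample_id), edges=edges, matrix=delta, degenerate_edges=degenerate)


def fourth_order_spcc(ref: ReferenceNetwork, sample, e1: Edge, e2: Edge) -> float:
    """Fourth-order sPCC of one edge-pair; symmetric in (e1, e2)."""
    net = EdgeNetwork(
        edges=[_canonical(*e1), _canonical(*e2)],
        scores=[np.nan, np.nan],
        ranking="manual",
        top_k=2,
    )
    scores = fourth_order_spcc_matrix(ref, sample, net)
    return scores.score(e1, e2)
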