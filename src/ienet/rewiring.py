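"""Group-level networks, differential-network comparison, and hub ranking.

Each clinical state gets its own weighted taxon network:

* the reference (healthy) network uses the absolute reference Pearson
  correlation |PCC_ref| as edge weight — the baseline co-occurrence wiring;
* a disease network uses the group consensus perturbation, the mean over the
  group's samples of |sPCC|, so its edges are the taxon pairs whose
  correlation the disease state consistently rewires.

Binarizing at a threshold yields the graphs whose degree ranking identifies
network-hub taxa; a hub present in exactly one state's top list is a
disease-specific hub.

Raw sPCC magnitudes are not comparable across pairs: a pair that is tightly
correlated in the reference barely moves when a consistent sample is added
(the sampling scale of a correlation perturbation is proportional to
1 - r^2), while loose pairs fluctuate freely — so thresholding raw
consensus favours unstable pairs over genuinely rewired ones. Disease
networks therefore default to a consensus normalized by a leave-one-out
null scale (:func:`loo_perturbation_scale`): edge weights count how many
times stronger the group's mean perturbation is than a healthy sample's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import AbundanceTable, SampleDesign
from .exceptions import GroupError
from .reference import ReferenceNetwork


def null_spcc_level(n_ref: int) -> float:
    """Analytic mean |sPCC| of an uncorrelated taxon pair.

    For independent standardized taxa the added sample shifts the Pearson
    correlation by roughly z_i * z_j / (n_ref + 1), and E|z_i z_j| = 2/pi,
    so E|sPCC| ~ (2/pi) / (n_ref + 1). Useful as a rough scale for
    thresholding raw perturbation-consensus networks.
    """
    return (2.0 / np.pi) / (n_ref + 1)


def loo_perturbation_scale(ref: ReferenceNetwork) -> pd.DataFrame:
    """Per-pair null scale of |sPCC|, calibrated by leave-one-out.

    Each reference sample is scored against the model refit on the remaining
    reference samples, giving an empirical null of single-sample
    perturbations. Because per-pair standard deviations over so few values
    are unstable, the scale is smoothed through the sampling-theory shape of
    a correlation perturbation, sd ~ lambda * (1 - r_ref^2), with the single
    factor lambda estimated as the median ratio across pairs. Pairs of a
    strongly correlated (stable) reference duo thus get a small null scale,
    loosely coupled pairs a large one.
    """
    from .exceptions import ReferenceSizeError

    X_ref = pd.DataFrame(ref.reference_, columns=ref.taxa_)
    if X_ref.shape[0] <= ReferenceNetwork().min_samples:
        raise ReferenceSizeError(
            "leave-one-out calibration needs more than the minimum reference size"
        )
    mats = []
    for i in range(X_ref.shape[0]):
        sub = ReferenceNetwork().fit(X_ref.drop(index=X_ref.index[i]))
        mats.append(np.abs(sub.spcc_matrix(X_ref.iloc[i]).to_numpy()))
    null_sd = np.asarray(mats).std(axis=0, ddof=1)
    shape = 1.0 - np.clip(ref.correlation_, -0.999, 0.999) ** 2
    np.fill_diagonal(shape, np.nan)
    iu = np.triu_indices(shape.shape[0], k=1)
    lam = float(np.nanmedian(null_sd[iu] / shape[iu]))
    scale = lam * shape
    return pd.DataFrame(scale, index=ref.taxa_, columns=ref.taxa_)


@dataclass
class GroupNetwork:
    """Thresholded weighted network of one clinical state."""

    group: str
    graph: nx.Graph
    threshold: float
    weight_kind: str  # "reference_pcc" or "mean_abs_spcc"
    nodes: list = field(default_factory=list)

    def edge_set(self) -> set:
        return {tuple(sorted(e, key=str)) for e in self.graph.edges}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_i": i, "taxon_j": j, "weight": d["weight"]}
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "weight"])


def _threshold_graph(weights: pd.DataFrame, threshold: float) -> nx.Graph:
    taxa = list(weights.index)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    w = weights.to_numpy()
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            if np.isfinite(w[a, b]) and w[a, b] >= threshold:
                g.add_edge(taxa[a], taxa[b], weight=float(w[a, b]))
    return g


def consensus_weights(
    ref: ReferenceNetwork,
    table: AbundanceTable,
    design: SampleDesign,
    group: str,
    normalize: bool = False,
) -> pd.DataFrame:
    """Edge-weight matrix for one group.

    Reference group: |PCC_ref|. Disease group: mean |sPCC| over the group's
    samples — the perturbation consensus — optionally divided by the
    leave-one-out null scale (``normalize=True``), which puts every pair on
    a common "times the healthy perturbation level" footing and is the
    recommended form for thresholding (see :func:`loo_perturbation_scale`).
    """
    taxa = ref.taxa_
    if group == design.reference:
        w = np.abs(ref.correlation_.copy())
        np.fill_diagonal(w, 0.0)
        return pd.DataFrame(w, index=taxa, columns=taxa)
    samples = design.samples_in(group)
    if not samples:
        raise GroupError(f"group {group!r} is empty")
    X = table.to_samples_matrix()
    acc = np.zeros((len(taxa), len(taxa)))
    for s in samples:
        acc += np.abs(ref.spcc_matrix(X.loc[s]).to_numpy())
    weights = acc / len(samples)
    if normalize:
        scale = loo_perturbation_scale(ref).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            weights = weights / np.where(scale <= 0, np.nan, scale)
    return pd.DataFrame(weights, index=taxa, columns=taxa)


DEFAULT_Z_THRESHOLD = 3.0  # normalized consensus: times the null scale


def build_group_network(
    ref: ReferenceNetwork,
    table: AbundanceTable,
    design: SampleDesign,
    group: str,
    threshold: float | None = None,
    normalize: bool = True,
) -> GroupNetwork:
    """Threshold the group's consensus weights into a state network.

    The reference network binarizes |PCC_ref| (default threshold 0.5). A
    disease network binarizes the group's perturbation consensus; with the
    default ``normalize=True`` the weights are in null-scale units and the
    default threshold is :data:`DEFAULT_Z_THRESHOLD`; with ``normalize=False``
    raw mean |sPCC| is thresholded (supply your own threshold, e.g. a
    multiple of :func:`null_spcc_level`).
    """
    is_ref = group == design.reference
    if threshold is None:
        threshold = 0.5 if is_ref else (DEFAULT_Z_THRESHOLD if normalize else 2 * null_spcc_level(len(ref.sample_ids_)))
    weights = consensus_weights(ref, table, design, group, normalize=not is_ref and normalize)
    if is_ref:
        kind = "reference_pcc"
    else:
        kind = "normalized_mean_abs_spcc" if normalize else "mean_abs_spcc"
    graph = _threshold_graph(weights, threshold)
    return GroupNetwork(
        group=group,
        graph=graph,
        threshold=threshold,
        weight_kind=kind,
        nodes=list(weights.index),
    )


@dataclass
class DifferentialNetwork:
    """Edge partition between two state networks plus per-taxon rewiring."""

    only_a: set
    only_b: set
    shared: set
    rewiring: pd.Series  # taxon -> count of state-exclusive incident edges


def differential_network(net_a: GroupNetwork, net_b: GroupNetwork) -> DifferentialNetwork:
    """Partition edges into A-only / B-only / shared and score rewiring.

    The node universe is the union of both networks; a taxon's rewiring
    score counts its incident edges present in exactly one of the states.
    """
    ea, eb = net_a.edge_set(), net_b.edge_set()
    only_a, only_b, shared = ea - eb, eb - ea, ea & eb
    nodes = sorted(set(net_a.nodes) | set(net_b.nodes), key=str)
    counts = {t: 0 for t in nodes}
    for i, j in only_a | only_b:
        counts[i] += 1
        counts[j] += 1
    return DifferentialNetwork(
        only_a=only_a,
        only_b=only_b,
        shared=shared,
        rewiring=pd.Series(counts, name="rewiring"),
    )


@dataclass
class HubReport:
    """Degree-ranked taxa of one state network with top-k hub flags."""

    group: str
    table: pd.DataFrame  # taxon, degree, weighted_degree, rank, is_hub
    top_k: int

    @property
    def hubs(self) -> list:
        return list(self.table.loc[self.table["is_hub"], "taxon"])


def rank_hubs(net: GroupNetwork, k: int = 3) -> HubReport:
    """Rank taxa by degree (weighted degree, then taxon id, break ties)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    g = net.graph
    rows = []
    for t in net.nodes:
        deg = g.degree(t) if t in g else 0
        wdeg = g.degree(t, weight="weight") if t in g else 0.0
        rows.append({"taxon": t, "degree": int(deg), "weighted_degree": float(wdeg)})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["degree", "weighted_degree", "taxon"],
        ascending=[False, False, True],
        key=lambda c: c.astype(str) if c.name == "taxon" else c,
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_hub"] = df["rank"] <= k
    return HubReport(group=net.group, table=df, top_k=k)


def disease_specific_hubs(reports: dict[str, HubReport]) -> dict[str, list]:
    """Per-group hubs found in that group's top-k and no other group's.

    ``reports`` maps group label -> HubReport (at the same or per-group k).
    """
    if len(reports) < 2:
        raise GroupError("need hub reports for at least two groups")
    hub_sets = {g: set(r.hubs) for g, r in reports.items()}
    out = {}
    for g, hubs in hub_sets.items():
        others = set().union(*(h for gg, h in hub_sets.items() if gg != g))
        out[g] = sorted(hubs - others, key=str)
    return out
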