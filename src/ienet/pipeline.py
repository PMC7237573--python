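"""End-to-end iENA marker model with a scikit-learn estimator interface.

``IENAMarkerModel.fit`` takes a labelled cohort (samples-by-taxa abundances
plus group labels, one label designated as the healthy reference), and runs
the full chain: reference correlation model -> top-edge selection ->
per-sample fourth-order edge-pair scores -> per-sample edge-biomarkers ->
per-group union marker sets -> sCI scoring and group assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .abundance import AbundanceTable, SampleDesign
from .edges import fourth_order_spcc_matrix, select_top_edges
from .exceptions import GroupError, ReferenceSizeError
from .markers import MarkerSet, compute_sci, sci_table, select_edge_biomarkers, union_markers
from .reference import ReferenceNetwork, _as_frame


def _loo_sci(ref_frame: pd.DataFrame, sample_id, marker: MarkerSet):
    """sCI of a reference sample via leave-one-out refit of the reference.

    A reference sample may not perturb a model it helped fit, so its score is
    computed against the model refit on the remaining reference samples. With
    exactly three reference samples leave-one-out is impossible and the full
    model is used (flagged upstream by the caller).
    """
    rest = ref_frame.drop(index=sample_id)
    model = ReferenceNetwork().fit(rest)
    return compute_sci(model, ref_frame.loc[sample_id], marker, sample_id=str(sample_id))


def classify_by_sci(
    ref: ReferenceNetwork,
    table: AbundanceTable,
    design: SampleDesign,
    markers: dict[str, MarkerSet],
    reference_percentile: float = 95.0,
):
    """Score every sample against each group's union markers and assign groups.

    Returns ``(scores_df, report)``. Reference samples are scored by
    leave-one-out refits. A sample is assigned to the disease marker set with
    its maximal sCI, or to the reference group when every sCI falls below
    that marker set's reference-cohort percentile threshold.

    The ``report`` dict carries per-group mean sCI per marker set, the
    assignment accuracy, and whether each disease group's mean exceeds the
    reference group's mean under its own markers (the expected ordering for
    perturbed states).
    """
    if not markers:
        raise GroupError("no union marker sets supplied")
    X = table.to_samples_matrix()
    design.require_cover(X.index)
    ref_ids = [s for s in X.index if design.groups[s] == design.reference]
    ref_frame = X.loc[ref_ids]
    loo_possible = len(ref_ids) > ReferenceNetwork().min_samples

    scores = []
    for s in X.index:
        for gid, marker in markers.items():
            if design.groups[s] == design.reference and loo_possible:
                sc = _loo_sci(ref_frame, s, marker)
            else:
                sc = compute_sci(ref, X.loc[s], marker, sample_id=str(s))
            sc.marker_id = gid
            scores.append(sc)
    df = sci_table(scores)

    wide = df.pivot(index="sample_id", columns="marker_set", values="sci")
    wide = wide.loc[[str(s) for s in X.index]]
    group_of = {str(s): design.groups[s] for s in X.index}

    thresholds = {
        gid: float(
            np.percentile(
                wide.loc[[str(s) for s in ref_ids], gid], reference_percentile
            )
        )
        for gid in markers
    }

    assignments = {}
    for s in wide.index:
        row = wide.loc[s]
        if all(row[g] < thresholds[g] for g in markers):
            assignments[s] = design.reference
        else:
            assignments[s] = row.idxmax()
    correct = [assignments[s] == group_of[s] for s in wide.index]

    group_means = (
        df.assign(group=[group_of[s] for s in df["sample_id"]])
        .groupby(["group", "marker_set"])["sci"]
        .mean()
        .unstack()
    )
    ordering = {
        gid: bool(
            group_means.loc[gid, gid] > group_means.loc[design.reference, gid]
        )
        for gid in markers
        if gid in group_means.index
    }
    report = {
        "group_means": group_means,
        "thresholds": thresholds,
        "assignments": assignments,
        "accuracy": float(np.mean(correct)),
        "disease_above_reference": ordering,
    }
    return df, report


class IENAMarkerModel(BaseEstimator, ClassifierMixin):
    """iENA edge-biomarker model over a labelled cohort.

    Parameters
    ----------
    reference_label : str
        Group label of the healthy reference cohort.
    top_k_edges : int or None
        Size of the edge-network; default min(200, 10% of taxon pairs).
    n_marker_pairs : int
        Number of top edge-pairs (m) whose taxa form a sample's marker set.
    edge_ranking : {"max_spcc", "reference_pcc"}
        Edge-selection score (see :func:`ienet.edges.select_top_edges`).
    reference_percentile : float
        Reference-cohort sCI percentile below which a sample is called
        reference-like at assignment time.

    Attributes (after fit)
    ----------------------
    reference_model_ : ReferenceNetwork
    edge_network_ : EdgeNetwork
    sample_markers_ : dict sample id -> MarkerSet (disease samples)
    union_markers_ : dict group label -> MarkerSet
    sci_ : long-format DataFrame of per-sample, per-marker-set scores
    report_ : classification report (means, thresholds, assignments, accuracy)
    classes_ : sorted group labels
    """

    def __init__(
        self,
        reference_label: str = "H",
        top_k_edges: int | None = None,
        n_marker_pairs: int = 10,
        edge_ranking: str = "max_spcc",
        reference_percentile: float = 95.0,
    ):
        self.reference_label = reference_label
        self.top_k_edges = top_k_edges
        self.n_marker_pairs = n_marker_pairs
        self.edge_ranking = edge_ranking
        self.reference_percentile = reference_percentile

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "IENAMarkerModel":
        frame = _as_frame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=frame.index).astype(str)
        design = SampleDesign(y, self.reference_label)
        self.design_ = design
        self.classes_ = np.array(design.group_labels)

        ref_ids = design.samples_in(self.reference_label)
        self.reference_model_ = ReferenceNetwork().fit(frame.loc[ref_ids])

        query_ids = [s for s in frame.index if y[s] != self.reference_label]
        if not query_ids:
            raise GroupError("cohort has no non-reference samples")
        query = frame.loc[query_ids, self.reference_model_.taxa_]
        self.edge_network_ = select_top_edges(
            self.reference_model_, query, k=self.top_k_edges, ranking=self.edge_ranking
        )

        self.sample_markers_ = {}
        for s in query_ids:
            scores = fourth_order_spcc_matrix(
                self.reference_model_, frame.loc[s], self.edge_network_, sample_id=str(s)
            )
            self.sample_markers_[s] = select_edge_biomarkers(
                scores, m=self.n_marker_pairs
            )

        self.union_markers_ = {
            g: union_markers(self.sample_markers_, design, g)
            for g in design.disease_groups
        }

        table = AbundanceTable(frame.T, closed=False)
        self.sci_, self.report_ = classify_by_sci(
            self.reference_model_,
            table,
            design,
            self.union_markers_,
            reference_percentile=self.reference_percentile,
        )
        self.training_accuracy_ = self.report_["accuracy"]
        return self

    # -- scoring new samples ----------------------------------------------

    def score_samples(self, X) -> pd.DataFrame:
        """sCI of each sample (rows) under each group's union markers (cols)."""
        check_is_fitted(self, "union_markers_")
        frame = _as_frame(X)
        rows = {}
        for s in frame.index:
            rows[str(s)] = {
                g: compute_sci(
                    self.reference_model_, frame.loc[s], marker, sample_id=str(s)
                ).sci
                for g, marker in self.union_markers_.items()
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def predict(self, X) -> np.ndarray:
        """Assign each sample to a group by its maximal sCI, or reference."""
        scores = self.score_samples(X)
        thresholds = self.report_["thresholds"]
        out = []
        for _, row in scores.iterrows():
            if all(row[g] < thresholds[g] for g in thresholds):
                out.append(self.reference_label)
            else:
                out.append(row.idxmax())
        return np.asarray(out, dtype=object)
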