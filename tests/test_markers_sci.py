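import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from ienet import (
    EdgePairScores,
    MarkerSet,
    ReferenceNetwork,
    compute_sci,
    select_edge_biomarkers,
    union_markers,
)
from ienet.abundance import SampleDesign
from ienet.exceptions import GroupError, MarkerError


def scores_from_pairs(pairs):
    """Build EdgePairScores from {(e1, e2): value} with canonical edges."""
    edges = sorted({e for pair in pairs for e in pair})
    idx = {e: i for i, e in enumerate(edges)}
    mat = np.zeros((len(edges), len(edges)))
    for (e1, e2), v in pairs.items():
        mat[idx[e1], idx[e2]] = mat[idx[e2], idx[e1]] = v
    return EdgePairScores(sample_id="s", edges=edges, matrix=mat)


class TestSelectEdgeBiomarkers:
    def test_single_top_pair_union(self):
        scores = scores_from_pairs({
            (("A", "B"), ("C", "D")): 0.9,
            (("A", "B"), ("E", "F")): 0.1,
            (("C", "D"), ("E", "F")): 0.2,
        })
        marker = select_edge_biomarkers(scores, m=1)
        assert set(marker.members) == {"A", "B", "C", "D"}

    def test_saturation_when_m_exceeds_pairs(self):
        scores = scores_from_pairs({(("A", "B"), ("C", "D")): 0.5})
        marker = select_edge_biomarkers(scores, m=50)
        assert set(marker.members) == {"A", "B", "C", "D"}

    def test_matches_sort_and_union_oracle(self):
        rng = np.random.default_rng(31)
        edges = [tuple(sorted((f"t{a}", f"t{a+b+1}"))) for a, b in
                 zip(rng.integers(0, 8, 10), rng.integers(0, 4, 10))]
        edges = sorted(set(edges))
        pairs = {}
        for i in range(len(edges)):
            for j in range(i + 1, len(edges)):
                pairs[(edges[i], edges[j])] = rng.normal()
        scores = scores_from_pairs(pairs)
        marker = select_edge_biomarkers(scores, m=3)
        ranked = sorted(pairs.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
        expected = set()
        for (e1, e2), _ in ranked[:3]:
            expected.update(e1)
            expected.update(e2)
        assert set(marker.members) == expected

    def test_no_pairs_rejected(self):
        scores = EdgePairScores("s", edges=[("A", "B")], matrix=np.zeros((1, 1)))
        with pytest.raises(MarkerError):
            select_edge_biomarkers(scores)


@pytest.fixture()
def micro_model():
    """4-taxon, 5-sample reference with a non-reference query sample."""
    rng = np.random.default_rng(77)
    X = rng.uniform(0.05, 0.5, size=(5, 4))
    model = ReferenceNetwork().fit(pd.DataFrame(X, columns=list("ABCD")))
    sample = pd.Series(rng.uniform(0.05, 0.5, size=4), index=list("ABCD"))
    return model, sample


class TestComputeSci:
    def test_micro_example_matches_hand_formula(self, micro_model):
        model, sample = micro_model
        marker = MarkerSet(members=frozenset({"A", "B"}), origin="toy")
        score = compute_sci(model, sample, marker)

        # independent evaluation of the three factors via explicit pearsonr
        def spcc(i, j):
            a, b = list("ABCD").index(i), list("ABCD").index(j)
            r_ref = pearsonr(model.reference_[:, a], model.reference_[:, b]).statistic
            aug = np.vstack([model.reference_, sample.to_numpy()])
            return pearsonr(aug[:, a], aug[:, b]).statistic - r_ref

        pcc_in = abs(spcc("A", "B"))
        pcc_out = np.mean([abs(spcc(x, y)) for x in "AB" for y in "CD"])
        sd_in = np.mean([abs(sample[t] - model.mean_[list("ABCD").index(t)]) for t in "AB"])
        assert score.pcc_in == pytest.approx(pcc_in, abs=1e-10)
        assert score.pcc_out == pytest.approx(pcc_out, abs=1e-10)
        assert score.sd_in == pytest.approx(sd_in, abs=1e-10)
        assert score.sci == pytest.approx(pcc_in / pcc_out * sd_in, abs=1e-10)

    def test_zero_in_correlations_give_zero_sci(self, micro_model):
        model, sample = micro_model
        marker = MarkerSet(members=frozenset({"A", "B"}), origin="toy")
        fake = pd.DataFrame(np.full((4, 4), 0.3), index=list("ABCD"), columns=list("ABCD"))
        fake.loc["A", "B"] = fake.loc["B", "A"] = 0.0
        score = compute_sci(model, sample, marker, spcc_matrix=fake)
        assert score.pcc_in == 0.0
        assert score.sci == 0.0

    def test_sample_at_reference_means_scores_zero(self, micro_model):
        model, _ = micro_model
        marker = MarkerSet(members=frozenset({"A", "B"}), origin="toy")
        at_mean = pd.Series(model.mean_, index=list("ABCD"))
        score = compute_sci(model, at_mean, marker)
        assert score.sd_in == pytest.approx(0.0, abs=1e-15)
        assert score.sci == pytest.approx(0.0, abs=1e-15)

    def test_singleton_marker_flagged_zero(self, micro_model):
        model, sample = micro_model
        score = compute_sci(model, sample, MarkerSet(frozenset({"A"}), origin="t"))
        assert score.sci == 0.0
        assert "singleton_marker" in score.flags

    def test_marker_equal_to_universe_rejected(self, micro_model):
        model, sample = micro_model
        with pytest.raises(MarkerError):
            compute_sci(model, sample, MarkerSet(frozenset("ABCD"), origin="t"))

    def test_zero_out_correlation_gives_inf_sentinel(self, micro_model):
        model, sample = micro_model
        marker = MarkerSet(members=frozenset({"A", "B"}), origin="toy")
        fake = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        fake.loc["A", "B"] = fake.loc["B", "A"] = 0.4
        score = compute_sci(model, sample, marker, spcc_matrix=fake)
        assert math.isinf(score.sci)
        assert "zero_pcc_out" in score.flags

    def test_invariant_to_relabeling_non_marker_taxa(self, micro_model):
        model, sample = micro_model
        marker = MarkerSet(members=frozenset({"A", "B"}), origin="toy")
        mat = model.spcc_matrix(sample)
        base = compute_sci(model, sample, marker, spcc_matrix=mat).sci
        # swap the identities of the two outside taxa everywhere
        perm = {"C": "D", "D": "C"}
        relabeled = mat.rename(index=perm, columns=perm)
        relabeled = relabeled.loc[list("ABCD"), list("ABCD")]
        swapped_sample = sample.rename(perm)[list("ABCD")]
        alt = compute_sci(model, sample, marker, spcc_matrix=relabeled).sci
        assert alt == pytest.approx(base, abs=1e-12)

    def test_sci_linear_in_deviation_term(self, micro_model):
        model, sample = micro_model
        marker = MarkerSet(members=frozenset({"A", "B"}), origin="toy")
        mat = model.spcc_matrix(sample)
        s1 = compute_sci(model, sample, marker, spcc_matrix=mat)
        moved = sample.copy()
        # triple each marker taxon's deviation from its reference mean
        for k, t in enumerate(list("ABCD")):
            if t in marker.members:
                moved[t] = model.mean_[k] + 3 * (sample[t] - model.mean_[k])
        s3 = compute_sci(model, moved, marker, spcc_matrix=mat)
        assert s3.sci == pytest.approx(3 * s1.sci, rel=1e-12)


class TestUnionMarkers:
    def design(self):
        return SampleDesign(pd.Series({"d1": "D", "d2": "D", "h": "H"}), reference="H")

    def test_simple_union_with_recurrence(self):
        per_sample = {
            "d1": MarkerSet(frozenset({"A", "B"}), origin="d1"),
            "d2": MarkerSet(frozenset({"B", "C"}), origin="d2"),
        }
        u = union_markers(per_sample, self.design(), "D")
        assert set(u.members) == {"A", "B", "C"}
        assert u.recurrent(2) == ["B"]

    def test_single_sample_group_identity(self):
        per_sample = {"d1": MarkerSet(frozenset({"A", "B"}), origin="d1")}
        design = SampleDesign(pd.Series({"d1": "D", "h": "H"}), reference="H")
        u = union_markers(per_sample, design, "D")
        assert set(u.members) == {"A", "B"}

    def test_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(13)
        labels = {f"d{i}": "D" for i in range(5)}
        labels["h"] = "H"
        design = SampleDesign(pd.Series(labels), reference="H")
        per_sample = {}
        for i in range(5):
            members = frozenset(rng.choice(list("ABCDEFG"), size=rng.integers(1, 5), replace=False))
            per_sample[f"d{i}"] = MarkerSet(members, origin=f"d{i}")
        u = union_markers(per_sample, design, "D")
        expected_counts = {}
        for s, m in per_sample.items():
            for t in m.members:
                expected_counts[t] = expected_counts.get(t, 0) + 1
        assert set(u.members) == set(expected_counts)
        assert {t: len(s) for t, s in u.support.items()} == expected_counts

    def test_empty_group_rejected(self):
        with pytest.raises(GroupError):
            union_markers({}, self.design(), "D")
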