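"""Reproducible validation experiments for the iENA pipeline.

Each function regenerates its synthetic inputs from an explicit seed, runs
the pipeline through the public API, and reduces the outcome to a scalar
(an oracle discrepancy, a recovery rate, a test size). They are used both
by the acceptance test-suite and by ``scripts/acceptance.py``.

Oracle functions here are deliberately independent of the implementation
path they check: they materialize vectors and call ``scipy.stats.pearsonr``
twice rather than reusing any package correlation code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .abundance import AbundanceTable, SampleDesign, prevalence_filter
from .differential import wilcoxon_differential
from .markers import MarkerSet, compute_sci
from .pipeline import IENAMarkerModel
from .reference import ReferenceNetwork, fit_reference
from .rewiring import build_group_network, disease_specific_hubs, rank_hubs
from .simulate import (
    generate_gene_table,
    generate_reference_cohort,
    study_scenario,
)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


def spcc_oracle_max_delta(n_instances: int = 100, seed: int = 0) -> float:
    """Worst |sPCC - two-pass Pearson oracle| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_ref = int(rng.integers(3, 21))
        p = int(rng.integers(4, 51))
        X = rng.uniform(0.01, 1.0, size=(n_ref, p))
        sample = rng.uniform(0.01, 1.0, size=p)
        model = ReferenceNetwork().fit(X)
        mat = model.spcc_matrix(sample).to_numpy()
        i, j = rng.choice(p, size=2, replace=False)
        r_ref = pearsonr(X[:, i], X[:, j]).statistic
        aug = np.vstack([X, sample])
        r_aug = pearsonr(aug[:, i], aug[:, j]).statistic
        worst = max(worst, abs(mat[i, j] - (r_aug - r_ref)))
    return float(worst)


def fourth_order_oracle_max_delta(n_instances: int = 100, seed: int = 1) -> float:
    """Worst |fourth-order sPCC - materialized profile oracle|."""
    from .edges import fourth_order_spcc

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_ref = int(rng.integers(4, 16))
        p = int(rng.integers(4, 13))
        X = rng.uniform(0.01, 1.0, size=(n_ref, p))
        sample = rng.uniform(0.01, 1.0, size=p)
        model = ReferenceNetwork().fit(X)
        taxa = model.taxa_
        chosen = rng.choice(len(taxa), size=4, replace=False)
        e1 = tuple(sorted((taxa[chosen[0]], taxa[chosen[1]])))
        e2 = tuple(sorted((taxa[chosen[2]], taxa[chosen[3]])))
        got = fourth_order_spcc(model, sample, e1, e2)

        def profile(data, edge):
            a, b = taxa.index(edge[0]), taxa.index(edge[1])
            za = (data[:, a] - model.mean_[a]) / model.std_[a]
            zb = (data[:, b] - model.mean_[b]) / model.std_[b]
            return za * zb

        aug = np.vstack([X, sample])
        expected = (
            pearsonr(profile(aug, e1), profile(aug, e2)).statistic
            - pearsonr(profile(X, e1), profile(X, e2)).statistic
        )
        worst = max(worst, abs(got - expected))
    return float(worst)


def sci_micro_example_delta(seed: int = 2) -> float:
    """|compute_sci - hand formula| on a 4-taxon, 2-marker micro-example."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.05, 0.5, size=(5, 4))
    model = ReferenceNetwork().fit(pd.DataFrame(X, columns=list("ABCD")))
    sample = pd.Series(rng.uniform(0.05, 0.5, size=4), index=list("ABCD"))
    score = compute_sci(model, sample, MarkerSet(frozenset({"A", "B"}), origin="t"))

    def spcc(i, j):
        a, b = "ABCD".index(i), "ABCD".index(j)
        aug = np.vstack([X, sample.to_numpy()])
        return (
            pearsonr(aug[:, a], aug[:, b]).statistic
            - pearsonr(X[:, a], X[:, b]).statistic
        )

    pcc_in = abs(spcc("A", "B"))
    pcc_out = float(np.mean([abs(spcc(x, y)) for x in "AB" for y in "CD"]))
    sd_in = float(np.mean([abs(sample[t] - X.mean(axis=0)["ABCD".index(t)]) for t in "AB"]))
    expected = pcc_in / pcc_out * sd_in
    return float(abs(score.sci - expected))


# ---------------------------------------------------------------------------
# recovery experiments on the study-scale scenario
# ---------------------------------------------------------------------------


def sci_ordering_rate(n_reps: int = 100, seed: int = 0, n_per_group: int = 5) -> float:
    """Fraction of replicates where each disease group's mean sCI under its
    own union markers exceeds the reference group's mean."""
    ok = 0
    for s in _child_seeds(seed, n_reps):
        sc = study_scenario(int(s), n_per_group=n_per_group)
        X = sc.table.to_samples_matrix()
        model = IENAMarkerModel().fit(X, X.index.map(sc.design.groups))
        gm = model.report_["group_means"]
        ok += int(
            gm.loc["G", "G"] > gm.loc["H", "G"] and gm.loc["I", "I"] > gm.loc["H", "I"]
        )
    return ok / n_reps


def marker_recovery(
    n_reps: int = 100, seed: int = 1, n_per_group: int = 20, jaccard_target: float = 0.5
) -> tuple[float, float]:
    """(fraction of replicates with Jaccard >= target, median Jaccard).

    Jaccard overlap between the G group's union markers and the planted
    rewired module.
    """
    jacs = []
    for s in _child_seeds(seed, n_reps):
        sc = study_scenario(int(s), n_per_group=n_per_group)
        X = sc.table.to_samples_matrix()
        model = IENAMarkerModel().fit(X, X.index.map(sc.design.groups))
        union = set(model.union_markers_["G"].members)
        module = set(sc.truth.module_members["G"])
        jacs.append(len(union & module) / len(union | module))
    jacs = np.asarray(jacs)
    return float(np.mean(jacs >= jaccard_target)), float(np.median(jacs))


def hub_recovery(
    n_reps: int = 100, seed: int = 2, n_per_group: int = 10, k: int = 3
) -> tuple[float, float]:
    """(top-k recovery rate, disease-specificity rate) for the planted hub.

    The scenario plants, per disease group, a hub whose latent coupling to a
    tightly correlated module (rho 0.95) is sign-inverted, giving it
    ``module_size - 1`` rewired edges among 50 taxa.
    """
    top = spec = 0
    for s in _child_seeds(seed, n_reps):
        sc = study_scenario(int(s), n_per_group=n_per_group, rho_module=0.95)
        ref = fit_reference(sc.table, sc.design)
        reports = {
            g: rank_hubs(build_group_network(ref, sc.table, sc.design, g), k=k)
            for g in ("H", "G", "I")
        }
        hub = sc.truth.hub["G"]
        in_top = hub in reports["G"].hubs
        top += int(in_top)
        spec += int(in_top and hub in disease_specific_hubs(reports)["G"])
    return top / n_reps, spec / n_reps


# ---------------------------------------------------------------------------
# conventional-statistics checks
# ---------------------------------------------------------------------------


def wilcoxon_type1_rate(
    n_features: int = 100_000, seed: int = 3, alpha: float = 0.05
) -> float:
    """Realized size of the per-feature rank-sum stage on 5 vs 5 null data."""
    rng = np.random.default_rng(seed)
    samples = [f"h{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
    design = SampleDesign(
        pd.Series({s: ("H" if s.startswith("h") else "D") for s in samples}),
        reference="H",
    )
    table = AbundanceTable(
        pd.DataFrame(rng.random(size=(n_features, 10)), columns=samples),
        closed=False,
    )
    res = wilcoxon_differential(table, design, "H", "D", alpha=alpha)
    return float(res["selected"].mean())


def derivation_roundtrip_error(seed: int = 4, depth: int = 100_000) -> float:
    """Worst absolute error of the gene-table -> taxon-table round trip."""
    from .abundance import aggregate_to_taxa, compute_gene_abundance, compute_relative_abundance

    taxa, _ = generate_reference_cohort(5, n_taxa=15, seed=seed)
    genes, annot = generate_gene_table(taxa, genes_per_taxon=3, seed=seed + 1, depth=depth)
    rel = compute_relative_abundance(compute_gene_abundance(genes))
    back = aggregate_to_taxa(rel.data, annot, rank="species")
    back_data = back.data.loc[taxa.data.index]
    return float(np.max(np.abs(back_data.to_numpy() - taxa.data.to_numpy())))


def prevalence_boundary_exact() -> bool:
    """4-of-15 detected removed and 5-of-15 retained at min_samples=5."""
    values = np.zeros((2, 15))
    values[0, :4] = 0.5
    values[1, :5] = 0.5
    table = AbundanceTable(pd.DataFrame(values, index=["four", "five"]), closed=False)
    filtered, removed = prevalence_filter(table, min_samples=5)
    return removed == ["four"] and list(filtered.data.index) == ["five"]
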