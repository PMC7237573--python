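# ienet — individual-specific edge-network analysis for microbiome tables

Small clinical metagenomics cohorts (a handful of stool samples per group)
rarely separate disease states by taxon abundance alone: the informative
signal is often in how the *co-occurrence wiring* of the community is
rewired. `ienet` implements individual-specific edge-network analysis
(iENA) for taxon-by-sample relative-abundance tables: it scores each single
sample against a healthy reference cohort by correlation perturbation,
builds edge-networks with fourth-order (edge-pair) correlations, selects
edge-biomarkers, quantifies each sample's disturbance with a composite
index, and compares state-specific networks for rewiring and hub taxa. It
is aimed at microbiome researchers analysing case/control or multi-state
cohorts at genus or species level.

## The method in brief

For a taxon pair `(i, j)` and a single query sample `s`, the single-sample
Pearson correlation perturbation is

    sPCC(i, j; s) = PCC_{ref ∪ {s}}(i, j) − PCC_ref(i, j)

where `ref` is the healthy reference cohort. Top-ranked pairs become the
"nodes" of an edge-network; each edge `(i, j)` has the per-sample profile
`e(s) = z_i(s) z_j(s)` of reference-standardized abundances, and the
*fourth-order* sPCC of an edge-pair applies the same perturbation to the
correlation of two edge profiles. The taxa of a sample's top `m` edge-pairs
form its marker set `M`, scored by the composite index

    sCI = (PCC̄in / PCC̄out) × SD̄in

with `PCC̄in` the mean |sPCC| within `M`, `PCC̄out` the mean |sPCC| between
`M` and the rest, and `SD̄in` the mean |x − μ_ref| over `M`. Healthy samples
score low; samples whose marker community is strongly co-perturbed and
displaced score high. Union marker sets per disease group drive group
assignment, and per-state networks (reference correlations for the healthy
state, null-calibrated perturbation consensus for disease states) expose
rewired edges and disease-specific hub taxa.

A synthetic-cohort generator (log-normal latent factor model with planted
correlation modules, sign-flip/decorrelate/strengthen effects, recorded
ground truth) stands in for the original sequencing data; see
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from ienet import IENAMarkerModel, study_scenario

cohort = study_scenario(seed=7)          # 3 groups x 5 samples, 50 genera
X = cohort.table.to_samples_matrix()     # samples x taxa, rows sum to 1
y = X.index.map(cohort.design.groups)    # 'H' (reference), 'G', 'I'

model = IENAMarkerModel(reference_label="H").fit(X, y)
print(model.report_["group_means"].round(4))
print("assignment accuracy:", round(model.report_["accuracy"], 3))
```

prints

```
marker_set       G       I
group
G           0.0150  0.0132
H           0.0056  0.0053
I           0.0127  0.0127
assignment accuracy: 0.6
```

Each cell is a group's mean composite index under one disease group's union
markers. The healthy row is lowest under both marker sets — healthy
communities are stable — and both disease groups score two-to-three-fold
above the reference under their own markers (G: 0.0150 vs 0.0056;
I: 0.0127 vs 0.0053), the ordering the index is designed to produce. The
accuracy is the fraction of the 15 samples whose maximal-sCI assignment
(with a reference fallback) matches their true group — modest on a
5-sample-per-group cohort, where the group-mean ordering is the robust
signal (it held in 100/100 replicates in the acceptance run).

The same pipeline is scriptable from a shell:

```
ienet simulate --seed 7 --out cohort/
ienet iena --table cohort/abundance.tsv --design cohort/design.tsv --out results/
ienet hubs --table cohort/abundance.tsv --design cohort/design.tsv --out results/
```

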