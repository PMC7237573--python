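# Methods

## The model

`ienet` implements individual-specific edge-network analysis (iENA) for
taxon-by-sample relative-abundance tables. The object of study is not the
abundance of any taxon but the *co-occurrence wiring* of the community, and
how far a single sample's wiring departs from a healthy baseline.

**Reference model.** A reference (healthy) cohort of `n` samples yields, per
taxon, a mean `μ` and standard deviation (ddof = 1), and, per taxon pair, a
Pearson correlation `r_ref`. Taxa with zero variance across the reference
carry no correlation information and are excluded (reported separately);
taxa absent from the reference have no baseline at all and never enter
networks.

**Single-sample perturbation (sPCC).** For a query sample `s` and a taxon
pair `(i, j)`,

    sPCC(i, j; s) = PCC_{ref ∪ {s}}(i, j) − PCC_ref(i, j) ∈ [−2, 2].

A sample consistent with the reference wiring leaves every correlation
almost unchanged; a sample from a rewired state drags the correlations of
the rewired pairs. This is a *perturbation* form: it needs no per-sample
replicate and is exact for one added observation.

**Edge-network and fourth-order scores.** The strongest pairs (by default
the maximum of |sPCC| over all non-reference samples; alternatively by
|PCC_ref|) become the `k` "background nodes" of an edge-network
(`k = min(200, 10 % of pairs)` by default). Each edge `(i, j)` has a
per-sample profile `e(s) = z_i(s)·z_j(s)` with `z = (x − μ)/sd` using
reference moments — a second-order quantity. The fourth-order sPCC of an
edge-pair applies the same perturbation form to the Pearson correlation of
two edge profiles. Restricting computation to the selected edges changes no
individual score (verified by a restriction-property test).

**Edge-biomarkers and the composite index.** Per sample, the top `m`
edge-pairs by |fourth-order sPCC| (ties broken lexicographically;
`m = 10` by default, never stated in the source analysis) contribute their
taxa to the sample's marker set. For a marker set `M`:

    sCI = (PCCin / PCCout) × SDin

with `PCCin` the mean |sPCC| over unordered pairs inside `M`, `PCCout` the
mean |sPCC| over `M × (universe − M)` pairs, and `SDin` the mean absolute
deviation |x − μ| over members of `M`. Conventions for degenerate inputs:
singleton markers have `PCCin = 0` (hence `sCI = 0`, flagged);
`M = universe` is rejected (`PCCout` undefined); `PCCout = 0` with signal
inside yields a flagged `+inf` sentinel. The deviation term uses the raw
|x − μ| with no division by the reference SD, matching the printed form of
the index; a normalized variant is deliberately not the default.

**Group markers and discrimination.** Union marker sets per disease group
(with per-taxon provenance, so recurrent taxa can be reported as robust)
feed a re-scoring of every sample. Reference samples are scored by
leave-one-out refits — a sample must not perturb a model it helped fit. A
sample is assigned to the disease marker set giving its maximal sCI, or to
the reference group when every sCI falls below that marker set's
95th-percentile reference score. The claim checked by the recovery
experiments is ordinal: disease groups score above the reference group
under their own markers.

**State networks, rewiring, hubs.** The healthy network binarizes
|PCC_ref| at 0.5. A disease network binarizes the group consensus
perturbation — the mean over the group's samples of |sPCC|. Raw consensus
values are not comparable across pairs: the sampling scale of a correlation
perturbation is ∝ (1 − r²)/(n − 1), so tightly correlated pairs barely move
while loose pairs fluctuate freely, and a single raw threshold rewards
instability rather than rewiring. Disease networks therefore default to a
consensus *normalized by a leave-one-out null scale*: each reference sample
is scored against the model refit without it, the per-pair null standard
deviation is smoothed through the `λ(1 − r²)` sampling shape (λ = median
ratio across pairs, making the estimate robust at n ≤ 10), and edges are
kept where the group consensus exceeds 3× this null scale. Hubs are ranked
by degree (weighted degree, then taxon id, as tie-breaks); a taxon in
exactly one group's top-k is that group's specific hub. Differential
network comparison partitions edges into state-exclusive and shared sets
and counts, per taxon, its state-exclusive incident edges.

## The synthetic cohorts

The generator emulates the statistical shape of a small fecal-metagenomics
study: three groups (healthy reference H and two disease states G and I) of
five samples each, 50 taxa, compositional abundances.

Construction: a latent factor model plants an exact target correlation
matrix — each correlated module loads √ρ on its own factor — then
`x = exp(μ_taxon + σ·z)` is closed per sample. Defaults: per-taxon log
baselines `μ_taxon ~ N(0, 1.0²)` (about a 50-fold abundance spread across
taxa) and latent log-scale σ = 0.5. These are at the moderate end of real
stool-community dispersion, deliberately: the method consumes Pearson
correlations of relative abundances, and at heavier dispersion (σ ≈ 1 with
a 1.5-SD baseline spread) single log-normal outlier samples induce spurious
|r| ≈ 0.9 between independent taxa at n ≤ 10, at which point *any*
correlation-based analysis of such data degenerates. Passing recovery tests
therefore show the method works where abundance-scale correlation is
informative; they do not show robustness to heavy-tailed communities, for
which a rank- or log-scale correlation (not part of the method) would be
needed.

The reference wiring holds one large "anchor" module (14 taxa, ρ = 0.9; the
stable backbone whose members are the healthy network's hubs) and one
module of 8 taxa per disease group (ρ = 0.8). The disease effect is applied
in latent space: `sign_flip` negates chosen members' loadings (flipping
their within-module correlations), `decorrelate` removes the module factor,
`strengthen(δ)` raises ρ. The default scenario flips only the module's
designated hub taxon, so every hub–member correlation inverts
(+ρ → −ρ) — one construction plants both a rewired module and a
disease-specific hub, and the truth record lists every altered edge with
before/after values. Marginals are untouched by design: the disease signal
is purely correlational, the hard case for abundance tests and exactly what
iENA targets. Closure-induced spurious correlation is accepted, as it
equally affects real relative-abundance data. The hub-recovery experiment
plants ρ = 0.95 modules so the plant is unambiguous at 10 samples/group.

Gene-level tables split each taxon's abundance over synthetic genes with a
single Dirichlet draw (constant across samples), uniform lengths in
300–3000 bp, and integer counts at a default depth of 100 000 reads, making
round-trip rounding error negligible (~10⁻⁸) at toy scale.

## Known limitations

* **Per-sample informativeness is gated.** A single sample carries
  information about a module's rewiring only when its module-factor
  magnitude is large (|f| ≳ 1, probability ≈ 0.32 per sample under the
  Gaussian factor); samples near the reference mean are silent about
  correlation structure no matter how strong the population-level effect.
  Consequently the *plain union* of per-sample markers across a group
  accumulates the noise picks of uninformative samples and its Jaccard
  overlap with the planted module saturates near 0.2 at 20 samples/group —
  this was measured to be insensitive to the edge-ranking rule, the
  null-normalization of the fourth-order scores, m, σ, module size and ρ.
  The per-taxon provenance counts on union marker sets exist precisely so
  users can read off the recurrent (robust) subset.
* The sPCC perturbation scale shrinks as O(1/n_ref); all thresholds on
  perturbation quantities must be (and here are) calibrated to the null
  scale rather than fixed constants.
* Exact rank-sum p-values are used up to group size 10 without ties
  (the study's n = 5 regime); the realized size of the 5 v 5 exact test at
  α = 0.05 is 8/252 ≈ 0.032, not 0.05 — an inherent property of the
  discrete null.
* PCA is run on raw relative abundances by default (matching the source
  pipeline's silence on transforms); a CLR option exists.
* Alpha diversity defaults to Shannon entropy (natural log); the index was
  never named in the source analysis.

## Problem sizes used by the validation experiments

Oracle checks use 100 random instances (reference size 3–20, 4–50 taxa).
Recovery experiments use 100 replicates each: score ordering at
5 samples/group, marker recovery at 20/group, hub recovery at 10/group.
The rank-sum size check uses 2 000–20 000 null features in the test-suite
and 100 000 in the acceptance script (the exact test is vectorized across
features). These sizes keep the full suite in the low minutes on one core.
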