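"""Synthetic compositional cohorts with planted correlation structure.

The generator emulates the statistical shape of a small fecal-metagenomics
study: a handful of samples per clinical group, tens of taxa, compositional
(sum-to-one) abundances, a shared reference correlation structure, and
disease groups whose only systematic difference is a *rewired* correlation
module (plus, optionally, a planted high-connectivity hub taxon).

Construction: a latent factor model plants the target correlation matrix
(each correlated module loads on its own factor), latent Gaussians are
exponentiated into log-normal abundances and closed per sample. Correlation
effects are applied in latent (pre-closure) space; the mild spurious
correlation induced by closure is accepted, as it equally affects real
relative-abundance data.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, GeneAbundanceTable, GeneAnnotation, SampleDesign
from .exceptions import SimulationError

LOG_MEAN_SD = 1.0  # spread of per-taxon log baseline abundances
LATENT_SD = 0.5  # scale of the latent Gaussian fluctuations
DEFAULT_DEPTH = 100_000  # sequencing depth for synthetic gene tables


# ---------------------------------------------------------------------------
# correlation specification
# ---------------------------------------------------------------------------


@dataclass
class ModuleSpec:
    """An equicorrelated taxon module driven by one latent factor."""

    members: list[int]  # taxon indices
    rho: float  # within-module latent correlation, in (0, 1)
    flipped: list[int] = field(default_factory=list)  # members with negated loading

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise SimulationError(f"module rho must be in (0, 1), got {self.rho}")
        if len(self.members) < 2:
            raise SimulationError("a module needs at least two members")
        if not set(self.flipped) <= set(self.members):
            raise SimulationError("flipped taxa must be module members")


@dataclass
class CorrelationSpec:
    """Factor-model correlation specification over ``n_taxa`` taxa.

    Taxa in no module are mutually independent. Modules must be disjoint.
    """

    n_taxa: int
    modules: list[ModuleSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for m in self.modules:
            if seen & set(m.members):
                raise SimulationError("modules must be disjoint")
            seen.update(m.members)
            if max(m.members) >= self.n_taxa:
                raise SimulationError("module member index out of range")

    def loadings(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_taxa, n_factors) loading matrix and idiosyncratic SDs."""
        L = np.zeros((self.n_taxa, len(self.modules)))
        for f, m in enumerate(self.modules):
            for t in m.members:
                L[t, f] = np.sqrt(m.rho) * (-1.0 if t in m.flipped else 1.0)
        idio = np.sqrt(1.0 - (L**2).sum(axis=1))
        return L, idio

    def correlation(self) -> np.ndarray:
        L, idio = self.loadings()
        C = L @ L.T + np.diag(idio**2)
        np.fill_diagonal(C, 1.0)
        return C


def _validate_matrix(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise SimulationError("correlation spec must be square")
    if not np.allclose(corr, corr.T):
        raise SimulationError("correlation spec must be symmetric")
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin <= 1e-10:
        raise SimulationError(f"correlation spec not positive-definite (min eig {eigmin:.3g})")
    return corr


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Everything a recovery test needs to know about a generated cohort."""

    seed: int
    taxa: list[str]
    latent_correlation: np.ndarray
    log_mean: np.ndarray
    log_sd: float
    module_members: dict[str, list[str]] = field(default_factory=dict)
    rewired_edges: dict[str, list[tuple]] = field(default_factory=dict)
    hub: dict[str, str] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)
    spec: CorrelationSpec | None = None
    latent: np.ndarray | None = None  # the raw latent Gaussian draws (samples x taxa)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "taxa": self.taxa,
            "log_sd": self.log_sd,
            "module_members": self.module_members,
            "rewired_edges": {
                g: [[i, j, float(b), float(a)] for i, j, b, a in edges]
                for g, edges in self.rewired_edges.items()
            },
            "hub": self.hub,
            "group_sizes": self.group_sizes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _taxon_names(n: int) -> list[str]:
    return [f"T{i:03d}" for i in range(n)]


def _latent_to_abundance(z: np.ndarray, log_mean: np.ndarray, log_sd: float) -> np.ndarray:
    """Exponentiate latent Gaussians and close columns. z is (n_samples, p)."""
    raw = np.exp(log_mean[None, :] + log_sd * z)
    return (raw / raw.sum(axis=1, keepdims=True)).T  # taxa x samples


def generate_reference_cohort(
    n_samples: int,
    n_taxa: int | None = None,
    base_correlation_spec: CorrelationSpec | np.ndarray | None = None,
    seed: int = 0,
    sample_prefix: str = "H",
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw a reference cohort from a log-normal latent correlation model."""
    if n_samples < 3:
        raise SimulationError("need at least 3 reference samples")
    if base_correlation_spec is None:
        if n_taxa is None:
            raise SimulationError("give n_taxa or a correlation spec")
        base_correlation_spec = CorrelationSpec(n_taxa)
    if isinstance(base_correlation_spec, CorrelationSpec):
        spec = base_correlation_spec
        corr = _validate_matrix(spec.correlation())
        n_taxa = spec.n_taxa
    else:
        corr = _validate_matrix(base_correlation_spec)
        n_taxa = corr.shape[0]
        spec = None
    if n_taxa < 4:
        raise SimulationError("need at least 4 taxa")

    rng = np.random.default_rng(seed)
    log_mean = rng.normal(0.0, LOG_MEAN_SD, size=n_taxa)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    values = _latent_to_abundance(z, log_mean, LATENT_SD)

    taxa = _taxon_names(n_taxa)
    samples = [f"{sample_prefix}{i + 1:02d}" for i in range(n_samples)]
    table = AbundanceTable(
        pd.DataFrame(values, index=taxa, columns=samples), rank="genus", closed=True
    )
    truth = SyntheticTruth(
        seed=seed,
        taxa=taxa,
        latent_correlation=corr,
        log_mean=log_mean,
        log_sd=LATENT_SD,
        group_sizes={sample_prefix: n_samples},
        spec=spec,
        latent=z,
    )
    return table, truth


def _apply_effect(
    spec: CorrelationSpec,
    module_idx: list[int],
    effect: str,
    flip: list[int] | None,
    delta: float,
) -> CorrelationSpec:
    """Transform one module of a factor spec according to the disease effect."""
    modules = []
    found = False
    for m in spec.modules:
        if set(m.members) == set(module_idx):
            found = True
            if effect == "sign_flip":
                flipped = flip if flip is not None else m.members[: (len(m.members) + 1) // 2]
                modules.append(ModuleSpec(m.members, m.rho, flipped=list(flipped)))
            elif effect == "decorrelate":
                continue  # drop the factor: members become independent
            elif effect == "strengthen":
                modules.append(ModuleSpec(m.members, min(m.rho + delta, 0.95)))
            else:
                raise SimulationError(f"unknown effect {effect!r}")
        else:
            modules.append(m)
    if not found:
        raise SimulationError("module_taxa do not match a module of the reference spec")
    return CorrelationSpec(spec.n_taxa, modules)


def generate_disease_cohort(
    reference_truth: SyntheticTruth,
    module_taxa: list[str],
    effect: str = "sign_flip",
    n_samples: int = 5,
    seed: int = 1,
    flip_taxa: list[str] | None = None,
    delta: float = 0.15,
    sample_prefix: str = "D",
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw a disease cohort: reference model with one module rewired.

    ``effect`` is one of ``sign_flip`` (negate the factor loadings of
    ``flip_taxa``, default the first half of the module), ``decorrelate``
    (remove the module factor) or ``strengthen`` (raise rho by ``delta``).
    Marginals and all non-module structure are untouched; the truth lists
    every latent edge whose correlation changed (before, after).
    """
    if reference_truth.spec is None:
        raise SimulationError("reference truth lacks a factor spec; cannot rewire")
    if len(module_taxa) < 2:
        raise SimulationError("module must have at least 2 taxa")
    name_to_idx = {t: i for i, t in enumerate(reference_truth.taxa)}
    module_idx = [name_to_idx[t] for t in module_taxa]
    flip_idx = [name_to_idx[t] for t in flip_taxa] if flip_taxa is not None else None

    disease_spec = _apply_effect(
        reference_truth.spec, module_idx, effect, flip_idx, delta
    )
    corr_before = reference_truth.latent_correlation
    corr_after = _validate_matrix(disease_spec.correlation())

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr_after)
    z = rng.standard_normal((n_samples, len(reference_truth.taxa))) @ chol.T
    values = _latent_to_abundance(z, reference_truth.log_mean, reference_truth.log_sd)

    taxa = reference_truth.taxa
    samples = [f"{sample_prefix}{i + 1:02d}" for i in range(n_samples)]
    table = AbundanceTable(
        pd.DataFrame(values, index=taxa, columns=samples), rank="genus", closed=True
    )

    rewired = []
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            if not np.isclose(corr_before[a, b], corr_after[a, b], atol=1e-12):
                rewired.append((taxa[a], taxa[b], corr_before[a, b], corr_after[a, b]))

    truth = SyntheticTruth(
        seed=seed,
        taxa=taxa,
        latent_correlation=corr_after,
        log_mean=reference_truth.log_mean,
        log_sd=reference_truth.log_sd,
        module_members={sample_prefix: list(module_taxa)},
        rewired_edges={sample_prefix: rewired},
        group_sizes={sample_prefix: n_samples},
        spec=disease_spec,
        latent=z,
    )
    return table, truth


# ---------------------------------------------------------------------------
# the study-scale scenario
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A generated cohort bundle: table, design, and ground truth."""

    table: AbundanceTable
    design: SampleDesign
    truth: SyntheticTruth


def study_scenario(
    seed: int,
    n_per_group: int = 5,
    n_taxa: int = 50,
    module_size: int = 8,
    anchor_size: int = 14,
    rho_module: float = 0.8,
    rho_anchor: float = 0.9,
    effect: str = "sign_flip",
) -> Scenario:
    """The default study-scale cohort: 3 groups (H reference, G, I).

    The reference wiring holds one large "anchor" module (the stable healthy
    backbone, strongest correlations, hence the healthy network's hubs) and
    two disease modules. Each disease group rewires its own module by
    ``effect``; for ``sign_flip`` only the module's designated hub taxon has
    its loading negated, so every hub-to-member latent correlation flips from
    +rho to -rho — the hub gains a full set of rewired edges while the other
    members keep their mutual wiring.
    """
    if anchor_size + 2 * module_size > n_taxa:
        raise SimulationError("modules do not fit into n_taxa")
    anchor = list(range(anchor_size))
    mod_g = list(range(anchor_size, anchor_size + module_size))
    mod_i = list(range(anchor_size + module_size, anchor_size + 2 * module_size))
    spec = CorrelationSpec(
        n_taxa,
        [
            ModuleSpec(anchor, rho_anchor),
            ModuleSpec(mod_g, rho_module),
            ModuleSpec(mod_i, rho_module),
        ],
    )
    rng = np.random.default_rng(seed)
    s_ref, s_g, s_i = rng.integers(0, 2**31 - 1, size=3)

    ref_table, ref_truth = generate_reference_cohort(
        n_per_group, base_correlation_spec=spec, seed=int(s_ref), sample_prefix="H"
    )
    taxa = ref_truth.taxa
    hub_g, hub_i = taxa[mod_g[0]], taxa[mod_i[0]]
    flip = {"sign_flip": [hub_g]}  # flip only the hub's loading
    g_table, g_truth = generate_disease_cohort(
        ref_truth,
        [taxa[i] for i in mod_g],
        effect=effect,
        n_samples=n_per_group,
        seed=int(s_g),
        flip_taxa=flip.get(effect),
        sample_prefix="G",
    )
    i_table, i_truth = generate_disease_cohort(
        ref_truth,
        [taxa[i] for i in mod_i],
        effect=effect,
        n_samples=n_per_group,
        seed=int(s_i),
        flip_taxa=[hub_i] if effect == "sign_flip" else None,
        sample_prefix="I",
    )

    data = pd.concat([ref_table.data, g_table.data, i_table.data], axis=1)
    table = AbundanceTable(data, rank="genus", closed=True)
    groups = pd.Series(
        {s: s[0] for s in data.columns}, name="group"
    )
    design = SampleDesign(groups, reference="H")

    truth = SyntheticTruth(
        seed=seed,
        taxa=taxa,
        latent_correlation=ref_truth.latent_correlation,
        log_mean=ref_truth.log_mean,
        log_sd=ref_truth.log_sd,
        module_members={
            "anchor": [taxa[i] for i in anchor],
            "G": [taxa[i] for i in mod_g],
            "I": [taxa[i] for i in mod_i],
        },
        rewired_edges={"G": g_truth.rewired_edges["G"], "I": i_truth.rewired_edges["I"]},
        hub={"G": hub_g, "I": hub_i},
        group_sizes={"H": n_per_group, "G": n_per_group, "I": n_per_group},
        spec=spec,
    )
    return Scenario(table=table, design=design, truth=truth)


# ---------------------------------------------------------------------------
# gene-level tables
# ---------------------------------------------------------------------------


def generate_gene_table(
    taxa_table: AbundanceTable,
    genes_per_taxon: int = 3,
    length_range: tuple[int, int] = (300, 3000),
    seed: int = 0,
    depth: int = DEFAULT_DEPTH,
    n_categories: int = 8,
) -> tuple[GeneAbundanceTable, GeneAnnotation]:
    """Split each taxon's abundance across synthetic genes and emit counts.

    Each taxon gets ``genes_per_taxon`` genes with a single Dirichlet split
    (constant across samples) and uniform random lengths; integer read
    counts are ``round(share * length * depth)``, so running the derivation
    chain (length-normalize, close, aggregate) recovers the input taxon
    table to within rounding (~1/depth).
    """
    if genes_per_taxon < 1:
        raise SimulationError("genes_per_taxon must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids, lengths, rows, species, genus, cats = [], [], [], [], [], []
    values = taxa_table.data
    for t in values.index:
        shares = rng.dirichlet(np.ones(genes_per_taxon))
        glens = rng.integers(length_range[0], length_range[1] + 1, size=genes_per_taxon)
        for g in range(genes_per_taxon):
            gid = f"{t}_g{g}"
            gene_ids.append(gid)
            lengths.append(int(glens[g]))
            rows.append(np.rint(values.loc[t].to_numpy() * shares[g] * glens[g] * depth))
            species.append(str(t))
            genus.append(str(t))
            n_cat = rng.integers(1, 3)
            cats.append(list(rng.choice([f"C{c}" for c in range(n_categories)], size=n_cat, replace=False)))
    counts = pd.DataFrame(
        np.vstack(rows), index=gene_ids, columns=values.columns
    ).astype(int)
    gene_table = GeneAbundanceTable(counts, pd.Series(lengths, index=gene_ids))
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"species": species, "genus": genus, "categories": cats}, index=gene_ids
        )
    )
    return gene_table, annotation
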