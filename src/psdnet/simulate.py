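"""Synthetic inputs with planted ground truth.

Everything downstream of raw mass spectrometry is exercised on data from
this module: a protein x region x replicate intensity tensor with planted
region-specific fold changes and co-abundance modules, a stochastic-block
PPI graph aligned to those modules, a region x region connectome matrix
linearly coupled to a subset of proteins, and a small is_a ontology whose
leaf terms annotate planted modules.

The generative model for intensities is multiplicative on the raw scale::

    I(p, r, k) = baseline(p) * moduleEffect(module(p), r)
                             * deEffect(p, r) * couplingEffect(p, r)
                             * exp(eps),   eps ~ N(0, ln(1 + noise_cv))

Baselines are log-normal, so summed peptide intensities are positive and
right-skewed, as real label-free data are.  A single global seed is split
into independent substreams for the abundance, PPI, connectome and
ontology components: changing one component's parameters never reshuffles
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from psdnet.quantify import AbundanceTensor

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_REGIONS",
    "simulate_abundance",
    "simulate_ppi",
    "simulate_connectome",
    "simulate_ontology",
    "simulate_all",
]

#: The seven dissected brain regions used as default labels: frontal,
#: medial and caudal cortex, hippocampus, striatum, hypothalamus and
#: cerebellum.
DEFAULT_REGIONS = ("CxF", "CxM", "CxCA", "Hip", "ST", "Hyp", "CB")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real study's scale: 1173 proteins quantified in
    seven brain regions of six animals, with six co-abundance modules and
    a PPI graph of roughly a thousand connected proteins and ~8000 edges.

    Parameters
    ----------
    n_proteins, n_regions, n_replicates, n_modules : int
        Tensor dimensions and number of planted co-abundance modules.
    frac_de : float
        Fraction of proteins given a planted differential-abundance
        effect in one region (up or down with equal probability).
    effect_fold : float
        Multiplicative fold of a planted effect (> 1); down effects use
        its reciprocal.
    noise_cv : float
        Replicate-level coefficient of variation; the log-scale noise sd
        is ``ln(1 + noise_cv)``.
    baseline_log_mean, baseline_log_sd : float
        Natural-log parameters of the log-normal baseline intensity.
    module_effect_sd : float
        Log-scale sd of per-(module, region) abundance multipliers; zero
        disables module structure in the tensor.
    region_group : tuple of int
        Indices of regions (e.g. the three cortices) whose module
        effects are drawn as a shared group value plus small jitter, so
        the region dendrogram has a planted clade.
    group_jitter_sd : float
        Log-scale sd of the within-group jitter.
    frac_single_peptide : float
        Fraction of proteins quantified by a single unique peptide
        (these fail the peptide filter by design).
    frac_unstable : float
        Fraction of proteins whose regional profile is shuffled
        independently in every replicate brain, destroying differential
        stability while preserving marginal intensities.
    frac_coupled : float
        Fraction of proteins whose regional mean abundance is an affine
        function of the connectome's connectivity vector.
    coupling_noise : float
        Log-scale sd of the deviation of a coupled protein's regional
        effect from the shared connectivity profile.
    ppi_p_in, ppi_p_out : float
        Within- and between-module edge probabilities of the planted
        stochastic block model; assortative when ``ppi_p_in > ppi_p_out``.
    n_terms : int
        Ontology size (including the root and module-signature leaves).
    annotation_noise : float
        Probability that a protein outside a term's planted module is
        annotated to it anyway.
    seed : int
        Global seed; split into per-component substreams.
    """

    n_proteins: int = 1173
    n_regions: int = 7
    n_replicates: int = 6
    n_modules: int = 6
    frac_de: float = 0.2
    effect_fold: float = 2.0
    noise_cv: float = 0.1
    baseline_log_mean: float = 13.0
    baseline_log_sd: float = 1.5
    module_effect_sd: float = 0.4
    region_group: tuple = (0, 1, 2)
    group_jitter_sd: float = 0.1
    frac_single_peptide: float = 0.1
    frac_unstable: float = 0.0
    frac_coupled: float = 0.1
    coupling_noise: float = 0.1
    ppi_p_in: float = 0.05
    ppi_p_out: float = 0.005
    n_terms: int = 40
    annotation_noise: float = 0.02
    seed: int = 0
    region_names: tuple = ()

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_regions", "n_replicates", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer, got {getattr(self, name)}")
        for name in (
            "frac_de",
            "frac_single_peptide",
            "frac_unstable",
            "frac_coupled",
            "ppi_p_in",
            "ppi_p_out",
            "annotation_noise",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_fold <= 1:
            raise ValueError(f"effect_fold must exceed 1, got {self.effect_fold}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.region_names and len(self.region_names) != self.n_regions:
            raise ValueError("region_names length must equal n_regions")

    @property
    def regions(self) -> list[str]:
        if self.region_names:
            return list(self.region_names)
        if self.n_regions == len(DEFAULT_REGIONS):
            return list(DEFAULT_REGIONS)
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def replicates(self) -> list[str]:
        return [f"b{k + 1}" for k in range(self.n_replicates)]

    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_proteins)]

    def substreams(self) -> dict[str, np.random.Generator]:
        """Independent generators for each simulated component."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("abundance", "ppi", "connectome", "ontology")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class GroundTruth:
    """Planted structure recorded alongside the synthetic data."""

    de_map: dict[str, dict[str, float]]  # protein -> {region: fold}
    module_labels: dict[str, int]  # protein -> module id (1-based)
    community_labels: dict[str, int]  # protein -> planted PPI community
    connectome_coupled: set = field(default_factory=set)
    unstable: set = field(default_factory=set)
    coupling_profile: np.ndarray | None = None  # per-region log-effect of coupling
    module_region_effects: np.ndarray | None = None  # (n_modules, n_regions) multipliers

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for prot, module in self.module_labels.items():
            de = self.de_map.get(prot, {})
            de_region = next(iter(de), "")
            rows.append(
                {
                    "protein_id": prot,
                    "module": module,
                    "community": self.community_labels[prot],
                    "de_region": de_region,
                    "de_fold": de.get(de_region, 1.0),
                    "coupled": int(prot in self.connectome_coupled),
                    "unstable": int(prot in self.unstable),
                }
            )
        return pd.DataFrame(rows)


def _select(rng: np.random.Generator, items: list[str], frac: float) -> set:
    k = int(round(frac * len(items)))
    if k == 0:
        return set()
    return set(rng.choice(items, size=k, replace=False))


def simulate_abundance(config: SimConfig) -> tuple[AbundanceTensor, GroundTruth]:
    """Generate the intensity tensor and its ground truth.

    Deterministic given the config (including seed).  With
    ``noise_cv = 0`` and ``module_effect_sd = 0`` every fold change in
    the tensor equals a planted fold exactly.
    """
    rng = config.substreams()["abundance"]
    P, R, B = config.n_proteins, config.n_regions, config.n_replicates
    proteins = config.protein_ids()
    regions = config.regions

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=P))

    # modules: contiguous blocks of near-equal size, deterministic
    module_of = np.repeat(np.arange(config.n_modules), int(np.ceil(P / config.n_modules)))[:P]
    module_labels = {p: int(m) + 1 for p, m in zip(proteins, module_of)}

    # per-(module, region) multipliers; grouped regions share a base value
    log_eff = rng.normal(0.0, config.module_effect_sd, size=(config.n_modules, R))
    group = [i for i in config.region_group if i < R]
    if len(group) > 1 and config.module_effect_sd > 0:
        base = rng.normal(0.0, config.module_effect_sd, size=config.n_modules)
        jitter = rng.normal(0.0, config.group_jitter_sd, size=(config.n_modules, len(group)))
        log_eff[:, group] = base[:, None] + jitter
    module_effects = np.exp(log_eff) if config.module_effect_sd > 0 else np.ones((config.n_modules, R))

    # planted DE: one region per selected protein, up or down
    de_set = _select(rng, proteins, config.frac_de)
    de_map: dict[str, dict[str, float]] = {}
    de_mult = np.ones((P, R))
    for i, prot in enumerate(proteins):
        if prot in de_set:
            r = int(rng.integers(R))
            fold = config.effect_fold if rng.random() < 0.5 else 1.0 / config.effect_fold
            de_map[prot] = {regions[r]: fold}
            de_mult[i, r] = fold

    # connectome coupling: shared per-region profile, replaces module effect
    coupled = _select(rng, proteins, config.frac_coupled)
    coupling_profile = rng.normal(0.0, 0.5, size=R)
    coupling_mult = np.ones((P, R))
    for i, prot in enumerate(proteins):
        if prot in coupled:
            dev = rng.normal(0.0, config.coupling_noise, size=R) if config.coupling_noise > 0 else 0.0
            coupling_mult[i] = np.exp(coupling_profile + dev)

    # coupled proteins follow the coupling profile instead of their module effect
    is_coupled = np.array([p in coupled for p in proteins])
    effect = np.where(is_coupled[:, None], coupling_mult, module_effects[module_of])

    mean = baseline[:, None] * effect * de_mult  # (P, R)

    sd_log = np.log1p(config.noise_cv)
    noise = rng.normal(0.0, sd_log, size=(P, R, B)) if sd_log > 0 else np.zeros((P, R, B))
    intensities = mean[:, :, None] * np.exp(noise)

    # unstable proteins: shuffle the region axis independently per brain
    unstable = _select(rng, proteins, config.frac_unstable)
    for i, prot in enumerate(proteins):
        if prot in unstable:
            for b in range(B):
                intensities[i, :, b] = intensities[i, rng.permutation(R), b]

    n_single = int(round(config.frac_single_peptide * P))
    peptides = 2 + rng.poisson(8, size=P)
    single_idx = rng.choice(P, size=n_single, replace=False) if n_single else np.array([], dtype=int)
    peptides[single_idx] = 1

    tensor = AbundanceTensor(
        intensities=intensities,
        proteins=proteins,
        regions=regions,
        replicates=config.replicates,
        n_unique_peptides=peptides,
    )
    truth = GroundTruth(
        de_map=de_map,
        module_labels=module_labels,
        community_labels=dict(module_labels),
        connectome_coupled=coupled,
        unstable=unstable,
        coupling_profile=coupling_profile,
        module_region_effects=module_effects,
    )
    return tensor, truth


def simulate_ppi(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Stochastic-block-model PPI edge list aligned to planted communities.

    Undirected simple graph: edge probability ``ppi_p_in`` within a
    planted community and ``ppi_p_out`` between; no self-loops or
    duplicate edges.  Returns a two-column DataFrame
    (``protein_a``, ``protein_b``) with ``protein_a < protein_b``.
    """
    rng = config.substreams()["ppi"]
    proteins = sorted(truth.community_labels)
    labels = np.array([truth.community_labels[p] for p in proteins])
    n = len(proteins)
    if n < 2:
        return pd.DataFrame(columns=["protein_a", "protein_b"])
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    prob = np.where(same, config.ppi_p_in, config.ppi_p_out)
    keep = rng.random(iu.size) < prob
    return pd.DataFrame(
        {
            "protein_a": [proteins[i] for i in iu[keep]],
            "protein_b": [proteins[j] for j in ju[keep]],
        }
    )


def simulate_connectome(
    config: SimConfig, truth: GroundTruth, tensor: AbundanceTensor
) -> pd.DataFrame:
    """Region x region projection-volume matrix coupled to the tensor.

    The matrix's row mean (the connectivity vector, self-projection
    included) is proportional to ``exp(coupling_profile)`` — the same
    per-region profile that scales the coupled proteins' abundances — so
    noise-free coupled proteins correlate perfectly with connectivity.
    """
    rng = config.substreams()["connectome"]
    R = config.n_regions
    regions = tensor.regions
    v = 1000.0 * np.exp(truth.coupling_profile)  # target row means
    raw = rng.lognormal(0.0, 0.3, size=(R, R))
    matrix = raw * (v / raw.mean(axis=1))[:, None]
    return pd.DataFrame(matrix, index=regions, columns=regions)


def simulate_ontology(
    config: SimConfig, truth: GroundTruth
) -> tuple["OntologyDAG", dict[str, set]]:
    """Small is_a ontology whose leaves mark planted modules.

    Structure: one root; one intermediate "branch" term per module; one
    signature leaf per module annotated (directly) to that module's
    proteins; remaining terms are filler leaves with random parents and
    sparse random annotation.  Some filler leaves get two parents, so
    the structure is a genuine DAG, not a tree.  Returns the DAG and the
    *direct* (unpropagated) annotation map term-wise inverted to
    ``protein -> set of term ids``.
    """
    from psdnet.enrichment import OntologyDAG

    if config.n_terms < 3:
        raise ValueError("n_terms must be >= 3")
    rng = config.substreams()["ontology"]
    proteins = sorted(truth.module_labels)
    M = config.n_modules

    terms: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    root = "T:0000000"
    terms[root] = "root"
    parents[root] = []
    branch_ids, leaf_ids = [], []
    for m in range(M):
        b = f"T:{m + 1:07d}"
        terms[b] = f"module-{m + 1} branch"
        parents[b] = [root]
        branch_ids.append(b)
    for m in range(M):
        t = f"T:{M + m + 1:07d}"
        terms[t] = f"module-{m + 1} signature"
        parents[t] = [branch_ids[m]]
        leaf_ids.append(t)
    n_filler = max(0, config.n_terms - 1 - 2 * M)
    filler_ids = []
    for j in range(n_filler):
        t = f"T:{2 * M + j + 1:07d}"
        terms[t] = f"background term {j + 1}"
        k = 2 if rng.random() < 0.25 and len(branch_ids) >= 2 else 1
        parents[t] = sorted(rng.choice(branch_ids, size=k, replace=False))
        filler_ids.append(t)

    annotations: dict[str, set] = {p: set() for p in proteins}
    for m, leaf in enumerate(leaf_ids):
        for p in proteins:
            in_module = truth.module_labels[p] == m + 1
            if (in_module and rng.random() < 0.9) or (
                not in_module and rng.random() < config.annotation_noise
            ):
                annotations[p].add(leaf)
    for t in filler_ids:
        for p in proteins:
            if rng.random() < 0.05:
                annotations[p].add(t)
    dag = OntologyDAG(terms=terms, parents=parents)
    return dag, {p: s for p, s in annotations.items() if s}


def simulate_all(config: SimConfig) -> dict:
    """Run all four generators; returns a dict of every artefact."""
    tensor, truth = simulate_abundance(config)
    edges = simulate_ppi(config, truth)
    connectome = simulate_connectome(config, truth, tensor)
    dag, annotations = simulate_ontology(config, truth)
    return {
        "tensor": tensor,
        "truth": truth,
        "edges": edges,
        "connectome": connectome,
        "ontology": dag,
        "annotations": annotations,
    }
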