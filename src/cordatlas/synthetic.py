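"""Seeded multi-study single-cell count simulator.

Generates negative-binomial count matrices for several "studies" that differ
in sequencing depth, per-gene capture efficiency, and protocol-linked
expression artifacts (immediate-early/stress and metabolism gene modules are
elevated when whole cells rather than nuclei are profiled).  Cell identities
follow a coarse -> family -> fine hierarchy with two separation regimes:
"discrete" fine types carry strong disjoint marker programs (the analogue of
well-separated dorsal populations), while "overlapping" fine types have weak,
partially shared programs (the analogue of continuously varying mid/ventral
populations).  Doublets, low-quality barcodes, a mitochondrial module, and an
"embryonic" companion dataset with a planted (possibly convergent) lineage
map are included so every downstream stage of the pipeline can be exercised
against ground truth.

All randomness flows through ``numpy.random.default_rng`` seeded from the
simulation config; identical inputs give byte-identical counts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CellTypeHierarchy",
    "StudyProfile",
    "SimulationConfig",
    "GroundTruth",
    "build_hierarchy",
    "simulate_study",
    "simulate_embryonic",
    "default_study_profiles",
    "simulate_atlas",
]

# Gene-module sizes (contiguous index blocks, recorded in the hierarchy so
# tests and the pipeline can address them by name).
_IEG_SIZE = 30
_METABOLIC_SIZE = 40
_IMMATURITY_SIZE = 40

DOUBLET_LABEL = "doublet"
LOWQ_LABEL = "low_quality"


@dataclass
class CellTypeHierarchy:
    """Coarse -> family -> fine cell-type structure with expression programs.

    ``programs`` holds per-fine-type mean log-expression over the shared gene
    universe; ``marker_sets`` maps each fine type to the gene indices boosted
    in it.  ``modules`` records the fixed index blocks for the mitochondrial,
    immediate-early (IEG), metabolic, and immaturity modules.
    """

    coarse_types: list[str]
    fine_types: list[str]
    coarse_parent: dict[str, str]
    family: dict[str, str]
    programs: np.ndarray  # (n_fine, n_genes) log-space means
    marker_sets: dict[str, np.ndarray]
    separation_regime: dict[str, str]  # fine type -> "discrete" | "overlapping"
    modules: dict[str, np.ndarray]
    gene_names: list[str]
    neuronal_coarse: str  # the coarse type routed to fine-type classification

    @property
    def n_genes(self) -> int:
        return self.programs.shape[1]

    @property
    def n_fine(self) -> int:
        return len(self.fine_types)

    def fine_of_coarse(self, coarse: str) -> list[str]:
        return [f for f in self.fine_types if self.coarse_parent[f] == coarse]

    def coarse_signature(self, coarse: str) -> np.ndarray:
        """Union of marker indices of all fine types under ``coarse``."""
        idx = np.concatenate([self.marker_sets[f] for f in self.fine_of_coarse(coarse)])
        return np.unique(idx)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.programs)):
            raise ValueError("programs must be finite")
        discrete = [f for f in self.fine_types if self.separation_regime[f] == "discrete"]
        seen: set[int] = set()
        for f in discrete:
            s = set(self.marker_sets[f].tolist())
            if s & seen:
                raise ValueError("discrete marker sets must be disjoint")
            seen |= s


@dataclass
class StudyProfile:
    """Per-study acquisition profile.

    ``depth_factor`` scales the expected library size; ``capture_bias_sd``
    sets the spread of the per-gene log capture efficiency specific to this
    study; ``ieg_boost``/``metabolic_boost`` multiply the corresponding
    module rates when ``protocol == "cell"`` (dissociation stress and
    metabolic enrichment are cell-protocol artifacts; both are forced to 1
    for nuclei).
    """

    name: str
    protocol: str = "nucleus"  # "cell" | "nucleus"
    n_cells: int = 1000
    depth_factor: float = 1.0
    capture_bias_sd: float = 0.15
    ieg_boost: float = 3.0
    metabolic_boost: float = 2.0
    condition: str = "naive"

    def __post_init__(self) -> None:
        if self.protocol not in ("cell", "nucleus"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be > 0")
        if self.protocol == "cell" and (self.ieg_boost < 1 or self.metabolic_boost < 1):
            raise ValueError("protocol-linked boosts must be >= 1 for cell protocol")

    @property
    def effective_ieg_boost(self) -> float:
        return self.ieg_boost if self.protocol == "cell" else 1.0

    @property
    def effective_metabolic_boost(self) -> float:
        return self.metabolic_boost if self.protocol == "cell" else 1.0


@dataclass
class SimulationConfig:
    """Global simulation parameters shared across studies."""

    seed: int = 0
    n_genes: int = 2000
    mito_gene_count: int = 10
    doublet_rate: float = 0.05
    lowq_rate: float = 0.05
    type_proportions: np.ndarray | None = None  # simplex over fine types
    dispersion: float = 0.15  # negative-binomial inverse size; 0 -> Poisson
    # calibrated so unintegrated graph clustering separates the studies
    # (nearly every unintegrated cluster is dominated by one study)
    batch_effect_strength: float = 2.0
    base_depth: float = 2500.0  # expected library size at depth_factor 1
    libsize_sigma: float = 0.4  # log-normal spread of library sizes
    lowq_target_counts: float = 120.0  # expected total counts after low-quality downsampling
    mito_fraction: float = 0.025  # baseline mitochondrial fraction of transcripts

    def __post_init__(self) -> None:
        if not (0 <= self.doublet_rate < 1 and 0 <= self.lowq_rate < 1):
            raise ValueError("doublet_rate and lowq_rate must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.batch_effect_strength < 0:
            raise ValueError("batch_effect_strength must be >= 0")
        if self.type_proportions is not None:
            p = np.asarray(self.type_proportions, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("type_proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    labels: np.ndarray  # fine type | "doublet" | "low_quality"
    study: np.ndarray
    doublet_parents: np.ndarray | None = None  # (n_doublets, 2) parent fine types
    lineage_map: dict[str, dict[str, float]] | None = None  # progenitor -> {fine: weight}


def _stable_seed(*parts: int | str) -> list[int]:
    out: list[int] = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode()) & 0x7FFFFFFF)
        else:
            out.append(int(p) & 0x7FFFFFFF)
    return out


def build_hierarchy(
    n_coarse: int = 4,
    n_fine_per_coarse: int = 3,
    markers_per_type: int = 10,
    overlap_fraction: float = 0.25,
    seed: int = 0,
    n_genes: int = 2000,
    mito_gene_count: int = 10,
    discrete_boost: float = 2.5,
    overlap_boost: float = 1.1,
    mito_fraction: float = 0.025,
) -> CellTypeHierarchy:
    """Build a coarse/family/fine hierarchy with planted expression programs.

    A fraction ``overlap_fraction`` of fine types (``floor`` of the product)
    are flagged "overlapping": their marker boosts are weak, roughly half of
    their marker genes are shared with a neighboring overlapping type, and
    their programs are pulled toward the mean of their coarse class.  All
    remaining types are "discrete" with strong, mutually disjoint marker
    sets.  Overlapping flags are spread across coarse classes (assigned
    round-robin from the last fine type backward) so both regimes co-occur
    within the neuronal class.

    The last coarse type is designated the "neuron" class and is the one the
    tiered classifier routes to fine-type resolution.
    """
    if n_coarse < 2 or n_fine_per_coarse < 1:
        raise ValueError("need n_coarse >= 2 and n_fine_per_coarse >= 1")
    if markers_per_type < 3:
        raise ValueError("markers_per_type must be >= 3")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")

    rng = np.random.default_rng(_stable_seed(seed, "hierarchy"))
    n_fine = n_coarse * n_fine_per_coarse

    # Fixed contiguous module blocks at the start of the gene index space.
    pos = 0
    modules: dict[str, np.ndarray] = {}
    for name, size in [
        ("mito", mito_gene_count),
        ("ieg", _IEG_SIZE),
        ("metabolic", _METABOLIC_SIZE),
        ("immaturity", _IMMATURITY_SIZE),
    ]:
        modules[name] = np.arange(pos, pos + size)
        pos += size
    marker_start = pos
    needed = marker_start + n_fine * markers_per_type
    if n_genes < needed:
        raise ValueError(f"n_genes={n_genes} too small; need at least {needed}")

    gene_names = [f"mt-{i + 1}" for i in range(mito_gene_count)] + [
        f"gene{i:04d}" for i in range(mito_gene_count, n_genes)
    ]

    coarse_types = [f"glia{i + 1}" for i in range(n_coarse - 1)] + ["neuron"]
    fine_types: list[str] = []
    coarse_parent: dict[str, str] = {}
    family: dict[str, str] = {}
    for c in coarse_types:
        for j in range(n_fine_per_coarse):
            f = f"{c}.f{j + 1}"
            fine_types.append(f)
            coarse_parent[f] = c
            family[f] = f"{c}/fam{j // 2 + 1}"

    # Overlapping flags: floor(overlap_fraction * n_fine) types.  Flags are
    # assigned from the end of the fine-type list in within-class pairs
    # (last two fine types of the neuronal class first, then the last two of
    # the preceding class, ...), so overlapping types have an overlapping
    # sibling to blend with and the neuronal class holds overlapping types
    # whenever any exist.
    n_overlap = int(np.floor(overlap_fraction * n_fine))
    regime = {f: "discrete" for f in fine_types}
    order: list[str] = []
    for ci in range(n_coarse - 1, -1, -1):
        group = fine_types[ci * n_fine_per_coarse : (ci + 1) * n_fine_per_coarse]
        order.extend(reversed(group[-2:]))
        order.extend(reversed(group[:-2]))
    # interleave: first the final pairs of every class, then the remainders
    pair_part = [f for ci in range(n_coarse - 1, -1, -1)
                 for f in reversed(fine_types[ci * n_fine_per_coarse:(ci + 1) * n_fine_per_coarse][-2:])]
    rest_part = [f for f in order if f not in pair_part]
    for f in (pair_part + rest_part)[:n_overlap]:
        regime[f] = "overlapping"

    # Marker blocks: contiguous, one per fine type, then partially shared
    # between overlapping neighbors within a coarse class.
    base_markers = {
        f: np.arange(marker_start + i * markers_per_type, marker_start + (i + 1) * markers_per_type)
        for i, f in enumerate(fine_types)
    }
    marker_sets: dict[str, np.ndarray] = {}
    for c in coarse_types:
        group = [f for f in fine_types if coarse_parent[f] == c]
        olap = [f for f in group if regime[f] == "overlapping"]
        for f in group:
            if regime[f] == "discrete" or len(olap) < 2:
                marker_sets[f] = base_markers[f].copy()
            else:
                # share the first half of the neighbor's block
                k = olap.index(f)
                nb = olap[(k + 1) % len(olap)]
                half = markers_per_type // 2
                shared = base_markers[nb][:half]
                own = base_markers[f][: markers_per_type - half]
                marker_sets[f] = np.unique(np.concatenate([own, shared]))

    # Programs: shared baseline + coarse shift + family shift + marker boost
    # + fine-specific jitter (weaker for overlapping types).
    base = rng.normal(0.0, 0.5, size=n_genes)
    module_idx = np.concatenate([modules[m] for m in modules])
    base[module_idx] = rng.normal(0.6, 0.15, size=module_idx.size)

    programs = np.zeros((n_fine, n_genes))
    coarse_shift = {c: rng.normal(0.0, 0.9, size=n_genes) for c in coarse_types}
    for c in coarse_types:
        coarse_shift[c][module_idx] = 0.0
    fam_shift: dict[str, np.ndarray] = {}
    for i, f in enumerate(fine_types):
        fam = family[f]
        if fam not in fam_shift:
            s = rng.normal(0.0, 0.3, size=n_genes)
            s[module_idx] = 0.0
            fam_shift[fam] = s
        jitter_sd = 0.25 if regime[f] == "discrete" else 0.08
        jitter = rng.normal(0.0, jitter_sd, size=n_genes)
        jitter[module_idx] = 0.0
        prog = base + coarse_shift[coarse_parent[f]] + fam_shift[fam] + jitter
        boost = discrete_boost if regime[f] == "discrete" else overlap_boost
        prog[marker_sets[f]] += boost
        programs[i] = prog

    # Pull overlapping types toward their coarse mean to create a continuum.
    for c in coarse_types:
        group_idx = [i for i, f in enumerate(fine_types) if coarse_parent[f] == c]
        mean_prog = programs[group_idx].mean(axis=0)
        for i in group_idx:
            if regime[fine_types[i]] == "overlapping":
                programs[i] = 0.45 * programs[i] + 0.55 * mean_prog

    # Calibrate the mitochondrial block so each type's expected mito fraction
    # matches mito_fraction.
    mito = modules["mito"]
    non_mito = np.setdiff1d(np.arange(n_genes), mito)
    for i in range(n_fine):
        tot = np.exp(programs[i, non_mito]).sum()
        target = mito_fraction / (1 - mito_fraction) * tot / mito.size
        programs[i, mito] = np.log(target)

    h = CellTypeHierarchy(
        coarse_types=coarse_types,
        fine_types=fine_types,
        coarse_parent=coarse_parent,
        family=family,
        programs=programs,
        marker_sets=marker_sets,
        separation_regime=regime,
        modules=modules,
        gene_names=gene_names,
        neuronal_coarse="neuron",
    )
    h.validate()
    return h


def _draw_counts(
    programs: np.ndarray,
    type_idx: np.ndarray,
    profile: StudyProfile,
    config: SimulationConfig,
    modules: Mapping[str, np.ndarray],
    bias: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts for cells whose programs are given row-wise."""
    rates = np.exp(programs[type_idx] + bias[None, :])
    if profile.effective_ieg_boost != 1.0:
        rates[:, modules["ieg"]] *= profile.effective_ieg_boost
    if profile.effective_metabolic_boost != 1.0:
        rates[:, modules["metabolic"]] *= profile.effective_metabolic_boost
    rates /= rates.sum(axis=1, keepdims=True)
    lib = rng.lognormal(
        mean=np.log(config.base_depth * profile.depth_factor),
        sigma=config.libsize_sigma,
        size=rates.shape[0],
    )
    mu = rates * lib[:, None]
    if config.dispersion == 0:
        return rng.poisson(mu).astype(np.int64)
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    return rng.poisson(lam).astype(np.int64)


def _cell_programs(
    hierarchy: CellTypeHierarchy, type_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell mean log-expression; overlapping types form a continuum.

    Discrete-regime cells use their type program as-is.  Overlapping-regime
    cells are pulled a random per-cell fraction (uniform on [0, 0.7]) toward
    the mean program of the overlapping types of their coarse class, so
    neighboring overlapping populations blend into each other the way
    continuously varying mid/ventral populations do.
    """
    progs = hierarchy.programs[type_idx].copy()
    anchors: dict[str, np.ndarray] = {}
    for c in hierarchy.coarse_types:
        olap = [
            hierarchy.fine_types.index(f)
            for f in hierarchy.fine_of_coarse(c)
            if hierarchy.separation_regime[f] == "overlapping"
        ]
        if olap:
            anchors[c] = hierarchy.programs[olap].mean(axis=0)
    for i, t in enumerate(type_idx):
        fine = hierarchy.fine_types[t]
        if hierarchy.separation_regime[fine] == "overlapping":
            anchor = anchors[hierarchy.coarse_parent[fine]]
            alpha = rng.uniform(0.0, 0.7)
            progs[i] = (1 - alpha) * progs[i] + alpha * anchor
    return progs


def _assemble_adata(
    counts: np.ndarray,
    labels: np.ndarray,
    hierarchy: CellTypeHierarchy,
    profile: StudyProfile,
) -> AnnData:
    X = sp.csr_matrix(counts.astype(np.int64))
    n = X.shape[0]
    obs = pd.DataFrame(
        {
            "study": pd.Categorical([profile.name] * n),
            "protocol": pd.Categorical([profile.protocol] * n),
            "condition": pd.Categorical([profile.condition] * n),
            "truth": pd.Categorical(labels),
        },
        index=[f"{profile.name}:cell{i:05d}" for i in range(n)],
    )
    var = pd.DataFrame(index=hierarchy.gene_names)
    var["mito"] = [g.startswith("mt-") for g in hierarchy.gene_names]
    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["modules"] = {k: v.tolist() for k, v in hierarchy.modules.items()}
    return adata


def simulate_study(
    hierarchy: CellTypeHierarchy,
    profile: StudyProfile,
    config: SimulationConfig,
) -> tuple[AnnData, GroundTruth]:
    """Simulate one study's cells-by-genes count matrix with planted truth.

    Doublet and low-quality rates are applied as fixed counts
    (``floor(rate * n_cells)``).  Doublets are the summed counts of two
    independently drawn singlets from the same study; low-quality barcodes
    are singlets binomially downsampled so their detected-gene count falls
    below typical QC thresholds with high probability.
    """
    if config.n_genes != hierarchy.n_genes:
        raise ValueError("config.n_genes must match hierarchy.n_genes")
    rng = np.random.default_rng(_stable_seed(config.seed, "study", profile.name))

    n = profile.n_cells
    n_doub = int(np.floor(config.doublet_rate * n))
    n_lowq = int(np.floor(config.lowq_rate * n))
    n_single = n - n_doub - n_lowq
    if n_single < 1:
        raise ValueError("rates leave no singlet cells")

    props = config.type_proportions
    if props is None:
        props = np.full(hierarchy.n_fine, 1.0 / hierarchy.n_fine)
    type_idx = rng.choice(hierarchy.n_fine, size=n_single, p=np.asarray(props, float))
    cell_programs = _cell_programs(hierarchy, type_idx, rng)

    # Per-study per-gene capture bias (kept off the planted modules so the
    # protocol boosts stay interpretable).
    bias = config.batch_effect_strength * rng.normal(
        0.0, profile.capture_bias_sd, size=hierarchy.n_genes
    )

    counts_s = _draw_counts(
        cell_programs, np.arange(n_single), profile, config, hierarchy.modules, bias, rng
    )
    fine_names = np.asarray(hierarchy.fine_types, dtype=object)
    labels = list(fine_names[type_idx])

    blocks = [counts_s]
    doublet_parents = None
    if n_doub:
        p1 = rng.integers(0, n_single, size=n_doub)
        p2 = rng.integers(0, n_single, size=n_doub)
        same = p1 == p2
        p2[same] = (p2[same] + 1) % n_single
        blocks.append(counts_s[p1] + counts_s[p2])
        labels += [DOUBLET_LABEL] * n_doub
        doublet_parents = np.stack(
            [fine_names[type_idx[p1]], fine_names[type_idx[p2]]], axis=1
        )
    if n_lowq:
        src = rng.integers(0, n_single, size=n_lowq)
        totals = counts_s[src].sum(axis=1)
        keep_p = np.minimum(1.0, config.lowq_target_counts / np.maximum(totals, 1))
        blocks.append(rng.binomial(counts_s[src], keep_p[:, None]))
        labels += [LOWQ_LABEL] * n_lowq

    counts = np.vstack(blocks)
    labels_arr = np.asarray(labels, dtype=object)
    adata = _assemble_adata(counts, labels_arr, hierarchy, profile)
    truth = GroundTruth(
        labels=labels_arr,
        study=np.asarray([profile.name] * counts.shape[0], dtype=object),
        doublet_parents=doublet_parents,
    )
    return adata, truth


def simulate_embryonic(
    hierarchy: CellTypeHierarchy,
    n_progenitors: int,
    convergence_pairs: Mapping[str, Sequence[int]] | None,
    profile: StudyProfile,
    config: SimulationConfig,
    mixtures: Mapping[int, Mapping[str, float]] | None = None,
    jitter_sd: float = 0.15,
) -> tuple[AnnData, GroundTruth]:
    """Simulate an embryonic companion dataset with a planted lineage map.

    Progenitor programs are convex mixtures of fine-type programs plus a
    shared "immaturity" module boost.  By default progenitor ``i`` descends
    1:1 into fine type ``i mod n_fine``; ``convergence_pairs`` maps a fine
    type name to >= 2 progenitor indices that all converge onto it, planting
    a convergent lineage; ``mixtures`` assigns explicit fine-type weight maps
    to individual progenitors (normalized to sum 1).  Progenitor-specific
    program jitter (``jitter_sd``) keeps convergent parents distinguishable.
    The returned ground truth records, per progenitor, the fine types it maps
    to with mixing weights summing to 1.
    """
    n_fine = hierarchy.n_fine
    weights = np.zeros((n_progenitors, n_fine))
    for i in range(n_progenitors):
        weights[i, i % n_fine] = 1.0
    if convergence_pairs:
        for fine, progs in convergence_pairs.items():
            if fine not in hierarchy.fine_types:
                raise ValueError(f"unknown fine type {fine!r} in convergence_pairs")
            if len(progs) < 2:
                raise ValueError("a convergence needs >= 2 progenitor parents")
            j = hierarchy.fine_types.index(fine)
            for p in progs:
                weights[p] = 0.0
                weights[p, j] = 1.0
    if mixtures:
        for p, wmap in mixtures.items():
            row = np.zeros(n_fine)
            for fine, w in wmap.items():
                if fine not in hierarchy.fine_types:
                    raise ValueError(f"unknown fine type {fine!r} in mixtures")
                row[hierarchy.fine_types.index(fine)] = w
            if row.sum() <= 0:
                raise ValueError("mixture weights must be positive")
            weights[p] = row / row.sum()

    prog_programs = weights @ hierarchy.programs
    imm = hierarchy.modules["immaturity"]
    prog_programs[:, imm] += 1.5
    jrng = np.random.default_rng(_stable_seed(config.seed, "embryonic-jitter"))
    if jitter_sd > 0:
        prog_programs += jrng.normal(0.0, jitter_sd, size=prog_programs.shape)

    rng = np.random.default_rng(_stable_seed(config.seed, "embryonic", profile.name))
    n = profile.n_cells
    type_idx = rng.integers(0, n_progenitors, size=n)
    bias = config.batch_effect_strength * rng.normal(
        0.0, profile.capture_bias_sd, size=hierarchy.n_genes
    )
    counts = _draw_counts(
        prog_programs, type_idx, profile, config, hierarchy.modules, bias, rng
    )
    prog_names = np.asarray([f"progenitor{i}" for i in range(n_progenitors)], dtype=object)
    labels = prog_names[type_idx]
    adata = _assemble_adata(counts, labels, hierarchy, profile)
    adata.uns["progenitor_programs"] = prog_programs
    lineage_map = {
        prog_names[i]: {
            hierarchy.fine_types[j]: float(weights[i, j])
            for j in np.flatnonzero(weights[i])
        }
        for i in range(n_progenitors)
    }
    truth = GroundTruth(
        labels=labels,
        study=np.asarray([profile.name] * n, dtype=object),
        lineage_map=lineage_map,
    )
    return adata, truth


def default_study_profiles(n_studies: int = 3, n_cells: int = 1000) -> list[StudyProfile]:
    """Three-study default emulating a mixed cell/nucleus atlas compilation."""
    base = [
        StudyProfile("studyA", protocol="nucleus", n_cells=n_cells, depth_factor=1.0,
                     capture_bias_sd=0.15),
        StudyProfile("studyB", protocol="cell", n_cells=n_cells, depth_factor=1.6,
                     capture_bias_sd=0.20, ieg_boost=3.0, metabolic_boost=2.0),
        StudyProfile("studyC", protocol="nucleus", n_cells=n_cells, depth_factor=0.7,
                     capture_bias_sd=0.25),
        StudyProfile("studyD", protocol="cell", n_cells=n_cells, depth_factor=1.2,
                     capture_bias_sd=0.18, ieg_boost=2.5, metabolic_boost=1.8),
        StudyProfile("studyE", protocol="nucleus", n_cells=n_cells, depth_factor=1.0,
                     capture_bias_sd=0.30),
        StudyProfile("studyF", protocol="cell", n_cells=n_cells, depth_factor=0.9,
                     capture_bias_sd=0.22, ieg_boost=2.0, metabolic_boost=1.5),
    ]
    if not (1 <= n_studies <= len(base)):
        raise ValueError(f"n_studies must be in 1..{len(base)}")
    return base[:n_studies]


def simulate_atlas(
    hierarchy: CellTypeHierarchy,
    profiles: Sequence[StudyProfile],
    config: SimulationConfig,
) -> tuple[AnnData, GroundTruth]:
    """Simulate and concatenate several studies into one merged dataset."""
    import anndata as ad

    adatas, truths = [], []
    for p in profiles:
        a, t = simulate_study(hierarchy, p, config)
        adatas.append(a)
        truths.append(t)
    merged = ad.concat(adatas, join="outer", merge="same")
    merged.obs_names_make_unique()
    truth = GroundTruth(
        labels=np.concatenate([t.labels for t in truths]),
        study=np.concatenate([t.study for t in truths]),
    )
    return merged, truth
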