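"""Self-contained synthetic single-cell data with known ground truth.

The generator emulates the benchmark design used to stress reference-based
annotation: a "world" of cell types with disjoint marker-gene blocks, from
which a query dataset, an annotated reference dataset and a broad
background atlas are simulated as independent draws (different cells, same
type parameters).  A platform effect (i.i.d. Gaussian noise on the query's
log-scale pseudobulk) stands in for the cross-platform split of real
benchmarks.

Counts follow a negative binomial with log-normal(0, 1) baseline gene
means; a cell of type t has its marker genes' means multiplied by
``marker_fold``.  Marker blocks are drawn from the lowest-baseline 40% of
genes: real cell-type markers are near-silent outside their type, and
drawing blocks uniformly from the baseline distribution would give
marker-gene profiles of unrelated types an unrealistically high
correlation.

Query/reference cell-type overlap follows the four benchmark scenarios:
1 equal sets, 2 query-subset, 3 reference-subset, 4 disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import ClusterProfile, FormatError, Species
from .preprocess import CountsWithLabels, aggregate_and_normalize

#: Fraction of lowest-baseline genes eligible to be marker genes.
MARKER_POOL_FRACTION = 0.4


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic query/reference/background triple."""

    n_types: int = 5
    markers_per_type: int = 40
    n_genes: int = 2000
    cells_per_type: int = 100
    marker_fold: float = 8.0
    dispersion: float = 0.3
    platform_noise_sd: float = 0.2
    scenario: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_types * self.markers_per_type:
            raise FormatError(
                "n_genes must be at least n_types * markers_per_type"
            )
        if min(
            self.n_types,
            self.markers_per_type,
            self.cells_per_type,
            self.n_genes,
        ) < 1:
            raise FormatError("count parameters must be positive")
        if self.marker_fold <= 1:
            raise FormatError("marker_fold must exceed 1")
        if self.dispersion <= 0:
            raise FormatError("dispersion must be positive")
        if self.scenario not in (1, 2, 3, 4):
            raise FormatError("scenario must be 1, 2, 3 or 4")


@dataclass
class World:
    """Shared type parameters behind one query/reference/background triple."""

    mu: np.ndarray  # baseline mean per gene
    blocks: list[np.ndarray]  # marker gene indices per type
    type_names: list[str]
    gene_ids: list[str]


def _make_world(spec: ScenarioSpec, rng: np.random.Generator, n_types: int) -> World:
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    pool_size = int(MARKER_POOL_FRACTION * spec.n_genes)
    needed = n_types * spec.markers_per_type
    if pool_size < needed:
        raise FormatError(
            f"marker pool of {pool_size} genes cannot host {n_types} types "
            f"x {spec.markers_per_type} markers; increase n_genes"
        )
    pool = np.argsort(mu)[:pool_size]
    perm = rng.permutation(pool)
    blocks = [
        perm[i * spec.markers_per_type : (i + 1) * spec.markers_per_type]
        for i in range(n_types)
    ]
    return World(
        mu=mu,
        blocks=blocks,
        type_names=[f"type{t:02d}" for t in range(n_types)],
        gene_ids=[f"G{g:05d}" for g in range(spec.n_genes)],
    )


def _simulate_cells(
    world: World,
    types: list[str],
    spec: ScenarioSpec,
    rng: np.random.Generator,
    cell_prefix: str,
) -> CountsWithLabels:
    """NB counts for ``cells_per_type`` cells of each requested type."""
    counts_blocks = []
    cell_ids: list[str] = []
    cluster_of: dict[str, str] = {}
    for t in types:
        block = world.blocks[world.type_names.index(t)]
        mean = world.mu.copy()
        mean[block] *= spec.marker_fold
        # Gamma-Poisson: var = m + dispersion * m^2.
        lam = rng.gamma(
            shape=1.0 / spec.dispersion,
            scale=mean[:, None] * spec.dispersion,
            size=(spec.n_genes, spec.cells_per_type),
        )
        counts_blocks.append(rng.poisson(lam))
        for i in range(spec.cells_per_type):
            cid = f"{cell_prefix}:{t}:{i}"
            cell_ids.append(cid)
            cluster_of[cid] = t
    return CountsWithLabels(
        gene_ids=world.gene_ids,
        cell_ids=cell_ids,
        counts=np.concatenate(counts_blocks, axis=1),
        cluster_of=cluster_of,
    )


def simulate_counts(spec: ScenarioSpec) -> tuple[CountsWithLabels, dict[str, str]]:
    """One dataset of ``n_types`` cell types; truth maps cluster -> type.

    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    world = _make_world(spec, rng, spec.n_types)
    data = _simulate_cells(world, world.type_names, spec, rng, "cell")
    return data, {t: t for t in world.type_names}


@dataclass
class ScenarioPair:
    """A simulated query profile plus reference-builder inputs and truth."""

    query: ClusterProfile
    reference: CountsWithLabels  # labels are the annotated cell types
    background: CountsWithLabels
    truth: dict[str, str]  # query cluster -> true cell type
    query_types: list[str]
    ref_types: list[str]
    spec: ScenarioSpec


def _scenario_type_sets(
    spec: ScenarioSpec, names: list[str]
) -> tuple[list[str], list[str]]:
    n = spec.n_types
    n_sub = max(1, n - 2)  # strict subset size for scenarios 2 and 3
    if spec.scenario == 1:
        return names[:n], names[:n]
    if spec.scenario == 2:
        return names[:n_sub], names[:n]
    if spec.scenario == 3:
        return names[:n], names[:n_sub]
    return names[n : 2 * n], names[:n]  # scenario 4: disjoint


def make_pair(spec: ScenarioSpec) -> ScenarioPair:
    """Simulate a query/reference/background triple for one scenario.

    The background atlas covers every type used by the query or reference
    plus ``2 * n_types`` additional types, mirroring a whole-organism atlas
    that contains relatives of whatever the user uploads.
    """
    rng = np.random.default_rng(spec.seed)
    n_world = (2 * spec.n_types if spec.scenario == 4 else spec.n_types) + (
        2 * spec.n_types
    )
    world = _make_world(spec, rng, n_world)
    query_types, ref_types = _scenario_type_sets(spec, world.type_names)
    bg_types = list(
        dict.fromkeys(query_types + ref_types + world.type_names[-2 * spec.n_types :])
    )

    reference = _simulate_cells(world, ref_types, spec, rng, "ref")
    background = _simulate_cells(world, bg_types, spec, rng, "bg")
    query_cells = _simulate_cells(world, query_types, spec, rng, "query")

    profile = aggregate_and_normalize(query_cells, species=Species.UNKNOWN)
    noisy = profile.values + rng.normal(
        0.0, spec.platform_noise_sd, size=profile.values.shape
    )
    # Anonymize query clusters the way a user's cluster ids would look.
    cluster_ids = [f"c{i}" for i in range(len(profile.cluster_ids))]
    truth = dict(zip(cluster_ids, profile.cluster_ids))
    query = ClusterProfile(
        gene_ids=profile.gene_ids,
        cluster_ids=cluster_ids,
        values=np.clip(noisy, 0.0, None),
        species=Species.UNKNOWN,
    )
    return ScenarioPair(
        query=query,
        reference=reference,
        background=background,
        truth=truth,
        query_types=query_types,
        ref_types=ref_types,
        spec=spec,
    )
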