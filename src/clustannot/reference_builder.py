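"""Build a reference bundle from an annotated dataset plus a background atlas.

The background atlas calibrates what "unrelated cell type" looks like.  The
reference and background cells are co-embedded and jointly clustered; the
combined-cluster profiles (Eb) and the distribution of each reference cell
type over combined clusters (Wb, column-stochastic) yield the corrected
cell-type expression Er = Eb · Wb.  Within each annotated main cell type,
cells are re-clustered at low resolution into sub-clusters whose pseudobulk
profiles (Er-sub) capture sub-type heterogeneity.  Marker sets are scored by
cluster-specificity cosine (a gene's expression vector across clusters
against the one-hot indicator of the cluster).

The original pipeline co-embeds with a deep generative integrator; here any
user-supplied joint embedding is accepted, with a joint-PCA fallback
(library-size normalized, log1p, per-gene standardized, 30 components).  The
downstream algebra (Eb, Wb, Er) does not depend on how the embedding was
made, and the bundle records which one was used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_model import (
    ClusterProfile,
    FormatError,
    InvariantError,
    MarkerEntry,
    MarkerRole,
    MarkerSet,
    ReferenceBundle,
    Species,
    WeightMatrix,
)
from .preprocess import CountsWithLabels, aggregate_and_normalize

logger = logging.getLogger("clustannot")

DEFAULT_SUB_RESOLUTION = 0.3
DEFAULT_JOINT_RESOLUTION = 1.0
DEFAULT_MARKERS_PER_CLUSTER = 50
DEFAULT_KNN = 15
DEFAULT_PCA_COMPONENTS = 30
DEFAULT_CLUSTER_SEED = 7
#: Main types with fewer cells than this are kept as a single sub-cluster.
MIN_CELLS_TO_SPLIT = 10


@dataclass
class JointClustering:
    """A partition of reference + background cells into combined clusters."""

    combined_cluster_of: dict[str, str]
    source_of: dict[str, str]  # cell -> "reference" | "background"
    ref_celltype_of: dict[str, str]

    def __post_init__(self) -> None:
        for cell, source in self.source_of.items():
            if cell not in self.combined_cluster_of:
                raise InvariantError(f"cell {cell!r} has no combined cluster")
            if source == "reference" and cell not in self.ref_celltype_of:
                raise InvariantError(
                    f"reference cell {cell!r} has no cell type"
                )


# ---------------------------------------------------------------------------
# Wb and Er
# ---------------------------------------------------------------------------


def compute_weight_matrix(jc: JointClustering) -> WeightMatrix:
    """Fraction of each reference cell type falling in each combined cluster.

    Column t of the result is the distribution of type-t reference cells
    over combined clusters; every column sums to one.
    """
    ref_cells = [c for c, s in jc.source_of.items() if s == "reference"]
    if not ref_cells:
        raise FormatError("joint clustering contains no reference cells")
    types: dict[str, None] = {}
    for c in ref_cells:
        types.setdefault(jc.ref_celltype_of[c], None)
    clusters: dict[str, None] = {}
    for c in jc.combined_cluster_of.values():
        clusters.setdefault(c, None)
    rows = list(clusters)
    cols = list(types)
    counts = np.zeros((len(rows), len(cols)))
    row_ix = {r: i for i, r in enumerate(rows)}
    col_ix = {c: j for j, c in enumerate(cols)}
    for cell in ref_cells:
        counts[
            row_ix[jc.combined_cluster_of[cell]],
            col_ix[jc.ref_celltype_of[cell]],
        ] += 1
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        empty = [cols[j] for j in np.where(totals == 0)[0]]
        raise FormatError(f"cell types with zero cells: {empty}")
    return WeightMatrix(rows=rows, cols=cols, values=counts / totals)


def correct_reference_expression(
    eb: ClusterProfile, wb: WeightMatrix
) -> ClusterProfile:
    """Er = Eb · Wb: the Wb-weighted average of combined-cluster profiles."""
    missing = [r for r in wb.rows if r not in eb.cluster_ids]
    extra = [c for c in eb.cluster_ids if c not in wb.rows]
    if missing or extra:
        raise FormatError(
            f"cluster ids of Eb and Wb disagree "
            f"(missing from Eb: {missing}, missing from Wb: {extra})"
        )
    order = [eb.cluster_ids.index(r) for r in wb.rows]
    er_values = eb.values[:, order] @ wb.values
    return ClusterProfile(
        gene_ids=eb.gene_ids,
        cluster_ids=list(wb.cols),
        values=er_values,
        species=eb.species,
    )


# ---------------------------------------------------------------------------
# Graph clustering
# ---------------------------------------------------------------------------


def _leiden_partition(
    coords: np.ndarray,
    resolution: float,
    k: int = DEFAULT_KNN,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> np.ndarray:
    """k-NN graph (Euclidean) + Leiden modularity communities."""
    n = coords.shape[0]
    if resolution <= 0:
        return np.zeros(n, dtype=int)
    k_eff = min(k, n - 1)
    if k_eff < 1:
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {
        (min(i, j), max(i, j))
        for i in range(n)
        for j in idx[i, 1:]
    }
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def joint_embedding(
    ref: CountsWithLabels,
    background: CountsWithLabels,
    n_components: int = DEFAULT_PCA_COMPONENTS,
) -> dict[str, np.ndarray]:
    """Joint-PCA fallback embedding over reference + background cells.

    Cells are library-size normalized to 1e5, log1p transformed, genes
    standardized, then projected on the top principal components.
    """
    if set(ref.gene_ids) != set(background.gene_ids):
        raise FormatError(
            "reference and background must share the same gene universe"
        )
    clash = set(ref.cell_ids) & set(background.cell_ids)
    if clash:
        raise FormatError(
            f"reference and background share {len(clash)} cell ids; "
            "relabel one of them (e.g. add a prefix)"
        )
    order = [background.gene_ids.index(g) for g in ref.gene_ids]
    counts = np.concatenate([ref.counts, background.counts[order, :]], axis=1)
    cells = list(ref.cell_ids) + list(background.cell_ids)
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise FormatError("cells with zero counts cannot be embedded")
    logcpm = np.log1p(1e5 * counts / totals).T  # cells x genes
    sd = logcpm.std(axis=0)
    sd[sd == 0] = 1.0
    standardized = (logcpm - logcpm.mean(axis=0)) / sd
    n_comp = min(n_components, standardized.shape[0] - 1, standardized.shape[1])
    coords = PCA(n_components=n_comp, random_state=0).fit_transform(standardized)
    return {c: coords[i] for i, c in enumerate(cells)}


def joint_cluster(
    ref: CountsWithLabels,
    background: CountsWithLabels,
    embedding: Mapping[str, np.ndarray],
    resolution: float = DEFAULT_JOINT_RESOLUTION,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> JointClustering:
    """Cluster all reference + background cells on the joint embedding."""
    cells = list(ref.cell_ids) + list(background.cell_ids)
    missing = [c for c in cells if c not in embedding]
    if missing:
        raise FormatError(
            f"embedding is missing {len(missing)} cells (e.g. {missing[:3]})"
        )
    coords = np.vstack([np.asarray(embedding[c], dtype=float) for c in cells])
    membership = _leiden_partition(coords, resolution, seed=seed)
    combined = {c: f"joint::{m}" for c, m in zip(cells, membership)}
    source = {c: "reference" for c in ref.cell_ids}
    source.update({c: "background" for c in background.cell_ids})
    return JointClustering(
        combined_cluster_of=combined,
        source_of=source,
        ref_celltype_of={c: ref.cluster_of[c] for c in ref.cell_ids},
    )


def refine_subclusters(
    ref: CountsWithLabels,
    embedding: Mapping[str, np.ndarray],
    resolution: float = DEFAULT_SUB_RESOLUTION,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> dict[str, str]:
    """Split each main cell type into sub-clusters on the embedding.

    Types with fewer than MIN_CELLS_TO_SPLIT cells stay whole (warning).
    Sub-cluster ids are ``<maintype>::<k>``.
    """
    missing = [c for c in ref.cell_ids if c not in embedding]
    if missing:
        raise FormatError(
            f"embedding is missing {len(missing)} cells (e.g. {missing[:3]})"
        )
    assignment: dict[str, str] = {}
    for main_type in ref.cluster_ids:
        cells = ref.cells_of(main_type)
        if len(cells) < MIN_CELLS_TO_SPLIT:
            logger.warning(
                "cell type %r has %d cells (<%d); kept as one sub-cluster",
                main_type,
                len(cells),
                MIN_CELLS_TO_SPLIT,
            )
            for c in cells:
                assignment[c] = f"{main_type}::0"
            continue
        coords = np.vstack([np.asarray(embedding[c], dtype=float) for c in cells])
        membership = _leiden_partition(coords, resolution, seed=seed)
        for c, m in zip(cells, membership):
            assignment[c] = f"{main_type}::{m}"
    return assignment


# ---------------------------------------------------------------------------
# Marker scoring
# ---------------------------------------------------------------------------


def marker_score(profile: ClusterProfile, cluster_id: str) -> list[tuple[str, float]]:
    """Cluster-specificity score per gene, ranked.

    For gene g and cluster k the score is e_gk / ||e_g||_2 — the cosine
    between the gene's cross-cluster expression vector and the one-hot
    indicator of cluster k.  A gene expressed only in k scores 1; a gene
    uniform across K clusters scores 1/sqrt(K); an all-zero gene scores 0.
    Ties are broken by higher expression in k, then by gene id.
    """
    if profile.n_clusters < 2:
        raise FormatError("marker scoring needs at least two clusters")
    j = profile.cluster_ids.index(cluster_id)
    norms = np.sqrt((profile.values**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(norms > 0, profile.values[:, j] / norms, 0.0)
    order = sorted(
        range(profile.n_genes),
        key=lambda i: (-scores[i], -profile.values[i, j], profile.gene_ids[i]),
    )
    return [(profile.gene_ids[i], float(scores[i])) for i in order]


def select_markers(
    profile: ClusterProfile,
    n_per_cluster: int = DEFAULT_MARKERS_PER_CLUSTER,
    role: MarkerRole = MarkerRole.MAIN,
) -> MarkerSet:
    """Top-n genes per cluster by specificity score.

    A gene may serve several clusters.  If n exceeds the gene count, all
    genes are taken (with a warning).
    """
    if n_per_cluster < 1:
        raise FormatError("n_per_cluster must be >= 1")
    n = n_per_cluster
    if n > profile.n_genes:
        logger.warning(
            "requested %d markers per cluster but profile has %d genes",
            n,
            profile.n_genes,
        )
        n = profile.n_genes
    entries: list[MarkerEntry] = []
    for cid in profile.cluster_ids:
        ranked = marker_score(profile, cid)[:n]
        entries.extend(
            MarkerEntry(cid, gene, score, rank)
            for rank, (gene, score) in enumerate(ranked, start=1)
        )
    return MarkerSet(role=role, entries=entries)


# ---------------------------------------------------------------------------
# End-to-end bundle construction
# ---------------------------------------------------------------------------


@dataclass
class BuildParams:
    sub_resolution: float = DEFAULT_SUB_RESOLUTION
    joint_resolution: float = DEFAULT_JOINT_RESOLUTION
    markers_n: int = DEFAULT_MARKERS_PER_CLUSTER
    knn: int = DEFAULT_KNN
    pca_components: int = DEFAULT_PCA_COMPONENTS
    seed: int = DEFAULT_CLUSTER_SEED
    name: str = "reference"


def build_reference(
    ref: CountsWithLabels,
    background: CountsWithLabels,
    embedding: Mapping[str, np.ndarray] | None = None,
    params: BuildParams | None = None,
    species: Species = Species.UNKNOWN,
) -> ReferenceBundle:
    """Run the full reference-preparation pipeline.

    joint clustering -> Eb (combined-cluster averages) -> Wb -> Er ->
    sub-cluster refinement -> Er-sub -> bg-/main-/sub-marker sets.
    """
    params = params or BuildParams()
    if not background.cell_ids:
        raise FormatError("background dataset is empty")
    if not ref.cell_ids:
        raise FormatError("reference dataset is empty")
    if set(ref.cell_ids) & set(background.cell_ids):
        raise FormatError(
            "reference and background share cell ids; relabel one of them"
        )
    embedding_source = "user-supplied"
    if embedding is None:
        embedding_source = f"joint-pca-{params.pca_components}"
        embedding = joint_embedding(ref, background, params.pca_components)

    jc = joint_cluster(
        ref, background, embedding, params.joint_resolution, params.seed
    )

    # Eb: pseudobulk of each combined cluster, via the same
    # sum-then-normalize transform used for query profiles so that
    # query-background correlations compare like with like.
    cells = list(ref.cell_ids) + list(background.cell_ids)
    order = [background.gene_ids.index(g) for g in ref.gene_ids]
    counts = np.concatenate([ref.counts, background.counts[order, :]], axis=1)
    combined = CountsWithLabels(
        gene_ids=ref.gene_ids,
        cell_ids=cells,
        counts=counts,
        cluster_of=jc.combined_cluster_of,
    )
    eb = aggregate_and_normalize(combined, species=species)

    wb = compute_weight_matrix(jc)
    er = correct_reference_expression(eb, wb)

    sub_of = refine_subclusters(
        ref, embedding, params.sub_resolution, params.seed
    )
    ref_sub = CountsWithLabels(
        gene_ids=ref.gene_ids,
        cell_ids=ref.cell_ids,
        counts=ref.counts,
        cluster_of=sub_of,
    )
    ersub = aggregate_and_normalize(ref_sub, species=species)
    sub_to_main = {s: s.rsplit("::", 1)[0] for s in ersub.cluster_ids}

    markers_bg = select_markers(eb, params.markers_n, MarkerRole.BG)
    # Main markers are scored on the original author-annotated cell types.
    e_main = aggregate_and_normalize(ref, species=species)
    markers_main_raw = select_markers(e_main, params.markers_n, MarkerRole.MAIN)
    markers_sub = select_markers(ersub, params.markers_n, MarkerRole.SUB)

    bundle = ReferenceBundle(
        er=er,
        ersub=ersub,
        sub_to_main=sub_to_main,
        markers_main=markers_main_raw,
        markers_sub=markers_sub,
        background=eb,
        markers_bg=markers_bg,
        meta={
            "name": params.name,
            "species": species.value,
            "embedding": embedding_source,
            "sub_resolution": params.sub_resolution,
            "joint_resolution": params.joint_resolution,
            "markers_n": params.markers_n,
            "knn": params.knn,
            "cluster_seed": params.seed,
            "n_combined_clusters": eb.n_clusters,
            "n_cell_types": er.n_clusters,
            "n_sub_clusters": ersub.n_clusters,
        },
    )
    return bundle
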