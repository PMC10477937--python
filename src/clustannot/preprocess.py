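"""Query/reference preprocessing: pseudobulk aggregation, species detection
and cross-species gene harmonization.

Aggregation follows the sum-then-normalize convention: raw counts are summed
over the cells of a cluster, scaled to counts-per-1e5, and log(1+x)
transformed.  This differs from averaging per-cell normalized values and the
summed order is kept deliberately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .io_model import (
    ClusterProfile,
    FormatError,
    InsufficientOverlapError,
    OrthologMap,
    Species,
)

logger = logging.getLogger("clustannot")

DEFAULT_SCALE = 1e5
#: Minimum genes that must survive ortholog mapping.
MIN_MAPPED_GENES = 100


@dataclass
class CountsWithLabels:
    """Raw per-cell counts plus a cluster label for every cell."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray  # genes x cells, non-negative integers
    cluster_of: dict[str, str]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if scipy.sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.size:
            if np.any(self.counts < 0):
                raise FormatError("counts must be non-negative")
            if not np.allclose(self.counts, np.round(self.counts)):
                raise FormatError("counts must be integral")
        missing = [c for c in self.cell_ids if c not in self.cluster_of]
        if missing:
            raise FormatError(
                f"{len(missing)} cells have no cluster label "
                f"(e.g. {missing[:3]})"
            )

    @property
    def cluster_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cell_ids:
            seen.setdefault(self.cluster_of[c], None)
        return list(seen)

    def cells_of(self, cluster_id: str) -> list[str]:
        return [c for c in self.cell_ids if self.cluster_of[c] == cluster_id]

    def subset_cells(self, cells: Sequence[str]) -> "CountsWithLabels":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cells]
        return CountsWithLabels(
            gene_ids=self.gene_ids,
            cell_ids=list(cells),
            counts=self.counts[:, cols],
            cluster_of={c: self.cluster_of[c] for c in cells},
        )


def aggregate_and_normalize(
    data: CountsWithLabels,
    scale: float = DEFAULT_SCALE,
    species: Species = Species.UNKNOWN,
) -> ClusterProfile:
    """Pseudobulk: sum counts per cluster, normalize to ``scale``, log1p.

    For cluster k and gene g, the output value is
    ``log(1 + scale * S(g,k) / T(k))`` with S the summed counts and T(k) the
    cluster total, so ``sum_g (exp(v)-1) == scale`` for every cluster.
    """
    if scale <= 0:
        raise FormatError("scale must be positive")
    clusters = data.cluster_ids
    if not clusters:
        raise FormatError("no cells to aggregate")
    labels = np.array([data.cluster_of[c] for c in data.cell_ids])
    values = np.empty((len(data.gene_ids), len(clusters)), dtype=float)
    for j, k in enumerate(clusters):
        summed = data.counts[:, labels == k].sum(axis=1).astype(float)
        total = summed.sum()
        if total == 0:
            raise FormatError(f"cluster {k!r} has zero total counts")
        values[:, j] = np.log1p(scale * summed / total)
    return ClusterProfile(
        gene_ids=data.gene_ids,
        cluster_ids=clusters,
        values=values,
        species=species,
    )


def detect_species(
    gene_ids: Sequence[str],
    human_universe: set[str] | Sequence[str],
    mouse_universe: set[str] | Sequence[str],
    threshold: float = 0.5,
) -> Species:
    """Assign a species when the symbol-overlap ratio strictly exceeds
    ``threshold``; the larger ratio wins if both do.  Returns
    ``Species.UNKNOWN`` (a warning condition) otherwise.

    Gene ids are de-duplicated case-insensitively before computing ratios.
    """
    if not len(gene_ids):
        raise FormatError("empty gene list")
    if not len(human_universe) or not len(mouse_universe):
        raise FormatError("species universes must be non-empty")
    ids = {g.upper() for g in gene_ids}
    human = {g.upper() for g in human_universe}
    mouse = {g.upper() for g in mouse_universe}
    ratio_h = len(ids & human) / len(ids)
    ratio_m = len(ids & mouse) / len(ids)
    if max(ratio_h, ratio_m) > threshold:
        if ratio_h == ratio_m:
            # Exact tie above threshold: ambiguous, warn rather than guess.
            logger.warning(
                "species detection tie (%.2f); returning unknown", ratio_h
            )
            return Species.UNKNOWN
        return Species.HUMAN if ratio_h > ratio_m else Species.MOUSE
    logger.warning(
        "species detection inconclusive (human %.1f%%, mouse %.1f%%)",
        100 * ratio_h,
        100 * ratio_m,
    )
    return Species.UNKNOWN


def map_orthologs(
    profile: ClusterProfile,
    ortho: OrthologMap,
    target_species: Species,
    min_genes: int = MIN_MAPPED_GENES,
) -> ClusterProfile:
    """Translate gene symbols across species via one-to-one ortholog pairs.

    Genes without a one-to-one partner are dropped (the count is logged);
    expression values are never altered.  Matching is case-insensitive and
    the target-side symbol casing from the map is used on output.
    """
    target_species = Species(target_species)
    if profile.species == Species.UNKNOWN:
        raise FormatError("profile species must be known to map orthologs")
    if target_species == Species.UNKNOWN:
        raise FormatError("target species must be human or mouse")
    if profile.species == target_species:
        raise FormatError("profile is already in the target species")
    pairs = ortho.one_to_one()
    if target_species == Species.HUMAN:
        lookup = {m.upper(): h for h, m in pairs}
    else:
        lookup = {h.upper(): m for h, m in pairs}
    keep_rows: list[int] = []
    new_genes: list[str] = []
    seen: set[str] = set()
    for i, g in enumerate(profile.gene_ids):
        target = lookup.get(g.upper())
        if target is None or target.upper() in seen:
            continue
        seen.add(target.upper())
        keep_rows.append(i)
        new_genes.append(target)
    dropped = profile.n_genes - len(keep_rows)
    if dropped:
        logger.info(
            "ortholog mapping dropped %d/%d genes without one-to-one partner",
            dropped,
            profile.n_genes,
        )
    if len(keep_rows) < min_genes:
        raise InsufficientOverlapError(
            f"only {len(keep_rows)} genes survive ortholog mapping "
            f"(need >= {min_genes}); check species and gene symbols"
        )
    return ClusterProfile(
        gene_ids=new_genes,
        cluster_ids=profile.cluster_ids,
        values=profile.values[keep_rows, :],
        species=target_species,
    )


# ---------------------------------------------------------------------------
# Loaders for raw inputs
# ---------------------------------------------------------------------------


def read_cluster_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (cell_id, cluster), with or without a header line."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if frame.shape[1] < 2:
        raise FormatError(f"label file {path} needs two columns")
    first = frame.iloc[0]
    if str(first[0]).lower() in ("cell", "cell_id", "barcode"):
        frame = frame.iloc[1:]
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def read_counts_dense(path: str | Path, labels_path: str | Path) -> CountsWithLabels:
    """Dense TSV of counts (genes in rows, cells in columns) plus labels."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    cluster_of = read_cluster_labels(labels_path)
    return CountsWithLabels(
        gene_ids=[str(g) for g in frame.index],
        cell_ids=[str(c) for c in frame.columns],
        counts=frame.to_numpy(),
        cluster_of=cluster_of,
    )


def read_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
) -> CountsWithLabels:
    """MatrixMarket counts (genes x cells) with sidecar gene/barcode lists."""
    matrix = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str)
    cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
    cluster_of = read_cluster_labels(labels_path)
    return CountsWithLabels(
        gene_ids=genes.tolist(),
        cell_ids=cells.tolist(),
        counts=np.asarray(matrix.todense())
        if scipy.sparse.issparse(matrix)
        else np.asarray(matrix),
        cluster_of=cluster_of,
    )


def read_gene_universe(path: str | Path) -> set[str]:
    """One gene symbol per line."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}
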