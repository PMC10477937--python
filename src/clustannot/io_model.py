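"""Shared domain types and on-disk formats.

Everything the pipeline passes between stages lives here: cluster-level
expression profiles, marker sets, the reference bundle, mixture/cutoff
results, and prediction records — together with plain-text readers and
writers (TSV matrices, JSON metadata, a reference-bundle directory).

All formats are UTF-8, tab-delimited, "." decimal, values written with 12
significant digits so every read/write pair is an exact round trip at that
precision.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("clustannot")

#: Reserved prediction literal; no input cluster may use it.
UNASSIGNED = "unassigned"

#: Float formatting used by every writer (12 significant digits).
_FLOAT_FMT = "%.12g"


class ClustannotError(Exception):
    """Base class for all package errors."""


class FormatError(ClustannotError):
    """Malformed or inconsistent input (CLI exit code 2)."""


class InsufficientOverlapError(ClustannotError):
    """Too few shared genes between query and reference (CLI exit code 3)."""


class InvariantError(ClustannotError):
    """An internal consistency contract was violated (CLI exit code 4)."""


class Species(str, enum.Enum):
    HUMAN = "human"
    MOUSE = "mouse"
    UNKNOWN = "unknown"


class MarkerRole(str, enum.Enum):
    BG = "bg"
    MAIN = "main"
    SUB = "sub"


# ---------------------------------------------------------------------------
# ClusterProfile
# ---------------------------------------------------------------------------


@dataclass
class ClusterProfile:
    """A genes × clusters matrix of average log-normalized expression.

    Values are log(1 + CPM-at-1e5) pseudobulk averages.  The same container
    serves for query profiles (Eq), background cluster profiles (Eb),
    corrected reference cell-type profiles (Er) and sub-cluster profiles
    (Er-sub); only the column semantics differ.
    """

    gene_ids: list[str]
    cluster_ids: list[str]
    values: np.ndarray
    species: Species = Species.UNKNOWN

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cluster_ids = list(self.cluster_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.species = Species(self.species)
        self.validate()

    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvariantError("duplicate gene ids in profile")
        if len(set(self.cluster_ids)) != len(self.cluster_ids):
            raise InvariantError("duplicate cluster ids in profile")
        if UNASSIGNED in self.cluster_ids:
            raise FormatError(
                f"cluster id {UNASSIGNED!r} is reserved for predictions"
            )
        if self.values.shape != (len(self.gene_ids), len(self.cluster_ids)):
            raise InvariantError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cluster_ids)} clusters"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvariantError("profile contains non-finite values")
        if self.values.size and self.values.min() < 0:
            raise InvariantError("profile contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.cluster_ids
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, species: Species = Species.UNKNOWN
    ) -> "ClusterProfile":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            cluster_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            species=species,
        )

    def column(self, cluster_id: str) -> np.ndarray:
        """Expression vector of one cluster (genes in profile order)."""
        try:
            j = self.cluster_ids.index(cluster_id)
        except ValueError:
            raise KeyError(f"no cluster {cluster_id!r} in profile") from None
        return self.values[:, j]

    def subset_genes(self, genes: Sequence[str]) -> "ClusterProfile":
        """Restrict to the given genes, preserving the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ClusterProfile(
            gene_ids=list(genes),
            cluster_ids=list(self.cluster_ids),
            values=self.values[rows, :],
            species=self.species,
        )


# ---------------------------------------------------------------------------
# MarkerSet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerEntry:
    cluster_id: str
    gene_id: str
    score: float
    rank: int


@dataclass
class MarkerSet:
    """Ranked marker genes per cluster (bg-, main- or sub-markers)."""

    role: MarkerRole
    entries: list[MarkerEntry]

    def __post_init__(self) -> None:
        self.role = MarkerRole(self.role)
        self.entries = [
            e if isinstance(e, MarkerEntry) else MarkerEntry(*e)
            for e in self.entries
        ]
        self.validate()

    def validate(self) -> None:
        by_cluster: dict[str, list[MarkerEntry]] = {}
        for e in self.entries:
            by_cluster.setdefault(e.cluster_id, []).append(e)
        for cid, ents in by_cluster.items():
            ranks = sorted(e.rank for e in ents)
            if ranks != list(range(1, len(ents) + 1)):
                raise InvariantError(f"marker ranks for {cid!r} are not 1..n")
            ordered = sorted(ents, key=lambda e: e.rank)
            scores = [e.score for e in ordered]
            if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
                raise InvariantError(
                    f"marker scores for {cid!r} increase with rank"
                )

    @property
    def cluster_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.cluster_id, None)
        return list(seen)

    def genes_for(self, cluster_id: str) -> list[str]:
        ents = [e for e in self.entries if e.cluster_id == cluster_id]
        return [e.gene_id for e in sorted(ents, key=lambda e: e.rank)]

    def all_genes(self) -> list[str]:
        """Union of marker genes over clusters, in first-seen order."""
        seen: dict[str, None] = {}
        for e in sorted(self.entries, key=lambda e: (e.cluster_id, e.rank)):
            seen.setdefault(e.gene_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# WeightMatrix
# ---------------------------------------------------------------------------


@dataclass
class WeightMatrix:
    """Column-stochastic cell-distribution matrix Wb.

    Rows are combined (reference + background) clusters, columns are
    reference cell types; entry (c, t) is the fraction of type-t reference
    cells that fall in combined cluster c.
    """

    rows: list[str]
    cols: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.rows = list(self.rows)
        self.cols = list(self.cols)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise InvariantError("weight matrix shape mismatch")
        if self.values.size and self.values.min() < 0:
            raise InvariantError("weight matrix has negative entries")
        sums = self.values.sum(axis=0)
        if self.values.size and not np.allclose(sums, 1.0, atol=1e-9):
            raise InvariantError(
                f"weight matrix columns must sum to 1 (got {sums})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)


# ---------------------------------------------------------------------------
# Mixture / cutoff results
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """A fitted univariate Gaussian mixture with 1-3 components.

    Components are stored sorted by ascending mean.  ``criterion`` is the
    model-selection score (BIC, smaller is better) of this fit.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    criterion: float
    n: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (1 <= self.k <= 3):
            raise InvariantError("mixture must have 1-3 components")
        for arr in (self.weights, self.means, self.sds):
            if arr.shape != (self.k,):
                raise InvariantError("component arrays must have length k")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InvariantError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise InvariantError("component sds must be positive")
        if np.any(np.diff(self.means) < 0):
            raise InvariantError("components must be sorted by mean")


@dataclass
class CutoffResult:
    """An adaptive correlation cutoff, clamped to [clamp_lo, clamp_hi]."""

    raw_cutoff: float
    cutoff: float
    k_selected: int
    clamp_lo: float = 0.4
    clamp_hi: float = 0.6
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not (self.clamp_lo - 1e-12 <= self.cutoff <= self.clamp_hi + 1e-12):
            raise InvariantError("cutoff outside clamp range")
        if (
            not self.fallback_used
            and self.clamp_lo <= self.raw_cutoff <= self.clamp_hi
            and abs(self.cutoff - self.raw_cutoff) > 1e-12
        ):
            raise InvariantError("in-range raw cutoff must be kept verbatim")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


@dataclass
class PredictionRecord:
    """Final outcome for one query cluster."""

    query_cluster: str
    status: str  # "assigned" | "unassigned"
    cell_type: str = ""
    sub_cluster: str = ""
    best_corr_module1: float = float("nan")
    best_corr_module2: float = float("nan")
    cutoff_module1: float = float("nan")
    cutoff_module2: float = float("nan")
    decided_by: str = ""  # "module1" | "module2" | "module3"
    candidate_pvalues: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("assigned", UNASSIGNED):
            raise InvariantError(f"bad status {self.status!r}")
        if (self.status == UNASSIGNED) != (self.cell_type == ""):
            raise InvariantError("status and cell_type disagree")
        if self.decided_by not in ("module1", "module2", "module3"):
            raise InvariantError(f"bad decided_by {self.decided_by!r}")
        if self.decided_by == "module3" and not self.candidate_pvalues:
            raise InvariantError("module3 decision requires candidate scores")


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------


@dataclass
class OrthologMap:
    """Human <-> mouse gene symbol pairs, filtered to one-to-one matches."""

    pairs: list[tuple[str, str]]

    def one_to_one(self) -> list[tuple[str, str]]:
        """Pairs whose symbols occur exactly once per species (case-folded)."""
        from collections import Counter

        h_count = Counter(h.upper() for h, _ in self.pairs)
        m_count = Counter(m.upper() for _, m in self.pairs)
        return [
            (h, m)
            for h, m in self.pairs
            if h_count[h.upper()] == 1 and m_count[m.upper()] == 1
        ]


# ---------------------------------------------------------------------------
# Reference bundle
# ---------------------------------------------------------------------------


@dataclass
class ReferenceBundle:
    """Everything needed to annotate a query against one reference."""

    er: ClusterProfile
    ersub: ClusterProfile
    sub_to_main: dict[str, str]
    markers_main: MarkerSet
    markers_sub: MarkerSet
    background: ClusterProfile
    markers_bg: MarkerSet
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        main_types = set(self.er.cluster_ids)
        for sub in self.ersub.cluster_ids:
            if sub not in self.sub_to_main:
                raise InvariantError(f"sub-cluster {sub!r} missing from map")
            if self.sub_to_main[sub] not in main_types:
                raise InvariantError(
                    f"sub-cluster {sub!r} maps to unknown type "
                    f"{self.sub_to_main[sub]!r}"
                )
        species = {self.er.species, self.ersub.species, self.background.species}
        if len(species) != 1:
            raise InvariantError("bundle profiles disagree on species")
        for mset, prof in (
            (self.markers_main, self.er),
            (self.markers_sub, self.ersub),
            (self.markers_bg, self.background),
        ):
            missing = set(mset.all_genes()) - set(prof.gene_ids)
            if missing:
                raise InvariantError(
                    f"{mset.role.value}-markers reference unknown genes: "
                    f"{sorted(missing)[:5]}"
                )

    @property
    def species(self) -> Species:
        return self.er.species


# ---------------------------------------------------------------------------
# TSV / JSON readers and writers
# ---------------------------------------------------------------------------


def read_cluster_profile(
    path: str | Path, species: Species = Species.UNKNOWN
) -> ClusterProfile:
    """Read a genes × clusters TSV (header of cluster names, first column
    ``gene``).

    Duplicate gene rows are collapsed by keeping the row with the highest
    total expression (a warning is logged).  Orientation is fixed: genes in
    rows; a transposed file is a user error, not auto-detected.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read profile {path}: {exc}") from exc
    if frame.empty or frame.shape[1] == 0:
        raise FormatError(f"profile {path} has no data")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = str(bad.index[0]) if len(bad) else "?"
            raise FormatError(
                f"non-numeric value in {path} at gene {row!r}, "
                f"cluster {col!r}"
            ) from exc
    genes = [str(g) for g in frame.index]
    if len(set(genes)) != len(genes):
        keep: dict[str, int] = {}
        totals = values.sum(axis=1)
        for i, g in enumerate(genes):
            if g not in keep or totals[i] > totals[keep[g]]:
                keep[g] = i
        n_dropped = len(genes) - len(keep)
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept highest total)",
            path,
            n_dropped,
        )
        rows = sorted(keep.values())
        genes = [genes[i] for i in rows]
        values = values[rows, :]
    return ClusterProfile(
        gene_ids=genes,
        cluster_ids=[str(c) for c in frame.columns],
        values=values,
        species=species,
    )


def write_cluster_profile(profile: ClusterProfile, path: str | Path) -> None:
    frame = profile.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _write_marker_set(mset: MarkerSet, path: Path) -> None:
    frame = pd.DataFrame(
        [(e.cluster_id, e.gene_id, e.score, e.rank) for e in mset.entries],
        columns=["cluster", "gene", "score", "rank"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_marker_set(path: Path, role: MarkerRole) -> MarkerSet:
    frame = pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene": str})
    entries = [
        MarkerEntry(str(r.cluster), str(r.gene), float(r.score), int(r.rank))
        for r in frame.itertuples()
    ]
    return MarkerSet(role=role, entries=entries)


_BUNDLE_FILES = (
    "er.tsv",
    "ersub.tsv",
    "background.tsv",
    "markers_bg.tsv",
    "markers_main.tsv",
    "markers_sub.tsv",
    "sub_to_main.tsv",
    "meta.json",
)


def write_reference_bundle(
    bundle: ReferenceBundle, directory: str | Path
) -> list[str]:
    """Write a bundle as a plain directory of TSV/JSON; returns the manifest."""
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cluster_profile(bundle.er, directory / "er.tsv")
    write_cluster_profile(bundle.ersub, directory / "ersub.tsv")
    write_cluster_profile(bundle.background, directory / "background.tsv")
    _write_marker_set(bundle.markers_bg, directory / "markers_bg.tsv")
    _write_marker_set(bundle.markers_main, directory / "markers_main.tsv")
    _write_marker_set(bundle.markers_sub, directory / "markers_sub.tsv")
    pd.DataFrame(
        sorted(bundle.sub_to_main.items()), columns=["sub_cluster", "main_type"]
    ).to_csv(directory / "sub_to_main.tsv", sep="\t", index=False)
    meta = dict(bundle.meta)
    meta.setdefault("species", bundle.species.value)
    with open(directory / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return list(_BUNDLE_FILES)


def read_reference_bundle(directory: str | Path) -> ReferenceBundle:
    directory = Path(directory)
    missing = [f for f in _BUNDLE_FILES if not (directory / f).exists()]
    if missing:
        raise FormatError(
            f"reference bundle {directory} is missing files: {missing}"
        )
    with open(directory / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    species = Species(meta.get("species", "unknown"))
    s2m_frame = pd.read_csv(directory / "sub_to_main.tsv", sep="\t", dtype=str)
    sub_to_main = dict(
        zip(s2m_frame["sub_cluster"], s2m_frame["main_type"])
    )
    return ReferenceBundle(
        er=read_cluster_profile(directory / "er.tsv", species),
        ersub=read_cluster_profile(directory / "ersub.tsv", species),
        sub_to_main=sub_to_main,
        markers_main=_read_marker_set(
            directory / "markers_main.tsv", MarkerRole.MAIN
        ),
        markers_sub=_read_marker_set(
            directory / "markers_sub.tsv", MarkerRole.SUB
        ),
        background=read_cluster_profile(directory / "background.tsv", species),
        markers_bg=_read_marker_set(
            directory / "markers_bg.tsv", MarkerRole.BG
        ),
        meta=meta,
    )


_PREDICTION_COLUMNS = (
    "query_cluster",
    "status",
    "predicted_cell_type",
    "predicted_subcluster",
    "best_corr_m1",
    "best_corr_m2",
    "cutoff_m1",
    "cutoff_m2",
    "decided_by",
)


def write_predictions(
    records: Iterable[PredictionRecord], path: str | Path
) -> None:
    """Write prediction records as a TSV, sorted by query cluster id."""
    records = list(records)
    ids = [r.query_cluster for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvariantError(f"duplicate query clusters in records: {dupes}")
    rows = [
        {
            "query_cluster": r.query_cluster,
            "status": r.status,
            "predicted_cell_type": r.cell_type,
            "predicted_subcluster": r.sub_cluster,
            "best_corr_m1": r.best_corr_module1,
            "best_corr_m2": r.best_corr_module2,
            "cutoff_m1": r.cutoff_module1,
            "cutoff_m2": r.cutoff_module2,
            "decided_by": r.decided_by,
        }
        for r in sorted(records, key=lambda r: r.query_cluster)
    ]
    frame = pd.DataFrame(rows, columns=list(_PREDICTION_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV with header ``human<TAB>mouse``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in frame.columns]
    if cols[:2] != ["human", "mouse"]:
        raise FormatError(
            f"ortholog map {path} must have columns 'human' and 'mouse'"
        )
    frame = frame.dropna()
    return OrthologMap(
        pairs=[
            (str(h), str(m))
            for h, m in zip(frame.iloc[:, 0], frame.iloc[:, 1])
        ]
    )
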