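"""The three-stage cluster-to-cluster annotation algorithm.

Stage 1 (screen): correlations between query clusters and the background
clusters (on bg-markers) set an adaptive cutoff; query clusters whose best
correlation with the corrected reference cell types (Er) stays below it are
finalized as unassigned.

Stage 2 (assign): correlations between query clusters and reference
sub-clusters (on main-markers) get their own mixture-derived cutoff.  No
sub-cluster above it — unassigned; exactly one above it, or several that
all belong to one main type — assigned; several above it from different
main types — the top three go to stage 3.

Stage 3 (resolve): for each candidate pair, a one-sided Wilcoxon rank-sum
test asks whether one candidate's sub-markers are expressed higher than the
other's in the query cluster; the candidate with the largest summed
-log10(p) over its own tests wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .io_model import (
    ClusterProfile,
    CutoffResult,
    InsufficientOverlapError,
    MarkerSet,
    PredictionRecord,
    ReferenceBundle,
    Species,
    OrthologMap,
    FormatError,
    UNASSIGNED,
)
from .mixture_cutoff import (
    DEFAULT_CLAMP_HI,
    DEFAULT_CLAMP_LO,
    estimate_cutoff,
)
from .preprocess import map_orthologs

logger = logging.getLogger("clustannot")

#: Minimum shared marker genes for a correlation screen.
MIN_SHARED_MARKERS = 30
#: Minimum usable sub-markers for a candidate to enter the rank test.
MIN_SUB_MARKERS = 5
#: Candidates carried into stage 3.
MAX_CANDIDATES = 3
#: Group size at or below which the rank-sum p-value is computed exactly.
EXACT_RANKSUM_MAX_N = 10


@dataclass
class AnnotateParams:
    clamp_lo: float = DEFAULT_CLAMP_LO
    clamp_hi: float = DEFAULT_CLAMP_HI
    min_shared_markers: int = MIN_SHARED_MARKERS

    def __post_init__(self) -> None:
        if self.clamp_lo > self.clamp_hi:
            raise FormatError("clamp_lo must not exceed clamp_hi")


@dataclass
class CandidateSet:
    """Top sub-cluster candidates for one query cluster (stage 3 input)."""

    query_cluster: str
    candidates: list[tuple[str, float]]  # (sub_cluster, correlation), desc

    def __post_init__(self) -> None:
        if len(self.candidates) > MAX_CANDIDATES:
            raise FormatError("at most three candidates allowed")
        corrs = [c for _, c in self.candidates]
        if any(a < b for a, b in zip(corrs, corrs[1:])):
            raise FormatError("candidates must be sorted by correlation")


def correlation_matrix(
    a: ClusterProfile,
    b: ClusterProfile,
    marker_genes: list[str],
    min_shared: int = MIN_SHARED_MARKERS,
) -> np.ndarray:
    """Pearson correlations between all cluster pairs of two profiles,
    restricted to the shared marker genes.

    Returns an (a-clusters × b-clusters) array.  Zero-variance vectors give
    a correlation of 0 (with a warning) rather than NaN.
    """
    genes_a = set(a.gene_ids)
    genes_b = set(b.gene_ids)
    shared = [g for g in dict.fromkeys(marker_genes) if g in genes_a and g in genes_b]
    if len(shared) < min_shared:
        raise InsufficientOverlapError(
            f"only {len(shared)} marker genes shared between profiles "
            f"(need >= {min_shared}); check species and reference choice"
        )
    va = a.subset_genes(shared).values  # genes x a-clusters
    vb = b.subset_genes(shared).values
    va_c = va - va.mean(axis=0)
    vb_c = vb - vb.mean(axis=0)
    sa = np.sqrt((va_c**2).sum(axis=0))
    sb = np.sqrt((vb_c**2).sum(axis=0))
    zero_a = sa == 0
    zero_b = sb == 0
    if zero_a.any() or zero_b.any():
        logger.warning(
            "zero-variance expression vectors in correlation "
            "(%d query, %d reference); their correlations set to 0",
            int(zero_a.sum()),
            int(zero_b.sum()),
        )
    sa[zero_a] = 1.0
    sb[zero_b] = 1.0
    corr = (va_c / sa).T @ (vb_c / sb)
    corr[zero_a, :] = 0.0
    corr[:, zero_b] = 0.0
    return np.clip(corr, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------


@dataclass
class Module1Result:
    cutoff: CutoffResult
    best_corr: dict[str, float]  # query cluster -> max corr vs Er
    passed: dict[str, bool]


def module1_screen(
    eq: ClusterProfile,
    bundle: ReferenceBundle,
    params: AnnotateParams | None = None,
) -> Module1Result:
    """Background-calibrated screen of the query clusters.

    The cutoff comes from the pooled query-vs-background correlations on
    bg-markers; a query cluster passes when its best correlation with any
    corrected reference cell type reaches it.
    """
    params = params or AnnotateParams()
    bg_genes = bundle.markers_bg.all_genes()
    pooled = correlation_matrix(
        eq, bundle.background, bg_genes, params.min_shared_markers
    )
    cutoff, _ = estimate_cutoff(
        pooled.ravel(), params.clamp_lo, params.clamp_hi
    )
    corr_er = correlation_matrix(
        eq, bundle.er, bg_genes, params.min_shared_markers
    )
    best = {
        q: float(corr_er[i].max()) for i, q in enumerate(eq.cluster_ids)
    }
    passed = {q: best[q] >= cutoff.cutoff for q in eq.cluster_ids}
    return Module1Result(cutoff=cutoff, best_corr=best, passed=passed)


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------


@dataclass
class Module2Result:
    cutoff: CutoffResult
    best_corr: dict[str, float]
    best_sub: dict[str, str]
    assigned: dict[str, str]  # query -> winning sub-cluster
    unassigned: list[str]
    needs_resolution: dict[str, CandidateSet]


def module2_assign(
    eq: ClusterProfile,
    bundle: ReferenceBundle,
    passing: list[str],
    params: AnnotateParams | None = None,
) -> Module2Result:
    """Sub-cluster assignment with a second mixture-derived cutoff.

    The cutoff is estimated from the pooled query-vs-sub-cluster
    correlations (on main-markers) of all query clusters; dispositions are
    computed for the clusters that passed stage 1.
    """
    params = params or AnnotateParams()
    main_genes = bundle.markers_main.all_genes()
    corr = correlation_matrix(
        eq, bundle.ersub, main_genes, params.min_shared_markers
    )
    cutoff, _ = estimate_cutoff(
        corr.ravel(), params.clamp_lo, params.clamp_hi
    )
    subs = bundle.ersub.cluster_ids
    best_corr: dict[str, float] = {}
    best_sub: dict[str, str] = {}
    assigned: dict[str, str] = {}
    unassigned: list[str] = []
    needs: dict[str, CandidateSet] = {}
    for i, q in enumerate(eq.cluster_ids):
        row = corr[i]
        # Deterministic ordering: correlation desc, then sub-cluster id.
        order = sorted(range(len(subs)), key=lambda j: (-row[j], subs[j]))
        best_sub[q] = subs[order[0]]
        best_corr[q] = float(row[order[0]])
        if q not in passing:
            continue
        above = [j for j in order if row[j] > cutoff.cutoff]
        if not above:
            unassigned.append(q)
            continue
        main_types = {bundle.sub_to_main[subs[j]] for j in above}
        if len(above) == 1 or len(main_types) == 1:
            assigned[q] = subs[above[0]]
            continue
        top = above[:MAX_CANDIDATES]
        needs[q] = CandidateSet(
            query_cluster=q,
            candidates=[(subs[j], float(row[j])) for j in top],
        )
    return Module2Result(
        cutoff=cutoff,
        best_corr=best_corr,
        best_sub=best_sub,
        assigned=assigned,
        unassigned=unassigned,
        needs_resolution=needs,
    )


# ---------------------------------------------------------------------------
# Stage 3
# ---------------------------------------------------------------------------


def _ranksum_pvalue(greater: np.ndarray, lesser: np.ndarray) -> float:
    """One-sided rank-sum p-value for 'greater' group being larger.

    Exact when both groups are small and tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    n1, n2 = greater.size, lesser.size
    pooled = np.concatenate([greater, lesser])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (n1 <= EXACT_RANKSUM_MAX_N and n2 <= EXACT_RANKSUM_MAX_N and not has_ties)
        else "asymptotic"
    )
    result = mannwhitneyu(
        greater, lesser, alternative="greater", method=method, use_continuity=True
    )
    return float(result.pvalue)


def module3_resolve(
    eq_column: np.ndarray,
    eq_genes: list[str],
    cands: CandidateSet,
    markers_sub: MarkerSet,
) -> tuple[str, list[tuple[str, float]]]:
    """Break a multi-candidate tie with pairwise marker rank tests.

    Each candidate's score is the sum of -log10(p) over its own one-sided
    tests against every other candidate; genes shared by both candidates of
    a pair are excluded from that pair's comparison.  Returns the winning
    sub-cluster and the per-candidate scores (descending).
    """
    if len(cands.candidates) < 2:
        raise FormatError("stage 3 needs at least two candidates")
    gene_ix = {g: i for i, g in enumerate(eq_genes)}
    usable: dict[str, list[str]] = {}
    corr_of = dict(cands.candidates)
    for sub, _ in cands.candidates:
        genes = [g for g in dict.fromkeys(markers_sub.genes_for(sub)) if g in gene_ix]
        if len(genes) < MIN_SUB_MARKERS:
            logger.warning(
                "candidate %r has %d usable sub-markers (<%d); dropped",
                sub,
                len(genes),
                MIN_SUB_MARKERS,
            )
            continue
        usable[sub] = genes
    if len(usable) < 2:
        winner = cands.candidates[0][0]
        logger.warning(
            "fewer than two candidates with usable markers; "
            "falling back to highest correlation (%r)",
            winner,
        )
        return winner, [(winner, float("nan"))]
    scores: dict[str, float] = {}
    for sub_a, genes_a in usable.items():
        total = 0.0
        for sub_b, genes_b in usable.items():
            if sub_b == sub_a:
                continue
            shared = set(genes_a) & set(genes_b)
            ga = [g for g in genes_a if g not in shared]
            gb = [g for g in genes_b if g not in shared]
            if not ga or not gb:
                continue
            va = eq_column[[gene_ix[g] for g in ga]]
            vb = eq_column[[gene_ix[g] for g in gb]]
            p = _ranksum_pvalue(va, vb)
            total += -np.log10(max(p, 1e-300))
        scores[sub_a] = total
    # Highest aggregate significance wins; ties broken by stage-2 correlation.
    ranked = sorted(
        scores.items(), key=lambda kv: (-kv[1], -corr_of[kv[0]], kv[0])
    )
    return ranked[0][0], ranked


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def predict(
    eq: ClusterProfile,
    bundle: ReferenceBundle,
    params: AnnotateParams | None = None,
    ortho: OrthologMap | None = None,
) -> list[PredictionRecord]:
    """Annotate every query cluster against one reference bundle.

    Returns exactly one record per query cluster, sorted by cluster id.
    Deterministic for fixed inputs and parameters.
    """
    params = params or AnnotateParams()
    if (
        eq.species != Species.UNKNOWN
        and bundle.species != Species.UNKNOWN
        and eq.species != bundle.species
    ):
        if ortho is None:
            raise FormatError(
                f"query is {eq.species.value} but reference is "
                f"{bundle.species.value}; supply an ortholog map"
            )
        eq = map_orthologs(eq, ortho, bundle.species)

    m1 = module1_screen(eq, bundle, params)
    passing = [q for q in eq.cluster_ids if m1.passed[q]]
    m2 = module2_assign(eq, bundle, passing, params)

    records: list[PredictionRecord] = []
    for q in eq.cluster_ids:
        common = dict(
            query_cluster=q,
            best_corr_module1=m1.best_corr[q],
            best_corr_module2=m2.best_corr.get(q, float("nan")),
            cutoff_module1=m1.cutoff.cutoff,
            cutoff_module2=m2.cutoff.cutoff,
        )
        if not m1.passed[q]:
            records.append(
                PredictionRecord(
                    status=UNASSIGNED, decided_by="module1", **common
                )
            )
        elif q in m2.unassigned:
            records.append(
                PredictionRecord(
                    status=UNASSIGNED, decided_by="module2", **common
                )
            )
        elif q in m2.assigned:
            sub = m2.assigned[q]
            records.append(
                PredictionRecord(
                    status="assigned",
                    cell_type=bundle.sub_to_main[sub],
                    sub_cluster=sub,
                    decided_by="module2",
                    **common,
                )
            )
        else:
            cands = m2.needs_resolution[q]
            winner, scored = module3_resolve(
                eq.column(q), eq.gene_ids, cands, bundle.markers_sub
            )
            records.append(
                PredictionRecord(
                    status="assigned",
                    cell_type=bundle.sub_to_main[winner],
                    sub_cluster=winner,
                    decided_by="module3",
                    candidate_pvalues=[(s, float(v)) for s, v in scored],
                    **common,
                )
            )
    return sorted(records, key=lambda r: r.query_cluster)
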