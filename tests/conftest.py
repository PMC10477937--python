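import numpy as np
import pytest

from clustannot import (
    ClusterProfile,
    MarkerEntry,
    MarkerRole,
    MarkerSet,
    ReferenceBundle,
    ScenarioSpec,
    Species,
    build_reference,
    make_pair,
)


@pytest.fixture(scope="session")
def small_pair():
    """A small scenario-1 triple shared by builder/annotate tests."""
    spec = ScenarioSpec(
        n_types=3,
        n_genes=1200,
        cells_per_type=40,
        scenario=1,
        seed=11,
    )
    return make_pair(spec)


@pytest.fixture(scope="session")
def small_bundle(small_pair):
    return build_reference(
        small_pair.reference, small_pair.background, species=Species.HUMAN
    )


def _uniform_markers(profile, role):
    """All genes as rank-ordered markers of every cluster (test helper)."""
    entries = []
    for cid in profile.cluster_ids:
        for rank, gene in enumerate(profile.gene_ids, start=1):
            entries.append(MarkerEntry(cid, gene, 1.0, rank))
    return MarkerSet(role=role, entries=entries)


@pytest.fixture()
def toy_bundle():
    """A hand-built two-type bundle with fully controlled expression.

    Types A and B each have two sub-clusters; 40 genes split into two
    20-gene marker halves so correlations are easy to reason about.
    """
    rng = np.random.default_rng(5)
    n_genes = 40
    genes = [f"g{i}" for i in range(n_genes)]
    base = rng.uniform(0.5, 3.0, n_genes)
    a = base.copy()
    a[:20] += 4.0
    b = base.copy()
    b[20:] += 4.0
    er = ClusterProfile(genes, ["A", "B"], np.column_stack([a, b]))
    jitter = rng.normal(0, 0.05, (n_genes, 4))
    ersub = ClusterProfile(
        genes,
        ["A::0", "A::1", "B::0", "B::1"],
        np.clip(np.column_stack([a, a, b, b]) + jitter, 0, None),
    )
    background = ClusterProfile(
        genes,
        ["bg0", "bg1", "bg2"],
        np.clip(
            np.column_stack(
                [a, b, rng.uniform(0.5, 3.0, n_genes)]
            )
            + rng.normal(0, 0.05, (n_genes, 3)),
            0,
            None,
        ),
    )

    def markers(profile, role):
        entries = []
        for cid in profile.cluster_ids:
            top = np.argsort(-profile.values[:, profile.cluster_ids.index(cid)])
            for rank, gi in enumerate(top[:20], start=1):
                entries.append(MarkerEntry(cid, genes[gi], float(20 - rank), rank))
        return MarkerSet(role=role, entries=entries)

    return ReferenceBundle(
        er=er,
        ersub=ersub,
        sub_to_main={"A::0": "A", "A::1": "A", "B::0": "B", "B::1": "B"},
        markers_main=markers(er, MarkerRole.MAIN),
        markers_sub=markers(ersub, MarkerRole.SUB),
        background=background,
        markers_bg=_uniform_markers(background, MarkerRole.BG),
        meta={"name": "toy"},
    )
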