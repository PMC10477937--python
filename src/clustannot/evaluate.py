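"""Benchmark scoring: the six-outcome framework and scenario taxonomy.

Given a truth label per query cluster, each prediction falls in exactly one
of six categories depending on (a) whether a label was assigned, (b)
whether it matches the truth (up to synonyms or a coarse/fine "partial"
pair), and (c) whether the truth cell type exists in the reference at all:

===================  ==========================  =======================
prediction           truth present in reference  truth absent
===================  ==========================  =======================
matches truth        correct                     (cannot occur)
partial match        correct_partial             (cannot occur)
other label          wrong                       wrong_unclassified
unassigned           failed                      correct_unclassified
===================  ==========================  =======================

The first three categories count as successful predictions.

Query/reference benchmark pairs are classified by cell-type overlap:
type 1 equal sets, type 2 query ⊂ reference, type 3 reference ⊂ query,
type 4 disjoint.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_model import FormatError, PredictionRecord, UNASSIGNED


class OutcomeLabel(str, enum.Enum):
    CORRECT = "correct"
    CORRECT_PARTIAL = "correct_partial"
    CORRECT_UNCLASSIFIED = "correct_unclassified"
    FAILED = "failed"
    WRONG = "wrong"
    WRONG_UNCLASSIFIED = "wrong_unclassified"


SUCCESS_OUTCOMES = frozenset(
    {
        OutcomeLabel.CORRECT,
        OutcomeLabel.CORRECT_PARTIAL,
        OutcomeLabel.CORRECT_UNCLASSIFIED,
    }
)


@dataclass
class SynonymTable:
    """Label equivalences and coarse/fine 'partial' relations.

    ``groups`` are sets of labels naming the same cell type (e.g. "BP" and
    "bipolar"); ``partial_pairs`` are (coarse, fine) pairs such as
    ("photoreceptor", "rod") that count as partially correct in either
    direction.
    """

    groups: list[set[str]] = field(default_factory=list)
    partial_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            for label in group:
                if label in seen:
                    raise FormatError(
                        f"label {label!r} appears in two synonym groups"
                    )
                seen.add(label)

    def canonical(self, label: str) -> str:
        for group in self.groups:
            if label in group:
                return min(group)
        return label

    def equivalent(self, a: str, b: str) -> bool:
        return self.canonical(a) == self.canonical(b)

    def partial(self, a: str, b: str) -> bool:
        ca, cb = self.canonical(a), self.canonical(b)
        for coarse, fine in self.partial_pairs:
            cc, cf = self.canonical(coarse), self.canonical(fine)
            if {ca, cb} == {cc, cf}:
                return True
        return False


def read_synonym_table(path: str | Path) -> SynonymTable:
    """TSV with columns canonical, alias and an optional 'partial' flag."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = [c.lower() for c in frame.columns]
    if cols[:2] != ["canonical", "alias"]:
        raise FormatError(
            f"synonym table {path} needs columns 'canonical' and 'alias'"
        )
    groups: dict[str, set[str]] = {}
    partial_pairs: list[tuple[str, str]] = []
    for row in frame.itertuples(index=False):
        canonical, alias = str(row[0]), str(row[1])
        is_partial = len(row) > 2 and str(row[2]).strip().lower() in (
            "1",
            "true",
            "partial",
            "yes",
        )
        if is_partial:
            partial_pairs.append((canonical, alias))
        else:
            groups.setdefault(canonical, {canonical}).add(alias)
    return SynonymTable(
        groups=[g for g in groups.values() if len(g) > 1],
        partial_pairs=partial_pairs,
    )


def classify_outcome(
    truth: str,
    prediction: PredictionRecord,
    ref_types: Iterable[str],
    syn: SynonymTable | None = None,
) -> OutcomeLabel:
    """Place one prediction in the six-outcome taxonomy (total function)."""
    if not truth:
        raise FormatError("truth label must be non-empty")
    syn = syn or SynonymTable()
    truth_canon = syn.canonical(truth)
    ref_canon = {syn.canonical(t) for t in ref_types}
    truth_in_ref = truth_canon in ref_canon
    if prediction.status == UNASSIGNED:
        return (
            OutcomeLabel.FAILED
            if truth_in_ref
            else OutcomeLabel.CORRECT_UNCLASSIFIED
        )
    pred = prediction.cell_type
    if syn.equivalent(pred, truth):
        return OutcomeLabel.CORRECT
    if syn.partial(pred, truth):
        return OutcomeLabel.CORRECT_PARTIAL
    return OutcomeLabel.WRONG if truth_in_ref else OutcomeLabel.WRONG_UNCLASSIFIED


def summarize(outcomes: Sequence[OutcomeLabel]) -> dict[str, float]:
    """Outcome composition fractions plus the overall success rate."""
    if not outcomes:
        raise FormatError("no outcomes to summarize")
    counts = Counter(outcomes)
    n = len(outcomes)
    summary = {label.value: counts.get(label, 0) / n for label in OutcomeLabel}
    summary["success"] = (
        sum(counts.get(label, 0) for label in SUCCESS_OUTCOMES) / n
    )
    return summary


def make_scenario_pairs(
    types_query: Iterable[str], types_ref: Iterable[str]
) -> int:
    """Scenario type by cell-type overlap: 1 equal, 2 query-subset,
    3 reference-subset, 4 disjoint.  Partial non-nested overlap errors."""
    q, r = set(types_query), set(types_ref)
    if not q or not r:
        raise FormatError("both type sets must be non-empty")
    if q == r:
        return 1
    if q < r:
        return 2
    if r < q:
        return 3
    if not (q & r):
        return 4
    raise FormatError(
        "query and reference cell types overlap without nesting; "
        "construct nested scenarios (equal / subset / superset / disjoint)"
    )


def evaluate_predictions(
    records: Sequence[PredictionRecord],
    truth: Mapping[str, str],
    ref_types: Iterable[str],
    syn: SynonymTable | None = None,
) -> tuple[dict[str, OutcomeLabel], dict[str, float]]:
    """Score a batch of predictions; returns per-cluster outcomes + summary."""
    ref_types = list(ref_types)
    outcomes = {
        r.query_cluster: classify_outcome(
            truth[r.query_cluster], r, ref_types, syn
        )
        for r in records
    }
    return outcomes, summarize(list(outcomes.values()))
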