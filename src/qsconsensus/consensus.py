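"""Majority-vote consensus over per-method annotations and benchmarking.

Each benchmark entry carries a curated reference annotation, the archive's
deposited annotation, and one :class:`~qsconsensus.annotations.QSAnnotation`
per method (SC = sequence clustering, TM = text mining, PISA, EPPIC).  The
consensus rules:

* not-available results (cluster too small, no article, no PISA assembly)
  are excluded from the vote entirely;
* inconclusive results abstain — by default they are also excluded from the
  majority denominator;
* stoichiometry and symmetry are voted separately.  A component's winner
  needs a strict majority (> half) of the votes cast for that component.
  TM votes on stoichiometry only, by oligomer order: its vote supports any
  candidate formula with the same total subunit count.  No strict majority
  means the component is inconclusive; an empty vote set means the consensus
  is not available.

Outcomes against the reference: both compared components match -> correct;
both mismatch -> incorrect; one of stoichiometry/symmetry right and the
other wrong -> inconclusive (mirroring how the benchmark scores a
half-right prediction); a not-available or inconclusive prediction keeps its
status as the outcome.

The module also provides the benchmark summary (outcome percentages per
method and for the consensus), the agreement analysis (which exact subset of
methods shares an outcome on each entry), and outlier flagging (entries
whose deposited archive annotation contradicts a conclusive consensus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import (
    Component,
    MatchResult,
    QSAnnotation,
    Source,
    Status,
    Stoichiometry,
    canonicalize_stoichiometry,
    match_annotations,
    parse_stoichiometry,
    parse_symmetry,
)

__all__ = [
    "METHODS",
    "BenchmarkEntry",
    "OutcomeRecord",
    "collect_votes",
    "consensus_predict",
    "classify_outcome",
    "benchmark_summary",
    "agreement_analysis",
    "flag_outliers",
    "read_wide_table",
    "write_wide_table",
]

METHODS = ("SC", "TM", "PISA", "EPPIC")

OUTCOMES = ("correct", "incorrect", "inconclusive", "not_available")


@dataclass
class BenchmarkEntry:
    """One PDB-like entry with reference, archive, and per-method annotations."""

    pdb_id: str
    reference: QSAnnotation
    method_results: dict[str, QSAnnotation]
    pdb_annotation: QSAnnotation | None = None

    def __post_init__(self) -> None:
        if not self.pdb_id:
            raise ValueError("empty pdb_id")
        unknown = set(self.method_results) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


@dataclass(frozen=True)
class OutcomeRecord:
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"invalid outcome {self.outcome!r}")


def collect_votes(
    entry: BenchmarkEntry,
    methods: Sequence[str] = METHODS,
    count_abstentions: bool = False,
) -> list[QSAnnotation]:
    """Voting annotations for one entry.

    Not-available results are always dropped.  Inconclusive results abstain;
    by default they are excluded entirely, with ``count_abstentions`` they
    are retained (enlarging the majority denominator without supporting any
    candidate).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    votes = []
    for method in methods:
        ann = entry.method_results.get(method)
        if ann is None or ann.status is Status.NOT_AVAILABLE:
            continue
        if ann.status is Status.INCONCLUSIVE and not count_abstentions:
            continue
        votes.append(ann)
    return votes


def _vote_stoichiometry(votes: Sequence[QSAnnotation]) -> tuple[Stoichiometry | None, bool]:
    """Strict-majority stoichiometry; returns (winner, order_only flag).

    Candidates are the canonical formulas of full votes; an order-only vote
    supports every candidate with the same total.  If only order-only votes
    exist, the candidate is the bare A<n> order.  Shared order-only support
    can lift two distinct candidates past half; that counts as a tie.
    """
    full = [v for v in votes if v.stoichiometry is not None and not v.order_only]
    order_only = [v for v in votes if v.stoichiometry is not None and v.order_only]
    n_votes = len(full) + len(order_only)
    if n_votes == 0:
        return None, False

    support: dict[Stoichiometry, int] = {}
    for v in full:
        key = canonicalize_stoichiometry(v.stoichiometry)  # type: ignore[arg-type]
        support[key] = support.get(key, 0) + 1
    totals_supported = {key.total_subunits for key in support}
    for v in order_only:
        order = v.stoichiometry.total_subunits  # type: ignore[union-attr]
        if order in totals_supported:
            for key in support:
                if key.total_subunits == order:
                    support[key] += 1
        else:
            key = Stoichiometry({"A": order})
            support[key] = support.get(key, 0) + 1
            totals_supported.add(order)

    winners = [key for key, s in support.items() if 2 * s > n_votes]
    if len(winners) != 1:
        return None, False
    winner = winners[0]
    winner_full_support = any(
        canonicalize_stoichiometry(v.stoichiometry) == winner for v in full  # type: ignore[arg-type]
    )
    return winner, not winner_full_support


def consensus_predict(votes: Sequence[QSAnnotation]) -> QSAnnotation:
    """Majority-vote consensus annotation from collected votes.

    Stoichiometry and symmetry are decided independently, each by strict
    majority of the votes that carry that component.  An empty vote set is
    not available; votes with no decided component yield an inconclusive
    consensus.  Invariant under vote order.
    """
    if not votes:
        return QSAnnotation.not_available(Source.CONSENSUS)
    votes = [v for v in votes if v.is_prediction]
    if not votes:
        return QSAnnotation.inconclusive(Source.CONSENSUS)

    stoich, order_only = _vote_stoichiometry(votes)

    sym_votes = [v.symmetry for v in votes if v.symmetry is not None]
    sym = None
    if sym_votes:
        counts: dict = {}
        for s in sym_votes:
            counts[s] = counts.get(s, 0) + 1
        top, top_count = max(counts.items(), key=lambda kv: kv[1])
        if 2 * top_count > len(sym_votes):
            sym = top

    if stoich is None and sym is None:
        return QSAnnotation.inconclusive(Source.CONSENSUS)
    return QSAnnotation(
        stoichiometry=stoich,
        symmetry=sym,
        source=Source.CONSENSUS,
        order_only=order_only,
    )


def classify_outcome(prediction: QSAnnotation, reference: QSAnnotation) -> OutcomeRecord:
    """Score a prediction against the curated reference.

    All compared components match -> correct; all mismatch -> incorrect; a
    half-right prediction (stoichiometry right, symmetry wrong, or vice
    versa) -> inconclusive.  Non-predictions keep their own status.
    """
    if reference.stoichiometry is None:
        raise ValueError("reference annotation must carry stoichiometry")
    if prediction.status is Status.NOT_AVAILABLE:
        return OutcomeRecord("not_available")
    if prediction.status is Status.INCONCLUSIVE:
        return OutcomeRecord("inconclusive")
    result = match_annotations(prediction, reference)
    compared = result.compared
    if not compared:
        return OutcomeRecord("inconclusive")
    if all(v is Component.MATCH for v in compared):
        return OutcomeRecord("correct")
    if all(v is Component.MISMATCH for v in compared):
        return OutcomeRecord("incorrect")
    return OutcomeRecord("inconclusive")


def _consensus_for_entry(
    entry: BenchmarkEntry,
    methods: Sequence[str],
    count_abstentions: bool = False,
) -> QSAnnotation:
    return consensus_predict(collect_votes(entry, methods, count_abstentions))


def benchmark_summary(
    entries: Sequence[BenchmarkEntry],
    methods: Sequence[str] = METHODS,
) -> pd.DataFrame:
    """Outcome percentages per method and for the consensus.

    Rows are the requested methods plus ``CONSENSUS``; columns are percent
    correct / incorrect / inconclusive / not_available over all entries, so
    every row sums to 100 within rounding.
    """
    if not entries:
        raise ValueError("empty benchmark")
    n = len(entries)
    counts = {m: {o: 0 for o in OUTCOMES} for m in [*methods, "CONSENSUS"]}
    for entry in entries:
        for method in methods:
            ann = entry.method_results.get(method)
            if ann is None:
                ann = QSAnnotation.not_available(method)
            outcome = classify_outcome(ann, entry.reference).outcome
            counts[method][outcome] += 1
        consensus = _consensus_for_entry(entry, methods)
        counts["CONSENSUS"][classify_outcome(consensus, entry.reference).outcome] += 1
    frame = pd.DataFrame(
        {
            row: {f"pct_{o}": 100.0 * c[o] / n for o in OUTCOMES}
            for row, c in counts.items()
        }
    ).T
    frame.index.name = "method"
    return frame


def agreement_analysis(
    entries: Sequence[BenchmarkEntry],
    methods: Sequence[str] = METHODS,
) -> dict[str, dict[frozenset, int]]:
    """Per-category counts of the exact method subsets sharing an outcome.

    For each outcome category, each entry is attributed to the exact subset
    of methods with that outcome on that entry (entries where no method has
    the outcome are not counted), so within a category the subset counts are
    disjoint and sum to the number of entries with at least one such method.
    """
    table: dict[str, dict[frozenset, int]] = {o: {} for o in OUTCOMES}
    for entry in entries:
        outcome_of = {}
        for method in methods:
            ann = entry.method_results.get(method)
            if ann is None:
                ann = QSAnnotation.not_available(method)
            outcome_of[method] = classify_outcome(ann, entry.reference).outcome
        for category in OUTCOMES:
            subset = frozenset(m for m in methods if outcome_of[m] == category)
            if subset:
                table[category][subset] = table[category].get(subset, 0) + 1
    return table


def flag_outliers(
    entries: Sequence[BenchmarkEntry],
    methods: Sequence[str] = METHODS,
) -> tuple[dict[str, bool], float]:
    """Entries whose archive annotation contradicts a conclusive consensus.

    An entry is an outlier iff the consensus is an actual prediction and
    disagrees with the deposited archive annotation on every compared
    component.  The fraction's denominator is the number of entries with a
    conclusive consensus (an inconclusive consensus is no evidence of error).
    """
    flags: dict[str, bool] = {}
    n_conclusive = 0
    n_outliers = 0
    for entry in entries:
        if entry.pdb_annotation is None:
            raise ValueError(f"{entry.pdb_id}: no archive annotation to compare")
        consensus = _consensus_for_entry(entry, methods)
        if not consensus.is_prediction:
            flags[entry.pdb_id] = False
            continue
        n_conclusive += 1
        result = match_annotations(consensus, entry.pdb_annotation)
        compared = result.compared
        is_outlier = bool(compared) and all(v is Component.MISMATCH for v in compared)
        flags[entry.pdb_id] = is_outlier
        n_outliers += int(is_outlier)
    fraction = n_outliers / n_conclusive if n_conclusive else 0.0
    return flags, fraction


# ---------------------------------------------------------------------------
# Wide-table (per-entry, one row) serialization

def _format_ann(ann: QSAnnotation | None) -> tuple[str, str, str]:
    if ann is None:
        return "", "", Status.NOT_AVAILABLE.value
    return (
        str(ann.stoichiometry) if ann.stoichiometry else "",
        str(ann.symmetry) if ann.symmetry else "",
        ann.status.value,
    )


def write_wide_table(entries: Sequence[BenchmarkEntry]) -> pd.DataFrame:
    """Serialize entries to the wide benchmark-table layout: one row per
    entry, with reference / archive columns and per-method
    ``{m}_stoich, {m}_sym, {m}_status`` triples."""
    rows = []
    for e in entries:
        row: dict[str, str] = {"pdb_id": e.pdb_id}
        row["ref_stoich"], row["ref_sym"], _ = _format_ann(e.reference)
        row["pdb_stoich"], row["pdb_sym"], _ = _format_ann(e.pdb_annotation)
        for m in METHODS:
            s, y, st = _format_ann(e.method_results.get(m))
            row[f"{m.lower()}_stoich"] = s
            row[f"{m.lower()}_sym"] = y
            row[f"{m.lower()}_status"] = st
        rows.append(row)
    return pd.DataFrame(rows)


def read_wide_table(frame: pd.DataFrame) -> list[BenchmarkEntry]:
    """Parse the wide benchmark-table layout back into entries."""
    frame = frame.fillna("")
    entries = []
    for row in frame.to_dict("records"):
        def ann_of(prefix: str, source: Source) -> QSAnnotation | None:
            stoich_text = str(row.get(f"{prefix}_stoich", "") or "")
            sym_text = str(row.get(f"{prefix}_sym", "") or "")
            status_text = str(row.get(f"{prefix}_status", "") or "")
            stoich = parse_stoichiometry(stoich_text) if stoich_text else None
            sym = parse_symmetry(sym_text) if sym_text else None
            if status_text in ("", Status.PREDICTED.value):
                if stoich is None and sym is None:
                    return None
                status = Status.PREDICTED
            else:
                status = Status(status_text)
            order_only = source is Source.TM and stoich is not None
            return QSAnnotation(
                stoichiometry=stoich,
                symmetry=sym,
                source=source,
                status=status,
                order_only=order_only,
            )

        reference = ann_of("ref", Source.PDB)
        if reference is None:
            raise ValueError(f"{row.get('pdb_id')}: missing reference annotation")
        methods = {}
        for m in METHODS:
            ann = ann_of(m.lower(), Source(m))
            if ann is not None:
                methods[m] = ann
        entries.append(
            BenchmarkEntry(
                pdb_id=str(row["pdb_id"]),
                reference=reference,
                method_results=methods,
                pdb_annotation=ann_of("pdb", Source.PDB),
            )
        )
    return entries
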