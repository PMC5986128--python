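"""Synthetic test-input generators with planted ground truth.

Every input kind the package consumes can be generated here with a known
expected result, so the whole pipeline is testable offline:

* annotated sequence clusters (FASTA + annotation TSV) whose representative
  state under the consistency-score rule is computed at generation time;
* labeled sentence corpora emulating the positive/negative construction used
  to train the relevance classifier (positives pair an oligomer keyword with
  an experimental-evidence phrase; negatives mention oligomers in
  asymmetric-unit / crystal-packing contexts);
* PISA-dialect assembly XML with analytically generated point-group operator
  sets, and EPPIC-dialect prediction XML;
* wide benchmark tables with per-method outcomes sampled at planted rates
  and the expected consensus outcome of every entry computed by an
  independent tally written into the generator itself.

Every generator is deterministic: the same spec (including seed) yields
byte-identical output.  The generators' own bookkeeping — not the modules
they exercise — produces the expected values, so downstream tests are
self-verifying.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    QSAnnotation,
    Source,
    Status,
    Stoichiometry,
    Symmetry,
    parse_stoichiometry,
    parse_symmetry,
)
from .pointgroup import RigidOperator

__all__ = [
    "ClusterSpec",
    "CorpusSpec",
    "BenchmarkSpec",
    "FixtureSpec",
    "make_cluster_fixture",
    "make_corpus",
    "group_operators",
    "make_assembly_xml",
    "make_eppic_xml",
    "make_benchmark_table",
    "DEFAULT_METHOD_RATES",
    "STATE_CATALOG",
    "SOURCE_BENCHMARKS",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Catalogue of (stoichiometry, symmetry) states the benchmark generator
#: samples from — the common oligomeric states of globular proteins.
STATE_CATALOG: tuple[tuple[str, str], ...] = (
    ("A", "C1"),
    ("A2", "C2"),
    ("A3", "C3"),
    ("A4", "D2"),
    ("A6", "D3"),
    ("A2B2", "C2"),
    ("A4B4", "D4"),
    ("A12", "T"),
)

#: Per-class compositions of the three published source benchmarks and of
#: their deduplicated union (oligomer order -> number of entries), together
#: with the pairwise overlaps.  These enter the package as reference inputs
#: for sanity arithmetic on the combined benchmark.
SOURCE_BENCHMARKS: dict[str, dict[int, int]] = {
    # 218 complexes: monomers, dimers, trimers, tetramers, hexamers
    "ponstingl": {1: 55, 2: 88, 3: 24, 4: 38, 6: 13},
    # 266 entries: monomers and dimers
    "bahadur": {1: 144, 2: 122},
    # 152 structures incl. one dodecamer
    "duarte": {1: 78, 2: 62, 3: 2, 4: 8, 6: 1, 12: 1},
    # deduplicated union of the three
    "combined": {1: 248, 2: 209, 3: 26, 4: 44, 6: 14, 8: 1, 12: 1},
}
SOURCE_OVERLAPS: dict[tuple[str, str], int] = {
    ("ponstingl", "bahadur"): 89,
    ("bahadur", "duarte"): 2,
    ("ponstingl", "duarte"): 1,
}

#: Default per-method outcome rates for the benchmark generator: the
#: conditions the generator emulates.  Individual-method accuracies span the
#: reported 46-81% range; not-available outcomes occur only for sequence
#: clustering (cluster below minimum size) and text mining (no article);
#: PISA carries the largest inconclusive share among the computational
#: methods (gray-region calls) and text mining is the most abstention-heavy
#: method overall.  See docs/methods.md.
DEFAULT_METHOD_RATES: dict[str, dict[str, float]] = {
    "SC": {"correct": 0.62, "incorrect": 0.04, "inconclusive": 0.26, "not_available": 0.08},
    "TM": {"correct": 0.46, "incorrect": 0.07, "inconclusive": 0.27, "not_available": 0.20},
    "PISA": {"correct": 0.75, "incorrect": 0.17, "inconclusive": 0.08, "not_available": 0.0},
    "EPPIC": {"correct": 0.81, "incorrect": 0.13, "inconclusive": 0.06, "not_available": 0.0},
}


# ---------------------------------------------------------------------------
# sequence clusters


@dataclass
class ClusterSpec:
    """One synthetic cluster: ``size`` members, ``n_noise`` of which carry an
    off-modal annotation."""

    size: int
    modal_stoich: str = "A2"
    modal_sym: str = "C2"
    n_noise: int = 0
    noise_stoich: str = "A4"
    noise_sym: str = "D2"
    length: int = 120
    mutations_per_member: int = 10

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not 0 <= self.n_noise <= self.size:
            raise ValueError("noise count outside [0, size]")
        if self.n_noise > self.size - self.n_noise:
            raise ValueError(
                "noise members outnumber modal members: expected outcome ambiguous"
            )


def _mutate(rng: np.random.Generator, base: str, n_mut: int) -> str:
    positions = rng.choice(len(base), size=n_mut, replace=False)
    seq = list(base)
    for p in positions:
        current = seq[p]
        choices = [a for a in _AA20 if a != current]
        seq[p] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def _expected_representative(
    spec: ClusterSpec, threshold_k: int, min_size: int
) -> QSAnnotation:
    # independent arithmetic: marginals are modal/noise frequencies, the
    # consistency score their product, accepted only above 0.5
    if spec.size < min_size:
        return QSAnnotation.not_available(Source.SC)
    n_modal = spec.size - spec.n_noise
    p_modal = n_modal / spec.size
    p_noise = spec.n_noise / spec.size
    best = max(p_modal * p_modal, p_noise * p_noise)
    if best <= 0.5:
        return QSAnnotation.inconclusive(Source.SC)
    if p_modal * p_modal >= p_noise * p_noise:
        return QSAnnotation(
            stoichiometry=parse_stoichiometry(spec.modal_stoich),
            symmetry=parse_symmetry(spec.modal_sym),
            source=Source.SC,
        )
    return QSAnnotation(
        stoichiometry=parse_stoichiometry(spec.noise_stoich),
        symmetry=parse_symmetry(spec.noise_sym),
        source=Source.SC,
    )


def make_cluster_fixture(
    clusters: Sequence[ClusterSpec],
    seed: int = 0,
    threshold_k: int = 70,
    min_size: int = 3,
) -> tuple[str, str, list[QSAnnotation]]:
    """FASTA + annotation TSV for synthetic clusters, with expected results.

    Members of one cluster are point-substitution mutants of a shared base
    sequence (no indels, so pairwise identity is analytically bounded below
    by ``1 - 2*mutations/length``, kept above the threshold); members of
    different clusters are unrelated random sequences.  Returns
    ``(fasta_text, annotation_tsv, expected)`` where ``expected[i]`` is the
    representative annotation of cluster ``i`` under the consistency-score
    rule, computed by the generator's own arithmetic.
    """
    rng = np.random.default_rng(seed)
    fasta_lines: list[str] = []
    tsv_lines: list[str] = ["id\tstoichiometry\tsymmetry"]
    expected: list[QSAnnotation] = []
    for ci, spec in enumerate(clusters):
        if 2 * spec.mutations_per_member / spec.length > 1 - threshold_k / 100:
            raise ValueError("mutation load would push members below the threshold")
        base = "".join(_AA20[int(i)] for i in rng.integers(0, 20, size=spec.length))
        for mi in range(spec.size):
            seq = _mutate(rng, base, spec.mutations_per_member) if mi else base
            member_id = f"c{ci}m{mi}"
            fasta_lines.append(f">{member_id}")
            fasta_lines.append(seq)
            if mi < spec.size - spec.n_noise:
                tsv_lines.append(f"{member_id}\t{spec.modal_stoich}\t{spec.modal_sym}")
            else:
                tsv_lines.append(f"{member_id}\t{spec.noise_stoich}\t{spec.noise_sym}")
        expected.append(_expected_representative(spec, threshold_k, min_size))
    return "\n".join(fasta_lines) + "\n", "\n".join(tsv_lines) + "\n", expected


# ---------------------------------------------------------------------------
# sentence corpora


@dataclass
class CorpusSpec:
    """Labeled sentence corpus with controllable class separability.

    ``vocab_overlap`` is the fraction of filler words drawn from a pool
    shared between classes (0 = disjoint vocabularies, separable corpus;
    1 = fully shared fillers, separable only through the template words).
    ``evidence_rate`` is the fraction of positive sentences that carry an
    experimental-evidence phrase.
    """

    n_pos: int = 200
    n_neg: int = 200
    vocab_size: int = 60
    vocab_overlap: float = 0.0
    evidence_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.vocab_overlap <= 1) or not (0 <= self.evidence_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sentence counts must be >= 0")


_OLIGO_WORDS = ("monomer", "dimer", "trimer", "tetramer", "hexamer")
_EVIDENCE_PHRASES = (
    "size exclusion chromatography",
    "gel filtration",
    "analytical ultracentrifugation",
    "light scattering",
    "native PAGE",
)


def make_corpus(spec: CorpusSpec, seed: int = 0) -> str:
    """TSV corpus (label <tab> sentence) with planted class structure.

    Positive sentences state an oligomeric state in solution and (at
    ``evidence_rate``) cite an experimental method; negatives mention the
    same oligomer keywords in asymmetric-unit or crystal-packing contexts.
    Deterministic for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    pos_vocab = [f"p{i}x" for i in range(spec.vocab_size)]
    neg_vocab = [f"n{i}x" for i in range(spec.vocab_size)]
    shared_vocab = [f"s{i}x" for i in range(spec.vocab_size)]

    def fillers(own: list[str], k: int = 3) -> str:
        words = []
        for _ in range(k):
            pool = shared_vocab if rng.random() < spec.vocab_overlap else own
            words.append(pool[int(rng.integers(len(pool)))])
        return " ".join(words)

    lines = []
    for _ in range(spec.n_pos):
        oligo = _OLIGO_WORDS[int(rng.integers(len(_OLIGO_WORDS)))]
        evidence = (
            f" as shown by {_EVIDENCE_PHRASES[int(rng.integers(len(_EVIDENCE_PHRASES)))]}"
            if rng.random() < spec.evidence_rate
            else ""
        )
        sentence = (
            f"The {fillers(pos_vocab)} protein forms a stable {oligo} in solution"
            f"{evidence}."
        )
        lines.append(f"positive\t{sentence}")
    for _ in range(spec.n_neg):
        oligo = _OLIGO_WORDS[int(rng.integers(len(_OLIGO_WORDS)))]
        sentence = (
            f"The asymmetric unit {fillers(neg_vocab)} contains a {oligo} arrangement"
            f" formed by crystal packing contacts."
        )
        lines.append(f"negative\t{sentence}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# assembly XML (PISA and EPPIC dialects)


def _closure(generators: list[np.ndarray], max_order: int = 60) -> list[np.ndarray]:
    elements = [np.eye(3)]

    def known(M: np.ndarray) -> bool:
        return any(np.allclose(M, E, atol=1e-9) for E in elements)

    frontier = [g for g in generators if not known(g)]
    elements.extend(frontier)
    while frontier:
        new: list[np.ndarray] = []
        for A in frontier:
            for B in elements[:]:
                for M in (A @ B, B @ A):
                    if not known(M):
                        elements.append(M)
                        new.append(M)
        frontier = new
        if len(elements) > max_order:
            raise ValueError("generator closure exceeds the supported group order")
    return elements


def _rot(axis: Sequence[float], angle: float) -> np.ndarray:
    return RigidOperator.from_axis_angle(axis, angle).rotation


def group_operators(
    group: Symmetry | str, center: Sequence[float] | None = None
) -> list[RigidOperator]:
    """The full rotation set of C_n, D_n, T or O about ``center``.

    Elements are generated analytically (closure of the standard generators)
    and returned as rigid operators whose axes pass through ``center``.
    """
    sym = parse_symmetry(group) if isinstance(group, str) else group
    z = (0.0, 0.0, 1.0)
    if sym.family.value == "C":
        mats = [_rot(z, 2 * np.pi * k / sym.order) for k in range(sym.order)]
    elif sym.family.value == "D":
        n = sym.order
        mats = [_rot(z, 2 * np.pi * k / n) for k in range(n)]
        mats += [
            _rot((np.cos(np.pi * k / n), np.sin(np.pi * k / n), 0.0), np.pi)
            for k in range(n)
        ]
    elif sym.family.value == "T":
        mats = _closure([_rot((1, 1, 1), 2 * np.pi / 3), _rot(z, np.pi)])
    elif sym.family.value == "O":
        mats = _closure([_rot((1, 1, 1), 2 * np.pi / 3), _rot(z, np.pi / 2)])
    else:
        raise ValueError(f"unsupported group {sym} for operator generation")
    ops = []
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    for R in mats:
        ops.append(RigidOperator(R, c - R @ c))
    return ops


def make_assembly_xml(
    stoichiometry: str,
    point_group: str,
    dg: float,
    asa: float = 12000.0,
    bsa: float = 3400.0,
    assembly_id: int = 1,
    center: Sequence[float] = (10.0, -5.0, 3.0),
    precision: int = 6,
) -> str:
    """PISA-dialect assembly XML for one candidate with exact symmetry.

    The requested stoichiometry's total subunit count must equal the group
    order; chains are labeled entity-wise (A, A, B, B, ... for A2B2) and get
    the group's operators in a fixed order.  Round-tripping through the PISA
    adapter recovers (stoichiometry, point group, dg).
    """
    stoich = parse_stoichiometry(stoichiometry)
    sym = parse_symmetry(point_group)
    ops = group_operators(sym, center)
    if stoich.total_subunits != len(ops):
        raise ValueError(
            f"stoichiometry {stoich} has {stoich.total_subunits} subunits but "
            f"{sym} has group order {len(ops)}"
        )
    entities = []
    for letter, count in sorted(stoich.composition.items()):
        entities.extend([letter] * count)

    fmt = f"{{:.{precision}f}}"
    lines = ["<pisa_assemblies>", "  <assembly>", f"    <id>{assembly_id}</id>"]
    lines.append(f"    <diss_energy>{fmt.format(dg)}</diss_energy>")
    lines.append(f"    <asa>{fmt.format(asa)}</asa>")
    lines.append(f"    <bsa>{fmt.format(bsa)}</bsa>")
    keys = ("rxx", "rxy", "rxz", "ryx", "ryy", "ryz", "rzx", "rzy", "rzz")
    for chain_idx, (entity, op) in enumerate(zip(entities, ops)):
        lines.append("    <molecule>")
        lines.append(f"      <chain_id>{chr(ord('a') + chain_idx)}</chain_id>")
        lines.append(f"      <entity>{entity}</entity>")
        flat = op.rotation.ravel()
        for key, value in zip(keys, flat):
            lines.append(f"      <{key}>{fmt.format(value)}</{key}>")
        for key, value in zip(("tx", "ty", "tz"), op.translation):
            lines.append(f"      <{key}>{fmt.format(value)}</{key}>")
        lines.append("    </molecule>")
    lines.append("  </assembly>")
    lines.append("</pisa_assemblies>")
    return "\n".join(lines) + "\n"


def make_eppic_xml(
    stoichiometry: str | None,
    symmetry: str | None,
    pdb_id: str = "1abc",
) -> str:
    """EPPIC-dialect prediction XML (either field may be omitted)."""
    lines = ["<eppicAnalysis>", f"  <pdbCode>{pdb_id}</pdbCode>", "  <assembly>"]
    if stoichiometry:
        lines.append(f"    <stoichiometry>{stoichiometry}</stoichiometry>")
    if symmetry:
        lines.append(f"    <symmetry>{symmetry}</symmetry>")
    lines.append("  </assembly>")
    lines.append("</eppicAnalysis>")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# benchmark tables


@dataclass
class BenchmarkSpec:
    """Planted benchmark: per-method outcome rates plus forced edge cases.

    The first ``n_forced_all_na`` entries have every method not available
    (consensus must be not available); the next ``n_forced_ties`` entries
    have two conclusive methods disagreeing 1-1 (consensus must be
    inconclusive).  Remaining entries sample each method's outcome category
    independently at ``method_rates``.
    """

    n_entries: int = 543
    method_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_METHOD_RATES
    )
    n_forced_all_na: int = 5
    n_forced_ties: int = 5
    #: fraction of entries whose deposited archive annotation is wrong; the
    #: reported archive error-rate estimates span ~7% (lower bound) to ~14%
    archive_error_rate: float = 0.14

    def __post_init__(self) -> None:
        if not 0 <= self.archive_error_rate <= 1:
            raise ValueError("archive_error_rate must be in [0, 1]")
        for method, rates in self.method_rates.items():
            total = sum(rates.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{method} outcome rates sum to {total}, not 1")
        if self.n_forced_all_na + self.n_forced_ties > self.n_entries:
            raise ValueError("forced entries exceed n_entries")


@dataclass
class FixtureSpec:
    """Aggregate spec for all generators (identical spec -> identical bytes)."""

    seed: int = 0
    benchmark: BenchmarkSpec = field(default_factory=BenchmarkSpec)
    corpus: CorpusSpec = field(default_factory=CorpusSpec)
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(size=5),
        ClusterSpec(size=3, n_noise=1),
        ClusterSpec(size=2),
    )


def _wrong_state(truth_idx: int) -> tuple[str, str]:
    """A catalogued state differing from the truth in BOTH components."""
    t_stoich, t_sym = STATE_CATALOG[truth_idx]
    truth_total = parse_stoichiometry(t_stoich).total_subunits
    for offset in range(1, len(STATE_CATALOG)):
        s, y = STATE_CATALOG[(truth_idx + offset) % len(STATE_CATALOG)]
        if parse_stoichiometry(s).total_subunits != truth_total and y != t_sym:
            return s, y
    raise RuntimeError("state catalogue cannot supply a doubly-wrong state")


def _plant_method(
    method: str, category: str, truth: tuple[str, str], wrong: tuple[str, str]
) -> QSAnnotation:
    if category == "not_available":
        return QSAnnotation.not_available(method)
    if category == "inconclusive":
        return QSAnnotation.inconclusive(method)
    stoich_text, sym_text = truth if category == "correct" else wrong
    stoich = parse_stoichiometry(stoich_text)
    if method == "TM":
        return QSAnnotation(
            stoichiometry=Stoichiometry({"A": stoich.total_subunits}),
            source=Source.TM,
            order_only=True,
        )
    return QSAnnotation(
        stoichiometry=stoich, symmetry=parse_symmetry(sym_text), source=Source(method)
    )


def _planted_consensus(
    method_annotations: Mapping[str, QSAnnotation],
    methods: Sequence[str],
) -> tuple[tuple[str, int, bool] | None, str | None, bool]:
    """Independent tally of the consensus rules, kept separate from the
    consensus module so it can serve as its oracle.

    Returns ``(stoich_winner, sym_winner, any_votes)`` where ``stoich_winner``
    is ``(formula, total, order_only)`` or ``None``.
    """
    votes = [
        a
        for m, a in method_annotations.items()
        if m in methods and a.status is Status.PREDICTED
    ]
    if not votes:
        return None, None, False

    # stoichiometry: candidates are full formulas; order-only votes support
    # every candidate with the same total
    full = [(str(v.stoichiometry), v.stoichiometry.total_subunits)
            for v in votes if v.stoichiometry is not None and not v.order_only]
    orders = [v.stoichiometry.total_subunits
              for v in votes if v.stoichiometry is not None and v.order_only]
    n_stoich_votes = len(full) + len(orders)
    stoich_winner: tuple[str, int] | None = None
    if n_stoich_votes:
        support: dict[tuple[str, int], int] = {}
        for formula, total in full:
            support[(formula, total)] = support.get((formula, total), 0) + 1
        full_totals = {total for _, total in full}
        for order in orders:
            if order in full_totals:
                for key in support:
                    if key[1] == order:
                        support[key] += 1
            else:
                key = (f"A{order}", order)
                support[key] = support.get(key, 0) + 1
                full_totals.add(order)
        winners = [k for k, s in support.items() if 2 * s > n_stoich_votes]
        if len(winners) == 1:
            formula, total = winners[0]
            order_only = formula not in [f for f, _ in full]
            stoich_winner = (formula, total, order_only)

    sym_votes = [str(v.symmetry) for v in votes if v.symmetry is not None]
    sym_winner = None
    if sym_votes:
        counts: dict[str, int] = {}
        for s in sym_votes:
            counts[s] = counts.get(s, 0) + 1
        top, top_count = max(counts.items(), key=lambda kv: kv[1])
        if 2 * top_count > len(sym_votes):
            sym_winner = top

    return stoich_winner, sym_winner, True


def _planted_outcome(
    stoich_winner: tuple[str, int, bool] | None,
    sym_winner: str | None,
    any_votes: bool,
    against: tuple[str, str],
) -> str:
    """Score the planted consensus against a (stoichiometry, symmetry) pair."""
    if not any_votes:
        return "not_available"
    if stoich_winner is None and sym_winner is None:
        return "inconclusive"
    ref_stoich, ref_sym = against
    ref_total = parse_stoichiometry(ref_stoich).total_subunits
    verdicts = []
    if stoich_winner is not None:
        formula, total, order_only = stoich_winner
        verdicts.append(total == ref_total if order_only else formula == ref_stoich)
    if sym_winner is not None:
        verdicts.append(sym_winner == ref_sym)
    if all(verdicts):
        return "correct"
    if not any(verdicts):
        return "incorrect"
    return "inconclusive"


def make_benchmark_table(
    spec: BenchmarkSpec, seed: int = 0, methods: Sequence[str] = ("SC", "TM", "PISA", "EPPIC")
) -> tuple[str, dict]:
    """Wide benchmark CSV plus the planted expected summary.

    Returns ``(csv_text, expected)`` where ``expected`` holds per-method
    outcome counts, the expected per-entry consensus outcomes, and the
    expected consensus outcome counts, all computed by the generator's own
    tally at generation time.
    """
    rng = np.random.default_rng(seed)
    categories = ("correct", "incorrect", "inconclusive", "not_available")
    header = ["pdb_id", "ref_stoich", "ref_sym", "pdb_stoich", "pdb_sym"]
    for m in methods:
        header += [f"{m.lower()}_stoich", f"{m.lower()}_sym", f"{m.lower()}_status"]
    rows = [",".join(header)]

    method_outcome_counts = {m: {c: 0 for c in categories} for m in methods}
    consensus_counts = {c: 0 for c in categories}
    per_entry_consensus: list[str] = []
    outlier_flags: list[bool] = []
    n_conclusive = 0

    for i in range(spec.n_entries):
        truth_idx = int(rng.integers(len(STATE_CATALOG)))
        truth = STATE_CATALOG[truth_idx]
        wrong = _wrong_state(truth_idx)
        archive = wrong if rng.random() < spec.archive_error_rate else truth
        annotations: dict[str, QSAnnotation] = {}
        if i < spec.n_forced_all_na:
            for m in methods:
                annotations[m] = QSAnnotation.not_available(m)
                method_outcome_counts[m]["not_available"] += 1
        elif i < spec.n_forced_all_na + spec.n_forced_ties:
            planted = {"SC": "correct", "PISA": "incorrect",
                       "TM": "not_available", "EPPIC": "not_available"}
            for m in methods:
                category = planted.get(m, "not_available")
                annotations[m] = _plant_method(m, category, truth, wrong)
                method_outcome_counts[m][category] += 1
        else:
            for m in methods:
                rates = spec.method_rates[m]
                p = np.array([rates[c] for c in categories])
                category = categories[int(rng.choice(len(categories), p=p / p.sum()))]
                annotations[m] = _plant_method(m, category, truth, wrong)
                method_outcome_counts[m][category] += 1

        stoich_winner, sym_winner, any_votes = _planted_consensus(annotations, methods)
        expected_outcome = _planted_outcome(stoich_winner, sym_winner, any_votes, truth)
        consensus_counts[expected_outcome] += 1
        per_entry_consensus.append(expected_outcome)

        conclusive = any_votes and (stoich_winner is not None or sym_winner is not None)
        n_conclusive += int(conclusive)
        outlier_flags.append(
            conclusive
            and _planted_outcome(stoich_winner, sym_winner, any_votes, archive)
            == "incorrect"
        )

        row = [f"e{i:04d}", truth[0], truth[1], archive[0], archive[1]]
        for m in methods:
            a = annotations[m]
            row += [
                str(a.stoichiometry) if a.stoichiometry else "",
                str(a.symmetry) if a.symmetry else "",
                a.status.value,
            ]
        rows.append(",".join(row))

    expected = {
        "n_entries": spec.n_entries,
        "method_outcome_counts": method_outcome_counts,
        "consensus_outcome_counts": consensus_counts,
        "per_entry_consensus": per_entry_consensus,
        "outlier_flags": outlier_flags,
        "outlier_fraction": (
            sum(outlier_flags) / n_conclusive if n_conclusive else 0.0
        ),
    }
    return "\n".join(rows) + "\n", expected
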