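"""Shared annotation model: stoichiometry formulas, point-group labels, records.

Quaternary structure is described by two descriptors.  *Stoichiometry* is a
composition formula such as ``A2B2`` (two copies each of two distinct
polypeptides — the hemoglobin heterotetramer); an uppercase letter denotes a
distinct subunit type and its coefficient the copy number.  The letters are
bookkeeping labels, not PDB chain identifiers, and every prediction method
assigns them independently — comparisons therefore go through a canonical,
label-free form (counts sorted non-increasing, relabeled from A).
*Symmetry* is a point-group descriptor: cyclic C\\ :sub:`n`, dihedral
D\\ :sub:`n`, tetrahedral T, octahedral O, icosahedral I, or helical H for
open helical symmetry.

Every prediction method in the package exchanges :class:`QSAnnotation`
records: an optional stoichiometry, an optional symmetry, the originating
method, and a status.  A method that could not be applied at all reports
``not_available``; one that ran but could not commit reports
``inconclusive``.  Text mining predicts only the oligomer order (a "dimer"
sentence cannot distinguish A2 from AB), which the ``order_only`` flag
records; order-only stoichiometries compare by total subunit count.
"""

from __future__ import annotations

import enum
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Source",
    "Status",
    "SymmetryFamily",
    "Stoichiometry",
    "Symmetry",
    "QSAnnotation",
    "Component",
    "MatchResult",
    "parse_stoichiometry",
    "canonicalize_stoichiometry",
    "parse_symmetry",
    "match_annotations",
    "annotations_to_frame",
    "annotations_from_frame",
]


class Source(str, enum.Enum):
    """Originating method of an annotation."""

    PDB = "PDB"          # archive's deposited annotation
    SC = "SC"            # sequence clustering
    TM = "TM"            # text mining
    PISA = "PISA"
    EPPIC = "EPPIC"
    CONSENSUS = "CONSENSUS"


class Status(str, enum.Enum):
    PREDICTED = "predicted"
    INCONCLUSIVE = "inconclusive"
    NOT_AVAILABLE = "not_available"


class SymmetryFamily(str, enum.Enum):
    CYCLIC = "C"
    DIHEDRAL = "D"
    TETRAHEDRAL = "T"
    OCTAHEDRAL = "O"
    ICOSAHEDRAL = "I"
    HELICAL = "H"


_FORMULA_TOKEN = re.compile(r"([A-Z])([0-9]*)")


@dataclass(frozen=True)
class Stoichiometry:
    """Subunit composition formula, e.g. ``A2B2`` or ``A3``.

    ``composition`` maps subunit letters to positive copy counts.  The
    canonical form (see :func:`canonicalize_stoichiometry`) has letters
    consecutive from ``A`` assigned in non-increasing count order, so that
    formulas from methods that label subunits independently compare equal
    exactly when their count multisets agree.
    """

    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if not comp:
            raise ValueError("stoichiometry must have at least one subunit type")
        for letter, count in comp.items():
            if letter not in string.ascii_uppercase:
                raise ValueError(f"invalid subunit letter {letter!r}")
            if not isinstance(count, int) or count < 1:
                raise ValueError(f"copy count for {letter} must be a positive integer")
        object.__setattr__(self, "composition", comp)

    @property
    def total_subunits(self) -> int:
        """Oligomer order: total number of subunits in the assembly."""
        return sum(self.composition.values())

    @property
    def counts(self) -> tuple[int, ...]:
        """Count multiset sorted non-increasing (the label-free content)."""
        return tuple(sorted(self.composition.values(), reverse=True))

    def is_canonical(self) -> bool:
        letters = sorted(self.composition)
        expected = list(string.ascii_uppercase[: len(letters)])
        if letters != expected:
            return False
        counts = [self.composition[c] for c in letters]
        return counts == sorted(counts, reverse=True)

    def __str__(self) -> str:
        return "".join(
            f"{letter}{count}" if count != 1 else letter
            for letter, count in sorted(self.composition.items())
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Stoichiometry):
            return NotImplemented
        return dict(self.composition) == dict(other.composition)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.composition.items())))


def parse_stoichiometry(text: str) -> Stoichiometry:
    """Parse a composition formula like ``A2B2`` or ``A4B2C1``.

    The grammar is one or more (uppercase letter, optional positive integer)
    tokens with strictly increasing letters; an omitted coefficient means 1.
    Formatting the result of parsing a canonical formula returns the
    identical string.
    """
    if not isinstance(text, str) or not text:
        raise ValueError("empty stoichiometry formula")
    pos = 0
    comp: dict[str, int] = {}
    prev = ""
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"invalid stoichiometry formula {text!r} at position {pos}")
        letter, digits = m.group(1), m.group(2)
        count = int(digits) if digits else 1
        if count < 1:
            raise ValueError(f"zero copy count for subunit {letter} in {text!r}")
        if letter in comp:
            raise ValueError(f"repeated subunit letter {letter} in {text!r}")
        if prev and letter <= prev:
            raise ValueError(f"subunit letters must be strictly increasing in {text!r}")
        comp[letter] = count
        prev = letter
        pos = m.end()
    return Stoichiometry(comp)


def canonicalize_stoichiometry(s: Stoichiometry) -> Stoichiometry:
    """Relabel subunits to the canonical form: A, B, C... by non-increasing
    count, ties broken by the original letter order.  Idempotent."""
    items = sorted(s.composition.items(), key=lambda kv: (-kv[1], kv[0]))
    return Stoichiometry(
        {string.ascii_uppercase[i]: count for i, (_, count) in enumerate(items)}
    )


_SYMMETRY_RE = re.compile(r"^(C|D)([0-9]+)$|^(T|O|I|H)$")


@dataclass(frozen=True)
class Symmetry:
    """Point-group descriptor: family plus rotation order for C/D groups."""

    family: SymmetryFamily
    order: int | None = None

    def __post_init__(self) -> None:
        fam = SymmetryFamily(self.family)
        object.__setattr__(self, "family", fam)
        if fam is SymmetryFamily.CYCLIC:
            if self.order is None or self.order < 1:
                raise ValueError("cyclic symmetry requires order >= 1")
        elif fam is SymmetryFamily.DIHEDRAL:
            if self.order is None or self.order < 2:
                raise ValueError("dihedral symmetry requires order >= 2")
        elif self.order is not None:
            raise ValueError(f"{fam.value} symmetry carries no numeric order")

    @property
    def group_order(self) -> int:
        """Number of rotations in the group (n for Cn, 2n for Dn, ...)."""
        if self.family is SymmetryFamily.CYCLIC:
            return self.order  # type: ignore[return-value]
        if self.family is SymmetryFamily.DIHEDRAL:
            return 2 * self.order  # type: ignore[operator]
        return {"T": 12, "O": 24, "I": 60}.get(self.family.value, 0)

    def __str__(self) -> str:
        if self.order is not None:
            return f"{self.family.value}{self.order}"
        return self.family.value


def parse_symmetry(text: str) -> Symmetry:
    """Parse a point-group label: ``C2``, ``D4``, ``T``, ``O``, ``I``, ``H``."""
    if not isinstance(text, str) or not text:
        raise ValueError("empty symmetry label")
    m = _SYMMETRY_RE.match(text)
    if m is None:
        raise ValueError(f"invalid symmetry label {text!r}")
    if m.group(1):
        return Symmetry(SymmetryFamily(m.group(1)), int(m.group(2)))
    return Symmetry(SymmetryFamily(m.group(3)))


@dataclass(frozen=True)
class QSAnnotation:
    """One method's quaternary-structure annotation for one entry.

    ``order_only`` marks stoichiometries that carry only the total subunit
    count (text mining: a "tetramer" sentence supports A4 and A2B2 alike).
    """

    stoichiometry: Stoichiometry | None = None
    symmetry: Symmetry | None = None
    source: Source = Source.PDB
    status: Status = Status.PREDICTED
    order_only: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        object.__setattr__(self, "status", Status(self.status))
        if self.status is Status.PREDICTED:
            if self.stoichiometry is None and self.symmetry is None:
                raise ValueError("a predicted annotation needs stoichiometry or symmetry")
        if self.source is Source.TM and self.symmetry is not None:
            raise ValueError("text-mining annotations never carry symmetry")
        if self.order_only and self.stoichiometry is not None:
            if len(self.stoichiometry.composition) != 1:
                raise ValueError("order-only stoichiometry must be a single A<n> term")

    @property
    def is_prediction(self) -> bool:
        return self.status is Status.PREDICTED

    @classmethod
    def not_available(cls, source: Source | str) -> "QSAnnotation":
        return cls(source=Source(source), status=Status.NOT_AVAILABLE)

    @classmethod
    def inconclusive(cls, source: Source | str) -> "QSAnnotation":
        return cls(source=Source(source), status=Status.INCONCLUSIVE)


class Component(str, enum.Enum):
    """Tri-state verdict for one compared component."""

    MATCH = "match"
    MISMATCH = "mismatch"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class MatchResult:
    stoich_match: Component
    sym_match: Component

    @property
    def compared(self) -> tuple[Component, ...]:
        """The verdicts for components both sides actually carried."""
        return tuple(
            c for c in (self.stoich_match, self.sym_match) if c is not Component.UNAVAILABLE
        )


def _stoich_equal(a: QSAnnotation, b: QSAnnotation) -> bool:
    sa, sb = a.stoichiometry, b.stoichiometry
    assert sa is not None and sb is not None
    if a.order_only or b.order_only:
        return sa.total_subunits == sb.total_subunits
    return canonicalize_stoichiometry(sa) == canonicalize_stoichiometry(sb)


def match_annotations(a: QSAnnotation, b: QSAnnotation) -> MatchResult:
    """Compare two annotations component-wise.

    Stoichiometry is compared after canonicalization (by total subunit count
    when either side is order-only); symmetry by (family, order).  A component
    absent from either side is reported ``unavailable``, never silently
    treated as agreement.  Symmetric in its arguments.
    """
    if a.stoichiometry is None or b.stoichiometry is None:
        stoich = Component.UNAVAILABLE
    else:
        stoich = Component.MATCH if _stoich_equal(a, b) else Component.MISMATCH
    if a.symmetry is None or b.symmetry is None:
        sym = Component.UNAVAILABLE
    else:
        sym = Component.MATCH if a.symmetry == b.symmetry else Component.MISMATCH
    return MatchResult(stoich, sym)


# ---------------------------------------------------------------------------
# CSV dialect shared with the consensus module: one row per (entry, source).

def annotations_to_frame(rows: Iterable[tuple[str, QSAnnotation]]):
    """Serialize (pdb_id, annotation) pairs to the shared tabular dialect
    with columns pdb_id, source, stoichiometry, symmetry, status."""
    import pandas as pd

    records = []
    for pdb_id, ann in rows:
        records.append(
            {
                "pdb_id": pdb_id,
                "source": ann.source.value,
                "stoichiometry": str(ann.stoichiometry) if ann.stoichiometry else "",
                "symmetry": str(ann.symmetry) if ann.symmetry else "",
                "status": ann.status.value,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["pdb_id", "source", "stoichiometry", "symmetry", "status"]
    )


def annotations_from_frame(frame) -> list[tuple[str, QSAnnotation]]:
    """Inverse of :func:`annotations_to_frame`."""
    out: list[tuple[str, QSAnnotation]] = []
    for row in frame.itertuples(index=False):
        stoich = parse_stoichiometry(row.stoichiometry) if row.stoichiometry else None
        sym = parse_symmetry(row.symmetry) if row.symmetry else None
        source = Source(row.source)
        order_only = source is Source.TM and stoich is not None
        out.append(
            (
                row.pdb_id,
                QSAnnotation(
                    stoichiometry=stoich,
                    symmetry=sym,
                    source=source,
                    status=Status(row.status),
                    order_only=order_only,
                ),
            )
        )
    return out
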