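"""Adapters for PISA assembly XML and EPPIC prediction XML.

PISA scores every candidate assembly in a crystal by its Gibbs free energy
of dissociation: a positive dG_diss means the associated state is
thermodynamically stable in solution, a negative one that it dissociates,
and values inside a small gray band are indeterminate.  The adapter parses
the per-assembly XML (dG, ASA, BSA, and one rotation/translation operator
per chain), picks the most stable candidate, and re-characterizes it as
(stoichiometry, symmetry) through the operator-based point-group classifier.

EPPIC enumerates the valid (point-group-symmetric) assemblies of the lattice
and reports its chosen quaternary structure directly as stoichiometry and
symmetry; that adapter is a straight XML read plus canonicalization.

The exact element names of both dialects are defined by this package's
fixture writers (see :mod:`qsconsensus.fixtures`) and documented in
``docs/formats.md``; real exports may need a thin renaming layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lxml import etree

from .annotations import (
    QSAnnotation,
    Source,
    Status,
    canonicalize_stoichiometry,
    parse_stoichiometry,
    parse_symmetry,
)
from .pointgroup import RigidOperator, assembly_descriptor

__all__ = [
    "AssemblyCandidate",
    "StabilityCall",
    "parse_pisa_xml",
    "classify_stability",
    "pisa_prediction",
    "parse_eppic_xml",
    "DEFAULT_GRAY_BAND",
]

#: Half-width of the indeterminate dG_diss band, kcal/mol.  The stability
#: rule is qualitative (positive = stable, negative = unstable, borderline =
#: indeterminate); +/-0.5 kcal/mol is well under thermal energy differences
#: that PISA's model can resolve and is configurable everywhere it is used.
DEFAULT_GRAY_BAND = 0.5


@dataclass(frozen=True)
class AssemblyCandidate:
    """One candidate oligomeric state from a PISA run."""

    assembly_id: int
    delta_g_diss: float          # kcal/mol
    asa: float                   # A^2, solvent-accessible surface area
    bsa: float                   # A^2, buried surface area
    chains: tuple[tuple[str, RigidOperator], ...]

    def __post_init__(self) -> None:
        if self.asa < 0 or self.bsa < 0:
            raise ValueError("surface areas must be non-negative")
        if not self.chains:
            raise ValueError("assembly candidate without chains")


@dataclass(frozen=True)
class StabilityCall:
    verdict: str  # "stable" | "unstable" | "gray"


_MATRIX_KEYS = ("rxx", "rxy", "rxz", "ryx", "ryy", "ryz", "rzx", "rzy", "rzz")
_TRANSLATION_KEYS = ("tx", "ty", "tz")


def _parse_operator(molecule: etree._Element) -> RigidOperator:
    values = {}
    for key in _MATRIX_KEYS + _TRANSLATION_KEYS:
        node = molecule.find(key)
        if node is None or node.text is None:
            raise ValueError(f"molecule is missing operator element <{key}>")
        values[key] = float(node.text)
    R = np.array([values[k] for k in _MATRIX_KEYS]).reshape(3, 3)
    t = np.array([values[k] for k in _TRANSLATION_KEYS])
    return RigidOperator(R, t)


def parse_pisa_xml(doc: str | bytes) -> list[AssemblyCandidate]:
    """Parse a PISA-dialect assembly XML document.

    Returns one :class:`AssemblyCandidate` per ``<assembly>`` element, each
    with its dissociation free energy, surface areas, and per-chain rigid
    operators.  An XML with zero assemblies parses to an empty list (the
    caller records PISA as not available for that entry).  Malformed XML,
    missing operator elements, and non-numeric energies raise ``ValueError``.
    """
    if isinstance(doc, str):
        doc = doc.encode()
    try:
        root = etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed PISA XML: {exc}") from exc
    candidates = []
    for assembly in root.iter("assembly"):
        def text_of(tag: str) -> str:
            node = assembly.find(tag)
            if node is None or node.text is None:
                raise ValueError(f"assembly is missing <{tag}>")
            return node.text

        try:
            dg = float(text_of("diss_energy"))
        except ValueError as exc:
            raise ValueError(f"non-numeric dissociation energy: {exc}") from exc
        chains = tuple(
            (
                mol.findtext("entity", default=mol.findtext("chain_id", default="?")),
                _parse_operator(mol),
            )
            for mol in assembly.iter("molecule")
        )
        candidates.append(
            AssemblyCandidate(
                assembly_id=int(text_of("id")),
                delta_g_diss=dg,
                asa=float(text_of("asa")),
                bsa=float(text_of("bsa")),
                chains=chains,
            )
        )
    return candidates


def classify_stability(dg: float, gray_band: float = DEFAULT_GRAY_BAND) -> StabilityCall:
    """Stable above +band, unstable below -band, gray in between (inclusive).

    Monotone in dG: raising dG never moves the verdict toward unstable.
    """
    if gray_band < 0:
        raise ValueError("gray band must be non-negative")
    if dg > gray_band:
        return StabilityCall("stable")
    if dg < -gray_band:
        return StabilityCall("unstable")
    return StabilityCall("gray")


def pisa_prediction(
    candidates: Sequence[AssemblyCandidate],
    gray_band: float = DEFAULT_GRAY_BAND,
) -> QSAnnotation:
    """Quaternary-structure annotation from PISA assembly candidates.

    The stable candidate with the largest dG_diss wins (ties by larger BSA,
    then lower assembly id) and is re-characterized via the operator-based
    point-group classifier.  If no candidate is stable: any gray candidate
    makes the call inconclusive; all-unstable candidates mean the dissociated
    state prevails, predicting a monomer (A, C1); an empty candidate list is
    not available (PISA produced no assembly).  Classification failures are
    re-raised with the assembly id attached.  Invariant under candidate
    reordering.
    """
    if not candidates:
        return QSAnnotation.not_available(Source.PISA)
    stable = [
        c for c in candidates if classify_stability(c.delta_g_diss, gray_band).verdict == "stable"
    ]
    if not stable:
        if any(
            classify_stability(c.delta_g_diss, gray_band).verdict == "gray"
            for c in candidates
        ):
            return QSAnnotation.inconclusive(Source.PISA)
        return QSAnnotation(
            stoichiometry=parse_stoichiometry("A"),
            symmetry=parse_symmetry("C1"),
            source=Source.PISA,
        )
    best = max(stable, key=lambda c: (c.delta_g_diss, c.bsa, -c.assembly_id))
    try:
        stoich, sym = assembly_descriptor(list(best.chains))
    except ValueError as exc:
        raise ValueError(f"assembly {best.assembly_id}: {exc}") from exc
    return QSAnnotation(stoichiometry=stoich, symmetry=sym, source=Source.PISA)


def parse_eppic_xml(doc: str | bytes) -> QSAnnotation:
    """Parse an EPPIC-dialect prediction XML into an annotation.

    Reads ``<stoichiometry>`` and ``<symmetry>`` from the selected assembly;
    either field may be absent, in which case that component is simply
    missing from the annotation.  A document with neither field present is
    reported inconclusive; malformed XML raises ``ValueError``.
    """
    if isinstance(doc, str):
        doc = doc.encode()
    if not doc.strip():
        raise ValueError("empty EPPIC document")
    try:
        root = etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed EPPIC XML: {exc}") from exc
    stoich_text = root.findtext(".//stoichiometry")
    sym_text = root.findtext(".//symmetry")
    stoich = (
        canonicalize_stoichiometry(parse_stoichiometry(stoich_text))
        if stoich_text
        else None
    )
    sym = parse_symmetry(sym_text) if sym_text else None
    if stoich is None and sym is None:
        return QSAnnotation.inconclusive(Source.EPPIC)
    return QSAnnotation(stoichiometry=stoich, symmetry=sym, source=Source.EPPIC)
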