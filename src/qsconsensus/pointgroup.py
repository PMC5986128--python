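"""Point-group classification of protein assemblies from rigid-body operators.

An assembly exported by a tool such as PISA comes with one rotation +
translation operator per chain.  If the assembly is symmetric, the distinct
operators form a finite rotation group once expressed about the assembly's
fixed point, and the finite rotation groups in 3D are completely catalogued:
cyclic C_n, dihedral D_n, tetrahedral T (order 12), octahedral O (order 24)
and icosahedral I (order 60).  Classification therefore reduces to

1. validating each operator (orthonormal rotation part, determinant +1 —
   proper rotations only, since macromolecules are chiral),
2. solving for the common fixed point and re-centering,
3. checking group closure (every pairwise product is a member),
4. reading the group off the axis/fold structure of its elements.

Helical (open) symmetry has no fixed point and is out of scope here; ``H``
exists only as an accepted label in the annotation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotations import (
    Stoichiometry,
    Symmetry,
    SymmetryFamily,
    canonicalize_stoichiometry,
)

__all__ = [
    "RigidOperator",
    "AxisElement",
    "rotation_axis_angle",
    "classify_point_group",
    "assembly_descriptor",
    "find_fixed_point",
    "operators_from_tsv",
]

#: Default matching tolerances.  Operators printed in PISA XML carry limited
#: decimal precision, so exact comparisons are useless; 0.05 rad on angles
#: and axis directions plus 1e-3 on closure distances absorbs that while
#: keeping distinct crystallographic folds (>= 30 deg apart) unambiguous.
DEFAULT_TOL_ANGLE = 0.05
DEFAULT_TOL_AXIS = 0.05
DEFAULT_TOL_CLOSURE = 1e-3


@dataclass(frozen=True)
class RigidOperator:
    """Proper rigid-body transform x -> R x + t (rotation unitless, t in A)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-4):
            raise ValueError("rotation part is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper operator (det = -1): reflections are rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def compose(self, other: "RigidOperator") -> "RigidOperator":
        """self after other: (R1, t1) o (R2, t2) = (R1 R2, R1 t2 + t1)."""
        return RigidOperator(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def is_identity(self, tol: float = 1e-4) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=1e-2)
        )

    @classmethod
    def identity(cls) -> "RigidOperator":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle: float,
        center: Sequence[float] | None = None,
    ) -> "RigidOperator":
        """Rotation by ``angle`` about ``axis`` through ``center`` (Rodrigues)."""
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        if center is None:
            t = np.zeros(3)
        else:
            c = np.asarray(center, dtype=float)
            t = c - R @ c
        return cls(R, t)


def operators_from_tsv(text: str) -> list[RigidOperator]:
    """Parse operators given as 12-number rows: row-major 3x3 rotation then
    the translation vector, whitespace-separated, one operator per line."""
    ops = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values = [float(v) for v in line.split()]
        if len(values) != 12:
            raise ValueError(f"line {lineno}: expected 12 numbers, got {len(values)}")
        ops.append(
            RigidOperator(np.array(values[:9]).reshape(3, 3), np.array(values[9:]))
        )
    if not ops:
        raise ValueError("no operators found")
    return ops


@dataclass(frozen=True)
class AxisElement:
    """A rotation axis of the group with its fold (rotation order)."""

    axis: np.ndarray
    fold: int

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("zero axis vector")
        if self.fold < 2:
            raise ValueError("axis fold must be >= 2")
        object.__setattr__(self, "axis", a / n)


def rotation_axis_angle(op: RigidOperator) -> tuple[np.ndarray, float]:
    """Axis (unit vector, defined up to sign) and angle in [0, pi].

    The angle comes from the trace formula cos(theta) = (tr R - 1)/2; the
    axis is the rotation's fixed eigenvector.  For the identity the angle is
    0 and the returned axis is arbitrary (z by convention).
    """
    R = op.rotation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_theta))
    if angle < 1e-7:
        return np.array([0.0, 0.0, 1.0]), 0.0
    if np.pi - angle > 1e-5:
        v = np.array(
            [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
        ) / (2.0 * np.sin(angle))
    else:
        # 180 deg: antisymmetric part vanishes; use eigenvector of (R + I)/2
        M = (R + np.eye(3)) / 2.0
        v = M[:, int(np.argmax(np.diag(M)))]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate rotation matrix")
    return v / norm, angle


def find_fixed_point(ops: Sequence[RigidOperator]) -> np.ndarray:
    """Least-squares common fixed point p of all operators (R p + t = p).

    For a genuine point group expressed in arbitrary coordinates every axis
    passes through one point; stacking (R_i - I) p = -t_i over all operators
    and solving in the least-squares sense recovers it.  The component of p
    along a shared axis is unconstrained; lstsq returns the minimum-norm
    solution, which is fine because any point on the axis serves.
    """
    A = np.vstack([op.rotation - np.eye(3) for op in ops])
    b = np.concatenate([-op.translation for op in ops])
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return p


def _recenter(ops: Sequence[RigidOperator], tol: float) -> list[RigidOperator]:
    """Express each operator about the common fixed point; reject screw-like
    residual translations, which signal open (helical/lattice) symmetry."""
    p = find_fixed_point(ops)
    out = []
    for op in ops:
        residual = op.rotation @ p + op.translation - p
        if np.linalg.norm(residual) > max(1.0, np.linalg.norm(p)) * 100 * tol:
            raise ValueError(
                "operator translations are not consistent with a single fixed "
                "point (open or helical symmetry?)"
            )
        out.append(RigidOperator(op.rotation, np.zeros(3)))
    return out


def _dedupe(ops: Iterable[RigidOperator], tol: float) -> list[RigidOperator]:
    unique: list[RigidOperator] = []
    for op in ops:
        if not any(np.allclose(op.rotation, u.rotation, atol=tol) for u in unique):
            unique.append(op)
    return unique


def _is_closed(ops: Sequence[RigidOperator], tol: float) -> bool:
    mats = [op.rotation for op in ops]
    for A in mats:
        for B in mats:
            prod = A @ B
            if not any(np.max(np.abs(prod - M)) <= 100 * tol for M in mats):
                return False
    return True


def group_axes(
    ops: Sequence[RigidOperator],
    tol_angle: float = DEFAULT_TOL_ANGLE,
    tol_axis: float = DEFAULT_TOL_AXIS,
) -> list[AxisElement]:
    """Distinct rotation axes of the group with the fold of each.

    The fold of an axis is the largest n for which a 2*pi/n rotation about it
    is in the group; n is inferred per element as round(2*pi/angle) with a
    consistency check, robust to the rounding in printed operators.
    """
    axes: list[tuple[np.ndarray, set[int]]] = []
    for op in ops:
        axis, angle = rotation_axis_angle(op)
        if angle == 0.0:
            continue
        # rotation order of the element: smallest m with m*angle = 0 mod 2*pi
        fold = 0
        for m in range(2, 61):
            turns = m * angle / (2 * np.pi)
            if round(turns) >= 1 and abs(m * angle - 2 * np.pi * round(turns)) <= tol_angle:
                fold = m
                break
        if fold == 0:
            raise ValueError(f"rotation angle {angle:.4f} rad has no fold <= 60")
        placed = False
        for seen_axis, folds in axes:
            if abs(float(np.dot(seen_axis, axis))) >= np.cos(tol_axis):
                folds.add(fold)
                placed = True
                break
        if not placed:
            axes.append((axis, {fold}))
    return [AxisElement(axis, max(folds)) for axis, folds in axes]


def classify_point_group(
    ops: Sequence[RigidOperator],
    tol_angle: float = DEFAULT_TOL_ANGLE,
    tol_axis: float = DEFAULT_TOL_AXIS,
    tol_closure: float = DEFAULT_TOL_CLOSURE,
) -> Symmetry:
    """Classify a set of rigid operators as C_n, D_n, T, O or I.

    The set must contain the identity and be closed under composition
    (checked within ``tol_closure``); operators are first re-centered about
    their common fixed point.  The decision uses the catalogue of finite
    rotation groups: all rotations about one axis -> C_N; an n-fold principal
    axis with n perpendicular 2-folds and N = 2n -> D_n; N = 12 with only 2-
    and 3-folds -> T; N = 24 with a 4-fold -> O; N = 60 -> I.

    Raises ``ValueError`` for empty input, a set without the identity, a
    non-closed set, improper operators, or a set matching no catalogued group.
    """
    ops = list(ops)
    if not ops:
        raise ValueError("empty operator set")
    ops = _recenter(ops, tol_closure)
    ops = _dedupe(ops, tol_closure * 10)
    if not any(op.is_identity() for op in ops):
        raise ValueError("operator set does not contain the identity")
    if not _is_closed(ops, tol_closure):
        raise ValueError("operator set is not closed under composition")
    N = len(ops)
    if N == 1:
        return Symmetry(SymmetryFamily.CYCLIC, 1)

    axes = group_axes(ops, tol_angle, tol_axis)
    folds = sorted((a.fold for a in axes), reverse=True)

    if len(axes) == 1:
        if axes[0].fold != N:
            raise ValueError(f"single-axis group of order {N} with fold {axes[0].fold}")
        return Symmetry(SymmetryFamily.CYCLIC, N)

    if N == 60:
        return Symmetry(SymmetryFamily.ICOSAHEDRAL)
    if N == 24 and 4 in folds:
        return Symmetry(SymmetryFamily.OCTAHEDRAL)
    if N == 12 and set(folds) <= {2, 3} and 3 in folds:
        return Symmetry(SymmetryFamily.TETRAHEDRAL)

    # dihedral: N = 2n, one n-fold principal axis, n perpendicular 2-folds.
    if N % 2 == 0:
        n = N // 2
        principal = [a for a in axes if a.fold == n]
        if principal:
            p = principal[0]
            perp_twofolds = [
                a
                for a in axes
                if a.fold == 2
                and abs(float(np.dot(a.axis, p.axis))) <= np.sin(tol_axis) + 1e-12
            ]
            # for D2 the principal 2-fold also counts among the three 2-folds
            needed = n if n > 2 else 2
            if len(perp_twofolds) >= needed:
                return Symmetry(SymmetryFamily.DIHEDRAL, n)
    raise ValueError(f"operator set of order {N} matches no catalogued point group")


def assembly_descriptor(
    chains: Sequence[tuple[str, RigidOperator]],
    tol_angle: float = DEFAULT_TOL_ANGLE,
    tol_axis: float = DEFAULT_TOL_AXIS,
    tol_closure: float = DEFAULT_TOL_CLOSURE,
    strict: bool = False,
) -> tuple[Stoichiometry, Symmetry]:
    """Stoichiometry and symmetry of an assembly given per-chain operators.

    Stoichiometry is the canonical count of entity labels.  Symmetry is the
    point group of the deduplicated operator set when that set forms a closed
    group about a common point; an assembly whose operators do not form a
    group is asymmetric (C1) unless ``strict`` is set, in which case the
    classification error propagates.  Distinct entity labels are never
    collapsed, so near-identical subunits yield pseudo-symmetric descriptors
    (hemoglobin is A2B2/C2, not A4/D2).
    """
    if not chains:
        raise ValueError("empty chain list")
    counts: dict[str, int] = {}
    for label, _ in chains:
        counts[label] = counts.get(label, 0) + 1
    letters = {}
    for i, label in enumerate(sorted(counts)):
        letters[chr(ord("A") + i)] = counts[label]
    stoich = canonicalize_stoichiometry(Stoichiometry(letters))

    ops = [op for _, op in chains]
    try:
        sym = classify_point_group(ops, tol_angle, tol_axis, tol_closure)
    except ValueError:
        if strict:
            raise
        sym = Symmetry(SymmetryFamily.CYCLIC, 1)
    return stoich, sym
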