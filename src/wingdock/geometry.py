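"""Rigid-body geometry: proper rotations, composition, and Kabsch superposition.

All coordinates are in Angstrom in a right-handed frame.  A
:class:`RigidTransform` maps a point ``x`` to ``rotation @ x + translation``;
rotations are required to be proper (det = +1), so chirality is always
preserved — mirror solutions of the superposition problem are rejected
explicitly (reflection guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "superpose", "SuperpositionError"]

_ORTHO_TOL = 1e-9


class SuperpositionError(ValueError):
    """Raised for degenerate point sets (too few or collinear points)."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation.

    Parameters
    ----------
    rotation : (3, 3) array
        Proper orthonormal matrix (``det = +1`` within 1e-9).
    translation : (3,) array
        Translation vector in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError(f"rotation is not proper: det = {np.linalg.det(R):.6f}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Axis-angle construction; ``|rotvec|`` is the angle in radians."""
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Functional form of :meth:`RigidTransform.compose` (t2 applied first)."""
    return t1.compose(t2)


def superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `mobile` onto `reference` (Kabsch).

    Returns the proper rigid transform minimising the RMS deviation and the
    residual RMSD (Angstrom) after applying it.  A reflection guard flips the
    smallest singular direction when the optimal orthogonal matrix would be
    improper, so chiral point sets are never mirrored.

    Raises
    ------
    SuperpositionError
        If fewer than 3 point pairs are given, the lengths differ, or either
        point set is (numerically) collinear.
    """
    A = np.asarray(mobile, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.ndim != 2 or A.shape[1] != 3 or B.shape != A.shape:
        raise SuperpositionError(
            f"point sets must be matching (N, 3) arrays, got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 point pairs, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # rank < 2 means all points lie on a line: rotation about it is undefined
    for label, M in (("mobile", A0), ("reference", B0)):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= max(1e-8, 1e-8 * s[0]):
            raise SuperpositionError(f"{label} point set is degenerate (collinear)")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A0 @ R.T - B0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd
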