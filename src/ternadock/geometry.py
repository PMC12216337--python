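"""Rigid-body geometry: Kabsch superposition, random rotations, RMSD.

The Kabsch solver is the load-bearing primitive of the whole assembly
stage: it returns the proper rotation and translation minimising the
least-squares residual between two corresponded point sets, with the
standard SVD determinant correction so reflections are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateGeometryError


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation ``R`` (3x3, det=+1) and translation ``t`` (3-vector, A)."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``source`` onto ``target``.

    Both inputs are n x 3 with index-wise correspondence, n >= 3.  Raises
    :class:`DegenerateGeometryError` when the source points are collinear
    (the rotation about the line is then unconstrained).
    """
    A = np.asarray(source, dtype=float)
    B = np.asarray(target, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ContractError(f"kabsch needs matching n x 3 arrays, got {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise DegenerateGeometryError("kabsch needs at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    # Collinearity of either set leaves the middle singular value at ~0.
    scale = max(np.linalg.norm(A0), 1e-12)
    sv_a = np.linalg.svd(A0, compute_uv=False)
    if sv_a[1] < 1e-8 * scale:
        raise DegenerateGeometryError("source points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    return RigidTransform(R, t)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure) via unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_rigid_transform(rng: np.random.Generator, box: float = 5.0) -> RigidTransform:
    """Uniform rotation composed with a translation uniform in [-box, box]^3."""
    return RigidTransform(random_rotation(rng), rng.uniform(-box, box, size=3))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unaligned) root-mean-square deviation of corresponded points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ContractError("rmsd needs identically-shaped arrays")
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def aligned_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of ``a`` onto ``b``."""
    tr = kabsch(a, b)
    return rmsd(tr.apply(a), b)
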