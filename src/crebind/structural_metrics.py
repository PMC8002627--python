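"""Structural discriminators for ensemble deduplication.

Two quantities decide whether two geometries are the same conformer: the
minimal root-mean-square deviation after optimal rigid superposition
(Kabsch), and the rotational constants from the principal moments of
inertia.  No atom re-indexing is attempted; ensembles from iterative
samplers are index-consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import MHZ_PER_AMU_A2
from .ensemble_io import ConsistencyError, Structure

__all__ = [
    "RotationalConstants",
    "kabsch_rmsd",
    "rotational_constants",
    "atomic_mass",
]

# Standard atomic weights (amu) for the elements that occur in host-guest
# ensembles and the synthetic bead chains.  Kept local: the package carries
# no dependency on a chemistry toolkit for a mass lookup.
_ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Fe": 55.845, "Zn": 65.38,
    "Br": 79.904, "I": 126.90447,
}


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in amu for an element symbol."""
    try:
        return _ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {symbol!r}") from None


@dataclass(frozen=True)
class RotationalConstants:
    """Principal rotational constants in MHz, sorted A >= B >= C.

    ``linear`` flags a linear rotor: the unique moment vanishes and only two
    (equal) finite constants exist; the formally infinite A constant is
    reported as ``inf``.
    """

    A: float
    B: float
    C: float
    linear: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C])

    def finite(self) -> np.ndarray:
        """The finite constants (drops the infinite axis of a linear rotor)."""
        vals = self.as_array()
        return vals[np.isfinite(vals)]


def _check_same_atoms(a: Structure, b: Structure) -> None:
    if a.atom_symbols != b.atom_symbols:
        raise ConsistencyError("structures have different atom symbol sequences")


def kabsch_rmsd(a: Structure, b: Structure, heavy_only: bool = False) -> float:
    """Minimal RMSD (Angstrom) between two geometries over proper rigid motions.

    Centroids are aligned, then the optimal proper rotation is found by the
    Kabsch algorithm (mirror superpositions are excluded).  Symmetric in its
    arguments.  With ``heavy_only`` hydrogens are excluded from both the fit
    and the deviation.
    """
    _check_same_atoms(a, b)
    pa, pb = a.coords, b.coords
    if heavy_only:
        mask = np.array([s not in ("H", "D") for s in a.atom_symbols])
        if not mask.any():
            raise ValueError("heavy_only RMSD requested but no heavy atoms present")
        pa, pb = pa[mask], pb[mask]
    if pa.shape[0] < 1:
        raise ValueError("need at least one atom")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    if pa.shape[0] == 1:
        return 0.0
    # align_vectors performs the Kabsch fit with the proper-rotation
    # determinant correction; the residual is evaluated explicitly to avoid
    # cancellation error for near-identical inputs.
    rot, _ = Rotation.align_vectors(pa, pb)
    diff = rot.apply(pb) - pa
    return float(np.sqrt((diff**2).sum() / pa.shape[0]))


def kabsch_rmsd_many(coords: np.ndarray, ref_coords: np.ndarray) -> np.ndarray:
    """Minimal RMSD of one geometry against a stack of references.

    Vectorized Kabsch with the proper-rotation determinant correction;
    ``coords`` is (N, 3) and ``ref_coords`` (R, N, 3).  Returns R RMSDs in
    Angstrom.  Atom correspondence is positional (no symbol checks).
    """
    p = coords - coords.mean(axis=0)
    q = ref_coords - ref_coords.mean(axis=1, keepdims=True)
    n = p.shape[0]
    cov = np.einsum("ai,raj->rij", p, q)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(u) * np.linalg.det(vt)
    s_corr = s.copy()
    s_corr[:, -1] *= np.sign(det)
    sq = (p**2).sum() + (q**2).sum(axis=(1, 2)) - 2.0 * s_corr.sum(axis=1)
    return np.sqrt(np.clip(sq, 0.0, None) / n)


def rotational_constants(structure: Structure, masses=None) -> RotationalConstants:
    """Rotational constants (MHz) from the mass-weighted inertia tensor.

    The tensor is taken about the centre of mass; principal moments I (amu
    Angstrom^2) map to constants via B[MHz] = 505379.0 / I.  Linear rotors
    (smallest moment ~ 0) are flagged and return an infinite A constant.
    """
    if structure.n_atoms < 2:
        raise ValueError("no rotational constants for a single atom")
    if masses is None:
        masses = np.array([atomic_mass(s) for s in structure.atom_symbols])
    else:
        masses = np.asarray(masses, dtype=float)
    xyz = structure.coords - np.average(structure.coords, axis=0, weights=masses)
    # inertia tensor I = sum m (|r|^2 E - r r^T)
    r2 = np.einsum("ij,ij->i", xyz, xyz)
    tensor = np.diag([float(np.sum(masses * r2))] * 3) - np.einsum(
        "i,ij,ik->jk", masses, xyz, xyz
    )
    moments = np.linalg.eigvalsh(tensor)  # ascending
    moments = np.clip(moments, 0.0, None)
    scale = float(np.sum(masses * r2))
    tol = 1e-10 * max(scale, 1.0)
    linear = moments[0] < tol
    constants = np.where(moments > tol, MHZ_PER_AMU_A2 / np.where(moments > tol, moments, 1.0), np.inf)
    constants = np.sort(constants)[::-1]  # A >= B >= C
    return RotationalConstants(float(constants[0]), float(constants[1]), float(constants[2]), linear=bool(linear))


def rotational_constant_difference(a: RotationalConstants, b: RotationalConstants) -> float:
    """Max over axes of |dB| / mean(B), the relative constant difference.

    Linear rotors are compared on their single finite constant; a linear vs
    non-linear pair is maximally different (returns ``inf``).
    """
    if a.linear != b.linear:
        return np.inf
    va, vb = a.finite(), b.finite()
    means = 0.5 * (va + vb)
    return float(np.max(np.abs(va - vb) / means))


def brute_force_min_rmsd(a: Structure, b: Structure, final_step_deg: float = 1.0) -> float:
    """Grid-search reference for :func:`kabsch_rmsd`.

    After centroid alignment, scans proper rotations on an Euler-angle grid,
    refined hierarchically down to ``final_step_deg`` spacing.  Serves as an
    independent check on the closed-form superposition; not for production.
    """
    _check_same_atoms(a, b)
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    n = pa.shape[0]

    def evaluate(angles):
        rots = Rotation.from_euler("zyz", angles, degrees=True)
        rotated = np.einsum("nij,aj->nai", rots.as_matrix(), pb)
        return np.sqrt(((rotated - pa) ** 2).sum(axis=(1, 2)) / n)

    def local_grid(center, step, half_span):
        offs = np.arange(-half_span, half_span + 1) * step
        grids = np.meshgrid(center[0] + offs, center[1] + offs, center[2] + offs, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    # coarse full scan at 10 degrees, then refine the best candidates
    step = 10.0
    az = np.arange(0.0, 360.0, step)
    el = np.arange(0.0, 180.0 + step, step)
    grids = np.meshgrid(az, el, az, indexing="ij")
    angles = np.stack([g.ravel() for g in grids], axis=1)
    rmsds = evaluate(angles)
    candidates = angles[np.argsort(rmsds)[:5]]

    best = float(np.min(rmsds))
    for center in candidates:
        s = step
        while s > final_step_deg:
            s = max(s / 4.0, final_step_deg)
            local = local_grid(center, s, 4)
            vals = evaluate(local)
            i = int(np.argmin(vals))
            center = local[i]
            best = min(best, float(vals[i]))
    return best
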