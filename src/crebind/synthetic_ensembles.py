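"""Synthetic torsional ensembles with known ground truth.

The real workflow samples flexible drug-like molecules (free and inside a
cage-shaped host) with a quantum Hamiltonian.  For testing and validation
this module provides a fully analytic stand-in: a bead chain whose energy
depends only on its torsion angles through per-torsion Fourier terms (plus
an optional nearest-neighbor coupling), optionally confined by a polynomial
ellipsoid wall emulating the non-covalent-interaction cage of a host.

Because conformer minima, energies and Boltzmann populations of this model
can be enumerated exhaustively on a torsion grid, the whole sampling ->
deduplication -> weighting pipeline can be validated against a brute-force
oracle.  Sampling itself is Metropolis Monte Carlo in torsion space, with
the same RMSD-Gaussian history-dependent bias used by metadynamics-based
conformer searches:

    V_bias = sum_i k_i exp(-alpha * Delta_i^2)

where Delta_i is the minimal (Kabsch) RMSD to the i-th previously deposited
reference structure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import rt
from .ensemble_io import Ensemble, Structure
from .structural_metrics import kabsch_rmsd_many

__all__ = [
    "HostWall",
    "ToyTorsionModel",
    "MTDParams",
    "ToyReference",
    "toy_energy",
    "embed",
    "measure_torsions",
    "brute_force_reference",
    "mtd_bias",
    "run_mtd",
    "run_unbiased",
    "genetic_cross",
    "numerical_frequencies",
    "assign_to_minima",
    "estimate_populations",
]


@dataclass(frozen=True)
class HostWall:
    """Polynomial ellipsoid confinement emulating a cage-shaped host.

    The chain centroid c contributes  strength * max(0, q - 1)^exponent
    with the ellipsoid quadratic form q = sum_j (c_j / semiaxes_j)^2: zero
    anywhere inside or on the surface, steeply rising outside.
    """

    semiaxes: tuple[float, float, float] = (4.0, 4.0, 4.0)
    strength: float = 10.0
    exponent: int = 6


@dataclass(frozen=True)
class ToyTorsionModel:
    """Analytic torsional bead-chain molecule.

    The chain has ``n_torsions + 3`` beads with fixed bond length and bond
    angle; the energy is a sum of per-torsion Fourier terms

        V_t(phi) = sum_k amp[t,k] * (1 - cos(mult[t,k] * phi - phase[t,k]))

    plus an optional nearest-neighbor coupling
    ``coupling * sum (1 - cos(phi_i - phi_{i+1}))`` and the host wall term.
    Amplitudes are barrier heights in kcal/mol.
    """

    n_torsions: int
    amplitudes: tuple = ((1.0,),)
    multiplicities: tuple = ((3,),)
    phases: tuple = ((0.0,),)
    coupling: float = 0.0
    bond_length: float = 1.5
    bond_angle_deg: float = 109.5
    atom_masses: tuple | None = None
    host: HostWall | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_torsions < 1:
            raise ValueError("need at least one torsion")
        for name in ("amplitudes", "multiplicities", "phases"):
            val = getattr(self, name)
            if len(val) != self.n_torsions:
                raise ValueError(f"{name} must have one entry per torsion")

    @property
    def n_atoms(self) -> int:
        return self.n_torsions + 3

    @property
    def symbols(self) -> tuple[str, ...]:
        return ("C",) * self.n_atoms

    @property
    def masses(self) -> np.ndarray:
        if self.atom_masses is not None:
            m = np.asarray(self.atom_masses, dtype=float)
            if m.size != self.n_atoms:
                raise ValueError("atom_masses length must equal atom count")
            return m
        return np.full(self.n_atoms, 12.011)


@dataclass(frozen=True)
class MTDParams:
    """Metadynamics-style sampling parameters.

    ``k_push`` (kcal/mol) and ``alpha`` (1/Angstrom^2) define the Gaussian
    bias; a snapshot becomes a new bias reference every
    ``deposition_interval`` steps up to ``max_references``.
    """

    steps: int = 2000
    T: float = 300.0
    k_push: float = 0.25
    alpha: float = 0.8
    deposition_interval: int = 50
    max_references: int = 30
    proposal_width: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_push < 0:
            raise ValueError("k_push must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class ToyReference:
    """Brute-force ground truth: minima, their energies and populations."""

    minima_torsions: np.ndarray  # (n_minima, n_torsions)
    minima_energies: np.ndarray  # kcal/mol, relative scale as toy_energy
    populations: np.ndarray  # basin-summed Boltzmann populations
    temperature: float
    grid_points: int


def _torsion_potential(model: ToyTorsionModel, phis: np.ndarray) -> np.ndarray:
    """Fourier + coupling energy for a batch of torsion vectors (..., n)."""
    phis = np.asarray(phis, dtype=float)
    e = np.zeros(phis.shape[:-1])
    for t in range(model.n_torsions):
        for a, m, d in zip(
            model.amplitudes[t], model.multiplicities[t], model.phases[t]
        ):
            e = e + a * (1.0 - np.cos(m * phis[..., t] - d))
    if model.coupling and model.n_torsions > 1:
        for t in range(model.n_torsions - 1):
            e = e + model.coupling * (1.0 - np.cos(phis[..., t] - phis[..., t + 1]))
    return e


def toy_energy(model: ToyTorsionModel, torsions, position=None) -> float:
    """Total toy energy (kcal/mol) of a torsion vector.

    ``position`` shifts the embedded chain centroid before the host wall is
    evaluated; without a host the wall term is identically zero and the
    position is irrelevant.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (model.n_torsions,):
        raise ValueError(
            f"expected {model.n_torsions} torsions, got shape {torsions.shape}"
        )
    e = float(_torsion_potential(model, torsions))
    if model.host is not None:
        coords = _embed_coords(model, torsions)
        centroid = coords.mean(axis=0)
        if position is not None:
            centroid = centroid + np.asarray(position, dtype=float)
        q = float(np.sum((centroid / np.asarray(model.host.semiaxes)) ** 2))
        e += model.host.strength * max(0.0, q - 1.0) ** model.host.exponent
    return e


def _embed_coords(model: ToyTorsionModel, torsions: np.ndarray) -> np.ndarray:
    """Internal-to-Cartesian chain construction (first atom at the origin)."""
    b = model.bond_length
    theta = math.radians(model.bond_angle_deg)
    n = model.n_atoms
    coords = np.zeros((n, 3))
    coords[1] = [b, 0.0, 0.0]
    coords[2] = coords[1] + [b * math.cos(math.pi - theta), b * math.sin(math.pi - theta), 0.0]
    for i in range(3, n):
        coords[i] = _nerf(
            coords[i - 3], coords[i - 2], coords[i - 1], b, theta, torsions[i - 3]
        )
    return coords


def _nerf(a, bb, c, bond, angle, torsion):
    """Natural extension reference frame placement of the next chain atom."""
    bc = c - bb
    bc /= np.linalg.norm(bc)
    ab = bb - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # sign convention chosen so the standard dihedral of the placed atom
    # equals `torsion` (trans = pi, extended chain)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def embed(model: ToyTorsionModel, torsions, position=None) -> Structure:
    """Embed a torsion vector as a 3D bead-chain :class:`Structure`.

    Deterministic canonical placement (first atom at the origin, first bond
    on x); the structure's energy is the full toy energy at these torsions.
    """
    torsions = np.asarray(torsions, dtype=float)
    coords = _embed_coords(model, torsions)
    if position is not None:
        coords = coords + np.asarray(position, dtype=float)
    return Structure(
        model.symbols,
        coords,
        toy_energy(model, torsions, position=position),
        tag="phi=" + ",".join(f"{p:.6f}" for p in torsions),
    )


def measure_torsions(structure: Structure) -> np.ndarray:
    """Dihedral angles (rad, in (-pi, pi]) along a bead chain."""
    xyz = structure.coords
    out = []
    for i in range(3, xyz.shape[0]):
        p0, p1, p2, p3 = xyz[i - 3 : i + 1]
        b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
        b1u = b1 / np.linalg.norm(b1)
        v = b0 - np.dot(b0, b1u) * b1u
        w = b2 - np.dot(b2, b1u) * b1u
        x = np.dot(v, w)
        y = np.dot(np.cross(b1u, v), w)
        out.append(math.atan2(y, x))
    return np.asarray(out)


def brute_force_reference(
    model: ToyTorsionModel, grid_points_per_torsion: int = 72, T: float = 300.0
) -> ToyReference:
    """Exhaustive grid oracle: minima, energies and basin populations.

    Evaluates the torsional potential on a regular periodic grid, finds
    local minima by neighbor comparison, assigns every grid point to its
    basin by steepest descent, and computes basin populations from the grid
    partition sum at temperature ``T``.
    """
    g = int(grid_points_per_torsion)
    n = model.n_torsions
    if g < 36:
        raise ValueError("need at least 36 grid points per torsion")
    if g**n > 10_000_000:
        raise ValueError("grid too large (> 1e7 points)")
    axes = [np.linspace(-math.pi, math.pi, g, endpoint=False)] * n
    mesh = np.meshgrid(*axes, indexing="ij")
    phis = np.stack([m.ravel() for m in mesh], axis=-1).reshape(*([g] * n), n)
    energy = _torsion_potential(model, phis)
    if model.host is not None:
        flat = phis.reshape(-1, n)
        wall = np.array(
            [toy_energy(model, p) - float(_torsion_potential(model, p)) for p in flat]
        )
        energy = energy + wall.reshape(energy.shape)

    # lowest neighbor (including self) over the 3^n - 1 periodic shifts
    best = energy.copy()
    best_idx = np.arange(energy.size).reshape(energy.shape)
    flat_index = np.arange(energy.size).reshape(energy.shape)
    for shift in itertools.product((-1, 0, 1), repeat=n):
        if all(s == 0 for s in shift):
            continue
        neigh_e = np.roll(energy, shift, axis=tuple(range(n)))
        neigh_i = np.roll(flat_index, shift, axis=tuple(range(n)))
        take = neigh_e < best
        best = np.where(take, neigh_e, best)
        best_idx = np.where(take, neigh_i, best_idx)

    # pointer-jump steepest descent to basin minima
    pointer = best_idx.ravel()
    for _ in range(64):
        nxt = pointer[pointer]
        if np.array_equal(nxt, pointer):
            break
        pointer = nxt
    minima_flat = np.unique(pointer)
    e_flat = energy.ravel()
    phis_flat = phis.reshape(-1, n)

    w = np.exp(-(e_flat - e_flat.min()) / rt(T))
    z = w.sum()
    pops = np.array([w[pointer == m].sum() / z for m in minima_flat])
    order = np.argsort(e_flat[minima_flat])
    minima_flat = minima_flat[order]
    return ToyReference(
        minima_torsions=phis_flat[minima_flat],
        minima_energies=e_flat[minima_flat],
        populations=pops[order],
        temperature=T,
        grid_points=g,
    )


def mtd_bias(structure: Structure, reference_structures, k_push, alpha: float) -> float:
    """History-dependent Gaussian bias sum(k_i exp(-alpha Delta_i^2)).

    Delta_i is the Kabsch RMSD (Angstrom) to the i-th reference; ``k_push``
    may be a scalar (shared strength) or one value per reference.  An empty
    reference list gives zero.
    """
    refs = list(reference_structures)
    if not refs:
        return 0.0
    ks = np.broadcast_to(np.asarray(k_push, dtype=float), (len(refs),))
    for ref in refs:
        if ref.atom_symbols != structure.atom_symbols:
            raise ValueError("bias reference does not share the structure's composition")
    deltas = kabsch_rmsd_many(
        structure.coords, np.stack([r.coords for r in refs])
    )
    return float(np.sum(ks * np.exp(-alpha * deltas**2)))


def run_mtd(model: ToyTorsionModel, params: MTDParams) -> Ensemble:
    """RMSD-biased Metropolis Monte Carlo sampling in torsion space.

    Every ``deposition_interval`` steps the current geometry is deposited as
    a new Gaussian bias reference (up to ``max_references``), pushing the
    walker away from already-visited regions.  Each accepted move emits a
    snapshot; recorded energies are the *unbiased* toy energies, and the
    bias energy at each snapshot is kept in ``ensemble.bias_energies`` (and
    the snapshot tag) for reweighting.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(params.seed)
    phis = rng.uniform(-math.pi, math.pi, size=model.n_torsions)
    position = np.zeros(3) if model.host is not None else None
    refs: list[Structure] = []
    current_e = toy_energy(model, phis, position)
    current_struct = embed(model, phis, position)
    current_bias = 0.0
    beta = 1.0 / rt(params.T)

    snapshots: list[Structure] = []
    biases: list[float] = []
    steps_at: list[int] = []
    for step in range(params.steps):
        if (
            params.deposition_interval > 0
            and step % params.deposition_interval == 0
            and len(refs) < params.max_references
        ):
            refs.append(current_struct)
            current_bias = mtd_bias(current_struct, refs, params.k_push, params.alpha)

        trial = phis.copy()
        t = int(rng.integers(model.n_torsions))
        trial[t] = ((trial[t] + rng.normal(0.0, params.proposal_width) + math.pi) % (2 * math.pi)) - math.pi
        trial_pos = position
        if position is not None:
            trial_pos = position + rng.normal(0.0, 0.2, size=3)
        trial_e = toy_energy(model, trial, trial_pos)
        trial_struct = embed(model, trial, trial_pos)
        trial_bias = (
            mtd_bias(trial_struct, refs, params.k_push, params.alpha)
            if params.k_push > 0 and refs
            else 0.0
        )
        d_total = (trial_e + trial_bias) - (current_e + current_bias)
        if d_total <= 0 or rng.uniform() < math.exp(-beta * d_total):
            phis, position = trial, trial_pos
            current_e, current_bias, current_struct = trial_e, trial_bias, trial_struct
            snap = Structure(
                trial_struct.atom_symbols,
                trial_struct.coords,
                trial_e,
                tag=f"step={step} bias={trial_bias:.10f}",
            )
            snapshots.append(snap)
            biases.append(trial_bias)
            steps_at.append(step)

    if not snapshots:  # walker never moved; keep the start point
        snapshots = [current_struct]
        biases = [current_bias]
        steps_at = [0]
    ens = Ensemble(snapshots, temperature=params.T, provenance=f"mtd seed={params.seed}")
    ens.bias_energies = np.asarray(biases)
    ens.step_indices = np.asarray(steps_at)
    ens.total_steps = params.steps
    return ens


def run_unbiased(
    model: ToyTorsionModel,
    T: float = 300.0,
    steps: int = 2000,
    seed: int = 0,
    proposal_width: float = 0.6,
) -> Ensemble:
    """Plain Metropolis sampling: :func:`run_mtd` with zero pushing strength.

    Uses the identical move sequence, so with the same seed the trajectory
    coincides with a bias-free metadynamics run.
    """
    params = MTDParams(
        steps=steps, T=T, k_push=0.0, proposal_width=proposal_width, seed=seed
    )
    return run_mtd(model, params)


def genetic_cross(torsions_a, torsions_b, max_children: int = 256, rng=None):
    """Torsion-vector crossing: children mix parental torsion subsets.

    For n <= 10 torsions all 2^n mixtures are formed; larger vectors are
    randomly subsampled to ``max_children``.  Children identical to either
    parent are excluded, as are duplicates.
    """
    a = np.asarray(torsions_a, dtype=float)
    b = np.asarray(torsions_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("parent torsion vectors must share one length")
    n = a.size
    children = []
    seen = {tuple(a), tuple(b)}
    if n <= 10:
        masks = itertools.product((0, 1), repeat=n)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        masks = (tuple(rng.integers(0, 2, size=n)) for _ in range(max_children * 2))
    for mask in masks:
        child = np.where(np.asarray(mask, dtype=bool), a, b)
        key = tuple(child)
        if key in seen:
            continue
        seen.add(key)
        children.append(child)
        if len(children) >= max_children:
            break
    return children


def assign_to_minima(torsions: np.ndarray, reference: ToyReference) -> np.ndarray:
    """Index of the nearest reference minimum (periodic torsion distance)."""
    t = np.atleast_2d(np.asarray(torsions, dtype=float))
    d = t[:, None, :] - reference.minima_torsions[None, :, :]
    d = (d + math.pi) % (2 * math.pi) - math.pi
    return np.argmin((d**2).sum(axis=-1), axis=1)


def estimate_populations(
    ensemble: Ensemble,
    reference: ToyReference,
    burn_in_steps: int = 0,
    n_blocks: int = 20,
):
    """Conformer populations from a sampled ensemble, with standard errors.

    Each snapshot is assigned to its nearest reference minimum and weighted
    by its Metropolis dwell time (steps until the next accepted move) times
    the bias-removal factor exp(+V_bias/RT), so biased runs are reweighted
    to the unbiased distribution.  Snapshots before ``burn_in_steps`` are
    discarded (the bias is still being built there).  Standard errors come
    from block averaging over ``n_blocks`` contiguous blocks.

    Returns ``(populations, standard_errors)`` aligned with
    ``reference.populations``.
    """
    steps = getattr(ensemble, "step_indices", None)
    biases = getattr(ensemble, "bias_energies", None)
    if steps is None or biases is None:
        raise ValueError("ensemble must come from run_mtd/run_unbiased")
    total = getattr(ensemble, "total_steps", int(steps[-1]) + 1)
    torsions = np.array([measure_torsions(s) for s in ensemble])
    basins = assign_to_minima(torsions, reference)
    dwell = np.diff(np.append(steps, total)).astype(float)
    beta = 1.0 / rt(ensemble.temperature)
    weights = dwell * np.exp(beta * np.asarray(biases))
    keep = steps >= burn_in_steps
    if not keep.any():
        raise ValueError("burn-in discards every snapshot")
    basins, weights = basins[keep], weights[keep]

    n_min = len(reference.populations)
    blocks = np.array_split(np.arange(len(weights)), n_blocks)
    block_p = np.full((n_blocks, n_min), np.nan)
    for bi, idx in enumerate(blocks):
        if len(idx) == 0:
            continue
        w = weights[idx]
        for m in range(n_min):
            block_p[bi, m] = w[basins[idx] == m].sum() / w.sum()
    valid = ~np.isnan(block_p[:, 0])
    block_p = block_p[valid]
    pops = np.array(
        [weights[basins == m].sum() / weights.sum() for m in range(n_min)]
    )
    if block_p.shape[0] > 1:
        se = block_p.std(axis=0, ddof=1) / math.sqrt(block_p.shape[0])
    else:
        se = np.zeros(n_min)
    return pops, se


def _rigid_projected_displacement(coords, masses, disp):
    """Remove overall translation and rotation from a displacement field."""
    m = masses[:, None]
    total = masses.sum()
    com = (m * coords).sum(axis=0) / total
    r = coords - com
    d = disp - (m * disp).sum(axis=0) / total
    # remove rigid rotation: solve I w = L with L = sum m r x d
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = np.diag([float((masses * r2).sum())] * 3) - np.einsum(
        "i,ij,ik->jk", masses, r, r
    )
    ang_mom = (m * np.cross(r, d)).sum(axis=0)
    omega = np.linalg.lstsq(inertia, ang_mom, rcond=None)[0]
    return d - np.cross(np.broadcast_to(omega, r.shape), r)


def numerical_frequencies(
    model: ToyTorsionModel, torsions_at_minimum, step: float = 1e-3
) -> np.ndarray:
    """Harmonic torsional frequencies (cm^-1) at a local minimum.

    Builds the finite-difference Hessian of the torsional potential and the
    mass-weighted kinetic metric G_ij = sum_a m_a (dr_a/dphi_i).(dr_a/dphi_j)
    (with rigid-body translation/rotation projected out of the displacement
    fields) and solves the generalized eigenproblem H c = omega^2 G c.
    Raises if any mode is imaginary, i.e. the input is not a minimum.
    """
    phi0 = np.asarray(torsions_at_minimum, dtype=float)
    n = model.n_torsions
    if phi0.shape != (n,):
        raise ValueError(f"expected {n} torsions")

    def V(p):
        return float(_torsion_potential(model, p))

    # central-difference Hessian (kcal/mol/rad^2)
    H = np.zeros((n, n))
    f0 = V(phi0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (V(phi0 + ei) - 2 * f0 + V(phi0 - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                V(phi0 + ei + ej) - V(phi0 + ei - ej) - V(phi0 - ei + ej) + V(phi0 - ei - ej)
            ) / (4 * step**2)

    # kinetic metric from embedding derivatives (amu Angstrom^2)
    masses = model.masses
    coords0 = _embed_coords(model, phi0)
    disp = []
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        d = (_embed_coords(model, phi0 + ei) - _embed_coords(model, phi0 - ei)) / (2 * step)
        disp.append(_rigid_projected_displacement(coords0, masses, d))
    G = np.array(
        [[float((masses[:, None] * di * dj).sum()) for dj in disp] for di in disp]
    )

    from scipy.linalg import eigh

    lam = eigh(H, G, eigvals_only=True)  # kcal/mol / (amu A^2)
    neg = [i for i, v in enumerate(lam) if v < -1e-8]
    if neg:
        raise ValueError(f"imaginary modes at indices {neg}: input is not a minimum")
    lam = np.clip(lam, 0.0, None)
    # omega[1/s] = sqrt(lambda * 4184 / N_A / (amu kg * 1e-20 m^2))
    from .constants import AMU_KG, AVOGADRO, SPEED_OF_LIGHT

    omega = np.sqrt(lam * 4184.0 / AVOGADRO / (AMU_KG * 1e-20))
    return omega / (2 * math.pi * SPEED_OF_LIGHT * 100.0)
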