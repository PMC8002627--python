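"""Conformer-rotamer ensemble (CRE) assembly.

A raw ensemble of sampled geometries is reduced to a CRE by pairwise
classification: two structures are *duplicates* when they agree in energy
and geometry, *rotamers* when they agree in energy and rotational constants
but differ in geometry (internal-rotation or symmetry images), and distinct
*conformers* otherwise.  Retained structures are grouped under conformer
representatives, sorted by energy, and pruned to an energy window above the
global minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .ensemble_io import Ensemble, Structure, write_multixyz
from .structural_metrics import (
    kabsch_rmsd,
    rotational_constant_difference,
    rotational_constants,
)

__all__ = [
    "CREThresholds",
    "ConformerGroup",
    "CRE",
    "classify_pair",
    "assemble_cre",
    "prune_window",
    "staged_refine",
]

DUPLICATE = "duplicate"
ROTAMER = "rotamer"
CONFORMER = "conformer"


@dataclass(frozen=True)
class CREThresholds:
    """Classification thresholds.

    Defaults follow the published defaults of iterative conformer samplers:
    0.1 kcal/mol energy, 0.125 Angstrom RMSD, 1% relative rotational-constant
    difference, and a 6 kcal/mol retention window above the global minimum.
    """

    e_thresh: float = 0.1
    rmsd_thresh: float = 0.125
    be_thresh: float = 0.01
    window: float = 6.0
    heavy_only: bool = False

    def __post_init__(self) -> None:
        for name in ("e_thresh", "rmsd_thresh", "be_thresh", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ConformerGroup:
    """A conformer representative together with its rotamer images."""

    representative: Structure
    rotamers: list[Structure] = field(default_factory=list)

    @property
    def members(self) -> list[Structure]:
        return [self.representative, *self.rotamers]

    @property
    def degeneracy(self) -> int:
        return 1 + len(self.rotamers)


@dataclass
class CRE:
    """Energy-window-pruned conformer/rotamer ensemble.

    Groups are sorted ascending by representative energy; group 0 holds the
    global minimum.  ``drop_log`` records every discarded input structure as
    ``(input_index, reason, matched_group)``.
    """

    groups: list[ConformerGroup]
    thresholds: CREThresholds
    drop_log: list[tuple[int, str, int | None]] = field(default_factory=list)
    stage_counts: list[int] = field(default_factory=list)

    @property
    def n_conformers(self) -> int:
        return len(self.groups)

    @property
    def n_structures(self) -> int:
        return sum(g.degeneracy for g in self.groups)

    @property
    def representative_energies(self) -> np.ndarray:
        return np.array([g.representative.energy_total for g in self.groups])

    def flatten(self, temperature: float = 298.15) -> Ensemble:
        """All retained structures (representatives first within each group)."""
        structures = [s for g in self.groups for s in g.members]
        return Ensemble(structures, temperature=temperature, provenance="CRE")

    def save(self, xyz_path, sidecar_path=None, energy_unit: str = "hartree") -> None:
        """Serialize as multi-frame XYZ plus a JSON membership/drop-log sidecar."""
        write_multixyz(self.flatten(), xyz_path, energy_unit=energy_unit)
        sidecar = {
            "groups": [
                {"representative_frame": None, "n_rotamers": len(g.rotamers)}
                for g in self.groups
            ],
            "drop_log": [list(entry) for entry in self.drop_log],
            "thresholds": {
                "e_thresh": self.thresholds.e_thresh,
                "rmsd_thresh": self.thresholds.rmsd_thresh,
                "be_thresh": self.thresholds.be_thresh,
                "window": self.thresholds.window,
            },
        }
        frame = 0
        for i, g in enumerate(self.groups):
            sidecar["groups"][i]["representative_frame"] = frame
            frame += g.degeneracy
        if sidecar_path is None:
            sidecar_path = str(xyz_path) + ".json"
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def classify_pair(a: Structure, b: Structure, thresholds: CREThresholds = CREThresholds()) -> str:
    """Classify a structure pair as duplicate, rotamer, or conformer.

    Duplicate: energies within ``e_thresh`` and RMSD below ``rmsd_thresh``.
    Rotamer: energies within ``e_thresh``, rotational constants within
    ``be_thresh`` relative difference, but RMSD at or above ``rmsd_thresh``.
    Anything else is a distinct conformer.
    """
    de = abs(a.energy_total - b.energy_total)
    if de >= thresholds.e_thresh:
        return CONFORMER
    rmsd = kabsch_rmsd(a, b, heavy_only=thresholds.heavy_only)
    if rmsd < thresholds.rmsd_thresh:
        return DUPLICATE
    be_diff = rotational_constant_difference(
        rotational_constants(a), rotational_constants(b)
    )
    if be_diff < thresholds.be_thresh:
        return ROTAMER
    return CONFORMER


def assemble_cre(
    ensemble: Ensemble,
    thresholds: CREThresholds = CREThresholds(),
    apply_window: bool = True,
) -> CRE:
    """Greedy energy-ordered grouping of an ensemble into a CRE.

    Structures are processed sorted ascending by energy and compared against
    the current group representatives: duplicates are dropped, rotamers are
    appended to the matching group (unless they duplicate one of its
    existing members), and structures distinct from every representative
    open a new group.  The energy window is applied last.  Deterministic for
    a given input.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot assemble a CRE from an empty ensemble")
    order = np.argsort([s.energy_total for s in ensemble], kind="stable")
    groups: list[ConformerGroup] = []
    drop_log: list[tuple[int, str, int | None]] = []
    for idx in order:
        s = ensemble[int(idx)]
        placed = False
        for gi, g in enumerate(groups):
            kind = classify_pair(s, g.representative, thresholds)
            if kind == DUPLICATE:
                drop_log.append((int(idx), DUPLICATE, gi))
                placed = True
                break
            if kind == ROTAMER:
                if any(
                    classify_pair(s, r, thresholds) == DUPLICATE for r in g.rotamers
                ):
                    drop_log.append((int(idx), DUPLICATE, gi))
                else:
                    g.rotamers.append(s)
                placed = True
                break
        if not placed:
            groups.append(ConformerGroup(representative=s))
    cre = CRE(groups=groups, thresholds=thresholds, drop_log=drop_log)
    if apply_window:
        cre = prune_window(cre, thresholds.window)
    return cre


def prune_window(cre: CRE, window: float) -> CRE:
    """Drop groups (and rotamers) above ``window`` kcal/mol over the minimum."""
    if window <= 0:
        raise ValueError("window must be positive")
    gmin = float(cre.representative_energies.min())
    cutoff = gmin + window
    kept: list[ConformerGroup] = []
    drop_log = list(cre.drop_log)
    for gi, g in enumerate(cre.groups):
        if g.representative.energy_total > cutoff:
            drop_log.append((-1, f"window:group{gi}", gi))
            continue
        rotamers = []
        for r in g.rotamers:
            if r.energy_total > cutoff:
                drop_log.append((-1, f"window:rotamer@group{gi}", gi))
            else:
                rotamers.append(r)
        kept.append(ConformerGroup(representative=g.representative, rotamers=rotamers))
    return replace(cre, groups=kept, drop_log=drop_log)


def staged_refine(
    ensemble: Ensemble,
    windows: tuple[float, ...] = (15.0, 10.0, 6.0),
    threshold_schedule: list[CREThresholds] | None = None,
) -> CRE:
    """Staged window refinement: assemble, then prune with tightening windows.

    ``windows`` must be strictly decreasing.  An optional per-stage threshold
    schedule tightens the classification criteria alongside the window; by
    default a single default threshold set is used throughout.  The survivor
    count after each stage is recorded on the result.
    """
    windows = tuple(float(w) for w in windows)
    if any(b >= a for a, b in zip(windows, windows[1:])):
        raise ValueError("windows must be strictly decreasing")
    if threshold_schedule is None:
        threshold_schedule = [CREThresholds(window=w) for w in windows]
    if len(threshold_schedule) != len(windows):
        raise ValueError("threshold_schedule length must match windows")
    counts: list[int] = []
    cre = assemble_cre(ensemble, threshold_schedule[0], apply_window=False)
    for w, thr in zip(windows, threshold_schedule):
        cre = assemble_cre(cre.flatten(), thr, apply_window=False)
        cre = prune_window(cre, w)
        counts.append(cre.n_structures)
    cre.stage_counts = counts
    return cre
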