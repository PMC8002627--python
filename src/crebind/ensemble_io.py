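"""Multi-frame XYZ ensemble I/O and reference-table parsing.

The ensemble file format is the plain multi-structure XYZ convention used by
conformer samplers: each frame is an atom count line, a comment line whose
first whitespace token parseable as a float is the total energy, then one
``symbol x y z`` line per atom.  Energies default to Hartree on disk (the
xtb convention) and are always converted to kcal/mol in memory; the unit is
an explicit flag and never guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_KCAL

__all__ = [
    "Structure",
    "Ensemble",
    "ReferenceRow",
    "ParseError",
    "ConsistencyError",
    "SchemaError",
    "read_multixyz",
    "write_multixyz",
    "read_reference_table",
]


class ParseError(ValueError):
    """A frame of a multi-XYZ file could not be parsed."""


class ConsistencyError(ValueError):
    """Structures of one ensemble disagree in composition or atom order."""


class SchemaError(ValueError):
    """A reference table is missing required columns."""


_UNIT_TO_KCAL = {
    "kcal/mol": 1.0,
    "kcal": 1.0,
    "hartree": HARTREE_TO_KCAL,
    "eh": HARTREE_TO_KCAL,
}


def _unit_factor(energy_unit: str) -> float:
    try:
        return _UNIT_TO_KCAL[energy_unit.lower()]
    except KeyError:
        raise ValueError(
            f"unknown energy unit {energy_unit!r}; expected one of {sorted(_UNIT_TO_KCAL)}"
        ) from None


@dataclass
class Structure:
    """One molecular geometry with its energy and optional correction terms.

    Parameters
    ----------
    atom_symbols
        Element labels, one per atom.
    coords
        Cartesian positions in Angstrom, shape ``(n_atoms, 3)``.
    energy_total
        Total (electronic) energy in kcal/mol.
    g_rrho
        Thermal + entropic rigid-rotor harmonic-oscillator correction at the
        working temperature, kcal/mol, or ``None`` when unavailable.
    g_solv
        Solvation free-energy term, kcal/mol, or ``None``.
    tag
        Free-text identifier (remainder of the XYZ comment line).
    """

    atom_symbols: tuple[str, ...]
    coords: np.ndarray
    energy_total: float
    g_rrho: float | None = None
    g_solv: float | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        self.atom_symbols = tuple(self.atom_symbols)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atom_symbols) != self.coords.shape[0]:
            raise ConsistencyError(
                f"{len(self.atom_symbols)} symbols but {self.coords.shape[0]} coordinate rows"
            )
        if not math.isfinite(self.energy_total):
            raise ValueError("energy_total must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    def moved(self, rotation: np.ndarray | None = None, translation=None) -> "Structure":
        """Return a rigidly moved copy (rotation about the origin, then shift)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, coords=xyz)


@dataclass
class Ensemble:
    """An ordered collection of same-composition structures."""

    structures: list[Structure]
    temperature: float = 298.15
    provenance: str = ""

    def __post_init__(self) -> None:
        self.structures = list(self.structures)
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")
        ref = self.structures[0].atom_symbols
        for i, s in enumerate(self.structures):
            if s.atom_symbols != ref:
                raise ConsistencyError(
                    f"structure {i} atom symbols differ from structure 0"
                )

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, i):
        return self.structures[i]

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy_total for s in self.structures])


@dataclass
class ReferenceRow:
    """One ligand of a benchmark reference table.

    Holds the experimental binding free energy with its uncertainty, the
    calculated top-pose and ensemble values, and optionally per-method
    association energies keyed by method name (all kcal/mol).
    """

    ligand_id: str
    exp_dg: float | None = None
    exp_unc: float | None = None
    calc_dg_top: float | None = None
    calc_dg_ens: float | None = None
    methods: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exp_unc is not None and self.exp_unc < 0:
            raise ValueError(f"{self.ligand_id}: exp_unc must be >= 0")


def read_multixyz(path, energy_unit: str = "hartree") -> Ensemble:
    """Read a multi-frame XYZ file with comment-line energies.

    Each frame's comment line must contain a leading floating-point energy
    (first float-parseable whitespace token); trailing tokens become the
    structure tag.  Energies are converted from ``energy_unit`` to kcal/mol.
    """
    factor = _unit_factor(energy_unit)
    lines = Path(path).read_text().splitlines()
    structures: list[Structure] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"frame {frame}: expected atom count, got {lines[pos]!r}")
        if pos + 2 + natoms > len(lines):
            raise ParseError(f"frame {frame}: truncated ({natoms} atoms expected)")
        comment = lines[pos + 1]
        energy = None
        tag_tokens: list[str] = []
        for tok_i, tok in enumerate(comment.split()):
            try:
                energy = float(tok)
            except ValueError:
                continue
            tag_tokens = comment.split()[tok_i + 1 :]
            break
        if energy is None:
            raise ParseError(f"frame {frame}: no parsable energy in comment {comment!r}")
        symbols: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            parts = lines[pos + 2 + a].split()
            if len(parts) < 4:
                raise ParseError(f"frame {frame}: malformed atom line {lines[pos + 2 + a]!r}")
            symbols.append(parts[0])
            try:
                coords[a] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise ParseError(f"frame {frame}: bad coordinates in {lines[pos + 2 + a]!r}")
        structures.append(
            Structure(tuple(symbols), coords, energy * factor, tag=" ".join(tag_tokens))
        )
        pos += 2 + natoms
        frame += 1
    if not structures:
        raise ParseError(f"{path}: no frames found")
    return Ensemble(structures, provenance=str(path))


def write_multixyz(ensemble: Ensemble, path, energy_unit: str = "hartree") -> None:
    """Write an ensemble as multi-frame XYZ, energies in ``energy_unit``."""
    factor = _unit_factor(energy_unit)
    out = []
    for s in ensemble:
        comment = f"{s.energy_total / factor:.12f}"
        if s.tag:
            comment += f" {s.tag}"
        out.append(f"{s.n_atoms}")
        out.append(comment)
        for sym, (x, y, z) in zip(s.atom_symbols, s.coords):
            out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


_TABLE_ALIASES = {
    "dg_top": "calc_dg_top",
    "dg_ens": "calc_dg_ens",
    "calc_dg_top": "calc_dg_top",
    "calc_dg_ens": "calc_dg_ens",
    "exp_dg": "exp_dg",
    "exp_unc": "exp_unc",
}


def read_reference_table(path) -> list[ReferenceRow]:
    """Read a delimited reference table into :class:`ReferenceRow` records.

    The table must have a header with a ``ligand_id`` column.  Recognised
    value columns are ``exp_dg``, ``exp_unc``, ``dg_top``/``calc_dg_top`` and
    ``dg_ens``/``calc_dg_ens``; any other numeric column is treated as a
    per-method association-energy column keyed by its header.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        raise SchemaError(f"{path}: empty or undelimited reference table")
    if "ligand_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'ligand_id'")
    known = set(_TABLE_ALIASES)
    rows: list[ReferenceRow] = []
    for _, rec in df.iterrows():
        kwargs: dict = {"ligand_id": str(rec["ligand_id"])}
        methods: dict[str, float] = {}
        for col in df.columns:
            if col == "ligand_id" or pd.isna(rec[col]):
                continue
            if col in known:
                kwargs[_TABLE_ALIASES[col]] = float(rec[col])
            else:
                methods[col] = float(rec[col])
        rows.append(ReferenceRow(methods=methods, **kwargs))
    if not rows:
        raise SchemaError(f"{path}: reference table has no data rows")
    return rows
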