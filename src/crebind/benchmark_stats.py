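"""Benchmark bookkeeping: deviations from experiment and summary statistics.

Signed deviations follow the overbinding convention d_i = exp - calc: a
positive deviation means the calculation binds more strongly (more negative
dG) than experiment.  Summary statistics are the mean absolute error, the
root-mean-square error, and the population standard deviation of the
absolute deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import ReferenceRow

__all__ = [
    "DeviationSet",
    "ErrorSummary",
    "deviations",
    "error_summary",
    "overbinding_count",
    "method_mean_difference",
    "ratio_to_experiment",
]

_FLAVOR_ATTR = {
    "top": "calc_dg_top",
    "ensemble": "calc_dg_ens",
}


@dataclass(frozen=True)
class DeviationSet:
    """Per-ligand signed deviations d_i = exp - calc (kcal/mol)."""

    ligand_ids: tuple[str, ...]
    values: np.ndarray
    flavor: str

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ErrorSummary:
    """MAE, RMSE and SD of absolute deviations (kcal/mol) over n ligands."""

    mae: float
    rmse: float
    sd: float
    n: int


def deviations(reference_rows: list[ReferenceRow], flavor: str = "top") -> DeviationSet:
    """Signed exp-minus-calc deviations for one calculated flavor.

    ``flavor`` is ``"top"`` (top-ranked pose) or ``"ensemble"`` (Boltzmann
    ensemble value).  Positive deviations indicate overbinding.
    """
    try:
        attr = _FLAVOR_ATTR[flavor]
    except KeyError:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {sorted(_FLAVOR_ATTR)}")
    ids, vals = [], []
    for row in reference_rows:
        calc = getattr(row, attr)
        if row.exp_dg is None or calc is None:
            raise ValueError(f"{row.ligand_id}: missing exp_dg or {attr} for flavor {flavor!r}")
        ids.append(row.ligand_id)
        vals.append(row.exp_dg - calc)
    return DeviationSet(tuple(ids), np.asarray(vals, dtype=float), flavor)


def error_summary(deviation_set: DeviationSet) -> ErrorSummary:
    """MAE, RMSE, and population SD of |d| for a deviation set."""
    d = deviation_set.values
    if d.size == 0:
        raise ValueError("empty deviation set")
    abs_d = np.abs(d)
    mae = float(abs_d.mean())
    rmse = float(np.sqrt(np.mean(d**2)))
    sd = float(abs_d.std(ddof=0))
    return ErrorSummary(mae=mae, rmse=rmse, sd=sd, n=int(d.size))


def overbinding_count(deviation_set: DeviationSet) -> int:
    """Number of ligands whose calculated dG is more negative than experiment."""
    return int(np.count_nonzero(deviation_set.values > 0))


def method_mean_difference(
    table_rows: list[ReferenceRow], method_a: str, method_b: str
) -> float:
    """Mean over ligands of E_a[method_a] - E_a[method_b] (kcal/mol)."""
    diffs = []
    for row in table_rows:
        missing = [m for m in (method_a, method_b) if m not in row.methods]
        if missing:
            raise ValueError(f"{row.ligand_id}: missing method column(s) {missing}")
        diffs.append(row.methods[method_a] - row.methods[method_b])
    if not diffs:
        raise ValueError("no rows to compare")
    return float(np.mean(diffs))


def ratio_to_experiment(calc_dg: float, exp_dg: float) -> float:
    """Ratio calc/exp of binding free energies (positive when signs agree)."""
    if exp_dg == 0:
        raise ZeroDivisionError("experimental dG is zero")
    return calc_dg / exp_dg
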