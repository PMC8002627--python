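"""Host-guest binding free energies from species ensembles.

For a 1:1 association  host + ligand -> complex  the binding free energy is
the difference of species free energies,

    dG = G(complex) - G(host) - G(ligand),

evaluated in three flavors over each species' conformer-rotamer ensemble:

* ``dg_top``      — best (lowest-G) structure of each species;
* ``dg_ens``      — Boltzmann population-averaged <G> of each species;
* ``dg_ens_tscr`` — ensemble average including the conformational-rotational
  entropy change, dg_ens - T*dS_CR, identically equal to the difference of
  partition-sum free energies F of the species.

Per-structure G values must already contain electronic, RRHO and solvation
terms; no standard-state concentration correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import DEFAULT_TEMPERATURE
from .ensemble_thermo import BoltzmannSummary, ensemble_summary

__all__ = ["BindingResult", "association_energy", "binding_free_energies"]


@dataclass(frozen=True)
class BindingResult:
    """The three binding free-energy flavors plus per-species summaries."""

    dg_top: float
    dg_ens: float
    dg_ens_tscr: float
    t_delta_s_cr: float
    temperature: float
    complex_summary: BoltzmannSummary
    host_summary: BoltzmannSummary
    ligand_summary: BoltzmannSummary

    def as_dict(self) -> dict:
        return {
            "dg_top": self.dg_top,
            "dg_ens": self.dg_ens,
            "dg_ens_tscr": self.dg_ens_tscr,
            "t_delta_s_cr": self.t_delta_s_cr,
            "temperature": self.temperature,
            "n_complex": self.complex_summary.n,
            "n_host": self.host_summary.n,
            "n_ligand": self.ligand_summary.n,
        }


def association_energy(e_complex: float, e_host: float, e_ligand: float) -> float:
    """Electronic association energy E_a = E(complex) - E(host) - E(ligand).

    Negative values mean favorable association.  Inputs in kcal/mol.
    """
    return e_complex - e_host - e_ligand


def binding_free_energies(
    complex_G,
    host_G,
    ligand_G,
    T: float = DEFAULT_TEMPERATURE,
) -> BindingResult:
    """Binding free-energy flavors from per-species Gibbs-energy lists.

    Each argument is the list of per-structure free energies (kcal/mol) of
    that species' retained ensemble.  When every species has exactly one
    structure all three flavors coincide.
    """
    summaries = {}
    for name, G in (("complex", complex_G), ("host", host_G), ("ligand", ligand_G)):
        if len(G) == 0:
            raise ValueError(f"empty free-energy list for species {name!r}")
        summaries[name] = ensemble_summary(G, T)
    cx, ho, li = summaries["complex"], summaries["host"], summaries["ligand"]

    dg_top = min(complex_G) - min(host_G) - min(ligand_G)
    dg_ens = cx.g_avg - ho.g_avg - li.g_avg
    t_ds_cr = T * (cx.s_cr - ho.s_cr - li.s_cr)
    dg_ens_tscr = cx.f_ens - ho.f_ens - li.f_ens  # == dg_ens - t_ds_cr

    return BindingResult(
        dg_top=float(dg_top),
        dg_ens=float(dg_ens),
        dg_ens_tscr=float(dg_ens_tscr),
        t_delta_s_cr=float(t_ds_cr),
        temperature=T,
        complex_summary=cx,
        host_summary=ho,
        ligand_summary=li,
    )
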