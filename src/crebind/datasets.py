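"""Packaged benchmark reference tables (SAMPL8 CB[8] host-guest set)."""

from importlib import resources

from .ensemble_io import ReferenceRow, read_reference_table

__all__ = [
    "load_binding_reference",
    "load_association_reference",
    "load_g0_protonation",
]


def _load(name: str) -> list[ReferenceRow]:
    with resources.as_file(resources.files("crebind") / "data" / name) as path:
        return read_reference_table(path)


def load_binding_reference() -> list[ReferenceRow]:
    """Experimental vs calculated binding free energies, ligands G0-G9."""
    return _load("sampl8_cb8_binding.csv")


def load_association_reference() -> list[ReferenceRow]:
    """Electronic association energies per method, ligands G0-G9."""
    return _load("sampl8_cb8_association.csv")


def load_g0_protonation() -> list[ReferenceRow]:
    """Calculated G0 binding free energies for three protonation states."""
    return _load("g0_protonation.csv")
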