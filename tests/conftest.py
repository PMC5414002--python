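"""Shared fixtures: synthetic ground-truth structures and PDB text helpers."""

from __future__ import annotations

from pathlib import Path

import pytest

from ftszkit.synthgen import SynthSpec, make_two_domain_structure, perturb_conformation

DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "pdb"


@pytest.fixture(scope="session")
def closed_synth():
    """Reference ("closed") synthetic two-domain structure + domains."""
    return make_two_domain_structure(SynthSpec(seed=3))


@pytest.fixture(scope="session")
def open_synth(closed_synth):
    """Conformer with a known 27° CTD rotation applied."""
    closed, domains = closed_synth
    spec = SynthSpec(seed=3, applied_angle=27.0)
    return perturb_conformation(closed, domains, spec), domains


def format_pdb_atom(serial, name, res_name, chain, res_seq, x, y, z, occ=1.0, b=0.0,
                    element=" C", altloc=" ", record="ATOM"):
    """Hand-format one fixed-column PDB ATOM/HETATM line."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{res_name:>3s} {chain}"
        f"{res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def deposit_path(pdb_id: str) -> Path:
    """Path of a user-fetched deposited coordinate file.

    Validation against deposited crystal structures needs the real
    entries; they are not redistributed with the package.  Fetch them
    with e.g. ``wget https://files.rcsb.org/download/<ID>.pdb`` into
    ``data/pdb/`` (see data/pdb/README.md).
    """
    for ext in (".pdb", ".cif", ".ent"):
        p = DATA_DIR / f"{pdb_id.upper()}{ext}"
        if p.exists():
            return p
        p = DATA_DIR / f"{pdb_id.lower()}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(
        f"deposited entry {pdb_id} not found under {DATA_DIR}; "
        "fetch it from the PDB (see data/pdb/README.md) to run real-structure validation"
    )
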