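"""Atomic-coordinate data model and PDB/mmCIF input/output.

This module owns the package's in-memory representation of a crystal
structure: a flat, ordered list of :class:`Atom` records grouped into
residues and chains, plus the unit cell when the file records one.
Parsing and serialization are delegated to :mod:`gemmi`; everything
downstream (superposition, domain-motion analysis, surface burial,
filament building) operates on these plain containers.

Residue numbering follows the author numbering of the source file,
1-based, and all residue intervals used in this package are inclusive at
both ends, matching how FtsZ literature refers to them (e.g. the
truncated S. aureus FtsZ construct spans residues 12 to 316).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "RigidTransform",
    "DomainDefinition",
    "FTSZ_DOMAINS",
    "FTSZ_DOMAINS_WIDE_NTD",
    "read_structure",
    "write_structure",
    "select",
    "apply_transform",
]

_ROTATION_TOL = 1e-8


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``res_seq`` is the author residue number; ``icode`` is the insertion
    code ('' for none) — residues with insertion codes are treated as
    distinct residues ordered after the base number.
    """

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    is_hetero: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class Structure:
    """An ordered collection of atoms with an optional unit cell.

    Invariant: atoms belonging to one residue are contiguous in
    ``atoms`` (guaranteed by the reader and preserved by ``select``).
    """

    atoms: list[Atom]
    cell: tuple[float, float, float, float, float, float] | None = None
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates in Å, file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with coordinates replaced row-for-row."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} does not match atom count {len(self.atoms)}")
        atoms = [dataclasses.replace(a, xyz=tuple(map(float, row))) for a, row in zip(self.atoms, xyz)]
        return Structure(atoms=atoms, cell=self.cell, id=self.id if id is None else id)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[Atom]]]:
        """Yield (residue key, atoms) in file order."""
        current_key: tuple[str, int, str] | None = None
        bucket: list[Atom] = []
        for a in self.atoms:
            key = a.residue_key
            if key != current_key:
                if bucket:
                    yield current_key, bucket  # type: ignore[misc]
                current_key, bucket = key, []
            bucket.append(a)
        if bucket:
            yield current_key, bucket  # type: ignore[misc]

    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def ca_atoms(self, include_hetero: bool = False) -> list[Atom]:
        return [a for a in self.atoms if a.atom_name == "CA" and (include_hetero or not a.is_hetero)]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x' = R x + t (R orthonormal, det +1)."""

    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        R = self.R
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant (improper)")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_arrays(R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return RigidTransform(tuple(map(tuple, R.tolist())), tuple(t.tolist()))

    @staticmethod
    def translation_only(t: Sequence[float]) -> "RigidTransform":
        return RigidTransform.from_arrays(np.eye(3), np.asarray(t, dtype=float))

    @staticmethod
    def from_axis_angle(
        axis: Sequence[float],
        angle_deg: float,
        center: Sequence[float] = (0.0, 0.0, 0.0),
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``,
        followed by ``translation``."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        k = axis / n
        th = math.radians(angle_deg)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
        c = np.asarray(center, dtype=float)
        t = c - R @ c + np.asarray(translation, dtype=float)
        return RigidTransform.from_arrays(R, t)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform.from_arrays(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        Rinv = self.R.T
        return RigidTransform.from_arrays(Rinv, -Rinv @ self.t)

    def power(self, k: int) -> "RigidTransform":
        if k < 0:
            return self.inverse().power(-k)
        out = RigidTransform.identity()
        for _ in range(k):
            out = self.compose(out)
        return out

    def angle_deg(self) -> float:
        """Rotation angle in degrees, in [0, 180]."""
        tr = float(np.trace(self.R))
        c = min(1.0, max(-1.0, (tr - 1.0) / 2.0))
        return math.degrees(math.acos(c))

    def axis(self) -> np.ndarray:
        """Unit rotation axis (eigenvector of R for eigenvalue 1).

        For the identity rotation, returns the +z axis by convention.
        """
        R = self.R
        if self.angle_deg() < 1e-9:
            return np.array([0.0, 0.0, 1.0])
        # antisymmetric part gives sin(theta) * axis; robust away from 180°
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        if np.linalg.norm(w) > 1e-8:
            return w / np.linalg.norm(w)
        # near 180°: use eigen-decomposition
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        v = vecs[:, np.argmax(vals)]
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class DomainDefinition:
    """Two-domain partition of an FtsZ-like chain plus named landmark atoms.

    Default intervals match the S. aureus FtsZ numbering: N-terminal
    GTP-binding domain (NTD) 12–165, central helix H-7 169–195, and
    C-terminal GTPase-activation domain (CTD) 196–316.  Intervals are
    inclusive and must not overlap.
    """

    ntd_range: tuple[int, int] = (12, 165)
    ctd_range: tuple[int, int] = (196, 316)
    h7_range: tuple[int, int] = (169, 195)
    landmarks: tuple[tuple[str, tuple[str, int, str]], ...] = (
        ("R29_CZ", ("A", 29, "CZ")),
        ("R191_CA", ("A", 191, "CA")),
        ("F138_CA", ("A", 138, "CA")),
        ("T66_CA", ("A", 66, "CA")),
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("ntd", self.ntd_range), ("ctd", self.ctd_range), ("h7", self.h7_range)):
            if lo > hi:
                raise ValueError(f"{name}_range is reversed: {lo} > {hi}")
        ivs = sorted([self.ntd_range, self.h7_range, self.ctd_range])
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 <= a1:
                raise ValueError("domain ranges overlap")

    def landmark(self, name: str) -> tuple[str, int, str]:
        for n, spec in self.landmarks:
            if n == name:
                return spec
        raise KeyError(f"unknown landmark {name!r}")


#: Default FtsZ domain partition (NTD 12–165).
FTSZ_DOMAINS = DomainDefinition()

#: Alternative preset with the wider NTD interval (12–176) used for
#: whole-census NTD alignments.
FTSZ_DOMAINS_WIDE_NTD = DomainDefinition(ntd_range=(12, 176), h7_range=(178, 195))


# ---------------------------------------------------------------------------
# reading / writing


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    """Resolve alternate locations: highest occupancy, ties to 'A'
    (more precisely: the lexicographically smallest altloc id)."""
    if len(group) == 1:
        return group[0]
    return sorted(group, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(path: str | Path, format_hint: str | None = None) -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    Only the first model is read.  Alternate locations are resolved to
    the highest-occupancy conformer (ties broken toward altloc 'A').
    The unit cell is captured when the file records one (CRYST1 /
    ``_cell``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = gemmi.CoorFormat.Unknown
    if format_hint:
        fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif, "cif": gemmi.CoorFormat.Mmcif}[
            format_hint.lower()
        ]
    try:
        st = gemmi.read_structure(str(path), format=fmt if fmt != gemmi.CoorFormat.Unknown else gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError(f"{path}: file contains no atoms")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                groups.setdefault(at.name, []).append(at)
            for name in groups:
                at = _pick_altloc(groups[name])
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name,
                        atom_name=name,
                        element=at.element.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        is_hetero=res.het_flag == "H",
                        icode=(res.seqid.icode or "").strip(),
                    )
                )
    cell = None
    c = st.cell
    if c and c.a > 1.0:  # gemmi uses a dummy 1 Å cell when absent
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return Structure(atoms=atoms, cell=cell, id=path.stem)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a PDB file (the only output format)."""
    st = gemmi.Structure()
    st.name = structure.id or "model"
    if structure.cell is not None:
        st.cell = gemmi.UnitCell(*structure.cell)
        st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in structure.atoms:
        ch = chain_map.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chain_map[a.chain_id] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chain_map[a.chain_id] = ch
        key = a.residue_key
        res = res_map.get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            res_map[key] = res
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.occ = 1.0
        at.b_iso = 0.0
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# selection / transformation


def select(
    structure: Structure,
    chain_id: str | None = None,
    residue_interval: tuple[int, int] | None = None,
    atom_names: Iterable[str] | None = None,
    include_hetero: bool = True,
) -> Structure:
    """Order-preserving subset of a structure.

    All filters are optional; an empty result is valid.  The residue
    interval is inclusive at both ends in author numbering.
    """
    names = set(atom_names) if atom_names is not None else None
    out: list[Atom] = []
    for a in structure.atoms:
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_interval is not None and not (residue_interval[0] <= a.res_seq <= residue_interval[1]):
            continue
        if names is not None and a.atom_name not in names:
            continue
        if not include_hetero and a.is_hetero:
            continue
        out.append(a)
    return Structure(atoms=out, cell=structure.cell, id=structure.id)


def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    """Apply a proper rigid transform to every atom; metadata preserved."""
    if not isinstance(transform, RigidTransform):
        raise TypeError("transform must be a RigidTransform")
    return structure.with_coords(transform.apply(structure.coords()))
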