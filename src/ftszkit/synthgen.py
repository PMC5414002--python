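"""Synthetic two-domain structures and crystal-like filaments.

Everything the structural half of this package measures — interdomain
rotations, Cα RMSDs, axial repeats, interface burial — can be exercised
on generated Cα-only structures whose ground truth is known exactly:
a compact pseudo-globular "NTD" and "CTD" joined by a straight
H-7-like segment, numbered to mimic the FtsZ presets (NTD 12–165,
H-7 169–195, CTD 196–316), plus multi-chain filaments with a fixed
axial repeat.  The geometry is deliberately not protein-like beyond
what the measurements need: point clouds stand in for folded domains,
and there are no side chains (BSA tests use inflated radii so Cα
chains make measurable contacts).
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass

import numpy as np

from .structio import Atom, DomainDefinition, RigidTransform, Structure, apply_transform

__all__ = [
    "SynthSpec",
    "make_two_domain_structure",
    "perturb_conformation",
    "make_filament_crystal",
]

# cycle of residue types for deterministic, alignable sequences
_RES_CYCLE = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic two-domain chain / filament.

    Residue counts default to the FtsZ-preset intervals (NTD 12–165,
    H-7 169–195, CTD 196–316).  ``applied_angle`` (degrees) rotates the
    CTD about ``axis`` through the interdomain hinge; ``h7_shift``
    translates the H-7 segment along its own axis; ``noise_sigma`` is
    isotropic per-atom Gaussian noise.  ``repeat`` is the axial repeat
    used for filament building (44 Å, the open-form protofilament
    repeat, by default).
    """

    n_res_ntd: int = 154
    n_res_h7: int = 27
    n_res_ctd: int = 121
    applied_angle: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    h7_shift: float = 0.0
    noise_sigma: float = 0.0
    repeat: float = 44.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_res_ntd, self.n_res_h7, self.n_res_ctd) <= 3:
            raise ValueError("residue counts must exceed 3")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _ball_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Deterministic quasi-uniform point cloud filling a ball, with a
    small seeded jitter so distinct seeds give distinct globules."""
    i = np.arange(n, dtype=float)
    # golden-spiral directions
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - 2 * (i + 0.5) / n
    r_dir = np.sqrt(np.maximum(0.0, 1 - z**2))
    dirs = np.stack([r_dir * np.cos(theta), r_dir * np.sin(theta), z], axis=1)
    radii = radius * ((i + 0.5) / n) ** (1.0 / 3.0)
    pts = dirs * radii[:, None]
    pts += rng.normal(0.0, 0.25, size=pts.shape)
    return pts


def make_two_domain_structure(spec: SynthSpec) -> tuple[Structure, DomainDefinition]:
    """Deterministic Cα-only chain with two globular domains and a
    straight connector, in the reference ("closed-like") conformation.

    The filament axis is z; the chain spans roughly 0–45 Å in z so that
    copies stacked at the default 44 Å repeat are in contact.  Returns
    the structure (chain A) and the matching domain definition.
    """
    rng = np.random.default_rng(spec.seed)
    r_ntd = 2.0 * spec.n_res_ntd ** (1.0 / 3.0)
    r_ctd = 2.0 * spec.n_res_ctd ** (1.0 / 3.0)

    ntd = _ball_points(spec.n_res_ntd, r_ntd, rng) + np.array([0.0, 0.0, r_ntd * 0.4])
    # H-7: straight segment alongside the two domains, running up the z axis
    h7_z0, h7_rise = 2.0, 1.0
    h7 = np.stack(
        [
            np.full(spec.n_res_h7, r_ntd + 2.0),
            np.zeros(spec.n_res_h7),
            h7_z0 + h7_rise * np.arange(spec.n_res_h7),
        ],
        axis=1,
    )
    h7 += rng.normal(0.0, 0.1, size=h7.shape)
    # place the CTD so the subunit spans nearly the default 44 Å
    # repeat: stacked copies then touch head-to-tail like protofilament
    # subunits
    ctd_center_z = r_ntd * 0.4 + r_ntd + r_ctd + 7.0
    ctd = _ball_points(spec.n_res_ctd, r_ctd, rng) + np.array([0.0, 0.0, ctd_center_z])

    ntd_lo = 12
    ntd_hi = ntd_lo + spec.n_res_ntd - 1
    h7_lo = ntd_hi + 4  # short disordered gap, as in the FtsZ numbering
    h7_hi = h7_lo + spec.n_res_h7 - 1
    ctd_lo = h7_hi + 1
    ctd_hi = ctd_lo + spec.n_res_ctd - 1

    atoms: list[Atom] = []
    res_seq_iter = (
        list(range(ntd_lo, ntd_hi + 1)) + list(range(h7_lo, h7_hi + 1)) + list(range(ctd_lo, ctd_hi + 1))
    )
    coords = np.vstack([ntd, h7, ctd])
    for k, (res_seq, xyz) in enumerate(zip(res_seq_iter, coords)):
        atoms.append(
            Atom(
                chain_id="A",
                res_seq=res_seq,
                res_name=_RES_CYCLE[k % len(_RES_CYCLE)],
                atom_name="CA",
                element="C",
                xyz=tuple(float(v) for v in xyz),
            )
        )
    domains = DomainDefinition(
        ntd_range=(ntd_lo, ntd_hi),
        ctd_range=(ctd_lo, ctd_hi),
        h7_range=(h7_lo, h7_hi),
        landmarks=(
            ("hinge_CA", ("A", ctd_lo, "CA")),
            ("ntd_core_CA", ("A", ntd_lo + spec.n_res_ntd // 2, "CA")),
        ),
    )
    return Structure(atoms=atoms, id=f"synth-{spec.seed}"), domains


def perturb_conformation(structure: Structure, domains: DomainDefinition, spec: SynthSpec) -> Structure:
    """Apply a known conformational change: rotate the CTD by
    ``spec.applied_angle`` about ``spec.axis`` through the interdomain
    hinge, shift H-7 by ``spec.h7_shift`` along its own axis, and add
    isotropic Gaussian noise ``spec.noise_sigma`` to every atom."""
    rng = np.random.default_rng(spec.seed + 1)
    coords = structure.coords()
    res_seq = np.array([a.res_seq for a in structure.atoms])
    in_ctd = (res_seq >= domains.ctd_range[0]) & (res_seq <= domains.ctd_range[1])
    in_h7 = (res_seq >= domains.h7_range[0]) & (res_seq <= domains.h7_range[1])

    new = coords.copy()
    if spec.applied_angle != 0.0 and in_ctd.any():
        hinge = coords[in_h7].mean(axis=0) if in_h7.any() else coords[in_ctd].mean(axis=0)
        T = RigidTransform.from_axis_angle(spec.axis, spec.applied_angle, center=hinge)
        new[in_ctd] = T.apply(coords[in_ctd])
    if spec.h7_shift != 0.0 and in_h7.any():
        seg = coords[in_h7]
        direction = seg[-1] - seg[0]
        direction = direction / np.linalg.norm(direction)
        new[in_h7] = new[in_h7] + spec.h7_shift * direction
    if spec.noise_sigma > 0:
        new = new + rng.normal(0.0, spec.noise_sigma, size=new.shape)
    return structure.with_coords(new, id=structure.id + "-perturbed")


def make_filament_crystal(subunit: Structure, repeat: float, n: int, twist: float = 0.0) -> Structure:
    """n copies of ``subunit`` related by translation ``repeat`` along z
    (plus an optional ``twist`` in degrees about z), as successive
    chains A, B, C, ... of one structure — a synthetic stand-in for a
    crystal protofilament."""
    if n < 2:
        raise ValueError("a filament needs at least 2 subunits")
    operator = RigidTransform.from_axis_angle((0, 0, 1), twist, translation=(0.0, 0.0, repeat))
    chain_ids = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n > len(chain_ids):
        raise ValueError(f"cannot label more than {len(chain_ids)} chains")
    atoms: list[Atom] = []
    for k in range(n):
        copy = apply_transform(subunit, operator.power(k))
        for a in copy.atoms:
            atoms.append(dataclasses.replace(a, chain_id=chain_ids[k]))
    cell = (60.0, 60.0, repeat * n, 90.0, 90.0, 90.0)
    return Structure(atoms=atoms, cell=cell, id=f"{subunit.id}-filament-{n}x{repeat:g}A")
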