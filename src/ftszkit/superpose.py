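"""Sequence-matched Cα superposition and all-vs-all RMSD matrices.

Residue correspondence is established by global sequence alignment
(Needleman–Wunsch, BLOSUM62, affine gaps), after which a weighted
Kabsch fit gives the least-squares rigid transform.  ``superpose``
additionally runs cycles of outlier rejection: after each fit, paired
atoms whose deviation exceeds ``cutoff`` times the current RMS
deviation are dropped and the remaining pairs are refit.  This mirrors
how structure-viewer "align" commands report Cα RMSDs, so the same
machinery serves both the quoted pairwise RMSDs (rejection on) and the
all-vs-all census matrix (rejection off, all sequence-matched residues
kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .structio import RigidTransform, Structure

__all__ = [
    "ResiduePairing",
    "SuperpositionResult",
    "pair_residues",
    "kabsch",
    "superpose",
    "rmsd_matrix",
    "ca_sequence",
]

logger = logging.getLogger(__name__)

_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()
#: Affine gap penalties (open, extend) used for residue pairing.
GAP_PENALTY = (-11, -1)


@dataclass(frozen=True)
class ResiduePairing:
    """Colinear residue correspondence between two sequences.

    ``pairs[k] = (i, j)`` maps position ``i`` of sequence A onto
    position ``j`` of sequence B; both columns are strictly increasing.
    """

    pairs: tuple[tuple[int, int], ...]
    alignment_score: float

    def __post_init__(self) -> None:
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if i1 <= i0 or j1 <= j0:
                raise ValueError("pairs must be strictly increasing in both columns")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.array(self.pairs, dtype=int).reshape(-1, 2)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid fit of structure A onto structure B with bookkeeping."""

    transform: RigidTransform
    rmsd: float
    n_input_pairs: int
    n_retained_pairs: int
    cycles_run: int
    retained_mask: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.n_retained_pairs > self.n_input_pairs:
            raise ValueError("cannot retain more pairs than supplied")


def pair_residues(seq_a: str, seq_b: str) -> ResiduePairing:
    """Global Needleman–Wunsch pairing of two one-letter sequences.

    BLOSUM62 with affine gap penalties (open 11, extend 1).  Returns
    only aligned (non-gap) columns, which are colinear by construction.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot pair an empty sequence")
    a = ProteinSequence(seq_a)
    b = ProteinSequence(seq_b)
    ali = align_optimal(a, b, _BLOSUM62, gap_penalty=GAP_PENALTY, terminal_penalty=True, max_number=1)[0]
    trace = ali.trace
    keep = (trace[:, 0] != -1) & (trace[:, 1] != -1)
    pairs = tuple((int(i), int(j)) for i, j in trace[keep])
    return ResiduePairing(pairs=pairs, alignment_score=float(ali.score))


def _check_nondegenerate(x: np.ndarray) -> None:
    c = x - x.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-8 * max(1.0, s[0]):
        raise ValueError("degenerate (collinear or coincident) point set")


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray, weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted least-squares rigid fit of ``coords_a`` onto ``coords_b``.

    Returns the proper rotation (reflections corrected to det +1) and
    translation minimizing the weighted RMSD, together with the residual
    RMSD.  Requires at least 3 non-collinear points.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    _check_nondegenerate(A)
    _check_nondegenerate(B)
    ca = w @ A
    cb = w @ B
    H = (A - ca).T @ ((B - cb) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return SuperpositionResult(
        transform=RigidTransform.from_arrays(R, t),
        rmsd=rmsd,
        n_input_pairs=n,
        n_retained_pairs=n,
        cycles_run=0,
        retained_mask=tuple([True] * n),
    )


def ca_sequence(
    structure: Structure,
    chain_id: str | None = None,
    residue_interval: tuple[int, int] | None = None,
) -> tuple[str, np.ndarray, list[int]]:
    """One-letter sequence, coordinates and residue numbers of the Cα trace.

    Hetero records are excluded; residues lacking a Cα atom are dropped.
    Unknown residue names map to 'X'.
    """
    seq: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    nums: list[int] = []
    for a in structure.atoms:
        if a.atom_name != "CA" or a.is_hetero:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_interval is not None and not (residue_interval[0] <= a.res_seq <= residue_interval[1]):
            continue
        try:
            letter = ProteinSequence.convert_letter_3to1(a.res_name)
        except KeyError:
            letter = "X"
        seq.append(letter)
        xyz.append(a.xyz)
        nums.append(a.res_seq)
    return "".join(seq), np.array(xyz, dtype=float).reshape(-1, 3), nums


def superpose(
    struct_a: Structure,
    struct_b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
    residue_interval: tuple[int, int] | None = None,
    cycles: int = 5,
    cutoff: float = 2.0,
) -> SuperpositionResult:
    """Cα superposition of A onto B with iterative outlier rejection.

    After each fit, pairs deviating by more than ``cutoff`` times the
    RMS deviation of currently retained pairs are rejected and the fit
    repeated, up to ``cycles`` times or until no pair is rejected.
    ``cycles=0`` keeps every sequence-matched pair.
    """
    seq_a, xyz_a, _ = ca_sequence(struct_a, chain_a, residue_interval)
    seq_b, xyz_b, _ = ca_sequence(struct_b, chain_b, residue_interval)
    pairing = pair_residues(seq_a, seq_b)
    ia, ib = pairing.as_arrays()
    if len(ia) < 3:
        raise ValueError(f"only {len(ia)} paired Cα atoms; need at least 3")
    A, B = xyz_a[ia], xyz_b[ib]
    n = len(A)
    mask = np.ones(n, dtype=bool)
    cycles_run = 0
    fit = kabsch(A, B)
    for _ in range(cycles):
        dev = np.linalg.norm(fit.transform.apply(A[mask]) - B[mask], axis=1)
        rms = float(np.sqrt(np.mean(dev**2)))
        reject = dev > cutoff * rms if rms > 0 else np.zeros(mask.sum(), dtype=bool)
        cycles_run += 1
        if not reject.any():
            break
        idx = np.flatnonzero(mask)[reject]
        if mask.sum() - len(idx) < 3:
            raise ValueError("outlier rejection left fewer than 3 pairs")
        mask[idx] = False
        fit = kabsch(A[mask], B[mask])
    return SuperpositionResult(
        transform=fit.transform,
        rmsd=fit.rmsd,
        n_input_pairs=n,
        n_retained_pairs=int(mask.sum()),
        cycles_run=cycles_run,
        retained_mask=tuple(bool(m) for m in mask),
    )


def rmsd_matrix(
    structures: dict[str, Structure] | list[Structure],
    chain_id: str | None = None,
    residue_interval: tuple[int, int] | None = None,
    rejection_cycles: int = 0,
    cutoff: float = 2.0,
) -> pd.DataFrame:
    """All-vs-all Cα RMSD matrix.

    With ``rejection_cycles=0`` every sequence-matched residue enters
    the RMSD, making the matrix symmetric; the diagonal is exactly 0.
    Failed pairs are logged and reported as NaN.
    """
    if isinstance(structures, dict):
        items = list(structures.items())
    else:
        items = [(s.id or f"structure_{i}", s) for i, s in enumerate(structures)]
    if len(items) < 2:
        raise ValueError("need at least 2 structures")
    ids = [k for k, _ in items]
    n = len(items)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if rejection_cycles == 0 and j < i:
                M[i, j] = M[j, i]  # symmetric without rejection
                continue
            try:
                res = superpose(
                    items[i][1],
                    items[j][1],
                    chain_a=chain_id,
                    chain_b=chain_id,
                    residue_interval=residue_interval,
                    cycles=rejection_cycles,
                    cutoff=cutoff,
                )
                M[i, j] = res.rmsd
            except ValueError as exc:
                logger.warning("superposition %s vs %s failed: %s", ids[i], ids[j], exc)
                M[i, j] = np.nan
    return pd.DataFrame(M, index=ids, columns=ids)
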