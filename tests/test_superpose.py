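"""Residue pairing, Kabsch fitting, outlier rejection and RMSD matrices."""

import itertools

import numpy as np
import pytest
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix

from ftszkit.structio import Atom, RigidTransform, Structure
from ftszkit.superpose import GAP_PENALTY, kabsch, pair_residues, rmsd_matrix, superpose
from ftszkit.synthgen import SynthSpec, make_two_domain_structure, perturb_conformation


# --- residue pairing -------------------------------------------------------


def _brute_force_best_pairings(seq_a: str, seq_b: str):
    """Exhaustive global-alignment oracle for tiny sequences.

    Enumerates every colinear pairing and scores it with BLOSUM62 plus
    affine gap costs (open + extend per gap symbol) applied to every
    maximal unpaired run, terminal runs included.  Returns the set of
    optimal pairings.
    """
    mat = SubstitutionMatrix.std_protein_matrix()
    open_pen, ext = -GAP_PENALTY[0], -GAP_PENALTY[1]

    def score(pairs):
        s = sum(mat.get_score(seq_a[i], seq_b[j]) for i, j in pairs)
        for seq, col in ((seq_a, 0), (seq_b, 1)):
            used = [p[col] for p in pairs]
            runs, prev = [], -1
            for u in used + [len(seq)]:
                gap = u - prev - 1
                if gap > 0:
                    runs.append(gap)
                prev = u
            s -= sum(open_pen + ext * (g - 1) for g in runs)
        return s

    best_score, best = -np.inf, []
    na, nb = len(seq_a), len(seq_b)
    for k in range(min(na, nb) + 1):
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.combinations(range(nb), k):
                pairs = tuple(zip(ia, ib))
                sc = score(pairs)
                if sc > best_score + 1e-9:
                    best_score, best = sc, [pairs]
                elif abs(sc - best_score) <= 1e-9:
                    best.append(pairs)
    return best_score, best


def test_identical_sequences_pair_identity():
    pr = pair_residues("MKVLATG", "MKVLATG")
    assert pr.pairs == tuple((i, i) for i in range(7))


def test_single_deletion_toy_matches_exhaustive_oracle():
    _, best = _brute_force_best_pairings("ACDEFG", "ACEFG")
    pr = pair_residues("ACDEFG", "ACEFG")
    assert len(pr.pairs) == 5
    assert pr.pairs == ((0, 0), (1, 1), (3, 2), (4, 3), (5, 4))  # D skipped
    assert pr.pairs in best


def test_pairing_symmetry_mirrored():
    fwd = pair_residues("ACDEFG", "ACEFG")
    rev = pair_residues("ACEFG", "ACDEFG")
    assert rev.pairs == tuple((j, i) for i, j in fwd.pairs)
    assert rev.alignment_score == fwd.alignment_score


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pair_residues("", "ACD")


# --- Kabsch ----------------------------------------------------------------


@pytest.fixture(scope="module")
def cloud():
    rng = np.random.default_rng(7)
    return rng.normal(size=(60, 3)) * 8.0


def test_kabsch_self_is_identity(cloud):
    res = kabsch(cloud, cloud)
    assert res.rmsd < 1e-12
    assert np.allclose(res.transform.R, np.eye(3), atol=1e-10)


def test_kabsch_recovers_known_transform(cloud):
    T = RigidTransform.from_axis_angle([2.0, -1.0, 0.5], 25.0, translation=[3.0, -7.0, 11.0])
    res = kabsch(cloud, T.apply(cloud))
    assert res.rmsd < 1e-9
    assert np.allclose(res.transform.R, T.R, atol=1e-9)
    assert np.allclose(res.transform.t, T.t, atol=1e-8)


def test_kabsch_agrees_with_scipy(cloud):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(1)
    noisy = cloud + rng.normal(scale=0.5, size=cloud.shape)
    T = RigidTransform.from_axis_angle([1, 1, 1], 40.0, translation=[1, 2, 3])
    target = T.apply(noisy)
    res = kabsch(cloud, target)
    rot, rssd = Rotation.align_vectors(target - target.mean(0), cloud - cloud.mean(0))
    assert np.allclose(res.transform.R, rot.as_matrix(), atol=1e-8)
    assert np.isclose(res.rmsd, rssd / np.sqrt(len(cloud)), atol=1e-8)


def test_kabsch_mirror_returns_proper_rotation(cloud):
    mirrored = cloud * np.array([1.0, 1.0, -1.0])
    res = kabsch(cloud, mirrored)
    assert np.isclose(np.linalg.det(res.transform.R), 1.0, atol=1e-9)
    assert res.rmsd > 0.1


def test_kabsch_degenerate_inputs():
    with pytest.raises(ValueError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.stack([np.arange(5.0)] * 3, axis=1)  # collinear
    with pytest.raises(ValueError):
        kabsch(line, line)


# --- superpose with rejection ---------------------------------------------


def _ca_structure(coords, id="x"):
    cycle = "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
    atoms = [
        Atom("A", i + 1, cycle[i % 20], "CA", "C", tuple(map(float, xyz)))
        for i, xyz in enumerate(coords)
    ]
    return Structure(atoms, id=id)


def test_rejection_removes_displaced_atoms():
    rng = np.random.default_rng(11)
    base = rng.normal(size=(100, 3)) * 9.0
    moved = base.copy()
    bad = rng.choice(100, size=10, replace=False)
    moved[bad] += rng.normal(size=(10, 3)) * 10.0 + 5.0
    res = superpose(_ca_structure(base), _ca_structure(moved), cycles=5)
    assert res.rmsd < 0.05
    assert res.n_retained_pairs <= 100 - len(bad) + 2
    assert res.n_input_pairs == 100


def test_rejection_never_increases_rmsd():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(80, 3)) * 9.0
    noisy = base + rng.normal(scale=0.8, size=base.shape)
    prev = np.inf
    for cycles in range(0, 6):
        res = superpose(_ca_structure(base), _ca_structure(noisy), cycles=cycles, cutoff=1.5)
        assert res.rmsd <= prev + 1e-12
        prev = res.rmsd


def test_rmsd_invariant_under_rigid_pretransform(closed_synth):
    closed, domains = closed_synth
    moved = perturb_conformation(closed, domains, SynthSpec(seed=3, applied_angle=20.0, noise_sigma=0.2))
    r0 = superpose(closed, moved, cycles=0).rmsd
    T = RigidTransform.from_axis_angle([0, 1, 0], 63.0, translation=[10, 20, -5])
    from ftszkit.structio import apply_transform

    r1 = superpose(apply_transform(closed, T), moved, cycles=0).rmsd
    r2 = superpose(closed, apply_transform(moved, T), cycles=0).rmsd
    assert np.isclose(r0, r1, atol=1e-8)
    assert np.isclose(r0, r2, atol=1e-8)


# --- rmsd matrix -----------------------------------------------------------


def test_rmsd_matrix_consistency_and_symmetry(closed_synth):
    closed, domains = closed_synth
    confs = {
        "ref": closed,
        "a15": perturb_conformation(closed, domains, SynthSpec(seed=3, applied_angle=15.0)),
        "a30n": perturb_conformation(closed, domains, SynthSpec(seed=3, applied_angle=30.0, noise_sigma=0.3)),
    }
    M = rmsd_matrix(confs, rejection_cycles=0)
    assert np.allclose(np.diag(M.to_numpy()), 0.0)
    assert np.allclose(M.to_numpy(), M.to_numpy().T, atol=1e-6)
    for i, j in itertools.permutations(confs, 2):
        direct = superpose(confs[i], confs[j], cycles=0).rmsd
        assert np.isclose(M.loc[i, j], direct, atol=1e-9)
    with pytest.raises(ValueError):
        rmsd_matrix({"only": closed})
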