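"""Stochastic kinetics of a single-stranded, tubulin-like filament.

The model formalizes the consequence of a polymerization-associated
conformational switch for filament dynamics.  Subunits carry one
nucleotide (T = triphosphate, D = diphosphate) on their top (plus-side)
face; the nucleotide of subunit i forms part of the interface with
subunit i+1, tubulin-fashion.  Free monomers sit in the closed
conformation; polymerized subunits are open.  Energies are in kT and
concentrations in units of a reference concentration c0 = 1, so the
rate table is fully determined by a handful of dimensionless numbers:

* association at an end:      k_on * c        (times ``end_asymmetry``
  at the structurally distinguished end — the switch makes the two
  addition pathways stereochemically different, so their rates may
  differ; the rigid variant forces the factor to 1),
* subunit loss from an end over an X interface:
                              k_on * c0 * exp(dG_X + dG_switch)
  — the departing subunit relaxes to the closed monomer form, and that
  favorable switch pays part of the interface cost, making end loss
  fast,
* breakage of an internal X interface:
                              k_on * c0 * exp(dG_X)
  — the newly exposed end subunits remain in the filament and cannot
  switch, so internal interfaces are effectively stronger than
  terminal ones by exp(dG_switch),
* dimer nucleation: association scaled by exp(-dG_switch) relative to
  elongation — elongation pays one closed->open switch against one new
  interface, dimerization pays two switches for one interface, so the
  nucleation equilibrium constant is weaker than the elongation
  constant by the Oosawa-type factor sigma = exp(-dG_switch); this is
  what makes assembly cooperative, with critical concentration
  c_crit = c0 * exp(dG_interface_T + dG_switch),
* hydrolysis at k_hyd per buried T nucleotide (only formed interfaces
  complete the composite active site), and nucleotide exchange D->T at
  k_exch per solvent-exposed D.

With dG_switch = 0 and end_asymmetry = 1 the model reduces to the
rigid-subunit filament, for which breakage of a terminal interface and
of any internal interface proceed at exactly the same rate and no
robust treadmilling is possible.

Trajectories are exact realizations of the continuous-time Markov
jump process (Gillespie direct method).  For small closed systems the
full generator can be enumerated and solved, providing an independent
stationary-distribution oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SimParams",
    "SimState",
    "Trajectory",
    "RateTable",
    "build_rates",
    "run_ssa",
    "exact_stationary_small",
    "measure_treadmilling",
    "mass_curve",
    "breakage_vs_endloss",
    "equilibrium_mass_fraction",
    "isodesmic_length_distribution",
    "critical_concentration",
    "estimate_onset",
]

T, D = 1, 0  # nucleotide codes


@dataclass(frozen=True)
class SimParams:
    """Reduced-unit parameters of the filament model (energies in kT,
    concentrations in c0, rates in 1/s or 1/(c0 s))."""

    variant: str = "switch"  # "switch" or "rigid"
    k_on: float = 1.0
    end_asymmetry: float = 1.0
    asymmetric_end: str = "plus"  # which end the asymmetry factor multiplies
    dG_interface_T: float = -7.0
    dG_interface_D: float = -2.0
    dG_switch: float = 2.0
    k_hyd: float = 0.0
    k_exch: float = 10.0
    mode: str = "closed_system"  # or "fixed_monomer"
    c_total: float = 1.0  # closed_system: total subunit concentration
    n_total: int = 100  # closed_system: subunit count (sets the volume)
    c_free: float = 0.2  # fixed_monomer: bath concentration of T monomers
    init_filament_length: int = 0  # seed filament (fixed_monomer runs)
    init_nucleotide: str = "T"
    exchange_in_filament: bool = True
    allow_annealing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("switch", "rigid"):
            raise ValueError("variant must be 'switch' or 'rigid'")
        if self.variant == "rigid" and (self.dG_switch != 0.0 or self.end_asymmetry != 1.0):
            raise ValueError("the rigid variant requires dG_switch = 0 and end_asymmetry = 1")
        for name in ("k_on", "k_hyd", "k_exch", "end_asymmetry", "c_total", "c_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dG_switch < 0:
            raise ValueError("dG_switch must be >= 0 (closed monomer is the relaxed form)")
        if self.asymmetric_end not in ("plus", "minus"):
            raise ValueError("asymmetric_end must be 'plus' or 'minus'")
        if self.mode not in ("closed_system", "fixed_monomer"):
            raise ValueError("mode must be 'closed_system' or 'fixed_monomer'")

    @staticmethod
    def rigid(**kw) -> "SimParams":
        kw.setdefault("dG_switch", 0.0)
        kw.setdefault("end_asymmetry", 1.0)
        return SimParams(variant="rigid", **kw)

    @property
    def volume(self) -> float:
        """Closed-system volume in units of 1/c0."""
        if self.c_total <= 0:
            raise ValueError("c_total must be positive in closed_system mode")
        return self.n_total / self.c_total


@dataclass(frozen=True)
class RateTable:
    """Elementary rates implied by a :class:`SimParams` (c0 = 1)."""

    assoc_plus: float  # 1/(c0 s): multiply by free T concentration
    assoc_minus: float
    k_off_end: tuple[float, float]  # indexed by nucleotide code (D, T)
    k_break: tuple[float, float]
    k_nucleation: float  # macroscopic dimerization constant, 1/(c0 s)
    k_hyd: float
    k_exch: float

    def off_end(self, nuc: int) -> float:
        return self.k_off_end[nuc]

    def brk(self, nuc: int) -> float:
        return self.k_break[nuc]


def build_rates(params: SimParams) -> RateTable:
    """Detailed-balance-consistent rate table.

    The elongation equilibrium constant is exp(-dG_X - dG_switch)/c0,
    so the critical concentration of an end over T interfaces is
    c0 * exp(dG_interface_T + dG_switch).  Breakage omits the switch
    payoff; with dG_switch = 0 (rigid) it equals end loss exactly.
    """
    p = params
    asym_p = p.end_asymmetry if p.asymmetric_end == "plus" else 1.0
    asym_m = p.end_asymmetry if p.asymmetric_end == "minus" else 1.0
    off = {X: p.k_on * math.exp(dg + p.dG_switch) for X, dg in ((T, p.dG_interface_T), (D, p.dG_interface_D))}
    brk = {X: p.k_on * math.exp(dg) for X, dg in ((T, p.dG_interface_T), (D, p.dG_interface_D))}
    # Dimerization flux lambda*c^2 with lambda = (sum of the two
    # addition channels) * exp(-dG_switch): a monomer pair can join
    # through either face, so the per-step association constant matches
    # two-ended elongation and the dG_switch = 0 limit is exactly
    # isodesmic (same K at every step, dimer included).
    return RateTable(
        assoc_plus=p.k_on * asym_p,
        assoc_minus=p.k_on * asym_m,
        k_off_end=(off[D], off[T]),
        k_break=(brk[D], brk[T]),
        k_nucleation=p.k_on * (asym_p + asym_m) * math.exp(-p.dG_switch),
        k_hyd=p.k_hyd,
        k_exch=p.k_exch,
    )


# ---------------------------------------------------------------------------
# state


@dataclass
class SimState:
    """Filament lattice state.

    Each filament is a list of nucleotide codes ordered minus -> plus;
    subunit i's nucleotide forms interface i (with subunit i+1), and
    the plus-end subunit's nucleotide is solvent exposed.  Polymerized
    subunits are in the open conformation, free monomers closed (in the
    switch variant); this is implied by position and not stored.
    """

    filaments: dict[int, list[int]] = field(default_factory=dict)
    free_T: int = 0
    free_D: int = 0
    time: float = 0.0
    next_id: int = 0

    def copy(self) -> "SimState":
        return SimState(
            filaments={k: list(v) for k, v in self.filaments.items()},
            free_T=self.free_T,
            free_D=self.free_D,
            time=self.time,
            next_id=self.next_id,
        )

    def polymer_mass(self) -> int:
        return sum(len(f) for f in self.filaments.values())

    def total_subunits(self) -> int:
        return self.polymer_mass() + self.free_T + self.free_D

    def canonical(self) -> tuple[tuple[int, ...], ...]:
        """Order-free fingerprint of the filament population (sorted
        tuples of nucleotide sequences) — used for occupancy
        histograms against the enumeration oracle."""
        return tuple(sorted(tuple(f) for f in self.filaments.values()))

    def canonical_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(len(f) for f in self.filaments.values()))


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    filament_id: int
    position: int


@dataclass
class Trajectory:
    """Event log, periodic observables and exposure bookkeeping of one
    SSA realization."""

    params: SimParams
    seed: int
    events: list[Event]
    obs_time: np.ndarray
    obs_polymer: np.ndarray
    obs_n_filaments: np.ndarray
    obs_free_T: np.ndarray
    obs_free_D: np.ndarray
    exposures: dict[str, float]
    counts: dict[str, int]
    occupancy: dict | None
    final_state: SimState
    t_end: float
    termination: str


def _initial_state(params: SimParams) -> SimState:
    st = SimState()
    nuc = T if params.init_nucleotide == "T" else D
    if params.init_filament_length >= 2:
        st.filaments[0] = [nuc] * params.init_filament_length
        st.next_id = 1
    if params.mode == "closed_system":
        st.free_T = params.n_total - params.init_filament_length
        if st.free_T < 0:
            raise ValueError("init_filament_length exceeds n_total")
    return st


def total_propensity(params: SimParams, state: SimState) -> float:
    rates = build_rates(params)
    a, _ = _propensities(params, rates, state)
    return float(sum(x for x, _ in a))


def _propensities(params: SimParams, rates: RateTable, state: SimState):
    """List of (propensity, action tag) plus exposure counts.

    Action tags are (kind, filament_id) tuples resolved at execution
    time; exposure counts feed the breakage-vs-end-loss bookkeeping.
    """
    chans: list[tuple[float, tuple]] = []
    if params.mode == "closed_system":
        V = params.volume
        cT = state.free_T / V
    else:
        V = None
        cT = params.c_free
    n_term_D = n_term_T = n_int_D = n_int_T = 0
    for fid, f in state.filaments.items():
        L = len(f)
        chans.append((rates.assoc_plus * cT, ("assoc_plus", fid)))
        chans.append((rates.assoc_minus * cT, ("assoc_minus", fid)))
        plus_iface = f[L - 2]
        minus_iface = f[0]
        chans.append((rates.off_end(plus_iface), ("dissoc_plus", fid)))
        chans.append((rates.off_end(minus_iface), ("dissoc_minus", fid)))
        n_term_D += (plus_iface == D) + (minus_iface == D)
        n_term_T += (plus_iface == T) + (minus_iface == T)
        if L >= 4:
            internal = f[1 : L - 2]  # interfaces 1 .. L-3
            nT = sum(internal)
            nD = len(internal) - nT
            n_int_T += nT
            n_int_D += nD
            if nT:
                chans.append((rates.brk(T) * nT, ("break", fid, T)))
            if nD:
                chans.append((rates.brk(D) * nD, ("break", fid, D)))
        if rates.k_hyd > 0:
            buried_T = sum(f[: L - 1])
            if buried_T:
                chans.append((rates.k_hyd * buried_T, ("hydrolysis", fid)))
        if params.exchange_in_filament and rates.k_exch > 0 and f[L - 1] == D:
            chans.append((rates.k_exch, ("exchange", fid)))
    if params.mode == "closed_system":
        if state.free_T >= 2 and rates.k_nucleation > 0:
            chans.append(
                (rates.k_nucleation * state.free_T * (state.free_T - 1) / V, ("nucleation",))
            )
        if state.free_D > 0 and rates.k_exch > 0:
            chans.append((rates.k_exch * state.free_D, ("exchange_free",)))
        if params.allow_annealing and len(state.filaments) >= 2:
            fids = list(state.filaments)
            npairs = len(fids) * (len(fids) - 1)
            chans.append((params.k_on / V * npairs, ("anneal",)))
    exposures = {
        "terminal_D": float(n_term_D),
        "terminal_T": float(n_term_T),
        "internal_D": float(n_int_D),
        "internal_T": float(n_int_T),
    }
    return chans, exposures


def run_ssa(
    params: SimParams,
    t_max: float,
    seed: int | None = None,
    max_events: int | None = None,
    snapshot_interval: float | None = None,
    track_occupancy: bool = False,
    log_events: bool = True,
    initial_state: SimState | None = None,
) -> Trajectory:
    """Exact stochastic simulation (Gillespie direct method).

    Reproducible for a fixed seed: identical parameters and seed give
    bit-identical event logs.  Terminates at ``t_max``, after
    ``max_events`` events, or cleanly when no reaction has positive
    propensity.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    p = params
    seed = p.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rates = build_rates(p)
    state = _initial_state(p) if initial_state is None else initial_state.copy()
    n_conserved = state.total_subunits()

    events: list[Event] = []
    snap_dt = snapshot_interval if snapshot_interval is not None else t_max / 200.0
    next_snap = 0.0
    obs: list[tuple[float, int, int, int, int]] = []
    exposures = {"terminal_D": 0.0, "terminal_T": 0.0, "internal_D": 0.0, "internal_T": 0.0}
    counts = {
        "endloss_D": 0, "endloss_T": 0, "break_D": 0, "break_T": 0,
        "assoc_plus": 0, "assoc_minus": 0, "dissoc_plus": 0, "dissoc_minus": 0,
        "hydrolysis": 0, "exchange": 0, "nucleation": 0, "anneal": 0,
    }
    occupancy: dict | None = {} if track_occupancy else None
    termination = "t_max"
    n_events = 0

    def snapshot(t: float) -> None:
        obs.append((t, state.polymer_mass(), len(state.filaments), state.free_T, state.free_D))

    while True:
        while next_snap <= state.time + 1e-15 and next_snap <= t_max:
            snapshot(next_snap)
            next_snap += snap_dt
        chans, expo = _propensities(p, rates, state)
        A = sum(a for a, _ in chans)
        if A <= 0.0:
            dt_rest = t_max - state.time
            for k in exposures:
                exposures[k] += expo[k] * dt_rest
            if occupancy is not None:
                key = state.canonical()
                occupancy[key] = occupancy.get(key, 0.0) + dt_rest
            state.time = t_max
            termination = "no_reactions"
            break
        dt = rng.exponential(1.0 / A)
        if state.time + dt > t_max:
            dt_rest = t_max - state.time
            for k in exposures:
                exposures[k] += expo[k] * dt_rest
            if occupancy is not None:
                key = state.canonical()
                occupancy[key] = occupancy.get(key, 0.0) + dt_rest
            state.time = t_max
            break
        for k in exposures:
            exposures[k] += expo[k] * dt
        if occupancy is not None:
            key = state.canonical()
            occupancy[key] = occupancy.get(key, 0.0) + dt
        state.time += dt
        r = rng.random() * A
        acc = 0.0
        chosen = chans[-1][1]
        for a, tag in chans:
            acc += a
            if r <= acc:
                chosen = tag
                break
        _execute(p, state, rng, chosen, counts, events if log_events else None)
        n_events += 1
        if p.mode == "closed_system" and state.total_subunits() != n_conserved:
            raise AssertionError("subunit conservation violated")  # pragma: no cover
        if max_events is not None and n_events >= max_events:
            termination = "max_events"
            break

    while next_snap <= t_max + 1e-12:
        snapshot(min(next_snap, t_max))
        next_snap += snap_dt
    arr = np.array(obs, dtype=float).reshape(-1, 5)
    return Trajectory(
        params=p,
        seed=seed,
        events=events,
        obs_time=arr[:, 0],
        obs_polymer=arr[:, 1],
        obs_n_filaments=arr[:, 2],
        obs_free_T=arr[:, 3],
        obs_free_D=arr[:, 4],
        exposures=exposures,
        counts=counts,
        occupancy=occupancy,
        final_state=state,
        t_end=state.time,
        termination=termination,
    )


def _return_monomer(p: SimParams, state: SimState, nuc: int) -> None:
    if p.mode == "closed_system":
        if nuc == T:
            state.free_T += 1
        else:
            state.free_D += 1
    # fixed_monomer: the bath absorbs it


def _take_monomer(p: SimParams, state: SimState) -> None:
    if p.mode == "closed_system":
        state.free_T -= 1


def _execute(p, state: SimState, rng, tag, counts, events) -> None:
    kind = tag[0]
    t = state.time
    fid = tag[1] if len(tag) > 1 and kind != "nucleation" else -1

    def log(kind: str, fid: int, pos: int) -> None:
        if events is not None:
            events.append(Event(time=t, kind=kind, filament_id=fid, position=pos))

    if kind == "assoc_plus":
        f = state.filaments[fid]
        f.append(T)
        _take_monomer(p, state)
        counts["assoc_plus"] += 1
        log(kind, fid, len(f) - 1)
    elif kind == "assoc_minus":
        f = state.filaments[fid]
        f.insert(0, T)
        _take_monomer(p, state)
        counts["assoc_minus"] += 1
        log(kind, fid, 0)
    elif kind in ("dissoc_plus", "dissoc_minus"):
        f = state.filaments[fid]
        L = len(f)
        iface = f[L - 2] if kind == "dissoc_plus" else f[0]
        counts["endloss_T" if iface == T else "endloss_D"] += 1
        counts[kind] += 1
        if L == 2:
            _return_monomer(p, state, f[0])
            _return_monomer(p, state, f[1])
            del state.filaments[fid]
            log(kind, fid, 0)
        elif kind == "dissoc_plus":
            nuc = f.pop()
            _return_monomer(p, state, nuc)
            log(kind, fid, L - 1)
        else:
            nuc = f.pop(0)
            _return_monomer(p, state, nuc)
            log(kind, fid, 0)
    elif kind == "break":
        which = tag[2]
        f = state.filaments[fid]
        L = len(f)
        idxs = [j for j in range(1, L - 2) if f[j] == which]
        j = idxs[rng.integers(len(idxs))]
        left, right = f[: j + 1], f[j + 1 :]
        counts["break_T" if which == T else "break_D"] += 1
        # the larger fragment keeps the filament id (tie -> minus side),
        # so per-filament end bookkeeping follows the dominant piece
        if len(left) >= len(right):
            state.filaments[fid] = left
            state.filaments[state.next_id] = right
        else:
            state.filaments[fid] = right
            state.filaments[state.next_id] = left
        state.next_id += 1
        log(kind, fid, j)
    elif kind == "hydrolysis":
        f = state.filaments[fid]
        idxs = [j for j in range(len(f) - 1) if f[j] == T]
        j = idxs[rng.integers(len(idxs))]
        f[j] = D
        counts["hydrolysis"] += 1
        log(kind, fid, j)
    elif kind == "exchange":
        f = state.filaments[fid]
        f[-1] = T
        counts["exchange"] += 1
        log(kind, fid, len(f) - 1)
    elif kind == "exchange_free":
        state.free_D -= 1
        state.free_T += 1
        counts["exchange"] += 1
        log(kind, -1, -1)
    elif kind == "nucleation":
        state.free_T -= 2
        state.filaments[state.next_id] = [T, T]
        counts["nucleation"] += 1
        log(kind, state.next_id, 0)
        state.next_id += 1
    elif kind == "anneal":
        fids = list(state.filaments)
        i = int(rng.integers(len(fids)))
        j = int(rng.integers(len(fids) - 1))
        if j >= i:
            j += 1
        a, b = fids[i], fids[j]
        state.filaments[a] = state.filaments[a] + state.filaments[b]
        del state.filaments[b]
        counts["anneal"] += 1
        log(kind, a, -1)
    else:  # pragma: no cover
        raise RuntimeError(f"unknown event kind {kind}")


# ---------------------------------------------------------------------------
# exact CTMC oracle (small closed systems, no hydrolysis)


def _enumerate_states(n_total: int) -> list[tuple[int, ...]]:
    """All canonical states of a closed all-T system: sorted tuples of
    filament lengths (each >= 2) with total <= n_total; free monomers
    make up the difference."""
    states: list[tuple[int, ...]] = []

    def rec(prefix: list[int], remaining: int, min_len: int) -> None:
        states.append(tuple(prefix))
        for L in range(min_len, remaining + 1):
            rec(prefix + [L], remaining - L, L)

    rec([], n_total, 2)
    return sorted(set(states))


def exact_stationary_small(params: SimParams, n_total: int | None = None, cap: int = 12) -> dict[tuple[int, ...], float]:
    """Stationary distribution of the full CTMC by linear solve.

    Only closed systems without hydrolysis are enumerable here (the
    nucleotide state is then constant all-T and a state is the multiset
    of filament lengths).  Returns canonical state -> probability.
    """
    p = params
    if p.mode != "closed_system":
        raise ValueError("exact enumeration requires closed_system mode")
    if p.k_hyd != 0:
        raise ValueError("exact enumeration supports k_hyd = 0 only")
    n = p.n_total if n_total is None else n_total
    if n > cap:
        raise ValueError(f"state space for n_total={n} exceeds cap {cap}")
    if n_total is not None:
        p = replace(p, n_total=n_total)
    rates = build_rates(p)
    V = p.volume
    states = _enumerate_states(p.n_total)
    index = {s: k for k, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))

    def add(src: tuple[int, ...], dst_list: list[int], rate: float) -> None:
        dst = tuple(sorted(dst_list))
        Q[index[src], index[dst]] += rate

    for s in states:
        m = p.n_total - sum(s)
        lengths = list(s)
        if m >= 2 and rates.k_nucleation > 0:
            add(s, lengths + [2], rates.k_nucleation * m * (m - 1) / V)
        for i, L in enumerate(lengths):
            rest = lengths[:i] + lengths[i + 1 :]
            if m >= 1:
                add(s, rest + [L + 1], (rates.assoc_plus + rates.assoc_minus) * m / V)
            if L == 2:
                add(s, rest, 2 * rates.off_end(T))
            else:
                add(s, rest + [L - 1], 2 * rates.off_end(T))
            for j in range(1, L - 2):
                add(s, rest + [j + 1, L - j - 1], rates.brk(T))
        if p.allow_annealing and len(lengths) >= 2:
            for i, j in itertools.permutations(range(len(lengths)), 2):
                if i < j:
                    rest = [lengths[k] for k in range(len(lengths)) if k not in (i, j)]
                    add(s, rest + [lengths[i] + lengths[j]], 2 * p.k_on / V)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # stationary distribution: pi Q = 0, sum pi = 1
    Amat = np.vstack([Q.T, np.ones(len(states))])
    bvec = np.zeros(len(states) + 1)
    bvec[-1] = 1.0
    pi, *_ = np.linalg.lstsq(Amat, bvec, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return {s: float(v) for s, v in zip(states, pi)}


# ---------------------------------------------------------------------------
# observables


def measure_treadmilling(
    trajectory: Trajectory,
    filament_id: int | None = None,
    n_blocks: int = 20,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Treadmilling velocity of one filament, subunits per unit time.

    Velocity is (net additions at the plus end - net additions at the
    minus end)/2 per unit time; for a treadmilling filament at steady
    state this is the drift speed of the filament body.  The confidence
    interval is a block bootstrap over equal time blocks of the
    filament's lifetime.
    """
    events = trajectory.events
    if filament_id is None:
        # default: the filament that lived longest (usually the seed)
        lifetime: dict[int, list[float]] = {}
        for e in events:
            lifetime.setdefault(e.filament_id, [e.time, e.time])
            lifetime[e.filament_id][1] = e.time
        if trajectory.final_state.filaments:
            for fid in trajectory.final_state.filaments:
                if fid in lifetime:
                    lifetime[fid][1] = trajectory.t_end
                else:
                    lifetime[fid] = [0.0, trajectory.t_end]
        if not lifetime:
            filament_id = 0
        else:
            filament_id = max(lifetime, key=lambda k: lifetime[k][1] - lifetime[k][0])
    fe = [e for e in events if e.filament_id == filament_id]
    t0 = 0.0
    t1 = trajectory.t_end if filament_id in trajectory.final_state.filaments else (fe[-1].time if fe else 0.0)
    if t1 <= t0:
        raise ValueError("no surviving filament epoch to measure")
    delta = {"assoc_plus": (1, 0), "dissoc_plus": (-1, 0), "assoc_minus": (0, 1), "dissoc_minus": (0, -1)}
    edges = np.linspace(t0, t1, n_blocks + 1)
    plus = np.zeros(n_blocks)
    minus = np.zeros(n_blocks)
    for e in fe:
        if e.kind not in delta:
            continue
        b = min(n_blocks - 1, int(np.searchsorted(edges, e.time, side="right")) - 1)
        dp, dm = delta[e.kind]
        plus[b] += dp
        minus[b] += dm
    block_dt = (t1 - t0) / n_blocks
    v_blocks = (plus - minus) / (2 * block_dt)
    velocity = float(v_blocks.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n_blocks, size=n_blocks)
        boots[k] = v_blocks[idx].mean()
    lo, hi = np.percentile(boots, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
    return {
        "filament_id": filament_id,
        "velocity": velocity,
        "ci": (float(lo), float(hi)),
        "plus_flux": float(plus.sum() / (t1 - t0)),
        "minus_flux": float(minus.sum() / (t1 - t0)),
        "duration": float(t1 - t0),
    }


def breakage_vs_endloss(trajectory: Trajectory, ci_level: float = 0.95) -> dict:
    """Per-interface-time breakage rate of internal D interfaces
    relative to the end-loss rate over terminal D interfaces.

    The rate construction forces this ratio to exp(-dG_switch); the
    measurement verifies it empirically.  CI is a log-normal Poisson
    ratio interval.
    """
    nb = trajectory.counts["break_D"]
    ne = trajectory.counts["endloss_D"]
    tb = trajectory.exposures["internal_D"]
    te = trajectory.exposures["terminal_D"]
    if tb <= 0 or te <= 0:
        raise ValueError("zero exposure time for internal or terminal D interfaces")
    if ne == 0:
        raise ValueError("no end-loss events over D interfaces; ratio undefined")
    from scipy.stats import norm

    z = norm.ppf(0.5 + ci_level / 2)
    rate_b = nb / tb
    rate_e = ne / te
    if nb == 0:
        upper = (z**2 / 2 + z * math.sqrt(z**2 / 4)) / tb  # ~ 1.92/tb at 95%
        return {"ratio": 0.0, "ci": (0.0, float(upper / rate_e)), "n_break": 0, "n_endloss": ne}
    ratio = rate_b / rate_e
    se_log = math.sqrt(1.0 / nb + 1.0 / ne)
    return {
        "ratio": float(ratio),
        "ci": (float(ratio * math.exp(-z * se_log)), float(ratio * math.exp(z * se_log))),
        "n_break": nb,
        "n_endloss": ne,
    }


# ---------------------------------------------------------------------------
# equilibrium closed forms and the mass curve


def equilibrium_mass_fraction(c_total: float, dG_interface: float, dG_switch: float = 0.0) -> float:
    """Equilibrium polymerized mass fraction of the infinite-volume
    model: elongation constant K = exp(-dG_interface - dG_switch), and
    dimer nucleation weakened by sigma = exp(-dG_switch).

    sigma = 1 (dG_switch = 0) is the isodesmic limit; sigma << 1 gives
    nucleation–elongation behavior with a critical concentration
    c_crit = 1/K = exp(dG_interface + dG_switch).
    """
    if c_total <= 0:
        return 0.0
    K = math.exp(-dG_interface - dG_switch)
    sigma = math.exp(-dG_switch)

    def total_minus_target(c1: float) -> float:
        x = K * c1
        if x >= 1.0:
            return float("inf")
        # species of length L >= 2 have concentration (sigma/K) x^L;
        # subunit count sum: sum_{L>=2} L x^L = x^2 (2 - x)/(1-x)^2
        poly = (sigma / K) * x**2 * (2 - x) / (1 - x) ** 2
        return c1 + poly - c_total

    hi = min(c_total, (1.0 - 1e-12) / K)
    if total_minus_target(hi) < 0:
        c1 = hi
    else:
        c1 = brentq(total_minus_target, 0.0, hi, xtol=1e-14, rtol=1e-12)
    return max(0.0, 1.0 - c1 / c_total)


def isodesmic_length_distribution(c_total: float, dG_interface: float, max_len: int = 200) -> np.ndarray:
    """Equilibrium number distribution over species length 1..max_len
    for the isodesmic model (geometric in K*c1), normalized over the
    returned range."""
    K = math.exp(-dG_interface)

    def f(c1: float) -> float:
        x = K * c1
        return c1 / (1 - x) ** 2 - c_total

    c1 = brentq(f, 0.0, min(c_total, (1 - 1e-12) / K), xtol=1e-14)
    x = K * c1
    L = np.arange(1, max_len + 1)
    dist = x ** (L - 1)
    return dist / dist.sum()


def critical_concentration(params: SimParams, end: str = "plus") -> float:
    """Concentration at which net growth at the given end stalls over T
    interfaces: c_crit = c0 exp(dG_T + dG_switch) / asymmetry(end)."""
    rates = build_rates(params)
    on = rates.assoc_plus if end == "plus" else rates.assoc_minus
    return rates.off_end(T) / on


def mass_curve(
    params: SimParams,
    c_grid: Iterable[float],
    t_eq: float,
    replicates: int = 3,
    seed: int = 0,
    max_events: int | None = None,
    snapshot_interval: float | None = None,
):
    """Equilibrated polymer mass fraction versus total concentration.

    For each concentration, closed-system SSA replicates are run to
    ``t_eq``; the mass fraction is averaged over the final half of the
    trajectory and over replicates.  Also reports the time to reach
    half the plateau (a lag-phase proxy: sigmoidal, cooperative
    assembly reaches half-plateau late relative to isodesmic assembly)
    and a drift flag comparing the 3rd and 4th quarters.
    """
    import pandas as pd

    if params.mode != "closed_system":
        raise ValueError("mass_curve requires closed_system mode")
    rows = []
    for ci, c in enumerate(c_grid):
        if c == 0:
            rows.append({"c_total": 0.0, "mass_fraction": 0.0, "sem": 0.0, "t_half": 0.0, "equilibrated": True})
            continue
        p = replace(params, c_total=float(c))
        fracs, t_halves, drift_ok = [], [], True
        for r in range(replicates):
            traj = run_ssa(p, t_max=t_eq, seed=seed + 1000 * ci + r, log_events=False,
                           max_events=max_events, snapshot_interval=snapshot_interval)
            mass = traj.obs_polymer / p.n_total
            tarr = traj.obs_time
            half2 = mass[tarr >= t_eq / 2]
            fracs.append(float(half2.mean()))
            plateau = float(mass[tarr >= 0.75 * t_eq].mean())
            reached = np.flatnonzero(mass >= plateau / 2)
            t_halves.append(float(tarr[reached[0]]) if len(reached) else float("nan"))
            q3 = mass[(tarr >= 0.5 * t_eq) & (tarr < 0.75 * t_eq)]
            q4 = mass[tarr >= 0.75 * t_eq]
            se = float(np.sqrt(np.var(q3) / max(1, len(q3)) + np.var(q4) / max(1, len(q4))))
            if abs(q4.mean() - q3.mean()) > max(3 * se, 0.02):
                drift_ok = False
        rows.append(
            {
                "c_total": float(c),
                "mass_fraction": float(np.mean(fracs)),
                "sem": float(np.std(fracs) / math.sqrt(len(fracs))) if len(fracs) > 1 else 0.0,
                "t_half": float(np.nanmean(t_halves)),
                "equilibrated": drift_ok,
            }
        )
    return pd.DataFrame(rows)


def estimate_onset(curve, threshold: float = 0.2) -> float:
    """Critical-concentration estimate from a mass curve.

    Above the onset of cooperative assembly the free monomer
    concentration pins at c_crit, so c_total * (1 - mass_fraction)
    plateaus there; the estimate averages that plateau over points
    with mass fraction above ``threshold``.
    """
    df = curve[curve["mass_fraction"] > threshold]
    if len(df) < 2:
        raise ValueError("not enough points above threshold to estimate an onset")
    c1 = (df["c_total"] * (1.0 - df["mass_fraction"])).to_numpy()
    return float(c1.mean())
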