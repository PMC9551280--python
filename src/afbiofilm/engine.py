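"""Stochastic lattice engine for biofilm colonization.

The system is an expanding 1-D column of microhabitats.  Habitats 0..L-1
are in the strongly attached biofilm state (B); the edge habitat L is in
the loosely attached pre-biofilm state (A) and is the only habitat that
receives immigrants and loses microbes by detachment.  When the edge
population reaches the threshold N*, the edge flips to state B and a new
empty edge habitat is appended; the run ends when simulated time reaches
``t_max`` or the column would exceed ``L_max`` habitats.

Dynamics are advanced with a fixed-step tau-leaping scheme that cannot
produce negative populations: for every (habitat, ecotype) subpopulation
the number of microbes leaving during a leap is drawn as a binomial with
per-capita exit probability ``1 - exp(-r_exit * tau)`` (so exits never
exceed the population), and is then split among the exit channels (death,
detachment, migration left/right) in proportion to their rates.  Births
and immigration are Poisson draws.  All rates are evaluated at the start
of the leap (parallel update).

Internally the population is a dense (ecotype x habitat) count matrix
held in preallocated buffers.  Per-capita exit probabilities, birth
coefficients and migration fractions do not depend on the population, so
they are cached per (ecotype, habitat) and only recomputed when rows
(immigration) or columns (biofilm expansion) are added.  Extinct
ecotypes are compacted away periodically so the matrix stays small even
though a six-month run sees ~10^5 immigration events.

Two independent oracles are provided for validation: an exact Gillespie
simulation of the same event channels (:func:`ssa_reference_run`, small
systems only) and the single-habitat mean-field ODE
(:func:`mean_field_trajectory`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParams, pharmacodynamic_rate

__all__ = [
    "HabitatState",
    "EndReason",
    "SystemState",
    "Snapshot",
    "Trajectory",
    "init_state",
    "channel_rates",
    "step_tau_leap",
    "apply_transition",
    "run_simulation",
    "run_replicates",
    "replicate_rng",
    "seed_population",
    "mean_field_trajectory",
    "ssa_reference_run",
]

_COMPACT_EVERY = 25  # leaps between dead-row compactions

try:  # optional JIT acceleration of the establishment kernel
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speed-up
    _HAVE_NUMBA = False


class HabitatState(Enum):
    PRE_BIOFILM = "A"
    BIOFILM = "B"


class EndReason(Enum):
    TIME_CAP = "TIME_CAP"
    THICKNESS_CAP = "THICKNESS_CAP"
    ESTABLISHED = "ESTABLISHED"  # only when stop_at_establishment is set


class SystemState:
    """Mutable simulation state over live ecotypes (rows) x habitats (cols).

    The row arrays are stored in over-allocated buffers; the public
    ``counts``, ``mics``, ``ecotype_ids`` attributes expose views of the
    active slice.  Rows whose total count has dropped to zero may linger
    (all-zero) until the next compaction; they are statistically inert.
    """

    __slots__ = (
        "params", "t", "L", "next_ecotype_id", "leap_index",
        "_E", "_cap", "_counts", "_mics", "_ids",
        "_phi", "_p_exit", "_btau", "_mig_frac", "_left_share",
        "conc",
    )

    def __init__(self, params: ModelParams):
        self.params = params
        self.t = 0.0
        self.L = 0
        self.next_ecotype_id = 0
        self.leap_index = 0
        self.conc = np.array([params.concentration(0)])
        self._E = 0
        self._cap = 256
        self._alloc(self._cap, 1)

    # -- buffer management -------------------------------------------------

    def _alloc(self, cap: int, H: int) -> None:
        self._counts = np.zeros((cap, H), dtype=np.int64)
        self._mics = np.zeros(cap)
        self._ids = np.zeros(cap, dtype=np.int64)
        self._phi = np.zeros((cap, H))
        self._p_exit = np.zeros((cap, H))
        self._btau = np.zeros((cap, H))
        self._mig_frac = np.zeros((cap, H))
        self._left_share = _left_share(H)
        self._cap = cap

    def _grow(self, need: int) -> None:
        cap = self._cap
        while cap < need:
            cap *= 2
        old = (self._counts, self._mics, self._ids, self._phi,
               self._p_exit, self._btau, self._mig_frac)
        self._alloc(cap, self.n_habitats)
        E = self._E
        for new, prev in zip(
            (self._counts, self._mics, self._ids, self._phi,
             self._p_exit, self._btau, self._mig_frac),
            old,
        ):
            new[:E] = prev[:E]

    def _compact(self) -> None:
        E = self._E
        alive = self._counts[:E].any(axis=1)
        k = int(alive.sum())
        if k == E:
            return
        idx = np.flatnonzero(alive)
        for buf in (self._counts, self._mics, self._ids, self._phi,
                    self._p_exit, self._btau, self._mig_frac):
            buf[:k] = buf[idx]
        self._counts[k:E] = 0
        self._E = k

    def _append_rows(self, mics: np.ndarray) -> np.ndarray:
        """Add fresh ecotypes (count set by caller); returns their row slice."""
        k = len(mics)
        if self._E + k > self._cap:
            self._grow(self._E + k)
        sl = slice(self._E, self._E + k)
        self._mics[sl] = mics
        ids = np.arange(self.next_ecotype_id, self.next_ecotype_id + k)
        self._ids[sl] = ids
        self.next_ecotype_id += k
        self._fill_rate_rows(sl)
        self._counts[sl] = 0
        self._E += k
        return ids

    def _fill_rate_rows(self, rows: slice) -> None:
        """(Re)compute the cached rate rows from the current geometry."""
        p = self.params
        mics = self._mics[rows]
        phi = _phi_matrix(mics, self.conc, p.r_max)
        self._phi[rows] = phi
        exit_pc = p.d_uniform + np.maximum(-phi, 0.0)
        exit_pc[:, self.L] += p.r_det
        if self.n_habitats > 1 and p.r_mig > 0.0:
            exit_pc += p.r_mig
            self._mig_frac[rows] = p.r_mig / exit_pc
        else:
            self._mig_frac[rows] = 0.0
        self._p_exit[rows] = -np.expm1(-exit_pc * p.tau)
        self._btau[rows] = np.maximum(phi, 0.0) * p.tau

    def _add_habitat(self) -> None:
        """Append an empty edge habitat and rebuild geometry-bound caches."""
        self.L += 1
        H = self.L + 1
        self.conc = np.append(self.conc, self.params.concentration(self.L))
        E, cap = self._E, self._cap
        counts = np.zeros((cap, H), dtype=np.int64)
        counts[:E, : H - 1] = self._counts[:E]
        self._counts = counts
        for name in ("_phi", "_p_exit", "_btau", "_mig_frac"):
            setattr(self, name, np.zeros((cap, H)))
        self._left_share = _left_share(H)
        self._fill_rate_rows(slice(0, E))

    # -- public views ------------------------------------------------------

    @property
    def counts(self) -> np.ndarray:
        return self._counts[: self._E]

    @property
    def mics(self) -> np.ndarray:
        return self._mics[: self._E]

    @property
    def ecotype_ids(self) -> np.ndarray:
        return self._ids[: self._E]

    @property
    def n_habitats(self) -> int:
        return self.L + 1

    def habitat_state(self, i: int) -> HabitatState:
        return HabitatState.PRE_BIOFILM if i == self.L else HabitatState.BIOFILM

    def habitat_populations(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total_population(self) -> int:
        return int(self.counts.sum())

    def ecotype_registry(self) -> dict[int, float]:
        alive = self.counts.any(axis=1)
        return {
            int(i): float(m)
            for i, m, a in zip(self.ecotype_ids, self.mics, alive)
            if a
        }


def _left_share(H: int) -> np.ndarray:
    """Probability a migrant moves toward the surface, per habitat."""
    share = np.full(H, 0.5)
    share[0] = 0.0
    share[H - 1] = 1.0
    return share


def _phi_matrix(mics: np.ndarray, conc: np.ndarray, r_max: float) -> np.ndarray:
    u = (conc[None, :] / np.asarray(mics)[:, None]) ** 2
    return r_max * (1.0 - 6.0 * u / (5.0 + u))


@dataclass(frozen=True)
class Snapshot:
    """Sparse record of the live population at one instant."""

    t: float
    habitat: np.ndarray
    ecotype_id: np.ndarray
    mic: np.ndarray
    count: np.ndarray

    def pooled_counts(self) -> np.ndarray:
        """Per-ecotype abundances pooled over all habitats."""
        if len(self.ecotype_id) == 0:
            return np.zeros(0, dtype=np.int64)
        _, inv = np.unique(self.ecotype_id, return_inverse=True)
        return np.bincount(inv, weights=self.count).astype(np.int64)


@dataclass
class Trajectory:
    """Everything recorded from one simulation run."""

    params: ModelParams
    seed: int
    snapshots: list[Snapshot] = field(default_factory=list)
    addition_times: list[float] = field(default_factory=list)
    end_reason: EndReason | None = None
    end_time: float = 0.0
    final_L: int = 0
    replicate: int = 0

    @property
    def establishment_time(self) -> float | None:
        """First time habitat 0 reached N* (None if censored)."""
        return self.addition_times[0] if self.addition_times else None

    @property
    def censored(self) -> bool:
        return not self.addition_times


def init_state(params: ModelParams) -> SystemState:
    """One empty pre-biofilm habitat adjacent to the surface, at t = 0."""
    if not isinstance(params, ModelParams):
        raise TypeError("params must be a ModelParams")
    return SystemState(params)


def seed_population(
    state: SystemState, mic: float, count: int, habitat: int | None = None
) -> int:
    """Insert ``count`` microbes of a fresh ecotype with the given MIC.

    Mainly for controlled experiments (oracle comparisons, pure-death
    checks); the colonization model itself only introduces microbes via
    immigration.  Returns the new ecotype id.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if mic <= 0:
        raise ValueError("mic must be > 0")
    h = state.L if habitat is None else habitat
    if not 0 <= h <= state.L:
        raise ValueError(f"habitat {h} does not exist")
    ids = state._append_rows(np.array([float(mic)]))
    state._counts[state._E - 1, h] = count
    return int(ids[0])


def channel_rates(state: SystemState, params: ModelParams) -> dict:
    """Per-capita rates for every (ecotype, habitat) subpopulation.

    Returns arrays shaped like ``state.counts``: ``birth`` (logistic-
    throttled growth), ``death`` (uniform mortality plus biocide
    killing), ``migration`` (zero when a habitat has no neighbour),
    ``detachment`` (edge column only), plus the scalar ``immigration``
    rate into the edge habitat.  Pure function of the state; used by the
    exact SSA oracle and by the tests, while :func:`step_tau_leap` works
    from cached equivalents.
    """
    E, H = state.counts.shape
    phi = _phi_matrix(state.mics, state.conc, params.r_max) if E else np.zeros((0, H))
    N = state.counts.sum(axis=0)
    room = np.maximum(1.0 - N / params.K, 0.0)
    birth = np.maximum(phi, 0.0) * room[None, :]
    death = params.d_uniform + np.maximum(-phi, 0.0) + np.zeros((E, H))
    migration = np.full((E, H), params.r_mig if H > 1 else 0.0)
    detachment = np.zeros((E, H))
    if E:
        detachment[:, state.L] = params.r_det
    return {
        "birth": birth,
        "death": death,
        "migration": migration,
        "detachment": detachment,
        "immigration": params.r_imm,
    }


def step_tau_leap(
    state: SystemState, params: ModelParams, rng: np.random.Generator
) -> SystemState:
    """Advance the state in place by one leap of length ``tau``.

    Exits are binomial (bounded by the subpopulation), allocated among
    death/detachment/migration in proportion to their rates; births and
    immigrants are Poisson.  Migrants are re-inserted into a uniformly
    chosen existing neighbour.
    """
    E = state._E
    if E:
        C = state._counts[:E]
        N = C.sum(axis=0)
        room = np.maximum(1.0 - N / params.K, 0.0)
        exits = rng.binomial(C, state._p_exit[:E])
        births = rng.poisson(state._btau[:E] * room[None, :] * C)
        C += births
        C -= exits
        if state.n_habitats > 1 and params.r_mig > 0.0:
            mig = rng.binomial(exits, state._mig_frac[:E])
            mig_left = rng.binomial(mig, state._left_share[None, :])
            mig_right = mig - mig_left
            C[:, :-1] += mig_left[:, 1:]
            C[:, 1:] += mig_right[:, :-1]

    n_imm = rng.poisson(params.r_imm * params.tau)
    if n_imm:
        mics = rng.lognormal(params.mic_mu, params.mic_sigma, n_imm)
        state._append_rows(mics)
        state._counts[state._E - n_imm : state._E, state.L] = 1

    state.leap_index += 1
    state.t = state.leap_index * params.tau
    if state.leap_index % _COMPACT_EVERY == 0:
        state._compact()
    return state


def apply_transition(state: SystemState, params: ModelParams) -> str | None:
    """Biofilm transition check for the edge habitat.

    If the edge population has reached N*, the edge flips to the biofilm
    state and a new empty pre-biofilm habitat is appended (with its own,
    lower, biocide concentration); returns ``"added"``.  If appending
    would push the habitat count past ``L_max``, nothing is appended and
    ``"cap"`` is returned (the run must stop).  Returns None when the
    threshold was not reached.
    """
    E = state._E
    if E == 0:
        return None
    n_edge = int(state._counts[:E, state.L].sum())
    if n_edge < params.N_star:
        return None
    if state.n_habitats + 1 > params.L_max:
        return "cap"
    state._compact()
    state._add_habitat()
    return "added"


def _take_snapshot(state: SystemState) -> Snapshot:
    counts = state.counts
    rows, cols = np.nonzero(counts)
    return Snapshot(
        t=state.t,
        habitat=cols.copy(),
        ecotype_id=state.ecotype_ids[rows].copy(),
        mic=state.mics[rows].copy(),
        count=counts[rows, cols].copy(),
    )


def _run_establishment_fast(
    params: ModelParams, rng: np.random.Generator
) -> int | None:
    """Single-habitat establishment kernel; returns the leap index of the
    first biofilm transition, or None if censored at ``t_max``.

    A distributionally exact reformulation of the leap loop for the
    pre-establishment phase, exploiting two facts about a lone habitat:
    immigration is state-independent, so all arrivals (and their MICs) can
    be drawn up front; and immigrants with MIC below the local biocide
    concentration never give birth and die at a state-independent rate, so
    their whole per-leap Bernoulli exit history collapses into one
    geometric removal-leap draw.  Only lineages able to grow (MIC >= c_0)
    need per-leap binomial/Poisson updates, because their birth rate
    depends on the total population through the logistic term.
    """
    tau = params.tau
    n_leaps = int(math.ceil(params.t_max / tau - 1e-9))
    c0 = params.concentration(0)

    # all immigration arrivals for the whole run, drawn up front
    arrivals = rng.poisson(params.r_imm * tau, n_leaps)
    total = int(arrivals.sum())
    mics = rng.lognormal(params.mic_mu, params.mic_sigma, total)
    arrival_leap = np.repeat(np.arange(n_leaps), arrivals)

    doomed = mics < c0
    # standing count of doomed microbes per leap, via a removal calendar
    phi_d = pharmacodynamic_rate(np.full(doomed.sum(), c0), mics[doomed], params.r_max)
    exit_d = params.d_uniform - phi_d + params.r_det
    p_d = -np.expm1(-exit_d * tau)
    removal = arrival_leap[doomed] + rng.geometric(p_d)
    flux = np.zeros(n_leaps + 1, dtype=np.int64)
    np.add.at(flux, arrival_leap[doomed], 1)
    np.add.at(flux, np.minimum(removal, n_leaps), -1)
    doomed_standing = np.cumsum(flux[:n_leaps])

    g_leaps = arrival_leap[~doomed]
    g_mics = mics[~doomed]
    bounds = np.searchsorted(g_leaps, np.arange(n_leaps + 1))

    phi_g = pharmacodynamic_rate(np.full(len(g_mics), c0), g_mics, params.r_max)
    btau_all = phi_g * tau  # phi >= 0 here
    p_exit_g = -math.expm1(-(params.d_uniform + params.r_det) * tau)

    if _HAVE_NUMBA:
        leap = _grower_loop_jit(
            int(rng.integers(1, 2**31 - 1)),
            n_leaps,
            doomed_standing,
            bounds.astype(np.int64),
            btau_all,
            float(p_exit_g),
            float(params.K),
            float(params.N_star),
        )
        return None if leap < 0 else int(leap)

    cap = 256
    g = np.zeros(cap, dtype=np.int64)
    bt = np.zeros(cap)
    E = 0
    n_star = params.N_star
    K = params.K

    for leap in range(n_leaps):
        if E:
            gv = g[:E]
            N = int(gv.sum()) + int(doomed_standing[leap - 1] if leap else 0)
            room = 1.0 - N / K
            exits = rng.binomial(gv, p_exit_g)
            if room > 0.0:
                births = rng.poisson(bt[:E] * room * gv)
                gv += births
            gv -= exits
        lo, hi = bounds[leap], bounds[leap + 1]
        k = hi - lo
        if k:
            if E + k > cap:
                cap = max(cap * 2, E + k)
                g = np.resize(g, cap)
                bt = np.resize(bt, cap)
            g[E : E + k] = 1
            bt[E : E + k] = btau_all[lo:hi]
            E += k
        if E and leap % _COMPACT_EVERY == 0:
            alive = g[:E] > 0
            m = int(alive.sum())
            if m < E:
                idx = np.flatnonzero(alive)
                g[:m] = g[idx]
                bt[:m] = bt[idx]
                E = m
        n_tot = (int(g[:E].sum()) if E else 0) + int(doomed_standing[leap])
        if n_tot >= n_star:
            return leap + 1
    return None


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _grower_loop_jit(
        seed, n_leaps, doomed_standing, bounds, btau_all, p_exit, K, n_star
    ):  # pragma: no cover - exercised via _run_establishment_fast
        np.random.seed(seed)
        cap = 1024
        g = np.zeros(cap, dtype=np.int64)
        bt = np.zeros(cap)
        E = 0
        for leap in range(n_leaps):
            if E:
                n_prev = doomed_standing[leap - 1] if leap else 0
                for i in range(E):
                    n_prev += g[i]
                room = 1.0 - n_prev / K
                if room < 0.0:
                    room = 0.0
                for i in range(E):
                    gi = g[i]
                    if gi > 0:
                        gi -= np.random.binomial(gi, p_exit)
                        lam = bt[i] * room * g[i]
                        if lam > 0.0:
                            gi += np.random.poisson(lam)
                        g[i] = gi
            lo = bounds[leap]
            hi = bounds[leap + 1]
            k = hi - lo
            if k:
                if E + k > cap:
                    new_cap = cap * 2
                    while new_cap < E + k:
                        new_cap *= 2
                    g2 = np.zeros(new_cap, dtype=np.int64)
                    bt2 = np.zeros(new_cap)
                    g2[:E] = g[:E]
                    bt2[:E] = bt[:E]
                    g, bt, cap = g2, bt2, new_cap
                for j in range(k):
                    g[E + j] = 1
                    bt[E + j] = btau_all[lo + j]
                E += k
            if E and leap % 25 == 0:
                m = 0
                for i in range(E):
                    if g[i] > 0:
                        g[m] = g[i]
                        bt[m] = bt[i]
                        m += 1
                E = m
            n_tot = doomed_standing[leap]
            for i in range(E):
                n_tot += g[i]
            if n_tot >= n_star:
                return leap + 1
        return -1


def run_simulation(
    params: ModelParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record_snapshots: bool = True,
    stop_at_establishment: bool = False,
) -> Trajectory:
    """Run one full colonization simulation.

    The loop alternates tau leaps with transition checks and records a
    sparse snapshot every ``record_dt`` hours.  The run stops when
    simulated time reaches ``t_max`` (TIME_CAP) or when a transition
    would push the column past ``L_max`` habitats (THICKNESS_CAP).
    Identical ``(params, seed)`` give bit-identical trajectories.

    ``stop_at_establishment`` ends the run at the first biofilm
    transition (end reason ESTABLISHED); the establishment time is
    unaffected because until that moment the system is a single habitat.
    This makes large waiting-time ensembles much cheaper.
    """
    if rng is None:
        if seed is None:
            seed = params.seed if params.seed is not None else 0
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    if seed is None:
        seed = -1  # externally supplied generator; seed unknown

    if stop_at_establishment and not record_snapshots and params.L_max >= 2:
        # single-habitat phase only: use the pre-sampled arrival kernel
        leap = _run_establishment_fast(params, rng)
        traj = Trajectory(params=params, seed=seed)
        if leap is None:
            traj.end_reason = EndReason.TIME_CAP
            traj.end_time = params.t_max
            traj.final_L = 0
        else:
            t_est = leap * params.tau
            traj.addition_times.append(t_est)
            traj.end_reason = EndReason.ESTABLISHED
            traj.end_time = t_est
            traj.final_L = 1
        return traj

    state = init_state(params)
    traj = Trajectory(params=params, seed=seed)
    if record_snapshots:
        traj.snapshots.append(_take_snapshot(state))
    next_record = params.record_dt

    eps = 1e-9
    while True:
        if state.t >= params.t_max - eps:
            traj.end_reason = EndReason.TIME_CAP
            break
        step_tau_leap(state, params, rng)
        event = apply_transition(state, params)
        if event == "cap":
            traj.end_reason = EndReason.THICKNESS_CAP
            break
        if event == "added":
            traj.addition_times.append(state.t)
            if stop_at_establishment:
                traj.end_reason = EndReason.ESTABLISHED
                break
        if record_snapshots and state.t >= next_record - eps:
            traj.snapshots.append(_take_snapshot(state))
            next_record += params.record_dt

    traj.end_time = state.t
    traj.final_L = state.L
    if record_snapshots and (
        not traj.snapshots or traj.snapshots[-1].t < state.t - eps
    ):
        traj.snapshots.append(_take_snapshot(state))
    return traj


def replicate_rng(base_seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible stream for replicate ``index``.

    Uses numpy's SeedSequence spawn-key mechanism:
    ``SeedSequence(base_seed, spawn_key=(index,))``, a documented, stable
    derivation producing statistically independent streams.
    """
    return np.random.default_rng(
        np.random.SeedSequence(base_seed, spawn_key=(index,))
    )


def run_replicates(
    params: ModelParams,
    n_reps: int,
    base_seed: int,
    record_snapshots: bool = False,
    stop_at_establishment: bool = False,
    progress: bool = False,
) -> list[Trajectory]:
    """Run ``n_reps`` independent replicates.

    Replicate ``r`` uses the stream ``SeedSequence(base_seed,
    spawn_key=(r,))``.  Snapshot recording is off by default because
    establishment-time ensembles only need the summary; pass
    ``record_snapshots=True`` for diversity analyses.  Use
    :func:`afbiofilm.analysis.establishment_table` to summarise the
    result as a DataFrame.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    iterator = range(n_reps)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="replicates")
        except ImportError:
            pass
    out = []
    for r in iterator:
        rng = replicate_rng(base_seed, r)
        traj = run_simulation(
            params,
            seed=base_seed,
            rng=rng,
            record_snapshots=record_snapshots,
            stop_at_establishment=stop_at_establishment,
        )
        traj.replicate = r
        out.append(traj)
    return out


def mean_field_trajectory(
    params: ModelParams,
    mic: float,
    habitat_index: int = 0,
    n0: float = 0.0,
    t_end: float | None = None,
    include_detachment: bool = True,
    n_points: int = 200,
):
    """Deterministic single-habitat population oracle.

    Integrates ``dN/dt = b(N) N - d N + r_imm`` with
    ``b(N) = max(phi, 0) (1 - N/K)`` clamped at zero above K and
    ``d = d_uniform + max(-phi, 0) + r_det`` — the mean-field limit of
    the stochastic channels for a single ecotype in one habitat (no
    migration, no biofilm transition).  Returns ``(times, N,
    steady_state)``.

    The logistic fixed point for a resistant microbe in a biocide-free
    habitat is ``K (1 - d/phi)``; with the baseline rates this is ~310
    microbes, *below* the biofilm threshold N* = 412.5 — the premise
    that biofilm initiation requires a stochastic fluctuation.
    """
    if t_end is None:
        t_end = params.t_max
    c = params.concentration(habitat_index)
    phi = pharmacodynamic_rate(c, mic, params.r_max)
    growth = max(phi, 0.0)
    death = params.d_uniform + max(-phi, 0.0) + (
        params.r_det if include_detachment else 0.0
    )

    def rhs(t, y):
        n = y[0]
        return [growth * max(1.0 - n / params.K, 0.0) * n - death * n + params.r_imm]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [float(n0)],
        t_eval=np.linspace(0.0, t_end, n_points),
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")

    if growth > 0 and params.r_imm == 0.0:
        ss = max(0.0, params.K * (1.0 - death / growth))
    elif growth == 0.0:
        ss = params.r_imm / death if death > 0 else math.inf
    else:
        # largest root of growth (1 - n/K) n - death n + r_imm = 0
        a = -growth / params.K
        b = growth - death
        disc = b * b - 4 * a * params.r_imm
        ss = (-b - math.sqrt(disc)) / (2 * a)
        if ss > params.K and death > 0:
            # above K the logistic term is clamped: linear balance instead
            ss = params.r_imm / death
    return sol.t, sol.y[0], ss


def ssa_reference_run(
    params: ModelParams,
    seed: int,
    t_end: float | None = None,
    max_events: int = 5_000_000,
    record_snapshots: bool = False,
) -> Trajectory:
    """Exact (Gillespie) simulation of the same event channels.

    Statistically exact but event-by-event, so intended as a validation
    oracle for small systems and short horizons only; raises if the
    event budget is exhausted.
    """
    if t_end is None:
        t_end = params.t_max
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    state = init_state(params)
    traj = Trajectory(params=params, seed=seed)
    if record_snapshots:
        traj.snapshots.append(_take_snapshot(state))
    next_record = params.record_dt

    events = 0
    while True:
        state._compact()
        rates = channel_rates(state, params)
        C = state.counts
        birth = rates["birth"] * C
        death = rates["death"] * C
        mig = rates["migration"] * C
        det = rates["detachment"] * C
        total = float(birth.sum() + death.sum() + mig.sum() + det.sum())
        total += params.r_imm
        if total <= 0.0:
            state.t = t_end
            break
        dt = rng.exponential(1.0 / total)
        if state.t + dt > t_end:
            state.t = t_end
            break
        state.t += dt
        events += 1
        if events > max_events:
            raise RuntimeError("SSA event budget exceeded")

        u = rng.uniform(0.0, total)
        if u < params.r_imm:
            mic = rng.lognormal(params.mic_mu, params.mic_sigma)
            state._append_rows(np.array([mic]))
            state._counts[state._E - 1, state.L] = 1
        else:
            u -= params.r_imm
            flat = np.concatenate(
                [birth.ravel(), death.ravel(), mig.ravel(), det.ravel()]
            )
            idx = int(np.searchsorted(np.cumsum(flat), u, side="right"))
            idx = min(idx, flat.size - 1)
            ch, rest = divmod(idx, C.size)
            e, h = divmod(rest, C.shape[1])
            if ch == 0:
                C[e, h] += 1
            elif ch == 2:  # migration
                if h == 0:
                    dest = h + 1
                elif h == state.L:
                    dest = h - 1
                else:
                    dest = h + 1 if rng.uniform() < 0.5 else h - 1
                C[e, h] -= 1
                C[e, dest] += 1
            else:  # death or detachment
                C[e, h] -= 1

        event = apply_transition(state, params)
        if event == "cap":
            traj.end_reason = EndReason.THICKNESS_CAP
            break
        if event == "added":
            traj.addition_times.append(state.t)
        if record_snapshots and state.t >= next_record:
            traj.snapshots.append(_take_snapshot(state))
            next_record += params.record_dt

    if traj.end_reason is None:
        traj.end_reason = EndReason.TIME_CAP
    traj.end_time = state.t
    traj.final_L = state.L
    if record_snapshots:
        traj.snapshots.append(_take_snapshot(state))
    return traj
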