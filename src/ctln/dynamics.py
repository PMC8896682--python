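"""Simulation of CTLN dynamics and attractor classification.

The dynamics are the threshold-linear system

    dx_i/dt = -x_i + [ (W x)_i + theta ]_+ ,

integrated either adaptively (scipy ``solve_ivp``, for single
trajectories) or with a vectorized fixed-step RK4 scheme that advances a
whole battery of initial conditions at once (used by the census, where
throughput dominates).  The state space is forward-invariant under
x >= 0, and a clipping guard removes the solver's tiny negative
undershoots.

Classification discards a transient, then decides between a stable fixed
point, a limit cycle (via peak-interval period estimation plus a
recurrence check), and an aperiodic orbit.  Limit cycles get an annotated
*peak sequence*: the cyclic order in which neurons reach peak firing
within one period, with synchronous peaks in parentheses and low-firing
participants flagged, starting from the lowest-numbered high-firing
neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .digraph import Digraph
from .network import CTLNParams, FPSet, build_W

__all__ = [
    "SimOptions",
    "ClassifyOptions",
    "Trajectory",
    "AttractorRecord",
    "rhs",
    "simulate",
    "simulate_batch",
    "battery",
    "classify_trajectory",
    "extract_sequence",
    "sequence_string",
    "same_attractor",
    "orbit_distance",
    "floquet_multipliers",
    "is_orbit_stable",
]

N_PHASE = 256  # phase points per stored orbit


@dataclass(frozen=True)
class SimOptions:
    """Integration settings.

    ``dt`` is both the RK4 step and the dense output grid; the adaptive
    path uses ``rtol``/``atol`` and samples on the same grid.
    """

    T: float = 400.0
    dt: float = 0.01
    rtol: float = 1e-9
    atol: float = 1e-12
    method: str = "rk4"  # "rk4" (fixed step) or an solve_ivp method name


@dataclass(frozen=True)
class ClassifyOptions:
    """Attractor-detection thresholds.

    The values are calibrated so the detected annotated sequences
    reproduce the published ones for the n = 5 census; all are
    configurable.
    """

    window: float = 150.0       # analysis window at the end of the run, time units
    tol_fp: float = 1e-6        # max state fluctuation for a fixed point
    tol_cycle: float = 1e-3     # relative recurrence residual for a limit cycle
    min_period: float = 0.5     # shortest admissible period
    tau_active: float = 0.01    # participation threshold, units of theta
    tau_low: float = 0.58       # low- vs high-firing split, fraction of max peak
    sync_frac: float = 0.01     # synchrony window, fraction of the period
    prominence_frac: float = 0.05  # secondary-peak prominence, fraction of max amplitude
    tol_match: float = 0.05     # mean L2 orbit distance within an attractor class


@dataclass(frozen=True)
class Trajectory:
    """A solution sampled on a uniform time grid (rows = time points)."""

    t: np.ndarray
    x: np.ndarray
    theta: float = 1.0

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def tail(self, duration: float) -> "Trajectory":
        k = max(2, int(round(duration / self.dt)))
        return Trajectory(self.t[-k:], self.x[-k:], self.theta)

    def to_csv(self) -> str:
        n = self.x.shape[1]
        lines = ["t," + ",".join(f"x{i+1}" for i in range(n))]
        for ti, row in zip(self.t, self.x):
            lines.append(f"{ti:.6g}," + ",".join(f"{v:.8g}" for v in row))
        return "\n".join(lines) + "\n"


def rhs(x: np.ndarray, W: np.ndarray, theta: float) -> np.ndarray:
    """-x + [W x + theta]_+ componentwise."""
    return -x + np.maximum(0.0, W @ x + theta)


def simulate(
    G: Digraph,
    params: CTLNParams,
    x0: Sequence[float],
    T: float | None = None,
    opts: SimOptions = SimOptions(),
    allow_illegal: bool = False,
) -> Trajectory:
    """Integrate one trajectory from x0 >= 0 for T time units."""
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial condition must be non-negative")
    T = float(T if T is not None else opts.T)
    if T <= 0:
        raise ValueError("T must be positive")
    W = build_W(G, params, allow_illegal=allow_illegal)
    theta = float(params.theta)
    t = np.arange(0.0, T + 0.5 * opts.dt, opts.dt)
    if opts.method == "rk4":
        X = simulate_batch(W, theta, x0[None, :], T, dt=opts.dt, record_from=0.0)[1]
        return Trajectory(t, X[:, 0, :], theta)
    sol = solve_ivp(
        lambda _t, x: rhs(np.maximum(x, 0.0), W, theta),
        (0.0, T),
        x0,
        t_eval=t,
        method=opts.method,
        rtol=opts.rtol,
        atol=opts.atol,
    )
    if not sol.success:
        raise RuntimeError(f"solver failed: {sol.message}")
    return Trajectory(sol.t, np.maximum(sol.y.T, 0.0), theta)


def simulate_batch(
    W: np.ndarray,
    theta: float,
    X0: np.ndarray,
    T: float,
    dt: float = 0.01,
    record_from: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 for a batch of initial conditions.

    ``X0`` has one row per trajectory.  Returns ``(t, X)`` where X has
    shape (time, batch, n) and covers t >= record_from.  States are
    clipped to be non-negative after every step.
    """
    X = np.array(X0, dtype=float)
    if X.ndim != 2:
        raise ValueError("X0 must be 2-D (batch, n)")
    WT = W.T.copy()

    def f(Y: np.ndarray) -> np.ndarray:
        return -Y + np.maximum(0.0, Y @ WT + theta)

    n_steps = int(round(T / dt))
    rec_start = int(round(record_from / dt))
    out = np.empty((n_steps - rec_start + 1, X.shape[0], X.shape[1]))
    t = (np.arange(rec_start, n_steps + 1)) * dt
    if rec_start == 0:
        out[0] = X
    for step in range(1, n_steps + 1):
        k1 = f(X)
        k2 = f(X + 0.5 * dt * k1)
        k3 = f(X + 0.5 * dt * k2)
        k4 = f(X + dt * k3)
        X = X + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.maximum(X, 0.0, out=X)
        if step >= rec_start:
            out[step - rec_start] = X
    return t, out


# ---------------------------------------------------------------------------
# Initial-condition battery
# ---------------------------------------------------------------------------

def battery(
    G: Digraph,
    fps: FPSet | None,
    eta: float = 0.05,
    n_random: int = 10,
    seed: int = 0,
) -> list[tuple[str, np.ndarray]]:
    """Labeled initial conditions: perturbations of every fixed point plus
    all 2^n corners of the unit cube.

    Each fixed point contributes the 2n coordinate perturbations +-eta e_i
    (clipped at 0) and ``n_random`` seeded random directions of norm eta.
    """
    n = G.n
    ics: list[tuple[str, np.ndarray]] = []
    rng = np.random.default_rng(seed)
    if fps is not None:
        for fp in fps.fixed_points:
            x = np.array([float(v) for v in fp.value])
            tag = "".join(map(str, sorted(fp.support)))
            for i in range(n):
                for s, sgn in (("+", 1.0), ("-", -1.0)):
                    ics.append(
                        (f"fp:{tag}:coord{s}{i+1}", np.maximum(x + sgn * eta * np.eye(n)[i], 0.0))
                    )
            for r in range(n_random):
                d = rng.standard_normal(n)
                d *= eta / np.linalg.norm(d)
                ics.append((f"fp:{tag}:rand{r}", np.maximum(x + d, 0.0)))
    for c in range(2**n):
        corner = np.array([(c >> i) & 1 for i in range(n)], dtype=float)
        ics.append(("corner:" + "".join(str(int(v)) for v in corner), corner))
    return ics


# ---------------------------------------------------------------------------
# Attractor records and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttractorRecord:
    """A classified attractor.

    ``sequence`` is the annotated cyclic peak order: a tuple of groups,
    each group a tuple of neuron labels peaking synchronously.  ``orbit``
    holds one period resampled to a fixed phase grid (or a representative
    window for aperiodic orbits).
    """

    kind: str  # "stable_fp" | "limit_cycle" | "aperiodic"
    high_set: frozenset[int]
    low_set: frozenset[int]
    sequence: tuple[tuple[int, ...], ...]
    period: float | None
    orbit: np.ndarray
    origin: str = ""

    @property
    def participating(self) -> frozenset[int]:
        return self.high_set | self.low_set

    @property
    def sequence_str(self) -> str:
        return sequence_string(self.sequence)

    def relabel(self, perm: dict[int, int]) -> "AttractorRecord":
        """Apply a vertex relabeling (orbit columns permuted accordingly)."""
        n = self.orbit.shape[1]
        cols = np.empty(n, dtype=int)
        for old in range(1, n + 1):
            cols[perm[old] - 1] = old - 1
        seq = tuple(tuple(sorted(perm[v] for v in grp)) for grp in self.sequence)
        rec = AttractorRecord(
            self.kind,
            frozenset(perm[v] for v in self.high_set),
            frozenset(perm[v] for v in self.low_set),
            seq,
            self.period,
            self.orbit[:, cols],
            self.origin,
        )
        return rec if rec.kind != "limit_cycle" else _rotate_to_convention(rec)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "high_set": sorted(self.high_set),
            "low_set": sorted(self.low_set),
            "sequence": self.sequence_str,
            "period": self.period,
            "origin": self.origin,
            "orbit": np.round(self.orbit, 6).tolist(),
        }


def sequence_string(groups: Iterable[Iterable[int]]) -> str:
    parts = []
    for grp in groups:
        g = sorted(grp)
        parts.append(str(g[0]) if len(g) == 1 else "(" + "".join(map(str, g)) + ")")
    return "".join(parts)


class InconclusiveError(RuntimeError):
    """The trajectory did not settle within the simulated horizon."""


def _interp_window(traj: Trajectory, duration: float) -> tuple[np.ndarray, np.ndarray]:
    tail = traj.tail(duration)
    return tail.t, tail.x


def _refined_peaks(y: np.ndarray, dt: float, prominence: float) -> tuple[np.ndarray, np.ndarray]:
    """Peak indices refined to sub-sample accuracy by parabolic interpolation.

    Returns (times, heights) relative to the start of y.
    """
    idx, _ = find_peaks(y, prominence=prominence)
    times, heights = [], []
    for i in idx:
        if 0 < i < len(y) - 1:
            a, b, c = y[i - 1], y[i], y[i + 1]
            denom = a - 2 * b + c
            off = 0.0 if denom == 0 else 0.5 * (a - c) / denom
            times.append((i + off) * dt)
            heights.append(b - 0.25 * (a - c) * off)
    return np.array(times), np.array(heights)


def _ref_peak_times(x: np.ndarray, dt: float) -> np.ndarray:
    """Refined peak times of the widest-swinging neuron."""
    amps = x.max(axis=0) - x.min(axis=0)
    ref = int(np.argmax(amps))
    times, _ = _refined_peaks(x[:, ref], dt, prominence=0.25 * amps[ref])
    return times


def _candidate_periods(times: np.ndarray, opts: ClassifyOptions) -> list[float]:
    """Period candidates from m-step peak intervals, m = 1..4.

    The reference neuron may peak several times per true period (with
    unequal spacing), so the candidate for multiplicity m is the median
    m-step interval, kept only when the m-step intervals are consistent.
    """
    cands = []
    for m in (1, 2, 3, 4, 5, 6):
        if len(times) < m + 2:
            break
        d = times[m:] - times[:-m]
        cand = float(np.median(d))
        if cand < opts.min_period or 2 * cand + 4 * opts.min_period > opts.window:
            continue
        if np.max(np.abs(d - cand)) > 0.05 * cand:
            continue
        cands.append(cand)
    return cands


def _recurrence_residual(x: np.ndarray, dt: float, period: float) -> float:
    """Mean relative mismatch between the last period and the one before it.

    The earlier period is sampled by linear interpolation, so the result
    is not polluted by the period not being a grid multiple.
    """
    k = int(round(period / dt))
    if 2 * k + 1 > len(x):
        return np.inf
    t = np.arange(len(x)) * dt
    t_last = t[-k:]
    prev = np.empty((k, x.shape[1]))
    for j in range(x.shape[1]):
        prev[:, j] = np.interp(t_last - period, t, x[:, j])
    scale = max(float(x.max()), 1e-12)
    return float(np.mean(np.linalg.norm(x[-k:] - prev, axis=1)) / scale)


def _resample_orbit(x: np.ndarray, t: np.ndarray, t0: float, period: float) -> np.ndarray:
    """One period starting at t0, linearly resampled to N_PHASE points."""
    phases = t0 + period * np.arange(N_PHASE) / N_PHASE
    out = np.empty((N_PHASE, x.shape[1]))
    for j in range(x.shape[1]):
        out[:, j] = np.interp(phases, t, x[:, j])
    return out


def extract_sequence(
    orbit: np.ndarray,
    period: float,
    theta: float = 1.0,
    opts: ClassifyOptions = ClassifyOptions(),
) -> tuple[tuple[tuple[int, ...], ...], frozenset[int], frozenset[int]]:
    """Annotated peak sequence of one period of a limit cycle.

    ``orbit`` is the (N_PHASE, n) resampled period.  Returns (groups,
    high_set, low_set).  Neurons whose peak stays below tau_active * theta
    do not participate; participants below tau_low * (largest peak) are
    low-firing.  A neuron may peak more than once per period; secondary
    peaks require prominence above prominence_frac * (largest amplitude).
    Peaks within sync_frac * period of each other form synchronous groups.
    """
    m, n = orbit.shape
    dt_phase = period / m
    peak_events: list[tuple[float, int]] = []  # (time within period, neuron)
    peak_height: dict[int, float] = {}
    global_amp = float(orbit.max() - orbit.min())
    for j in range(n):
        y = orbit[:, j]
        if y.max() < opts.tau_active * theta:
            continue
        # periodic extension so peaks at the phase seam are found too
        yy = np.concatenate([y, y, y])
        times, heights = _refined_peaks(
            yy, dt_phase, prominence=opts.prominence_frac * max(global_amp, 1e-12)
        )
        sel = (times >= period) & (times < 2 * period)
        times, heights = times[sel] - period, heights[sel]
        if len(times) == 0:
            # flat-topped participant: fall back to argmax
            times = np.array([np.argmax(y) * dt_phase])
            heights = np.array([y.max()])
        peak_height[j + 1] = float(max(heights))
        for tt in times:
            peak_events.append((float(tt), j + 1))
    if not peak_events:
        return (), frozenset(), frozenset()
    max_peak = max(peak_height.values())
    high = frozenset(v for v, h in peak_height.items() if h >= opts.tau_low * max_peak)
    low = frozenset(peak_height) - high

    # group synchronous peaks (circular single-linkage in time)
    peak_events.sort()
    tol = opts.sync_frac * period
    groups: list[list[tuple[float, int]]] = [[peak_events[0]]]
    for ev in peak_events[1:]:
        if ev[0] - groups[-1][-1][0] <= tol:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    if len(groups) > 1 and (period - groups[-1][-1][0]) + groups[0][0][0] <= tol:
        groups[0] = groups.pop() + groups[0]

    seq = tuple(tuple(sorted(v for _, v in grp)) for grp in groups)
    seq = _primitive_word(seq)
    rec = _rotate_groups(seq, high)
    return rec, high, low


def _primitive_word(seq: tuple[tuple[int, ...], ...]) -> tuple[tuple[int, ...], ...]:
    """Collapse an exact k-fold repetition of a cyclic word to the word.

    A period-doubled orbit peaks in the same cyclic order twice per true
    period (with different amplitudes); the reported sequence is the order
    itself, e.g. 12341234 -> 1234.
    """
    L = len(seq)
    for sub in range(1, L):
        if L % sub == 0 and seq == seq[:sub] * (L // sub):
            return seq[:sub]
    return seq


def _rotate_groups(
    seq: tuple[tuple[int, ...], ...], high: frozenset[int]
) -> tuple[tuple[int, ...], ...]:
    """Rotate a cyclic word to start at the lowest-numbered high neuron."""
    if not seq or not high:
        return seq
    start_v = min(high)
    for k, grp in enumerate(seq):
        if start_v in grp:
            return seq[k:] + seq[:k]
    return seq


def _rotate_to_convention(rec: AttractorRecord) -> AttractorRecord:
    return replace(rec, sequence=_rotate_groups(rec.sequence, rec.high_set))


def classify_trajectory(
    traj: Trajectory,
    opts: ClassifyOptions = ClassifyOptions(),
    origin: str = "",
) -> AttractorRecord:
    """Classify the post-transient behavior of a trajectory.

    The caller is responsible for having simulated long enough; the
    analysis window is the final ``opts.window`` time units.  Raises
    :class:`InconclusiveError` when the window still shows a drifting,
    non-recurrent state (the caller should extend the horizon).
    """
    if traj.t[-1] - traj.t[0] < opts.window:
        raise InconclusiveError("trajectory shorter than the analysis window")
    t, x = _interp_window(traj, opts.window)
    dt = traj.dt
    theta = traj.theta

    fluct = float(np.max(x.max(axis=0) - x.min(axis=0)))
    if fluct < opts.tol_fp:
        xbar = x.mean(axis=0)
        support = frozenset(i + 1 for i in range(x.shape[1]) if xbar[i] > opts.tau_active * theta)
        orbit = np.tile(xbar, (N_PHASE, 1))
        return AttractorRecord("stable_fp", support, frozenset(), (), None, orbit, origin)

    times = _ref_peak_times(x, dt)
    period = None
    for cand in _candidate_periods(times, opts):
        if _recurrence_residual(x, dt, cand) < opts.tol_cycle:
            period = cand
            break
    if period is not None:
        # stability guard: the two halves of the window must agree
        half = len(x) // 2
        amps1 = x[:half].max(axis=0)
        amps2 = x[half:].max(axis=0)
        m1 = max(float(amps1.max()), 1e-12)
        m2 = max(float(amps2.max()), 1e-12)
        high1 = frozenset(np.flatnonzero(amps1 >= opts.tau_low * m1) + 1)
        high2 = frozenset(np.flatnonzero(amps2 >= opts.tau_low * m2) + 1)
        if high1 == high2:
            # phase origin: the latest reference peak leaving one full
            # period inside the window
            t0 = t[0]
            for pt in reversed(times):
                if t[0] + pt + period <= t[-1]:
                    t0 = t[0] + pt
                    break
            orbit = _resample_orbit(x, t, t0, period)
            seq, high, low = extract_sequence(orbit, period, theta, opts)
            return AttractorRecord("limit_cycle", high, low, seq, period, orbit, origin)
    # aperiodic (or unresolved): describe the window itself
    peaks = x.max(axis=0)
    max_peak = max(float(peaks.max()), 1e-12)
    part = frozenset(i + 1 for i in range(x.shape[1]) if peaks[i] >= opts.tau_active * theta)
    high = frozenset(v for v in part if peaks[v - 1] >= opts.tau_low * max_peak)
    low = part - high
    step = max(1, len(x) // N_PHASE)
    orbit = x[::step][:N_PHASE]
    return AttractorRecord("aperiodic", high, low, (), None, orbit, origin)


# ---------------------------------------------------------------------------
# Attractor comparison
# ---------------------------------------------------------------------------

def floquet_multipliers(
    W: np.ndarray, theta: float, orbit: np.ndarray, period: float
) -> np.ndarray:
    """Floquet multiplier moduli of a periodic orbit, descending.

    Integrates the variational equation M' = J(x(t)) M over one period
    along the resampled orbit; the Jacobian of the threshold-linear flow
    is J = -I + diag(a) W with a_i the indicator of (Wx + theta)_i > 0
    (piecewise constant, so the matrix exponential per phase step is
    exact up to the orbit sampling).  A stable limit cycle has one
    trivial multiplier at 1 and the rest inside the unit circle.
    """
    from scipy.linalg import expm

    n = W.shape[0]
    # refine the phase grid so the activity-pattern switching times are
    # resolved well enough for the monodromy product
    m0 = len(orbit)
    m = 2048
    src = np.arange(m0 + 1)
    wrapped = np.vstack([orbit, orbit[:1]])
    fine = np.empty((m, n))
    ph = np.linspace(0.0, m0, m, endpoint=False)
    for j in range(n):
        fine[:, j] = np.interp(ph, src, wrapped[:, j])
    dt = period / m
    M = np.eye(n)
    eye = np.eye(n)
    cache: dict[tuple, np.ndarray] = {}
    for x in fine:
        a = tuple((W @ x + theta) > 0.0)
        E = cache.get(a)
        if E is None:
            J = -eye + np.asarray(a, dtype=float)[:, None] * W
            E = expm(J * dt)
            cache[a] = E
        M = E @ M
    mults = np.abs(np.linalg.eigvals(M))
    return np.sort(mults)[::-1]


def is_orbit_stable(
    W: np.ndarray,
    theta: float,
    rec: AttractorRecord,
    tol_trivial: float = 0.2,
    tol_second: float = 0.05,
) -> bool:
    """Is a classified limit cycle an actual attractor?

    Trajectories launched on invariant subspaces (symmetric corners,
    perturbations inside a synchrony plane) can converge to orbits that
    are unstable in the full space; the Floquet multipliers expose them.
    The largest multiplier is the trivial phase mode (= 1 up to sampling
    error); the rest must lie inside the unit circle.
    """
    if rec.kind != "limit_cycle" or rec.period is None:
        return True
    mults = floquet_multipliers(W, theta, rec.orbit, rec.period)
    if mults[0] > 1.0 + tol_trivial:
        return False
    return len(mults) < 2 or mults[1] < 1.0 + tol_second


def orbit_persists(
    W: np.ndarray,
    theta: float,
    rec: AttractorRecord,
    eps: float = 1e-4,
    n_periods: int = 24,
    dt: float = 0.01,
    seed: int = 0,
    growth_factor: float = 30.0,
) -> bool:
    """Empirical attractor test: does a generic small perturbation of the
    orbit stay near it?

    The Floquet product can report spurious instability for orbits with
    grazing switching events (the linearization is not valid through a
    graze), so verdicts are confirmed by integrating the orbit and a
    perturbed twin for ``n_periods`` periods: bounded separation means
    the cycle is an attractor.
    """
    if rec.kind != "limit_cycle" or rec.period is None:
        return True
    rng = np.random.default_rng(seed)
    d = rng.standard_normal(W.shape[0])
    d *= eps / np.linalg.norm(d)
    x0 = np.maximum(rec.orbit[0], 0.0)
    T = n_periods * rec.period
    _, X = simulate_batch(W, theta, np.stack([x0, np.maximum(x0 + d, 0.0)]), T, dt)
    k = int(round(rec.period / dt))
    marks = np.arange(k, len(X), k)
    dev = np.linalg.norm(X[marks, 1] - X[marks, 0], axis=1)
    return float(dev.max()) < growth_factor * eps


def orbit_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean L2 distance between two phase-resampled orbits, minimized over
    cyclic phase shifts of b."""
    if a.shape != b.shape:
        return np.inf
    m = a.shape[0]
    # distances for all cyclic shifts via correlation sums
    a2 = float((a * a).sum())
    b2 = float((b * b).sum())
    cross = np.zeros(m)
    for j in range(a.shape[1]):
        fa = np.fft.rfft(a[:, j])
        fb = np.fft.rfft(b[:, j])
        cross += np.fft.irfft(fa * np.conj(fb), m)
    d2 = np.maximum(a2 + b2 - 2.0 * cross, 0.0)
    return float(np.sqrt(d2.min() / m))


def same_attractor(
    a: AttractorRecord,
    b: AttractorRecord,
    perm: dict[int, int] | None = None,
    opts: ClassifyOptions = ClassifyOptions(),
) -> bool:
    """Are two records the same attractor (after relabeling a by perm)?

    Requires matching types, matching annotated sequences and high/low
    sets, and (for limit cycles) phase-aligned orbits within ``tol_match``
    mean L2 distance.  Aperiodic records compare combinatorially only.
    """
    if perm is not None:
        a = a.relabel(perm)
    if a.kind != b.kind:
        return False
    if a.high_set != b.high_set or a.low_set != b.low_set:
        return False
    if a.kind == "limit_cycle":
        if _cyclic_rotations(a.sequence) != _cyclic_rotations(b.sequence):
            if a.sequence not in _all_rotations(b.sequence):
                return False
        return orbit_distance(a.orbit, b.orbit) < opts.tol_match
    if a.kind == "stable_fp":
        return orbit_distance(a.orbit, b.orbit) < opts.tol_match
    return a.sequence == b.sequence  # aperiodic: combinatorial identity


def _all_rotations(seq: tuple) -> set[tuple]:
    return {seq[k:] + seq[:k] for k in range(max(1, len(seq)))}


def _cyclic_rotations(seq: tuple) -> tuple:
    if not seq:
        return seq
    return min(_all_rotations(seq))
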