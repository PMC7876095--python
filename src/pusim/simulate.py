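"""Per-cell Monte Carlo simulation of locus replication and ensemble profiles.

The engine is continuous-time and event-driven: origin firings, arrivals at
barriers, fork resumptions, fork-fork collisions and domain-edge arrivals are
processed in chronological order, so fork trajectories are exact under the
piecewise-constant velocities of the model.  A fixed-time-step twin
(:func:`simulate_cell_fixed_step`) implements the same semantics by explicit
sweeping and serves as an independent oracle in the test suite.

Per-cell stochastic draws, in order: for each origin (in list order) one
competence Bernoulli(efficiency) and, if competent, one truncated-normal
firing time; then one Bernoulli(arrest_probability) per susceptible
fork-barrier encounter, in chronological encounter order.

Polymerase bookkeeping per bin per cell:

* canonical rightward fork — Watson: Pol epsilon (leading); Crick: Pol delta,
  of which a fraction ``alpha_fraction`` is attributed to Pol alpha (lagging);
* canonical leftward fork — mirror image;
* HR-restarted fork (either direction) — Pol delta on both strands, no alpha.

A bin is attributed to the fork that synthesised its left-edge coordinate
last (re-replication after an HR restart with a negative offset overwrites
the earlier copy); at exact time ties the rightward fork wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .locus import Barrier, BinGrid, LocusConfig, SimulationParams, RIGHTWARD

CANONICAL = 0
RESTARTED = 1

_MOVING = 0
_ARRESTED = 1
_STOPPED = 2

WATSON = "watson"
CRICK = "crick"
STRANDS = (WATSON, CRICK)
POLS = ("epsilon", "delta", "alpha")


class SimulationError(RuntimeError):
    """A cell finished with unreplicated bins (or never started)."""


class TransitionNotFoundError(LookupError):
    """No crossing of the requested level in the window."""


@dataclass
class CellOutcome:
    """Per-bin replication record for one simulated cell."""

    replication_time: np.ndarray  # minutes, float per bin
    direction: np.ndarray  # +1 rightward / -1 leftward, int8 per bin
    fork_type: np.ndarray  # CANONICAL / RESTARTED, int8 per bin
    n_resampled: int = 0  # redraws because no origin was competent


@dataclass
class ReplicationProfile:
    """Ensemble per-bin fractions over ``n_cells`` simulated cells."""

    grid: BinGrid
    frac_rightward: np.ndarray
    frac_restarted: np.ndarray
    mean_replication_time: np.ndarray
    usage: dict  # (strand, pol) -> per-bin fraction
    n_cells: int
    seed: int

    def usage_channel(self, pol: str, strand: str) -> np.ndarray:
        return self.usage[(strand, pol)]


def _velocity_bp(v_kb: float) -> float:
    return v_kb * 1000.0


def _draw_origin_schedule(config: LocusConfig, rng: np.random.Generator):
    """Competence Bernoullis and truncated-normal firing times, origin order."""
    schedule = []
    for o in config.origins:
        if o.suppressed:
            continue
        if rng.random() >= o.efficiency:
            continue
        if o.firing_time_sd > 0:
            # Normal(mean, sd) truncated at 0 by inverse-CDF sampling
            a = -o.mean_firing_time / o.firing_time_sd
            lo = ndtr(a)
            u = lo + rng.random() * (1.0 - lo)
            t = o.mean_firing_time + o.firing_time_sd * float(ndtri(u))
        else:
            t = o.mean_firing_time
        schedule.append((t, config.grid.snap(o.position)))
    return schedule


def _barrier_applies(b: Barrier, direction: int, fork_type: int) -> bool:
    blocked = +1 if b.blocks_direction == RIGHTWARD else -1
    if direction != blocked:
        return False
    if fork_type == RESTARTED:
        return (b.restarted_fork_delay > 0) or (not b.canonical_only)
    return True


class _Fork:
    __slots__ = ("x", "t", "direction", "fork_type", "velocity", "state",
                 "resume_time", "resume_barrier", "passed", "segments",
                 "min_x", "max_x", "order")

    def __init__(self, x: float, t: float, direction: int, velocity: float, order: int):
        self.x = x          # position at checkpoint time self.t
        self.t = t
        self.direction = direction  # +1 / -1
        self.fork_type = CANONICAL
        self.velocity = velocity    # bp/min
        self.state = _MOVING
        self.resume_time = np.inf
        self.resume_barrier: Barrier | None = None
        self.passed: set[int] = set()
        self.segments: list[tuple] = []  # (t0, x0, t1, x1, direction, fork_type)
        self.min_x = x
        self.max_x = x
        self.order = order

    def position_at(self, t: float) -> float:
        if self.state != _MOVING:
            return self.x
        return self.x + self.direction * self.velocity * (t - self.t)

    def checkpoint(self, t: float) -> None:
        """Close the current motion segment at time t."""
        if self.state == _MOVING and t > self.t:
            x1 = self.position_at(t)
            self.segments.append((self.t, self.x, t, x1, self.direction, self.fork_type))
            self.x = x1
            self.min_x = min(self.min_x, x1)
            self.max_x = max(self.max_x, x1)
        self.t = t


def _apply_restart(fork, barrier: Barrier) -> None:
    """HR restart: jump behind the barrier, become a delta/delta fork."""
    # offset is signed along the direction of travel: the restart point lies
    # |restart_offset| bp behind the barrier, re-replicating the interval
    fork_dir = fork.direction if isinstance(fork, _Fork) else fork.dir
    new_x = fork.x + fork_dir * barrier.restart_offset
    fork.x = new_x
    fork.min_x = min(fork.min_x, new_x)
    fork.max_x = max(fork.max_x, new_x)
    if isinstance(fork, _Fork):
        fork.fork_type = RESTARTED
        if barrier.restart_velocity != "inherit":
            fork.velocity = _velocity_bp(barrier.restart_velocity)
    else:
        fork.ft = RESTARTED
        if barrier.restart_velocity != "inherit":
            fork.vel = _velocity_bp(barrier.restart_velocity)


def simulate_cell(config: LocusConfig, params: SimulationParams,
                  cell_rng: np.random.Generator) -> CellOutcome:
    """Simulate replication of the locus in one cell (event-driven, exact).

    Cells in which no origin is competent are redrawn from the same stream
    (counted in ``n_resampled``).
    """
    grid = config.grid
    v = _velocity_bp(params.fork_velocity)
    barriers = [(i, b, grid.snap(b.position)) for i, b in enumerate(config.barriers)]

    n_resampled = 0
    schedule = _draw_origin_schedule(config, cell_rng)
    while not schedule:
        n_resampled += 1
        if n_resampled > 1000:
            raise SimulationError("no competent origin after 1000 redraws")
        schedule = _draw_origin_schedule(config, cell_rng)

    forks: list[_Fork] = []
    pending = [[t, pos, False] for t, pos in
               sorted(schedule, key=lambda s: (s[0], s[1]))]
    order_counter = 0

    def covered(pos: float, t: float) -> bool:
        eps = 1e-6  # bp; absorbs float residue at segment endpoints
        for f in forks:
            x_now = f.position_at(t)
            if min(f.min_x, x_now) - eps <= pos <= max(f.max_x, x_now) + eps:
                return True
        return False

    while True:
        # candidate events: (time, priority, seq, kind, payload)
        events = []
        for entry in pending:
            if not entry[2]:
                events.append((entry[0], 0, 0, "fire", entry))
        for f in forks:
            if f.state == _ARRESTED:
                events.append((f.resume_time, 1, f.order, "resume", f))
        movers = [f for f in forks if f.state == _MOVING]
        for f in movers:
            best_d = (grid.end - f.x) if f.direction > 0 else (f.x - grid.start)
            best = ("edge", None)
            for bi, b, bpos in barriers:
                if bi in f.passed or not _barrier_applies(b, f.direction, f.fork_type):
                    continue
                d = (bpos - f.x) * f.direction
                if 0 < d < best_d:
                    best_d, best = d, ("barrier", (bi, b, bpos))
            events.append((f.t + best_d / f.velocity, 2, f.order, best[0], (f, best[1])))
        # closing fork pairs (collision, or rescue of an arrested fork)
        for a in movers:
            for c in forks:
                if c is a or (c.state == _MOVING and c.order <= a.order):
                    continue
                tau = max(a.t, c.t)
                va = a.direction * a.velocity
                vc = c.direction * c.velocity if c.state == _MOVING else 0.0
                rel = va - vc
                if rel == 0.0:
                    continue
                gap = c.position_at(tau) - a.position_at(tau)
                s = gap / rel
                if s <= 1e-12:
                    continue
                events.append((tau + s, 3, (a.order, c.order), "collide", (a, c)))
        if not events:
            break
        events.sort(key=lambda e: (e[0], e[1], str(e[2])))
        t, _, _, kind, payload = events[0]

        if kind == "fire":
            payload[2] = True
            pos = payload[1]
            if covered(pos, t):
                continue  # passively replicated: never fires
            for d in (+1, -1):
                forks.append(_Fork(pos, t, d, v, order_counter))
                order_counter += 1
        elif kind == "resume":
            f = payload
            b = f.resume_barrier
            f.state = _MOVING
            f.t = t
            if b is not None and b.kind == "restart":
                _apply_restart(f, b)
            f.resume_barrier = None
            f.resume_time = np.inf
        elif kind == "barrier":
            f, (bi, b, bpos) = payload
            f.checkpoint(t)
            f.x = bpos
            f.passed.add(bi)
            if f.fork_type == RESTARTED and b.restarted_fork_delay > 0:
                f.state = _ARRESTED
                f.resume_time = t + b.restarted_fork_delay
                f.resume_barrier = None  # plain transit pause, no type change
            elif cell_rng.random() < b.arrest_probability:
                f.state = _ARRESTED
                f.resume_time = t + b.delay
                f.resume_barrier = b
        elif kind == "edge":
            f, _ = payload
            f.checkpoint(t)
            f.x = grid.end if f.direction > 0 else grid.start
            f.min_x = min(f.min_x, f.x)
            f.max_x = max(f.max_x, f.x)
            f.state = _STOPPED
        elif kind == "collide":
            a, c = payload
            a.checkpoint(t)
            a.state = _STOPPED
            if c.state == _ARRESTED:
                # rescue: the converging fork reaches the arrested fork before
                # it restarts; the arrested fork is cancelled where it stands
                c.state = _STOPPED
                c.resume_time = np.inf
                c.resume_barrier = None
            else:
                c.checkpoint(t)
                c.state = _STOPPED

    segments = [seg for f in forks for seg in f.segments]
    return _assign_bins(grid, segments, n_resampled)


def _assign_bins(grid: BinGrid, segments, n_resampled: int) -> CellOutcome:
    n = grid.n_bins
    xs = grid.bin_starts().astype(float)
    best_t = np.full(n, -np.inf)
    best_dir = np.zeros(n, dtype=np.int8)
    best_type = np.zeros(n, dtype=np.int8)
    bs = grid.bin_size
    for (t0, x0, t1, x1, d, ft) in segments:
        lo, hi = (x0, x1) if x0 <= x1 else (x1, x0)
        k0 = max(int(np.ceil((lo - grid.start) / bs - 1e-9)), 0)
        k1 = min(int(np.floor((hi - grid.start) / bs + 1e-9)), n - 1)
        if k1 < k0:
            continue
        pts = xs[k0:k1 + 1]
        if t1 > t0 and x1 != x0:
            vel = abs(x1 - x0) / (t1 - t0)
            tt = t0 + (pts - x0) * d / vel
        else:
            tt = np.full(pts.shape, t0)
        cur_t = best_t[k0:k1 + 1]
        cur_d = best_dir[k0:k1 + 1]
        upd = (tt > cur_t) | ((tt == cur_t) & (cur_d < d))
        cur_t[upd] = tt[upd]
        cur_d[upd] = d
        best_type[k0:k1 + 1][upd] = ft
    if not np.all(np.isfinite(best_t)):
        gaps = np.flatnonzero(~np.isfinite(best_t))
        raise SimulationError(
            f"cell finished with {gaps.size} unreplicated bins, first at "
            f"{grid.start + gaps[0] * bs} bp"
        )
    return CellOutcome(replication_time=best_t, direction=best_dir,
                       fork_type=best_type, n_resampled=n_resampled)


class _StepFork:
    """Fixed-step fork record (independent of the event-driven _Fork)."""

    __slots__ = ("x", "dir", "ft", "vel", "state", "resume_time", "resume_b",
                 "passed", "min_x", "max_x", "tcur", "pieces")

    def __init__(self, x: float, t: float, d: int, vel: float):
        self.x, self.dir, self.ft, self.vel = x, d, CANONICAL, vel
        self.state, self.resume_time, self.resume_b = _MOVING, np.inf, None
        self.passed: set[int] = set()
        self.min_x = self.max_x = x
        self.tcur = t
        self.pieces: list[list] = []  # mutable [t0, x0, t1, x1, dir, ft]


def simulate_cell_fixed_step(config: LocusConfig, params: SimulationParams,
                             dt: float, cell_rng: np.random.Generator) -> CellOutcome:
    """Brute-force fixed-time-step twin of :func:`simulate_cell`.

    Time advances in increments of ``dt`` minutes; within each step every
    fork is swept forward (clamping at barriers), then converging forks that
    crossed during the step are clamped back to their exact meeting point.
    Stochastic draws are consumed in the same order as the event-driven
    engine.  Intended as a slow, independent oracle for small loci.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = config.grid
    v = _velocity_bp(params.fork_velocity)
    barriers = [(i, b, grid.snap(b.position)) for i, b in enumerate(config.barriers)]

    n_resampled = 0
    schedule = _draw_origin_schedule(config, cell_rng)
    while not schedule:
        n_resampled += 1
        if n_resampled > 1000:
            raise SimulationError("no competent origin after 1000 redraws")
        schedule = _draw_origin_schedule(config, cell_rng)
    schedule = [[t, pos, False] for t, pos in sorted(schedule, key=lambda s: (s[0], s[1]))]

    forks: list[_StepFork] = []
    all_pieces: list[tuple] = []

    def sweep(f: _StepFork, t_from: float, t_to: float) -> None:
        """Advance one moving fork from t_from to t_to, clamping at barriers
        and the domain edge; records motion pieces."""
        t0 = t_from
        while f.state == _MOVING and t0 < t_to:
            edge = grid.end if f.dir > 0 else grid.start
            d_edge = (edge - f.x) * f.dir
            d_best, hit = d_edge, None
            for bi, b, bpos in barriers:
                if bi in f.passed or not _barrier_applies(b, f.dir, f.ft):
                    continue
                d = (bpos - f.x) * f.dir
                if 0 < d < d_best:
                    d_best, hit = d, (bi, b, bpos)
            d_step = f.vel * (t_to - t0)
            if d_best <= d_step:
                t_arr = t0 + d_best / f.vel
                x_new = f.x + f.dir * d_best
                f.pieces.append([t0, f.x, t_arr, x_new, f.dir, f.ft])
                f.x = x_new
                f.min_x, f.max_x = min(f.min_x, x_new), max(f.max_x, x_new)
                f.tcur = t_arr
                if hit is None:  # domain edge
                    f.state = _STOPPED
                    return
                bi, b, bpos = hit
                f.passed.add(bi)
                if f.ft == RESTARTED and b.restarted_fork_delay > 0:
                    f.state = _ARRESTED
                    f.resume_time = t_arr + b.restarted_fork_delay
                    f.resume_b = None
                    return
                if cell_rng.random() < b.arrest_probability:
                    f.state = _ARRESTED
                    f.resume_time = t_arr + b.delay
                    f.resume_b = b
                    return
                t0 = t_arr
                continue
            x_new = f.x + f.dir * d_step
            f.pieces.append([t0, f.x, t_to, x_new, f.dir, f.ft])
            f.x = x_new
            f.min_x, f.max_x = min(f.min_x, x_new), max(f.max_x, x_new)
            f.tcur = t_to
            return

    def clamp_collisions(prev_pos: dict) -> None:
        """Clamp pairs of forks whose positions met or swapped during this
        step back to their exact meeting point (truncating overshot pieces).
        ``prev_pos`` maps id(fork) -> position at the start of the step (or at
        spawn, for forks born within it)."""
        for _ in range(64):
            hit = None
            for i, a in enumerate(forks):
                if a.state == _STOPPED:
                    continue
                for c in forks[i + 1:]:
                    if c.state == _STOPPED:
                        continue
                    g_prev = prev_pos[id(c)] - prev_pos[id(a)]
                    if g_prev == 0.0:
                        continue  # diverging newborn pair
                    g_now = c.x - a.x
                    if g_now == 0.0 or g_now * g_prev < 0:
                        hit = (a, c)
                        break
                if hit:
                    break
            if not hit:
                return
            a, c = hit
            _meet(a, c)
            prev_pos[id(a)] = a.x
            prev_pos[id(c)] = c.x

    def _meet(a: _StepFork, c: _StepFork) -> None:
        """Resolve an exact meeting between two forks that touched/crossed."""
        if a.state == _ARRESTED or c.state == _ARRESTED:
            arr, mov = (a, c) if a.state == _ARRESTED else (c, a)
            x_m = arr.x
            _truncate(mov, x_m)
            arr.state = _STOPPED
            arr.resume_time, arr.resume_b = np.inf, None
            mov.state = _STOPPED
            return
        va, vc = a.dir * a.vel, c.dir * c.vel
        ta, tc = a.tcur, c.tcur
        # meet where xa(t) = xc(t)
        t_m = ((c.x - vc * tc) - (a.x - va * ta)) / (va - vc)
        x_m = a.x + va * (t_m - ta)
        _truncate(a, x_m)
        _truncate(c, x_m)
        a.state = c.state = _STOPPED

    def _truncate(f: _StepFork, x_m: float) -> None:
        """Pull a fork back to x_m, trimming its overshot last piece."""
        if f.pieces:
            t0, x0, t1, x1, d, ft = f.pieces[-1]
            if (x1 - x_m) * d > 0:  # overshot
                vel = abs(x1 - x0) / (t1 - t0) if t1 > t0 else f.vel
                t_m = t0 + (x_m - x0) * d / vel
                f.pieces[-1] = [t0, x0, t_m, x_m, d, ft]
                f.tcur = t_m
        f.x = x_m
        f.min_x, f.max_x = min(f.min_x, x_m), max(f.max_x, x_m)

    t = 0.0
    t_last_fire = max(s[0] for s in schedule)
    for _ in range(10_000_000):
        t_next = t + dt
        prev_pos = {id(f): f.x for f in forks}
        for entry in schedule:
            if entry[2] or entry[0] > t_next:
                continue
            entry[2] = True
            t_fire, pos = entry[0], entry[1]
            def _cov(f):
                x_now = (f.x + f.dir * f.vel * (t_fire - f.tcur)
                         if f.state == _MOVING else f.x)
                return min(f.min_x, x_now) - 1e-6 <= pos <= max(f.max_x, x_now) + 1e-6
            if any(_cov(f) for f in forks):
                continue
            for d in (+1, -1):
                nf = _StepFork(pos, entry[0], d, v)
                forks.append(nf)
                prev_pos[id(nf)] = pos
                sweep(nf, entry[0], t_next)
        for f in forks:
            if f.state == _ARRESTED and f.resume_time <= t_next:
                b = f.resume_b
                if b is not None and b.kind == "restart":
                    _apply_restart(f, b)
                f.state = _MOVING
                f.resume_b = None
                rt = f.resume_time
                f.resume_time = np.inf
                sweep(f, rt, t_next)
            elif f.state == _MOVING and f.tcur < t_next:
                sweep(f, f.tcur, t_next)
        clamp_collisions(prev_pos)
        t = t_next
        if (all(f.state == _STOPPED for f in forks)
                and all(s[2] for s in schedule) and t >= t_last_fire):
            break
    else:
        raise SimulationError("fixed-step simulation exceeded step budget")

    for f in forks:
        all_pieces.extend(tuple(p) for p in f.pieces)
    return _assign_bins(grid, all_pieces, n_resampled)


def simulate_ensemble(config: LocusConfig, params: SimulationParams) -> ReplicationProfile:
    """Aggregate ``params.n_cells`` independent cells into a profile.

    Per-cell RNG substreams are spawned deterministically from
    ``params.master_seed`` so ensembles are reproducible and independent of
    execution order.
    """
    grid = config.grid
    n = grid.n_bins
    a = params.alpha_fraction
    children = np.random.SeedSequence(params.master_seed).spawn(params.n_cells)

    n_right = np.zeros(n)
    n_restarted = np.zeros(n)
    sum_time = np.zeros(n)
    usage = {(s, p): np.zeros(n) for s in STRANDS for p in POLS}

    for i in range(params.n_cells):
        rng = np.random.default_rng(children[i])
        try:
            cell = simulate_cell(config, params, rng)
        except SimulationError as exc:
            raise SimulationError(f"cell {i}: {exc}") from exc
        right = cell.direction > 0
        restarted = cell.fork_type == RESTARTED
        n_right += right
        n_restarted += restarted
        sum_time += cell.replication_time
        can_r = right & ~restarted
        can_l = ~right & ~restarted
        usage[(WATSON, "epsilon")] += can_r
        usage[(CRICK, "delta")] += can_r * (1.0 - a)
        usage[(CRICK, "alpha")] += can_r * a
        usage[(CRICK, "epsilon")] += can_l
        usage[(WATSON, "delta")] += can_l * (1.0 - a)
        usage[(WATSON, "alpha")] += can_l * a
        usage[(WATSON, "delta")] += restarted
        usage[(CRICK, "delta")] += restarted

    m = float(params.n_cells)
    return ReplicationProfile(
        grid=grid,
        frac_rightward=n_right / m,
        frac_restarted=n_restarted / m,
        mean_replication_time=sum_time / m,
        usage={k: u / m for k, u in usage.items()},
        n_cells=params.n_cells,
        seed=params.master_seed,
    )


def termination_midpoint(profile: ReplicationProfile,
                         window: tuple[float, float]) -> float:
    """Interpolated position where ``frac_rightward`` crosses 0.5 in window.

    The 0.5-crossing of the rightward-fork fraction marks the expected fork
    merger (termination) position.
    """
    grid = profile.grid
    xs = grid.bin_starts().astype(float)
    sel = (xs >= window[0]) & (xs <= window[1])
    if sel.sum() < 2:
        raise TransitionNotFoundError("window contains fewer than two bins")
    return _interp_crossing(xs[sel], profile.frac_rightward[sel], 0.5)


def _interp_crossing(x: np.ndarray, f: np.ndarray, level: float) -> float:
    g = f - level
    for i in range(len(g) - 1):
        if g[i] == 0.0:
            return float(x[i])
        if g[i] * g[i + 1] < 0:
            w = g[i] / (g[i] - g[i + 1])
            return float(x[i] + w * (x[i + 1] - x[i]))
    if g[-1] == 0.0:
        return float(x[-1])
    raise TransitionNotFoundError(f"no {level}-crossing in window")
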