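"""Event-driven stochastic simulation of RNAP traffic between convergent promoters.

Geometry
--------
The sense promoter pX occupies positions -70..-1, the overlap runs from +1 to
L, and the antisense promoter pY occupies L+1..L+70.  Elongation-complex (EC)
positions are tracked by the RNAP *center*: a sense EC starts at +1 and runs to
L + 70 + fp_ec/2 (past the far edge of pY), an antisense EC starts at L and
runs to 1 - 70 - fp_ec/2.  Initiation complexes (ICs) have a 70-bp footprint,
ECs a 35-bp footprint.

Interference mechanisms
-----------------------
*Occlusion* — a binding attempt fails while an opposing EC's center is inside
the promoter-transit window ([L - fp/2, L + 70 + fp/2] for pY and the mirror
image for pX).

*Sitting-duck interference (SDI)* — an opposing EC reaches the promoter
boundary while an IC is still initiating.  With probability
``1 - sdc_survival`` the sitting duck is dislodged (its round produces no
RNA); otherwise it survives as a roadblock and the incoming EC terminates with
a truncated RNA of length L - fp/2.

*Collision* — two converging ECs close within ``delta_critical`` inside the
overlap.  With probability ``1 - collision_one_survives`` both fall; otherwise
one survives with equal odds (the 0.2 / 0.4 / 0.4 split of the default
configuration).  Fallen ECs leave truncated RNAs whose length is given by the
center position at the collision.  A paused RNAP hit by an opposing EC follows
the sitting-duck rule of its pause site instead.

Every source of randomness flows from one ``numpy`` generator seeded from
``TIConfig.seed``, so a (config, seed) pair reproduces a simulation exactly.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError, PromoterParams, TIConfig

__all__ = [
    "Trajectory",
    "RoundOutcome",
    "TrafficResult",
    "RateTable",
    "CollisionOutcome",
    "sample_firing_schedule",
    "sample_trajectory",
    "occlusion_window",
    "check_occlusion",
    "sdi_boundary",
    "resolve_sdi",
    "draw_collision_outcome",
    "meet_time",
    "resolve_collision",
    "simulate_traffic",
    "compute_rate_table",
]

FATES = ("occluded", "sdi_dislodged", "truncated", "full_length")


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Gaussian samples redrawn until strictly positive."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def sample_firing_schedule(p: PromoterParams, n: int,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Binding and initiation-complete times for ``n`` rounds of transcription.

    Binding times are the cumulative sum of n positive Gaussian intervals with
    mean ``tau_B`` and SD ``noise_cv * tau_B``; each round fires (IC becomes
    EC) one positive Gaussian ``tau_I`` interval after binding.  The schedule
    is fixed ahead of the simulation: interference consumes rounds, it does
    not shift later attempts.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if p.noise_cv == 0:
        intervals = np.full(n, p.tau_B)
        init = np.full(n, p.tau_I)
    else:
        intervals = _truncated_normal(rng, p.tau_B, p.noise_cv * p.tau_B, n)
        init = _truncated_normal(rng, p.tau_I, p.noise_cv * p.tau_I, n)
    binding = np.cumsum(intervals)
    return binding, binding + init


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Piecewise-linear path of one elongation complex.

    ``positions`` are RNAP-center coordinates visited in travel order
    (increasing for sense ECs, decreasing for antisense ones) and ``times``
    the matching absolute arrival times.  Querying between the knots
    interpolates linearly, which reproduces the discrete per-nucleotide
    stepping to within one base pair.
    """

    origin: str  # "pX" | "pY"
    fire_time: float
    positions: np.ndarray
    times: np.ndarray
    round_index: int = 0
    # (t_enter, t_leave, position, removal_prob) per pause actually on path
    pause_windows: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        self._forward = bool(self.positions[-1] >= self.positions[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    def time_at(self, pos: float) -> float:
        """Absolute time at which the EC center reaches ``pos``."""
        if self._forward:
            return float(np.interp(pos, self.positions, self.times))
        return float(np.interp(pos, self.positions[::-1], self.times[::-1]))

    def pos_at(self, t: float) -> float:
        """EC center position at absolute time ``t`` (clamped to the path)."""
        return float(np.interp(t, self.times, self.positions))

    def pause_at(self, t: float) -> tuple[float, float] | None:
        """(position, removal_prob) if the EC is paused at time ``t``."""
        for t0, t1, pos, prob in self.pause_windows:
            if t0 <= t <= t1:
                return pos, prob
        return None


def sample_trajectory(origin: str, fire_time: float, config: TIConfig,
                      rng: np.random.Generator, round_index: int = 0) -> Trajectory:
    """Sample one EC path with per-nucleotide velocities and pause dwell times.

    The local velocity at every position is an independent positive Gaussian
    draw (mean ``v_mean``, SD ``v_sd``); the residence time at position m is
    ``1/v_m`` plus the pause duration if m hosts a pause site on the EC's
    strand.  The path extends past the opposing promoter so both full-length
    completion (length > L + 70) and the occlusion window are covered.
    """
    L = config.L
    half_fp = config.fp_ec / 2.0
    n_steps = int(math.ceil(L + 70 + half_fp))  # number of 1-bp moves
    if origin == "pX":
        positions = np.arange(1.0, n_steps + 2.0)  # 1 .. L+70+ceil(fp/2)+1
        strand = "sense"
    elif origin == "pY":
        positions = L - np.arange(0.0, n_steps + 1.0)  # L .. down past pX
        strand = "antisense"
    else:
        raise ValueError(f"unknown origin {origin!r}")

    if config.v_sd == 0:
        residence = np.full(n_steps, 1.0 / config.v_mean)
    else:
        residence = 1.0 / _truncated_normal(rng, config.v_mean, config.v_sd, n_steps)

    pause_windows = []
    pauses = [ps for ps in config.pause_sites if ps.strand == strand
              and ps.duration > 0]
    if pauses:
        for ps in pauses:
            idx = np.nonzero(positions[:-1] == ps.position)[0]
            if idx.size:
                residence[idx[0]] += ps.duration
        times = np.empty(n_steps + 1)
        times[0] = fire_time
        np.cumsum(residence, out=times[1:])
        times[1:] += fire_time
        for ps in pauses:
            idx = np.nonzero(positions[:-1] == ps.position)[0]
            if idx.size:
                i = int(idx[0])
                pause_windows.append((float(times[i]), float(times[i + 1]),
                                      float(ps.position), ps.removal_prob_on_hit))
    else:
        times = np.empty(n_steps + 1)
        times[0] = fire_time
        np.cumsum(residence, out=times[1:])
        times[1:] += fire_time

    return Trajectory(origin=origin, fire_time=fire_time, positions=positions,
                      times=times, round_index=round_index,
                      pause_windows=tuple(pause_windows))


# ---------------------------------------------------------------------------
# interference predicates
# ---------------------------------------------------------------------------

def occlusion_window(target: str, config: TIConfig) -> tuple[float, float]:
    """Center positions between which an opposing EC occludes ``target``.

    Returned in the opposing EC's travel order (entry first).
    """
    half_fp = config.fp_ec / 2.0
    if target == "pY":  # opposing = sense EC
        return (config.L - half_fp, config.L + 70 + half_fp)
    if target == "pX":  # opposing = antisense EC
        return (1 + half_fp, -70 - half_fp)
    raise ValueError(f"unknown promoter {target!r}")


def check_occlusion(attempt_time: float, target: str,
                    active_opposing_trajectories, config: TIConfig) -> bool:
    """True when any live opposing EC is transiting ``target`` at the attempt."""
    entry, exit_ = occlusion_window(target, config)
    for tr in active_opposing_trajectories:
        if tr.time_at(entry) < attempt_time < tr.time_at(exit_):
            return True
    return False


def sdi_boundary(target: str, config: TIConfig) -> float:
    """Opposing-EC center position at which its front edge reaches ``target``."""
    half_fp = config.fp_ec / 2.0
    if target == "pY":
        return config.L - half_fp
    if target == "pX":
        return 1 + half_fp
    raise ValueError(f"unknown promoter {target!r}")


def truncated_length(origin: str, center: float, L: int) -> int:
    """Length of the RNA released by an EC falling at ``center``.

    Sense transcripts span 1..center, antisense ones center..L; fractional
    footprint offsets are floored to whole nucleotides.
    """
    if origin == "pX":
        return int(math.floor(center))
    return int(math.floor(L - center + 1))


def resolve_sdi(ec: Trajectory, sdc: tuple[float, float, str], config: TIConfig,
                rng: np.random.Generator) -> str:
    """Outcome of an EC meeting a sitting duck: ``"sdc_dislodged"`` (the usual
    case) or ``"ec_truncated"`` when the duck survives as a roadblock."""
    binding_time, fire_t, promoter = sdc
    boundary = sdi_boundary(promoter, config)
    t_cross = ec.time_at(boundary)
    if not (binding_time < t_cross < fire_t):
        raise RuntimeError(
            "resolve_sdi called outside the SDI window: "
            f"{binding_time} < {t_cross} < {fire_t} does not hold")
    if rng.random() < config.sdc_survival:
        return "ec_truncated"
    return "sdc_dislodged"


def draw_collision_outcome(rng: np.random.Generator, one_survives: float) -> str:
    """Draw the head-on collision outcome: both fall with probability
    ``1 - one_survives``; otherwise the survivor is sense or antisense with
    equal odds."""
    if rng.random() >= one_survives:
        return "both_fall"
    return "sense_survives" if rng.random() < 0.5 else "anti_survives"


def meet_time(ec_sense: Trajectory, ec_anti: Trajectory,
              config: TIConfig) -> tuple[float, float, float] | None:
    """Earliest time two converging ECs are within ``delta_critical``.

    Returns ``(t, sense_center, antisense_center)`` or ``None`` when the pair
    never closes within the critical distance while both are inside the
    overlap.
    """
    delta = config.delta_critical
    t0 = max(ec_sense.fire_time, ec_anti.fire_time)
    t1 = min(ec_sense.end_time, ec_anti.end_time,
             ec_sense.time_at(config.L), ec_anti.time_at(1.0))
    if t1 < t0:
        return None

    def gap(t: float) -> float:
        return ec_anti.pos_at(t) - ec_sense.pos_at(t)

    if gap(t0) <= delta:
        return t0, ec_sense.pos_at(t0), ec_anti.pos_at(t0)
    if gap(t1) > delta:
        return None
    # knots of the piecewise-linear gap inside (t0, t1]
    ks = ec_sense.times[(ec_sense.times > t0) & (ec_sense.times < t1)]
    ka = ec_anti.times[(ec_anti.times > t0) & (ec_anti.times < t1)]
    knots = np.concatenate(([t0], ks, ka, [t1]))
    knots.sort(kind="stable")
    gaps = (np.interp(knots, ec_anti.times, ec_anti.positions)
            - np.interp(knots, ec_sense.times, ec_sense.positions))
    idx = int(np.argmax(gaps <= delta))  # first index at/below delta
    ta, tb = knots[idx - 1], knots[idx]
    ga, gb = gaps[idx - 1], gaps[idx]
    t = ta if gb == ga else ta + (ga - delta) * (tb - ta) / (ga - gb)
    return float(t), ec_sense.pos_at(t), ec_anti.pos_at(t)


@dataclass(frozen=True)
class CollisionOutcome:
    kind: str  # both_fall | sense_survives | anti_survives | no_collision
    time: float | None = None
    pos_sense: float | None = None
    pos_anti: float | None = None


def resolve_collision(ec_sense: Trajectory, ec_anti: Trajectory, config: TIConfig,
                      rng: np.random.Generator) -> CollisionOutcome:
    """Detect and resolve a head-on collision between two opposing ECs."""
    meet = meet_time(ec_sense, ec_anti, config)
    if meet is None:
        return CollisionOutcome("no_collision")
    t, pos_s, pos_a = meet
    kind = draw_collision_outcome(rng, config.collision_one_survives)
    return CollisionOutcome(kind, t, pos_s, pos_a)


# ---------------------------------------------------------------------------
# round bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class RoundOutcome:
    origin: str
    round_index: int
    fate: str  # occluded | sdi_dislodged | truncated | full_length
    truncated_length: int | None = None
    cause: str = "none"


@dataclass
class TrafficResult:
    config: TIConfig
    outcomes: list[RoundOutcome]
    n_rounds_pX: int
    n_rounds_pY: int

    def counts(self, origin: str) -> dict[str, int]:
        c = {f: 0 for f in FATES}
        for o in self.outcomes:
            if o.origin == origin:
                c[o.fate] += 1
        return c

    def truncated_lengths(self, origin: str) -> np.ndarray:
        return np.array([o.truncated_length for o in self.outcomes
                         if o.origin == origin and o.fate == "truncated"],
                        dtype=int)


# ---------------------------------------------------------------------------
# the event-driven simulator
# ---------------------------------------------------------------------------

_KIND_ATTEMPT, _KIND_FIRE, _KIND_MOVE = 0, 1, 2
_PROM_RANK = {"pX": 0, "pY": 1}


class _EC:
    __slots__ = ("eid", "traj", "dead_at")

    def __init__(self, eid: int, traj: Trajectory):
        self.eid = eid
        self.traj = traj
        self.dead_at: float | None = None

    def alive_at(self, t: float) -> bool:
        return self.dead_at is None or self.dead_at > t


class _Simulator:
    """Chronological event loop over binding attempts, firings, sitting-duck
    encounters and collisions.

    Pairwise encounter times are computed exactly once (when the later
    trajectory is created); queued candidates are validated against death
    times when popped, which keeps the loop exact because a truncation is the
    only way a trajectory ever changes.
    """

    def __init__(self, config: TIConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.heap: list = []
        self.seq = itertools.count()
        self.ecs: dict[int, _EC] = {}
        self.active: dict[str, list[int]] = {"pX": [], "pY": []}  # by origin
        self.pending_ic: dict[str, dict[int, tuple[float, float]]] = {
            "pX": {}, "pY": {}}
        self.outcomes: dict[str, list[RoundOutcome]] = {"pX": [], "pY": []}
        self._next_eid = itertools.count()

    # -- schedule -----------------------------------------------------------
    def _build_schedules(self) -> None:
        cfg = self.config
        stronger = "pX" if cfg.pX.tau_B <= cfg.pY.tau_B else "pY"
        weaker = "pY" if stronger == "pX" else "pX"
        p_strong = getattr(cfg, stronger)
        p_weak = getattr(cfg, weaker)
        b_s, f_s = sample_firing_schedule(p_strong, cfg.n_rounds, self.rng)
        horizon = b_s[-1]
        # weaker promoter: as many rounds as bind within the horizon
        n_guess = max(8, int(horizon / p_weak.tau_B * 1.2) + 8)
        b_w, f_w = sample_firing_schedule(p_weak, n_guess, self.rng)
        while b_w[-1] <= horizon:  # extend until past the horizon
            b2, f2 = sample_firing_schedule(p_weak, n_guess, self.rng)
            b_w = np.concatenate([b_w, b_w[-1] + b2])
            f_w = np.concatenate([f_w, b_w[-1 - len(b2)] + f2])
        keep = b_w <= horizon
        b_w, f_w = b_w[keep], f_w[keep]
        self.schedule = {stronger: (b_s, f_s), weaker: (b_w, f_w)}
        for prom in ("pX", "pY"):
            b, f = self.schedule[prom]
            self.outcomes[prom] = [None] * len(b)  # type: ignore[list-item]
            for j, t in enumerate(b):
                self._push(t, _KIND_ATTEMPT, prom, ("attempt", prom, j))

    # -- queue helpers ------------------------------------------------------
    def _push(self, t: float, kind: int, prom: str, payload: tuple) -> None:
        heapq.heappush(self.heap,
                       (t, kind, _PROM_RANK[prom], next(self.seq), payload))

    def _live_opposing(self, prom: str, t: float) -> list[_EC]:
        other = "pY" if prom == "pX" else "pX"
        lst = self.active[other]
        keep, out = [], []
        for eid in lst:
            ec = self.ecs[eid]
            if ec.dead_at is not None and ec.dead_at <= t:
                continue
            if ec.traj.end_time <= t:
                continue
            keep.append(eid)
            out.append(ec)
        self.active[other] = keep
        return out

    # -- event handlers -----------------------------------------------------
    def _on_attempt(self, t: float, prom: str, j: int) -> None:
        cfg = self.config
        opposing = self._live_opposing(prom, t)
        if check_occlusion(t, prom, [e.traj for e in opposing], cfg):
            self.outcomes[prom][j] = RoundOutcome(prom, j, "occluded")
            return
        fire_t = self.schedule[prom][1][j]
        self.pending_ic[prom][j] = (t, fire_t)
        self._push(fire_t, _KIND_FIRE, prom, ("fire", prom, j))
        boundary = sdi_boundary(prom, cfg)
        for ec in opposing:
            t_cross = ec.traj.time_at(boundary)
            if t < t_cross < fire_t:
                self._push(t_cross, _KIND_MOVE, prom,
                           ("sdi", ec.eid, prom, j, t_cross))

    def _on_fire(self, t: float, prom: str, j: int) -> None:
        if j not in self.pending_ic[prom]:
            return  # dislodged during initiation
        del self.pending_ic[prom][j]
        cfg = self.config
        traj = sample_trajectory(prom, t, cfg, self.rng, round_index=j)
        eid = next(self._next_eid)
        ec = _EC(eid, traj)
        self.ecs[eid] = ec
        self.active[prom].append(eid)
        self.outcomes[prom][j] = RoundOutcome(prom, j, "full_length")
        other = "pY" if prom == "pX" else "pX"
        # sitting ducks this EC may run into
        boundary = sdi_boundary(other, cfg)
        for j2, (b2, f2) in self.pending_ic[other].items():
            t_cross = traj.time_at(boundary)
            if b2 < t_cross < f2:
                self._push(t_cross, _KIND_MOVE, other,
                           ("sdi", eid, other, j2, t_cross))
        # head-on encounters with live opposing ECs
        for ec2 in self._live_opposing(prom, t):
            s, a = (ec, ec2) if prom == "pX" else (ec2, ec)
            meet = meet_time(s.traj, a.traj, cfg)
            if meet is not None:
                self._push(meet[0], _KIND_MOVE, "pX",
                           ("meet", s.eid, a.eid, meet))

    def _truncate(self, ec: _EC, t: float, center: float, cause: str) -> None:
        ec.dead_at = t
        prom = ec.traj.origin
        out = self.outcomes[prom][ec.traj.round_index]
        out.fate = "truncated"
        out.cause = cause
        out.truncated_length = truncated_length(prom, center, self.config.L)

    def _on_sdi(self, t: float, eid: int, prom: str, j: int) -> None:
        ec = self.ecs[eid]
        if not ec.alive_at(t) or j not in self.pending_ic[prom]:
            return
        if self.rng.random() < self.config.sdc_survival:
            # the duck holds on; the incoming EC terminates at the boundary
            self._truncate(ec, t, sdi_boundary(prom, self.config),
                           "sdc_roadblock")
        else:
            del self.pending_ic[prom][j]
            self.outcomes[prom][j] = RoundOutcome(prom, j, "sdi_dislodged")

    def _on_meet(self, t: float, s_eid: int, a_eid: int,
                 meet: tuple[float, float, float]) -> None:
        ec_s, ec_a = self.ecs[s_eid], self.ecs[a_eid]
        if not (ec_s.alive_at(t) and ec_a.alive_at(t)):
            return
        _, pos_s, pos_a = meet
        pause_s = ec_s.traj.pause_at(t)
        pause_a = ec_a.traj.pause_at(t)
        if pause_s is not None and pause_a is None:
            self._resolve_pause_hit(t, paused=ec_s, mover=ec_a,
                                    pos_paused=pos_s, pos_mover=pos_a,
                                    removal_prob=pause_s[1])
            return
        if pause_a is not None and pause_s is None:
            self._resolve_pause_hit(t, paused=ec_a, mover=ec_s,
                                    pos_paused=pos_a, pos_mover=pos_s,
                                    removal_prob=pause_a[1])
            return
        kind = draw_collision_outcome(self.rng,
                                      self.config.collision_one_survives)
        if kind == "both_fall":
            self._truncate(ec_s, t, pos_s, "collision_both_fall")
            self._truncate(ec_a, t, pos_a, "collision_both_fall")
        elif kind == "sense_survives":
            self._truncate(ec_a, t, pos_a, "collision_lost_to_survivor")
        else:
            self._truncate(ec_s, t, pos_s, "collision_lost_to_survivor")

    def _resolve_pause_hit(self, t: float, paused: _EC, mover: _EC,
                           pos_paused: float, pos_mover: float,
                           removal_prob: float) -> None:
        """A moving EC runs into a paused RNAP (sitting-duck-like rule)."""
        if self.rng.random() < removal_prob:
            self._truncate(paused, t, pos_paused, "collision_lost_to_survivor")
        else:
            self._truncate(mover, t, pos_mover, "pause_roadblock")

    # -- main loop ----------------------------------------------------------
    def run(self) -> TrafficResult:
        self._build_schedules()
        while self.heap:
            t, _, _, _, payload = heapq.heappop(self.heap)
            kind = payload[0]
            if kind == "attempt":
                self._on_attempt(t, payload[1], payload[2])
            elif kind == "fire":
                self._on_fire(t, payload[1], payload[2])
            elif kind == "sdi":
                self._on_sdi(t, payload[1], payload[2], payload[3])
            else:  # meet
                self._on_meet(t, payload[1], payload[2], payload[3])
        outcomes = [o for prom in ("pX", "pY") for o in self.outcomes[prom]]
        assert all(o is not None for o in outcomes)
        return TrafficResult(config=self.config, outcomes=outcomes,
                             n_rounds_pX=len(self.outcomes["pX"]),
                             n_rounds_pY=len(self.outcomes["pY"]))


def simulate_traffic(config: TIConfig) -> TrafficResult:
    """Run the discrete interference simulation.

    The stronger promoter performs ``config.n_rounds`` rounds of transcription;
    the weaker one as many as its schedule fits inside that horizon.  Each
    round ends in exactly one fate: ``occluded``, ``sdi_dislodged``,
    ``truncated`` (with a cause and an RNA length) or ``full_length``.
    """
    return _Simulator(config).run()


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

@dataclass
class RateTable:
    """Per-promoter success fractions and net RNA production rates.

    ``eta_x``/``eta_y`` are the fractions of rounds yielding full-length RNA;
    ``eta_xk``/``eta_yh`` map truncated length (nt) to its fraction of rounds.
    Rates follow k = f * eta scaled by ``concentration_per_event`` (nM/s per
    event/s); the aggregate truncated rates count only RNAs longer than 60 nt,
    the pool able to fold the structures needed for antisense interaction.
    """

    eta_x: float
    eta_y: float
    eta_xk: dict[int, float]
    eta_yh: dict[int, float]
    f_X: float
    f_Y: float
    concentration_per_event: float = 1.0
    ar_min_length: int = 60

    @property
    def k_x(self) -> float:
        return self.f_X * self.eta_x * self.concentration_per_event

    @property
    def k_y(self) -> float:
        return self.f_Y * self.eta_y * self.concentration_per_event

    @property
    def k_xk_total(self) -> float:
        frac = sum(v for l, v in self.eta_xk.items() if l > self.ar_min_length)
        return self.f_X * frac * self.concentration_per_event

    @property
    def k_yh_total(self) -> float:
        frac = sum(v for l, v in self.eta_yh.items() if l > self.ar_min_length)
        return self.f_Y * frac * self.concentration_per_event

    @classmethod
    def from_rates(cls, k_x: float, k_y: float, k_xk: float, k_yh: float
                   ) -> "RateTable":
        """Build a table directly from the four net production rates (nM/s),
        hiding the truncated pools behind single >60-nt lengths."""
        return cls(eta_x=k_x, eta_y=k_y, eta_xk={100: k_xk}, eta_yh={100: k_yh},
                   f_X=1.0, f_Y=1.0)


def compute_rate_table(result: TrafficResult,
                       concentration_per_event: float = 1.0) -> RateTable:
    """Tabulate success fractions and production rates from simulated rounds."""
    cfg = result.config
    n = {"pX": result.n_rounds_pX, "pY": result.n_rounds_pY}
    eta_full = {}
    eta_trunc: dict[str, dict[int, float]] = {}
    for prom in ("pX", "pY"):
        counts = result.counts(prom)
        eta_full[prom] = counts["full_length"] / n[prom] if n[prom] else 0.0
        lengths = result.truncated_lengths(prom)
        hist: dict[int, float] = {}
        if n[prom]:
            vals, cnts = np.unique(lengths, return_counts=True)
            hist = {int(v): int(c) / n[prom] for v, c in zip(vals, cnts)}
        eta_trunc[prom] = hist
    return RateTable(eta_x=eta_full["pX"], eta_y=eta_full["pY"],
                     eta_xk=eta_trunc["pX"], eta_yh=eta_trunc["pY"],
                     f_X=cfg.pX.firing_rate, f_Y=cfg.pY.firing_rate,
                     concentration_per_event=concentration_per_event)
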