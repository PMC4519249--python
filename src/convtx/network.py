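"""Protein feedback layer and bistability analysis of the antisense switch.

Gene X encodes a repressor that binds the pY operator and throttles the
antisense promoter between a repressed firing rate ``f_Y_min`` and a
de-repressed ``f_Y_max``; gene Y feeds back positively by (indirectly)
activating production of Z, which sequesters the repressor in an X:Z complex.
Z is also supplied externally at rate ``k_WZ``, the dose variable of the
switch.

Because the RNAP-traffic layer is a discrete simulation, the coupled problem
is solved self-consistently: the ODE system for the twelve cellular species
is solved with guessed transcription rates, the resulting repressor level
fixes the pY firing rate, the traffic simulation is rerun at that rate, and
the ODE system is solved again with the realised transcription rates (the
two-step scheme; more fixed-point updates are optional).  Sweeping ``k_WZ``
quasi-statically in both directions exposes hysteresis: OFF→ON and ON→OFF
thresholds are located from branch jumps and refined by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .odes import RNAState, SteadyStateError, _integrate_to_steady, tiar_rhs
from .params import GNParams, RNAKinetics, TIConfig
from .traffic import RateTable, compute_rate_table, simulate_traffic

__all__ = [
    "GNState",
    "BistabilityResult",
    "operator_occupancy",
    "effective_firing_rate",
    "gn_rhs",
    "solve_self_consistent",
    "bistability_scan",
    "classify_response",
]

GN_SPECIES = ("x", "y", "xk", "yh", "xy", "xky", "xyh", "xkyh",
              "X", "Y", "Z", "XZ")


def operator_occupancy(X: float, K_OY: float) -> float:
    """Fraction of pY operator sites free of repressor, K_OY / (K_OY + [X])."""
    if X < 0:
        raise ValueError(f"repressor concentration must be >= 0, got {X}")
    if K_OY <= 0:
        raise ValueError("K_OY must be > 0")
    return K_OY / (K_OY + X)


def effective_firing_rate(unbound_fraction: float, f_Y_min: float,
                          f_Y_max: float) -> float:
    """pY firing rate interpolated between repressed and de-repressed states."""
    return f_Y_max * unbound_fraction + f_Y_min * (1.0 - unbound_fraction)


@dataclass
class GNState:
    """Steady state of the twelve cellular species plus the realised pY rate."""

    x: float = 0.0
    y: float = 0.0
    xk: float = 0.0
    yh: float = 0.0
    xy: float = 0.0
    xky: float = 0.0
    xyh: float = 0.0
    xkyh: float = 0.0
    X: float = 0.0
    Y: float = 0.0
    Z: float = 0.0
    XZ: float = 0.0
    f_Y: float = 0.0
    converged: bool = True
    X_iterates: tuple[float, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in GN_SPECIES])

    @property
    def rna(self) -> RNAState:
        return RNAState(self.x, self.y, self.xk, self.yh, self.xy, self.xky,
                        self.xyh, self.xkyh, converged=self.converged)

    @classmethod
    def from_array(cls, a, **kw) -> "GNState":
        return cls(**dict(zip(GN_SPECIES, (float(v) for v in a))), **kw)


def gn_rhs(state: np.ndarray, rates: RateTable, kin: RNAKinetics, p: GNParams,
           *, dynamic_fy: bool = False) -> np.ndarray:
    """Derivatives of the twelve species (eight RNAs, then X, Y, Z, X:Z).

    Transcription rates are those frozen in ``rates``; the feedback onto pY
    enters through the outer self-consistency loop, not the RHS.  The
    ``dynamic_fy`` flag serves only the initial-guess stage, where the y
    production rate tracks the instantaneous repressor level through the
    operator-occupancy relation (with a unit success fraction).
    """
    rna = state[:8]
    X, Y, Z, XZ = state[8:]
    if dynamic_fy:
        f_y = effective_firing_rate(operator_occupancy(max(X, 0.0), p.K_OY),
                                    p.f_Y_min, p.f_Y_max)
        rates = replace_k_y(rates, f_y * rates.concentration_per_event)
    d_rna = tiar_rhs(rna, rates, kin)
    x, y = rna[0], rna[1]
    bind = p.k_XZ * X * Z
    d_X = p.k_X * x - bind + p.k_uXZ * XZ - (p.mu + p.lambda_X) * X
    d_Y = p.k_Y * y - (p.mu + p.lambda_Y) * Y
    d_Z = p.k_WZ + p.k_YZ * Y - bind + p.k_uXZ * XZ - (p.mu + p.lambda_Z) * Z
    d_XZ = bind - (p.k_uXZ + p.mu + p.lambda_XZ) * XZ
    return np.concatenate([d_rna, [d_X, d_Y, d_Z, d_XZ]])


def replace_k_y(rates: RateTable, k_y: float) -> RateTable:
    """Copy of a rate table with the full-length y production rate replaced."""
    return RateTable(eta_x=rates.k_x, eta_y=k_y,
                     eta_xk={100: rates.k_xk_total},
                     eta_yh={100: rates.k_yh_total},
                     f_X=1.0, f_Y=1.0, concentration_per_event=1.0)


def _solve_gn_odes(rates: RateTable, kin: RNAKinetics, p: GNParams, *,
                   y0: np.ndarray | None = None, dynamic_fy: bool = False,
                   t_max: float = 2e7, tol: float = 1e-9
                   ) -> tuple[np.ndarray, bool]:
    start = np.zeros(12) if y0 is None else np.asarray(y0, dtype=float)
    rhs = lambda s: gn_rhs(s, rates, kin, p, dynamic_fy=dynamic_fy)
    return _integrate_to_steady(rhs, start, t_max, tol)


def _ti_seed(base_seed: int, k_WZ: float, update: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(round(k_WZ * 1e6)) & 0x7FFFFFFF,
                                 int(update)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def solve_self_consistent(k_WZ: float, kin: RNAKinetics, p: GNParams,
                          ti_template: TIConfig, *,
                          init: np.ndarray | None = None,
                          n_updates: int = 1,
                          guess_rates: tuple[float, float, float] = (0.05, 0.01, 0.01),
                          t_max: float = 2e7, tol: float = 1e-9,
                          raise_on_failure: bool = False) -> GNState:
    """Two-step (optionally iterated) coupling of the ODE and traffic layers.

    Step 1 solves the cellular ODEs with guessed rates for x, x_k and y_h
    (defaults 0.05, 0.01 and 0.01 nM/s) and the y rate slaved to the
    instantaneous repressor level, yielding a repressor estimate.  Each update
    then converts that estimate into a pY firing rate, reruns the traffic
    simulation at it, and re-solves the ODEs with the realised rates.
    ``init`` warm-starts the integrations (used by quasi-static sweeps).
    Steady states with negative concentrations are rejected as unphysical.
    """
    if n_updates < 1:
        raise ValueError("n_updates must be >= 1")
    p = replace(p, k_WZ=float(k_WZ))
    k_x0, k_xk0, k_yh0 = guess_rates
    rates = RateTable.from_rates(k_x0, 0.0, k_xk0, k_yh0)
    state, ok = _solve_gn_odes(rates, kin, p, y0=init, dynamic_fy=True,
                               t_max=t_max, tol=tol)
    X_iters = [float(state[8])]
    f_y = float("nan")
    for upd in range(n_updates):
        frac = operator_occupancy(max(float(state[8]), 0.0), p.K_OY)
        f_y = effective_firing_rate(frac, p.f_Y_min, p.f_Y_max)
        cfg = ti_template.with_alpha(f_y * ti_template.pX.tau_B)
        cfg = cfg.with_seed(_ti_seed(ti_template.seed, k_WZ, upd))
        rates = compute_rate_table(simulate_traffic(cfg))
        state, ok = _solve_gn_odes(rates, kin, p, y0=state, t_max=t_max, tol=tol)
        X_iters.append(float(state[8]))
    physical = bool((state >= -1e-9).all())
    ok = ok and physical
    if not ok and raise_on_failure:
        raise SteadyStateError(
            f"self-consistent solve failed at k_WZ={k_WZ:g} "
            f"(physical={physical})")
    return GNState.from_array(np.clip(state, 0.0, None), f_Y=f_y,
                              converged=ok, X_iterates=tuple(X_iters))


@dataclass
class BistabilityResult:
    """Quasi-static up/down sweep over the external Z production rate."""

    k_WZ_grid: np.ndarray
    up_branch: list[GNState]
    down_branch: list[GNState]
    threshold_on: float | None  # OFF -> ON, from the up sweep
    threshold_off: float | None  # ON -> OFF, from the down sweep
    classification: str = "unclassified"

    def branch_values(self, which: str, species: str = "Y") -> np.ndarray:
        states = self.up_branch if which == "up" else self.down_branch
        return np.array([getattr(s, species) for s in states])

    @property
    def bistable(self) -> bool:
        return self.classification in ("bistable_reversible",
                                       "bistable_irreversible")


def _find_jump(grid: np.ndarray, values: np.ndarray, converged: np.ndarray,
               jump_factor: float) -> int | None:
    """Index i of the first adjacent pair (i, i+1) whose response jumps by more
    than ``jump_factor`` in either direction, skipping unconverged points."""
    eps = 1e-30
    for i in range(len(grid) - 1):
        if not (converged[i] and converged[i + 1]):
            continue
        lo, hi = values[i] + eps, values[i + 1] + eps
        if hi / lo > jump_factor or lo / hi > jump_factor:
            return i
    return None


def _refine_threshold(k_pre: float, k_post: float, state_pre: GNState,
                      v_pre: float, v_post: float, species: str,
                      solve, refine_tol: float) -> float:
    """Bisect the jump between ``k_pre`` (pre-jump, sweep side) and ``k_post``.

    Every probe continues quasi-statically from the last state known to sit on
    the pre-jump branch; a probe is assigned to a branch by comparing its
    response with the geometric midpoint of the two branch values.
    """
    sep = np.sqrt(max(v_pre, 1e-30) * max(v_post, 1e-30))
    pre_is_low = v_pre < v_post
    state = state_pre
    while abs(k_post - k_pre) > refine_tol:
        mid = 0.5 * (k_pre + k_post)
        st = solve(mid, state.as_array())
        v = getattr(st, species)
        if (v < sep) == pre_is_low:  # still on the pre-jump branch
            k_pre, state = mid, st
        else:
            k_post = mid
    return 0.5 * (k_pre + k_post)


def bistability_scan(k_WZ_grid, kin: RNAKinetics, p: GNParams,
                     ti_template: TIConfig, *, species: str = "Y",
                     jump_factor: float = 5.0, refine_tol: float = 0.1,
                     n_updates: int = 1, classify: bool = True
                     ) -> BistabilityResult:
    """Bidirectional quasi-static sweep of the dose variable ``k_WZ``.

    The up sweep seeds every grid point with the previous converged state; the
    down sweep runs the grid reversed.  A branch transition is a jump of more
    than ``jump_factor`` in the response species between adjacent converged
    grid points, refined by bisection to ``refine_tol`` (nM/s).
    """
    grid = np.asarray(k_WZ_grid, dtype=float)
    if len(grid) < 10:
        raise ValueError("k_WZ grid needs at least 10 points")
    if not (np.diff(grid) > 0).all():
        raise ValueError("k_WZ grid must be strictly ascending")

    def solve(k, init):
        return solve_self_consistent(k, kin, p, ti_template, init=init,
                                     n_updates=n_updates)

    def sweep(ks):
        states, prev = [], None
        for k in ks:
            st = solve(k, prev)
            states.append(st)
            if st.converged:
                prev = st.as_array()
        return states

    up = sweep(grid)
    down = sweep(grid[::-1])[::-1]

    up_v = np.array([getattr(s, species) for s in up])
    down_v = np.array([getattr(s, species) for s in down])
    up_ok = np.array([s.converged for s in up])
    down_ok = np.array([s.converged for s in down])

    threshold_on = threshold_off = None
    i = _find_jump(grid, up_v, up_ok, jump_factor)
    if i is not None:
        threshold_on = _refine_threshold(
            grid[i], grid[i + 1], up[i], up_v[i], up_v[i + 1], species,
            solve, refine_tol)
    j = _find_jump(grid[::-1], down_v[::-1], down_ok[::-1], jump_factor)
    if j is not None:
        jj = len(grid) - 1 - j  # pair (jj, jj-1) in ascending indexing
        threshold_off = _refine_threshold(
            grid[jj], grid[jj - 1], down[jj], down_v[jj], down_v[jj - 1],
            species, solve, refine_tol)

    # thresholds that coincide within the refinement precision are one sharp
    # transition crossed by both sweeps, not hysteresis
    if threshold_on is not None and threshold_off is not None \
            and abs(threshold_on - threshold_off) <= 2 * refine_tol:
        threshold_on = threshold_off = None

    result = BistabilityResult(grid, up, down, threshold_on, threshold_off)
    if classify:
        result.classification = classify_response(result, species=species)
    return result


def classify_response(result: BistabilityResult, hill_fit=None, *,
                      species: str = "Y", jump_factor: float = 5.0) -> str:
    """Label the dose-response: bistable (reversible or irreversible when the
    down sweep stays ON across the grid), else by the Hill exponent of the up
    branch (|H| > 2 ultrasensitive, |H| in [0.8, 1.2] Michaelian, otherwise
    ramping)."""
    up_ok = [s.converged for s in result.up_branch]
    down_ok = [s.converged for s in result.down_branch]
    if not (any(up_ok) and any(down_ok)):
        return "unclassifiable"
    up_v = result.branch_values("up", species)
    down_v = result.branch_values("down", species)
    eps = 1e-30
    branches_differ = bool(np.any(
        (np.maximum(up_v, down_v) + eps) / (np.minimum(up_v, down_v) + eps)
        > jump_factor))
    if result.threshold_on is not None and result.threshold_off is None \
            and branches_differ:
        return "bistable_irreversible"
    if result.threshold_on is not None and result.threshold_off is not None:
        return "bistable_reversible"
    if result.threshold_off is not None and branches_differ:
        return "bistable_reversible"
    if hill_fit is None:
        from .analysis import fit_hill
        mask = np.array(up_ok)
        try:
            hill_fit = fit_hill(result.k_WZ_grid[mask][up_v[mask] > 0],
                                up_v[mask][up_v[mask] > 0])
        except (ValueError, RuntimeError):
            return "ramping"
    H = abs(hill_fit.H)
    if H > 2:
        return "ultrasensitive"
    if 0.8 <= H <= 1.2:
        return "michaelian"
    return "ramping"
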