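"""Deterministic mass-balance ODE layers for cellular RNA levels.

Two systems are provided.  The interference-only model treats the four RNA
pools (full-length x, y and truncated x_k, y_h) as independent
production-decay balances, so its steady state is closed form.  The coupled
interference + antisense-RNA model adds second-order hybrid formation between
complementary species (x:y, x_k:y, x:y_h, x_k:y_h), first-order unbinding
(the doubly truncated hybrid unbinds faster) and first-order loss of every
species through degradation and growth dilution.  Steady states are found by
integration from an empty cell followed by an algebraic root polish, so the
convergence tolerance is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import RNAKinetics
from .traffic import RateTable

__all__ = [
    "RNAState",
    "ti_steady_state",
    "tiar_rhs",
    "tiar_steady_state",
    "SteadyStateError",
]

RNA_SPECIES = ("x", "y", "xk", "yh", "xy", "xky", "xyh", "xkyh")


class SteadyStateError(RuntimeError):
    """The system has no steady state or the solver failed to reach one."""


@dataclass
class RNAState:
    """Concentrations (nM) of the eight RNA species."""

    x: float = 0.0
    y: float = 0.0
    xk: float = 0.0
    yh: float = 0.0
    xy: float = 0.0
    xky: float = 0.0
    xyh: float = 0.0
    xkyh: float = 0.0
    converged: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.xk, self.yh,
                         self.xy, self.xky, self.xyh, self.xkyh])

    @classmethod
    def from_array(cls, a, converged: bool = True) -> "RNAState":
        return cls(*(float(v) for v in a), converged=converged)


def ti_steady_state(rates: RateTable, kin: RNAKinetics) -> RNAState:
    """Closed-form steady state of the interference-only model.

    Each pool balances production against first-order loss:
    ``x* = k_x / (mu + lambda_x)`` and likewise for y, x_k, y_h; the hybrid
    species stay at zero because no interaction is modelled.
    """
    out = {}
    for name, k, lam in (("x", rates.k_x, kin.lambda_x),
                         ("y", rates.k_y, kin.lambda_y),
                         ("xk", rates.k_xk_total, kin.lambda_xk),
                         ("yh", rates.k_yh_total, kin.lambda_yh)):
        loss = kin.mu + lam
        if loss == 0:
            if k > 0:
                raise SteadyStateError(
                    f"species {name}: production {k} nM/s with zero loss rate "
                    "has no steady state")
            out[name] = 0.0
        else:
            out[name] = k / loss
    return RNAState(**out)


def tiar_rhs(state: np.ndarray, rates: RateTable, kin: RNAKinetics) -> np.ndarray:
    """Time derivatives of the eight RNA species under interference + antisense
    interaction.

    The species order is ``(x, y, xk, yh, x:y, xk:y, x:yh, xk:yh)``.  The
    first three hybrids unbind at ``k_uxy``; only x_k:y_h uses ``k_uxkyh``.
    """
    x, y, xk, yh, xy, xky, xyh, xkyh = state
    k = kin
    form_xy = k.k_bxy * x * y
    form_xky = k.k_bxky * xk * y
    form_xyh = k.k_bxyh * x * yh
    form_xkyh = k.k_bxkyh * xk * yh
    return np.array([
        rates.k_x - form_xy - form_xyh + k.k_uxy * (xy + xyh)
        - (k.mu + k.lambda_x) * x,
        rates.k_y - form_xy - form_xky + k.k_uxy * (xy + xky)
        - (k.mu + k.lambda_y) * y,
        rates.k_xk_total - form_xky - form_xkyh + k.k_uxy * xky
        + k.k_uxkyh * xkyh - (k.mu + k.lambda_xk) * xk,
        rates.k_yh_total - form_xyh - form_xkyh + k.k_uxy * xyh
        + k.k_uxkyh * xkyh - (k.mu + k.lambda_yh) * yh,
        form_xy - (k.k_uxy + k.mu + k.lambda_xy) * xy,
        form_xky - (k.k_uxy + k.mu + k.lambda_xky) * xky,
        form_xyh - (k.k_uxy + k.mu + k.lambda_xyh) * xyh,
        form_xkyh - (k.k_uxkyh + k.mu + k.lambda_xkyh) * xkyh,
    ])


def _integrate_to_steady(rhs, y0: np.ndarray, t_max: float, tol: float
                         ) -> tuple[np.ndarray, bool]:
    """LSODA integration from ``y0`` with a root polish at the end."""
    sol = solve_ivp(lambda t, y: rhs(y), (0.0, t_max), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]
    polish = root(rhs, y, method="hybr", tol=1e-13)
    if polish.success and (polish.x >= -1e-9).all():
        y = np.clip(polish.x, 0.0, None)
    scale = max(1.0, float(np.max(np.abs(y))))
    converged = bool(np.max(np.abs(rhs(y))) / scale < tol)
    return y, converged


def tiar_steady_state(rates: RateTable, kin: RNAKinetics, *,
                      t_max: float = 5e6, tol: float = 1e-9,
                      y0: np.ndarray | None = None,
                      raise_on_failure: bool = True) -> RNAState:
    """Steady state of the coupled model, integrated from an empty cell.

    The trajectory starts at zero concentrations (or ``y0`` when continuing a
    sweep), runs until ``t_max`` seconds and is refined by root finding.  The
    state is flagged unconverged — or a :class:`SteadyStateError` is raised —
    when the normalised residual ``max|d/dt| / max(1, max|c|)`` stays above
    ``tol``.
    """
    start = np.zeros(8) if y0 is None else np.asarray(y0, dtype=float)
    y, converged = _integrate_to_steady(lambda s: tiar_rhs(s, rates, kin),
                                        start, t_max, tol)
    if not converged and raise_on_failure:
        raise SteadyStateError(
            f"no steady state within t_max={t_max:g}s at tol={tol:g}")
    return RNAState.from_array(y, converged=converged)
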