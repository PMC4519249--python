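"""Sweep analytics: switch curves, expression maps, Hill fits, sensitivities.

The switch variable throughout is the relative promoter strength
``alpha = f_Y / f_X``; a sweep retunes pY's binding time to ``tau_BX / alpha``
per point, reruns the traffic simulation, and (optionally) converts the rate
table into cellular steady-state levels through the RNA ODE layers.  Response
curves are summarised by least-squares fits of the Hill form

    k(alpha) = k_max * alpha^H / (K^H + alpha^H)

with a signed exponent: H < 0 describes responses falling with alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .odes import ti_steady_state, tiar_steady_state
from .params import ParameterError, RNAKinetics, TIConfig
from .traffic import (RateTable, TrafficResult, compute_rate_table,
                      simulate_traffic)

__all__ = [
    "HillFit",
    "ExpressionMap",
    "default_alpha_grid",
    "alpha_sweep",
    "build_expression_map",
    "fit_hill",
    "hill_curve",
    "dynamic_range",
    "sensitivity_sweep",
]


# ---------------------------------------------------------------------------
# alpha sweeps
# ---------------------------------------------------------------------------

def default_alpha_grid(n: int = 20, lo: float = 0.1, hi: float = 2.0) -> np.ndarray:
    """Linearly spaced alpha grid over the study range [0.1, 2].

    Linear spacing mirrors how switch curves in this system are plotted and
    fitted; it weights the fit toward the upper half of the range where the
    promoters compete most strongly.
    """
    return np.linspace(lo, hi, n)


def alpha_sweep(ti_template: TIConfig, alpha_values: Sequence[float], *,
                seeds: Sequence[int] | None = None,
                kin: RNAKinetics | None = None,
                model: str = "ti",
                keep_results: bool = False) -> pd.DataFrame:
    """Rerun the traffic simulation across promoter-strength ratios.

    Per grid point pY's binding time becomes ``tau_BX / alpha`` (points whose
    binding time would not exceed pY's initiation time raise a parameter
    error).  When ``kin`` is given, steady-state levels of the four free RNA
    pools are appended using the closed-form balance (``model="ti"``) or the
    antisense-interaction ODEs (``model="tiar"``).  Seeds default to children
    of the template seed, so a sweep is reproducible as a whole.
    """
    alphas = np.asarray(list(alpha_values), dtype=float)
    if seeds is None:
        ss = np.random.SeedSequence(ti_template.seed)
        seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF)
                 for c in ss.spawn(len(alphas))]
    if len(seeds) != len(alphas):
        raise ValueError("need one seed per alpha value")
    rows = []
    results = []
    for alpha, seed in zip(alphas, seeds):
        cfg = ti_template.with_alpha(alpha).with_seed(seed)
        res = simulate_traffic(cfg)
        rates = compute_rate_table(res)
        row = {
            "alpha": alpha, "seed": seed,
            "tau_BY": cfg.pY.tau_B,
            "eta_x": rates.eta_x, "eta_y": rates.eta_y,
            "k_x": rates.k_x, "k_y": rates.k_y,
            "k_xk_total": rates.k_xk_total, "k_yh_total": rates.k_yh_total,
            "n_rounds_pX": res.n_rounds_pX, "n_rounds_pY": res.n_rounds_pY,
        }
        if kin is not None:
            if model == "ti":
                st = ti_steady_state(rates, kin)
            elif model == "tiar":
                st = tiar_steady_state(rates, kin)
            else:
                raise ValueError(f"unknown model {model!r}")
            row.update(x=st.x, y=st.y, xk=st.xk, yh=st.yh)
        rows.append(row)
        if keep_results:
            results.append(res)
    df = pd.DataFrame(rows)
    if keep_results:
        df.attrs["results"] = results
    return df


# ---------------------------------------------------------------------------
# expression maps
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMap:
    """Per-alpha distribution of round fates over normalised-length bins.

    Rows are bins: ``0.0`` collects rounds that failed to fire (occlusion or
    dislodged sitting ducks), interior bins of width ``bin_width`` hold
    truncated RNAs at length/L, and the ``>1`` bin the full-length fraction.
    Every column is a probability distribution over that promoter's rounds.
    """

    alphas: np.ndarray
    bin_edges: np.ndarray  # interior bin left edges
    fractions: pd.DataFrame  # index: bin labels; columns: alpha values

    def column(self, alpha: float) -> pd.Series:
        idx = int(np.argmin(np.abs(self.alphas - alpha)))
        return self.fractions.iloc[:, idx]


def _map_from_outcomes(result: TrafficResult, origin: str,
                       bin_width: float) -> pd.Series:
    cfg = result.config
    n_bins = int(round(1.0 / bin_width))
    edges = np.round(np.arange(n_bins) * bin_width, 10)
    counts = np.zeros(n_bins)
    failed = full = total = 0
    for o in result.outcomes:
        if o.origin != origin:
            continue
        total += 1
        if o.fate in ("occluded", "sdi_dislodged"):
            failed += 1
        elif o.fate == "full_length":
            full += 1
        else:
            frac = o.truncated_length / cfg.L
            b = min(int(frac / bin_width), n_bins - 1)
            counts[b] += 1
    labels = ["0"] + ["0+" if e == 0 else f"{e:g}" for e in edges] + [">1"]
    vals = np.concatenate(([failed], counts, [full]))
    if total:
        vals = vals / total
    return pd.Series(vals, index=labels)


def build_expression_map(sweep: pd.DataFrame | Sequence[TrafficResult],
                        origin: str = "pX",
                        bin_width: float = 0.05) -> ExpressionMap:
    """Histogram the fate of every simulated round per alpha value.

    Accepts either the DataFrame of :func:`alpha_sweep` run with
    ``keep_results=True`` or a plain sequence of traffic results.
    """
    if isinstance(sweep, pd.DataFrame):
        results = sweep.attrs.get("results")
        if not results:
            raise ValueError(
                "sweep DataFrame carries no simulation results; rerun "
                "alpha_sweep(keep_results=True)")
        alphas = sweep["alpha"].to_numpy()
    else:
        results = list(sweep)
        if not results:
            raise ValueError("no results to map")
        alphas = np.array([r.config.alpha for r in results])
    cols = {f"{a:g}": _map_from_outcomes(r, origin, bin_width)
            for a, r in zip(alphas, results)}
    frame = pd.DataFrame(cols)
    n_bins = int(round(1.0 / bin_width))
    edges = np.round(np.arange(n_bins) * bin_width, 10)
    return ExpressionMap(alphas=alphas, bin_edges=edges, fractions=frame)


# ---------------------------------------------------------------------------
# Hill fits
# ---------------------------------------------------------------------------

@dataclass
class HillFit:
    """Least-squares Hill description of a switch curve.

    ``H`` is signed: positive for responses rising with alpha, negative for
    falling ones.  ``adj_r2`` uses n - 3 residual degrees of freedom; fits
    below the 0.95 acceptance level are flagged ``low_quality``.
    """

    k_max: float
    K: float
    H: float
    adj_r2: float
    converged: bool = True

    @property
    def low_quality(self) -> bool:
        return not (self.adj_r2 >= 0.95)

    def __call__(self, alpha) -> np.ndarray:
        return hill_curve(np.asarray(alpha, dtype=float),
                          self.k_max, self.K, self.H)

    def summary(self) -> str:
        flag = "  [low quality]" if self.low_quality else ""
        return (f"Hill fit: k_max={self.k_max:.4g}, K={self.K:.4g}, "
                f"H={self.H:+.3g}, adj R^2={self.adj_r2:.4f}{flag}")


def hill_curve(alpha: np.ndarray, k_max: float, K: float, H: float) -> np.ndarray:
    """Signed-exponent Hill response k_max * alpha^H / (K^H + alpha^H)."""
    r = np.power(alpha / K, H)
    return k_max * r / (1.0 + r)


def fit_hill(alpha, response, *, h_starts=(1.0, -1.0, 3.0, -3.0, 6.0, -6.0),
             h_max: float = 15.0, k_bounds: tuple[float, float] = (0.05, 20.0)
             ) -> HillFit:
    """Fit the signed Hill form by multi-start bounded least squares.

    Requires at least five strictly positive abscissae and a non-trivial
    response.  Starts are seeded at H in {±1, ±3, ±6} with K at the abscissa
    of the half-range crossing; the best converged start wins.
    """
    a = np.asarray(alpha, dtype=float)
    y = np.asarray(response, dtype=float)
    if a.size < 5:
        raise ValueError("need at least 5 points to fit a Hill curve")
    if (a <= 0).any():
        raise ValueError("alpha values must be strictly positive")
    if (y < 0).any():
        raise ValueError("response values must be nonnegative")
    if not (y > 0).any():
        raise ValueError("all-zero response cannot be fitted")

    half = 0.5 * (y.min() + y.max())
    crossing = a[np.argmin(np.abs(y - half))]
    K0 = float(np.clip(crossing, *k_bounds))
    kmax0 = float(max(y.max(), 1e-12))

    def residual(theta):
        k_max, K, H = theta
        return hill_curve(a, k_max, K, H) - y

    best = None
    lo = [1e-12, k_bounds[0], -h_max]
    hi = [np.inf, k_bounds[1], h_max]
    for h0 in h_starts:
        try:
            sol = least_squares(residual, x0=[kmax0, K0, h0],
                                bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, -np.inf, converged=False)
    k_max, K, H = best.x
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    if ss_tot == 0:
        adj = -np.inf
    else:
        adj = 1.0 - (ss_res / max(n - 3, 1)) / (ss_tot / (n - 1))
    return HillFit(float(k_max), float(K), float(H), float(adj),
                   converged=bool(best.success))


# ---------------------------------------------------------------------------
# dynamic range and sensitivity
# ---------------------------------------------------------------------------

def dynamic_range(sweep: pd.DataFrame, species: str, *,
                  alpha_lo: float = 0.1, alpha_hi: float = 2.0
                  ) -> tuple[float, str]:
    """Fold change of ``species`` between two alpha grid points.

    Returns ``(fold, direction)`` with fold >= 1 and direction one of
    ``"increasing"``, ``"decreasing"``, ``"flat"`` or ``"infinite"``.
    """
    def level(a):
        i = np.flatnonzero(np.isclose(sweep["alpha"], a, rtol=1e-6))
        if i.size == 0:
            raise ValueError(f"alpha={a} not present in the sweep")
        return float(sweep[species].iloc[i[0]])

    lo, hi = level(alpha_lo), level(alpha_hi)
    if lo == hi:
        return 1.0, "flat"
    if min(lo, hi) == 0:
        return float("inf"), "infinite"
    if hi > lo:
        return hi / lo, "increasing"
    return lo / hi, "decreasing"


def sensitivity_sweep(base: dict, parameter: str, factors: Sequence[float],
                      evaluate: Callable[[dict], dict]) -> pd.DataFrame:
    """One-factor-at-a-time sensitivity table.

    ``base`` maps component names (e.g. ``"ti"``, ``"kin"``, ``"gn"``) to
    parameter objects; ``parameter`` is ``"component.field"``.  Each factor
    scales the base value, the modified bundle is passed to ``evaluate`` and
    its returned record becomes one row.  Factors that violate a structural
    constraint are recorded as rejected rather than silently dropped.
    """
    comp, _, fieldname = parameter.partition(".")
    if comp not in base:
        raise KeyError(f"unknown component {comp!r}")
    obj = base[comp]
    if not hasattr(obj, fieldname):
        raise KeyError(f"{comp!r} has no parameter {fieldname!r}")
    base_value = getattr(obj, fieldname)
    rows = []
    for f in factors:
        row = {"parameter": parameter, "factor": f,
               "value": base_value * f, "rejected": False, "error": ""}
        try:
            mod = dict(base)
            mod[comp] = replace(obj, **{fieldname: base_value * f})
            row.update(evaluate(mod))
        except (ParameterError, ValueError) as err:
            row["rejected"] = True
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)
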