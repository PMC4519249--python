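"""Parameter containers for the three model layers.

The traffic layer (:class:`TIConfig`) describes two convergent promoters, pX on
the sense strand and pY on the antisense strand, separated by an overlapping
region of ``L`` base pairs.  The RNA layer (:class:`RNAKinetics`) holds the
binding / unbinding / degradation constants of the sense-antisense hybrid
kinetics, and the protein layer (:class:`GNParams`) the translation and
feedback constants of the gene-network model.

Main-text parameter values (binding and initiation times, geometry, velocity,
survival probabilities) are experimentally grounded and carry provenance tag
``"literature"``.  Constants known only to within broad ranges (RNA kinetic constants,
degradation rates, protein constants) are exposed with documented placeholder
defaults and tag ``"placeholder"``; see ``docs/methods.md`` for how each
default was chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

__all__ = [
    "PromoterParams",
    "PauseSite",
    "TIConfig",
    "RNAKinetics",
    "GNParams",
    "PROVENANCE",
]


class ParameterError(ValueError):
    """A parameter violates one of the model's structural constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class PromoterParams:
    """One promoter of the convergent pair.

    Parameters
    ----------
    name : str
        Label, conventionally ``"pX"`` or ``"pY"``.
    tau_B : float
        Mean RNAP binding time in seconds; the firing rate is ``1 / tau_B``.
    tau_I : float
        Mean initiation (open-complex) time in seconds.  Must be smaller than
        ``tau_B`` so that self-occlusion can be neglected.
    noise_cv : float
        Coefficient of variation of the Gaussian noise applied to both times.
    """

    name: str
    tau_B: float
    tau_I: float
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        _require(self.tau_B > 0, f"{self.name}: tau_B must be > 0, got {self.tau_B}")
        _require(self.tau_I > 0, f"{self.name}: tau_I must be > 0, got {self.tau_I}")
        _require(
            self.tau_I < self.tau_B,
            f"{self.name}: initiation time tau_I ({self.tau_I}) must stay below the "
            f"binding time tau_B ({self.tau_B}) so self-occlusion is negligible",
        )
        _require(self.noise_cv >= 0, f"{self.name}: noise_cv must be >= 0")

    @property
    def firing_rate(self) -> float:
        """RNAP firing rate f = 1/tau_B (1/s)."""
        return 1.0 / self.tau_B


@dataclass(frozen=True)
class PauseSite:
    """A transcriptional pause site inside the overlap.

    A paused elongation complex behaves like a promoter-bound sitting duck for
    opposing traffic: when an opposing EC closes within the critical distance,
    the paused RNAP is removed with probability ``removal_prob_on_hit``
    (producing a truncated RNA ending at the pause position); otherwise it acts
    as a roadblock and the incoming EC is the one that terminates.
    """

    strand: str  # "sense" | "antisense"
    position: int  # bp coordinate in the overlap, 1..L
    duration: float  # extra residence time in seconds
    removal_prob_on_hit: float = 0.9

    def __post_init__(self) -> None:
        _require(self.strand in ("sense", "antisense"),
                 f"pause strand must be 'sense' or 'antisense', got {self.strand!r}")
        _require(self.position >= 1, "pause position must be >= 1")
        _require(self.duration >= 0, "pause duration must be >= 0")
        _require(0 <= self.removal_prob_on_hit <= 1,
                 "removal_prob_on_hit must be in [0, 1]")


@dataclass(frozen=True)
class TIConfig:
    """Full configuration of the discrete RNAP-traffic simulation."""

    pX: PromoterParams
    pY: PromoterParams
    L: int = 400
    fp_ic: float = 70.0
    fp_ec: float = 35.0
    v_mean: float = 50.0
    v_sd: float = 2.5
    delta_critical: float | None = None  # defaults to fp_ec
    sdc_survival: float = 0.1
    collision_one_survives: float = 0.8
    pause_sites: tuple[PauseSite, ...] = ()
    n_rounds: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.L > 0, "overlap length L must be > 0")
        _require(self.v_mean > 0, "v_mean must be > 0")
        _require(self.v_sd >= 0, "v_sd must be >= 0")
        _require(self.fp_ic > 0 and self.fp_ec > 0, "footprints must be > 0")
        if self.delta_critical is None:
            object.__setattr__(self, "delta_critical", self.fp_ec)
        _require(self.delta_critical >= 0, "delta_critical must be >= 0")
        _require(0 <= self.sdc_survival <= 1, "sdc_survival must be in [0, 1]")
        _require(0 <= self.collision_one_survives <= 1,
                 "collision_one_survives must be in [0, 1]")
        _require(self.n_rounds >= 1, "n_rounds must be >= 1")
        object.__setattr__(self, "pause_sites", tuple(self.pause_sites))
        for ps in self.pause_sites:
            _require(ps.position <= self.L,
                     f"pause position {ps.position} outside overlap 1..{self.L}")

    # -- derived quantities -------------------------------------------------
    @property
    def alpha(self) -> float:
        """Relative promoter strength alpha = f_Y / f_X = tau_BX / tau_BY."""
        return self.pX.tau_B / self.pY.tau_B

    def with_alpha(self, alpha: float) -> "TIConfig":
        """Return a copy with pY retuned so that f_Y/f_X equals ``alpha``.

        pX is left untouched (it plays the constitutive promoter); pY's binding
        time becomes ``tau_BX / alpha``.  Raises :class:`ParameterError` when
        the resulting binding time would not exceed pY's initiation time.
        """
        _require(alpha > 0, "alpha must be > 0")
        tau_BY = self.pX.tau_B / alpha
        return replace(self, pY=replace(self.pY, tau_B=tau_BY))

    def with_seed(self, seed: int) -> "TIConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def study_defaults(cls, *, n_rounds: int = 30_000, seed: int = 0) -> "TIConfig":
        """The main study condition: tau_BX=20 s, tau_IX=12 s, tau_IY=9.5 s,
        L=400 bp, v=50±2.5 bp/s, 5% timing noise, alpha=1 (tau_BY=20 s)."""
        return cls(
            pX=PromoterParams("pX", tau_B=20.0, tau_I=12.0, noise_cv=0.05),
            pY=PromoterParams("pY", tau_B=20.0, tau_I=9.5, noise_cv=0.05),
            L=400,
            n_rounds=n_rounds,
            seed=seed,
        )


@dataclass(frozen=True)
class RNAKinetics:
    """Kinetic constants of the antisense-RNA interaction layer.

    The four second-order binding constants (nM^-1 s^-1) cover the hybrid
    species x:y, x_k:y, x:y_h and x_k:y_h.  The first three hybrids share the
    unbinding rate ``k_uxy``; the doubly-truncated hybrid x_k:y_h has the
    larger ``k_uxkyh`` because its complementary region is shorter.  All
    defaults are placeholders inside the literature ranges (binding 10^6-10^7
    M^-1 s^-1, mRNA decay on the E. coli half-life scale).
    """

    k_bxy: float = 0.0017
    k_bxky: float = 0.0017
    k_bxyh: float = 0.0017
    k_bxkyh: float = 0.0017
    k_uxy: float = 1e-3
    k_uxkyh: float = 1e-2
    lambda_x: float = 3e-3
    lambda_y: float = 3e-3
    lambda_xk: float = 3e-3
    lambda_yh: float = 3e-3
    lambda_xy: float = 3e-3
    lambda_xky: float = 3e-3
    lambda_xyh: float = 3e-3
    lambda_xkyh: float = 3e-3
    mu: float = 3e-4

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")
        _require(self.k_uxkyh >= self.k_uxy,
                 "k_uxkyh must be >= k_uxy (shorter complementary region)")

    def without_binding(self) -> "RNAKinetics":
        """Copy with all hybrid-formation constants zeroed (AR switched off)."""
        return replace(self, k_bxy=0.0, k_bxky=0.0, k_bxyh=0.0, k_bxkyh=0.0)


@dataclass(frozen=True)
class GNParams:
    """Protein-layer constants of the gene-network model.

    Repressor X binds the pY operator with equilibrium constant ``K_OY``; the
    pY firing rate interpolates between ``f_Y_min`` (fully repressed) and
    ``f_Y_max`` (de-repressed).  The strength ratios f_Y,min/f_X=0.37
    and f_Y,max/f_X=1.74 are enforced by the defaults (f_X = 0.05 1/s).
    Activator Z is produced externally at rate ``k_WZ`` and by Y at rate
    ``k_YZ * [Y]``; Z sequesters X in the X:Z complex.  All numeric defaults
    other than the two ratios are documented placeholders, chosen (see
    ``docs/methods.md``) so that the default network sits in the reversible
    bistable regime with an OFF-to-ON threshold on the 10 nM/s dose scale and
    loses bistability when antisense interaction is switched off.
    """

    k_X: float = 1.4
    k_Y: float = 0.01
    k_WZ: float = 0.0
    k_YZ: float = 2e-3
    k_XZ: float = 0.01
    k_uXZ: float = 1e-3
    K_OY: float = 10.0
    f_Y_min: float = 0.0185
    f_Y_max: float = 0.087
    lambda_X: float = 3e-3
    lambda_Y: float = 3e-4
    lambda_Z: float = 3e-3
    lambda_XZ: float = 3e-4
    mu: float = 3e-4

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")
        _require(self.K_OY > 0, "K_OY must be > 0")
        _require(self.f_Y_min <= self.f_Y_max, "f_Y_min must be <= f_Y_max")


#: Provenance of every configurable constant: experimentally grounded
#: literature values versus placeholders chosen inside stated ranges.
PROVENANCE: dict[str, str] = {
    # traffic layer -- literature-grounded values
    "pX.tau_B": "literature", "pX.tau_I": "literature", "pY.tau_I": "literature",
    "pX.noise_cv": "literature", "pY.noise_cv": "literature",
    "L": "literature", "fp_ic": "literature", "fp_ec": "literature",
    "v_mean": "literature", "v_sd": "literature", "delta_critical": "literature",
    "sdc_survival": "literature", "collision_one_survives": "literature",
    "n_rounds": "literature",
    "pY.tau_B": "literature",  # set through alpha
    # RNA layer -- literature gives ranges only
    "k_bxy": "placeholder", "k_bxky": "placeholder", "k_bxyh": "placeholder",
    "k_bxkyh": "placeholder", "k_uxy": "placeholder", "k_uxkyh": "placeholder",
    "lambda_x": "placeholder", "lambda_y": "placeholder",
    "lambda_xk": "placeholder", "lambda_yh": "placeholder",
    "lambda_xy": "placeholder", "lambda_xky": "placeholder",
    "lambda_xyh": "placeholder", "lambda_xkyh": "placeholder",
    "mu": "placeholder",
    # protein layer
    "f_Y_min": "literature", "f_Y_max": "literature",  # fix the ratios 0.37 / 1.74
    "k_X": "placeholder", "k_Y": "placeholder", "k_YZ": "placeholder",
    "k_XZ": "placeholder", "k_uXZ": "placeholder", "K_OY": "placeholder",
    "lambda_X": "placeholder", "lambda_Y": "placeholder",
    "lambda_Z": "placeholder", "lambda_XZ": "placeholder",
}
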