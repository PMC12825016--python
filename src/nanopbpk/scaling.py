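"""Allometric mouse-to-human extrapolation of the kinetic parameters.

First-order rate constants scale across species with body weight to the
power −0.25 (the standard allometric exponent for rates):

    P_h = P_m * (BW_h / BW_m) ** b,     b = −0.25

Only the two excretion rate constants are scaled.  Unbound fractions are
treated as species-portable initial guesses and the empirical blood flows
are replaced by the target species' physiological values; the assembled
set is a *starting point* for recalibration against clinical data, not a
prediction in itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite

from .params import KineticParams, PhysiologyParams

__all__ = ["ScalingSpec", "allometric_scale", "build_human_model"]


@dataclass(frozen=True)
class ScalingSpec:
    """Body weights (kg) and allometric exponent for interspecies scaling."""

    bw_m: float = 0.02
    bw_h: float = 70.0
    exponent: float = -0.25

    def __post_init__(self) -> None:
        if not (isfinite(self.bw_m) and self.bw_m > 0):
            raise ValueError("mouse body weight must be strictly positive")
        if not (isfinite(self.bw_h) and self.bw_h > 0):
            raise ValueError("human body weight must be strictly positive")

    @property
    def factor(self) -> float:
        """The multiplicative scaling factor (BW_h / BW_m) ** exponent."""
        return (self.bw_h / self.bw_m) ** self.exponent


def allometric_scale(p_mouse: float, spec: ScalingSpec = ScalingSpec()) -> float:
    """Scale a first-order rate constant (h^-1) from mouse to human."""
    if p_mouse < 0:
        raise ValueError("rate constants must be non-negative")
    return p_mouse * spec.factor


def build_human_model(
    mouse_kin: KineticParams,
    human_phys: PhysiologyParams,
    spec: ScalingSpec = ScalingSpec(),
) -> KineticParams:
    """Assemble a human initial-guess parameter set from a mouse fit.

    Excretion rate constants are allometrically scaled; unbound fractions
    carry over unchanged; the empirical MPS/others flows are replaced by
    the human physiological defaults.  Feed the result to
    :meth:`~nanopbpk.mpbpk.MinimalPBPKModel.fit` as the starting point for
    recalibration.
    """
    return KineticParams(
        f_lu=mouse_kin.f_lu,
        f_mps=mouse_kin.f_mps,
        f_k=mouse_kin.f_k,
        f_o=mouse_kin.f_o,
        k_e_mps=allometric_scale(mouse_kin.k_e_mps, spec),
        k_e_k=allometric_scale(mouse_kin.k_e_k, spec),
        q_mps=human_phys.q_mps,
        q_o=human_phys.q_o,
        np_label=mouse_kin.np_label,
        species=human_phys.species,
    )
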