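"""Closed-form approximations and scaling laws, calibrated against numerics.

The adiabatic pipeline admits analytic limits when at most ternary complexes
matter and hybridization is weak:

* the optimal free-strand concentration ratio of VCG oligomers to feedstock
  decays exponentially with oligomer length,
  ``ratio_opt ~ sqrt(1/Lambda_FF - 1/L_V) * exp(-|gamma| L_V / 2)``;
* the maximal replication efficiency approaches one as
  ``eta_max ~ 1 - eta0 * sqrt(1/Lambda_FF - 1/L_V) * L_V * exp(-|gamma| L_V/2)``;
* with dimer feedstock the competition of correct and false monomer/dimer
  extensions bounds the efficiency by a ratio of effective association
  prefactors;
* under kinetic suppression the high-concentration plateau of the
  monomer-extension-competent fraction is set by the monomer concentration
  and affinity alone, and the half-saturation VCG concentration scales as
  ``exp(-|gamma| L_V)``.

The constants ``Lambda_FF``, ``eta0`` and the ``K``-prefactors are treated as
calibration constants: they are fitted (least squares, on a log scale where
appropriate) to the equilibrium pipeline on a training range of oligomer
lengths, then validated on disjoint lengths.  The numerics are always the
reference, never the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import build_system, solve_equilibrium
from .observables import extension_fractions, optimize_single_length
from .pool import LengthDistribution

__all__ = [
    "TheoryConstants",
    "optimal_ratio",
    "eta_max_approx",
    "dimer_bound",
    "r_inf",
    "threshold_scaling",
    "calibrate_optimal_ratio",
    "calibrate_eta_max",
    "half_saturation",
    "CalibrationResult",
]


@dataclass(frozen=True)
class TheoryConstants:
    """Genome- and model-dependent constants of the scaling laws."""

    Lambda_FF: float = 1.0  # length scale of the F+F flux (nt)
    eta0: float = 1.0  # prefactor of the efficiency shortfall
    amplitude: float = 1.0  # proportionality constant of the ratio law
    K_1Vc: float = 1.0  # effective association prefactors (per M)
    K_2Vc: float = 1.0
    K_2Vf: float = 1.0

    def __post_init__(self) -> None:
        if min(self.Lambda_FF, self.eta0, self.amplitude, self.K_1Vc, self.K_2Vc, self.K_2Vf) <= 0:
            raise ValueError("theory constants must be positive")


def optimal_ratio(L_V: float, gamma: float, consts: TheoryConstants) -> float:
    """Optimal equilibrium concentration ratio of free VCG to free feedstock
    strands; decays exponentially in ``L_V`` with rate ``|gamma|/2``."""
    arg = 1.0 / consts.Lambda_FF - 1.0 / L_V
    if arg <= 0:
        raise ValueError(f"L_V={L_V} below the domain boundary Lambda_FF={consts.Lambda_FF}")
    return consts.amplitude * math.sqrt(arg) * math.exp(-abs(gamma) * L_V / 2.0)


def eta_max_approx(L_V: float, gamma: float, consts: TheoryConstants) -> float:
    """Maximal replication efficiency attainable at oligomer length ``L_V``."""
    arg = 1.0 / consts.Lambda_FF - 1.0 / L_V
    if arg <= 0:
        raise ValueError(f"L_V={L_V} below the domain boundary Lambda_FF={consts.Lambda_FF}")
    return 1.0 - consts.eta0 * math.sqrt(arg) * L_V * math.exp(-abs(gamma) * L_V / 2.0)


def dimer_bound(kappa_F: float, consts: TheoryConstants) -> float:
    """Upper efficiency bound for monomer+dimer feedstock; the dimer fraction
    enters through ``exp(-kappa_F)`` and the bound tends to 1 without
    dimers."""
    if kappa_F < 0:
        raise ValueError("kappa_F must be >= 0")
    e = math.exp(-kappa_F)
    num = consts.K_1Vc + 0.5 * consts.K_2Vc * e
    den = consts.K_1Vc + 0.5 * (consts.K_2Vc + consts.K_2Vf) * e
    return num / den


def r_inf(c1: float, Kd1: float, c_std: float = 1.0) -> float:
    """High-concentration plateau of the monomer-extension-competent
    fraction: set by the monomer concentration ``c1`` and the dissociation
    constant ``Kd1`` of a monomer binding next to a primer on a duplex."""
    if c1 < 0 or Kd1 <= 0:
        raise ValueError("need c1 >= 0 and Kd1 > 0")
    return (c_std / Kd1 + 1.0 - 2.0 * Kd1 / (3.0 * c_std)) * c1 / (6.0 * c_std)


def threshold_scaling(L_V: float, gamma: float, prefactor: float = 1.0) -> float:
    """Half-saturation VCG concentration, up to a prefactor:
    ``prefactor * exp(-L_V * |gamma|)``."""
    if gamma >= 0:
        raise ValueError("gamma must be < 0")
    return prefactor * math.exp(-L_V * abs(gamma))


# ---------------------------------------------------------------------------
# Calibration against the adiabatic numerics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    consts: TheoryConstants
    lengths: tuple
    targets: tuple  # numerical values the fit was trained on
    residual_rms: float  # rms misfit on the (log) training scale

    def to_dict(self) -> dict:
        return {
            "constants": {
                "Lambda_FF": self.consts.Lambda_FF,
                "eta0": self.consts.eta0,
                "amplitude": self.consts.amplitude,
            },
            "training_lengths": list(self.lengths),
            "training_values": list(self.targets),
            "residual_rms": self.residual_rms,
        }


def _numerical_optima(scales, model, lengths, c_feed=1e-4, c_range=(1e-12, 1e-4)):
    """Optimal free-concentration ratio and maximal efficiency per length."""
    ratios, etas = [], []
    for L in lengths:
        system = build_system([1, L], scales, model)
        base = LengthDistribution.from_concentrations({1: c_feed, L: 1e-8}, scales.L_U)
        res = optimize_single_length(base, system, *c_range)
        ratios.append(res.eq_ratio)
        etas.append(res.eta_max)
    return np.array(ratios), np.array(etas)


def calibrate_optimal_ratio(scales, model, lengths=(5, 6, 7, 8)) -> CalibrationResult:
    """Fit (amplitude, Lambda_FF) of the optimal-ratio law to numerical
    optima on the training lengths (least squares in log space)."""
    lengths = tuple(lengths)
    ratios, _ = _numerical_optima(scales, model, lengths)
    g = abs(model.gamma)

    def resid(p):
        log_amp, lam = p
        out = []
        for L, r in zip(lengths, ratios):
            arg = max(1.0 / lam - 1.0 / L, 1e-12)
            out.append(log_amp + 0.5 * math.log(arg) - g * L / 2.0 - math.log(r))
        return out

    sol = least_squares(resid, [0.0, 1.5], bounds=([-50, 1e-3], [50, min(lengths) - 1e-6]))
    consts = TheoryConstants(Lambda_FF=float(sol.x[1]), amplitude=math.exp(sol.x[0]))
    rms = float(np.sqrt(np.mean(np.square(sol.fun))))
    return CalibrationResult(consts, lengths, tuple(ratios), rms)


def calibrate_eta_max(scales, model, lengths=(5, 6, 7, 8), Lambda_FF=None) -> CalibrationResult:
    """Fit (eta0, Lambda_FF) of the maximal-efficiency law to numerical
    optima (least squares on log(1 - eta))."""
    lengths = tuple(lengths)
    _, etas = _numerical_optima(scales, model, lengths)
    g = abs(model.gamma)

    def shortfall(L, eta0, lam):
        arg = max(1.0 / lam - 1.0 / L, 1e-12)
        return eta0 * math.sqrt(arg) * L * math.exp(-g * L / 2.0)

    if Lambda_FF is None:

        def resid(p):
            log_eta0, lam = p
            return [
                math.log(shortfall(L, math.exp(log_eta0), lam)) - math.log(1.0 - e)
                for L, e in zip(lengths, etas)
            ]

        sol = least_squares(resid, [0.0, 1.5], bounds=([-50, 1e-3], [50, min(lengths) - 1e-6]))
        consts = TheoryConstants(eta0=math.exp(sol.x[0]), Lambda_FF=float(sol.x[1]))
    else:

        def resid(p):
            return [
                math.log(shortfall(L, math.exp(p[0]), Lambda_FF)) - math.log(1.0 - e)
                for L, e in zip(lengths, etas)
            ]

        sol = least_squares(resid, [0.0])
        consts = TheoryConstants(eta0=math.exp(sol.x[0]), Lambda_FF=Lambda_FF)
    rms = float(np.sqrt(np.mean(np.square(sol.fun))))
    return CalibrationResult(consts, lengths, tuple(etas), rms)


def half_saturation(scales, model, L_V, c_feed=(0.091e-3, 9.1e-6), c_range=(1e-12, 1e-3)) -> float:
    """Numerically determined VCG concentration at which r_1+V reaches half
    its high-concentration plateau (single-length pool, kinetic
    suppression)."""
    from scipy.optimize import brentq

    system = build_system([1, 2, L_V], scales, model)
    c1, c2 = c_feed

    def r_at(c):
        dist = LengthDistribution.from_concentrations(
            {1: c1, 2: c2, L_V: c}, scales.L_U
        )
        state = solve_equilibrium(dist, system)
        r, _ = extension_fractions(state)
        return r[L_V]

    plateau = r_at(c_range[1])
    root = brentq(
        lambda lg: r_at(10.0**lg) - plateau / 2.0,
        math.log10(c_range[0]),
        math.log10(c_range[1]),
        xtol=1e-4,
    )
    return 10.0**root
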