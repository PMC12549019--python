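"""Mass-action (de)hybridization equilibrium under the adiabatic assumption.

Ligation is far slower than hybridization, so strand lengths are conserved
while binding equilibrates.  For every oligomer length the free strands plus
all complexes containing that length must add up to the total concentration;
complex concentrations follow the mass-action law with effective association
constants.  This yields one fourth-degree polynomial equation per length,
solved by Levenberg-Marquardt root finding in log concentration space.

Complex bookkeeping is aggregated by length multiset: the equilibrium (and
every observable derived from it) only needs sums of effective association
constants grouped by the participating strand lengths, so the cost per solver
iteration is set by the number of length combinations, not by the (much
larger) number of configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .complexes import (
    EnergyModel,
    enumerate_configs,
    geometry,
    hybridization_energy,
    multiplicity,
)

__all__ = ["ComplexSystem", "EquilibriumState", "build_system", "solve_equilibrium", "free_fraction"]


@dataclass(frozen=True)
class ComplexSystem:
    """All complexes over a fixed strand-length set, aggregated by length
    multiset.

    ``multisets[m]`` is a sorted length tuple, ``A[m]`` the summed effective
    association constant of every configuration with those strand lengths, and
    ``N[m, l]`` the number of strands of ``lengths[l]`` in the multiset.
    ``channels`` maps ``(m, le1, le2, lo1, lo2, template_len)`` to the summed
    effective association constant of all ligation-competent (nicked)
    junctions with those educt lengths and educt-template overlaps.
    """

    lengths: tuple
    scales: object
    model: EnergyModel
    max_order: int
    multisets: tuple
    A: np.ndarray
    AE: np.ndarray  # energy-weighted sums: sum of Ka*E per multiset (kT)
    N: np.ndarray
    channels: dict
    n_configs: int
    index: dict = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {L: i for i, L in enumerate(self.lengths)})


def build_system(lengths_present, scales, model: EnergyModel, max_order: int = 4) -> ComplexSystem:
    """Enumerate and aggregate every complex over the given lengths."""
    lengths = tuple(sorted(set(int(L) for L in lengths_present)))
    mass: dict = {}
    emass: dict = {}
    channels: dict = {}
    n_configs = 0
    for cfg in enumerate_configs(lengths, max_order):
        geo = geometry(cfg)
        E = hybridization_energy(cfg, model, geo)
        ka = multiplicity(cfg, scales, geo) * np.exp(-E) / model.c_std ** (
            cfg.n_strands - 1
        )
        m = tuple(sorted(cfg.lengths))
        mass[m] = mass.get(m, 0.0) + ka
        emass[m] = emass.get(m, 0.0) + ka * E
        for nick in geo.nicks:
            key = (m, *nick)
            channels[key] = channels.get(key, 0.0) + ka
        n_configs += 1
    multisets = tuple(sorted(mass))
    A = np.array([mass[m] for m in multisets])
    AE = np.array([emass[m] for m in multisets])
    N = np.zeros((len(multisets), len(lengths)), dtype=float)
    idx = {L: i for i, L in enumerate(lengths)}
    for mi, m in enumerate(multisets):
        for L in m:
            N[mi, idx[L]] += 1
    mindex = {m: i for i, m in enumerate(multisets)}
    channels = {
        (mindex[key[0]],) + key[1:]: ka for key, ka in channels.items()
    }
    return ComplexSystem(
        lengths=lengths,
        scales=scales,
        model=model,
        max_order=max_order,
        multisets=multisets,
        A=A,
        AE=AE,
        N=N,
        channels=channels,
        n_configs=n_configs,
    )


@dataclass(frozen=True)
class EquilibriumState:
    """Free-strand and aggregated complex concentrations at equilibrium.

    ``x[l]`` is the free concentration of one specific sequence of length
    ``lengths[l]``; coarse-grained free concentrations are ``C(L) * x``.
    """

    system: ComplexSystem
    totals: np.ndarray  # coarse totals per length (M)
    x: np.ndarray  # per-sequence free concentrations (M)
    residual_norm: float
    n_iterations: int

    @property
    def lengths(self) -> tuple:
        return self.system.lengths

    @property
    def c_free(self) -> np.ndarray:
        """Coarse-grained free-strand concentration per length (M)."""
        mult = np.array([self.system.scales.multiplicity(L) for L in self.lengths])
        return mult * self.x

    @property
    def multiset_conc(self) -> np.ndarray:
        """Aggregated complex concentration per length multiset (M)."""
        with np.errstate(divide="ignore"):
            u = np.log(self.x)
        return self.system.A * np.exp(self.system.N @ u)

    def monomials(self) -> np.ndarray:
        """``prod_j x_{L_j}`` per multiset -- multiply by a group's summed
        effective association constant to get its concentration."""
        with np.errstate(divide="ignore"):
            u = np.log(self.x)
        return np.exp(self.system.N @ u)

    def expected_total_energy(self, nav: float) -> float:
        """Expected total hybridization energy of a volume holding ``nav``
        counts per molar (kT) -- the adiabatic prediction for the stochastic
        simulator's dG_tot."""
        return float(self.system.AE @ self.monomials()) * nav

    def free_total(self, vcg: bool, split_length: int) -> float:
        """Summed free coarse concentration of the VCG (or feedstock) side."""
        sel = [
            i
            for i, L in enumerate(self.lengths)
            if (L >= split_length) == vcg
        ]
        return float(self.c_free[sel].sum())


class EquilibriumError(RuntimeError):
    pass


def _solve_once(system: ComplexSystem, totals: np.ndarray, u0: np.ndarray, tol: float, max_iter: int):
    N, A = system.N, system.A
    mult = np.array([float(system.scales.multiplicity(L)) for L in system.lengths])

    def residual(u):
        t = A * np.exp(N @ u)
        lhs = mult * np.exp(u) + N.T @ t
        return lhs / totals - 1.0

    def jac(u):
        t = A * np.exp(N @ u)
        J = (N.T * t) @ N  # d(complex part)/du
        J += np.diag(mult * np.exp(u))
        return J / totals[:, None]

    sol = least_squares(
        residual,
        u0,
        jac=jac,
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=max_iter * len(u0),
    )
    return sol.x, float(np.max(np.abs(residual(sol.x)))), sol.nfev


def solve_equilibrium(
    dist,
    system: ComplexSystem,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the coupled mass-conservation equations for the pool ``dist``.

    Unknowns are log per-sequence free concentrations (positivity is then
    automatic and the pM..mM dynamic range is well conditioned); residuals are
    relative conservation violations.  Initialization at free = total lies in
    the convergence basin for all tested regimes; a damped continuation in the
    total concentrations is used as a fallback.
    """
    totals = np.array([dist[L] for L in system.lengths], dtype=float)
    if np.any(totals < 0):
        raise ValueError("negative total concentration")
    if np.all(totals == 0):
        return EquilibriumState(system, totals, np.zeros_like(totals), 0.0, 0)
    if np.any(totals == 0):
        raise ValueError(
            "system was built for lengths not present in the pool; "
            "rebuild with the pool's length set"
        )
    mult = np.array([float(system.scales.multiplicity(L)) for L in system.lengths])
    u0 = np.log(totals / mult)
    u, res, nfev = _solve_once(system, totals, u0, tol, max_iter)
    if res > tol:  # damped continuation from a dilute pool
        u = u0.copy()
        for scale in np.logspace(-6, 0, 13):
            u, res, n2 = _solve_once(system, totals * scale, u, tol, max_iter)
            nfev += n2
    if res > tol:
        raise EquilibriumError(
            f"equilibrium solver did not converge: worst relative residual "
            f"{res:.3e} after {nfev} evaluations"
        )
    return EquilibriumState(system, totals, np.exp(u), res, nfev)


def free_fraction(state: EquilibriumState, L: int) -> float:
    """Fraction of oligomers of length ``L`` that are free (unbound)."""
    i = state.system.index[L]
    if state.totals[i] == 0:
        raise ValueError(f"length {L} has zero total concentration")
    return float(state.c_free[i] / state.totals[i])
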