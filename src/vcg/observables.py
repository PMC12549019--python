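"""Replication observables from an equilibrium state.

All observables are ratios of nucleotide-incorporation fluxes through
ligation-competent (nicked) complexes, with each junction weighted by the
length of the shorter educt strand:

* yield ``y``      -- fraction of flux producing VCG-length products
                      (product length >= L_U);
* fidelity ``f``   -- genome-compatible fraction of the VCG-producing flux,
                      via the combinatorial correct-product probability
                      ``p_corr``;
* efficiency ``eta = f * y``;
* ligation shares ``s(type)`` over F+F / F+V / V+V channels (educts shorter
  than L_U count as feedstock), split into correct/false parts;
* extension-competent fractions ``r_1+V(L)`` -- the fraction of L-mers
  sitting in a complex where a monomer could be ligated onto them.

Under kinetic suppression only junctions that incorporate a monomer count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .equilibrium import ComplexSystem, EquilibriumState, solve_equilibrium

__all__ = [
    "LigationChannel",
    "ReplicationObservables",
    "ligation_channels",
    "p_correct",
    "compute_observables",
    "extension_fractions",
    "find_crossing",
    "optimize_single_length",
    "optimize_two_length",
    "OptimumResult",
]


@dataclass(frozen=True)
class LigationChannel:
    """One ligation-competent junction class with its aggregated weight."""

    multiset: tuple
    le1: int
    le2: int
    lo1: int
    lo2: int
    template: int
    ka_sum: float
    p_corr: float
    type_label: str  # 'F+F' | 'F+V' | 'V+V'

    @property
    def weight(self) -> int:
        return min(self.le1, self.le2)

    @property
    def product_length(self) -> int:
        return self.le1 + self.le2


def p_correct(le1: int, le2: int, lo1: int, lo2: int, scales) -> float:
    """Probability that a nicked configuration ligates into a product whose
    sequence is compatible with the genome.

    The number of realizable products is set by the multiplicity of possible
    templates across the nick and of the educts at their overlaps; only
    product sequences that exist on the genome are correct.  Capped at 1 for
    robustness on biased genomes.
    """
    C = scales.multiplicity
    p = (C(le1 + le2) * C(lo1) * C(lo2)) / (C(lo1 + lo2) * C(le1) * C(le2))
    return min(p, 1.0)


def _type_label(le1: int, le2: int, L_U: int) -> str:
    n_vcg = (le1 >= L_U) + (le2 >= L_U)
    return ("F+F", "F+V", "V+V")[n_vcg]


def ligation_channels(system: ComplexSystem, kinetic_suppression: bool = False):
    """Aggregated ligation channels of a complex system (one entry per
    distinct (length multiset, educt lengths, overlaps, template) class)."""
    scales = system.scales
    out = []
    for (mi, le1, le2, lo1, lo2, lt), ka in system.channels.items():
        if kinetic_suppression and min(le1, le2) != 1:
            continue
        out.append(
            LigationChannel(
                multiset=system.multisets[mi],
                le1=le1,
                le2=le2,
                lo1=lo1,
                lo2=lo2,
                template=lt,
                ka_sum=ka,
                p_corr=p_correct(le1, le2, lo1, lo2, scales),
                type_label=_type_label(le1, le2, scales.L_U),
            )
        )
    return out


@dataclass(frozen=True)
class ReplicationObservables:
    yield_y: float
    fidelity_f: float
    efficiency_eta: float
    shares: dict
    total_flux: float
    defined: bool

    def __str__(self) -> str:  # pragma: no cover - convenience only
        if not self.defined:
            return "ReplicationObservables(undefined: zero ligation flux)"
        s = ", ".join(f"{k}={v:.3f}" for k, v in self.shares.items())
        return (
            f"y={self.yield_y:.3f} f={self.fidelity_f:.3f} "
            f"eta={self.efficiency_eta:.3f} [{s}]"
        )


def compute_observables(
    state: EquilibriumState,
    kinetic_suppression: bool = False,
    use_lu_min: bool = False,
) -> ReplicationObservables:
    """Yield, fidelity, efficiency and ligation shares from the equilibrium
    concentrations of nicked complexes.

    A product counts as a VCG oligomer when its length reaches the genome's
    measured unique length ``L_U`` (switchable to the lower bound
    ``L_U_min``).  Zero total flux leaves the observables undefined
    (NaN, ``defined=False``).
    """
    system = state.system
    scales = system.scales
    threshold = scales.L_U_min if use_lu_min else scales.L_U
    mono = state.monomials()
    total = 0.0
    vcg_flux = 0.0
    correct_vcg_flux = 0.0
    shares = {k: 0.0 for k in ("F+F", "F+V,c", "F+V,f", "V+V,c", "V+V,f", "1+1")}
    for (mi, le1, le2, lo1, lo2, lt), ka in system.channels.items():
        if kinetic_suppression and min(le1, le2) != 1:
            continue
        flux = min(le1, le2) * ka * mono[mi]
        if flux == 0.0:
            continue
        total += flux
        p = p_correct(le1, le2, lo1, lo2, scales)
        label = _type_label(le1, le2, scales.L_U)
        if label == "F+F":
            shares["F+F"] += flux
            if le1 == le2 == 1:
                shares["1+1"] += flux
        else:
            shares[f"{label},c"] += p * flux
            shares[f"{label},f"] += (1.0 - p) * flux
        if le1 + le2 >= threshold:
            vcg_flux += flux
            correct_vcg_flux += p * flux
    if total == 0.0:
        nan = float("nan")
        return ReplicationObservables(nan, nan, nan, shares, 0.0, False)
    y = vcg_flux / total
    f = correct_vcg_flux / vcg_flux if vcg_flux > 0 else float("nan")
    eta = correct_vcg_flux / total
    shares = {k: v / total for k, v in shares.items()}
    return ReplicationObservables(y, f, eta, shares, total, True)


def extension_fractions(state: EquilibriumState):
    """Monomer-extension-competent fractions.

    Returns ``(r, r_decomposed)``: ``r[L]`` is the fraction of L-mers bound in
    a complex with a monomer ligatable onto them,
    ``r_decomposed[(L_educt, L_template)]`` splits it by template length.
    """
    system = state.system
    mono = state.monomials()
    conc: dict = {}
    decomposed: dict = {}
    for (mi, le1, le2, lo1, lo2, lt), ka in system.channels.items():
        if min(le1, le2) != 1 or max(le1, le2) == 1:
            continue
        L = max(le1, le2)
        c = ka * mono[mi]
        conc[L] = conc.get(L, 0.0) + c
        decomposed[(L, lt)] = decomposed.get((L, lt), 0.0) + c
    totals = {L: state.totals[state.system.index[L]] for L in state.lengths}
    r = {L: conc.get(L, 0.0) / totals[L] for L in totals if L > 1}
    r_dec = {key: v / totals[key[0]] for key, v in decomposed.items()}
    return r, r_dec


# ---------------------------------------------------------------------------
# Sweeps: crossing concentrations and efficiency optima
# ---------------------------------------------------------------------------


def find_crossing(
    base_dist,
    system: ComplexSystem,
    L_a: int,
    L_b: int,
    c_lo: float,
    c_hi: float,
    n_scan: int = 13,
) -> float:
    """Total VCG concentration at which the monomer-extension-competent
    fraction of ``L_a``-mers overtakes that of ``L_b``-mers.

    Scans ``cV_tot`` on a log grid to bracket the sign change of
    ``r(L_a) - r(L_b)`` and polishes the root by bisection; raises if no sign
    change occurs in the scanned range.
    """
    if L_a == L_b:
        raise ValueError("need two distinct oligomer lengths")

    def diff(log_c):
        state = solve_equilibrium(base_dist.scaled_vcg(10.0**log_c), system)
        r, _ = extension_fractions(state)
        return r[L_a] - r[L_b]

    grid = np.linspace(math.log10(c_lo), math.log10(c_hi), n_scan)
    vals = [diff(g) for g in grid]
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            return 10.0 ** grid[k]
        if vals[k] * vals[k + 1] < 0:
            root = brentq(diff, grid[k], grid[k + 1], xtol=1e-4)
            return 10.0**root
    raise ValueError(
        f"r({L_a}) - r({L_b}) does not change sign in "
        f"[{c_lo:.3e}, {c_hi:.3e}] M"
    )


@dataclass(frozen=True)
class OptimumResult:
    c_opt: tuple
    eta_max: float
    window: tuple  # concentration window of <=1% sub-optimality (1D only)
    eq_ratio: float  # free c_V / free c_F at the optimum (1D only)


def _eta_single(base_dist, system, c, kinetic_suppression=False):
    state = solve_equilibrium(base_dist.scaled_vcg(c), system)
    return compute_observables(state, kinetic_suppression).efficiency_eta, state


def optimize_single_length(
    base_dist,
    system: ComplexSystem,
    c_lo: float,
    c_hi: float,
    points_per_decade: int = 8,
    kinetic_suppression: bool = False,
) -> OptimumResult:
    """Maximize replication efficiency over the total VCG concentration.

    Log grid scan followed by golden-section refinement; also reports the
    concentration window within which the efficiency stays within 1% of the
    optimum, and the free-strand concentration ratio at the optimum.
    """
    lo, hi = math.log10(c_lo), math.log10(c_hi)
    n = max(int((hi - lo) * points_per_decade) + 1, 5)
    grid = np.linspace(lo, hi, n)
    etas = np.array([_eta_single(base_dist, system, 10.0**g, kinetic_suppression)[0] for g in grid])
    if np.all(np.isnan(etas)) or np.nanmax(etas) - np.nanmin(etas) < 1e-12:
        raise ValueError("efficiency landscape is flat over the scanned range")
    k = int(np.nanargmax(etas))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, n - 1)]
    res = minimize_scalar(
        lambda g: -_eta_single(base_dist, system, 10.0**g, kinetic_suppression)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-4},
    )
    g_opt = float(res.x)
    eta_max, state = _eta_single(base_dist, system, 10.0**g_opt, kinetic_suppression)
    if eta_max < np.nanmax(etas):  # guard against refinement between wrong neighbors
        g_opt = float(grid[k])
        eta_max, state = _eta_single(base_dist, system, 10.0**g_opt, kinetic_suppression)

    def short(g):
        return _eta_single(base_dist, system, 10.0**g, kinetic_suppression)[0] - 0.99 * eta_max

    w_lo = 10.0**lo if short(lo) >= 0 else 10.0 ** brentq(short, lo, g_opt, xtol=1e-3)
    w_hi = 10.0**hi if short(hi) >= 0 else 10.0 ** brentq(short, g_opt, hi, xtol=1e-3)
    split = system.scales.L_U
    ratio = state.free_total(True, split) / state.free_total(False, split)
    return OptimumResult((10.0**g_opt,), eta_max, (w_lo, w_hi), ratio)


def optimize_two_length(
    make_dist,
    system: ComplexSystem,
    range_a: tuple,
    range_b: tuple,
    points_per_decade: int = 8,
    flat_tol: float | None = None,
) -> OptimumResult:
    """Maximize efficiency over two independently varied VCG concentrations.

    ``make_dist(c_a, c_b)`` must build the pool; a log grid scan locates the
    basin and Nelder-Mead refines the optimum in log space.

    If ``flat_tol`` is given, efficiencies within ``flat_tol`` of the maximum
    are treated as numerically indistinguishable and the *largest* ``c_a`` on
    the resulting plateau is reported for the first axis.  This resolves
    landscapes that are monotone (degenerate) along ``c_a``: the optimum then
    sits on a flat shoulder whose edge, not the scan boundary, is the
    meaningful coordinate.  For a genuine interior optimum the rule is
    neutral, since the plateau hugs the maximum.
    """

    def eta(ga, gb):
        state = solve_equilibrium(make_dist(10.0**ga, 10.0**gb), system)
        return compute_observables(state).efficiency_eta

    ga_grid = np.arange(
        math.log10(range_a[0]), math.log10(range_a[1]) + 1e-9, 1.0 / points_per_decade
    )
    gb_grid = np.arange(
        math.log10(range_b[0]), math.log10(range_b[1]) + 1e-9, 1.0 / points_per_decade
    )
    grid_eta = np.array([[eta(ga, gb) for gb in gb_grid] for ga in ga_grid])
    ia, ib = np.unravel_index(np.nanargmax(grid_eta), grid_eta.shape)
    res = minimize(
        lambda v: -eta(*v),
        x0=np.array([ga_grid[ia], gb_grid[ib]]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12},
    )
    ga_opt, gb_opt = (float(v) for v in res.x)
    eta_max = max(-float(res.fun), float(grid_eta[ia, ib]))
    if flat_tol is None:
        return OptimumResult((10.0**ga_opt, 10.0**gb_opt), eta_max, (), float("nan"))
    profile = np.array([eta(ga, gb_opt) for ga in ga_grid])
    threshold = float(np.nanmax(profile)) - flat_tol
    tied = np.nonzero(profile >= threshold)[0]
    ka = int(tied.max())
    ga_edge = float(ga_grid[ka])

    def short(ga):
        return eta(ga, gb_opt) - threshold

    if ka + 1 < len(ga_grid) and short(float(ga_grid[ka + 1])) < 0:
        ga_edge = brentq(short, ga_edge, float(ga_grid[ka + 1]), xtol=1e-3)
    return OptimumResult((10.0**ga_edge, 10.0**gb_opt), eta_max, (), float("nan"))
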