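"""Sequence-explicit stochastic simulation of hybridization and ligation.

The simulator evolves explicit molecules (single strands and complexes of up
to four strands) with the Gillespie algorithm:

* association of any two molecules at every geometrically valid relative
  placement, each placement at the encounter rate ``k_enc = 1/(c_std*t0)``;
  by default placements creating a non-Watson-Crick pair are rejected
  outright (the ``penalized`` policy admits them with a ``gamma_mm`` energy
  penalty per affected block);
* dissociation of a complex into any two connected sub-assemblies at
  ``k_off = k_enc * c_std * exp(dG)``, the detailed-balance partner of the
  association move;
* templated ligation at every nick (two strands abutting over a paired
  template) at the configured rate, optionally split between
  monomer-incorporating and oligomer-only ligations.

Complexes are laid out on two rows: bottom strands run 5'->3' left-to-right,
top strands antiparallel.  A complex and its 180-degree rotation are the same
molecule; species are canonicalized accordingly.

Because realistic ligation rates make actual ligation events vanishingly
rare, replication observables are estimated from the *occupancy* of
ligation-competent complexes in decorrelated equilibrium snapshots, with
Gaussian error propagation for the ratio estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .complexes import EnergyModel

__all__ = [
    "SimulationParams",
    "Trajectory",
    "TimescaleResult",
    "EstimatorResult",
    "simulate",
    "detect_timescales",
    "estimate_observables",
    "estimate_total_energy",
]

AVOGADRO = 6.02214076e23
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationParams:
    """Run settings: ``volume`` in cubic micrometres fixes the
    concentration-to-count conversion; times are in units of ``t0``."""

    volume: float
    t_final: float
    seed: int = 0
    mismatch_policy: str = "reject"  # or "penalized"
    max_strands: int = 4
    n_record: int = 2000
    n_snapshots: int = 120

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.t_final <= 0:
            raise ValueError("volume and t_final must be positive")
        if self.mismatch_policy not in ("reject", "penalized"):
            raise ValueError(f"unknown mismatch policy {self.mismatch_policy!r}")

    @property
    def nav(self) -> float:
        """Counts per molar: N_A * V in litres."""
        return AVOGADRO * self.volume * 1e-15


# ---------------------------------------------------------------------------
# Assembly geometry (tuples of (row, start, sequence))
# ---------------------------------------------------------------------------


def _normalize(strands):
    lo = min(s for _, s, _ in strands)
    return tuple(sorted((r, s - lo, q) for r, s, q in strands))


def _flip(strands):
    hi = max(s + len(q) for _, s, q in strands)
    return tuple(sorted((1 - r, hi - (s + len(q)), q) for r, s, q in strands))


def canonical(strands):
    """Canonical representative of an assembly under translation and
    180-degree rotation (sequences ride along unchanged: rotating swaps row
    and mirrors position but preserves 5'->3' reading)."""
    a = _normalize(strands)
    return min(a, _normalize(_flip(a)))


def _columns(strands):
    """col -> {row: base} occupancy map."""
    occ: dict = {}
    for r, s, q in strands:
        L = len(q)
        for idx, ch in enumerate(q):
            c = s + idx if r == 0 else s + L - 1 - idx
            occ.setdefault(c, {})[r] = ch
    return occ


def _paired_columns(occ):
    return {c: d for c, d in occ.items() if len(d) == 2}


def _is_wc(d):
    return _COMP[d[0]] == d[1]


def assembly_energy(strands, model: EnergyModel) -> float:
    """Nearest-neighbor block energy of an explicit assembly (kT).

    Matches the coarse-grained convention exactly: gamma per block of two
    paired columns (a nick closes a block), gamma/2 per dangling end, and in
    'penalized' accounting gamma_mm per block touching a mismatched pair.
    """
    if len(strands) == 1:
        return 0.0
    occ = _columns(strands)
    paired = _paired_columns(occ)
    E = 0.0
    for c, d in paired.items():
        if c + 1 in paired:
            bad = not _is_wc(d) or not _is_wc(paired[c + 1])
            E += model.gamma_mm if bad else model.gamma
        elif c + 1 in occ:
            E += model.gamma / 2.0
        if c - 1 not in paired and c - 1 in occ:
            E += model.gamma / 2.0
    return E


def _part_valid(strands):
    """Every strand pairs within the part and the pairing graph connects."""
    n = len(strands)
    if n == 1:
        return True
    adj = [set() for _ in range(n)]
    for i, (ri, si, qi) in enumerate(strands):
        for j in range(i + 1, n):
            rj, sj, qj = strands[j]
            if ri != rj and min(si + len(qi), sj + len(qj)) - max(si, sj) >= 1:
                adj[i].add(j)
                adj[j].add(i)
    if any(not a for a in adj):
        return False
    seen, stack = {0}, [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def _same_row_clash(strands):
    for r in (0, 1):
        spans = sorted((s, s + len(q)) for rr, s, q in strands if rr == r)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                return True
    return False


def assembly_nicks(strands):
    """Ligatable junctions: (le1, le2, product_sequence, weight)."""
    occ = _columns(strands)
    paired = _paired_columns(occ)
    out = []
    for row in (0, 1):
        rs = sorted((st for st in strands if st[0] == row), key=lambda st: st[1])
        for A, B in zip(rs, rs[1:]):
            if A[1] + len(A[2]) != B[1]:
                continue
            if B[1] - 1 in paired and B[1] in paired:
                le1, le2 = len(A[2]), len(B[2])
                # bottom row reads left-to-right 5'->3', top row the reverse
                product = A[2] + B[2] if row == 0 else B[2] + A[2]
                out.append((le1, le2, product, min(le1, le2)))
    return out


def enumerate_splits(strands, model: EnergyModel):
    """Dissociation channels: ((part1, part2), k_off) for every bipartition
    into two valid sub-assemblies."""
    n = len(strands)
    if n < 2:
        return []
    E_total = assembly_energy(strands, model)
    out = []
    for mask in range(1, 2 ** (n - 1)):
        p = tuple(strands[i] for i in range(n) if mask >> i & 1)
        q = tuple(strands[i] for i in range(n) if not mask >> i & 1)
        if not (_part_valid(p) and _part_valid(q)):
            continue
        dG = E_total - assembly_energy(p, model) - assembly_energy(q, model)
        k_off = model.k_enc * model.c_std * math.exp(dG)
        out.append(((canonical(p), canonical(q)), k_off))
    return out


from functools import lru_cache


@lru_cache(maxsize=200_000)
def _static(strands):
    """Cached geometry of an assembly: single-occupancy columns as
    (col, row, base) triples, per-row spans, and the horizontal extent."""
    occ = _columns(strands)
    singles = tuple(
        (c, *next(iter(d.items()))) for c, d in occ.items() if len(d) == 1
    )
    spans = (
        tuple((s, s + len(q)) for r, s, q in strands if r == 0),
        tuple((s, s + len(q)) for r, s, q in strands if r == 1),
    )
    lo = min(s for _, s, _ in strands)
    hi = max(s + len(q) for _, s, q in strands)
    return occ, singles, spans, lo, hi


@lru_cache(maxsize=10_000)
def _orientations(strands):
    # sorted so that channel enumeration order (and hence the event
    # sequence under a fixed seed) is independent of hash randomization
    return tuple(sorted({strands, _normalize(_flip(strands))}))


def enumerate_joins(a, b, policy="reject", max_strands=4):
    """Association channels: canonical results of every valid relative
    placement of ``b`` (either orientation) against ``a``."""
    if len(a) + len(b) > max_strands:
        return []
    results = []
    occ_a, singles_a, spans_a, a_min, a_max = _static(a)
    single_map_a = {c: (r, base) for c, r, base in singles_a}
    reject = policy == "reject"
    for orient in _orientations(b):
        _, singles_b, spans_b, b_min, b_max = _static(orient)
        for d in range(a_min - b_max + 1, a_max - b_min):
            clash = False
            for row in (0, 1):
                for s1, e1 in spans_a[row]:
                    for s2, e2 in spans_b[row]:
                        if s2 + d < e1 and s1 < e2 + d:
                            clash = True
                            break
                    if clash:
                        break
                if clash:
                    break
            if clash:
                continue
            paired = False
            ok = True
            for c, rb, base_b in singles_b:
                hit = single_map_a.get(c + d)
                if hit is None:
                    continue
                ra, base_a = hit
                if ra == rb:
                    continue
                paired = True
                if reject:
                    b0 = base_a if ra == 0 else base_b
                    b1 = base_b if ra == 0 else base_a
                    if _COMP[b0] != b1:
                        ok = False
                        break
            if paired and ok:
                shifted = tuple((r, s + d, q) for r, s, q in orient)
                results.append(canonical(a + shifted))
    return results


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------


@dataclass
class EstimatorResult:
    mean: float
    sigma: float
    n_samples: int


@dataclass
class TimescaleResult:
    tau_star: float
    tau_eq: float
    tau_corr: float
    fit_ok: bool


@dataclass
class Trajectory:
    """Recorded output of one stochastic run."""

    times: np.ndarray  # uniform recording grid
    dG: np.ndarray  # total hybridization energy on the grid (kT)
    snapshots: list  # (time, {species_id: count})
    species: dict  # species_id -> assembly tuple
    energies: dict  # species_id -> energy (kT)
    nicks: dict  # species_id -> ((le1, le2, product, weight), ...)
    genome: object
    model: EnergyModel
    params: SimulationParams
    n_events: int
    event_counts: dict
    ligations: list  # (time, le1, le2, product_len, correct)
    realized_concentrations: dict = None  # length -> molar, after count rounding

    def nucleotide_count(self, counts) -> int:
        return sum(
            n * sum(len(q) for _, _, q in self.species[sid])
            for sid, n in counts.items()
        )


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------


class _Sim:
    def __init__(self, genome, model, params):
        self.genome = genome
        self.model = model
        self.params = params
        self.species: dict = {}  # id -> assembly
        self.ids: dict = {}  # assembly -> id
        self.energy: dict = {}
        self.unary: dict = {}  # id -> (rate cumsum array, outcomes list)
        self.nicks: dict = {}
        self.counts: dict = {}
        self.present: set = set()
        self.joins_cache: dict = {}
        self.pair_nchan: dict = {}
        self.k0 = model.k_enc / params.nav
        # propensity slots as flat arrays for fast selection
        self.prop = np.zeros(1024)
        self.slot_key: list = []
        self.slot_idx: dict = {}
        self.by_species: dict = {}  # id -> set of slot indices

    def sid(self, assembly):
        if assembly not in self.ids:
            i = len(self.species)
            self.ids[assembly] = i
            self.species[i] = assembly
            self.energy[i] = assembly_energy(assembly, self.model)
            nicks = assembly_nicks(assembly)
            self.nicks[i] = tuple(
                (le1, le2, prod, w, self.genome.contains_motif(prod))
                for le1, le2, prod, w in nicks
            )
            self._build_unary(i)
        return self.ids[assembly]

    def _build_unary(self, i):
        assembly = self.species[i]
        rates, outcomes = [], []
        for (p, q), k_off in enumerate_splits(assembly, self.model):
            rates.append(k_off)
            outcomes.append(("split", p, q))
        for nick_idx, (le1, le2, prod, w, _) in enumerate(self.nicks[i]):
            rate = (
                self.model.lig_rate_mono
                if min(le1, le2) == 1
                else self.model.lig_rate_oligo
            )
            if rate > 0:
                rates.append(rate)
                outcomes.append(("ligate", (nick_idx, le1, le2, prod), None))
        self.unary[i] = (np.cumsum(rates), outcomes)

    def n_joins(self, i, j):
        """Join channels for a species pair, cached as canonical assemblies;
        species registration is deferred until a join actually fires."""
        key = (i, j) if i <= j else (j, i)
        res = self.joins_cache.get(key)
        if res is None:
            res = enumerate_joins(
                self.species[key[0]],
                self.species[key[1]],
                self.params.mismatch_policy,
                self.params.max_strands,
            )
            self.joins_cache[key] = res
        return res

    # -- propensity bookkeeping ------------------------------------------

    def _slot(self, key):
        idx = self.slot_idx.get(key)
        if idx is None:
            idx = len(self.slot_key)
            self.slot_idx[key] = idx
            self.slot_key.append(key)
            if idx >= self.prop.size:
                self.prop = np.concatenate([self.prop, np.zeros(self.prop.size)])
            for sid in key[1:]:
                self.by_species.setdefault(sid, set()).add(idx)
        return idx

    def touch(self, i):
        n = self.counts.get(i, 0)
        if n <= 0:
            self.present.discard(i)
            for idx in self.by_species.get(i, ()):
                self.prop[idx] = 0.0
            return
        self.present.add(i)
        cum, _ = self.unary[i]
        if len(cum) and cum[-1] > 0:
            idx = self._slot(("u", i))
            self.prop[idx] = n * cum[-1]
        # tight loop: pair propensities of i against every present species
        counts = self.counts
        pair_n = self.pair_nchan
        slot_idx = self.slot_idx
        prop = self.prop
        k0 = self.k0
        for j in self.present:
            key = (i, j) if i <= j else (j, i)
            nch = pair_n.get(key)
            if nch is None:
                nch = len(self.n_joins(i, j))
                pair_n[key] = nch
            if not nch:
                continue
            pairs = n * (n - 1) * 0.5 if i == j else n * counts[j]
            pk = ("p",) + key
            idx = slot_idx.get(pk)
            if idx is None:
                idx = self._slot(pk)
                prop = self.prop  # may have been reallocated
            prop[idx] = k0 * nch * pairs

    def compact(self):
        """Drop zeroed slots so selection stays O(active channels)."""
        keep = [k for k, v in zip(self.slot_key, self.prop) if v > 0.0]
        vals = {k: self.prop[self.slot_idx[k]] for k in keep}
        self.slot_key = []
        self.slot_idx = {}
        self.by_species = {}
        self.prop = np.zeros(max(1024, 2 * len(keep)))
        for k in keep:
            self.prop[self._slot(k)] = vals[k]

    def change(self, i, delta):
        self.counts[i] = self.counts.get(i, 0) + delta
        if self.counts[i] < 0:  # pragma: no cover - internal consistency
            raise RuntimeError("negative count")
        self.touch(i)


def simulate(
    dist,
    genome,
    model: EnergyModel,
    params: SimulationParams,
    initial: dict | None = None,
) -> Trajectory:
    """Run the Gillespie dynamics of pool ``dist`` on ``genome``.

    The initial ensemble holds single strands only: every genome-compatible
    sequence of each pooled length at (rounded) equal counts; ``initial``
    ({sequence: count}) overrides it for bespoke mixtures.  Reproducible
    under a fixed ``params.seed``.
    """
    from .genome import length_scales

    scales = length_scales(genome)
    rng = np.random.default_rng(params.seed)
    sim = _Sim(genome, model, params)

    if initial is not None:
        for seq, n in sorted(initial.items()):
            sim.change(sim.sid(((0, 0, seq),)), int(n))
    else:
        for L in dist.lengths:
            motifs = set()
            for strand in (genome.sequence, genome.complement):
                doubled = strand + strand
                for s in range(genome.L_G):
                    motifs.add(doubled[s : s + L])
            c_per_seq = dist[L] / scales.multiplicity(L)
            n = int(round(c_per_seq * params.nav))
            if n == 0:
                raise ValueError(
                    f"length {L}: fewer than one molecule per sequence at this "
                    f"volume ({c_per_seq * params.nav:.2f}); increase the volume"
                )
            for seq in sorted(motifs):
                sim.change(sim.sid(((0, 0, seq),)), n)

    realized: dict = {}
    for sid, n in sim.counts.items():
        L = len(sim.species[sid][0][2])
        realized[L] = realized.get(L, 0.0) + n / params.nav

    grid = np.linspace(0.0, params.t_final, params.n_record)
    dG_series = np.zeros(params.n_record)
    snap_times = np.linspace(0.0, params.t_final, params.n_snapshots + 1)[1:]
    snapshots = []
    dG = sum(sim.energy[i] * n for i, n in sim.counts.items())

    t = 0.0
    gi = 0  # next grid index to fill
    si = 0  # next snapshot index
    n_events = 0
    event_counts = {"assoc": 0, "dissoc": 0, "ligate": 0}
    ligations = []

    while t < params.t_final:
        if n_events % 4096 == 4095 and len(sim.slot_key) > 4 * max(
            1, len(sim.present) ** 2 // 2
        ):
            sim.compact()
        vals = sim.prop[: len(sim.slot_key)]
        total = float(vals.sum())
        if total <= 0.0:
            break
        tau = rng.exponential(1.0 / total)
        t_new = t + tau
        while gi < params.n_record and grid[gi] <= t_new:
            dG_series[gi] = dG
            gi += 1
        while si < len(snap_times) and snap_times[si] <= t_new:
            snapshots.append((snap_times[si], dict(sim.counts)))
            si += 1
        t = t_new
        if t >= params.t_final:
            break
        r = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(vals), r))
        idx = min(idx, len(sim.slot_key) - 1)
        key = sim.slot_key[idx]
        if key[0] == "u":
            i = key[1]
            cum_rates, outcomes = sim.unary[i]
            choice = int(np.searchsorted(cum_rates, rng.random() * cum_rates[-1]))
            choice = min(choice, len(outcomes) - 1)
            kind, x, y = outcomes[choice]
            if kind == "split":
                sim.change(i, -1)
                sim.change(sim.sid(x), +1)
                sim.change(sim.sid(y), +1)
                dG += (
                    sim.energy[sim.ids[x]] + sim.energy[sim.ids[y]] - sim.energy[i]
                )
                event_counts["dissoc"] += 1
            else:  # ligation
                nick_idx, le1, le2, prod = x
                new_assembly = _ligate(sim.species[i], nick_idx)
                sim.change(i, -1)
                j = sim.sid(new_assembly)
                sim.change(j, +1)
                dG += sim.energy[j] - sim.energy[i]
                event_counts["ligate"] += 1
                ligations.append(
                    (t, le1, le2, le1 + le2, genome.contains_motif(prod))
                )
        else:
            _, i, j = key
            chans = sim.n_joins(i, j)
            k = sim.sid(chans[int(rng.integers(len(chans)))])
            sim.change(i, -1)
            sim.change(j, -1)
            sim.change(k, +1)
            dG += sim.energy[k] - sim.energy[i] - sim.energy[j]
            event_counts["assoc"] += 1
        n_events += 1

    while gi < params.n_record:
        dG_series[gi] = dG
        gi += 1
    while si < len(snap_times):
        snapshots.append((snap_times[si], dict(sim.counts)))
        si += 1

    return Trajectory(
        times=grid,
        dG=dG_series,
        snapshots=snapshots,
        species=dict(sim.species),
        energies=dict(sim.energy),
        nicks=dict(sim.nicks),
        genome=genome,
        model=model,
        params=params,
        n_events=n_events,
        event_counts=event_counts,
        ligations=ligations,
        realized_concentrations=realized,
    )


def _ligate(strands, nick_index):
    """Fuse the two strands of the ``nick_index``-th nick (enumeration order
    of :func:`assembly_nicks`)."""
    occ = _columns(strands)
    paired = _paired_columns(occ)
    k = -1
    for row in (0, 1):
        rs = sorted((st for st in strands if st[0] == row), key=lambda st: st[1])
        for A, B in zip(rs, rs[1:]):
            if A[1] + len(A[2]) != B[1]:
                continue
            if not (B[1] - 1 in paired and B[1] in paired):
                continue
            k += 1
            if k != nick_index:
                continue
            prod = A[2] + B[2] if row == 0 else B[2] + A[2]
            rest = tuple(st for st in strands if st not in (A, B))
            merged = (row, A[1], prod)
            return canonical(rest + (merged,))
    raise RuntimeError("nick not found for ligation")  # pragma: no cover


# ---------------------------------------------------------------------------
# Diagnostics and estimators
# ---------------------------------------------------------------------------


def detect_timescales(traj: Trajectory) -> TimescaleResult:
    """Equilibration and correlation times from the energy trace.

    A single exponential ``A*exp(-t/tau*) + B`` is fitted to ``dG_tot(t)``
    and the equilibration time is taken as ``tau_eq = 5*tau*``; the
    correlation time comes from an exponential fit to the autocorrelation of
    the post-equilibration trace.  Fit failures fall back to conservative
    defaults with ``fit_ok=False``.
    """
    t, y = traj.times, traj.dG
    dt = t[1] - t[0]
    ok = True
    try:
        p0 = (y[0] - y[-1], max(t[-1] / 10.0, dt), y[-1])
        popt, _ = curve_fit(
            lambda tt, A, tau, B: A * np.exp(-tt / tau) + B, t, y, p0=p0, maxfev=10000
        )
        tau_star = abs(popt[1])
        if not np.isfinite(tau_star) or tau_star > t[-1]:
            raise RuntimeError
    except Exception:
        tau_star, ok = t[-1] / 10.0, False
    tau_eq = 5.0 * tau_star
    post = y[t > min(tau_eq, t[-1] / 2.0)]
    tau_corr = dt
    if post.size >= 16 and np.var(post) > 0:
        z = post - post.mean()
        ac = np.correlate(z, z, mode="full")[z.size - 1 :]
        ac /= ac[0]
        n_lag = int(np.argmax(ac < 0.05)) or min(z.size // 2, 50)
        lags = np.arange(n_lag) * dt
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda k, tau: np.exp(-k / tau), lags, ac[:n_lag],
                    p0=(max(dt, lags[-1] / 3.0),), maxfev=10000,
                )
            tau_corr = max(float(abs(popt[0])), dt)
        except Exception:
            ok = False
    return TimescaleResult(tau_star, tau_eq, tau_corr, ok)


def _ratio(xs, ys) -> EstimatorResult:
    """Ratio-of-means estimator <X>/<Y> with Gaussian error propagation
    including the covariance term."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    n = xs.size
    mx, my = xs.mean(), ys.mean()
    if my == 0:
        return EstimatorResult(float("nan"), float("nan"), n)
    if n < 2:
        return EstimatorResult(mx / my, float("nan"), n)
    vx = xs.var(ddof=1) / n
    vy = ys.var(ddof=1) / n
    cxy = np.cov(xs, ys, ddof=1)[0, 1] / n
    var = vx / my**2 + mx**2 * vy / my**4 - 2.0 * mx * cxy / my**3
    return EstimatorResult(mx / my, math.sqrt(max(var, 0.0)), n)


def select_snapshots(traj: Trajectory, tau_eq: float, tau_corr: float):
    """Post-equilibration snapshots thinned to spacing >= tau_corr."""
    out, t_last = [], -math.inf
    for t, counts in traj.snapshots:
        if t >= tau_eq and t - t_last >= tau_corr:
            out.append((t, counts))
            t_last = t
    return out


def estimate_observables(
    traj: Trajectory,
    scales,
    tau_eq: float | None = None,
    tau_corr: float | None = None,
    kinetic_suppression: bool = False,
) -> dict:
    """Yield, fidelity and efficiency from productive-complex occupancy.

    Each decorrelated snapshot contributes counters of ligation-competent
    complexes weighted by the shorter educt length; product correctness is
    decided by explicit genome membership of the ligated sequence (no
    combinatorial argument needed at the sequence level).
    """
    if tau_eq is None or tau_corr is None:
        ts = detect_timescales(traj)
        tau_eq = ts.tau_eq if tau_eq is None else tau_eq
        tau_corr = ts.tau_corr if tau_corr is None else tau_corr
    picked = select_snapshots(traj, tau_eq, tau_corr)
    if len(picked) < 2:
        raise ValueError("fewer than two decorrelated post-equilibration snapshots")
    tot, vcg, corr = [], [], []
    for _, counts in picked:
        x_tot = x_vcg = x_corr = 0.0
        for sid, n in counts.items():
            if n <= 0:
                continue
            for le1, le2, _prod, w, is_correct in traj.nicks[sid]:
                if kinetic_suppression and min(le1, le2) != 1:
                    continue
                x_tot += n * w
                if le1 + le2 >= scales.L_U:
                    x_vcg += n * w
                    if is_correct:
                        x_corr += n * w
        tot.append(x_tot)
        vcg.append(x_vcg)
        corr.append(x_corr)
    return {
        "yield": _ratio(vcg, tot),
        "fidelity": _ratio(corr, vcg),
        "efficiency": _ratio(corr, tot),
    }


def estimate_total_energy(
    traj: Trajectory, tau_eq: float | None = None, tau_corr: float | None = None
) -> EstimatorResult:
    """Mean total hybridization energy over decorrelated snapshots (kT)."""
    if tau_eq is None or tau_corr is None:
        ts = detect_timescales(traj)
        tau_eq = ts.tau_eq if tau_eq is None else tau_eq
        tau_corr = ts.tau_corr if tau_corr is None else tau_corr
    picked = select_snapshots(traj, tau_eq, tau_corr)
    if len(picked) < 2:
        raise ValueError("fewer than two decorrelated post-equilibration snapshots")
    es = [
        sum(n * traj.energies[sid] for sid, n in counts.items())
        for _, counts in picked
    ]
    es = np.asarray(es, float)
    n = es.size
    return EstimatorResult(es.mean(), es.std(ddof=1) / math.sqrt(n), n)
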