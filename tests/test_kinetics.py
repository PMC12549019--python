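"""Stochastic simulator: geometry, detailed balance, diagnostics, estimators."""

import math

import numpy as np
import pytest

from vcg.complexes import EnergyModel
from vcg.genome import length_scales
from vcg.kinetics import (
    SimulationParams,
    Trajectory,
    assembly_energy,
    assembly_nicks,
    canonical,
    detect_timescales,
    enumerate_joins,
    enumerate_splits,
    estimate_observables,
    estimate_total_energy,
    _ratio,
    simulate,
)
from vcg.pool import LengthDistribution

GAMMA = -2.5


def hexamer_pair():
    a = "AAAGAG"
    b = "CUCUUU"  # reverse complement of a
    return a, b


class TestAssemblyGeometry:
    def test_energy_matches_coarse_convention(self, model):
        a, b = hexamer_pair()
        blunt = (((0, 0, a), (1, 0, b)))
        assert assembly_energy(canonical(blunt), model) == pytest.approx(5 * GAMMA)
        # nicked ternary: two trimers abutting over the hexamer
        nicked = ((0, 0, a), (1, 0, "UUU"), (1, 3, "CUC"))
        assert assembly_energy(canonical(nicked), model) == pytest.approx(5 * GAMMA)

    def test_canonical_is_rotation_invariant(self, model):
        a, b = hexamer_pair()
        asm = ((0, 0, a), (1, 1, "CUCUU"))
        flipped = ((1, 0, a), (0, 0, "CUCUU"))
        assert canonical(asm) == canonical(flipped)
        assert assembly_energy(canonical(asm), model) == assembly_energy(
            canonical(flipped), model
        )

    def test_nick_requires_paired_flanks(self):
        a, _ = hexamer_pair()
        nicked = canonical(((0, 0, a), (1, 0, "UUU"), (1, 3, "CUC")))
        nicks = assembly_nicks(nicked)
        assert len(nicks) == 1
        le1, le2, product, w = nicks[0]
        assert {le1, le2} == {3} and w == 3
        # top strands run 5'->3' right-to-left: the ligated strand is the
        # full reverse complement of the template
        assert product == "CUCUUU"
        # gapped arrangement: no nick
        gapped = canonical(((0, 0, a), (1, 0, "UU"), (1, 3, "CUC")))
        assert assembly_nicks(gapped) == []

    def test_joins_and_splits_are_mutually_consistent(self, model):
        a, b = hexamer_pair()
        sa, sb = canonical((((0, 0, a)),)), canonical((((0, 0, b)),))
        results = enumerate_joins(sa, sb)
        assert results  # complementary strands do hybridize
        for res in set(results):
            parts = {frozenset(pq) for pq, _ in enumerate_splits(res, model)}
            assert frozenset((sa, sb)) in parts

    def test_mismatched_strands_never_join_under_reject(self):
        sa = canonical((((0, 0, "AAAGAG")),))
        sc = canonical((((0, 0, "AAAGAG")),))
        assert enumerate_joins(sa, sc) == []  # A/G-only strands cannot pair


class TestTwoStrandEquilibrium:
    def test_bound_fraction_matches_mass_action(self, genome16, model):
        """Two complementary hexamer species: the duplex occupancy follows
        the closed-form quadratic of two-species mass action."""
        a, b = hexamer_pair()
        # independent oracle: sum exp(-E) over complementary placements
        K_tot = 0.0
        for d in range(-5, 6):
            lo = 6 - abs(d)
            # complementarity base by base at this offset
            match = all(
                a[i] == {"A": "U", "U": "A", "G": "C", "C": "G"}[b[5 - (i - d)]]
                for i in range(max(0, d), min(6, 6 + d))
            )
            if match:
                E = GAMMA * (lo - 1) + (GAMMA / 2) * (2 if d != 0 else 0)
                K_tot += math.exp(-E)
        params = SimulationParams(volume=0.1, t_final=2e7, seed=2, n_record=400, n_snapshots=200)
        n0 = 80
        c = n0 / params.nav
        x = (-1 + math.sqrt(1 + 4 * K_tot * c)) / (2 * K_tot)
        expected = K_tot * x * x * params.nav
        dist = LengthDistribution.from_concentrations({6: 64 * c}, 3)
        traj = simulate(dist, genome16, model, params, initial={a: n0, b: n0})
        bound = [
            sum(n for sid, n in counts.items() if len(traj.species[sid]) == 2)
            for t, counts in traj.snapshots
            if t > 2e6
        ]
        bound = np.array(bound, float)[::5]  # thin to roughly independent
        sem = bound.std(ddof=1) / math.sqrt(bound.size)
        assert abs(bound.mean() - expected) < 3 * max(sem, 0.5)


@pytest.fixture(scope="module")
def short_run(genome16, model):
    dist = LengthDistribution.from_concentrations({6: 3.2e-5}, 3)
    params = SimulationParams(volume=0.02, t_final=5e5, seed=7, n_record=100, n_snapshots=20)
    return simulate(dist, genome16, model, params)


class TestSimulationContracts:
    def test_determinism(self, genome16, model, short_run):
        dist = LengthDistribution.from_concentrations({6: 3.2e-5}, 3)
        params = SimulationParams(volume=0.02, t_final=5e5, seed=7, n_record=100, n_snapshots=20)
        again = simulate(dist, genome16, model, params)
        assert again.n_events == short_run.n_events
        assert again.event_counts == short_run.event_counts
        final_a = {again.species[s]: n for s, n in again.snapshots[-1][1].items() if n}
        final_b = {short_run.species[s]: n for s, n in short_run.snapshots[-1][1].items() if n}
        assert final_a == final_b
        np.testing.assert_array_equal(again.dG, short_run.dG)

    def test_nucleotide_conservation(self, short_run):
        counts = [short_run.nucleotide_count(c) for _, c in short_run.snapshots]
        assert len(set(counts)) == 1

    def test_equilibrium_energy_matches_adiabatic_prediction(self, genome16, scales16, model):
        """<dG_tot> from the stochastic run agrees with the aggregated
        equilibrium prediction within 3 sigma (small residual finite-volume
        bias is expected and stays within the band)."""
        from vcg.equilibrium import build_system, solve_equilibrium

        dist = LengthDistribution.from_concentrations({6: 3.2e-5}, scales16.L_U)
        params = SimulationParams(volume=0.05, t_final=3e6, seed=1, n_record=500, n_snapshots=60)
        traj = simulate(dist, genome16, model, params)
        est = estimate_total_energy(traj)
        state = solve_equilibrium(dist, build_system([6], scales16, model))
        expected = state.expected_total_energy(params.nav)
        assert abs(est.mean - expected) < 3 * est.sigma

    def test_split_ligation_rates_suppress_oligomer_ligation(self, genome16, scales16):
        """With k_lig_oligo = 0 no V+V ligation ever fires, while monomer
        ligations do occur at an artificially high rate."""
        model = EnergyModel(k_lig=1e-3, k_lig_mono=1e-3, k_lig_oligo=0.0)
        dist = LengthDistribution.from_concentrations({1: 1e-4, 6: 3.3e-6}, scales16.L_U)
        params = SimulationParams(volume=0.02, t_final=2e6, seed=9, n_record=100, n_snapshots=10)
        traj = simulate(dist, genome16, model, params)
        assert traj.event_counts["ligate"] > 0
        assert all(min(le1, le2) == 1 for _, le1, le2, _, _ in traj.ligations)

    def test_too_small_volume_is_rejected(self, genome16, scales16, model):
        dist = LengthDistribution.from_concentrations({6: 1e-9}, scales16.L_U)
        with pytest.raises(ValueError, match="volume"):
            simulate(dist, genome16, model, SimulationParams(volume=0.01, t_final=1e3))


class TestDiagnostics:
    @staticmethod
    def _synthetic_traj(tau, noise, seed=0, n=2000, t_final=5e5):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, t_final, n)
        y = -100.0 * np.exp(-t / tau) - 500.0 + noise * rng.standard_normal(n)
        return Trajectory(
            times=t, dG=y, snapshots=[], species={}, energies={}, nicks={},
            genome=None, model=None, params=None, n_events=0, event_counts={},
            ligations=[],
        )

    def test_recovers_known_equilibration_time(self):
        traj = self._synthetic_traj(tau=3e4, noise=0.5)
        ts = detect_timescales(traj)
        assert ts.fit_ok
        assert ts.tau_star == pytest.approx(3e4, rel=0.05)
        assert ts.tau_eq == pytest.approx(5 * ts.tau_star)

    def test_white_noise_has_correlation_time_of_one_sample(self):
        traj = self._synthetic_traj(tau=1e3, noise=5.0, seed=3)
        ts = detect_timescales(traj)
        dt = traj.times[1] - traj.times[0]
        assert ts.tau_corr <= 2 * dt


class TestEstimators:
    def test_identical_counters_give_unit_ratio_with_zero_sigma(self):
        xs = [3.0, 5.0, 2.0, 7.0]
        res = _ratio(xs, xs)
        assert res.mean == 1.0
        # perfect covariance cancels the variance up to float roundoff
        assert res.sigma == pytest.approx(0.0, abs=1e-6)

    def test_sigma_shrinks_with_volume(self, genome16, model):
        """sigma of the energy estimator scales roughly as 1/sqrt(V) at
        fixed sampling."""
        dist = LengthDistribution.from_concentrations({6: 3.2e-5}, 3)
        sigmas = []
        for vol, seed in ((0.02, 21), (0.18, 22)):
            params = SimulationParams(volume=vol, t_final=1.5e6, seed=seed, n_record=300, n_snapshots=40)
            traj = simulate(dist, genome16, model, params)
            est = estimate_total_energy(traj, tau_eq=5e5, tau_corr=5e4)
            sigmas.append(est.sigma / abs(est.mean))
        # ninefold volume: relative sigma should drop by about 3 (loose band)
        assert 1.5 < sigmas[0] / sigmas[1] < 6.0

    def test_estimate_requires_decorrelated_samples(self, genome16, model):
        dist = LengthDistribution.from_concentrations({6: 3.2e-5}, 3)
        params = SimulationParams(volume=0.02, t_final=2e5, seed=4, n_record=50, n_snapshots=4)
        traj = simulate(dist, genome16, model, params)
        with pytest.raises(ValueError, match="decorrelated"):
            estimate_observables(traj, length_scales(genome16), tau_eq=1e9, tau_corr=1.0)
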