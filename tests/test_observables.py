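"""Replication observables: correctness probabilities, fluxes, sweeps."""

import math

import numpy as np
import pytest

from conftest import brute_force_shapes, motif_list, rc
from vcg.complexes import ComplexConfig, enumerate_configs, geometry
from vcg.equilibrium import build_system, solve_equilibrium
from vcg.genome import MHConfig, length_scales, sample_genome
from vcg.observables import (
    compute_observables,
    extension_fractions,
    find_crossing,
    ligation_channels,
    optimize_single_length,
    p_correct,
)
from vcg.pool import LengthDistribution


def dist_16(scales, c):
    return LengthDistribution.from_concentrations(dict(c), scales.L_U)


class TestChannels:
    def test_gapped_ternary_has_no_channel(self):
        cfg = ComplexConfig("ternary", (6, 2, 2), (0, 3))  # 1-nt gap
        assert geometry(cfg).nicks == ()

    def test_nicked_1_8_on_9(self, scales16, model):
        """The monomer-extension complex 1|8 on a 9-mer template: one F+V
        channel of weight 1."""
        system = build_system([1, 8, 9], scales16, model)
        chans = [
            ch
            for ch in ligation_channels(system)
            if ch.multiset == (1, 8, 9) and {ch.le1, ch.le2} == {1, 8} and ch.template == 9
        ]
        assert chans
        assert all(ch.weight == 1 and ch.type_label == "F+V" for ch in chans)

    def test_channel_count_matches_brute_force_placements(self, scales16, model):
        """Total nick count over all complexes equals an independent count of
        adjacent-strand placements from the exhaustive shape enumerator."""
        ours = sum(
            len(geometry(cfg).nicks) for cfg in enumerate_configs([1, 6], max_order=3)
        )

        def brute_nicks(shape):
            n = 0
            for row in (0, 1):
                spans = sorted((s, s + L) for r, s, L in shape if r == row)
                other = [(s, s + L) for r, s, L in shape if r != row]
                for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                    if b1 == a2 and any(s <= b1 - 1 and b1 < e for s, e in other):
                        n += 1
            return n

        brute = sum(brute_nicks(s) for s in brute_force_shapes([1, 6], 2))
        brute += sum(brute_nicks(s) for s in brute_force_shapes([1, 6], 3))
        assert ours == brute

    def test_kinetic_suppression_keeps_only_monomer_channels(self, scales16, model):
        system = build_system([1, 6], scales16, model)
        chans = ligation_channels(system, kinetic_suppression=True)
        assert chans
        assert all(min(ch.le1, ch.le2) == 1 for ch in chans)


class TestPCorrect:
    def test_hexamer_short_overlap_error_probability(self, scales16):
        """Hexamer educts with overlaps (1,5): 8 candidate educts, one
        correct -> error probability 7/8."""
        assert p_correct(6, 6, 1, 5, scales16) == pytest.approx(1 / 8)

    def test_unique_overlaps_guarantee_correctness(self, scales16):
        assert p_correct(6, 6, 3, 3, scales16) == 1.0
        assert p_correct(8, 7, 4, 5, scales16) == 1.0

    def test_dimerization_is_always_genome_compatible(self, scales16):
        assert p_correct(1, 1, 1, 1, scales16) == 1.0

    def test_matches_sequence_level_product_checking(self, genome16, scales16):
        """For every nicked ternary educt/overlap class (lengths <= 8),
        explicit enumeration of complementary educt pairs and genome-
        membership checking of the ligated product reproduces p_corr."""
        classes = {}
        for cfg in enumerate_configs(range(1, 9), max_order=3):
            if cfg.kind != "ternary":
                continue
            geo = geometry(cfg)
            for nick in geo.nicks:
                classes.setdefault((nick.le1, nick.le2, nick.lo1, nick.lo2), cfg)
        assert len(classes) > 100

        def partners(length, i, a, b, template):
            sub = rc(template[a:b])
            start = (i + length) - b
            return [
                w
                for w in motif_list(genome16, length)
                if w[start : start + len(sub)] == sub
            ]

        for (le1, le2, lo1, lo2), cfg in classes.items():
            (Lc, Lw1, Lw2), (i, j) = cfg.lengths, cfg.aligns
            n_total = n_correct = 0
            products = set(motif_list(genome16, le1 + le2))
            for s in motif_list(genome16, Lc):
                p1 = partners(Lw1, i, max(i, 0), i + Lw1, s)
                p2 = partners(Lw2, j, j, min(j + Lw2, Lc), s)
                for w1 in p1:
                    for w2 in p2:
                        n_total += 1
                        # Watson strands run 5'->3' right-to-left: the joined
                        # strand reads W2 then W1
                        if w2 + w1 in products:
                            n_correct += 1
            assert n_total > 0
            assert n_correct / n_total == pytest.approx(
                p_correct(le1, le2, lo1, lo2, scales16)
            ), (le1, le2, lo1, lo2)


class TestObservables:
    def test_efficiency_is_fidelity_times_yield(self, scales16, model):
        system = build_system([1, 6], scales16, model)
        for ratio in (1e-4, 1e-3, 1e-2):
            state = solve_equilibrium(dist_16(scales16, {1: 1e-4, 6: 1e-4 * ratio}), system)
            obs = compute_observables(state)
            assert obs.efficiency_eta == pytest.approx(obs.fidelity_f * obs.yield_y)

    def test_shares_partition_to_one(self, scales16, model):
        system = build_system([1, 6, 8], scales16, model)
        state = solve_equilibrium(
            dist_16(scales16, {1: 1e-4, 6: 1e-7, 8: 1e-7}), system
        )
        obs = compute_observables(state)
        main = ["F+F", "F+V,c", "F+V,f", "V+V,c", "V+V,f"]
        assert sum(obs.shares[k] for k in main) == pytest.approx(1.0)
        assert obs.shares["1+1"] <= obs.shares["F+F"] + 1e-15

    def test_dimer_products_never_count_toward_yield(self, scales16, model):
        """In a monomer+hexamer pool the only F+F channel is 1+1, whose dimer
        products fall below L_U: the yield is exactly the non-F+F flux."""
        system = build_system([1, 6], scales16, model)
        state = solve_equilibrium(dist_16(scales16, {1: 1e-4, 6: 1e-9}), system)
        obs = compute_observables(state)
        assert obs.defined
        assert obs.yield_y == pytest.approx(1.0 - obs.shares["F+F"])
        assert obs.yield_y < 0.05  # dimerization dominates the dilute-VCG limit

    def test_monomer_only_pool_flux_is_undefined(self, scales16, model):
        """With only monomers no template can host two educts at all."""
        system = build_system([1], scales16, model)
        state = solve_equilibrium(dist_16(scales16, {1: 1e-4}), system)
        obs = compute_observables(state)
        assert not obs.defined
        assert math.isnan(obs.yield_y)

    def test_yield_monotone_in_vcg_concentration(self, scales16, model):
        system = build_system([1, 6], scales16, model)
        ys = []
        for c in np.logspace(-9, -5.5, 10):
            state = solve_equilibrium(dist_16(scales16, {1: 1e-4, 6: c}), system)
            ys.append(compute_observables(state).yield_y)
        assert all(a < b for a, b in zip(ys, ys[1:]))

    def test_observable_identities_hold_on_sampled_64nt_genome(self, model):
        """The example-genome invariants carry over to a designed genome."""
        res = sample_genome(64, cfg=MHConfig(beta=1e5, seed=5, n_steps=20_000))
        sc = length_scales(res.genome)
        assert sc.L_E < sc.L_U
        system = build_system([1, 8], sc, model)
        dist = LengthDistribution.from_concentrations({1: 1e-4, 8: 1e-7}, sc.L_U)
        obs = compute_observables(solve_equilibrium(dist, system))
        assert obs.efficiency_eta == pytest.approx(obs.fidelity_f * obs.yield_y)
        main = ["F+F", "F+V,c", "F+V,f", "V+V,c", "V+V,f"]
        assert sum(obs.shares[k] for k in main) == pytest.approx(1.0)
        assert 0.0 <= obs.efficiency_eta <= obs.yield_y <= 1.0


@pytest.fixture(scope="module")
def suppressed_multilength_pool(scales16, model):
    """Multi-length pool: reactive monomers 0.091 mM, dimers 9.1 uM, uniform
    VCG lengths 3..9."""
    c = {1: 0.091e-3, 2: 9.1e-6}
    for L in range(3, 10):
        c[L] = 1e-7 / 7
    base = LengthDistribution.from_concentrations(c, scales16.L_U)
    system = build_system(range(1, 10), scales16, model)
    return base, system


class TestExtensionFractions:
    def test_dilute_vcg_limit(self, scales16, model):
        system = build_system([1, 2, 8], scales16, model)
        state = solve_equilibrium(
            dist_16(scales16, {1: 0.091e-3, 2: 9.1e-6, 8: 1e-16}), system
        )
        r, _ = extension_fractions(state)
        assert r[8] < 1e-6

    def test_crossing_exists_and_is_unique(self, suppressed_multilength_pool):
        """r(8) overtakes r(9) exactly once in the scanned range."""
        base, system = suppressed_multilength_pool
        signs = []
        for c in np.logspace(-8, -5, 16):
            state = solve_equilibrium(base.scaled_vcg(c), system)
            r, _ = extension_fractions(state)
            signs.append(math.copysign(1, r[8] - r[9]))
        flips = sum(a != b for a, b in zip(signs, signs[1:]))
        assert flips == 1
        cross = find_crossing(base, system, 8, 9, 1e-8, 1e-5)
        assert 1e-8 < cross < 1e-5

    def test_decomposition_sums_to_total(self, suppressed_multilength_pool):
        base, system = suppressed_multilength_pool
        state = solve_equilibrium(base.scaled_vcg(1e-6), system)
        r, r_dec = extension_fractions(state)
        for L in range(3, 10):
            total = sum(v for (le, lt), v in r_dec.items() if le == L)
            assert total == pytest.approx(r[L])

    def test_degenerate_crossing_pair_rejected(self, suppressed_multilength_pool):
        base, system = suppressed_multilength_pool
        with pytest.raises(ValueError):
            find_crossing(base, system, 8, 8, 1e-8, 1e-5)


class TestOptimization:
    def test_optimum_beats_grid(self, scales16, model):
        system = build_system([1, 6], scales16, model)
        base = dist_16(scales16, {1: 1e-4, 6: 1e-7})
        res = optimize_single_length(base, system, 1e-9, 1e-4)
        grid_best = max(
            compute_observables(
                solve_equilibrium(base.scaled_vcg(c), system)
            ).efficiency_eta
            for c in np.logspace(-9, -4, 30)
        )
        assert res.eta_max >= grid_best - 1e-9
        assert res.window[0] < res.c_opt[0] < res.window[1]

    def test_single_length_outperforms_multi_length_pool(self, scales16, model):
        """A pool holding only the longest oligomer replicates at least as
        efficiently as any uniform multi-length pool with the same maximum."""
        single = build_system([1, 8], scales16, model)
        res_single = optimize_single_length(
            dist_16(scales16, {1: 1e-4, 8: 1e-7}), single, 1e-10, 1e-5
        )
        multi = build_system([1, 6, 7, 8], scales16, model)
        res_multi = optimize_single_length(
            dist_16(scales16, {1: 1e-4, 6: 1e-7, 7: 1e-7, 8: 1e-7}),
            multi,
            1e-10,
            1e-5,
        )
        assert res_single.eta_max >= res_multi.eta_max - 1e-9
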