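import numpy as np
import pytest

import contextmut as cm
from contextmut import synthetic as syn
from contextmut.context_counting import ContextCountTable, ContextualVariant
from contextmut.errors import ConfigurationError, ScalingError
from contextmut.rate_engine import CANONICAL_KEYS, TRIPLETS

from oracles import brute_rate_groupby


def _cv(up, ref, alt, down, position=10, replichore="left"):
    return ContextualVariant(
        position=position, ref=ref, alt=alt, up_base=up, down_base=down,
        replichore=replichore, oriented_triplet=up + ref + down,
        oriented_ref=ref, oriented_alt=alt,
    )


def _counts(mapping, region="genome"):
    return ContextCountTable(k=3, region=region, strand="reference",
                             counts=dict(mapping))


class TestComputeRates:
    def test_formula_substitution(self):
        params = cm.RunParameters(100, 10)
        m = cm.compute_rates([_cv("A", "C", "T", "G")],
                             _counts({"ACG": 1000}), params, "genome")
        assert m.entries[("A", "C", "T", "G")].rate == pytest.approx(1.0e-6, rel=1e-12)
        assert m.entries[("A", "C", "T", "G")].M == 1

    def test_keyspace_is_192_and_64(self):
        assert len(CANONICAL_KEYS) == 192
        assert len(set(CANONICAL_KEYS)) == 192
        assert len(TRIPLETS) == 64
        params = cm.RunParameters(10, 1)
        m = cm.compute_rates([], _counts({"AAA": 5}), params, "genome")
        assert len(m.entries) == 192
        assert len(cm.aggregate_to_triplets(m)) == 64

    def test_empty_variant_list_zero_and_missing_split(self):
        params = cm.RunParameters(10, 2)
        m = cm.compute_rates([], _counts({"ACG": 7}), params, "genome")
        assert all(e.M == 0 for e in m.entries.values())
        for alt in "AGT":
            assert m.entries[("A", "C", alt, "G")].rate == 0.0  # observed none
        assert m.entries[("A", "A", "C", "A")].rate is None  # unobservable

    def test_zero_denominator_with_mutations_flagged(self):
        params = cm.RunParameters(10, 1)
        with pytest.warns(UserWarning, match="inconsistent"):
            m = cm.compute_rates([_cv("A", "C", "T", "G")],
                                 _counts({"TTT": 3}), params, "genome")
        e = m.entries[("A", "C", "T", "G")]
        assert e.inconsistent and e.rate is None and e.M == 1

    def test_region_and_k_preconditions(self):
        params = cm.RunParameters(10, 1)
        with pytest.raises(ConfigurationError):
            cm.compute_rates([], _counts({}, region="left_replichore"),
                             params, "genome")
        bad_k = ContextCountTable(k=5, region="genome", strand="reference")
        with pytest.raises(ConfigurationError):
            cm.compute_rates([], bad_k, params, "genome")

    def test_planted_counts_recovered_exactly(self, planted_run):
        genome, frame, params, table, manifest = planted_run
        counts = cm.count_contexts(genome, frame, 3)
        ov, _ = cm.orient_variants(genome, frame, table.records)
        m = cm.compute_rates(ov, counts, params, "genome")
        planted = manifest["planted_counts"]
        for (u, r, a, d), e in m.entries.items():
            assert e.M == planted.get(f"{u}{r}{d}>{a}", 0)
        assert m.total_mutations == manifest["n_total"]

    def test_rate_formula_inverts_to_relative_1e12(self, planted_run):
        genome, frame, params, table, _ = planted_run
        counts = cm.count_contexts(genome, frame, 3)
        ov, _ = cm.orient_variants(genome, frame, table.records)
        m = cm.compute_rates(ov, counts, params, "genome")
        GN = params.generations * params.lineages
        for e in m.entries.values():
            if e.rate is not None and e.denominator > 0:
                assert e.rate * e.denominator * GN == pytest.approx(e.M, rel=1e-12)

    def test_replichore_mutation_conservation(self, planted_run):
        genome, frame, params, table, _ = planted_run
        gw = cm.count_contexts(genome, frame, 3)
        lw = cm.count_contexts(genome, frame, 3, region="left_replichore")
        rwc = cm.count_contexts(genome, frame, 3, region="right_replichore",
                                strand="complement")
        ov_g, _ = cm.orient_variants(genome, frame, table.records)
        ov_l, _ = cm.orient_variants(genome, frame, table.records,
                                     "lagging_template_revcomp", "left_replichore")
        ov_r, _ = cm.orient_variants(genome, frame, table.records,
                                     "lagging_template_revcomp", "right_replichore")
        mg = cm.compute_rates(ov_g, gw, params, "genome")
        ml = cm.compute_rates(ov_l, lw, params, "left_replichore")
        mr = cm.compute_rates(ov_r, rwc, params, "right_replichore")
        assert mg.total_mutations == ml.total_mutations + mr.total_mutations
        assert not any(e.inconsistent for e in ml.entries.values())
        assert not any(e.inconsistent for e in mr.entries.values())


class TestAggregation:
    def test_single_entry_sum(self):
        params = cm.RunParameters(10, 1)
        m = cm.compute_rates([_cv("A", "C", "T", "G")] * 2,
                             _counts({"ACG": 100}), params, "genome")
        agg = cm.aggregate_to_triplets(m)
        assert agg["ACG"][0] == 2
        assert agg["ACG"][1] == pytest.approx(2 / (100 * 10), rel=1e-12)

    def test_matches_brute_force_groupby(self, planted_run):
        genome, frame, params, table, _ = planted_run
        counts = cm.count_contexts(genome, frame, 3)
        ov, _ = cm.orient_variants(genome, frame, table.records)
        m = cm.compute_rates(ov, counts, params, "genome")
        agg = cm.aggregate_to_triplets(m)
        brute = brute_rate_groupby(m.entries)
        for t in TRIPLETS:
            assert agg[t][0] == brute[t][0]
            if brute[t][1] is None:
                assert agg[t][1] is None
            else:
                assert agg[t][1] == pytest.approx(brute[t][1], rel=1e-12)
        assert sum(v[0] for v in agg.values()) == m.total_mutations


class TestConditionalRates:
    def test_formula_substitution(self):
        params = cm.RunParameters(100, 10)
        m = cm.compute_rates([_cv("A", "C", "T", "G")] * 5,
                             _counts({"ACG": 1000}), params, "genome")
        cond = cm.conditional_rates(m, {"A": 1, "C": 25000, "G": 1, "T": 1})
        assert cond["ACG"] == pytest.approx(2.0e-7, rel=1e-12)

    def test_conditional_below_triplet_rate_when_base_commoner(self):
        params = cm.RunParameters(100, 10)
        m = cm.compute_rates([_cv("A", "C", "T", "G")],
                             _counts({"ACG": 10}), params, "genome")
        cond = cm.conditional_rates(m, {"A": 0, "C": 500, "G": 0, "T": 0})
        triplet_rate = cm.aggregate_to_triplets(m)["ACG"][1]
        assert cond["ACG"] < triplet_rate

    def test_missing_center_base(self):
        params = cm.RunParameters(10, 1)
        m = cm.compute_rates([], _counts({"ACG": 5}), params, "genome")
        cond = cm.conditional_rates(m, {"A": 5, "C": 0, "G": 5, "T": 5})
        assert cond["ACG"] is None

    def test_fixture_oracle(self, planted_run):
        genome, frame, params, table, _ = planted_run
        counts = cm.count_contexts(genome, frame, 3)
        ov, _ = cm.orient_variants(genome, frame, table.records)
        m = cm.compute_rates(ov, counts, params, "genome")
        base_counts = {b: genome.sequence.count(b) for b in "ACGT"}
        cond = cm.conditional_rates(m, base_counts)
        GN = params.generations * params.lineages
        agg = cm.aggregate_to_triplets(m)
        for t, (m_total, _) in agg.items():
            assert cond[t] == pytest.approx(
                m_total / (base_counts[t[1]] * GN), rel=1e-12
            )


class TestScaling:
    def _matrix(self, rate_pairs, params):
        variants = []
        counts = {}
        for (u, r, a, d), (m_count, denom) in rate_pairs.items():
            variants.extend([_cv(u, r, a, d)] * m_count)
            counts[u + r + d] = denom
        return cm.compute_rates(variants, _counts(counts), params, "genome")

    def test_default_mode_divides_by_1e8(self):
        params = cm.RunParameters(100, 10, scaling_mode="default_1e-8")
        m = self._matrix({("A", "C", "T", "G"): (30, 1_000_000)}, params)
        scaled = cm.apply_scaling(m, params)
        # rate 30/(1e6*100*10) = 3e-8 -> displays as 3.0
        assert scaled.entries[("A", "C", "T", "G")].scaled == pytest.approx(3.0)
        assert scaled.scale_applied == 1e-8

    def test_mean_scaled_identity_when_uniform(self, planted_run):
        genome, frame, _, table, _ = planted_run
        params = cm.RunParameters(5077, 50, scaling_mode="mean_scaled")
        counts = cm.count_contexts(genome, frame, 3)
        ov, _ = cm.orient_variants(genome, frame, table.records)
        m = cm.compute_rates(ov, counts, params, "genome")
        scaled = cm.apply_scaling(m, params)
        vals = [e.scaled for e in scaled.entries.values() if e.scaled is not None]
        assert np.mean(vals) == pytest.approx(1.0, rel=1e-9)

    def test_custom_factor_elementwise(self, planted_run):
        genome, frame, _, table, _ = planted_run
        params = cm.RunParameters(5077, 50, scaling_mode="custom",
                                  custom_factor=2e-9)
        counts = cm.count_contexts(genome, frame, 3)
        ov, _ = cm.orient_variants(genome, frame, table.records)
        m = cm.compute_rates(ov, counts, params, "genome")
        scaled = cm.apply_scaling(m, params)
        for k, e in scaled.entries.items():
            if e.rate is not None:
                assert e.scaled == pytest.approx(e.rate / 2e-9, rel=1e-12)

    def test_all_zero_rates_cannot_mean_scale(self):
        params = cm.RunParameters(10, 1, scaling_mode="mean_scaled")
        m = cm.compute_rates([], _counts({"ACG": 5}), params, "genome")
        with pytest.raises(ScalingError):
            cm.apply_scaling(m, params)

    def test_scaling_preserves_rank_order(self, planted_run):
        genome, frame, _, table, _ = planted_run
        for mode, factor in (("default_1e-8", None), ("mean_scaled", None),
                             ("custom", 7e-10)):
            params = cm.RunParameters(5077, 50, scaling_mode=mode,
                                      custom_factor=factor)
            counts = cm.count_contexts(genome, frame, 3)
            ov, _ = cm.orient_variants(genome, frame, table.records)
            m = cm.compute_rates(ov, counts, params, "genome")
            scaled = cm.apply_scaling(m, params)
            keys = [k for k in CANONICAL_KEYS if m.entries[k].rate is not None]
            raw = np.array([m.entries[k].rate for k in keys])
            disp = np.array([scaled.entries[k].scaled for k in keys])
            assert (np.argsort(raw, kind="stable") ==
                    np.argsort(disp, kind="stable")).all()


class TestParameterRecovery:
    def test_error_shrinks_with_planted_totals(self):
        """Relative error of recovered rates falls as expected counts grow."""
        G, N = 5077, 50
        params = cm.RunParameters(G, N)

        def mare(u, seeds):
            errs = []
            for seed in seeds:
                genome, _ = syn.generate_genome(4000, 0.45, seed=seed)
                frame = cm.make_frame(1, 2001, genome.length)
                table, _ = syn.plant_mutations(
                    genome, frame, syn.uniform_rate_map(u), G, N, seed=seed
                )
                counts = cm.count_contexts(genome, frame, 3)
                ov, _ = cm.orient_variants(genome, frame, table.records)
                m = cm.compute_rates(ov, counts, params, "genome")
                rates = [e.rate for e in m.entries.values() if e.rate is not None]
                errs.append(np.mean([abs(r - u) / u for r in rates]))
            return np.mean(errs)

        seeds = range(40, 60)
        low, high = 2e-9, 2e-7  # ~0.5 vs ~50 expected events per context
        assert mare(high, seeds) < mare(low, seeds)
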