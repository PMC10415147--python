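"""Enrichment ratios, paired fitness, completeness, and PAM preferences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from spacerscope.acquisition_stats import (
    acquisition_by_pam_class,
    class_rate_log10_ratio,
    complete_cases,
    enrichment,
    fitness_partition,
    nucleotide_preference,
    pair_fitness,
    pair_fitness_table,
    PairResult,
)
from spacerscope.synthetic_data import sim_selection, table_from_counts


def _table(sample_id, counts: dict[str, int], pam_class: str = "NAGG"):
    seqs = list(counts)
    t = table_from_counts(sample_id, seqs, np.array([counts[s] for s in seqs]))
    t.df["pam_class"] = pam_class
    return t


class TestEnrichment:
    def test_simple_ratio(self):
        res = enrichment(_table("i", {"A": 2, "B": 98}), _table("u", {"A": 1, "B": 99}))
        r = res.df.set_index("spacer_seq")["enrichment_ratio"]
        assert r["A"] == pytest.approx(2.0 / 1.0 * (100 / 100))
        assert r["A"] == pytest.approx((2 / 100) / (1 / 100))

    def test_identical_tables_give_unit_ratios(self):
        t = _table("x", {"A": 5, "B": 10, "C": 1})
        res = enrichment(t, _table("y", {"A": 5, "B": 10, "C": 1}))
        assert np.allclose(res.df["enrichment_ratio"], 1.0)

    def test_one_sided_spacers_dropped_not_scored(self):
        res = enrichment(_table("i", {"A": 5, "B": 5}), _table("u", {"B": 5, "C": 5}))
        assert set(res.df["spacer_seq"]) == {"B"} and set(res.dropped) == {"A", "C"}

    def test_empty_intersection_warns_and_returns_empty(self):
        res = enrichment(_table("i", {"A": 5}), _table("u", {"B": 5}))
        assert len(res.df) == 0 and set(res.dropped) == {"A", "B"}

    def test_selection_ratios_track_planted_protection(self, rng):
        # expected enrichment ratio is s_i / mean(s); rank order must survive
        n, depth = 500, 100_000
        s = 10 ** rng.uniform(-2, 0, n)
        seqs = [f"S{i:04d}" for i in range(n)]
        uninf, inf = sim_selection(s, depth, rng)
        res = enrichment(table_from_counts("i", seqs, inf),
                         table_from_counts("u", seqs, uninf))
        merged = res.df.set_index("spacer_seq")["enrichment_ratio"]
        truth = pd.Series(s / s.mean(), index=seqs).loc[merged.index]
        rho = spearmanr(merged, truth).statistic
        assert rho > 0.9

    def test_neutral_spacers_have_mean_ratio_one(self, rng):
        # 1,000 unselected spacers: mean ratio within 3 SE of 1
        n, depth = 1000, 2_000_000
        seqs = [f"S{i:04d}" for i in range(n)]
        uninf, inf = sim_selection(np.full(n, 0.7), depth, rng)
        res = enrichment(table_from_counts("i", seqs, inf),
                         table_from_counts("u", seqs, uninf))
        er = res.df["enrichment_ratio"]
        se = er.std(ddof=1) / np.sqrt(len(er))
        assert abs(er.mean() - 1.0) <= 3 * se


class TestPairFitness:
    def test_equal_ratios_give_half(self):
        assert pair_fitness(3.7, 3.7) == pytest.approx(0.5)

    def test_arithmetic(self):
        assert pair_fitness(2, 6) == pytest.approx(0.25)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pair_fitness(0.0, 1.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-3, 1e3))
    def test_complement_and_scale_invariance(self, a, b, k):
        assert pair_fitness(a, b) + pair_fitness(b, a) == pytest.approx(1.0)
        assert pair_fitness(k * a, k * b) == pytest.approx(pair_fitness(a, b), rel=1e-9)
        assert 0 < pair_fitness(a, b) < 1

    def test_manifest_scoring_and_variant(self):
        res = enrichment(_table("i", {"N1": 2, "A1": 6, "N2": 1, "A2": 1}),
                         _table("u", {"N1": 2.5, "A1": 2.5, "N2": 2.5, "A2": 2.5}))
        manifest = pd.DataFrame({"pair_id": ["p1", "p2"],
                                 "nagg_spacer": ["N1", "N2"],
                                 "agg_spacer": ["A1", "A2"]})
        pairs = pair_fitness_table(res, manifest)
        by_id = {p.pair_id: p for p in pairs}
        assert by_id["p1"].fitness == pytest.approx(0.25)
        assert by_id["p2"].fitness == pytest.approx(0.5)
        freq_pairs = pair_fitness_table(res, manifest, variant="frequency")
        assert {p.pair_id: p.fitness for p in freq_pairs}["p1"] == pytest.approx(2 / 8)

    def test_pairs_missing_a_member_are_dropped(self):
        res = enrichment(_table("i", {"N1": 2, "A1": 6}), _table("u", {"N1": 1, "A1": 1}))
        manifest = pd.DataFrame({"pair_id": ["p1", "p2"],
                                 "nagg_spacer": ["N1", "N2"],
                                 "agg_spacer": ["A1", "A2"]})
        assert [p.pair_id for p in pair_fitness_table(res, manifest)] == ["p1"]


class TestFitnessPartition:
    def _pairs(self, values):
        return [PairResult(f"p{i}", "n", "a", 1, 1, v) for i, v in enumerate(values)]

    def test_thirds(self):
        part = fitness_partition(self._pairs([0.6, 0.3, 0.05]))
        assert part == {"frac_above_hi": pytest.approx(1 / 3),
                        "frac_mid": pytest.approx(1 / 3),
                        "frac_below_lo": pytest.approx(1 / 3)}

    def test_boundary_values_fall_in_middle_band(self):
        part = fitness_partition(self._pairs([0.5, 0.5, 0.1]))
        assert part["frac_above_hi"] == 0 and part["frac_below_lo"] == 0
        assert part["frac_mid"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        part = fitness_partition(self._pairs(rng.uniform(0, 1, 97)))
        assert sum(part.values()) == pytest.approx(1.0)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            fitness_partition(self._pairs([0.5]), hi=0.1, lo=0.5)

    def test_recovers_planted_partition_from_selection(self, rng):
        # paired competition: estimated fractions within binomial 3-sigma of
        # the fractions implied by the planted protection values
        n_pairs, depth = 400, 400_000
        s_n = 10 ** rng.uniform(-2, 0, n_pairs)
        s_a = 10 ** rng.uniform(-2, 0, n_pairs)
        true_fit = s_n / (s_n + s_a)
        seqs = [f"N{i}" for i in range(n_pairs)] + [f"A{i}" for i in range(n_pairs)]
        uninf, inf = sim_selection(np.concatenate([s_n, s_a]), depth, rng)
        res = enrichment(table_from_counts("i", seqs, inf),
                         table_from_counts("u", seqs, uninf))
        manifest = pd.DataFrame({"pair_id": [f"p{i}" for i in range(n_pairs)],
                                 "nagg_spacer": [f"N{i}" for i in range(n_pairs)],
                                 "agg_spacer": [f"A{i}" for i in range(n_pairs)]})
        pairs = pair_fitness_table(res, manifest)
        part = fitness_partition(pairs)
        for key, true_frac in (("frac_above_hi", (true_fit > 0.5).mean()),
                               ("frac_below_lo", (true_fit < 0.1).mean())):
            tol = 3 * np.sqrt(true_frac * (1 - true_frac) / n_pairs)
            assert abs(part[key] - true_frac) <= tol


class TestCompleteCases:
    def test_intersection(self):
        tables = [_table("1", {"A": 1, "B": 1}), _table("2", {"B": 1, "C": 1})]
        assert complete_cases(tables) == {"B"}

    def test_identical_tables_keep_everything(self):
        tables = [_table(str(i), {"A": 1, "B": 2}) for i in range(4)]
        assert complete_cases(tables) == {"A", "B"}

    def test_monotone_in_number_of_tables(self, rng):
        pool = [f"S{i}" for i in range(50)]
        tables = []
        for k in range(4):
            kept = [s for s in pool if rng.random() > 0.3]
            tables.append(_table(str(k), {s: 1 for s in kept}))
        prev = complete_cases(tables[:2])
        for k in range(3, 5):
            cur = complete_cases(tables[:k])
            assert cur <= prev
            prev = cur

    def test_dropout_model_retention(self, rng):
        # independent per-sample dropout d: retained fraction ~ (1-d)^k
        n, d, k = 2000, 0.2, 4
        pool = [f"S{i}" for i in range(n)]
        tables = [_table(str(j), {s: 1 for s in pool if rng.random() > d})
                  for j in range(k)]
        frac = len(complete_cases(tables)) / n
        expect = (1 - d) ** k
        assert abs(frac - expect) <= 3 * np.sqrt(expect * (1 - expect) / n)

    def test_needs_two_tables(self):
        with pytest.raises(ValueError):
            complete_cases([_table("1", {"A": 1})])


class TestByPamClass:
    def test_single_class_single_group(self):
        t = _table("x", {"A": 3, "B": 1}, pam_class="NGG")
        summary = acquisition_by_pam_class(t)
        assert list(summary["pam_class"]) == ["NGG"]
        assert int(summary["total_reads"].iloc[0]) == 4

    def test_equal_total_counts_give_equal_aggregate_frequencies(self):
        t = _table("x", {"A": 2, "B": 2})
        t.df.loc[t.df["spacer_seq"] == "A", "pam_class"] = "NGG"
        t.df.loc[t.df["spacer_seq"] == "B", "pam_class"] = "NAGG"
        summary = acquisition_by_pam_class(t)
        f = summary.set_index("pam_class")["total_frequency"]
        assert f["NGG"] == pytest.approx(f["NAGG"])

    def test_per_site_rate_ratio(self):
        t = _table("x", {"A": 90, "B": 10})
        t.df.loc[t.df["spacer_seq"] == "A", "pam_class"] = "NGG"
        t.df.loc[t.df["spacer_seq"] == "B", "pam_class"] = "NAGG"
        summary = acquisition_by_pam_class(t, site_counts={"NGG": 9, "NAGG": 10})
        # (10 reads / 10 sites) / (90 reads / 9 sites) = 0.1
        assert class_rate_log10_ratio(summary, "NAGG", "NGG") == pytest.approx(-1.0)


class TestNucleotidePreference:
    def _df(self, ratios, pams, seeds=None):
        n = len(ratios)
        seeds = seeds or ["A"] * n
        return pd.DataFrame({
            "enrichment_ratio": ratios,
            "pam4": pams,
            "spacer_seq": ["C" * 29 + s for s in seeds],
        })

    def test_equal_ratios_yield_pvalues_of_one(self):
        df = self._df([1.0] * 40, (["AAGG", "CAGG", "GAGG", "TAGG"] * 10))
        res = nucleotide_preference(df, "pam_first_nt")
        assert np.allclose(res.table["p_value"], 1.0)
        assert not res.table["significant"].any()

    def test_group_sizes_sum_to_total(self):
        df = self._df([1.0] * 40, (["AAGG", "CAGG", "GAGG", "TAGG"] * 10))
        res = nucleotide_preference(df, "pam_first_nt")
        assert res.table["n"].sum() == 40

    def test_tiny_group_skipped(self):
        df = self._df([1.0, 2.0, 1.5, 0.5, 1.1], ["AAGG"] * 4 + ["CAGG"])
        res = nucleotide_preference(df, "pam_first_nt")
        assert bool(res.table.set_index("group").loc["C", "skipped"])

    def test_shifted_group_flagged_with_high_power(self):
        # one group shifted by a large constant: detected in >= 95% of replicates
        rng = np.random.default_rng(31)
        detected = 0
        reps = 200
        for _ in range(reps):
            pams = np.repeat(["AAGG", "CAGG", "GAGG", "TAGG"], 25)
            ratios = rng.lognormal(0, 0.5, 100)
            ratios[:25] += 5.0
            res = nucleotide_preference(self._df(list(ratios), list(pams)), "pam_first_nt")
            t = res.table.set_index("group")
            detected += bool(t.loc["A", "significant"]) and not t.loc[["C", "G", "T"], "significant"].any()
        assert detected / reps >= 0.95

    def test_null_labels_keep_type_one_error_nominal(self):
        # permuting group labels destroys significance: per-family flag rate
        # over 500 null replicates stays at or below alpha (Holm controls FWER)
        rng = np.random.default_rng(32)
        reps, flags = 500, 0
        for _ in range(reps):
            pams = rng.permutation(np.repeat(["AAGG", "CAGG", "GAGG", "TAGG"], 25))
            ratios = rng.lognormal(0, 0.5, 100)
            res = nucleotide_preference(self._df(list(ratios), list(pams)), "pam_first_nt")
            flags += bool(res.table["significant"].any())
        alpha = 0.05
        assert flags / reps <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_seed_pam_dinucleotide_grouping(self):
        df = self._df([1.0, 2.0, 1.0, 2.0] * 5,
                      ["AAGG", "CAGG"] * 10,
                      seeds=["A", "C"] * 10)
        res = nucleotide_preference(df, "seed_pam_dinucleotide")
        assert set(res.table["group"]) == {"AA", "CC"}

    def test_permutation_variant_agrees_on_strong_effect(self):
        rng = np.random.default_rng(33)
        pams = np.repeat(["AAGG", "CAGG", "GAGG", "TAGG"], 25)
        ratios = rng.lognormal(0, 0.3, 100)
        ratios[:25] += 4.0
        df = self._df(list(ratios), list(pams))
        res = nucleotide_preference(df, "pam_first_nt", method="permutation",
                                    n_perm=2000, rng=np.random.default_rng(34))
        assert bool(res.table.set_index("group").loc["A", "significant"])
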