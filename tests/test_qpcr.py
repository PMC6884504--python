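import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from ginigenes import (
    CqSimulationConfig,
    CqTable,
    aggregate_replicates,
    apply_cq_cutoff,
    delta_cq_relative,
    genorm_m_values,
    genorm_stepwise,
    qpcr_gene_stability,
    relative_expression_from_cq,
    run_qpcr_pipeline,
    simulate_cq_table,
)
from ginigenes.errors import (
    InsufficientDataError,
    MalformedDataError,
    UndefinedStatisticError,
)


def long_table(entries, cutoff=32.0) -> CqTable:
    """entries: iterable of (gene, line, replicate, cq)."""
    return CqTable(
        data=pd.DataFrame(entries, columns=["gene", "cell_line", "replicate", "cq"]),
        cutoff=cutoff,
    )


class TestAggregateReplicates:
    def test_triplicate_mean(self):
        t = long_table([("G", "A", r, cq) for r, cq in enumerate([20.0, 20.2, 20.4], 1)])
        agg = aggregate_replicates(t)
        assert agg.loc[0, "mean_cq"] == pytest.approx(20.2)
        assert agg.loc[0, "n_replicates"] == 3
        assert not agg.loc[0, "discordant"]

    def test_single_replicate_has_undefined_sd(self):
        agg = aggregate_replicates(long_table([("G", "A", 1, 25.0)]))
        assert agg.loc[0, "mean_cq"] == 25.0
        assert math.isnan(agg.loc[0, "sd_cq"])

    def test_discordant_replicates_flagged_not_dropped(self):
        t = long_table([("G", "A", 1, 20.0), ("G", "A", 2, 21.0)])
        agg = aggregate_replicates(t)
        assert bool(agg.loc[0, "discordant"])
        assert agg.loc[0, "mean_cq"] == pytest.approx(20.5)

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(2)
        entries = []
        expected = {}
        for g in ("G1", "G2", "G3"):
            reps = rng.uniform(18, 30, size=3)
            expected[g] = statistics.mean(reps)
            entries += [(g, "A", r + 1, cq) for r, cq in enumerate(reps)]
        agg = aggregate_replicates(long_table(entries)).set_index("gene")
        for g, mean in expected.items():
            assert agg.loc[g, "mean_cq"] == pytest.approx(mean, abs=1e-12)

    def test_nonpositive_cq_rejected(self):
        with pytest.raises(MalformedDataError):
            long_table([("G", "A", 1, 0.0)])


class TestCqCutoff:
    def test_above_cutoff_censored(self):
        df = pd.DataFrame({"gene": ["G"], "cell_line": ["A"], "mean_cq": [33.0]})
        out = apply_cq_cutoff(df, 32.0)
        assert not out.loc[0, "expressed"]
        assert math.isnan(out.loc[0, "mean_cq"])  # censored, never clamped
        assert out.attrs["n_censored"] == 1

    def test_exact_cutoff_retained(self):
        df = pd.DataFrame({"gene": ["G"], "cell_line": ["A"], "mean_cq": [32.0]})
        out = apply_cq_cutoff(df, 32.0)
        assert bool(out.loc[0, "expressed"]) and out.loc[0, "mean_cq"] == 32.0

    def test_all_expressed_unchanged(self):
        df = pd.DataFrame(
            {"gene": ["G", "H"], "cell_line": ["A", "A"], "mean_cq": [20.0, 30.0]}
        )
        out = apply_cq_cutoff(df, 32.0)
        assert out["expressed"].all() and out.attrs["n_censored"] == 0
        np.testing.assert_allclose(out["mean_cq"], df["mean_cq"])


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "cq, expected", [(32.0, 1.0), (16.0, 2.0), (25.6, 1.25)]
    )
    def test_cutoff_over_cq(self, cq, expected):
        assert relative_expression_from_cq(cq, 32.0) == pytest.approx(expected)

    def test_not_expressed_is_nan_not_number(self):
        assert math.isnan(relative_expression_from_cq(33.0, 32.0))


class TestQpcrGeneStability:
    def test_constant_gene_has_zero_gini_and_rsd(self):
        rel = pd.DataFrame({f"L{i}": [1.5] for i in range(10)}, index=["G"])
        summary, _ = qpcr_gene_stability(rel)
        assert summary.loc[0, "gini"] == 0.0
        assert summary.loc[0, "rsd_percent"] == 0.0
        assert summary.loc[0, "n_lines_expressed"] == 10

    def test_single_line_gene_excluded_with_reason(self):
        rel = pd.DataFrame(
            {"L1": [1.0, 1.0], "L2": [np.nan, 1.1], "L3": [np.nan, 1.2]},
            index=["ONE", "OK"],
        )
        summary, excluded = qpcr_gene_stability(rel)
        assert excluded.loc[0, "gene"] == "ONE"
        assert excluded.loc[0, "reason"] == "expressed-in-too-few-lines"
        assert summary["gene"].tolist() == ["OK"]

    def test_partial_coverage_flagged(self):
        rel = pd.DataFrame(
            [[1.0, 1.1, np.nan, np.nan, np.nan, np.nan]], index=["G"],
            columns=[f"L{i}" for i in range(6)],
        )
        summary, _ = qpcr_gene_stability(rel, min_expressed_fraction=0.5)
        assert bool(summary.loc[0, "low_coverage"])

    def test_matches_elementwise_oracle(self):
        from conftest import brute_force_gini

        rng = np.random.default_rng(8)
        rel = pd.DataFrame(
            rng.uniform(1.0, 2.0, size=(5, 10)),
            index=[f"G{i}" for i in range(5)],
            columns=[f"L{j}" for j in range(10)],
        )
        summary, _ = qpcr_gene_stability(rel)
        for _, row in summary.iterrows():
            vec = rel.loc[row["gene"]].to_numpy()
            assert row["gini"] == pytest.approx(brute_force_gini(vec), abs=1e-10)
            assert row["median_relative"] == pytest.approx(np.median(vec))
            assert row["rsd_percent"] == pytest.approx(
                100 * vec.std(ddof=1) / vec.mean()
            )


class TestDeltaCq:
    def test_panel_minimum_maps_to_one(self):
        cq = pd.DataFrame([[20.0, 21.0, 23.321928]], index=["G"],
                          columns=["A", "B", "C"])
        out = delta_cq_relative(cq).set_index("cell_line")
        assert out.loc["A", "delta_cq"] == 0.0
        assert out.loc["A", "relative_value"] == 1.0
        assert out.loc["B", "relative_value"] == pytest.approx(0.5)
        assert out.loc["C", "relative_value"] == pytest.approx(0.1, abs=1e-6)

    def test_missing_entries_propagate(self):
        cq = pd.DataFrame([[20.0, np.nan, 22.0]], index=["G"], columns=["A", "B", "C"])
        out = delta_cq_relative(cq)
        assert set(out["cell_line"]) == {"A", "C"}

    def test_single_expressed_line_rejected(self):
        cq = pd.DataFrame([[20.0, np.nan]], index=["G"], columns=["A", "B"])
        with pytest.raises(InsufficientDataError):
            delta_cq_relative(cq)

    def test_max_r_is_exactly_one_per_gene(self):
        rng = np.random.default_rng(4)
        cq = pd.DataFrame(
            rng.uniform(18, 30, size=(6, 8)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"L{j}" for j in range(8)],
        )
        out = delta_cq_relative(cq)
        assert (out.groupby("gene")["relative_value"].max() == 1.0).all()
        assert (out.groupby("gene")["delta_cq"].min() == 0.0).all()


def genorm_oracle(relative: pd.DataFrame):
    """Independent direct-formula geNorm: V via statistics.stdev over
    explicit log2 ratios, M via mean over partners."""
    genes = list(relative.index)
    v = {}
    for a, b in itertools.combinations(genes, 2):
        ratios = [
            math.log2(x / y)
            for x, y in zip(relative.loc[a], relative.loc[b])
        ]
        v[(a, b)] = v[(b, a)] = statistics.stdev(ratios)
    m = {
        g: statistics.mean(v[(g, h)] for h in genes if h != g) for g in genes
    }
    return v, m


class TestGeNorm:
    def test_scalar_multiple_gives_zero_pairwise_variation(self):
        rel = pd.DataFrame(
            {"s1": [1.0, 2.0, 5.0], "s2": [3.0, 6.0, 1.0], "s3": [2.0, 4.0, 9.0]},
            index=["A", "B", "C"],
        )  # B = 2*A in every sample
        result = genorm_m_values(rel)
        assert result.pairwise_variation.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        assert result.pairwise_variation.loc["A", "C"] > 0

    def test_noisiest_gene_has_largest_m(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(1, 2, size=8)
        rel = pd.DataFrame(
            {
                "steady1": base * 1.0,
                "steady2": base * np.exp(0.05 * rng.standard_normal(8)),
                "noisy": base * np.exp(1.0 * rng.standard_normal(8)),
            }
        ).T
        result = genorm_m_values(rel)
        assert result.m_values.idxmax() == "noisy"

    def test_v_and_m_match_direct_oracle(self):
        rng = np.random.default_rng(10)
        rel = pd.DataFrame(
            rng.uniform(0.5, 3.0, size=(4, 7)),
            index=["A", "B", "C", "D"],
            columns=[f"s{j}" for j in range(7)],
        )
        result = genorm_m_values(rel)
        v, m = genorm_oracle(rel)
        for pair, value in v.items():
            assert result.pairwise_variation.loc[pair] == pytest.approx(value, abs=1e-12)
        for gene, value in m.items():
            assert result.m_values[gene] == pytest.approx(value, abs=1e-12)

    def test_m_invariant_to_gene_rescaling(self):
        rng = np.random.default_rng(12)
        rel = pd.DataFrame(
            rng.uniform(0.5, 3.0, size=(4, 6)), index=list("ABCD")
        )
        scaled = rel.copy()
        scaled.loc["B"] *= 37.5
        np.testing.assert_allclose(
            genorm_m_values(rel).m_values, genorm_m_values(scaled).m_values,
            atol=1e-12,
        )

    def test_scalar_multiples_survive_to_final_pair(self):
        rng = np.random.default_rng(14)
        base = rng.uniform(1, 2, size=6)
        rel = pd.DataFrame(
            {
                "A": base,
                "B": base * 3.0,
                "C": base * np.exp(0.8 * rng.standard_normal(6)),
            }
        ).T
        result = genorm_stepwise(rel)
        assert result.final_pair == ("A", "B")
        assert result.exclusion_order[0] == "C"
        # normalisation factor is the per-sample geometric mean of A and B
        np.testing.assert_allclose(
            result.normalization_factor, np.sqrt(base * base * 3.0), rtol=1e-12
        )

    def test_stepwise_deterministic(self):
        rng = np.random.default_rng(15)
        rel = pd.DataFrame(
            rng.uniform(0.5, 3.0, size=(5, 8)), index=list("ABCDE")
        )
        r1, r2 = genorm_stepwise(rel), genorm_stepwise(rel.copy())
        assert r1.exclusion_order == r2.exclusion_order

    def test_stepwise_matches_full_recompute_oracle(self):
        rng = np.random.default_rng(16)
        rel = pd.DataFrame(
            rng.uniform(0.5, 3.0, size=(5, 8)), index=list("ABCDE")
        )
        result = genorm_stepwise(rel)
        current = rel.copy()
        expected_order = []
        while len(current) > 2:
            _, m = genorm_oracle(current)
            worst = min(sorted(m), key=lambda g: -m[g])
            # highest M; ties (none here) by id
            worst = sorted([g for g, v in m.items() if v == max(m.values())])[0]
            expected_order.append(worst)
            current = current.drop(index=worst)
        expected_order.extend(sorted(current.index))
        assert result.exclusion_order == expected_order

    def test_ranking_ties_final_pair_at_rank_one(self):
        rng = np.random.default_rng(18)
        rel = pd.DataFrame(rng.uniform(0.5, 3.0, size=(4, 6)), index=list("ABCD"))
        ranking = genorm_stepwise(rel).ranking()
        assert ranking["rank"].tolist()[:2] == [1, 1]

    def test_nonpositive_values_rejected(self):
        rel = pd.DataFrame([[1.0, 2.0], [0.0, 1.0], [1.0, 1.0]], index=list("ABC"))
        with pytest.raises(UndefinedStatisticError):
            genorm_m_values(rel)

    def test_too_few_genes_rejected(self):
        rel = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]], index=list("AB"))
        with pytest.raises(InsufficientDataError):
            genorm_m_values(rel)


class TestPipeline:
    def test_stage_composition(self, cq_table):
        result = run_qpcr_pipeline(cq_table, genorm=True)
        summary = result["summary"].set_index("gene")
        # STAB constant across lines: minimum GC and RSD
        assert summary.loc["STAB", "gini"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc["STAB", "rsd_percent"] == pytest.approx(0.0, abs=1e-12)
        # censored pair (HIGH in line B, Cq 33) excluded, not imputed
        assert result["aggregated"].attrs["n_censored"] == 1
        assert summary.loc["HIGH", "n_lines_expressed"] == 2
        # relative expression of STAB: 32/20 everywhere
        np.testing.assert_allclose(result["relative"].loc["STAB"], 1.6)

    def test_cross_measure_concordance_on_zero_variance_gene(self, cq_table):
        """A gene with zero across-line variance wins on every measure:
        GC, %RSD, and survival into the geNorm final pair."""
        result = run_qpcr_pipeline(cq_table, genorm=True)
        summary = result["summary"].set_index("gene")
        expressed_everywhere = summary[summary["n_lines_expressed"] == 3]
        assert summary.loc["STAB", "gini"] <= expressed_everywhere["gini"].min() + 1e-12
        assert (
            summary.loc["STAB", "rsd_percent"]
            <= expressed_everywhere["rsd_percent"].min() + 1e-12
        )
        assert "STAB" in result["genorm"].final_pair
        # DOUBLE differs from STAB by a constant Cq offset => constant
        # ratio => the two form the most stable pair
        assert result["genorm"].final_pair == ("DOUBLE", "STAB")

    def test_two_transforms_differ_in_general(self, cq_table):
        """cutoff/Cq and 2^-dCq are different transforms: their per-gene
        GCs across lines agree only in degenerate cases."""
        from ginigenes.gini import gini_coefficient

        result = run_qpcr_pipeline(cq_table)
        rel = result["relative"].loc["VARY"].dropna().to_numpy()
        dcq = result["delta_cq"]
        r_vals = dcq.loc[dcq["gene"] == "VARY", "relative_value"].to_numpy()
        assert gini_coefficient(rel) != pytest.approx(gini_coefficient(r_vals), abs=1e-3)


class TestCqSimulation:
    def test_zero_technical_sd_gives_identical_replicates(self):
        cfg = CqSimulationConfig(n_genes=3, n_lines=2, technical_sd=0.0, seed=1)
        table, _ = simulate_cq_table(cfg)
        ranges = table.data.groupby(["gene", "cell_line"])["cq"].agg(lambda v: v.max() - v.min())
        assert (ranges == 0.0).all()

    def test_all_above_cutoff_censors_everything(self):
        cfg = CqSimulationConfig(n_genes=3, n_lines=2, base_cq_range=(35.0, 38.0),
                                 line_sd=0.1, stable_line_sd=0.1, seed=2)
        table, _ = simulate_cq_table(cfg, cutoff=32.0)
        agg = aggregate_replicates(table)
        out = apply_cq_cutoff(agg, 32.0)
        assert not out["expressed"].any()

    def test_same_seed_reproducible(self):
        cfg = CqSimulationConfig(seed=5)
        t1, _ = simulate_cq_table(cfg)
        t2, _ = simulate_cq_table(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_planted_genes_attain_lowest_gc_across_seeds(self):
        """In >= 90% of 100 seeded runs the 3 planted stable genes have
        the 3 lowest cross-line GCs."""
        hits = 0
        for seed in range(100):
            cfg = CqSimulationConfig(seed=seed)
            table, truth = simulate_cq_table(cfg)
            result = run_qpcr_pipeline(table)
            summary = result["summary"]
            lowest3 = set(summary.sort_values("gini")["gene"].head(3))
            planted = set(truth.loc[truth["planted"], "gene"])
            hits += lowest3 == planted
        assert hits >= 90
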