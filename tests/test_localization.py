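import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mirsort.io_formats import AbundanceProfile, SequenceSet
from mirsort.localization import (
    LocalizationTable,
    au_fraction,
    classify_localization,
    compare_class_sequence_stats,
    composition,
    detect_reliable,
    equal_variance_ttest,
    fdr_bky_two_stage,
)
from mirsort.synthetic_data import SimulationConfig, simulate


# ---------------------------------------------------------------------------
# Independent oracle: the published two-stage step-up procedure, written as
# an explicit loop over the sorted p-values.
# ---------------------------------------------------------------------------


def bh_reject_stepup(p, level):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * level / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    return np.array(reject)


def bky_two_stage_oracle(p, q):
    m = len(p)
    q1 = q / (1.0 + q)
    stage1 = bh_reject_stepup(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return bh_reject_stepup(p, q1 * m / (m - r1))


def _profile(compartment, ids, signals, ps):
    return AbundanceProfile(compartment, ids, np.asarray(signals, float),
                            np.asarray(ps, float))


class TestDetectReliable:
    def test_all_replicates_rule(self):
        prof = _profile(
            "CELL", ["in", "out"],
            [[1, 1, 1], [1, 1, 1]],
            [[0.01, 0.02, 0.03], [0.01, 0.2, 0.01]],
        )
        assert detect_reliable(prof) == {"in"}
        assert detect_reliable(prof, rule="any") == {"in", "out"}


class TestComposition:
    def test_single_mirna_is_unity(self):
        prof = _profile("CELL", ["a"], [[5, 7, 2]], [[0.01] * 3])
        np.testing.assert_allclose(composition(prof, {"a"}).to_numpy(), 1.0)

    def test_two_mirna_split(self):
        prof = _profile("CELL", ["a", "b"], [[30, 30], [10, 10]], [[0.01] * 2] * 2)
        comp = composition(prof, {"a", "b"})
        np.testing.assert_allclose(comp.loc["a"], 0.75)
        np.testing.assert_allclose(comp.loc["b"], 0.25)

    def test_zero_total_replicate_errors(self):
        prof = _profile("SEV", ["a", "b"], [[0, 1], [0, 1]], [[0.01] * 2] * 2)
        with pytest.raises(ValueError, match="replicate 1"):
            composition(prof, {"a", "b"})

    def test_columns_sum_to_one(self, default_sim):
        for prof in (default_sim.cell, default_sim.sev):
            comp = composition(prof, detect_reliable(prof))
            np.testing.assert_allclose(comp.sum(axis=0), 1.0, atol=1e-9)

    def test_noiseless_generator_composition_recovered(self):
        cfg = SimulationConfig(n_mirna=60, n_sev_detected=60, noise_cv=0.0, seed=3)
        sim = simulate(cfg)
        comp = composition(sim.cell, detect_reliable(sim.cell))
        # noiseless replicates are identical and recover the planted weights
        np.testing.assert_allclose(comp["rep1"], comp["rep2"], rtol=1e-12)
        sig = sim.cell.signals[:, 0]
        np.testing.assert_allclose(
            comp.loc[sim.cell.mirna_ids, "rep1"].to_numpy(), sig / sig.sum(),
            rtol=1e-9,
        )


class TestEqualVarianceTTest:
    def test_identical_groups(self):
        t, p = equal_variance_ttest([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert t == 0 and p == 1

    def test_matches_reference_implementation(self, rng):
        for _ in range(300):
            nx, ny = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            x, y = rng.normal(size=nx), rng.normal(size=ny)
            t, p = equal_variance_ttest(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10

    def test_swap_negates_t_keeps_p(self):
        x, y = [0.2, 0.3, 0.25], [0.05, 0.06, 0.07]
        t1, p1 = equal_variance_ttest(x, y)
        t2, p2 = equal_variance_ttest(y, x)
        assert t1 == -t2 and p1 == p2

    def test_zero_variance_unequal_means(self):
        t, p = equal_variance_ttest([1.0, 1.0], [0.0, 0.0])
        assert np.isinf(t) and t > 0 and p == 0


class TestBkyTwoStageFdr:
    def test_all_ones_rejects_none(self):
        assert not fdr_bky_two_stage(np.ones(20)).reject.any()

    def test_all_zeros_rejects_all(self):
        assert fdr_bky_two_stage(np.zeros(20)).reject.all()

    def test_empty_input(self):
        q, r = fdr_bky_two_stage([])
        assert q.size == 0 and r.size == 0

    @pytest.mark.parametrize("style", ["uniform", "signal", "ties"])
    def test_rejections_match_independent_oracles(self, style, rng):
        for _ in range(100):
            m = int(rng.integers(1, 80))
            p = rng.uniform(0, 1, m)
            if style == "signal":
                p[: m // 3] *= 1e-3
            elif style == "ties":
                p = np.round(p, 1)
            mine = fdr_bky_two_stage(p, 0.05).reject
            assert np.array_equal(mine, bky_two_stage_oracle(p, 0.05))
            assert np.array_equal(
                mine, multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            )

    def test_qvalues_reproduce_rejection_rule_at_any_level(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 60))
            p = rng.uniform(0, 1, m)
            p[: m // 4] *= 1e-2
            qv = fdr_bky_two_stage(p).q_values
            for level in (0.01, 0.05, 0.2, 0.5):
                assert np.array_equal(qv <= level, bky_two_stage_oracle(p, level))

    def test_dominates_bh_at_shrunk_level(self, rng):
        # the provable containment: BKY at q rejects everything BH rejects
        # at q/(1+q); the naive same-q superset claim fails in the regime
        # where stage 1 rejects fewer than m*q/(1+q) points.
        q = 0.05
        for _ in range(300):
            p = rng.uniform(0, 1, 200)
            p[:30] *= rng.uniform(1e-4, 1)
            bh_small = bh_reject_stepup(p, q / (1 + q))
            bky = fdr_bky_two_stage(p, q).reject
            assert not np.any(bh_small & ~bky)
            r1 = bh_small.sum()
            if r1 >= 200 * q / (1 + q):  # adaptive regime: BKY >= plain BH
                bh = bh_reject_stepup(p, q)
                assert not np.any(bh & ~bky)


class TestClassifyLocalization:
    def test_single_shared_mirna_is_neutral(self):
        cell = _profile("CELL", ["a"], [[5, 6, 7]], [[0.01] * 3])
        sev = _profile("SEV", ["a"], [[1, 2, 3]], [[0.01] * 3])
        table = classify_localization(cell, sev).table
        assert table.at["a", "call"] == "NEUTRAL"
        assert table.at["a", "mean_comp_cell"] == 1.0
        assert table.at["a", "mean_comp_sev"] == 1.0

    def test_undetected_in_both(self):
        cell = _profile("CELL", ["a", "b"], [[5, 6, 7], [1, 1, 1]],
                        [[0.01] * 3, [0.9] * 3])
        sev = _profile("SEV", ["a", "b"], [[1, 2, 3], [1, 1, 1]],
                       [[0.01] * 3, [0.9] * 3])
        table = classify_localization(cell, sev).table
        assert table.at["b", "call"] == "UNDETECTED"
        assert np.isnan(table.at["b", "q_value"])

    def test_row_order_permutation_equivariance(self, small_sim):
        base = classify_localization(small_sim.cell, small_sim.sev).table
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_sim.cell.mirna_ids))
        ids = [small_sim.cell.mirna_ids[i] for i in perm]
        cell_p = AbundanceProfile("CELL", ids, small_sim.cell.signals[perm],
                                  small_sim.cell.detection_p[perm])
        sev_p = AbundanceProfile("SEV", ids, small_sim.sev.signals[perm],
                                 small_sim.sev.detection_p[perm])
        permuted = classify_localization(cell_p, sev_p).table
        assert (permuted.loc[base.index, "call"] == base["call"]).all()
        np.testing.assert_allclose(
            permuted.loc[base.index, "q_value"], base["q_value"], rtol=1e-9
        )

    def test_replicate_scaling_invariance(self, small_sim):
        base = classify_localization(small_sim.cell, small_sim.sev).table
        scaled_sig = small_sim.cell.signals.copy()
        scaled_sig[:, 1] *= 10.0
        cell_s = AbundanceProfile("CELL", small_sim.cell.mirna_ids, scaled_sig,
                                  small_sim.cell.detection_p)
        scaled = classify_localization(cell_s, small_sim.sev).table
        assert (scaled["call"] == base["call"]).all()
        np.testing.assert_allclose(scaled["p_value"], base["p_value"],
                                   rtol=1e-9, equal_nan=True)

    def test_recovers_planted_class_proportions(self):
        # default (strong) effect, full detection: the planted 15%/45%
        # split is recovered within 5 percentage points
        cfg = SimulationConfig(n_mirna=300, n_sev_detected=300, seed=11)
        sim = simulate(cfg)
        table = classify_localization(sim.cell, sim.sev)
        n = len(table.table)
        frac_sev = table.counts["SEV_ENRICHED"] / n
        frac_cell = table.counts["CELL_ENRICHED"] / n
        assert abs(frac_sev - 0.15) < 0.05
        assert abs(frac_cell - 0.45) < 0.05

    def test_null_generator_calls_few_enriched(self):
        from mirsort.synthetic_data import null_config
        fracs = []
        for s in range(10):
            sim = simulate(null_config(seed=100 + s, n_mirna=200))
            table = classify_localization(sim.cell, sim.sev)
            n = len(table.table) - table.counts["UNDETECTED"]
            fracs.append(
                (table.counts["SEV_ENRICHED"] + table.counts["CELL_ENRICHED"]) / n
            )
        assert np.mean(fracs) <= 2 * 0.05

    def test_power_monotone_in_fold_change(self):
        folds = [1.0, 1.5, 2.0, 4.0, 8.0]
        power = []
        for fc in folds:
            hits = []
            for s in range(20):
                cfg = SimulationConfig(n_mirna=100, n_sev_detected=100,
                                       fold_change=fc, seed=500 + s)
                sim = simulate(cfg)
                table = classify_localization(sim.cell, sim.sev)
                sev_true = [m for m, c in sim.truth.mirna_class.items()
                            if c == "SEV_ENRICHED"]
                calls = table.table.loc[sev_true, "call"]
                hits.append((calls == "SEV_ENRICHED").mean())
            power.append(np.mean(hits))
        assert all(b >= a - 0.02 for a, b in zip(power, power[1:]))
        assert power[-1] > power[0] + 0.5


class TestClassSequenceStats:
    def test_au_fraction_of_printed_mir2137(self):
        assert au_fraction("GCCGGCGGGAGCCCCAGGGAG") == pytest.approx(3 / 21)

    def test_all_au_sequence(self):
        assert au_fraction("AUAU") == 1.0

    def test_gc_biased_secreted_class_has_lower_au(self):
        cfg = SimulationConfig(n_mirna=400, n_sev_detected=400, gc_bias=True,
                               fold_change=8.0, seed=21)
        sim = simulate(cfg)
        table = classify_localization(sim.cell, sim.sev)
        report = compare_class_sequence_stats(table, sim.seqs)
        per = report.per_class.set_index("class")
        assert (
            per.at["SEV_ENRICHED", "mean_au_fraction"]
            < per.at["CELL_ENRICHED", "mean_au_fraction"]
        )
        au_test = report.tests.set_index("statistic").loc["au_fraction"]
        assert au_test["p_value"] < 0.05

    def test_small_class_skips_test_with_notice(self):
        import pandas as pd
        df = pd.DataFrame(
            {
                "mean_comp_cell": [0.9, 0.1],
                "mean_comp_sev": [0.1, 0.9],
                "t_stat": [5.0, -5.0],
                "p_value": [0.001, 0.001],
                "q_value": [0.01, 0.01],
                "call": ["CELL_ENRICHED", "SEV_ENRICHED"],
            },
            index=pd.Index(["a", "b"], name="mirna_id"),
        )
        report = compare_class_sequence_stats(
            LocalizationTable(df), SequenceSet({"a": "ACGU", "b": "GGCC"})
        )
        assert (report.tests["note"] != "").all()
        assert np.isnan(report.tests["p_value"]).all()
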