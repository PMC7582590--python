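"""Normalization and DE statistics: CPM, TMM, dispersion, exact test, TE."""

import numpy as np
import pandas as pd
import pytest
from helpers_oracles import exact_p_enumeration

from ribopulse import diffexpr, simulate
from ribopulse.diffexpr import CountMatrix
from conftest import make_stable_counts


class TestCpm:
    def test_hand_values(self):
        frame = pd.DataFrame({"s1": [5, 10 ** 6 - 5], "s2": [123, 2 * 10 ** 6 - 123]})
        c = diffexpr.cpm(frame)
        assert c.loc[0, "s1"] == pytest.approx(5.0)
        assert c.loc[0, "s2"] == pytest.approx(61.5)

    def test_columns_sum_to_one_million(self, toy_count_matrix):
        sums = diffexpr.cpm(toy_count_matrix).sum(axis=0)
        assert np.allclose(sums, 1e6, atol=1e-6)

    def test_zero_library_names_sample(self):
        frame = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            diffexpr.cpm(frame)


class TestFilterLow:
    def test_zero_threshold_keeps_everything(self, toy_count_matrix):
        out = diffexpr.filter_low(toy_count_matrix, 0, 1)
        assert out.gene_ids == toy_count_matrix.gene_ids

    def test_all_zero_gene_removed(self, toy_count_matrix):
        out = diffexpr.filter_low(toy_count_matrix, 1.0, 1)
        assert "C" not in out.gene_ids

    def test_exact_survivor_set_from_hand_cpm(self):
        # libraries of 100 -> CPM = count * 1e4; threshold 2.5e5 means
        # count >= 25 needed in >= 2 samples
        frame = pd.DataFrame({"mRNA_c_1": [30, 25, 10],
                              "mRNA_c_2": [40, 10, 26]},
                             index=["keep", "dropA", "dropB"])
        frame.loc["pad"] = [30, 24]
        cm = CountMatrix.from_frame(frame)
        out = diffexpr.filter_low(cm, 2.5e5, 2)
        survivors = set(out.gene_ids)
        assert "keep" in survivors
        assert "dropA" not in survivors and "dropB" not in survivors


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(0).poisson(50, 500)
        frame = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(diffexpr.tmm_factors(frame), 1.0)

    @pytest.mark.parametrize("scale", [2.0, 3.0])
    def test_pure_scaling_closed_form(self, scale):
        col = np.random.default_rng(1).poisson(200, 2000) + 1
        frame = pd.DataFrame({"a": col, "b": (scale * col).astype(int)})
        f = diffexpr.tmm_factors(frame)
        assert f["b"] / f["a"] == pytest.approx(scale, abs=1e-6)
        assert f["a"] == pytest.approx(1 / np.sqrt(scale), abs=1e-6)

    def test_geometric_mean_is_one(self, toy_count_matrix):
        f = diffexpr.tmm_factors(toy_count_matrix)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)


class TestDispersion:
    def test_poisson_data_gives_near_zero_common(self):
        truth, counts = make_stable_counts(n_genes=2000, dispersion=0.0,
                                           seed=3)
        _, common = diffexpr.estimate_dispersion(counts["mRNA"])
        assert common <= 0.01

    def test_recovers_planted_dispersion(self):
        truth, counts = make_stable_counts(n_genes=2000, dispersion=0.1,
                                           seed=4)
        _, common = diffexpr.estimate_dispersion(counts["mRNA"])
        assert 0.08 <= common <= 0.12

    def test_all_zero_gene_floored_at_zero(self):
        frame = pd.DataFrame({
            "mRNA_c_1": [100, 0], "mRNA_c_2": [90, 0],
            "mRNA_t_1": [110, 0], "mRNA_t_2": [95, 0]}, index=["A", "Z"])
        phi, _ = diffexpr.estimate_dispersion(CountMatrix.from_frame(frame))
        assert phi["Z"] == 0.0


class TestExactTest:
    @pytest.mark.parametrize("phi", [0.0, 0.1])
    @pytest.mark.parametrize("groups", [(4, 4), (3, 4)])
    def test_matches_enumeration_oracle(self, phi, groups):
        n_a, n_b = groups
        for total in (2, 17, 60, 200):
            for sum_a in range(0, total + 1, max(1, total // 5)):
                got = diffexpr.exact_nb_pvalue(sum_a, total - sum_a,
                                               n_a, n_b, phi)
                want = exact_p_enumeration(sum_a, total - sum_a, n_a, n_b,
                                           phi)
                assert got == pytest.approx(want, abs=1e-10)

    def test_identical_groups_are_null(self):
        frame = pd.DataFrame({
            "mRNA_a_1": [50, 7], "mRNA_a_2": [60, 9],
            "mRNA_b_1": [50, 7], "mRNA_b_2": [60, 9]}, index=["A", "B"])
        cm = CountMatrix.from_frame(frame)
        res = diffexpr.exact_test(cm, ["mRNA_a_1", "mRNA_a_2"],
                                  ["mRNA_b_1", "mRNA_b_2"], 0.1,
                                  factors=pd.Series(1.0, index=frame.columns))
        assert (res["pvalue"] >= 1.0 - 1e-9).all()
        assert np.allclose(res["log2fc"], 0.0)

    def test_bh_fdr_monotone_in_sorted_pvalues(self):
        truth, counts = make_stable_counts(n_genes=400, dispersion=0.1,
                                           seed=5)
        cm = counts["mRNA"]
        res = diffexpr.exact_test(cm, cm.samples_for(condition="0h"),
                                  cm.samples_for(condition="control"), 0.1)
        ordered = res.sort_values("pvalue")["fdr"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_planted_effect_power_and_fdr(self):
        genes = [f"g{i}" for i in range(1000)]
        modes = simulate.plant_modes(genes, {"transcriptional": 0.3,
                                             "stable": 0.7},
                                     effect_size=1.0, seed=6)
        truth = simulate.SimTruth(
            genes=genes, baseline=simulate.random_baseline(genes, seed=7),
            modes={"0h": modes}, dispersion=0.04)
        cm = simulate.simulate_counts(truth, depth=1e6, seed=8)["mRNA"]
        factors = diffexpr.tmm_factors(cm)
        phi, _ = diffexpr.estimate_dispersion(cm, factors=factors)
        res = diffexpr.exact_test(cm, cm.samples_for(condition="0h"),
                                  cm.samples_for(condition="control"),
                                  phi, factors)
        changed = modes["mrna_log2fc"] != 0
        sens = res.loc[changed, "significant"].mean()
        called = res.index[res["significant"]]
        fdr = (~changed.loc[called]).mean() if len(called) else 0.0
        assert sens >= 0.9
        assert fdr <= 0.1


class TestTeTest:
    @staticmethod
    def _sim(mode_mix, n_genes, dispersion, seed):
        genes = [f"g{i}" for i in range(n_genes)]
        modes = simulate.plant_modes(genes, mode_mix, effect_size=1.0,
                                     seed=seed)
        truth = simulate.SimTruth(
            genes=genes,
            baseline=simulate.random_baseline(genes, seed=seed + 1),
            modes={"0h": modes}, dispersion=dispersion)
        counts = simulate.simulate_counts(truth, depth=1e6, seed=seed + 2)
        return modes, counts

    @staticmethod
    def _joint_phi(counts):
        joint = CountMatrix(
            pd.concat([counts["mRNA"].counts, counts["RPF"].counts], axis=1),
            pd.concat([counts["mRNA"].samples, counts["RPF"].samples]))
        return diffexpr.estimate_dispersion(joint)[0]

    def test_recovers_negated_mrna_shift_for_buffered_genes(self):
        modes, counts = self._sim(simulate.DEFAULT_MODE_MIX_0H, 500, 0.04,
                                  seed=9)
        phi = self._joint_phi(counts)
        res = diffexpr.te_test(counts["mRNA"], counts["RPF"], "0h",
                               "control", phi)
        tr = modes.index[modes["mode"] == "transcriptional"]
        err = res.loc[tr, "dlog2_te"] + modes.loc[tr, "mrna_log2fc"]
        assert abs(err.median()) <= 0.15

    def test_equal_shifts_leave_interaction_null(self):
        # Poisson-level noise isolates the bias property: equal mRNA and
        # RPF shifts must not leak into the interaction term
        modes, counts = self._sim({"homodirectional": 0.3, "stable": 0.7},
                                  400, 0.0, seed=10)
        phi = self._joint_phi(counts)
        res = diffexpr.te_test(counts["mRNA"], counts["RPF"], "0h",
                               "control", phi)
        hd = modes.index[modes["mode"] == "homodirectional"]
        assert res.loc[hd, "dlog2_te"].abs().median() < 0.1

    def test_interaction_invariant_to_global_scaling(self):
        modes, counts = self._sim({"transcriptional": 0.5, "stable": 0.5},
                                  60, 0.04, seed=11)
        phi = self._joint_phi(counts)
        factors = pd.Series(
            1.0, index=list(counts["mRNA"].counts.columns)
            + list(counts["RPF"].counts.columns))
        res1 = diffexpr.te_test(counts["mRNA"], counts["RPF"], "0h",
                                "control", phi, factors=factors)
        doubled = {
            a: CountMatrix(cm.counts * 2, cm.samples)
            for a, cm in counts.items()}
        res2 = diffexpr.te_test(doubled["mRNA"], doubled["RPF"], "0h",
                                "control", phi, factors=factors)
        ok = res1["converged"] & res2["converged"]
        assert np.allclose(res1.loc[ok, "dlog2_te"],
                           res2.loc[ok, "dlog2_te"], atol=5e-3)

    def test_null_pvalues_uniform(self):
        modes, counts = self._sim({"stable": 1.0}, 600, 0.04, seed=12)
        phi = self._joint_phi(counts)
        res = diffexpr.te_test(counts["mRNA"], counts["RPF"], "0h",
                               "control", phi)
        from scipy import stats
        ps = res["pvalue"].dropna()
        assert stats.kstest(ps, "uniform").pvalue > 0.01
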