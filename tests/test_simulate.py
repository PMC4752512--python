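"""Generator determinism, planted-truth closure and null calibration."""

import numpy as np
import pytest
from scipy import stats

from grnctx.expression import call_degs, deg_test, log_fold_change, read_expression
from grnctx.network import load_edge_list
from grnctx.pwm import read_transfac
from grnctx.scan import ScanConfig, scan_promoter
from grnctx.simulate import (
    ScenarioConfig,
    ScenarioTruth,
    gen_expression,
    gen_full_scenario,
    gen_literature_network,
    gen_promoters,
    gen_pwm_library,
    read_fasta,
)


class TestPwmLibrary:
    def test_degenerate_concentration_gives_consensus_only(self):
        pwm = gen_pwm_library(n_tf=1, motif_len_range=(8, 8),
                              concentration=np.inf, seed=1)[0]
        assert np.all(pwm.freq.max(axis=1) == 1.0)

    def test_seed_determinism(self):
        a = gen_pwm_library(10, (8, 12), 5.0, seed=7)
        b = gen_pwm_library(10, (8, 12), 5.0, seed=7)
        assert [p.tf_id for p in a] == [p.tf_id for p in b]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.freq, y.freq)

    def test_rows_normalized(self):
        for pwm in gen_pwm_library(10, (8, 12), 5.0, seed=3):
            np.testing.assert_allclose(pwm.freq.sum(axis=1), 1.0, atol=1e-12)

    def test_higher_concentration_sharper(self):
        lo = gen_pwm_library(20, (10, 10), 1.0, seed=5)
        hi = gen_pwm_library(20, (10, 10), 50.0, seed=5)
        mean_max = lambda lib: np.mean([p.freq.max(axis=1).mean() for p in lib])
        assert mean_max(hi) > mean_max(lo)

    def test_short_motifs_rejected_naming_core(self):
        with pytest.raises(ValueError, match="core"):
            gen_pwm_library(1, (4, 8), 5.0, seed=0)


class TestPromoters:
    def test_window_geometry(self):
        pwms = gen_pwm_library(2, (8, 8), np.inf, seed=0)
        promoters, _ = gen_promoters(["g1", "g2"], pwms, sites_per_gene=1,
                                     window=(2000, 1000), seed=1)
        assert all(len(s) == 3000 for s in promoters.values())
        assert all(set(s) <= set("ACGT") for s in promoters.values())

    def test_no_sites_requested_truth_empty(self):
        pwms = gen_pwm_library(2, (8, 8), np.inf, seed=0)
        _, truth = gen_promoters(["g1"], pwms, sites_per_gene=0, window=(100, 50), seed=2)
        assert truth.planted_sites == []

    def test_plant_recover_closure(self):
        """Scanning a planted consensus with its own PWM yields an MSS=1.0
        hit at the recorded offset and strand."""
        pwms = gen_pwm_library(3, (9, 11), np.inf, seed=6)
        promoters, truth = gen_promoters(["gA", "gB"], pwms,
                                         sites_per_gene={"gA": ["TF01", "TF02"],
                                                         "gB": ["TF03"]},
                                         window=(400, 200), seed=8)
        by_id = {p.tf_id: p for p in pwms}
        assert len(truth.planted_sites) == 3
        for tf_id, gene, offset, strand in truth.planted_sites:
            hits = scan_promoter(by_id[tf_id], promoters[gene], ScanConfig(), gene_id=gene)
            match = [h for h in hits if h.offset == offset and h.strand == strand]
            assert match and match[0].mss == pytest.approx(1.0)

    def test_invalid_gc_rejected(self):
        pwms = gen_pwm_library(1, (8, 8), np.inf, seed=0)
        with pytest.raises(ValueError, match="background_gc"):
            gen_promoters(["g"], pwms, background_gc=1.5, seed=0)


class TestLiteratureNetwork:
    def test_depth_one_single_tf(self):
        grn = gen_literature_network(["A"], stimulus="LPS", depth=1, seed=0)
        assert set(grn.edges) == {("LPS", "A")}

    def test_sign_mix_zero_all_activating(self):
        grn = gen_literature_network([f"t{i}" for i in range(12)], depth=3,
                                     sign_mix=0.0, seed=4)
        assert all(ix.sign == "+" for ix in grn.edges.values())

    def test_stimulus_is_unique_root_and_acyclic(self):
        import networkx as nx

        grn = gen_literature_network([f"t{i}" for i in range(15)], depth=4,
                                     sign_mix=0.3, extra_edge_p=0.2, seed=11)
        g = grn.to_networkx()
        assert g.in_degree("LPS") == 0 and g.out_degree("LPS") >= 1
        assert nx.is_directed_acyclic_graph(g)

    def test_determinism_and_empty_tfs_error(self):
        a = gen_literature_network([f"t{i}" for i in range(8)], depth=2, seed=5)
        b = gen_literature_network([f"t{i}" for i in range(8)], depth=2, seed=5)
        assert a == b
        with pytest.raises(ValueError, match="empty"):
            gen_literature_network([], depth=1, seed=0)


class TestExpression:
    def test_bitwise_deterministic(self):
        genes = [f"g{i}" for i in range(20)]
        m1, c1 = gen_expression(genes, {}, seed=9)
        m2, c2 = gen_expression(genes, {}, seed=9)
        assert m1.equals(m2) and c1.equals(c2)

    def test_null_effect_mean_lfc_near_zero(self):
        genes = [f"g{i}" for i in range(200)]
        m, c = gen_expression(genes, {}, n_reps=3, lfc_effect=0.0, noise_sd=0.25, seed=2)
        lfc = log_fold_change(m, c)
        assert abs(lfc.mean()) < 3 * 0.25 / np.sqrt(3 * 200)

    def test_planted_shift_recovered(self):
        truth = {"up1": "up", "dn1": "down"}
        m, c = gen_expression(["up1", "dn1", "flat"], truth, n_reps=50,
                              lfc_effect=2.0, noise_sd=0.1, seed=3)
        lfc = log_fold_change(m, c)
        assert lfc["up1"] == pytest.approx(2.0, abs=0.1)
        assert lfc["dn1"] == pytest.approx(-2.0, abs=0.1)
        assert lfc["flat"] == pytest.approx(0.0, abs=0.1)

    def test_replicate_minimum(self):
        with pytest.raises(ValueError, match="n_reps"):
            gen_expression(["g"], {}, n_reps=1, seed=0)

    def test_null_false_call_rate_calibrated(self):
        """Under the null the t-test should reject at its nominal 1% rate:
        pooled across seeds the p<0.01 count stays inside binomial 99%
        bounds."""
        n_genes, n_seeds = 400, 25
        hits = 0
        for seed in range(n_seeds):
            m, c = gen_expression([f"g{i}" for i in range(n_genes)], {},
                                  n_reps=3, lfc_effect=0.0, noise_sd=0.25, seed=seed)
            hits += int((deg_test(m, c) < 0.01).sum())
        n = n_genes * n_seeds
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.01)
        assert lo <= hits <= hi

    def test_power_at_study_effect_size(self):
        """lfc=4, sd=0.25, n=3: every planted up-gene called in >=95/100
        seeds; the noncentral-t power calculation predicts ~1."""
        genes = [f"g{i}" for i in range(10)]
        truth = {g: "up" for g in genes}
        ok = 0
        for seed in range(100):
            m, c = gen_expression(genes, truth, n_reps=3, lfc_effect=4.0,
                                  noise_sd=0.25, seed=seed)
            degs = call_degs(log_fold_change(m, c), deg_test(m, c))
            ok += (degs["call"] == "up").all()
        assert ok >= 95
        # analytic cross-check: power of the two-sided t at delta=4
        delta = 4.0 / (0.25 * np.sqrt(2 / 3))
        crit = stats.t.ppf(1 - 0.005, 4)
        power = 1 - stats.nct.cdf(crit, 4, delta)
        assert power > 0.999


class TestFullScenario:
    def test_files_written_and_parseable(self, tmp_path):
        scenario = gen_full_scenario(ScenarioConfig(n_background_genes=20), seed=3)
        files = scenario.write(tmp_path / "scn")
        promoters = read_fasta(files["promoters"])
        assert set(promoters) == set(scenario.promoters)
        pwms = read_transfac(files["pwms"])
        assert [p.tf_id for p in pwms] == [p.tf_id for p in scenario.pwms]
        lit = load_edge_list(files["literature"])
        assert lit == scenario.literature
        matrix, cond = read_expression(files["expression"], files["conditions"])
        assert matrix.shape == scenario.expression.shape
        truth = ScenarioTruth.from_json(files["truth"])
        assert truth == scenario.truth

    def test_truth_consistency_invariants(self):
        scenario = gen_full_scenario(ScenarioConfig(n_background_genes=10), seed=7)
        truth = scenario.truth
        # every planted site's (tf, gene) pair is a signed true edge
        for tf_id, gene, _, _ in truth.planted_sites:
            assert f"{tf_id}->{gene}" in truth.true_signs
        # deg truth matches the expression generator's shift assignment
        lfc = log_fold_change(scenario.expression, scenario.conditions)
        for gene, call in truth.deg_truth.items():
            if call == "up":
                assert lfc[gene] > 1.0
        # the essential relay is the only direct stimulus target
        stim_out = [t for (s, t) in scenario.literature.edges if s == "LPS"]
        assert stim_out == [truth.essential_regulator]

    def test_misconfigured_target_rejected(self):
        with pytest.raises(ValueError, match="no planted regulator"):
            gen_full_scenario(ScenarioConfig(plant_target_sites=False), seed=0)
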