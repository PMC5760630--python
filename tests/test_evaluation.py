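import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prcnet import (
    DirectedNetwork,
    KnockoutScreen,
    PerturbationDesign,
    noise_free_inferable_flags,
    partial_correlation_matrix,
    roc_vs_inferable,
    true_positive_fraction,
)
from prcnet import datagen
from prcnet.evaluation import (
    EvaluationError,
    auroc_aupr,
    dream3_overall_score,
    dream3_score,
    fit_null_pvalue,
    partial_correlation_coefficients,
    read_dream3_gold,
    read_dream3_prediction,
    write_report,
)
from prcnet.networks import count_inferable_links

from conftest import random_weighted_net


class TestPartialCorrelations:
    def test_independent_nodes_near_zero(self):
        rng = np.random.default_rng(0)
        pc = partial_correlation_matrix(rng.standard_normal((4, 3000)))
        off = pc.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_chain_markov_property_low_noise(self):
        net = datagen.three_node_chain(1.0, 1.0)
        design = PerturbationDesign(
            n_nodes=3,
            experiments=[(1 if k % 2 else 2, k, float(s)) for k, s in
                         enumerate(np.random.default_rng(1).standard_normal(3000))],
        )
        screen = datagen.simulate_linear_knockouts(
            net, design, sigma=1e-3, noise_mode="additive", seed=2, n_wt_replicates=0
        )
        pc = partial_correlation_matrix(screen)
        assert abs(pc.loc["G1", "G3"]) < 0.05

    def test_noisy_middle_node_induces_false_partial_correlation(self):
        screens = datagen.make_three_node_demo([0.1, 0.6], n_experiments=3000, seed=4)
        vals = [
            abs(partial_correlation_coefficients(s).loc["G3", "G1"]) for s in screens
        ]
        assert vals[1] > vals[0] > 0


class TestROC:
    @pytest.fixture
    def truth(self):
        return DirectedNetwork(nodes=list("abcd"), edges={("a", "b"), ("b", "c"), ("a", "d")})

    def test_perfect_ranking_auroc_one(self, truth):
        scores = {e: 1.0 for e in truth.edges}
        rep = roc_vs_inferable(scores, truth)
        assert rep.auroc == pytest.approx(1.0)
        assert rep.tp_fraction == 1.0

    def test_random_ranking_near_half(self, truth):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(300):
            pairs = [(s, t) for s in truth.nodes for t in truth.nodes if s != t]
            scores = {p: rng.random() for p in pairs}
            aucs.append(roc_vs_inferable(scores, truth).auroc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self, truth):
        rng = np.random.default_rng(1)
        pairs = [(s, t) for s in truth.nodes for t in truth.nodes if s != t]
        scores = {p: rng.random() for p in pairs}
        a = roc_vs_inferable(scores, truth).auroc
        b = roc_vs_inferable({p: np.exp(5 * v) for p, v in scores.items()}, truth).auroc
        assert a == pytest.approx(b)

    def test_inferable_denominator_ratio_identity(self, truth):
        flags = {("a", "b"): True, ("b", "c"): False, ("a", "d"): True}
        predicted = set(truth.edges)
        tp_all = true_positive_fraction(predicted, truth, flags, "all_links")
        tp_inf = true_positive_fraction(predicted, truth, flags, "inferable_links")
        assert tp_all == pytest.approx(1.0)
        assert tp_inf == pytest.approx(1.0)
        # at full recall the counts differ exactly by |inferable|/|all|
        tp_all_c = len(predicted & truth.edges)
        tp_inf_c = len({e for e in predicted & truth.edges if flags[e]})
        assert tp_inf_c / tp_all_c == pytest.approx(2 / 3)

    def test_empty_truth_rejected(self):
        with pytest.raises(EvaluationError):
            roc_vs_inferable({}, DirectedNetwork(nodes=["a", "b"], edges=set()))

    def test_inferable_mode_requires_flags(self, truth):
        with pytest.raises(EvaluationError):
            roc_vs_inferable({}, truth, None, "inferable_links")


class TestNoiseFreeInferability:
    def test_matches_refined_counting_small_network(self):
        net, rng = random_weighted_net(15, seed=31)
        pert = sorted(int(v) for v in rng.choice(15, size=8, replace=False))
        design = PerturbationDesign.single_knockouts(
            pert, 15, n_replicates=3, rng=rng, random_strength=True
        )
        screen = datagen.simulate_linear_knockouts(net, design, sigma=0.0, seed=rng, n_wt_replicates=2)
        numeric = noise_free_inferable_flags(screen, datagen.relabel_to_genes(net))
        _, refined = count_inferable_links(net, set(pert), "refined")
        refined = {(datagen.gene_id(s), datagen.gene_id(t)): v for (s, t), v in refined.items()}
        agree = np.mean([numeric[e] == refined[e] for e in refined])
        assert agree >= 0.95


class TestDream3Scoring:
    def test_all_pvalues_one_scores_zero(self):
        assert dream3_overall_score([1.0] * 5, [1.0] * 5) == pytest.approx(0.0)

    def test_t_fit_tail_matches_analytic(self):
        rng = np.random.default_rng(2)
        samples = stats.t.rvs(df=8, loc=0.5, scale=0.05, size=200_000, random_state=rng)
        for x in (0.62, 0.66, 0.70):
            p_fit = fit_null_pvalue(samples, x, fit_mode="t_fit")
            p_true = stats.t.sf(x, 8, loc=0.5, scale=0.05)
            assert p_fit == pytest.approx(p_true, rel=0.05)

    def test_exponential_tail_fit_reasonable(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(0.5, 0.05, 100_000)
        p = fit_null_pvalue(samples, 0.65, fit_mode="two_tail_exp_family")
        assert 0 < p < 0.05

    def test_prediction_format_validation(self, tmp_path):
        good = tmp_path / "pred.txt"
        good.write_text("G1\tG2\t0.9\nG2\tG3\t0.5\n")
        assert len(read_dream3_prediction(good)) == 2
        bad = tmp_path / "bad.txt"
        bad.write_text("G1\tG2\t0.1\nG2\tG3\t0.9\n")  # ascending confidences
        with pytest.raises(EvaluationError):
            read_dream3_prediction(bad)
        with pytest.raises(FileNotFoundError):
            read_dream3_prediction(tmp_path / "missing.txt")

    def test_full_scoring_on_synthetic_challenge(self, tmp_path):
        # perfect predictions against a synthetic gold standard must beat
        # the sampled null distribution decisively
        rng = np.random.default_rng(4)
        gold = tmp_path / "gold.txt"
        pred = tmp_path / "pred.txt"
        lines, plines = [], []
        edges = [("G%d" % i, "G%d" % j) for i in range(6) for j in range(6) if i != j]
        true = set(edges[::4])
        for conf, (a, b) in enumerate(sorted(edges, key=lambda e: e not in true)):
            lines.append(f"{a}\t{b}\t{int((a, b) in true)}")
            plines.append(f"{a}\t{b}\t{1.0 - conf * 0.01:.3f}")
        gold.write_text("\n".join(lines) + "\n")
        pred.write_text("\n".join(plines) + "\n")
        nulls = {"net1": (rng.uniform(0.3, 0.7, 5000), rng.uniform(0.05, 0.3, 5000))}
        out = dream3_score({"net1": pred}, {"net1": gold}, nulls, fit_mode="t_fit")
        assert out["per_network"]["net1"]["auroc"] == pytest.approx(1.0)
        assert out["overall_score"] > 2.0
        with pytest.raises(FileNotFoundError):
            dream3_score({"net1": pred}, {}, nulls)

    def test_auroc_aupr_basic(self):
        universe = {("a", "b"), ("b", "a"), ("a", "c"), ("c", "a")}
        positives = {("a", "b")}
        pred = [("a", "b", 0.9), ("a", "c", 0.5)]
        auroc, aupr = auroc_aupr(pred, positives, universe)
        assert auroc == 1.0 and aupr == 1.0
        rev = [("a", "c", 0.9), ("b", "a", 0.8), ("c", "a", 0.7), ("a", "b", 0.1)]
        auroc_r, _ = auroc_aupr(rev, positives, universe)
        assert auroc_r == 0.0


class TestScreenIO:
    def test_round_trip(self, tmp_path):
        net, rng = random_weighted_net(6, seed=1)
        design = PerturbationDesign.single_knockouts([0, 2], 6, n_replicates=2, rng=rng)
        screen = datagen.simulate_linear_knockouts(net, design, sigma=0.1, seed=rng)
        screen.to_tsv(tmp_path / "e.tsv", tmp_path / "a.tsv")
        back = KnockoutScreen.from_tsv(tmp_path / "e.tsv", tmp_path / "a.tsv")
        pd.testing.assert_frame_equal(back.values, screen.values)
        assert back.wild_type_samples() == screen.wild_type_samples()
        assert back.perturbed_genes() == screen.perturbed_genes()

    def test_unknown_sample_in_annotation_rejected(self, tmp_path):
        (tmp_path / "e.tsv").write_text("gene\ts1\ng1\t0.0\n")
        (tmp_path / "a.tsv").write_text("sample_id\tperturbed_gene\treplicate\nsX\tWT\t0\n")
        from prcnet.datasets import DataFormatError

        with pytest.raises(DataFormatError, match="sX"):
            KnockoutScreen.from_tsv(tmp_path / "e.tsv", tmp_path / "a.tsv")

    def test_write_report(self, tmp_path):
        write_report({"auroc": 0.9}, tmp_path / "r.json")
        import json

        assert json.loads((tmp_path / "r.json").read_text())["auroc"] == 0.9
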