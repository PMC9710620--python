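import math

import numpy as np
import pytest

from mundo import (AnnotationMap, GoDag, LabelPrediction, MundoError,
                   close_annotations, estimate_conditional_probs, f1_max,
                   filter_terms, information_content, inverted_kfold,
                   percent_accuracy, resnik_pair, resnik_scores, resnik_set_set,
                   restrict_terms, standard_kfold_accuracy, grid_search)


def chain_dag():
    """root -> a -> b with Pr(a|root)=Pr(b|a)=0.5."""
    return GoDag(
        terms=frozenset({"root", "a", "b"}),
        parents={"root": frozenset(), "a": frozenset({"root"}),
                 "b": frozenset({"a"})},
        conditional_prob={"a": 0.5, "b": 0.5},
    )


def pred(protein, *labels):
    return LabelPrediction(protein=protein, ranked_labels=tuple(labels))


class TestFilterTerms:
    def test_specificity_window(self):
        mapping = {}
        for i in range(60):
            mapping[f"p{i:03d}"] = frozenset({"g1"})
        for i in range(10):
            mapping[f"q{i:03d}"] = frozenset({"g2"})
        for i in range(60, 660):
            mapping.setdefault(f"r{i:03d}", frozenset({"g3"}))
        ann = AnnotationMap(mapping, "BP")
        out = filter_terms(ann, 50, 500)
        assert out.all_terms == {"g1"}

    def test_unbounded_window_is_identity(self):
        ann = AnnotationMap({"p": frozenset({"g1"}), "q": frozenset({"g2"})}, "BP")
        out = filter_terms(ann, 0, math.inf)
        assert out.protein_to_terms == ann.protein_to_terms

    def test_matches_counting_oracle(self, small_dataset):
        ann = small_dataset.target_ann
        out = filter_terms(ann, 5, 40)
        counts = {}
        for terms in ann.protein_to_terms.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        expected = {t for t, n in counts.items() if 5 <= n <= 40}
        assert out.all_terms == expected

    def test_empty_result_errors(self):
        ann = AnnotationMap({"p": frozenset({"g1"})}, "BP")
        with pytest.raises(MundoError):
            filter_terms(ann, 10, 20)


class TestPercentAccuracy:
    def test_all_correct(self):
        truth = AnnotationMap({"p": frozenset({"g1"})}, "BP")
        assert percent_accuracy({"p": pred("p", ("g1", 1.0))}, truth) == 100.0

    def test_three_of_four(self):
        truth = AnnotationMap({f"p{i}": frozenset({"g1"}) for i in range(4)}, "BP")
        preds = {f"p{i}": pred(f"p{i}", ("g1", 1.0)) for i in range(3)}
        preds["p3"] = pred("p3", ("gX", 1.0))
        assert percent_accuracy(preds, truth) == 75.0

    def test_abstention_counts_as_wrong(self):
        truth = AnnotationMap({"p": frozenset({"g1"}), "q": frozenset({"g1"})}, "BP")
        preds = {"p": pred("p", ("g1", 1.0)),
                 "q": LabelPrediction("q", (), abstain=True)}
        assert percent_accuracy(preds, truth) == 50.0

    def test_matches_hand_loop(self):
        rng = np.random.default_rng(3)
        truth = {}
        preds = {}
        for i in range(50):
            name = f"p{i:02d}"
            true_terms = frozenset({f"g{rng.integers(5)}"})
            truth[name] = true_terms
            preds[name] = pred(name, (f"g{rng.integers(5)}", 1.0))
        ann = AnnotationMap(truth, "BP")
        got = percent_accuracy(preds, ann)
        expected = 100.0 * sum(
            preds[n].ranked_labels[0][0] in truth[n] for n in truth
        ) / 50
        assert got == pytest.approx(expected)


class TestF1Max:
    def test_single_protein_worked_example(self):
        """T={g1,g2}, prediction {g1@0.9}: prec 1, recall 1/2, F1 2/3."""
        truth = AnnotationMap({"p": frozenset({"g1", "g2"})}, "BP")
        preds = {"p": pred("p", ("g1", 0.9))}
        f1, tau = f1_max(preds, truth, tau_grid=[0.5])
        assert f1 == pytest.approx(2 / 3)

    def test_perfect_predictions_reach_one(self):
        truth = AnnotationMap({"p": frozenset({"g1"}), "q": frozenset({"g2"})}, "BP")
        preds = {"p": pred("p", ("g1", 1.0)), "q": pred("q", ("g2", 1.0))}
        f1, _ = f1_max(preds, truth)
        assert f1 == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        terms = [f"g{i}" for i in range(6)]
        truth, preds = {}, {}
        for i in range(30):
            name = f"p{i:02d}"
            truth[name] = frozenset(rng.choice(terms, size=2, replace=False))
            k = int(rng.integers(0, 4))
            labels = []
            for t in rng.choice(terms, size=k, replace=False):
                labels.append((str(t), float(rng.integers(1, 11)) / 10))
            preds[name] = pred(name, *labels)
        ann = AnnotationMap(truth, "BP")
        grid = [i / 20 for i in range(21)]
        got, _ = f1_max(preds, ann, tau_grid=grid)

        best = 0.0
        for tau in grid:
            m, prec_sum, rec_sum = 0, 0.0, 0.0
            for name in truth:
                p_tau = {t for t, c in preds[name].ranked_labels if c > tau}
                if p_tau:
                    m += 1
                    prec_sum += len(p_tau & truth[name]) / len(p_tau)
                rec_sum += len(p_tau & truth[name]) / len(truth[name])
            prec = prec_sum / m if m else 0.0
            rec = rec_sum / len(truth)
            if prec + rec:
                best = max(best, 2 * prec * rec / (prec + rec))
        assert got == pytest.approx(best)

    def test_precision_pool_shrinks_with_tau(self):
        truth = AnnotationMap({"p": frozenset({"g1"}), "q": frozenset({"g2"})}, "BP")
        preds = {"p": pred("p", ("g1", 0.9)), "q": pred("q", ("g1", 0.2))}
        # at tau=0.5 only p predicts; recall still averages over both
        f1_low, _ = f1_max(preds, truth, tau_grid=[0.1])
        f1_high, _ = f1_max(preds, truth, tau_grid=[0.5])
        # prec averages over the single predicting protein (1.0), recall
        # still averages over both test proteins ((1 + 0)/2)
        assert f1_high == pytest.approx(2 * 1.0 * 0.5 / 1.5)
        assert f1_low <= f1_high


class TestInformationContent:
    def test_probability_half_chain_in_bits(self):
        ic = information_content(chain_dag(), base=2)
        assert ic.i["b"] == pytest.approx(2.0)
        assert ic.i["a"] == pytest.approx(1.0)
        assert ic.i["root"] == pytest.approx(0.0)

    def test_certain_terms_carry_no_information(self):
        dag = GoDag(
            terms=frozenset({"r", "x"}),
            parents={"r": frozenset(), "x": frozenset({"r"})},
            conditional_prob={"x": 1.0},
        )
        ic = information_content(dag)
        assert all(v == 0.0 for v in ic.i.values())

    def test_matches_path_product_oracle(self):
        rng = np.random.default_rng(4)
        terms = {"r": frozenset()}
        probs = {}
        names = [f"t{i}" for i in range(12)]
        for i, t in enumerate(names):
            pool = ["r"] + names[:i]
            ps = set(rng.choice(pool, size=min(len(pool), 1 + int(rng.random() < 0.4)),
                                replace=False))
            terms[t] = frozenset(ps)
            probs[t] = float(rng.uniform(0.1, 1.0))
        dag = GoDag(terms=frozenset(terms), parents=terms, conditional_prob=probs)
        ic = information_content(dag)
        for t in names:
            closure = dag.ancestors(t, include_self=True)
            expected = -sum(math.log(probs.get(v, 1.0)) for v in closure)
            assert ic.i[t] == pytest.approx(expected)

    def test_bad_probability_rejected(self):
        dag = chain_dag()
        with pytest.raises(MundoError):
            information_content(dag, conditional_prob={"a": 0.0, "b": 0.5})

    def test_estimated_probs_follow_counts(self):
        dag = chain_dag()
        ann = AnnotationMap(
            {"p1": frozenset({"b"}), "p2": frozenset({"a"}),
             "p3": frozenset({"a"}), "p4": frozenset({"a"})}, "BP")
        probs = estimate_conditional_probs(dag, ann)
        assert probs["a"] == pytest.approx(1.0)   # all 4 closed sets contain a
        assert probs["b"] == pytest.approx(0.25)  # 1 of the 4 a-carriers has b


class TestResnik:
    def test_self_similarity_is_information_content(self):
        dag = chain_dag()
        ic = information_content(dag, base=2)
        x = {"a", "b"}
        got = resnik_set_set(x, x, ic, dag)
        assert got == pytest.approx(np.mean([ic.i["a"], ic.i["b"]]))

    def test_root_only_overlap_scores_zero(self):
        dag = GoDag(
            terms=frozenset({"r", "x", "y"}),
            parents={"r": frozenset(), "x": frozenset({"r"}), "y": frozenset({"r"})},
            conditional_prob={"x": 0.5, "y": 0.5},
        )
        ic = information_content(dag)
        assert resnik_set_set({"x"}, {"y"}, ic, dag) == 0.0

    def test_symmetry(self):
        dag = chain_dag()
        ic = information_content(dag)
        assert resnik_set_set({"a"}, {"b"}, ic, dag) == \
            resnik_set_set({"b"}, {"a"}, ic, dag)

    def test_matches_exhaustive_lca_enumeration(self):
        # 5-term toy: r -> {u, v}; u -> {x}; {u, v} -> y (two parents)
        parents = {"r": frozenset(), "u": frozenset({"r"}), "v": frozenset({"r"}),
                   "x": frozenset({"u"}), "y": frozenset({"u", "v"})}
        probs = {"u": 0.5, "v": 0.25, "x": 0.5, "y": 0.125}
        dag = GoDag(terms=frozenset(parents), parents=parents,
                    conditional_prob=probs)
        ic = information_content(dag, base=2)
        for a in parents:
            for b in parents:
                common = dag.ancestors(a) & dag.ancestors(b)
                expected = max((ic.i[c] for c in common), default=0.0)
                assert resnik_pair(a, b, ic, dag) == pytest.approx(expected)
        # x vs y share u (i=1) as the most informative common ancestor
        assert resnik_pair("x", "y", ic, dag) == pytest.approx(1.0)

    def test_scores_maximize_over_thresholds(self):
        dag = chain_dag()
        ic = information_content(dag, base=2)
        truth = AnnotationMap({"p": frozenset({"b"})}, "BP")
        preds = {"p": pred("p", ("b", 0.6), ("a", 0.4))}
        res = resnik_scores(preds, truth, ic, dag)
        # best threshold keeps {a, b}: closure of truth is {a, b} too
        assert res == pytest.approx(np.mean([2.0, 1.0]))


class TestClosure:
    def test_close_annotations_excludes_roots(self):
        dag = chain_dag()
        ann = AnnotationMap({"p": frozenset({"b"})}, "BP")
        closed = close_annotations(ann, dag)
        assert closed.terms_of("p") == {"a", "b"}

    def test_restrict_terms_drops_emptied_proteins(self):
        ann = AnnotationMap({"p": frozenset({"g1"}), "q": frozenset({"g2"})}, "BP")
        out = restrict_terms(ann, {"g1"})
        assert set(out.proteins) == {"p"}


def prior_predictor(train_ann, test_nodes):
    """Votes the most common training label for everyone (deterministic)."""
    counts = {}
    for terms in train_ann.protein_to_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    return {n: pred(n, (top, 1.0)) for n in test_nodes}


class TestInvertedKFold:
    def make_ann(self, n=40):
        rng = np.random.default_rng(0)
        return AnnotationMap(
            {f"p{i:02d}": frozenset({"a" if rng.random() < 0.6 else "b"})
             for i in range(n)}, "BP")

    def test_k2_splits_in_half(self):
        dag = chain_dag()
        ic = information_content(dag)
        rep = inverted_kfold(self.make_ann(), dag, ic, 2, prior_predictor,
                             seed=1, n_runs=1)
        assert rep.train_sizes == [20, 20]
        assert rep.test_sizes == [20, 20]

    def test_fixed_seed_bit_identical(self):
        dag = chain_dag()
        ic = information_content(dag)
        r1 = inverted_kfold(self.make_ann(), dag, ic, 4, prior_predictor,
                            seed=7, n_runs=2)
        r2 = inverted_kfold(self.make_ann(), dag, ic, 4, prior_predictor,
                            seed=7, n_runs=2)
        assert r1.accuracy == r2.accuracy
        assert r1.f1 == r2.f1
        assert r1.resnik == r2.resnik

    @pytest.mark.parametrize("k", [2, 4, 6, 10])
    def test_fold_bookkeeping(self, k):
        dag = chain_dag()
        ic = information_content(dag)
        ann = self.make_ann(43)
        rep = inverted_kfold(ann, dag, ic, k, prior_predictor, seed=3, n_runs=1)
        a = len(ann)
        for train, test in zip(rep.train_sizes, rep.test_sizes):
            assert a // k <= train <= a // k + 1
            assert train + test == a
        assert sum(rep.train_sizes) == a  # each node trains exactly once

    def test_k_exceeding_annotated_rejected(self):
        dag = chain_dag()
        ic = information_content(dag)
        ann = AnnotationMap({"p": frozenset({"a"}), "q": frozenset({"a"})}, "BP")
        with pytest.raises(MundoError):
            inverted_kfold(ann, dag, ic, 5, prior_predictor, seed=0)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        ann = TestInvertedKFold().make_ann()
        ranked, validation = grid_search(
            ann, ["only"], lambda cfg: prior_predictor, seed=0)
        assert ranked[0][0] == "only"
        assert len(validation) == len(ann) // 2

    def test_ranking_matches_reevaluation(self):
        ann = TestInvertedKFold().make_ann(60)

        def make(cfg):
            if cfg == "good":
                return prior_predictor

            def bad(train_ann, nodes):
                return {n: pred(n, ("zzz", 1.0)) for n in nodes}

            return bad

        ranked, _ = grid_search(ann, ["bad", "good"], make, seed=0)
        assert ranked[0][0] == "good"
        accs = dict((c, a) for c, a in ranked)
        # re-evaluate each configuration independently with the same split
        for cfg in ("good", "bad"):
            again, _ = grid_search(ann, [cfg], make, seed=0)
            assert again[0][1] == pytest.approx(accs[cfg])
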