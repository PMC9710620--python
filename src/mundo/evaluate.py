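"""Evaluation stack: label filtering, accuracy, protein-centric F1-max,
Resnik semantic similarity, and (inverted) k-fold cross-validation.

Conventions fixed here and documented in the methods note:

* annotation sets (truth and predictions) are ancestor-closed before
  scoring, excluding ontology roots, so every scored set is a consistent
  sub-DAG;
* the F1/Resnik confidence grid defaults to the distinct emitted
  confidences plus 0 (both scores are piecewise constant in tau, so this
  maximizes exactly over achievable thresholds);
* thresholding is strict: a term is "predicted at tau" when its confidence
  exceeds tau;
* the least common ancestor on a DAG is taken as the common ancestor of
  maximal information content (the standard Resnik-on-DAG generalization);
* information content uses the natural log by default (the base rescales
  Resnik uniformly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .netio import AnnotationMap, GoDag, MundoError
from .predict import LabelPrediction

Predictor = Callable[[AnnotationMap, Sequence[str]], Mapping[str, LabelPrediction]]


# ---------------------------------------------------------------------------
# Label filtering
# ---------------------------------------------------------------------------

def term_counts(ann: AnnotationMap) -> dict[str, int]:
    counts: dict[str, int] = {}
    for terms in ann.protein_to_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return counts


def filter_terms(ann: AnnotationMap, min_count: int, max_count: float) -> AnnotationMap:
    """Keep terms of intermediate specificity: those annotating between
    ``min_count`` and ``max_count`` proteins of ``ann`` (the target
    network's annotations).  Proteins left with zero terms are dropped."""
    counts = term_counts(ann)
    keep = {t for t, n in counts.items() if min_count <= n <= max_count}
    return restrict_terms(ann, keep)


def restrict_terms(ann: AnnotationMap, keep: Iterable[str]) -> AnnotationMap:
    """Intersect every protein's term set with ``keep``; drop emptied proteins."""
    keep = frozenset(keep)
    mapping = {}
    for prot, terms in ann.protein_to_terms.items():
        kept = terms & keep
        if kept:
            mapping[prot] = kept
    if not mapping:
        raise MundoError("term filtering removed every annotation")
    return AnnotationMap(protein_to_terms=mapping, namespace=ann.namespace)


def close_annotations(ann: AnnotationMap, dag: GoDag) -> AnnotationMap:
    """Ancestor-close every term set along is_a edges (roots excluded)."""
    roots = dag.roots
    mapping = {}
    for prot, terms in ann.protein_to_terms.items():
        closed: set[str] = set()
        for t in terms:
            closed |= dag.ancestors(t, include_self=True)
        closed -= roots
        if closed:
            mapping[prot] = frozenset(closed)
    if not mapping:
        raise MundoError("ancestor closure emptied the annotation map")
    return AnnotationMap(protein_to_terms=mapping, namespace=ann.namespace)


def _closed_set(terms: Iterable[str], dag: GoDag | None) -> frozenset[str]:
    if dag is None:
        return frozenset(terms)
    out: set[str] = set()
    for t in terms:
        out |= dag.ancestors(t, include_self=True)
    return frozenset(out - dag.roots)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def percent_accuracy(
    preds: Mapping[str, LabelPrediction],
    truth: AnnotationMap,
) -> float:
    """Percent of evaluated proteins whose rank-1 label lies in their true
    set.  Abstentions count as wrong; proteins evaluated are those of
    ``preds`` that carry truth labels."""
    evaluated = [p for p in preds if truth.terms_of(p)]
    if not evaluated:
        raise MundoError("no proteins with truth labels to evaluate")
    correct = 0
    for p in evaluated:
        top = preds[p].top_label
        if top is not None and top in truth.terms_of(p):
            correct += 1
    return 100.0 * correct / len(evaluated)


# ---------------------------------------------------------------------------
# Protein-centric F1-max
# ---------------------------------------------------------------------------

def _prediction_sets(
    preds: Mapping[str, LabelPrediction], dag: GoDag | None
) -> dict[str, tuple[tuple[str, float], ...]]:
    """Per protein: (term, confidence) with ancestor closure applied at each
    confidence level (an ancestor inherits the max confidence of its
    descendants)."""
    out = {}
    for prot, lp in preds.items():
        conf: dict[str, float] = {}
        for term, c in lp.ranked_labels:
            for t in _closed_set([term], dag):
                conf[t] = max(conf.get(t, 0.0), c)
        out[prot] = tuple(sorted(conf.items()))
    return out


def default_tau_grid(preds: Mapping[str, LabelPrediction]) -> tuple[float, ...]:
    taus = {0.0}
    for lp in preds.values():
        for _, c in lp.ranked_labels:
            taus.add(c)
    return tuple(sorted(taus))


def f1_max(
    preds: Mapping[str, LabelPrediction],
    truth: AnnotationMap,
    tau_grid: Sequence[float] | None = None,
    dag: GoDag | None = None,
) -> tuple[float, float]:
    """Protein-centric F-max.

    Precision at tau averages only over proteins with at least one
    prediction above tau; recall averages over all test proteins.  Returns
    (F1*, argmax tau).
    """
    test = [p for p in preds if truth.terms_of(p)]
    if not test:
        raise MundoError("no proteins with truth labels to evaluate")
    if tau_grid is None:
        tau_grid = default_tau_grid(preds)
    if len(tau_grid) == 0:
        raise MundoError("tau grid is empty")
    pred_sets = _prediction_sets(preds, dag)
    truths = {p: _closed_set(truth.terms_of(p), dag) for p in test}

    best, best_tau = 0.0, tau_grid[0]
    n = len(test)
    for tau in tau_grid:
        prec_terms, m = 0.0, 0
        recall_sum = 0.0
        for p in test:
            p_tau = {t for t, c in pred_sets.get(p, ()) if c > tau}
            tset = truths[p]
            if p_tau:
                m += 1
                prec_terms += len(p_tau & tset) / len(p_tau)
            recall_sum += len(p_tau & tset) / len(tset)
        prec = prec_terms / m if m else 0.0
        rec = recall_sum / n
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        if f1 > best:
            best, best_tau = f1, tau
    return best, best_tau


# ---------------------------------------------------------------------------
# Information content and Resnik similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InformationContent:
    """ia(v) = −log Pr(v | parents(v)); i(term) sums ia over the term's
    ancestor closure (including itself)."""

    ia: Mapping[str, float]
    i: Mapping[str, float]


def estimate_conditional_probs(dag: GoDag, ann: AnnotationMap) -> dict[str, float]:
    """Estimate Pr(v | parents(v)) by counting over the ancestor-closed
    annotation corpus: (#proteins with v) / (#proteins with all parents of
    v).  Terms without parent support get probability 1 (ia = 0)."""
    closed: dict[str, set[str]] = {}
    for prot, terms in ann.protein_to_terms.items():
        s: set[str] = set()
        for t in terms:
            s |= dag.ancestors(t, include_self=True)
        closed[prot] = s
    probs: dict[str, float] = {}
    for v in dag.terms:
        parents = dag.parents.get(v, frozenset())
        with_v = sum(1 for s in closed.values() if v in s)
        if parents:
            with_parents = sum(
                1 for s in closed.values() if parents <= s
            )
        else:
            with_parents = len(closed)
        if with_parents == 0 or with_v == 0:
            probs[v] = 1.0
        else:
            probs[v] = min(1.0, with_v / with_parents)
    return probs


def information_content(
    dag: GoDag,
    conditional_prob: Mapping[str, float] | None = None,
    base: float = math.e,
) -> InformationContent:
    """Information accretion and cumulative information content per term."""
    probs = conditional_prob if conditional_prob is not None else dag.conditional_prob
    if probs is None:
        raise MundoError(
            "no conditional probabilities: supply them or call "
            "estimate_conditional_probs first"
        )
    log = math.log
    ia = {}
    for t in dag.terms:
        p = probs.get(t, 1.0)
        if not (0.0 < p <= 1.0):
            raise MundoError(f"Pr({t}|parents)={p} outside (0, 1]")
        ia[t] = -log(p) / log(base)
    i = {}
    for t in dag.terms:
        i[t] = sum(ia[a] for a in dag.ancestors(t, include_self=True))
    return InformationContent(ia=ia, i=i)


def resnik_pair(x: str, y: str, ic: InformationContent, dag: GoDag) -> float:
    """i of the most informative common ancestor; 0 when only a virtual
    root is shared."""
    common = dag.ancestors(x, include_self=True) & dag.ancestors(y, include_self=True)
    if not common:
        return 0.0
    return max(ic.i[a] for a in common)


def resnik_set_term(
    xs: Iterable[str], y: str, ic: InformationContent, dag: GoDag
) -> float:
    return max(resnik_pair(x, y, ic, dag) for x in xs)


def resnik_set_set(
    xs: Iterable[str], ys: Iterable[str], ic: InformationContent, dag: GoDag
) -> float:
    """Symmetric max-then-average Resnik similarity between term sets."""
    xs, ys = list(xs), list(ys)
    if not xs or not ys:
        return 0.0
    total = sum(resnik_set_term(ys, x, ic, dag) for x in xs)
    total += sum(resnik_set_term(xs, y, ic, dag) for y in ys)
    return total / (len(xs) + len(ys))


def resnik_scores(
    preds: Mapping[str, LabelPrediction],
    truth: AnnotationMap,
    ic: InformationContent,
    dag: GoDag,
    tau_grid: Sequence[float] | None = None,
) -> float:
    """Best-threshold mean set-set Resnik similarity over the test proteins."""
    test = [p for p in preds if truth.terms_of(p)]
    if not test:
        raise MundoError("no proteins with truth labels to evaluate")
    if tau_grid is None:
        tau_grid = default_tau_grid(preds)
    pred_sets = _prediction_sets(preds, dag)
    truths = {p: _closed_set(truth.terms_of(p), dag) for p in test}

    pair_memo: dict[tuple[str, str], float] = {}

    def pair(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in pair_memo:
            pair_memo[key] = resnik_pair(x, y, ic, dag)
        return pair_memo[key]

    def set_set(xs: frozenset[str], ys: set[str]) -> float:
        if not xs or not ys:
            return 0.0
        total = sum(max(pair(x, y) for y in ys) for x in xs)
        total += sum(max(pair(x, y) for x in xs) for y in ys)
        return total / (len(xs) + len(ys))

    best = 0.0
    for tau in tau_grid:
        total = 0.0
        for p in test:
            p_tau = {t for t, c in pred_sets.get(p, ()) if c > tau}
            total += set_set(truths[p], p_tau)
        best = max(best, total / len(test))
    return best


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Mean ± std over runs × folds for each metric, with fold bookkeeping."""

    namespace: str
    k: int
    n_runs: int
    seed: int
    accuracy: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    resnik: list[float] = field(default_factory=list)
    train_sizes: list[int] = field(default_factory=list)
    test_sizes: list[int] = field(default_factory=list)

    def _mean_std(self, xs: list[float]) -> tuple[float, float]:
        arr = np.asarray(xs, dtype=float)
        return float(arr.mean()), float(arr.std())

    @property
    def accuracy_mean(self) -> float:
        return self._mean_std(self.accuracy)[0]

    @property
    def accuracy_std(self) -> float:
        return self._mean_std(self.accuracy)[1]

    @property
    def f1_mean(self) -> float:
        return self._mean_std(self.f1)[0]

    @property
    def f1_std(self) -> float:
        return self._mean_std(self.f1)[1]

    @property
    def resnik_mean(self) -> float:
        return self._mean_std(self.resnik)[0]

    @property
    def resnik_std(self) -> float:
        return self._mean_std(self.resnik)[1]

    def summary(self) -> dict:
        return {
            "namespace": self.namespace,
            "k": self.k,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "f1_max_mean": self.f1_mean,
            "f1_max_std": self.f1_std,
            "resnik_mean": self.resnik_mean,
            "resnik_std": self.resnik_std,
            "train_sizes": self.train_sizes,
            "test_sizes": self.test_sizes,
        }


def _fold_split(nodes: list[str], k: int, rng: np.random.Generator) -> list[list[str]]:
    order = list(nodes)
    rng.shuffle(order)
    return [order[i::k] for i in range(k)]


def inverted_kfold(
    ann: AnnotationMap,
    dag: GoDag,
    ic: InformationContent,
    k: int,
    predictor: Predictor,
    seed: int,
    n_runs: int = 5,
) -> EvalReport:
    """Inverted k-fold cross-validation.

    Annotated proteins are shuffled and split into k folds; each fold in
    turn is the *training* set (its labels visible to the predictor) while
    the other k − 1 folds have their annotations hidden and are scored.
    Larger k therefore means sparser training labels.  Metrics are collected
    per fold over ``n_runs`` reshuffles.
    """
    if k < 2:
        raise MundoError("k must be >= 2")
    nodes = sorted(ann.protein_to_terms)
    if len(nodes) < k:
        raise MundoError(f"need at least k={k} annotated proteins, have {len(nodes)}")
    report = EvalReport(namespace=ann.namespace, k=k, n_runs=n_runs, seed=seed)
    for run in range(n_runs):
        rng = np.random.default_rng((seed, run))
        folds = _fold_split(nodes, k, rng)
        for fi, train_nodes in enumerate(folds):
            if not train_nodes:
                raise MundoError(f"fold {fi} has no labeled training nodes")
            test_nodes = sorted(n for fj, f in enumerate(folds) if fj != fi for n in f)
            train_ann = AnnotationMap(
                protein_to_terms={n: ann.protein_to_terms[n] for n in train_nodes},
                namespace=ann.namespace,
            )
            preds = predictor(train_ann, test_nodes)
            preds = {n: preds[n] for n in test_nodes}
            report.accuracy.append(percent_accuracy(preds, ann))
            report.f1.append(f1_max(preds, ann, dag=dag)[0])
            report.resnik.append(resnik_scores(preds, ann, ic, dag))
            report.train_sizes.append(len(train_nodes))
            report.test_sizes.append(len(test_nodes))
    return report


def standard_kfold_accuracy(
    ann: AnnotationMap,
    k: int,
    predictor: Predictor,
    seed: int,
) -> float:
    """Mean accuracy of ordinary k-fold CV (k−1 folds train, 1 tests)."""
    nodes = sorted(ann.protein_to_terms)
    if len(nodes) < k:
        raise MundoError(f"need at least k={k} annotated proteins, have {len(nodes)}")
    rng = np.random.default_rng(seed)
    folds = _fold_split(nodes, k, rng)
    accs = []
    for fi, test_fold in enumerate(folds):
        train_nodes = [n for fj, f in enumerate(folds) if fj != fi for n in f]
        train_ann = AnnotationMap(
            protein_to_terms={n: ann.protein_to_terms[n] for n in train_nodes},
            namespace=ann.namespace,
        )
        preds = predictor(train_ann, sorted(test_fold))
        accs.append(percent_accuracy(preds, ann))
    return float(np.mean(accs))


def grid_search(
    ann: AnnotationMap,
    configs: Sequence,
    make_predictor: Callable[[object], Predictor],
    seed: int,
    k: int = 5,
) -> tuple[list[tuple[object, float]], list[str]]:
    """Parameter search by standard k-fold CV on half the labeled data.

    Labeled proteins are split 50/50; the held-out validation half is never
    touched.  Returns configurations ranked by mean CV accuracy (descending,
    ties by iteration order) together with the validation node list.
    """
    if not configs:
        raise MundoError("empty configuration grid")
    nodes = sorted(ann.protein_to_terms)
    rng = np.random.default_rng(seed)
    order = list(nodes)
    rng.shuffle(order)
    half = len(order) // 2
    validation = sorted(order[:half])
    train_nodes = order[half:]
    train_ann = AnnotationMap(
        protein_to_terms={n: ann.protein_to_terms[n] for n in train_nodes},
        namespace=ann.namespace,
    )
    scored = []
    for idx, cfg in enumerate(configs):
        acc = standard_kfold_accuracy(train_ann, k, make_predictor(cfg), seed)
        scored.append((idx, cfg, acc))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return [(cfg, acc) for _, cfg, acc in scored], validation
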