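"""GO label assignment by weighted two-source nearest-neighbor voting.

The core predictor polls two voter pools for a target-network protein u:

* its ``d`` nearest *labeled* target-network neighbors under DSD
  (distance ascending), each contributing weight ``alpha`` to every GO term
  it carries, and
* its ``c`` nearest *labeled* model-network neighbors under the cross-species
  similarity D12 (similarity descending), each contributing weight 1.

Term confidences are normalized vote mass; the top ``top_r`` terms are
emitted.  Setting c=0 reduces exactly to the single-network DSD k-NN vote
and d=0 to the cross-embedding-only k-NN vote.  Six simpler homology
baselines replace the cross-embedding pool with direct sequence hits
(top hit, first 100 hits, thresholded hits — each optionally extended by
the hits' own model-network DSD neighborhoods).

Tie-breaking is lexicographic everywhere (term id for labels, node id for
neighbors) so predictions are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .coembed import CoEmbedding
from .dsd import DSDMatrix
from .netio import AnnotationMap, HitTable, MundoError

logger = logging.getLogger("mundo")

SIMPLE_METHODS = (
    "top_hit",
    "top_hit_nbhd",
    "all_hits",
    "all_hits_nbhd",
    "thresh_hits",
    "thresh_hits_nbhd",
)

#: BLAST's default number of reported hits; cap for the all_hits baselines.
MAX_HITS = 100


@dataclass(frozen=True)
class VoteConfig:
    """Voting parameters: d target neighbors, c cross-source neighbors,
    target-vote weight alpha, and the number of ranked labels emitted."""

    d: int = 20
    c: int = 10
    alpha: float = 1.5
    top_r: int = 3

    def __post_init__(self) -> None:
        if self.d < 0 or self.c < 0:
            raise MundoError("d and c must be >= 0")
        if self.d + self.c < 1:
            raise MundoError("at least one of d, c must be positive")
        if self.alpha <= 0:
            raise MundoError("alpha must be > 0")


@dataclass(frozen=True)
class LabelPrediction:
    protein: str
    ranked_labels: tuple[tuple[str, float], ...]
    abstain: bool = False

    @property
    def top_label(self) -> str | None:
        return self.ranked_labels[0][0] if self.ranked_labels else None


# ---------------------------------------------------------------------------
# Neighbor selection
# ---------------------------------------------------------------------------

def nearest_labeled_by_distance(
    dsd: DSDMatrix, node: str, labels: AnnotationMap, d: int,
) -> list[str]:
    """The d nearest labeled nodes by DSD, skipping unlabeled nodes and the
    query itself; ties break lexicographically by node id."""
    if d == 0:
        return []
    i = dsd.index(node)
    out = []
    for j in dsd.neighbor_order(i):
        if j == i:
            continue
        if dsd.nodes[j] in labels.protein_to_terms:
            out.append(dsd.nodes[j])
            if len(out) == d:
                break
    return out


def nearest_labeled_by_similarity(
    ce: CoEmbedding, node: str, labels: AnnotationMap, c: int,
) -> list[str]:
    """The c most d12-similar labeled model nodes; ties lexicographic."""
    if c == 0:
        return []
    out = []
    for i in ce.similarity_order(ce.target_index(node)):
        if ce.model_nodes[i] in labels.protein_to_terms:
            out.append(ce.model_nodes[i])
            if len(out) == c:
                break
    return out


def _nearest_labeled_model_by_dsd(
    dsd_model: DSDMatrix, node: str, labels: AnnotationMap, c: int,
) -> list[str]:
    return nearest_labeled_by_distance(dsd_model, node, labels, c)


# ---------------------------------------------------------------------------
# Vote accumulation
# ---------------------------------------------------------------------------

def _tally(
    protein: str,
    target_voters: list[str],
    model_voters: list[str],
    labels_target: AnnotationMap | None,
    labels_model: AnnotationMap | None,
    cfg: VoteConfig,
) -> LabelPrediction:
    weights: dict[str, float] = {}
    for v in target_voters:
        for term in labels_target.terms_of(v):
            weights[term] = weights.get(term, 0.0) + cfg.alpha
    for v in model_voters:
        for term in labels_model.terms_of(v):
            weights[term] = weights.get(term, 0.0) + 1.0
    if not weights:
        return LabelPrediction(protein=protein, ranked_labels=(), abstain=True)
    total = sum(weights.values())
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = ranked[: cfg.top_r]
    return LabelPrediction(
        protein=protein,
        ranked_labels=tuple((term, w / total) for term, w in ranked),
    )


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

def mundo_predict(
    node: str,
    dsd: DSDMatrix,
    ce: CoEmbedding | None,
    labels_target: AnnotationMap | None,
    labels_model: AnnotationMap | None,
    cfg: VoteConfig,
) -> LabelPrediction:
    """Weighted two-source vote for one target protein.

    ``ce``/``labels_model`` may be None when cfg.c == 0 (single-network
    mode).  A node with no labeled voter in either pool abstains.
    """
    if cfg.d > 0 and labels_target is None:
        raise MundoError("d > 0 requires target labels")
    target_voters = nearest_labeled_by_distance(dsd, node, labels_target, cfg.d)
    if cfg.c > 0:
        if ce is None or labels_model is None:
            raise MundoError("c > 0 requires a co-embedding and model labels")
        model_voters = nearest_labeled_by_similarity(ce, node, labels_model, cfg.c)
    else:
        model_voters = []
    return _tally(node, target_voters, model_voters, labels_target, labels_model, cfg)


def dsd_knn_predict(
    node: str, dsd: DSDMatrix, labels_target: AnnotationMap, cfg: VoteConfig
) -> LabelPrediction:
    """Single-network DSD k-NN vote (the c=0 degenerate case)."""
    only_d = VoteConfig(d=cfg.d, c=0, alpha=cfg.alpha, top_r=cfg.top_r)
    return mundo_predict(node, dsd, None, labels_target, None, only_d)


def munk_knn_predict(
    node: str,
    dsd: DSDMatrix,
    ce: CoEmbedding,
    labels_model: AnnotationMap,
    cfg: VoteConfig,
) -> LabelPrediction:
    """Cross-embedding-only k-NN vote (the d=0 degenerate case)."""
    only_c = VoteConfig(d=0, c=cfg.c, alpha=cfg.alpha, top_r=cfg.top_r)
    return mundo_predict(node, dsd, ce, None, labels_model, only_c)


def _model_side_voters(
    method: str,
    node: str,
    dsd_model: DSDMatrix | None,
    hits: HitTable,
    labels_model: AnnotationMap,
    cfg: VoteConfig,
    thresholds: tuple[float, float],
) -> list[str]:
    p_thr, q_thr = thresholds
    rows = hits.rows[hits.rows["qseqid"] == node]
    if len(rows) == 0:
        return []
    rows = rows.sort_values(
        ["bitscore", "pident", "sseqid"], ascending=[False, False, True],
        kind="mergesort",
    )
    if method.startswith("top_hit"):
        selected = [rows.iloc[0]["sseqid"]]
    elif method.startswith("all_hits"):
        selected = list(rows["sseqid"].head(MAX_HITS))
    elif method.startswith("thresh_hits"):
        ok = rows[(rows["pident"] >= p_thr) & (rows["qcovs"] >= q_thr)]
        selected = list(ok["sseqid"])
    else:
        raise MundoError(f"unknown simple method {method!r}")
    voters: list[str] = []
    seen: set[str] = set()

    def add(name: str) -> None:
        if name not in seen:
            seen.add(name)
            voters.append(name)

    for s in selected:
        add(s)
    if method.endswith("_nbhd"):
        if dsd_model is None:
            raise MundoError(f"method {method!r} requires the model DSD matrix")
        for s in selected:
            if s not in dsd_model.nodes:
                continue
            for nb in _nearest_labeled_model_by_dsd(dsd_model, s, labels_model, cfg.c):
                add(nb)
    return voters


def simple_predict(
    method: str,
    node: str,
    dsd_target: DSDMatrix,
    dsd_model: DSDMatrix | None,
    hits: HitTable,
    labels_target: AnnotationMap,
    labels_model: AnnotationMap,
    cfg: VoteConfig,
    thresholds: tuple[float, float] = (85.0, 90.0),
) -> LabelPrediction:
    """One of the six direct homology-transfer baselines.

    ``hits`` has target proteins as queries against the model proteome;
    ``thresholds`` is (percent identity p, query coverage q) for the
    thresholded variants.  All model-side voters carry weight 1, target
    DSD voters weight alpha; a node with zero hits falls back to the
    target-only vote (logged).
    """
    if method not in SIMPLE_METHODS:
        raise MundoError(f"unknown simple method {method!r}; choose from {SIMPLE_METHODS}")
    target_voters = nearest_labeled_by_distance(dsd_target, node, labels_target, cfg.d)
    model_voters = _model_side_voters(
        method, node, dsd_model, hits, labels_model, cfg, thresholds
    )
    if not model_voters:
        logger.debug("node %s has no usable hits; falling back to target-only vote", node)
    return _tally(node, target_voters, model_voters, labels_target, labels_model, cfg)


def predict_all(nodes, predictor, *args, **kwargs) -> list[LabelPrediction]:
    """Apply a single-node predictor over ``nodes`` in deterministic order.

    Per-node MundoErrors become abstentions (logged) rather than aborting
    the batch.
    """
    out = []
    for node in nodes:
        try:
            out.append(predictor(node, *args, **kwargs))
        except MundoError as exc:
            logger.warning("prediction failed for %s: %s", node, exc)
            out.append(LabelPrediction(protein=node, ranked_labels=(), abstain=True))
    return out
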