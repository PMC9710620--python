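"""End-to-end orchestration: read inputs → diffusion states → landmarks →
co-embedding → predictions → cross-validated report, with content-addressed
caching of the expensive embedding stages (they only need computing once per
species pair)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dsd as dsd_mod
from . import evaluate as ev
from . import netio
from .coembed import CoEmbedding, coembed_target, model_embedding
from .dsd import CONVERGED, DSDMatrix, converged_diffusion_state, diffusion_state, dsd_matrix
from .landmarks import select_rbh_landmarks
from .netio import AnnotationMap, MundoError
from .predict import LabelPrediction, VoteConfig, mundo_predict, predict_all

logger = logging.getLogger("mundo")


@dataclass
class RunConfig:
    """Configuration of one full run; defaults follow the recommended
    operating point (d=20, c=10, alpha=1.5; landmark thresholds (90, 85);
    term-specificity window 50–500)."""

    model_network: str = ""
    target_network: str = ""
    fwd_hits: str = ""
    rev_hits: str = ""
    go_dag: str = ""
    model_annotations: str = ""
    target_annotations: str = ""
    namespace: str = "BP"

    dsd_mode: str = "converged"  # or "fixed_t"
    dsd_t: int = 7

    q_threshold: float = 90.0
    p_threshold: float = 85.0

    d: int = 20
    c: int = 10
    alpha: float = 1.5
    top_r: int = 3

    cv_k: int = 2
    cv_runs: int = 5
    seed: int = 0

    min_term_count: int = 50
    max_term_count: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MundoError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def vote_config(self) -> VoteConfig:
        return VoteConfig(d=self.d, c=self.c, alpha=self.alpha, top_r=self.top_r)


def _hash_inputs(paths: list[str], extra: dict) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    h.update(json.dumps(extra, sort_keys=True).encode())
    return h.hexdigest()[:16]


def _diffusion(net, cfg: RunConfig):
    if cfg.dsd_mode == "converged":
        return converged_diffusion_state(net)
    if cfg.dsd_mode == "fixed_t":
        return diffusion_state(net, cfg.dsd_t)
    raise MundoError(f"unknown dsd_mode {cfg.dsd_mode!r}")


@dataclass
class PipelineState:
    """Computed artifacts of the embedding stages, reusable across votes."""

    model_net: object
    target_net: object
    target_dsd: DSDMatrix
    ce: CoEmbedding | None
    model_ann: AnnotationMap | None
    target_ann: AnnotationMap
    dag: object
    ic: ev.InformationContent


def build_state(cfg: RunConfig, cache_dir: str | Path | None = None) -> PipelineState:
    """Run the input and embedding stages (with optional caching)."""
    try:
        model_net = netio.largest_connected_component(
            netio.read_network(cfg.model_network))
        target_net = netio.largest_connected_component(
            netio.read_network(cfg.target_network))
    except MundoError as exc:
        raise MundoError(f"[stage: networks] {exc}") from exc

    try:
        dag = netio.read_go_dag(cfg.go_dag)
        target_ann = netio.read_annotations(cfg.target_annotations, dag, cfg.namespace)
        model_ann = netio.read_annotations(cfg.model_annotations, dag, cfg.namespace)
    except MundoError as exc:
        raise MundoError(f"[stage: annotations] {exc}") from exc

    cache = None
    if cache_dir is not None:
        cache = Path(cache_dir)
        cache.mkdir(parents=True, exist_ok=True)
        key = _hash_inputs(
            [cfg.model_network, cfg.target_network, cfg.fwd_hits, cfg.rev_hits],
            {"dsd_mode": cfg.dsd_mode, "dsd_t": cfg.dsd_t,
             "q": cfg.q_threshold, "p": cfg.p_threshold},
        )

    if cache is not None and (cache / f"{key}.npz").exists():
        logger.info("embedding cache hit (%s); skipping embedding stages", key)
        data = np.load(cache / f"{key}.npz", allow_pickle=False)
        meta = json.loads((cache / f"{key}.meta.json").read_text())
        target_dsd = DSDMatrix(dist=data["target_dsd"],
                               nodes=tuple(meta["target_nodes"]))
        from .landmarks import LandmarkSet
        lm = LandmarkSet(pairs=tuple(map(tuple, meta["landmarks"])),
                         q_threshold=cfg.q_threshold, p_threshold=cfg.p_threshold)
        ce = CoEmbedding(
            c_mat=data["c_mat"], d12=data["d12"], p_mat=data["p_mat"],
            model_nodes=tuple(meta["model_nodes"]),
            target_nodes=tuple(meta["target_nodes"]), landmark_ref=lm,
        )
    else:
        try:
            fwd = netio.read_hits(cfg.fwd_hits, direction="model->target")
            rev = netio.read_hits(cfg.rev_hits, direction="target->model")
            lm_all = select_rbh_landmarks(fwd, rev, cfg.q_threshold, cfg.p_threshold)
        except MundoError as exc:
            raise MundoError(f"[stage: landmarks] {exc}") from exc
        # landmarks must live inside the LCC-restricted networks
        pairs = tuple(
            (m, t) for m, t in lm_all.pairs
            if m in model_net.nodes and t in target_net.nodes
        )
        if not pairs:
            raise MundoError("[stage: landmarks] no landmark survives the LCC restriction")
        from .landmarks import LandmarkSet
        lm = LandmarkSet(pairs=pairs, q_threshold=cfg.q_threshold,
                         p_threshold=cfg.p_threshold)

        try:
            model_ds = _diffusion(model_net, cfg)
            target_ds = _diffusion(target_net, cfg)
            target_dsd = dsd_matrix(target_ds)
            emb = model_embedding(model_ds)
            ce = coembed_target(emb, target_ds, lm)
        except MundoError as exc:
            raise MundoError(f"[stage: embedding] {exc}") from exc

        if cache is not None:
            np.savez(cache / f"{key}.npz", target_dsd=target_dsd.dist,
                     c_mat=ce.c_mat, d12=ce.d12, p_mat=ce.p_mat)
            (cache / f"{key}.meta.json").write_text(json.dumps({
                "model_nodes": list(ce.model_nodes),
                "target_nodes": list(ce.target_nodes),
                "landmarks": [list(p) for p in lm.pairs],
            }))

    try:
        target_ann = ev.filter_terms(target_ann, cfg.min_term_count, cfg.max_term_count)
        model_ann = ev.restrict_terms(model_ann, target_ann.all_terms)
    except MundoError as exc:
        raise MundoError(f"[stage: term filtering] {exc}") from exc

    probs = dag.conditional_prob or ev.estimate_conditional_probs(dag, target_ann)
    ic = ev.information_content(dag, conditional_prob=probs)
    return PipelineState(
        model_net=model_net, target_net=target_net, target_dsd=target_dsd,
        ce=ce, model_ann=model_ann, target_ann=target_ann, dag=dag, ic=ic,
    )


def make_mundo_predictor(state: PipelineState, cfg: VoteConfig) -> ev.Predictor:
    """A cross-validation predictor closing over fixed embeddings."""

    def predictor(train_ann: AnnotationMap, test_nodes):
        preds = predict_all(
            test_nodes, mundo_predict, state.target_dsd, state.ce,
            train_ann, state.model_ann, cfg,
        )
        return {p.protein: p for p in preds}

    return predictor


def embed_pair(model_net, target_net, lm, mode: str = "converged", t: int = 7):
    """Compute (target DSD matrix, co-embedding) for a network pair."""
    if mode == "converged":
        model_ds = converged_diffusion_state(model_net)
        target_ds = converged_diffusion_state(target_net)
    else:
        model_ds = diffusion_state(model_net, t)
        target_ds = diffusion_state(target_net, t)
    target_dsd = dsd_matrix(target_ds)
    ce = coembed_target(model_embedding(model_ds), target_ds, lm)
    return target_dsd, ce


def make_dsd_predictor(target_dsd: DSDMatrix, cfg: VoteConfig) -> ev.Predictor:
    """Single-network predictor: target DSD k-NN vote only."""
    from .predict import dsd_knn_predict

    def predictor(train_ann: AnnotationMap, test_nodes):
        preds = predict_all(test_nodes, dsd_knn_predict, target_dsd, train_ann, cfg)
        return {p.protein: p for p in preds}

    return predictor


def make_munk_predictor(
    target_dsd: DSDMatrix, ce: CoEmbedding, model_ann: AnnotationMap, cfg: VoteConfig
) -> ev.Predictor:
    """Cross-embedding-only predictor; ignores target training labels."""
    from .predict import munk_knn_predict

    def predictor(train_ann: AnnotationMap, test_nodes):
        preds = predict_all(test_nodes, munk_knn_predict, target_dsd, ce,
                            model_ann, cfg)
        return {p.protein: p for p in preds}

    return predictor


#: Frozen study conditions of the scaled-down sparse-training comparison:
#: two 300-node species with 150 planted orthologs of which 20 anchor the
#: co-embedding, 20 mid-specificity GO terms, fully annotated ground truth
#: (so a 10-fold training fold still exceeds d = 20), default vote
#: parameters, 10-fold inverted CV.
TREND_CONDITIONS = dict(
    n_model=300, n_target=300, n_orthologs=150, n_strong_pairs=20,
    n_terms=20, label_density=1.0,
)
TREND_FILTER = (5, 150)


def trend_experiment(seed: int, k: int = 10, n_runs: int = 1) -> dict[str, ev.EvalReport]:
    """Compare the two-source vote against its single-source degenerate
    variants on one synthetic species pair under the frozen scaled-down
    conditions; returns per-method inverted-CV reports."""
    from .synth import SynthSpec, generate_dataset

    spec = SynthSpec(seed=seed, **TREND_CONDITIONS)
    data = generate_dataset(spec)
    lm = select_rbh_landmarks(data.fwd_hits, data.rev_hits, 90.0, 85.0)
    target_dsd, ce = embed_pair(data.model_net, data.target_net, lm)
    target_ann = ev.filter_terms(data.target_ann, *TREND_FILTER)
    model_ann = ev.restrict_terms(data.model_ann, target_ann.all_terms)
    ic = ev.information_content(data.dag)
    cfg = VoteConfig()  # d=20, c=10, alpha=1.5
    state = PipelineState(
        model_net=data.model_net, target_net=data.target_net,
        target_dsd=target_dsd, ce=ce, model_ann=model_ann,
        target_ann=target_ann, dag=data.dag, ic=ic,
    )
    predictors = {
        "mundo": make_mundo_predictor(state, cfg),
        "dsd": make_dsd_predictor(target_dsd, cfg),
        "munk": make_munk_predictor(target_dsd, ce, model_ann, cfg),
    }
    return {
        name: ev.inverted_kfold(target_ann, data.dag, ic, k, pred,
                                seed=seed, n_runs=n_runs)
        for name, pred in predictors.items()
    }


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> ev.EvalReport:
    """Execute the full flow and write predictions + report to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", dataclasses.asdict(cfg))
    state = build_state(cfg, cache_dir=outdir / "cache")

    vote_cfg = cfg.vote_config()
    report = ev.inverted_kfold(
        state.target_ann, state.dag, state.ic, cfg.cv_k,
        make_mundo_predictor(state, vote_cfg), seed=cfg.seed, n_runs=cfg.cv_runs,
    )

    # full-data predictions for the unannotated target proteins
    annotated = set(state.target_ann.protein_to_terms)
    unannotated = [n for n in state.target_net.nodes if n not in annotated]
    preds = predict_all(
        unannotated, mundo_predict, state.target_dsd, state.ce,
        state.target_ann, state.model_ann, vote_cfg,
    )
    with open(outdir / "predictions.tsv", "w") as fh:
        fh.write("protein\trank\tgo_id\tconfidence\n")
        for lp in preds:
            for rank, (term, conf) in enumerate(lp.ranked_labels, start=1):
                fh.write(f"{lp.protein}\t{rank}\t{term}\t{conf:.6f}\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)
    return report
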