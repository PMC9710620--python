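"""Synthetic paired-species fixtures: two correlated PPI networks with
planted orthologs, cross-proteome hit tables, a layered GO DAG and
community-structured annotations.

The generator emulates the study conditions of a model/target species pair:

* the model network comes from a duplication–divergence process (giving a
  hub-dominated, biologically shaped degree distribution; a small-world
  alternative is available for speed);
* the target network copies an induced subgraph over the planted ortholog
  nodes, rewires each copied edge with probability ``rewire_prob`` and
  attaches fresh species-specific nodes preferentially;
* ortholog pairs receive mutual sequence hits whose identity/coverage are
  drawn from separated distributions — "strong" pairs clear the (90, 85)
  reciprocal-best-hit preset, the rest stay mutual-best but sub-threshold —
  while decoy hits are strictly one-directional and far below threshold, so
  thresholded RBH selection recovers exactly the planted strong pairs;
* GO labels follow network communities (graph proximity predicts shared
  labels) and ortholog partners share labels with high probability; target
  labels are subsampled to ``label_density`` to mimic a sparsely annotated
  species while the model species stays fully annotated.

Everything is deterministic under ``SynthSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netio import AnnotationMap, GoDag, HitTable, MundoError, PPINetwork
from . import netio


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic species pair."""

    n_model: int = 300
    n_target: int = 300
    n_orthologs: int = 150
    rewire_prob: float = 0.3
    n_terms: int = 20
    dag_depth: int = 3
    label_density: float = 0.6
    decoy_hit_rate: float = 0.3
    seed: int = 0
    #: ortholog pairs whose hits clear the strict (90, 85) thresholds;
    #: None means all of them do.
    n_strong_pairs: int | None = None
    #: probability an ortholog partner inherits each individual label.
    ortholog_label_fidelity: float = 0.8
    generator: str = "duplication_divergence"

    def __post_init__(self) -> None:
        if self.n_orthologs > min(self.n_model, self.n_target):
            raise MundoError("n_orthologs exceeds a network size")
        for name in ("rewire_prob", "label_density", "decoy_hit_rate",
                     "ortholog_label_fidelity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise MundoError(f"{name}={v} outside [0, 1]")
        if self.n_strong_pairs is not None and self.n_strong_pairs > self.n_orthologs:
            raise MundoError("n_strong_pairs exceeds n_orthologs")


def _model_graph(spec: SynthSpec, seed: int) -> nx.Graph:
    if spec.generator == "duplication_divergence":
        g = nx.duplication_divergence_graph(spec.n_model, 0.7, seed=seed)
    elif spec.generator == "small_world":
        g = nx.connected_watts_strogatz_graph(spec.n_model, 6, 0.3, seed=seed)
    else:
        raise MundoError(f"unknown generator {spec.generator!r}")
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    return g.subgraph(comp).copy()


def generate_pair(spec: SynthSpec) -> tuple[PPINetwork, PPINetwork, dict[str, str]]:
    """Generate (model network, target network, model→target ortholog map)."""
    rng = np.random.default_rng((spec.seed, 1))
    g = _model_graph(spec, seed=int(rng.integers(2**31)))
    if g.number_of_nodes() < spec.n_orthologs:
        raise MundoError(
            "model generator produced a largest component smaller than n_orthologs"
        )
    raw_nodes = sorted(g.nodes())
    model_name = {v: f"m{i:04d}" for i, v in enumerate(raw_nodes)}
    g = nx.relabel_nodes(g, model_name)

    # BFS from a random start collects a connected ortholog subgraph.
    start = sorted(g.nodes())[int(rng.integers(g.number_of_nodes()))]
    ortho_model: list[str] = []
    for v in nx.bfs_tree(g, start):
        ortho_model.append(v)
        if len(ortho_model) == spec.n_orthologs:
            break
    ortho_model.sort()
    t_name = {m: "t" + m[1:] for m in ortho_model}

    tg = nx.Graph()
    tg.add_nodes_from(t_name.values())
    sub_edges = list(g.subgraph(ortho_model).edges())
    target_nodes = sorted(t_name.values())
    for u, v in sorted(sub_edges):
        if rng.random() < spec.rewire_prob:
            # replace by a uniformly random fresh edge among target nodes
            while True:
                a, b = rng.choice(target_nodes, size=2, replace=False)
                if not tg.has_edge(a, b):
                    tg.add_edge(a, b)
                    break
        else:
            tg.add_edge(t_name[u], t_name[v])

    # fresh species-specific nodes, preferential attachment with 2 edges
    n_fresh = spec.n_target - spec.n_orthologs
    for i in range(n_fresh):
        name = f"x{i:04d}"
        existing = sorted(tg.nodes())
        degs = np.array([max(tg.degree(v), 1) for v in existing], dtype=float)
        probs = degs / degs.sum()
        picks = rng.choice(len(existing), size=min(2, len(existing)),
                           replace=False, p=probs)
        tg.add_node(name)
        for j in picks:
            tg.add_edge(name, existing[j])

    comp = max(nx.connected_components(tg), key=lambda c: (len(c), sorted(c)))
    if len(comp) < 10:
        raise MundoError("target remnant below 10 nodes; adjust the spec")
    tg = tg.subgraph(comp).copy()

    model_net = PPINetwork.from_edges(list(g.edges()))
    target_net = PPINetwork.from_edges(list(tg.edges()))
    ortho_map = {
        m: t for m, t in t_name.items()
        if m in model_net.nodes and t in target_net.nodes
    }
    return model_net, target_net, ortho_map


def generate_hits(
    ortho_map: dict[str, str], spec: SynthSpec
) -> tuple[HitTable, HitTable]:
    """Generate (fwd: model-as-query, rev: target-as-query) hit tables.

    Strong ortholog pairs draw identity in [86, 99] and coverage in
    [91, 100] (clearing the (90, 85) preset); weak pairs draw identity in
    [60, 80] (mutual best, sub-threshold).  Decoys draw identity in
    [30, 50], are always directed at ortholog-paired subjects (whose own
    best hit is their partner) and are never reciprocated, so they can
    never form a mutual best pair.  Bitscore rises with identity with a
    gap that keeps every ortholog hit above every decoy hit.
    """
    if not ortho_map:
        raise MundoError("empty ortholog map")
    rng = np.random.default_rng((spec.seed, 2))
    pairs = sorted(ortho_map.items())
    n_strong = len(pairs) if spec.n_strong_pairs is None else spec.n_strong_pairs
    strong_idx = set(rng.choice(len(pairs), size=n_strong, replace=False).tolist())

    fwd_rows: list[tuple[str, str, float, float, float]] = []
    rev_rows: list[tuple[str, str, float, float, float]] = []

    def bitscore(identity: float, coverage: float) -> float:
        return 2.0 * identity + 0.05 * coverage + float(rng.normal(0, 0.5))

    for i, (m, t) in enumerate(pairs):
        if i in strong_idx:
            ident = float(rng.uniform(86, 99))
            cov = float(rng.uniform(91, 100))
        else:
            ident = float(rng.uniform(60, 80))
            cov = float(rng.uniform(60, 95))
        fwd_rows.append((m, t, ident, cov, bitscore(ident, cov)))
        # reverse direction gets its own slightly jittered measurement
        ident_r = float(np.clip(ident + rng.normal(0, 0.5), 0, 100))
        cov_r = float(np.clip(cov + rng.normal(0, 0.5), 0, 100))
        if i in strong_idx:
            ident_r = float(np.clip(ident_r, 86, 100))
            cov_r = float(np.clip(cov_r, 91, 100))
        rev_rows.append((t, m, ident_r, cov_r, bitscore(ident_r, cov_r)))

    models = [m for m, _ in pairs]
    targets = [t for _, t in pairs]
    for q_pool, s_pool, rows in ((models, targets, fwd_rows),
                                 (targets, models, rev_rows)):
        partner = dict(pairs) if rows is fwd_rows else {t: m for m, t in pairs}
        existing = {(q, s) for q, s, *_ in rows}
        for q in q_pool:
            if rng.random() >= spec.decoy_hit_rate:
                continue
            s = s_pool[int(rng.integers(len(s_pool)))]
            if s == partner[q] or (q, s) in existing:
                continue
            ident = float(rng.uniform(30, 50))
            cov = float(rng.uniform(40, 90))
            rows.append((q, s, ident, cov, bitscore(ident, cov)))
    return (
        HitTable.from_records(sorted(fwd_rows), direction="model->target"),
        HitTable.from_records(sorted(rev_rows), direction="target->model"),
    )


def _layer_sizes(n_terms: int, depth: int) -> list[int]:
    sizes = [n_terms]
    for _ in range(depth - 1):
        sizes.append(max(2, sizes[-1] // 2))
    sizes.reverse()  # root-adjacent layer first
    return sizes


def generate_go(
    spec: SynthSpec,
    model_net: PPINetwork,
    target_net: PPINetwork,
    ortho_map: dict[str, str],
    namespace: str = "BP",
) -> tuple[GoDag, AnnotationMap, AnnotationMap]:
    """Generate (dag, model annotations, target annotations).

    The DAG is layered with ``spec.n_terms`` assignable leaf terms under
    ``spec.dag_depth`` levels; conditional probabilities are constant within
    a layer (so a depth-1 ontology has uniform information accretion).
    Labels follow model-network communities; ortholog partners inherit the
    model labels with probability ``ortholog_label_fidelity``; target
    annotations are then subsampled to ``label_density``.
    """
    rng = np.random.default_rng((spec.seed, 3))
    root = "GO:0000000"
    sizes = _layer_sizes(spec.n_terms, spec.dag_depth)
    layers: list[list[str]] = [[root]]
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    probs: dict[str, float] = {}
    counter = 1
    layer_probs = rng.uniform(0.2, 0.7, size=len(sizes))
    for li, size in enumerate(sizes):
        layer = []
        for _ in range(size):
            term = f"GO:{counter:07d}"
            counter += 1
            ps = {layers[-1][int(rng.integers(len(layers[-1])))]}
            if len(layers[-1]) > 1 and rng.random() < 0.3:
                ps.add(layers[-1][int(rng.integers(len(layers[-1])))])
            parents[term] = frozenset(ps)
            probs[term] = float(layer_probs[li])
            layer.append(term)
        layers.append(layer)
    leaves = layers[-1]
    dag = GoDag(
        terms=frozenset(parents),
        parents=parents,
        conditional_prob=probs or None,
        namespace_of={t: namespace for t in parents},
    )

    # community structure on the model network drives label assignment;
    # leaf terms are dealt round-robin across communities so every term is
    # populated (keeps term counts inside a mid-specificity filter band)
    communities = list(
        nx.algorithms.community.greedy_modularity_communities(model_net.to_networkx())
    )
    comm_of = {v: ci for ci, comm in enumerate(communities) for v in comm}
    shuffled = [str(t) for t in rng.permutation(leaves)]
    n_comm = len(communities)
    comm_terms = {ci: sorted(shuffled[ci::n_comm]) for ci in range(n_comm)}
    for ci in range(n_comm):
        while len(comm_terms[ci]) < min(3, len(leaves)):
            extra = shuffled[int(rng.integers(len(shuffled)))]
            if extra not in comm_terms[ci]:
                comm_terms[ci] = sorted(comm_terms[ci] + [extra])

    def draw_labels(ci: int) -> frozenset[str]:
        prefs = comm_terms[ci]
        chosen = {t for t in prefs if rng.random() < 0.7}
        if not chosen:
            chosen = {prefs[int(rng.integers(len(prefs)))]}
        if rng.random() < 0.1:
            chosen.add(leaves[int(rng.integers(len(leaves)))])
        return frozenset(chosen)

    model_ann = {v: draw_labels(comm_of[v]) for v in model_net.nodes}

    # target node community: via ortholog partner where one exists,
    # otherwise propagated from neighbors, otherwise random.
    rev_map = {t: m for m, t in ortho_map.items()}
    t_comm: dict[str, int] = {
        t: comm_of[m] for t, m in rev_map.items() if m in comm_of
    }
    tg = target_net.to_networkx()
    pending = [v for v in target_net.nodes if v not in t_comm]
    for _ in range(3):
        still = []
        for v in pending:
            known = sorted(t_comm[nb] for nb in tg.neighbors(v) if nb in t_comm)
            if known:
                t_comm[v] = known[len(known) // 2]
            else:
                still.append(v)
        pending = still
    for v in pending:
        t_comm[v] = int(rng.integers(len(communities)))

    target_ann: dict[str, frozenset[str]] = {}
    for v in target_net.nodes:
        m = rev_map.get(v)
        if m is not None:
            inherited = {
                t for t in sorted(model_ann[m])
                if rng.random() < spec.ortholog_label_fidelity
            }
            if not inherited or rng.random() < 0.3:
                inherited |= {
                    comm_terms[t_comm[v]][int(rng.integers(len(comm_terms[t_comm[v]])))]
                }
            target_ann[v] = frozenset(inherited)
        else:
            target_ann[v] = draw_labels(t_comm[v])

    keep_n = int(round(spec.label_density * len(target_ann)))
    kept = sorted(
        rng.choice(sorted(target_ann), size=keep_n, replace=False).tolist()
    )
    target_ann = {v: target_ann[v] for v in kept}
    if not target_ann:
        raise MundoError("label_density left no annotated target proteins")
    return (
        dag,
        AnnotationMap(protein_to_terms=model_ann, namespace=namespace),
        AnnotationMap(protein_to_terms=target_ann, namespace=namespace),
    )


@dataclass(frozen=True)
class SynthDataset:
    model_net: PPINetwork
    target_net: PPINetwork
    ortho_map: dict[str, str]
    fwd_hits: HitTable
    rev_hits: HitTable
    dag: GoDag
    model_ann: AnnotationMap
    target_ann: AnnotationMap


def generate_dataset(spec: SynthSpec, namespace: str = "BP") -> SynthDataset:
    """Run all three generators and bundle their outputs."""
    model_net, target_net, ortho_map = generate_pair(spec)
    fwd, rev = generate_hits(ortho_map, spec)
    dag, model_ann, target_ann = generate_go(
        spec, model_net, target_net, ortho_map, namespace=namespace
    )
    return SynthDataset(model_net, target_net, ortho_map, fwd, rev,
                        dag, model_ann, target_ann)


def write_dataset(ds: SynthDataset, outdir) -> dict[str, str]:
    """Write every input format consumed by the I/O layer; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model_network": outdir / "model_network.tsv",
        "target_network": outdir / "target_network.tsv",
        "fwd_hits": outdir / "hits_model_to_target.tsv",
        "rev_hits": outdir / "hits_target_to_model.tsv",
        "go_dag": outdir / "go_dag.tsv",
        "model_annotations": outdir / "model_annotations.tsv",
        "target_annotations": outdir / "target_annotations.tsv",
        "ortholog_map": outdir / "ortholog_map.tsv",
    }
    netio.write_network(ds.model_net, paths["model_network"])
    netio.write_network(ds.target_net, paths["target_network"])
    netio.write_hits(ds.fwd_hits, paths["fwd_hits"])
    netio.write_hits(ds.rev_hits, paths["rev_hits"])
    netio.write_go_dag(ds.dag, paths["go_dag"])
    netio.write_annotations(ds.model_ann, paths["model_annotations"])
    netio.write_annotations(ds.target_ann, paths["target_annotations"])
    with open(paths["ortholog_map"], "w") as fh:
        for m, t in sorted(ds.ortho_map.items()):
            fh.write(f"{m}\t{t}\n")
    return {k: str(v) for k, v in paths.items()}
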