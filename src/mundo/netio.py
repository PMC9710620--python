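"""Input/output for PPI networks, GO annotations, ontologies and sequence-hit tables.

All in-memory containers fix a *lexicographic node order* at construction
time; every matrix produced downstream (diffusion states, DSD, embeddings)
is aligned to that order, which makes eigendecompositions and neighbor
tie-breaks reproducible across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("mundo")


class MundoError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MundoError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# PPI networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPINetwork:
    """An undirected, unweighted protein-protein interaction network.

    ``nodes`` is lexicographically sorted and ``adjacency`` (a dense
    symmetric 0/1 matrix) is aligned to it.  Self-loops are never stored.
    """

    nodes: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise MundoError("adjacency shape does not match node count")
        if np.any(np.diag(a) != 0):
            raise MundoError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise MundoError("adjacency must be symmetric")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        """Build a network from an iterable of (possibly repeated) edges.

        Self-loops are dropped, duplicates collapse, nodes sort
        lexicographically.
        """
        seen: set[frozenset[str]] = set()
        names: set[str] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            names.add(u)
            names.add(v)
            if u == v:
                continue
            seen.add(frozenset((u, v)))
        if not names:
            raise MundoError("empty network")
        nodes = tuple(sorted(names))
        index = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for e in seen:
            u, v = tuple(e)
            adj[index[u], index[v]] = 1.0
            adj[index[v], index[u]] = 1.0
        return cls(nodes=nodes, adjacency=adj)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        iu, ju = np.nonzero(np.triu(self.adjacency))
        return {frozenset((self.nodes[i], self.nodes[j])) for i, j in zip(iu, ju)}

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency)))

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise MundoError(f"node {node!r} not in network") from None

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            u, v = tuple(e)
            g.add_edge(u, v)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


# BioGRID tab3 column names actually consumed; everything else is ignored.
_BIOGRID_A = "Official Symbol Interactor A"
_BIOGRID_B = "Official Symbol Interactor B"


def read_network(path: str | Path, format: str = "edgelist") -> PPINetwork:
    """Read a PPI network from ``path``.

    ``format`` is ``"edgelist"`` (two tab-separated columns, ``#`` comments)
    or ``"biogrid_tsv"`` (BioGRID tab3; only the two official-symbol columns
    are consumed and every edge is unweighted).
    """
    path = Path(path)
    if format == "edgelist":
        edges = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    parts = line.split()
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ParseError(f"{path}:{lineno}: malformed edge line: {line!r}")
                edges.append((parts[0], parts[1]))
        if not edges:
            raise MundoError(f"{path}: no edges found")
        return PPINetwork.from_edges(edges)
    if format == "biogrid_tsv":
        df = pd.read_csv(path, sep="\t", comment=None, dtype=str, low_memory=False)
        for col in (_BIOGRID_A, _BIOGRID_B):
            if col not in df.columns:
                raise ParseError(f"{path}: missing BioGRID tab3 column {col!r}")
        pairs = df[[_BIOGRID_A, _BIOGRID_B]].dropna().itertuples(index=False)
        edges = [(a, b) for a, b in pairs]
        if not edges:
            raise MundoError(f"{path}: no edges found")
        return PPINetwork.from_edges(edges)
    raise MundoError(f"unknown network format {format!r}")


def write_network(net: PPINetwork, path: str | Path) -> None:
    """Write a network as a canonical two-column edge list (sorted)."""
    lines = sorted(tuple(sorted(e)) for e in net.edges)
    with open(path, "w") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")


def largest_connected_component(net: PPINetwork) -> PPINetwork:
    """Restrict a network to its largest connected component.

    Ties between equally sized components break toward the component whose
    sorted node tuple is lexicographically smallest.
    """
    g = net.to_networkx()
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    keep = set(comps[0])
    idx = [i for i, n in enumerate(net.nodes) if n in keep]
    sub = net.adjacency[np.ix_(idx, idx)]
    return PPINetwork(nodes=tuple(net.nodes[i] for i in idx), adjacency=sub)


# ---------------------------------------------------------------------------
# GO DAG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoDag:
    """A Gene Ontology subset: terms, is_a parents and (optionally) the
    conditional probabilities Pr(v | parents(v)) used for information
    accretion."""

    terms: frozenset[str]
    parents: Mapping[str, frozenset[str]]
    conditional_prob: Mapping[str, float] | None = None
    namespace_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        for t, ps in self.parents.items():
            missing = ps - self.terms
            if missing:
                raise MundoError(f"term {t} has unknown parents {sorted(missing)}")
        if self.conditional_prob is not None:
            for t, p in self.conditional_prob.items():
                if not (0.0 < p <= 1.0):
                    raise MundoError(f"conditional_prob[{t}]={p} outside (0, 1]")
        # acyclicity
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            raise MundoError("GO parent relation contains a cycle")

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """Ancestor closure of ``term`` along is_a edges (memoized)."""
        if term not in self.terms:
            raise MundoError(f"unknown GO term {term!r}")
        cache = self.__dict__.setdefault("_ancestor_cache", {})
        if term not in cache:
            out: set[str] = set()
            stack = list(self.parents.get(term, ()))
            while stack:
                t = stack.pop()
                if t in out:
                    continue
                out.add(t)
                stack.extend(self.parents.get(t, ()))
            cache[term] = frozenset(out)
        closure = cache[term]
        return closure | {term} if include_self else closure


def read_go_dag(path: str | Path) -> GoDag:
    """Read a GO DAG from an OBO file (via obonet) or a 3-column TSV
    ``term<TAB>parent<TAB>conditional_prob`` (parent empty or '-' for roots,
    one row per is_a edge, conditional_prob repeated per term)."""
    path = Path(path)
    if path.suffix == ".obo":
        import obonet

        g = obonet.read_obo(path)
        terms = frozenset(g.nodes)
        parents = {
            t: frozenset(
                v for _, v, k in g.out_edges(t, keys=True) if k == "is_a"
            )
            for t in terms
        }
        ns = {
            t: {"biological_process": "BP", "molecular_function": "MF",
                "cellular_component": "CC"}.get(d.get("namespace", ""), "")
            for t, d in g.nodes(data=True)
        }
        return GoDag(terms=terms, parents=parents, namespace_of=ns)

    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    probs: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected ≥2 columns")
            term, parent = parts[0], parts[1]
            terms.add(term)
            parents.setdefault(term, set())
            if parent and parent != "-":
                terms.add(parent)
                parents.setdefault(parent, set())
                parents[term].add(parent)
            if len(parts) >= 3 and parts[2]:
                try:
                    probs[term] = float(parts[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad probability {parts[2]!r}")
    if not terms:
        raise MundoError(f"{path}: empty ontology")
    return GoDag(
        terms=frozenset(terms),
        parents={t: frozenset(ps) for t, ps in parents.items()},
        conditional_prob=probs or None,
    )


def write_go_dag(dag: GoDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(dag.terms):
            ps = sorted(dag.parents.get(term, ())) or ["-"]
            prob = ""
            if dag.conditional_prob and term in dag.conditional_prob:
                prob = repr(dag.conditional_prob[term])
            for p in ps:
                fh.write(f"{term}\t{p}\t{prob}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationMap:
    """Protein → GO term assignments within a single namespace (BP or MF)."""

    protein_to_terms: Mapping[str, frozenset[str]]
    namespace: str

    def __post_init__(self) -> None:
        for prot, ts in self.protein_to_terms.items():
            if not ts:
                raise MundoError(f"protein {prot} has an empty term set")

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self.protein_to_terms))

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.protein_to_terms.get(protein, frozenset())

    @property
    def all_terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.protein_to_terms.values():
            out |= ts
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.protein_to_terms)


def read_annotations(path: str | Path, dag: GoDag, namespace: str) -> AnnotationMap:
    """Read a 3-column TSV ``protein_id<TAB>go_id<TAB>namespace``.

    Rows whose term is absent from ``dag`` are dropped with a logged count;
    only rows in the requested namespace are retained.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            prot, term, ns = parts[0], parts[1], parts[2]
            if ns != namespace:
                continue
            if term not in dag.terms:
                dropped += 1
                continue
            mapping.setdefault(prot, set()).add(term)
    if dropped:
        logger.warning("%s: dropped %d annotation rows with unknown GO terms", path, dropped)
    if not mapping:
        raise MundoError(f"{path}: no annotations retained for namespace {namespace}")
    return AnnotationMap(
        protein_to_terms={p: frozenset(ts) for p, ts in mapping.items()},
        namespace=namespace,
    )


_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


def read_gaf(path: str | Path, dag: GoDag, namespace: str) -> AnnotationMap:
    """Convenience GAF-2 reader (columns: DB object symbol 3, GO id 5, aspect 9)."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            prot, term, aspect = parts[2], parts[4], parts[8]
            if _GAF_ASPECT.get(aspect) != namespace:
                continue
            if term not in dag.terms:
                dropped += 1
                continue
            mapping.setdefault(prot, set()).add(term)
    if dropped:
        logger.warning("%s: dropped %d GAF rows with unknown GO terms", path, dropped)
    if not mapping:
        raise MundoError(f"{path}: no annotations retained for namespace {namespace}")
    return AnnotationMap(
        protein_to_terms={p: frozenset(ts) for p, ts in mapping.items()},
        namespace=namespace,
    )


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in ann.proteins:
            for term in sorted(ann.terms_of(prot)):
                fh.write(f"{prot}\t{term}\t{ann.namespace}\n")


# ---------------------------------------------------------------------------
# Sequence hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = ("qseqid", "sseqid", "pident", "qcovs", "bitscore")


@dataclass(frozen=True)
class HitTable:
    """All-vs-all sequence hits in one direction (query species → subject
    species), BLAST outfmt-6 style.  At most one row per (query, subject)."""

    rows: pd.DataFrame
    direction: str = ""

    def __post_init__(self) -> None:
        df = self.rows
        missing = set(HIT_COLUMNS) - set(df.columns)
        if missing:
            raise MundoError(f"hit table missing columns {sorted(missing)}")
        if df.duplicated(subset=["qseqid", "sseqid"]).any():
            raise MundoError("hit table has duplicate (query, subject) rows")
        for col in ("pident", "qcovs"):
            vals = df[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 100)):
                raise MundoError(f"{col} outside [0, 100]")
        if np.any(df["bitscore"].to_numpy(dtype=float) < 0):
            raise MundoError("negative bitscore")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float, float]], direction: str = ""
    ) -> "HitTable":
        df = pd.DataFrame(list(records), columns=list(HIT_COLUMNS))
        return cls(rows=df.reset_index(drop=True), direction=direction)

    def __len__(self) -> int:
        return len(self.rows)


def read_hits(
    path: str | Path,
    direction: str = "",
    columns: Mapping[str, str] | None = None,
) -> HitTable:
    """Read a BLAST-tabular-style TSV.

    ``columns`` optionally maps the canonical names (qseqid, sseqid, pident,
    qcovs, bitscore) to the file's own header names; headerless files are
    assumed to carry the five canonical columns in order.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = any(c.isalpha() for c in first.split("\t")[2:3])
    if has_header:
        df = pd.read_csv(path, sep="\t", comment="#")
        if columns:
            df = df.rename(columns={v: k for k, v in columns.items()})
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=list(HIT_COLUMNS))
    df = df[list(HIT_COLUMNS)].astype(
        {"qseqid": str, "sseqid": str, "pident": float, "qcovs": float, "bitscore": float}
    )
    # collapse accidental duplicates toward the strongest row
    df = (
        df.sort_values(["qseqid", "sseqid", "bitscore"], ascending=[True, True, False])
        .drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
        .reset_index(drop=True)
    )
    return HitTable(rows=df, direction=direction)


def write_hits(hits: HitTable, path: str | Path) -> None:
    hits.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dense matrix persistence (array + node-order sidecar)
# ---------------------------------------------------------------------------

def save_matrix(mat: np.ndarray, nodes: Iterable[str], path: str | Path) -> None:
    """Persist a node-aligned matrix as .npy with a JSON node-order sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), mat)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(list(nodes), fh)


def load_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    path = Path(path)
    mat = np.load(path.with_suffix(".npy"))
    with open(path.with_suffix(".json")) as fh:
        nodes = tuple(json.load(fh))
    return mat, nodes
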