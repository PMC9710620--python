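"""Reciprocal-best-hit (RBH) landmark selection from precomputed hit tables.

A landmark is a cross-species protein pair (model, target) such that each is
the other's best sequence hit and both direction rows pass the query-coverage
and percent-identity thresholds (q, p).  Defaults (90, 85) suit closely
related proteomes; a relaxed preset (75, 50) is the documented choice for
more distant pairs where the strict thresholds starve the landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .netio import HitTable, MundoError

#: (q, p) percent thresholds for closely related species pairs.
STRICT_THRESHOLDS = (90.0, 85.0)
#: Relaxed preset for distant pairs where STRICT yields too few landmarks.
RELAXED_THRESHOLDS = (75.0, 50.0)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered bijection of (model_protein, target_protein) landmark pairs."""

    pairs: tuple[tuple[str, str], ...]
    q_threshold: float
    p_threshold: float

    def __post_init__(self) -> None:
        models = [m for m, _ in self.pairs]
        targets = [t for _, t in self.pairs]
        if len(set(models)) != len(models) or len(set(targets)) != len(targets):
            raise MundoError("landmark pairs must form a bijection")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def model_proteins(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.pairs)

    @property
    def target_proteins(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.pairs)

    def swapped(self) -> "LandmarkSet":
        """The same landmarks with model/target roles exchanged."""
        return LandmarkSet(
            pairs=tuple(sorted((t, m) for m, t in self.pairs)),
            q_threshold=self.q_threshold,
            p_threshold=self.p_threshold,
        )


def best_hits(hits: HitTable) -> dict[str, str]:
    """Best subject per query: maximal bitscore, ties broken by higher
    percent identity then lexicographically smaller subject id."""
    if len(hits) == 0:
        raise MundoError("empty hit table")
    df = hits.rows.sort_values(
        ["qseqid", "bitscore", "pident", "sseqid"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    top = df.drop_duplicates(subset="qseqid", keep="first")
    return dict(zip(top["qseqid"], top["sseqid"]))


def select_rbh_landmarks(
    fwd: HitTable, rev: HitTable, q: float, p: float
) -> LandmarkSet:
    """Select thresholded reciprocal best hits.

    ``fwd`` has model proteins as queries, ``rev`` target proteins.  A pair
    (m, t) is kept when m's best hit is t, t's best hit is m, and *both*
    direction rows satisfy coverage >= q and identity >= p.  Pairs come back
    sorted by model protein.
    """
    fwd_best = best_hits(fwd)
    rev_best = best_hits(rev)
    fwd_rows = fwd.rows.set_index(["qseqid", "sseqid"])
    rev_rows = rev.rows.set_index(["qseqid", "sseqid"])

    def passes(rows, query, subject) -> bool:
        r = rows.loc[(query, subject)]
        return bool(r["qcovs"] >= q and r["pident"] >= p)

    pairs = []
    for m, t in fwd_best.items():
        if rev_best.get(t) != m:
            continue
        if passes(fwd_rows, m, t) and passes(rev_rows, t, m):
            pairs.append((m, t))
    if not pairs:
        raise MundoError(
            f"no reciprocal best hits survive thresholds (q={q}, p={p}); "
            "consider relaxing them (e.g. the (75, 50) preset for distant species)"
        )
    return LandmarkSet(pairs=tuple(sorted(pairs)), q_threshold=q, p_threshold=p)
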