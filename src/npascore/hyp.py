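"""HYP and causal network model data structures.

A HYP couples one upstream biological entity (for example a transcription
factor's activity) to the set of downstream measurable genes it is known to
regulate, each with a regulation sign (+1 positive, -1 negative) and optional
literature evidence.  A causal network model is a signed directed graph of
such entities; when the model is causally consistent it can be flattened into
a single aggregated HYP relative to a chosen reference node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: accepted relation tokens in tabular files, mapped to signs
SIGN_TOKENS = {
    "increases": 1,
    "decreases": -1,
    "+1": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "→": 1,  # right arrow
    "--|": -1,
    "1": 1,
}


class HypError(ValueError):
    """Malformed or empty HYP input."""


class InconsistentNetworkError(ValueError):
    """The signed network admits no unambiguous sign assignment (negative feedback)."""


@dataclass(frozen=True)
class DownstreamEdge:
    """One signed, evidence-annotated downstream gene of a HYP."""

    gene: str
    sign: int
    evidence: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene:
            raise HypError("downstream gene identifier must be non-empty")
        if self.sign not in (1, -1):
            raise HypError(f"sign must be +1 or -1, got {self.sign!r}")


@dataclass
class Hyp:
    """An upstream entity plus its signed downstream gene set.

    ``dropped_ambiguous`` records genes removed because they were asserted
    with both signs (within one source table or across aggregated nodes).
    """

    upstream: str
    downstreams: list[DownstreamEdge]
    dropped_ambiguous: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes = [d.gene for d in self.downstreams]
        if len(genes) != len(set(genes)):
            raise HypError(f"duplicate downstream genes in HYP {self.upstream!r}")

    @property
    def n(self) -> int:
        """Number of downstream measurable genes (N in the scores)."""
        return len(self.downstreams)

    def genes(self) -> set[str]:
        return {d.gene for d in self.downstreams}

    def signs(self) -> dict[str, int]:
        return {d.gene: d.sign for d in self.downstreams}


@dataclass
class CausalNetwork:
    """Signed directed graph of entities, some carrying HYPs, with a reference node."""

    nodes: set[str]
    edges: list[tuple[str, str, int]]
    node_hyps: dict[str, Hyp]
    reference: str

    def __post_init__(self) -> None:
        for s, t, sign in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise HypError(f"edge ({s!r}, {t!r}) has an endpoint outside the node set")
            if sign not in (1, -1):
                raise HypError(f"edge sign must be +1 or -1, got {sign!r}")
        if self.reference not in self.nodes:
            raise HypError(f"reference node {self.reference!r} not in the network")
        if not self.node_hyps:
            raise HypError("network carries no HYPs; nothing to aggregate")


def _parse_sign(token: str) -> int:
    tok = str(token).strip()
    if tok not in SIGN_TOKENS:
        raise HypError(
            f"unknown relation token {tok!r}; accepted: {sorted(SIGN_TOKENS)}"
        )
    return SIGN_TOKENS[tok]


def _rows_to_hyp(upstream: str, rows: pd.DataFrame) -> Hyp:
    """Collapse raw (gene, sign, evidence) rows into a deduplicated HYP.

    Rows repeating a (gene, sign) pair merge their evidence; genes asserted
    with both signs are excluded and recorded in ``dropped_ambiguous``.
    """
    by_gene: dict[str, dict[int, set[str]]] = {}
    for _, row in rows.iterrows():
        gene = str(row["gene"]).strip()
        if not gene:
            raise HypError("empty gene identifier")
        sign = _parse_sign(row["relation"])
        ev_raw = row.get("evidence")
        ev = set()
        if ev_raw is not None and not pd.isna(ev_raw) and str(ev_raw).strip():
            ev = {e.strip() for e in str(ev_raw).split(";") if e.strip()}
        by_gene.setdefault(gene, {}).setdefault(sign, set()).update(ev)

    rows_per_gene = rows["gene"].astype(str).str.strip().value_counts()
    downstreams: list[DownstreamEdge] = []
    dropped: list[str] = []
    for gene in sorted(by_gene):
        signs = by_gene[gene]
        if len(signs) > 1:
            dropped.append(gene)
            continue
        sign, ev = next(iter(signs.items()))
        downstreams.append(DownstreamEdge(gene, sign, frozenset(ev)))
    n_merged = int(len(rows) - rows_per_gene[dropped].sum()) - len(downstreams)
    if not downstreams:
        raise HypError(f"HYP {upstream!r} is empty after ambiguity filtering")
    logger.info(
        "HYP %s: kept %d genes, merged %d duplicate rows, dropped %d ambiguous",
        upstream, len(downstreams), n_merged, len(dropped),
    )
    return Hyp(upstream=upstream, downstreams=downstreams, dropped_ambiguous=dropped)


def _read_hyp_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise HypError(f"HYP file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("upstream", "relation", "gene"):
        if col not in df.columns:
            raise HypError(f"HYP file {path} lacks mandatory column {col!r}")
    return df


def load_hyp(path: str | Path, format: str = "tsv") -> Hyp:
    """Load a single HYP from a TSV of causal statements.

    Columns: ``upstream  relation  gene  evidence`` (evidence optional,
    semicolon-separated citation IDs).  Exactly one distinct upstream entity
    must appear.
    """
    if format != "tsv":
        raise HypError(f"unsupported HYP format {format!r}")
    df = _read_hyp_frame(path)
    ups = sorted(df["upstream"].astype(str).str.strip().unique())
    if len(ups) != 1:
        raise HypError(f"expected one upstream entity in {path}, found {ups}")
    return _rows_to_hyp(ups[0], df)


def load_hyp_table(path: str | Path) -> dict[str, Hyp]:
    """Load a multi-upstream HYP table, returning one HYP per upstream entity."""
    df = _read_hyp_frame(path)
    out: dict[str, Hyp] = {}
    for upstream, rows in df.groupby(df["upstream"].astype(str).str.strip()):
        out[str(upstream)] = _rows_to_hyp(str(upstream), rows)
    return out


def load_network(
    edges_path: str | Path,
    reference: str,
    hyp_paths: list[str | Path] | str | Path,
) -> CausalNetwork:
    """Load a causal network model: signed edges TSV + node HYP file(s).

    The edges file has header columns ``source  relation  target``; node HYPs
    are HYP tables keyed by their upstream entity, which must match a network
    node name.
    """
    edges_path = Path(edges_path)
    if not edges_path.exists():
        raise HypError(f"network file not found: {edges_path}")
    df = pd.read_csv(edges_path, sep="\t", dtype=str)
    for col in ("source", "relation", "target"):
        if col not in df.columns:
            raise HypError(f"network file {edges_path} lacks mandatory column {col!r}")
    edges = [
        (str(r["source"]).strip(), str(r["target"]).strip(), _parse_sign(r["relation"]))
        for _, r in df.iterrows()
    ]
    nodes = {s for s, _, _ in edges} | {t for _, t, _ in edges} | {reference}
    if isinstance(hyp_paths, (str, Path)):
        hyp_paths = [hyp_paths]
    node_hyps: dict[str, Hyp] = {}
    for p in hyp_paths:
        for upstream, h in load_hyp_table(p).items():
            if upstream not in nodes:
                raise HypError(f"HYP upstream {upstream!r} is not a network node")
            node_hyps[upstream] = h
    return CausalNetwork(nodes=nodes, edges=edges, node_hyps=node_hyps, reference=reference)


def check_consistency(net: CausalNetwork) -> dict[str, int]:
    """Propagate signs from the reference node over the signed graph.

    Every edge, traversed in either orientation, constrains the relative sign
    of its endpoints: sign(target) = sign(source) x edge sign.  Returns the
    node -> {+1,-1} assignment, or raises :class:`InconsistentNetworkError`
    when a node would receive both signs (a negative-feedback cycle) or a
    HYP-carrying node is unreachable from the reference.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for s, t, sign in net.edges:
        if g.has_edge(s, t) and g[s][t]["sign"] != sign:
            # parallel edges with opposite signs: a 2-cycle contradiction
            raise InconsistentNetworkError(
                f"nodes {s!r} and {t!r} are linked by edges of both signs"
            )
        g.add_edge(s, t, sign=sign)

    assignment: dict[str, int] = {net.reference: 1}
    stack = [net.reference]
    while stack:
        u = stack.pop()
        for v in g.neighbors(u):
            want = assignment[u] * g[u][v]["sign"]
            if v in assignment:
                if assignment[v] != want:
                    raise InconsistentNetworkError(
                        f"node {v!r} receives both signs via paths from "
                        f"{net.reference!r} (negative feedback through {u!r}-{v!r}); "
                        "resolve the loop by editing the model"
                    )
            else:
                assignment[v] = want
                stack.append(v)

    unreachable = [n for n in net.node_hyps if n not in assignment]
    if unreachable:
        raise InconsistentNetworkError(
            f"HYP-carrying node(s) unreachable from reference {net.reference!r}: "
            f"{sorted(unreachable)}"
        )
    return assignment


def aggregate_network(net: CausalNetwork) -> Hyp:
    """Flatten a causally consistent network into a single aggregated HYP.

    Each node's downstream signs are multiplied by the node's sign relative to
    the reference; genes contributed with a consistent adjusted sign appear
    once with evidence unioned, genes with contradictory adjusted signs are
    omitted and recorded in ``dropped_ambiguous``.
    """
    assignment = check_consistency(net)
    by_gene: dict[str, dict[int, set[str]]] = {}
    total_genes: set[str] = set()
    for node, h in net.node_hyps.items():
        node_sign = assignment[node]
        for d in h.downstreams:
            adj = node_sign * d.sign
            by_gene.setdefault(d.gene, {}).setdefault(adj, set()).update(d.evidence)
            total_genes.add(d.gene)

    downstreams: list[DownstreamEdge] = []
    dropped: list[str] = []
    for gene in sorted(by_gene):
        signs = by_gene[gene]
        if len(signs) > 1:
            dropped.append(gene)
            continue
        sign, ev = next(iter(signs.items()))
        downstreams.append(DownstreamEdge(gene, sign, frozenset(ev)))
    if not downstreams:
        raise HypError("aggregated HYP is empty")
    frac = len(dropped) / len(total_genes)
    logger.info(
        "aggregated HYP %s: %d genes kept, %d (%.1f%%) dropped as ambiguous",
        net.reference, len(downstreams), len(dropped), 100 * frac,
    )
    return Hyp(upstream=net.reference, downstreams=downstreams, dropped_ambiguous=dropped)


def hyp_overlap(a: Hyp, b: Hyp) -> int:
    """Number of downstream genes shared by two HYPs (signs ignored)."""
    return len(a.genes() & b.genes())


def subsample_hyp(h: Hyp, fraction_removed: float, seed: int) -> Hyp:
    """Uniformly remove ``floor(fraction_removed * N)`` downstream genes.

    Signs and evidence are preserved; reproducible for a fixed seed.  Used by
    the robustness experiment that re-scores a HYP after random edge removal.
    """
    if not 0 <= fraction_removed < 1:
        raise ValueError(f"fraction_removed must be in [0, 1), got {fraction_removed}")
    n_keep = h.n - int(np.floor(fraction_removed * h.n))
    if n_keep < 1:
        raise ValueError("subsampling would empty the HYP")
    if n_keep == h.n:
        return Hyp(h.upstream, list(h.downstreams), list(h.dropped_ambiguous))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(h.n, size=n_keep, replace=False))
    kept = [h.downstreams[i] for i in idx]
    return Hyp(h.upstream, kept, list(h.dropped_ambiguous))
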