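"""Bipartite reaction-metabolite network representation and I/O.

A genome-scale metabolic model is viewed here as an undirected bipartite
graph: reaction nodes on one side, metabolite nodes on the other, with an
edge whenever a metabolite participates in a reaction (as substrate or
product -- the network is deliberately reversibility-agnostic, since no
claims about flux directions are made downstream).  Each reaction carries a
possibly-empty set of associated gene ids, through which expression data
are later mapped onto the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, UnknownNodeError, ValidationError

REACTION = "reaction"
METABOLITE = "metabolite"

_TABLE_COLUMNS = ("reaction_id", "metabolite_ids", "gene_ids")


@dataclass(frozen=True)
class ModuleNodeSet:
    """A subset of network nodes, split by node class.

    Instances produced by :func:`connected_components` induce a connected
    subgraph; singletons (one reaction, or one reaction plus one metabolite)
    are perfectly valid modules.
    """

    reaction_ids: frozenset
    metabolite_ids: frozenset

    @property
    def nodes(self) -> frozenset:
        return self.reaction_ids | self.metabolite_ids

    @property
    def composition(self) -> tuple:
        """(number of reactions, number of metabolites)."""
        return (len(self.reaction_ids), len(self.metabolite_ids))

    def __len__(self) -> int:
        return len(self.reaction_ids) + len(self.metabolite_ids)


@dataclass(frozen=True)
class MetabolicNetwork:
    """Undirected bipartite graph of reactions and metabolites.

    Ids are opaque, case-sensitive strings; reaction and metabolite id sets
    must be disjoint.  ``gene_map`` assigns each reaction a (possibly empty)
    set of gene ids.
    """

    reactions: frozenset
    metabolites: frozenset
    edges: frozenset  # of (reaction_id, metabolite_id) pairs
    gene_map: Mapping

    # adjacency caches, built lazily
    _adj: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        overlap = self.reactions & self.metabolites
        if overlap:
            raise ValidationError(
                f"ids used as both reaction and metabolite: {sorted(overlap)[:5]}"
            )
        for r, m in self.edges:
            if r not in self.reactions or m not in self.metabolites:
                raise ValidationError(f"edge ({r!r}, {m!r}) references unknown node")
        missing = self.reactions - set(self.gene_map)
        if missing:
            # normalise: every reaction has an entry
            gm = dict(self.gene_map)
            for r in missing:
                gm[r] = frozenset()
            object.__setattr__(self, "gene_map", gm)

    # -- basic graph primitives -------------------------------------------------

    @property
    def adjacency(self) -> dict:
        """node id -> frozenset of neighbour ids (both directions)."""
        if not self._adj:
            adj = {n: set() for n in self.reactions | self.metabolites}
            for r, m in self.edges:
                adj[r].add(m)
                adj[m].add(r)
            self._adj.update({n: frozenset(v) for n, v in adj.items()})
        return self._adj

    @property
    def nodes(self) -> frozenset:
        return self.reactions | self.metabolites

    def node_type(self, node) -> str:
        if node in self.reactions:
            return REACTION
        if node in self.metabolites:
            return METABOLITE
        raise UnknownNodeError(node)

    def metabolite_degree(self, m) -> int:
        """Number of distinct reactions the metabolite participates in."""
        if m not in self.metabolites:
            raise UnknownNodeError(m)
        return len(self.adjacency[m])

    def genes(self) -> frozenset:
        """All gene ids mentioned in the gene map."""
        out = set()
        for gs in self.gene_map.values():
            out |= gs
        return frozenset(out)

    def to_networkx(self, nodes: Iterable | None = None) -> nx.Graph:
        """Export (a node-induced subgraph of) the network as networkx Graph."""
        g = nx.Graph()
        keep = self.nodes if nodes is None else set(nodes)
        for n in keep:
            g.add_node(n, node_type=self.node_type(n))
        for r, m in self.edges:
            if r in keep and m in keep:
                g.add_edge(r, m)
        return g


def connected_components(net: MetabolicNetwork, nodes: Iterable) -> list:
    """Maximal connected components of the subgraph induced by ``nodes``.

    Returns a deterministic partition: components ordered by descending
    size, ties broken by their lexicographically smallest node id.
    """
    nodes = set(nodes)
    unknown = nodes - net.nodes
    if unknown:
        raise UnknownNodeError(sorted(unknown)[0])
    adj = net.adjacency
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in adj[v]:
                if w in nodes and w not in comp:
                    comp.add(w)
                    frontier.append(w)
        seen |= comp
        comps.append(
            ModuleNodeSet(
                reaction_ids=frozenset(comp & net.reactions),
                metabolite_ids=frozenset(comp & net.metabolites),
            )
        )
    comps.sort(key=lambda c: (-len(c), min(c.nodes)))
    return comps


# -- reaction-table I/O ----------------------------------------------------------


def _split_multi(value) -> frozenset:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    s = str(value).strip()
    if not s or s.upper() == "NA":
        return frozenset()
    return frozenset(x.strip() for x in s.split(";") if x.strip())


def load_reaction_table(path) -> MetabolicNetwork:
    """Load a network from a TSV with columns reaction_id, metabolite_ids, gene_ids.

    Multi-valued fields are ``;``-separated; an empty or ``NA`` gene field
    means the reaction has no associated genes.  Duplicate
    (reaction, metabolite) pairs collapse to a single edge.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"reaction table is missing required column {col!r}")
    reactions = {}
    edges = set()
    gene_map = {}
    for row in df.itertuples(index=False):
        rid = str(row.reaction_id).strip()
        if not rid:
            raise FormatError("empty reaction_id")
        mets = _split_multi(row.metabolite_ids)
        genes = _split_multi(row.gene_ids)
        if rid in reactions:
            if reactions[rid] != (mets, genes):
                raise ValidationError(f"conflicting rows for reaction {rid!r}")
            continue
        reactions[rid] = (mets, genes)
        edges |= {(rid, m) for m in mets}
        gene_map[rid] = genes
    metabolites = {m for _, m in edges}
    return MetabolicNetwork(
        reactions=frozenset(reactions),
        metabolites=frozenset(metabolites),
        edges=frozenset(edges),
        gene_map=gene_map,
    )


def write_reaction_table(net: MetabolicNetwork, path) -> None:
    """Inverse of :func:`load_reaction_table` (round-trips exactly)."""
    adj = net.adjacency
    rows = []
    for r in sorted(net.reactions):
        rows.append(
            {
                "reaction_id": r,
                "metabolite_ids": ";".join(sorted(adj[r])),
                "gene_ids": ";".join(sorted(net.gene_map.get(r, ()))),
            }
        )
    pd.DataFrame(rows, columns=list(_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def import_sbml(path) -> MetabolicNetwork:
    """Import a network from an SBML file (Level 2/3).

    Species become metabolite nodes, reactions become reaction nodes, and
    each reactant/product relation becomes one undirected edge; reversibility
    flags are ignored.  Gene associations are read from the model's
    gene-reaction rules where present.
    """
    from cobra.io import read_sbml_model  # deferred: cobra import is slow

    try:
        model = read_sbml_model(str(path))
    except Exception as exc:  # pragma: no cover - exercised via invalid file test
        raise FormatError(f"could not parse SBML file {path}: {exc}") from exc
    edges = set()
    gene_map = {}
    for rxn in model.reactions:
        rid = rxn.id
        for met in rxn.metabolites:
            edges.add((rid, met.id))
        gene_map[rid] = frozenset(g.id for g in rxn.genes)
    return MetabolicNetwork(
        reactions=frozenset(r.id for r in model.reactions),
        metabolites=frozenset(m.id for m in model.metabolites),
        edges=frozenset(edges),
        gene_map=gene_map,
    )


# -- graph exports ----------------------------------------------------------------


def write_graphml(net: MetabolicNetwork, path, nodes=None, node_attrs=None) -> None:
    """Write (a subgraph of) the network as GraphML.

    ``node_attrs`` maps attribute name -> {node: value} for extra per-node
    annotation (scores, weights, imputation flags, ...).
    """
    g = net.to_networkx(nodes)
    for name, mapping in (node_attrs or {}).items():
        for n, v in mapping.items():
            if n in g:
                g.nodes[n][name] = v
    nx.write_graphml(g, path)


def write_sif(net: MetabolicNetwork, path, nodes=None) -> None:
    """Write (a subgraph of) the network in simple interaction format."""
    keep = net.nodes if nodes is None else set(nodes)
    with open(path, "w", encoding="utf-8") as fh:
        isolated = set(keep)
        for r, m in sorted(net.edges):
            if r in keep and m in keep:
                fh.write(f"{r}\trm\t{m}\n")
                isolated.discard(r)
                isolated.discard(m)
        for n in sorted(isolated):
            fh.write(f"{n}\n")
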