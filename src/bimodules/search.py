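"""Simulated-annealing search for high-scoring connected subnetworks.

The search state is a binary on/off assignment over all nodes (reactions
and metabolites).  A candidate module is a connected component of the
on-subgraph that contains at least one metabolite -- in a bipartite
metabolic network reactions are only "linked" at all through shared
metabolites, and an isolated reaction is not a pathway.  The objective
being maximised is

    sum of the K highest positive candidate-module scores
    + sum of all negative component scores,

with K the number of modules sought per direction (20 by default).  The
second term charges stray negative material (lone metabolites, blobs of
repressed reactions in an up-direction search), so the state stays
parsimonious: a metabolite only switches on when the coordinated
expression signal around it pays its connectivity weight, which is the
mechanism that keeps modules off promiscuous currency metabolites.

Proposals toggle one uniformly random node; worsening moves are accepted
with probability exp(dS/T) under a geometric cooling schedule, and the
best state ever visited (across all restarts) is returned.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .network import MetabolicNetwork, ModuleNodeSet, connected_components
from .scoring import ScoredNetwork, module_score


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule and budget.

    ``initial_temperature=None`` means "one SD of the reaction scores",
    which puts typical single-node moves in the readily-accepted range at
    the start of the search.  ``steps_per_temperature=None`` scales as
    4x the number of network nodes.
    """

    seed: int
    initial_temperature: float | None = None
    cooling_factor: float = 0.9
    steps_per_temperature: int | None = None
    n_temperatures: int = 60
    restarts: int = 2
    n_modules: int = 20

    def __post_init__(self):
        if self.initial_temperature is not None and not (self.initial_temperature > 0):
            raise ValidationError("initial_temperature must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValidationError("cooling_factor must lie in (0, 1)")
        for name in ("n_temperatures", "restarts", "n_modules"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive count")
        if self.steps_per_temperature is not None and self.steps_per_temperature < 1:
            raise ValidationError("steps_per_temperature must be a positive count")


@dataclass(frozen=True)
class Module:
    """A connected subnetwork with its score and reporting metadata."""

    nodes: ModuleNodeSet
    score: float
    direction: str
    n_reactions: int
    n_metabolites: int
    n_reactions_with_genes: int
    p_empirical: float | None = None
    q: float | None = None
    label: str = ""

    @property
    def composition(self) -> tuple:
        return (self.n_reactions, self.n_metabolites)


@dataclass
class AnnealResult:
    on_state: frozenset
    objective: float
    config: AnnealConfig


class _TopKSum:
    """Sum of the K largest values of a dynamic multiset (positive scores)."""

    __slots__ = ("k", "vals", "topsum")

    def __init__(self, k: int):
        self.k = k
        self.vals: list = []
        self.topsum = 0.0

    def insert(self, x: float) -> None:
        L = self.vals
        insort(L, x)
        n = len(L)
        if n <= self.k:
            self.topsum += x
        else:
            b = n - self.k  # index of the smallest member of the top-k
            if bisect_left(L, x) >= b:
                # x entered the top-k, evicting the previous boundary element
                self.topsum += x - L[b - 1]

    def remove(self, x: float) -> None:
        L = self.vals
        i = bisect_left(L, x)
        n = len(L)
        if n <= self.k:
            self.topsum -= x
        else:
            b = n - self.k
            if i >= b:
                # a top-k member leaves; the element just below is promoted
                self.topsum += L[b - 1] - x
        del L[i]


def _objective_of_components(comps: Iterable, k: int) -> float:
    """Objective from (score, contains_metabolite) component summaries."""
    counted = sorted((s for s, has_met in comps if s > 0 and has_met), reverse=True)
    neg = math.fsum(s for s, _ in comps if s < 0)
    return math.fsum(counted[:k]) + neg


def anneal(scored: ScoredNetwork, cfg: AnnealConfig) -> AnnealResult:
    """Run the annealing search and return the best-ever on-state.

    Deterministic for a given config: restart ``r`` uses seed ``seed + r``
    and all randomness flows from those generators.
    """
    net = scored.base
    nodes = sorted(net.reactions) + sorted(net.metabolites)
    if not nodes:
        raise ValidationError("cannot anneal an empty network")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    score = np.array([scored.node_score(v) for v in nodes], dtype=float)
    adj: list = [()] * n
    for v in nodes:
        adj[index[v]] = tuple(index[w] for w in net.adjacency[v])

    T0 = cfg.initial_temperature
    if T0 is None:
        sd = float(np.std(list(scored.reaction_score.values())))
        T0 = sd if sd > 0 else 1.0
    steps = cfg.steps_per_temperature or 4 * n
    k = cfg.n_modules
    score_l = score.tolist()
    n_rxn = len(net.reactions)
    is_met = [False] * n_rxn + [True] * (n - n_rxn)
    exp = math.exp

    best_obj = 0.0
    best_state = bytes(n)

    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        on = bytearray(n)
        comp_of = [-1] * n  # node index -> component id
        comps: dict = {}  # component id -> [score, members, n_metabolites]
        next_id = 0
        top = _TopKSum(k)  # positive metabolite-containing component scores
        negsum = 0.0  # running sum of negative component scores
        obj = 0.0
        T = T0
        for _t in range(cfg.n_temperatures):
            picks = rng.integers(0, n, size=steps).tolist()
            us = rng.random(steps).tolist()
            for j in range(steps):
                v = picks[j]
                sv = score_l[v]
                if not on[v]:
                    # ---- propose switching v on: merge neighbouring comps
                    cids = set()
                    for w in adj[v]:
                        if on[w]:
                            cids.add(comp_of[w])
                    merged = sv
                    mets = 1 if is_met[v] else 0
                    d_neg = 0.0
                    undo = []
                    for cid in cids:
                        s, _members, cm = comps[cid]
                        merged += s
                        mets += cm
                        if s > 0:
                            if cm:
                                top.remove(s)
                                undo.append((s, True))
                        elif s < 0:
                            d_neg -= s
                    if merged > 0:
                        if mets:
                            top.insert(merged)
                            undo.append((merged, False))
                    elif merged < 0:
                        d_neg += merged
                    new_obj = top.topsum + negsum + d_neg
                    delta = new_obj - obj
                    if delta >= 0 or us[j] < exp(delta / T):
                        # commit: build merged component
                        if cids:
                            base = max(cids, key=lambda c: len(comps[c][1]))
                            entry = comps[base]
                            members = entry[1]
                            for cid in cids:
                                if cid != base:
                                    for u in comps[cid][1]:
                                        comp_of[u] = base
                                    members |= comps.pop(cid)[1]
                            members.add(v)
                            comp_of[v] = base
                            entry[0] = merged
                            entry[2] = mets
                        else:
                            comps[next_id] = [merged, {v}, mets]
                            comp_of[v] = next_id
                            next_id += 1
                        on[v] = 1
                        negsum += d_neg
                        obj = new_obj
                        if obj > best_obj:
                            best_obj = obj
                            best_state = bytes(on)
                    else:
                        for s, was_removed in reversed(undo):
                            if was_removed:
                                top.insert(s)
                            else:
                                top.remove(s)
                else:
                    # ---- propose switching v off: component may split
                    cid = comp_of[v]
                    centry = comps[cid]
                    cscore, members, cmets = centry
                    on_nbrs = [w for w in adj[v] if on[w]]
                    parts = None  # None -> no split: one remaining part
                    if len(on_nbrs) > 1:
                        # does the component stay connected without v?
                        # BFS from one neighbour, stopping once all other
                        # neighbours are reached (cheap on cyclic regions)
                        targets = set(on_nbrs)
                        start = on_nbrs[0]
                        seen = {start, v}
                        targets.discard(start)
                        stack = [start]
                        while stack and targets:
                            u = stack.pop()
                            for w in adj[u]:
                                if on[w] and w not in seen:
                                    seen.add(w)
                                    targets.discard(w)
                                    stack.append(w)
                        if targets:
                            # genuine split: finish this part, then the rest
                            while stack:
                                u = stack.pop()
                                for w in adj[u]:
                                    if on[w] and w not in seen:
                                        seen.add(w)
                                        stack.append(w)
                            seen.discard(v)
                            parts = [seen]
                            unvisited = members - seen - {v}
                            while unvisited:
                                start = next(iter(unvisited))
                                comp = {start}
                                stack = [start]
                                while stack:
                                    u = stack.pop()
                                    for w in adj[u]:
                                        if w in unvisited and w not in comp:
                                            comp.add(w)
                                            stack.append(w)
                                unvisited -= comp
                                parts.append(comp)
                    if parts is None:
                        if len(members) > 1:
                            part_summaries = [
                                (cscore - sv, cmets - (1 if is_met[v] else 0))
                            ]
                        else:
                            part_summaries = []
                    else:
                        part_summaries = []
                        for comp in parts:
                            psum = 0.0
                            pmets = 0
                            for u in comp:
                                psum += score_l[u]
                                if is_met[u]:
                                    pmets += 1
                            part_summaries.append((psum, pmets))
                    d_neg = 0.0
                    undo = []
                    if cscore > 0:
                        if cmets:
                            top.remove(cscore)
                            undo.append((cscore, True))
                    elif cscore < 0:
                        d_neg -= cscore
                    for psum, pmets in part_summaries:
                        if psum > 0:
                            if pmets:
                                top.insert(psum)
                                undo.append((psum, False))
                        elif psum < 0:
                            d_neg += psum
                    new_obj = top.topsum + negsum + d_neg
                    delta = new_obj - obj
                    if delta >= 0 or us[j] < exp(delta / T):
                        on[v] = 0
                        comp_of[v] = -1
                        if parts is None:
                            if len(members) > 1:
                                members.discard(v)
                                centry[0] = cscore - sv
                                centry[2] = part_summaries[0][1]
                            else:
                                del comps[cid]
                        else:
                            del comps[cid]
                            for (psum, pmets), comp in zip(part_summaries, parts):
                                comps[next_id] = [psum, comp, pmets]
                                for u in comp:
                                    comp_of[u] = next_id
                                next_id += 1
                        negsum += d_neg
                        obj = new_obj
                        if obj > best_obj:
                            best_obj = obj
                            best_state = bytes(on)
                    else:
                        for s, was_removed in reversed(undo):
                            if was_removed:
                                top.insert(s)
                            else:
                                top.remove(s)
            T *= cfg.cooling_factor

    # report an exactly recomputed objective for the best state (the running
    # value accumulates float round-off over millions of incremental updates)
    on_nodes = frozenset(nodes[i] for i in range(n) if best_state[i])
    summaries = []
    for comp in connected_components(net, on_nodes):
        summaries.append(
            (module_score(scored, comp), bool(comp.metabolite_ids))
        )
    return AnnealResult(
        on_state=on_nodes,
        objective=_objective_of_components(summaries, k),
        config=cfg,
    )


def exhaustive_best_objective(scored: ScoredNetwork, n_modules: int = 20):
    """Brute-force optimum of the annealing objective by subset enumeration.

    Independent reference for small networks (hard limit of 20 nodes):
    every node subset is enumerated with bitmask connected-component
    extraction.  Returns ``(best_objective, best_node_set)``.
    """
    net = scored.base
    nodes = sorted(net.reactions) + sorted(net.metabolites)
    n = len(nodes)
    if n > 20:
        raise ValidationError("exhaustive enumeration limited to 20 nodes")
    index = {v: i for i, v in enumerate(nodes)}
    score = [scored.node_score(v) for v in nodes]
    nbr = [0] * n
    for v in nodes:
        for w in net.adjacency[v]:
            nbr[index[v]] |= 1 << index[w]

    n_rxn = len(net.reactions)
    met_mask = ((1 << n) - 1) ^ ((1 << n_rxn) - 1)  # metabolite index bits

    best = (0.0, frozenset())
    for mask in range(1 << n):
        rem = mask
        summaries = []
        while rem:
            seed_bit = rem & -rem
            comp = seed_bit
            frontier = seed_bit
            while frontier:
                nxt = 0
                f = frontier
                while f:
                    b = f & -f
                    f ^= b
                    nxt |= nbr[b.bit_length() - 1]
                frontier = nxt & mask & ~comp
                comp |= frontier
            rem &= ~comp
            s = 0.0
            c = comp
            while c:
                b = c & -c
                c ^= b
                s += score[b.bit_length() - 1]
            summaries.append((s, bool(comp & met_mask)))
        obj = _objective_of_components(summaries, n_modules)
        if obj > best[0]:
            best = (obj, frozenset(nodes[i] for i in range(n) if mask >> i & 1))
    return best


def extract_modules(
    scored: ScoredNetwork, on_state: Iterable, top_n: int = 20
) -> list:
    """Connected components of the on-state, ranked as candidate modules.

    Components with non-positive score, and components containing no
    metabolite (transient search debris -- a candidate module is a set of
    reactions linked via metabolites), are dropped; the rest are sorted by
    descending score, then by reaction count, then by smallest reaction
    id, and truncated to ``top_n``.
    """
    comps = connected_components(scored.base, on_state)
    modules = []
    for comp in comps:
        s = module_score(scored, comp)
        if s <= 0 or not comp.metabolite_ids:
            continue
        measured = sum(1 for r in comp.reaction_ids if r not in scored.imputed)
        modules.append(
            Module(
                nodes=comp,
                score=s,
                direction=scored.direction,
                n_reactions=len(comp.reaction_ids),
                n_metabolites=len(comp.metabolite_ids),
                n_reactions_with_genes=measured,
            )
        )
    modules.sort(
        key=lambda m: (
            -m.score,
            -m.n_reactions,
            min(m.nodes.reaction_ids) if m.nodes.reaction_ids else "",
        )
    )
    return modules[:top_n]


def exclude_unsupported(modules: Sequence) -> tuple:
    """Split off modules in which no reaction has expression data.

    A module whose every reaction score was median-imputed carries no
    experimental evidence and is excluded from significance testing.
    Returns ``(kept, excluded)`` with input order preserved.
    """
    kept = [m for m in modules if m.n_reactions_with_genes > 0]
    excluded = [m for m in modules if m.n_reactions_with_genes == 0]
    return kept, excluded


def merge_modules(scored: ScoredNetwork, modules: Sequence, bridge) -> Module:
    """Combine modules through a shared metabolite and rescore as one.

    The bridge metabolite must be adjacent to at least one reaction of
    every input module; its (negative) weight is paid exactly once in the
    merged score.
    """
    if bridge not in scored.base.metabolites:
        raise ValidationError(f"bridge {bridge!r} is not a metabolite of the network")
    bridge_rxns = scored.base.adjacency[bridge]
    rxns, mets = set(), {bridge}
    for i, m in enumerate(modules):
        if not (m.nodes.reaction_ids & bridge_rxns):
            raise ValidationError(
                f"bridge {bridge!r} is not adjacent to any reaction of module {i}"
            )
        rxns |= m.nodes.reaction_ids
        mets |= m.nodes.metabolite_ids
    merged = ModuleNodeSet(frozenset(rxns), frozenset(mets))
    comps = connected_components(scored.base, merged.nodes)
    if len(comps) != 1:
        raise ValidationError("merged node set is not connected")
    measured = sum(1 for r in rxns if r not in scored.imputed)
    return Module(
        nodes=merged,
        score=module_score(scored, merged),
        direction=modules[0].direction,
        n_reactions=len(rxns),
        n_metabolites=len(mets),
        n_reactions_with_genes=measured,
    )


def extend_module(net: MetabolicNetwork, module: Module) -> ModuleNodeSet:
    """Close a module over all metabolites touched by its member reactions.

    Used to place modules in their metabolic context (e.g. to see which
    modules share substrates or products); extended sets are for display
    and are never re-tested for significance.
    """
    mets = set(module.nodes.metabolite_ids)
    for r in module.nodes.reaction_ids:
        mets |= net.adjacency[r]
    return ModuleNodeSet(module.nodes.reaction_ids, frozenset(mets))


def with_significance(module: Module, p: float, q: float | None = None) -> Module:
    """Return a copy of the module with empirical p (and optionally q) filled."""
    return replace(module, p_empirical=p, q=q)
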