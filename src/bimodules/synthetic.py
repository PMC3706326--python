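"""Synthetic networks, expression data and pathway maps with known ground truth.

The generator emulates the shape of a draft-quality automated metabolic
reconstruction for a bacterium: on the order of a thousand reactions,
each linked to a few ordinary metabolites (degree-biased, giving a
right-skewed metabolite degree distribution), plus a handful of
promiscuous "currency" metabolites of fixed high connectivity.  Modules
are planted as dedicated pathway backbones -- fresh low-degree
metabolites chaining a small group of reactions -- and their genes are
given coherent fold-changes on top of replicate-level noise, so every
downstream stage (scoring, search, significance, enrichment) can be
tested against a known truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .network import MetabolicNetwork, ModuleNodeSet, connected_components
from .scoring import ScoredNetwork, weight_metabolites


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted modules and the distributional parameters of the simulation."""

    planted_modules: tuple = ()  # of (ModuleNodeSet, direction) pairs
    effect_size: float = 2.0
    noise_sd: float = 0.5
    background_responsive_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.planted_modules and self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        all_rxns: set = set()
        for nodes, direction in self.planted_modules:
            if direction not in ("up", "down"):
                raise ValidationError(f"bad planted direction {direction!r}")
            if all_rxns & nodes.reaction_ids:
                raise ValidationError("planted modules must be disjoint")
            all_rxns |= nodes.reaction_ids


def generate_network(
    n_reactions: int = 963,
    n_metabolites: int = 960,
    mean_degree: float = 3.0,
    n_currency: int = 8,
    currency_degree: int = 12,
    geneless_fraction: float = 0.10,
    seed: int = 0,
) -> MetabolicNetwork:
    """Random bipartite reaction-metabolite network with currency hubs.

    Each reaction is linked to 2-4 ordinary metabolites chosen by
    degree-biased attachment (capped below ``currency_degree`` so the
    currency metabolites are exactly the maximum-degree hubs); each of the
    ``n_currency`` currency metabolites is attached to exactly
    ``currency_degree`` distinct reactions.  A bridging pass then joins
    any stray components to the giant component through ordinary
    metabolites, so the result is a single connected graph.  By default
    one gene per reaction, with ``geneless_fraction`` of reactions left
    without a gene to exercise median imputation downstream.
    """
    if min(n_reactions, n_metabolites, n_currency, currency_degree) <= 0:
        raise ValidationError("network size parameters must be positive")
    if currency_degree < mean_degree:
        raise ValidationError("currency_degree must be at least mean_degree")
    if currency_degree > n_reactions:
        raise ValidationError("currency_degree exceeds the number of reactions")
    rng = np.random.default_rng(seed)
    rxn_ids = [f"R{i:04d}" for i in range(n_reactions)]
    met_ids = [f"M{i:04d}" for i in range(n_metabolites)]
    cur_ids = [f"C{i:02d}" for i in range(n_currency)]

    # degree-biased attachment to ordinary metabolites, 2-4 per reaction
    lo = max(2, int(round(mean_degree)) - 1)
    hi = lo + 2
    deg = np.ones(n_metabolites)  # +1 smoothing so new metabolites can be drawn
    cap = currency_degree - 1
    edges = set()
    for r in rxn_ids:
        k = int(rng.integers(lo, hi + 1))
        w = np.where(deg <= cap, deg, 0.0)
        w = w / w.sum()
        chosen = rng.choice(n_metabolites, size=min(k, n_metabolites), replace=False, p=w)
        for j in chosen:
            edges.add((r, met_ids[j]))
            deg[j] += 1

    # mass-balance cleanup: an intermediate consumed by a single reaction
    # would be a dead end, so every used ordinary metabolite gets a second
    # reaction; metabolites that were never drawn are dropped entirely
    used = sorted({m for _, m in edges})
    deg_of = {m: 0 for m in used}
    partners: dict = {m: set() for m in used}
    for r, m in edges:
        deg_of[m] += 1
        partners[m].add(r)
    for m in used:
        if deg_of[m] == 1:
            while True:
                r = rxn_ids[int(rng.integers(0, n_reactions))]
                if r not in partners[m]:
                    edges.add((r, m))
                    break
    met_ids = used

    # currency hubs: exactly currency_degree reactions each
    for cid in cur_ids:
        chosen = rng.choice(n_reactions, size=currency_degree, replace=False)
        for j in chosen:
            edges.add((rxn_ids[j], cid))

    gene_map = {r: frozenset({f"g_{r}"}) for r in rxn_ids}
    n_geneless = int(round(geneless_fraction * n_reactions))
    if n_geneless:
        for j in rng.choice(n_reactions, size=n_geneless, replace=False):
            gene_map[rxn_ids[j]] = frozenset()

    net = MetabolicNetwork(
        reactions=frozenset(rxn_ids),
        metabolites=frozenset(met_ids) | frozenset(cur_ids),
        edges=frozenset(edges),
        gene_map=gene_map,
    )

    # bridging pass: connect every component to the largest one through
    # ordinary metabolites only (currency degrees stay exact)
    comps = connected_components(net, net.nodes)
    if len(comps) > 1:
        giant = comps[0]
        anchor_mets = sorted(
            m
            for m in giant.metabolite_ids - set(cur_ids)
            if net.metabolite_degree(m) < cap  # keep hubs the degree maximum
        )
        extra = set()
        for comp in comps[1:]:
            if comp.reaction_ids:
                r = sorted(comp.reaction_ids)[int(rng.integers(0, len(comp.reaction_ids)))]
                m = anchor_mets[int(rng.integers(0, len(anchor_mets)))]
                extra.add((r, m))
            else:
                # isolated metabolite: hook it to a random giant reaction
                m = sorted(comp.metabolite_ids)[0]
                if m in cur_ids:
                    continue  # cannot touch currency degrees; leave isolated
                anchors = sorted(giant.reaction_ids)
                extra.add((anchors[int(rng.integers(0, len(anchors)))], m))
        net = MetabolicNetwork(
            reactions=net.reactions,
            metabolites=net.metabolites,
            edges=net.edges | frozenset(extra),
            gene_map=gene_map,
        )
    return net


def plant_module(
    net: MetabolicNetwork,
    n_reactions: int = 8,
    n_metabolites: int = 2,
    seed: int = 0,
    avoid: set | None = None,
) -> tuple:
    """Plant a connected pathway backbone and return (network, node set).

    ``n_reactions`` existing gene-bearing reactions are chained through
    ``n_metabolites`` fresh dedicated intermediates (consecutive groups
    share one linker reaction, the way a linear pathway shares
    intermediates).  The new metabolites carry no edges outside the
    module -- they model pathway-specific intermediates, which is exactly
    the low-connectivity situation the metabolite weighting favours.
    The default composition (8 reactions, 2 metabolites) mirrors a tight
    assimilation pathway of the kind that tops real module lists.
    """
    if n_metabolites < 1 or n_reactions < n_metabolites:
        raise ValidationError("need at least one metabolite and more reactions than metabolites")
    rng = np.random.default_rng(seed)
    avoid = set(avoid or ())
    eligible = sorted(r for r in net.reactions if net.gene_map.get(r) and r not in avoid)
    if len(eligible) < n_reactions:
        raise ValidationError("not enough gene-bearing reactions to plant the module")
    rxns = [eligible[i] for i in rng.choice(len(eligible), size=n_reactions, replace=False)]
    mets = []
    existing = net.metabolites | net.reactions
    i = 0
    while len(mets) < n_metabolites:
        mid = f"P{seed:03d}_{i}"
        if mid not in existing:
            mets.append(mid)
        i += 1
    # split reactions into n_metabolites groups; consecutive groups share a linker
    bounds = np.linspace(0, n_reactions - 1, n_metabolites + 1).round().astype(int)
    new_edges = set()
    for g in range(n_metabolites):
        lo, hi = bounds[g], bounds[g + 1]
        for r in rxns[lo : hi + 1]:
            new_edges.add((r, mets[g]))
    planted = ModuleNodeSet(frozenset(rxns), frozenset(mets))
    out = MetabolicNetwork(
        reactions=net.reactions,
        metabolites=net.metabolites | frozenset(mets),
        edges=net.edges | frozenset(new_edges),
        gene_map=net.gene_map,
    )
    return out, planted


def plant_and_simulate(net: MetabolicNetwork, truth: SyntheticTruth) -> pd.DataFrame:
    """Simulate replicate expression and return a per-gene score table.

    Genes of up-planted reactions receive a mean log2 fold-change of
    ``+effect_size`` (down-planted: ``-effect_size``), everything else 0,
    except that ``background_responsive_fraction`` of background genes are
    shifted by +-effect_size as well (a "globally responsive" stress mode
    for specificity testing).  Three replicates per condition are drawn,
    and p-values come from a two-sample t-test on the replicates, so the
    DE filter and multiple-testing stages downstream see honest p-values.
    The fold-change estimate has standard deviation ``noise_sd``.
    """
    rng = np.random.default_rng(truth.seed)
    genes = sorted(net.genes())
    if not genes:
        raise ValidationError("network has no genes to simulate")
    delta = dict.fromkeys(genes, 0.0)
    for nodes, direction in truth.planted_modules:
        sgn = 1.0 if direction == "up" else -1.0
        for r in sorted(nodes.reaction_ids):
            if not net.gene_map.get(r):
                raise ValidationError(f"planted reaction {r!r} has no genes")
            for g in sorted(net.gene_map[r]):
                delta[g] = sgn * truth.effect_size
    if truth.background_responsive_fraction > 0:
        bg = [g for g in genes if delta[g] == 0.0]
        n_resp = int(round(truth.background_responsive_fraction * len(bg)))
        idx = rng.choice(len(bg), size=n_resp, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_resp)
        for j, s in zip(idx, signs):
            delta[bg[j]] = s * truth.effect_size

    n_rep = 3
    # per-replicate noise chosen so the fold-change estimate has SD = noise_sd
    rep_sd = truth.noise_sd * np.sqrt(n_rep / 2.0)
    base = rng.normal(8.0, 1.0, size=len(genes))
    d = np.array([delta[g] for g in genes])
    ctl = base[:, None] + rng.normal(0.0, rep_sd, size=(len(genes), n_rep))
    trt = (base + d)[:, None] + rng.normal(0.0, rep_sd, size=(len(genes), n_rep))
    log2fc = trt.mean(axis=1) - ctl.mean(axis=1)
    pvals = stats.ttest_ind(trt, ctl, axis=1).pvalue
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvals}, index=pd.Index(genes, name="gene_id"))


def generate_pathways(
    net: MetabolicNetwork,
    n_pathways: int = 30,
    size_range: tuple = (3, 94),
    planted_overlap_fraction: float = 0.0,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
):
    """Random pathway map over the network's genes, optionally with a spiked pathway.

    Pathway sizes are uniform over ``size_range``.  With
    ``planted_overlap_fraction > 0`` the first pathway is built to draw
    that fraction of its genes from the planted modules' genes, giving a
    known positive for the enrichment comparison.  Returns a
    :class:`~bimodules.enrichment.PathwayMap` whose universe is all genes.
    """
    from .enrichment import PathwayMap

    rng = np.random.default_rng(seed)
    genes = sorted(net.genes())
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(genes)):
        raise ValidationError("infeasible pathway size range")
    planted_genes: list = []
    if truth is not None:
        pg = set()
        for nodes, _dir in truth.planted_modules:
            for r in nodes.reaction_ids:
                pg |= net.gene_map.get(r, frozenset())
        planted_genes = sorted(pg)
    pathways = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if i == 0 and planted_overlap_fraction > 0 and planted_genes:
            n_plant = min(len(planted_genes), int(round(planted_overlap_fraction * size)))
            members = set(
                planted_genes[j]
                for j in rng.choice(len(planted_genes), size=n_plant, replace=False)
            )
            rest = [g for g in genes if g not in members]
            fill = rng.choice(len(rest), size=size - len(members), replace=False)
            members |= {rest[j] for j in fill}
        else:
            members = {genes[j] for j in rng.choice(len(genes), size=size, replace=False)}
        pathways[f"path{i:03d}"] = (f"synthetic pathway {i}", frozenset(members))
    return PathwayMap(pathways=pathways, universe=frozenset(genes))


def random_scored_network(seed: int, max_nodes: int = 14) -> ScoredNetwork:
    """Small random scored network for exhaustive-vs-heuristic comparisons.

    Reaction scores are N(0, 1); the weight constant is drawn in
    [0.1, 0.5] so bridging is sometimes, but not always, worthwhile.
    """
    rng = np.random.default_rng(seed)
    n_r = int(rng.integers(3, 9))
    n_m = int(rng.integers(2, max(3, max_nodes - n_r + 1)))
    n_m = min(n_m, max_nodes - n_r)
    rxns = [f"R{i}" for i in range(n_r)]
    mets = [f"M{i}" for i in range(n_m)]
    edges = set()
    for r in rxns:
        k = int(rng.integers(1, 3))
        for j in rng.choice(n_m, size=min(k, n_m), replace=False):
            edges.add((r, mets[j]))
    net = MetabolicNetwork(
        reactions=frozenset(rxns),
        metabolites=frozenset(mets),
        edges=frozenset(edges),
        gene_map={r: frozenset({f"g{r}"}) for r in rxns},
    )
    scores = {r: float(rng.normal(0.0, 1.0)) for r in sorted(rxns)}
    c = float(rng.uniform(0.1, 0.5))
    return ScoredNetwork(
        base=net,
        reaction_score=scores,
        metabolite_weight=weight_metabolites(net, c),
        weight_constant=c,
        imputed=frozenset(),
        direction="up",
    )
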