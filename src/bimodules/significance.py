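"""Empirical significance of modules against same-composition random node sets.

Each observed module is compared with B random connected node sets of
identical composition (same reaction and metabolite counts), scored on the
same network; the one-sided empirical p-value uses the add-one rule
``p = (r + 1) / (B + 1)`` so it can never be exactly zero.  Up- and
down-direction module families are corrected for multiple testing
together within a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InfeasibleCompositionError, ValidationError
from .scoring import ScoredNetwork, benjamini_hochberg, module_score
from .search import Module, with_significance
from .enrichment import storey_qvalue

#: q-value threshold below which a module is called significant.
MODULE_FDR = 0.05


@dataclass(frozen=True)
class NullDistribution:
    composition: tuple  # (n_reactions, n_metabolites)
    samples: np.ndarray
    sampler_seed: int

    @property
    def size(self) -> int:
        return len(self.samples)


def _grow_connected(net, rng, need_r, need_m, reactions, metabolites, max_tries):
    """One connected node set of exact composition, by seeded random growth."""
    adj = net.adjacency
    for _ in range(max_tries):
        pool = []
        if need_r:
            pool.extend(reactions)
        if need_m:
            pool.extend(metabolites)
        start = pool[rng.integers(0, len(pool))]
        chosen = {start}
        r_left = need_r - (start in net.reactions)
        m_left = need_m - (start in net.metabolites)
        frontier = set(adj[start])
        while r_left or m_left:
            cands = [
                u
                for u in frontier
                if (r_left and u in net.reactions) or (m_left and u in net.metabolites)
            ]
            if not cands:
                break  # dead end: restart from scratch
            cands.sort()
            pick = cands[rng.integers(0, len(cands))]
            chosen.add(pick)
            if pick in net.reactions:
                r_left -= 1
            else:
                m_left -= 1
            frontier |= adj[pick]
            frontier -= chosen
        else:
            return chosen
    raise InfeasibleCompositionError(
        f"no connected set with composition ({need_r}, {need_m}) "
        f"found in {max_tries} attempts"
    )


def sample_null(
    scored: ScoredNetwork,
    composition: tuple,
    B: int = 1000,
    seed: int = 0,
    connected: bool = True,
    max_tries: int = 1000,
) -> NullDistribution:
    """Scores of B random node sets with the given (reactions, metabolites) counts.

    ``connected=True`` (the default) draws connected sets by random growth:
    start at a uniform random node of a still-needed type, then repeatedly
    add a uniform random frontier neighbour of a needed type, restarting on
    dead ends.  ``connected=False`` draws unconstrained uniform node sets,
    kept only for comparison -- observed modules are connected, and an
    unconnected null is the more liberal reference.
    """
    need_r, need_m = composition
    if need_r < 0 or need_m < 0 or need_r + need_m == 0:
        raise ValidationError(f"bad composition {composition!r}")
    if B < 100:
        raise ValidationError("B must be at least 100")
    net = scored.base
    if need_r > len(net.reactions) or need_m > len(net.metabolites):
        raise InfeasibleCompositionError(f"composition {composition} exceeds network")
    reactions = sorted(net.reactions)
    metabolites = sorted(net.metabolites)
    rng = np.random.default_rng(seed)
    samples = np.empty(B, dtype=float)
    for i in range(B):
        if connected:
            nodes = _grow_connected(
                net, rng, need_r, need_m, reactions, metabolites, max_tries
            )
        else:
            nodes = set(
                rng.choice(reactions, size=need_r, replace=False)
            ) | set(rng.choice(metabolites, size=need_m, replace=False))
        samples[i] = module_score(scored, nodes)
    return NullDistribution(
        composition=(need_r, need_m), samples=samples, sampler_seed=seed
    )


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """One-sided add-one empirical p: (#{samples >= observed} + 1) / (B + 1)."""
    if null.size == 0:
        raise ValidationError("empty null distribution")
    r = int(np.count_nonzero(null.samples >= observed))
    return (r + 1) / (null.size + 1)


def pvalue_floor(B: int) -> float:
    """Smallest attainable empirical p for a null of size B."""
    return 1.0 / (B + 1)


def assess_modules(
    scored: ScoredNetwork,
    modules: Sequence,
    B: int = 1000,
    seed: int = 0,
    connected: bool = True,
    cache: dict | None = None,
) -> list:
    """Fill ``p_empirical`` for each module, sharing nulls per composition.

    The null for a composition depends only on the network and scores, so a
    cache (keyed by composition) may be passed in and shared between calls
    on the same scored network.
    """
    if cache is None:
        cache = {}
    out = []
    for m in modules:
        comp = (m.n_reactions, m.n_metabolites)
        if comp not in cache:
            # stable per-composition seed so the cache layout cannot change results
            comp_seed = (seed + 100003 * comp[0] + 257 * comp[1]) % (2**31 - 1)
            cache[comp] = sample_null(
                scored, comp, B=B, seed=comp_seed, connected=connected
            )
        p = empirical_pvalue(m.score, cache[comp])
        out.append(with_significance(m, p))
    return out


def module_qvalues(modules: Sequence, method: str = "bh") -> list:
    """Multiple-testing correction across a family of tested modules."""
    if not modules:
        return []
    ps = []
    for m in modules:
        if m.p_empirical is None:
            raise ValidationError("module without empirical p-value")
        ps.append(m.p_empirical)
    if method == "bh":
        qs = benjamini_hochberg(ps)
    elif method == "storey":
        qs = storey_qvalue(ps)
    else:
        raise ValidationError(f"unknown q-value method {method!r}")
    return [with_significance(m, m.p_empirical, float(q)) for m, q in zip(modules, qs)]
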