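"""Map per-gene differential expression onto reaction scores and metabolite weights.

Reactions are scored with the mean log2 fold-change of their associated,
measured genes; reactions with no measured gene receive the median of the
data-derived scores (and are flagged as imputed).  Metabolites receive
negative weights proportional to their connectivity, ``w_m = -c * d_m``,
which is what keeps the module search from routing through promiscuous
currency metabolites (water, ATP, ...) unless the expression signal
justifies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .network import MetabolicNetwork, ModuleNodeSet

#: Default metabolite weight constant, expressed as a multiple of the
#: standard deviation of the data-derived reaction scores per unit of
#: metabolite degree.  At 1.5, the cheapest possible bridge (a degree-2
#: metabolite) costs 3 SD -- above the most extreme single-reaction score
#: expected by chance in a network of ~10^3 reactions -- so connected
#: modules only form where several adjacent reactions move together.
DEFAULT_WEIGHT_SD_MULTIPLE = 1.5

GENE_SCORE_COLUMNS = ("log2fc", "pvalue")


def read_gene_scores(path) -> pd.DataFrame:
    """Read a per-gene score table (TSV: gene_id, log2fc, pvalue[, qvalue])."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValidationError("gene score table is missing column 'gene_id'")
    df = df.set_index("gene_id")
    return validate_gene_scores(df)


def validate_gene_scores(genes: pd.DataFrame) -> pd.DataFrame:
    """Check the GeneScoreTable contract: unique ids, finite log2fc, p in [0,1]."""
    if "log2fc" not in genes.columns:
        raise ValidationError("gene score table is missing column 'log2fc'")
    if genes.index.has_duplicates:
        dups = genes.index[genes.index.duplicated()][:3].tolist()
        raise ValidationError(f"duplicate gene ids: {dups}")
    if not np.isfinite(genes["log2fc"]).all():
        raise ValidationError("non-finite log2fc values")
    if "pvalue" in genes.columns:
        p = genes["pvalue"].to_numpy(float)
        if np.nanmin(p) < 0 or np.nanmax(p) > 1:
            raise ValidationError("p-values outside [0, 1]")
    return genes


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_de_genes(
    genes: pd.DataFrame, fold_threshold: float = 2.0, fdr_threshold: float = 0.01
):
    """Differential-expression filter: |fold change| > threshold and q < FDR.

    Both inequalities are strict.  The q-value column is computed with
    Benjamini-Hochberg from ``pvalue`` when absent.  Returns
    ``(up_genes, down_genes)`` as sets of gene ids.
    """
    if fold_threshold <= 0:
        raise ValidationError("fold_threshold must be positive")
    genes = validate_gene_scores(genes)
    if "qvalue" in genes.columns:
        q = genes["qvalue"].to_numpy(float)
    else:
        if "pvalue" not in genes.columns:
            raise ValidationError("need a pvalue or qvalue column for the DE filter")
        q = benjamini_hochberg(genes["pvalue"].to_numpy(float))
    lfc = genes["log2fc"].to_numpy(float)
    cut = math.log2(fold_threshold)
    up = set(genes.index[(lfc > cut) & (q < fdr_threshold)])
    down = set(genes.index[(lfc < -cut) & (q < fdr_threshold)])
    return up, down


def score_reactions(net: MetabolicNetwork, genes: pd.DataFrame, direction: str = "up"):
    """Per-reaction scores: mean log2fc of measured genes, median-imputed.

    Genes absent from the table are treated as unmeasured.  Reactions with
    no measured gene receive the median of the data-derived scores and are
    recorded in the returned ``imputed`` set.  ``direction="down"`` negates
    every score *after* imputation, so a single maximisation routine finds
    both up- and down-regulated modules.

    Returns ``(scores, imputed)``.
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if not net.reactions:
        raise ValidationError("network has no reactions")
    genes = validate_gene_scores(genes)
    lfc = genes["log2fc"]
    scores = {}
    imputed = set()
    for r in net.reactions:
        measured = [lfc[g] for g in net.gene_map.get(r, ()) if g in lfc.index]
        if measured:
            scores[r] = float(np.mean(measured))
        else:
            imputed.add(r)
    if not scores:
        raise ValidationError("no expression information: all reactions unmeasured")
    median = float(np.median(list(scores.values())))
    for r in imputed:
        scores[r] = median
    if direction == "down":
        scores = {r: -s for r, s in scores.items()}
    return scores, frozenset(imputed)


def weight_metabolites(net: MetabolicNetwork, c: float) -> dict:
    """Connectivity-proportional weights, ``w_m = -c * d_m`` for every metabolite."""
    if not (c > 0):
        raise ValidationError("weight constant c must be positive")
    return {m: -c * net.metabolite_degree(m) for m in net.metabolites}


def default_weight_constant(scores: Mapping, imputed: Iterable = ()) -> float:
    """Default c: a fixed multiple of the SD of the data-derived reaction scores.

    The SD is taken over reactions whose score came from data (imputed ones
    all carry the median and would shrink it), before any direction flip --
    so the same constant is obtained for up- and down-direction runs.
    """
    imputed = set(imputed)
    vals = np.array([s for r, s in scores.items() if r not in imputed], dtype=float)
    sd = float(np.std(vals))
    if sd == 0.0:
        sd = 1.0  # degenerate flat data: fall back to unit scale
    return DEFAULT_WEIGHT_SD_MULTIPLE * sd


@dataclass(frozen=True)
class ScoredNetwork:
    """A network together with reaction scores and metabolite weights."""

    base: MetabolicNetwork
    reaction_score: Mapping
    metabolite_weight: Mapping
    weight_constant: float
    imputed: frozenset
    direction: str = "up"

    def node_score(self, node) -> float:
        if node in self.reaction_score:
            return self.reaction_score[node]
        return self.metabolite_weight[node]


def score_network(
    net: MetabolicNetwork,
    genes: pd.DataFrame,
    direction: str = "up",
    c: float | None = None,
) -> ScoredNetwork:
    """Convenience constructor chaining score_reactions and weight_metabolites."""
    scores, imputed = score_reactions(net, genes, direction=direction)
    if c is None:
        # derive from pre-negation scores so up/down runs share the constant
        up_scores = scores if direction == "up" else {r: -s for r, s in scores.items()}
        c = default_weight_constant(up_scores, imputed)
    weights = weight_metabolites(net, c)
    return ScoredNetwork(
        base=net,
        reaction_score=scores,
        metabolite_weight=weights,
        weight_constant=c,
        imputed=imputed,
        direction=direction,
    )


def module_score(scored: ScoredNetwork, nodes) -> float:
    """Module score S: sum of member reaction scores and metabolite weights."""
    if isinstance(nodes, ModuleNodeSet):
        rxns, mets = nodes.reaction_ids, nodes.metabolite_ids
    else:
        nodes = set(nodes)
        rxns = nodes & scored.base.reactions
        mets = nodes & scored.base.metabolites
        unknown = nodes - rxns - mets
        if unknown:
            raise ValidationError(f"unknown nodes in module: {sorted(unknown)[:5]}")
    return math.fsum(scored.reaction_score[r] for r in rxns) + math.fsum(
        scored.metabolite_weight[m] for m in mets
    )
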