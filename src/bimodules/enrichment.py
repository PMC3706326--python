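"""Pathway over-representation analysis of differentially expressed genes.

This is the conventional gene-set comparison run alongside the module
search: for each pathway, a one-tailed Fisher's exact test asks whether
the DE gene set overlaps the pathway more than expected under random
sampling from the gene universe.  The one-tailed Fisher p-value equals
the hypergeometric upper tail P(X >= overlap), which is how it is
computed here.  False discovery rates use Storey's q-value estimator by
default (pi0 estimated at a single lambda), with plain Benjamini-Hochberg
available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError

logger = logging.getLogger(__name__)

PATHWAY_FDR = 0.05


@dataclass(frozen=True)
class PathwayMap:
    """Pathway id -> (name, gene set), plus the gene universe.

    Every pathway gene must belong to the universe; the universe is the
    set of genes that could have been called differentially expressed
    (all analysed genes present in the annotation).
    """

    pathways: Mapping  # id -> (name, frozenset of gene ids)
    universe: frozenset

    def __post_init__(self):
        for pid, (name, genes) in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has no genes")
            if not genes <= self.universe:
                raise ValidationError(f"pathway {pid!r} has genes outside the universe")

    def __len__(self) -> int:
        return len(self.pathways)


def read_pathway_table(path, universe: Iterable | None = None) -> PathwayMap:
    """Read a TSV with columns pathway_id, name, gene_ids (';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("pathway_id", "name", "gene_ids"):
        if col not in df.columns:
            raise ValidationError(f"pathway table is missing column {col!r}")
    pathways = {}
    seen_genes = set()
    for row in df.itertuples(index=False):
        genes = frozenset(g.strip() for g in row.gene_ids.split(";") if g.strip())
        pathways[row.pathway_id] = (row.name, genes)
        seen_genes |= genes
    uni = frozenset(universe) if universe is not None else frozenset(seen_genes)
    return PathwayMap(pathways=pathways, universe=uni)


def overrepresentation_pvalue(overlap, pathway_size, de_size, universe_size):
    """One-tailed Fisher / hypergeometric upper-tail p-value, P(X >= overlap).

    Accepts scalars or broadcastable arrays.
    """
    return hypergeom.sf(
        np.asarray(overlap) - 1, universe_size, pathway_size, de_size
    )


def fisher_enrich(de_genes: Iterable, pathways: PathwayMap, direction: str = "") -> pd.DataFrame:
    """Over-representation test of a DE gene set against every pathway.

    Genes outside the universe are dropped with a logged warning.  Returns
    a DataFrame with one row per pathway: pathway_id, name, size, overlap,
    pvalue (sorted by ascending p), plus the direction tag.
    """
    if not pathways.universe:
        raise ValidationError("empty gene universe")
    de = set(de_genes)
    outside = de - pathways.universe
    if outside:
        logger.warning(
            "dropping %d DE genes outside the annotation universe", len(outside)
        )
        de &= pathways.universe
    if not de:
        raise ValidationError("empty DE gene set (after universe restriction)")
    N, n = len(pathways.universe), len(de)
    rows = []
    for pid in sorted(pathways.pathways):
        name, genes = pathways.pathways[pid]
        k = len(genes & de)
        rows.append(
            {
                "pathway_id": pid,
                "name": name,
                "size": len(genes),
                "overlap": k,
                "pvalue": float(overrepresentation_pvalue(k, len(genes), n, N)),
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["pvalue", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )


def storey_qvalue(pvalues, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m)); q_i = pi0 * BH_i with
    step-up monotonicity.  This is the simplest published variant of the
    estimator behind the Bioconductor qvalue package.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    if not (0 < lam < 1):
        raise ValidationError("lambda must lie in (0, 1)")
    m = p.size
    pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_qvalues(result: pd.DataFrame, method: str = "storey") -> pd.DataFrame:
    """Append a qvalue column to a fisher_enrich result."""
    if method == "storey":
        q = storey_qvalue(result["pvalue"].to_numpy())
    elif method == "bh":
        from .scoring import benjamini_hochberg

        q = benjamini_hochberg(result["pvalue"].to_numpy())
    else:
        raise ValidationError(f"unknown q-value method {method!r}")
    out = result.copy()
    out["qvalue"] = q
    return out


def significant_pathways(result: pd.DataFrame, fdr: float = PATHWAY_FDR) -> pd.DataFrame:
    """Rows with q < fdr, sorted by ascending p (Table-style output)."""
    if "qvalue" not in result.columns:
        raise ValidationError("qvalue column missing; run add_qvalues first")
    out = result[result["qvalue"] < fdr]
    return out.sort_values(["pvalue", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )
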