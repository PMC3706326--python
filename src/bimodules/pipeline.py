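"""End-to-end orchestration: load, score, search, assess, compare, report.

A run is fully determined by its configuration (including a mandatory
seed): identical configurations produce byte-identical tabular outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .network import (
    MetabolicNetwork,
    load_reaction_table,
    write_graphml,
    write_sif,
)
from .scoring import filter_de_genes, read_gene_scores, score_network
from .search import AnnealConfig, Module, anneal, exclude_unsupported, extend_module, extract_modules
from .significance import assess_modules, module_qvalues, pvalue_floor
from .enrichment import PathwayMap, add_qvalues, fisher_enrich, read_pathway_table, significant_pathways

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; ``seed`` is mandatory by design."""

    seed: int
    network_path: str | None = None
    gene_scores_path: str | None = None
    pathway_path: str | None = None
    out_dir: str = "bimodules_out"
    weight_constant: float | None = None
    top_n: int = 20
    null_samples: int = 1000
    qvalue_method: str = "bh"
    pathway_qvalue_method: str = "storey"
    fold_threshold: float = 2.0
    gene_fdr: float = 0.01
    module_fdr: float = 0.05
    pathway_fdr: float = 0.05
    anneal: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, v in (
            ("gene_fdr", self.gene_fdr),
            ("module_fdr", self.module_fdr),
            ("pathway_fdr", self.pathway_fdr),
        ):
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.fold_threshold <= 0:
            raise ValidationError("fold_threshold must be positive")
        if self.seed is None:
            raise ValidationError("a seed is required (no wall-clock seeding)")


@dataclass
class RunResult:
    up_modules: list
    down_modules: list
    excluded: list
    enrichment: dict  # direction -> DataFrame (with qvalue column)
    weight_constant: float
    config: RunConfig
    de_sets: dict  # direction -> set of gene ids


def _search_direction(net, genes, direction, cfg: RunConfig):
    scored = score_network(net, genes, direction=direction, c=cfg.weight_constant)
    acfg = AnnealConfig(
        seed=cfg.seed + (0 if direction == "up" else 1),
        n_modules=cfg.top_n,
        **cfg.anneal,
    )
    logger.info(
        "search direction=%s c=%.6g T0=%s alpha=%s temps=%s steps=%s restarts=%s seed=%s",
        direction, scored.weight_constant, acfg.initial_temperature,
        acfg.cooling_factor, acfg.n_temperatures, acfg.steps_per_temperature,
        acfg.restarts, acfg.seed,
    )
    result = anneal(scored, acfg)
    modules = extract_modules(scored, result.on_state, top_n=cfg.top_n)
    kept, excluded = exclude_unsupported(modules)
    return scored, kept, excluded


def analyse(
    net: MetabolicNetwork,
    genes: pd.DataFrame,
    pathways: PathwayMap | None = None,
    cfg: RunConfig | None = None,
) -> RunResult:
    """Run the full analysis in memory.

    Stages: score (up) -> anneal -> extract -> exclude unsupported ->
    the same with direction=down -> empirical significance with a shared
    multiple-testing family -> DE-filter + pathway enrichment comparison.
    """
    if cfg is None:
        raise ValidationError("a RunConfig (with seed) is required")
    scored_up, kept_up, excl_up = _search_direction(net, genes, "up", cfg)
    scored_dn, kept_dn, excl_dn = _search_direction(net, genes, "down", cfg)

    tested_up = assess_modules(
        scored_up, kept_up, B=cfg.null_samples, seed=cfg.seed + 2
    )
    tested_dn = assess_modules(
        scored_dn, kept_dn, B=cfg.null_samples, seed=cfg.seed + 3
    )
    # one multiple-testing family per run, across both directions
    both = module_qvalues(tested_up + tested_dn, method=cfg.qvalue_method)
    tested_up, tested_dn = both[: len(tested_up)], both[len(tested_up) :]

    enrichment = {}
    de_sets = {}
    if pathways is not None:
        up_genes, down_genes = filter_de_genes(
            genes, cfg.fold_threshold, cfg.gene_fdr
        )
        de_sets = {"up": up_genes, "down": down_genes}
        for direction, de in de_sets.items():
            de_in = de & pathways.universe
            if de_in:
                res = fisher_enrich(de_in, pathways, direction=direction)
                enrichment[direction] = add_qvalues(res, method=cfg.pathway_qvalue_method)
            else:
                enrichment[direction] = pd.DataFrame(
                    columns=["pathway_id", "name", "size", "overlap", "pvalue", "direction", "qvalue"]
                )
    return RunResult(
        up_modules=tested_up,
        down_modules=tested_dn,
        excluded=excl_up + excl_dn,
        enrichment=enrichment,
        weight_constant=scored_up.weight_constant,
        config=cfg,
        de_sets=de_sets,
    )


# -- reporting --------------------------------------------------------------------


def format_q(module: Module, B: int) -> str:
    """Module q-value to 2 significant figures, with the Monte-Carlo floor rule.

    When the empirical p sits exactly at its smallest attainable value
    1/(B+1), the q is reported as an upper bound ("<0.004" for B=249):
    the data cannot resolve anything smaller.
    """
    if module.p_empirical is not None and module.p_empirical == pvalue_floor(B):
        return f"<{pvalue_floor(B):.2g}"
    if module.q is None:
        return ""
    return f"{module.q:.2g}"


def module_ids(modules, direction: str) -> list:
    prefix = "u" if direction == "up" else "d"
    return [f"{prefix}{i + 1}" for i in range(len(modules))]


def write_module_table(modules, path, B: int, direction: str = "up") -> None:
    """Ranked module report (one row per module, header always written)."""
    rows = []
    for mid, m in zip(module_ids(modules, direction), modules):
        rows.append(
            {
                "module": mid,
                "q_value": format_q(m, B),
                "score": f"{m.score:.4f}",
                "n_reactions": m.n_reactions,
                "n_metabolites": m.n_metabolites,
                "n_reactions_with_genes": m.n_reactions_with_genes,
                "label": m.label,
            }
        )
    cols = ["module", "q_value", "score", "n_reactions", "n_metabolites",
            "n_reactions_with_genes", "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_module_nodes(modules, net, path, direction: str = "up") -> None:
    rows = []
    for mid, m in zip(module_ids(modules, direction), modules):
        for n in sorted(m.nodes.reaction_ids):
            rows.append({"module": mid, "node_id": n, "node_type": "reaction"})
        for n in sorted(m.nodes.metabolite_ids):
            rows.append({"module": mid, "node_id": n, "node_type": "metabolite"})
    pd.DataFrame(rows, columns=["module", "node_id", "node_type"]).to_csv(
        path, sep="\t", index=False
    )


def write_enrichment_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("pvalue", "qvalue"):
        if col in out.columns:
            out[col] = out[col].map(lambda x: f"{x:.6g}")
    out.to_csv(path, sep="\t", index=False)


def export_module_graph(
    net: MetabolicNetwork,
    module: Module,
    prefix,
    scored=None,
    extended: bool = False,
) -> list:
    """Write a module (optionally context-extended) as GraphML and SIF.

    Node attributes: ``node_type``, and when a scored network is given,
    ``score`` (reactions), ``weight`` (metabolites) and ``imputed``.
    Returns the paths written.
    """
    nodes = (extend_module(net, module) if extended else module.nodes).nodes
    attrs = {}
    if scored is not None:
        attrs["score"] = {r: scored.reaction_score[r] for r in nodes & net.reactions}
        attrs["weight"] = {
            m: scored.metabolite_weight[m] for m in nodes & net.metabolites
        }
        attrs["imputed"] = {
            r: bool(r in scored.imputed) for r in nodes & net.reactions
        }
    prefix = str(prefix)
    gml, sif = prefix + ".graphml", prefix + ".sif"
    write_graphml(net, gml, nodes=nodes, node_attrs=attrs)
    write_sif(net, sif, nodes=nodes)
    return [gml, sif]


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Load inputs from the configured paths, analyse, and write reports."""
    if not cfg.network_path or not cfg.gene_scores_path:
        raise ValidationError("network_path and gene_scores_path are required")
    net = load_reaction_table(cfg.network_path)
    genes = read_gene_scores(cfg.gene_scores_path)
    pathways = read_pathway_table(cfg.pathway_path) if cfg.pathway_path else None

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        result = analyse(net, genes, pathways, cfg)
        for direction, modules in (("up", result.up_modules), ("down", result.down_modules)):
            p = out / f"modules_{direction}.tsv"
            write_module_table(modules, p, B=cfg.null_samples, direction=direction)
            written.append(p)
            p = out / f"module_nodes_{direction}.tsv"
            write_module_nodes(modules, net, p, direction=direction)
            written.append(p)
        for direction, df in result.enrichment.items():
            p = out / f"enrichment_{direction}.tsv"
            write_enrichment_table(df, p)
            written.append(p)
            p = out / f"enrichment_{direction}_significant.tsv"
            write_enrichment_table(significant_pathways(df, cfg.pathway_fdr), p)
            written.append(p)
        params = asdict(cfg)
        params["derived_weight_constant"] = float(result.weight_constant)
        with open(out / "run_params.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(params, fh, sort_keys=True)
        written.append(out / "run_params.yaml")
    except Exception:
        for p in written:  # no partial outputs on failure
            Path(p).unlink(missing_ok=True)
        raise
    return result
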