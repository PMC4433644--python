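"""End-to-end orchestration: expression -> modules -> topology -> regulators.

A single :class:`PipelineConfig` (loadable from a YAML key-value file)
names the input tables and the thresholds, and :func:`run_all` executes the
four stages, persisting every intermediate table, the resolved
configuration, a run log and a machine-readable JSON summary of the counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .exceptions import ConfigurationError
from .expression import differential_test
from .network import (
    detect_modules,
    evaluate_modules,
    read_ppi,
    select_maocs,
)
from .regulation import calls_to_frame, regulator_screen, target_map_from_pairs
from .topology import topology_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gene_expression: str = ""
    gene_groups: str = ""
    mirna_expression: str = ""
    mirna_groups: str = ""
    ppi_edges: str = ""
    mirna_targets: str = ""
    output_dir: str = "modmir_output"
    case_label: str = "case"
    control_label: str = "control"
    de_alpha: float = 0.01
    module_alpha: float = 0.01
    enrichment_alpha: float = 0.01
    cpm_k: int = 3
    n_perm: int = 10000
    seed: int = 0
    t_variant: str = "pooled"
    degree_scope: str = "induced"
    hub_threshold: float = 0.9
    min_modules: int = 2
    top_n: int = 5
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("de_alpha", "module_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.cpm_k < 3:
            raise ConfigurationError(f"cpm_k must be >= 3, got {self.cpm_k}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("extra")
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle under ``output_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Any stage failure propagates with the stage name prepended; tables
    written before the failure are retained for inspection.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("modmir")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        summary = _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _run_stages(config: PipelineConfig, out: Path) -> dict:
    config.to_yaml(out / "resolved_config.yaml")

    @_stage("expression_de")
    def de_stage():
        genes = io.load_expression(config.gene_expression, config.gene_groups)
        mirnas = io.load_expression(config.mirna_expression, config.mirna_groups)
        gene_de = differential_test(
            genes, config.case_label, config.control_label,
            alpha=config.de_alpha, variant=config.t_variant,
        )
        mirna_de = differential_test(
            mirnas, config.case_label, config.control_label,
            alpha=config.de_alpha, variant=config.t_variant,
        )
        io.write_de_table(gene_de, out / "de_genes.tsv")
        io.write_de_table(mirna_de, out / "de_mirnas.tsv")
        return gene_de, mirna_de

    gene_de, mirna_de = de_stage()

    @_stage("network_modules")
    def module_stage():
        net = read_ppi(config.ppi_edges)
        member_sets = detect_modules(net, k=config.cpm_k)
        modules = evaluate_modules(
            member_sets, gene_de, n_perm=config.n_perm, seed=config.seed
        )
        maocs = select_maocs(modules, alpha=config.module_alpha)
        io.write_modules(modules, out / "modules.tsv")
        io.write_modules(maocs, out / "maocs.tsv")
        return net, modules, maocs

    net, modules, maocs = module_stage()

    @_stage("topology")
    def topology_stage():
        if not maocs:
            logger.warning("no significant module; topology stage skipped")
            return pd.DataFrame(columns=["gene", "degree", "K", "roles", "cs", "member_of"])
        report = topology_report(
            net, maocs,
            scope=config.degree_scope,
            hub_threshold=config.hub_threshold,
            min_modules=config.min_modules,
        )
        report.to_csv(out / "topology.tsv", sep="\t", index=False, float_format="%.6g")
        return report

    topo = topology_stage()

    @_stage("mirna_regulation")
    def regulation_stage():
        pairs = io.read_target_pairs(config.mirna_targets)
        tmap = target_map_from_pairs(pairs)
        universe = set(net.nodes) & tmap.genes
        calls, all_pairs = regulator_screen(
            mirna_de, gene_de, maocs, tmap, universe, alpha=config.enrichment_alpha
        )
        frame = calls_to_frame(calls)
        frame.to_csv(out / "regulators.tsv", sep="\t", index=False, float_format="%.6g")
        all_pairs.to_csv(
            out / "regulator_tests.tsv", sep="\t", index=False, float_format="%.6g"
        )
        frame[["mirna", "module_id"]].to_csv(
            out / "mirna_module_edges.tsv", sep="\t", index=False
        )
        return calls

    calls = regulation_stage()

    roles = topo["roles"].fillna("") if len(topo) else pd.Series(dtype=str)
    summary = {
        "n_gene_features": int(len(gene_de)),
        "n_mirna_features": int(len(mirna_de)),
        "n_degs": int(gene_de["is_significant"].sum()),
        "n_demirs": int(mirna_de["is_significant"].sum()),
        "n_network_nodes": int(net.number_of_nodes()),
        "n_network_edges": int(net.number_of_edges()),
        "n_modules": len(modules),
        "n_maocs": len(maocs),
        "n_hub_genes": int(roles.str.contains("hub").sum()) if len(topo) else 0,
        "n_intra_connectors": int(roles.str.contains("intra_maoc").sum()) if len(topo) else 0,
        "n_inter_connectors": int(roles.str.contains("inter_maoc").sum()) if len(topo) else 0,
        "n_regulator_calls": len(calls),
        "n_anti_correlated": sum(1 for c in calls if c.anti_correlated),
        "parameters": {
            "de_alpha": config.de_alpha,
            "module_alpha": config.module_alpha,
            "enrichment_alpha": config.enrichment_alpha,
            "cpm_k": config.cpm_k,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "t_variant": config.t_variant,
            "degree_scope": config.degree_scope,
            "hub_threshold": config.hub_threshold,
            "min_modules": config.min_modules,
            "top_n": config.top_n,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
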