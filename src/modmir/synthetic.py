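"""Synthetic benchmark generator with planted ground truth.

Emulates the statistical structure the pipeline assumes, so every stage is
testable without any external download:

* a scale-free (preferential-attachment) background interaction network
  with planted dense, clique-rich communities;
* two-group expression for genes and miRNAs: homoscedastic Gaussian noise
  around per-feature baselines, with planted-community genes shifted up in
  the case group by a configurable standardized effect size, and planted
  regulator miRNAs shifted the opposite way;
* a sparse miRNA -> target map in which planted regulators concentrate at
  least half their targets inside their intended community.

Each generator draws from its own RNG stream derived from the single
configuration seed, so the graph, the expression matrices and the target
map can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .exceptions import ConfigurationError
from .expression import ExpressionMatrix

CASE = "case"
CONTROL = "control"

# stream offsets: graph, gene expression, miRNA expression, target map
_STREAMS = {"graph": 1, "genes": 2, "mirnas": 3, "targets": 4}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale study: 1000 genes and 100 miRNAs over
    25 + 25 samples, five planted 8-gene communities whose members are
    shifted by 3 noise standard deviations in the case group, a
    preferential-attachment background with mean degree 4, and a tenth of
    miRNAs planted as repressors of a community.

    The background mean degree is kept low enough that 3-clique percolation
    on the background alone stays subcritical: curated interactomes yield
    hundreds of small overlapping communities, not one giant one, and a
    percolating background would swallow every planted community and defeat
    the generator's purpose.
    """

    n_genes: int = 1000
    n_mirnas: int = 100
    n_samples_per_group: int = 25
    n_planted_modules: int = 5
    planted_module_size: int = 8
    planted_effect_size: float = 3.0
    background_noise_sd: float = 1.0
    ppi_mean_degree: float = 4.0
    intra_module_edge_prob: float = 0.9
    targets_per_mirna: int = 12
    planted_regulator_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_samples_per_group": self.n_samples_per_group,
            "n_planted_modules": self.n_planted_modules,
            "planted_module_size": self.planted_module_size,
            "targets_per_mirna": self.targets_per_mirna,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value}")
        for name, value in (
            ("intra_module_edge_prob", self.intra_module_edge_prob),
            ("planted_regulator_fraction", self.planted_regulator_fraction),
        ):
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {value}")
        for name, value in (
            ("planted_effect_size", self.planted_effect_size),
            ("background_noise_sd", self.background_noise_sd),
            ("ppi_mean_degree", self.ppi_mean_degree),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {value}")
        if self.planted_module_size < 3:
            raise ConfigurationError(
                "planted_module_size must be >= 3 so communities are detectable "
                "by clique percolation"
            )
        if self.n_planted_modules * self.planted_module_size > self.n_genes:
            raise ConfigurationError(
                "n_planted_modules * planted_module_size exceeds n_genes"
            )
        background_density = self.ppi_mean_degree / max(self.n_genes - 1, 1)
        if self.intra_module_edge_prob <= background_density:
            raise ConfigurationError(
                "intra_module_edge_prob must exceed the background edge density "
                f"({background_density:.4g})"
            )
        if self.targets_per_mirna > self.n_genes:
            raise ConfigurationError("targets_per_mirna exceeds the gene universe")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one of the named artifact streams."""
        return np.random.default_rng([_STREAMS[stream], int(self.seed)])


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded at generation time."""

    planted_module_members: list[list[str]] = field(default_factory=list)
    truly_shifted_genes: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    planted_regulators: dict[str, dict] = field(default_factory=dict)  # mirna -> {module, sign}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def mirna_names(n: int) -> list[str]:
    return [f"miR-{i:03d}" for i in range(n)]


def generate_ppi(config: SyntheticConfig):
    """Scale-free background network with planted near-clique communities.

    Background edges follow Barabási–Albert preferential attachment with
    mean degree ``ppi_mean_degree``; each planted community's within-pair
    edges are then added independently with ``intra_module_edge_prob``.
    Planted member sets are disjoint and drawn uniformly over nodes, so they
    are not confounded with attachment-order hubs.  Returns the simple
    undirected graph and a :class:`SyntheticTruth` with memberships and the
    (all-up) shifted-gene directions.
    """
    config.validate()
    rng = config.rng("graph")
    names = gene_names(config.n_genes)
    m_attach = max(1, int(round(config.ppi_mean_degree / 2)))
    g = nx.barabasi_albert_graph(config.n_genes, m_attach, seed=rng)
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    picked = rng.choice(
        config.n_genes,
        size=config.n_planted_modules * config.planted_module_size,
        replace=False,
    )
    truth = SyntheticTruth()
    for i in range(config.n_planted_modules):
        block = picked[i * config.planted_module_size : (i + 1) * config.planted_module_size]
        members = sorted(names[j] for j in block)
        truth.planted_module_members.append(members)
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                if rng.random() < config.intra_module_edge_prob:
                    g.add_edge(members[a_idx], members[b_idx])
        for gene in members:
            truth.truly_shifted_genes[gene] = +1

    n_reg = max(1, int(round(config.planted_regulator_fraction * config.n_mirnas)))
    mirnas = mirna_names(config.n_mirnas)
    reg_idx = rng.choice(config.n_mirnas, size=n_reg, replace=False)
    for j, idx in enumerate(sorted(int(i) for i in reg_idx)):
        truth.planted_regulators[mirnas[idx]] = {
            "module": j % config.n_planted_modules,
            "sign": -1,  # repressors move opposite to their up-shifted targets
        }
    return g, truth


def generate_expression(
    config: SyntheticConfig, truth: SyntheticTruth, feature_kind: str
) -> ExpressionMatrix:
    """Two-group expression matrix for genes or miRNAs.

    Per-feature baselines are drawn once from N(8, 2^2); samples get i.i.d.
    Gaussian noise with sd ``background_noise_sd``.  Truly shifted features
    receive a case-minus-control mean difference of
    ``planted_effect_size * background_noise_sd`` in their recorded
    direction.
    """
    config.validate()
    if feature_kind == "gene":
        rng = config.rng("genes")
        features = gene_names(config.n_genes)
        shifts = dict(truth.truly_shifted_genes)
        prefix = "GS"
    elif feature_kind == "mirna":
        rng = config.rng("mirnas")
        features = mirna_names(config.n_mirnas)
        shifts = {m: info["sign"] for m, info in truth.planted_regulators.items()}
        prefix = "MS"
    else:
        raise ConfigurationError(f"feature_kind must be 'gene' or 'mirna', got {feature_kind!r}")

    n = config.n_samples_per_group
    baselines = rng.normal(8.0, 2.0, size=len(features))
    noise = rng.normal(0.0, config.background_noise_sd, size=(len(features), 2 * n))
    X = baselines[:, None] + noise
    delta = config.planted_effect_size * config.background_noise_sd
    for i, f in enumerate(features):
        sign = shifts.get(f, 0)
        if sign:
            X[i, :n] += sign * delta  # case samples come first
    samples = [f"{prefix}_{CASE}_{i:03d}" for i in range(n)] + [
        f"{prefix}_{CONTROL}_{i:03d}" for i in range(n)
    ]
    groups = pd.Series([CASE] * n + [CONTROL] * n, index=samples, name="group")
    values = pd.DataFrame(X, index=pd.Index(features, name="feature_id"), columns=samples)
    return ExpressionMatrix(values=values, groups=groups)


def generate_mirna_targets(config: SyntheticConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Sparse miRNA -> gene map with regulator targets planted in modules.

    Each planted regulator draws ceil(targets_per_mirna / 2) of its targets
    from its intended community (all of it if the community is smaller) and
    the rest uniformly from the remaining genes; non-planted miRNAs draw all
    targets uniformly.  Returns a (mirna, gene) pair table.
    """
    config.validate()
    half = math.ceil(config.targets_per_mirna / 2)
    if half > config.planted_module_size:
        raise ConfigurationError(
            "ceil(targets_per_mirna/2) exceeds planted_module_size; planted "
            "regulators cannot place half their targets inside their module"
        )
    rng = config.rng("targets")
    names = gene_names(config.n_genes)
    rows = []
    for mirna in mirna_names(config.n_mirnas):
        if mirna in truth.planted_regulators:
            module = truth.planted_regulators[mirna]["module"]
            members = truth.planted_module_members[module]
            n_in = min(len(members), half)
            inside = rng.choice(members, size=n_in, replace=False)
            outside_pool = [g for g in names if g not in set(inside)]
            outside = rng.choice(
                outside_pool, size=config.targets_per_mirna - n_in, replace=False
            )
            targets = list(inside) + list(outside)
        else:
            targets = list(rng.choice(names, size=config.targets_per_mirna, replace=False))
        rows.extend({"mirna": mirna, "gene": g} for g in sorted(targets))
    return pd.DataFrame(rows, columns=["mirna", "gene"])


def write_bundle(config: SyntheticConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate every artifact and write it in the formats the pipeline reads.

    Writes gene/miRNA expression + group TSVs, the PPI edge list, the
    miRNA-target pair table, and a ``truth.json`` sidecar with the planted
    ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = generate_ppi(config)
    genes = generate_expression(config, truth, "gene")
    mirnas = generate_expression(config, truth, "mirna")
    targets = generate_mirna_targets(config, truth)

    io.write_expression(genes.values, out / "gene_expression.tsv")
    io.write_groups(genes.groups, out / "gene_groups.tsv")
    io.write_expression(mirnas.values, out / "mirna_expression.tsv")
    io.write_groups(mirnas.groups, out / "mirna_groups.tsv")
    with open(out / "ppi_edges.tsv", "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
    io.write_target_pairs(targets, out / "mirna_targets.tsv")
    truth.to_json(out / "truth.json")
    return truth
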