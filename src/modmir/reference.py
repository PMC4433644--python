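"""Bundled reference tables and their recomputed summary statistics.

The package ships a small curated reference dataset describing thirteen
oral-cancer-associated interaction modules: their member genes with
differential-expression flags, a relevance-scored list of known
oral-cancer genes, the degrees and connecting scores of topologically
important genes, and the change directions of eight module-regulating
miRNAs and their targets.  The tables are plain TSV transcriptions,
checksummed so edits are detected.

:func:`recompute_report` re-derives the dataset-level summary numbers from
the tables alone — unique gene count, DEG percentage, overlap with the
known-gene list, anti-correlated miRNA count and hub calls — and compares
each with its recorded value.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import IntegrityError
from .regulation import direction_correlation
from .topology import call_hubs


def _data_dir() -> Path:
    return Path(str(resources.files("modmir") / "data"))


def _verify(path: Path, data_dir: Path) -> None:
    with open(data_dir / "checksums.json") as fh:
        sums = json.load(fh)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if sums.get(path.name) != digest:
        raise IntegrityError(f"checksum mismatch for bundled table {path.name}")


def _load(name: str, data_dir: Path | None) -> pd.DataFrame:
    d = Path(data_dir) if data_dir is not None else _data_dir()
    path = d / name
    _verify(path, d)
    return pd.read_csv(path, sep="\t", comment="#")


def load_module_table(data_dir=None) -> pd.DataFrame:
    """Long-form module membership: module_id, gene, is_deg."""
    return _load("module_gene_table.tsv", data_dir)


def load_relevance_table(data_dir=None) -> pd.DataFrame:
    return _load("gene_relevance_table.tsv", data_dir)


def load_topology_table(data_dir=None) -> pd.DataFrame:
    return _load("topology_table.tsv", data_dir)


def load_mirna_table(data_dir=None) -> pd.DataFrame:
    return _load("mirna_direction_table.tsv", data_dir)


def expected_summary(data_dir=None) -> dict:
    d = Path(data_dir) if data_dir is not None else _data_dir()
    with open(d / "expected_summary.json") as fh:
        return json.load(fh)


# -- recomputation ----------------------------------------------------------


def unique_module_genes(modules: pd.DataFrame) -> set[str]:
    return set(modules["gene"])


def deg_percent(modules: pd.DataFrame) -> float:
    """Percentage of unique module genes flagged differentially expressed."""
    genes = unique_module_genes(modules)
    degs = set(modules.loc[modules["is_deg"] == 1, "gene"])
    return round(100.0 * len(degs) / len(genes), 2)


def relevance_overlap(modules: pd.DataFrame, relevance: pd.DataFrame):
    """Count and percentage of module genes present in the known-gene list."""
    genes = unique_module_genes(modules)
    overlap = genes & set(relevance["gene"])
    return len(overlap), round(100.0 * len(overlap) / len(genes), 2)


def anti_correlated_mirnas(mirna_table: pd.DataFrame) -> list[str]:
    """miRNAs whose direction opposes the direction of every listed target."""
    out = []
    for mirna, rows in mirna_table.groupby("mirna", sort=False):
        mdir = rows["mirna_direction"].iloc[0]
        tdirs = dict(zip(rows["target_gene"], rows["target_direction"]))
        if direction_correlation(mdir, tdirs):
            out.append(mirna)
    return out


def hub_calls(topology: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Hub genes recomputed from the tabulated degrees."""
    hubs_rows = topology[topology["role"] == "hub"]
    degrees = {g: int(k) for g, k in zip(hubs_rows["gene"], hubs_rows["degree"])}
    k_max = max(degrees.values())
    return call_hubs(degrees, k_max, threshold)


def recompute_report(data_dir=None) -> dict:
    """Recompute every summary number and compare with its recorded value.

    Returns a mapping of check name to ``{"computed", "expected", "pass"}``.
    """
    modules = load_module_table(data_dir)
    relevance = load_relevance_table(data_dir)
    topology = load_topology_table(data_dir)
    mirnas = load_mirna_table(data_dir)
    expected = expected_summary(data_dir)

    n_unique = len(unique_module_genes(modules))
    pct_deg = deg_percent(modules)
    n_overlap, pct_overlap = relevance_overlap(modules, relevance)
    anti = anti_correlated_mirnas(mirnas)
    hubs = hub_calls(topology)

    checks = {
        "unique_module_genes": (n_unique, expected["unique_module_genes"]),
        "deg_percent": (pct_deg, expected["deg_percent"]),
        "relevance_overlap_count": (n_overlap, expected["relevance_overlap_count"]),
        "relevance_overlap_percent": (pct_overlap, expected["relevance_overlap_percent"]),
        "anti_correlated_mirnas": (len(anti), expected["anti_correlated_mirnas"]),
        "hub_genes": (sorted(hubs), sorted(expected["hub_genes"])),
    }
    return {
        name: {"computed": comp, "expected": exp, "pass": comp == exp}
        for name, (comp, exp) in checks.items()
    }
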