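"""Tab-delimited readers and writers for the pipeline's artifacts.

All tabular I/O is plain TSV.  Expression matrices carry the feature
identifier in the first column and sample identifiers in the header; group
annotations, probe maps and miRNA-target pairs are two-column tables;
module sets are written in a GMT-like layout (one module per line:
identifier, score, P-value, then member symbols).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import InputError
from .expression import ExpressionMatrix

# -- expression -------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return df


def read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"group file {path} needs two columns (sample, group)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    s.index.name = "sample_id"
    return s


def load_expression(expr_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(values=read_expression(expr_path), groups=read_groups(groups_path))


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t")


def write_groups(groups: pd.Series, path: str | Path) -> None:
    df = groups.rename("group").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"probe map {path} needs two columns (probe, feature)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# -- differential-expression tables ----------------------------------------


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", float_format="%.10g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- module sets ------------------------------------------------------------


def write_modules(modules: Iterable, path: str | Path) -> None:
    """Write modules as GMT-like TSV: id, score, p_value, member symbols."""
    with open(path, "w") as fh:
        for mod in modules:
            fields = [mod.module_id, f"{mod.score:.10g}", f"{mod.p_value:.10g}"]
            fields.extend(mod.members)
            fh.write("\t".join(fields) + "\n")


def read_modules(path: str | Path) -> list:
    from .network import Module

    modules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputError(f"{path}:{lineno}: expected id, score, p, members")
            modules.append(
                Module(
                    module_id=fields[0],
                    members=tuple(fields[3:]),
                    score=float(fields[1]),
                    p_value=float(fields[2]),
                    n_scored=len(fields) - 3,
                )
            )
    return modules


# -- miRNA-target pairs ------------------------------------------------------


def read_target_pairs(path: str | Path) -> pd.DataFrame:
    """Read an already-consolidated miRNA -> target table (mirna, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise InputError(f"target table {path} needs two columns (mirna, gene)")
    df = df.iloc[:, :2]
    df.columns = ["mirna", "gene"]
    return df.drop_duplicates(ignore_index=True)


def write_target_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[["mirna", "gene"]].to_csv(path, sep="\t", index=False)
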