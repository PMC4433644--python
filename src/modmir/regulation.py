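"""miRNA regulators of network modules.

A consolidated miRNA -> target map is built from per-tool prediction rows
(a predicted pair is kept only when at least two distinct tools agree) and
extended with experimentally supported pairs, which are kept regardless of
prediction support.

A differentially expressed miRNA is called a regulator of a module when its
targets are significantly enriched among the module's members — a one-sided
Fisher exact test on the 2x2 table (in-module x is-target) over a declared
gene universe.  Because miRNAs repress their targets, each call is further
annotated with a direction anti-correlation flag: true when every in-module
target's group-change direction is opposite to the miRNA's own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

DEFAULT_TOOLS = ("pictar", "miranda", "microt", "targetscan")


@dataclass
class MiRNATargetMap:
    """Unique (miRNA, gene) pairs with their evidence counts.

    ``pairs`` has columns ``mirna``, ``gene``, ``n_tools`` (distinct
    predicting tools) and ``experimental`` (bool).
    """

    pairs: pd.DataFrame

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.pairs["mirna"].unique())

    @property
    def genes(self) -> set[str]:
        return set(self.pairs["gene"])

    def targets_of(self, mirna: str) -> set[str]:
        return set(self.pairs.loc[self.pairs["mirna"] == mirna, "gene"])


def build_target_map(
    predictions: pd.DataFrame,
    experimental: pd.DataFrame | None = None,
    tools=DEFAULT_TOOLS,
    min_tools: int = 2,
) -> MiRNATargetMap:
    """Consensus-plus-experimental target map.

    ``predictions`` holds one row per (mirna, gene, tool); a pair survives
    when predicted by at least ``min_tools`` distinct tools.  ``experimental``
    pairs are unioned in unconditionally.  Tool names outside ``tools``
    raise a validation error.
    """
    pred = predictions.copy()
    pred.columns = ["mirna", "gene", "tool"][: pred.shape[1]]
    unknown = set(pred["tool"].str.lower()) - set(t.lower() for t in tools)
    if unknown:
        raise ConfigurationError(f"unknown prediction tools: {sorted(unknown)}")
    pred["tool"] = pred["tool"].str.lower()
    counts = (
        pred.drop_duplicates()
        .groupby(["mirna", "gene"])["tool"]
        .nunique()
        .rename("n_tools")
        .reset_index()
    )
    kept = counts[counts["n_tools"] >= min_tools].copy()
    kept["experimental"] = False
    if experimental is not None and len(experimental):
        exp = experimental.copy()
        exp.columns = ["mirna", "gene"][: exp.shape[1]]
        exp = exp.drop_duplicates()
        exp = exp.merge(counts, on=["mirna", "gene"], how="left")
        exp["n_tools"] = exp["n_tools"].fillna(0).astype(int)
        exp["experimental"] = True
        merged = pd.concat([kept, exp], ignore_index=True)
        merged = (
            merged.groupby(["mirna", "gene"])
            .agg(n_tools=("n_tools", "max"), experimental=("experimental", "max"))
            .reset_index()
        )
    else:
        merged = kept
    merged = merged.sort_values(["mirna", "gene"]).reset_index(drop=True)
    logger.info(
        "build_target_map: %d pairs, %d miRNAs, %d genes",
        len(merged), merged["mirna"].nunique(), merged["gene"].nunique(),
    )
    return MiRNATargetMap(pairs=merged)


def target_map_from_pairs(pairs: pd.DataFrame) -> MiRNATargetMap:
    """Wrap an already-consolidated (mirna, gene) table."""
    df = pairs.iloc[:, :2].copy()
    df.columns = ["mirna", "gene"]
    df = df.drop_duplicates().sort_values(["mirna", "gene"]).reset_index(drop=True)
    df["n_tools"] = 0
    df["experimental"] = False
    return MiRNATargetMap(pairs=df)


@dataclass
class RegulatorCall:
    """One tested (miRNA, module) pair."""

    mirna: str
    module_id: str
    overlap: int
    n_targets: int
    module_size: int
    enrichment_p: float
    significant: bool
    mirna_direction: str | None = None
    target_directions: dict[str, str] = field(default_factory=dict)
    anti_correlated: bool | None = None


def module_enrichment(
    targets: set[str], module_members: set[str], universe: set[str], alpha: float = 0.01
):
    """One-sided Fisher exact test for target enrichment in a module.

    All counting happens inside ``universe``: the 2x2 table crosses module
    membership with target status.  Returns (overlap, P-value, significant).
    """
    if not universe:
        raise InputError("enrichment universe is empty")
    if not module_members <= universe:
        raise InputError("module members must be contained in the universe")
    t = targets & universe
    if not t:
        raise InputError("miRNA has no target in the universe")
    m = module_members
    a = len(t & m)
    b = len(t - m)
    c = len(m - t)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return a, float(p), bool(p < alpha)


def direction_correlation(mirna_direction: str, target_directions: dict[str, str]):
    """True iff every target's change direction opposes the miRNA's.

    Directions are compared case-insensitively as up/down.  With no directed
    target the flag is not evaluable and ``None`` is returned.
    """
    directed = {g: d.lower() for g, d in target_directions.items() if d}
    if not directed:
        return None
    mdir = mirna_direction.lower()
    if mdir not in ("up", "down"):
        raise InputError(f"miRNA direction must be up/down, got {mirna_direction!r}")
    return all(d != mdir and d in ("up", "down") for d in directed.values())


def regulator_screen(
    mirna_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    maocs,
    tmap: MiRNATargetMap,
    universe: set[str],
    alpha: float = 0.01,
):
    """Test every (differentially expressed miRNA, module) pair.

    Returns ``(calls, all_pairs)``: the significant :class:`RegulatorCall`
    objects annotated with anti-correlation, and a DataFrame of every tested
    pair for auditing.  A miRNA with no target in the universe is skipped.
    """
    demirs = [m for m in mirna_de.index[mirna_de["is_significant"]] if m in set(tmap.mirnas)]
    gene_dirs = gene_de["direction"].to_dict() if "direction" in gene_de else {}
    calls: list[RegulatorCall] = []
    rows = []
    for mirna in demirs:
        targets = tmap.targets_of(mirna) & universe
        if not targets:
            continue
        mdir = str(mirna_de.loc[mirna, "direction"]) if "direction" in mirna_de else None
        for mod in maocs:
            members = set(mod.members) & universe
            if not members:
                continue
            overlap, p, sig = module_enrichment(targets, members, universe, alpha=alpha)
            rows.append(
                {
                    "mirna": mirna,
                    "module_id": mod.module_id,
                    "overlap": overlap,
                    "n_targets": len(targets),
                    "module_size": len(members),
                    "enrichment_p": p,
                    "significant": sig,
                }
            )
            if not sig:
                continue
            in_module = targets & set(mod.members)
            tdirs = {g: gene_dirs[g] for g in sorted(in_module) if g in gene_dirs}
            anti = direction_correlation(mdir, tdirs) if mdir else None
            calls.append(
                RegulatorCall(
                    mirna=mirna,
                    module_id=mod.module_id,
                    overlap=overlap,
                    n_targets=len(targets),
                    module_size=len(members),
                    enrichment_p=p,
                    significant=True,
                    mirna_direction=mdir,
                    target_directions=tdirs,
                    anti_correlated=anti,
                )
            )
    all_pairs = pd.DataFrame(
        rows,
        columns=[
            "mirna", "module_id", "overlap", "n_targets",
            "module_size", "enrichment_p", "significant",
        ],
    )
    logger.info(
        "regulator_screen: %d DEmiRs tested against %d modules; %d significant calls",
        len(demirs), len(maocs), len(calls),
    )
    return calls, all_pairs


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "mirna": c.mirna,
                "module_id": c.module_id,
                "overlap": c.overlap,
                "n_targets": c.n_targets,
                "module_size": c.module_size,
                "enrichment_p": c.enrichment_p,
                "mirna_direction": c.mirna_direction or "",
                "target_directions": ";".join(
                    f"{g}:{d}" for g, d in sorted(c.target_directions.items())
                ),
                "anti_correlated": "" if c.anti_correlated is None else str(c.anti_correlated),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "module_id", "overlap", "n_targets", "module_size",
            "enrichment_p", "mirna_direction", "target_directions", "anti_correlated",
        ],
    )
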