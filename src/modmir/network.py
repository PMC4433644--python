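"""Overlapping module detection and permutation-calibrated relevance scoring.

Modules are k-clique percolation communities of the protein-protein
interaction (PPI) graph: maximal unions of k-cliques chained by adjacency,
where two k-cliques are adjacent when they share k-1 nodes.  Communities may
overlap, so a gene can belong to several modules.

Each module's relevance to the case/control contrast is the mean of its
members' signed t-scores,

    S = (1/m) * sum_i t_i ,

where m counts members with an available t-score.  Significance is
calibrated empirically: random gene sets of the same size are drawn without
replacement from the universe of scored genes, and the P-value is the
fraction of draws whose score is strictly greater than S.  The test is
therefore one-sided toward positive (case-elevated) scores; an absolute-t
variant is available for symmetric screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Module:
    """An overlapping network module with its relevance score.

    ``score`` is the mean t-score of scored members, ``p_value`` the
    empirical permutation P, and ``n_scored`` the number of members that had
    a t-score (members without expression contribute to neither the
    numerator nor the denominator of the mean).
    """

    module_id: str
    members: tuple[str, ...]
    score: float = float("nan")
    p_value: float = float("nan")
    n_scored: int = 0


# -- PPI input ---------------------------------------------------------------


def read_ppi(path) -> nx.Graph:
    """Read a two-column tab-delimited edge list into a simple graph.

    Self-interactions are dropped and duplicate pairs (in either order) are
    merged; the counts are logged.  A line without exactly two non-empty
    fields raises :class:`InputError` with its line number.
    """
    net = nx.Graph()
    n_self = 0
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise InputError(f"{path}:{lineno}: expected two tab-separated symbols")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                n_self += 1
                continue
            if net.has_edge(a, b):
                n_dup += 1
                continue
            net.add_edge(a, b)
    if net.number_of_edges() == 0:
        logger.warning("read_ppi: %s yielded an empty network", path)
    logger.info(
        "read_ppi: %d nodes, %d edges (%d self-loops and %d duplicates dropped)",
        net.number_of_nodes(), net.number_of_edges(), n_self, n_dup,
    )
    return net


# -- clique percolation ------------------------------------------------------


def detect_modules(net: nx.Graph, k: int = 3) -> list[tuple[str, ...]]:
    """All k-clique percolation communities, deterministically ordered.

    Members of each community are sorted; communities are sorted by
    decreasing size and then lexicographically.
    """
    if k < 3:
        raise ConfigurationError(f"clique-percolation k must be >= 3, got {k}")
    communities = [
        tuple(sorted(c, key=str)) for c in nx.community.k_clique_communities(net, k)
    ]
    communities.sort(key=lambda c: (-len(c), c))
    return communities


# -- scoring and permutation calibration ------------------------------------


def _as_t_series(de) -> pd.Series:
    """Accept a DE table (with a ``t_score`` column) or a bare Series."""
    if isinstance(de, pd.DataFrame):
        return de["t_score"]
    return pd.Series(de)


def score_module(members, de) -> float:
    """Mean t-score over the module members that have a t-score."""
    t = _as_t_series(de)
    scored = t.reindex([m for m in members if m in t.index]).dropna()
    if scored.empty:
        raise InputError("no module member has a t-score")
    return float(scored.mean())


def _scored_members(members, t: pd.Series) -> list[str]:
    return [m for m in members if m in t.index and pd.notna(t[m])]


def permutation_pvalue(
    members,
    de,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    universe=None,
    absolute: bool = False,
    add_one: bool = False,
) -> float:
    """Empirical P for a module score against same-size random gene sets.

    Draws ``n_perm`` gene sets of the module's scored size without
    replacement from ``universe`` (default: every feature with a t-score),
    scores each as the mean t, and returns the fraction of draws strictly
    greater than the observed score.  ``add_one`` applies the (x+1)/(n+1)
    bias correction; ``absolute`` scores mean |t| instead of mean t.
    """
    t = _as_t_series(de).dropna()
    if universe is not None:
        t = t.reindex([g for g in universe if g in t.index]).dropna()
    members = tuple(members)
    if len(t) < len(members):
        raise InputError(
            f"universe of {len(t)} genes smaller than module size {len(members)}"
        )
    scored = _scored_members(members, t)
    if not scored:
        raise InputError("no module member has a t-score in the universe")
    m = len(scored)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = t.to_numpy(dtype=float)
    if absolute:
        pool = np.abs(pool)
        observed = float(np.mean(np.abs(t[scored].to_numpy(dtype=float))))
    else:
        observed = float(t[scored].mean())
    null = _null_scores(pool, m, n_perm, rng)
    return _empirical_p(observed, null, add_one)


def _null_scores(pool: np.ndarray, m: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rng.choice(pool, size=m, replace=False).mean()
    return null


def _empirical_p(observed: float, null: np.ndarray, add_one: bool) -> float:
    count = int(np.sum(null > observed))
    if add_one:
        return (count + 1) / (len(null) + 1)
    return count / len(null)


def evaluate_modules(
    member_sets,
    de,
    n_perm: int = 10000,
    seed: int | None = None,
    universe=None,
    absolute: bool = False,
    add_one: bool = False,
) -> list[Module]:
    """Score every module and attach its permutation P-value.

    Null score distributions depend only on the number of scored members, so
    one null of ``n_perm`` draws is generated per distinct size and shared by
    all modules of that size; each module's P remains a valid ``n_perm``-draw
    estimate.  Modules with no scored member are skipped with a warning.
    """
    t = _as_t_series(de).dropna()
    if universe is not None:
        t = t.reindex([g for g in universe if g in t.index]).dropna()
    pool = np.abs(t.to_numpy(dtype=float)) if absolute else t.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    modules: list[Module] = []
    width = max(3, len(str(len(member_sets))))
    for idx, members in enumerate(member_sets, 1):
        members = tuple(members)
        module_id = f"M{idx:0{width}d}"
        if len(t) < len(members):
            raise InputError(
                f"universe of {len(t)} genes smaller than module size {len(members)}"
            )
        scored = _scored_members(members, t)
        if not scored:
            logger.warning("module %s has no scored member; skipped", module_id)
            continue
        m = len(scored)
        vals = t[scored].to_numpy(dtype=float)
        observed = float(np.mean(np.abs(vals))) if absolute else float(np.mean(vals))
        if m not in null_by_size:
            null_by_size[m] = _null_scores(pool, m, n_perm, rng)
        p = _empirical_p(observed, null_by_size[m], add_one)
        modules.append(
            Module(
                module_id=module_id,
                members=tuple(members),
                score=observed,
                p_value=p,
                n_scored=m,
            )
        )
    return modules


def select_maocs(modules, alpha: float = 0.01) -> list[Module]:
    """Modules significant at ``alpha`` (strict), in significance order."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    selected = [m for m in modules if m.p_value < alpha]
    selected.sort(key=lambda m: (m.p_value, -m.score, m.module_id))
    return selected


def relabel_modules(modules) -> list[Module]:
    """Renumber module identifiers 1..n preserving order."""
    width = max(3, len(str(len(modules))))
    return [replace(m, module_id=f"M{i:0{width}d}") for i, m in enumerate(modules, 1)]
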