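"""Topological characterisation of the significant-module (MAOC) network.

Three gene roles are called:

* **hubs** — genes whose scaled connectivity K_i = k_i / k_max exceeds a
  threshold (default 0.9, strict), with k_max the maximum degree among
  module member genes;
* **intra-module connectors** — members of at least one module with at
  least one interaction partner in a module they do not belong to; their
  connecting score CS counts the distinct other modules reached;
* **inter-module connectors** — non-members whose partners span at least
  ``min_modules`` distinct modules; CS counts all modules reached.

Degrees are computed by default on the subgraph induced by the union of all
module members (the module network itself); connecting scores always use the
full interaction network, since inter-module connectors lie outside the
induced subgraph.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)


def _member_map(maocs) -> dict[str, set[str]]:
    membership: dict[str, set[str]] = {}
    for mod in maocs:
        for gene in mod.members:
            membership.setdefault(gene, set()).add(mod.module_id)
    return membership


def maoc_degrees(net: nx.Graph, maocs, scope: str = "induced"):
    """Per-gene degree over module members, plus the maximum degree k_max.

    ``scope='induced'`` counts edges within the subgraph induced by the
    union of all module members; ``scope='full'`` counts edges in the whole
    network.  Either way k_max is taken over module member genes.
    """
    if scope not in ("induced", "full"):
        raise InputError(f"unknown degree scope: {scope!r}")
    union = set().union(*(set(m.members) for m in maocs)) if maocs else set()
    union &= set(net.nodes)
    if not union:
        raise InputError("no module member is present in the network")
    if scope == "induced":
        sub = net.subgraph(union)
        degrees = {g: int(sub.degree(g)) for g in union}
    else:
        degrees = {g: int(net.degree(g)) for g in union}
    k_max = max(degrees.values())
    return degrees, k_max


def scaled_connectivity(degrees: dict[str, int], k_max: int) -> dict[str, float]:
    if k_max <= 0:
        raise InputError("k_max must be positive")
    return {g: k / k_max for g, k in degrees.items()}


def call_hubs(degrees: dict[str, int], k_max: int, threshold: float = 0.9) -> list[str]:
    """Genes with scaled connectivity strictly above ``threshold``."""
    if k_max <= 0:
        raise InputError("k_max must be positive")
    hubs = [g for g, k in degrees.items() if k / k_max > threshold]
    hubs.sort(key=lambda g: (-degrees[g], g))
    return hubs


def connecting_scores(net: nx.Graph, maocs, min_modules: int = 2):
    """Intra- and inter-module connector tables with connecting scores.

    Returns two DataFrames (intra, inter) with columns ``gene``, ``cs``,
    ``degree`` (full-network degree, used for tie-breaking) and, for intra
    connectors, ``member_of``.  Both are sorted by (cs desc, degree desc,
    symbol).
    """
    membership = _member_map(maocs)
    missing = set(membership) - set(net.nodes)
    if missing:
        raise InputError(f"module members absent from the network: {sorted(missing)[:5]}")
    module_members = {m.module_id: set(m.members) for m in maocs}

    def neighbor_modules(gene: str) -> set[str]:
        nbrs = set(net.neighbors(gene))
        return {mid for mid, members in module_members.items() if nbrs & members}

    intra_rows = []
    for gene, own in membership.items():
        linked = neighbor_modules(gene) - own
        if linked:
            intra_rows.append(
                {
                    "gene": gene,
                    "cs": len(linked),
                    "degree": int(net.degree(gene)),
                    "member_of": ";".join(sorted(own)),
                }
            )
    inter_rows = []
    union = set(membership)
    candidates = {n for g in union for n in net.neighbors(g)} - union
    for gene in candidates:
        linked = neighbor_modules(gene)
        if len(linked) >= min_modules:
            inter_rows.append(
                {"gene": gene, "cs": len(linked), "degree": int(net.degree(gene))}
            )

    def finish(rows, columns):
        df = pd.DataFrame(rows, columns=columns)
        return df.sort_values(
            ["cs", "degree", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)

    intra = finish(intra_rows, ["gene", "cs", "degree", "member_of"])
    inter = finish(inter_rows, ["gene", "cs", "degree"])
    return intra, inter


def top_connectors(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """First ``n`` rows of a connector table under its documented sort."""
    if len(table) < n:
        logger.warning("top_connectors: only %d candidates for top %d", len(table), n)
        return table.copy()
    if len(table) > n and table.iloc[n - 1]["cs"] == table.iloc[n]["cs"]:
        logger.info(
            "top_connectors: tie at the boundary (cs=%s) broken by degree then symbol",
            table.iloc[n - 1]["cs"],
        )
    return table.head(n).copy()


def topology_report(
    net: nx.Graph,
    maocs,
    scope: str = "induced",
    hub_threshold: float = 0.9,
    min_modules: int = 2,
) -> pd.DataFrame:
    """Combined per-gene table of degree, K, roles and connecting score.

    Rows cover every module member plus every inter-module connector.
    Scaled connectivity K is defined only for module members; connector
    genes outside all modules carry their full-network degree and empty
    ``member_of``.
    """
    degrees, k_max = maoc_degrees(net, maocs, scope=scope)
    K = scaled_connectivity(degrees, k_max)
    hubs = set(call_hubs(degrees, k_max, hub_threshold))
    intra, inter = connecting_scores(net, maocs, min_modules=min_modules)
    membership = _member_map(maocs)
    intra_cs = dict(zip(intra["gene"], intra["cs"]))
    inter_cs = dict(zip(inter["gene"], inter["cs"]))

    rows = []
    for gene in sorted(degrees):
        roles = []
        if gene in hubs:
            roles.append("hub")
        if gene in intra_cs:
            roles.append("intra_maoc")
        rows.append(
            {
                "gene": gene,
                "degree": degrees[gene],
                "K": K[gene],
                "roles": ";".join(roles),
                "cs": intra_cs.get(gene, 0),
                "member_of": ";".join(sorted(membership.get(gene, set()))),
            }
        )
    for _, row in inter.iterrows():
        rows.append(
            {
                "gene": row["gene"],
                "degree": row["degree"],
                "K": float("nan"),
                "roles": "inter_maoc",
                "cs": row["cs"],
                "member_of": "",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "degree", "K", "roles", "cs", "member_of"])
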