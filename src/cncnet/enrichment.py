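"""Gene-set over-representation analysis (hypergeometric test).

For a query of n genes drawn from a background of N, a set with m members
and k query hits is scored with the one-sided hypergeometric tail
P(X >= k) -- equivalently Fisher's exact test for over-representation.
Alongside p, each set gets the *richness factor* k/m (query hits over set
size; larger = stronger enrichment) and -LgP = -log10(p), the two axes the
field's enrichment figures use.  Up- and down-regulated queries are run
independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["set_id", "name", "k", "m", "n", "N", "p_value",
                  "richness_factor", "neg_log_p", "direction",
                  "significant", "genes"]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common background universe."""

    sets: dict[str, tuple[str, frozenset]] = field(default_factory=dict)
    background: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.background:
            self.background = frozenset().union(
                *(members for _, members in self.sets.values())) if self.sets else frozenset()
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")
            stray = members - self.background
            if stray:
                raise ValueError(
                    f"gene set {sid!r} has members outside the background: "
                    f"{sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset:
        return self.sets[set_id][1]


def hypergeom_pvalue(k: int, m: int, n: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, m, n)."""
    for name, v in (("k", k), ("m", m), ("n", n), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer")
    if m > N or n > N:
        raise ValueError("set size and query size cannot exceed the background")
    if k > min(m, n):
        raise ValueError("overlap k cannot exceed min(set size, query size)")
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def enrich(query, collection: GeneSetCollection, alpha: float = 0.05,
           direction: str = "", correction: str = "none") -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    Query genes outside the background are dropped with a warning.  The
    result has one row per set, sorted by ascending p then set id; the
    ``genes`` column holds the overlap (comma-joined, sorted).
    ``correction`` is ``"none"`` (raw p, the default filter convention
    here) or ``"BH"``.
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    query = list(dict.fromkeys(query))  # dedupe, keep order
    inside = [g for g in query if g in collection.background]
    dropped = len(query) - len(inside)
    if dropped:
        logger.warning("%d query gene(s) outside the background dropped", dropped)
    qset = set(inside)
    n, N = len(qset), len(collection.background)

    rows = []
    for sid in sorted(collection.sets):
        name, members = collection.sets[sid]
        overlap = sorted(qset & members)
        k, m = len(overlap), len(members)
        p = hypergeom_pvalue(k, m, n, N) if n else 1.0
        rows.append({
            "set_id": sid, "name": name, "k": k, "m": m, "n": n, "N": N,
            "p_value": p,
            "richness_factor": k / m,
            "neg_log_p": -math.log10(p) if p > 0 else math.inf,
            "direction": direction,
            "genes": ",".join(overlap),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    p_eff = out["p_value"].to_numpy()
    if correction == "BH":
        p_eff = stats.false_discovery_control(p_eff, method="bh")
        out["p_adjusted"] = p_eff
    out["significant"] = p_eff < alpha
    out = out.sort_values(["p_value", "set_id"]).reset_index(drop=True)
    cols = ENRICH_COLUMNS + (["p_adjusted"] if correction == "BH" else [])
    return out[cols]


def genes_from_significant_sets(results: pd.DataFrame,
                                query=None) -> set[str]:
    """Union over significant sets of (set members intersect query).

    The ``genes`` column of an enrichment table already holds each set's
    overlap with its query, so the union is taken from there; an optional
    ``query`` re-intersects (useful when pooling tables from several runs).
    """
    out: set[str] = set()
    if results.empty:
        return out
    for _, row in results[results["significant"]].iterrows():
        if row["genes"]:
            out.update(row["genes"].split(","))
    if query is not None:
        out &= set(query)
    return out


def plot_enrichment(results: pd.DataFrame, path: str, top: int = 10) -> None:
    """Simple horizontal -LgP bar summary of the top enriched sets."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = results.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(sub), 4) + 1.2))
    colors = np.where(sub["direction"] == "down", "tab:blue", "tab:red")
    ax.barh(sub["set_id"], sub["neg_log_p"], color=colors)
    ax.set_xlabel("-LgP")
    ax.set_title("Gene-set over-representation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
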