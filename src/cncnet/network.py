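"""Coding-noncoding co-expression (CNC) network construction.

Edges connect genes of different classes whose pooled-sample Pearson
correlation exceeds the threshold in magnitude (strictly), with a sign
rule per edge type reflecting negative regulation by miRNAs:

* miRNA-mRNA: r < 0 and a supporting predicted binding site,
* miRNA-lncRNA: r < 0,
* lncRNA-mRNA: r > 0 (co-regulation on the coding side).

When the mRNA side was never measured (targets predicted only), miRNA-mRNA
edges can instead be taken straight from the target table with opposite
predicted directions, and r is recorded as missing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .matrix import ExpressionMatrix
from .targets import TargetTable

logger = logging.getLogger(__name__)

CORR_COLUMNS = ["gene_a", "gene_b", "class_a", "class_b", "r", "n_samples"]
EDGE_TYPES = {
    frozenset(["miRNA", "mRNA"]): "miRNA-mRNA",
    frozenset(["miRNA", "lncRNA"]): "miRNA-lncRNA",
    frozenset(["lncRNA", "mRNA"]): "lncRNA-mRNA",
}


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def cross_class_correlations(matrix: ExpressionMatrix,
                             genes_by_class: dict[str, list[str]]) -> pd.DataFrame:
    """Pearson r for every cross-class gene pair, pooled over all samples.

    ``genes_by_class`` maps each class label to the genes of interest of
    that class (e.g. DE miRNAs, DE lncRNAs, candidate mRNAs).  Pairs
    within one class are skipped; genes with a constant profile are
    excluded with a warning and do not appear in any record.
    """
    if not matrix.is_log2:
        from .diffexpr import log2_normalize
        matrix = log2_normalize(matrix)
    all_genes: list[str] = []
    classes: list[str] = []
    for cls in sorted(genes_by_class):
        for g in genes_by_class[cls]:
            if g not in matrix.values.index:
                raise KeyError(f"gene {g!r} not in expression matrix")
            all_genes.append(g)
            classes.append(cls)
    if not all_genes:
        return pd.DataFrame(columns=CORR_COLUMNS)

    vals = matrix.values.loc[all_genes].to_numpy(float)
    constant = np.ptp(vals, axis=1) == 0
    for g in np.asarray(all_genes)[constant]:
        logger.warning("gene %s has a constant profile; its pairs are excluded", g)

    n = vals.shape[1]
    with np.errstate(invalid="ignore"):
        rmat = np.corrcoef(vals)
    rows = []
    for ia, ib in itertools.combinations(range(len(all_genes)), 2):
        if classes[ia] == classes[ib]:
            continue
        if constant[ia] or constant[ib]:
            continue
        ga, gb = all_genes[ia], all_genes[ib]
        # canonical order: sorted gene ids, so the table is symmetric-stable
        if gb < ga:
            ga, gb = gb, ga
            ca, cb = classes[ib], classes[ia]
        else:
            ca, cb = classes[ia], classes[ib]
        rows.append({"gene_a": ga, "gene_b": gb, "class_a": ca, "class_b": cb,
                     "r": float(rmat[ia, ib]), "n_samples": n})
    out = pd.DataFrame(rows, columns=CORR_COLUMNS)
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


@dataclass
class CNCNetwork:
    """Typed tripartite co-expression network."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, data in sorted(self.graph.edges(data=True)):
            rows.append({
                "source": a, "target": b,
                "edge_type": data["edge_type"],
                "r": data.get("r", float("nan")),
                "support": data.get("support", ""),
            })
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "r", "support"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            rows.append({
                "gene_id": node, "gene_class": data["gene_class"],
                "direction": data["direction"], "degree": self.graph.degree(node),
            })
        return pd.DataFrame(rows, columns=["gene_id", "gene_class", "direction", "degree"])

    def assert_edge_law(self, targets: TargetTable | None = None) -> None:
        """Exhaustively re-check the sign/threshold/support rule per edge."""
        for a, b, data in self.graph.edges(data=True):
            et = data["edge_type"]
            r = data.get("r")
            if r is not None and not math.isnan(r):
                assert abs(r) > self.threshold, (a, b, r)
                if et in ("miRNA-mRNA", "miRNA-lncRNA"):
                    assert r < 0, (a, b, r, et)
                else:
                    assert r > 0, (a, b, r, et)
            if et == "miRNA-mRNA":
                assert data.get("support") == "predicted_site", (a, b)
                if targets is not None:
                    mir, gene = (a, b) if self.graph.nodes[a]["gene_class"] == "miRNA" else (b, a)
                    assert targets.has_pair(mir, gene), (mir, gene)


def build_cnc_network(corrs: pd.DataFrame, targets: TargetTable,
                      de_nodes: pd.DataFrame,
                      candidate_directions: pd.DataFrame,
                      threshold: float = 0.9,
                      mrna_measured: bool = True) -> CNCNetwork:
    """Assemble the CNC network from correlations, predictions and DE calls.

    Parameters
    ----------
    corrs
        Cross-class correlation records (``cross_class_correlations``).
    targets
        Predicted miRNA->target table; required support for miRNA-mRNA edges.
    de_nodes
        DE table for the measured noncoding side; significant miRNAs and
        lncRNAs become nodes with their measured direction.
    candidate_directions
        Candidate mRNA list with predicted directions (negative-regulation
        rule); these become the mRNA nodes.
    threshold
        Strict magnitude cut on r (the classic "strong correlation" 0.9).
    mrna_measured
        If False, the mRNA side has no expression profile: miRNA-mRNA
        edges are taken from the target table with r recorded as missing,
        and no lncRNA-mRNA edges are formed.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()

    sig = de_nodes[de_nodes["significant"]]
    directions: dict[str, str] = {}
    classes: dict[str, str] = {}
    for _, row in sig.iterrows():
        if row["gene_class"] in ("miRNA", "lncRNA"):
            directions[row["gene_id"]] = row["direction"]
            classes[row["gene_id"]] = row["gene_class"]
    for _, row in candidate_directions.iterrows():
        directions[row["gene_id"]] = row["direction"]
        classes[row["gene_id"]] = "mRNA"

    for gene in sorted(directions):
        g.add_node(gene, gene_class=classes[gene], direction=directions[gene])

    def add_edge(a, b, r, edge_type, support=""):
        g.add_edge(a, b, r=r, edge_type=edge_type, support=support)

    if not corrs.empty:
        for _, rec in corrs.iterrows():
            a, b = rec["gene_a"], rec["gene_b"]
            if a not in g or b not in g:
                continue
            pair = frozenset([rec["class_a"], rec["class_b"]])
            edge_type = EDGE_TYPES.get(pair)
            if edge_type is None:
                continue
            r = float(rec["r"])
            if abs(r) <= threshold:
                continue
            if edge_type == "miRNA-mRNA":
                if r >= 0:
                    continue
                mir, gene = (a, b) if rec["class_a"] == "miRNA" else (b, a)
                if not targets.has_pair(mir, gene):
                    continue
                add_edge(a, b, r, edge_type, support="predicted_site")
            elif edge_type == "miRNA-lncRNA":
                if r >= 0:
                    continue
                add_edge(a, b, r, edge_type)
            else:  # lncRNA-mRNA
                if r <= 0:
                    continue
                add_edge(a, b, r, edge_type)

    if not mrna_measured and not targets.pairs.empty:
        for _, row in targets.pairs.iterrows():
            mir, gene = row["mirna_id"], row["target_id"]
            if row["target_class"] != "mRNA" or mir not in g or gene not in g:
                continue
            if directions.get(mir) != _opposite(directions.get(gene)):
                continue
            add_edge(mir, gene, float("nan"), "miRNA-mRNA", support="predicted_site")

    net = CNCNetwork(graph=g, threshold=threshold)
    net.assert_edge_law()
    return net


def _opposite(direction: str | None) -> str | None:
    return {"up": "down", "down": "up"}.get(direction)


def select_mrnas_by_degree(net: CNCNetwork, min_degree: int = 1) -> pd.DataFrame:
    """mRNA nodes with degree >= min_degree, by descending degree then id."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    rows = []
    for node, data in net.graph.nodes(data=True):
        if data["gene_class"] != "mRNA":
            continue
        deg = net.graph.degree(node)
        if deg >= min_degree:
            rows.append({"gene_id": node, "direction": data["direction"], "degree": deg})
    out = pd.DataFrame(rows, columns=["gene_id", "direction", "degree"])
    return out.sort_values(["degree", "gene_id"],
                           ascending=[False, True]).reset_index(drop=True)
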