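"""Core-gene funnel: GO x KEGG intersection, reference filter, core network.

The funnel narrows the candidate mRNAs in three steps: (1) core genes are
the mRNAs recovered by BOTH enrichment analyses; (2) sub-core mRNAs are
the core genes found in a curated disease/process reference list (here a
user-supplied osteogenesis gene list standing in for the online
databases); (3) the core CNC network is the induced subgraph on the
sub-core mRNAs plus their miRNA and lncRNA network neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .network import CNCNetwork

logger = logging.getLogger(__name__)


def intersect_core(go_genes, kegg_genes) -> list[str]:
    """Genes recovered by both enrichment routes, sorted."""
    return sorted(set(go_genes) & set(kegg_genes))


def filter_by_reference(core, reference) -> list[str]:
    """Case-insensitive intersection of core genes with a reference list.

    Returns the core genes (original casing) whose upper-cased, stripped
    id appears in the reference.  An empty reference is a misconfiguration
    and is rejected outright.
    """
    reference = [str(r).strip() for r in reference]
    reference = [r for r in reference if r]
    if not reference:
        raise ValueError("reference gene list is empty; supply a curated list")
    ref_upper = {r.upper() for r in reference}
    return sorted(g for g in core if str(g).strip().upper() in ref_upper)


@dataclass
class CoreSelection:
    """Outcome of the funnel."""

    core_genes: list[str] = field(default_factory=list)
    sub_core_mrnas: list[str] = field(default_factory=list)
    core_mirnas: list[str] = field(default_factory=list)
    core_lncrnas: list[str] = field(default_factory=list)
    core_network: CNCNetwork | None = None

    @property
    def all_core(self) -> list[str]:
        return sorted(self.sub_core_mrnas + self.core_mirnas + self.core_lncrnas)


def extract_core_network(net: CNCNetwork, sub_core,
                         core_genes=None,
                         adjacency_mode: str = "direct") -> CoreSelection:
    """Induced neighbourhood subgraph around the sub-core mRNAs.

    ``adjacency_mode`` controls how core lncRNAs are identified:
    ``"direct"`` takes lncRNAs adjacent to a sub-core mRNA;
    ``"shared_mirna"`` additionally takes lncRNAs adjacent to any core
    miRNA (one step through the shared regulator).
    """
    if adjacency_mode not in ("direct", "shared_mirna"):
        raise ValueError(f"unknown adjacency_mode {adjacency_mode!r}")
    g = net.graph
    present = [m for m in sorted(set(sub_core)) if m in g]
    absent = sorted(set(sub_core) - set(present))
    if absent:
        logger.warning("sub-core gene(s) absent from the network: %s", absent)

    mirnas: set[str] = set()
    lncrnas: set[str] = set()
    for m in present:
        for nb in g.neighbors(m):
            cls = g.nodes[nb]["gene_class"]
            if cls == "miRNA":
                mirnas.add(nb)
            elif cls == "lncRNA":
                lncrnas.add(nb)
    if adjacency_mode == "shared_mirna":
        for mir in list(mirnas):
            for nb in g.neighbors(mir):
                if g.nodes[nb]["gene_class"] == "lncRNA":
                    lncrnas.add(nb)

    keep = set(present) | mirnas | lncrnas
    sub = nx.Graph()
    for node in sorted(keep):
        sub.add_node(node, **g.nodes[node])
    for a, b, data in g.edges(data=True):
        if a in keep and b in keep:
            sub.add_edge(a, b, **data)

    return CoreSelection(
        core_genes=sorted(core_genes) if core_genes is not None else [],
        sub_core_mrnas=present,
        core_mirnas=sorted(mirnas),
        core_lncrnas=sorted(lncrnas),
        core_network=CNCNetwork(graph=sub, threshold=net.threshold),
    )
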