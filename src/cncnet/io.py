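"""Readers and writers for the pipeline's plain-text dialects.

Formats: expression TSV (gene_id, class, then sample columns) with a
sample->group sidecar TSV; FASTA for sequences (via Biopython); GMT for
gene sets; one-id-per-line gene lists; TSV edge lists and GraphML for
networks.  Writers use a fixed float format so that equal inputs give
byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import ExpressionMatrix
from .network import CNCNetwork

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------- expression

def write_expression(matrix: ExpressionMatrix, path, sidecar_path=None) -> None:
    """Expression TSV + group sidecar (``<stem>.samples.tsv`` by default)."""
    path = Path(path)
    out = matrix.values.copy()
    out.insert(0, "class", matrix.gene_class)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".samples.tsv")
    groups = matrix.groups.rename("group").to_frame()
    groups.index.name = "sample_id"
    groups.to_csv(sidecar, sep="\t")


def read_expression(path, sidecar_path=None, is_log2: bool = False) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing 'class' column")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    gene_class = df.pop("class")
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".samples.tsv")
    groups_df = pd.read_csv(sidecar, sep="\t", index_col="sample_id")
    if "group" not in groups_df.columns:
        raise ValueError(f"{sidecar}: missing 'group' column")
    return ExpressionMatrix(df, gene_class, groups_df["group"], is_log2=is_log2)


# --------------------------------------------------------------------- fasta

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


# ----------------------------------------------------------------------- gmt

def write_gmt(collection, path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            name, members = collection.sets[sid]
            fh.write("\t".join([sid, name] + sorted(members)) + "\n")


def read_gmt(path, background=None):
    """GMT: one set per line -- set_id, description, then member genes.

    With an explicit ``background`` (e.g. the assayed gene universe), set
    members are intersected with it -- the conventional
    annotation-intersect-assayed universe -- and sets left empty are
    dropped with a warning.  Without one, the background defaults to the
    union of all set members.
    """
    from .enrichment import GeneSetCollection

    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, "
                                 f"description and at least one gene")
            sid, name, members = fields[0], fields[1], fields[2:]
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = (name, frozenset(m for m in members if m))
    if background is not None:
        bg = frozenset(background)
        restricted = {}
        for sid, (name, members) in sets.items():
            kept = members & bg
            if kept:
                restricted[sid] = (name, kept)
            else:
                logger.warning("%s: set %s has no member in the background; dropped",
                               path, sid)
        return GeneSetCollection(sets=restricted, background=bg)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------- gene lists

def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    out: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


# -------------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------ networks

def write_network(net: CNCNetwork, path, fmt: str = "tsv") -> None:
    """Edge-list TSV (source, target, edge_type, r, support) or GraphML."""
    if fmt == "tsv":
        write_table(net.edge_table(), path)
    elif fmt == "graphml":
        g = nx.Graph()
        for node, data in sorted(net.graph.nodes(data=True)):
            g.add_node(node, gene_class=data["gene_class"],
                       direction=data["direction"],
                       degree=int(net.graph.degree(node)))
        for a, b, data in sorted(net.graph.edges(data=True)):
            r = data.get("r")
            g.add_edge(a, b, edge_type=data["edge_type"],
                       r=float("nan") if r is None else float(r),
                       support=data.get("support", ""))
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, threshold: float) -> CNCNetwork:
    g = nx.read_graphml(str(path))
    return CNCNetwork(graph=nx.Graph(g), threshold=threshold)
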