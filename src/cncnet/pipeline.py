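"""End-to-end pipeline: simulate -> DE -> targets -> network -> enrich -> core.

``run_pipeline`` executes the whole chain on a synthetic study (or on
user-supplied input files), writes every intermediate as TSV/FASTA/GMT/
GraphML into a run directory, and records a manifest (config echo, seed,
package version) sufficient to re-run a byte-identical analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .alignment import ScoringScheme
from .core import CoreSelection, extract_core_network, filter_by_reference, intersect_core
from .diffexpr import de_summary, differential_expression, log2_normalize
from .enrichment import enrich, genes_from_significant_sets
from .network import build_cnc_network, cross_class_correlations, select_mrnas_by_degree
from .synthetic import SyntheticSpec, simulate_all, spec_to_dict
from .targets import infer_candidate_directions, predict_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the documented defaults.

    ``inputs`` may name existing files (expression, mirna_fasta, utr_fasta,
    go_gmt, kegg_gmt, reference); anything missing is simulated from
    ``synthetic`` overrides applied to :class:`SyntheticSpec`.
    """

    rng_seed: int = 1234
    alpha: float = 0.05
    correction: str = "none"            # none | BH
    log2_floor: float = 1.0
    quantile_normalize: bool = False
    correlation_threshold: float = 0.9
    min_degree: int = 1
    adjacency_mode: str = "direct"      # direct | shared_mirna
    scan_lncrna_targets: bool = False
    mrna_measured: bool = True
    scoring: dict = field(default_factory=dict)      # ScoringScheme overrides
    synthetic: dict = field(default_factory=dict)    # SyntheticSpec overrides
    inputs: dict = field(default_factory=dict)       # optional file paths

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.min_degree < 0:
            raise ValueError("min_degree must be >= 0")
        if self.correction not in ("none", "BH"):
            raise ValueError("correction must be 'none' or 'BH'")
        if self.adjacency_mode not in ("direct", "shared_mirna"):
            raise ValueError("adjacency_mode must be 'direct' or 'shared_mirna'")
        known_scoring = {f.name for f in dataclasses.fields(ScoringScheme)}
        bad = set(self.scoring) - known_scoring
        if bad:
            raise ValueError(f"unknown scoring key(s): {sorted(bad)}")
        known_syn = {f.name for f in dataclasses.fields(SyntheticSpec)}
        bad = set(self.synthetic) - known_syn
        if bad:
            raise ValueError(f"unknown synthetic key(s): {sorted(bad)}")
        known_inputs = {"expression", "samples", "mirna_fasta", "utr_fasta",
                        "go_gmt", "kegg_gmt", "reference"}
        bad = set(self.inputs) - known_inputs
        if bad:
            raise ValueError(f"unknown input key(s): {sorted(bad)}")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(**self.scoring)

    @property
    def synthetic_spec(self) -> SyntheticSpec:
        overrides = dict(self.synthetic)
        overrides.setdefault("rng_seed", self.rng_seed)
        return SyntheticSpec(**overrides)


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown top-level keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    matrix: object
    truth: object
    de: pd.DataFrame
    targets: object
    candidates: pd.DataFrame
    correlations: pd.DataFrame
    network: object
    degree_selection: pd.DataFrame
    enrichment_go: pd.DataFrame
    enrichment_kegg: pd.DataFrame
    core: CoreSelection


def _write_truth(truth, outdir: Path) -> None:
    de = pd.DataFrame(
        [{"gene_id": g, "direction": d} for g, d in sorted(truth.de_genes.items())],
        columns=["gene_id", "direction"])
    cio.write_table(de, outdir / "truth_de_genes.tsv")
    pairs = pd.DataFrame(
        [{"mirna_id": p.mirna, "target_id": p.gene,
          "utr_site_start": p.utr_site_start, "utr_site_end": p.utr_site_end}
         for p in truth.target_pairs],
        columns=["mirna_id", "target_id", "utr_site_start", "utr_site_end"])
    cio.write_table(pairs, outdir / "truth_target_pairs.tsv")
    cio.write_gene_list(truth.enriched_sets, outdir / "truth_enriched_sets.txt")
    cio.write_gene_list(truth.reference_genes, outdir / "truth_reference_genes.txt")


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute the full analysis chain and write every intermediate.

    Stage order: (simulate?) -> log2 normalization -> differential
    expression of the measured classes -> target prediction ->
    candidate-direction inference -> cross-class correlations -> CNC
    network -> degree selection -> per-direction GO/KEGG enrichment ->
    core-gene funnel -> core network, plus a run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme
    truth = None

    if "expression" in config.inputs:
        matrix = cio.read_expression(config.inputs["expression"],
                                     config.inputs.get("samples"))
        mirna_seqs = cio.read_fasta(config.inputs["mirna_fasta"])
        utrs = cio.read_fasta(config.inputs["utr_fasta"])
        # enrichment universe: annotation genes intersected with the assayed mRNAs
        mrna_universe = matrix.genes_of_class("mRNA")
        go_sets = cio.read_gmt(config.inputs["go_gmt"], background=mrna_universe)
        kegg_sets = cio.read_gmt(config.inputs["kegg_gmt"], background=mrna_universe)
        reference = cio.read_gene_list(config.inputs["reference"])
    else:
        bundle = simulate_all(config.synthetic_spec)
        matrix, truth = bundle.matrix, bundle.truth
        mirna_seqs, utrs = bundle.mirna_seqs, bundle.utrs
        go_sets, kegg_sets = bundle.go_sets, bundle.kegg_sets
        reference = bundle.reference
        cio.write_expression(matrix, outdir / "expression.tsv",
                             outdir / "samples.tsv")
        cio.write_fasta(mirna_seqs, outdir / "mirnas.fasta")
        cio.write_fasta(utrs, outdir / "utrs.fasta")
        cio.write_gmt(go_sets, outdir / "go_sets.gmt")
        cio.write_gmt(kegg_sets, outdir / "kegg_sets.gmt")
        cio.write_gene_list(reference, outdir / "reference_genes.txt")
        _write_truth(truth, outdir)

    # ---- differential expression (noncoding classes measured; mRNA too if present)
    norm = log2_normalize(matrix, floor=config.log2_floor,
                          quantile=config.quantile_normalize)
    de = differential_expression(norm, alpha=config.alpha, correction=config.correction)
    cio.write_table(de, outdir / "de_results.tsv")
    cio.write_table(de_summary(de), outdir / "de_summary.tsv")

    # ---- target prediction for significant DE miRNAs
    sig_mirnas = de[(de["gene_class"] == "miRNA") & de["significant"]]["gene_id"]
    scan_mirnas = {m: mirna_seqs[m] for m in sig_mirnas if m in mirna_seqs}
    target_classes = {g: "mRNA" for g in utrs}
    if config.scan_lncrna_targets:
        logger.info("lncRNA target scanning enabled; provide lncRNA sequences in utrs")
    targets = predict_targets(scan_mirnas, utrs, scheme, target_classes)
    cio.write_table(targets.sites, outdir / "target_sites.tsv")
    cio.write_table(targets.pairs, outdir / "target_pairs.tsv")

    candidates = infer_candidate_directions(de[de["gene_class"] == "miRNA"], targets)
    cio.write_table(candidates, outdir / "candidates.tsv")

    # ---- correlations over DE noncoding genes and candidate mRNAs
    genes_by_class = {
        "miRNA": sorted(de[(de["gene_class"] == "miRNA") & de["significant"]]["gene_id"]),
        "lncRNA": sorted(de[(de["gene_class"] == "lncRNA") & de["significant"]]["gene_id"]),
        "mRNA": sorted(candidates["gene_id"]) if config.mrna_measured else [],
    }
    corrs = cross_class_correlations(norm, genes_by_class)
    cio.write_table(corrs, outdir / "correlations.tsv")

    net = build_cnc_network(corrs, targets, de, candidates,
                            threshold=config.correlation_threshold,
                            mrna_measured=config.mrna_measured)
    cio.write_network(net, outdir / "network_edges.tsv", fmt="tsv")
    cio.write_network(net, outdir / "network.graphml", fmt="graphml")
    cio.write_table(net.node_table(), outdir / "network_nodes.tsv")

    degree_sel = select_mrnas_by_degree(net, min_degree=config.min_degree)
    cio.write_table(degree_sel, outdir / "mrnas_by_degree.tsv")

    # ---- enrichment, run independently per direction
    selected = degree_sel.set_index("gene_id")["direction"]
    query_up = sorted(selected.index[selected == "up"])
    query_down = sorted(selected.index[selected == "down"])

    enr_go = pd.concat([
        enrich(query_up, go_sets, alpha=config.alpha, direction="up",
               correction=config.correction),
        enrich(query_down, go_sets, alpha=config.alpha, direction="down",
               correction=config.correction),
    ], ignore_index=True)
    enr_kegg = pd.concat([
        enrich(query_up, kegg_sets, alpha=config.alpha, direction="up",
               correction=config.correction),
        enrich(query_down, kegg_sets, alpha=config.alpha, direction="down",
               correction=config.correction),
    ], ignore_index=True)
    cio.write_table(enr_go, outdir / "enrichment_go.tsv")
    cio.write_table(enr_kegg, outdir / "enrichment_kegg.tsv")

    # ---- core-gene funnel
    go_genes = genes_from_significant_sets(enr_go)
    kegg_genes = genes_from_significant_sets(enr_kegg)
    core_genes = intersect_core(go_genes, kegg_genes)
    sub_core = filter_by_reference(core_genes, reference)
    core = extract_core_network(net, sub_core, core_genes=core_genes,
                                adjacency_mode=config.adjacency_mode)

    report = pd.DataFrame(
        [{"gene_id": g, "role": role}
         for role, genes in (
             ("core_gene", core.core_genes),
             ("sub_core_mrna", core.sub_core_mrnas),
             ("core_mirna", core.core_mirnas),
             ("core_lncrna", core.core_lncrnas),
         ) for g in genes],
        columns=["gene_id", "role"])
    cio.write_table(report, outdir / "core_selection.tsv")
    if core.core_network is not None:
        cio.write_network(core.core_network, outdir / "core_network_edges.tsv", fmt="tsv")
        cio.write_network(core.core_network, outdir / "core_network.graphml", fmt="graphml")

    manifest = {
        "tool": "cncnet",
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": asdict(config),
        "synthetic_spec": spec_to_dict(config.synthetic_spec)
        if "expression" not in config.inputs else None,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(
        outdir=outdir, matrix=matrix, truth=truth, de=de, targets=targets,
        candidates=candidates, correlations=corrs, network=net,
        degree_selection=degree_sel, enrichment_go=enr_go,
        enrichment_kegg=enr_kegg, core=core,
    )
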