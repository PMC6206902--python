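"""Synthetic microarray-style data with planted, recoverable structure.

Every downstream stage of the pipeline (differential expression, target
prediction, network construction, enrichment, core-gene selection) can be
exercised end to end without external data: the generator plants

* up/down differentially expressed genes per class at a fixed log2 fold
  change,
* miRNA -> mRNA regulations whose expression profiles are anticorrelated
  and whose 3'UTRs carry an exact full-length complement of the miRNA,
* gene sets enriched for the planted differentially expressed mRNAs, and
* a curated-style reference gene list covering part of the planted targets,

and records all of it in a :class:`TruthTable` for recovery testing.

Intensities are drawn on the log2 scale and exponentiated, so the
pipeline's log2 transform inverts the generative model exactly.  All
randomness flows from ``rng_seed``; per-output substreams are derived from
it with fixed keys so each ``simulate_*`` call is deterministic on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

RNA_BASES = np.array(["A", "C", "G", "U"])
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# substream keys so that each generator op has its own deterministic stream
_STREAMS = {"expression": 1, "mirnas": 2, "utrs": 3, "genesets": 4, "reference": 5}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults emulate a small two-group microarray experiment: three
    replicates per group (the usual design at this assay scale), log-normal
    intensities around 2**8, a 2.0 log2-unit planted effect against a
    0.25 log2-unit within-group noise, and ten planted miRNA->mRNA
    regulations with full-length complementary 3'UTR sites.
    """

    n_mirna: int = 40
    n_lncrna: int = 60
    n_mrna: int = 200
    n_ctrl: int = 3
    n_induced: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    de_fraction_per_class: float = 0.3
    planted_log2fc: float = 2.0
    noise_sd: float = 0.25
    n_target_pairs: int = 10
    mirna_length: int = 22
    utr_length: int = 300
    n_genesets: int = 12
    geneset_size: int = 15
    enriched_fraction: float = 0.6
    rng_seed: int = 1234

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_lncrna", "n_mrna", "mirna_length",
                     "utr_length", "geneset_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_ctrl < 2 or self.n_induced < 2:
            raise ValueError("need at least 2 replicates per group (t-test undefined)")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.de_fraction_per_class <= 1.0:
            raise ValueError("de_fraction_per_class must be in [0, 1]")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must be in [0, 1]")
        if self.n_target_pairs < 0 or self.n_genesets < 0:
            raise ValueError("counts must be >= 0")
        if self.utr_length < self.mirna_length:
            raise ValueError("utr_length must be >= mirna_length to hold a planted site")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.rng_seed])


@dataclass
class TargetPair:
    mirna: str
    gene: str
    utr_site_start: int  # 1-based inclusive
    utr_site_end: int    # 1-based inclusive


@dataclass
class TruthTable:
    """Planted ground truth: what a perfect pipeline should recover."""

    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    target_pairs: list[TargetPair] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    reference_genes: list[str] = field(default_factory=list)
    rng_seed: int = 0

    def de_of_class(self, matrix_or_prefix, direction: str | None = None) -> list[str]:
        """Planted DE genes filtered by id prefix ('miR', 'lnc', 'gene')."""
        out = [
            g for g, d in self.de_genes.items()
            if g.startswith(matrix_or_prefix) and (direction is None or d == direction)
        ]
        return sorted(out)

    @property
    def target_mrnas(self) -> list[str]:
        return sorted({p.gene for p in self.target_pairs})

    def regulators_of(self, genes) -> list[str]:
        genes = set(genes)
        return sorted({p.mirna for p in self.target_pairs if p.gene in genes})


def _gene_ids(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    mirnas = [f"miR-{i + 1:03d}" for i in range(spec.n_mirna)]
    lncrnas = [f"lnc-{i + 1:03d}" for i in range(spec.n_lncrna)]
    mrnas = [f"gene-{i + 1:03d}" for i in range(spec.n_mrna)]
    return mirnas, lncrnas, mrnas


def simulate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw an intensity matrix and its planted truth.

    Planted DE genes differ in group mean by exactly ``+-planted_log2fc``
    on the log2 scale (up = higher in the induced group).  Each planted
    miRNA->mRNA pair links a down(up) miRNA to an up(down) mRNA and the
    two share one mirrored per-sample residual stream, so their pooled
    log2 profiles are anticorrelated with |r| close to 1 even at three
    replicates per group.
    """
    rng = spec.rng("expression")
    mirnas, lncrnas, mrnas = _gene_ids(spec)
    genes = mirnas + lncrnas + mrnas
    classes = (["miRNA"] * spec.n_mirna + ["lncRNA"] * spec.n_lncrna
               + ["mRNA"] * spec.n_mrna)
    samples = ([f"ctrl_{i + 1}" for i in range(spec.n_ctrl)]
               + [f"ind_{i + 1}" for i in range(spec.n_induced)])
    group = np.array([0] * spec.n_ctrl + [1] * spec.n_induced, float)

    truth = TruthTable(rng_seed=spec.rng_seed)

    # ---- choose planted DE genes, alternating up/down within each class
    for ids in (mirnas, lncrnas, mrnas):
        n_de = int(round(spec.de_fraction_per_class * len(ids)))
        chosen = sorted(rng.choice(len(ids), size=n_de, replace=False))
        for j, idx in enumerate(chosen):
            truth.de_genes[ids[idx]] = "up" if j % 2 == 0 else "down"

    # ---- choose planted target pairs: miRNA direction opposite to target
    if spec.n_target_pairs:
        de_mir_up = truth.de_of_class("miR", "up")
        de_mir_dn = truth.de_of_class("miR", "down")
        de_mrna_up = truth.de_of_class("gene", "up")
        de_mrna_dn = truth.de_of_class("gene", "down")
        capacity = min(len(de_mir_up), len(de_mrna_dn)) + min(len(de_mir_dn), len(de_mrna_up))
        if spec.n_target_pairs > capacity:
            raise ValueError(
                f"n_target_pairs={spec.n_target_pairs} exceeds the "
                f"{capacity} opposite-direction DE miRNA/mRNA pairings available; "
                "raise de_fraction_per_class or gene counts"
            )
        pool: list[tuple[str, str]] = []
        # alternate down-miRNA->up-mRNA (the dominant pattern in induced
        # differentiation, where repressors fall and targets rise) and the reverse
        dn_pairs = list(zip(de_mir_dn, de_mrna_up))
        up_pairs = list(zip(de_mir_up, de_mrna_dn))
        while len(pool) < spec.n_target_pairs:
            if dn_pairs and (len(pool) % 2 == 0 or not up_pairs):
                pool.append(dn_pairs.pop(0))
            else:
                pool.append(up_pairs.pop(0))
        for mir, gene in pool:
            truth.target_pairs.append(TargetPair(mir, gene, 0, 0))  # site set later

    # ---- draw log2 intensities
    n_genes, n_samp = len(genes), len(samples)
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n_genes)
    log2 = np.tile(baseline[:, None], (1, n_samp))
    gene_index = {g: i for i, g in enumerate(genes)}

    # group effect: induced mean +- planted_log2fc
    for g, direction in truth.de_genes.items():
        eff = spec.planted_log2fc if direction == "up" else -spec.planted_log2fc
        log2[gene_index[g]] += eff * group

    # residuals: independent per gene ...
    noise = rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samp))
    # ... except planted pair members, which share one mirrored stream plus
    # a small independent jitter.  This pins the pooled-sample Pearson r of
    # each pair near -1 without touching group means or within-group sd.
    for pair in truth.target_pairs:
        shared = rng.normal(0.0, spec.noise_sd, n_samp)
        jitter_sd = spec.noise_sd / 10.0
        noise[gene_index[pair.mirna]] = -shared + rng.normal(0, jitter_sd, n_samp)
        noise[gene_index[pair.gene]] = shared + rng.normal(0, jitter_sd, n_samp)
    log2 += noise

    values = pd.DataFrame(np.exp2(log2), index=genes, columns=samples)
    matrix = ExpressionMatrix(
        values,
        gene_class=pd.Series(classes, index=genes),
        groups=pd.Series(["control"] * spec.n_ctrl + ["induced"] * spec.n_induced,
                         index=samples),
        meta={"rng_seed": spec.rng_seed},
    )
    return matrix, truth


def simulate_mirnas(spec: SyntheticSpec) -> dict[str, str]:
    """Uniform-random miRNA sequences, one per miRNA id."""
    rng = spec.rng("mirnas")
    mirnas, _, _ = _gene_ids(spec)
    return {
        mid: "".join(rng.choice(RNA_BASES, size=spec.mirna_length))
        for mid in mirnas
    }


def simulate_utrs(spec: SyntheticSpec, truth: TruthTable,
                  mirna_seqs: dict[str, str]) -> dict[str, str]:
    """Uniform-random 3'UTRs with planted full-complement binding sites.

    For every planted (miRNA, gene) pair the gene's UTR carries the exact
    reverse complement of the full miRNA; the 1-based inclusive site
    coordinates are written back into ``truth.target_pairs``.
    """
    rng = spec.rng("utrs")
    _, _, mrnas = _gene_ids(spec)
    utrs = {
        g: rng.choice(RNA_BASES, size=spec.utr_length) for g in mrnas
    }
    for pair in truth.target_pairs:
        if pair.mirna not in mirna_seqs:
            raise ValueError(f"planted pair miRNA {pair.mirna!r} has no sequence")
        site = reverse_complement(mirna_seqs[pair.mirna])
        if len(site) > spec.utr_length:
            raise ValueError("utr_length shorter than miRNA length")
        start0 = int(rng.integers(0, spec.utr_length - len(site) + 1))
        utrs[pair.gene][start0:start0 + len(site)] = list(site)
        pair.utr_site_start = start0 + 1
        pair.utr_site_end = start0 + len(site)
    return {g: "".join(arr) for g, arr in utrs.items()}


def simulate_genesets(spec: SyntheticSpec, truth: TruthTable,
                      prefix: str = "GO"):
    """Gene-set collection over the mRNA universe with planted enriched sets.

    Up to four enriched sets are planted, alternating direction (up, down,
    up, down).  An enriched set draws ``enriched_fraction`` of its members
    from planted DE mRNAs of its direction, always starting with the
    planted target-pair mRNAs of that direction (the genes the planted
    regulatory program acts on), then fills with background genes.
    Non-enriched sets are uniform draws from the background.
    """
    from .enrichment import GeneSetCollection  # local import to avoid cycle

    # decorrelate collections generated with different prefixes; zlib.crc32
    # is stable across processes (str hash() is salted)
    import zlib
    prefix_key = zlib.crc32(prefix.encode()) % (2 ** 31)
    rng = np.random.default_rng([_STREAMS["genesets"], prefix_key, spec.rng_seed])
    _, _, mrnas = _gene_ids(spec)
    background = list(mrnas)
    sets: dict[str, tuple[str, frozenset]] = {}
    enriched_ids: list[str] = []

    n_enriched = min(4, spec.n_genesets) if truth.de_genes else 0
    n_enr_members = int(round(spec.enriched_fraction * spec.geneset_size))
    directions = ["up", "down", "up", "down"]

    for i in range(spec.n_genesets):
        sid = f"{prefix}_SET_{i + 1:03d}"
        if i < n_enriched:
            direction = directions[i]
            de_pool = truth.de_of_class("gene", direction)
            targets = [g for g in truth.target_mrnas if truth.de_genes.get(g) == direction]
            rest = [g for g in de_pool if g not in targets]
            rng.shuffle(rest)
            members = (targets + rest)[:n_enr_members]
            others = [g for g in background if g not in members]
            fill = rng.choice(len(others), size=spec.geneset_size - len(members),
                              replace=False)
            members = members + [others[j] for j in sorted(fill)]
            name = f"planted {direction}-enriched set"
            enriched_ids.append(sid)
        else:
            idx = rng.choice(len(background), size=spec.geneset_size, replace=False)
            members = [background[j] for j in sorted(idx)]
            name = "background set"
        sets[sid] = (name, frozenset(members))

    truth.enriched_sets.extend(enriched_ids)
    return GeneSetCollection(sets=sets, background=frozenset(background))


def simulate_reference(spec: SyntheticSpec, truth: TruthTable,
                       fraction_of_targets: float = 0.6) -> list[str]:
    """Curated-style reference gene list (stands in for an online database).

    Contains ``fraction_of_targets`` of the planted target-pair mRNAs plus
    an equal number of decoy mRNAs that carry no planted regulation.  Ids
    are upper-cased to exercise case-insensitive matching downstream.
    """
    rng = spec.rng("reference")
    targets = truth.target_mrnas
    n_hit = max(1, int(round(fraction_of_targets * len(targets)))) if targets else 0
    hits = sorted(rng.choice(targets, size=n_hit, replace=False)) if n_hit else []
    _, _, mrnas = _gene_ids(spec)
    decoy_pool = [g for g in mrnas if g not in set(targets)]
    decoys = sorted(rng.choice(decoy_pool, size=min(n_hit, len(decoy_pool)),
                               replace=False)) if n_hit else []
    reference = sorted(g.upper() for g in list(hits) + list(decoys))
    truth.reference_genes = reference
    return reference


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces."""

    spec: SyntheticSpec
    matrix: ExpressionMatrix
    truth: TruthTable
    mirna_seqs: dict[str, str]
    utrs: dict[str, str]
    go_sets: object
    kegg_sets: object
    reference: list[str]

    @property
    def expected_sub_core(self) -> list[str]:
        """Planted reference-annotated target mRNAs (funnel ground truth)."""
        ref = {g.upper() for g in self.truth.reference_genes}
        return sorted(g for g in self.truth.target_mrnas if g.upper() in ref)


def simulate_all(spec: SyntheticSpec) -> SyntheticBundle:
    """Run every generator stage in a fixed order (fully seed-deterministic)."""
    matrix, truth = simulate_expression(spec)
    mirna_seqs = simulate_mirnas(spec)
    utrs = simulate_utrs(spec, truth, mirna_seqs)
    go_sets = simulate_genesets(spec, truth, prefix="GO")
    kegg_sets = simulate_genesets(spec, truth, prefix="KEGG")
    reference = simulate_reference(spec, truth)
    return SyntheticBundle(spec, matrix, truth, mirna_seqs, utrs,
                           go_sets, kegg_sets, reference)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)
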