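"""Candidate-target prediction: scan miRNAs against UTRs, dual thresholds.

A gene is called a candidate target of a miRNA when at least one binding
site passes BOTH filters: alignment score >= ``score_threshold`` and
duplex free energy <= ``energy_threshold``.  Candidate direction is then
inferred by the negative-regulation rule: a target is predicted to move
opposite to (the majority of) its significantly differentially expressed
regulating miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .alignment import ScoringScheme, sw_align_seeded, normalize_sequence
from .duplex import annotate_energy

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["mirna_id", "target_id", "utr_start", "utr_end",
                "score", "energy", "mirna_aln", "utr_aln"]
PAIR_COLUMNS = ["mirna_id", "target_id", "target_class",
                "best_score", "best_energy", "site_count"]


@dataclass
class TargetTable:
    """Predicted miRNA -> target hits.

    ``sites`` holds every passing binding site (one row per site, fixed
    column order); ``pairs`` aggregates to one row per (miRNA, target)
    with the best score, best (lowest) energy and the site count.
    """

    sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SITE_COLUMNS))
    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PAIR_COLUMNS))

    def has_pair(self, mirna_id: str, target_id: str) -> bool:
        p = self.pairs
        if p.empty:
            return False
        return bool(((p["mirna_id"] == mirna_id)
                     & (p["target_id"] == target_id)).any())

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.pairs["target_id"].unique()) if not self.pairs.empty else []


def predict_targets(mirnas: dict[str, str], utrs: dict[str, str],
                    scheme: ScoringScheme | None = None,
                    target_classes: dict[str, str] | None = None) -> TargetTable:
    """Scan every (miRNA, UTR) pair and keep dual-threshold hits.

    Parameters
    ----------
    mirnas, utrs
        id -> sequence mappings (RNA or DNA alphabet; normalized here).
    scheme
        Scoring scheme; defaults to :class:`ScoringScheme` defaults.
    target_classes
        Optional id -> class ('mRNA'/'lncRNA') for the UTR side; anything
        missing is labelled mRNA.  Scanning lncRNA sequences as targets is
        just a matter of including them in ``utrs``.
    """
    if not mirnas or not utrs:
        return TargetTable()
    scheme = scheme or ScoringScheme()
    target_classes = target_classes or {}
    mirnas = {k: normalize_sequence(v) for k, v in mirnas.items()}
    utrs = {k: normalize_sequence(v) for k, v in utrs.items()}

    site_rows = []
    pair_rows = []
    for mid in sorted(mirnas):
        for tid in sorted(utrs):
            sites = sw_align_seeded(mirnas[mid], utrs[tid], scheme,
                                    mirna_id=mid, utr_id=tid)
            annotate_energy(sites)
            passing = [s for s in sites if s.free_energy <= scheme.energy_threshold]
            if not passing:
                continue
            for s in passing:
                site_rows.append({
                    "mirna_id": mid, "target_id": tid,
                    "utr_start": s.utr_start, "utr_end": s.utr_end,
                    "score": s.score, "energy": s.free_energy,
                    "mirna_aln": s.mirna_aln, "utr_aln": s.utr_aln,
                })
            pair_rows.append({
                "mirna_id": mid, "target_id": tid,
                "target_class": target_classes.get(tid, "mRNA"),
                "best_score": max(s.score for s in passing),
                "best_energy": min(s.free_energy for s in passing),
                "site_count": len(passing),
            })

    sites_df = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    pairs_df = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    if not pairs_df.empty:
        pairs_df = pairs_df.sort_values(
            ["mirna_id", "best_score", "target_id"],
            ascending=[True, False, True]).reset_index(drop=True)
        sites_df = sites_df.sort_values(
            ["mirna_id", "score", "target_id", "utr_start"],
            ascending=[True, False, True, True]).reset_index(drop=True)
    return TargetTable(sites=sites_df, pairs=pairs_df)


def infer_candidate_directions(de_mirnas: pd.DataFrame,
                               table: TargetTable) -> pd.DataFrame:
    """Predicted direction of each candidate mRNA by negative regulation.

    Each target's predicted direction is the opposite of the majority
    direction among its *significant* regulating miRNAs; exact ties are
    dropped with a warning.  ``de_mirnas`` is a differential-expression
    table (as from :func:`cncnet.diffexpr.differential_expression`)
    restricted to or containing the miRNA class.

    Raises if a miRNA in the target table has no DE record at all.
    """
    if table.pairs.empty:
        return pd.DataFrame(columns=["gene_id", "direction", "n_up_mirnas", "n_down_mirnas"])
    de = de_mirnas.set_index("gene_id")
    known = set(de.index)
    used = set(table.pairs["mirna_id"])
    orphans = used - known
    if orphans:
        raise ValueError(f"miRNA(s) in target table without DE record: {sorted(orphans)}")

    sig = de[de["significant"]]
    rows = []
    mrna_pairs = table.pairs[table.pairs["target_class"] == "mRNA"]
    for tid, grp in mrna_pairs.groupby("target_id"):
        mirs = [m for m in grp["mirna_id"] if m in sig.index]
        if not mirs:
            logger.warning("candidate %s: no significant regulating miRNA; dropped", tid)
            continue
        n_up = sum(sig.loc[m, "direction"] == "up" for m in mirs)
        n_down = len(mirs) - n_up
        if n_up == n_down:
            logger.warning("candidate %s: tied miRNA directions (%d up / %d down); dropped",
                           tid, n_up, n_down)
            continue
        predicted = "down" if n_up > n_down else "up"
        rows.append({"gene_id": tid, "direction": predicted,
                     "n_up_mirnas": n_up, "n_down_mirnas": n_down})
    out = pd.DataFrame(rows, columns=["gene_id", "direction", "n_up_mirnas", "n_down_mirnas"])
    return out.sort_values("gene_id").reset_index(drop=True)
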