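"""Reduced nearest-neighbour free-energy model for miRNA:UTR duplexes.

The stability of a candidate duplex is estimated as

    dG = dG_init + sum(stack terms over consecutive paired columns)
         + n_mismatch_columns * MISMATCH_PENALTY
         + n_gap_columns * GAP_PENALTY        [kcal/mol]

A column is *paired* when it holds a Watson-Crick or G:U wobble pair; a
stack term is added for every two adjacent paired columns, looked up in
the shipped nearest-neighbour table.  Watson-Crick stack values are the
standard unified RNA parameters; wobble-containing stacks carry
representative negative values (small or slightly positive for pure
wobble-on-wobble stacks).  There is no loop-entropy model: interior
mismatches and gaps contribute flat destabilisation penalties.  Lower dG
means a more stable duplex; hits must come in at or below the scheme's
``energy_threshold``.
"""

from __future__ import annotations

import logging

from .alignment import DuplexAlignment, pair_kind

logger = logging.getLogger(__name__)

INITIATION = 4.09          # duplex initiation, kcal/mol
MISMATCH_PENALTY = 0.8     # per interior mismatch column
GAP_PENALTY = 2.0          # per gap column

# Nearest-neighbour stacks, keyed "XY/WZ": 5'-X Y-3' on the UTR strand over
# 3'-W Z-5' on the miRNA strand (X pairs W, Y pairs Z).  Values kcal/mol.
# Watson-Crick block: unified RNA nearest-neighbour parameters.
_RAW_STACKS = {
    "AA/UU": -0.93, "AU/UA": -1.10, "UA/AU": -1.33,
    "CU/GA": -2.08, "CA/GU": -2.11, "GU/CA": -2.24,
    "GA/CU": -2.35, "CG/GC": -2.36, "GG/CC": -3.26, "GC/CG": -3.42,
    # wobble-containing stacks (representative values; one G:U pair)
    "AG/UU": -0.55, "AU/UG": -1.36, "CG/GU": -1.41, "CU/GG": -2.11,
    "GG/CU": -1.53, "GU/CG": -2.51, "UG/AU": -1.27, "UU/AG": -1.00,
    # two G:U pairs stacked: weak or destabilising
    "GU/UG": +0.47, "UG/GU": -0.50, "GG/UU": +0.30, "UU/GG": +0.30,
}


def _build_table() -> dict[str, float]:
    """Complete the table under strand-flip symmetry XY/WZ == ZW/YX."""
    table = dict(_RAW_STACKS)
    for key, val in list(_RAW_STACKS.items()):
        x, y = key[0], key[1]
        w, z = key[3], key[4]
        flipped = f"{z}{w}/{y}{x}"
        table.setdefault(flipped, val)
    return table


STACK_TABLE = _build_table()


def stack_energy(utr_pair: str, mirna_pair: str) -> float:
    """Stack term for adjacent paired columns (utr 5'->3', miRNA 3'->5')."""
    key = f"{utr_pair}/{mirna_pair}"
    try:
        return STACK_TABLE[key]
    except KeyError:  # pragma: no cover - only reachable with unpaired input
        raise ValueError(f"no stack entry for {key}; columns must be paired")


def duplex_free_energy(aln: DuplexAlignment,
                       table: dict[str, float] | None = None) -> float:
    """Free energy (kcal/mol) of one alignment under the reduced model.

    An alignment without a single paired column gets the initiation term
    only, with a warning (nothing hybridises).
    """
    table = table if table is not None else STACK_TABLE
    cols = aln.columns()
    if len(aln.mirna_aln) != len(aln.utr_aln):
        raise ValueError("aligned strings must have equal length")

    dg = INITIATION
    paired_flags = []
    for mb, ub in cols:
        if mb == "-" or ub == "-":
            paired_flags.append(False)
            dg += GAP_PENALTY
        elif pair_kind(mb, ub) == "mismatch":
            paired_flags.append(False)
            dg += MISMATCH_PENALTY
        else:
            paired_flags.append(True)

    n_paired = sum(paired_flags)
    if n_paired == 0:
        logger.warning("alignment %s/%s has no paired columns: dG = initiation only",
                       aln.mirna_id, aln.utr_id)
        return dg

    for k in range(len(cols) - 1):
        if paired_flags[k] and paired_flags[k + 1]:
            (m1, u1), (m2, u2) = cols[k], cols[k + 1]
            dg += table[f"{u1}{u2}/{m1}{m2}"]
    return dg


def annotate_energy(alignments: list[DuplexAlignment],
                    table: dict[str, float] | None = None) -> list[DuplexAlignment]:
    """Fill ``free_energy`` in place for a list of alignments."""
    for aln in alignments:
        aln.free_energy = duplex_free_energy(aln, table)
    return alignments
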