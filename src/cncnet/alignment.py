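"""Seeded Smith-Waterman alignment of miRNAs against 3'UTRs.

The aligner scores the antiparallel hybridisation of a miRNA (written
3'->5') over a UTR (5'->3'): A:U and G:C columns are matches, G:U is the
wobble pair (scored between match and mismatch), anything else is a
mismatch.  Gaps follow the affine model (opening costs more than
extending).  The seed region -- positions ``seed_start..seed_end`` counted
from the miRNA 5' end -- is special in three ways:

* substitution scores inside the seed are multiplied by ``seed_scale``;
* no gap may touch the seed: seed bases cannot be deleted and no
  insertion may sit between two seed bases;
* every emitted site must cover the entire seed.  This anchors sites the
  way the original heuristic does and is what makes "all non-overlapping
  sites above threshold" well defined (without it, any single
  complementary base would qualify at a low threshold).

The dynamic program is vectorised row-wise over the UTR, so a full
miRNA x UTR scan is a handful of numpy operations per miRNA base.
Non-overlapping sites are extracted best-first: after each site the
covered UTR positions are masked and the scan repeats.  Tie-breaking is
deterministic: highest score, then leftmost UTR end/start; in traceback,
pairing is preferred over a gap in the UTR, over a gap in the miRNA.
Adjacent gap columns of opposite type are disallowed (canonical
alignments only); the brute-force enumeration used in testing follows the
same rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

NEG = -1e18  # effectively -infinity for the DP

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_VALID_BASES = frozenset("ACGU")


def normalize_sequence(seq: str) -> str:
    """Uppercase, DNA->RNA (T->U); reject anything outside A/C/G/U/T."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid base(s) {sorted(bad)} in sequence {seq[:30]!r}")
    if not s:
        raise ValueError("empty sequence")
    return s


def pair_kind(mirna_base: str, utr_base: str) -> str:
    """'match' | 'wobble' | 'mismatch' for one alignment column."""
    p = (mirna_base, utr_base)
    if p in _WATSON_CRICK:
        return "match"
    if p in _WOBBLE:
        return "wobble"
    return "mismatch"


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters (defaults: the canonical heuristic set).

    ``seed_start``/``seed_end`` are 1-based positions from the miRNA 5'
    end; ``seed_scale`` multiplies substitution scores inside the seed;
    gaps are never allowed in the seed.  A site is emitted only if its
    score is >= ``score_threshold`` and its duplex free energy is <=
    ``energy_threshold`` (kcal/mol; more negative = more stable).
    """

    match_score: float = 5.0
    mismatch_score: float = -3.0
    wobble_score: float = 2.0
    gap_open_penalty: float = -9.0
    gap_extend_penalty: float = -4.0
    seed_start: int = 2
    seed_end: int = 8
    seed_scale: float = 4.0
    score_threshold: float = 140.0
    energy_threshold: float = -20.0

    def __post_init__(self) -> None:
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if not self.wobble_score > self.mismatch_score:
            raise ValueError("wobble_score must exceed mismatch_score")
        if self.gap_open_penalty > 0 or self.gap_extend_penalty > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.seed_start < 1 or self.seed_start >= self.seed_end:
            raise ValueError("need 1 <= seed_start < seed_end")
        if self.seed_scale < 1:
            raise ValueError("seed_scale must be >= 1")

    def substitution(self, mirna_base: str, utr_base: str) -> float:
        kind = pair_kind(mirna_base, utr_base)
        if kind == "match":
            return self.match_score
        if kind == "wobble":
            return self.wobble_score
        return self.mismatch_score


@dataclass
class DuplexAlignment:
    """One candidate binding site.

    ``mirna_aln`` is written 3'->5' (so it reads left-to-right under the
    UTR), ``utr_aln`` 5'->3'; both contain '-' for gaps and have equal
    length.  ``utr_start``/``utr_end`` are 1-based inclusive UTR
    coordinates of the site; ``mirna_start``/``mirna_end`` are the 1-based
    inclusive positions (from the miRNA 5' end) of the aligned miRNA
    segment.
    """

    mirna_id: str
    utr_id: str
    mirna_aln: str
    utr_aln: str
    utr_start: int
    utr_end: int
    score: float
    free_energy: float | None = None
    mirna_start: int = 1
    mirna_end: int = 0

    def columns(self) -> list[tuple[str, str]]:
        """(mirna_base_or_gap, utr_base_or_gap) per column."""
        return list(zip(self.mirna_aln, self.utr_aln))


def _seed_rows(scheme: ScoringScheme, mirna_len: int) -> tuple[int, int]:
    """Seed block in reversed (3'->5') 1-based row coordinates."""
    seed_end = min(scheme.seed_end, mirna_len)
    sa = mirna_len - seed_end + 1
    sb = mirna_len - scheme.seed_start + 1
    return sa, sb


def _dp_fill(mrev: str, utr: str, scheme: ScoringScheme,
             masked: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three affine-gap DP matrices row by row (vectorised in j).

    States per cell (i miRNA bases consumed in 3'->5' order, j UTR bases):
    M ends in a substitution column, X ends in a miRNA-base-vs-gap column
    (gap in UTR), Y ends in a UTR-base-vs-gap column (gap in miRNA).
    Fresh local starts are only allowed at rows <= sa and sites may only
    end at rows >= sb, which together force full seed coverage.
    """
    L, n = len(mrev), len(utr)
    sa, sb = _seed_rows(scheme, L)
    open_, ext = scheme.gap_open_penalty, scheme.gap_extend_penalty

    utr_arr = np.frombuffer(utr.encode(), dtype="S1")
    M = np.full((L + 1, n + 1), NEG)
    X = np.full((L + 1, n + 1), NEG)
    Y = np.full((L + 1, n + 1), NEG)

    # contiguous unmasked UTR segments (an insertion run may not cross a mask)
    seg_bounds = np.flatnonzero(masked) + 1  # 1-based masked positions

    for i in range(1, L + 1):
        base = mrev[i - 1]
        orig_pos = L - i + 1
        in_seed = scheme.seed_start <= orig_pos <= scheme.seed_end
        scale = scheme.seed_scale if in_seed else 1.0
        subs = np.full(n, scheme.mismatch_score)
        kinds_match = utr_arr == {"A": b"U", "U": b"A", "G": b"C", "C": b"G"}[base]
        subs[kinds_match] = scheme.match_score
        if base in "GU":
            wob = utr_arr == {"G": b"U", "U": b"G"}[base]
            subs[wob] = scheme.wobble_score
        subs *= scale
        subs[masked] = NEG

        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        start_opt = 0.0 if i <= sa else NEG
        M[i, 1:] = subs + np.maximum(prev_best[:-1], start_opt)
        np.maximum(M[i, 1:], NEG, out=M[i, 1:])  # keep masked cells pinned

        # X: delete miRNA base i (no UTR consumed); forbidden inside seed
        if not in_seed:
            X[i] = np.maximum(M[i - 1] + open_, X[i - 1] + ext)

        # Y: insertion between reversed rows i and i+1; forbidden when both
        # flanking miRNA positions are in the seed
        next_in_seed = (i < L) and (scheme.seed_start <= (L - i) <= scheme.seed_end)
        if not (in_seed and next_in_seed):
            # scan Y[i, j] = max(M[i, j-1] + open, Y[i, j-1] + ext) within
            # each unmasked segment, via a running-max trick
            row_m = M[i]
            y = Y[i]
            start = 1
            for stop in list(seg_bounds) + [n + 1]:
                if stop > start:
                    jj = np.arange(start, stop)
                    b = row_m[start - 1:stop - 1] + open_ - ext * jj
                    y[start:stop] = ext * jj + np.maximum.accumulate(b)
                start = stop + 1
            y[:1] = NEG
            if len(seg_bounds):
                y[seg_bounds] = NEG
            np.maximum(y, NEG, out=y)

    return M, X, Y


def _traceback(mrev: str, utr: str, scheme: ScoringScheme,
               M: np.ndarray, X: np.ndarray, Y: np.ndarray,
               i: int, j: int) -> tuple[str, str, int, int]:
    """Walk back from M[i, j]; returns (mirna_aln, utr_aln, utr_start0,
    mirna_row_start0) where the last entry is the 0-based first consumed
    reversed miRNA row."""
    open_, ext = scheme.gap_open_penalty, scheme.gap_extend_penalty
    L = len(mrev)
    sa, _ = _seed_rows(scheme, L)
    cols_m: list[str] = []
    cols_u: list[str] = []
    state = "M"

    def close(a, b):
        return np.isclose(a, b, rtol=1e-9, atol=1e-9)

    while True:
        if state == "M":
            cols_m.append(mrev[i - 1])
            cols_u.append(utr[j - 1])
            orig_pos = L - i + 1
            scale = scheme.seed_scale if scheme.seed_start <= orig_pos <= scheme.seed_end else 1.0
            sub = scheme.substitution(mrev[i - 1], utr[j - 1]) * scale
            rest = M[i, j] - sub
            row_consumed = i  # row of the column just emitted
            i, j = i - 1, j - 1
            # preference: pairing, then gap-in-UTR, then gap-in-miRNA, then start
            if close(rest, M[i, j]):
                state = "M"
            elif close(rest, X[i, j]):
                state = "X"
            elif close(rest, Y[i, j]):
                state = "Y"
            elif row_consumed <= sa and close(rest, 0.0):
                break
            else:  # pragma: no cover - guards numerical drift
                raise AssertionError("traceback lost: inconsistent DP matrices")
        elif state == "X":
            cols_m.append(mrev[i - 1])
            cols_u.append("-")
            val = X[i, j]
            i -= 1
            if close(val, M[i, j] + open_):
                state = "M"
            else:
                state = "X"
        else:  # Y
            cols_m.append("-")
            cols_u.append(utr[j - 1])
            val = Y[i, j]
            j -= 1
            if close(val, M[i, j] + open_):
                state = "M"
            else:
                state = "Y"
        if state == "M" and (i == 0 or j == 0):  # pragma: no cover
            raise AssertionError("traceback ran off the matrix")
    return "".join(reversed(cols_m)), "".join(reversed(cols_u)), j, i


def _best_site(mirna: str, utr: str, scheme: ScoringScheme,
               masked: np.ndarray, mirna_id: str,
               utr_id: str) -> DuplexAlignment | None:
    L, n = len(mirna), len(utr)
    mrev = mirna[::-1]
    sa, sb = _seed_rows(scheme, L)
    if sb - sa + 1 > n:
        return None
    M, X, Y = _dp_fill(mrev, utr, scheme, masked)
    region = M[sb:, :]
    best = region.max()
    if best <= NEG / 2:
        return None
    # deterministic pick: max score, then leftmost UTR end, then 5'-most end row
    cand = np.argwhere(np.isclose(region, best, rtol=0.0, atol=1e-9))
    j_end, i_end = min((int(j), int(i_rel) + sb) for i_rel, j in cand)
    m_aln, u_aln, j_start0, i_start0 = _traceback(mrev, utr, scheme, M, X, Y, i_end, j_end)
    return DuplexAlignment(
        mirna_id=mirna_id, utr_id=utr_id,
        mirna_aln=m_aln, utr_aln=u_aln,
        utr_start=j_start0 + 1, utr_end=j_end,
        score=float(best),
        mirna_start=L - i_end + 1, mirna_end=L - (i_start0 + 1) + 1,
    )


def sw_align_seeded(mirna: str, utr: str, scheme: ScoringScheme | None = None,
                    mirna_id: str = "miRNA", utr_id: str = "UTR",
                    max_sites: int | None = None) -> list[DuplexAlignment]:
    """All non-overlapping binding sites with score >= ``score_threshold``.

    Sites are found best-first: the optimal seed-covering local alignment
    is reported, its UTR footprint masked, and the scan repeated.  The
    returned list is ordered by descending score, then ascending UTR
    start.  A miRNA longer than the UTR simply yields no sites.

    Note: only the score threshold is applied here; the free-energy
    threshold is the business of :func:`cncnet.targets.predict_targets`.
    """
    scheme = scheme or ScoringScheme()
    mirna = normalize_sequence(mirna)
    utr = normalize_sequence(utr)
    if scheme.seed_start > len(mirna):
        raise ValueError("seed_start beyond miRNA length")
    masked = np.zeros(len(utr), dtype=bool)
    sites: list[DuplexAlignment] = []
    while True:
        aln = _best_site(mirna, utr, scheme, masked, mirna_id, utr_id)
        if aln is None or aln.score < scheme.score_threshold:
            break
        sites.append(aln)
        masked[aln.utr_start - 1:aln.utr_end] = True
        if max_sites is not None and len(sites) >= max_sites:
            break
    sites.sort(key=lambda a: (-a.score, a.utr_start))
    return sites


def alignment_has_seed_gap(aln: DuplexAlignment, scheme: ScoringScheme) -> bool:
    """True if any gap column touches the seed (diagnostic for tests)."""
    consumed = 0  # miRNA bases consumed, 3'->5'
    seed_cols = []
    for idx, (mb, ub) in enumerate(aln.columns()):
        if mb != "-":
            consumed += 1
            orig = aln.mirna_end - (consumed - 1)  # 5'-based miRNA position
            if scheme.seed_start <= orig <= scheme.seed_end:
                seed_cols.append(idx)
                if ub == "-":
                    return True
    if not seed_cols:
        return False
    lo, hi = min(seed_cols), max(seed_cols)
    return any("-" in (aln.mirna_aln[k], aln.utr_aln[k]) for k in range(lo, hi + 1))
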