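"""Independent reference implementations used only to check the package.

These deliberately share no code with cncnet: the aligner oracle is a
memoized recursion over explicit alignment moves, the hypergeometric
oracles use integer combinatorics / literal subset enumeration, and the
Welch oracle is the textbook formula.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

NEG_INF = float("-inf")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOB = {("G", "U"), ("U", "G")}


def oracle_best_score(mirna: str, utr: str, scheme) -> float | None:
    """Best seeded local-alignment score by exhaustive (memoized) recursion.

    Rules mirrored from the aligner's definition: antiparallel
    complementarity scoring with seed scaling; affine gaps (first gap
    column costs gap_open, each further gap_extend); no gap column may
    touch the seed and every alignment must cover the whole seed; no
    terminal gaps; no adjacent gap columns of opposite type.  Returns None
    when no valid alignment exists.
    """
    mr = mirna[::-1]
    L, n = len(mirna), len(utr)
    seed_end = min(scheme.seed_end, L)
    sa = L - seed_end + 1                 # reversed row of seed 3' edge
    sb = L - scheme.seed_start + 1        # reversed row of seed 5' edge

    def in_seed_row(row1: int) -> bool:   # 1-based reversed row
        orig = L - row1 + 1
        return scheme.seed_start <= orig <= seed_end

    def sub(i: int, j: int) -> float:     # 0-based indices into mr / utr
        pair = (mr[i], utr[j])
        if pair in _WC:
            s = scheme.match_score
        elif pair in _WOB:
            s = scheme.wobble_score
        else:
            s = scheme.mismatch_score
        if in_seed_row(i + 1):
            s *= scheme.seed_scale
        return s

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, state: str) -> float:
        """Best continuation score after consuming i rows / j UTR bases."""
        best = 0.0 if (state == "M" and i >= sb) else NEG_INF
        if i < L and j < n:
            cont = ext(i + 1, j + 1, "M")
            if cont > NEG_INF:
                best = max(best, sub(i, j) + cont)
        # delete miRNA row i+1 (gap in UTR); never in seed, never after Y
        if i < L and state != "Y" and not in_seed_row(i + 1):
            cost = scheme.gap_open_penalty if state != "X" else scheme.gap_extend_penalty
            cont = ext(i + 1, j, "X")
            if cont > NEG_INF:
                best = max(best, cost + cont)
        # insert utr[j] (gap in miRNA) between rows i and i+1; never between
        # two seed rows, never after X
        if j < n and state != "X":
            between_seed = (1 <= i < L and in_seed_row(i) and in_seed_row(i + 1))
            if not between_seed:
                cost = scheme.gap_open_penalty if state != "Y" else scheme.gap_extend_penalty
                cont = ext(i, j + 1, "Y")
                if cont > NEG_INF:
                    best = max(best, cost + cont)
        return best

    best = NEG_INF
    for i0 in range(min(sa, L)):          # first column row i0+1 <= sa
        for j0 in range(n):
            cont = ext(i0 + 1, j0 + 1, "M")
            if cont > NEG_INF:
                best = max(best, sub(i0, j0) + cont)
    ext.cache_clear()
    return None if best == NEG_INF else best


def hypergeom_tail_comb(k: int, m: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, m, n) via exact integer combinatorics."""
    denom = math.comb(N, n)
    num = sum(math.comb(m, i) * math.comb(N - m, n - i)
              for i in range(k, min(m, n) + 1))
    return num / denom


def hypergeom_tail_enumeration(k: int, m: int, n: int, N: int) -> float:
    """P(X >= k) by literally enumerating every size-n draw (tiny N only)."""
    marked = set(range(m))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def welch_oracle(x, y):
    """Textbook Welch statistic / Satterthwaite df / two-sided p for x - y."""
    from scipy import stats

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def random_scheme(rng, mirna_len: int):
    """A random valid scoring scheme fitting a miRNA of the given length."""
    from cncnet.alignment import ScoringScheme

    mismatch = float(rng.integers(-4, 0))
    match = float(rng.integers(int(mismatch) + 2, 7))
    wobble = float(rng.integers(int(mismatch) + 1, int(match) + 1))
    seed_start = int(rng.integers(1, min(2, mirna_len - 1) + 1))
    seed_end = int(rng.integers(seed_start + 1, max(seed_start + 2, mirna_len + 1)))
    return ScoringScheme(
        match_score=match, mismatch_score=mismatch, wobble_score=wobble,
        gap_open_penalty=float(rng.integers(-9, -4)),
        gap_extend_penalty=float(rng.integers(-4, 0)),
        seed_start=seed_start, seed_end=seed_end,
        seed_scale=float(rng.integers(1, 5)),
        score_threshold=-1e9, energy_threshold=1e9,
    )
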