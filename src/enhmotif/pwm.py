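"""Position weight matrix construction, scanning and motif comparison.

A count matrix from JASPAR is turned into a log-odds matrix (bits) against
a background base composition. Scanning reports only the maximally scoring
placement per sequence; any placement touching a masked base (lowercase or
N) is invalid. Motif-to-motif comparison follows the column-correlation
idea of TOMTOM in a deliberately simplified form: mean per-column Pearson
correlation of base frequencies over the best overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import BASES, IUPAC_SETS, EnhancerSequence, PositionCountMatrix, revcomp

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "MotifMatch",
    "counts_to_pwm",
    "scan_best_hit",
    "count_hits",
    "match_iupac",
    "compare_motifs",
    "DEFAULT_RELSCORE_THRESHOLD",
    "UNIFORM_BACKGROUND",
    "write_hits_tsv",
    "write_hits_bed",
]

#: Presence/absence cut-off on the relative score, the 80%-of-maximum
#: convention of common PWM scanners.
DEFAULT_RELSCORE_THRESHOLD = 0.8

UNIFORM_BACKGROUND = np.full(4, 0.25)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i  # uppercase only: masked (lowercase, N) stays -1


def encode(seq: str) -> np.ndarray:
    """Integer-encode a sequence: A,C,G,T -> 0..3; masked bases -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds scoring matrix in bits (rows A, C, G, T)."""

    motif_id: str
    log_odds: np.ndarray  # (4, w)
    background: np.ndarray  # (4,)
    pseudocount: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.motif_id,
            self.log_odds[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )

    def relative(self, score: float) -> float:
        """Rescale a raw score to [0, 1] between min and max attainable."""
        span = self.max_score - self.min_score
        if span == 0.0:  # flat matrix: every placement attains the maximum
            return 1.0
        return float((score - self.min_score) / span)


@dataclass(frozen=True)
class MotifHit:
    """The best-scoring placement of one motif in one sequence."""

    enhancer_id: str
    motif_id: str
    offset: int
    strand: str  # "+" or "-"
    score: float
    relative_score: float


@dataclass(frozen=True)
class MotifMatch:
    """Best alignment of a query motif against a target motif."""

    query_id: str
    target_id: str
    offset: int  # target start relative to query start, in columns
    orientation: str  # "same" or "revcomp"
    similarity: float  # mean per-column Pearson r over the overlap
    overlap: int


def counts_to_pwm(
    pcm: PositionCountMatrix,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Turn a position count matrix into a log2 odds matrix.

    The pseudocount is distributed across bases proportionally to the
    background, so a column of all-equal counts under a uniform background
    scores exactly 0 everywhere:

        log_odds[b, j] = log2( (c[b,j] + pc * bg[b]) / (sum_b c[b,j] + pc)
                               / bg[b] )
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError(f"background sums to {bg.sum()}, not 1")
    counts = pcm.counts
    col_tot = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (col_tot + pseudocount)
    log_odds = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(pcm.motif_id, log_odds, bg.copy(), pseudocount)


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every placement; placements touching a masked base get -inf."""
    w = log_odds.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    invalid = (windows < 0).any(axis=1)
    safe = np.where(windows < 0, 0, windows)
    scores = log_odds[safe, np.arange(w)].sum(axis=1)
    scores[invalid] = -np.inf
    return scores


def scan_best_hit(
    pwm: PositionWeightMatrix,
    seq: EnhancerSequence | str,
    strands: str = "both",
    enhancer_id: str | None = None,
) -> MotifHit | None:
    """Return the maximally scoring motif placement, or None if all masked.

    Ties are broken by the smallest offset, then the + strand. ``strands``
    is ``"both"`` or ``"+"``. Offsets are 0-based on the + strand.
    """
    if strands not in ("both", "+"):
        raise ValueError(f"strands must be '+' or 'both', got {strands!r}")
    if isinstance(seq, EnhancerSequence):
        name = seq.name
        s = seq.seq
    else:
        name = enhancer_id or ""
        s = seq
    if len(s) < pwm.width:
        raise ValueError(
            f"sequence {name!r} shorter ({len(s)}) than motif width {pwm.width}"
        )
    codes = encode(s)
    plus = _window_scores(codes, pwm.log_odds)
    if strands == "both":
        minus = _window_scores(codes, pwm.log_odds[::-1, ::-1])
    else:
        minus = np.full_like(plus, -np.inf)
    best = max(plus.max(), minus.max())
    if best == -np.inf:
        return None  # every placement overlaps a masked base
    # smallest offset wins; at equal offset the + strand wins. Scores within
    # 1e-9 bits count as tied so cross-strand ties are broken consistently
    # regardless of floating-point summation order.
    plus_idx = np.flatnonzero(plus >= best - 1e-9)
    minus_idx = np.flatnonzero(minus >= best - 1e-9)
    o_plus = plus_idx[0] if plus_idx.size else None
    o_minus = minus_idx[0] if minus_idx.size else None
    if o_minus is None or (o_plus is not None and o_plus <= o_minus):
        offset, strand = int(o_plus), "+"
    else:
        offset, strand = int(o_minus), "-"
    return MotifHit(name, pwm.motif_id, offset, strand, float(best), pwm.relative(best))


def count_hits(
    pwm: PositionWeightMatrix,
    seq: EnhancerSequence | str,
    threshold: float = DEFAULT_RELSCORE_THRESHOLD,
    strands: str = "both",
) -> int:
    """Number of placements whose relative score clears the threshold.

    Unlike :func:`scan_best_hit` this counts every qualifying placement on
    the requested strands; masked placements never count.
    """
    s = seq.seq if isinstance(seq, EnhancerSequence) else seq
    if len(s) < pwm.width:
        raise ValueError(f"sequence shorter than motif width {pwm.width}")
    cut = pwm.min_score + threshold * (pwm.max_score - pwm.min_score)
    codes = encode(s)
    n = int((_window_scores(codes, pwm.log_odds) >= cut).sum())
    if strands == "both":
        n += int((_window_scores(codes, pwm.log_odds[::-1, ::-1]) >= cut).sum())
    return n


def _iupac_row_match(pattern: str) -> list[frozenset]:
    sets = []
    for c in pattern.upper():
        if c not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC code {c!r} in pattern {pattern!r}")
        sets.append(frozenset(IUPAC_SETS[c]))
    return sets


def match_iupac(pattern: str, seq: str, strands: str = "both") -> list[tuple[int, str]]:
    """All exact degenerate matches of an IUPAC pattern in a sequence.

    Masked bases (lowercase or N) never match. Returns (offset, strand)
    pairs sorted by offset, + before - at equal offset. Offsets index the
    + strand; a - strand match means the pattern matches the reverse
    complement of ``seq[offset:offset+len(pattern)]``.
    """
    if strands not in ("both", "+"):
        raise ValueError(f"strands must be '+' or 'both', got {strands!r}")
    patterns = [(pattern, "+")]
    if strands == "both":
        rc = revcomp(pattern.upper())
        patterns.append((rc, "-"))
    hits: list[tuple[int, str]] = []
    k = len(pattern)
    for pat, strand in patterns:
        sets = _iupac_row_match(pat)
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if all(c in s for c, s in zip(window, sets)):
                hits.append((i, strand))
    hits.sort(key=lambda h: (h[0], h[1] != "+"))
    # a palindromic pattern matches both strands at one offset; keep both
    return hits


def write_hits_tsv(path, hits: list[MotifHit]) -> None:
    """Full-precision hit table (one row per best hit)."""
    with open(path, "w") as fh:
        fh.write("enhancer_id\tmotif_id\toffset\tstrand\tscore\trelative_score\n")
        for h in hits:
            fh.write(
                f"{h.enhancer_id}\t{h.motif_id}\t{h.offset}\t{h.strand}\t"
                f"{h.score!r}\t{h.relative_score!r}\n"
            )


def write_hits_bed(path, hits: list[MotifHit], width: int) -> None:
    """Hits as BED6 relative to each sequence; score = 1000 * relative score."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.enhancer_id}\t{h.offset}\t{h.offset + width}\t"
                f"{h.motif_id}\t{round(1000 * h.relative_score)}\t{h.strand}\n"
            )


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two 4-vectors; 0 when either is constant."""
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        return 0.0
    return float((da @ db) / denom)


def compare_motifs(
    query: PositionCountMatrix,
    target: PositionCountMatrix,
    min_overlap: int = 4,
) -> MotifMatch:
    """Best ungapped alignment of two count matrices by column correlation.

    Every offset with at least ``min_overlap`` aligned columns is scored in
    both target orientations; the similarity is the mean per-column Pearson
    correlation of base-frequency vectors. Ties go to the smaller |offset|,
    then the same orientation.
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    if query.width < min_overlap or target.width < min_overlap:
        raise ValueError(
            f"overlap {min_overlap} impossible for widths "
            f"{query.width} and {target.width}"
        )
    fq = query.frequencies()
    candidates: list[MotifMatch] = []
    for orientation, tgt in (
        ("same", target),
        ("revcomp", target.reverse_complement()),
    ):
        ft = tgt.frequencies()
        wq, wt = fq.shape[1], ft.shape[1]
        for offset in range(-(wt - min_overlap), wq - min_overlap + 1):
            q_lo, q_hi = max(0, offset), min(wq, offset + wt)
            overlap = q_hi - q_lo
            if overlap < min_overlap:
                continue
            rs = [
                _column_correlation(fq[:, j], ft[:, j - offset])
                for j in range(q_lo, q_hi)
            ]
            candidates.append(
                MotifMatch(
                    query.motif_id, target.motif_id, offset, orientation,
                    float(np.mean(rs)), overlap,
                )
            )
    candidates.sort(
        key=lambda m: (-m.similarity, abs(m.offset), m.orientation != "same")
    )
    return candidates[0]
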