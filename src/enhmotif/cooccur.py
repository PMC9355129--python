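"""Co-motif discovery in the flanks of an anchor motif.

The anchor (e.g. the TCF/LEF 5'-CTTTGT-3' word) is located on the + strand
only; fixed-width windows immediately left and right of each occurrence are
collected, and short words enriched in one window set versus another are
found by exact-word Fisher testing with greedy sequence removal — a
deliberately simplified, deterministic stand-in for DREME's generalized
IUPAC search. Discovered words are then mapped back to a PWM library by
column correlation.

Word counting is per window (a word counts once per window, on either
strand) and words are collapsed with their reverse complements, so TTGGCA
and TGCCAA are one candidate. When no contrast set is supplied, the
negative set defaults to dinucleotide-shuffled copies of the positive
windows, preserving the local dinucleotide composition the background
model assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._types import IUPAC_SETS, EnhancerSequence, PositionCountMatrix, revcomp
from .pwm import MotifMatch, compare_motifs, match_iupac

log = logging.getLogger(__name__)

__all__ = [
    "FlankWindow",
    "FlankWindowSet",
    "WordMotif",
    "extract_flanks",
    "dinucleotide_shuffle",
    "shuffled_control",
    "discover_words",
    "word_to_pcm",
    "words_to_known_motifs",
]


@dataclass(frozen=True)
class FlankWindow:
    enhancer_id: str
    side: str  # "left" or "right"
    seq: str  # reported on the + strand


@dataclass
class FlankWindowSet:
    anchor_pattern: str
    half_width: int
    windows: list[FlankWindow] = field(default_factory=list)
    source_group: str = "pooled"

    def __len__(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class WordMotif:
    """An exact word enriched in positive versus negative flank windows."""

    word: str  # canonical orientation (lexicographic min of word/revcomp)
    pos_count: int
    pos_total: int
    neg_count: int
    neg_total: int
    p: float  # one-sided Fisher exact (hypergeometric upper tail)
    e_value: float  # p x number of candidate words examined


def extract_flanks(
    seqs: list[EnhancerSequence],
    anchor: str,
    half_width: int = 15,
    source_group: str = "pooled",
) -> FlankWindowSet:
    """Windows of ``half_width`` bp left and right of each + strand anchor.

    The anchor occurrence itself is excluded; windows are truncated at
    sequence boundaries and empty ones dropped. Masked bases are retained
    in the windows (word counting skips them later).
    """
    out = FlankWindowSet(anchor, half_width, source_group=source_group)
    k = len(anchor)
    n_anchors = 0
    for s in seqs:
        for offset, _strand in match_iupac(anchor, s.seq, strands="+"):
            n_anchors += 1
            left = s.seq[max(0, offset - half_width) : offset]
            right = s.seq[offset + k : offset + k + half_width]
            if left:
                out.windows.append(FlankWindow(s.name, "left", left))
            if right:
                out.windows.append(FlankWindow(s.name, "right", right))
    if n_anchors == 0:
        log.warning("no + strand occurrences of anchor %r in %d sequences",
                    anchor, len(seqs))
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erikson style: pick a random last out-edge per symbol such
    that the last-edge graph reaches the terminal symbol, shuffle the
    remaining edges, and walk the Eulerian path.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last_char = seq[-1]

    def reaches_terminal(last_edge: dict[str, str]) -> bool:
        for v in vertices:
            if v == last_char:
                continue
            cur, steps = v, 0
            while cur != last_char and cur in last_edge and steps <= len(vertices):
                cur = last_edge[cur]
                steps += 1
            if cur != last_char:
                return False
        return True

    for _ in range(1000):
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != last_char
        }
        if reaches_terminal(last_edge):
            break
    else:  # pragma: no cover - degenerate composition
        return seq
    shuffled: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v != last_char:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last_char:
            rest.append(last_edge[v])
        shuffled[v] = rest
    out = [seq[0]]
    counters = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffled_control(pos: FlankWindowSet, seed: int = 0) -> FlankWindowSet:
    """Dinucleotide-shuffled copies of the positive windows (seeded)."""
    rng = np.random.default_rng(seed)
    ctrl = FlankWindowSet(pos.anchor_pattern, pos.half_width,
                          source_group="shuffled")
    for w in pos.windows:
        ctrl.windows.append(
            FlankWindow(w.enhancer_id, w.side, dinucleotide_shuffle(w.seq, rng))
        )
    return ctrl


def write_windows_fasta(path, windows: FlankWindowSet) -> None:
    """Export flank windows as FASTA for inspection."""
    from .io import write_fasta

    write_fasta(
        path,
        [
            (f"{w.enhancer_id}|{w.side}|{i}", w.seq)
            for i, w in enumerate(windows.windows)
        ],
    )


def _canonical_words(seq: str, k_min: int, k_max: int) -> set[str]:
    """Canonical (revcomp-collapsed) k-mers of a window; masked bases break words."""
    words: set[str] = set()
    n = len(seq)
    for k in range(k_min, k_max + 1):
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue  # touches a masked base
            words.add(min(w, revcomp(w)))
    return words


def discover_words(
    pos: FlankWindowSet,
    neg: FlankWindowSet | None = None,
    k_min: int = 4,
    k_max: int = 8,
    e_threshold: float = 0.05,
    max_motifs: int = 10,
    seed: int = 0,
) -> list[WordMotif]:
    """Greedy exact-word enrichment of positive versus negative windows.

    Candidates are all revcomp-collapsed words of length k_min..k_max seen
    in at least one positive window. Each is Fisher-tested (one-sided) on
    per-window presence; the E-value multiplies the p-value by the number
    of candidates examined in the first round. The best word is reported,
    windows containing it are removed from both sets, and the search
    repeats until the best E-value exceeds ``e_threshold`` or
    ``max_motifs`` words are reported.
    """
    if not 4 <= k_min <= k_max <= 8:
        raise ValueError("need 4 <= k_min <= k_max <= 8")
    if len(pos) == 0:
        raise ValueError("positive window set is empty")
    if neg is None:
        neg = shuffled_control(pos, seed=seed)
    if len(neg) == 0:
        raise ValueError("negative window set is empty")
    pos_words = [_canonical_words(w.seq, k_min, k_max) for w in pos.windows]
    neg_words = [_canonical_words(w.seq, k_min, k_max) for w in neg.windows]
    if not any(pos_words):
        raise ValueError(f"all positive windows are shorter than {k_min} "
                         "or fully masked")
    # inverted index: word -> indices of windows containing it
    pos_index: dict[str, list[int]] = {}
    neg_index: dict[str, list[int]] = {}
    for i, words in enumerate(pos_words):
        for w in words:
            pos_index.setdefault(w, []).append(i)
    for i, words in enumerate(neg_words):
        for w in words:
            neg_index.setdefault(w, []).append(i)
    candidates = sorted(pos_index)
    n_candidates = len(candidates)
    pos_arr = {w: np.asarray(ix) for w, ix in pos_index.items()}
    neg_arr = {w: np.asarray(neg_index.get(w, [])) for w in candidates}

    results: list[WordMotif] = []
    alive_pos = np.ones(len(pos_words), dtype=bool)
    alive_neg = np.ones(len(neg_words), dtype=bool)
    while len(results) < max_motifs and alive_pos.any():
        n_pos = int(alive_pos.sum())
        n_neg = int(alive_neg.sum())
        a = np.array([alive_pos[pos_arr[w]].sum() for w in candidates])
        b = np.array(
            [alive_neg[neg_arr[w]].sum() if neg_arr[w].size else 0
             for w in candidates]
        )
        live = a > 0  # word still present in some remaining positive window
        if not live.any():
            break
        # one-sided Fisher exact == hypergeometric upper tail on the 2x2 margin
        pvals = stats.hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos)
        evals = np.where(live, pvals * n_candidates, np.inf)
        order = sorted(
            np.flatnonzero(live), key=lambda i: (evals[i], candidates[i])
        )
        best = order[0]
        if evals[best] > e_threshold:
            break
        word = candidates[best]
        results.append(
            WordMotif(word, int(a[best]), n_pos, int(b[best]), n_neg,
                      float(pvals[best]), float(evals[best]))
        )
        alive_pos[pos_arr[word]] = False
        if neg_arr[word].size:
            alive_neg[neg_arr[word]] = False
    return results


def word_to_pcm(word: str, motif_id: str | None = None) -> PositionCountMatrix:
    """Degenerate count matrix for an IUPAC word (matched bases share weight 1)."""
    cols = []
    for c in word.upper():
        if c not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC code {c!r} in word {word!r}")
        matched = IUPAC_SETS[c]
        cols.append([1.0 / len(matched) if b in matched else 0.0 for b in "ACGT"])
    counts = np.array(cols, dtype=float).T
    return PositionCountMatrix(motif_id or f"word:{word}", counts)


def words_to_known_motifs(
    words: list[WordMotif],
    library: list[PositionCountMatrix],
    min_overlap: int = 4,
) -> list[tuple[WordMotif, MotifMatch]]:
    """Best library match for each discovered word, by column correlation."""
    if not library:
        raise ValueError("motif library is empty")
    out: list[tuple[WordMotif, MotifMatch]] = []
    for wm in words:
        if len(wm.word) < min_overlap:
            log.info("word %s shorter than min_overlap %d; skipped",
                     wm.word, min_overlap)
            continue
        query = word_to_pcm(wm.word)
        matches = [compare_motifs(query, t, min_overlap) for t in library]
        matches.sort(key=lambda m: (-m.similarity, m.target_id))
        out.append((wm, matches[0]))
    return out
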