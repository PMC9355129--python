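"""PWM construction, best-hit scanning, IUPAC matching, motif comparison.

The scanning and comparison operations are checked against exhaustive
brute-force oracles implemented here with plain Python string handling.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhmotif import (
    PositionCountMatrix,
    compare_motifs,
    counts_to_pwm,
    match_iupac,
    revcomp,
    scan_best_hit,
)
from enhmotif.pwm import count_hits
from enhmotif._types import IUPAC_SETS

from conftest import make_enhancer

BASES = "ACGT"


def random_pcm(rng, width=None, motif_id="M"):
    w = int(width if width is not None else rng.integers(4, 11))
    counts = rng.integers(0, 50, size=(4, w)).astype(float)
    counts[rng.integers(0, 4), :] += 1  # no zero-sum column
    return PositionCountMatrix(motif_id, counts)


def brute_force_best(pwm, seq, tol=1e-9):
    """Oracle: score every offset and strand with explicit loops.

    Scores within ``tol`` of the maximum count as tied; ties go to the
    smallest offset, then the + strand.
    """
    w = pwm.width
    scored = []
    for strand in ("+", "-"):
        for off in range(len(seq) - w + 1):
            window = seq[off : off + w]
            if any(c.islower() or c == "N" for c in window):
                continue
            if strand == "-":
                window = revcomp(window)
            score = sum(
                pwm.log_odds[BASES.index(c), j] for j, c in enumerate(window)
            )
            scored.append((score, off, strand))
    if not scored:
        return None
    best_score = max(s for s, _, _ in scored)
    ties = [(off, strand, s) for s, off, strand in scored if s >= best_score - tol]
    ties.sort(key=lambda t: (t[0], t[1] != "+"))
    return ties[0]


class TestCountsToPwm:
    def test_uniform_counts_uniform_background_all_zero(self):
        pcm = PositionCountMatrix("U", np.full((4, 5), 3.0))
        pwm = counts_to_pwm(pcm)
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)
        assert pwm.max_score == pwm.min_score == 0.0

    def test_single_base_column_log_odds_value(self):
        counts = np.zeros((4, 4))
        counts[0, :] = 10.0  # all-A columns
        pwm = counts_to_pwm(PositionCountMatrix("A4", counts), pseudocount=4.0)
        # pseudocount 4 spread uniformly adds 1 per cell: (10+1)/(10+4)
        expected = np.log2((11.0 / 14.0) / 0.25)
        np.testing.assert_allclose(pwm.log_odds[0, :], expected)

    def test_probability_reconstruction(self, rng):
        for _ in range(20):
            bg = rng.dirichlet([5, 5, 5, 5])
            pwm = counts_to_pwm(random_pcm(rng), pseudocount=float(rng.uniform(0.1, 5)),
                                background=bg)
            recon = (2.0 ** pwm.log_odds * bg[:, None]).sum(axis=0)
            np.testing.assert_allclose(recon, 1.0, atol=1e-10)

    def test_invalid_background_rejected(self, rng):
        pcm = random_pcm(rng)
        with pytest.raises(ValueError, match="sums"):
            counts_to_pwm(pcm, background=np.array([0.3, 0.3, 0.3, 0.3]))
        with pytest.raises(ValueError, match="pseudocount"):
            counts_to_pwm(pcm, pseudocount=0.0)

    def test_max_min_are_column_extrema_sums(self, rng):
        pwm = counts_to_pwm(random_pcm(rng))
        assert pwm.max_score == pytest.approx(pwm.log_odds.max(axis=0).sum())
        assert pwm.min_score == pytest.approx(pwm.log_odds.min(axis=0).sum())


class TestScanBestHit:
    def test_consensus_embedding_is_perfect_hit(self, rng, library_by_id):
        pwm = counts_to_pwm(library_by_id["NFIX_syn"])
        seq = "A" * 20 + pwm.consensus() + "A" * 20
        hit = scan_best_hit(pwm, make_enhancer(seq))
        assert hit.offset == 20 and hit.strand == "+"
        assert hit.relative_score == pytest.approx(1.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(60):
            pwm = counts_to_pwm(random_pcm(rng))
            chars = list(rng.choice(list("ACGT"), size=60))
            # sprinkle soft-masked stretches
            if rng.random() < 0.7:
                i = int(rng.integers(0, 50))
                run = int(rng.integers(2, 10))
                chars[i : i + run] = [c.lower() for c in chars[i : i + run]]
            seq = "".join(chars)
            oracle = brute_force_best(pwm, seq)
            hit = scan_best_hit(pwm, make_enhancer(seq))
            if oracle is None:
                assert hit is None
            else:
                assert (hit.offset, hit.strand) == oracle[:2]
                assert hit.score == pytest.approx(oracle[2])

    def test_fully_masked_returns_sentinel(self, rng, library_by_id):
        pwm = counts_to_pwm(library_by_id["LEF1_syn"])
        assert scan_best_hit(pwm, make_enhancer("acgtacgtacgt")) is None

    def test_short_sequence_rejected(self, library_by_id):
        pwm = counts_to_pwm(library_by_id["SOX2_syn"])
        with pytest.raises(ValueError, match="shorter"):
            scan_best_hit(pwm, make_enhancer("ACGT"))

    def test_revcomp_invariance_of_score(self, rng):
        for _ in range(20):
            pwm = counts_to_pwm(random_pcm(rng))
            seq = "".join(rng.choice(list("ACGT"), size=50))
            h1 = scan_best_hit(pwm, make_enhancer(seq))
            h2 = scan_best_hit(pwm, make_enhancer(revcomp(seq)))
            assert h1.score == pytest.approx(h2.score)

    def test_relative_score_in_unit_interval(self, rng):
        for _ in range(20):
            bg = rng.dirichlet([2, 2, 2, 2]) * 0.8 + 0.05
            bg = bg / bg.sum()
            pwm = counts_to_pwm(random_pcm(rng), background=bg)
            seq = "".join(rng.choice(list("ACGT"), size=40))
            hit = scan_best_hit(pwm, make_enhancer(seq))
            assert 0.0 <= hit.relative_score <= 1.0

    def test_count_hits_counts_all_clearing_placements(self, library_by_id):
        pwm = counts_to_pwm(library_by_id["NFIX_syn"])
        word = pwm.consensus()
        seq = "A" * 10 + word + "A" * 10 + revcomp(word) + "A" * 10
        assert count_hits(pwm, seq, threshold=0.99) == 2
        assert count_hits(pwm, seq, threshold=0.99, strands="+") == 1


def expand_iupac(pattern):
    words = [""]
    for c in pattern:
        words = [w + b for w in words for b in IUPAC_SETS[c]]
    return words


class TestMatchIupac:
    def test_wre_variant_matches_w_code(self):
        # the degenerate TCF/LEF response element CTTTGWW
        assert match_iupac("CTTTGWW", "ACTTTGTTA", strands="+") == [(1, "+")]

    def test_all_n_matches_everywhere(self):
        assert [o for o, _ in match_iupac("NNNN", "ACGTAC", strands="+")] == [0, 1, 2]

    def test_masked_bases_never_match(self):
        assert match_iupac("ACGT", "aCGTACGT", strands="+") == [(4, "+")]

    def test_illegal_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            match_iupac("ACXG", "ACGTACGT")

    def test_matches_enumeration_oracle(self, rng):
        codes = list(IUPAC_SETS)
        for _ in range(30):
            pattern = "".join(rng.choice(codes, size=int(rng.integers(4, 7))))
            seq = "".join(rng.choice(list("ACGT"), size=60))
            found = set(match_iupac(pattern, seq))
            oracle = set()
            for word in expand_iupac(pattern):
                for variant, strand in ((word, "+"), (revcomp(word), "-")):
                    start = 0
                    while (i := seq.find(variant, start)) != -1:
                        oracle.add((i, strand))
                        start = i + 1
            assert found == oracle


class TestCompareMotifs:
    def test_self_comparison_identity(self, rng):
        pcm = random_pcm(rng, width=8)
        m = compare_motifs(pcm, pcm)
        assert (m.offset, m.orientation) == (0, "same")
        assert m.similarity == pytest.approx(1.0)

    def test_reverse_complement_detected(self, rng):
        pcm = random_pcm(rng, width=7)
        m = compare_motifs(pcm, pcm.reverse_complement())
        assert m.orientation == "revcomp"
        assert m.similarity == pytest.approx(1.0)

    def test_impossible_overlap_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_motifs(random_pcm(rng, width=4), random_pcm(rng, width=4),
                           min_overlap=5)

    def test_matches_exhaustive_oracle(self, rng):
        def oracle(q, t, min_overlap):
            fq = q.frequencies()
            best = None
            for orientation, tgt in (("same", t), ("revcomp", t.reverse_complement())):
                ft = tgt.frequencies()
                wq, wt = fq.shape[1], ft.shape[1]
                for off in range(-wt + min_overlap, wq - min_overlap + 1):
                    cols = [
                        (j, j - off)
                        for j in range(max(0, off), min(wq, off + wt))
                    ]
                    if len(cols) < min_overlap:
                        continue
                    rs = []
                    for jq, jt in cols:
                        a, b = fq[:, jq], ft[:, jt]
                        if np.std(a) == 0 or np.std(b) == 0:
                            rs.append(0.0)
                        else:
                            rs.append(np.corrcoef(a, b)[0, 1])
                    sim = float(np.mean(rs))
                    key = (-sim, abs(off), orientation != "same")
                    if best is None or key < best[0]:
                        best = (key, off, orientation, sim)
            return best[1:]

        for _ in range(25):
            q = random_pcm(rng, width=int(rng.integers(6, 11)), motif_id="q")
            t = random_pcm(rng, width=int(rng.integers(6, 11)), motif_id="t")
            m = compare_motifs(q, t, min_overlap=4)
            off, orient, sim = oracle(q, t, 4)
            assert (m.offset, m.orientation) == (off, orient)
            assert m.similarity == pytest.approx(sim)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=10, max_size=80), st.integers(0, 2**31 - 1))
def test_consensus_scan_agrees_with_iupac_match(seq, seed):
    """Where the consensus is the unique argmax word, the best + strand hit
    of the PWM sits at an offset where the consensus literally occurs."""
    rng = np.random.default_rng(seed)
    pcm = random_pcm(rng, width=5)
    pwm = counts_to_pwm(pcm)
    consensus = pwm.consensus()
    full = seq + consensus  # guarantee at least one occurrence
    hit = scan_best_hit(pwm, make_enhancer(full), strands="+")
    occurrences = [o for o, _ in match_iupac(consensus, full, strands="+")]
    # unique argmax per column means no other word can reach max_score
    if all(
        sorted(col)[-1] > sorted(col)[-2] for col in pwm.log_odds.T
    ) and hit.score == pytest.approx(pwm.max_score):
        assert hit.offset in occurrences
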