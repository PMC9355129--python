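"""Flank controls, bootstrap enrichment and positional bias."""

import numpy as np
import pytest

from enhmotif import (
    EnhancerSequence,
    GenomicInterval,
    bootstrap_enrichment,
    counts_to_pwm,
    group_differential_enrichment,
    make_flank_controls,
    positional_bias,
    scan_best_hit,
)
from enhmotif.pwm import MotifHit
from enhmotif.synthetic import random_sequences

from conftest import make_enhancer, plant


def _on_contig(contig, start, end, name, group="Q"):
    return EnhancerSequence(
        GenomicInterval("c1", start, end, name, group), contig[start:end]
    )


class TestFlankControls:
    def test_adjacent_length_matched(self, rng):
        contig = "".join(rng.choice(list("ACGT"), size=1000))
        enh = _on_contig(contig, 100, 200, "e1")
        controls = make_flank_controls([enh], {"c1": contig})
        coords = {(c.interval.start, c.interval.end) for c in controls}
        assert coords == {(0, 100), (200, 300)}
        assert all(c.group == "Q" for c in controls)
        assert all(len(c.seq) == 100 for c in controls)

    def test_contig_start_keeps_downstream_only(self, rng):
        contig = "".join(rng.choice(list("ACGT"), size=300))
        enh = _on_contig(contig, 0, 100, "e1")
        controls = make_flank_controls([enh], {"c1": contig})
        assert [(c.interval.start, c.interval.end) for c in controls] == [(100, 200)]

    def test_controls_disjoint_from_all_enhancers(self, rng):
        contig = "".join(rng.choice(list("ACGT"), size=20_000))
        starts = np.sort(rng.choice(np.arange(100, 19_000, 250), size=30, replace=False))
        enhancers = [
            _on_contig(contig, int(s), int(s) + int(rng.integers(40, 120)), f"e{i}")
            for i, s in enumerate(starts)
        ]
        controls = make_flank_controls(enhancers, {"c1": contig})
        for c in controls:
            # length matched to its parent enhancer
            parent = c.interval.name.rsplit("__", 1)[0]
            (src,) = [e for e in enhancers if e.name == parent]
            assert c.interval.length == src.interval.length
            # interval-intersection oracle: no overlap with any enhancer
            for e in enhancers:
                assert c.interval.end <= e.interval.start or e.interval.end <= c.interval.start


class TestBootstrapEnrichment:
    def test_saturated_enrichment_reaches_p_floor(self, library_by_id):
        pwm = counts_to_pwm(library_by_id["SOX2_syn"])
        word = pwm.consensus()
        enh = [make_enhancer(plant("A" * 60, word, 20), f"e{i}") for i in range(200)]
        ctrl = [make_enhancer("A" * 60, f"c{i}") for i in range(200)]
        res = bootstrap_enrichment(pwm, enh, ctrl, B=999, seed=3)
        assert res.statistic == pytest.approx(1.0)
        assert res.bootstrap_p == pytest.approx(1.0 / 1000.0)

    def test_self_comparison_statistic_zero(self, background_pool):
        seqs = [make_enhancer(s, f"e{i}") for i, s in enumerate(background_pool[:50])]
        from enhmotif import demo_motif_library

        pwm = counts_to_pwm(demo_motif_library()[0])
        res = bootstrap_enrichment(pwm, seqs, seqs, B=199, seed=1)
        assert res.statistic == 0.0

    def test_parameter_validation(self, library_by_id, background_pool):
        pwm = counts_to_pwm(library_by_id["LEF1_syn"])
        seqs = [make_enhancer(background_pool[0])]
        with pytest.raises(ValueError, match="B must"):
            bootstrap_enrichment(pwm, seqs, seqs, B=50)
        with pytest.raises(ValueError, match="non-empty"):
            bootstrap_enrichment(pwm, [], seqs)
        with pytest.raises(ValueError, match="threshold"):
            bootstrap_enrichment(pwm, seqs, seqs, threshold=0.0)

    def test_seed_determinism(self, library_by_id, background_pool):
        pwm = counts_to_pwm(library_by_id["SOX2_syn"])
        enh = [make_enhancer(s, f"e{i}") for i, s in enumerate(background_pool[:40])]
        ctrl = [make_enhancer(s, f"c{i}") for i, s in enumerate(background_pool[40:120])]
        r1 = bootstrap_enrichment(pwm, enh, ctrl, B=199, seed=11)
        r2 = bootstrap_enrichment(pwm, enh, ctrl, B=199, seed=11)
        assert r1 == r2

    def test_p_within_theoretical_bounds(self, library_by_id, background_pool):
        pwm = counts_to_pwm(library_by_id["SOX2_syn"])
        enh = [make_enhancer(s, f"e{i}") for i, s in enumerate(background_pool[:30])]
        ctrl = [make_enhancer(s, f"c{i}") for i, s in enumerate(background_pool[30:90])]
        res = bootstrap_enrichment(pwm, enh, ctrl, B=199, seed=5)
        assert 1.0 / 200.0 <= res.bootstrap_p <= 1.0
        assert -1.0 <= res.statistic <= 1.0

    def test_spike_monotonicity_in_p(self, library_by_id):
        """Raising the planted rate never raises the median bootstrap p."""
        pwm = counts_to_pwm(library_by_id["SOX2_syn"])
        word = pwm.consensus()
        medians = []
        for rate in (0.0, 0.3, 0.8):
            ps = []
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                seqs = random_sequences(rng, 80, 120)
                enh = [
                    make_enhancer(
                        plant(s, word, int(rng.integers(0, 120 - len(word))))
                        if rng.random() < rate else s,
                        f"e{i}",
                    )
                    for i, s in enumerate(seqs[:40])
                ]
                ctrl = [make_enhancer(s, f"c{i}") for i, s in enumerate(seqs[40:])]
                ps.append(bootstrap_enrichment(pwm, enh, ctrl, B=199, seed=seed).bootstrap_p)
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]


class TestGroupDifferential:
    def test_identical_groups_statistic_zero(self, library_by_id, background_pool):
        pwm = counts_to_pwm(library_by_id["NFIX_syn"])
        seqs = [make_enhancer(s, f"e{i}") for i, s in enumerate(background_pool[:30])]
        res = group_differential_enrichment(
            pwm, {"Q": seqs, "A": list(seqs)}, B=199, seed=2
        )
        assert res[("Q", "A")].statistic == 0.0
        assert res[("A", "Q")].statistic == 0.0

    def test_spiked_group_detected(self, library_by_id):
        pwm = counts_to_pwm(library_by_id["SOX2_syn"])
        word = pwm.consensus()
        rng = np.random.default_rng(42)
        seqs = random_sequences(rng, 200, 150)
        q = [
            make_enhancer(
                plant(s, word, int(rng.integers(0, 150 - len(word))))
                if rng.random() < 0.4 else s,
                f"q{i}", "Q",
            )
            for i, s in enumerate(seqs[:100])
        ]
        a = [
            make_enhancer(
                plant(s, word, int(rng.integers(0, 150 - len(word))))
                if rng.random() < 0.05 else s,
                f"a{i}", "A",
            )
            for i, s in enumerate(seqs[100:])
        ]
        res = group_differential_enrichment(pwm, {"Q": q, "A": a}, B=499, seed=7)
        assert res[("Q", "A")].statistic > 0
        assert res[("Q", "A")].bootstrap_p < 0.05
        assert res[("A", "Q")].bootstrap_p > 0.5

    def test_empty_group_rejected(self, library_by_id, background_pool):
        pwm = counts_to_pwm(library_by_id["LEF1_syn"])
        seqs = [make_enhancer(background_pool[0])]
        with pytest.raises(ValueError, match="empty"):
            group_differential_enrichment(pwm, {"Q": seqs, "A": []})


class TestPositionalBias:
    @staticmethod
    def _hits(offsets, length=100):
        return (
            [MotifHit(f"e{i}", "M", off, "+", 1.0, 1.0) for i, off in enumerate(offsets)],
            {f"e{i}": length for i in range(len(offsets))},
        )

    def test_all_central_hits_extreme_tail(self):
        hits, lengths = self._hits([50] * 100)
        res = positional_bias(hits, lengths, central_window_fraction=0.5)
        assert res.central_fraction == 1.0
        assert res.p == pytest.approx(0.5**100, rel=1e-9)

    def test_uniform_hits_not_significant(self, rng):
        offs = rng.integers(0, 100, size=200)
        hits, lengths = self._hits(list(offs))
        res = positional_bias(hits, lengths, central_window_fraction=0.5)
        assert res.p > 0.01 or res.central_fraction < 0.6

    def test_degenerate_inputs_rejected(self):
        hits, lengths = self._hits([10])
        with pytest.raises(ValueError, match="fraction"):
            positional_bias(hits, lengths, central_window_fraction=1.0)
        with pytest.raises(ValueError, match="hits"):
            positional_bias([], {}, central_window_fraction=0.5)
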