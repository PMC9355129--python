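"""Self-contained statistical benchmarks of the pipeline's operating
characteristics on synthetic data.

Each routine simulates its own inputs under a stated condition (null, a
planted spike, a known odds ratio or decay rate), runs the corresponding
pipeline operation, and returns the measured rate or error. They exist so
that calibration and power claims about the methods are reproducible
numbers computed by the package itself, not assertions in prose.

Simulation sizes are chosen to resolve the quantities of interest on a
single CPU in minutes: 200-bp sequences, hundreds of sequences per set,
and an 8-bp scanning motif whose chance presence rate at the 0.8
relative-score cut is far from saturation at that length (short 6-bp
words clear the cut somewhere in almost any long sequence, which is why
the count statistic exists; see the methods note).
"""

from __future__ import annotations

import numpy as np

from .assays import DecaySeries, GelLane, fit_half_life, percent_exon_retention
from .cooccur import FlankWindow, FlankWindowSet, discover_words
from .enrichment import bootstrap_enrichment
from .linkage import build_contingency, chi_squared_test
from .pwm import PositionWeightMatrix, counts_to_pwm
from .synthetic import (
    SyntheticConfig,
    demo_motif_library,
    gen_de_table,
    random_sequences,
)
from ._types import EnhancerSequence, GenomicInterval, revcomp

__all__ = [
    "benchmark_pwm",
    "null_calibration",
    "enrichment_power",
    "comotif_recovery",
    "contingency_rates",
    "half_life_recovery",
    "psi_recovery",
]


def benchmark_pwm() -> PositionWeightMatrix:
    """The 8-bp SOX2-like matrix used by the enrichment benchmarks."""
    (pcm,) = [m for m in demo_motif_library() if m.motif_id == "SOX2_syn"]
    return counts_to_pwm(pcm)


def _wrap(seqs: list[str], prefix: str) -> list[EnhancerSequence]:
    return [
        EnhancerSequence(
            GenomicInterval("c", 0, len(s), f"{prefix}{i}", "Q"), s
        )
        for i, s in enumerate(seqs)
    ]


def _plant(seq: str, word: str, rng: np.random.Generator) -> str:
    off = int(rng.integers(0, len(seq) - len(word) + 1))
    return seq[:off] + word + seq[off + len(word):]


def null_calibration(
    seed: int,
    n_datasets: int = 500,
    n_pos: int = 100,
    n_ctrl: int = 400,
    length: int = 200,
    B: int = 199,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the bootstrap enrichment test under the null.

    Enhancer and control sets are drawn from the same background model with
    no planted motif; returns the fraction of datasets rejected at
    ``alpha``. The control pool is four times the enhancer set: the
    resampling null estimates only the enhancer-fraction variability, so a
    small control pool adds unmodelled noise to the observed statistic.
    """
    pwm = benchmark_pwm()
    rng = np.random.default_rng(seed)
    rejections = 0
    for d in range(n_datasets):
        seqs = random_sequences(rng, n_pos + n_ctrl, length)
        res = bootstrap_enrichment(
            pwm,
            _wrap(seqs[:n_pos], "e"),
            _wrap(seqs[n_pos:], "c"),
            B=B,
            seed=int(rng.integers(2**31)),
        )
        rejections += res.bootstrap_p < alpha
    return rejections / n_datasets


def enrichment_power(
    seed: int,
    n_runs: int = 20,
    spike_pos: float = 0.4,
    spike_ctrl: float = 0.05,
    n_pos: int = 200,
    n_ctrl: int = 400,
    length: int = 200,
    B: int = 500,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs detecting a planted enrichment at ``alpha``.

    The motif consensus is planted in ``spike_pos`` of the enhancers and
    ``spike_ctrl`` of the controls.
    """
    pwm = benchmark_pwm()
    word = pwm.consensus()
    hits = 0
    for r in range(n_runs):
        rng = np.random.default_rng(seed + 1000 * (r + 1))
        seqs = random_sequences(rng, n_pos + n_ctrl, length)
        pos = [
            _plant(s, word, rng) if rng.random() < spike_pos else s
            for s in seqs[:n_pos]
        ]
        ctrl = [
            _plant(s, word, rng) if rng.random() < spike_ctrl else s
            for s in seqs[n_pos:]
        ]
        res = bootstrap_enrichment(
            pwm, _wrap(pos, "e"), _wrap(ctrl, "c"), B=B,
            seed=int(rng.integers(2**31)),
        )
        hits += res.bootstrap_p < alpha
    return hits / n_runs


def _window_sets(
    rng: np.random.Generator,
    word: str,
    n_windows: int,
    pos_rate: float,
    neg_rate: float,
    width: int = 15,
    neg_factor: int = 5,
) -> tuple[FlankWindowSet, FlankWindowSet]:
    """Positive and negative flank-window sets with planted words.

    The negative set is ``neg_factor`` times larger: control windows are
    cheap, and a larger contrast set pins down background word frequencies
    so the full planted word separates cleanly from its subwords.
    """
    sets = []
    for rate, label, n in (
        (pos_rate, "Q", n_windows),
        (neg_rate, "A", neg_factor * n_windows),
    ):
        ws = FlankWindowSet("CTTTGT", width, source_group=label)
        for i, s in enumerate(random_sequences(rng, n, width)):
            if rng.random() < rate:
                s = _plant(s, word, rng)
            ws.windows.append(FlankWindow(f"{label}{i}", "right", s))
        sets.append(ws)
    return sets[0], sets[1]


def comotif_recovery(
    seed: int,
    n_runs: int = 20,
    word: str = "TTGGCA",
    pos_rate: float = 0.6,
    neg_rate: float = 0.05,
    n_windows: int = 300,
) -> tuple[float, float]:
    """Word-discovery benchmark on planted and null flank windows.

    Returns (fraction of planted runs whose top word is the planted word
    up to reverse complement, fraction of null runs reporting any word at
    the default E-value threshold).
    """
    canonical = min(word, revcomp(word))
    recovered = 0
    false_pos = 0
    for r in range(n_runs):
        rng = np.random.default_rng(seed + 1000 * (r + 1))
        pos, neg = _window_sets(rng, word, n_windows, pos_rate, neg_rate)
        words = discover_words(pos, neg)
        recovered += bool(words) and words[0].word == canonical
        pos0, neg0 = _window_sets(rng, word, n_windows, 0.0, 0.0)
        false_pos += bool(discover_words(pos0, neg0))
    return recovered / n_runs, false_pos / n_runs


def contingency_rates(
    seed: int,
    n_null: int = 500,
    n_power: int = 20,
    n_genes: int = 600,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Chi-squared rejection rate at odds ratio 1 (null) and 3 (power)."""

    def rejection_rate(odds_ratio: float, reps: int) -> float:
        rej = 0
        for r in range(reps):
            cfg = SyntheticConfig(
                seed=seed + 7919 * (r + 1), n_genes=n_genes,
                odds_ratio=odds_ratio,
            )
            genes, presence, _, _ = gen_de_table(cfg)
            _, _, p = chi_squared_test(build_contingency(genes, presence))
            rej += p < alpha
        return rej / reps

    return rejection_rate(1.0, n_null), rejection_rate(3.0, n_power)


def half_life_recovery(
    seed: int,
    n_sims: int = 100,
    t_half: float = 3.3,
    noise: float = 0.05,
    timepoints: tuple = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0),
) -> tuple[float, float]:
    """(median fitted half-life, median relative error) over noisy chases."""
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints)
    fits = []
    for i in range(n_sims):
        y = np.exp(-np.log(2) / t_half * t)
        y = y * np.exp(rng.normal(0.0, noise, size=t.size))
        fits.append(fit_half_life(DecaySeries(f"s{i}", tuple(t), tuple(y))).t_half)
    fits = np.asarray(fits)
    return float(np.median(fits)), float(np.median(np.abs(fits - t_half) / t_half))


def psi_recovery(
    seed: int,
    n_lanes: int = 100,
    psi_true: float = 0.61,
    noise: float = 0.05,
) -> float:
    """Mean percent exon retention recovered from noisy gel lanes."""
    rng = np.random.default_rng(seed)
    values = []
    for i in range(n_lanes):
        fl = 1000.0 * psi_true * np.exp(rng.normal(0.0, noise))
        de6 = 1000.0 * (1.0 - psi_true) * np.exp(rng.normal(0.0, noise))
        values.append(percent_exon_retention(GelLane(f"l{i}", fl, de6)))
    return float(np.mean(values))
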