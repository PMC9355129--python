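"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs end to end:

* grouped enhancer sequences (Q/A/PAN) over an order-1 Markov background,
  each placed mid-contig so length-matched flanking controls exist, with an
  anchor motif planted on the + strand at a per-group rate and a co-motif
  word planted within a fixed window beside the anchor;
* differential-expression gene tables with a configurable motif-presence
  odds ratio between upregulated and unchanged genes, plus per-group
  presence profiles with known exclusivity ground truth;
* noisy assay tables (gel densitometry, qPCR Ct quadruples, cycloheximide
  decay series) around known true values.

All randomness flows from one seed through named substreams, so changing
the parameters of one stage leaves the draws of the others untouched, and
every generator records machine-readable ground truth.

Default sizes are desk scale (hundreds of enhancers of 500 bp rather than
the thousands of a genome-wide atlas); the planted rates default to a
clearly detectable anchor in every group and a Q-biased co-motif, the
qualitative pattern the pipeline is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._types import BASES, EnhancerSequence, GeneMotifProfile, GeneRecord, GenomicInterval
from .io import write_bed, write_fasta, write_gene_table

__all__ = [
    "SyntheticConfig",
    "SyntheticEnhancerDataset",
    "gen_enhancer_dataset",
    "gen_de_table",
    "gen_assay_data",
    "demo_motif_library",
    "random_sequences",
]

_STREAMS = {"sequences": 0, "masking": 1, "planting": 2, "de": 3, "assays": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stage of the simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study, one seed for everything."""

    seed: int
    n_per_group: dict = field(
        default_factory=lambda: {"Q": 300, "A": 300, "PAN": 300}
    )
    length_bp: int = 200
    #: 4x4 dinucleotide transition matrix (rows sum to 1); None = uniform
    transition: list | None = None
    #: per-group (anchor consensus, planting probability), + strand
    spike: dict = field(
        default_factory=lambda: {
            "Q": ("CTTTGT", 0.6),
            "A": ("CTTTGT", 0.6),
            "PAN": ("CTTTGT", 0.6),
        }
    )
    #: co-motif word, per-group probability given a planted anchor, and the
    #: half-width of the window beside the anchor it lands in
    comotif_word: str = "TTGGCA"
    comotif_prob: dict = field(
        default_factory=lambda: {"Q": 0.6, "A": 0.05, "PAN": 0.05}
    )
    comotif_half_width: int = 15
    masked_fraction: float = 0.05
    # differential-expression table
    n_genes: int = 600
    de_proportions: tuple = (0.2, 0.2, 0.6)  # up, down, ns
    de_p_threshold: float = 0.01
    presence_baseline: float = 0.3  # motif-presence probability in ns genes
    odds_ratio: float = 3.0  # up vs ns motif-presence odds ratio
    presence_other_groups: float = 0.3  # A / PAN presence probability
    dual_prob: float = 0.9  # P(NFIX co-hit at the Q enhancer | Q presence)
    # assays
    psi_true: float = 0.61
    gel_noise: float = 0.05
    fold_true: float = 8.0
    ct_noise: float = 0.2
    t_half_true: float = 3.3
    decay_noise: float = 0.05
    decay_timepoints: tuple = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


def _markov_codes(
    rng: np.random.Generator, n: int, length: int, transition: np.ndarray | None
) -> np.ndarray:
    """Integer-coded sequences from an order-1 Markov chain (uniform start)."""
    if transition is None:
        return rng.integers(0, 4, size=(n, length))
    T = np.asarray(transition, dtype=float)
    if T.shape != (4, 4) or (T < 0).any():
        raise ValueError("transition must be a nonnegative 4x4 matrix")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    cum = T.cumsum(axis=1)
    out = np.empty((n, length), dtype=np.int64)
    out[:, 0] = rng.integers(0, 4, size=n)
    u = rng.random(size=(n, length - 1))
    for j in range(1, length):
        out[:, j] = (u[:, j - 1, None] >= cum[out[:, j - 1]]).sum(axis=1)
    return out


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def random_sequences(
    rng: np.random.Generator,
    n: int,
    length: int,
    transition: np.ndarray | None = None,
) -> list[str]:
    """Plain background sequences (no planting, no masking), as strings."""
    codes = _markov_codes(rng, n, length, transition)
    return [_codes_to_str(codes[i]) for i in range(n)]


@dataclass
class SyntheticEnhancerDataset:
    """Generated enhancers plus the contigs and ground truth behind them."""

    enhancers: list  # list[EnhancerSequence]
    contigs: dict  # chrom -> full contig sequence (enhancer + both flanks)
    truth: pd.DataFrame  # one row per enhancer: what was planted where

    def by_group(self) -> dict:
        out: dict[str, list[EnhancerSequence]] = {}
        for e in self.enhancers:
            out.setdefault(e.group, []).append(e)
        return out

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            outdir / "enhancers.fa", [(e.name, e.seq) for e in self.enhancers]
        )
        write_fasta(outdir / "contigs.fa", sorted(self.contigs.items()))
        write_bed(outdir / "enhancers.bed", [e.interval for e in self.enhancers])
        self.truth.to_csv(outdir / "enhancer_truth.tsv", sep="\t", index=False)


def _apply_masking(
    seq_codes: np.ndarray, rng: np.random.Generator, fraction: float
) -> np.ndarray:
    """Boolean mask of soft-masked positions, in runs of geometric length."""
    L = seq_codes.shape[0]
    mask = np.zeros(L, dtype=bool)
    target = int(round(fraction * L))
    while mask.sum() < target:
        start = int(rng.integers(0, L))
        run = 1 + int(rng.geometric(0.15))
        mask[start : start + run] = True
    return mask


def gen_enhancer_dataset(config: SyntheticConfig) -> SyntheticEnhancerDataset:
    """Generate grouped enhancer sequences with planted anchor and co-motif.

    Each enhancer of length L sits at [L, 2L) of its own 3L contig, so both
    length-matched flanks are available for controls. With the per-group
    spike probability, one anchor occurrence is planted at a uniform offset
    on the + strand (kept clear of the contig-derived masking); with the
    conditional co-motif probability, the co-motif word is planted at a
    uniform position inside the window of ``comotif_half_width`` bp to the
    left or right of the anchor.
    """
    L = config.length_bp
    hw = config.comotif_half_width
    kc = len(config.comotif_word)
    if hw < kc:
        raise ValueError("comotif window narrower than the co-motif word")
    seq_rng = stream_rng(config.seed, "sequences")
    mask_rng = stream_rng(config.seed, "masking")
    plant_rng = stream_rng(config.seed, "planting")
    transition = (
        np.asarray(config.transition) if config.transition is not None else None
    )
    enhancers: list[EnhancerSequence] = []
    contigs: dict[str, str] = {}
    rows = []
    for group in ("Q", "A", "PAN"):
        n = config.n_per_group.get(group, 0)
        anchor, spike_p = config.spike[group]
        ka = len(anchor)
        if L < ka + hw:
            raise ValueError(
                f"length_bp {L} too short to plant anchor plus co-motif window"
            )
        codes = _markov_codes(seq_rng, n, 3 * L, transition)
        for i in range(n):
            name = f"{group}_{i:04d}"
            chrom = f"ctg_{name}"
            contig_chars = list(_codes_to_str(codes[i]))
            mask = _apply_masking(codes[i], mask_rng, config.masked_fraction)
            planted_anchor = plant_rng.random() < spike_p
            anchor_off = comotif_off = -1
            comotif_side = ""
            planted_comotif = False
            if planted_anchor:
                # uniform over all valid offsets: no positional bias
                anchor_off = int(plant_rng.integers(0, L - ka + 1))
                g_start = L + anchor_off
                contig_chars[g_start : g_start + ka] = list(anchor)
                mask[g_start : g_start + ka] = False
                if plant_rng.random() < config.comotif_prob.get(group, 0.0):
                    # co-motif start ranges inside the +/- half_width window,
                    # clipped to the enhancer, per side
                    left_lo = max(0, anchor_off - hw)
                    left_hi = anchor_off - kc
                    right_lo = anchor_off + ka
                    right_hi = min(L - kc, anchor_off + ka + hw - kc)
                    sides = []
                    if left_hi >= left_lo:
                        sides.append(("left", left_lo, left_hi))
                    if right_hi >= right_lo:
                        sides.append(("right", right_lo, right_hi))
                    if sides:
                        planted_comotif = True
                        comotif_side, lo, hi = sides[
                            int(plant_rng.integers(0, len(sides)))
                        ]
                        comotif_off = int(plant_rng.integers(lo, hi + 1))
                        gc = L + comotif_off
                        contig_chars[gc : gc + kc] = list(config.comotif_word)
                        mask[gc : gc + kc] = False
            contig = "".join(
                c.lower() if m else c for c, m in zip(contig_chars, mask)
            )
            contigs[chrom] = contig
            iv = GenomicInterval(chrom, L, 2 * L, name, group)
            enhancers.append(EnhancerSequence(iv, contig[L : 2 * L]))
            rows.append(
                {
                    "enhancer_id": name,
                    "group": group,
                    "anchor": anchor,
                    "anchor_planted": planted_anchor,
                    "anchor_offset": anchor_off,
                    "comotif": config.comotif_word,
                    "comotif_planted": planted_comotif,
                    "comotif_offset": comotif_off,
                    "comotif_side": comotif_side,
                }
            )
    return SyntheticEnhancerDataset(enhancers, contigs, pd.DataFrame(rows))


def gen_de_table(
    config: SyntheticConfig,
) -> tuple[list, dict, list, dict]:
    """Gene table with a configurable motif-presence odds ratio.

    DE classes are drawn with ``de_proportions``; motif presence in the Q
    compartment is drawn per class so that the odds ratio of presence
    between up and ns genes equals ``odds_ratio``. Presence in A and PAN is
    independent at ``presence_other_groups``. Returns (gene records,
    presence mapping used for the contingency test, per-gene profiles,
    ground truth).
    """
    if config.n_genes < 100:
        raise ValueError("need n_genes >= 100 for stable odds-ratio targets")
    p0 = config.presence_baseline
    if not 0.0 < p0 < 1.0:
        raise ValueError(
            "presence_baseline must lie strictly in (0, 1); "
            "feasible odds ratios require a non-degenerate baseline"
        )
    odds_up = config.odds_ratio * p0 / (1.0 - p0)
    p_up = odds_up / (1.0 + odds_up)
    rng = stream_rng(config.seed, "de")
    n = config.n_genes
    classes = rng.choice(
        ["up", "down", "ns"], size=n, p=list(config.de_proportions)
    )
    thr = config.de_p_threshold
    u_pval, u_q, u_a, u_pan, u_dual = rng.random(size=(5, n))
    class_presence = {"up": p_up, "down": p0, "ns": p0}
    genes: list[GeneRecord] = []
    profiles: list[GeneMotifProfile] = []
    presence: dict[str, bool] = {}
    for i, cls in enumerate(classes):
        gene_id = f"gene_{i:05d}"
        if cls == "ns":
            p_val = thr + u_pval[i] * (1.0 - thr)
        else:
            p_val = u_pval[i] * thr
        q_present = bool(u_q[i] < class_presence[cls])
        a_present = bool(u_a[i] < config.presence_other_groups)
        pan_present = bool(u_pan[i] < config.presence_other_groups)
        dual = bool(q_present and u_dual[i] < config.dual_prob)
        genes.append(GeneRecord(gene_id, cls, float(p_val), (f"enh_{gene_id}",)))
        profiles.append(
            GeneMotifProfile(
                gene_id, {"Q": q_present, "A": a_present, "PAN": pan_present}, dual
            )
        )
        presence[gene_id] = q_present
    exclusive = {
        p.gene_id
        for p in profiles
        if p.presence["Q"] and not p.presence["A"] and not p.presence["PAN"]
    }
    dual_set = {
        p.gene_id for p in profiles if p.gene_id in exclusive and p.dual
    }
    truth = {
        "p_up": p_up,
        "p_ns": p0,
        "class_counts": {
            c: int((classes == c).sum()) for c in ("up", "down", "ns")
        },
        "exclusive_q_genes": sorted(exclusive),
        "exclusive_q_dual_genes": sorted(dual_set),
    }
    return genes, presence, profiles, truth


def write_de_table(path, genes: list) -> None:
    write_gene_table(
        path,
        [
            (g.gene_id, "+" if g.de_class != "down" else "-", g.de_pvalue,
             g.enhancer_ids)
            for g in genes
        ],
    )


def gen_assay_data(config: SyntheticConfig, n_replicates: int = 6) -> dict:
    """Noisy gel, qPCR and decay tables around known true values.

    Gel band intensities follow the true exon-retention fraction with
    multiplicative lognormal noise; Ct quadruples realise the true fold
    change with additive Gaussian Ct noise; decay series follow first-order
    decay at the true half-life with multiplicative lognormal noise. With
    all noise parameters at 0 the assay calculators recover the truth
    exactly.
    """
    if config.gel_noise < 0 or config.ct_noise < 0 or config.decay_noise < 0:
        raise ValueError("noise parameters must be nonnegative")
    if not config.decay_timepoints:
        raise ValueError("decay series needs timepoints")
    rng = stream_rng(config.seed, "assays")
    gel_rows, qpcr_rows, decay_rows = [], [], []
    for r in range(n_replicates):
        base = 1000.0
        noise = np.exp(rng.normal(0.0, config.gel_noise, size=2)) \
            if config.gel_noise > 0 else np.ones(2)
        gel_rows.append(
            {
                "sample_id": f"gel_{r}",
                "intensity_fl": base * config.psi_true * noise[0],
                "intensity_de6": base * (1.0 - config.psi_true) * noise[1],
            }
        )
        # calibrator Ct values fixed; the sample's target Ct encodes the fold
        ct_ref, ct_tgt_cal, ct_ref_cal = 18.0, 24.0, 18.0
        ct_tgt = ct_tgt_cal - np.log2(config.fold_true)
        eps = rng.normal(0.0, config.ct_noise, size=4) \
            if config.ct_noise > 0 else np.zeros(4)
        qpcr_rows.append(
            {
                "sample_id": f"qpcr_{r}",
                "ct_target": ct_tgt + eps[0],
                "ct_reference": ct_ref + eps[1],
                "ct_target_cal": ct_tgt_cal + eps[2],
                "ct_reference_cal": ct_ref_cal + eps[3],
            }
        )
        t = np.asarray(config.decay_timepoints)
        y = np.exp(-np.log(2) / config.t_half_true * t)
        if config.decay_noise > 0:
            y = y * np.exp(rng.normal(0.0, config.decay_noise, size=t.size))
        for ti, yi in zip(t, y):
            decay_rows.append(
                {"sample_id": f"decay_{r}", "time_h": ti, "intensity": yi}
            )
    return {
        "gel": pd.DataFrame(gel_rows),
        "qpcr": pd.DataFrame(qpcr_rows),
        "decay": pd.DataFrame(decay_rows),
        "truth": {
            "psi_percent": 100.0 * config.psi_true,
            "fold": config.fold_true,
            "t_half_h": config.t_half_true,
        },
    }


def demo_motif_library() -> list:
    """Synthetic stand-in PWM library built from published consensus words.

    Count matrices are constructed programmatically: the consensus base of
    each column gets 80 counts and the others share 20, with IUPAC
    degeneracy split evenly. They are stand-ins for the JASPAR matrices of
    the corresponding factors, not JASPAR data.
    """
    from .cooccur import word_to_pcm
    from ._types import PositionCountMatrix

    consensi = {
        "LEF1_syn": "CTTTGT",
        "LEF1alt_syn": "CTTTGA",
        "SOX2_syn": "CCWTTGTT",
        "NFIX_syn": "TTGGCA",
        "ASCL1_syn": "GCAGCTG",
        "ASCL2_syn": "CAGCTGC",
    }
    library = []
    for motif_id, word in consensi.items():
        sharp = word_to_pcm(word).counts  # degenerate weights summing to 1
        # 80 counts on the consensus base(s), remaining 20 over the others
        spread = (sharp == 0) * (20.0 / np.maximum((sharp == 0).sum(axis=0), 1))
        counts = sharp * 80.0 + spread
        library.append(PositionCountMatrix(motif_id, counts, motif_id))
    return library
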