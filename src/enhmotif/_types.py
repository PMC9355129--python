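"""Domain containers shared across the pipeline.

The atlas under study partitions enhancers into three activity groups:
quiescence-specific (Q), active-specific (A) and pan (PAN, active in both
cell states). Every container here carries that label through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("Q", "A", "PAN")

BASES = "ACGT"
# complements for plain bases and every degenerate IUPAC code
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware; preserves soft-masking case."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open enhancer interval with its activity group."""

    chrom: str
    start: int
    end: int
    name: str
    group: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.name}: [{self.start}, {self.end})"
            )
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for {self.name}; "
                f"expected one of {GROUPS}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EnhancerSequence:
    """A labelled enhancer interval together with its (soft-masked) DNA.

    Lowercase bases mark repeats/low-complexity sequence from the masked
    genome assembly; N bases are hard-masked. Both count as masked and are
    excluded from motif matching downstream.
    """

    interval: GenomicInterval
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.interval.length:
            raise ValueError(
                f"{self.interval.name}: sequence length {len(self.seq)} != "
                f"interval length {self.interval.length}"
            )
        bad = set(self.seq) - set("ACGTNacgtn")
        if bad:
            raise ValueError(
                f"{self.interval.name}: illegal characters {sorted(bad)}"
            )

    @property
    def name(self) -> str:
        return self.interval.name

    @property
    def group(self) -> str:
        return self.interval.group

    @property
    def masked_fraction(self) -> float:
        n_masked = sum(1 for c in self.seq if c.islower() or c == "N")
        return n_masked / len(self.seq)

    def mask_array(self) -> np.ndarray:
        """Boolean array, True where the base is masked (lowercase or N)."""
        arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        return lower | (arr == ord("N"))


@dataclass(frozen=True)
class PositionCountMatrix:
    """Nucleotide counts per motif column, rows in A, C, G, T order."""

    motif_id: str
    counts: np.ndarray  # shape (4, w), float
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x w")
        if counts.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: width must be >= 4")
        if (counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative count")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.motif_id}: zero-sum column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        """Column-normalised base frequencies (4 x w)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        """Column-wise argmax base (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PositionCountMatrix":
        return PositionCountMatrix(
            self.motif_id, self.counts[::-1, ::-1].copy(), self.name
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its differential-expression call and linked enhancers."""

    gene_id: str
    de_class: str  # up | down | ns
    de_pvalue: float
    enhancer_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.de_class not in ("up", "down", "ns"):
            raise ValueError(f"{self.gene_id}: bad DE class {self.de_class!r}")
        if not 0.0 <= self.de_pvalue <= 1.0:
            raise ValueError(
                f"{self.gene_id}: p-value {self.de_pvalue} outside [0, 1]"
            )
        object.__setattr__(self, "enhancer_ids", tuple(self.enhancer_ids))


@dataclass
class GeneMotifProfile:
    """Per-group motif presence for one gene.

    ``presence[group]`` is True when any enhancer of that group linked to the
    gene carries a motif hit; ``dual`` flags a single Q enhancer carrying
    hits for both the anchor motif and a second motif.
    """

    gene_id: str
    presence: dict = field(default_factory=dict)  # {"Q": bool, "A": ..., "PAN": ...}
    dual: bool = False

    def __post_init__(self) -> None:
        if self.dual and not self.presence.get("Q", False):
            raise ValueError(
                f"{self.gene_id}: dual hit implies Q presence"
            )
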