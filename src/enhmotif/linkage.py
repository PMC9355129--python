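"""Linking motif presence in enhancers to differential gene expression.

Genes are tied to enhancers either through a provided association table or
by nearest-enhancer assignment from the TSS. Presence of a motif at a gene
(any linked enhancer with a best hit clearing the relative-score cut)
is crossed with the gene's differential-expression class in a 3x2
contingency table — up, down, not-significant versus motif present/absent —
and tested with a plain Pearson chi-squared test on 2 degrees of freedom.
Gene sets with group-exclusive motifs (present in Q enhancers, absent from
A and PAN) and dual-motif requirements are built from per-gene profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._types import GeneMotifProfile, GeneRecord, GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable3x2",
    "assign_nearest_enhancer",
    "build_contingency",
    "build_gene_profiles",
    "chi_squared_test",
    "exclusive_motif_genes",
]

DE_CLASSES = ("up", "down", "ns")


@dataclass(frozen=True)
class ContingencyTable3x2:
    """DE class (up/down/ns) by motif presence/absence counts."""

    counts: np.ndarray  # shape (3, 2), rows up/down/ns, cols present/absent

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (3, 2):
            raise ValueError("contingency table must be 3 x 2")
        if (counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True)
        cols = self.counts.sum(axis=0, keepdims=True)
        return rows @ cols / self.counts.sum()


def _distance(iv: GenomicInterval, pos: int) -> int:
    """0 when the position lies inside the interval, else bp to the nearer edge."""
    if iv.start <= pos < iv.end:
        return 0
    if pos < iv.start:
        return iv.start - pos
    return pos - (iv.end - 1)


def assign_nearest_enhancer(
    tss: list[tuple[str, str, int]],
    enhancers: list[GenomicInterval],
) -> dict[str, str]:
    """Map each gene to its nearest enhancer on the same chromosome.

    ``tss`` rows are (gene_id, chrom, position). Ties go to the upstream
    enhancer (entirely at lower coordinates than the TSS), then to the one
    with the smaller start. Genes on chromosomes without enhancers are left
    unassigned and logged.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in enhancers:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    assignment: dict[str, str] = {}
    n_unassigned = 0
    for gene_id, chrom, pos in tss:
        cands = by_chrom.get(chrom)
        if not cands:
            n_unassigned += 1
            continue
        best = min(
            cands,
            key=lambda iv: (_distance(iv, pos), not iv.end <= pos, iv.start),
        )
        assignment[gene_id] = best.name
    if n_unassigned:
        log.info("%d genes on chromosomes without enhancers left unassigned",
                 n_unassigned)
    return assignment


def build_contingency(
    genes: list[GeneRecord], presence: dict[str, bool]
) -> ContingencyTable3x2:
    """Cross DE class with motif presence; genes absent from ``presence``
    count as motif-absent."""
    if not genes:
        raise ValueError("empty gene list")
    counts = np.zeros((3, 2))
    for g in genes:
        row = DE_CLASSES.index(g.de_class)
        col = 0 if presence.get(g.gene_id, False) else 1
        counts[row, col] += 1
    return ContingencyTable3x2(counts)


def chi_squared_test(table: ContingencyTable3x2) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on the 3x2 table.

    Returns (chi2, df, p) with df = 2 and no continuity correction. Raises
    on a zero margin (test undefined); logs a warning when any expected
    count is below 5.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero margin: chi-squared test undefined")
    expected = table.expected()
    if (expected < 5).any():
        log.warning("expected count below 5; chi-squared approximation weak")
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = 2
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def build_gene_profiles(
    genes: list[GeneRecord],
    enhancer_groups: dict[str, str],
    hits: dict[str, set[str]],
    motif: str,
    second_motif: str | None = None,
) -> list[GeneMotifProfile]:
    """Per-gene, per-group motif presence from enhancer-level hit calls.

    ``hits`` maps a motif id to the set of enhancer ids carrying a hit for
    it. A gene is present in a group when any of its linked enhancers of
    that group carries the motif; the ``dual`` flag marks a single Q
    enhancer carrying both ``motif`` and ``second_motif``.
    """
    if motif not in hits:
        raise KeyError(f"unknown motif id {motif!r}")
    if second_motif is not None and second_motif not in hits:
        raise KeyError(f"unknown motif id {second_motif!r}")
    profiles: list[GeneMotifProfile] = []
    for g in genes:
        presence = {grp: False for grp in ("Q", "A", "PAN")}
        dual = False
        for enh in g.enhancer_ids:
            grp = enhancer_groups.get(enh)
            if grp is None:
                continue
            if enh in hits[motif]:
                presence[grp] = True
                if (
                    second_motif is not None
                    and grp == "Q"
                    and enh in hits[second_motif]
                ):
                    dual = True
        profiles.append(GeneMotifProfile(g.gene_id, presence, dual))
    return profiles


def exclusive_motif_genes(
    profiles: list[GeneMotifProfile],
    require_dual: bool = False,
) -> set[str]:
    """Genes whose motif occurs in Q enhancers only (absent from A and PAN).

    With ``require_dual``, additionally require that a single Q enhancer
    carries hits for both the anchor motif and the second motif (the
    profile's ``dual`` flag).
    """
    out: set[str] = set()
    for prof in profiles:
        missing = {"Q", "A", "PAN"} - set(prof.presence)
        if missing:
            raise ValueError(
                f"{prof.gene_id}: profile incomplete, missing {sorted(missing)}"
            )
        if not prof.presence["Q"]:
            continue
        if prof.presence["A"] or prof.presence["PAN"]:
            continue
        if require_dual and not prof.dual:
            continue
        out.add(prof.gene_id)
    return out
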