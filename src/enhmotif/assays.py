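"""Quantitative assay calculators: exon retention, qPCR, reporters, decay.

These are the bench-side formulas of the study: percent exon retention
from gel band densitometry (full-length versus exon-skipped amplicon),
relative qPCR quantification by the Livak 2^-ddCt method, dual-fluorophore
reporter normalisation (eGFP over mCherry against a calibrator), and
protein half-life from a cycloheximide-chase time course by log-linear
least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GelLane",
    "QPCRMeasure",
    "DecaySeries",
    "HalfLifeFit",
    "percent_exon_retention",
    "ddct_fold_change",
    "reporter_ratio",
    "fit_half_life",
    "exon_residue_count",
    "exon_nt_length",
]


@dataclass(frozen=True)
class GelLane:
    """Band intensities of the full-length and exon-skipped RT-PCR products."""

    sample_id: str
    intensity_fl: float
    intensity_de6: float
    length_fl: float | None = None  # amplicon lengths (bp) for molar correction
    length_de6: float | None = None

    def __post_init__(self) -> None:
        if self.intensity_fl < 0 or self.intensity_de6 < 0:
            raise ValueError(f"{self.sample_id}: negative band intensity")
        if self.intensity_fl == 0 and self.intensity_de6 == 0:
            raise ValueError(f"{self.sample_id}: both band intensities zero")


@dataclass(frozen=True)
class QPCRMeasure:
    """Ct values of target and reference gene, sample and calibrator."""

    sample_id: str
    ct_target: float
    ct_reference: float
    ct_target_cal: float
    ct_reference_cal: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference,
                  self.ct_target_cal, self.ct_reference_cal):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{self.sample_id}: Ct values must be finite "
                                 "and positive")


@dataclass(frozen=True)
class DecaySeries:
    """Normalised band intensity over time after translation blockade."""

    sample_id: str
    timepoints: tuple  # hours, strictly increasing, first is 0
    intensities: tuple  # > 0, normalised to loading control

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.timepoints)
        y = tuple(float(x) for x in self.intensities)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "intensities", y)
        if len(t) != len(y):
            raise ValueError(f"{self.sample_id}: timepoint/intensity mismatch")
        if len(t) < 3:
            raise ValueError(f"{self.sample_id}: need >= 3 timepoints")
        if t[0] != 0.0:
            raise ValueError(f"{self.sample_id}: first timepoint must be 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"{self.sample_id}: timepoints must increase")
        if any(v <= 0 for v in y):
            raise ValueError(f"{self.sample_id}: intensities must be > 0")


@dataclass(frozen=True)
class HalfLifeFit:
    """First-order decay fit: rate k (per hour) and half-life ln(2)/k."""

    sample_id: str
    k: float
    t_half: float
    r_squared: float
    valid: bool  # False when the fitted slope is non-negative


def percent_exon_retention(lane: GelLane, molar_correct: bool = False) -> float:
    """Percent of transcripts retaining the alternative exon.

    PSI = 100 * I_FL / (I_FL + I_dE6); with ``molar_correct`` each band
    intensity is first divided by its amplicon length to convert mass-like
    signal to molar amounts.
    """
    fl, de6 = lane.intensity_fl, lane.intensity_de6
    if molar_correct:
        if lane.length_fl is None or lane.length_de6 is None:
            raise ValueError(f"{lane.sample_id}: molar correction needs "
                             "amplicon lengths")
        fl = fl / lane.length_fl
        de6 = de6 / lane.length_de6
    return 100.0 * fl / (fl + de6)


def ddct_fold_change(m: QPCRMeasure) -> float:
    """Relative expression by the Livak 2^-ddCt method.

    dCt = Ct_target - Ct_reference in sample and calibrator;
    fold = 2^-(dCt_sample - dCt_calibrator). Amplification efficiency is
    assumed to be 2 (perfect doubling per cycle).
    """
    dct_sample = m.ct_target - m.ct_reference
    dct_cal = m.ct_target_cal - m.ct_reference_cal
    return float(2.0 ** -(dct_sample - dct_cal))


def reporter_ratio(
    egfp: float, mcherry: float, egfp_cal: float, mcherry_cal: float
) -> float:
    """Dual-reporter fold change: (eGFP/mCherry) over the calibrator ratio."""
    for v in (egfp, mcherry, egfp_cal, mcherry_cal):
        if v <= 0:
            raise ValueError("reporter signals must be > 0")
    return (egfp / mcherry) / (egfp_cal / mcherry_cal)


def fit_half_life(series: DecaySeries) -> HalfLifeFit:
    """Half-life from a cycloheximide-chase series by log-linear OLS.

    ln(intensity) is regressed on time; k = -slope and t_half = ln(2)/k.
    A non-negative slope (no detectable decay) returns an invalid fit with
    t_half = +inf.
    """
    t = np.asarray(series.timepoints)
    logy = np.log(np.asarray(series.intensities))
    slope, intercept = np.polyfit(t, logy, 1)
    resid = logy - (slope * t + intercept)
    ss_tot = float(((logy - logy.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    k = -float(slope)
    if k <= 0:
        return HalfLifeFit(series.sample_id, k, math.inf, r2, valid=False)
    return HalfLifeFit(series.sample_id, k, math.log(2) / k, r2, valid=True)


def exon_residue_count(nt_length: int) -> int:
    """Residues encoded by an in-frame exon (e.g. an 84-nt exon: 28 aa)."""
    if nt_length <= 0 or nt_length % 3 != 0:
        raise ValueError(f"{nt_length} nt is not a positive multiple of 3")
    return nt_length // 3


def exon_nt_length(n_residues: int) -> int:
    """Nucleotides of an in-frame exon encoding ``n_residues`` amino acids."""
    if n_residues <= 0:
        raise ValueError("residue count must be positive")
    return 3 * n_residues
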