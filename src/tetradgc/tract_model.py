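"""Arithmetic reconciliation of observed and expected conversion frequencies.

A single-SNP conversion assay sees an event only when the conversion tract
overlaps the assayed nucleotide, so the observed per-locus frequency is the
per-nucleotide event frequency multiplied by the mean tract length.  Working
from cytological DSB counts (RAD51 foci), the genome size, and the fraction
of heteroduplex mismatches that mismatch repair restores, this module
derives the expected number of conversions per meiosis, the expected
per-nucleotide frequency, the tract length implied by an observed per-locus
frequency, and the expected genome-wide CO:NCO balance.

All quantities are interval arithmetic on [min, max] input bounds; the
defaults are the *A. thaliana* constants used by the reference screen.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conversion_stats import round_half_up

__all__ = [
    "TractModelInputs",
    "TractEstimate",
    "expected_conversions",
    "per_nt_frequency",
    "tract_length",
    "expected_co_nco_ratio",
]


@dataclass(frozen=True)
class TractModelInputs:
    """Genome-scale constants.

    genome_min is the sequenced nuclear genome; genome_max adds the
    unsequenced centromere (~15 Mb) and rDNA (~7 Mb) estimates.  DSB bounds
    come from RAD51 focus counts; restoration_fraction is the share of
    heteroduplex mismatches that MMR repairs back to the original allele
    (0.5 = unbiased).  co_per_meiosis is the organism's typical crossover
    count per meiosis.
    """

    genome_min: int = 119_146_348
    genome_max: int = 141_146_348
    dsb_min: int = 120
    dsb_max: int = 222
    restoration_fraction: float = 0.5
    co_per_meiosis: float = 9.0

    def __post_init__(self) -> None:
        if not 0 < self.genome_min <= self.genome_max:
            raise ValueError("genome bounds must satisfy 0 < genome_min <= genome_max")
        if not 0 <= self.dsb_min <= self.dsb_max:
            raise ValueError("DSB bounds must satisfy 0 <= dsb_min <= dsb_max")
        if not 0.0 <= self.restoration_fraction <= 1.0:
            raise ValueError("restoration_fraction must lie in [0, 1]")
        if self.co_per_meiosis <= 0:
            raise ValueError("co_per_meiosis must be positive")


@dataclass(frozen=True)
class TractEstimate:
    expected_conversions: tuple[int, int]    # per meiosis, genome-wide
    per_nt_frequency: tuple[float, float]    # events per nucleotide per meiosis
    tract_length: tuple[int, int]            # bp, rounded bounds
    tract_length_mean: int                   # bp, midpoint of unrounded bounds


def expected_conversions(inputs: TractModelInputs = TractModelInputs()) -> tuple[int, int]:
    """Genome-wide conversions per meiosis: DSB bounds times the fraction
    of heteroduplex events MMR does not restore."""
    keep = 1.0 - inputs.restoration_fraction
    return (round_half_up(inputs.dsb_min * keep), round_half_up(inputs.dsb_max * keep))


def per_nt_frequency(inputs: TractModelInputs = TractModelInputs()) -> tuple[float, float]:
    """Expected conversion events per nucleotide per meiosis.

    The bounds pair conservatively: fewest conversions over the largest
    genome (low) and most conversions over the smallest genome (high).
    """
    conv_lo, conv_hi = expected_conversions(inputs)
    return (conv_lo / inputs.genome_max, conv_hi / inputs.genome_min)


def tract_length(f_observed: float, inputs: TractModelInputs = TractModelInputs()) -> TractEstimate:
    """Conversion tract length implied by an observed per-locus frequency.

    f_observed is the adjusted (doubling-corrected) per-locus per-meiosis
    frequency.  Since f_locus = f_per_nt * L, the implied tract bounds are
    f_observed divided by the high and low per-nucleotide frequencies.
    Bounds are rounded to the nearest bp; the mean uses unrounded bounds.
    """
    if f_observed <= 0:
        raise ValueError("tract length is undefined for a zero observed frequency")
    freq_lo, freq_hi = per_nt_frequency(inputs)
    if freq_lo <= 0 or freq_hi <= 0:
        raise ValueError("expected per-nucleotide frequency is zero under these inputs")
    lo = f_observed / freq_hi
    hi = f_observed / freq_lo
    return TractEstimate(
        expected_conversions=expected_conversions(inputs),
        per_nt_frequency=(freq_lo, freq_hi),
        tract_length=(round_half_up(lo), round_half_up(hi)),
        tract_length_mean=round_half_up((lo + hi) / 2.0),
    )


def expected_co_nco_ratio(inputs: TractModelInputs = TractModelInputs()) -> tuple[float, float]:
    """Expected CO:NCO balance as the 1:x denominators (low, high).

    If ~co_per_meiosis of the DSBs resolve as crossovers and the rest as
    non-crossovers, the NCO:CO quotient spans
    (dsb_min - co) / co to (dsb_max - co) / co.
    """
    if inputs.dsb_min <= inputs.co_per_meiosis:
        raise ValueError("dsb_min must exceed co_per_meiosis for a meaningful NCO count")
    nco_lo = inputs.dsb_min - inputs.co_per_meiosis
    nco_hi = inputs.dsb_max - inputs.co_per_meiosis
    return (nco_lo / inputs.co_per_meiosis, nco_hi / inputs.co_per_meiosis)
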