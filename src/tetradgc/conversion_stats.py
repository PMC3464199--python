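"""Gene-conversion frequency estimation and statistics.

Frequencies come from tetrad counts as n31/N (raw) and 2*n31/N (adjusted).
The doubling compensates for the unscorable reciprocal 1:3 class: mismatch
repair converts toward and away from the fluorescent allele at equal rates,
but 1:3 tetrads are confounded by pollen-development defects and are dropped,
so each observed 3:1 tetrad stands in for one unobserved 1:3 tetrad.

Locus-to-locus comparisons use the G-test of independence (likelihood-ratio
chi-square) on 2x2 tables of raw 3:1 counts versus remaining tetrads, with
no continuity or Williams correction by default.  The position analysis is
an ordinary least-squares regression of adjusted frequency on the SNP's
coding-sequence position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tetrad_data import AlleleRecord, TetradCounts

__all__ = [
    "ConversionEstimate",
    "GTestResult",
    "RegressionResult",
    "ControlComparison",
    "PairwiseMatrix",
    "estimate_frequency",
    "pool_counts",
    "g_test_independence",
    "pairwise_matrix",
    "control_comparison",
    "position_regression",
    "regression_points",
    "format_sci",
    "format_p",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_sci(x: float, sig: int = 3) -> str:
    """Scientific notation at ``sig`` significant figures, e.g. 2.28E-04."""
    return f"{x:.{sig - 1}E}"


def format_p(p: float) -> str:
    """P-value for display; values below 1e-15 print as '<1E-15'."""
    if p < 1e-15:
        return "<1E-15"
    return f"{p:.2f}" if p >= 0.005 else f"{p:.0E}"


@dataclass(frozen=True)
class ConversionEstimate:
    """Conversion frequency at one locus (or pooled over loci)."""

    label: str
    n_31: int
    n_tetrads: int
    raw_frequency: float
    adjusted_frequency: float
    meioses_per_conversion: Optional[int]  # None when no conversions observed


def estimate_frequency(counts: TetradCounts) -> ConversionEstimate:
    """Per-meiosis conversion frequency from 3:1 tetrad counts.

    adjusted = 2 * n31 / N; meioses_per_conversion = N / (2 * n31), rounded
    half-up to match the reporting convention of the reference screen.
    """
    if counts.n_tetrads == 0:
        raise ValueError(f"{counts.label}: cannot estimate a frequency from zero tetrads")
    raw = counts.n_31 / counts.n_tetrads
    adjusted = 2.0 * raw
    if adjusted > 1.0:
        warnings.warn(
            f"{counts.label}: adjusted frequency {adjusted:.3g} exceeds 1; the doubling "
            "adjustment is only meaningful for rare conversions",
            RuntimeWarning,
            stacklevel=2,
        )
    mpc = round_half_up(counts.n_tetrads / (2.0 * counts.n_31)) if counts.n_31 > 0 else None
    return ConversionEstimate(
        label=counts.label,
        n_31=counts.n_31,
        n_tetrads=counts.n_tetrads,
        raw_frequency=raw,
        adjusted_frequency=adjusted,
        meioses_per_conversion=mpc,
    )


def pool_counts(counts: Sequence[TetradCounts], label: str = "pooled") -> ConversionEstimate:
    """Pool loci by summing conversions and tetrads, then estimate."""
    if not counts:
        raise ValueError("cannot pool an empty list of counts")
    total = TetradCounts(
        label=label,
        n_tetrads=sum(c.n_tetrads for c in counts),
        n_31=sum(c.n_31 for c in counts),
        n_13=sum(c.n_13 for c in counts),
        n_40=sum(c.n_40 for c in counts),
        n_04=sum(c.n_04 for c in counts),
    )
    return estimate_frequency(total)


# ---------------------------------------------------------------------------
# G-test of independence

@dataclass(frozen=True)
class GTestResult:
    g_statistic: float
    df: int
    p_value: float
    degenerate: bool = False  # a marginal total was zero; independence holds trivially


def g_test_independence(k1: int, n1: int, k2: int, n2: int, williams: bool = False) -> GTestResult:
    """Likelihood-ratio (G) test of independence on the 2x2 table
    [[k1, n1-k1], [k2, n2-k2]].

    G = 2 * sum O*ln(O/E) with expecteds from the marginals and the
    convention 0*ln(0/E) = 0; P is the upper tail of chi-square with 1 df.
    ``williams=True`` applies the Williams small-sample correction
    (G divided by q); off by default, which is the variant that reproduces
    the reference screen's printed P-values.
    """
    for k, n, grp in ((k1, n1, "first"), (k2, n2, "second")):
        if n <= 0:
            raise ValueError(f"{grp} group: trials must be positive, got {n}")
        if not 0 <= k <= n:
            raise ValueError(f"{grp} group: successes {k} outside [0, {n}]")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if (cols == 0).any():
        return GTestResult(g_statistic=0.0, df=1, p_value=1.0, degenerate=True)
    expected = np.outer(rows, cols) / n
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    if williams:
        q = 1.0 + ((n / rows[0] + n / rows[1] - 1.0) * (n / cols[0] + n / cols[1] - 1.0)) / (6.0 * n)
        g /= q
    g = max(g, 0.0)
    return GTestResult(g_statistic=g, df=1, p_value=float(stats.chi2.sf(g, 1)))


@dataclass(frozen=True)
class PairwiseMatrix:
    """All-pairs G-test comparison of raw 3:1 counts between loci."""

    labels: tuple[str, ...]
    results: dict[tuple[str, str], GTestResult]

    def get(self, a: str, b: str) -> GTestResult:
        key = (a, b) if (a, b) in self.results else (b, a)
        return self.results[key]

    def p_value_frame(self) -> pd.DataFrame:
        """Symmetric DataFrame of P-values; diagonal is NaN (not applicable)."""
        m = pd.DataFrame(np.nan, index=list(self.labels), columns=list(self.labels))
        for (a, b), r in self.results.items():
            m.loc[a, b] = r.p_value
            m.loc[b, a] = r.p_value
        return m


def pairwise_matrix(counts: Sequence[TetradCounts], williams: bool = False) -> PairwiseMatrix:
    """G-test every pair of loci on raw 3:1 counts (not doubled: doubling
    would inflate G roughly two-fold and misstate the evidence)."""
    if len(counts) < 2:
        raise ValueError("pairwise comparison requires at least two count sets")
    labels = tuple(c.label for c in counts)
    if len(set(labels)) != len(labels):
        raise ValueError("count labels must be unique for a pairwise matrix")
    results: dict[tuple[str, str], GTestResult] = {}
    for i, a in enumerate(counts):
        for b in counts[i + 1 :]:
            results[(a.label, b.label)] = g_test_independence(
                a.n_31, a.n_tetrads, b.n_31, b.n_tetrads, williams=williams
            )
    return PairwiseMatrix(labels=labels, results=results)


@dataclass(frozen=True)
class ControlComparison:
    control: ConversionEstimate
    reference: ConversionEstimate
    result: GTestResult

    @property
    def report(self) -> str:
        return (
            f"control {self.control.label}: {self.control.n_31}/{self.control.n_tetrads} "
            f"(adjusted {format_sci(self.control.adjusted_frequency)}) vs "
            f"{self.reference.label}: {self.reference.n_31}/{self.reference.n_tetrads} "
            f"(adjusted {format_sci(self.reference.adjusted_frequency)}); "
            f"G = {self.result.g_statistic:.3f}, P = {self.result.p_value:.6f}"
        )


def control_comparison(control: TetradCounts, reference: TetradCounts) -> ControlComparison:
    """Compare a false-positive control (reversion or misgrouping; typically
    0 events) against an observed locus, by G-test on raw counts."""
    return ControlComparison(
        control=estimate_frequency(control),
        reference=estimate_frequency(reference),
        result=g_test_independence(control.n_31, control.n_tetrads, reference.n_31, reference.n_tetrads),
    )


# ---------------------------------------------------------------------------
# SNP-position regression

@dataclass(frozen=True)
class RegressionResult:
    slope: float  # frequency change per nucleotide of SNP position
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope, n-2 df
    n: int


def position_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS regression of conversion frequency on SNP coding-sequence position.

    Tests for conversion polarity (a 5' to 3' gradient) across loci.
    """
    if len(points) < 3:
        raise ValueError("position regression requires at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if (x <= 0).any():
        raise ValueError("SNP positions must be positive (1-based)")
    if np.ptp(x) == 0:
        raise ValueError("all SNP positions identical: slope undefined")
    if np.ptp(y) == 0:
        # constant response: zero slope, no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=len(points))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(points),
    )


def regression_points(
    alleles: Iterable[AlleleRecord], counts: Iterable[TetradCounts]
) -> list[tuple[float, float]]:
    """Pair SNP positions with adjusted frequencies by allele name.

    Alleles without a sequenced mutation or without a matching count record
    are skipped.
    """
    by_name = {a.allele_name: a for a in alleles}
    pts: list[tuple[float, float]] = []
    for c in counts:
        a = by_name.get(c.label)
        if a is None or a.snp_position is None:
            continue
        pts.append((float(a.snp_position), estimate_frequency(c).adjusted_frequency))
    return pts
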