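"""Forward simulation of meiotic DSB repair in a fluorescent/non-fluorescent
heterozygote, emitting pollen-tetrad phenotypes with ground-truth event logs.

Generative model per meiosis (tetrad):

* Four chromatids; chromatids 0 and 1 carry the fluorescent test allele and
  the flanking hemizygous markers (in coupling), chromatids 2 and 3 carry
  the non-fluorescent allele and no markers.
* A Poisson (or fixed) number of DSBs; each DSB picks a uniform genome
  position and a uniform chromatid.
* With probability ``p_homolog`` the break is repaired off a random
  non-sister chromatid; sister-templated repair is phenotypically silent.
* A heteroduplex (conversion) tract of drawn length is placed around the
  break with a uniform offset, so the probability that it covers any fixed
  interior locus is exactly tract_mean / genome_length.
* If the tract covers the test locus and donor and recipient alleles differ,
  mismatch repair converts (copies the template allele onto the broken
  chromatid) with probability ``p_conversion``, else restores.
* With probability ``p_co`` a homolog-templated repair resolves as a
  crossover: the two participating chromatids exchange all tracked loci
  distal to the conversion tract (this is what moves flanking markers).
* The four chromatids are randomly assigned to the four grains; reversion
  and tetrad-misgrouping false positives are applied last.

``simulate_tetrad``/``simulate_experiment`` run this model tetrad by tetrad
and keep phenotypes plus the event log.  ``simulate_counts`` draws from the
same law with vectorized bookkeeping (only tetrads containing a
locus-covering homolog repair need chromatid-level replay) and is the fast
path for million-tetrad runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .conversion_stats import estimate_frequency
from .tetrad_data import TetradCounts, TetradPhenotype

__all__ = [
    "SimulationParams",
    "MeiosisEvent",
    "ExperimentResult",
    "RecoveryReport",
    "simulate_tetrad",
    "simulate_experiment",
    "simulate_counts",
    "recover_parameters",
    "expected_adjusted_frequency",
]

_TRACT_LAWS = ("fixed", "geometric", "gamma")
_DSB_LAWS = ("poisson", "fixed")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the forward meiosis model.

    Defaults are the study conditions of the *A. thaliana* screen this
    package models: the sequenced genome size, a DSB count at the midpoint
    of the cytological 120-222 range, a 605 bp mean tract, unbiased MMR
    (restoration fraction = 1 - p_conversion = 0.5), ~9 of ~171 homolog
    repairs resolving as crossovers, and a reversion rate in the measured
    mitotic range.
    """

    genome_length: int = 119_146_348
    dsb_mean: float = 171.0
    dsb_law: str = "poisson"
    test_locus: int = 59_573_174
    flank_left: Optional[int] = None
    flank_right: Optional[int] = None
    tract_mean: float = 605.0
    tract_law: str = "geometric"
    tract_shape: float = 2.0  # gamma law only
    p_homolog: float = 1.0
    p_co: float = 9.0 / 171.0
    p_conversion: float = 0.5
    reversion_rate: float = 1e-7
    misgrouping_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p_homolog", "p_co", "p_conversion", "reversion_rate", "misgrouping_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 1 <= self.tract_mean <= self.genome_length:
            raise ValueError("tract_mean must lie in [1, genome_length]")
        if not 1 <= self.test_locus <= self.genome_length:
            raise ValueError("test_locus must lie within the genome")
        if self.tract_law not in _TRACT_LAWS:
            raise ValueError(f"tract_law must be one of {_TRACT_LAWS}")
        if self.dsb_law not in _DSB_LAWS:
            raise ValueError(f"dsb_law must be one of {_DSB_LAWS}")
        if self.dsb_mean < 0:
            raise ValueError("dsb_mean must be non-negative")
        if self.tract_shape <= 0:
            raise ValueError("tract_shape must be positive")
        for name in ("flank_left", "flank_right"):
            v = getattr(self, name)
            if v is not None and not 1 <= v <= self.genome_length:
                raise ValueError(f"{name} must lie within the genome")


@dataclass(frozen=True)
class MeiosisEvent:
    """Ground truth for one DSB-repair event."""

    dsb_position: int
    broken_chromatid: int          # 0-3
    template: str                  # "homolog" | "sister"
    template_chromatid: int
    pathway: str                   # "CO" | "NCO" (meaningful for homolog repair)
    tract_start: int
    tract_end: int
    covered_test_locus: bool
    mmr_outcome: Optional[str]     # "converted" | "restored" | "no_mismatch" | None (sister/silent)


def _draw_tract_length(params: SimulationParams, rng: np.random.Generator, size: int | None = None):
    if params.tract_law == "fixed":
        L = round(params.tract_mean)
        return L if size is None else np.full(size, L, dtype=np.int64)
    if params.tract_law == "geometric":
        draw = rng.geometric(1.0 / params.tract_mean, size=size)
        return int(draw) if size is None else draw.astype(np.int64)
    # gamma with fixed shape, scale set by the mean; lengths at least 1 bp
    draw = rng.gamma(params.tract_shape, params.tract_mean / params.tract_shape, size=size)
    if size is None:
        return max(1, int(round(float(draw))))
    return np.maximum(1, np.rint(draw)).astype(np.int64)


def _draw_event_fields(params: SimulationParams, rng: np.random.Generator):
    """One event's random fields, in a fixed draw order."""
    pos = int(rng.integers(1, params.genome_length + 1))
    chromatid = int(rng.integers(0, 4))
    homolog = bool(rng.random() < params.p_homolog)
    template_choice = int(rng.integers(0, 2))
    is_co = bool(rng.random() < params.p_co)
    length = int(_draw_tract_length(params, rng))
    offset = int(rng.integers(0, length))
    convert = bool(rng.random() < params.p_conversion)
    return pos, chromatid, homolog, template_choice, is_co, length, offset, convert


def _apply_event(
    alleles: list[bool],
    left: list[bool],
    right: list[bool],
    params: SimulationParams,
    pos: int,
    chromatid: int,
    homolog: bool,
    template_choice: int,
    is_co: bool,
    length: int,
    offset: int,
    convert: bool,
) -> MeiosisEvent:
    """Mutate chromatid state for one DSB and return its ground-truth record."""
    start = pos - offset
    end = start + length - 1
    sister = chromatid ^ 1
    if not homolog:
        # sister-templated repair: identical sequence, phenotypically silent
        return MeiosisEvent(
            dsb_position=pos,
            broken_chromatid=chromatid,
            template="sister",
            template_chromatid=sister,
            pathway="CO" if is_co else "NCO",
            tract_start=start,
            tract_end=end,
            covered_test_locus=start <= params.test_locus <= end,
            mmr_outcome=None,
        )
    template = (2 + template_choice) if chromatid < 2 else template_choice
    covers = start <= params.test_locus <= end
    outcome: Optional[str] = None
    if covers:
        if alleles[chromatid] == alleles[template]:
            outcome = "no_mismatch"
        elif convert:
            alleles[chromatid] = alleles[template]
            outcome = "converted"
        else:
            outcome = "restored"
    if is_co:
        # reciprocal exchange of everything distal to the conversion tract
        for values, locus in (
            (alleles, params.test_locus),
            (left, params.flank_left),
            (right, params.flank_right),
        ):
            if locus is not None and locus > end:
                values[chromatid], values[template] = values[template], values[chromatid]
    return MeiosisEvent(
        dsb_position=pos,
        broken_chromatid=chromatid,
        template="homolog",
        template_chromatid=template,
        pathway="CO" if is_co else "NCO",
        tract_start=start,
        tract_end=end,
        covered_test_locus=covers,
        mmr_outcome=outcome,
    )


def _draw_n_dsb(params: SimulationParams, rng: np.random.Generator, size: int | None = None):
    if params.dsb_law == "fixed":
        d = round(params.dsb_mean)
        return d if size is None else np.full(size, d, dtype=np.int64)
    draw = rng.poisson(params.dsb_mean, size=size)
    return int(draw) if size is None else draw.astype(np.int64)


def simulate_tetrad(
    params: SimulationParams, rng: np.random.Generator, tetrad_id: str = "sim"
) -> tuple[TetradPhenotype, list[MeiosisEvent]]:
    """Simulate one meiosis and its pollen tetrad."""
    alleles = [True, True, False, False]          # fluorescent test allele
    left = [True, True, False, False]             # hemizygous left marker
    right = [True, True, False, False]            # hemizygous right marker
    events: list[MeiosisEvent] = []
    for _ in range(_draw_n_dsb(params, rng)):
        events.append(_apply_event(alleles, left, right, params, *_draw_event_fields(params, rng)))

    order = rng.permutation(4)
    has_left = params.flank_left is not None
    has_right = params.flank_right is not None

    if params.misgrouping_rate > 0 and rng.random() < params.misgrouping_rate:
        # mechanical re-association: four unrelated grains, each drawn from the
        # population of parental chromatid types (fluorescent w.p. 1/2)
        kinds = rng.random(4) < 0.5
        grain_states = [(bool(k), bool(k), bool(k)) for k in kinds]
    else:
        grain_states = [(left[c], alleles[c], right[c]) for c in order]

    grains = []
    for l, y, r in grain_states:
        if not y and params.reversion_rate > 0 and rng.random() < params.reversion_rate:
            y = True  # back-mutation restores fluorescence
        grains.append((l if has_left else None, y, r if has_right else None))
    return TetradPhenotype(tetrad_id=tetrad_id, grains=tuple(grains)), events


@dataclass(frozen=True)
class ExperimentResult:
    counts: TetradCounts
    phenotypes: list[TetradPhenotype]
    events: list[list[MeiosisEvent]]
    seed: Optional[int]


def _counts_from_yellow(y: np.ndarray, label: str) -> TetradCounts:
    return TetradCounts(
        label=label,
        n_tetrads=int(y.size),
        n_31=int(np.count_nonzero(y == 3)),
        n_13=int(np.count_nonzero(y == 1)),
        n_40=int(np.count_nonzero(y == 4)),
        n_04=int(np.count_nonzero(y == 0)),
    )


def simulate_experiment(
    params: SimulationParams,
    n_tetrads: int,
    seed: Optional[int] = None,
    label: str = "simulated",
) -> ExperimentResult:
    """Simulate ``n_tetrads`` meioses, keeping phenotypes and event logs.

    Fully reproducible: the same seed yields identical output.  For
    counts-only runs at large n prefer :func:`simulate_counts`.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    phenotypes: list[TetradPhenotype] = []
    event_log: list[list[MeiosisEvent]] = []
    yellow = np.empty(n_tetrads, dtype=np.int64)
    for i in range(n_tetrads):
        pheno, events = simulate_tetrad(params, rng, tetrad_id=f"T{i + 1:06d}")
        phenotypes.append(pheno)
        event_log.append(events)
        yellow[i] = sum(1 for g in pheno.grains if g[1] is True)
    return ExperimentResult(
        counts=_counts_from_yellow(yellow, label),
        phenotypes=phenotypes,
        events=event_log,
        seed=seed,
    )


def simulate_counts(
    params: SimulationParams,
    n_tetrads: int,
    seed: Optional[int] = None,
    label: str = "simulated",
) -> TetradCounts:
    """Vectorized counts-only simulation from the same generative law.

    Crossovers exchange alleles reciprocally and never change segregation
    counts on their own, so only tetrads containing at least one
    locus-covering homolog-templated repair need chromatid-level replay;
    everything else stays 2:2 before noise.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    # block the run so event arrays stay a few million entries at most
    block = max(1, int(5_000_000 / max(params.dsb_mean, 1.0)))
    parts = []
    done = 0
    while done < n_tetrads:
        size = min(block, n_tetrads - done)
        parts.append(_simulate_yellow_block(params, size, rng))
        done += size
    return _counts_from_yellow(np.concatenate(parts), label)


def _simulate_yellow_block(params: SimulationParams, n_tetrads: int, rng: np.random.Generator) -> np.ndarray:
    """Fluorescent-grain counts for one block of tetrads (vectorized)."""
    G, t = params.genome_length, params.test_locus

    d_arr = _draw_n_dsb(params, rng, size=n_tetrads)
    m = int(d_arr.sum())
    yellow = np.full(n_tetrads, 2, dtype=np.int64)

    if m > 0:
        pos = rng.integers(1, G + 1, size=m)
        chromatid = rng.integers(0, 4, size=m)
        homolog = rng.random(m) < params.p_homolog
        template_choice = rng.integers(0, 2, size=m)
        is_co = rng.random(m) < params.p_co
        length = _draw_tract_length(params, rng, size=m)
        offset = (rng.random(m) * length).astype(np.int64)
        convert = rng.random(m) < params.p_conversion

        start = pos - offset
        covers = (start <= t) & (t <= start + length - 1)
        effective = homolog & covers

        bounds = np.concatenate(([0], np.cumsum(d_arr)))
        tetrad_of = np.repeat(np.arange(n_tetrads), d_arr)
        hot = np.unique(tetrad_of[effective])
        for j in hot:
            alleles = [True, True, False, False]
            left = [True, True, False, False]
            right = [True, True, False, False]
            for i in range(bounds[j], bounds[j + 1]):
                _apply_event(
                    alleles, left, right, params,
                    int(pos[i]), int(chromatid[i]), bool(homolog[i]), int(template_choice[i]),
                    bool(is_co[i]), int(length[i]), int(offset[i]), bool(convert[i]),
                )
            yellow[j] = sum(alleles)

    if params.misgrouping_rate > 0:
        mask = rng.random(n_tetrads) < params.misgrouping_rate
        yellow[mask] = rng.binomial(4, 0.5, size=int(mask.sum()))
    if params.reversion_rate > 0:
        yellow = yellow + rng.binomial(4 - yellow, params.reversion_rate)
    return yellow


# ---------------------------------------------------------------------------
# closed forms and parameter recovery

def expected_adjusted_frequency(params: SimulationParams) -> float:
    """First-order closed form for the adjusted (doubled 3:1) frequency.

    Per DSB, the chance of converting the test locus in a given direction is
    (1/2) * p_homolog * (L/G) * p_conversion (the 1/2 picks which homolog
    broke); with D expected DSBs the 3:1 class frequency is D times that,
    and doubling gives D * p_homolog * (L/G) * p_conversion.  Exact up to
    multi-event parity terms of order (D * L/G)^2 and noise.
    """
    return (
        params.dsb_mean
        * params.p_homolog
        * (params.tract_mean / params.genome_length)
        * params.p_conversion
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Estimator / tract-model recovery against programmed simulator truth."""

    expected_frequency: float
    observed_frequency: float
    frequency_se: float            # binomial SE of the adjusted frequency
    within_3se: bool
    tract_true: float
    tract_recovered: Optional[float]
    tract_relative_error: Optional[float]
    sufficient_events: bool


def recover_parameters(sim_counts: TetradCounts, params: SimulationParams) -> RecoveryReport:
    """Close the loop: estimate frequency from simulated counts and invert
    the closed form to recover the programmed tract length."""
    est = estimate_frequency(sim_counts)
    f_exp = expected_adjusted_frequency(params)
    p31 = f_exp / 2.0
    se = 2.0 * math.sqrt(max(p31 * (1.0 - p31), 0.0) / sim_counts.n_tetrads)
    sufficient = sim_counts.n_31 > 0
    per_nt = params.dsb_mean * params.p_homolog * params.p_conversion / params.genome_length
    tract_rec = est.adjusted_frequency / per_nt if (sufficient and per_nt > 0) else None
    return RecoveryReport(
        expected_frequency=f_exp,
        observed_frequency=est.adjusted_frequency,
        frequency_se=se,
        within_3se=abs(est.adjusted_frequency - f_exp) <= 3.0 * se if se > 0 else est.adjusted_frequency == f_exp,
        tract_true=params.tract_mean,
        tract_recovered=tract_rec,
        tract_relative_error=(abs(tract_rec - params.tract_mean) / params.tract_mean) if tract_rec is not None else None,
        sufficient_events=sufficient,
    )
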