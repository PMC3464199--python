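"""CO/NCO classification of conversion tetrads from three-color phenotypes.

In the three-color layout a hemizygous DsRed transgene and a hemizygous
AmCyan transgene flank the heterozygous eYFP test locus, all in coupling on
one homolog.  A 3:1 yellow tetrad marks a gene conversion at the test locus;
whether the flanking red/cyan markers stayed in their parental configuration
(both present or both absent in every grain) or recombined decides whether
the conversion rode along with a crossover (DSBR outcome) or a non-crossover
(SDSA outcome).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .tetrad_data import TetradPhenotype

__all__ = ["ConversionClass", "MarkerLayout", "ClassSummary", "classify_tetrad", "summarize_classes"]


class ConversionClass(enum.Enum):
    NO_GC = "no_gc"            # Mendelian 2:2 at the test locus
    GC_31 = "gc_31"            # 3:1 conversion, flanking markers not scored
    GC_13 = "gc_13"            # 1:3 class; recorded but excluded from conversion counts
    CO_GC = "co_gc"            # 3:1 conversion with recombinant flanking markers
    NCO_GC = "nco_gc"          # 3:1 conversion, flanking markers all parental
    AMBIGUOUS = "ambiguous"    # 3:1 conversion but a flanking signal is unscorable
    ABERRANT = "aberrant"      # segregation inconsistent with a single meiosis


@dataclass(frozen=True)
class MarkerLayout:
    """Channel roles in a tetrad phenotype record.

    The default is the assay's DsRed — eYFP — AmCyan interval; other
    triple-color intervals map their channels here.  ``flanking=False``
    describes a plain two-color conversion assay: 3:1 tetrads are then
    reported as ``GC_31`` without CO/NCO resolution.
    """

    test_channel: int = 1   # yellow
    left_channel: int = 0   # red
    right_channel: int = 2  # cyan
    flanking: bool = True

    @classmethod
    def from_config(cls, path: str | Path) -> "MarkerLayout":
        """Read a flat key=value layout file (channels named red/yellow/cyan)."""
        names = {"red": 0, "yellow": 1, "cyan": 2}
        kv: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            test_channel=names[kv.get("test_channel", "yellow")],
            left_channel=names[kv.get("left_channel", "red")],
            right_channel=names[kv.get("right_channel", "cyan")],
            flanking=kv.get("flanking", "1") not in ("0", "false", "no"),
        )


def _count(values: Sequence[Optional[bool]]) -> tuple[int, int, int]:
    present = sum(1 for v in values if v is True)
    absent = sum(1 for v in values if v is False)
    unknown = sum(1 for v in values if v is None)
    return present, absent, unknown


def classify_tetrad(tetrad: TetradPhenotype, layout: MarkerLayout = MarkerLayout()) -> ConversionClass:
    """Assign a conversion class to one tetrad.

    3:1 tetrads with full flanking information are split into CO_GC
    (recombinant flanking grains present) and NCO_GC (every grain parental);
    an unscorable flanking channel on any conversion-carrying grain yields
    AMBIGUOUS.  Patterns impossible for a single meiosis — flanking channels
    off 2:2, or multiply-recombinant flank configurations — are ABERRANT
    rather than guessed.
    """
    yellow = tetrad.channel(layout.test_channel)
    y_present, y_absent, y_unknown = _count(yellow)
    if y_unknown:
        return ConversionClass.AMBIGUOUS
    if y_present == 2 and y_absent == 2:
        return ConversionClass.NO_GC
    if y_present == 1 and y_absent == 3:
        return ConversionClass.GC_13
    if not (y_present == 3 and y_absent == 1):
        return ConversionClass.ABERRANT  # 4:0 / 0:4 cannot come from one heterozygous meiosis
    if not layout.flanking:
        return ConversionClass.GC_31

    left = tetrad.channel(layout.left_channel)
    right = tetrad.channel(layout.right_channel)
    # Unscorable flanking signal on any fluorescent (conversion-side) grain
    # blocks the CO/NCO call.
    for grain, y in zip(tetrad.grains, yellow):
        if y is True and (grain[layout.left_channel] is None or grain[layout.right_channel] is None):
            return ConversionClass.AMBIGUOUS
    for chan in (left, right):
        p, a, u = _count(chan)
        if u == 0 and (p, a) != (2, 2):
            return ConversionClass.ABERRANT  # hemizygous markers must segregate 2:2
    # Given 2:2 marker segregation the call is determined by the three
    # conversion-side (yellow-positive) grains; the fourth is forced.
    pairs = [
        (grain[layout.left_channel], grain[layout.right_channel])
        for grain, y in zip(tetrad.grains, yellow)
        if y is True
    ]
    parental = sum(1 for l, r in pairs if l == r)
    left_only = sum(1 for l, r in pairs if l is True and r is False)
    right_only = sum(1 for l, r in pairs if l is False and r is True)
    if parental == len(pairs):
        return ConversionClass.NCO_GC
    if left_only == 1 and right_only == 1:
        return ConversionClass.CO_GC
    return ConversionClass.ABERRANT  # e.g. double-CO flank patterns


@dataclass(frozen=True)
class ClassSummary:
    counts: dict[ConversionClass, int]

    @property
    def n_classified(self) -> int:
        """Conversions with a definite CO/NCO call."""
        return self.counts[ConversionClass.CO_GC] + self.counts[ConversionClass.NCO_GC]

    @property
    def co_nco_ratio(self) -> Optional[float]:
        """CO:NCO ratio among classified conversions; None if no NCOs."""
        nco = self.counts[ConversionClass.NCO_GC]
        if nco == 0:
            return None
        return self.counts[ConversionClass.CO_GC] / nco

    def total(self) -> int:
        return sum(self.counts.values())


def summarize_classes(
    tetrads: Iterable[TetradPhenotype], layout: MarkerLayout = MarkerLayout()
) -> ClassSummary:
    """Classify every tetrad and tally per-class counts."""
    tally: Counter[ConversionClass] = Counter()
    for t in tetrads:
        tally[classify_tetrad(t, layout)] += 1
    return ClassSummary(counts={cls: tally.get(cls, 0) for cls in ConversionClass})
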