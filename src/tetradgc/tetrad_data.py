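"""Domain types and I/O for fluorescent pollen-tetrad gene-conversion data.

The central objects are per-locus segregation-class counts (``TetradCounts``)
and per-tetrad fluorescence phenotypes (``TetradPhenotype``).  A bundled
reference dataset carries the allele descriptions and genome-wide conversion
counts of a seven-locus *Arabidopsis thaliana* tetrad screen, used throughout
the package as fixed numeric input.

Conventions: coordinates are 1-based inclusive; tables are UTF-8 TSV with
"." as the decimal mark; fluorescence channel values are 1 (present),
0 (absent) or NA (unscorable — distinct from absent).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AlleleRecord",
    "TetradCounts",
    "TetradPhenotype",
    "TableFormatError",
    "parse_mutation",
    "read_counts_table",
    "write_counts_table",
    "read_tetrad_phenotypes",
    "write_tetrad_phenotypes",
    "load_reference_data",
    "load_three_color_example",
    "COUNTS_COLUMNS",
    "TETRAD_COLUMNS",
]

COUNTS_COLUMNS = ["label", "chromosome", "n_31", "n_tetrads", "n_13", "n_40", "n_04", "genome_panel"]
TETRAD_COLUMNS = ["tetrad_id", "grain", "red", "yellow", "cyan"]

_MUTATION_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


class TableFormatError(ValueError):
    """A table is structurally malformed (missing column, bad token)."""


def parse_mutation(code: str) -> tuple[str, int, str]:
    """Split a point-mutation code like ``G95A`` into (ref, position, alt).

    The position is the 1-based nucleotide within the fluorophore coding
    sequence, counted from the transcriptional start site.
    """
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise TableFormatError(f"unrecognized mutation code: {code!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class AlleleRecord:
    """A non-fluorescent (EMS-derived) allele of a fluorescent transgene locus."""

    allele_name: str
    chromosome: int
    transgene_position: int
    fluorophore: str
    snp_position: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chromosome not in {1, 2, 3, 4, 5}:
            raise ValueError(f"{self.allele_name}: chromosome must be 1-5, got {self.chromosome}")
        if self.fluorophore not in {"yfp", "dsred", "amcyan"}:
            raise ValueError(f"{self.allele_name}: unknown fluorophore {self.fluorophore!r}")
        if self.snp_position is not None and self.snp_position < 1:
            raise ValueError(f"{self.allele_name}: snp_position must be >= 1")


@dataclass(frozen=True)
class TetradCounts:
    """Segregation-class counts from one locus/condition.

    ``n_31`` counts tetrads with three fluorescent and one non-fluorescent
    grain — the scorable gene-conversion class.  The reciprocal 1:3 class and
    the 4:0 / 0:4 classes are stored but never added to conversion counts;
    2:2 is the Mendelian remainder.
    """

    label: str
    n_tetrads: int
    n_31: int
    n_13: int = 0
    n_40: int = 0
    n_04: int = 0
    chromosome: Optional[int] = None
    genome_panel: bool = True

    def __post_init__(self) -> None:
        for name in ("n_tetrads", "n_31", "n_13", "n_40", "n_04"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{self.label}: {name} must be a non-negative integer, got {v!r}")
        if self.n_31 + self.n_13 + self.n_40 + self.n_04 > self.n_tetrads:
            raise ValueError(
                f"{self.label}: segregation-class counts exceed total tetrads "
                f"({self.n_31}+{self.n_13}+{self.n_40}+{self.n_04} > {self.n_tetrads})"
            )

    @property
    def n_22(self) -> int:
        """Mendelian 2:2 tetrads, derived as the remainder."""
        return self.n_tetrads - self.n_31 - self.n_13 - self.n_40 - self.n_04


# Channel value: True = present, False = absent, None = unscorable.
Grain = tuple[Optional[bool], Optional[bool], Optional[bool]]


@dataclass(frozen=True)
class TetradPhenotype:
    """One pollen tetrad: four grains x (red, yellow, cyan) fluorescence."""

    tetrad_id: str
    grains: tuple[Grain, ...]

    def __post_init__(self) -> None:
        if len(self.grains) != 4:
            raise ValueError(f"tetrad {self.tetrad_id}: expected exactly 4 grains, got {len(self.grains)}")

    def channel(self, index: int) -> tuple[Optional[bool], ...]:
        """Values of one channel (0=red, 1=yellow, 2=cyan) across the 4 grains."""
        return tuple(g[index] for g in self.grains)


# ---------------------------------------------------------------------------
# counts tables

def _parse_int(token: object, column: str, label: str) -> int:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        raise TableFormatError(f"row {label!r}: missing value in column {column!r}")
    s = str(token).strip()
    if not re.fullmatch(r"[+-]?\d+", s):
        raise TableFormatError(f"row {label!r}: malformed integer {s!r} in column {column!r}")
    return int(s)


def _opt_int(token: object, column: str, label: str, default: int = 0) -> int:
    if token is None or (isinstance(token, float) and pd.isna(token)) or str(token).strip() == "":
        return default
    return _parse_int(token, column, label)


def read_counts_table(path: str | Path) -> list[TetradCounts]:
    """Read a per-locus segregation-count TSV.

    Required columns: ``label``, ``n_31``, ``n_tetrads``.  Optional:
    ``chromosome``, ``n_13``, ``n_40``, ``n_04``, ``genome_panel``.
    Lines starting with ``#`` are metadata headers and are skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("label", "n_31", "n_tetrads"):
        if col not in df.columns:
            raise TableFormatError(f"counts table {path}: missing required column {col!r}")
    out: list[TetradCounts] = []
    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        out.append(
            TetradCounts(
                label=label,
                n_tetrads=_parse_int(row["n_tetrads"], "n_tetrads", label),
                n_31=_parse_int(row["n_31"], "n_31", label),
                n_13=_opt_int(row.get("n_13"), "n_13", label),
                n_40=_opt_int(row.get("n_40"), "n_40", label),
                n_04=_opt_int(row.get("n_04"), "n_04", label),
                chromosome=(
                    _opt_int(row.get("chromosome"), "chromosome", label, default=-1)
                    if "chromosome" in df.columns and str(row.get("chromosome", "")).strip() not in ("", "nan")
                    else None
                ),
                genome_panel=bool(_opt_int(row.get("genome_panel"), "genome_panel", label, default=1)),
            )
        )
    return out


def write_counts_table(counts: Iterable[TetradCounts], path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write counts as TSV; ``header_lines`` become leading ``#`` comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for c in counts:
            chrom = "" if c.chromosome is None else str(c.chromosome)
            fh.write(
                f"{c.label}\t{chrom}\t{c.n_31}\t{c.n_tetrads}\t{c.n_13}\t{c.n_40}\t{c.n_04}\t{int(c.genome_panel)}\n"
            )


# ---------------------------------------------------------------------------
# tetrad phenotype tables

_CHANNEL_TOKENS = {"1": True, "0": False, "NA": None}


def _parse_channel(token: object, column: str, tetrad_id: str) -> Optional[bool]:
    s = "NA" if token is None or (isinstance(token, float) and pd.isna(token)) else str(token).strip()
    if s not in _CHANNEL_TOKENS:
        raise TableFormatError(f"tetrad {tetrad_id!r}: unknown {column} channel token {s!r} (expected 0/1/NA)")
    return _CHANNEL_TOKENS[s]


def read_tetrad_phenotypes(path: str | Path) -> list[TetradPhenotype]:
    """Read a per-grain phenotype TSV into tetrads (4 grains each, file order)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in TETRAD_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"tetrad table {path}: missing required column {col!r}")
    out: list[TetradPhenotype] = []
    for tid, group in df.groupby("tetrad_id", sort=False):
        if len(group) != 4:
            raise ValueError(f"tetrad {tid!r}: expected exactly 4 grains, got {len(group)}")
        group = group.copy()
        group["_gi"] = [_parse_int(g, "grain", str(tid)) for g in group["grain"]]
        if sorted(group["_gi"]) != [1, 2, 3, 4]:
            raise ValueError(f"tetrad {tid!r}: grain indices must be 1-4, got {sorted(group['_gi'])}")
        grains = tuple(
            (
                _parse_channel(row["red"], "red", str(tid)),
                _parse_channel(row["yellow"], "yellow", str(tid)),
                _parse_channel(row["cyan"], "cyan", str(tid)),
            )
            for _, row in group.sort_values("_gi").iterrows()
        )
        out.append(TetradPhenotype(tetrad_id=str(tid), grains=grains))
    return out


def write_tetrad_phenotypes(
    tetrads: Iterable[TetradPhenotype], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    fmt = {True: "1", False: "0", None: "NA"}
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(TETRAD_COLUMNS) + "\n")
        for t in tetrads:
            for i, (r, y, c) in enumerate(t.grains, start=1):
                fh.write(f"{t.tetrad_id}\t{i}\t{fmt[r]}\t{fmt[y]}\t{fmt[c]}\n")


# ---------------------------------------------------------------------------
# bundled reference dataset

def _data_path(name: str):
    return resources.files("tetradgc.data").joinpath(name)


def load_reference_data() -> tuple[list[AlleleRecord], list[TetradCounts]]:
    """Load the bundled reference dataset of the genome-wide tetrad screen.

    Returns 17 allele records (15 sequenced; two carry null mutation fields
    because they were never sequenced) and 8 count records: the seven
    genome-panel loci plus a second allele of the chromosome-3 locus
    (``genome_panel=False``) used for the intra-locus comparison.
    """
    adf = pd.read_csv(_data_path("alleles.tsv"), sep="\t", dtype=str)
    alleles: list[AlleleRecord] = []
    for _, row in adf.iterrows():
        mut = row["mutation"]
        if isinstance(mut, str) and mut.strip():
            ref, pos, alt = parse_mutation(mut)
            aa = row["aa_change"].strip()
        else:
            ref = alt = aa = None
            pos = None
        alleles.append(
            AlleleRecord(
                allele_name=row["allele_name"].strip(),
                chromosome=int(row["chromosome"]),
                transgene_position=int(row["transgene_position"]),
                fluorophore=row["fluorophore"].strip(),
                snp_position=pos,
                ref_base=ref,
                alt_base=alt,
                aa_change=aa,
            )
        )
    counts = read_counts_table(_data_path("counts.tsv"))
    return alleles, counts


def load_three_color_example() -> list[TetradPhenotype]:
    """Load the synthetic three-color conversion-tetrad example set.

    Thirteen 3:1 tetrads from a DsRed — eYFP-test-locus — AmCyan interval,
    reconstructed to match the reported class totals of the screen's
    three-color experiment (11 crossover-pattern, 1 non-crossover-pattern,
    1 with an unscorable AmCyan signal).  The grain-level patterns are
    synthetic: only the class totals are constrained by the source counts.
    """
    return read_tetrad_phenotypes(_data_path("three_color_conversions_synthetic.tsv"))
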