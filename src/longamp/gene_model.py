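"""Gene model: reference sequence, exon/CDS structure and the amplicon panel.

The model is the coordinate authority for the whole pipeline: every
conversion between genomic (reference) coordinates, coding-sequence (CDS)
coordinates and report-level labels (promoter / exon N / intron / UTR) goes
through it.

Coordinates are 1-based inclusive at the API boundary (HGVS, GFF3, reports)
and 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Interval",
    "GeneModel",
    "Amplicon",
    "NonCoding",
    "CoverageReport",
    "load_gene_model",
    "load_amplicons",
    "genomic_to_cds",
    "cds_to_genomic",
    "amplicon_coverage_check",
]

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open reference interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    @classmethod
    def from_1based(cls, start1: int, end1: int) -> "Interval":
        """Build from a 1-based inclusive pair (the GFF3/HGVS convention)."""
        return cls(start1 - 1, end1)

    def to_1based(self) -> tuple[int, int]:
        return (self.start + 1, self.end)


@dataclass(frozen=True)
class NonCoding:
    """Marker returned for reference positions outside the CDS."""

    region: str  # promoter | intron | utr | downstream
    exon: int | None = None  # 1-based exon number for UTR positions
    intron: int | None = None  # 1-based intron number for intronic positions


@dataclass
class GeneModel:
    name: str
    reference: str
    exons: list[Interval]
    cds_intervals: list[Interval]
    strand: str = "+"
    complete: bool = True
    _cds: str = field(init=False, repr=False, default="")

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        bad = set(self.reference) - _VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGTN characters: {sorted(bad)}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        n = len(self.reference)
        for which, ivs in (("exon", self.exons), ("CDS", self.cds_intervals)):
            if not ivs:
                raise ValueError(f"gene model needs at least one {which} interval")
            for iv in ivs:
                if iv.end > n:
                    raise ValueError(
                        f"{which} interval {iv.to_1based()} exceeds reference length {n}"
                    )
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"{which} intervals overlap or are unsorted: {a}, {b}")
        exon_pos = set()
        for iv in self.exons:
            exon_pos.update(range(iv.start, iv.end))
        for iv in self.cds_intervals:
            if not set(range(iv.start, iv.end)) <= exon_pos:
                raise ValueError(f"CDS interval {iv.to_1based()} not contained in exons")
        self._cds = "".join(self.reference[iv.start : iv.end] for iv in self.cds_intervals)
        if self.complete:
            if len(self._cds) % 3 != 0:
                raise ValueError(f"CDS length {len(self._cds)} not divisible by 3")
            if not self._cds.startswith("ATG"):
                raise ValueError("complete CDS must start with ATG")
            if self._cds[-3:] not in ("TAA", "TAG", "TGA"):
                raise ValueError("complete CDS must end with a stop codon")

    @property
    def cds(self) -> str:
        """Concatenated coding sequence (gene-forward orientation)."""
        return self._cds

    def __len__(self) -> int:
        return len(self.reference)

    def exon_number(self, pos1: int) -> int | None:
        """1-based exon number containing a 1-based position, or None."""
        pos0 = pos1 - 1
        for i, iv in enumerate(self.exons, start=1):
            if iv.contains(pos0):
                return i
        return None


@dataclass(frozen=True)
class Amplicon:
    """One PCR fragment of the panel; reads are full-length copies of it."""

    id: str
    interval: Interval
    expected_copies: float = 1.0  # relative molarity weight (equimolar default)

    def __post_init__(self) -> None:
        if self.expected_copies <= 0:
            raise ValueError("expected_copies must be positive")


def genomic_to_cds(model: GeneModel, genomic_pos: int) -> int | NonCoding:
    """Map a 1-based reference position to a 1-based CDS position.

    Non-coding positions return a :class:`NonCoding` marker labelled
    promoter (upstream of exon 1), intron, utr (exonic but outside the
    CDS) or downstream (past the last exon).
    """
    pos0 = genomic_pos - 1
    if pos0 < 0 or pos0 >= len(model.reference):
        raise ValueError(f"position {genomic_pos} outside reference (1..{len(model.reference)})")
    offset = 0
    for iv in model.cds_intervals:
        if iv.contains(pos0):
            return offset + (pos0 - iv.start) + 1
        offset += len(iv)
    exon = model.exon_number(genomic_pos)
    if exon is not None:
        return NonCoding("utr", exon=exon)
    if pos0 < model.exons[0].start:
        return NonCoding("promoter")
    if pos0 >= model.exons[-1].end:
        return NonCoding("downstream")
    for i, (a, b) in enumerate(zip(model.exons, model.exons[1:]), start=1):
        if a.end <= pos0 < b.start:
            return NonCoding("intron", intron=i)
    raise AssertionError("unreachable: position classified nowhere")


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Map a 1-based CDS position back to the 1-based reference position."""
    if cds_pos < 1:
        raise ValueError("CDS positions are 1-based")
    offset = cds_pos - 1
    for iv in model.cds_intervals:
        if offset < len(iv):
            return iv.start + offset + 1
        offset -= len(iv)
    raise ValueError(f"CDS position {cds_pos} beyond CDS length {len(model.cds)}")


@dataclass
class CoverageReport:
    covered: list[Interval]
    gaps: list[Interval]

    @property
    def passed(self) -> bool:
        return not self.gaps


def amplicon_coverage_check(model: GeneModel, panel: list[Amplicon]) -> CoverageReport:
    """Check that the amplicon panel covers every CDS base.

    Returns the CDS intervals covered by the union of the panel and any
    uncovered gaps (1-based-convertible intervals). Passing means no gaps.
    """
    if not panel:
        raise ValueError("amplicon panel is empty")
    covered_pos: set[int] = set()
    for amp in panel:
        if amp.interval.end > len(model.reference):
            raise ValueError(f"amplicon {amp.id} outside reference bounds")
        covered_pos.update(range(amp.interval.start, amp.interval.end))
    covered: list[Interval] = []
    gaps: list[Interval] = []
    for iv in model.cds_intervals:
        run_start: int | None = None
        run_is_gap = False
        for pos in range(iv.start, iv.end + 1):
            is_gap = pos < iv.end and pos not in covered_pos
            if run_start is None:
                run_start, run_is_gap = pos, is_gap
            elif pos == iv.end or is_gap != run_is_gap:
                (gaps if run_is_gap else covered).append(Interval(run_start, pos))
                run_start, run_is_gap = pos, is_gap
    return CoverageReport(covered=covered, gaps=gaps)


# ---------------------------------------------------------------------------
# File loading


def _read_single_fasta(path: Path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise ValueError(f"{path}: expected a single record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def _intervals_from_bed(path: Path) -> pd.DataFrame:
    """BED is 0-based half-open; column 4 names the feature (exon/CDS/id)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )
    return df


def _intervals_from_gff3(path: Path) -> pd.DataFrame:
    """GFF3 is 1-based inclusive; converted to 0-based half-open here."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.all_features():
        rows.append(
            {
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "name": feat.featuretype,
            }
        )
    return pd.DataFrame(rows)


def _load_feature_table(path: Path, dialect: str) -> pd.DataFrame:
    if dialect == "bed":
        return _intervals_from_bed(path)
    if dialect == "gff3":
        return _intervals_from_gff3(path)
    raise ValueError(f"unknown annotation dialect {dialect!r} (use 'bed' or 'gff3')")


def load_gene_model(
    fasta_path: str | Path,
    annotation_path: str | Path,
    *,
    dialect: str = "bed",
    strand: str = "+",
    complete: bool = True,
) -> GeneModel:
    """Load a gene model from a single-record FASTA and an interval file.

    The annotation dialect is declared, never guessed: ``bed`` (0-based
    half-open) or ``gff3`` (1-based inclusive). Feature names ``exon`` and
    ``CDS`` (case-insensitive) select the respective intervals.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)
    name, seq = _read_single_fasta(fasta_path)
    table = _load_feature_table(annotation_path, dialect)
    kinds = table["name"].str.lower()
    exons = [Interval(r.start, r.end) for r in table[kinds == "exon"].itertuples()]
    cds = [Interval(r.start, r.end) for r in table[kinds == "cds"].itertuples()]
    exons.sort()
    cds.sort()
    return GeneModel(
        name=name, reference=seq, exons=exons, cds_intervals=cds,
        strand=strand, complete=complete,
    )


def load_amplicons(path: str | Path, *, dialect: str = "bed") -> list[Amplicon]:
    """Load the amplicon panel; the name column is the amplicon id."""
    table = _load_feature_table(Path(path), dialect)
    return [
        Amplicon(id=str(r.name), interval=Interval(r.start, r.end))
        for r in table.itertuples()
    ]
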