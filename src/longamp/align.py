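"""Read alignment and strand-aware pileup assembly.

Amplicon reads have a known, single target, so alignment is semi-global
(free end gaps on the reference side): each read, or its reverse
complement, is placed as a whole inside the reference. The engine is
edlib's infix mode with an extended CIGAR; an identity floor rejects
junk reads as unmapped. The pileup tallies per-position, per-strand base
and deletion counts plus anchored insertions, and is the sole substrate
for variant calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .gene_model import Amplicon, GeneModel

__all__ = [
    "Alignment",
    "Pileup",
    "PileupColumn",
    "align_read",
    "align_reads",
    "build_pileup",
    "coverage_stats",
    "write_sam",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
DEL_CODE = 4
_CODE_LOOKUP = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _CODE_LOOKUP[ord(_b)] = _c


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Alignment:
    read_id: str
    ref_start: int  # 0-based
    ref_end: int  # half-open
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]  # ops '=', 'X', 'I', 'D'
    edit_distance: int
    identity: float
    mapped: bool = True

    def oriented_query(self, read_seq: str) -> str:
        """Read sequence in reference orientation."""
        return read_seq if self.strand == "+" else reverse_complement(read_seq)


_CIGAR_OPS = set("=XIDM")


def _parse_cigar(text: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"unexpected CIGAR symbol {ch!r}")
    return ops


def _identity(cigar: list[tuple[str, int]]) -> float:
    matches = sum(n for op, n in cigar if op == "=")
    columns = sum(n for _, n in cigar)
    return matches / columns if columns else 0.0


def align_read(
    read_seq: str,
    model: GeneModel,
    read_id: str = "read",
    *,
    min_length: int = 200,
    min_identity: float = 0.70,
) -> Alignment:
    """Semi-global alignment of one read against the gene reference.

    Both orientations are tried; the lower edit distance wins, ties going
    to the forward strand. Reads shorter than ``min_length`` or below the
    identity floor come back with ``mapped=False``.
    """
    if not read_seq:
        raise ValueError("empty read")
    read_seq = read_seq.upper()
    if len(read_seq) < min_length:
        return Alignment(read_id, 0, 0, "+", [], -1, 0.0, mapped=False)
    # orientation by distance first; the (costlier) path only for the winner
    fwd_d = edlib.align(read_seq, model.reference, mode="HW", task="distance")
    if fwd_d["editDistance"] == 0:
        strand = "+"  # an exact forward hit cannot be beaten (ties go forward)
    else:
        rev_d = edlib.align(
            reverse_complement(read_seq), model.reference, mode="HW", task="distance"
        )
        strand = "-" if rev_d["editDistance"] < fwd_d["editDistance"] else "+"
    query = read_seq if strand == "+" else reverse_complement(read_seq)
    res = edlib.align(query, model.reference, mode="HW", task="path")
    start, end = res["locations"][0]
    cigar = _parse_cigar(res["cigar"])
    identity = _identity(cigar)
    mapped = identity >= min_identity
    return Alignment(
        read_id=read_id, ref_start=start, ref_end=end + 1, strand=strand,
        cigar=cigar, edit_distance=res["editDistance"], identity=identity,
        mapped=mapped,
    )


def align_reads(
    reads: dict[str, str], model: GeneModel, **kwargs
) -> list[Alignment]:
    """Align a batch of reads; order follows the input mapping.

    Identical read sequences share one alignment computation (amplicon
    sequencing produces many exact duplicates, error-free simulations
    almost nothing else).
    """
    from dataclasses import replace

    cache: dict[str, Alignment] = {}
    out: list[Alignment] = []
    for rid, seq in reads.items():
        hit = cache.get(seq)
        if hit is None:
            hit = align_read(seq, model, read_id=rid, **kwargs)
            cache[seq] = hit
            out.append(hit)
        else:
            out.append(replace(hit, read_id=rid))
    return out


@dataclass
class PileupColumn:
    """Per-position view of the pileup (1-based position)."""

    position: int
    counts_fwd: dict[str, int]  # A/C/G/T/'-' (deletion)
    counts_rev: dict[str, int]
    insertions: dict[str, tuple[int, int]]  # inserted seq -> (fwd, rev)

    @property
    def depth(self) -> int:
        return sum(self.counts_fwd.values()) + sum(self.counts_rev.values())


@dataclass
class Pileup:
    """Strand-split base/deletion counts over the whole reference.

    ``counts`` has shape (2 strands, 5 symbols, reference length); symbol
    rows are A, C, G, T, deletion. Insertions are anchored to the column
    of the base to their left, keyed by inserted sequence.
    """

    reference: str
    counts: np.ndarray
    insertions: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))

    def column(self, position: int) -> PileupColumn:
        j = position - 1
        if not 0 <= j < len(self.reference):
            raise ValueError(f"position {position} outside reference")
        symbols = "ACGT-"
        ins = {
            seq: (int(v[0]), int(v[1]))
            for seq, v in self.insertions.get(j, {}).items()
        }
        return PileupColumn(
            position=position,
            counts_fwd={s: int(self.counts[0, k, j]) for k, s in enumerate(symbols)},
            counts_rev={s: int(self.counts[1, k, j]) for k, s in enumerate(symbols)},
            insertions=ins,
        )

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready per-position table (fwd/rev counts per symbol, depth)."""
        cols = {}
        for si, strand in enumerate(("fwd", "rev")):
            for k, sym in enumerate(("A", "C", "G", "T", "del")):
                cols[f"{sym}_{strand}"] = self.counts[si, k]
        df = pd.DataFrame(cols)
        df.insert(0, "pos", np.arange(1, len(self.reference) + 1))
        df["depth"] = self.depth
        return df


def build_pileup(
    alignments: list[Alignment], reads: dict[str, str], model: GeneModel
) -> Pileup:
    """Assemble the strand-split pileup from mapped alignments.

    Every aligned base or deletion contributes to exactly one column, so
    column depth equals the number of reads whose alignment spans the
    column (depth conservation). Unmapped alignments are skipped.
    """
    n = len(model.reference)
    counts = np.zeros((2, 5, n), dtype=np.int64)
    insertions: dict[int, dict[str, np.ndarray]] = {}
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.ref_end > n or aln.ref_start < 0:
            raise ValueError(f"alignment of {aln.read_id} outside reference bounds")
        seq = aln.oriented_query(reads[aln.read_id])
        codes = _CODE_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]
        si = 0 if aln.strand == "+" else 1
        rpos, qpos = aln.ref_start, 0
        for op, length in aln.cigar:
            if op in "=XM":
                seg = codes[qpos : qpos + length]
                valid = seg >= 0  # skip N bases
                positions = np.arange(rpos, rpos + length)[valid]
                np.add.at(counts[si], (seg[valid].astype(np.intp), positions), 1)
                rpos += length
                qpos += length
            elif op == "D":
                counts[si, DEL_CODE, rpos : rpos + length] += 1
                rpos += length
            elif op == "I":
                anchor = rpos - 1
                if anchor >= 0:
                    ins_seq = seq[qpos : qpos + length]
                    slot = insertions.setdefault(anchor, {}).setdefault(
                        ins_seq, np.zeros(2, dtype=np.int64)
                    )
                    slot[si] += 1
                qpos += length
    return Pileup(reference=model.reference, counts=counts, insertions=insertions)


def coverage_stats(pileup: Pileup, panel: list[Amplicon]) -> pd.DataFrame:
    """Mean/min depth per amplicon plus a global row.

    Amplicons with zero coverage anywhere are flagged rather than erroring;
    a panel interval outside the pileup range raises at model construction
    already, so here every interval indexes validly.
    """
    depth = pileup.depth
    if depth.size == 0:
        raise ValueError("empty pileup")
    rows = []
    for amp in panel:
        d = depth[amp.interval.start : amp.interval.end]
        rows.append(
            {
                "amplicon": amp.id,
                "start": amp.interval.start + 1,
                "end": amp.interval.end,
                "mean_coverage": float(d.mean()),
                "min_coverage": int(d.min()),
                "flagged": bool((d == 0).any()),
            }
        )
    lo = min(a.interval.start for a in panel)
    hi = max(a.interval.end for a in panel)
    d = depth[lo:hi]
    rows.append(
        {
            "amplicon": "__global__",
            "start": lo + 1,
            "end": hi,
            "mean_coverage": float(d.mean()),
            "min_coverage": int(d.min()),
            "flagged": bool((d == 0).any()),
        }
    )
    return pd.DataFrame(rows)


def _cigar_for_sam(cigar: list[tuple[str, int]]) -> str:
    # SAM spec allows '=' and 'X'; collapse to M for wider tool support
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        op = "M" if op in "=X" else op
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return "".join(f"{n}{op}" for op, n in out)


def write_sam(
    alignments: list[Alignment],
    reads: dict[str, str],
    model: GeneModel,
    path: str | Path,
) -> None:
    """Export mapped alignments as plain-text SAM (mandatory fields only)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.name, "LN": len(model.reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            if not aln.mapped:
                continue
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.oriented_query(reads[aln.read_id])
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = aln.ref_start
            rec.mapping_quality = 60
            rec.cigarstring = _cigar_for_sam(aln.cigar)
            rec.set_tag("NM", aln.edit_distance)
            out.write(rec)
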