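"""Synthetic nanopore-like data: diploid genotypes, amplicon reads, truth tables.

The generator emulates the study conditions of a single-gene long-amplicon
nanopore run: equimolar full-length reads from a 5-amplicon panel covering
a promoter and 18 exons, drawn evenly from the two haplotypes of a diploid
genotype (heterozygous, homozygous or compound-heterozygous), on both
strands, with substitution and indel errors whose indel component is
inflated inside homopolymer/tandem-repeat context — the characteristic
nanopore error mode. Every injected variant is recorded in a truth table
so calling, filtering and zygosity classification can be scored exactly.

Also provides :func:`ldlr_like_gene`, a fully synthetic stand-in for the
LDLR RefSeqGene record: an 861-codon coding sequence split over 18 exons
with a promoter and a 5-amplicon panel, constructed so that the codons at
the classic FH variant positions (c.653, c.761, c.1474, c.1567, c.1729,
c.1844, c.1916) carry the amino acids those variants are known to affect.
The construction fixes codons directly and never consults the consequence
predictor, so it can serve as ground truth for it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import RepeatParams, repeat_context_mask
from .gene_model import Amplicon, GeneModel, Interval, cds_to_genomic
from .hgvs import CodingVariant
from .calling import left_align

__all__ = [
    "GenomicVariant",
    "GenotypeVariant",
    "GenotypeSpec",
    "ErrorModel",
    "Haplotype",
    "make_diploid_haplotypes",
    "simulate_reads",
    "subsample_reads",
    "write_fastq",
    "read_fastq",
    "ldlr_like_gene",
    "demo_catalog_frame",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass(frozen=True)
class GenomicVariant:
    """Pure-representation variant in 1-based reference coordinates.

    ``ref`` empty = insertion after ``pos``; ``alt`` empty = deletion
    starting at ``pos``; both set and length 1 = substitution.
    """

    pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "substitution" if len(self.ref) == len(self.alt) == 1 else "delins"
        return "deletion" if self.ref else "insertion"


@dataclass(frozen=True)
class GenotypeVariant:
    variant: CodingVariant | GenomicVariant
    zygosity: str  # heterozygous | homozygous
    haplotype: int | None = None  # 0 or 1 for heterozygous; ignored if homozygous


@dataclass(frozen=True)
class GenotypeSpec:
    sample_id: str
    variants: tuple[GenotypeVariant, ...] = ()


@dataclass(frozen=True)
class ErrorModel:
    """Per-base nanopore-like error rates.

    ``tandem_context_multiplier`` scales the indel rate inside
    homopolymer/tandem-repeat context (>= 1); ``strand_error_asymmetry``
    scales both rates on reverse-strand reads. Products are clamped to 1.

    The defaults are calibrated so that simulated variant frequencies
    land where amplicon nanopore runs report them (heterozygous ~39-48%,
    homozygous ~87-95%): alignment noise around a variant trades the
    substitution against nearby indels, so the homozygous frequency is
    roughly 100% minus the local indel-error mass.
    """

    substitution_rate: float = 0.01
    indel_rate: float = 0.01
    tandem_context_multiplier: float = 6.0
    strand_error_asymmetry: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tandem_context_multiplier < 1:
            raise ValueError("tandem_context_multiplier must be >= 1")
        if self.strand_error_asymmetry <= 0:
            raise ValueError("strand_error_asymmetry must be positive")


@dataclass
class Haplotype:
    """One haplotype sequence plus the coordinate shifts its variants caused."""

    seq: str
    edits: list[tuple[int, int]] = field(default_factory=list)  # (ref pos0, length delta)

    def lift(self, ref_pos0: int) -> int:
        """Map a 0-based reference position to this haplotype's coordinates."""
        shift = 0
        for p, d in self.edits:
            if p < ref_pos0:
                shift += d
        return ref_pos0 + shift


def _to_genomic(model: GeneModel, v: CodingVariant | GenomicVariant) -> GenomicVariant:
    if isinstance(v, GenomicVariant):
        return v
    g_start = cds_to_genomic(model, v.cds_position)
    if v.ref_allele:
        g_end = cds_to_genomic(model, v.cds_position + len(v.ref_allele) - 1)
        if g_end - g_start != len(v.ref_allele) - 1:
            raise ValueError(
                f"variant at c.{v.cds_position} spans an exon boundary; not supported"
            )
    return GenomicVariant(pos=g_start, ref=v.ref_allele, alt=v.alt_allele)


def make_diploid_haplotypes(
    model: GeneModel, spec: GenotypeSpec
) -> tuple[Haplotype, Haplotype, pd.DataFrame]:
    """Build the two haplotype sequences and the truth table for a sample.

    Homozygous variants are applied to both haplotypes, heterozygous ones
    to exactly one (``haplotype`` 0 or 1; compound heterozygotes assign
    their two variants to different haplotypes). Variants are left-aligned
    against the reference first so truth rows use the caller's convention.
    """
    ref = model.reference
    per_hap: list[list[GenomicVariant]] = [[], []]
    rows = []
    for gv in spec.variants:
        if gv.zygosity not in ("heterozygous", "homozygous"):
            raise ValueError(f"unknown zygosity {gv.zygosity!r}")
        raw = _to_genomic(model, gv.variant)
        if raw.ref and ref[raw.pos - 1 : raw.pos - 1 + len(raw.ref)] != raw.ref:
            raise ValueError(
                f"reference mismatch at {raw.pos}: reference has "
                f"{ref[raw.pos - 1 : raw.pos - 1 + len(raw.ref)]!r}, variant states {raw.ref!r}"
            )
        pos, r, a = left_align(raw.pos, raw.ref, raw.alt, ref)
        norm = GenomicVariant(pos, r, a)
        if gv.zygosity == "homozygous":
            targets, hap_label = [0, 1], "both"
        else:
            h = gv.haplotype if gv.haplotype is not None else 0
            if h not in (0, 1):
                raise ValueError("haplotype assignment must be 0 or 1")
            targets, hap_label = [h], "AB"[h]
        for t in targets:
            per_hap[t].append(norm)
        rows.append(
            {
                "sample_id": spec.sample_id, "pos": norm.pos, "ref": norm.ref,
                "alt": norm.alt, "kind": norm.kind, "zygosity": gv.zygosity,
                "haplotype": hap_label,
            }
        )
    haps = []
    for variants in per_hap:
        variants.sort(key=lambda v: v.pos)
        for u, w in zip(variants, variants[1:]):
            if u.pos + max(len(u.ref), 1) > w.pos:
                raise ValueError(f"overlapping variants on one haplotype at {u.pos}/{w.pos}")
        seq = ref
        edits = []
        for v in sorted(variants, key=lambda v: v.pos, reverse=True):
            i = v.pos - 1
            if not v.ref:  # insertion after pos
                seq = seq[: i + 1] + v.alt + seq[i + 1 :]
                edits.append((i + 1, len(v.alt)))
            else:
                seq = seq[:i] + v.alt + seq[i + len(v.ref) :]
                if len(v.alt) != len(v.ref):
                    edits.append((i, len(v.alt) - len(v.ref)))
        edits.sort()
        haps.append(Haplotype(seq=seq, edits=edits))
    truth = pd.DataFrame(
        rows, columns=["sample_id", "pos", "ref", "alt", "kind", "zygosity", "haplotype"]
    ).sort_values("pos", kind="stable", ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "pos", "ref", "alt", "kind", "zygosity", "haplotype"]
    )
    return haps[0], haps[1], truth


_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BYTES[codes].tobytes().decode()


def simulate_reads(
    haplotypes: tuple[Haplotype, Haplotype],
    panel: list[Amplicon],
    n_reads: int,
    err: ErrorModel,
    seed: int | None = None,
    repeat_params: RepeatParams = RepeatParams(),
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate full-length amplicon reads from a diploid genotype.

    Each read draws a haplotype (uniform), an amplicon (by molarity
    weight) and a strand (50/50); reverse-strand reads are emitted
    reverse-complemented. Errors follow the :class:`ErrorModel`:
    substitutions to a uniformly random other base, indels split 50/50
    between deleting the current base and duplicating it (the homopolymer
    slip mode), with the indel rate multiplied inside tandem-repeat
    context. Returns (records, provenance); records are (id, sequence,
    quality) with a constant placeholder quality.

    Deterministic: a fixed seed yields byte-identical output.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not panel:
        raise ValueError("empty amplicon panel")
    weights = np.array([a.expected_copies for a in panel], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("zero-weight amplicon panel")
    weights = weights / weights.sum()
    seed = err.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # per (haplotype, amplicon): template codes and per-base indel rates
    templates: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for hap in haplotypes:
        row = []
        for amp in panel:
            lo = hap.lift(amp.interval.start)
            hi = hap.lift(amp.interval.end)
            tpl = hap.seq[lo:hi]
            codes = _encode(tpl)
            rate = np.full(len(tpl), err.indel_rate)
            if err.indel_rate > 0 and err.tandem_context_multiplier > 1:
                mask = repeat_context_mask(tpl, repeat_params)
                rate[mask] = min(err.indel_rate * err.tandem_context_multiplier, 1.0)
            row.append((codes, rate))
        templates.append(row)

    hap_choice = rng.integers(0, 2, n_reads)
    amp_choice = rng.choice(len(panel), size=n_reads, p=weights)
    strand_choice = rng.integers(0, 2, n_reads)  # 0 = forward, 1 = reverse

    records: list[tuple[str, str, str]] = []
    prov_rows = []
    for i in range(n_reads):
        h, a, s = int(hap_choice[i]), int(amp_choice[i]), int(strand_choice[i])
        codes, indel_rate = templates[h][a]
        asym = err.strand_error_asymmetry if s == 1 else 1.0
        sub_rate = min(err.substitution_rate * asym, 1.0)
        out = codes
        if sub_rate > 0 or err.indel_rate > 0:
            out = codes.copy()
            L = len(out)
            if sub_rate > 0:
                sub_idx = np.nonzero(rng.random(L) < sub_rate)[0]
                if sub_idx.size:
                    out[sub_idx] = (out[sub_idx] + rng.integers(1, 4, sub_idx.size)) % 4
            if err.indel_rate > 0:
                rate = np.minimum(indel_rate * asym, 1.0)
                indel_idx = np.nonzero(rng.random(L) < rate)[0]
                if indel_idx.size:
                    repeats = np.ones(L, dtype=np.intp)
                    is_del = rng.random(indel_idx.size) < 0.5
                    repeats[indel_idx[is_del]] = 0  # drop the base
                    repeats[indel_idx[~is_del]] = 2  # duplicate it
                    out = np.repeat(out, repeats)
        if s == 1:
            out = (3 - out)[::-1]  # reverse complement in code space
        seq = _decode(out)
        rid = f"{read_prefix}_{i:06d}"
        records.append((rid, seq, "I" * len(seq)))
        prov_rows.append(
            {"read_id": rid, "haplotype": "AB"[h], "amplicon": panel[a].id,
             "strand": "+-"[s]}
        )
    return records, pd.DataFrame(prov_rows)


def subsample_reads(
    records: list[tuple[str, str, str]], k: int, seed: int
) -> list[tuple[str, str, str]]:
    """Uniform subsample without replacement, deterministic per seed."""
    if k > len(records):
        raise ValueError(f"cannot draw {k} reads from {len(records)}")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=k, replace=False))
    return [records[i] for i in idx]


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write 4-line FASTQ records."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seq_records = []
    for rid, seq, qual in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in qual]
        seq_records.append(rec)
    seqio_write(seq_records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)))
    return out


# ---------------------------------------------------------------------------
# Synthetic LDLR-like gene (stand-in for the real RefSeqGene record)

# codons fixed so the classic FH variants have their known effects:
#   c.653del  -> Gly218 frameshift (codon GGT; deletion leaves G+T+next = Val)
#   c.761A>C  -> Gln254Pro (CAA -> CCA)
#   c.1474G>A -> Asp492Asn (GAC -> AAC)
#   c.1567G>A -> Val523Met (GTG -> ATG)
#   c.1729T>C -> Trp577Arg (TGG -> CGG)
#   c.1844A>G -> Glu615Gly (GAA -> GGA)
#   c.1916T>A -> Val639Asp (GTC -> GAC)
# codons 217/219 are pinned so the GG pair of Gly218 sits in repeat-free
# context (the deletion must be left-alignable without entering a tandem run)
_FIXED_CODONS = {
    1: "ATG", 217: "CAC", 218: "GGT", 219: "ACC", 254: "CAA", 492: "GAC",
    523: "GTG", 577: "TGG", 615: "GAA", 639: "GTC", 861: "TGA",
}
# CDS positions of the variant sites; their neighbourhoods are kept free of
# homopolymer/tandem context so sequencing-error smearing does not sit on
# top of the variants themselves (matching the clean support the real
# amplicon runs show at these sites)
_VARIANT_CDS_SITES = (653, 761, 1474, 1567, 1729, 1844, 1916)
_SITE_CLEARANCE = 9  # nt of repeat-free sequence demanded on each side
_N_CODONS = 861  # 860 residues + stop, the length of the LDL receptor precursor
# After deleting c.653 the shifted reading frame must terminate at the 47th
# codon counting the first altered residue (218) as 1.  Shifted codon j >= 2
# occupies CDS indices (0-based) 3j+649 .. 3j+651; j = 47 is forced to TAA.
_FS_TER = 47
_FS_STOP_IDX = 3 * _FS_TER + 649  # 790


def _shifted_codon(cds: list[str], j: int) -> str:
    s = "".join(cds)
    if j == 1:
        return s[651] + s[653] + s[654]
    i = 3 * j + 649
    return s[i : i + 3]


def _build_cds(rng: np.random.Generator) -> str:
    from .filters import detect_repeat_context

    sense = [c for c in ("".join(p) for p in itertools.product(_BASES, repeat=3))
             if c not in _STOPS]
    codons = [sense[rng.integers(len(sense))] for _ in range(_N_CODONS)]
    for idx, codon in _FIXED_CODONS.items():
        codons[idx - 1] = codon
    fixed_idx = set()
    for ci in _FIXED_CODONS:
        fixed_idx.update(range(3 * (ci - 1), 3 * ci))
    fixed_idx.update((_FS_STOP_IDX, _FS_STOP_IDX + 1, _FS_STOP_IDX + 2))

    def force_fs_stop() -> None:
        # post-frameshift stop: CDS indices 790..792 = TAA. Indices 790/791
        # sit in codon 264 (x,T,A: never a stop); 792 starts codon 265
        # (A,x,x: never a stop).
        codons[263] = codons[263][0] + "TA"
        codons[264] = "A" + codons[264][1:]

    def resample(idx0: int) -> None:
        codons[idx0 // 3] = sense[int(rng.integers(len(sense)))]
        if idx0 // 3 in (263, 264):
            force_fs_stop()

    def fix_shifted_stops() -> bool:
        changed = False
        for j in range(2, _FS_TER):
            if _shifted_codon(codons, j) in _STOPS:
                i = 3 * j + 649
                free = [p for p in (i, i + 1, i + 2) if p not in fixed_idx]
                resample(free[int(rng.integers(len(free)))])
                changed = True
        return changed

    def fix_variant_windows() -> bool:
        # no tandem/homopolymer context within the clearance window of any
        # variant site: resample a free codon inside the offending run
        cds = "".join(codons)
        for v in _VARIANT_CDS_SITES:
            for w in range(max(1, v - _SITE_CLEARANCE), min(len(cds), v + _SITE_CLEARANCE) + 1):
                ctx = detect_repeat_context(cds, w)
                if not ctx.is_tandem:
                    continue
                free = [
                    p for p in range(ctx.span.start, ctx.span.end) if p not in fixed_idx
                ]
                if not free:  # pragma: no cover - fixed codons form no runs
                    raise RuntimeError("repeat run pinned by fixed codons")
                resample(free[int(rng.integers(len(free)))])
                return True
        return False

    force_fs_stop()
    for _ in range(10_000):
        if not (fix_shifted_stops() or fix_variant_windows()):
            break
    else:  # pragma: no cover - construction failed to converge
        raise RuntimeError("CDS construction did not converge")
    cds = "".join(codons)
    # construction self-checks (plain translation, independent of the
    # consequence predictor's parsing/application machinery)
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate())
    assert prot[-1] == "*" and "*" not in prot[:-1]
    mutated = cds[:652] + cds[653:]
    fs_prot = str(Seq(mutated[: len(mutated) - len(mutated) % 3]).translate())
    first_stop = fs_prot.find("*", 217)
    assert first_stop - 217 + 1 == _FS_TER, "frameshift stop misplaced"
    return cds


def ldlr_like_gene(seed: int = 20220) -> tuple[GeneModel, list[Amplicon]]:
    """Deterministic synthetic LDLR-like gene model and 5-amplicon panel.

    Fully synthetic stand-in (not the RefSeqGene sequence): 861-codon CDS
    split over 18 exons with a promoter, intervening introns carrying
    deliberate homopolymer/tandem-repeat runs (the nanopore error hotspots),
    and a panel of 5 overlapping amplicons that covers the promoter and
    every coding base, with the last amplicon reaching only the coding
    start of exon 18.
    """
    from .filters import detect_repeat_context

    rng = np.random.default_rng(seed)
    cds = _build_cds(rng)

    # split the CDS over 18 exons (sizes jittered around the mean); every
    # variant site must keep its clearance window inside a single exon
    base, extra = divmod(len(cds), 18)
    base_sizes = [base + (1 if i < extra else 0) for i in range(18)]
    for _ in range(200):
        sizes = list(base_sizes)
        for i in range(17):
            d = int(rng.integers(-30, 31))
            if sizes[i] + d >= 60 and sizes[i + 1] - d >= 60:
                sizes[i] += d
                sizes[i + 1] -= d
        edges = np.cumsum([0] + sizes)
        ok = True
        for v in _VARIANT_CDS_SITES:
            k = int(np.searchsorted(edges, v - 1, side="right")) - 1
            if v - 1 - edges[k] <= _SITE_CLEARANCE or edges[k + 1] - v < _SITE_CLEARANCE + 1:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not place exon boundaries clear of variant sites")

    def rand_seq(n: int) -> str:
        return "".join(_BASES[c] for c in rng.integers(0, 4, n))

    def with_repeats(seq: str, n_runs: int) -> str:
        # plant homopolymer / short tandem runs at random offsets
        s = list(seq)
        for _ in range(n_runs):
            unit = ["A", "T", "C", "G", "AT", "CA", "TG"][int(rng.integers(7))]
            copies = int(rng.integers(5, 9)) if len(unit) == 1 else int(rng.integers(3, 6))
            run = unit * copies
            if len(run) >= len(s) - 2:
                continue
            at = int(rng.integers(1, len(s) - len(run) - 1))
            s[at : at + len(run)] = run
        return "".join(s)

    for _ in range(50):
        promoter = with_repeats(rand_seq(400), 3)
        utr5, utr3 = rand_seq(60), with_repeats(rand_seq(200), 1)
        parts: list[str] = [promoter]
        exons: list[Interval] = []
        cds_intervals: list[Interval] = []
        cursor = len(promoter)
        offset = 0
        for i, size in enumerate(sizes):
            chunk = cds[offset : offset + size]
            offset += size
            if i == 0:
                exon_seq = utr5 + chunk
                cds_start = cursor + len(utr5)
            elif i == 17:
                exon_seq = chunk + utr3
                cds_start = cursor
            else:
                exon_seq = chunk
                cds_start = cursor
            exons.append(Interval(cursor, cursor + len(exon_seq)))
            cds_intervals.append(Interval(cds_start, cds_start + size))
            parts.append(exon_seq)
            cursor += len(exon_seq)
            if i < 17:
                intron = with_repeats(rand_seq(int(rng.integers(150, 301))), 2)
                parts.append(intron)
                cursor += len(intron)
        reference = "".join(parts)
        model = GeneModel(
            name="LDLR_like_synthetic", reference=reference, exons=exons,
            cds_intervals=cds_intervals, strand="+",
        )
        # repeat runs crossing an exon boundary must not reach a variant's
        # clearance window; redraw the non-coding parts otherwise
        clean = True
        for v in _VARIANT_CDS_SITES:
            g = cds_to_genomic(model, v)
            for w in range(g - _SITE_CLEARANCE, g + _SITE_CLEARANCE + 1):
                if detect_repeat_context(reference, w).is_tandem:
                    clean = False
                    break
            if not clean:
                break
        if clean:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not assemble repeat-free variant windows")

    # 5 overlapping amplicons; the last stops just past the exon-18 CDS
    groups = [(0, 4), (3, 8), (7, 12), (11, 15), (14, 18)]
    pad = 25
    panel = []
    for k, (g0, g1) in enumerate(groups, start=1):
        start = 0 if k == 1 else max(0, exons[g0].start - pad)
        if k == 5:
            end = min(cds_intervals[-1].end + 20, len(reference))
        else:
            end = min(exons[g1 - 1].end + pad, len(reference))
        panel.append(Amplicon(id=f"fragment_{k}", interval=Interval(start, end)))
    report = None
    from .gene_model import amplicon_coverage_check

    report = amplicon_coverage_check(model, panel)
    assert report.passed, "synthetic panel must cover the whole CDS"
    return model, panel


def intron_midpoint_variant(model: GeneModel, intron_index: int) -> GenomicVariant:
    """Benign marker substitution near the midpoint of an intron (1-based).

    The exact position is nudged off the midpoint if needed so that its
    local context is repeat-free (a benign SNV should not sit under the
    error-inflated tandem loci).
    """
    from .filters import detect_repeat_context

    a, b = model.exons[intron_index - 1], model.exons[intron_index]
    mid = (a.end + b.start) // 2
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for delta in range(0, 60):
        for p0 in dict.fromkeys((mid - delta, mid + delta)):
            if not (a.end + 3 <= p0 < b.start - 3):
                continue
            pos = p0 + 1
            if any(
                detect_repeat_context(model.reference, q).is_tandem
                for q in range(pos - 3, pos + 4)
            ):
                continue
            ref = model.reference[p0]
            return GenomicVariant(pos, ref, flip[ref])
    raise RuntimeError(f"no repeat-free site found in intron {intron_index}")


_DEMO_CATALOG = [
    # (HGVS c., dbSNP id, clinical significance, SIFT, PolyPhen2)
    ("c.761A>C", "rs879254667", "pathogenic", "deleterious", "probably damaging"),
    ("c.1567G>A", "rs28942080", "pathogenic", "deleterious", "probably damaging"),
    ("c.1916T>A", "rs794728584", "likely pathogenic", "deleterious", "benign"),
    ("c.653del", "rs137853966", "pathogenic", "", ""),
    ("c.1474G>A", "rs373646964", "pathogenic", "deleterious", "probably damaging"),
    ("c.1729T>C", "rs879255000", "pathogenic", "deleterious", "probably damaging"),
]


def demo_catalog_frame(model: GeneModel) -> pd.DataFrame:
    """Recorded-variant catalog for the synthetic gene, as a TSV-ready table.

    Carries the dbSNP identifiers and annotations of the classic FH
    variants (c.1844A>G is deliberately absent — the novel variant) plus
    one benign intronic marker per intron under synthetic ``synrs`` ids.
    """
    from .hgvs import parse_hgvs_c

    rows = []
    for hgvs_c, rsid, signif, sift, polyphen in _DEMO_CATALOG:
        cv = parse_hgvs_c(hgvs_c, model)
        gv = _to_genomic(model, cv)
        pos, ref, alt = left_align(gv.pos, gv.ref, gv.alt, model.reference)
        rows.append(
            {
                "position": pos, "ref": ref, "alt": alt, "id": rsid,
                "clinical_significance": signif, "SIFT": sift, "PolyPhen2": polyphen,
            }
        )
    for i in range(1, len(model.exons)):
        gv = intron_midpoint_variant(model, i)
        rows.append(
            {
                "position": gv.pos, "ref": gv.ref, "alt": gv.alt,
                "id": f"synrs{i:03d}", "clinical_significance": "benign",
                "SIFT": "", "PolyPhen2": "",
            }
        )
    return pd.DataFrame(rows).sort_values("position", ignore_index=True)
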