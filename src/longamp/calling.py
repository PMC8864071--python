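"""Pileup-based variant calling.

Each pileup column with adequate depth is screened for non-reference
alleles: alternative bases, deletions (adjacent deleted columns merged
into one left-aligned event) and anchored insertions. A call carries its
variant frequency (percent of covering reads supporting the alternate),
per-strand support, strand bias (majority-strand share of the alternate
support) and a significance value — the upper-tail binomial probability
of seeing at least the observed support if the site were pure sequencing
error at the null per-base error rate. True variants at high depth drive
this probability to zero; error pileups do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .align import Pileup
from .gene_model import GeneModel

__all__ = [
    "VariantCall",
    "call_variants",
    "strand_bias_pct",
    "left_align",
    "write_vcf",
    "calls_to_frame",
]

_BASES = "ACGT"


@dataclass
class VariantCall:
    pos: int  # 1-based reference position (left-aligned; insertion: left flank)
    ref: str  # deleted sequence; empty for insertion
    alt: str  # inserted/substituted sequence; empty for deletion
    kind: str  # substitution | deletion | insertion
    depth: int
    alt_fwd: int
    alt_rev: int
    variant_frequency: float  # percent
    strand_bias: float  # percent, in [50, 100]
    p_value: float
    filter_flags: set[str] = field(default_factory=set)

    @property
    def alt_support(self) -> int:
        return self.alt_fwd + self.alt_rev

    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def strand_bias_pct(alt_fwd: int, alt_rev: int) -> float:
    """Majority-strand share of alternate support, in percent [50, 100]."""
    total = alt_fwd + alt_rev
    if total < 1:
        raise ValueError("strand bias undefined without alternate support")
    return 100.0 * max(alt_fwd, alt_rev) / total


def left_align(
    pos: int, ref: str, alt: str, reference: str
) -> tuple[int, str, str]:
    """Left-align a pure insertion or deletion against the reference.

    ``pos`` is 1-based: for deletions the first deleted base, for
    insertions the base left of the insertion point. Substitutions and
    delins pass through unchanged. Shifting preserves the edited sequence
    exactly (the classic rotate-while-flanking-base-matches rule).
    """
    if ref and alt:
        return pos, ref, alt
    if not ref and not alt:
        raise ValueError("empty variant")
    if ref:  # deletion of `ref` starting at pos
        p0 = pos - 1
        while p0 > 0 and reference[p0 - 1] == ref[-1]:
            ref = reference[p0 - 1] + ref[:-1]
            p0 -= 1
        return p0 + 1, ref, alt
    # insertion of `alt` after pos (pos may reach 0 = before first base)
    p0 = pos
    while p0 > 0 and reference[p0 - 1] == alt[-1]:
        alt = reference[p0 - 1] + alt[:-1]
        p0 -= 1
    return p0, ref, alt


def _binom_p(alt: int, depth: int, null_rate: float) -> float:
    # P(X >= alt) for X ~ Binomial(depth, null_rate); 1.0 when alt == 0
    return float(stats.binom.sf(alt - 1, depth, null_rate))


def call_variants(
    pileup: Pileup,
    model: GeneModel,
    *,
    min_frequency: float = 20.0,
    min_depth: int = 100,
    null_error_rate: float = 0.05,
) -> list[VariantCall]:
    """Call substitutions, deletions and insertions from the pileup.

    A non-reference allele at a column with depth >= ``min_depth`` and
    frequency >= ``min_frequency`` (percent) yields one call; multi-allelic
    columns yield one call per alternate allele. Runs of adjacent deleted
    columns are merged into single left-aligned deletion events, insertion
    calls are left-aligned likewise.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0 < min_frequency < 100:
        raise ValueError("min_frequency must lie strictly between 0 and 100")
    ref = model.reference
    n = len(ref)
    counts = pileup.counts  # (2, 5, n)
    depth = pileup.depth
    ok_depth = depth >= min_depth
    calls: list[VariantCall] = []

    def make_call(pos: int, ref_a: str, alt_a: str, kind: str, d: int, f: int, r: int) -> VariantCall:
        alt_total = f + r
        return VariantCall(
            pos=pos, ref=ref_a, alt=alt_a, kind=kind, depth=d,
            alt_fwd=f, alt_rev=r,
            variant_frequency=100.0 * alt_total / d,
            strand_bias=strand_bias_pct(f, r),
            p_value=_binom_p(alt_total, d, null_error_rate),
        )

    # substitutions: vectorized screen, then per-hit construction
    with np.errstate(invalid="ignore", divide="ignore"):
        base_tot = counts.sum(axis=0)  # (5, n)
        freq = 100.0 * base_tot / np.where(depth > 0, depth, 1)
    for b, base in enumerate(_BASES):
        hits = np.nonzero(ok_depth & (freq[b] >= min_frequency))[0]
        for j in hits:
            if ref[j] == base or ref[j] == "N":
                continue
            calls.append(
                make_call(
                    int(j) + 1, ref[j], base, "substitution", int(depth[j]),
                    int(counts[0, b, j]), int(counts[1, b, j]),
                )
            )

    # deletions: merge maximal runs of qualifying adjacent columns
    del_hit = ok_depth & (freq[4] >= min_frequency)
    j = 0
    while j < n:
        if not del_hit[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and del_hit[k + 1]:
            k += 1
        fwd = int(round(counts[0, 4, j : k + 1].mean()))
        rev = int(round(counts[1, 4, j : k + 1].mean()))
        d = int(round(depth[j : k + 1].mean()))
        pos, ref_a, alt_a = left_align(j + 1, ref[j : k + 1], "", ref)
        calls.append(make_call(pos, ref_a, alt_a, "deletion", d, fwd, rev))
        j = k + 1

    # insertions: anchored per (left-flank column, inserted sequence)
    for anchor, variants in pileup.insertions.items():
        if not ok_depth[anchor]:
            continue
        d = int(depth[anchor])
        for seq, strand_counts in variants.items():
            total = int(strand_counts.sum())
            if 100.0 * total / d < min_frequency:
                continue
            pos, ref_a, alt_a = left_align(anchor + 1, "", seq, ref)
            calls.append(
                make_call(pos, ref_a, alt_a, "insertion", d,
                          int(strand_counts[0]), int(strand_counts[1]))
            )

    calls.sort(key=lambda c: (c.pos, c.kind, c.alt))
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "pos": c.pos, "ref": c.ref, "alt": c.alt, "kind": c.kind,
            "depth": c.depth, "alt_fwd": c.alt_fwd, "alt_rev": c.alt_rev,
            "variant_frequency": round(c.variant_frequency, 2),
            "strand_bias": round(c.strand_bias, 2),
            "p_value": c.p_value,
            "filter": ";".join(sorted(c.filter_flags)) or "PASS",
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["pos", "ref", "alt", "kind", "depth", "alt_fwd", "alt_rev",
                 "variant_frequency", "strand_bias", "p_value", "filter"],
    )


def calls_from_frame(df: pd.DataFrame) -> list[VariantCall]:
    """Rebuild :class:`VariantCall` objects from a ``calls_to_frame`` table."""
    calls = []
    for r in df.itertuples(index=False):
        ref = "" if pd.isna(r.ref) else str(r.ref)
        alt = "" if pd.isna(r.alt) else str(r.alt)
        calls.append(
            VariantCall(
                pos=int(r.pos), ref=ref, alt=alt, kind=r.kind, depth=int(r.depth),
                alt_fwd=int(r.alt_fwd), alt_rev=int(r.alt_rev),
                variant_frequency=float(r.variant_frequency),
                strand_bias=float(r.strand_bias), p_value=float(r.p_value),
                filter_flags=set() if r.filter == "PASS" else set(r.filter.split(";")),
            )
        )
    return calls


def _vcf_alleles(call: VariantCall, reference: str) -> tuple[int, str, str]:
    """Convert the pure internal representation to VCF anchored alleles."""
    if call.kind == "substitution":
        return call.pos, call.ref, call.alt
    if call.kind == "deletion":
        if call.pos == 1:  # no left anchor; use right anchor per VCF spec
            anchor = reference[len(call.ref)]
            return 1, call.ref + anchor, anchor
        anchor = reference[call.pos - 2]
        return call.pos - 1, anchor + call.ref, anchor
    anchor = reference[call.pos - 1] if call.pos >= 1 else reference[0]
    if call.pos == 0:
        return 1, reference[0], call.alt + reference[0]
    return call.pos, anchor, anchor + call.alt


def write_vcf(
    calls: list[VariantCall],
    model: GeneModel,
    path: str | Path,
    ids: dict[tuple[int, str, str], str] | None = None,
) -> None:
    """Write a minimal VCF (text) via pysam with DP/AF/SBIAS/strand counts."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(model.name, length=len(model.reference))
    header.info.add("DP", 1, "Integer", "Read depth at the call")
    header.info.add("AF", 1, "Float", "Variant frequency (fraction)")
    header.info.add("SBIAS", 1, "Float", "Strand bias percent (majority-strand share)")
    header.info.add("SAF", 1, "Integer", "Alternate support, forward strand")
    header.info.add("SAR", 1, "Integer", "Alternate support, reverse strand")
    header.filters.add("strand_bias_100", None, None, "Alternate support on one strand only")
    header.filters.add("tandem_repeat_indel", None, None,
                       "Indel in tandem-repeat/homopolymer context")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: c.pos):
            pos, ref_a, alt_a = _vcf_alleles(call, model.reference)
            rec = out.new_record(
                contig=model.name, start=pos - 1, stop=pos - 1 + len(ref_a),
                alleles=(ref_a, alt_a),
            )
            if ids and call.key() in ids:
                rec.id = ids[call.key()]
            capped = min(-10.0 * np.log10(max(call.p_value, 1e-100)), 1000.0)
            rec.qual = round(capped, 2)
            rec.info["DP"] = call.depth
            rec.info["AF"] = round(call.variant_frequency / 100.0, 6)
            rec.info["SBIAS"] = round(call.strand_bias, 2)
            rec.info["SAF"] = call.alt_fwd
            rec.info["SAR"] = call.alt_rev
            for flag in sorted(call.filter_flags):
                rec.filter.add(flag)
            out.write(rec)
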