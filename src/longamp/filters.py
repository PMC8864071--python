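"""Call-level exclusion rules and zygosity classification.

Three rules, applied in narrative order:

1. strand-bias filter — a call whose alternate support sits entirely on one
   strand (bias 100%) is a low-confidence hit and is excluded;
2. tandem-repeat indel exclusion — insertions/deletions inside homopolymer
   or tandem-repeat context are the signature error mode of nanopore
   sequencing (indistinguishable conductance states across repeated bases)
   and are excluded, a decision justified statistically by a one-sided
   Fisher exact test on their recurrence across samples;
3. zygosity classification — the variant frequency of a surviving call
   places it in a heterozygous band (30–70% by default), a homozygous range
   (>= 80% by default) or an ambiguous gap between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calling import VariantCall
from .gene_model import GeneModel, Interval

__all__ = [
    "RepeatContext",
    "ZygosityCall",
    "RepeatParams",
    "filter_strand_bias",
    "detect_repeat_context",
    "repeat_context_mask",
    "exclude_tandem_indels",
    "fisher_tandem_test",
    "build_tandem_table",
    "classify_zygosity",
]

FLAG_STRAND_BIAS = "strand_bias_100"
FLAG_TANDEM = "tandem_repeat_indel"


@dataclass(frozen=True)
class RepeatParams:
    """Thresholds defining tandem-repeat context.

    A homopolymer needs ``min_homopolymer`` copies of one base; a multi-base
    unit needs at least ``min_copies`` copies and a total span of at least
    ``min_span`` nucleotides. Units longer than ``max_unit`` are ignored.
    """

    max_unit: int = 4
    min_copies: int = 2
    min_span: int = 6
    min_homopolymer: int = 3


@dataclass(frozen=True)
class RepeatContext:
    is_tandem: bool
    unit: str = ""
    unit_length: int = 0
    copies: int = 0
    span: Interval | None = None

    def __post_init__(self) -> None:
        if self.is_tandem:
            if self.copies < 2:
                raise ValueError("tandem context needs >= 2 copies")
            if self.span is None:
                raise ValueError("tandem context needs a span")


@dataclass(frozen=True)
class ZygosityCall:
    label: str  # heterozygous | homozygous | ambiguous
    variant_frequency: float


def filter_strand_bias(calls: list[VariantCall]) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (retained, excluded) by the 100%-strand-bias rule.

    The partition is exhaustive and disjoint; excluded calls carry the
    ``strand_bias_100`` flag.
    """
    retained, excluded = [], []
    for call in calls:
        if call.strand_bias >= 100.0 - 1e-9:
            call.filter_flags.add(FLAG_STRAND_BIAS)
            excluded.append(call)
        else:
            retained.append(call)
    return retained, excluded


def detect_repeat_context(
    reference: str, pos: int, params: RepeatParams = RepeatParams()
) -> RepeatContext:
    """Find the tandem-repeat/homopolymer context covering a 1-based position.

    Scans unit lengths 1..max_unit; for each, computes the maximal run of
    period-u sequence containing the position and keeps the qualifying
    context with the longest span (ties broken toward the shortest unit,
    i.e. homopolymers win over equivalent dinucleotide descriptions).
    """
    n = len(reference)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside reference (1..{n})")
    if params.max_unit < 1:
        raise ValueError("max_unit must be >= 1")
    s = pos - 1
    best: RepeatContext = RepeatContext(is_tandem=False)
    best_span = 0
    for u in range(1, params.max_unit + 1):
        # self-match relation M[x]: reference has period u across x .. x+u;
        # a maximal M-run [lo, hi] describes the repeat region [lo, hi+1+u).
        # The region covers s when the run intersects [s-u, s], so those
        # positions are the candidate anchors.
        seen_lo: set[int] = set()
        for anchor in range(max(0, s - u), min(s, n - 1 - u) + 1):
            if reference[anchor] != reference[anchor + u]:
                continue
            lo = anchor
            while lo - 1 >= 0 and reference[lo - 1] == reference[lo - 1 + u]:
                lo -= 1
            if lo in seen_lo:
                continue
            seen_lo.add(lo)
            hi = anchor
            while hi + 1 <= n - 1 - u and reference[hi + 1] == reference[hi + 1 + u]:
                hi += 1
            end = hi + 1 + u
            if not (lo <= s < end):
                continue
            span_len = end - lo
            copies = span_len // u
            if copies < 2:
                continue
            if u == 1:
                if span_len < params.min_homopolymer:
                    continue
            else:
                if span_len < params.min_span or copies < params.min_copies:
                    continue
            unit = reference[lo : lo + u]
            if len(set(unit)) == 1 and u > 1:
                continue  # homopolymer already described at u == 1
            if span_len > best_span:
                best = RepeatContext(
                    is_tandem=True, unit=unit, unit_length=u, copies=copies,
                    span=Interval(lo, end),
                )
                best_span = span_len
    return best


def repeat_context_mask(reference: str, params: RepeatParams = RepeatParams()) -> np.ndarray:
    """Boolean per-position mask of tandem/homopolymer context.

    Shared between the simulator (where to inflate indel error rates) and
    the filter (which indel calls to exclude), so both sides agree on what
    counts as repeat context.
    """
    n = len(reference)
    mask = np.zeros(n, dtype=bool)
    pos = 1
    while pos <= n:
        ctx = detect_repeat_context(reference, pos, params)
        if ctx.is_tandem and ctx.span is not None:
            mask[ctx.span.start : ctx.span.end] = True
            pos = ctx.span.end + 1
        else:
            pos += 1
    return mask


def _indel_positions(call: VariantCall) -> range:
    if call.kind == "deletion":
        return range(call.pos, call.pos + len(call.ref) + 1)
    return range(call.pos, call.pos + 2)  # insertion: both flanks


def exclude_tandem_indels(
    calls: list[VariantCall],
    model: GeneModel,
    params: RepeatParams = RepeatParams(),
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (retained, excluded) by tandem-indel context.

    Only insertions/deletions are ever excluded; substitutions pass through
    regardless of context. Calls must be left-aligned so the checked
    positions line up with catalog and caller conventions.
    """
    retained, excluded = [], []
    n = len(model.reference)
    for call in calls:
        if call.kind in ("deletion", "insertion"):
            in_repeat = any(
                detect_repeat_context(model.reference, p, params).is_tandem
                for p in _indel_positions(call)
                if 1 <= p <= n
            )
            if in_repeat:
                call.filter_flags.add(FLAG_TANDEM)
                excluded.append(call)
                continue
        retained.append(call)
    return retained, excluded


def fisher_tandem_test(table: list[list[int]] | np.ndarray) -> float:
    """One-sided Fisher exact p-value for tandem-indel recurrence.

    The 2x2 table rows are {tandem-repeat indels, all other variants} and
    columns {shared between the two compared samples, sample-specific};
    the alternative is enrichment of tandem indels among shared calls
    (recurrent artifacts). Computed from the hypergeometric tail.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    return float(stats.fisher_exact(t, alternative="greater")[1])


def build_tandem_table(
    calls_a: list[VariantCall],
    calls_b: list[VariantCall],
    model: GeneModel,
    params: RepeatParams = RepeatParams(),
) -> np.ndarray:
    """Cross-tabulate the union of two samples' calls for the Fisher test.

    Rows: tandem-repeat indel vs other variant. Columns: called in both
    samples vs in exactly one.
    """
    def key(c: VariantCall) -> tuple[int, str, str]:
        return (c.pos, c.ref, c.alt)

    a = {key(c): c for c in calls_a}
    b = {key(c): c for c in calls_b}
    table = np.zeros((2, 2), dtype=int)
    for k in set(a) | set(b):
        call = a.get(k, b.get(k))
        is_tandem_indel = False
        if call.kind in ("deletion", "insertion"):
            is_tandem_indel = any(
                detect_repeat_context(model.reference, p, params).is_tandem
                for p in _indel_positions(call)
                if 1 <= p <= len(model.reference)
            )
        shared = k in a and k in b
        table[0 if is_tandem_indel else 1, 0 if shared else 1] += 1
    return table


def classify_zygosity(
    call: VariantCall | float,
    het_band: tuple[float, float] = (30.0, 70.0),
    hom_floor: float = 80.0,
) -> ZygosityCall:
    """Classify zygosity from variant frequency (%) alone.

    Frequencies inside ``het_band`` (edges inclusive) are heterozygous,
    at or above ``hom_floor`` homozygous, anything else ambiguous. The
    bands must not overlap.
    """
    lo, hi = het_band
    if not (0 <= lo <= hi <= 100) or not (0 <= hom_floor <= 100):
        raise ValueError("bands must lie in [0, 100]")
    if hom_floor <= hi:
        raise ValueError("homozygous floor must lie above the heterozygous band")
    freq = call if isinstance(call, (int, float)) else call.variant_frequency
    if not 0 <= freq <= 100:
        raise ValueError("variant frequency must be a percentage")
    if lo <= freq <= hi:
        label = "heterozygous"
    elif freq >= hom_floor:
        label = "homozygous"
    else:
        label = "ambiguous"
    return ZygosityCall(label=label, variant_frequency=float(freq))
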