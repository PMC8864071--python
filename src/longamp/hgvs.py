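"""HGVS coding-sequence (c.) descriptions and protein-level consequences.

Covers the variant classes a single-gene amplicon panel produces:
substitutions (c.1729T>C), deletions (c.653del, c.12_14del), insertions
(c.12_13insACT) and deletion-insertions (c.12_14delinsGG). Intronic
offset notation (c.123+5G>A) is deliberately rejected: the pipeline reports
exonic variants only and refuses to mis-parse what it cannot represent.

Protein consequences are computed by mutating the CDS and translating:
missense / synonymous / nonsense for substitutions, frameshift with a
Ter-offset scan for length-changing indels, in-frame delins otherwise.
The Ter offset counts codons from the first altered residue (that residue
being 1), the standard HGVS ``fsTer#`` convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_model import GeneModel

__all__ = [
    "CodingVariant",
    "ProteinConsequence",
    "parse_hgvs_c",
    "format_hgvs_c",
    "format_hgvs_p",
    "codon_index",
    "predict_consequence",
]

KIND_SUB = "substitution"
KIND_DEL = "deletion"
KIND_INS = "insertion"
KIND_DELINS = "delins"


@dataclass(frozen=True)
class CodingVariant:
    """A variant in CDS coordinates (1-based).

    ``ref_allele`` is empty for a pure insertion (inserted after
    ``cds_position``); ``alt_allele`` is empty for a pure deletion starting
    at ``cds_position``.
    """

    cds_position: int
    ref_allele: str
    alt_allele: str
    kind: str

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise ValueError("CDS positions are 1-based")
        if self.kind == KIND_SUB:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
        elif self.kind == KIND_DEL:
            if self.alt_allele:
                raise ValueError("deletion must have empty alt allele")
        elif self.kind == KIND_INS:
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have empty ref, non-empty alt")
        elif self.kind == KIND_DELINS:
            if not self.ref_allele or not self.alt_allele:
                raise ValueError("delins needs both alleles")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass(frozen=True)
class ProteinConsequence:
    codon_index: int  # 1-based first affected/altered codon
    ref_aa: str  # 3-letter code ('Ter' for stop)
    alt_aa: str  # 3-letter code, 'fs' for frameshift
    kind: str  # missense | synonymous | nonsense | frameshift | inframe_delins | extension
    ter_offset: int | None = None  # frameshift only: codons to new stop, 1-based

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise ValueError("codon index is 1-based")
        if self.ter_offset is not None and self.ter_offset < 1:
            raise ValueError("ter_offset is 1-based")


_POS = r"(?P<{}>\*?[-]?\d+(?P<{}>[+-]\d+)?)"
_RE_SUB = re.compile(r"^c\.(?P<pos>\S+?)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_RE_DEL = re.compile(r"^c\.(?P<start>\S+?)(?:_(?P<end>\S+?))?del(?P<seq>[ACGT]+)?$")
_RE_INS = re.compile(r"^c\.(?P<start>\S+?)_(?P<end>\S+?)ins(?P<seq>[ACGT]+)$")
_RE_DELINS = re.compile(
    r"^c\.(?P<start>\S+?)(?:_(?P<end>\S+?))?delins(?P<seq>[ACGT]+)$"
)
_RE_OFFSET = re.compile(r"^\d+[+-]\d+$")


def _parse_pos(token: str) -> int:
    """Parse a c. position token; intronic/UTR offsets are unsupported."""
    if _RE_OFFSET.match(token):
        raise ValueError(
            f"intronic offset position c.{token} is not supported (exonic variants only)"
        )
    if token.startswith("*") or token.startswith("-"):
        raise ValueError(f"UTR position c.{token} is not supported")
    if not token.isdigit():
        raise ValueError(f"malformed HGVS position {token!r}")
    pos = int(token)
    if pos < 1:
        raise ValueError("HGVS c. positions are 1-based")
    return pos


def parse_hgvs_c(text: str, model: GeneModel | None = None) -> CodingVariant:
    """Parse an HGVS coding description into a :class:`CodingVariant`.

    A gene model is required to fill in deleted sequence when the
    description omits it (e.g. ``c.653del``).
    """
    text = text.strip()
    if not text.startswith("c."):
        raise ValueError(f"{text!r} is not an HGVS c. description")

    m = _RE_SUB.match(text)
    if m:
        pos = _parse_pos(m["pos"])
        return CodingVariant(pos, m["ref"], m["alt"], KIND_SUB)

    m = _RE_INS.match(text)
    if m and "delins" not in text:
        start, end = _parse_pos(m["start"]), _parse_pos(m["end"])
        if end != start + 1:
            raise ValueError(f"insertion bounds must be adjacent: {text!r}")
        return CodingVariant(start, "", m["seq"], KIND_INS)

    m = _RE_DELINS.match(text)
    if m:
        start = _parse_pos(m["start"])
        end = _parse_pos(m["end"]) if m["end"] else start
        if end < start:
            raise ValueError(f"reversed range in {text!r}")
        ref = _ref_slice(model, start, end, text)
        return CodingVariant(start, ref, m["seq"], KIND_DELINS)

    m = _RE_DEL.match(text)
    if m:
        start = _parse_pos(m["start"])
        end = _parse_pos(m["end"]) if m["end"] else start
        if end < start:
            raise ValueError(f"reversed range in {text!r}")
        if m["seq"]:
            ref = m["seq"]
            if len(ref) != end - start + 1:
                raise ValueError(f"deleted sequence length disagrees with range: {text!r}")
        else:
            ref = _ref_slice(model, start, end, text)
        return CodingVariant(start, ref, "", KIND_DEL)

    raise ValueError(f"unsupported or malformed HGVS description {text!r}")


def _ref_slice(model: GeneModel | None, start: int, end: int, text: str) -> str:
    if model is None:
        return "N" * (end - start + 1)
    cds = model.cds
    if end > len(cds):
        raise ValueError(f"{text!r} extends past CDS end ({len(cds)} nt)")
    return cds[start - 1 : end]


def format_hgvs_c(v: CodingVariant) -> str:
    """Canonical HGVS c. text; inverse of :func:`parse_hgvs_c`."""
    p = v.cds_position
    if v.kind == KIND_SUB:
        return f"c.{p}{v.ref_allele}>{v.alt_allele}"
    if v.kind == KIND_DEL:
        if len(v.ref_allele) == 1:
            return f"c.{p}del"
        return f"c.{p}_{p + len(v.ref_allele) - 1}del"
    if v.kind == KIND_INS:
        return f"c.{p}_{p + 1}ins{v.alt_allele}"
    if len(v.ref_allele) == 1:
        return f"c.{p}delins{v.alt_allele}"
    return f"c.{p}_{p + len(v.ref_allele) - 1}delins{v.alt_allele}"


def codon_index(cds_pos: int) -> int:
    """1-based codon number containing a 1-based CDS position: ceil(pos/3)."""
    if cds_pos < 1:
        raise ValueError("CDS positions are 1-based")
    return (cds_pos + 2) // 3


def _apply_to_cds(cds: str, v: CodingVariant) -> str:
    i = v.cds_position - 1
    if v.kind == KIND_INS:
        # inserted between cds_position and cds_position + 1
        return cds[: i + 1] + v.alt_allele + cds[i + 1 :]
    if cds[i : i + len(v.ref_allele)] != v.ref_allele:
        raise ValueError(
            f"reference mismatch at c.{v.cds_position}: CDS has "
            f"{cds[i : i + len(v.ref_allele)]!r}, variant states {v.ref_allele!r}"
        )
    return cds[:i] + v.alt_allele + cds[i + len(v.ref_allele) :]


def _translate(seq: str) -> str:
    # truncate to full codons; partial tail codons are not translated
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def _aa3(aa1: str) -> str:
    return "Ter" if aa1 == "*" else seq3(aa1)


def predict_consequence(model: GeneModel, variant: CodingVariant) -> ProteinConsequence:
    """Compute the protein-level consequence of a coding variant.

    The variant's stated reference allele is validated against the CDS;
    a mismatch raises. Frameshifts report ``ter_offset``, the 1-based codon
    count from the first altered residue to the new stop; if the shifted
    frame reaches the CDS end without a stop the consequence is reported as
    an extension with no ter_offset.
    """
    cds = model.cds
    if variant.cds_position > len(cds):
        raise ValueError(f"c.{variant.cds_position} beyond CDS length {len(cds)}")
    mutated = _apply_to_cds(cds, variant)

    if variant.kind == KIND_SUB:
        ci = codon_index(variant.cds_position)
        ref_codon = cds[(ci - 1) * 3 : ci * 3]
        alt_codon = mutated[(ci - 1) * 3 : ci * 3]
        ref_aa = _translate(ref_codon)
        alt_aa = _translate(alt_codon)
        if ref_aa == alt_aa:
            kind = "synonymous"
        elif alt_aa == "*":
            kind = "nonsense"
        elif ref_aa == "*":
            kind = "extension"
        else:
            kind = "missense"
        return ProteinConsequence(ci, _aa3(ref_aa), _aa3(alt_aa), kind)

    shift = len(variant.alt_allele) - len(variant.ref_allele)
    ref_prot = _translate(cds)
    alt_prot = _translate(mutated)

    if shift % 3 != 0:
        # frameshift: first altered residue, then scan the new frame for Ter
        diff = _first_difference(ref_prot, alt_prot)
        ref_aa = ref_prot[diff] if diff < len(ref_prot) else "*"
        alt_aa = alt_prot[diff] if diff < len(alt_prot) else ""
        if alt_aa == "*":
            return ProteinConsequence(diff + 1, _aa3(ref_aa), "Ter", "nonsense")
        stop_rel = alt_prot.find("*", diff)
        if stop_rel < 0:
            return ProteinConsequence(diff + 1, _aa3(ref_aa), _aa3(alt_aa) + "fs", "extension")
        return ProteinConsequence(
            diff + 1, _aa3(ref_aa), _aa3(alt_aa) + "fs", "frameshift",
            ter_offset=stop_rel - diff + 1,
        )

    ci = codon_index(variant.cds_position)
    ref_aa = ref_prot[ci - 1] if ci <= len(ref_prot) else "*"
    alt_aa = alt_prot[ci - 1] if ci <= len(alt_prot) else ""
    return ProteinConsequence(ci, _aa3(ref_aa), _aa3(alt_aa) if alt_aa else "del", "inframe_delins")


def _first_difference(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def format_hgvs_p(c: ProteinConsequence) -> str:
    """Report-style protein description, e.g. ``p.(Gly218ValfsTer47)``."""
    if c.kind == "synonymous":
        return f"p.({c.ref_aa}{c.codon_index}=)"
    if c.kind == "frameshift":
        return f"p.({c.ref_aa}{c.codon_index}{c.alt_aa}Ter{c.ter_offset})"
    if c.kind == "extension":
        return f"p.({c.ref_aa}{c.codon_index}{c.alt_aa}ext*?)"
    return f"p.({c.ref_aa}{c.codon_index}{c.alt_aa})"
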