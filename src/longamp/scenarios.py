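"""Canonical study scenarios shared by the analysis scripts and the test suite.

Encodes, in one place, the simulated conditions the pipeline is evaluated
under: the ten-patient FH cohort genotypes on the synthetic LDLR-like gene,
a deliberately tiny single-amplicon gene for high-replicate statistics
(depth matters for those questions, amplicon length does not), and the
replicate loops for heterozygous-frequency concentration and for the
tandem-repeat indel recurrence test.
"""

from __future__ import annotations

import numpy as np

from . import align as al
from . import calling as vc
from . import filters as flt
from . import synthetic as syn
from .gene_model import Amplicon, GeneModel, Interval
from .hgvs import CodingVariant, parse_hgvs_c

__all__ = [
    "tiny_gene",
    "tiny_het_spec",
    "tiny_het_hom_spec",
    "PATIENT_GENOTYPES",
    "patient_spec",
    "het_frequency_replicates",
    "het_hom_recovery_replicates",
    "tandem_recurrence_replicates",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

# heterozygous / homozygous marker sites on the tiny gene (CDS positions)
TINY_HET_CDS = 120
TINY_HOM_CDS = 201


def tiny_gene(seed: int = 7) -> tuple[GeneModel, list[Amplicon]]:
    """Minimal single-exon gene with one amplicon spanning the reference.

    Reads are ~280 nt, so a depth-1000 experiment is cheap; used wherever a
    question depends on coverage depth rather than on gene structure.
    """
    rng = np.random.default_rng(seed)
    sense = []
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                if a + b + c not in _STOPS:
                    sense.append(a + b + c)
    codons = ["ATG"] + [sense[int(rng.integers(len(sense)))] for _ in range(78)] + ["TAA"]
    cds = "".join(codons)
    rand = lambda n: "".join(_BASES[i] for i in rng.integers(0, 4, n))
    promoter, utr3 = rand(25), rand(15)
    reference = promoter + cds + utr3
    model = GeneModel(
        name="tiny_gene", reference=reference,
        exons=[Interval(25, len(reference))],
        cds_intervals=[Interval(25, 25 + len(cds))],
    )
    panel = [Amplicon(id="amp_1", interval=Interval(0, len(reference)))]
    return model, panel


def _sub_at(model: GeneModel, cds_pos: int) -> CodingVariant:
    ref = model.cds[cds_pos - 1]
    alt = {"A": "T", "T": "A", "C": "G", "G": "C"}[ref]
    return CodingVariant(cds_pos, ref, alt, "substitution")


def tiny_het_spec(model: GeneModel) -> syn.GenotypeSpec:
    return syn.GenotypeSpec(
        "tiny_het",
        (syn.GenotypeVariant(_sub_at(model, TINY_HET_CDS), "heterozygous", 0),),
    )


def tiny_het_hom_spec(model: GeneModel) -> syn.GenotypeSpec:
    return syn.GenotypeSpec(
        "tiny_het_hom",
        (
            syn.GenotypeVariant(_sub_at(model, TINY_HET_CDS), "heterozygous", 0),
            syn.GenotypeVariant(_sub_at(model, TINY_HOM_CDS), "homozygous"),
        ),
    )


# ten-patient cohort: (HGVS c., zygosity, haplotype) per patient
PATIENT_GENOTYPES: dict[str, list[tuple[str, str, int | None]]] = {
    "patient_01": [("c.1729T>C", "heterozygous", 0)],
    "patient_02": [("c.761A>C", "homozygous", None)],
    "patient_03": [("c.761A>C", "heterozygous", 0)],
    "patient_04": [("c.1567G>A", "homozygous", None)],
    "patient_05": [("c.1916T>A", "heterozygous", 0)],
    "patient_06": [("c.1916T>A", "heterozygous", 0), ("c.1844A>G", "heterozygous", 1)],
    "patient_07": [("c.1844A>G", "heterozygous", 0)],
    "patient_08": [("c.653del", "heterozygous", 0)],
    "patient_09": [("c.1474G>A", "homozygous", None)],
    "patient_10": [("c.1729T>C", "homozygous", None)],
}


def patient_spec(model: GeneModel, patient_id: str) -> syn.GenotypeSpec:
    variants = tuple(
        syn.GenotypeVariant(parse_hgvs_c(h, model), zyg, hap)
        for h, zyg, hap in PATIENT_GENOTYPES[patient_id]
    )
    return syn.GenotypeSpec(patient_id, variants)


def intron_benign_variants(model: GeneModel, introns: list[int]) -> list[syn.GenotypeVariant]:
    """Heterozygous benign passenger substitutions, one per listed intron."""
    return [
        syn.GenotypeVariant(syn.intron_midpoint_variant(model, i), "heterozygous", 0)
        for i in introns
    ]


def _call_sample(
    model: GeneModel,
    panel: list[Amplicon],
    spec: syn.GenotypeSpec,
    err: syn.ErrorModel,
    n_reads: int,
    seed: int,
    *,
    min_frequency: float = 20.0,
    min_depth: int = 100,
) -> tuple[list[vc.VariantCall], "object"]:
    hap_a, hap_b, truth = syn.make_diploid_haplotypes(model, spec)
    records, _ = syn.simulate_reads((hap_a, hap_b), panel, n_reads, err, seed=seed)
    reads = {rid: s for rid, s, _ in records}
    alignments = al.align_reads(reads, model)
    pileup = al.build_pileup(alignments, reads, model)
    calls = vc.call_variants(
        pileup, model, min_frequency=min_frequency, min_depth=min_depth
    )
    return calls, truth


def het_frequency_replicates(
    n_reps: int = 1000, n_reads: int = 1000, seed: int = 1
) -> np.ndarray:
    """Called variant frequency (%) of one error-free heterozygous site.

    Each replicate simulates ``n_reads`` full-length amplicon reads on the
    tiny gene (so site depth equals ``n_reads``), runs alignment, pileup
    and the caller, and records the frequency of the call at the truth
    position. Returns the array of frequencies over replicates.
    """
    model, panel = tiny_gene()
    spec = tiny_het_spec(model)
    err = syn.ErrorModel(substitution_rate=0.0, indel_rate=0.0,
                         tandem_context_multiplier=1.0)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    freqs = np.empty(n_reps)
    for i, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        calls, truth = _call_sample(model, panel, spec, err, n_reads, rep_seed)
        pos = int(truth["pos"].iloc[0])
        hits = [c for c in calls if c.pos == pos and c.kind == "substitution"]
        assert len(hits) == 1, f"expected exactly one call at the truth site, got {hits}"
        freqs[i] = hits[0].variant_frequency
    return freqs


def het_hom_recovery_replicates(
    n_reps: int = 200, n_reads: int = 1000, seed: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """Zygosity recovery for one het and one hom site per replicate.

    Returns boolean arrays (het_correct, hom_correct) under the default
    bands (heterozygous 30-70%, homozygous >= 80%).
    """
    model, panel = tiny_gene()
    spec = tiny_het_hom_spec(model)
    err = syn.ErrorModel(substitution_rate=0.0, indel_rate=0.0,
                         tandem_context_multiplier=1.0)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    het_ok = np.zeros(n_reps, dtype=bool)
    hom_ok = np.zeros(n_reps, dtype=bool)
    for i, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        calls, truth = _call_sample(model, panel, spec, err, n_reads, rep_seed)
        by_pos = {c.pos: c for c in calls}
        for row in truth.itertuples(index=False):
            call = by_pos.get(row.pos)
            if call is None:
                continue
            label = flt.classify_zygosity(call).label
            if row.zygosity == "heterozygous" and label == "heterozygous":
                het_ok[i] = True
            if row.zygosity == "homozygous" and label == "homozygous":
                hom_ok[i] = True
    return het_ok, hom_ok


def tandem_recurrence_replicates(
    n_reps: int = 5, n_reads: int = 400, seed: int = 3
) -> np.ndarray:
    """One-sided Fisher p-values for tandem-indel recurrence across samples.

    Each replicate simulates a healthy control and an FH sample on the
    LDLR-like gene with strongly inflated repeat-context indel errors
    (substitution 2%, indel 3%, context multiplier 8), calls both with a
    permissive 10% frequency threshold, applies the strand-bias filter,
    cross-tabulates the union of calls as (tandem indel vs other) x
    (shared vs sample-specific) and records the Fisher p-value.
    """
    model, panel = syn.ldlr_like_gene()
    err = syn.ErrorModel(substitution_rate=0.02, indel_rate=0.03,
                         tandem_context_multiplier=8.0)
    control = syn.GenotypeSpec(
        "control", tuple(intron_benign_variants(model, [1, 3, 5]))
    )
    fh = syn.GenotypeSpec(
        "fh_sample",
        tuple(
            [syn.GenotypeVariant(parse_hgvs_c("c.1729T>C", model), "heterozygous", 0)]
            + intron_benign_variants(model, [2, 4, 6])
        ),
    )
    children = np.random.SeedSequence(seed).spawn(n_reps)
    pvals = np.empty(n_reps)
    for i, child in enumerate(children):
        s1, s2 = (int(x % (2**31)) for x in child.generate_state(2))
        calls_a, _ = _call_sample(
            model, panel, control, err, n_reads, s1, min_frequency=10.0, min_depth=40
        )
        calls_b, _ = _call_sample(
            model, panel, fh, err, n_reads, s2, min_frequency=10.0, min_depth=40
        )
        calls_a, _ = flt.filter_strand_bias(calls_a)
        calls_b, _ = flt.filter_strand_bias(calls_b)
        table = flt.build_tandem_table(calls_a, calls_b, model)
        pvals[i] = flt.fisher_tandem_test(table)
    return pvals
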