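#!/usr/bin/env python
"""Simulate the FH study cohort on the synthetic LDLR-like gene.

Writes the shared inputs (reference FASTA, exon/CDS annotation, amplicon
panel, recorded-variant catalog) under results/inputs/, per-sample FASTQ
under scratch/cohort/ and the combined truth table under results/cohort/.

The cohort is the ten patients' genotypes (heterozygous, homozygous and
one compound-heterozygous carrier, plus a frameshift) and one healthy
control, sequenced with the default nanopore-like error model. Read
counts are scaled to desk size (default 2,000 per sample; the study-scale
condition is 50,000) — coverage is what matters downstream and stays far
above every calling threshold.
"""

import argparse
from pathlib import Path

import pandas as pd

from longamp.scenarios import PATIENT_GENOTYPES, intron_benign_variants, patient_spec
from longamp.synthetic import (
    ErrorModel,
    GenotypeSpec,
    demo_catalog_frame,
    ldlr_like_gene,
    make_diploid_haplotypes,
    simulate_reads,
    subsample_reads,
    write_fastq,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-reads", type=int, default=2000, help="reads kept per sample")
    ap.add_argument("--seed", type=int, default=2022)
    args = ap.parse_args()

    inputs = ROOT / "results" / "inputs"
    cohort = ROOT / "results" / "cohort"
    fastq_dir = ROOT / "scratch" / "cohort"
    for d in (inputs, cohort, fastq_dir):
        d.mkdir(parents=True, exist_ok=True)

    model, panel = ldlr_like_gene()
    (inputs / "reference.fa").write_text(f">{model.name}\n{model.reference}\n")
    ann = [f"{model.name}\t{iv.start}\t{iv.end}\texon" for iv in model.exons]
    ann += [f"{model.name}\t{iv.start}\t{iv.end}\tCDS" for iv in model.cds_intervals]
    (inputs / "annotation.bed").write_text("\n".join(ann) + "\n")
    (inputs / "panel.bed").write_text(
        "\n".join(
            f"{model.name}\t{a.interval.start}\t{a.interval.end}\t{a.id}" for a in panel
        )
        + "\n"
    )
    demo_catalog_frame(model).to_csv(inputs / "catalog.tsv", sep="\t", index=False)
    print(f"gene: {len(model.reference)} nt, CDS {len(model.cds)} nt, "
          f"{len(model.exons)} exons, {len(panel)} amplicons")

    err = ErrorModel()  # defaults: sub 1%, indel 1%, x6 in repeat context
    # each individual also carries 3 benign heterozygous intron variants
    # (recorded population markers); control and patient_01 get disjoint
    # sets so their cross-tabulation isolates recurrent artifacts
    passenger_introns = {"control": [1, 3, 5], "patient_01": [2, 4, 6]}
    samples = {}
    for k, pid in enumerate(sorted(PATIENT_GENOTYPES) + ["control"]):
        introns = passenger_introns.get(
            pid, [(3 * k + 6) % 17 + 1, (3 * k + 7) % 17 + 1, (3 * k + 8) % 17 + 1]
        )
        passengers = intron_benign_variants(model, introns)
        base = patient_spec(model, pid) if pid in PATIENT_GENOTYPES else GenotypeSpec(pid)
        samples[pid] = GenotypeSpec(pid, base.variants + tuple(passengers))

    truth_frames = []
    for i, (sid, spec) in enumerate(sorted(samples.items())):
        ha, hb, truth = make_diploid_haplotypes(model, spec)
        # draw an excess, then keep a fixed random subset (the analysis
        # protocol fixes the mapped read count per sample)
        records, _ = simulate_reads(
            (ha, hb), panel, int(args.n_reads * 1.25), err,
            seed=args.seed + i, read_prefix=sid,
        )
        records = subsample_reads(records, args.n_reads, seed=args.seed + i)
        write_fastq(records, fastq_dir / f"{sid}.fastq")
        truth_frames.append(truth)
        variants = ", ".join(
            f"{h} ({z})" for h, z, _ in PATIENT_GENOTYPES.get(sid, [])
        ) or "none"
        print(f"{sid}: {len(records)} reads; truth variants: {variants}")

    pd.concat(truth_frames, ignore_index=True).to_csv(
        cohort / "truth.tsv", sep="\t", index=False
    )
    print(f"\nwrote inputs to {inputs}, reads to {fastq_dir}, truth to {cohort}/truth.tsv")


if __name__ == "__main__":
    main()
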