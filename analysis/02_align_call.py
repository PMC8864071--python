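#!/usr/bin/env python
"""Align every cohort sample, assemble pileups and call raw variants.

Reads the FASTQ files produced by 01_simulate_cohort.py, maps each read
to the LDLR-like reference (semi-global, both orientations), tallies the
strand-split pileup, and calls every allele above the frequency/depth
thresholds. Writes per-amplicon coverage and the raw (pre-filter) call
tables under results/cohort/.
"""

import argparse
from pathlib import Path

import pandas as pd

from longamp import align as al
from longamp import calling as vc
from longamp.gene_model import load_amplicons, load_gene_model
from longamp.synthetic import read_fastq

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--min-frequency", type=float, default=10.0)
    ap.add_argument("--min-depth", type=int, default=100)
    args = ap.parse_args()

    inputs = ROOT / "results" / "inputs"
    cohort = ROOT / "results" / "cohort"
    fastq_dir = ROOT / "scratch" / "cohort"
    model = load_gene_model(inputs / "reference.fa", inputs / "annotation.bed")
    panel = load_amplicons(inputs / "panel.bed")

    cov_rows, call_frames = [], []
    for fastq in sorted(fastq_dir.glob("*.fastq")):
        sid = fastq.stem
        records = read_fastq(fastq)
        reads = {rid: seq for rid, seq, _ in records}
        alignments = al.align_reads(reads, model)
        mapped = [a for a in alignments if a.mapped]
        pileup = al.build_pileup(mapped, reads, model)
        cov = al.coverage_stats(pileup, panel)
        cov.insert(0, "sample_id", sid)
        cov_rows.append(cov)
        calls = vc.call_variants(
            pileup, model, min_frequency=args.min_frequency, min_depth=args.min_depth
        )
        frame = vc.calls_to_frame(calls)
        frame.insert(0, "sample_id", sid)
        call_frames.append(frame)
        gmean = cov.loc[cov.amplicon == "__global__", "mean_coverage"].iloc[0]
        print(
            f"{sid}: {len(mapped)}/{len(alignments)} reads mapped, "
            f"mean coverage {gmean:.0f}, {len(calls)} raw calls"
        )

    pd.concat(cov_rows, ignore_index=True).to_csv(
        cohort / "coverage.tsv", sep="\t", index=False
    )
    pd.concat(call_frames, ignore_index=True).to_csv(
        fastq_dir / "calls_raw.tsv", sep="\t", index=False
    )
    print(f"\nwrote {cohort}/coverage.tsv and {fastq_dir}/calls_raw.tsv")


if __name__ == "__main__":
    main()
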