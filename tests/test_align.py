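"""Alignment and pileup: oracle equivalence, depth conservation, coverage."""

import numpy as np
import pytest

from longamp import align as al
from longamp.gene_model import Amplicon, GeneModel, Interval
from longamp.synthetic import (
    ErrorModel,
    GenotypeSpec,
    make_diploid_haplotypes,
    simulate_reads,
)

from conftest import random_seq


def dp_semi_global(query: str, target: str) -> int:
    """Brute-force dynamic-programming oracle for infix edit distance.

    Free gaps at both target ends: best edit distance of the query against
    any substring of the target.
    """
    m, n = len(query), len(target)
    prev = [0] * (n + 1)  # free leading target gap
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        qc = query[i - 1]
        for j in range(1, n + 1):
            cost = 0 if qc == target[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return min(prev)


def _mutate(rng, seq: str, n_sub: int, n_indel: int) -> str:
    s = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(len(s)))
        s[i] = "ACGT"[(("ACGT".index(s[i])) + 1 + int(rng.integers(3))) % 4]
    for _ in range(n_indel):
        i = int(rng.integers(len(s)))
        if rng.random() < 0.5 and len(s) > 10:
            del s[i]
        else:
            s.insert(i, "ACGT"[int(rng.integers(4))])
    return "".join(s)


@pytest.fixture(scope="module")
def ref_model():
    rng = np.random.default_rng(5)
    seq = "ATG" + random_seq(rng, 994) + "TAA"  # 1 kb reference
    return GeneModel(
        name="ref1k", reference=seq,
        exons=[Interval(0, len(seq))], cds_intervals=[Interval(0, len(seq))],
        complete=False,
    )


class TestAlignRead:
    def test_exact_substring_forward(self, ref_model):
        read = ref_model.reference[100:500]
        aln = al.align_read(read, ref_model)
        assert aln.mapped and aln.strand == "+"
        assert aln.edit_distance == 0
        assert (aln.ref_start, aln.ref_end) == (100, 500)
        assert aln.cigar == [("=", 400)]

    def test_reverse_complement_same_interval(self, ref_model):
        read = al.reverse_complement(ref_model.reference[100:500])
        aln = al.align_read(read, ref_model)
        assert aln.mapped and aln.strand == "-"
        assert (aln.ref_start, aln.ref_end) == (100, 500)
        assert aln.edit_distance == 0

    def test_single_substitution_edit_distance(self, ref_model):
        read = list(ref_model.reference[200:600])
        read[50] = "A" if read[50] != "A" else "C"
        read = "".join(read)
        aln = al.align_read(read, ref_model)
        assert aln.edit_distance == 1 == dp_semi_global(read, ref_model.reference)

    def test_empty_read_rejected(self, ref_model):
        with pytest.raises(ValueError):
            al.align_read("", ref_model)

    def test_short_read_unmapped(self, ref_model):
        aln = al.align_read(ref_model.reference[:50], ref_model)
        assert not aln.mapped

    def test_junk_read_fails_identity_floor(self, ref_model):
        rng = np.random.default_rng(8)
        junk = random_seq(rng, 400)
        aln = al.align_read(junk, ref_model, min_identity=0.9)
        assert not aln.mapped

    def test_edit_distance_matches_dp_oracle(self, ref_model):
        rng = np.random.default_rng(13)
        for _ in range(15):
            start = int(rng.integers(0, 500))
            length = int(rng.integers(250, 500))
            read = ref_model.reference[start : start + length]
            read = _mutate(rng, read, int(rng.integers(0, 12)), int(rng.integers(0, 6)))
            if rng.random() < 0.5:
                read = al.reverse_complement(read)
            aln = al.align_read(read, ref_model)
            oriented = aln.oriented_query(read)
            assert aln.edit_distance == dp_semi_global(oriented, ref_model.reference)


class TestPileup:
    def test_uniform_depth_from_identical_reads(self, ref_model):
        read = ref_model.reference[0:300]
        reads = {f"r{i}": read for i in range(10)}
        alns = al.align_reads(reads, ref_model)
        pileup = al.build_pileup(alns, reads, ref_model)
        assert (pileup.depth[0:300] == 10).all()
        assert (pileup.depth[300:] == 0).all()

    def test_deletion_counted_in_column(self, ref_model):
        # pick a deletion site whose base differs from both neighbours so
        # the aligned deletion column is unambiguous
        ref = ref_model.reference
        j = next(
            k for k in range(40, 80) if ref[k] != ref[k - 1] and ref[k] != ref[k + 1]
        )
        read = ref[0:j] + ref[j + 1 : 300]
        reads = {"r0": read}
        alns = al.align_reads(reads, ref_model)
        pileup = al.build_pileup(alns, reads, ref_model)
        col = pileup.column(j + 1)
        assert col.counts_fwd["-"] == 1
        assert sum(v for k, v in col.counts_fwd.items() if k != "-") == 0
        assert pileup.depth[j] == 1

    def test_insertion_anchored_left(self, ref_model):
        read = ref_model.reference[0:100] + "TTTT" + ref_model.reference[100:300]
        reads = {"r0": read}
        alns = al.align_reads(reads, ref_model)
        pileup = al.build_pileup(alns, reads, ref_model)
        col = pileup.column(100)  # base left of the insertion point
        assert col.insertions.get("TTTT") == (1, 0)

    def test_strand_counts_recount_provenance(self, tiny):
        model, panel = tiny
        ha, hb, _ = make_diploid_haplotypes(model, GenotypeSpec("s"))
        err = ErrorModel(substitution_rate=0.0, indel_rate=0.0, tandem_context_multiplier=1.0)
        records, prov = simulate_reads((ha, hb), panel, 300, err, seed=3)
        reads = {r[0]: r[1] for r in records}
        alns = al.align_reads(reads, model)
        pileup = al.build_pileup(alns, reads, model)
        n_fwd = (prov.strand == "+").sum()
        n_rev = (prov.strand == "-").sum()
        # full-length amplicon reads cover every column of the amplicon
        j = panel[0].interval.start + 50
        assert pileup.counts[0, :, j].sum() == n_fwd
        assert pileup.counts[1, :, j].sum() == n_rev

    def test_depth_conservation_with_noisy_reads(self, tiny):
        model, panel = tiny
        ha, hb, _ = make_diploid_haplotypes(model, GenotypeSpec("s"))
        records, _ = simulate_reads((ha, hb), panel, 150, ErrorModel(), seed=11)
        reads = {r[0]: r[1] for r in records}
        alns = al.align_reads(reads, model)
        pileup = al.build_pileup(alns, reads, model)
        spans = np.zeros(len(model.reference), dtype=int)
        for a in alns:
            if a.mapped:
                spans[a.ref_start : a.ref_end] += 1
        # every aligned base/deletion lands in exactly one spanned column
        assert (pileup.depth == spans).all()
        # and depth equals the sum of per-strand base + deletion counts
        assert (pileup.depth == pileup.counts.sum(axis=(0, 1))).all()

    def test_error_free_pileup_has_no_spurious_columns(self, tiny):
        from longamp.scenarios import tiny_het_spec

        model, panel = tiny
        ha, hb, truth = make_diploid_haplotypes(model, tiny_het_spec(model))
        err = ErrorModel(substitution_rate=0.0, indel_rate=0.0, tandem_context_multiplier=1.0)
        records, _ = simulate_reads((ha, hb), panel, 400, err, seed=19)
        reads = {r[0]: r[1] for r in records}
        alns = al.align_reads(reads, model)
        pileup = al.build_pileup(alns, reads, model)
        ref_codes = al._CODE_LOOKUP[np.frombuffer(model.reference.encode(), np.uint8)]
        nonref = pileup.counts.sum(axis=0).copy()
        nonref[ref_codes, np.arange(len(model.reference))] = 0
        truth_pos = set(truth.pos - 1)
        assert set(np.nonzero(nonref.sum(axis=0))[0]) == truth_pos
        assert not pileup.insertions


class TestCoverage:
    def test_uniform_and_empty_amplicon_means(self, ref_model):
        read = ref_model.reference[0:500]
        reads = {f"r{i}": read for i in range(10)}
        alns = al.align_reads(reads, ref_model)
        pileup = al.build_pileup(alns, reads, ref_model)
        panel = [
            Amplicon("covered", Interval(0, 500)),
            Amplicon("empty", Interval(500, 1000)),
        ]
        stats = al.coverage_stats(pileup, panel).set_index("amplicon")
        assert stats.loc["covered", "mean_coverage"] == 10
        assert stats.loc["empty", "mean_coverage"] == 0
        assert bool(stats.loc["empty", "flagged"])

    def test_simulated_equimolar_coverage(self, ldlr):
        model, panel = ldlr
        ha, hb, _ = make_diploid_haplotypes(model, GenotypeSpec("s"))
        err = ErrorModel(substitution_rate=0.0, indel_rate=0.0, tandem_context_multiplier=1.0)
        n = 2000
        records, _ = simulate_reads((ha, hb), panel, n, err, seed=29)
        reads = {r[0]: r[1] for r in records}
        alns = al.align_reads(reads, model)
        pileup = al.build_pileup(alns, reads, model)
        # in each amplicon's exclusive region (not shared with neighbours),
        # coverage equals that amplicon's read count: binomial around n/5
        from scipy import stats as sps

        lo, hi = sps.binom.interval(0.999, n, 1 / 5)
        depth = pileup.depth
        for i, amp in enumerate(panel):
            excl_lo = panel[i - 1].interval.end if i > 0 else amp.interval.start
            excl_hi = panel[i + 1].interval.start if i < len(panel) - 1 else amp.interval.end
            d = depth[excl_lo:excl_hi]
            assert lo <= d.mean() <= hi


def test_sam_export_readable_by_pysam(tmp_path, ref_model):
    import pysam

    reads = {
        "fwd": ref_model.reference[10:400],
        "rev": al.reverse_complement(ref_model.reference[300:700]),
    }
    alns = al.align_reads(reads, ref_model)
    path = tmp_path / "out.sam"
    al.write_sam(alns, reads, ref_model, path)
    with pysam.AlignmentFile(str(path)) as fh:
        recs = list(fh)
    assert len(recs) == 2
    by_name = {r.query_name: r for r in recs}
    assert by_name["fwd"].reference_start == 10
    assert by_name["rev"].is_reverse
    assert by_name["rev"].reference_start == 300
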