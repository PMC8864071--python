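"""Catalog matching, report count identities, end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from longamp import report as rp
from longamp.calling import VariantCall, strand_bias_pct
from longamp.gene_model import genomic_to_cds
from longamp.hgvs import parse_hgvs_c
from longamp.synthetic import demo_catalog_frame


def make_call(pos, ref, alt, freq=45.0, depth=1000):
    alt_n = int(round(freq / 100 * depth))
    f, r = alt_n // 2, alt_n - alt_n // 2
    kind = (
        "substitution" if ref and alt else ("deletion" if ref else "insertion")
    )
    return VariantCall(
        pos=pos, ref=ref, alt=alt, kind=kind, depth=depth, alt_fwd=f, alt_rev=r,
        variant_frequency=100.0 * alt_n / depth,
        strand_bias=strand_bias_pct(f, r), p_value=0.0,
    )


@pytest.fixture(scope="module")
def catalog_file(tmp_path_factory, ldlr):
    model, _ = ldlr
    path = tmp_path_factory.mktemp("cat") / "catalog.tsv"
    demo_catalog_frame(model).to_csv(path, sep="\t", index=False)
    return path


class TestLoadCatalog:
    def test_tsv_entries(self, catalog_file, ldlr):
        model, _ = ldlr
        entries = rp.load_catalog(catalog_file, model)
        assert len(entries) == 6 + 17  # FH variants + one benign marker per intron
        ids = {e.identifier for e in entries}
        assert "rs879254667" in ids and "rs137853966" in ids
        by_id = {e.identifier: e for e in entries}
        assert by_id["rs879254667"].clinical_significance == "pathogenic"
        assert dict(by_id["rs879254667"].predictions)["SIFT"] == "deleterious"

    def test_unnormalized_indel_stored_left_aligned(self, tmp_path, ldlr):
        model, _ = ldlr
        # plant a deletion inside a homopolymer run and describe it at the
        # rightmost position; loading must store the left-aligned twin
        ref = model.reference
        j = ref.find("AAAAA")
        right_pos = j + 5  # 1-based position of the run's last A
        df = pd.DataFrame(
            [{"position": right_pos, "ref": "A", "alt": "", "id": "rsX"}]
        )
        p = tmp_path / "c.tsv"
        df.to_csv(p, sep="\t", index=False)
        (entry,) = rp.load_catalog(p, model)
        from longamp.calling import left_align

        assert (entry.pos, entry.ref, entry.alt) == left_align(right_pos, "A", "", ref)
        assert entry.pos < right_pos

    def test_duplicate_entries_rejected_with_line_numbers(self, tmp_path, ldlr):
        model, _ = ldlr
        df = pd.DataFrame(
            [
                {"position": 100, "ref": "A", "alt": "T", "id": "rs1"},
                {"position": 100, "ref": "A", "alt": "T", "id": "rs2"},
            ]
        )
        p = tmp_path / "dup.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="line 3.*line 2"):
            rp.load_catalog(p, model)

    def test_vcf_catalog_anchored_alleles_normalized(self, tmp_path, ldlr):
        model, _ = ldlr
        ref = model.reference
        j = ref.find("AAAAA")  # 0-based run start
        vcf = tmp_path / "cat.vcf"
        # anchored deletion of one A inside the run, VCF-style
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={model.name},length={len(ref)}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"{model.name}\t{j}\trsDel\t{ref[j - 1]}A\t{ref[j - 1]}\t.\t.\t.\n"
            f"{model.name}\t200\trsSub\t{ref[199]}\t"
            f"{'A' if ref[199] != 'A' else 'C'}\t.\t.\t.\n"
        )
        entries = rp.load_catalog(vcf, model)
        by_id = {e.identifier: e for e in entries}
        assert by_id["rsSub"].pos == 200
        assert by_id["rsDel"].ref == "A" and by_id["rsDel"].alt == ""
        assert by_id["rsDel"].pos == j + 1  # left edge of the run


class TestMatchCatalog:
    def test_exact_match_attaches_identifier(self, catalog_file, ldlr):
        model, _ = ldlr
        catalog = rp.load_catalog(catalog_file, model)
        v = parse_hgvs_c("c.761A>C", model)
        from longamp.gene_model import cds_to_genomic

        call = make_call(cds_to_genomic(model, 761), "A", "C")
        hit = rp.match_catalog(call, catalog)
        assert hit is not None and hit.identifier == "rs879254667"

    def test_different_alt_is_novel(self, catalog_file, ldlr):
        model, _ = ldlr
        catalog = rp.load_catalog(catalog_file, model)
        from longamp.gene_model import cds_to_genomic

        call = make_call(cds_to_genomic(model, 761), "A", "G")
        assert rp.match_catalog(call, catalog) is None

    def test_absent_position_is_novel(self, catalog_file, ldlr):
        model, _ = ldlr
        catalog = rp.load_catalog(catalog_file, model)
        assert rp.match_catalog(make_call(33, model.reference[32], "T"), catalog) is None

    def test_matching_invariant_under_representation_shift(self, ldlr, tmp_path):
        model, _ = ldlr
        ref = model.reference
        j = ref.find("AAAAA")
        # catalog written right-shifted; call left-aligned by the caller
        df = pd.DataFrame([{"position": j + 5, "ref": "A", "alt": "", "id": "rsY"}])
        p = tmp_path / "c.tsv"
        df.to_csv(p, sep="\t", index=False)
        catalog = rp.load_catalog(p, model)
        from longamp.calling import left_align

        pos, r, a = left_align(j + 3, "A", "", ref)  # mid-run representation
        call = make_call(pos, r, a)
        assert rp.match_catalog(call, catalog).identifier == "rsY"


class TestBuildReport:
    def test_counting_example(self, ldlr, catalog_file):
        model, _ = ldlr
        catalog = rp.load_catalog(catalog_file, model)
        from longamp.gene_model import cds_to_genomic

        calls = [
            make_call(cds_to_genomic(model, 761), "A", "C"),  # recorded, CDS
            make_call(50, model.reference[49], "T"),  # novel, promoter
            make_call(
                cds_to_genomic(model, 1567), "G", "A", freq=90.0
            ),  # recorded, CDS
        ]
        annotated = rp.annotate_calls(calls, model, catalog)
        report = rp.build_report(annotated, model, pd.DataFrame(), "s1")
        s = report.summary
        assert (
            s["total_variants"], s["recorded"], s["not_recorded"], s["cds"], s["non_cds"]
        ) == (3, 2, 1, 2, 1)

    def test_empty_call_list(self, ldlr):
        model, _ = ldlr
        annotated = rp.annotate_calls([], model, [])
        report = rp.build_report(annotated, model, pd.DataFrame(), "empty")
        assert report.summary["total_variants"] == 0
        assert report.summary["recorded"] == 0

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=30
        )
    )
    def test_count_identities_on_random_inputs(self, flags):
        rows = pd.DataFrame(
            [
                {"pos": i + 1, "ref": "A", "alt": "T", "kind": "substitution",
                 "region": "CDS" if in_cds else "intron", "exon": "",
                 "hgvs_c": "", "hgvs_p": "", "zygosity": "heterozygous",
                 "variant_frequency": 50.0, "strand_bias": 50.0, "p_value": 0.0,
                 "recorded": rec, "identifier": "x", "clinical_significance": "",
                 "predictions": ""}
                for i, (rec, in_cds) in enumerate(flags)
            ],
            columns=["pos", "ref", "alt", "kind", "region", "exon", "hgvs_c",
                     "hgvs_p", "zygosity", "variant_frequency", "strand_bias",
                     "p_value", "recorded", "identifier", "clinical_significance",
                     "predictions"],
        )
        report = rp.build_report(rows, None, pd.DataFrame(), "rand")
        s = report.summary
        assert s["recorded"] + s["not_recorded"] == s["total_variants"] == len(flags)
        assert s["cds"] + s["non_cds"] == s["total_variants"]


def _pipeline_config(tmp_path, model, panel, genotype, n_reads, error_model, seed=1):
    from longamp.synthetic import demo_catalog_frame

    fasta = tmp_path / "ref.fa"
    fasta.write_text(f">{model.name}\n{model.reference}\n")
    ann = tmp_path / "ann.bed"
    lines = [f"{model.name}\t{iv.start}\t{iv.end}\texon" for iv in model.exons]
    lines += [f"{model.name}\t{iv.start}\t{iv.end}\tCDS" for iv in model.cds_intervals]
    ann.write_text("\n".join(lines) + "\n")
    panel_bed = tmp_path / "panel.bed"
    panel_bed.write_text(
        "\n".join(f"{model.name}\t{a.interval.start}\t{a.interval.end}\t{a.id}" for a in panel)
        + "\n"
    )
    cat = tmp_path / "catalog.tsv"
    demo_catalog_frame(model).to_csv(cat, sep="\t", index=False)
    return {
        "sample_id": "test_sample",
        "reference": str(fasta), "annotation": str(ann), "panel": str(panel_bed),
        "catalog": str(cat), "seed": seed,
        "simulation": {
            "genotype": genotype, "n_reads": n_reads, "error_model": error_model,
        },
        "thresholds": {"min_frequency": 20.0, "min_depth": 50},
        "_base_dir": tmp_path,
    }


class TestRunPipeline:
    def test_error_free_report_equals_truth(self, tmp_path, ldlr):
        model, panel = ldlr
        genotype = [
            {"hgvs_c": "c.1916T>A", "zygosity": "heterozygous", "haplotype": 0},
            {"hgvs_c": "c.1844A>G", "zygosity": "heterozygous", "haplotype": 1},
        ]
        cfg = _pipeline_config(
            tmp_path, model, panel, genotype, 600,
            {"substitution_rate": 0.0, "indel_rate": 0.0, "tandem_context_multiplier": 1.0},
        )
        report = rp.run_pipeline(cfg, output_dir=tmp_path / "out")
        assert report.summary["total_variants"] == 2
        assert set(report.rows.hgvs_c) == {"c.1916T>A", "c.1844A>G"}
        assert set(report.rows.zygosity) == {"heterozygous"}
        # the novel variant is flagged, the recorded one carries its rs id
        by_c = report.rows.set_index("hgvs_c")
        assert by_c.loc["c.1844A>G", "identifier"] == "novel"
        assert by_c.loc["c.1916T>A", "identifier"] == "rs794728584"
        assert (tmp_path / "out" / "test_sample.calls.vcf").exists()

    def test_homozygous_patient_like_report(self, tmp_path, ldlr):
        # one homozygous CDS missense: report row homozygous, CDS count >= 1
        model, panel = ldlr
        cfg = _pipeline_config(
            tmp_path, model, panel,
            [{"hgvs_c": "c.761A>C", "zygosity": "homozygous"}], 600,
            {"substitution_rate": 0.0, "indel_rate": 0.0, "tandem_context_multiplier": 1.0},
        )
        report = rp.run_pipeline(cfg)
        assert report.summary["cds"] >= 1
        row = report.rows[report.rows.hgvs_c == "c.761A>C"].iloc[0]
        assert row.zygosity == "homozygous"
        assert row.identifier == "rs879254667"

    def test_deterministic_given_config(self, tmp_path, ldlr):
        model, panel = ldlr
        cfg = _pipeline_config(
            tmp_path, model, panel,
            [{"hgvs_c": "c.1729T>C", "zygosity": "heterozygous", "haplotype": 0}],
            400, {"substitution_rate": 0.01, "indel_rate": 0.01}, seed=5,
        )
        r1 = rp.run_pipeline(cfg, output_dir=tmp_path / "o1")
        r2 = rp.run_pipeline(cfg, output_dir=tmp_path / "o2")
        assert r1.rows.equals(r2.rows)
        assert (tmp_path / "o1" / "test_sample.report.tsv").read_bytes() == (
            tmp_path / "o2" / "test_sample.report.tsv"
        ).read_bytes()

    def test_config_schema_violations_listed(self, tmp_path):
        with pytest.raises(ValueError) as err:
            rp.run_pipeline({"sample_id": "x"})
        msg = str(err.value)
        for missing in ("reference", "annotation", "panel", "seed", "reads"):
            assert missing in msg
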