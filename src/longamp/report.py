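"""Catalog annotation and the per-sample diagnostic report.

Surviving calls are matched against a recorded-variant catalog (exact
position/ref/alt after left-alignment — a shifted indel representation
never changes the outcome), labelled CDS / promoter / intron / UTR,
given HGVS c. and p. descriptions where they fall in coding sequence,
and summarised into the per-sample report: total variants, recorded vs
novel, CDS vs non-CDS, one annotated row per call, plus per-amplicon
coverage. ``run_pipeline`` composes the whole analysis behind one
declarative config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align as al
from . import calling as vc
from . import filters as flt
from . import synthetic as syn
from .gene_model import (
    Amplicon,
    GeneModel,
    NonCoding,
    genomic_to_cds,
    load_amplicons,
    load_gene_model,
)
from .hgvs import (
    KIND_DEL,
    KIND_INS,
    KIND_SUB,
    CodingVariant,
    format_hgvs_c,
    format_hgvs_p,
    predict_consequence,
)

log = logging.getLogger("longamp")

__all__ = [
    "CatalogVariant",
    "SampleReport",
    "load_catalog",
    "match_catalog",
    "annotate_calls",
    "build_report",
    "run_pipeline",
]


@dataclass(frozen=True)
class CatalogVariant:
    """One recorded variant; predictions are carried verbatim, never computed."""

    pos: int  # 1-based, left-aligned pure representation
    ref: str
    alt: str
    identifier: str
    clinical_significance: str = ""
    predictions: tuple[tuple[str, str], ...] = ()

    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def _catalog_from_frame(df: pd.DataFrame, reference: str, source: str) -> list[CatalogVariant]:
    required = {"position", "ref", "alt", "id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source}: catalog missing columns {sorted(missing)}")
    known = {"position", "ref", "alt", "id", "clinical_significance"}
    pred_cols = [c for c in df.columns if c not in known]
    entries: list[CatalogVariant] = []
    seen: dict[tuple[int, str, str], int] = {}
    problems: list[str] = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            pos = int(d["position"])
            ref = "" if pd.isna(d["ref"]) else str(d["ref"]).upper()
            alt = "" if pd.isna(d["alt"]) else str(d["alt"]).upper()
            ref = "" if ref in (".", "-") else ref
            alt = "" if alt in (".", "-") else alt
            pos, ref, alt = vc.left_align(pos, ref, alt, reference) if (not ref or not alt) and (ref or alt) else (pos, ref, alt)
        except Exception as exc:  # noqa: BLE001 - collected for the error report
            problems.append(f"line {line}: {exc}")
            continue
        key = (pos, ref, alt)
        if key in seen:
            problems.append(
                f"line {line}: duplicate entry for {key}, first seen at line {seen[key]}"
            )
            continue
        seen[key] = line
        preds = tuple(
            (c, str(d[c])) for c in pred_cols if not pd.isna(d[c]) and str(d[c]).strip()
        )
        entries.append(
            CatalogVariant(
                pos=pos, ref=ref, alt=alt, identifier=str(d["id"]),
                clinical_significance=""
                if pd.isna(d.get("clinical_significance"))
                else str(d.get("clinical_significance", "")),
                predictions=preds,
            )
        )
    if problems:
        raise ValueError(f"{source}: malformed catalog records:\n" + "\n".join(problems))
    return entries


def _catalog_from_vcf(path: Path, reference: str) -> list[CatalogVariant]:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        sig_key = "CLNSIG" if "CLNSIG" in vf.header.info else None
        pred_keys = [k for k in vf.header.info if k not in ("CLNSIG",)]
        for rec in vf:
            for alt in rec.alts or ():
                # strip the VCF anchor base to the pure representation
                pos, ref_a, alt_a = rec.pos, rec.ref, alt
                while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[0] == alt_a[0]:
                    pos, ref_a, alt_a = pos + 1, ref_a[1:], alt_a[1:]
                if len(ref_a) != len(alt_a) and ref_a and alt_a and ref_a[0] == alt_a[0]:
                    if len(ref_a) > len(alt_a):
                        pos, ref_a, alt_a = pos + 1, ref_a[1:], ""
                    else:
                        pos, ref_a, alt_a = pos, "", alt_a[1:]
                row = {
                    "position": pos, "ref": ref_a, "alt": alt_a,
                    "id": rec.id or ".",
                    "clinical_significance": str(rec.info.get(sig_key, ""))
                    if sig_key
                    else "",
                }
                for k in pred_keys:
                    if k in rec.info:
                        v = rec.info[k]
                        row[k] = v if isinstance(v, str) else str(v)
                rows.append(row)
    return _catalog_from_frame(pd.DataFrame(rows), reference, str(path))


def load_catalog(path: str | Path, model: GeneModel) -> list[CatalogVariant]:
    """Load a recorded-variant catalog from TSV or VCF.

    Entries are normalized (pure representation, left-aligned) exactly like
    caller output, so matching is representation-independent. Duplicate
    (position, ref, alt) entries or malformed records raise with line
    numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".vcf":
        return _catalog_from_vcf(path, model.reference)
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str}, keep_default_na=True)
    return _catalog_from_frame(df, model.reference, str(path))


def match_catalog(
    call: vc.VariantCall, catalog: list[CatalogVariant] | dict
) -> CatalogVariant | None:
    """Exact (position, ref, alt) match after normalization; None = novel."""
    index = catalog if isinstance(catalog, dict) else {c.key(): c for c in catalog}
    return index.get(call.key())


def _region_and_exon(model: GeneModel, call: vc.VariantCall) -> tuple[str, str]:
    loc = genomic_to_cds(model, call.pos)
    if isinstance(loc, NonCoding):
        exon = model.exon_number(call.pos)
        label = f"exon {exon}" if exon else (loc.region if loc.region != "intron" else f"intron {loc.intron}")
        return loc.region, label
    return "CDS", f"exon {model.exon_number(call.pos)}"


def _coding_description(model: GeneModel, call: vc.VariantCall) -> tuple[str, str]:
    """HGVS c./p. text for a call fully inside the CDS, else blanks."""
    start = genomic_to_cds(model, call.pos)
    if isinstance(start, NonCoding):
        return "", ""
    try:
        if call.kind == "substitution":
            cv = CodingVariant(start, call.ref, call.alt, KIND_SUB)
        elif call.kind == "deletion":
            end = genomic_to_cds(model, call.pos + len(call.ref) - 1)
            if isinstance(end, NonCoding) or end - start != len(call.ref) - 1:
                return "", ""
            cv = CodingVariant(start, call.ref, "", KIND_DEL)
        else:
            cv = CodingVariant(start, "", call.alt, KIND_INS)
        cons = predict_consequence(model, cv)
        return format_hgvs_c(cv), format_hgvs_p(cons)
    except ValueError:
        return "", ""


def annotate_calls(
    calls: list[vc.VariantCall],
    model: GeneModel,
    catalog: list[CatalogVariant],
    het_band: tuple[float, float] = (30.0, 70.0),
    hom_floor: float = 80.0,
) -> pd.DataFrame:
    """One annotated report row per surviving call."""
    index = {c.key(): c for c in catalog}
    rows = []
    for call in calls:
        region, exon_label = _region_and_exon(model, call)
        hgvs_c, hgvs_p = _coding_description(model, call)
        zyg = flt.classify_zygosity(call, het_band, hom_floor)
        hit = match_catalog(call, index)
        rows.append(
            {
                "pos": call.pos, "ref": call.ref, "alt": call.alt, "kind": call.kind,
                "region": region, "exon": exon_label,
                "hgvs_c": hgvs_c, "hgvs_p": hgvs_p,
                "zygosity": zyg.label,
                "variant_frequency": round(call.variant_frequency, 1),
                "strand_bias": round(call.strand_bias, 1),
                "p_value": call.p_value,
                "recorded": hit is not None,
                "identifier": hit.identifier if hit else "novel",
                "clinical_significance": hit.clinical_significance if hit else "not recorded",
                "predictions": "; ".join(f"{k}: {v}" for k, v in hit.predictions)
                if hit
                else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pos", "ref", "alt", "kind", "region", "exon", "hgvs_c", "hgvs_p",
                 "zygosity", "variant_frequency", "strand_bias", "p_value",
                 "recorded", "identifier", "clinical_significance", "predictions"],
    )


@dataclass
class SampleReport:
    sample_id: str
    rows: pd.DataFrame
    summary: dict
    coverage: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        s = self.summary
        lines = [
            f"Sample {self.sample_id}",
            f"  total variants:        {s['total_variants']}",
            f"  recorded in catalog:   {s['recorded']}",
            f"  not recorded:          {s['not_recorded']}",
            f"  variants in CDS:       {s['cds']}",
            f"  variants in non-CDS:   {s['non_cds']}",
            "",
        ]
        for r in self.rows.itertuples(index=False):
            desc = r.hgvs_c or f"g.{r.pos}{r.ref or '-'}>{r.alt or '-'}"
            prot = f" {r.hgvs_p}" if r.hgvs_p else ""
            lines.append(
                f"  {desc}{prot} [{r.exon}] {r.zygosity} ({r.variant_frequency}%) "
                f"{r.identifier} {r.clinical_significance}"
            )
        return "\n".join(lines)


def build_report(
    annotated: pd.DataFrame,
    model: GeneModel,
    coverage: pd.DataFrame,
    sample_id: str,
) -> SampleReport:
    """Assemble the per-sample report and enforce its count identities:
    recorded + not recorded = total and CDS + non-CDS = total."""
    total = len(annotated)
    recorded = int(annotated["recorded"].sum()) if total else 0
    cds = int((annotated["region"] == "CDS").sum()) if total else 0
    summary = {
        "sample_id": sample_id,
        "total_variants": total,
        "recorded": recorded,
        "not_recorded": total - recorded,
        "cds": cds,
        "non_cds": total - cds,
    }
    assert summary["recorded"] + summary["not_recorded"] == total
    assert summary["cds"] + summary["non_cds"] == total
    return SampleReport(sample_id=sample_id, rows=annotated, summary=summary, coverage=coverage)


# ---------------------------------------------------------------------------
# Pipeline orchestration


_REQUIRED_CONFIG = ("sample_id", "reference", "annotation", "panel", "seed")


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        cfg.setdefault("_base_dir", Path(config).parent)
    else:
        cfg = dict(config)
        cfg.setdefault("_base_dir", Path("."))
    problems = [f"missing required field: {k}" for k in _REQUIRED_CONFIG if k not in cfg]
    if "reads" not in cfg and "simulation" not in cfg:
        problems.append("one of 'reads' or 'simulation' is required")
    if problems:
        raise ValueError("config schema violations:\n" + "\n".join(problems))
    return cfg


def _resolve(cfg: dict, key: str) -> Path:
    return Path(cfg["_base_dir"]) / cfg[key]


def _genotype_from_config(entries: list[dict], model: GeneModel) -> syn.GenotypeSpec:
    from .hgvs import parse_hgvs_c

    gvs = []
    for e in entries:
        if "hgvs_c" in e:
            var = parse_hgvs_c(e["hgvs_c"], model)
        else:
            var = syn.GenomicVariant(int(e["pos"]), e.get("ref", ""), e.get("alt", ""))
        gvs.append(
            syn.GenotypeVariant(
                variant=var, zygosity=e["zygosity"], haplotype=e.get("haplotype")
            )
        )
    return syn.GenotypeSpec(sample_id="sample", variants=tuple(gvs))


def run_pipeline(config: str | Path | dict, output_dir: str | Path | None = None) -> SampleReport:
    """Run the full analysis from a declarative config.

    Deterministic for a fixed config and seed. Writes the report (TSV,
    text and JSON summary), the call set (VCF), the filter report and the
    coverage table when an output directory is given or configured.
    """
    cfg = _load_config(config)
    sample_id = str(cfg["sample_id"])
    seed = int(cfg["seed"])
    thresholds = cfg.get("thresholds", {})
    zyg_cfg = cfg.get("zygosity", {})
    het_band = tuple(zyg_cfg.get("het_band", (30.0, 70.0)))
    hom_floor = float(zyg_cfg.get("hom_floor", 80.0))
    repeat_params = flt.RepeatParams(**cfg.get("repeat", {}))

    model = load_gene_model(
        _resolve(cfg, "reference"), _resolve(cfg, "annotation"),
        dialect=cfg.get("annotation_dialect", "bed"),
    )
    panel = load_amplicons(_resolve(cfg, "panel"), dialect=cfg.get("panel_dialect", "bed"))
    catalog: list[CatalogVariant] = []
    if "catalog" in cfg:
        catalog = load_catalog(_resolve(cfg, "catalog"), model)

    if "reads" in cfg:
        records = syn.read_fastq(_resolve(cfg, "reads"))
        log.info("loaded %d reads", len(records))
    else:
        sim = cfg["simulation"]
        spec = _genotype_from_config(sim.get("genotype", []), model)
        hap_a, hap_b, truth = syn.make_diploid_haplotypes(model, spec)
        err = syn.ErrorModel(**sim.get("error_model", {}))
        records, _ = syn.simulate_reads(
            (hap_a, hap_b), panel, int(sim.get("n_reads", 50_000)), err,
            seed=seed, repeat_params=repeat_params,
        )
        log.info("simulated %d reads (%d truth variants)", len(records), len(truth))
    if "subsample" in cfg and int(cfg["subsample"]) < len(records):
        records = syn.subsample_reads(records, int(cfg["subsample"]), seed)
        log.info("subsampled to %d reads", len(records))

    reads = {rid: seq for rid, seq, _ in records}
    alignments = al.align_reads(
        reads, model,
        min_length=int(cfg.get("min_read_length", 200)),
        min_identity=float(cfg.get("min_identity", 0.70)),
    )
    mapped = [a for a in alignments if a.mapped]
    log.info("aligned %d/%d reads", len(mapped), len(alignments))
    pileup = al.build_pileup(mapped, reads, model)
    coverage = al.coverage_stats(pileup, panel)
    calls = vc.call_variants(
        pileup, model,
        min_frequency=float(thresholds.get("min_frequency", 20.0)),
        min_depth=int(thresholds.get("min_depth", 100)),
        null_error_rate=float(thresholds.get("null_error_rate", 0.05)),
    )
    log.info("raw calls: %d", len(calls))
    retained, sb_excluded = flt.filter_strand_bias(calls)
    retained, tr_excluded = flt.exclude_tandem_indels(retained, model, repeat_params)
    log.info(
        "excluded %d strand-bias, %d tandem-indel; %d calls retained",
        len(sb_excluded), len(tr_excluded), len(retained),
    )
    annotated = annotate_calls(retained, model, catalog, het_band, hom_floor)
    report = build_report(annotated, model, coverage, sample_id)

    out = output_dir or cfg.get("output_dir")
    if out:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        annotated.to_csv(out / f"{sample_id}.report.tsv", sep="\t", index=False)
        (out / f"{sample_id}.report.txt").write_text(report.to_text() + "\n")
        with open(out / f"{sample_id}.summary.json", "w") as fh:
            json.dump(report.summary, fh, indent=2)
        coverage.to_csv(out / f"{sample_id}.coverage.tsv", sep="\t", index=False)
        vc.write_vcf(
            retained + sb_excluded + tr_excluded, model, out / f"{sample_id}.calls.vcf",
            ids={c.key(): e.identifier for c in retained
                 for e in [match_catalog(c, catalog)] if e},
        )
        excluded_frame = vc.calls_to_frame(sb_excluded + tr_excluded)
        excluded_frame.to_csv(out / f"{sample_id}.filtered_out.tsv", sep="\t", index=False)
    return report
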