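"""Seeded synthetic-data generation.

Emulates the data every other module consumes — MVLD precuration records,
CIViC-API-shaped JSON (variants, evidence items, assertions) and a
matching offline allele-registry cache — with no downloads. Identical
configurations produce byte-identical outputs, and the manifest labels
exactly which entities were generated deliberately invalid (and under
which rule), so the generator's labels serve as ground truth for
validator tests.

Synthetic gene, drug and disease names come from small bundled lists; the
disease list includes both DOID-bearing and DOID-free entries so both
branches of the ClinVar condition-ID logic are exercised. PMIDs and
identifiers are synthetic integers.
"""

from __future__ import annotations

import json
import random
from pathlib import Path

from pydantic import BaseModel, Field

from .alleles import derived_coordinates
from .civic import (
    AmpClassification,
    Assertion,
    CivicBundle,
    CivicVariant,
    Disease,
    EvidenceItem,
    build_genomic_hgvs,
    write_civic_json,
)
from .harmonize import format_cancer_type
from .mvld import (
    AlleleDescriptive,
    AlleleInterpretive,
    GenomicChange,
    MVLDRecord,
    SomaticInterpretive,
    write_mvld,
)

__all__ = ["FixtureConfig", "FixtureSet", "generate_entities", "generate_fixtures", "worked_example"]

_GENES = ("BRAF", "KRAS", "EGFR", "TP53", "PIK3CA", "ALK", "KIT", "NRAS")
_DRUGS = ("Dabrafenib", "Trametinib", "Erlotinib", "Imatinib", "Cetuximab", "Vemurafenib")
_DISEASES = (
    Disease(name="Melanoma", doid="1909"),
    Disease(name="Lung Non-small Cell Carcinoma", doid="3908"),
    Disease(name="Colorectal Cancer", doid="9256"),
    Disease(name="Chronic Myeloid Leukemia", doid="8552"),
    Disease(name="Rare Sarcoma NOS", doid=None),
    Disease(name="Carcinoma Of Unknown Primary", doid=None),
)
_SNV_CONSEQUENCES = ("missense_variant", "stop_gained", "synonymous_variant")
_DEL_CONSEQUENCES = ("frameshift_variant", "inframe_deletion")
_INS_CONSEQUENCES = ("frameshift_variant", "inframe_insertion")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X",)
_AMP_STRINGS = ("Tier I Level A", "Tier I Level B", "Tier II Level C", "Tier II Level D")


class FixtureConfig(BaseModel):
    """Parameters of one deterministic fixture set."""

    seed: int
    n_variants: int = 20
    n_evidence_per_variant: int = 3
    n_assertions: int = 10
    build_mix: dict[str, float] = Field(
        default_factory=lambda: {"GRCh37": 0.5, "GRCh38": 0.5}
    )
    edge_case_rate: float = 0.0


class FixtureSet(BaseModel):
    """In-memory fixture set plus its ground-truth manifest."""

    mvld_records: list[MVLDRecord]
    bundle: CivicBundle
    registry_cache: dict[str, str]
    manifest: dict


def _pick_build(rng: random.Random, mix: dict[str, float]) -> str:
    r = rng.random()
    total = sum(mix.values())
    cum = 0.0
    for build in sorted(mix):
        cum += mix[build] / total
        if r < cum:
            return build
    return sorted(mix)[-1]


def _make_change(rng: random.Random) -> tuple[GenomicChange, str]:
    """Random trimmed SNV/del/ins with a matching SO consequence."""
    pos = rng.randint(100_000, 200_000_000)
    kind = rng.random()
    if kind < 0.7:
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        consequence = rng.choice(_SNV_CONSEQUENCES)
    elif kind < 0.85:
        ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 4)))
        alt = ""
        consequence = rng.choice(_DEL_CONSEQUENCES)
    else:
        ref = ""
        alt = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
        consequence = rng.choice(_INS_CONSEQUENCES)
    return GenomicChange(start=pos, reference_allele=ref, alternate_allele=alt), consequence


def generate_entities(cfg: FixtureConfig) -> FixtureSet:
    """Generate the full fixture set in memory.

    Clean entities satisfy every validation rule; with a positive
    ``edge_case_rate`` a matching fraction of MVLD records, evidence items
    and assertions each receive exactly one labeled defect (missing
    therapeutic context or direction, oversized allele, out-of-range
    rating, incompatible significance, invalid AMP pair, dangling
    evidence reference). Variants are always clean so coordinate-derived
    products (HGVS keys, the registry cache, export rows) stay usable.
    """
    rng = random.Random(cfg.seed)
    variants: list[CivicVariant] = []
    records: list[MVLDRecord] = []
    evidence: list[EvidenceItem] = []
    assertions: list[Assertion] = []
    cache: dict[str, str] = {}
    invalid: dict[str, list[dict]] = {"mvld": [], "evidence_items": [], "assertions": []}

    for i in range(cfg.n_variants):
        vid = i + 1
        gene = rng.choice(_GENES)
        chrom = rng.choice(_CHROMS)
        build = _pick_build(rng, cfg.build_mix)
        change, consequence = _make_change(rng)
        start, stop = derived_coordinates(
            change.start, change.reference_allele, change.alternate_allele
        )
        aa_pos = rng.randint(10, 900)
        name = f"{rng.choice(_AA)}{aa_pos}{rng.choice(_AA)}"
        transcript = f"NM_{rng.randint(100000, 999999)}.{rng.randint(1, 4)}"
        protein = f"NP_{rng.randint(100000, 999999)}.{rng.randint(1, 4)}"
        dna_sub = f"c.{rng.randint(1, 5000)}{change.reference_allele or 'del'}" + (
            f">{change.alternate_allele}" if change.reference_allele and change.alternate_allele else ""
        )
        protein_sub = f"p.{name}"
        variant = CivicVariant(
            variant_id=vid,
            gene_symbol=gene,
            name=name,
            chromosome=chrom,
            start=start,
            stop=stop,
            reference_bases=change.reference_allele,
            variant_bases=change.alternate_allele,
            reference_build=build,
            representative_transcript=transcript,
            variant_types=[consequence],
            hgvs_expressions=[f"{transcript}:{dna_sub}", f"{protein}:{protein_sub}"],
            allele_registry_id=None,
        )
        variants.append(variant)
        cache[build_genomic_hgvs(variant)] = f"CA{100000 + vid}"

        # one aligned MVLD record per variant
        biomarker = ("Predictive", "Prognostic", "Diagnostic")[i % 3]
        disease = rng.choice(_DISEASES)
        effect = ""
        drug = ""
        extensions: dict[str, str] = {}
        if biomarker == "Predictive":
            effect = rng.choice(
                ("Resistant", "Responsive", "Not-Responsive", "Sensitive", "Reduced Sensitivity")
            )
            drug = rng.choice(_DRUGS)
        else:
            extensions["evidence_direction"] = rng.choice(("Supports", "Does not support"))
            if biomarker == "Prognostic" and rng.random() < 0.5:
                effect = rng.choice(("Responsive", "Resistant"))
        record = MVLDRecord(
            allele_descriptive=AlleleDescriptive(
                genome_build=build,
                gene_name=gene,
                chromosome=chrom,
                dna_position=change,
                refseq_transcript=transcript,
                refseq_protein=protein,
            ),
            allele_interpretive=AlleleInterpretive(
                dna_sub_and_position=dna_sub,
                protein_sub_and_position=protein_sub,
                variant_type=(
                    "SNV" if change.reference_allele and change.alternate_allele else "indel"
                ),
                variant_consequence=consequence,
                somatic_classification=rng.choice(
                    ("Confirmed somatic", "Confirmed germline", "Unknown")
                ),
                pmids=[str(rng.randint(10_000_000, 35_000_000)) for _ in range(rng.randint(1, 3))],
            ),
            somatic_interpretive=SomaticInterpretive(
                cancer_type=format_cancer_type(disease),
                biomarker_class=biomarker,
                therapeutic_context=drug,
                effect=effect,
                level_of_evidence=rng.choice(_AMP_STRINGS),
                sub_level_of_evidence=rng.choice(("", "Expert opinion: reviewed by task team")),
            ),
            extensions=extensions,
        )
        if rng.random() < cfg.edge_case_rate:
            choices = ["oversized_allele"]
            if biomarker == "Predictive":
                choices.append("missing_therapeutic_context")
            else:
                choices.append("missing_evidence_direction")
            defect = rng.choice(choices)
            if defect == "oversized_allele":
                record.allele_descriptive.dna_position = GenomicChange(
                    start=change.start,
                    reference_allele="A" * 60,
                    alternate_allele="G",
                )
            elif defect == "missing_therapeutic_context":
                record.somatic_interpretive.therapeutic_context = ""
            else:
                record.extensions.pop("evidence_direction", None)
            invalid["mvld"].append({"index": i, "defect": defect})
        records.append(record)

    eid = 0
    for v in variants:
        for j in range(cfg.n_evidence_per_variant):
            eid += 1
            etype = ("Predictive", "Prognostic", "Diagnostic")[j % 3]
            disease = rng.choice(_DISEASES)
            if etype == "Predictive":
                significance = rng.choice(
                    ("Sensitivity/Response", "Resistance", "Reduced Sensitivity")
                )
                drugs = [rng.choice(_DRUGS)]
            elif etype == "Prognostic":
                significance = rng.choice(("Better Outcome", "Poor Outcome"))
                drugs = []
            else:
                significance = rng.choice(("Positive", "Negative"))
                drugs = []
            item = EvidenceItem(
                eid=eid,
                variant_id=v.variant_id,
                disease=disease,
                drugs=drugs,
                evidence_type=etype,
                evidence_direction=rng.choice(("Supports", "Does not support")),
                clinical_significance=significance,
                evidence_level=rng.choice("ABCDE"),
                rating=rng.randint(1, 5),
                pmid=str(rng.randint(10_000_000, 35_000_000)),
                statement=f"{etype} evidence for {v.gene_symbol} {v.name} in {disease.name}.",
                status="accepted",
            )
            if rng.random() < cfg.edge_case_rate:
                defect = rng.choice(
                    ["rating_out_of_range", "incompatible_significance"]
                    + (["missing_direction"] if etype in ("Prognostic", "Diagnostic") else [])
                )
                if defect == "rating_out_of_range":
                    item.rating = 6
                elif defect == "incompatible_significance":
                    item.clinical_significance = (
                        "Positive" if etype != "Diagnostic" else "Better Outcome"
                    )
                else:
                    item.evidence_direction = ""
                invalid["evidence_items"].append({"eid": eid, "defect": defect})
            evidence.append(item)

    by_variant: dict[int, list[EvidenceItem]] = {}
    for e in evidence:
        by_variant.setdefault(e.variant_id, []).append(e)
    for k in range(min(cfg.n_assertions, cfg.n_variants)):
        aid = k + 1
        v = variants[k]
        supporting = by_variant[v.variant_id]
        atype = ("Predictive", "Prognostic", "Diagnostic")[k % 3]
        disease = rng.choice(_DISEASES)
        if atype == "Predictive":
            significance = rng.choice(("Sensitivity/Response", "Resistance"))
            drugs = [rng.choice(_DRUGS)]
        elif atype == "Prognostic":
            significance = rng.choice(("Better Outcome", "Poor Outcome"))
            drugs = []
        else:
            significance = rng.choice(("Positive", "Negative"))
            drugs = []
        tier, level = rng.choice(sorted(
            (("Tier I", "Level A"), ("Tier I", "Level B"),
             ("Tier II", "Level C"), ("Tier II", "Level D"))
        ))
        a = Assertion(
            aid=aid,
            variant_id=v.variant_id,
            disease=disease,
            drugs=drugs,
            assertion_type=atype,
            amp=AmpClassification(tier=tier, level=level),
            clinical_significance=significance,
            summary=f"{atype} assertion for {v.gene_symbol} {v.name} in {disease.name}.",
            description=f"Summary of the state of the field for {v.gene_symbol} {v.name}.",
            evidence_ids=[e.eid for e in supporting],
            status="accepted",
            organization=None,
        )
        if rng.random() < cfg.edge_case_rate:
            defect = rng.choice(
                ["invalid_amp_pair", "dangling_evidence_ref"]
                + (["missing_drugs"] if atype == "Predictive" else [])
            )
            if defect == "invalid_amp_pair":
                a.amp = AmpClassification(tier="Tier I", level="Level C")
            elif defect == "dangling_evidence_ref":
                a.evidence_ids = a.evidence_ids + [999000 + aid]
            else:
                a.drugs = []
            invalid["assertions"].append({"aid": aid, "defect": defect})
        assertions.append(a)

    manifest = {
        "config": cfg.model_dump(),
        "counts": {
            "mvld_records": len(records),
            "variants": len(variants),
            "evidence_items": len(evidence),
            "assertions": len(assertions),
        },
        "invalid": invalid,
        "invalid_counts": {k: len(v) for k, v in invalid.items()},
    }
    return FixtureSet(
        mvld_records=records,
        bundle=CivicBundle(variants=variants, evidence_items=evidence, assertions=assertions),
        registry_cache=cache,
        manifest=manifest,
    )


def generate_fixtures(cfg: FixtureConfig, out_dir: str | Path) -> dict:
    """Write ``mvld.tsv``, ``civic.json``, ``registry_cache.tsv`` and
    ``manifest.json`` into ``out_dir``; returns the manifest.

    Outputs are byte-identical across runs with the same configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = generate_entities(cfg)
    write_mvld(fs.mvld_records, out_dir / "mvld.tsv", fmt="tsv", bypass_validation=True)
    write_civic_json(fs.bundle, out_dir / "civic.json")
    cache_lines = ["hgvs_key\tcaid"] + [
        f"{k}\t{fs.registry_cache[k]}" for k in sorted(fs.registry_cache)
    ]
    (out_dir / "registry_cache.tsv").write_text("\n".join(cache_lines) + "\n", encoding="utf-8")
    manifest = dict(fs.manifest, files=["mvld.tsv", "civic.json", "registry_cache.tsv"])
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def worked_example() -> tuple[MVLDRecord, CivicBundle]:
    """A fully valid predictive worked example for demos and end-to-end
    checks: a BRAF V600E-like MVLD record plus a matching assertion
    bundle (AID 5, Tier I Level A, three supporting evidence items).
    All literature identifiers are synthetic."""
    change = GenomicChange(start=140453136, reference_allele="A", alternate_allele="T")
    record = MVLDRecord(
        allele_descriptive=AlleleDescriptive(
            genome_build="GRCh37",
            gene_name="BRAF",
            chromosome="7",
            dna_position=change,
            refseq_transcript="NM_004333.4",
            refseq_protein="NP_004324.2",
        ),
        allele_interpretive=AlleleInterpretive(
            dna_sub_and_position="c.1799T>A",
            protein_sub_and_position="p.V600E",
            variant_type="SNV",
            variant_consequence="missense_variant",
            somatic_classification="Confirmed somatic",
            pmids=["10000001", "10000002", "10000003"],
        ),
        somatic_interpretive=SomaticInterpretive(
            cancer_type="Melanoma [DOID:1909]",
            biomarker_class="Predictive",
            therapeutic_context="Dabrafenib",
            effect="Sensitive",
            level_of_evidence="Tier I Level A",
            sub_level_of_evidence="Expert opinion: reviewed by task team",
        ),
    )
    variant = CivicVariant(
        variant_id=1,
        gene_symbol="BRAF",
        name="V600E",
        chromosome="7",
        start=140453136,
        stop=140453136,
        reference_bases="A",
        variant_bases="T",
        reference_build="GRCh37",
        representative_transcript="NM_004333.4",
        variant_types=["missense_variant"],
        hgvs_expressions=["NM_004333.4:c.1799T>A", "NP_004324.2:p.V600E"],
        allele_registry_id=None,
    )
    disease = Disease(name="Melanoma", doid="1909")
    evidence = [
        EvidenceItem(
            eid=10 + i,
            variant_id=1,
            disease=disease,
            drugs=["Dabrafenib"],
            evidence_type="Predictive",
            evidence_direction="Supports",
            clinical_significance="Sensitivity/Response",
            evidence_level="A",
            rating=4,
            pmid=pmid,
            statement=f"Predictive evidence for BRAF V600E sensitivity (PMID {pmid}).",
            status="accepted",
        )
        for i, pmid in enumerate(["10000001", "10000002", "10000003"], start=1)
    ]
    assertion = Assertion(
        aid=5,
        variant_id=1,
        disease=disease,
        drugs=["Dabrafenib"],
        assertion_type="Predictive",
        amp=AmpClassification(tier="Tier I", level="Level A"),
        clinical_significance="Sensitivity/Response",
        summary="BRAF V600E confers sensitivity to BRAF inhibition in melanoma.",
        description="Multiple trials support sensitivity of BRAF V600E melanoma to dabrafenib.",
        evidence_ids=[11, 12, 13],
        status="accepted",
        organization="ClinGen Somatic WG",
    )
    bundle = CivicBundle(variants=[variant], evidence_items=evidence, assertions=[assertion])
    return record, bundle
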