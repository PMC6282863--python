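"""CIViC entities: JSON reader, validators, AMP pairs, HGVS builder,
registry lookup."""

import itertools

import pytest

from mvldkit import (
    AmpClassification,
    build_genomic_hgvs,
    CivicVariant,
    load_registry_cache,
    lookup_allele_registry_id,
    read_civic_json,
    ReferentialIntegrityError,
    validate_assertion,
    validate_evidence_item,
    write_civic_json,
)
from mvldkit.alleles import DegenerateVariantError, HgvsError
from mvldkit.vocab import AMP_VALID_PAIRS


def _write(bundle, tmp_path, name="civic.json"):
    path = tmp_path / name
    write_civic_json(bundle, path)
    return path


def test_reader_returns_typed_counts(worked, tmp_path):
    _, bundle = worked
    back = read_civic_json(_write(bundle, tmp_path))
    assert (len(back.variants), len(back.evidence_items), len(back.assertions)) == (1, 3, 1)
    assert back.assertions[0].evidence_ids == [11, 12, 13]


def test_dangling_evidence_reference_names_both_ids(worked, tmp_path):
    _, bundle = worked
    broken = bundle.model_copy(deep=True)
    broken.assertions[0].evidence_ids = [11, 999]
    path = _write(broken, tmp_path)
    with pytest.raises(ReferentialIntegrityError, match="999") as exc:
        read_civic_json(path)
    assert "5" in str(exc.value)  # the assertion's AID appears too
    tolerant = read_civic_json(path, strict=False)
    assert any("999" in issue for issue in tolerant.issues)


def test_generator_reader_round_trip(clean_set, tmp_path):
    path = _write(clean_set.bundle, tmp_path)
    back = read_civic_json(path)
    assert back.variants == clean_set.bundle.variants
    assert back.evidence_items == clean_set.bundle.evidence_items
    assert back.assertions == clean_set.bundle.assertions
    assert back.issues == []


@pytest.mark.parametrize(
    "mutator, rule_id",
    [
        (lambda e: setattr(e, "evidence_direction", ""), "EV-R2"),
        (lambda e: setattr(e, "statement", " "), "EV-R2"),
        (lambda e: setattr(e, "rating", 6), "EV-R4"),
        (lambda e: setattr(e, "rating", 0), "EV-R4"),
        (lambda e: setattr(e, "clinical_significance", "Sensitivity/Response"), "EV-R5"),
        (lambda e: setattr(e, "pmid", ""), "EV-R7"),
        (lambda e: setattr(e, "status", "draft"), "EV-R8"),
    ],
)
def test_evidence_item_rules(clean_set, mutator, rule_id):
    diagnostic = next(
        e for e in clean_set.bundle.evidence_items if e.evidence_type == "Diagnostic"
    )
    item = diagnostic.model_copy(deep=True)
    mutator(item)
    report = validate_evidence_item(item)
    assert any(i.rule_id == rule_id for i in report.errors), [str(i) for i in report.issues]


def test_predictive_evidence_requires_drugs(clean_set):
    predictive = next(
        e for e in clean_set.bundle.evidence_items if e.evidence_type == "Predictive"
    )
    item = predictive.model_copy(deep=True)
    item.drugs = []
    assert any(i.rule_id == "EV-R3" for i in validate_evidence_item(item).errors)


def test_significance_compatibility_is_total():
    """Every evidence_type x term pair classifies as valid or invalid."""
    from mvldkit.vocab import EVIDENCE_TYPES, SIGNIFICANCE_BY_TYPE, is_significance_valid

    all_terms = sorted({t for v in SIGNIFICANCE_BY_TYPE.values() for t in v})
    for etype in EVIDENCE_TYPES + ("Nonsense",):
        for term in all_terms + ["Banana"]:
            verdict = is_significance_valid(etype, term)
            assert verdict == (term in SIGNIFICANCE_BY_TYPE.get(etype, ()))


@pytest.mark.parametrize(
    "tier, level",
    list(itertools.product(("Tier I", "Tier II"),
                           ("Level A", "Level B", "Level C", "Level D"))),
)
def test_exactly_four_amp_pairs_validate(worked, tier, level):
    _, bundle = worked
    a = bundle.assertions[0].model_copy(deep=True)
    a.amp = AmpClassification(tier=tier, level=level)
    report = validate_assertion(a, bundle.evidence_items)
    if (tier, level) in AMP_VALID_PAIRS:
        assert report.is_valid
    else:
        assert any(i.rule_id == "AS-R1" for i in report.errors)


def test_amp_valid_pairs_are_the_expected_four():
    assert AMP_VALID_PAIRS == {
        ("Tier I", "Level A"), ("Tier I", "Level B"),
        ("Tier II", "Level C"), ("Tier II", "Level D"),
    }


def test_assertion_evidence_must_share_the_variant(worked):
    _, bundle = worked
    stray = bundle.evidence_items[0].model_copy(deep=True)
    stray.eid = 99
    stray.variant_id = 2
    a = bundle.assertions[0].model_copy(deep=True)
    a.evidence_ids = [11, 99]
    report = validate_assertion(a, bundle.evidence_items + [stray])
    assert any(i.rule_id == "AS-R4" for i in report.errors)


def test_assertion_with_no_evidence_fails(worked):
    _, bundle = worked
    a = bundle.assertions[0].model_copy(deep=True)
    a.evidence_ids = []
    assert any(i.rule_id == "AS-R2" for i in validate_assertion(a, []).errors)


def _variant(**kw) -> CivicVariant:
    base = dict(
        variant_id=1, gene_symbol="BRAF", name="V600E", chromosome="7",
        start=140453136, stop=140453136, reference_bases="A", variant_bases="T",
        reference_build="GRCh37", representative_transcript="NM_004333.4",
    )
    base.update(kw)
    return CivicVariant(**base)


@pytest.mark.parametrize(
    "kw, expected",
    [
        ({}, "NC_000007.13:g.140453136A>T"),
        ({"reference_build": "GRCh38"}, "NC_000007.14:g.140453136A>T"),
        ({"stop": 140453137, "reference_bases": "CT", "variant_bases": ""},
         "NC_000007.13:g.140453136_140453137del"),
        ({"reference_bases": "C", "variant_bases": ""},
         "NC_000007.13:g.140453136del"),
        ({"stop": 140453137, "reference_bases": "", "variant_bases": "GG"},
         "NC_000007.13:g.140453136_140453137insGG"),
        ({"stop": 140453137, "reference_bases": "AT", "variant_bases": "G"},
         "NC_000007.13:g.140453136_140453137delinsG"),
        ({"chromosome": "MT", "start": 100, "stop": 100}, "NC_012920.1:g.100A>T"),
    ],
)
def test_genomic_hgvs_formatting(kw, expected):
    assert build_genomic_hgvs(_variant(**kw)) == expected


def test_degenerate_variant_is_rejected():
    with pytest.raises(DegenerateVariantError):
        build_genomic_hgvs(_variant(variant_bases="A"))


def test_unknown_chromosome_or_build_is_a_lookup_error():
    with pytest.raises(HgvsError):
        build_genomic_hgvs(_variant(chromosome="Z"))
    with pytest.raises(HgvsError):
        build_genomic_hgvs(_variant(reference_build="NCBI36"))


def test_hgvs_is_injective_over_distinct_variants(clean_set):
    variants = clean_set.bundle.variants
    keys = {build_genomic_hgvs(v) for v in variants}
    distinct = {
        (v.reference_build, v.chromosome, v.start, v.reference_bases, v.variant_bases)
        for v in variants
    }
    assert len(keys) == len(distinct)


def test_registry_cache_lookup(clean_set, fixture_dir):
    cache = load_registry_cache(fixture_dir / "registry_cache.tsv")
    assert cache == clean_set.registry_cache
    # closure: every generated variant's key resolves
    for v in clean_set.bundle.variants:
        caid = lookup_allele_registry_id(build_genomic_hgvs(v), cache)
        assert caid is not None and caid.startswith("CA")
    assert lookup_allele_registry_id("NC_000001.10:g.1A>T", cache) is None
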