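"""Flatfile parsing, seed filtering, cluster enrichment, working set."""

import io

import pytest

from breps.data_selection import (
    FilterConfig,
    apply_seed_filters,
    build_working_set,
    enrich_seeds,
    parse_flatfile,
    read_uniref_table,
    select_similar,
)
from conftest import make_record


class TestParseFlatfile:
    def test_fields_mapped(self, flatfile_text):
        records = {r.accession: r for r in parse_flatfile(io.StringIO(flatfile_text))}
        adh = records["P00001"]
        assert adh.is_enzyme
        assert adh.evidence_level == 1
        assert adh.has_publication
        assert adh.length == 120
        assert adh.ec_sets == (frozenset({"1.1.1.1"}),)

    def test_multi_ec_grouped_into_one_and_set(self, flatfile_text):
        records = {r.accession: r for r in parse_flatfile(io.StringIO(flatfile_text))}
        assert records["P00002"].ec_sets == (frozenset({"6.4.1.2", "6.3.4.14"}),)

    def test_record_without_ec_is_not_enzyme(self, flatfile_text):
        records = {r.accession: r for r in parse_flatfile(io.StringIO(flatfile_text))}
        rec = records["P00006"]
        assert not rec.is_enzyme
        assert rec.ec_sets == ()
        assert not rec.has_publication

    def test_malformed_record_skipped(self, flatfile_text, caplog):
        with caplog.at_level("WARNING"):
            records = parse_flatfile(io.StringIO(flatfile_text))
        assert "P00007" not in {r.accession for r in records}
        assert len(records) == 6
        assert any("malformed" in m for m in caplog.messages)


class TestSeedFilters:
    def test_filters_applied(self, flatfile_text):
        records = parse_flatfile(io.StringIO(flatfile_text))
        kept = {r.accession for r in apply_seed_filters(records)}
        # putative keyword, length 99, PE 2 and the non-enzyme all drop out
        assert kept == {"P00001", "P00002"}

    @pytest.mark.parametrize(
        "length,expected",
        [(99, False), (100, True), (7000, True), (7001, False)],
    )
    def test_length_boundaries_inclusive(self, length, expected):
        rec = make_record(sequence="A" * length)
        assert bool(apply_seed_filters([rec])) is expected

    @pytest.mark.parametrize(
        "description",
        [
            "RecName: Full=PUTATIVE kinase; EC=2.7.1.1;",
            "RecName: Full=Hypothetical protein; EC=1.1.1.1;",
            "RecName: Full=Lipase (Fragment); EC=3.1.1.3;",
            "RecName: Full=Probable hydrolase; EC=3.1.1.3;",
            "RecName: Full=Possible ligase; EC=6.1.1.1;",
            "RecName: Full=Potential transferase; EC=2.1.1.37;",
        ],
    )
    def test_banned_keywords_case_insensitive(self, description):
        rec = make_record(description=description)
        assert apply_seed_filters([rec]) == []

    def test_requires_ec_and_evidence(self):
        assert apply_seed_filters([make_record(ecs=())]) == []
        assert apply_seed_filters([make_record(evidence_level=2)]) == []

    def test_idempotent(self, flatfile_text):
        records = parse_flatfile(io.StringIO(flatfile_text))
        once = apply_seed_filters(records)
        assert apply_seed_filters(once) == once


class TestSelectSimilar:
    def _cluster(self, seed, *members):
        return [seed, *members]

    def test_length_deviation_boundary(self):
        seed = make_record("SEED", sequence="A" * 200)
        at_boundary = make_record("M1", sequence="A" * 150)  # 25.0%
        beyond = make_record("M2", sequence="A" * 149)  # 25.5%
        out = select_similar(seed, self._cluster(seed, at_boundary, beyond))
        assert [m.accession for m in out] == ["M1"]

    def test_requires_publication(self):
        seed = make_record("SEED", sequence="A" * 200)
        unpub = make_record("M1", sequence="A" * 200, has_publication=False)
        assert select_similar(seed, self._cluster(seed, unpub)) == []

    def test_annotation_transfer_and_source(self):
        seed = make_record("SEED", ecs=("1.1.1.27",))
        member = make_record("M1", ecs=("9.9.9.9",))
        (out,) = select_similar(seed, self._cluster(seed, member))
        assert out.ec_sets == seed.ec_sets
        assert out.source == "enriched"

    def test_seed_never_returned(self):
        seed = make_record("SEED")
        out = select_similar(seed, self._cluster(seed))
        assert out == []

    def test_seed_missing_from_cluster_errors(self):
        seed = make_record("SEED")
        other = make_record("M1")
        with pytest.raises(ValueError, match="own cluster"):
            select_similar(seed, [other])


class TestWorkingSet:
    def test_seed_precedence_over_enriched_duplicate(self):
        seed = make_record("P1")
        dup = make_record("P1", source="enriched")
        ws = build_working_set([seed], [dup], [seed])
        assert [r.accession for r in ws.seeds] == ["P1"]
        assert ws.enriched == []

    def test_non_enzymes_collected(self):
        seed = make_record("P1")
        non_enzyme = make_record("P2", ecs=(), evidence_level=1)
        pe2_non_enzyme = make_record("P3", ecs=(), evidence_level=2)
        ws = build_working_set([seed], [], [seed, non_enzyme, pe2_non_enzyme])
        assert [r.accession for r in ws.non_enzymes] == ["P2"]
        assert all(
            r.evidence_level == 1 and not r.is_enzyme for r in ws.non_enzymes
        )

    def test_conflicting_sequences_error(self):
        a = make_record("P1", sequence="A" * 100)
        b = make_record("P1", sequence="C" * 100)
        with pytest.raises(ValueError, match="conflicting"):
            build_working_set([a], [b], [])

    def test_empty_inputs(self):
        ws = build_working_set([], [], [])
        assert ws.seeds == ws.enriched == ws.non_enzymes == []


class TestEnrichment:
    def test_enrich_via_cluster_table(self):
        seed = make_record("SEED", sequence="A" * 200)
        similar = make_record("M1", sequence="A" * 180, ecs=("7.7.7.7",))
        outsider = make_record("OUT", sequence="A" * 200)
        clusters = read_uniref_table(
            io.StringIO("C1\tSEED\nC1\tM1\nC2\tOUT\n")
        )
        enriched = enrich_seeds([seed], [seed, similar, outsider], clusters)
        assert [m.accession for m in enriched] == ["M1"]
        assert enriched[0].ec_sets == seed.ec_sets

    def test_surviving_count_matches_brute_force(self):
        """Independent re-implementation of the filter over a synthetic set."""
        from breps.synthetic import default_benchmark_specs, generate_families

        ds = generate_families(default_benchmark_specs(seed=7), n_decoys=20)
        cfg = FilterConfig()
        kept = apply_seed_filters(ds.records, cfg)
        brute = [
            r
            for r in ds.records
            if 100 <= len(r.sequence) <= 7000
            and not any(
                k in r.description.lower()
                for k in ("putative", "hypothetical", "fragment", "probable",
                          "possible", "potential")
            )
            and any(r.ec_sets)
            and r.evidence_level == 1
        ]
        assert len(kept) == len(brute) == 30
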