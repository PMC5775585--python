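import io
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from riskallele.catalog import (
    Ancestry,
    AssociationRecord,
    CatalogFormatError,
    FilterCriteria,
    LdTable,
    RiskClass,
    classify_risk_allele,
    filter_associations,
    ld_prune,
    parse_association_table,
    write_association_tsv,
)


def _rec(snv="rs1", disease="d", raf=0.1, p=1e-9, ancestry=Ancestry.EUROPEAN,
         is_disease=True):
    return AssociationRecord(
        snv_id=snv, disease=disease, risk_allele="A",
        risk_allele_frequency=raf, p_value=p, ancestry_label=ancestry,
        is_disease_trait=is_disease,
    )


class TestParse:
    def test_header_only_yields_empty(self):
        stream = io.StringIO(
            "SNPS\tDISEASE/TRAIT\tSTRONGEST SNP-RISK ALLELE\t"
            "RISK ALLELE FREQUENCY\tP-VALUE\tINITIAL SAMPLE SIZE\n"
        )
        assert list(parse_association_table(stream)) == []

    def test_fixture_rows(self, catalog_tsv):
        result = parse_association_table(catalog_tsv)
        assert len(result) == 4 and result.n_skipped == 1
        by_id = {r.snv_id: r for r in result}
        # "NR" frequency becomes missing, row survives parsing
        assert by_id["rs0002"].risk_allele_frequency is None
        # ancestry from the sample description text
        assert by_id["rs0003"].ancestry_label is Ancestry.OTHER
        assert by_id["rs0001"].ancestry_label is Ancestry.EUROPEAN
        # risk allele symbol split from "rsID-X"; "?" marks unknown
        assert by_id["rs0001"].risk_allele == "A"
        assert by_id["rs0005"].risk_allele == "?"

    def test_two_malformed_pvalues_reported(self):
        header = "SNPS\tDISEASE/TRAIT\tSTRONGEST SNP-RISK ALLELE\tRISK ALLELE FREQUENCY\tP-VALUE\tINITIAL SAMPLE SIZE"
        rows = [
            f"rs{i}\td\trs{i}-A\t0.2\t{p}\tEuropean"
            for i, p in enumerate(["1e-9", "oops", "2e-9", "pending", "3e-9"])
        ]
        result = parse_association_table(io.StringIO("\n".join([header, *rows])))
        assert len(result) == 3 and result.n_skipped == 2
        assert all("P-value" in reason for _, reason in result.skipped)

    def test_missing_column_names_it(self):
        stream = io.StringIO(
            "SNPS\tDISEASE/TRAIT\tSTRONGEST SNP-RISK ALLELE\t"
            "P-VALUE\tINITIAL SAMPLE SIZE\n"
        )
        with pytest.raises(CatalogFormatError, match="RISK ALLELE FREQUENCY"):
            parse_association_table(stream)

    def test_disease_allowlist_sets_trait_flag(self, catalog_tsv):
        result = parse_association_table(catalog_tsv, disease_allowlist=["myopia"])
        flags = {r.snv_id: r.is_disease_trait for r in result}
        assert flags["rs0001"] and not flags["rs0003"]

    def test_roundtrip_through_tsv(self, catalog_tsv):
        first = parse_association_table(catalog_tsv)
        buf = io.StringIO()
        write_association_tsv(first.records, buf)
        buf.seek(0)
        second = parse_association_table(buf)
        assert [
            (r.snv_id, r.risk_allele_frequency, r.p_value) for r in second
        ] == [(r.snv_id, r.risk_allele_frequency, r.p_value) for r in first]


class TestFilter:
    def test_p_above_threshold_removed(self):
        result = filter_associations([_rec(p=1e-7)], FilterCriteria())
        assert len(result) == 0 and result.removed["p_value"] == 1

    def test_known_composition_survives(self):
        """100 records, 40 built to fail exactly one criterion each -> 60 pass."""
        records = [_rec(snv=f"rs{i}") for i in range(60)]
        records += [_rec(snv=f"rsp{i}", p=1e-6) for i in range(10)]
        records += [_rec(snv=f"rsf{i}", raf=None) for i in range(10)]
        records += [_rec(snv=f"rsa{i}", ancestry=Ancestry.OTHER) for i in range(10)]
        records += [_rec(snv=f"rst{i}", is_disease=False) for i in range(10)]
        result = filter_associations(records, FilterCriteria())
        assert len(result) == 60
        assert result.removed == {
            "p_value": 10, "invalid_raf": 10, "ancestry": 10, "non_disease": 10,
        }

    def test_pass_through_preserves_order(self):
        records = [_rec(snv=f"rs{i}", raf=0.01 * i + 0.1) for i in range(10)]
        result = filter_associations(records, FilterCriteria())
        assert list(result) == records

    def test_idempotent_and_order_independent(self):
        records = [_rec(snv=f"rs{i}", p=p) for i, p in
                   enumerate([1e-9, 1e-7, 1e-10, 0.5, 4e-8])]
        once = filter_associations(records, FilterCriteria())
        twice = filter_associations(list(once), FilterCriteria())
        assert list(twice) == list(once) and twice.n_removed == 0
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        assert (
            filter_associations(shuffled, FilterCriteria()).removed == once.removed
        )


class TestClassify:
    @pytest.mark.parametrize(
        "raf,expected",
        [
            (0.3, RiskClass.MINOR),
            (0.5, RiskClass.AMBIGUOUS),
            (0.7, RiskClass.MAJOR),
            (None, RiskClass.AMBIGUOUS),
            (0.0, RiskClass.MINOR),
            (1.0, RiskClass.MAJOR),
        ],
    )
    def test_examples(self, raf, expected):
        assert classify_risk_allele(raf) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_risk_allele(1.2)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_mirror_symmetry(self, f):
        a, b = classify_risk_allele(f), classify_risk_allele(1.0 - f)
        if f == 0.5:
            assert a is RiskClass.AMBIGUOUS and b is RiskClass.AMBIGUOUS
        else:
            assert {a, b} == {RiskClass.MINOR, RiskClass.MAJOR}


class TestLdPrune:
    def _trio(self, disease="d"):
        return [
            _rec(snv="rs1", disease=disease, p=1e-9),
            _rec(snv="rs2", disease=disease, p=1e-10),
            _rec(snv="rs3", disease=disease, p=1e-12),
        ]

    def test_no_linked_pairs_keeps_all(self):
        records = self._trio()
        assert ld_prune(records, LdTable(), 0.8) == tuple(records)

    def test_block_keeps_lowest_p(self):
        records = self._trio()
        ld = LdTable({("rs1", "rs2"): 0.9, ("rs1", "rs3"): 0.9, ("rs2", "rs3"): 0.9})
        survivors = ld_prune(records, ld, 0.8)
        assert [r.snv_id for r in survivors] == ["rs3"]

    def test_pruning_is_per_disease(self):
        records = self._trio("a") + self._trio("b")
        ld = LdTable({("rs1", "rs2"): 0.9, ("rs1", "rs3"): 0.9, ("rs2", "rs3"): 0.9})
        survivors = ld_prune(records, ld, 0.8)
        assert [(r.disease, r.snv_id) for r in survivors] == [
            ("a", "rs3"), ("b", "rs3"),
        ]

    def test_threshold_is_strict(self):
        records = self._trio()
        ld = LdTable({("rs1", "rs2"): 0.8, ("rs1", "rs3"): 0.8, ("rs2", "rs3"): 0.8})
        assert len(ld_prune(records, ld, 0.8)) == 3

    def test_transitive_closure_merges_chains(self):
        # rs1-rs2 and rs2-rs3 linked, rs1-rs3 not: still one block
        records = self._trio()
        ld = LdTable({("rs1", "rs2"): 0.95, ("rs2", "rs3"): 0.95})
        assert [r.snv_id for r in ld_prune(records, ld, 0.8)] == ["rs3"]

    def test_survivors_are_minimal_p_subset(self):
        records = self._trio() + [_rec(snv="rs9", disease="d", p=1e-20)]
        ld = LdTable({("rs1", "rs2"): 0.9})
        survivors = ld_prune(records, ld, 0.8)
        ids = {r.snv_id for r in survivors}
        assert ids == {"rs2", "rs3", "rs9"}
        assert set(survivors) <= set(records)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ld_prune([], LdTable(), 0.0)
        with pytest.raises(ValueError):
            ld_prune([], LdTable(), 1.5)


def test_ld_table_validates_and_symmetric():
    t = LdTable()
    t.set("a", "b", 0.9)
    assert t.r2("b", "a") == 0.9 and t.r2("a", "a") == 1.0
    assert t.r2("a", "zz") == 0.0  # absent pair means unlinked
    with pytest.raises(ValueError):
        t.set("a", "c", 1.5)
    buf = io.StringIO()
    t.to_tsv(buf)
    buf.seek(0)
    assert LdTable.from_tsv(buf).r2("a", "b") == 0.9
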