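"""Removal-filter predicates and the apply_filters driver."""

import itertools
import random

import pytest

from ieivf import ConfigError, FilterConfig, Zygosity, apply_filters
from ieivf.filter_engine import (
    filter_min_depth,
    remove_blacklist_genes,
    remove_consequences,
    remove_hom_alt_in_controls,
    remove_reference_in_patients,
    remove_shared_het,
    trio_recessive_filter,
)
from ieivf.fixtures import mini_blacklist, table1_fixture
from ieivf.genotype_model import classify_records
from ieivf.tabular_io import GeneList, Polarity

from conftest import full_config, make_record, roster_for

ZYGS = ("hom_ref", "het", "hom_alt")


def cfg(**kw):
    roster = kw.pop("roster", roster_for(n_patients=1, n_controls=1))
    return FilterConfig(roster=roster, **kw)


class TestReferenceInPatients:
    @pytest.mark.parametrize(
        "patients, removed",
        [(("het",), False), (("hom_ref",), True), (("hom_ref", "het"), False),
         (("no_call",), True), (("hom_alt",), False)],
    )
    def test_examples(self, patients, removed):
        rec = make_record(patients=patients)
        got = remove_reference_in_patients(rec, cfg())
        assert (got == "ref_in_patients") is removed

    def test_two_patient_grid_any_carrier_survives(self):
        """Enumerate the 4x4 two-patient zygosity grid against the rule."""
        for z1, z2 in itertools.product(ZYGS + ("no_call",), repeat=2):
            rec = make_record(patients=(z1, z2))
            survives = remove_reference_in_patients(rec, cfg()) is None
            assert survives == (z1 in ("het", "hom_alt") or z2 in ("het", "hom_alt"))


class TestHomAltInControls:
    @pytest.mark.parametrize(
        "controls, removed",
        [(("hom_alt",), True), (("het", "het"), False), (("no_call",), False)],
    )
    def test_examples(self, controls, removed):
        rec = make_record(patients=("het",), controls=controls)
        got = remove_hom_alt_in_controls(rec, cfg())
        assert (got == "hom_alt_in_control") is removed

    def test_any_of_five_controls_brute_force(self):
        """All 2^5 hom/het control patterns: one homozygote suffices."""
        for pattern in itertools.product(("het", "hom_alt"), repeat=5):
            rec = make_record(patients=("het",), controls=pattern)
            removed = remove_hom_alt_in_controls(rec, cfg()) is not None
            assert removed == ("hom_alt" in pattern)


class TestBlacklist:
    BL = GeneList("bl", Polarity.BLACK, frozenset({"TTN"}), frozenset({777}))

    def test_symbol_match_case_folded(self):
        rec = make_record(patients=("het",), gene="ttn")
        assert remove_blacklist_genes(rec, cfg(blacklist=self.BL)) == "blacklist"

    def test_absent_gene_survives(self):
        rec = make_record(patients=("het",), gene="EZR")
        assert remove_blacklist_genes(rec, cfg(blacklist=self.BL)) is None

    def test_hgnc_id_match_without_symbol_match(self):
        rec = make_record(patients=("het",), gene="ALIAS", gene_id=777)
        assert remove_blacklist_genes(rec, cfg(blacklist=self.BL)) == "blacklist"


class TestSharedHet:
    @pytest.mark.parametrize(
        "patients, controls, removed",
        [
            (("het",), ("het",), True),
            (("het",), ("hom_ref", "hom_ref"), False),
            (("hom_alt",), ("het",), False),   # scoped to het-only patients
            (("hom_ref",), ("het",), False),   # no carrying patient
        ],
    )
    def test_examples(self, patients, controls, removed):
        rec = make_record(patients=patients, controls=controls)
        got = remove_shared_het(rec, cfg())
        assert (got == "shared_het") is removed

    def test_truth_table_two_patients_two_controls(self):
        """Enumerated oracle: all carrying patients het AND some control het."""
        for pz in itertools.product(ZYGS, repeat=2):
            for cz in itertools.product(ZYGS, repeat=2):
                rec = make_record(patients=pz, controls=cz)
                carriers = [z for z in pz if z in ("het", "hom_alt")]
                expect = (
                    bool(carriers)
                    and all(z == "het" for z in carriers)
                    and "het" in cz
                )
                assert (remove_shared_het(rec, cfg()) is not None) == expect, (pz, cz)


class TestConsequences:
    @pytest.mark.parametrize(
        "effect, reasons",
        [
            ("synonymous_variant", ["synonymous"]),
            ("5_prime_UTR_variant", ["utr"]),
            ("3_prime_UTR_variant", ["utr"]),
            ("missense_variant", []),
            ("splice_acceptor_variant", []),
            ("Synonymous_Variant", []),  # matching is exact and case-sensitive
            ("5_prime_utr_variant", []),
        ],
    )
    def test_exact_term_matching(self, effect, reasons):
        rec = make_record(patients=("het",), effect=effect)
        got = remove_consequences(rec, cfg(remove_utr=True, remove_synonymous=True))
        assert got == reasons

    def test_checkboxes_gate_each_term(self):
        rec = make_record(patients=("het",), effect="synonymous_variant")
        assert remove_consequences(rec, cfg(remove_utr=True)) == []


class TestMinDepth:
    def test_case_study_threshold_10(self, table1):
        records, roster = table1
        records, report = apply_filters(records, FilterConfig(roster=roster, min_depth=10))
        survivors = [r.gene_symbol for r in records if r.surviving]
        assert survivors == ["MAML2", "LILRB3", "EZR", "MAP3K4"]
        assert report.per_filter_fired == {"low_depth": 4}

    def test_zero_disables(self, table1):
        records, roster = table1
        records, report = apply_filters(records, FilterConfig(roster=roster, min_depth=0))
        assert all(r.surviving for r in records)

    def test_threshold_22_keeps_two(self, table1):
        records, roster = table1
        records, _ = apply_filters(records, FilterConfig(roster=roster, min_depth=22))
        assert [r.gene_symbol for r in records if r.surviving] == ["MAML2", "EZR"]

    def test_covered_in_any_patient_survives(self):
        rec = make_record(patients=("het", "het"), depths={"PAT1": 3, "PAT2": 50})
        assert filter_min_depth(rec, cfg(min_depth=10, roster=roster_for(2))) is None

    def test_monotone_in_threshold(self, rich_table):
        records, roster, _ = rich_table
        prev = None
        for depth in (0, 5, 10, 20, 40):
            recs, _ = apply_filters(records, FilterConfig(roster=roster, min_depth=depth))
            surv = {r.key for r in recs if r.surviving}
            if prev is not None:
                assert surv <= prev
            prev = surv


class TestTrioRecessive:
    def test_exactly_one_of_27_combinations_survives(self):
        roster = roster_for(n_patients=1, n_parents=2)
        survivors = []
        for pz, m, f in itertools.product(ZYGS, repeat=3):
            rec = make_record(patients=(pz,), parents=(m, f))
            config = FilterConfig(roster=roster, trio_recessive=True)
            if trio_recessive_filter(rec, config) is None:
                survivors.append((pz, m, f))
        assert survivors == [("hom_alt", "het", "het")]

    def test_roster_shape_checked_before_records(self, table1):
        records, roster = table1  # one patient, no parents
        with pytest.raises(ConfigError, match="two"):
            apply_filters(records, FilterConfig(roster=roster, trio_recessive=True))


class TestApplyFilters:
    def test_all_disabled_is_identity(self, rich_table):
        records, roster, _ = rich_table
        records, report = apply_filters(records, FilterConfig(roster=roster))
        assert report.surviving_count == report.input_count
        assert report.per_filter_fired == {}

    def test_reasons_accumulate(self):
        roster = roster_for(n_patients=1, n_controls=1)
        rec = make_record(patients=("hom_ref",), controls=("hom_alt",),
                          effect="synonymous_variant")
        _, report = apply_filters(
            [rec],
            FilterConfig(roster=roster, remove_ref_in_patients=True,
                         remove_hom_alt_in_controls=True, remove_synonymous=True),
        )
        assert rec.removal_reasons == ["ref_in_patients", "hom_alt_in_control", "synonymous"]
        assert report.surviving_count == 0

    def test_idempotent(self, rich_table):
        records, roster, _ = rich_table
        config = full_config(roster, trio=True)
        once, r1 = apply_filters(records, config)
        snapshot = [list(r.removal_reasons) for r in once]
        twice, r2 = apply_filters(once, config)
        assert [list(r.removal_reasons) for r in twice] == snapshot
        assert r1.per_filter_fired == r2.per_filter_fired

    def test_order_invariance(self, rich_table):
        """Shuffled filter order changes nothing but reason ordering."""
        records, roster, _ = rich_table
        config = full_config(roster, trio=True)
        _, base = apply_filters(records, config)
        base_surv = {r.key for r in records if r.surviving}
        base_reasons = {r.key: set(r.removal_reasons) for r in records}
        rng = random.Random(5)
        for _ in range(4):
            order = config.enabled_filters()
            rng.shuffle(order)
            _, rep = apply_filters(records, config, order=order)
            assert {r.key for r in records if r.surviving} == base_surv
            assert {r.key: set(r.removal_reasons) for r in records} == base_reasons
            assert rep.per_filter_fired == base.per_filter_fired

    def test_accounting_identity(self, rich_table):
        records, roster, _ = rich_table
        records, report = apply_filters(records, full_config(roster, trio=True))
        removed = sum(1 for r in records if r.removal_reasons)
        assert report.input_count == report.surviving_count + removed
        assert report.input_count == len(records)

    def test_missing_blacklist_is_config_error(self):
        with pytest.raises(ConfigError, match="blacklist"):
            apply_filters([], cfg(remove_blacklist=True))

    def test_filtering_without_patient_is_config_error(self):
        roster = roster_for(n_patients=0, n_controls=1)
        with pytest.raises(ConfigError, match="patient"):
            apply_filters([], FilterConfig(roster=roster, min_depth=10))
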