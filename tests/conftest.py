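import pytest

from ieivf import (
    Assembly,
    FilterConfig,
    Role,
    SampleObservation,
    SampleRoster,
    VariantKey,
    VariantRecord,
    classify_records,
)

# canonical allele balances realizing each zygosity under default thresholds
AB = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0}


def make_observation(sample_id, role, zyg, depth=30, label=""):
    """Observation whose numeric classification is *zyg* (or no_call)."""
    if zyg == "no_call":
        return SampleObservation(sample_id=sample_id, role=role, depth=0,
                                 allele_balance=None, genotype_label=label)
    return SampleObservation(sample_id=sample_id, role=role, depth=depth,
                             allele_balance=AB[zyg], genotype_label=label)


_serial = iter(range(1, 10**6))


def make_record(patients=(), controls=(), parents=(), gene="GENEX", gene_id=None,
                effect="missense_variant", depths=None, classify=True):
    """Build a one-off record from per-role zygosity strings.

    ``patients``/``controls``/``parents`` are sequences of zygosity names
    ("hom_ref", "het", "hom_alt", "no_call"); ``depths`` optionally maps
    sample ids to depths.
    """
    n = next(_serial)
    obs = {}
    for prefix, role, zygs in (("PAT", Role.PATIENT, patients),
                               ("CTL", Role.CONTROL, controls),
                               ("PAR", Role.PARENT, parents)):
        for i, z in enumerate(zygs):
            sid = f"{prefix}{i + 1}"
            depth = (depths or {}).get(sid, 30)
            obs[sid] = make_observation(sid, role, z, depth=depth)
    rec = VariantRecord(
        key=VariantKey("chr1", 1000 + n, "A", "C", Assembly.GRCH38),
        gene_symbol=gene,
        gene_id=gene_id,
        variant_effect=effect,
        existing_variation="",
        observations=obs,
    )
    if classify:
        classify_records([rec])
    return rec


def roster_for(n_patients=1, n_controls=0, n_parents=0, assembly=Assembly.GRCH38):
    samples = [(f"PAT{i + 1}", Role.PATIENT) for i in range(n_patients)]
    samples += [(f"CTL{i + 1}", Role.CONTROL) for i in range(n_controls)]
    samples += [(f"PAR{i + 1}", Role.PARENT) for i in range(n_parents)]
    return SampleRoster(samples=samples, assembly=assembly)


@pytest.fixture
def table1():
    from ieivf.fixtures import table1_fixture

    records, roster = table1_fixture()
    classify_records(records)
    return records, roster


#: fraction recipe planting every category (needs n_parents=2)
ALL_CATEGORY_FRACTIONS = {
    "ref_in_patient": 0.06,
    "hom_in_control": 0.06,
    "shared_het": 0.06,
    "blacklist_gene": 0.06,
    "utr": 0.06,
    "synonymous": 0.06,
    "low_depth": 0.06,
    "compound_het_pair": 0.06,
    "trio_recessive_hit": 0.06,
    "whitelist_gene": 0.06,
}


@pytest.fixture
def rich_table():
    """500-record table planting every category, with a trio + controls."""
    from ieivf.fixtures import FixtureSpec, generate_table

    spec = FixtureSpec(
        n_variants=500, n_patients=1, n_controls=2, n_parents=2, seed=20260926,
        fractions=dict(ALL_CATEGORY_FRACTIONS),
    )
    records, roster, labels = generate_table(spec)
    classify_records(records)
    return records, roster, labels


def full_config(roster, whitelist=None, blacklist=None, trio=False):
    from ieivf.fixtures import mini_blacklist, mini_whitelist

    return FilterConfig(
        roster=roster,
        remove_ref_in_patients=True,
        remove_hom_alt_in_controls=True,
        remove_blacklist=True,
        remove_shared_het=True,
        remove_utr=True,
        remove_synonymous=True,
        min_depth=10,
        trio_recessive=trio,
        flag_compound_het=True,
        flag_whitelist=True,
        whitelist=whitelist or mini_whitelist(),
        blacklist=blacklist or mini_blacklist(),
    )
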