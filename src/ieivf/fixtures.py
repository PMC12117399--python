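"""Synthetic variant tables with planted, labelled structure.

Real patient exomes cannot be redistributed, so every filter and flag is
exercised on generated tables instead.  :func:`generate_table` plants records
of named categories — each detectable by exactly one filter or flag — among
"clean" background records that no filter touches, and returns the intended
category of every record so tests can assert exact agreement.  Depth draws
emulate exome capture coverage (a dispersed integer distribution over
[10, 120], matching the range seen in practice); allele balances sit near 0,
0.5 or 1 with Gaussian noise for planted hom-ref / het / hom-alt genotypes.

:func:`table1_fixture` reconstructs the published eight-variant shortlist of
a consanguineous patient with an EZR deficiency (homozygous white-list
variants, patient RP0047), which anchors the exact-reproduction tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .genotype_model import (
    Assembly,
    Role,
    SampleObservation,
    VariantKey,
    VariantRecord,
)
from .tabular_io import GeneList, Polarity, SampleRoster

#: categories a record can be planted as; "clean" marks background records
CATEGORIES = (
    "ref_in_patient",
    "hom_in_control",
    "shared_het",
    "blacklist_gene",
    "utr",
    "synonymous",
    "low_depth",
    "compound_het_pair",
    "trio_recessive_hit",
    "whitelist_gene",
)

# small curated panels so list-matching tests need no external download:
# 20 genes with established immune/IEI relevance ...
MINI_WHITELIST = (
    "EZR", "BTK", "WAS", "IL2RG", "RAG1", "RAG2", "JAK3", "ADA", "STAT1",
    "STAT3", "NFKB1", "IRAK4", "MYD88", "TLR3", "UNC93B1", "DOCK8", "LRBA",
    "CTLA4", "PIK3CD", "FOXP3",
)
# ... and 20 without (structural, metabolic, sensory)
MINI_BLACKLIST = (
    "TTN", "OBSCN", "MUC16", "PCLO", "RYR1", "NEB", "USH2A", "FLG", "AHNAK",
    "SYNE1", "DNAH5", "ABCA4", "CFTR", "COL1A1", "FBN1", "MYH7", "DMD",
    "PKD1", "LDLR", "APOB",
)

_BASES = "ACGT"


def mini_whitelist() -> GeneList:
    return GeneList("mini_whitelist", Polarity.WHITE, frozenset(MINI_WHITELIST))


def mini_blacklist() -> GeneList:
    return GeneList("mini_blacklist", Polarity.BLACK, frozenset(MINI_BLACKLIST))


@dataclass
class FixtureSpec:
    """Recipe for one synthetic table.

    ``fractions`` maps category name -> fraction of ``n_variants`` to plant
    (compound-het plants come in pairs, so odd planted counts are rounded
    down to even); the remainder are clean background records.
    """

    n_variants: int = 100
    n_patients: int = 1
    n_controls: int = 2
    n_parents: int = 0
    seed: int = 0
    fractions: dict[str, float] = field(default_factory=dict)
    depth_range: tuple[int, int] = (10, 120)
    low_depth_range: tuple[int, int] = (1, 9)
    het_ab_sd: float = 0.05
    hom_ab_sd: float = 0.02
    assembly: Assembly = Assembly.GRCH38

    def validate(self) -> None:
        unknown = set(self.fractions) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown planted categories: {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ConfigError("planted fractions must be non-negative")
        if sum(self.fractions.values()) > 1.0 + 1e-9:
            raise ConfigError(
                f"planted fractions sum to {sum(self.fractions.values()):.3f} > 1"
            )
        if self.fractions.get("trio_recessive_hit", 0) > 0 and self.n_parents != 2:
            raise ConfigError("trio_recessive_hit plants require n_parents = 2")
        if self.n_patients < 1:
            raise ConfigError("at least one patient sample is required")


def _roster(spec: FixtureSpec) -> SampleRoster:
    samples = [(f"PAT{i + 1}", Role.PATIENT) for i in range(spec.n_patients)]
    samples += [(f"CTL{i + 1}", Role.CONTROL) for i in range(spec.n_controls)]
    samples += [(f"PAR{i + 1}", Role.PARENT) for i in range(spec.n_parents)]
    return SampleRoster(samples=samples, assembly=spec.assembly)


class _Drawer:
    """Seeded draws for depths, allele balances and loci."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        # unique positions: ample spacing avoids collisions by construction
        self._pos = iter(
            self.rng.choice(
                np.arange(10_000, 50_000_000, 137), size=spec.n_variants * 2, replace=False
            )
        )

    def depth(self) -> int:
        lo, hi = self.spec.depth_range
        # right-skewed coverage, floor at lo so the read-quality filter
        # never fires on a non-planted record
        d = lo + self.rng.negative_binomial(4, 0.12)
        return int(min(d, hi))

    def low_depth(self) -> int:
        lo, hi = self.spec.low_depth_range
        return int(self.rng.integers(lo, hi + 1))

    def ab(self, zyg: str) -> float:
        if zyg == "het":
            return float(np.clip(self.rng.normal(0.5, self.spec.het_ab_sd), 0.3, 0.7))
        if zyg == "hom_alt":
            return float(np.clip(1.0 - abs(self.rng.normal(0, self.spec.hom_ab_sd)), 0.9, 1.0))
        return float(np.clip(abs(self.rng.normal(0, self.spec.hom_ab_sd)), 0.0, 0.1))

    def obs(self, sid: str, role: Role, zyg: str, depth: int | None = None) -> SampleObservation:
        d = self.depth() if depth is None else depth
        return SampleObservation(
            sample_id=sid, role=role, depth=d, allele_balance=self.ab(zyg)
        )

    def key(self, assembly: Assembly) -> VariantKey:
        chrom = f"chr{int(self.rng.integers(1, 23))}"
        pos = int(next(self._pos))
        ref, alt = self.rng.choice(list(_BASES), size=2, replace=False)
        return VariantKey(chrom, pos, str(ref), str(alt), assembly)


def _planted_counts(spec: FixtureSpec) -> dict[str, int]:
    counts = {}
    for cat in CATEGORIES:
        k = int(round(spec.fractions.get(cat, 0.0) * spec.n_variants))
        if cat == "compound_het_pair":
            k -= k % 2
        counts[cat] = k
    if sum(counts.values()) > spec.n_variants:
        raise ConfigError("planted counts exceed n_variants after rounding")
    return counts


def generate_table(
    spec: FixtureSpec,
) -> tuple[list[VariantRecord], SampleRoster, list[str]]:
    """Generate a reproducible table; returns (records, roster, truth labels).

    Truth labels align with records: each entry is a category name or
    ``"clean"``.  Clean records are heterozygous in the first patient, absent
    from the controls, well covered, missense, and on genes off both panels —
    so no removal filter fires on them and no flag is raised.  Each planted
    category perturbs exactly the feature its filter or flag inspects.
    """
    spec.validate()
    roster = _roster(spec)
    draw = _Drawer(spec)
    counts = _planted_counts(spec)

    pat_ids = roster.ids_with_role(Role.PATIENT)
    ctl_ids = roster.ids_with_role(Role.CONTROL)
    par_ids = roster.ids_with_role(Role.PARENT)
    for cat, needs in (("hom_in_control", ctl_ids), ("shared_het", ctl_ids)):
        if counts[cat] and not needs:
            raise ConfigError(f"{cat} plants require at least one control sample")

    gene_serial = 0

    def neutral_gene() -> tuple[str, int]:
        nonlocal gene_serial
        gene_serial += 1
        return f"NGN{gene_serial:04d}", 100_000 + gene_serial

    def build(
        gene: tuple[str, int] | None = None,
        effect: str = "missense_variant",
        patient_zyg: str = "het",
        patient_depth: int | None = None,
        control_zygs: dict[str, str] | None = None,
        parent_zygs: tuple[str, str] | None = None,
    ) -> VariantRecord:
        symbol, gid = gene if gene else neutral_gene()
        obs: dict[str, SampleObservation] = {}
        for pid in pat_ids:
            obs[pid] = draw.obs(pid, Role.PATIENT, patient_zyg, patient_depth)
        for cid in ctl_ids:
            zyg = (control_zygs or {}).get(cid, "hom_ref")
            obs[cid] = draw.obs(cid, Role.CONTROL, zyg)
        for i, rid in enumerate(par_ids):
            zyg = parent_zygs[i] if parent_zygs else ("het" if i == 0 else "hom_ref")
            obs[rid] = draw.obs(rid, Role.PARENT, zyg)
        rs_serial = draw.rng.integers(10_000, 99_999_999)
        return VariantRecord(
            key=draw.key(spec.assembly),
            gene_symbol=symbol,
            gene_id=gid,
            variant_effect=effect,
            existing_variation=f"rs{rs_serial}" if draw.rng.random() < 0.8 else "",
            observations=obs,
        )

    records: list[VariantRecord] = []
    labels: list[str] = []

    def add(rec: VariantRecord, label: str) -> None:
        records.append(rec)
        labels.append(label)

    for _ in range(counts["ref_in_patient"]):
        add(build(patient_zyg="hom_ref"), "ref_in_patient")
    for i in range(counts["hom_in_control"]):
        cid = ctl_ids[i % len(ctl_ids)]
        add(build(control_zygs={cid: "hom_alt"}), "hom_in_control")
    for i in range(counts["shared_het"]):
        cid = ctl_ids[i % len(ctl_ids)]
        add(build(control_zygs={cid: "het"}), "shared_het")
    for i in range(counts["blacklist_gene"]):
        sym = MINI_BLACKLIST[i % len(MINI_BLACKLIST)]
        add(build(gene=(sym, 200_000 + i)), "blacklist_gene")
    for i in range(counts["utr"]):
        effect = ("5_prime_UTR_variant", "3_prime_UTR_variant")[i % 2]
        add(build(effect=effect), "utr")
    for _ in range(counts["synonymous"]):
        add(build(effect="synonymous_variant"), "synonymous")
    for _ in range(counts["low_depth"]):
        add(build(patient_depth=draw.low_depth()), "low_depth")
    for _ in range(counts["compound_het_pair"] // 2):
        gene = neutral_gene()
        add(build(gene=gene), "compound_het_pair")
        add(build(gene=gene), "compound_het_pair")
    for _ in range(counts["trio_recessive_hit"]):
        add(
            build(patient_zyg="hom_alt", parent_zygs=("het", "het")),
            "trio_recessive_hit",
        )
    for i in range(counts["whitelist_gene"]):
        sym = MINI_WHITELIST[i % len(MINI_WHITELIST)]
        add(build(gene=(sym, 300_000 + i)), "whitelist_gene")
    while len(records) < spec.n_variants:
        add(build(), "clean")

    # deterministic shuffle so plants are not positionally clustered
    perm = draw.rng.permutation(len(records))
    records = [records[i] for i in perm]
    labels = [labels[i] for i in perm]
    return records, roster, labels


# ---------------------------------------------------------------------------
# the published case-study shortlist

_TABLE1_ROWS = (
    # symbol, HGNC id, chrom, pos, ref, alt, depth, effect, dbSNP id
    ("HLA-B", 4932, "chr6", 31356431, "G", "A", 2, "missense_variant", ""),
    ("PDE4DIP", 15580, "chr1", 148870282, "G", "T", 2, "missense_variant", "rs12118314"),
    ("PDE4DIP", 15580, "chr1", 148870283, "T", "G", 2, "missense_variant", "rs12119750"),
    ("MAML2", 16259, "chr11", 96093510, "C", "T", 36, "missense_variant", "rs61749254"),
    ("LILRB3", 6607, "chr19", 54222457, "T", "C", 14, "missense_variant", "rs200199363"),
    ("EZR", 12691, "chr6", 158785391, "C", "T", 29, "missense_variant", "rs528409234"),
    ("MAP3K4", 6856, "chr6", 161070652, "G", "T", 21, "missense_variant", "rs34018542"),
    ("SRP9", 11304, "chr1", 225786860, "A", "T", 1, "splice_acceptor_variant", ""),
)

TABLE1_PATIENT = "RP0047"
TABLE1_GENES = tuple(dict.fromkeys(r[0] for r in _TABLE1_ROWS))


def table1_fixture() -> tuple[list[VariantRecord], SampleRoster]:
    """The eight homozygous white-list variants of the EZR-deficiency patient.

    Single consanguineous patient RP0047, all calls labelled ``P_Homo_var``
    with allele balance 1; depths {2, 2, 2, 36, 14, 29, 21, 1}; seven
    missense variants plus one splice-acceptor variant.
    """
    roster = SampleRoster(
        samples=[(TABLE1_PATIENT, Role.PATIENT)], assembly=Assembly.GRCH37
    )
    records = []
    for symbol, gid, chrom, pos, ref, alt, depth, effect, rsid in _TABLE1_ROWS:
        obs = SampleObservation(
            sample_id=TABLE1_PATIENT,
            role=Role.PATIENT,
            depth=depth,
            allele_balance=1.0,
            genotype_label="P_Homo_var",
        )
        records.append(
            VariantRecord(
                key=VariantKey(chrom, pos, ref, alt, Assembly.GRCH37),
                gene_symbol=symbol,
                gene_id=gid,
                variant_effect=effect,
                existing_variation=rsid,
                observations={TABLE1_PATIENT: obs},
            )
        )
    return records, roster


def table1_whitelist() -> GeneList:
    """White list covering every gene of the case-study shortlist."""
    return GeneList("table1_whitelist", Polarity.WHITE, frozenset(TABLE1_GENES))
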