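"""Removal filters for candidate-variant triage.

Every filter is a pure, record-wise predicate: it looks at one record's
per-sample zygosity calls (stamped beforehand by
:func:`ieivf.genotype_model.classify_records`) and either returns a removal
reason string or ``None``.  Enabled filters are evaluated independently on
every record and a record accumulates *every* reason that fires, so the
provenance report can explain each removal fully.  Because the predicates
never look at other records or at previous reasons, any evaluation order
yields the same survivor set.

The filters implement the recessive-disease triage used for inborn errors of
immunity:

* ``ref_in_patients`` — the patient does not carry the variant at all;
* ``hom_alt_in_control`` — an unaffected control is homozygous for it, so it
  cannot be the recessive cause of the patient's disease;
* ``shared_het`` — a simple heterozygous variant also seen heterozygous in a
  control is not disease-causing under a fully penetrant model;
* ``blacklist`` — the gene is on a curated not-immunology-related list;
* ``utr`` / ``synonymous`` — consequence classes with no protein change or
  outside the coding sequence;
* ``low_depth`` — too few reads in the patient to trust the call;
* ``trio_recessive`` — under the consanguinity hypothesis, keep only variants
  homozygous in the patient with both parents heterozygous carriers.

"Present in controls" always means presence in ANY control, never a
population frequency: allele-frequency filtering is deliberately out of scope
and should be done upstream.  Observations with no call are treated as
non-carrying for rules that need evidence of carriage, and as non-homozygous
for control-based removal — a no-call can neither rescue nor remove a record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .errors import ConfigError
from .genotype_model import VariantRecord, Zygosity, ZygosityThresholds
from .tabular_io import GeneList, SampleRoster

log = logging.getLogger(__name__)

UTR_EFFECTS = ("5_prime_UTR_variant", "3_prime_UTR_variant")
SYNONYMOUS_EFFECT = "synonymous_variant"

#: canonical reason strings, in checkbox order
FILTER_NAMES = (
    "ref_in_patients",
    "hom_alt_in_control",
    "blacklist",
    "shared_het",
    "utr",
    "synonymous",
    "low_depth",
    "trio_recessive",
)

_CARRIER = frozenset({Zygosity.HET, Zygosity.HOM_ALT})


@dataclass
class FilterConfig:
    """Mirror of the filter form: sample roles, checkboxes and thresholds.

    ``min_depth`` of 0 disables the read-quality filter.  The compound-het
    ranges gate which heterozygous patient calls may pair up into a flagged
    compound heterozygote (see :mod:`ieivf.annotator`); their defaults mirror
    the read-quality threshold and the heterozygous allele-balance band.
    """

    roster: SampleRoster
    remove_ref_in_patients: bool = False
    remove_hom_alt_in_controls: bool = False
    remove_blacklist: bool = False
    remove_shared_het: bool = False
    remove_utr: bool = False
    remove_synonymous: bool = False
    min_depth: int = 0
    trio_recessive: bool = False
    flag_compound_het: bool = False
    flag_whitelist: bool = False
    compound_het_depth_range: tuple[float, float] = (10, math.inf)
    compound_het_ab_range: tuple[float, float] = (0.2, 0.8)
    strict_trio_phase: bool = False
    thresholds: ZygosityThresholds = field(default_factory=ZygosityThresholds)
    whitelist: Optional[GeneList] = None
    blacklist: Optional[GeneList] = None

    def validate(self) -> None:
        """Raise :class:`ConfigError` on an internally inconsistent config."""
        if self.min_depth < 0:
            raise ConfigError(f"min_depth must be >= 0, got {self.min_depth}")
        for label, (lo, hi) in (
            ("compound_het_depth_range", self.compound_het_depth_range),
            ("compound_het_ab_range", self.compound_het_ab_range),
        ):
            if lo > hi:
                raise ConfigError(f"{label} is not well-ordered: [{lo}, {hi}]")
        if self.remove_blacklist and self.blacklist is None:
            raise ConfigError("remove_blacklist is on but no blacklist was loaded")
        if self.flag_whitelist and self.whitelist is None:
            raise ConfigError("flag_whitelist is on but no white list was loaded")
        if self.trio_recessive and (
            self.roster.n_patients != 1 or self.roster.n_parents != 2
        ):
            raise ConfigError(
                "the trio recessive filter needs exactly one patient and two "
                f"parents; roster has {self.roster.n_patients} patient(s) and "
                f"{self.roster.n_parents} parent(s)"
            )
        if self.any_filter_enabled and self.roster.n_patients == 0:
            raise ConfigError("filtering requested but no sample has the patient role")

    @property
    def any_filter_enabled(self) -> bool:
        return any(
            (
                self.remove_ref_in_patients,
                self.remove_hom_alt_in_controls,
                self.remove_blacklist,
                self.remove_shared_het,
                self.remove_utr,
                self.remove_synonymous,
                self.min_depth > 0,
                self.trio_recessive,
            )
        )

    def enabled_filters(self) -> list[str]:
        names = []
        if self.remove_ref_in_patients:
            names.append("ref_in_patients")
        if self.remove_hom_alt_in_controls:
            names.append("hom_alt_in_control")
        if self.remove_blacklist:
            names.append("blacklist")
        if self.remove_shared_het:
            names.append("shared_het")
        if self.remove_utr:
            names.append("utr")
        if self.remove_synonymous:
            names.append("synonymous")
        if self.min_depth > 0:
            names.append("low_depth")
        if self.trio_recessive:
            names.append("trio_recessive")
        return names


# ---------------------------------------------------------------------------
# predicates — each returns a reason string or None


def remove_reference_in_patients(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire when no patient carries the variant (all hom_ref or no-call)."""
    patients = record.patients
    if not patients:
        return None
    if any(p.zygosity in _CARRIER for p in patients):
        return None
    return "ref_in_patients"


def remove_hom_alt_in_controls(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire when any unaffected control is homozygous for the variant."""
    if any(c.zygosity is Zygosity.HOM_ALT for c in record.controls):
        return "hom_alt_in_control"
    return None


def remove_blacklist_genes(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire when the gene (symbol or HGNC id) is on the not-immunology list."""
    assert config.blacklist is not None
    if config.blacklist.contains(record.gene_symbol, record.gene_id):
        return "blacklist"
    return None


def remove_shared_het(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire on simple het variants shared between patients and controls.

    Scoped to variants in heterozygosis: every carrying patient must be het
    (a variant homozygous in any patient is never removed here) and at least
    one control must be het.
    """
    carriers = [p for p in record.patients if p.zygosity in _CARRIER]
    if not carriers:
        return None
    if any(p.zygosity is Zygosity.HOM_ALT for p in carriers):
        return None
    if any(c.zygosity is Zygosity.HET for c in record.controls):
        return "shared_het"
    return None


def remove_utr(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire on untranslated-region consequences (exact term match)."""
    if record.variant_effect in UTR_EFFECTS:
        return "utr"
    return None


def remove_synonymous(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire on synonymous consequences (exact term match)."""
    if record.variant_effect == SYNONYMOUS_EFFECT:
        return "synonymous"
    return None


def remove_consequences(record: VariantRecord, config: FilterConfig) -> list[str]:
    """UTR + synonymous consequence removal, honouring the two checkboxes."""
    reasons = []
    if config.remove_utr and remove_utr(record, config):
        reasons.append("utr")
    if config.remove_synonymous and remove_synonymous(record, config):
        reasons.append("synonymous")
    return reasons


def filter_min_depth(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Fire when every patient covers the site with fewer than min_depth reads.

    A variant well covered in any one patient survives; control depth is
    never a removal criterion.
    """
    patients = record.patients
    if config.min_depth <= 0 or not patients:
        return None
    if all(p.depth < config.min_depth for p in patients):
        return "low_depth"
    return None


def trio_recessive_filter(record: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Recessive consanguinity hypothesis: patient hom_alt, both parents het."""
    (patient,) = record.patients
    parents = record.parents
    if patient.zygosity is Zygosity.HOM_ALT and all(
        p.zygosity is Zygosity.HET for p in parents
    ):
        return None
    return "trio_recessive"


_PREDICATES: dict[str, Callable[[VariantRecord, FilterConfig], Optional[str]]] = {
    "ref_in_patients": remove_reference_in_patients,
    "hom_alt_in_control": remove_hom_alt_in_controls,
    "blacklist": remove_blacklist_genes,
    "shared_het": remove_shared_het,
    "utr": remove_utr,
    "synonymous": remove_synonymous,
    "low_depth": filter_min_depth,
    "trio_recessive": trio_recessive_filter,
}


# ---------------------------------------------------------------------------
# report + driver


@dataclass
class FilterReport:
    """Per-run accounting: what came in, what fired, what survived."""

    input_count: int
    surviving_count: int
    per_filter_fired: dict[str, int]
    flagged_whitelist: int = 0
    flagged_compound_het: int = 0
    config_echo: dict = field(default_factory=dict)
    tool_version: str = ""
    timestamp: str = ""

    def check(self, removed_count: int) -> None:
        assert self.surviving_count <= self.input_count
        assert self.surviving_count == self.input_count - removed_count

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "surviving_count": self.surviving_count,
            "per_filter_fired": dict(self.per_filter_fired),
            "flagged_whitelist": self.flagged_whitelist,
            "flagged_compound_het": self.flagged_compound_het,
            "config": self.config_echo,
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
        }


def apply_filters(
    records: Iterable[VariantRecord],
    config: FilterConfig,
    order: Optional[Sequence[str]] = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Stamp removal reasons on every record and return the accounting report.

    Each enabled filter is evaluated independently on every record; reasons
    accumulate rather than short-circuit.  *order* permutes the evaluation
    sequence (it must be a permutation of the enabled filter names) — the
    survivor set is provably invariant under it, and the option exists so the
    test suite can demonstrate that.

    Previous removal reasons are cleared first, making the operation
    idempotent.
    """
    config.validate()
    enabled = config.enabled_filters()
    if order is not None:
        if sorted(order) != sorted(enabled):
            raise ConfigError(
                f"order {list(order)} is not a permutation of the enabled "
                f"filters {enabled}"
            )
        enabled = list(order)
    if config.remove_hom_alt_in_controls and config.roster.n_controls == 0:
        log.warning("remove_hom_alt_in_controls enabled but the roster has no controls; no-op")
    if config.remove_shared_het and config.roster.n_controls == 0:
        log.warning("remove_shared_het enabled but the roster has no controls; no-op")

    records = list(records)
    fired = {name: 0 for name in enabled}
    removed = 0
    for rec in records:
        rec.removal_reasons = []
        for name in enabled:
            reason = _PREDICATES[name](rec, config)
            if reason is not None:
                rec.removal_reasons.append(reason)
                fired[name] += 1
        if rec.removal_reasons:
            removed += 1

    report = FilterReport(
        input_count=len(records),
        surviving_count=len(records) - removed,
        per_filter_fired=fired,
    )
    report.check(removed)
    return records, report
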