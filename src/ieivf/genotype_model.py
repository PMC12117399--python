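"""Core variant/sample data types and allele-balance zygosity classification.

A whole-exome variant table carries, per sample and per site, only two pieces
of genotype evidence: the total read depth and the allele balance (variant
reads / total reads, the table's ``Var/Depth`` column).  Zygosity is therefore
classified from the allele balance with conventional germline short-read
cut-offs: balances near 0 are homozygous reference, balances in a central band
are heterozygous, and balances near 1 are homozygous for the variant allele.
When the table also carries an explicit caller label (e.g. ``P_Homo_var``),
the label wins, because the upstream caller saw read-level evidence the table
no longer carries.

All types here are plain in-memory containers; file I/O lives in
:mod:`ieivf.tabular_io` and filtering logic in :mod:`ieivf.filter_engine`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .errors import SchemaError

log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


class Assembly(str, Enum):
    """Reference genome assembly a table was annotated against."""

    GRCH37 = "GRCh37.p13"
    GRCH38 = "GRCh38.p14"

    @classmethod
    def parse(cls, tag: str) -> "Assembly":
        t = tag.strip()
        for member in cls:
            if t == member.value or t.lower() == member.name.lower():
                return member
        # accept the short form without the patch level
        for member in cls:
            if member.value.lower().startswith(t.lower()) and t:
                return member
        raise SchemaError(
            f"unknown genome assembly {tag!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class Role(str, Enum):
    PATIENT = "patient"
    CONTROL = "control"
    PARENT = "parent"


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class VariantKey:
    """Identity of one decomposed variant: locus, alleles and assembly.

    Coordinates are 1-based and fully closed (VCF convention).  Multi-allelic
    sites must arrive decomposed, one alternate allele per row.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    assembly: Assembly

    def __post_init__(self):
        if self.position < 1:
            raise SchemaError(f"position must be >= 1, got {self.position} at {self.chromosome}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _NUCLEOTIDES:
                raise SchemaError(
                    f"{name} allele must be a non-empty uppercase A/C/G/T string, "
                    f"got {allele!r} at {self.chromosome}:{self.position}"
                )
        if self.ref == self.alt:
            raise SchemaError(
                f"ref and alt alleles are identical ({self.ref!r}) at "
                f"{self.chromosome}:{self.position}"
            )

    @property
    def locus(self) -> str:
        return f"{self.chromosome}:{self.position}"


@dataclass(frozen=True)
class ZygosityThresholds:
    """Allele-balance bands used by :func:`classify_zygosity`.

    Defaults are the conventional cut-offs for germline short-read calls:
    heterozygous for balances in [0.2, 0.8), homozygous-variant at >= 0.8,
    homozygous-reference below 0.2.  ``min_call_depth`` sites covered by fewer
    reads are not called at all.
    """

    het_min_ab: float = 0.2
    het_max_ab: float = 0.8
    hom_min_ab: float = 0.8
    min_call_depth: int = 1

    def __post_init__(self):
        if not (0.0 <= self.het_min_ab < self.het_max_ab <= self.hom_min_ab <= 1.0):
            raise SchemaError(
                "zygosity thresholds must satisfy "
                "0 <= het_min_ab < het_max_ab <= hom_min_ab <= 1, got "
                f"({self.het_min_ab}, {self.het_max_ab}, {self.hom_min_ab})"
            )
        if self.min_call_depth < 0:
            raise SchemaError("min_call_depth must be >= 0")


@dataclass
class SampleObservation:
    """One sample's evidence at one variant.

    ``allele_balance`` is undefined (``None``) when ``depth`` is 0: with no
    reads there is no fraction, and such observations always classify as
    ``no_call``.  ``zygosity`` is derived state stamped by
    :func:`classify_zygosity`; it is excluded from equality so that records
    round-trip through files before and after classification compare equal.
    """

    sample_id: str
    role: Role
    depth: int
    allele_balance: Optional[float]
    genotype_label: str = ""
    zygosity: Zygosity = field(default=Zygosity.NO_CALL, compare=False)

    def __post_init__(self):
        if self.depth < 0:
            raise SchemaError(f"sample {self.sample_id}: depth must be >= 0, got {self.depth}")
        if self.depth == 0:
            # no reads -> no defined allele balance
            self.allele_balance = None
        elif self.allele_balance is None:
            raise SchemaError(
                f"sample {self.sample_id}: allele balance missing at depth {self.depth}"
            )
        elif not (0.0 <= self.allele_balance <= 1.0):
            raise SchemaError(
                f"sample {self.sample_id}: allele balance {self.allele_balance} "
                "outside [0, 1]"
            )


_LABEL_UNKNOWN_SEEN: set[str] = set()


def parse_genotype_label(raw: str) -> Optional[Zygosity]:
    """Map a free-text caller label to a zygosity, or ``None`` if unrecognized.

    The matching is a case-insensitive substring rule over the vocabulary seen
    in real tables (``P_Homo_var`` and relatives): ``ref`` -> hom_ref,
    ``het`` -> het, ``hom`` -> hom_alt.  Unknown non-empty labels are tolerated
    and logged once per distinct label.
    """
    s = raw.strip().lower()
    if not s:
        return None
    if "ref" in s:
        return Zygosity.HOM_REF
    if "het" in s:
        return Zygosity.HET
    if "hom" in s:
        return Zygosity.HOM_ALT
    if raw not in _LABEL_UNKNOWN_SEEN:
        _LABEL_UNKNOWN_SEEN.add(raw)
        log.warning("unrecognized genotype label %r; falling back to numeric call", raw)
    return None


def classify_zygosity(
    obs: SampleObservation, thresholds: ZygosityThresholds = ZygosityThresholds()
) -> Zygosity:
    """Classify one observation's zygosity.

    Order of precedence: insufficient depth -> ``no_call``; a recognized
    genotype label -> that call; otherwise the allele-balance bands of
    *thresholds*.  Balances in ``[het_max_ab, hom_min_ab)`` (an empty interval
    under the defaults) resolve to ``het``.
    """
    if obs.depth == 0 or obs.depth < thresholds.min_call_depth:
        return Zygosity.NO_CALL
    labelled = parse_genotype_label(obs.genotype_label)
    if labelled is not None:
        return labelled
    ab = obs.allele_balance
    assert ab is not None  # guaranteed by SampleObservation validation
    if ab >= thresholds.hom_min_ab:
        return Zygosity.HOM_ALT
    if ab >= thresholds.het_min_ab:
        return Zygosity.HET
    return Zygosity.HOM_REF


@dataclass
class VariantRecord:
    """One annotated variant row with per-sample evidence and triage state.

    ``removal_reasons`` empty means the record survives filtering;
    ``whitelist_hit``/``compound_het`` are only meaningful on survivors.
    ``existing_variation`` is the dbSNP identifier, with the empty string
    encoding "none" (input tables may spell that ``Null``).
    """

    key: VariantKey
    gene_symbol: str
    gene_id: Optional[int]
    variant_effect: str
    existing_variation: str
    observations: dict[str, SampleObservation]
    whitelist_hit: bool = False
    compound_het: bool = False
    removal_reasons: list[str] = field(default_factory=list)

    @property
    def surviving(self) -> bool:
        return not self.removal_reasons

    def by_role(self, role: Role) -> list[SampleObservation]:
        return [o for o in self.observations.values() if o.role == role]

    @property
    def patients(self) -> list[SampleObservation]:
        return self.by_role(Role.PATIENT)

    @property
    def controls(self) -> list[SampleObservation]:
        return self.by_role(Role.CONTROL)

    @property
    def parents(self) -> list[SampleObservation]:
        return self.by_role(Role.PARENT)


def classify_records(
    records: Iterable[VariantRecord],
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> None:
    """Stamp ``zygosity`` on every observation of every record, in place."""
    for rec in records:
        for obs in rec.observations.values():
            obs.zygosity = classify_zygosity(obs, thresholds)
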