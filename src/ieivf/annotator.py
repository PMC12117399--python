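"""Highlighting of surviving records: compound heterozygotes and white-list hits.

Annotation never removes anything — the survivor set before and after is
identical.  Flags correspond to the coloured highlights of the triage output:
green for genes on the immune white list, pink for putative compound
heterozygotes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations
from typing import Iterable, Sequence

from .filter_engine import FilterConfig
from .genotype_model import Role, SampleObservation, VariantRecord, Zygosity
from .tabular_io import GeneList

log = logging.getLogger(__name__)


def _qualifies(obs: SampleObservation, config: FilterConfig) -> bool:
    d_lo, d_hi = config.compound_het_depth_range
    ab_lo, ab_hi = config.compound_het_ab_range
    return (
        obs.zygosity is Zygosity.HET
        and d_lo <= obs.depth <= d_hi
        and obs.allele_balance is not None
        and ab_lo <= obs.allele_balance <= ab_hi
    )


def _trans_compatible(r1: VariantRecord, r2: VariantRecord) -> bool:
    # two variants can sit on different haplotypes if each is het in a parent
    # and the parents can be assigned distinctly
    c1 = {p.sample_id for p in r1.parents if p.zygosity is Zygosity.HET}
    c2 = {p.sample_id for p in r2.parents if p.zygosity is Zygosity.HET}
    return any(a != b for a in c1 for b in c2)


def flag_compound_het(
    records: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Set ``compound_het`` on qualifying pairs of surviving het variants.

    Surviving records are grouped by gene symbol.  Within a gene, a record
    qualifies for a given patient when that patient's call is heterozygous
    with depth and allele balance inside the configured ranges (both mates
    must pass the ranges).  If a patient has two or more qualifying records
    in the gene, all of that patient's qualifying records there are flagged —
    so flagged counts per (gene, patient) are never exactly one.

    Qualification is per patient: two variants het in *different* patients do
    not combine.  By default flagging is phase-naive (without parental reads
    both variants could sit on one haplotype).  With ``strict_trio_phase``
    and parental samples present, a record is flagged only if some other
    qualifying record can be placed on the opposite parental haplotype (each
    of the pair het in a different parent).
    """
    records = list(records)
    survivors = [r for r in records if r.surviving]
    for rec in survivors:
        rec.compound_het = False

    by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for rec in survivors:
        by_gene[rec.gene_symbol.upper()].append(rec)

    patient_ids = config.roster.ids_with_role(Role.PATIENT)
    for gene_records in by_gene.values():
        for pid in patient_ids:
            quals = [
                r for r in gene_records
                if pid in r.observations and _qualifies(r.observations[pid], config)
            ]
            if len(quals) < 2:
                continue
            if config.strict_trio_phase and config.roster.n_parents == 2:
                for r1, r2 in combinations(quals, 2):
                    if _trans_compatible(r1, r2):
                        r1.compound_het = True
                        r2.compound_het = True
            else:
                for r in quals:
                    r.compound_het = True
    return records


def flag_whitelist(
    records: Iterable[VariantRecord], whitelist: GeneList
) -> list[VariantRecord]:
    """Set ``whitelist_hit`` on surviving records whose gene is on the list.

    Matching is by case-folded symbol or, when the list carries them, by
    HGNC id.  Idempotent and independent of record order.
    """
    records = list(records)
    for rec in records:
        if rec.surviving:
            rec.whitelist_hit = whitelist.contains(rec.gene_symbol, rec.gene_id)
    return records


def select_candidates(
    records: Sequence[VariantRecord],
    require_hom: bool = False,
    require_whitelist: bool = False,
) -> list[VariantRecord]:
    """Convenience triage: surviving records passing the requested predicates.

    ``require_hom`` keeps records homozygous-variant in at least one patient
    (the consanguinity shortlist); ``require_whitelist`` keeps white-list
    hits, so flags must have been computed first.  With neither requirement
    this is the identity on survivors.
    """
    out = []
    for rec in records:
        if not rec.surviving:
            continue
        if require_hom and not any(
            p.zygosity is Zygosity.HOM_ALT for p in rec.patients
        ):
            continue
        if require_whitelist and not rec.whitelist_hit:
            continue
        out.append(rec)
    return out
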