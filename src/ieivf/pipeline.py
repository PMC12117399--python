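"""Pipeline orchestration: load -> classify -> filter -> annotate -> write.

The stage order is fixed.  Removal predicates commute, so ordering only
matters for the flag stages, which are defined on survivors (highlights are
applied within the filtered list, as in the interactive tool).  The pipeline
uses no randomness anywhere: identical inputs and configuration produce
byte-identical TSV output and report (minus the timestamp field).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml

from . import __version__
from .annotator import flag_compound_het, flag_whitelist
from .errors import ConfigError
from .filter_engine import FilterConfig, FilterReport, apply_filters
from .genotype_model import Assembly, Role, VariantRecord, ZygosityThresholds, classify_records
from .tabular_io import (
    Dialect,
    Polarity,
    SampleRoster,
    merge_tables,
    read_gene_list,
    read_variant_table,
    write_filtered_table,
)

log = logging.getLogger(__name__)


def _echo_config(config: FilterConfig) -> dict[str, Any]:
    """JSON-safe serialization of the effective configuration."""
    def _num(x):
        return None if x in (float("inf"), float("-inf")) else x

    return {
        "assembly": config.roster.assembly.value,
        "patients": config.roster.ids_with_role(Role.PATIENT),
        "controls": config.roster.ids_with_role(Role.CONTROL),
        "parents": config.roster.ids_with_role(Role.PARENT),
        "remove_ref_in_patients": config.remove_ref_in_patients,
        "remove_hom_alt_in_controls": config.remove_hom_alt_in_controls,
        "remove_blacklist": config.remove_blacklist,
        "remove_shared_het": config.remove_shared_het,
        "remove_utr": config.remove_utr,
        "remove_synonymous": config.remove_synonymous,
        "min_depth": config.min_depth,
        "trio_recessive": config.trio_recessive,
        "flag_compound_het": config.flag_compound_het,
        "flag_whitelist": config.flag_whitelist,
        "compound_het_depth_range": [_num(v) for v in config.compound_het_depth_range],
        "compound_het_ab_range": list(config.compound_het_ab_range),
        "strict_trio_phase": config.strict_trio_phase,
        "zygosity_thresholds": {
            "het_min_ab": config.thresholds.het_min_ab,
            "het_max_ab": config.thresholds.het_max_ab,
            "hom_min_ab": config.thresholds.hom_min_ab,
            "min_call_depth": config.thresholds.min_call_depth,
        },
        "whitelist": None if config.whitelist is None
        else {"name": config.whitelist.name, "n_genes": len(config.whitelist)},
        "blacklist": None if config.blacklist is None
        else {"name": config.blacklist.name, "n_genes": len(config.blacklist)},
    }


def run_pipeline(
    config: FilterConfig,
    input_paths: Sequence[str | Path],
    output_path: str | Path,
    report_path: Optional[str | Path] = None,
    dialect: Optional[Dialect | str] = None,
    include_removed: bool = False,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the full triage on one or more variant tables.

    Reads every input against the configured roster (all tables must share
    the roster's assembly), classifies zygosity for every observation,
    applies the enabled removal filters, computes the compound-het and
    white-list flags on the survivors, writes the filtered table and —
    optionally — a machine-readable JSON report next to the human-readable
    log lines.
    """
    config.validate()
    loaded = [
        read_variant_table(p, config.roster.assembly, roster_hint=config.roster)
        for p in input_paths
    ]
    records, _ = merge_tables(loaded) if loaded else ([], config.roster)
    log.info("stage=load inputs=%d records=%d", len(loaded), len(records))

    classify_records(records, config.thresholds)
    log.info("stage=classify records=%d", len(records))

    records, report = apply_filters(records, config)
    log.info(
        "stage=filter input=%d surviving=%d fired=%s",
        report.input_count, report.surviving_count, report.per_filter_fired,
    )

    if config.flag_compound_het:
        flag_compound_het(records, config)
    if config.flag_whitelist and config.whitelist is not None:
        flag_whitelist(records, config.whitelist)
    report.flagged_compound_het = sum(1 for r in records if r.surviving and r.compound_het)
    report.flagged_whitelist = sum(1 for r in records if r.surviving and r.whitelist_hit)
    log.info(
        "stage=annotate whitelist_hits=%d compound_het=%d",
        report.flagged_whitelist, report.flagged_compound_het,
    )

    report.config_echo = _echo_config(config)
    report.tool_version = __version__
    report.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    write_filtered_table(
        records, output_path, dialect=dialect,
        include_removed=include_removed, roster=config.roster,
    )
    log.info("stage=write path=%s rows=%d", output_path,
             report.surviving_count if not include_removed else report.input_count)
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    return records, report


# ---------------------------------------------------------------------------
# configuration loading

#: config-file keys that mirror CLI flags, with defaults
_CONFIG_DEFAULTS: dict[str, Any] = {
    "assembly": None,
    "patients": [],
    "controls": [],
    "parents": [],
    "whitelist": None,
    "blacklist": None,
    "remove_ref_in_patients": False,
    "remove_hom_alt_in_controls": False,
    "remove_blacklist": False,
    "remove_shared_het": False,
    "remove_utr": False,
    "remove_synonymous": False,
    "min_depth": 0,
    "trio_recessive": False,
    "flag_compound_het": False,
    "flag_whitelist": False,
    "compound_het_depth_range": [10, None],
    "compound_het_ab_range": [0.2, 0.8],
    "strict_trio_phase": False,
    "zygosity_thresholds": {},
}


def load_config(
    config_file: Optional[str | Path] = None, **overrides: Any
) -> FilterConfig:
    """Build a :class:`FilterConfig` from defaults, a YAML file and overrides.

    Precedence: explicit *overrides* (CLI flags) beat the config file, which
    beats defaults.  Override values of ``None`` mean "not given" and are
    ignored.  A sample assigned more than one role is a configuration error.
    """
    effective = dict(_CONFIG_DEFAULTS)
    if config_file is not None:
        loaded = yaml.safe_load(Path(config_file).read_text()) or {}
        unknown = set(loaded) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        effective.update(loaded)
    for key, value in overrides.items():
        if key not in _CONFIG_DEFAULTS:
            raise ConfigError(f"unknown configuration key {key!r}")
        if value is None or (isinstance(value, (list, tuple)) and not value
                             and key in ("patients", "controls", "parents")):
            continue
        effective[key] = value

    if effective["assembly"] is None:
        raise ConfigError("a genome assembly must be specified")
    assembly = Assembly.parse(str(effective["assembly"]))

    samples: list[tuple[str, Role]] = []
    seen: dict[str, Role] = {}
    for role, key in ((Role.PATIENT, "patients"), (Role.CONTROL, "controls"),
                      (Role.PARENT, "parents")):
        for sid in effective[key]:
            sid = str(sid)
            if sid in seen:
                raise ConfigError(
                    f"sample {sid!r} assigned two roles ({seen[sid].value} and {role.value})"
                )
            seen[sid] = role
            samples.append((sid, role))
    roster = SampleRoster(samples=samples, assembly=assembly)

    whitelist = blacklist = None
    if effective["whitelist"]:
        whitelist = read_gene_list(effective["whitelist"], Polarity.WHITE)
    if effective["blacklist"]:
        blacklist = read_gene_list(effective["blacklist"], Polarity.BLACK)

    d_lo, d_hi = effective["compound_het_depth_range"]
    ab_lo, ab_hi = effective["compound_het_ab_range"]
    thresholds = ZygosityThresholds(**effective["zygosity_thresholds"])

    config = FilterConfig(
        roster=roster,
        remove_ref_in_patients=bool(effective["remove_ref_in_patients"]),
        remove_hom_alt_in_controls=bool(effective["remove_hom_alt_in_controls"]),
        remove_blacklist=bool(effective["remove_blacklist"]),
        remove_shared_het=bool(effective["remove_shared_het"]),
        remove_utr=bool(effective["remove_utr"]),
        remove_synonymous=bool(effective["remove_synonymous"]),
        min_depth=int(effective["min_depth"]),
        trio_recessive=bool(effective["trio_recessive"]),
        flag_compound_het=bool(effective["flag_compound_het"]),
        flag_whitelist=bool(effective["flag_whitelist"]),
        compound_het_depth_range=(
            float(d_lo), float("inf") if d_hi is None else float(d_hi)
        ),
        compound_het_ab_range=(float(ab_lo), float(ab_hi)),
        strict_trio_phase=bool(effective["strict_trio_phase"]),
        thresholds=thresholds,
        whitelist=whitelist,
        blacklist=blacklist,
    )
    config.validate()
    return config
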