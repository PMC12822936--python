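"""End-to-end validation pipeline: cohort I/O, analysis runner, reports.

The cohort interchange format is a UTF-8, comma-separated file with a
mandatory header, one row per patient, lower-snake-case enum tokens and the
empty string as the missing-value token. Reading applies a complete-case
filter (rows missing any classifier input are dropped and logged), while
unknown enum tokens are hard errors naming row and field.

:func:`run_validation` produces the full report bundle of an external
validation — banded incidence and relative risks, overall and
care-setting-stratified AUROCs with incalculable markers, all pairwise
DeLong comparisons among the seven score variants, and complete threshold
sweeps with the Youden-optimal point flagged — both as plain data and as
versioned JSON plus TSV tables. Logging goes to standard error; standard
output stays clean for piping.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .classifiers import (
    SCORE_VARIANTS,
    System,
    collapse_risk_category,
    mw_grade,
    risk_bands,
    saint_elian,
    sinbad_score,
    ut_classify,
)
from .model import (
    ENUM_FIELDS,
    Cohort,
    OutcomeRecord,
    WoundRecord,
)
from .stats import (
    Incalculable,
    OperatingPoint,
    OutcomeSelector,
    build_contingency,
    cumulative_incidence,
    delong_paired_test,
    discrimination_label,
    risk_ratio,
    round_half_away,
    stratified_auc,
    threshold_sweep,
    roc_auc,
    youden_best,
)

__all__ = [
    "COLUMNS",
    "CohortFormatError",
    "DegenerateCohortError",
    "RunConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "score_table",
    "run_validation",
    "write_report",
    "EXIT_OK",
    "EXIT_IO_ERROR",
    "EXIT_VALIDATION_ERROR",
    "EXIT_DEGENERATE",
]

log = logging.getLogger("dfuvalid")

REPORT_SCHEMA_VERSION = "1.0"

EXIT_OK = 0
EXIT_IO_ERROR = 2
EXIT_VALIDATION_ERROR = 3
EXIT_DEGENERATE = 4

#: Column dictionary of the cohort CSV, in file order.
COLUMNS: tuple[str, ...] = (
    "patient_id",
    "depth",
    "osteomyelitis_or_abscess",
    "gangrene",
    "infection_idsa",
    "ischemia_grade",
    "neuropathy_grade",
    "edema_grade",
    "site_region",
    "se_location",
    "se_topography",
    "se_zones",
    "area_cm2",
    "healing_phase",
    "major_amputation",
    "minor_amputation",
    "inpatient",
    "follow_up_months",
)

_BOOL_COLUMNS = ("osteomyelitis_or_abscess", "major_amputation", "minor_amputation", "inpatient")


class CohortFormatError(ValueError):
    """Malformed cohort CSV: bad header, unknown token, or empty after filtering."""


class DegenerateCohortError(ValueError):
    """Cohort unusable for discrimination analysis (no events or no non-events)."""


def _parse_bool(token: str, row: int, column: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise CohortFormatError(f"row {row}: column {column!r}: invalid boolean token {token!r}")


def read_cohort_csv(path: str | Path, provenance: Optional[str] = None) -> Cohort:
    """Read a typed cohort from CSV, applying a complete-case filter.

    Rows with any empty classifier-input cell are dropped (each exclusion is
    logged); unknown enum tokens, malformed numbers and missing mandatory
    columns are hard errors naming the row. Raises
    :class:`CohortFormatError` if nothing survives filtering.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in COLUMNS if c not in header]
        if missing_cols:
            raise CohortFormatError(f"{path}: missing mandatory columns {missing_cols}")
        records: list[tuple[WoundRecord, OutcomeRecord]] = []
        dropped = 0
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            values = {c: (row.get(c) or "").strip() for c in COLUMNS}
            if any(values[c] == "" for c in COLUMNS):
                empty = [c for c in COLUMNS if values[c] == ""]
                log.info("row %d (%s): dropped, missing %s", i, values["patient_id"] or "?", empty)
                dropped += 1
                continue
            try:
                enum_values = {
                    name: cls.from_token(values[name]) for name, cls in ENUM_FIELDS.items()
                }
                wound = WoundRecord(
                    patient_id=values["patient_id"],
                    osteomyelitis_or_abscess=_parse_bool(
                        values["osteomyelitis_or_abscess"], i, "osteomyelitis_or_abscess"
                    ),
                    area_cm2=float(values["area_cm2"]),
                    **enum_values,
                )
                outcome = OutcomeRecord(
                    major_amputation=_parse_bool(values["major_amputation"], i, "major_amputation"),
                    minor_amputation=_parse_bool(values["minor_amputation"], i, "minor_amputation"),
                    inpatient=_parse_bool(values["inpatient"], i, "inpatient"),
                    follow_up_months=float(values["follow_up_months"]),
                )
            except CohortFormatError:
                raise
            except ValueError as exc:
                raise CohortFormatError(f"{path}: row {i}: {exc}") from None
            records.append((wound, outcome))
    if not records:
        raise CohortFormatError(f"{path}: no complete rows after complete-case filtering")
    if dropped:
        log.info("complete-case filter dropped %d of %d rows", dropped, dropped + len(records))
    return Cohort(records=tuple(records), provenance=provenance or f"csv:{path.name}")


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; a round trip through the reader is lossless.

    Floats are written with ``repr`` so every field value survives exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for wound, outcome in cohort:
            writer.writerow(
                [
                    wound.patient_id,
                    wound.depth.token,
                    str(wound.osteomyelitis_or_abscess).lower(),
                    wound.gangrene.token,
                    wound.infection_idsa.token,
                    wound.ischemia_grade.token,
                    wound.neuropathy_grade.token,
                    wound.edema_grade.token,
                    wound.site_region.token,
                    wound.se_location.token,
                    wound.se_topography.token,
                    wound.se_zones.token,
                    repr(float(wound.area_cm2)),
                    wound.healing_phase.token,
                    str(outcome.major_amputation).lower(),
                    str(outcome.minor_amputation).lower(),
                    str(outcome.inpatient).lower(),
                    repr(float(outcome.follow_up_months)),
                ]
            )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_table(cohort: Cohort) -> list[dict[str, object]]:
    """Per-patient classifier outputs for all four systems."""
    rows = []
    for wound, outcome in cohort:
        ut = ut_classify(wound)
        se = saint_elian(wound)
        sinbad = sinbad_score(wound)
        rows.append(
            {
                "patient_id": wound.patient_id,
                "mw_grade": mw_grade(wound),
                "ut_class": str(ut),
                "sinbad_total": sinbad.total,
                "se_total": se.total,
                "se_severity": se.severity.value,
                "mw_band": collapse_risk_category(System.MW, mw_grade(wound)),
                "ut_band": collapse_risk_category(System.UT, ut),
                "sinbad_band": collapse_risk_category(System.SINBAD, sinbad),
                "se_band": collapse_risk_category(System.SE, se),
                "major_amputation": outcome.major_amputation,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one validation run.

    Exactly one of ``input_csv`` (a cohort file) or ``simulation`` (keyword
    arguments for :class:`~dfuvalid.simulate.SimulationConfig`) must be
    given. ``seed`` overrides the simulation block's seed.
    """

    input_csv: Optional[str] = None
    simulation: Optional[Mapping[str, object]] = None
    outcome_selector: OutcomeSelector = OutcomeSelector.MAJOR
    systems: tuple[str, ...] = tuple(SCORE_VARIANTS)
    strata_column: str = "inpatient"
    output_dir: Optional[str] = None
    report_formats: tuple[str, ...] = ("json", "tsv")
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("exactly one of input_csv / simulation must be configured")
        unknown = sorted(set(self.systems) - set(SCORE_VARIANTS))
        if unknown:
            raise ValueError(f"unknown score variants: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "outcome_selector" in raw:
            raw["outcome_selector"] = OutcomeSelector(raw["outcome_selector"])
        for key in ("systems", "report_formats"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)

    def load_cohort(self) -> Cohort:
        if self.input_csv is not None:
            return read_cohort_csv(self.input_csv)
        from .simulate import SimulationConfig, generate_cohort

        kwargs = dict(self.simulation or {})
        if self.seed is not None:
            kwargs["seed"] = self.seed
        return generate_cohort(SimulationConfig(**kwargs))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _jsonable(x: object) -> object:
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return x
    return x


def _prop_dict(p) -> dict[str, object]:
    return {
        "value": _jsonable(p.value) if p.defined else None,
        "ci_low": _jsonable(p.ci_low) if p.defined else None,
        "ci_high": _jsonable(p.ci_high) if p.defined else None,
        "defined": p.defined,
    }


def _op_dict(op: OperatingPoint) -> dict[str, object]:
    return {
        "threshold": _jsonable(op.threshold),
        "tp": op.tp,
        "fp": op.fp,
        "fn": op.fn,
        "tn": op.tn,
        "sensitivity": _prop_dict(op.sensitivity),
        "specificity": _prop_dict(op.specificity),
        "ppv": _prop_dict(op.ppv),
        "npv": _prop_dict(op.npv),
        "lr_pos": {
            "value": _jsonable(op.lr_pos.value),
            "ci_low": _jsonable(op.lr_pos.ci_low),
            "ci_high": _jsonable(op.lr_pos.ci_high),
        },
        "lr_neg": {
            "value": _jsonable(op.lr_neg.value),
            "ci_low": _jsonable(op.lr_neg.ci_low),
            "ci_high": _jsonable(op.lr_neg.ci_high),
        },
        "youden": op.youden,
    }


def _roc_dict(result) -> dict[str, object]:
    if isinstance(result, Incalculable):
        return {
            "calculable": False,
            "n": result.n,
            "n_pos": result.n_pos,
            "n_neg": result.n_neg,
            "reason": result.reason,
        }
    return {
        "calculable": True,
        "auc": result.auc,
        "se_auc": result.se_auc,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n_pos": result.n_pos,
        "n_neg": result.n_neg,
        "discrimination": discrimination_label(result.auc).band.value,
    }


def run_validation(config: RunConfig, cohort: Optional[Cohort] = None) -> dict[str, object]:
    """Run the full external-validation analysis and return the report bundle.

    The bundle contains the banded incidence / relative-risk table, overall
    and stratified AUROCs for each requested score variant, all pairwise
    DeLong comparisons, full threshold sweeps with the Youden-best point
    flagged, and the cohort's cumulative incidences. Deterministic given
    cohort and config. Raises :class:`DegenerateCohortError` when the
    selected outcome has no events or no non-events.
    """
    if cohort is None:
        cohort = config.load_cohort()
    wounds = cohort.wounds
    outcomes = cohort.outcomes
    if config.outcome_selector is OutcomeSelector.MAJOR:
        events = [o.major_amputation for o in outcomes]
    else:
        events = [o.major_amputation or o.minor_amputation for o in outcomes]
    strata = [("inpatient" if o.inpatient else "outpatient") for o in outcomes]

    n_events = sum(events)
    if n_events == 0 or n_events == len(events):
        raise DegenerateCohortError(
            f"cohort has {n_events} events out of {len(events)}; discrimination undefined"
        )

    scores = {
        name: [SCORE_VARIANTS[name](w) for w in wounds]
        for name in config.systems
    }

    # (a) banded incidence + relative risks per system
    classify = {
        System.MW: lambda w: collapse_risk_category(System.MW, mw_grade(w)),
        System.UT: lambda w: collapse_risk_category(System.UT, ut_classify(w)),
        System.SINBAD: lambda w: collapse_risk_category(System.SINBAD, sinbad_score(w)),
        System.SE: lambda w: collapse_risk_category(System.SE, saint_elian(w)),
    }
    risk_tables = {}
    for system, bander in classify.items():
        bands = [bander(w) for w in wounds]
        order = risk_bands(system)
        table = build_contingency(bands, events, reference=order[0], band_order=order)
        rows = []
        for j, label in enumerate(table.band_labels):
            row: dict[str, object] = {
                "band": label,
                "events": table.events[j],
                "nonevents": table.nonevents[j],
                "n": table.totals[j],
            }
            if j == table.reference_index:
                row["rr"] = 1.0
                row["reference"] = True
            else:
                rr = risk_ratio(table, label)
                row.update(
                    rr=_jsonable(rr.rr),
                    rr_ci_low=_jsonable(rr.ci_low),
                    rr_ci_high=_jsonable(rr.ci_high),
                    rr_p=_jsonable(rr.p_value),
                    calculable=rr.calculable,
                )
            rows.append(row)
        risk_tables[system.value] = rows

    # (b) overall + stratified AUROC per score variant
    auc_table = {}
    for name in config.systems:
        overall = roc_auc(scores[name], events)
        per_stratum = stratified_auc(scores[name], events, strata)
        auc_table[name] = {
            "overall": _roc_dict(overall),
            "strata": {str(k): _roc_dict(v) for k, v in sorted(per_stratum.items(), key=lambda kv: str(kv[0]))},
        }

    # (c) all pairwise DeLong comparisons
    pairwise = []
    names = list(config.systems)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            cmp = delong_paired_test(scores[names[i]], scores[names[j]], events)
            pairwise.append(
                {
                    "a": names[i],
                    "b": names[j],
                    "auc_a": cmp.auc_a,
                    "auc_b": cmp.auc_b,
                    "delta_auc": cmp.delta_auc,
                    "ci_low": cmp.ci_low,
                    "ci_high": cmp.ci_high,
                    "p_value": cmp.p_value,
                }
            )

    # (d) threshold sweeps with Youden-best flag
    sweeps = {}
    for name in config.systems:
        points = threshold_sweep(scores[name], events)
        best = youden_best(points)
        sweeps[name] = [
            dict(_op_dict(p), youden_best=(p.threshold == best.threshold)) for p in points
        ]

    incidence_major = cumulative_incidence(outcomes, OutcomeSelector.MAJOR)
    incidence_any = cumulative_incidence(outcomes, OutcomeSelector.ANY)

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": cohort.provenance,
        "n": len(cohort),
        "outcome_selector": config.outcome_selector.value,
        "incidence": {
            "major": {
                "events": incidence_major.events,
                "n": incidence_major.n,
                "proportion": incidence_major.proportion,
                "ci_low": incidence_major.ci_low,
                "ci_high": incidence_major.ci_high,
            },
            "any": {
                "events": incidence_any.events,
                "n": incidence_any.n,
                "proportion": incidence_any.proportion,
                "ci_low": incidence_any.ci_low,
                "ci_high": incidence_any.ci_high,
            },
        },
        "risk_tables": risk_tables,
        "auroc": auc_table,
        "pairwise_delong": pairwise,
        "threshold_sweeps": sweeps,
    }


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def format_p(p: Optional[float]) -> str:
    if p is None:
        return "NC"
    return "<0.001" if p < 0.001 else f"{round_half_away(p, 3):.3f}"


def _fmt_pct(x: Optional[float]) -> str:
    if x is None:
        return "NC"
    v = round_half_away(100.0 * x, 1)
    return f"{v:g}"


def _pct_ci(d: Mapping[str, object]) -> str:
    if not d.get("defined", True) or d.get("value") is None:
        return "NC"
    return f"{_fmt_pct(d['value'])} ({_fmt_pct(d['ci_low'])}-{_fmt_pct(d['ci_high'])})"


def _tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[object]]) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def write_report(bundle: Mapping[str, object], output_dir: str | Path, formats: Sequence[str] = ("json", "tsv")) -> list[Path]:
    """Write the report bundle as versioned JSON and human-readable TSVs.

    Every number in the TSV tables is a formatted copy of its JSON twin;
    formatting (rounding, "<0.001", "NC") is the only lossy step.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(p)
    if "tsv" in formats:
        rows = []
        for system, table in bundle["risk_tables"].items():  # type: ignore[union-attr]
            for r in table:
                if r.get("reference"):
                    rr, ci, pval = "1.0 (reference)", "", ""
                elif not r.get("calculable", True):
                    rr, ci, pval = "NC", "", ""
                else:
                    rr = f"{round_half_away(r['rr'], 2):g}"
                    ci = f"{round_half_away(r['rr_ci_low'], 2):g}-{round_half_away(r['rr_ci_high'], 2):g}"
                    pval = format_p(r["rr_p"])
                rows.append([system, r["band"], r["events"], r["nonevents"], rr, ci, pval])
        p = out / "risk_table.tsv"
        _tsv(p, ["system", "band", "events", "nonevents", "rr", "rr_95ci", "p"], rows)
        written.append(p)

        rows = []
        for name, entry in bundle["auroc"].items():  # type: ignore[union-attr]
            o = entry["overall"]
            line = [name, f"{o['auc']:.3f}", f"{o['ci_low']:.3f}-{o['ci_high']:.3f}", o["discrimination"]]
            for stratum in sorted(entry["strata"]):
                s = entry["strata"][stratum]
                if s["calculable"]:
                    line.append(f"{stratum}: {s['auc']:.3f} ({s['ci_low']:.3f}-{s['ci_high']:.3f})")
                else:
                    line.append(f"{stratum}: NC ({s['reason']})")
            rows.append(line)
        p = out / "auroc_table.tsv"
        _tsv(p, ["score", "auroc", "auroc_95ci", "band", "stratum_1", "stratum_2"], rows)
        written.append(p)

        rows = [
            [
                c["a"],
                c["b"],
                f"{c['delta_auc']:.3f}",
                f"{c['ci_low']:.3f} to {c['ci_high']:.3f}",
                format_p(c["p_value"]),
            ]
            for c in bundle["pairwise_delong"]  # type: ignore[union-attr]
        ]
        p = out / "pairwise_delong.tsv"
        _tsv(p, ["score_a", "score_b", "delta_auc", "delta_95ci", "p"], rows)
        written.append(p)

        rows = []
        for name, sweep in bundle["threshold_sweeps"].items():  # type: ignore[union-attr]
            for pt in sweep:
                rows.append(
                    [
                        name,
                        f">= {pt['threshold']:g}",
                        _pct_ci(pt["sensitivity"]),
                        _pct_ci(pt["specificity"]),
                        _pct_ci(pt["ppv"]),
                        _pct_ci(pt["npv"]),
                        f"{round_half_away(100.0 * pt['youden'], 1):g}",
                        "*" if pt["youden_best"] else "",
                    ]
                )
        p = out / "threshold_sweeps.tsv"
        _tsv(
            p,
            ["score", "cutoff", "sensitivity", "specificity", "ppv", "npv", "youden_pct", "youden_best"],
            rows,
        )
        written.append(p)
    return written
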