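"""End-to-end orchestration: eligibility -> anthropometry -> prediction ->
accuracy report, plus the population summary table and figure data files.

All numbers written to disk are either full precision (canonical CSVs) or
pass through the single display-rounding routine in :mod:`pedree.metrics`;
no stage rounds internally.  Given a fixed config and seed the outputs are
byte-identical across runs, and the manifest records a sha256 per file so a
re-run can be checked for bit-reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import metrics
from .anthropometry import (
    LMSReference,
    WeightStatusCutoffs,
    derive_anthropometry,
    synthetic_growth_reference,
)
from .core import (
    ALL_CHILDREN,
    STRATA,
    PedreeError,
    Sex,
    StudyConfig,
    Subject,
    WeightStatus,
    apply_eligibility,
    load_cohort,
    logger,
    stratify,
)
from .equations import coefficient_file_sha256, evaluate_all, registry
from .metrics import build_report, render_report, report_frame

#: age (years) splitting the child/adolescent categories; the boundary age
#: itself counts as adolescent
ADOLESCENT_AGE = 13.0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def selected_specs(config: StudyConfig):
    reg = registry()
    if config.equation_ids is None:
        return list(reg.values())
    try:
        return [reg[eq] for eq in config.equation_ids]
    except KeyError as exc:
        raise PedreeError(f"unknown equation id {exc.args[0]!r} in config") from None


def run_validation(
    cohort: str | Path | Sequence[Subject],
    config: StudyConfig | None = None,
    out_dir: str | Path = "pedree_out",
    reference: LMSReference | None = None,
) -> dict:
    """Run the full validation on a cohort and write the report products.

    cohort may be a cohort CSV path or an in-memory subject list; subjects
    must carry measured REE and RQ.  Writes, under out_dir:

    * report_full.csv   - one row per equation x group, full precision
    * report.csv        - the same table display-rounded
    * figure_percent_bias.csv - median percent bias per equation x group
    * figure_ccf.csv    - CCF with exact CI per equation x group
    * bland_altman.csv  - per-subject agreement points per equation x stratum
    * manifest.json     - config snapshot, coefficient checksum, file hashes

    Returns the manifest as a dict.
    """
    t0 = time.perf_counter()
    config = config or StudyConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    subjects = list(load_cohort(cohort, config)) if isinstance(cohort, (str, Path)) else list(cohort)
    if not subjects:
        raise PedreeError("empty cohort")

    kept, excluded = apply_eligibility(subjects, config)
    if not kept:
        raise PedreeError("no subjects left after eligibility filtering")
    logger.info("eligibility: kept %d, excluded %d", len(kept), len(excluded))

    reference = reference or synthetic_growth_reference()
    derive_anthropometry(kept, reference, WeightStatusCutoffs())

    specs = selected_specs(config)
    eree = evaluate_all(kept, specs)
    reports = build_report(eree, kept, config)
    full = report_frame(reports)
    rendered = render_report(reports)

    fig1 = full[["equation_id", "group", "n", "pct_bias_median"]].copy()
    fig2 = full[["equation_id", "group", "n", "ccf_count", "ccf_fraction",
                 "ccf_ci_low", "ccf_ci_high"]].copy()

    by_id = {s.id: s for s in kept}
    ba_rows = []
    strata = stratify(kept)
    for eq_id in eree.columns:
        for stratum, members in strata.items():
            for s in members:
                e = float(eree.at[s.id, eq_id])
                m = s.mree_kcal_d
                ba_rows.append({
                    "equation_id": eq_id,
                    "group": stratum.label,
                    "id": s.id,
                    "average": (e + m) / 2.0,
                    "abs_difference": e - m,
                    "pct_difference": 100.0 * (e - m) / m,
                })
    ba = pd.DataFrame(ba_rows)

    files = {
        "report_full.csv": full,
        "report.csv": rendered,
        "figure_percent_bias.csv": fig1,
        "figure_ccf.csv": fig2,
        "bland_altman.csv": ba,
    }
    written = {}
    for name, frame in files.items():
        path = out_dir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written[name] = _sha256(path)

    manifest = {
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_input": len(subjects),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "exclusion_reasons": _count_reasons(excluded),
        "equations": [spec.id for spec in specs],
        "coefficient_file_sha256": coefficient_file_sha256(),
        "outputs": written,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("validation pipeline finished in %.2f s", time.perf_counter() - t0)
    return manifest


def _count_reasons(excluded) -> dict[str, int]:
    counts: dict[str, int] = {}
    for exc in excluded:
        counts[exc.reason] = counts.get(exc.reason, 0) + 1
    return counts


# --------------------------------------------------------------------------
# population summary
# --------------------------------------------------------------------------

def summarize_population(
    cohort: Sequence[Subject],
    eree_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Population-description table: one column per stratum plus all children.

    Continuous variables as "median (q25; q75)", categorical as "n (pct%)".
    Requires derived weight_status on every subject.
    """
    strata = stratify(cohort)
    groups: list[tuple[str, list[Subject]]] = [(st.label, strata[st]) for st in STRATA]
    groups.append((ALL_CHILDREN, list(cohort)))

    def fmt_cont(values, decimals=1):
        if len(values) == 0:
            return ""
        q50, q25, q75 = metrics.median_iqr(values)
        r = metrics.round_half_up
        return f"{r(q50, decimals):.{decimals}f} ({r(q25, decimals):.{decimals}f}; {r(q75, decimals):.{decimals}f})"

    def fmt_cat(k, n):
        pct = 0.0 if n == 0 else 100.0 * k / n
        return f"{k} ({metrics.round_half_up(pct, 1):.1f}%)"

    rows: dict[str, dict[str, str]] = {}

    def put(row, col, value):
        rows.setdefault(row, {})[col] = value

    for label, members in groups:
        n = len(members)
        put("N", label, str(n))
        put("Female", label, fmt_cat(sum(1 for s in members if s.sex is Sex.FEMALE), n))
        put("Male", label, fmt_cat(sum(1 for s in members if s.sex is Sex.MALE), n))
        ages = [s.age_years for s in members]
        put("Age (years)", label, fmt_cont(ages))
        put(f"Children (< {ADOLESCENT_AGE:.0f} years)", label,
            fmt_cat(sum(1 for s in members if s.age_years < ADOLESCENT_AGE), n))
        put(f"Adolescents (>= {ADOLESCENT_AGE:.0f} years)", label,
            fmt_cat(sum(1 for s in members if s.age_years >= ADOLESCENT_AGE), n))
        put("Weight (kg)", label, fmt_cont([s.weight_kg for s in members]))
        put("Height (cm)", label, fmt_cont([s.height_cm for s in members]))
        put("BMI (kg/m2)", label, fmt_cont([s.bmi_kg_m2 for s in members]))
        put("BMI SDS", label, fmt_cont([s.bmi_sds for s in members], 2))
        for status in WeightStatus:
            put(f"BMI class: {status.value}", label,
                fmt_cat(sum(1 for s in members if s.weight_status is status), n))
        rqs = [s.rq for s in members if s.rq is not None]
        put("Respiratory quotient", label, fmt_cont(rqs, 2) if rqs else "")
        mrees = [s.mree_kcal_d for s in members if s.mree_kcal_d is not None]
        put("mREE (kcal/day)", label, fmt_cont(mrees, 0) if mrees else "")
        if eree_table is not None:
            ids = [s.id for s in members]
            for eq_id in eree_table.columns:
                put(f"eREE {eq_id} (kcal/day)", label,
                    fmt_cont(eree_table.loc[ids, eq_id].to_numpy(float), 0) if ids else "")

    frame = pd.DataFrame(rows).T
    frame = frame[[label for label, _ in groups]]
    frame.index.name = "variable"
    return frame
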