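"""Deterministic reporting and pipeline orchestration.

``run_pipeline`` composes the full analysis in the natural order —
measurements → validation → indices → grouping (published labels or
clustering) → per-footprint biometrics → per-morphotype summaries — and
writes CSV reports, PCA exports and a JSON run manifest sufficient to
replay the run.  Rendering is byte-deterministic: two runs on identical
inputs and config produce identical files.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .biometry import BiometricEstimate, profile_individuals
from .io import (
    load_basura_fixtures,
    read_footprint_table,
)
from .morphometry import (
    MorphotypeAssignment,
    assignment_from_descriptors,
    group_morphotypes,
    impute_missing,
    log_transform,
    pca,
)
from .records import FootprintTable, validate_table
from .utils import fmt, fmt_pm, round_half_up


def estimates_frame(
    estimates: list[BiometricEstimate], *, fi_scale100: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-footprint and per-group DataFrames, rounded for reporting."""
    fi_k = 100.0 if fi_scale100 else 1.0
    foot_rows, group_rows = [], []
    for e in estimates:
        pf = e.per_footprint
        for _, r in pf.iterrows():
            row = {
                "footprint_id": r["footprint_id"],
                "morphotype": e.label,
                "max_FL": r["max_FL"],
                "stature": round_half_up(r["stature"]),
            }
            for m in e.mass_models:
                row[f"mass_{m}"] = round_half_up(r[f"mass_{m}"])
            foot_rows.append(row)
        g = {
            "morphotype": e.label,
            "n": e.n_footprints,
            "FL_mean": round_half_up(e.fl_mean),
            "FL_sd": None if e.fl_sd is None else round_half_up(e.fl_sd),
            "FI_mean": None if e.fi_mean is None else round_half_up(e.fi_mean * fi_k),
            "FI_sd": None if e.fi_sd is None else round_half_up(e.fi_sd * fi_k),
            "stature_mean": round_half_up(e.stature_mean),
            "stature_sd": None if e.stature_sd is None else round_half_up(e.stature_sd),
            "age_class": e.age.age_class,
            "point_age": round_half_up(e.age.point_age, 1),
            "sex": e.sex.call,
            "sex_rationale": e.sex.rationale,
        }
        for m, (mean, sd) in e.mass_by_model.items():
            g[f"mass_{m}_mean"] = round_half_up(mean)
            g[f"mass_{m}_sd"] = None if sd is None else round_half_up(sd)
        group_rows.append(g)
    return pd.DataFrame(foot_rows), pd.DataFrame(group_rows)


def render_report(
    estimates: list[BiometricEstimate],
    assignment: Optional[MorphotypeAssignment] = None,
    style: str = "text",
    *,
    fi_scale100: bool = False,
) -> str:
    """Human-readable (or CSV) report of per-group biometric profiles.

    Numbers print at 2 decimals, half-up; single-member groups print
    '± n/a'.  Re-rendering identical estimates is byte-identical.
    """
    if not estimates:
        raise ValueError("no estimates to render")
    foot_df, group_df = estimates_frame(estimates, fi_scale100=fi_scale100)
    if style == "csv":
        return group_df.to_csv(index=False)
    if style != "text":
        raise ValueError(f"unknown report style {style!r}")

    lines = ["Morphotype biometric profiles", "=" * 29, ""]
    for e in estimates:
        lines.append(f"Morphotype {e.label} ({e.n_footprints} footprints: "
                     f"{', '.join(e.footprint_ids)})")
        lines.append(f"  foot length (cm): {fmt_pm(e.fl_mean, e.fl_sd)}")
        if e.fi_mean is not None:
            k = 100.0 if fi_scale100 else 1.0
            lines.append(
                "  foot index:       "
                + fmt_pm(e.fi_mean * k, None if e.fi_sd is None else e.fi_sd * k)
            )
        lines.append(f"  stature (cm):     {fmt_pm(e.stature_mean, e.stature_sd)}")
        for m, (mean, sd) in e.mass_by_model.items():
            lines.append(f"  body mass {m} (kg): {fmt_pm(mean, sd)}")
        lines.append(f"  age class:        {e.age.age_class} "
                     f"(interpolated {fmt(e.age.point_age, 1)} yr)")
        if e.age.arch_note:
            lines.append(f"  arch note:        {e.age.arch_note}")
        lines.append(f"  sex:              {e.sex.call} — {e.sex.rationale}")
        lines.append("")
    if assignment is not None and len(estimates) > 1:
        lines.append(f"Groups: {assignment.n_groups} ({assignment.provenance}); "
                     f"minimum number of individuals: {assignment.n_groups}")
        if assignment.spread:
            spread = ", ".join(
                f"{g}: {100 * s:.1f}%" for g, s in sorted(assignment.spread.items())
            )
            lines.append(f"Within-group relative measurement spread — {spread}")
        lines.append("")
    return "\n".join(lines)


def write_report_files(estimates: list[BiometricEstimate], path: Path) -> None:
    """Per-footprint CSV at ``path`` + summary CSV and text alongside."""
    if not estimates:
        raise ValueError("no estimates to write")
    path = Path(path)
    foot_df, group_df = estimates_frame(estimates)
    foot_df.to_csv(path, index=False)
    group_df.to_csv(path.with_name(path.stem + "_summary.csv"), index=False)
    path.with_suffix(".txt").write_text(render_report(estimates), encoding="utf-8")


def run_pipeline(
    input: Union[str, Path],
    config: Optional[dict] = None,
    out_dir: Union[str, Path] = "ichnometry_out",
) -> dict:
    """Run the full footprint-to-biometrics pipeline and write report files.

    ``input`` is a measurement CSV path or the literal ``"basura-fixture"``.
    Grouping uses published morphotype labels when the input carries them
    (config key ``grouping: "published"``, the fixture default) or
    hierarchical clustering (``grouping: "clustered"``).  Writes
    ``footprints.csv``, ``summary.csv``, ``report.txt``, PCA exports and
    ``manifest.json``; returns the manifest.  Raises on an empty or invalid
    input table (no partial outputs are left behind).
    """
    cfg = dict(config or {})
    out = Path(out_dir)

    if str(input) == "basura-fixture":
        table = load_basura_fixtures("table3")
        grouping_mode = cfg.get("grouping", "published")
    else:
        table = read_footprint_table(input)
        grouping_mode = cfg.get("grouping", "clustered")
    if len(table) == 0:
        raise ValueError(f"input table {input} has no footprint records")
    issues = validate_table(table)
    if issues:
        raise ValueError(f"input table failed validation: {issues}")

    if grouping_mode == "published":
        assignment = assignment_from_descriptors(table)
    else:
        assignment = group_morphotypes(table, config=cfg)

    estimates = profile_individuals(table, assignment, config=cfg)

    # PCA export on whatever subset of the nine variables the table carries
    pca_result = None
    M = table.measurement_matrix()
    M = M.dropna(axis=1, how="all")
    if M.shape[1] >= 2 and len(M) >= 3:
        logM = log_transform(M.sort_index(kind="stable"))
        if logM.isna().any().any():
            k = min(int(cfg.get("pca_k", 3)), min(logM.shape) - 1)
            logM = impute_missing(logM, k=max(k, 1),
                                  tol=float(cfg.get("impute_tol", 1e-6)),
                                  max_iter=int(cfg.get("impute_max_iter", 200)))
        pca_result = pca(logM)

    out.mkdir(parents=True, exist_ok=True)
    foot_df, group_df = estimates_frame(estimates)
    foot_df.to_csv(out / "footprints.csv", index=False)
    group_df.to_csv(out / "summary.csv", index=False)
    (out / "report.txt").write_text(
        render_report(estimates, assignment), encoding="utf-8"
    )
    if pca_result is not None:
        pca_result.scores.to_csv(out / "pca_scores.csv")
        pca_result.loadings.to_csv(out / "pca_loadings.csv")

    manifest = {
        "package_version": __version__,
        "input": str(input),
        "config": {k: v for k, v in cfg.items()},
        "grouping": {
            "mode": grouping_mode,
            "n_groups": assignment.n_groups,
            "labels": assignment.labels,
            "spread": assignment.spread,
        },
        "n_footprints": len(table),
        "n_profiled_groups": len(estimates),
        "explained_variance": (
            None if pca_result is None
            else [float(v) for v in pca_result.explained_variance]
        ),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
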