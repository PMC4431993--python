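"""Per-sample analysis orchestration and cross-sample comparison.

``analyze_sample`` runs the stages in a fixed order — optional
zero-referencing, optional tip reconstruction, roughness statistics and
height PDF, the fractal estimator suite (on the reconstructed map), and
the Minkowski threshold sweep — and collects everything into a
:class:`SampleReport` that serializes deterministically: identical config
and input produce a byte-identical JSON report.

``compare_samples`` builds a long-format table of (sample, metric, value)
with pairwise differences.  No hypothesis testing is attempted: single
scans per condition support descriptive comparison only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from nanotex.errors import NanotexError
from nanotex.fractal import METHODS, FitConfig, fractal_suite
from nanotex.minkowski import connectivity_landmarks, minkowski_curves, volume_symmetry_score
from nanotex.roughness import height_pdf, roughness_report, unimodality_check
from nanotex.surface_io import HeightMap
from nanotex.tip import build_tip, reconstruct_surface

_pkg_version = "0.1.0"


@dataclass
class AnalysisConfig:
    """Everything a run depends on; embedded verbatim in its report."""

    zero_reference: bool = True
    tip_correction: bool = True
    tip_apex_nm: float = 12.0
    tip_rotation_deg: float = 45.0
    tip_half_angle_deg: float = 17.5
    tip_extent_px: int = 15
    bins: int = 256
    fractal_methods: tuple[str, ...] = METHODS
    fit_range: str = "auto"
    bspline_factor: int = 1
    n_thresholds: int = 256
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["fractal_methods"] = list(d["fractal_methods"])
        return d


@dataclass
class SampleReport:
    """Complete per-sample analysis result with provenance."""

    label: str
    roughness: Optional[dict]
    fractal: dict
    minkowski: Optional[dict]
    stages: dict
    config: dict
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "roughness": self.roughness,
            "fractal": self.fractal,
            "minkowski": self.minkowski,
            "stages": self.stages,
            "config": self.config,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent, sort_keys=True,
                          allow_nan=True)


def _round_floats(obj, ndigits: int = 10):
    """Round every float so reports are byte-stable at fixed precision."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def analyze_sample(map: HeightMap, config: AnalysisConfig | None = None) -> SampleReport:
    """Run the full texture analysis on one height map.

    A stage that fails is recorded in ``stages`` with its error message
    and the remaining stages are still attempted; a report never silently
    omits a requested metric.
    """
    config = config or AnalysisConfig()
    stages: dict[str, str] = {}
    input_hash = hashlib.sha256(
        np.ascontiguousarray(map.heights).tobytes()
    ).hexdigest()[:16]

    working = map
    if config.zero_reference:
        working = map.copy_with(map.heights - map.heights.min())
        stages["zero_reference"] = "ok"
    else:
        stages["zero_reference"] = "skipped: disabled in config"

    reconstructed = working
    if config.tip_correction:
        try:
            tip = build_tip(
                apex_radius=config.tip_apex_nm,
                rotation_deg=config.tip_rotation_deg,
                half_angle_deg=config.tip_half_angle_deg,
                pixel_size=working.require_square_pixels(),
                extent_px=config.tip_extent_px,
            )
            reconstructed, certainty = reconstruct_surface(working, tip)
            stages["tip_correction"] = "ok"
            stages["tip_certainty_fraction"] = f"{float(certainty.mean()):.6f}"
        except NanotexError as e:
            stages["tip_correction"] = f"failed: {e}"
            reconstructed = working
    else:
        stages["tip_correction"] = "skipped: disabled in config"

    roughness = None
    try:
        rep = roughness_report(working, bins=config.bins)
        pdf = height_pdf(working, bins=config.bins)
        uni = unimodality_check(pdf, rep)
        roughness = rep.as_dict()
        roughness["unimodal"] = bool(uni.unimodal)
        roughness["mean_median_gap_nm"] = uni.mean_median_gap
        roughness["median_mode_gap_nm"] = uni.median_mode_gap
        stages["roughness"] = "ok"
    except NanotexError as e:
        stages["roughness"] = f"failed: {e}"

    fractal: dict[str, dict] = {}
    try:
        fit_cfg = FitConfig(
            fit_range=config.fit_range if config.fit_range == "auto"
            else tuple(int(v) for v in config.fit_range.split(":")),
            bspline_factor=config.bspline_factor,
        )
        # the estimators run on the tip-corrected map, mirroring the
        # correct-then-measure order for fractal analysis
        suite = fractal_suite(reconstructed, config.fractal_methods, fit_cfg)
        for name, est in suite.items():
            fractal[name] = {
                "D_f": est.d_f,
                "slope": est.slope,
                "r_squared": est.r_squared,
                "out_of_range": est.out_of_range,
                "degenerate": est.degenerate,
                "warnings": est.warnings,
            }
        stages["fractal"] = "ok"
    except NanotexError as e:
        stages["fractal"] = f"failed: {e}"

    minkowski = None
    try:
        curves = minkowski_curves(working, n_thresholds=config.n_thresholds)
        lm = connectivity_landmarks(curves)
        minkowski = lm.as_dict()
        minkowski["volume_symmetry_score"] = volume_symmetry_score(curves)
        stages["minkowski"] = "ok"
    except NanotexError as e:
        stages["minkowski"] = f"failed: {e}"

    report = SampleReport(
        label=map.label,
        roughness=_round_floats(roughness),
        fractal=_round_floats(fractal),
        minkowski=_round_floats(minkowski),
        stages=stages,
        config=config.as_dict(),
        provenance={
            "input_sha256_16": input_hash,
            "software": f"nanotex {_pkg_version}",
            "rows": map.rows,
            "cols": map.cols,
            "pixel_size_x_nm": map.pixel_size_x,
            "pixel_size_y_nm": map.pixel_size_y,
        },
    )
    return report


_TABLE1_COLUMNS = [
    "sample",
    "mean_abs_height_nm",
    "Ra_nm",
    "Rq_nm",
    "median_nm",
    "mode_nm",
    "Rt_nm",
    "Rmvd_nm",
    "Rmph_nm",
    "Rsk_abs",
    "Rku_abs",
]


def roughness_table(reports: Sequence[SampleReport]) -> pd.DataFrame:
    """Wide table of amplitude statistics, one row per sample, in the
    conventional column order (sample, mean height, Ra, Rq, ...)."""
    rows = []
    for r in reports:
        row = {"sample": r.label}
        if r.roughness:
            for c in _TABLE1_COLUMNS[1:]:
                row[c] = r.roughness.get(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE1_COLUMNS)


def fractal_table(reports: Sequence[SampleReport]) -> pd.DataFrame:
    """Wide table of per-method fractal dimensions, one row per sample."""
    rows = []
    for r in reports:
        row = {"sample": r.label}
        for m, est in r.fractal.items():
            row[f"D_{m}"] = est.get("D_f")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_samples(reports: Sequence[SampleReport]) -> pd.DataFrame:
    """Long-format comparison of two or more sample reports.

    Returns (sample, metric, value) rows plus, for every metric present
    in at least two reports, pairwise difference rows
    ``sample='<a> - <b>'`` and a sign summary.  Metrics missing from some
    report are kept with a warning flag rather than dropped.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    records = []
    for r in reports:
        metrics: dict[str, float] = {}
        if r.roughness:
            for k, v in r.roughness.items():
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    metrics[k] = float(v)
        for m, est in r.fractal.items():
            v = est.get("D_f")
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                metrics[f"D_{m}"] = float(v)
        if r.minkowski:
            for k, v in r.minkowski.items():
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    metrics[k] = float(v)
        for k, v in metrics.items():
            records.append({"sample": r.label, "metric": k, "value": v, "kind": "value"})
    df = pd.DataFrame(records)
    diffs = []
    labels = [r.label for r in reports]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = df[(df["sample"] == labels[i]) & (df["kind"] == "value")]
            b = df[(df["sample"] == labels[j]) & (df["kind"] == "value")]
            merged = a.merge(b, on="metric", suffixes=("_a", "_b"), how="outer")
            for _, row in merged.iterrows():
                if pd.isna(row.get("value_a")) or pd.isna(row.get("value_b")):
                    diffs.append(
                        {
                            "sample": f"{labels[i]} - {labels[j]}",
                            "metric": row["metric"],
                            "value": float("nan"),
                            "kind": "diff (metric missing in one report)",
                        }
                    )
                    continue
                d = row["value_a"] - row["value_b"]
                diffs.append(
                    {
                        "sample": f"{labels[i]} - {labels[j]}",
                        "metric": row["metric"],
                        "value": d,
                        "kind": "diff",
                    }
                )
    return pd.concat([df, pd.DataFrame(diffs)], ignore_index=True)
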