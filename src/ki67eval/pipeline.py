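"""End-to-end evaluation: transform → match → metrics → scores → statistics.

The pipeline consumes a manifest (JSON) listing, per case and ROI, the
reference-standard CSV and one CSV per detector, each with its own coordinate
frame.  Detector coordinates are mapped onto the reference grid, matched
under the distance cap (all cells, and the Ki67-positive subset separately),
and summarized as per-ROI/per-case detection metrics, Ki67 scores with WHO
grades, count-comparison tallies and agreement statistics.

Manifest layout::

    {
      "cases": [
        {"case_id": "case_01",
         "rois": [
           {"roi_id": "roi_01",
            "reference": {"path": "...csv", "frame": {"width_px":..,"height_px":..,"um_per_px":..}},
            "detectors": {"ml": {"path": "...csv", "frame": {...}}, ...}}
         ]}
      ]
    }

Relative paths are resolved against the manifest's directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import scoring, stats
from .annotations import AnnotationSet, CoordinateFrame, read_points
from .errors import FormatError, Ki67EvalError
from .matching import DEFAULT_MAX_DIST_UM, MatchConfig, stratified_match
from .metrics import (
    DetectionMetrics,
    aggregate_case,
    compare_counts,
    linear_fit,
    metrics_from_match,
)
from .transform import apply_mapping, build_mapping

logger = logging.getLogger("ki67eval")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one evaluation run."""

    manifest_path: Path
    out_dir: Path
    max_dist_um: float = DEFAULT_MAX_DIST_UM
    icc_variant: str = stats.CONSISTENCY
    aggregation: str = "pooled"


def load_manifest(path: str | Path) -> dict:
    """Read and structurally validate a manifest file."""
    path = Path(path)
    try:
        manifest = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    if not isinstance(manifest, dict) or "cases" not in manifest:
        raise FormatError(f"manifest {path} must be an object with a 'cases' list")
    base = path.parent
    for case in manifest["cases"]:
        if "case_id" not in case or "rois" not in case:
            raise FormatError("each case needs 'case_id' and 'rois'")
        for roi in case["rois"]:
            for key in ("roi_id", "reference", "detectors"):
                if key not in roi:
                    raise FormatError(
                        f"ROI entry in case {case['case_id']} lacks '{key}'"
                    )
            entries = [roi["reference"], *roi["detectors"].values()]
            for entry in entries:
                if "path" not in entry or "frame" not in entry:
                    raise FormatError(
                        f"ROI {roi['roi_id']} of case {case['case_id']}: each "
                        "source needs 'path' and 'frame'"
                    )
                p = base / entry["path"]
                if not p.exists():
                    raise FormatError(f"annotation file not found: {p}")
    return manifest


def _load_source(entry: dict, base: Path, source: str, roi_id: str,
                 case_id: str) -> AnnotationSet:
    frame = CoordinateFrame.from_dict(entry["frame"])
    return read_points(base / entry["path"], frame, source=source,
                       roi_id=roi_id, case_id=case_id)


def evaluate_manifest(
    manifest: dict,
    base_dir: str | Path,
    max_dist_um: float = DEFAULT_MAX_DIST_UM,
    aggregation: str = "pooled",
) -> dict[str, Any]:
    """Run the full evaluation over a loaded manifest.

    Returns a results dict with per-ROI rows, per-case summaries and one
    agreement block per detector.  Deterministic for fixed inputs: iteration
    follows manifest order and all tables are sorted on output.
    """
    base = Path(base_dir)
    cfg = MatchConfig(max_dist_um=max_dist_um)

    roi_rows: list[dict] = []
    score_rows: list[dict] = []
    detector_names: list[str] = []
    # per detector: per-ROI paired series
    series: dict[str, dict[str, list]] = {}

    for case in manifest["cases"]:
        case_id = case["case_id"]
        for roi in case["rois"]:
            roi_id = roi["roi_id"]
            ref = _load_source(roi["reference"], base, "reference", roi_id, case_id)
            ref_score = scoring.roi_score(ref)
            for det_name, entry in roi["detectors"].items():
                if det_name not in series:
                    detector_names.append(det_name)
                    series[det_name] = {
                        "ref_total": [], "det_total": [],
                        "ref_pos": [], "det_pos": [],
                        "ref_score": [], "det_score": [],
                        "case_ids": [], "roi_ids": [],
                    }
                det = _load_source(entry, base, det_name, roi_id, case_id)
                if det.frame != ref.frame:
                    mapping = build_mapping(det.frame, ref.frame)
                    det = apply_mapping(mapping, det)
                total, positive = stratified_match(ref, det, cfg)
                det_score = scoring.roi_score(det)
                for stratum, m in (("total", total), ("positive", positive)):
                    dm = metrics_from_match(m)
                    roi_rows.append({
                        "case_id": case_id, "roi_id": roi_id,
                        "detector": det_name, "stratum": stratum,
                        **dm.to_dict(),
                    })
                s = series[det_name]
                s["ref_total"].append(ref.n_total)
                s["det_total"].append(det.n_total)
                s["ref_pos"].append(ref.n_positive)
                s["det_pos"].append(det.n_positive)
                s["ref_score"].append(ref_score.score_pct)
                s["det_score"].append(det_score.score_pct)
                s["case_ids"].append(case_id)
                s["roi_ids"].append(roi_id)
                score_rows.append({
                    "case_id": case_id, "roi_id": roi_id, "detector": det_name,
                    "ref_n_positive": ref.n_positive, "ref_n_total": ref.n_total,
                    "ref_score_pct": ref_score.score_pct,
                    "det_n_positive": det.n_positive, "det_n_total": det.n_total,
                    "det_score_pct": det_score.score_pct,
                })

    roi_df = pd.DataFrame(roi_rows)
    score_df = pd.DataFrame(score_rows)

    # ---- per-case summaries ------------------------------------------------
    case_rows: list[dict] = []
    grade_rows: list[dict] = []
    for det_name in detector_names:
        sub = roi_df[roi_df.detector == det_name]
        for case_id in sub.case_id.unique():
            for stratum in ("total", "positive"):
                part = sub[(sub.case_id == case_id) & (sub.stratum == stratum)]
                items = [
                    DetectionMetrics(**{k: r[k] for k in
                                        ("tp", "fp", "fn", "fdr", "precision",
                                         "recall", "f_score")})
                    for r in part.to_dict("records")
                ]
                agg = aggregate_case(items, mode=aggregation)
                case_rows.append({
                    "case_id": case_id, "detector": det_name,
                    "stratum": stratum, "aggregation": aggregation,
                    **agg.to_dict(),
                })
        ssub = score_df[score_df.detector == det_name]
        for case_id in ssub.case_id.unique():
            part = ssub[ssub.case_id == case_id]
            ref_cs = scoring.case_score(
                [scoring.Ki67Score(int(r.ref_n_positive), int(r.ref_n_total))
                 for r in part.itertuples()])
            det_cs = scoring.case_score(
                [scoring.Ki67Score(int(r.det_n_positive), int(r.det_n_total))
                 for r in part.itertuples()])
            ref_grade = scoring.grade(ref_cs) if ref_cs.defined else None
            det_grade = scoring.grade(det_cs) if det_cs.defined else None
            grade_rows.append({
                "case_id": case_id, "detector": det_name,
                "ref_score_pct": ref_cs.score_pct, "det_score_pct": det_cs.score_pct,
                "ref_grade": ref_grade.value if ref_grade else "",
                "det_grade": det_grade.value if det_grade else "",
                "grade_changed": bool(ref_grade and det_grade
                                      and ref_grade != det_grade),
            })
    case_df = pd.DataFrame(case_rows)
    grade_df = pd.DataFrame(grade_rows)

    # ---- agreement statistics ---------------------------------------------
    agreement: dict[str, Any] = {}
    for det_name in detector_names:
        s = series[det_name]
        ref_total = np.array(s["ref_total"], dtype=float)
        det_total = np.array(s["det_total"], dtype=float)
        ref_pos = np.array(s["ref_pos"], dtype=float)
        det_pos = np.array(s["det_pos"], dtype=float)
        ref_sc = np.array(s["ref_score"], dtype=float)
        det_sc = np.array(s["det_score"], dtype=float)
        defined = ~(np.isnan(ref_sc) | np.isnan(det_sc))

        case_ids = pd.Series(s["case_ids"])
        case_grade = grade_df[grade_df.detector == det_name]

        def _safe_report(x: np.ndarray, y: np.ndarray) -> dict:
            try:
                return stats.agreement_report(x, y).to_dict()
            except Ki67EvalError as exc:
                return {"error": str(exc)}

        block: dict[str, Any] = {"match_max_dist_um": max_dist_um}
        block["roi_total_count"] = _safe_report(ref_total, det_total)
        block["roi_positive_count"] = _safe_report(ref_pos, det_pos)
        block["roi_ki67_score"] = _safe_report(ref_sc[defined], det_sc[defined])
        case_ref = case_grade["ref_score_pct"].to_numpy(dtype=float)
        case_det = case_grade["det_score_pct"].to_numpy(dtype=float)
        if case_ref.size >= 3:
            block["case_ki67_score"] = _safe_report(case_ref, case_det)
        block["count_comparison"] = {
            "total_cells": compare_counts(ref_total, det_total).to_dict(),
            "positive_cells": compare_counts(ref_pos, det_pos).to_dict(),
            "ki67_score": compare_counts(ref_sc[defined], det_sc[defined]).to_dict(),
        }
        try:
            slope, intercept = linear_fit(ref_total, det_total)
            block["total_count_regression"] = {"slope": slope, "intercept": intercept}
        except Ki67EvalError:
            pass
        block["grade_changes"] = int(case_grade["grade_changed"].sum())
        agreement[det_name] = block

    return {
        "config": {"max_dist_um": max_dist_um, "aggregation": aggregation},
        "roi_metrics": roi_df,
        "case_metrics": case_df,
        "scores": score_df,
        "case_scores": grade_df,
        "agreement": agreement,
    }


def write_reports(results: dict[str, Any], out_dir: str | Path) -> None:
    """Write the evaluation results as fixed-layout CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, key in (("roi_metrics", "roi_metrics"),
                      ("case_metrics", "case_metrics"),
                      ("scores", "scores"),
                      ("case_scores", "case_scores")):
        df: pd.DataFrame = results[key]
        df = df.sort_values(list(df.columns[:4])).reset_index(drop=True)
        df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    report = {"config": results["config"], "agreement": results["agreement"]}
    (out / "agreement.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("reports written to %s", out)


# ---------------------------------------------------------------------------
# Study simulation: synthetic dataset in the manifest layout evaluate consumes
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Shape of a simulated study: cases × ROIs with reference + detectors.

    Defaults mirror the evaluation setting this package targets: 10 cases of
    8 ROIs each (80 ROIs), ~200 cells per ROI with a ~3% positive fraction,
    and the two preset detector error models.  ``markup_frame``, when set,
    is the coordinate frame detector outputs are *written* in (emulating
    mark-up images rendered at a different resolution); the evaluation maps
    them back onto the reference grid.
    """

    n_cases: int = 10
    n_rois_per_case: int = 8
    reference: "ReferenceConfig" = None  # type: ignore[assignment]
    detectors: dict[str, "DetectorErrorModel"] = field(default_factory=dict)
    markup_frames: dict[str, CoordinateFrame] = field(default_factory=dict)
    #: SD of the per-ROI cell count around ``reference.n_cells`` ("~200 cells
    #: per ROI": tissue density varies between regions and cases).
    n_cells_sd: float = 25.0
    #: Per-case Ki67-positive fraction is drawn uniformly from this range —
    #: low-proliferation NETs, scores below 5%, straddling the G1/G2 boundary.
    p_positive_range: tuple[float, float] = (0.002, 0.045)
    seed: int = 0

    def __post_init__(self) -> None:
        from .synthetic import ReferenceConfig, preset_detectors
        if self.reference is None:
            self.reference = ReferenceConfig()
        if not self.detectors:
            self.detectors = preset_detectors()


def simulate_study(cfg: StudyConfig) -> list[dict[str, AnnotationSet]]:
    """Generate all ROIs of a study in memory.

    Returns one dict per ROI mapping ``"reference"`` and each detector name
    to its :class:`AnnotationSet` (all in the reference frame).  Per-ROI and
    per-detector seeds are derived deterministically from ``cfg.seed``.
    """
    from dataclasses import replace

    from .synthetic import generate_reference, simulate_detector

    rois: list[dict[str, AnnotationSet]] = []
    ss = np.random.SeedSequence(cfg.seed)
    n_rois = cfg.n_cases * cfg.n_rois_per_case
    n_sources = 1 + len(cfg.detectors)
    study_ss, *children = ss.spawn(n_rois * n_sources + 1)
    study_rng = np.random.default_rng(study_ss)
    idx = 0
    for c in range(cfg.n_cases):
        case_id = f"case_{c + 1:02d}"
        p_pos = float(study_rng.uniform(*cfg.p_positive_range))
        for r in range(cfg.n_rois_per_case):
            roi_id = f"roi_{r + 1:02d}"
            n_cells = max(1, int(round(study_rng.normal(
                cfg.reference.n_cells, cfg.n_cells_sd))))
            ref_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            ref = generate_reference(
                replace(cfg.reference, seed=ref_seed, n_cells=n_cells,
                        p_positive=p_pos),
                roi_id=roi_id, case_id=case_id,
            )
            entry = {"reference": ref}
            for name, model in cfg.detectors.items():
                det_seed = int(children[idx].generate_state(1)[0] % (2**31))
                idx += 1
                entry[name] = simulate_detector(
                    ref, model.with_seed(det_seed), source=name
                )
            rois.append(entry)
    return rois


def write_study(cfg: StudyConfig, out_dir: str | Path) -> Path:
    """Simulate a study and write it as per-ROI CSVs plus ``manifest.json``.

    Detector sets whose name appears in ``cfg.markup_frames`` are transformed
    into that frame before writing, exercising the coordinate-transformation
    step on re-evaluation.  Returns the manifest path.
    """
    from .annotations import write_points

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rois = simulate_study(cfg)
    cases: dict[str, list[dict]] = {}
    for entry in rois:
        ref = entry["reference"]
        case_dir = out / ref.case_id
        case_dir.mkdir(exist_ok=True)
        roi_entry: dict[str, Any] = {"roi_id": ref.roi_id, "detectors": {}}
        ref_path = case_dir / f"{ref.roi_id}_reference.csv"
        write_points(ref, ref_path)
        roi_entry["reference"] = {
            "path": str(ref_path.relative_to(out)),
            "frame": ref.frame.to_dict(),
        }
        for name, det in entry.items():
            if name == "reference":
                continue
            if name in cfg.markup_frames:
                mapping = build_mapping(det.frame, cfg.markup_frames[name])
                det = apply_mapping(mapping, det)
            det_path = case_dir / f"{det.roi_id}_{name}.csv"
            write_points(det, det_path)
            roi_entry["detectors"][name] = {
                "path": str(det_path.relative_to(out)),
                "frame": det.frame.to_dict(),
            }
        cases.setdefault(ref.case_id, []).append(roi_entry)
    manifest = {
        "cases": [{"case_id": cid, "rois": rois_} for cid, rois_ in cases.items()],
        "simulation": {
            "n_cases": cfg.n_cases,
            "n_rois_per_case": cfg.n_rois_per_case,
            "seed": cfg.seed,
            "detectors": sorted(cfg.detectors),
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def run_evaluation(cfg: RunConfig) -> dict[str, Any]:
    """Load a manifest, evaluate it and write reports to ``cfg.out_dir``."""
    manifest = load_manifest(cfg.manifest_path)
    results = evaluate_manifest(
        manifest,
        base_dir=Path(cfg.manifest_path).parent,
        max_dist_um=cfg.max_dist_um,
        aggregation=cfg.aggregation,
    )
    write_reports(results, cfg.out_dir)
    return results
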