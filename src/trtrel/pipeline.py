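"""End-to-end reliability analysis of a paired-session cohort.

Runs, per bundle, the spatial-overlap analysis (session-1 bundles carried
into session-2 space by each subject's affine, both rasterized on a shared
grid, weighted Dice per subject) and, per bundle x metric, the scalar
agreement analysis (ICC(A,1) with confidence interval and F-test,
Bland-Altman limits of agreement), then writes a report shaped like the
classic per-bundle reliability table: one row per bundle with its overlap
summary and one column group per metric.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, icc_a1
from .bundle_geometry import density_map, transform_streamlines
from .cohort_io import (CohortLayout, read_affine, read_density_map,
                        read_metric_table, read_streamlines)
from .overlap import WDSC_THRESHOLD, classify_overlap, wdsc

__all__ = ["PipelineConfig", "ReliabilityReport", "run_overlap_analysis",
           "run_agreement_analysis", "build_report", "run_pipeline"]

log = logging.getLogger("trtrel")

#: metric column order of the human-readable report
REPORT_METRIC_ORDER = ["FA", "AD", "MD", "RD", "NuFO", "volume", "MLS"]


@dataclass
class PipelineConfig:
    wdsc_threshold: float = WDSC_THRESHOLD
    loa_multiplier: float = 2.0
    alpha: float = 0.05
    fallback_voxel_size: float = 1.0   # mm, when no density map provides a grid
    min_subjects: int = 3

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReliabilityReport:
    overlap: dict
    agreement: list
    status: str = "complete"        # complete | partial
    files: dict = field(default_factory=dict)


def _stars(p) -> str:
    if p is None or not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def _grid_for(layout: CohortLayout, subject: str, bundle: str,
              bundles, voxel_size: float):
    """Rasterization grid: the session-2 density map's grid when present,
    otherwise a padded bounding box of both bundles."""
    p = layout.density_path(subject, layout.session_labels[1], bundle)
    if p is not None:
        dm = read_density_map(p)
        return dm.data.shape, dm.affine
    pts = np.vstack([np.vstack(b.streamlines) for b in bundles])
    lo = np.floor(pts.min(axis=0) / voxel_size) - 2
    hi = np.ceil(pts.max(axis=0) / voxel_size) + 2
    shape = tuple(int(s) for s in (hi - lo))
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo * voxel_size
    return shape, affine


def run_overlap_analysis(layout: CohortLayout,
                         config: PipelineConfig | None = None) -> dict:
    """Per-bundle weighted Dice between the two sessions, across subjects.

    For every subject with both sessions of a bundle: load both
    reconstructions, apply the subject's session-1 -> session-2 affine to
    the session-1 bundle, rasterize both onto the session-2 grid and compute
    the weighted Dice.  Subjects missing either session are skipped and
    listed; a bundle no subject provides is marked not analyzable.
    """
    config = config or PipelineConfig()
    ses1, ses2 = layout.session_labels
    results = {}
    for bundle in layout.bundle_names:
        values, subjects_used, skipped = [], [], []
        for subject in layout.subject_ids:
            p1 = layout.streamline_path(subject, ses1, bundle)
            p2 = layout.streamline_path(subject, ses2, bundle)
            if p1 is None or p2 is None:
                skipped.append(subject)
                continue
            b1 = read_streamlines(p1, name=bundle, space="time1")
            b2 = read_streamlines(p2, name=bundle, space="time2")
            ap = layout.affine_path(subject)
            T = read_affine(ap) if ap is not None else np.eye(4)
            b1 = transform_streamlines(b1, T, space="time2")
            shape, affine = _grid_for(layout, subject, bundle, (b1, b2),
                                      config.fallback_voxel_size)
            d1 = density_map(b1, shape, affine)
            d2 = density_map(b2, shape, affine)
            res = wdsc(d1, d2, threshold=config.wdsc_threshold)
            values.append(res.wdsc)
            subjects_used.append(subject)
        if not values:
            log.warning("bundle %s: no subject has both sessions", bundle)
            results[bundle] = {"analyzable": False, "subjects": [],
                               "values": [], "skipped": skipped}
            continue
        arr = np.asarray(values)
        results[bundle] = {
            "analyzable": True,
            "subjects": subjects_used,
            "values": values,
            "skipped": skipped,
            "n_used": len(values),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "min": float(arr.min()),
            "max": float(arr.max()),
            "category": classify_overlap(float(arr.mean()),
                                         config.wdsc_threshold),
        }
        log.info("bundle %s: %d subjects, mean wDSC %.3f (%d skipped)",
                 bundle, len(values), arr.mean(), len(skipped))
    return results


def run_agreement_analysis(layout: CohortLayout,
                           config: PipelineConfig | None = None) -> list:
    """ICC(A,1) + Bland-Altman per bundle x metric on pairwise-complete rows."""
    config = config or PipelineConfig()
    tables = read_metric_table(layout.metrics_path,
                               session_labels=layout.session_labels)
    rows = []
    for bundle in layout.bundle_names:
        for metric in layout.metric_names:
            row = {"bundle": bundle, "metric": metric}
            t = tables.get((bundle, metric))
            if t is None or t.n_complete < config.min_subjects:
                reason = ("missing_table" if t is None
                          else "insufficient_subjects")
                row.update({"ok": False, "reason": reason,
                            "n_used": 0 if t is None else t.n_complete})
                rows.append(row)
                continue
            icc = icc_a1(t, alpha=config.alpha)
            ba = bland_altman(t, multiplier=config.loa_multiplier)
            row.update({
                "ok": True, "reason": "",
                "n_used": icc.n,
                "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
                "p_value": icc.p_value, "stars": _stars(icc.p_value),
                "category": icc.category,
                "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "fraction_within": ba.fraction_within,
                "n_outside": ba.n_outside,
                "subjects": [t.subject_ids[i] for i in
                             np.flatnonzero(t.complete_mask)],
                "pair_means": ba.pair_means, "pair_diffs": ba.pair_diffs,
            })
            rows.append(row)
    return rows


_CSV_COLUMNS = ["section", "bundle", "metric", "n_used", "wdsc_mean",
                "wdsc_median", "wdsc_min", "wdsc_max", "overlap_category",
                "icc", "ci_low", "ci_high", "p_value", "stars", "category",
                "mean_diff", "sd_diff", "loa_low", "loa_high",
                "fraction_within", "n_outside", "reason"]


def build_report(overlap: dict, agreement: list, out_dir,
                 config: PipelineConfig | None = None) -> ReliabilityReport:
    """Write report.csv (long form), report.md (grouped table),
    blandaltman_points.csv and provenance.json; deterministic ordering."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = []
    partial = False
    for bundle, o in overlap.items():
        if not o.get("analyzable", False):
            partial = True
            records.append({"section": "wdsc", "bundle": bundle,
                            "reason": "not_analyzable"})
            continue
        records.append({"section": "wdsc", "bundle": bundle,
                        "n_used": o["n_used"], "wdsc_mean": o["mean"],
                        "wdsc_median": o["median"], "wdsc_min": o["min"],
                        "wdsc_max": o["max"],
                        "overlap_category": o["category"]})
    ba_rows = []
    for r in agreement:
        if not r.get("ok", False):
            partial = True
            records.append({"section": "icc", "bundle": r["bundle"],
                            "metric": r["metric"], "n_used": r.get("n_used"),
                            "reason": r["reason"]})
            continue
        records.append({"section": "icc", "bundle": r["bundle"],
                        "metric": r["metric"], "n_used": r["n_used"],
                        "icc": r["icc"], "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"], "p_value": r["p_value"],
                        "stars": r["stars"], "category": r["category"],
                        "mean_diff": r["mean_diff"], "sd_diff": r["sd_diff"],
                        "loa_low": r["loa_low"], "loa_high": r["loa_high"],
                        "fraction_within": r["fraction_within"],
                        "n_outside": r["n_outside"]})
        for s, m, d in zip(r["subjects"], r["pair_means"], r["pair_diffs"]):
            ba_rows.append({"bundle": r["bundle"], "metric": r["metric"],
                            "subject": s, "pair_mean": m, "pair_diff": d})

    df = pd.DataFrame(records, columns=_CSV_COLUMNS)
    csv_path = out / "report.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    ba_path = out / "blandaltman_points.csv"
    pd.DataFrame(ba_rows, columns=["bundle", "metric", "subject",
                                   "pair_mean", "pair_diff"]
                 ).to_csv(ba_path, index=False, float_format="%.10g")

    md_path = out / "report.md"
    md_path.write_text(_report_markdown(overlap, agreement))

    prov = {"config": config.__dict__, "config_digest": config.digest(),
            "trtrel_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                    sort_keys=True) + "\n")

    return ReliabilityReport(
        overlap=overlap, agreement=agreement,
        status="partial" if partial else "complete",
        files={"csv": csv_path, "md": md_path, "blandaltman": ba_path,
               "provenance": out / "provenance.json"})


def _report_markdown(overlap: dict, agreement: list) -> str:
    bundles = list(overlap.keys())
    metrics = [m for m in REPORT_METRIC_ORDER
               if any(r["metric"] == m for r in agreement)]
    metrics += sorted({r["metric"] for r in agreement} - set(metrics))
    by_key = {(r["bundle"], r["metric"]): r for r in agreement}
    lines = ["# Test-retest reliability report", "",
             "wDSC is the across-subject mean weighted Dice between sessions;"
             " per metric: ICC(A,1) with 95% CI and significance stars.", "",
             "| Bundle | wDSC | " + " | ".join(f"{m} ICC (95% CI)" for m in metrics) + " |",
             "|" + "---|" * (len(metrics) + 2)]
    for b in bundles:
        o = overlap[b]
        wd = f"{o['mean']:.2f}" if o.get("analyzable") else "NA"
        cells = []
        for m in metrics:
            r = by_key.get((b, m))
            if r is None or not r.get("ok"):
                cells.append("NA")
            else:
                cells.append(f"{r['icc']:.2f}{r['stars']} "
                             f"({r['ci_low']:.2f}, {r['ci_high']:.2f})")
        lines.append(f"| {b} | {wd} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def run_pipeline(layout: CohortLayout, out_dir,
                 config: PipelineConfig | None = None) -> ReliabilityReport:
    """Full analysis: overlap + agreement + report files."""
    config = config or PipelineConfig()
    overlap = run_overlap_analysis(layout, config)
    agreement = run_agreement_analysis(layout, config)
    return build_report(overlap, agreement, out_dir, config)
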