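"""Per-slide workflow orchestration and cohort aggregation.

One slide runs through: optional control-tissue crop → preliminary tissue
segmentation → background/stain-vector estimation → stain-adaptive custom
threshold → refined tissue segmentation → nucleus segmentation → adaptive
DAB threshold → classification → labeling index → density maps → writers.
Slides are processed in a single round; quality flags (weak hematoxylin,
empty mask, extreme DAB threshold) are recorded for the user to act on
rather than auto-excluding, since exclusion is a pathologist's judgment.
"""

from __future__ import annotations

import json
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import density as _density
from . import nuclei as _nuclei
from . import stains as _stains
from . import tissue as _tissue
from . import wsi_io
from .config import PipelineConfig
from .stats import (
    SlideSummary,
    agreement_stats,
    bonferroni_adjust,
    boxplot_table,
    kruskal_wallis,
    summaries_frame,
    summarize_by_group,
)
from .wsi_io import SlideImage



class _StageLog:
    """One JSON line per stage per slide, so cohort failures are diagnosable."""

    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.write_text("")

    def __call__(self, slide_id: str, stage: str, **fields) -> None:
        if self.path is None:
            return
        rec = {"slide_id": slide_id, "stage": stage, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_slide(
    slide: str | Path | SlideImage,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    group: str = "",
    descriptor: str | None = None,
    has_control_tissue: bool = False,
    force: bool = False,
    log: _StageLog | None = None,
) -> SlideSummary:
    """Run the full per-slide analysis; returns the slide summary.

    ``slide`` may be a path (read at the nucleus-segmentation resolution) or
    an in-memory :class:`SlideImage`.  When ``out_dir`` is given, detections
    (GeoJSON), the stain model, density maps, the text summary and the
    resolved config are written there; an existing summary is reused unless
    ``force``.  A slide whose refined tissue mask is empty yields a summary
    with zero counts and NA labeling index, not an error.
    """
    cfg = config or PipelineConfig()
    log = log or _StageLog(None)

    if isinstance(slide, (str, Path)):
        slide = wsi_io.read_slide(
            slide, target_mpp=cfg["nuclei.target_mpp"], mpp=cfg["io.mpp_override"]
        )
    slide_id = slide.slide_id

    slide_out = None
    if out_dir is not None:
        slide_out = Path(out_dir) / slide_id
        summary_path = slide_out / "summary.txt"
        if summary_path.exists() and not force:
            prior = wsi_io.read_slide_summary(summary_path)
            prior.group = group or prior.group
            prior.descriptor = descriptor or prior.descriptor
            log(slide_id, "resume", reused=True)
            return prior
        slide_out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if has_control_tissue:
        slide = wsi_io.crop_control_tissue(slide, cfg["io.control_crop_fraction"])
        log(slide_id, "crop", fraction=cfg["io.control_crop_fraction"])

    prelim = _tissue.segment_preliminary(
        slide,
        working_mpp=cfg["tissue.working_mpp"],
        threshold=cfg["tissue.preliminary_threshold"],
        sigma=cfg["tissue.gaussian_sigma_px"],
        min_area_um2=cfg["tissue.preliminary_min_area_um2"],
        min_hole_area_um2=cfg["tissue.min_hole_area_um2"],
    )
    log(slide_id, "segment_preliminary", area_mm2=prelim.total_area_mm2)

    # Estimation needs nucleus interiors at near-pure stain color, so it
    # runs at the nucleus-segmentation resolution, never coarser.
    est_slide = wsi_io.resample_to_mpp(
        slide, max(cfg["stain.estimation_mpp"], slide.mpp)
    )
    est_mask = _mask_on_raster(prelim, est_slide)
    model = _stains.estimate_stain_vectors(
        est_slide.pixel_data,
        est_mask,
        od_gate=(cfg["stain.od_gate_low"], cfg["stain.od_gate_high"]),
        min_mask_pixels=cfg["stain.min_mask_pixels"],
        min_cluster_pixels=cfg["stain.min_cluster_pixels"],
        smooth_sigma=cfg["stain.background_smooth_sigma"],
    )
    model.weak_h_component = cfg["stain.weak_h_component"]
    model.weak_h_cutoff = cfg["stain.weak_h_cutoff"]
    log(
        slide_id, "estimate_stains",
        weak_hematoxylin=model.weak_hematoxylin,
        background=model.background_rgb,
    )
    if slide_out is not None:
        model.to_json(slide_out / "stain_model.json")

    threshold = _tissue.compute_custom_threshold(
        model,
        margin_strong=cfg["tissue.margin_strong"],
        margin_weak=cfg["tissue.margin_weak"],
        clamp=tuple(cfg["tissue.threshold_clamp"]),
    )
    refined = _tissue.segment_refined(
        slide, threshold, preliminary=prelim,
        working_mpp=cfg["tissue.working_mpp"],
        sigma=cfg["tissue.gaussian_sigma_px"],
        min_area_um2=cfg["tissue.refined_min_area_um2"],
        min_hole_area_um2=cfg["tissue.min_hole_area_um2"],
    )
    area_mm2 = refined.total_area_mm2
    log(slide_id, "segment_refined", threshold=threshold, area_mm2=area_mm2)
    if slide_out is not None:
        _tissue.export_mask_geojson(refined, slide_out / "tissue_mask.geojson")
        _tissue.export_mask_png(refined, slide_out / "tissue_mask.png")

    if not refined.mask.any():
        summary = SlideSummary(
            slide_id=slide_id, group=group, descriptor=descriptor,
            n_pos=0, n_neg=0, area_mm2=0.0,
            weak_hematoxylin=model.weak_hematoxylin,
        )
        log(slide_id, "empty_mask", flagged=True)
        _write_outputs(summary, [], None, slide, cfg, slide_out)
        return summary

    nuclei = _nuclei.segment_nuclei(
        slide, refined, model,
        backend=cfg["nuclei.backend"],
        prob_threshold=cfg["nuclei.prob_threshold"],
        target_mpp=cfg["nuclei.target_mpp"],
        tile_px=cfg["nuclei.tile_px"],
        overlap_px=cfg["nuclei.overlap_px"],
        p_low=cfg["nuclei.norm_p_low"],
        p_high=cfg["nuclei.norm_p_high"],
        min_area_um2=cfg["nuclei.min_area_um2"],
        max_area_um2=cfg["nuclei.max_area_um2"],
        max_od=cfg["nuclei.max_od"],
    )
    log(slide_id, "segment_nuclei", n_detections=len(nuclei))

    if nuclei:
        dab_thr, hist = _classify.adaptive_dab_threshold(
            slide, refined, model,
            downsample=cfg["classify.downsample"],
            target_mpp=cfg["nuclei.target_mpp"],
            bins=cfg["classify.hist_bins"],
            od_max=cfg["classify.hist_od_max"],
        )
        result = _classify.classification_result(nuclei, dab_thr, hist)
        n_pos, n_neg = result.n_positive, result.n_negative
        extreme = not (0.02 <= dab_thr <= 1.5)
        log(slide_id, "classify", dab_threshold=dab_thr, n_pos=n_pos,
            n_neg=n_neg, extreme_threshold_flag=extreme)
    else:
        dab_thr, n_pos, n_neg = None, 0, 0
        log(slide_id, "classify", skipped="no detections")

    summary = SlideSummary(
        slide_id=slide_id, group=group, descriptor=descriptor,
        n_pos=n_pos, n_neg=n_neg, area_mm2=area_mm2,
        dab_threshold=dab_thr, weak_hematoxylin=model.weak_hematoxylin,
    )
    _write_outputs(summary, nuclei, dab_thr, slide, cfg, slide_out)
    log(slide_id, "done", seconds=round(time.perf_counter() - t0, 3))
    return summary


def _mask_on_raster(mask: _tissue.TissueMask, slide: SlideImage) -> np.ndarray:
    """Rasterize a tissue mask onto another raster's pixel grid."""
    ys, xs = np.mgrid[0 : slide.height, 0 : slide.width]
    ox, oy = slide.origin_um
    x_um = (xs + 0.5) * slide.mpp + ox
    y_um = (ys + 0.5) * slide.mpp + oy
    return mask.contains_um(x_um.ravel(), y_um.ravel()).reshape(slide.height, slide.width)


def _write_outputs(summary, nuclei, dab_thr, slide, cfg, slide_out):
    if slide_out is None:
        return
    wsi_io.write_detections(nuclei, slide_out / "detections.geojson")

    pos_pts = [n.centroid for n in nuclei if n.label == "positive"]
    neg_pts = [n.centroid for n in nuclei if n.label == "negative"]
    ox, oy = slide.origin_um
    extent = slide.extent_um
    kwargs = dict(
        extent_um=extent,
        grid_mpp=cfg["density.grid_mpp"],
        radius_um=cfg["density.radius_um"],
        origin_um=(ox, oy),
        kernel=cfg["density.kernel"],
    )
    pos_map = _density.compute_density_map(pos_pts, class_label="positive", **kwargs)
    neg_map = _density.compute_density_map(neg_pts, class_label="negative", **kwargs)
    li_map = _density.compute_li_map(pos_map, neg_map)
    for dmap, stem in [(neg_map, "neg_density"), (pos_map, "pos_density"), (li_map, "li_map")]:
        _density.save_density_map(dmap, slide_out / f"{summary.slide_id}_{stem}.tif")
        if np.isfinite(dmap.grid).any():
            render, scale = _density.normalize_and_render(dmap, cfg["density.colormap"])
            import imageio.v3 as iio

            iio.imwrite(slide_out / f"{summary.slide_id}_{stem}.png", render)

    wsi_io.write_slide_summary(summary, slide_out / "summary.txt")
    cfg.dump(slide_out / "config.json")


def run_cohort(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    compare_csv: str | Path | None = None,
    force: bool = False,
) -> dict:
    """Process every slide in a manifest and aggregate cohort statistics.

    Returns a report dict with per-slide summaries, the group table,
    Kruskal–Wallis + Bonferroni results per metric, box-plot quartile
    tables, failures, and (when ``compare_csv`` is given) agreement
    statistics against a second method's per-slide results.
    """
    cfg = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    manifest = wsi_io.read_manifest(manifest_path)
    if len(manifest) == 0:
        raise ValueError("empty manifest")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "pipeline_log.jsonl" if out is not None else None)

    summaries: list[SlideSummary] = []
    failures: list[dict] = []
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        try:
            summary = run_slide(
                path, cfg, out_dir=out, group=row.group,
                descriptor=row.descriptor or None,
                has_control_tissue=bool(row.has_control_tissue),
                force=force, log=log,
            )
            summary.group = row.group
            summaries.append(summary)
        except Exception as exc:  # keep going: one bad slide must not kill a cohort
            failures.append({"slide_id": row.slide_id, "reason": str(exc)})
            log(row.slide_id, "failed", reason=str(exc))
    if not summaries:
        raise RuntimeError("no slide processed successfully")

    group_table = summarize_by_group(summaries)
    df = summaries_frame(summaries)

    tests = {}
    groups_present = [g for g, sub in df.groupby("group") if len(sub)]
    pvals, metric_names = [], []
    for metric in ("li_percent", "pos_density", "neg_density"):
        vectors = [
            sub[metric].dropna().to_numpy()
            for _, sub in df.groupby("group")
            if len(sub[metric].dropna())
        ]
        if len(vectors) >= 2:
            h, p = kruskal_wallis(vectors)
            tests[metric] = {"H": h, "p": p}
            pvals.append(p)
            metric_names.append(metric)
    if pvals:
        adj, flags = bonferroni_adjust(pvals, alpha=cfg["stats.alpha"])
        for name, pa, fl in zip(metric_names, adj, flags):
            tests[name]["p_bonferroni"] = pa
            tests[name]["significant"] = fl
        tests["_bonferroni_m"] = len(pvals)

    report: dict = {
        "summaries": df,
        "group_table": group_table,
        "kruskal_wallis": tests,
        "boxplot_tables": {
            m: boxplot_table(summaries, m) for m in ("li_percent", "pos_density", "neg_density")
        },
        "failures": failures,
        "n_groups": len(groups_present),
    }

    if compare_csv is not None:
        other = pd.read_csv(compare_csv)
        merged = df.merge(other, on="slide_id", suffixes=("", "_other"))
        agreement = {}
        for metric, col in [("li_percent", "li_percent_other"),
                            ("n_pos", "n_pos_other"), ("n_neg", "n_neg_other")]:
            if col in merged.columns:
                sub = merged[[metric, col]].dropna()
                if len(sub) >= 3:
                    agreement[metric] = agreement_stats(
                        sub[metric].to_numpy(dtype=float),
                        sub[col].to_numpy(dtype=float),
                    )
        report["agreement"] = agreement

    if out is not None:
        cohort_csv = out / "cohort.csv"
        if cohort_csv.exists():
            cohort_csv.unlink()   # rebuilt every run for deterministic bytes
        for s in summaries:
            wsi_io.append_cohort_row(s, cohort_csv)
        group_table.to_csv(out / "group_table.csv", index=False)
        serializable = {
            k: v for k, v in report.items()
            if k not in {"summaries", "group_table", "boxplot_tables"}
        }
        (out / "report.json").write_text(json.dumps(serializable, indent=2, default=str))
        for metric, table in report["boxplot_tables"].items():
            table.to_csv(out / f"boxplot_{metric}.csv", index=False)
            _render_boxplot(df, metric, out / f"boxplot_{metric}.png")
    return report


def _render_boxplot(df: pd.DataFrame, metric: str, path: Path) -> None:
    """Per-group box plot; the quartile table beside it carries the numbers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups, data = [], []
    for group, sub in df.groupby("group", sort=False):
        vals = sub[metric].dropna()
        if len(vals):
            groups.append(group)
            data.append(vals.to_numpy())
    if not data:
        return
    fig, ax = plt.subplots(figsize=(1.5 + len(groups), 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
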