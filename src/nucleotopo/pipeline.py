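"""Reproducible generate → segment → measure → compare → report pipeline.

Stages communicate exclusively through files (CSV tables, PNG images,
JSON configs) inside one output directory, so each stage can be run,
inspected and re-run independently:

    outdir/
      <population>/images/*.png     generate
      <population>/ground_truth.csv
      <population>/spec.json
      <population>/nuclei.csv        segment (fitted geometry per nucleus)
      <population>/blobs.csv         segment (one row per detected blob)
      <population>/boundaries.csv    segment (blob boundary pixels)
      <population>/per_nucleus.csv   measure
      <population>/per_signal.csv    measure
      comparison.csv                 compare (one row per metric)
      fraction_split.json            compare (r-threshold split per group)
      hist_<metric>.csv              compare (cumulative histograms)
      figures/*.png                  report
      medians_summary.csv            report
      manifest.json                  written last; run metadata + checksums

A config is a JSON-able dict; ``run_pipeline`` validates it, executes
the requested stages in order and fails fast with a stage-named error.
Identical config + seed reproduce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import fit_geometry, normalized_radius, nucleolus_surface_distance
from .popstats import METRICS, split_by_threshold, two_sample_compare, cumulative_histogram
from .segmentation import NoNucleusError, SegmentationConfig, detect_signals, segment_nucleus
from .synthetic_nuclei import PopulationSpec, condition_spec, write_population

__all__ = ["run_pipeline", "StageError", "segment_directory", "measure_tables",
           "compare_tables", "DEFAULT_METRICS"]

DEFAULT_METRICS = ["r", "S_norm", "d_norm", "alpha_deg", "S_agnor", "r_agnor", "agnor_count"]
STAGES = ("generate", "segment", "measure", "compare", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# segment


def segment_directory(
    imgdir: Path, cfg: SegmentationConfig, kind: str = "circle"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Segment every PNG/TIFF in ``imgdir``; returns (nuclei, blobs,
    boundaries) tables keyed by nucleus_id = file stem."""
    import imageio.v3 as iio

    imgdir = Path(imgdir)
    paths = sorted(list(imgdir.glob("*.png")) + list(imgdir.glob("*.tif"))
                   + list(imgdir.glob("*.tiff")))
    if not paths:
        raise FileNotFoundError(f"no images found in {imgdir}")
    nuclei_rows, blob_rows, boundary_rows = [], [], []
    for path in paths:
        nid = path.stem
        img = iio.imread(path)
        try:
            mask, border = segment_nucleus(img, cfg)
        except NoNucleusError:
            continue
        geom = fit_geometry(mask, kind)
        nuclei_rows.append(dict(
            nucleus_id=nid, kind=geom.kind, cx=geom.center[0], cy=geom.center[1],
            R=geom.R, a=geom.a, b=geom.b, theta_deg=geom.theta_deg,
            axis_ratio=geom.axis_ratio, Sn=geom.Sn, border_flag=border,
        ))
        channels = ["fish", "agnor"] if cfg.image_style == "fish" else ["agnor"]
        for channel in channels:
            for blob in detect_signals(img, mask, channel, cfg):
                blob_rows.append(dict(
                    nucleus_id=nid, channel=channel, label=blob.label,
                    cx=blob.centroid[0], cy=blob.centroid[1], area_px=blob.area_px,
                ))
                for x, y in blob.boundary:
                    boundary_rows.append(dict(
                        nucleus_id=nid, channel=channel, label=blob.label, x=x, y=y,
                    ))
    nuclei = pd.DataFrame(nuclei_rows)
    blobs = pd.DataFrame(blob_rows, columns=["nucleus_id", "channel", "label",
                                             "cx", "cy", "area_px"])
    boundaries = pd.DataFrame(boundary_rows, columns=["nucleus_id", "channel", "label",
                                                      "x", "y"])
    return nuclei, blobs, boundaries


# ---------------------------------------------------------------------------
# measure


class _CsvBlob:
    """Blob reconstructed from the segment-stage CSV contract."""

    def __init__(self, label, centroid, area_px, boundary):
        self.label = int(label)
        self.centroid = centroid
        self.area_px = float(area_px)
        self.boundary = boundary


def measure_tables(
    nuclei: pd.DataFrame, blobs: pd.DataFrame, boundaries: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn segmentation tables into per-nucleus and per-signal tables.

    Pair metrics (d, alpha) are defined only for nuclei with exactly two
    FISH blobs; others are flagged, kept, and excluded from d/alpha
    statistics.  Signal-to-nucleolus distances use the boundary-pixel
    contract.  Border-touching nuclei are flagged and skipped in
    downstream statistics.
    """
    from .geometry import NucleusGeometry

    bnd_groups = {}
    if len(boundaries):
        bnd_groups = {k: v for k, v in boundaries.groupby(["nucleus_id", "channel", "label"])}
    per_nucleus_rows, per_signal_rows = [], []
    blob_by_nuc = {k: v for k, v in blobs.groupby("nucleus_id")} if len(blobs) else {}
    for row in nuclei.itertuples(index=False):
        if row.kind == "circle":
            geom = NucleusGeometry("circle", (row.cx, row.cy), row.R, row.R, row.R, 0.0, row.Sn)
        else:
            geom = NucleusGeometry("ellipse", (row.cx, row.cy), row.R, row.a, row.b,
                                   row.theta_deg, row.Sn)
        nuc_blobs = blob_by_nuc.get(row.nucleus_id)

        def _blobs(channel):
            out = []
            if nuc_blobs is None:
                return out
            sel = nuc_blobs[nuc_blobs.channel == channel]
            for b in sel.itertuples(index=False):
                key = (row.nucleus_id, channel, b.label)
                bnd = bnd_groups.get(key)
                bnd = bnd[["x", "y"]].to_numpy(float) if bnd is not None else np.empty((0, 2))
                out.append(_CsvBlob(b.label, (b.cx, b.cy), b.area_px, bnd))
            return out

        fish, agnor = _blobs("fish"), _blobs("agnor")
        rec_fish = []
        for b in fish:
            r = normalized_radius(geom, b.centroid)
            rec_fish.append((b, r))
        d_norm = alpha = None
        if len(fish) == 2:
            from .geometry import pair_metrics

            d_norm, alpha = pair_metrics(geom, fish[0].centroid, fish[1].centroid)
        agnor_boundaries = [b.boundary for b in agnor if len(b.boundary)]
        s_agnor = float(sum(b.area_px for b in agnor)) / geom.Sn if agnor else None
        per_nucleus_rows.append(dict(
            nucleus_id=row.nucleus_id, kind=geom.kind, cx=geom.center[0], cy=geom.center[1],
            R=geom.R, a=geom.a, b=geom.b, theta_deg=geom.theta_deg,
            axis_ratio=geom.axis_ratio, Sn=geom.Sn,
            d_norm=d_norm, alpha_deg=alpha, n_fish=len(fish),
            n_fish_flag=len(fish) != 2, agnor_count=len(agnor), S_agnor=s_agnor,
            border_flag=bool(row.border_flag),
        ))
        for b, r in rec_fish:
            dist_px = dist_norm = None
            if agnor_boundaries:
                dist_px, dist_norm = nucleolus_surface_distance(
                    b.centroid, agnor_boundaries, None, norm_radius=geom.norm_radius)
            per_signal_rows.append(dict(
                nucleus_id=row.nucleus_id, channel="fish", label=b.label,
                cx=b.centroid[0], cy=b.centroid[1], area_px=b.area_px,
                r=r, S_norm=b.area_px / geom.Sn,
                d_norm=d_norm, alpha_deg=alpha,
                nucleolus_dist_px=dist_px, nucleolus_dist_norm=dist_norm,
                outside_boundary=r > 1.0, n_fish_flag=len(fish) != 2,
                border_flag=bool(row.border_flag),
            ))
        for b in agnor:
            r = normalized_radius(geom, b.centroid)
            per_signal_rows.append(dict(
                nucleus_id=row.nucleus_id, channel="agnor", label=b.label,
                cx=b.centroid[0], cy=b.centroid[1], area_px=b.area_px,
                r=r, S_norm=b.area_px / geom.Sn,
                d_norm=None, alpha_deg=None,
                nucleolus_dist_px=None, nucleolus_dist_norm=None,
                outside_boundary=r > 1.0, n_fish_flag=len(fish) != 2,
                border_flag=bool(row.border_flag),
            ))
    return pd.DataFrame(per_nucleus_rows), pd.DataFrame(per_signal_rows)


# ---------------------------------------------------------------------------
# compare


def _metric_values(per_signal: pd.DataFrame, per_nucleus: pd.DataFrame, metric: str):
    ps = per_signal[~per_signal.border_flag] if len(per_signal) else per_signal
    pn = per_nucleus[~per_nucleus.border_flag] if len(per_nucleus) else per_nucleus
    if metric == "r":
        return ps[ps.channel == "fish"].r.dropna().to_numpy(float)
    if metric == "S_norm":
        return ps[ps.channel == "fish"].S_norm.dropna().to_numpy(float)
    if metric == "r_agnor":
        return ps[ps.channel == "agnor"].r.dropna().to_numpy(float)
    if metric == "nucleolus_dist":
        sel = ps[(ps.channel == "fish")].nucleolus_dist_norm
        return sel.dropna().to_numpy(float)
    if metric in ("d_norm", "alpha_deg"):
        sel = pn[~pn.n_fish_flag][metric]
        return sel.dropna().to_numpy(float)
    if metric == "S_agnor":
        return pn.S_agnor.dropna().to_numpy(float)
    if metric == "agnor_count":
        return pn.agnor_count.dropna().to_numpy(float)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def compare_tables(
    tables_a: tuple[pd.DataFrame, pd.DataFrame],
    tables_b: tuple[pd.DataFrame, pd.DataFrame],
    metrics=DEFAULT_METRICS,
    threshold: float = 0.75,
    seed: int = 0,
    min_group: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Metric-by-metric comparison of two measured populations.

    Returns the comparison table and a dict with the r-threshold
    fraction-split summary of each group.
    """
    rows = []
    for metric in metrics:
        a = _metric_values(tables_a[1], tables_a[0], metric)
        b = _metric_values(tables_b[1], tables_b[0], metric)
        if a.size < min_group or b.size < min_group:
            rows.append(dict(metric=metric, skipped=True, n_a=a.size, n_b=b.size))
            continue
        res = two_sample_compare(a, b)
        rows.append(dict(
            metric=metric, skipped=False, D=res.D, ks_sig=res.ks_sig, U=res.U, p=res.p,
            median_a=res.median_x, median_b=res.median_y, n_a=res.n_x, n_b=res.n_y,
            significant=res.significant,
        ))
    splits = {}
    for name, (pn, ps) in (("a", tables_a), ("b", tables_b)):
        fish = ps[(ps.channel == "fish") & (~ps.border_flag)]
        if not len(fish):
            splits[name] = dict(empty_group=True)
            continue
        sp = split_by_threshold(fish.r.to_numpy(float), fish.S_norm.to_numpy(float),
                                threshold=threshold, seed=seed)
        splits[name] = dict(
            threshold=sp.threshold,
            n_peripheral=int(sp.peripheral.size), n_interior=int(sp.interior.size),
            median_peripheral=sp.median_peripheral, median_interior=sp.median_interior,
            median_ratio=sp.median_ratio, ratio_ci=sp.ratio_ci,
            empty_group=sp.empty_group,
            comparison=sp.comparison.to_dict() if sp.comparison else None,
            tie_rule="ties at the threshold are assigned peripheral",
        )
    return pd.DataFrame(rows), splits


# ---------------------------------------------------------------------------
# full pipeline


def _population_spec(name: str, pop_cfg: dict, base_seed: int, index: int) -> PopulationSpec:
    overrides = dict(pop_cfg.get("overrides", {}))
    overrides.setdefault("seed", (int(base_seed) * 9973 + 101 * index + 1) % (2**31))
    if "condition" in pop_cfg:
        return condition_spec(pop_cfg["condition"], **overrides)
    if "spec" in pop_cfg:
        d = dict(pop_cfg["spec"])
        d.update(overrides)
        return PopulationSpec.from_dict(d)
    raise ValueError(f"population {name!r} needs a 'condition' or a 'spec' entry")


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the configured stages in order; write manifest last.

    Config keys: ``stages`` (subset of generate/segment/measure/compare/
    report, in canonical order), ``seed``, ``populations`` (mapping of
    name -> {"condition": ...} or {"spec": {...}}, plus optional
    "overrides"), ``segmentation`` (SegmentationConfig fields),
    ``compare`` ({"a": name, "b": name, "metrics": [...], "threshold"}),
    ``report`` ({"model_curve": "surface" | null}).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise StageError("config", f"unknown stages {unknown}")
    seed = int(config.get("seed", 0))
    populations = config.get("populations", {})
    if not populations:
        raise StageError("config", "config must declare at least one population")
    seg_cfg = SegmentationConfig(**config.get("segmentation", {}))
    counts: dict[str, dict] = {}
    t0 = time.time()

    if "generate" in stages:
        for i, (name, pop_cfg) in enumerate(populations.items()):
            spec = _population_spec(name, pop_cfg, seed, i)
            truth = write_population(spec, outdir / name)
            counts.setdefault(name, {})["generated_objects"] = int(len(truth))

    per_pop_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    if "segment" in stages or "measure" in stages:
        for name, pop_cfg in populations.items():
            imgdir = outdir / name / "images"
            if not imgdir.is_dir():
                raise StageError("segment", f"missing image directory: {imgdir}")
            kind = pop_cfg.get("geometry_kind")
            if kind is None:
                spec_path = outdir / name / "spec.json"
                kind = (PopulationSpec.from_json(spec_path).nucleus_shape
                        if spec_path.exists() else "circle")
            try:
                nuclei, blobs, boundaries = segment_directory(imgdir, seg_cfg, kind)
            except FileNotFoundError as exc:
                raise StageError("segment", str(exc)) from exc
            _float_csv(nuclei, outdir / name / "nuclei.csv")
            _float_csv(blobs, outdir / name / "blobs.csv")
            _float_csv(boundaries, outdir / name / "boundaries.csv")
            counts.setdefault(name, {})["segmented_nuclei"] = int(len(nuclei))
            counts[name]["segmented_blobs"] = int(len(blobs))

    if "measure" in stages:
        for name in populations:
            base = outdir / name
            for fname in ("nuclei.csv", "blobs.csv", "boundaries.csv"):
                if not (base / fname).exists():
                    raise StageError("measure", f"missing segmentation table: {base / fname}")
            nuclei = pd.read_csv(base / "nuclei.csv")
            blobs = pd.read_csv(base / "blobs.csv")
            boundaries = pd.read_csv(base / "boundaries.csv")
            per_nucleus, per_signal = measure_tables(nuclei, blobs, boundaries)
            _float_csv(per_nucleus, base / "per_nucleus.csv")
            _float_csv(per_signal, base / "per_signal.csv")
            per_pop_tables[name] = (per_nucleus, per_signal)
            counts.setdefault(name, {})["measured_nuclei"] = int(len(per_nucleus))
            counts[name]["flagged_n_fish"] = int(per_nucleus.n_fish_flag.sum()) if len(per_nucleus) else 0
            counts[name]["flagged_border"] = int(per_nucleus.border_flag.sum()) if len(per_nucleus) else 0

    if "compare" in stages:
        cmp_cfg = config.get("compare", {})
        names = list(populations)
        a = cmp_cfg.get("a", names[0])
        b = cmp_cfg.get("b", names[1] if len(names) > 1 else names[0])
        for name in (a, b):
            base = outdir / name
            if name not in per_pop_tables:
                for fname in ("per_nucleus.csv", "per_signal.csv"):
                    if not (base / fname).exists():
                        raise StageError("compare", f"missing measure table: {base / fname}")
                per_pop_tables[name] = (pd.read_csv(base / "per_nucleus.csv"),
                                        pd.read_csv(base / "per_signal.csv"))
        metrics = cmp_cfg.get("metrics", DEFAULT_METRICS)
        comparison, splits = compare_tables(
            per_pop_tables[a], per_pop_tables[b], metrics,
            threshold=float(cmp_cfg.get("threshold", 0.75)), seed=seed,
            min_group=int(cmp_cfg.get("min_group", 20)),
        )
        _float_csv(comparison, outdir / "comparison.csv")
        (outdir / "fraction_split.json").write_text(
            json.dumps({"group_a": a, "group_b": b, "splits": splits}, indent=2))
        for metric in metrics:
            rows = []
            for name in (a, b):
                vals = _metric_values(per_pop_tables[name][1], per_pop_tables[name][0], metric)
                if vals.size == 0:
                    continue
                upper = max(1.0, float(np.nanmax(vals)))
                edges, cum = cumulative_histogram(vals, bins=20, upper=upper)
                for e, c in zip(edges[1:], cum):
                    rows.append(dict(group=name, bin_upper=e, cumulative_count=int(c),
                                     n=int(vals.size)))
            if rows:
                _float_csv(pd.DataFrame(rows), outdir / f"hist_{metric}.csv")
        counts["compare"] = {"metrics": len(metrics)}

    if "report" in stages:
        from .report import render_report

        if not (outdir / "comparison.csv").exists():
            raise StageError("report", f"missing comparison output: {outdir/'comparison.csv'}")
        n_figs = render_report(outdir, model_curve=config.get("report", {}).get("model_curve"))
        counts["report"] = {"figures": n_figs}

    manifest = dict(
        tool="nucleotopo",
        version=__version__,
        config=config,
        seed=seed,
        stages=stages,
        started_unix=t0,
        finished_unix=time.time(),
        record_counts=counts,
        outputs={
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.rglob("*.csv"))
        },
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
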