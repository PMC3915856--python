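"""End-to-end study orchestration: generate -> quantify -> statistics.

``run_all`` drives a complete reproducible run from a validated YAML config:
it writes a synthetic study to disk, computes the wall-shear time-course from
the flow tables, quantifies marker intensity and PLA event densities from the
phantom images, and produces the statistical report tables (time-courses,
per-day tests against baseline, correlations against time and against wall
shear stress) plus a machine-readable run manifest (seed, config hash,
package version).  Each stage is independently callable on saved outputs;
re-running the statistics stage on saved quantification tables reproduces
the full run's statistics exactly.

``recover_marker_timecourse`` / ``recover_interaction_timecourse`` are
in-memory recovery experiments over a single arm (no disk I/O), used for
parameter-recovery validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .hemodynamics import FlowTrace, VesselGeometry, percent_change, wss_timecourse
from .if_quant import marker_timecourse, measure_if_specimen
from .pla_quant import (
    DEFAULT_MEDIAN_SPOT_AREA,
    DEFAULT_MIN_AREA,
    DEFAULT_SINGLE_MAX_AREA,
    DEFAULT_THRESHOLD,
    ImageStack,
    measure_pla_specimen,
    place_rois,
    pla_timecourse,
)
from .stats import correlate_timecourses, ttest_baseline
from .synthetic import (
    CalibrationProfile,
    VesselPhantom,
    compartment_masks,
    default_phantom,
    gen_study,
    iter_if_specimens,
    iter_pla_specimens,
    pla_default_phantom,
    small_phantom,
)

__all__ = [
    "StudyConfig",
    "StageError",
    "validate_config",
    "default_config_dict",
    "run_all",
    "recover_marker_timecourse",
    "recover_interaction_timecourse",
    "wss_stage",
    "if_stage",
    "pla_stage",
    "stats_stage",
]

log = logging.getLogger("avfstudy")

SCHEMA_VERSION = 1

_PHANTOM_PRESETS = {
    "default": default_phantom,
    "pla_default": pla_default_phantom,
    "small": small_phantom,
}

_PHANTOM_FIELDS = {
    "lumen_radius_px", "intima_thickness_px", "media_thickness_px",
    "pixel_size_um", "image_shape", "n_z_slices", "z_step_um",
}

_CALIBRATION_FIELDS = {
    "time_grid_days", "flow_baseline_ml_min", "flow_day0_factor",
    "flow_day42_fold", "wss_day0", "wss_day42", "plateau_after_day42",
    "marker_timecourses", "interaction_timecourses", "marker_base_fiu",
    "pla_base_rate_mm2", "nonspecific_rate_mm2", "marker_effect_compartment",
    "interaction_effect_compartment", "merged_fraction", "replicate_noise_cv",
    "rats_per_timepoint", "flow_rats_per_timepoint",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class StudyConfig:
    """A validated study configuration (see :func:`default_config_dict`)."""

    seed: int
    output_dir: Path
    profile: CalibrationProfile
    markers: list
    pairs: list
    if_phantom: VesselPhantom
    pla_phantom: VesselPhantom
    threshold: int = DEFAULT_THRESHOLD
    min_size: int = DEFAULT_MIN_AREA
    max_size: int = DEFAULT_SINGLE_MAX_AREA
    median_size: int = DEFAULT_MEDIAN_SPOT_AREA
    connectivity: int = 8
    alpha: float = 0.05
    variance_gate_alpha: float = 0.05
    welch: bool = False
    holm: bool = False
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def skimage_connectivity(self) -> int:
        return 2 if self.connectivity == 8 else 1


def default_config_dict() -> dict:
    """The shipped default configuration: every rule parameter at its
    protocol value (threshold 100, size gate 2-50 px, median event size
    10 px, alpha 0.05) and a reduced default arm list so a demonstration run
    stays quick."""
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": 1,
        "output_dir": "avfstudy_run",
        "calibration": {},
        "arms": {"markers": ["caspase3", "Notch1"], "pairs": ["Notch1-Delta1"]},
        "phantoms": {"if": {"preset": "default"}, "pla": {"preset": "pla_default"}},
        "pla_rules": {
            "threshold": 100, "min_size": 2, "max_size": 50,
            "median_size": 10, "connectivity": 8,
        },
        "stats": {
            "alpha": 0.05, "variance_gate_alpha": 0.05,
            "welch": False, "holm": False,
        },
    }


def _check_unknown(section, data, allowed, errors):
    for key in data:
        if key not in allowed:
            errors.append(f"{section}: unknown key {key!r}")


def _build_phantom(spec_dict, errors, section):
    if "preset" in spec_dict:
        extra = set(spec_dict) - {"preset"}
        if extra:
            errors.append(f"{section}: preset cannot be combined with {sorted(extra)}")
            return None
        name = spec_dict["preset"]
        if name not in _PHANTOM_PRESETS:
            errors.append(
                f"{section}: unknown preset {name!r}; "
                f"choose from {sorted(_PHANTOM_PRESETS)}"
            )
            return None
        return _PHANTOM_PRESETS[name]()
    _check_unknown(section, spec_dict, _PHANTOM_FIELDS, errors)
    try:
        kwargs = dict(spec_dict)
        if "image_shape" in kwargs:
            kwargs["image_shape"] = tuple(kwargs["image_shape"])
        return VesselPhantom(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def validate_config(source):
    """Validate a config mapping or YAML file path.

    Returns ``(StudyConfig, [])`` on success or ``(None, errors)`` with a
    complete list of schema violations.  Unknown keys anywhere are errors:
    typos never pass silently.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    errors: list[str] = []
    if not isinstance(data, dict):
        return None, ["config must be a mapping"]

    top_allowed = {"schema_version", "seed", "output_dir", "calibration",
                   "arms", "phantoms", "pla_rules", "stats"}
    _check_unknown("top level", data, top_allowed, errors)
    if data.get("schema_version") != SCHEMA_VERSION:
        errors.append(f"schema_version must be {SCHEMA_VERSION}")
    seed = data.get("seed")
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        errors.append("seed must be a non-negative integer")
    if not data.get("output_dir"):
        errors.append("output_dir is required")
    if "calibration" not in data:
        errors.append("calibration section is required (may be empty {})")

    cal = data.get("calibration") or {}
    profile = None
    if isinstance(cal, dict):
        _check_unknown("calibration", cal, _CALIBRATION_FIELDS, errors)
        try:
            profile = CalibrationProfile(
                seed=seed if isinstance(seed, int) else 0,
                **{k: v for k, v in cal.items() if k in _CALIBRATION_FIELDS},
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"calibration: {exc}")
    else:
        errors.append("calibration must be a mapping")

    arms = data.get("arms", {})
    _check_unknown("arms", arms, {"markers", "pairs"}, errors)
    markers = arms.get("markers")
    pairs = arms.get("pairs")
    if profile is not None:
        markers = list(profile.marker_timecourses) if markers is None else list(markers)
        pairs = list(profile.interaction_timecourses) if pairs is None else list(pairs)
        for m in markers:
            if m not in profile.marker_timecourses:
                errors.append(f"arms.markers: unknown marker {m!r}")
        for p in pairs:
            if p not in profile.interaction_timecourses:
                errors.append(f"arms.pairs: unknown pair {p!r}")

    phantoms = data.get("phantoms", {})
    _check_unknown("phantoms", phantoms, {"if", "pla"}, errors)
    if_phantom = _build_phantom(phantoms.get("if", {"preset": "default"}),
                                errors, "phantoms.if")
    pla_phantom = _build_phantom(phantoms.get("pla", {"preset": "pla_default"}),
                                 errors, "phantoms.pla")

    rules = data.get("pla_rules", {})
    _check_unknown("pla_rules", rules,
                   {"threshold", "min_size", "max_size", "median_size",
                    "connectivity"}, errors)
    threshold = rules.get("threshold", DEFAULT_THRESHOLD)
    min_size = rules.get("min_size", DEFAULT_MIN_AREA)
    max_size = rules.get("max_size", DEFAULT_SINGLE_MAX_AREA)
    median_size = rules.get("median_size", DEFAULT_MEDIAN_SPOT_AREA)
    connectivity = rules.get("connectivity", 8)
    if not isinstance(threshold, int) or not 0 <= threshold <= 255:
        errors.append("pla_rules.threshold must be an integer in [0, 255]")
    if not isinstance(min_size, int) or min_size < 1:
        errors.append("pla_rules.min_size must be an integer >= 1")
    if not isinstance(max_size, int) or max_size <= min_size:
        errors.append("pla_rules.max_size must be an integer > min_size")
    if not isinstance(median_size, int) or median_size < 1:
        errors.append("pla_rules.median_size must be an integer >= 1")
    if connectivity not in (4, 8):
        errors.append("pla_rules.connectivity must be 4 or 8")

    st = data.get("stats", {})
    _check_unknown("stats", st,
                   {"alpha", "variance_gate_alpha", "welch", "holm"}, errors)
    alpha = st.get("alpha", 0.05)
    gate_alpha = st.get("variance_gate_alpha", 0.05)
    for name, val in (("alpha", alpha), ("variance_gate_alpha", gate_alpha)):
        if not (isinstance(val, (int, float)) and 0 < val < 1):
            errors.append(f"stats.{name} must be in (0, 1)")

    if errors:
        return None, errors
    return (
        StudyConfig(
            seed=seed, output_dir=Path(data["output_dir"]), profile=profile,
            markers=markers, pairs=pairs, if_phantom=if_phantom,
            pla_phantom=pla_phantom, threshold=threshold, min_size=min_size,
            max_size=max_size, median_size=median_size,
            connectivity=connectivity, alpha=float(alpha),
            variance_gate_alpha=float(gate_alpha),
            welch=bool(st.get("welch", False)), holm=bool(st.get("holm", False)),
            raw=data,
        ),
        [],
    )


# ---------------------------------------------------------------------------
# stage implementations (each usable on saved outputs)
# ---------------------------------------------------------------------------

def wss_stage(flows: pd.DataFrame, geometry: pd.DataFrame,
              days_0_to_42=None) -> dict:
    """Per-rat shear estimates and the per-day wall-shear time-course.

    ``flows`` is long format (rat_id, day, vessel_label, t_s, flow_ml_min);
    ``geometry`` has one row per (rat_id, day) with internal_radius_cm and
    viscosity.
    """
    traces = []
    for (rat, day, label), sub in flows.groupby(["rat_id", "day", "vessel_label"]):
        sub = sub.sort_values("t_s")
        traces.append(FlowTrace(
            t_s=sub["t_s"].to_numpy(float),
            flow_ml_min=sub["flow_ml_min"].to_numpy(float),
            vessel_label=label, rat_id=rat, day=int(day),
        ))
    geometries = {
        (row.rat_id, int(row.day)): VesselGeometry(
            internal_radius_cm=float(row.internal_radius_cm),
            viscosity=float(row.viscosity))
        for row in geometry.itertuples()
    }
    timecourse = wss_timecourse(traces, geometries)
    flow_means = (
        flows.groupby(["rat_id", "day"])["flow_ml_min"].mean().reset_index()
        .groupby("day")["flow_ml_min"].agg(["count", "mean", "sem"]).reset_index()
        .rename(columns={"count": "n", "sem": "se"})
    )
    return {"wss_timecourse": timecourse, "flow_timecourse": flow_means}


def _rois_for(segmentation, pixel_size_um):
    return place_rois(segmentation, pixel_size_um)


def if_stage(manifest: pd.DataFrame, root) -> pd.DataFrame:
    """Quantify every immunofluorescence specimen listed in a manifest."""
    root = Path(root)
    sub = manifest[manifest["arm"] == "if"]
    rows = []
    for seg_file, seg_group in sub.groupby("segmentation"):
        seg = tifffile.imread(root / seg_file)
        pixel = float(seg_group["pixel_size_um"].iloc[0])
        rois = _rois_for(seg, pixel)
        for (name, rat, day), files in seg_group.groupby(["name", "rat_id", "day"]):
            by_channel = dict(zip(files["channel"], files["file"]))
            marker_img = ImageStack.load(root / by_channel["marker"], pixel)
            control_img = ImageStack.load(root / by_channel["primary_control"], pixel)
            rows.append(measure_if_specimen(
                marker_img, control_img, rois,
                keys={"marker": name, "rat_id": rat, "day": int(day)}))
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def pla_stage(manifest: pd.DataFrame, root, threshold=DEFAULT_THRESHOLD,
              min_size=DEFAULT_MIN_AREA, max_size=DEFAULT_SINGLE_MAX_AREA,
              median_size=DEFAULT_MEDIAN_SPOT_AREA, connectivity=2) -> pd.DataFrame:
    """Quantify every PLA specimen listed in a manifest."""
    root = Path(root)
    sub = manifest[manifest["arm"] == "pla"]
    rows = []
    for seg_file, seg_group in sub.groupby("segmentation"):
        seg = tifffile.imread(root / seg_file)
        pixel = float(seg_group["pixel_size_um"].iloc[0])
        rois = _rois_for(seg, pixel)
        for (name, rat, day), files in seg_group.groupby(["name", "rat_id", "day"]):
            by_channel = dict(zip(files["channel"], files["file"]))
            pla_img = ImageStack.load(root / by_channel["pla"], pixel)
            nc_img = ImageStack.load(root / by_channel["negative_control"], pixel)
            rows.append(measure_pla_specimen(
                pla_img, nc_img, rois, threshold=threshold, min_area=min_size,
                single_max_area=max_size, median_spot_area=median_size,
                connectivity=connectivity,
                keys={"pair": name, "rat_id": rat, "day": int(day)}))
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def stats_stage(wss_tables: dict, fiu: pd.DataFrame, pla: pd.DataFrame,
                baseline_day: int = -1, welch: bool = False) -> dict:
    """Time-courses, baseline tests and correlations from saved tables."""
    out = {}
    wss_tc = wss_tables["wss_timecourse"]
    flow_tc = wss_tables["flow_timecourse"]

    correlations = []
    early = [d for d in wss_tc["day"] if 0 <= d <= 42]
    corr = correlate_timecourses(
        wss_tc, wss_tc.assign(measure="wss"), mode="vs_time",
        by=["measure"], days=early)
    corr.insert(0, "table", "wss")
    correlations.append(corr)
    corr = correlate_timecourses(
        wss_tc, flow_tc.assign(measure="flow"),
        mode="vs_time", by=["measure"], days=early)
    corr.insert(0, "table", "flow")
    correlations.append(corr)

    tests = []

    def _baseline_tests(df, value, by, label):
        for key, sub in df.groupby(by):
            key_tuple = key if isinstance(key, tuple) else (key,)
            base = sub.loc[sub["day"] == baseline_day, value].to_numpy(float)
            if base.size < 2:
                continue
            for day in sorted(sub["day"].unique()):
                if day == baseline_day:
                    continue
                grp = sub.loc[sub["day"] == day, value].to_numpy(float)
                if grp.size < 2:
                    continue
                res = ttest_baseline(grp, base, welch=welch)
                row = dict(zip(by, key_tuple))
                row.update(table=label, day=day, method=res.method,
                           statistic=res.statistic, p_value=res.p_value)
                tests.append(row)

    if fiu is not None and len(fiu):
        fiu_tc = marker_timecourse(fiu, baseline_day=baseline_day)
        out["fiu_timecourse"] = fiu_tc
        _baseline_tests(fiu, "fiu_corrected", ["marker", "compartment"], "fiu")
        post = [d for d in fiu_tc["day"].unique() if d > 0]
        corr = correlate_timecourses(wss_tc, fiu_tc, mode="vs_time",
                                     by=["marker", "compartment"], days=post)
        corr.insert(0, "table", "fiu")
        correlations.append(corr)

    if pla is not None and len(pla):
        pla_tc = pla_timecourse(pla, baseline_day=baseline_day)
        out["pla_timecourse"] = pla_tc
        _baseline_tests(pla, "corrected_density", ["pair", "compartment"], "pla")
        post = [d for d in pla_tc["day"].unique() if d > 0]
        corr = correlate_timecourses(wss_tc, pla_tc, mode="vs_time",
                                     by=["pair", "compartment"], days=post)
        corr.insert(0, "table", "pla")
        correlations.append(corr)
        corr = correlate_timecourses(wss_tc, pla_tc, mode="vs_wss",
                                     by=["pair", "compartment"])
        corr.insert(0, "table", "pla")
        correlations.append(corr)
        # pooled WSS-interaction correlation across all pairs (endothelium)
        endo = pla_tc[pla_tc["compartment"] == "endothelium"].copy()
        if endo["pair"].nunique() > 1:
            pooled = endo.assign(pair="all_pairs")
            merged = pooled.merge(
                wss_tc[["day", "mean"]].rename(columns={"mean": "wss_mean"}),
                on="day")
            from .stats import pearson_corr
            res = pearson_corr(merged["wss_mean"], merged["mean"],
                               regression=True, pair="all_pairs vs_wss")
            correlations.append(pd.DataFrame([{
                "table": "pla", "pair": "all_pairs",
                "compartment": "endothelium", "mode": "vs_wss", "n": res.n,
                "r": res.r, "p_value": res.p_value, "slope": res.slope,
                "intercept": res.intercept,
            }]))

    out["tests"] = pd.DataFrame(tests)
    out["correlations"] = pd.concat(correlations, ignore_index=True)
    out["summary"] = _summary_table(wss_tc, flow_tc, out)
    return out


def _summary_table(wss_tc, flow_tc, tables) -> pd.DataFrame:
    """Headline quantities in one tidy (quantity, value) table."""
    rows = []

    def add(name, value):
        rows.append({"quantity": name, "value": float(value)})

    base = flow_tc.loc[flow_tc["day"] == flow_tc["day"].min()]
    add("flow_baseline_ml_min", base["mean"].iloc[0])
    if 0 in set(flow_tc["day"]):
        day0 = float(flow_tc.loc[flow_tc["day"] == 0, "mean"].iloc[0])
        add("flow_day0_pct_change",
            float(percent_change(day0, base["mean"].iloc[0])))
    for day in (0, 42, 84):
        sel = wss_tc.loc[wss_tc["day"] == day]
        if len(sel):
            add(f"wss_day{day}_dyn_cm2", sel["mean"].iloc[0])
    if {0, 42} <= set(wss_tc["day"]):
        w0 = float(wss_tc.loc[wss_tc["day"] == 0, "mean"].iloc[0])
        w42 = float(wss_tc.loc[wss_tc["day"] == 42, "mean"].iloc[0])
        add("wss_fold_day42_vs_day0", w42 / w0)
    corr = tables.get("correlations")
    if corr is not None:
        for row in corr.itertuples():
            key_parts = [str(getattr(row, k)) for k in ("marker", "pair", "measure")
                         if hasattr(row, k) and isinstance(getattr(row, k), str)]
            comp = getattr(row, "compartment", None)
            if isinstance(comp, str):
                key_parts.append(comp)
            add(f"r_{'_'.join(key_parts)}_{row.mode}", row.r)
    for tab, key in (("fiu_timecourse", "marker"), ("pla_timecourse", "pair")):
        tc = tables.get(tab)
        if tc is None:
            continue
        endo = tc[(tc["compartment"] == "endothelium") & (tc["day"] > 0)]
        for name, sub in endo.groupby(key):
            peak = sub.loc[sub["pct_change"].abs().idxmax()]
            add(f"{name}_peak_pct_change_day{int(peak['day'])}", peak["pct_change"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in-memory recovery experiments
# ---------------------------------------------------------------------------

def recover_marker_timecourse(profile: CalibrationProfile, marker: str,
                              phantom: VesselPhantom | None = None) -> pd.DataFrame:
    """Generate one marker's phantom arm in memory, quantify it, and return
    the recovered per-day time-course (mean, SE, percent change vs baseline)."""
    phantom = phantom or default_phantom()
    seg = compartment_masks(phantom)["segmentation"]
    rois = place_rois(seg, phantom.pixel_size_um)
    rows = []
    for rat, day, _levels, stack, ctrl in iter_if_specimens(profile, marker, phantom):
        rows.append(measure_if_specimen(
            stack, ctrl, rois, keys={"marker": marker, "rat_id": rat, "day": day}))
    return marker_timecourse(pd.concat(rows, ignore_index=True),
                             baseline_day=profile.baseline_day)


def recover_interaction_timecourse(
        profile: CalibrationProfile, pair: str,
        phantom: VesselPhantom | None = None,
        threshold=DEFAULT_THRESHOLD, min_size=DEFAULT_MIN_AREA,
        max_size=DEFAULT_SINGLE_MAX_AREA,
        median_size=DEFAULT_MEDIAN_SPOT_AREA) -> pd.DataFrame:
    """Generate one pair's PLA phantom arm in memory, count events, and
    return the recovered corrected-density time-course."""
    phantom = phantom or pla_default_phantom()
    seg = compartment_masks(phantom)["segmentation"]
    rois = place_rois(seg, phantom.pixel_size_um)
    rows = []
    for rat, day, _rates, pla, nc, _truth in iter_pla_specimens(profile, pair, phantom):
        rows.append(measure_pla_specimen(
            pla, nc, rois, threshold=threshold, min_area=min_size,
            single_max_area=max_size, median_spot_area=median_size,
            keys={"pair": pair, "rat_id": rat, "day": day}))
    return pla_timecourse(pd.concat(rows, ignore_index=True),
                          baseline_day=profile.baseline_day)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _config_hash(data: dict) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()


def run_all(config: StudyConfig) -> dict:
    """Run generate -> WSS -> IF -> PLA -> stats and write the report bundle.

    Returns a dict of output paths.  On stage failure an ``INVALID`` marker
    file naming the failed stage is left in the output directory and a
    :class:`StageError` is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    paths = {}
    stage = "generate"
    try:
        t0 = time.perf_counter()
        dataset = out / "dataset"
        manifest = gen_study(config.profile, dataset, markers=config.markers,
                             pairs=config.pairs, if_phantom=config.if_phantom,
                             pla_phantom=config.pla_phantom)
        log.info("generate: %d images in %.1fs", len(manifest),
                 time.perf_counter() - t0)

        stage = "wss"
        t0 = time.perf_counter()
        flows = pd.read_csv(dataset / "flows.csv")
        geometry = pd.read_csv(dataset / "geometry.csv")
        wss_tables = wss_stage(flows, geometry)
        wss_tables["wss_timecourse"].to_csv(out / "wss.csv", index=False)
        wss_tables["flow_timecourse"].to_csv(out / "flow.csv", index=False)
        paths["wss"] = out / "wss.csv"
        log.info("wss: %d days in %.1fs", len(wss_tables["wss_timecourse"]),
                 time.perf_counter() - t0)

        stage = "ifquant"
        t0 = time.perf_counter()
        fiu = if_stage(manifest, dataset)
        fiu.to_csv(out / "fiu.csv", index=False)
        paths["fiu"] = out / "fiu.csv"
        log.info("ifquant: %d rows in %.1fs", len(fiu), time.perf_counter() - t0)

        stage = "pla"
        t0 = time.perf_counter()
        pla = pla_stage(manifest, dataset, threshold=config.threshold,
                        min_size=config.min_size, max_size=config.max_size,
                        median_size=config.median_size,
                        connectivity=config.skimage_connectivity)
        pla.to_csv(out / "pla.csv", index=False)
        paths["pla"] = out / "pla.csv"
        log.info("pla: %d rows in %.1fs", len(pla), time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        # statistics always run from the saved CSVs so that an isolated
        # re-run of this stage reproduces the bundle byte for byte
        tables = stats_stage(
            {"wss_timecourse": pd.read_csv(out / "wss.csv"),
             "flow_timecourse": pd.read_csv(out / "flow.csv")},
            pd.read_csv(out / "fiu.csv"), pd.read_csv(out / "pla.csv"),
            baseline_day=config.profile.baseline_day,
            welch=config.welch)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            paths[name] = out / f"{name}.csv"
        log.info("stats: %d result tables in %.1fs", len(tables),
                 time.perf_counter() - t0)

        manifest_info = {
            "seed": config.seed,
            "config_sha256": _config_hash(config.raw),
            "version": __version__,
            "n_images": int(len(manifest)),
            "markers": list(config.markers),
            "pairs": list(config.pairs),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest_info, fh, indent=2, sort_keys=True)
        paths["run_manifest"] = out / "run_manifest.json"
        return paths
    except Exception as exc:
        (out / "INVALID").write_text(
            f"stage {stage} failed: {exc}\npartial outputs are invalid\n")
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
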