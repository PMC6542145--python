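"""Config-driven end-to-end orchestration.

Stages: simulate (or load) a two-timepoint cohort -> fit voxel-wise
parameter maps -> place lesion ROIs and extract per-patient marker values
-> group statistics and ROC evaluation -> JSON report + CSV cohort table.
Every random choice descends from the single master seed, so a fixed
config reproduces the report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import load_volume, save_parameter_maps, save_volume
from .models import DKIParams, fit_parameter_maps
from .phantom import (
    CohortSpec,
    MarkerMeans,
    SimulatedCohort,
    simulate_cohort,
)
from .roi import extract_measurement, place_rois
from .scheme import AcquisitionScheme
from .stats import (
    DEFAULT_POLARITY,
    MarkerSeries,
    delong_test,
    evaluate_marker,
    paired_t_test,
    two_sample_t_test,
)

logger = logging.getLogger("liverdki")

MARKERS = ("adc", "md", "mk")
TIMEPOINTS = ("pre", "post")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (one input mode, mandatory seed)."""

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "results/run"
    b_values: tuple[float, ...] = (0.0, 800.0, 1500.0, 2000.0)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None
    refine_fit: bool = False
    roi_area_bounds_cm2: tuple[float, float] = (1.0, 2.5)
    save_maps: bool = False
    save_signals: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        cohort = d.pop("cohort")
        gm = cohort.pop("group_means")
        cohort["group_means"] = {
            grp: {tp: dict(md=m["md"], mk=m["mk"], adc=m["adc"])
                  for (g, tp), m in sorted(gm.items()) if g == grp}
            for grp in ("recurrence", "non-recurrence")
        }
        for key in ("background", "necrosis"):
            p = cohort[key]
            cohort[key] = dict(s0=p["s0"], d=p["d"], k=p["k"])
        d["cohort"] = cohort
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        issues = validate_config(raw)
        if issues:
            raise ValueError("invalid configuration:\n" + "\n".join(f"- {i}" for i in issues))
        raw = dict(raw)
        cohort_raw = dict(raw.pop("cohort", {}))
        gm_raw = cohort_raw.pop("group_means", None)
        kwargs: dict[str, Any] = {}
        for key in (
            "n_patients", "recurrence_fraction", "sd_fraction", "adc_jitter_sd",
            "snr", "noise_model", "diam_mean_cm", "diam_sd_cm", "lesion_s0",
            "post_necrosis_fraction",
        ):
            if key in cohort_raw:
                kwargs[key] = cohort_raw[key]
        for key in ("grid_shape", "spacing", "diam_bounds_cm", "recurrence_growth",
                    "nonrecurrence_growth"):
            if key in cohort_raw:
                kwargs[key] = tuple(cohort_raw[key])
        for key in ("background", "necrosis"):
            if key in cohort_raw:
                p = cohort_raw[key]
                kwargs[key] = DKIParams(p["s0"], p["d"], p["k"])
        if gm_raw is not None:
            kwargs["group_means"] = {
                (grp, tp): MarkerMeans(md=v["md"], mk=v["mk"], adc=v.get("adc"))
                for grp, tps in gm_raw.items()
                for tp, v in tps.items()
            }
        seed = int(raw.get("seed", 0))
        cohort = CohortSpec(seed=seed, **kwargs)
        cfg_kwargs: dict[str, Any] = {"cohort": cohort, "seed": seed}
        for key in ("mode", "out_dir", "input_dir", "refine_fit", "save_maps",
                    "save_signals", "log_level"):
            if key in raw:
                cfg_kwargs[key] = raw[key]
        if "b_values" in raw:
            cfg_kwargs["b_values"] = tuple(raw["b_values"])
        if "roi_area_bounds_cm2" in raw:
            cfg_kwargs["roi_area_bounds_cm2"] = tuple(raw["roi_area_bounds_cm2"])
        return cls(**cfg_kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_config_file(path))

    @property
    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(self.b_values)


def load_config_file(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def validate_config(config: dict[str, Any] | RunConfig | str | Path) -> list[str]:
    """Collect every configuration violation (empty list = valid).

    Accepts a raw dict, a path to a YAML/JSON file, or a built RunConfig;
    the input is never mutated.
    """
    if isinstance(config, RunConfig):
        config = config.to_dict()
    elif isinstance(config, (str, Path)):
        config = load_config_file(config)
    issues: list[str] = []
    mode = config.get("mode", "simulate")
    if mode not in ("simulate", "load"):
        issues.append(f"mode: must be 'simulate' or 'load', got {mode!r}")
    if mode == "simulate":
        if config.get("input_dir"):
            issues.append("input_dir: must be unset in simulate mode (exactly one input mode)")
        if "seed" in config and not isinstance(config["seed"], int):
            issues.append("seed: must be an integer in simulate mode")
    if mode == "load" and not config.get("input_dir"):
        issues.append("input_dir: required in load mode")
    b = config.get("b_values")
    if b is not None:
        b = list(b)
        if len(b) < 3:
            issues.append("b_values: kurtosis fitting needs at least 3 b-values")
        if b and b[0] != 0:
            issues.append("b_values: first value must be 0")
        if any(y <= x for x, y in zip(b, b[1:])):
            issues.append("b_values: must be strictly ascending")
    cohort = config.get("cohort", {})
    frac = cohort.get("recurrence_fraction")
    if frac is not None and not 0 <= frac <= 1:
        issues.append(f"cohort.recurrence_fraction: must lie in [0, 1], got {frac}")
    if cohort.get("n_patients") is not None and cohort["n_patients"] < 1:
        issues.append("cohort.n_patients: must be >= 1")
    if cohort.get("sd_fraction") is not None and cohort["sd_fraction"] < 0:
        issues.append("cohort.sd_fraction: must be >= 0")
    if cohort.get("snr") is not None and cohort["snr"] <= 0:
        issues.append("cohort.snr: must be > 0")
    if cohort.get("noise_model") not in (None, "rician", "gaussian", "none"):
        issues.append(f"cohort.noise_model: unknown model {cohort.get('noise_model')!r}")
    gm = cohort.get("group_means")
    if gm:
        for grp, tps in gm.items():
            for tp, v in tps.items():
                if v.get("md", 1) <= 0 or not 0 <= v.get("mk", 0) <= 3:
                    issues.append(f"cohort.group_means.{grp}.{tp}: md must be > 0, mk in [0, 3]")
    bounds = config.get("roi_area_bounds_cm2")
    if bounds is not None:
        lo, hi = bounds
        if not 0 < lo <= hi:
            issues.append("roi_area_bounds_cm2: need 0 < lower <= upper")
    return issues


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _load_cohort(config: RunConfig) -> SimulatedCohort:
    """Load mode: read a manifest of NIfTI volumes and masks from disk."""
    from .phantom import PatientScan, PhantomTruth

    root = Path(config.input_dir)  # type: ignore[arg-type]
    manifest = pd.read_csv(root / "manifest.csv")
    scheme = AcquisitionScheme.from_bval_file(root / "bvals")
    if tuple(scheme.b_values) != tuple(config.b_values):
        raise ValueError("bvals file disagrees with configured b_values")
    scans: dict[tuple[str, str], PatientScan] = {}
    rows = []
    for _, row in manifest.iterrows():
        vol, spacing = load_volume(root / row["volume"])
        lesion, _ = load_volume(root / row["lesion_mask"])
        necrosis = np.zeros_like(lesion)
        if isinstance(row.get("necrosis_mask"), str) and row["necrosis_mask"]:
            necrosis, _ = load_volume(root / row["necrosis_mask"])
        if vol.ndim == 4 and vol.shape[2] == 1:  # stored planar
            vol, lesion, necrosis = vol[:, :, 0, :], lesion[:, :, 0], necrosis[:, :, 0]
            spacing = spacing[:2]
        truth = PhantomTruth(
            s0=np.full(lesion.shape, np.nan), d=np.full(lesion.shape, np.nan),
            k=np.full(lesion.shape, np.nan), lesion_mask=lesion > 0.5,
            necrosis_mask=necrosis > 0.5, spacing=tuple(spacing),
            background_s0=float(np.nanmedian(vol[..., 0])),
        )
        scans[(row["patient_id"], row["timepoint"])] = PatientScan(truth=truth, signal=vol)
        rows.append({k: row.get(k) for k in
                     ("patient_id", "group", "timepoint", "diam_baseline", "diam_followup")})
    table = pd.DataFrame(rows)
    for col in ("true_adc", "true_md", "true_mk"):
        table[col] = np.nan
    return SimulatedCohort(table=table, scans=scans, warnings=[])


def _measure_cohort(config: RunConfig, cohort: SimulatedCohort) -> pd.DataFrame:
    """Fit maps and extract ROI measurements for every scan."""
    scheme = config.scheme
    table = cohort.table.copy()
    for col in ("meas_adc", "meas_md", "meas_mk", "meas_diameter_cm"):
        table[col] = np.nan
    table["protocol_deviation"] = False
    roi_seeds = np.random.SeedSequence(config.seed + 1).generate_state(len(table))
    out_dir = Path(config.out_dir)
    rois_json: dict[str, Any] = {}
    for i, row in table.iterrows():
        key = (row["patient_id"], row["timepoint"])
        scan = cohort.scans[key]
        # only lesion voxels feed the ROI statistics; restricting the fit to
        # the lesion keeps the optional non-linear refinement affordable
        maps = fit_parameter_maps(
            scan.signal, scheme, mask=scan.truth.lesion_mask,
            spacing=scan.truth.spacing, refine=config.refine_fit,
        )
        rois = place_rois(
            scan.truth.lesion_mask, scan.truth.necrosis_mask, scan.truth.spacing,
            area_bounds_cm2=config.roi_area_bounds_cm2, seed=int(roi_seeds[i] % 2**31),
        )
        meas = extract_measurement(maps, rois, scan.truth.lesion_mask)
        for marker in MARKERS:
            table.loc[i, f"meas_{marker}"] = meas.means[marker]
        table.loc[i, "meas_diameter_cm"] = meas.diameter_cm
        table.loc[i, "protocol_deviation"] = meas.protocol_deviation
        rois_json[f"{key[0]}_{key[1]}"] = json.loads(rois.to_json())
        if config.save_maps:
            save_parameter_maps(maps, out_dir / "maps", f"{key[0]}_{key[1]}")
        if config.save_signals:
            save_volume(out_dir / "signals" / f"{key[0]}_{key[1]}.nii",
                        scan.signal, scan.truth.spacing)
        logger.debug("measured %s/%s", *key)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "rois.json").write_text(json.dumps(rois_json, indent=2))
    return table


def compute_statistics(table: pd.DataFrame, value_prefix: str = "meas") -> dict[str, Any]:
    """Marker statistics on a cohort table (per patient per timepoint rows).

    Uses columns ``{prefix}_{marker}``; labels come from ``group``.
    Returns group means, paired pre/post t-tests, Welch between-group
    tests, per-timepoint ROC evaluations and post-RFA DeLong comparisons.
    """
    wide = table.pivot_table(
        index=["patient_id", "group"], columns="timepoint",
        values=[f"{value_prefix}_{m}" for m in MARKERS], aggfunc="first",
    )
    labels = np.array([g == "recurrence" for _, g in wide.index])

    def col(marker: str, tp: str) -> np.ndarray:
        return wide[(f"{value_prefix}_{marker}", tp)].to_numpy(dtype=float)

    out: dict[str, Any] = {
        "n": int(len(wide)),
        "n_recurrence": int(labels.sum()),
        "n_nonrecurrence": int((~labels).sum()),
        "group_means": {}, "paired_tests": {}, "between_group_tests": {}, "roc": {},
        "delong": {},
    }
    out["recurrence_rate_pct"] = 100.0 * labels.sum() / len(wide)
    series: dict[tuple[str, str], MarkerSeries] = {}
    for tp in TIMEPOINTS:
        out["group_means"][tp] = {}
        out["between_group_tests"][tp] = {}
        out["roc"][tp] = {}
        for marker in MARKERS:
            v = col(marker, tp)
            out["group_means"][tp][marker] = {
                "recurrence": float(np.mean(v[labels])),
                "non-recurrence": float(np.mean(v[~labels])),
            }
            try:
                tt = two_sample_t_test(v[labels], v[~labels])
                out["between_group_tests"][tp][marker] = dict(t=tt.t, df=tt.df, p=tt.p)
            except ValueError as exc:
                out["between_group_tests"][tp][marker] = {"error": str(exc)}
            s = MarkerSeries(v, labels, polarity=DEFAULT_POLARITY[marker],
                             name=f"{tp}_{marker}")
            series[(tp, marker)] = s
            try:
                r = evaluate_marker(s)
                out["roc"][tp][marker] = {
                    "auc": r.auc, "se": r.se, "ci": list(r.ci),
                    "youden": asdict(r.youden), "n_pos": r.n_pos, "n_neg": r.n_neg,
                    "polarity": r.polarity,
                }
            except ValueError as exc:
                out["roc"][tp][marker] = {"error": str(exc)}
    for marker in MARKERS:
        try:
            tt = paired_t_test(col(marker, "pre"), col(marker, "post"))
            out["paired_tests"][marker] = dict(t=tt.t, df=tt.df, p=tt.p)
        except ValueError as exc:
            out["paired_tests"][marker] = {"error": str(exc)}
    for other in ("adc", "md"):
        try:
            res = delong_test(series[("post", "mk")], series[("post", other)])
            out["delong"][f"post_mk_vs_{other}"] = dict(
                auc_mk=res.auc_a, **{f"auc_{other}": res.auc_b}, z=res.z, p=res.p
            )
        except ValueError as exc:
            out["delong"][f"post_mk_vs_{other}"] = {"error": str(exc)}
    return out


def _sanitize(obj: Any) -> Any:
    """Replace non-finite floats so the report is strict JSON."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and write cohort.csv, rois.json and report.json.

    Any stage failure aborts with a stage-tagged :class:`PipelineError`
    after writing an incomplete report marker.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import scipy

    report: dict[str, Any] = {
        "status": "incomplete",
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": {
            "liverdki": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
        },
        "stages": [],
    }

    def fail(stage: str, exc: Exception) -> PipelineError:
        report["status"] = f"incomplete:{stage}"
        report["error"] = str(exc)
        (out_dir / "report.json").write_text(json.dumps(_sanitize(report), indent=2))
        return PipelineError(stage, str(exc))

    try:
        if config.mode == "simulate":
            spec = replace(config.cohort, seed=config.seed)
            cohort = simulate_cohort(spec, scheme=config.scheme, with_images=True)
        else:
            cohort = _load_cohort(config)
        report["stages"].append("cohort")
        report["cohort_warnings"] = cohort.warnings
    except PipelineError:
        raise
    except Exception as exc:
        raise fail("cohort", exc) from exc

    try:
        table = _measure_cohort(config, cohort)
        report["stages"].append("measure")
    except Exception as exc:
        raise fail("measure", exc) from exc

    try:
        stats = compute_statistics(table, value_prefix="meas")
        if np.isfinite(table["true_md"]).all():
            stats["true_group_means"] = compute_statistics(
                table, value_prefix="true"
            )["group_means"]
        report["statistics"] = stats
        report["stages"].append("stats")
    except Exception as exc:
        raise fail("stats", exc) from exc

    table.to_csv(out_dir / "cohort.csv", index=False)
    report["status"] = "complete"
    report["outputs"] = {
        "cohort_csv": str(out_dir / "cohort.csv"),
        "rois_json": str(out_dir / "rois.json"),
        "report_json": str(out_dir / "report.json"),
    }
    report = _sanitize(report)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline complete: %s", out_dir / "report.json")
    return report
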