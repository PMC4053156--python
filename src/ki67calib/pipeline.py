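"""End-to-end experiment orchestration.

Runs the whole validation methodology on a simulated cohort: generate one
synthetic TMA spot per case with a right-skewed labelling-index
distribution, obtain stereological reference counts (with optional
imperfect observers), run the image-analysis profiles, compare methods
(ANOVA/Duncan, correlations, forward and orthogonal regression, confidence
ellipses and accuracy factors, Bland-Altman), calibrate the detector
settings against the references, fit inverse-regression corrections and
report dichotomization accuracy at clinical cutoffs.

Everything is deterministic given the experiment seed: per-spot randomness
is derived through ``numpy.random.SeedSequence([seed, spot_index])``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .correction import (apply_correction, dichotomize_and_report,
                         fit_inverse_regression, fit_joint_model)
from .dia import PROFILES, CalibrationResult, calibrate_settings, run_dia
from .errors import ConfigError, Ki67CalibError, UndefinedLIError
from .method_comparison import (anova_duncan, bland_altman,
                                confidence_ellipse, correlation_matrix,
                                fit_ols, fit_orthogonal, variability_profile)
from .stereology import (CEParams, build_grid, ci_agreement, grid_count)
from .synthetic import (ObserverErrorModel, SpotSpec, generate_spot,
                        simulate_observer_counts, TUMOUR_POSITIVE,
                        TUMOUR_NEGATIVE)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "summarize_methods"]


@dataclass(frozen=True)
class ObserverSpec:
    """Error level of one simulated human counter."""

    miss_prob: float = 0.02
    class_flip_prob: float = 0.01


def _default_observers():
    return (ObserverSpec(), ObserverSpec(), ObserverSpec())


def _default_calibration_space():
    return {"min_nuclear_size_um2": (20.0, 40.0, 45.0),
            "weak_threshold": (200.0, 210.0, 229.0)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Study design: one spot per simulated case.

    ``spot`` is a template; per-spot seed, true LI (scaled
    Beta(li_alpha, li_beta), right-skewed like clinical Ki67 cohorts) and
    lymphocyte admixture (uniform over ``lymphocyte_density_range``) are
    drawn per case.
    """

    n_spots: int = 164
    seed: int = 42
    spot: SpotSpec = field(default_factory=SpotSpec)
    li_alpha: float = 1.0
    li_beta: float = 1.7
    lymphocyte_density_range: tuple[float, float] = (0.0, 300.0)
    frame_size_px: int = 125
    spacing_px: int = 250
    random_grid_offset: bool = True
    ce: CEParams = field(default_factory=CEParams)
    rule: str = "simple"
    min_overlap_fraction: float = 0.0
    observers: tuple[ObserverSpec, ...] = field(default_factory=_default_observers)
    ve_observer: ObserverSpec = field(
        default_factory=lambda: ObserverSpec(miss_prob=0.25,
                                             class_flip_prob=0.05))
    dia_profiles: tuple[str, ...] = ("DIA-0", "DIA-1")
    calibration_space: dict | None = field(
        default_factory=_default_calibration_space)
    calibration_base: str = "DIA-1"
    calibration_n_spots: int = 20
    primary_method: str = "dia_cal"
    cutoffs: tuple[float, ...] = (10.0, 15.0, 20.0)
    fit_range_upper: float = 40.0
    mask_mode: str = "oracle"

    def __post_init__(self):
        if self.n_spots < 1:
            raise ConfigError("n_spots must be >= 1")
        for p in self.dia_profiles:
            if p not in PROFILES:
                raise ConfigError(f"unknown DIA profile {p!r}")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load a config from JSON or YAML."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "spot" in raw:
            raw["spot"] = SpotSpec.from_json(json.dumps(raw["spot"]))
        if "ce" in raw:
            raw["ce"] = CEParams(**raw["ce"])
        if "observers" in raw:
            raw["observers"] = tuple(ObserverSpec(**o) for o in raw["observers"])
        if "ve_observer" in raw:
            raw["ve_observer"] = ObserverSpec(**raw["ve_observer"])
        for key in ("dia_profiles", "cutoffs", "lymphocyte_density_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("calibration_space"):
            raw["calibration_space"] = {
                k: tuple(v) for k, v in raw["calibration_space"].items()}
        return cls(**raw)


@dataclass
class ExperimentReport:
    """All tables and fitted models of one experiment run."""

    config: ExperimentConfig
    measurements: pd.DataFrame          # rows = spots, columns = methods
    grid_details: pd.DataFrame          # per spot x observer grid-count rows
    summary: pd.DataFrame
    anova: object
    correlations: pd.DataFrame
    fits: dict
    agreement: object
    variability: pd.DataFrame | None
    calibration: CalibrationResult | None
    correction_models: dict
    corrected: pd.DataFrame
    dichotomization: pd.DataFrame
    warnings: list
    metadata: dict

    def to_dir(self, out_dir) -> None:
        """Serialize every table deterministically (CSV + sorted JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index_label="spot")
        self.grid_details.to_csv(out / "grid_counts.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index_label="method")
        self.correlations.to_csv(out / "correlations.csv", index_label="method")
        self.corrected.to_csv(out / "corrected.csv", index_label="spot")
        self.dichotomization.to_csv(out / "dichotomization.csv", index=False)
        blobs = {
            "anova.json": None if self.anova is None else {
                "f": self.anova.f_statistic, "p": self.anova.p_value,
                "letters": dict(self.anova.letters),
                "means": {k: float(v) for k, v in self.anova.means.items()},
            },
            "fits.json": self.fits,
            "agreement.json": None if self.agreement is None else {
                "n_spots": self.agreement.n_spots,
                "pairwise": {f"{i}-{j}": v
                             for (i, j), v in self.agreement.pairwise.items()},
                "all_way": self.agreement.all_way,
            },
            "correction_models.json": self.correction_models,
            "metadata.json": self.metadata,
        }
        for name, obj in blobs.items():
            (out / name).write_text(json.dumps(obj, sort_keys=True, indent=1,
                                               default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def summarize_methods(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method median, mean, SD, SE, min, max (NaN-aware)."""
    df = pd.DataFrame(table)
    if df.empty:
        raise ConfigError("empty measurement table")
    rows = {}
    for col in df.columns:
        v = df[col].dropna()
        n = len(v)
        sd = float(v.std(ddof=1)) if n > 1 else 0.0
        rows[col] = {
            "median": float(v.median()), "mean": float(v.mean()),
            "sd": sd, "se": sd / np.sqrt(n) if n else np.nan,
            "min": float(v.min()), "max": float(v.max()), "n": n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _spot_spec_for(config: ExperimentConfig, index: int) -> SpotSpec:
    ss = np.random.SeedSequence([config.seed, index])
    rng = np.random.default_rng(ss)
    li = 100.0 * float(rng.beta(config.li_alpha, config.li_beta))
    lo, hi = config.lymphocyte_density_range
    lymph = float(rng.uniform(lo, hi))
    seed = int(ss.generate_state(1)[0] >> 1)     # keep below 2**31
    return replace(config.spot, seed=seed, true_li_percent=li,
                   lymphocyte_density_per_mm2=lymph)


def _spot_rng(config: ExperimentConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index, 1]))


def _measure_spot(config: ExperimentConfig, index: int, spot,
                  dia_settings: dict):
    """All per-spot measurements; returns (row dict, grid rows, observer results)."""
    rng = _spot_rng(config, index)
    size = spot.spec.image_size_px
    offset = (int(rng.integers(config.spacing_px)),
              int(rng.integers(config.spacing_px))) \
        if config.random_grid_offset else (0, 0)
    grid = build_grid((size, size), config.frame_size_px, config.spacing_px,
                      offset)
    row: dict = {"true_li": spot.true_li_percent}
    grid_rows = []
    obs_results = []
    warnings = []
    try:
        ref = grid_count(spot, grid, config.rule, config.ce,
                         min_overlap_fraction=config.min_overlap_fraction)
        row["reference"] = ref.li_percent
        row["reference_ce"] = ref.ce
        grid_rows.append({"spot": index, "observer": "reference",
                          **ref.as_row()})
    except UndefinedLIError as exc:
        warnings.append(f"spot {index}: reference count undefined ({exc})")
        ref = None
        row["reference"] = np.nan
        row["reference_ce"] = np.nan
    for j, ob in enumerate(config.observers, start=1):
        try:
            res = grid_count(
                spot, grid, config.rule, config.ce,
                observer=ObserverErrorModel(
                    ob.miss_prob, ob.class_flip_prob,
                    seed=int(rng.integers(2 ** 31))),
                min_overlap_fraction=config.min_overlap_fraction)
            row[f"count_{j}"] = res.li_percent
            grid_rows.append({"spot": index, "observer": f"count_{j}",
                              **res.as_row()})
            obs_results.append(res)
        except UndefinedLIError as exc:
            warnings.append(f"spot {index}: observer {j} undefined ({exc})")
            row[f"count_{j}"] = np.nan
            obs_results.append(None)
    # visual estimate: whole-spot impression with heavy observer error,
    # reported to the nearest 5%
    pos = sum(1 for c in spot.truth if c.cell_class == TUMOUR_POSITIVE)
    neg = sum(1 for c in spot.truth if c.cell_class == TUMOUR_NEGATIVE)
    ve = config.ve_observer
    p2, n2 = simulate_observer_counts(
        pos, neg, ObserverErrorModel(ve.miss_prob, ve.class_flip_prob,
                                     seed=int(rng.integers(2 ** 31))))
    if p2 + n2 > 0:
        row["ve"] = float(np.clip(5.0 * round(100.0 * p2 / (p2 + n2) / 5.0),
                                  0.0, 100.0))
    else:
        row["ve"] = np.nan
    for name, settings in dia_settings.items():
        try:
            row[name] = run_dia(spot, settings, config.mask_mode).li_percent
        except (UndefinedLIError, Ki67CalibError) as exc:
            warnings.append(f"spot {index}: {name} undefined ({exc})")
            row[name] = np.nan
    return row, grid_rows, obs_results, warnings


def _calibrate(config: ExperimentConfig) -> CalibrationResult | None:
    if not config.calibration_space:
        return None
    n_cal = min(config.calibration_n_spots, config.n_spots)
    spots, refs = [], []
    for i in range(n_cal):
        spot = generate_spot(_spot_spec_for(config, i))
        rng = _spot_rng(config, i)
        size = spot.spec.image_size_px
        offset = (int(rng.integers(config.spacing_px)),
                  int(rng.integers(config.spacing_px))) \
            if config.random_grid_offset else (0, 0)
        grid = build_grid((size, size), config.frame_size_px,
                          config.spacing_px, offset)
        try:
            refs.append(grid_count(
                spot, grid, config.rule, config.ce,
                min_overlap_fraction=config.min_overlap_fraction).li_percent)
            spots.append(spot)
        except UndefinedLIError:
            continue
    if len(spots) < 3:
        return None
    return calibrate_settings(spots, refs, dict(config.calibration_space),
                              base=PROFILES[config.calibration_base],
                              mask_mode=config.mask_mode)


def run_experiment(config: ExperimentConfig,
                   out_dir=None) -> ExperimentReport:
    """Execute every stage; deterministic given ``config``.

    When ``out_dir`` is given the report is also serialized there.
    """
    calibration = _calibrate(config)
    dia_settings = {p.lower().replace("-", "_"): PROFILES[p]
                    for p in config.dia_profiles}
    if calibration is not None:
        dia_settings["dia_cal"] = calibration.settings

    rows, grid_rows, per_spot_obs, warnings = [], [], [], []
    for i in range(config.n_spots):
        spot = generate_spot(_spot_spec_for(config, i))
        row, g_rows, obs, warn = _measure_spot(config, i, spot, dia_settings)
        rows.append(row)
        grid_rows.extend(g_rows)
        per_spot_obs.append(obs)
        warnings.extend(warn)

    measurements = pd.DataFrame(rows)
    method_cols = [c for c in measurements.columns
                   if c not in ("true_li", "reference_ce")]
    summary = summarize_methods(measurements[method_cols])

    complete = measurements[method_cols].dropna()
    anova = anova_duncan(complete) if len(complete) >= 2 else None
    correlations = (correlation_matrix(complete) if len(complete) >= 3
                    else pd.DataFrame())

    fits = {}
    for col in method_cols:
        if col == "reference":
            continue
        both = measurements[["reference", col, "reference_ce"]].dropna()
        if len(both) < 3 or both["reference"].nunique() < 2:
            continue
        x, y = both["reference"].to_numpy(), both[col].to_numpy()
        ols = fit_ols(x, y)
        ba = bland_altman(x, y)
        entry = {
            "n": int(len(both)),
            "ols": {"slope": ols.slope, "intercept": ols.intercept,
                    "r_square": ols.r_square, "slope_p": ols.slope_p,
                    "intercept_p": ols.intercept_p,
                    "standardized_slope": ols.standardized_slope},
            "bland_altman": {"mean_difference": ba.mean_difference,
                             "sd_difference": ba.sd_difference,
                             "loa_low": ba.loa_low, "loa_high": ba.loa_high},
        }
        try:
            orth = fit_orthogonal(x, y)
            entry["orthogonal"] = {"slope": orth.slope,
                                   "intercept": orth.intercept,
                                   "tilt_deg": orth.line_tilt_deg}
        except Ki67CalibError:
            orth = None
        try:
            ell = confidence_ellipse(np.column_stack((x, y)),
                                     ce_per_point=both["reference_ce"])
            entry["ellipse"] = {"centre": ell.centre,
                                "major": ell.major_axis_length,
                                "minor": ell.minor_axis_length,
                                "tilt_deg": ell.tilt_deg}
            tilt_line = float(np.degrees(np.arctan(ols.slope)))
            if 0 < tilt_line < 90 and 0 < ell.tilt_deg < 90:
                entry["accuracy_factor"] = tilt_line / ell.tilt_deg
                if orth is not None and 0 < orth.line_tilt_deg < 90:
                    entry["accuracy_factor_orthogonal"] = (
                        orth.line_tilt_deg / ell.tilt_deg)
        except Ki67CalibError:
            pass
        fits[col] = entry

    # inter-observer agreement and variability (spots where all observers valid)
    agreement = None
    obs_cols = [c for c in method_cols if c.startswith("count_")]
    variability = None
    if len(obs_cols) >= 2:
        valid = [obs for obs in per_spot_obs
                 if obs and all(o is not None for o in obs)]
        if valid:
            agreement = ci_agreement(valid)
        variability = variability_profile(measurements[obs_cols].dropna())

    # inverse-regression correction on the primary method
    correction_models: dict = {}
    corrected = pd.DataFrame(index=measurements.index)
    dich_rows = []
    primary = config.primary_method if config.primary_method in measurements \
        else next((c for c in ("dia_cal", "dia_1", "dia_0")
                   if c in measurements), None)
    if primary is not None:
        both = measurements[["reference", primary]].dropna()
        if len(both) >= 3:
            x = both[primary].to_numpy()
            r = both["reference"].to_numpy()
            full = fit_inverse_regression(x, r)
            correction_models[primary] = {
                "slope": full.slope, "intercept": full.intercept,
                "fit_range_upper": None,
                "r_square": full.source_fit.r_square}
            corrected.loc[both.index, f"{primary}_corrected"] = \
                apply_correction(full, x)
            try:
                restricted = fit_inverse_regression(
                    x, r, fit_range_upper=config.fit_range_upper)
                correction_models[f"{primary}_lt{config.fit_range_upper:g}"] = {
                    "slope": restricted.slope,
                    "intercept": restricted.intercept,
                    "fit_range_upper": config.fit_range_upper,
                    "r_square": restricted.source_fit.r_square}
                corrected.loc[both.index, f"{primary}_corrected_lt"] = \
                    apply_correction(restricted, x)
            except Ki67CalibError:
                restricted = None
            if "ve" in measurements:
                trio = measurements[["reference", primary, "ve"]].dropna()
                if len(trio) >= 4:
                    try:
                        joint = fit_joint_model(trio[primary], trio["ve"],
                                                trio["reference"])
                        correction_models["joint"] = {
                            "intercept": joint.intercept,
                            **{f"coef_{k}": v
                               for k, v in joint.coefficients.items()},
                            "r_square": joint.r_square}
                    except Ki67CalibError:
                        pass
            # dichotomization accuracy at the clinical cutoffs
            candidates = {primary: x}
            for col in corrected.columns:
                candidates[col] = corrected.loc[both.index, col].to_numpy()
            if "ve" in measurements:
                ve_both = measurements[["reference", "ve"]].dropna()
                for cutoff in config.cutoffs:
                    rep = dichotomize_and_report(ve_both["ve"],
                                                 ve_both["reference"], cutoff)
                    dich_rows.append({"method": "ve", **rep.as_row()})
            for name, vals in candidates.items():
                for cutoff in config.cutoffs:
                    rep = dichotomize_and_report(vals, r, cutoff)
                    dich_rows.append({"method": name, **rep.as_row()})
    dichotomization = pd.DataFrame(dich_rows)

    metadata = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "n_spots": config.n_spots,
        "primary_method": primary,
        "n_warnings": len(warnings),
        "warnings": warnings,
    }
    report = ExperimentReport(
        config=config, measurements=measurements,
        grid_details=pd.DataFrame(grid_rows), summary=summary, anova=anova,
        correlations=correlations, fits=fits, agreement=agreement,
        variability=variability, calibration=calibration,
        correction_models=correction_models, corrected=corrected,
        dichotomization=dichotomization, warnings=warnings,
        metadata=metadata)
    if out_dir is not None:
        report.to_dir(out_dir)
    return report
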