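"""Model evaluation metrics, RPD grading and the end-to-end pipeline.

Six indicators evaluate a calibration/prediction pair:

    Rc   = 1 - sum_i (y_ia - y_ip)^2 / sum_i (y_ia - y_cm)^2   (calibration)
    RMSECV = sqrt( sum_i (y_ia - y_ip)^2 / n )                 (out-of-fold)
    Rp   = 1 - sum_j (y_ja - y_jp)^2 / sum_j (y_ja - y_pm)^2   (prediction)
    RMSEP  = sqrt( sum_j (y_ja - y_jp)^2 / m )
    RPD    = SD_pred / RMSEP      (SD_pred: sample s.d. of prediction refs)
    Bias   = mean_j (y_ja - y_jp)

Because the "correlation coefficient" label is ambiguous in the
chemometrics literature, a plain Pearson r is reported alongside the
coefficient-of-determination forms above.  RPD grading: < 1.5 not usable,
1.5-2.0 rough, 2.0-2.5 quantitative, >= 2.5 excellent (lower-inclusive).

:func:`run_pipeline` composes synth -> optics -> partition -> preprocess ->
select -> models -> evaluate with a strict leakage discipline: the split
happens before preprocessing statistics or wavelength selection, the MSC
reference is the calibration mean frozen for prediction rows, and a
non-finite feature matrix is an explicit refusal, never a silent NaN.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as models_mod
from . import select as select_mod
from .optics import build_datasets
from .partition import stratified_split
from .preprocess import NonFiniteError, PreprocessSpec, apply_preprocess, msc
from .synth import CohortConfig, generate_cohort, read_cohort

__all__ = [
    "EvaluationSet",
    "EvaluationReport",
    "PipelineStageError",
    "PipelineResult",
    "compute_metrics",
    "rpd_grade",
    "build_report",
    "run_pipeline",
]

REPORT_COLUMNS = [
    "combination", "LVs_or_hparams", "Rc", "RMSECV", "Rp", "RMSEP", "RPD",
    "Bias", "grade",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class EvaluationSet:
    """Reference/predicted pairs for one role (calibration or prediction)."""

    y_a: np.ndarray
    y_p: np.ndarray
    role: str  # calibration | prediction

    def __post_init__(self):
        self.y_a = np.asarray(self.y_a, float).ravel()
        self.y_p = np.asarray(self.y_p, float).ravel()
        if self.y_a.size != self.y_p.size:
            raise ValueError("reference and predicted vectors differ in length")
        if self.y_a.size < 2:
            raise ValueError("need at least 2 samples")
        if self.role not in ("calibration", "prediction"):
            raise ValueError("role must be calibration or prediction")

    @property
    def n(self):
        return self.y_a.size

    @property
    def mean_reference(self):
        return float(self.y_a.mean())

    @property
    def sd_reference(self):
        """Sample (m-1) standard deviation of the reference values."""
        return float(np.std(self.y_a, ddof=1))


@dataclass
class EvaluationReport:
    combination: str
    Rc: float
    RMSECV: float
    Rp: float
    RMSEP: float
    RPD: float
    Bias: float
    rpd_grade: str
    hyperparameters: str = ""
    pearson_r_cal: float = float("nan")
    pearson_r_pred: float = float("nan")
    extras: dict = field(default_factory=dict)

    def row(self):
        return {
            "combination": self.combination,
            "LVs_or_hparams": self.hyperparameters,
            "Rc": self.Rc,
            "RMSECV": self.RMSECV,
            "Rp": self.Rp,
            "RMSEP": self.RMSEP,
            "RPD": self.RPD,
            "Bias": self.Bias,
            "grade": self.rpd_grade,
        }


def _r_squared_form(y_a, y_p, mean_ref):
    ss_res = float(np.sum((y_a - y_p) ** 2))
    ss_tot = float(np.sum((y_a - mean_ref) ** 2))
    if ss_tot == 0:
        raise ValueError("reference values are constant: R undefined (SStot = 0)")
    return 1.0 - ss_res / ss_tot


def _pearson(a, b):
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def rpd_grade(rpd):
    """Map an RPD value to its qualitative grade (boundaries lower-inclusive)."""
    if not rpd >= 0:
        raise ValueError(f"RPD must be non-negative, got {rpd}")
    if rpd < 1.5:
        return "not_usable"
    if rpd < 2.0:
        return "rough"
    if rpd < 2.5:
        return "quantitative"
    return "excellent"


def compute_metrics(cal: EvaluationSet, pred: EvaluationSet, combination=""):
    """All six indicators for one calibration/prediction pair.

    ``cal.y_p`` should hold out-of-fold cross-validation predictions so that
    RMSECV is a genuine cross-validation error.
    """
    if cal.role != "calibration" or pred.role != "prediction":
        raise ValueError("expected (calibration, prediction) evaluation sets")
    Rc = _r_squared_form(cal.y_a, cal.y_p, cal.mean_reference)
    RMSECV = float(np.sqrt(np.mean((cal.y_a - cal.y_p) ** 2)))
    Rp = _r_squared_form(pred.y_a, pred.y_p, pred.mean_reference)
    RMSEP = float(np.sqrt(np.mean((pred.y_a - pred.y_p) ** 2)))
    RPD = float("inf") if RMSEP == 0 else pred.sd_reference / RMSEP
    Bias = float(np.mean(pred.y_a - pred.y_p))
    return EvaluationReport(
        combination,
        Rc,
        RMSECV,
        Rp,
        RMSEP,
        RPD,
        Bias,
        rpd_grade(RPD),
        pearson_r_cal=_pearson(cal.y_a, cal.y_p),
        pearson_r_pred=_pearson(pred.y_a, pred.y_p),
    )


def build_report(reports):
    """Comparison table over (preprocess x selector x model) combinations.

    Returns a DataFrame in the standard column order with the best row
    (lowest RMSEP, ties to higher Rp) flagged.
    """
    if not reports:
        raise ValueError("no reports to tabulate")
    df = pd.DataFrame([r.row() for r in reports], columns=REPORT_COLUMNS)
    best = df.sort_values(["RMSEP", "Rp"], ascending=[True, False]).index[0]
    df["best"] = False
    df.loc[best, "best"] = True
    return df


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    reports: list
    table: pd.DataFrame  # sample table with set assignment
    failures: list  # [{combination, stage, detail}]
    artifacts: dict

    def report_frame(self):
        return build_report(self.reports)


_DEF_SELECT = {"method": "CARS"}
_DEF_MODEL = {"method": "PLSR"}


def _as_list(x, default):
    if x is None:
        return [dict(default)]
    if isinstance(x, dict):
        return [x]
    return [dict(d) for d in x]


def _fit_model(name, X, y, params, seed):
    cv = models_mod.CvSpec(params.get("cv_folds", 10), seed)
    if name == "PLSR":
        return models_mod.fit_plsr(X, y, params.get("max_lv", 15), cv)
    if name == "MLR":
        return models_mod.fit_mlr(X, y)
    if name == "PCR":
        return models_mod.fit_pcr(X, y, params.get("variance_threshold", 0.95))
    if name == "SVR":
        return models_mod.fit_svr(X, y, cv=cv)
    raise ValueError(f"unknown model {name!r}")


def _oof_fitter(name, model, params, seed):
    """Fold fitter for out-of-fold calibration predictions.

    Centering/scaling/coefficients (and the PLSR LV choice and PCR component
    count) are refit inside each fold; SVR reuses the (C, gamma) pair chosen
    on the calibration set — re-running the 256-point grid search per fold
    would multiply its cost tenfold for a near-identical choice.
    """
    if name != "SVR":
        return lambda A, b: _fit_model(name, A, b, params, seed)
    h = model.hyperparameters

    def fit_fixed(A, b):
        from sklearn.svm import SVR as _SkSVR

        A = np.asarray(A, float)
        mu, sg = A.mean(axis=0), A.std(axis=0)
        sg[sg < 1e-15] = 1.0
        est = _SkSVR(kernel="rbf", C=h["C"], gamma=h["gamma"], epsilon=h["epsilon"])
        est.fit((A - mu) / sg, b)
        return models_mod.RegressionModel(
            "SVR", {"estimator": est, "x_mean": mu, "x_scale": sg}, dict(h)
        )

    return fit_fixed


def _run_selector(name, X, y, freq, seed, params):
    p = dict(params)
    p.pop("method", None)
    if name == "none":
        return None
    if name == "CARS":
        cfg = select_mod.CarsConfig(
            n_runs=p.get("n_runs", 100),
            max_lv=p.get("max_lv", 10),
            cv_folds=p.get("cv_folds", 10),
            mc_fraction=p.get("mc_fraction", 0.8),
            seed=seed,
        )
        return select_mod.cars(X, y, cfg, freq)
    if name == "SPA":
        return select_mod.spa(
            X, y, p.get("k_min", 1), p.get("k_max"), p.get("cv_folds", 10), freq
        )
    if name == "GA":
        return select_mod.ga_select(X, y, seed=seed, freq_THz=freq, **p)
    if name == "BOSS":
        return select_mod.boss(X, y, seed=seed, freq_THz=freq, **p)
    raise ValueError(f"unknown selector {name!r}")


def run_pipeline(config, outdir=None):
    """Execute the full analysis described by a config mapping.

    Config keys (all optional except a data source):
      ``seed``; ``simulate`` (CohortConfig fields) or ``cohort_dir``;
      ``dataset`` (one of the four optical parameters, default absorption);
      ``screening`` {snr_floor_db}; ``split`` {ratio}; ``preprocess`` (one
      PreprocessSpec mapping or a list); ``select`` (mapping/list with
      ``method`` in none|SPA|CARS|GA|BOSS plus selector options); ``model``
      (mapping/list with ``method`` in PLSR|MLR|PCR|SVR plus options);
      ``rc_mode`` ("cv" default, or "insample").

    Combinations are the cross product of the preprocess/select/model lists.
    A combination whose feature matrix fails the finiteness check is recorded
    under ``failures`` (no metrics row), mirroring how non-finite spectra
    invalidate external prediction; other stage errors abort with the stage
    name.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            text = fh.read()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    config = dict(config)
    seed = int(config.get("seed", 0))

    # --- data source -------------------------------------------------------
    try:
        if "cohort_dir" in config:
            table, traces, reference, cohort_cfg = read_cohort(config["cohort_dir"])
            if reference is None:
                raise ValueError("cohort directory lacks a REF trace")
        else:
            sim = dict(config.get("simulate", {}))
            sim.setdefault("seed", seed)
            cohort_cfg = CohortConfig(**sim)
            table, traces, reference = generate_cohort(cohort_cfg)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("synth", str(e)) from e

    # --- optics ------------------------------------------------------------
    scr = dict(config.get("screening", {}))
    try:
        datasets = build_datasets(
            traces,
            reference,
            table,
            snr_floor_dB=scr.get("snr_floor_db", 10.0),
            fresnel=scr.get("fresnel", False),
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("optics", str(e)) from e
    param = config.get("dataset", "absorption")
    if param not in datasets:
        raise PipelineStageError("optics", f"unknown dataset {param!r}")
    ds = datasets[param]
    freq, X_full = ds.valid()
    delta = float(freq[1] - freq[0]) if freq.size > 1 else 1.0
    ids = list(ds.sample_ids)
    y_all = table.set_index("sample_id").loc[ids, "ash_true"].to_numpy(float)

    pre_list = _as_list(config.get("preprocess"), {"method": "SG"})
    sel_list = _as_list(config.get("select"), _DEF_SELECT)
    mod_list = _as_list(config.get("model"), _DEF_MODEL)
    rc_mode = config.get("rc_mode", "cv")

    # --- split (before preprocessing statistics / selection) ---------------
    # KS distances live in spectral space; row-wise operators carry no
    # cross-sample statistics, so the first row-independent preprocessing of
    # the sweep informs the distances (MSC would leak and falls back to raw).
    split_cfg = dict(config.get("split", {}))
    first = PreprocessSpec(**{k: v for k, v in pre_list[0].items()})
    try:
        if first.method == "MSC":
            X_dist = X_full
        else:
            X_dist, dist_rep = apply_preprocess(X_full, first, delta)
            if not dist_rep.ok:  # KS needs finite rows; fall back to raw
                X_dist = X_full
        assignment = stratified_split(
            X_dist, table, ratio=split_cfg.get("ratio", 3.0)
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("partition", str(e)) from e
    table = assignment.apply(table)
    cal_rows = np.array([i for i, s in enumerate(ids) if s in set(assignment.calibration_ids)])
    pred_rows = np.array([i for i, s in enumerate(ids) if s in set(assignment.prediction_ids)])

    reports, failures = [], []
    artifacts = {
        "assignment": assignment,
        "datasets": datasets,
        "selections": {},
        "models": {},
        "config": config,
    }
    for pre_params in pre_list:
        spec = PreprocessSpec(**pre_params)
        label_pre = spec.method
        try:
            if spec.method == "MSC":
                ref_spectrum = X_full[cal_rows].mean(axis=0)  # calibration mean only
                Xp, rep = msc(X_full, ref_spectrum)
            else:
                Xp, rep = apply_preprocess(X_full, spec, delta)
        except Exception as e:  # noqa: BLE001
            failures.append({"combination": label_pre, "stage": "preprocess",
                             "detail": str(e)})
            continue
        if not rep.ok:
            failures.append(
                {"combination": label_pre, "stage": "assert_finite",
                 "detail": rep.summary()}
            )
            continue
        X_cal, y_cal = Xp[cal_rows], y_all[cal_rows]
        X_pred, y_pred = Xp[pred_rows], y_all[pred_rows]
        for sel_params in sel_list:
            sel_name = sel_params.get("method", "CARS")
            try:
                sel = _run_selector(sel_name, X_cal, y_cal, freq, seed, sel_params)
            except Exception as e:  # noqa: BLE001
                failures.append(
                    {"combination": f"{label_pre}-{sel_name}", "stage": "select",
                     "detail": str(e)}
                )
                continue
            cols = np.arange(X_cal.shape[1]) if sel is None else sel.chosen
            label_sel = f"{label_pre}-{sel_name}"
            artifacts["selections"][label_sel] = sel
            for mod_params in mod_list:
                mod_name = mod_params.get("method", "PLSR")
                label = f"{label_sel}-{mod_name}"
                try:
                    model = _fit_model(mod_name, X_cal[:, cols], y_cal, mod_params, seed)
                    cv = models_mod.CvSpec(mod_params.get("cv_folds", 10), seed)
                    oof = models_mod.cross_val_predictions(
                        _oof_fitter(mod_name, model, mod_params, seed),
                        X_cal[:, cols],
                        y_cal,
                        cv,
                    )
                    cal_pred = (
                        model.metadata.get("fitted") if rc_mode == "insample" else oof
                    )
                    yp = models_mod.predict(model, X_pred[:, cols])
                    report = compute_metrics(
                        EvaluationSet(y_cal, cal_pred, "calibration"),
                        EvaluationSet(y_pred, yp, "prediction"),
                        label,
                    )
                    report.hyperparameters = _hparam_label(model)
                    report.extras["n_variables"] = int(len(cols))
                    reports.append(report)
                    artifacts["models"][label] = model
                except (NonFiniteError, models_mod.ModelRefusalError, ValueError) as e:
                    failures.append(
                        {"combination": label, "stage": "fit", "detail": str(e)}
                    )

    result = PipelineResult(reports, table, failures, artifacts)
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _hparam_label(model):
    h = model.hyperparameters
    if model.method == "PLSR":
        return f"LVs={h['n_lv']}"
    if model.method == "PCR":
        return f"PCs={h['n_pc']}"
    if model.method == "SVR":
        return f"C={h['C']:g},gamma={h['gamma']:g}"
    return "-"


def _write_outputs(result: PipelineResult, outdir):
    os.makedirs(outdir, exist_ok=True)
    result.table.to_csv(os.path.join(outdir, "samples.csv"), index=False,
                        lineterminator="\n")
    if result.reports:
        result.report_frame().to_csv(
            os.path.join(outdir, "report.csv"), index=False, lineterminator="\n"
        )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(
            {
                "reports": [r.row() for r in result.reports],
                "failures": result.failures,
            },
            fh,
            indent=2,
            default=str,
        )
    assignment = result.artifacts["assignment"]
    with open(os.path.join(outdir, "split.json"), "w") as fh:
        fh.write(assignment.to_json())
    for label, sel in result.artifacts["selections"].items():
        if sel is None:
            continue
        safe = label.replace("/", "_")
        with open(os.path.join(outdir, f"selection_{safe}.json"), "w") as fh:
            json.dump(sel.to_json_dict(), fh, indent=2)
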