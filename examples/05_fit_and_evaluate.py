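"""Fit the four regression models on one selected-variable matrix and grade them.

Metrics: Rc/RMSECV on out-of-fold calibration predictions, Rp/RMSEP/RPD/Bias
on the held-out prediction set; RPD >= 2.5 grades as "excellent".
"""
import numpy as np

from thzash import (CvSpec, EvaluationSet, compute_metrics, cross_val_predictions,
                    fit_mlr, fit_pcr, fit_plsr, planted_cohort, predict)

X, y, info, _ = planted_cohort(seed=5)
cols = np.concatenate(info)  # suppose a selector chose the informative bands
cal, pred = np.arange(0, 90), np.arange(90, 120)
Xc, yc, Xp, yp = X[cal][:, cols], y[cal], X[pred][:, cols], y[pred]

for name, fitter in [
    ("PLSR", lambda A, b: fit_plsr(A, b, 10, CvSpec(10, 5))),
    ("MLR", lambda A, b: fit_mlr(A, b)),
    ("PCR", lambda A, b: fit_pcr(A, b, 0.95)),
]:
    model = fitter(Xc, yc)
    oof = cross_val_predictions(fitter, Xc, yc, CvSpec(10, 5))
    rep = compute_metrics(
        EvaluationSet(yc, oof, "calibration"),
        EvaluationSet(yp, predict(model, Xp), "prediction"),
        name,
    )
    print(f"{name:4s}  Rc={rep.Rc:.3f} RMSECV={rep.RMSECV:.4f}%  "
          f"Rp={rep.Rp:.3f} RMSEP={rep.RMSEP:.4f}%  RPD={rep.RPD:.2f} "
          f"({rep.rpd_grade})")
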