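"""External-validation statistics for observed/predicted activity pairs.

Implements the Golbraikh–Tropsha criteria, the r2m metrics, the
Q2_F1/F2/F3 external predictivity coefficients, and Lin's concordance
correlation coefficient, over a prediction table with train/test flags.

Axis conventions, which the QSAR literature never fixes uniformly, are
pinned down here once:

* ``k``   — slope of the through-origin regression of predicted on
  observed, sum(y*yhat)/sum(y^2).
* ``k'``  — the mirrored slope, sum(y*yhat)/sum(yhat^2).
* ``r0'2`` — 1 - sum((y - k'*yhat)^2) / sum((y - ybar)^2): observed
  explained by the through-origin line in predicted.
* ``r02``  — the mirrored convention,
  1 - sum((yhat - k*y)^2) / sum((yhat - yhatbar)^2).

The r2m metric is computed in its square-root form,
r2m = r2 * (1 - sqrt(|r2 - r02|)); the linear variant (without the
square root) is also reported under an explicit label because both
appear in print.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Raised when a constant vector makes a correlation undefined."""


def _validate(y_obs, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_obs, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape or y.ndim != 1:
        raise ValueError("equal-length 1D vectors required")
    if len(y) < 3:
        raise ValueError("at least three pairs required")
    if np.ptp(y) == 0 or np.ptp(yh) == 0:
        raise UndefinedMetricError("constant vector: correlation undefined")
    return y, yh


def regression_metrics(y_obs, y_pred) -> dict[str, float]:
    """Pearson r2 plus the through-origin slopes and r02 pair."""
    y, yh = _validate(y_obs, y_pred)
    r2 = float(np.corrcoef(y, yh)[0, 1] ** 2)
    k = float((y * yh).sum() / (y * y).sum())
    k_prime = float((y * yh).sum() / (yh * yh).sum())
    ss_y = float(((y - y.mean()) ** 2).sum())
    ss_yh = float(((yh - yh.mean()) ** 2).sum())
    r0_prime2 = 1.0 - float(((y - k_prime * yh) ** 2).sum()) / ss_y
    r02 = 1.0 - float(((yh - k * y) ** 2).sum()) / ss_yh
    return {"r2": r2, "k": k, "k_prime": k_prime, "r02": r02, "r0_prime2": r0_prime2}


def rm2_metrics(y_obs, y_pred) -> dict[str, float]:
    """r2m metrics in both axis conventions and their spread.

    ``rm2`` puts experimental values on the ordinate (uses r02);
    ``rm2_prime`` on the abscissa (uses r0'2).  ``delta_rm2`` is their
    absolute difference.  The ``*_linear`` variants drop the square root.
    """
    m = regression_metrics(y_obs, y_pred)
    r2 = m["r2"]
    rm2 = r2 * (1.0 - np.sqrt(abs(r2 - m["r02"])))
    rm2_prime = r2 * (1.0 - np.sqrt(abs(r2 - m["r0_prime2"])))
    return {
        "rm2": float(rm2),
        "rm2_prime": float(rm2_prime),
        "delta_rm2": float(abs(rm2 - rm2_prime)),
        "rm2_linear": float(r2 * (1.0 - abs(r2 - m["r02"]))),
        "rm2_prime_linear": float(r2 * (1.0 - abs(r2 - m["r0_prime2"]))),
    }


def ccc(y_obs, y_pred) -> float:
    """Lin's concordance correlation coefficient.

    Penalizes both scatter and location/scale shift:
    CCC = 2*S_xy / (S_xx + S_yy + n*(xbar - ybar)^2).
    """
    y, yh = _validate(y_obs, y_pred)
    n = len(y)
    sxy = float(((y - y.mean()) * (yh - yh.mean())).sum())
    sxx = float(((y - y.mean()) ** 2).sum())
    syy = float(((yh - yh.mean()) ** 2).sum())
    return 2.0 * sxy / (sxx + syy + n * (y.mean() - yh.mean()) ** 2)


# ---------------------------------------------------------------------------
# Prediction tables


@dataclass
class PredictionTable:
    """Observed/predicted pIC50 pairs with train/test flags."""

    frame: pd.DataFrame  # columns: id, observed, predicted, subset

    def __post_init__(self) -> None:
        required = {"id", "observed", "predicted", "subset"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"prediction table missing columns {sorted(missing)}")
        subsets = set(self.frame["subset"])
        if not subsets <= {"train", "test"}:
            raise ValueError(f"subset flags must be train/test, got {subsets}")

    @classmethod
    def from_file(cls, path) -> "PredictionTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, ids, observed, predicted, subset) -> "PredictionTable":
        return cls(
            pd.DataFrame(
                {"id": ids, "observed": observed, "predicted": predicted, "subset": subset}
            )
        )

    @property
    def train(self) -> pd.DataFrame:
        return self.frame[self.frame["subset"] == "train"]

    @property
    def test(self) -> pd.DataFrame:
        return self.frame[self.frame["subset"] == "test"]

    @property
    def residuals(self) -> pd.Series:
        return self.frame["observed"] - self.frame["predicted"]


def qf_metrics(table: PredictionTable) -> dict[str, float]:
    """The three external predictivity coefficients Q2_F1, Q2_F2, Q2_F3.

    F1 scales the test-set squared error by spread around the *training*
    mean, F2 by spread around the *test* mean, and F3 compares mean
    squared errors: test MSE over training activity variance.
    """
    test, train = table.test, table.train
    if len(test) < 3:
        raise ValueError("at least three test rows required")
    if len(train) == 0:
        raise ValueError("training rows required for Q2_F1 and Q2_F3")
    y = test["observed"].to_numpy(float)
    yh = test["predicted"].to_numpy(float)
    y_tr = train["observed"].to_numpy(float)
    press = float(((y - yh) ** 2).sum())
    qf1 = 1.0 - press / float(((y - y_tr.mean()) ** 2).sum())
    qf2 = 1.0 - press / float(((y - y.mean()) ** 2).sum())
    qf3 = 1.0 - (press / len(y)) / (
        float(((y_tr - y_tr.mean()) ** 2).sum()) / len(y_tr)
    )
    return {"qf1": qf1, "qf2": qf2, "qf3": qf3}


# ---------------------------------------------------------------------------
# Golbraikh–Tropsha verdict and the full report

GT_THRESHOLDS = {
    "q2": 0.5,
    "r2": 0.6,
    "ratio": 0.1,
    "k_low": 0.85,
    "k_high": 1.15,
    "r0_gap": 0.3,
}


def golbraikh_tropsha(metrics: dict[str, float], q2: float) -> dict[str, bool]:
    """Condition-by-condition predictivity verdict.

    Conditions: q2 > 0.5; r2 > 0.6; (r2-r02)/r2 < 0.1 or the primed
    analogue; one of the through-origin slopes within [0.85, 1.15];
    |r02 - r0'2| < 0.3.  Overall pass requires all of them.
    """
    r2 = metrics["r2"]
    cond = {
        "q2_gt_0.5": q2 > GT_THRESHOLDS["q2"],
        "r2_gt_0.6": r2 > GT_THRESHOLDS["r2"],
        "r0_ratio_lt_0.1": (
            (r2 - metrics["r02"]) / r2 < GT_THRESHOLDS["ratio"]
            or (r2 - metrics["r0_prime2"]) / r2 < GT_THRESHOLDS["ratio"]
        ),
        "slope_in_band": (
            GT_THRESHOLDS["k_low"] <= metrics["k"] <= GT_THRESHOLDS["k_high"]
            or GT_THRESHOLDS["k_low"] <= metrics["k_prime"] <= GT_THRESHOLDS["k_high"]
        ),
        "r0_gap_lt_0.3": abs(metrics["r02"] - metrics["r0_prime2"])
        < GT_THRESHOLDS["r0_gap"],
    }
    cond["overall"] = all(cond.values())
    return cond


@dataclass
class ValidationReport:
    """All external-validation parameters with pass/fail verdicts."""

    values: dict[str, float]
    conditions: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("q2", ">0.5", self.values["q2"], self.values["q2"] > 0.5),
            ("r2", ">0.6", self.values["r2"], self.values["r2"] > 0.6),
            ("r02", "close to r2", self.values["r02"], None),
            ("r0_prime2", "close to r2", self.values["r0_prime2"], None),
            ("k", "0.85<k<1.15", self.values["k"], 0.85 < self.values["k"] < 1.15),
            (
                "k_prime",
                "0.85<k'<1.15",
                self.values["k_prime"],
                0.85 < self.values["k_prime"] < 1.15,
            ),
            (
                "(r2-r02)/r2",
                "<0.1",
                self.values["r02_ratio"],
                self.values["r02_ratio"] < 0.1,
            ),
            (
                "(r2-r0'2)/r2",
                "<0.1",
                self.values["r0_prime2_ratio"],
                self.values["r0_prime2_ratio"] < 0.1,
            ),
            (
                "|r02-r0'2|",
                "<0.3",
                self.values["r0_gap"],
                self.values["r0_gap"] < 0.3,
            ),
            ("rm2", ">0.5", self.values["rm2"], self.values["rm2"] > 0.5),
            ("qf1", ">0.7", self.values["qf1"], self.values["qf1"] > 0.7),
            ("qf2", ">0.7", self.values["qf2"], self.values["qf2"] > 0.7),
            ("qf3", ">0.7", self.values["qf3"], self.values["qf3"] > 0.7),
            ("ccc", ">0.85", self.values["ccc"], self.values["ccc"] > 0.85),
            (
                "delta_rm2",
                "<0.2",
                self.values["delta_rm2"],
                self.values["delta_rm2"] < 0.2,
            ),
        ]
        return pd.DataFrame(rows, columns=["parameter", "threshold", "value", "pass"])

    def to_file(self, path) -> None:
        frame = self.to_frame()
        frame["overall"] = self.conditions["overall"]
        frame.to_csv(path, sep="\t", index=False)


def validate(table: PredictionTable, q2: float) -> ValidationReport:
    """Full external-validation suite on a prediction table's test rows."""
    test = table.test
    y = test["observed"].to_numpy(float)
    yh = test["predicted"].to_numpy(float)
    reg = regression_metrics(y, yh)
    rm2 = rm2_metrics(y, yh)
    qf = qf_metrics(table)
    values = {
        "q2": q2,
        **reg,
        **rm2,
        **qf,
        "ccc": ccc(y, yh),
        "r02_ratio": (reg["r2"] - reg["r02"]) / reg["r2"],
        "r0_prime2_ratio": (reg["r2"] - reg["r0_prime2"]) / reg["r2"],
        "r0_gap": abs(reg["r02"] - reg["r0_prime2"]),
        "n_train": float(len(table.train)),
        "n_test": float(len(test)),
    }
    conditions = golbraikh_tropsha(reg, q2)
    return ValidationReport(values=values, conditions=conditions)
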