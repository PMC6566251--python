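"""Partial least squares on similarity-field descriptors.

The regression core is PLS1 via NIPALS on column-centered descriptors
and centered activities (no per-column variance scaling: fields enter on
their natural similarity-index scale).  Internal validation follows the
classical leave-one-out protocol: for each candidate component count c,

    q2(c)  = 1 - PRESS(c) / sum_i (y_i - ybar)^2
    SEP(c) = sqrt(PRESS(c) / (n - c - 1))

with the optimum component count N the argmax of q2 (ties broken toward
fewer components).  Fitted-model statistics mirror the conventional
QSAR report: r2_ncv, SEE = sqrt(RSS/(n-c-1)) and
F = (r2/c) / ((1-r2)/(n-c-1)).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fields import (
    FIELD_ORDER,
    DescriptorMatrix,
    FieldConfig,
    assemble_descriptor_matrix,
    build_lattice,
    prune_columns,
)
from .structures import Molecule


def _nipals_coefficients(
    Xc: np.ndarray, yc: np.ndarray, max_components: int
) -> np.ndarray:
    """Regression coefficient vectors for 1..A components, columns of (p, A).

    Deflation is performed once; coefficients for every intermediate
    component count come out of the same pass, which is what makes the
    leave-one-out scan affordable.
    """
    n, p = Xc.shape
    A = min(max_components, n - 1, p)
    if A < 1:
        raise ValueError("no PLS components computable for this problem size")
    X = Xc.copy()
    y = yc.astype(float).copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    n_eff = 0
    for a in range(A):
        w = X.T @ y
        wnorm = np.linalg.norm(w)
        if wnorm < 1e-12:
            break
        w /= wnorm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        P[:, a] = X.T @ t / tt
        q[a] = float(y @ t) / tt
        W[:, a] = w
        X = X - np.outer(t, P[:, a])
        y = y - q[a] * t
        n_eff = a + 1
    if n_eff == 0:
        raise ValueError("zero-variance response or descriptors; nothing to fit")
    B = np.zeros((p, n_eff))
    for a in range(1, n_eff + 1):
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        B[:, a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return B


@dataclass
class PLSModel:
    """A fitted centered PLS regression with its internal statistics."""

    n_components: int
    x_center: np.ndarray
    y_center: float
    coefficients: np.ndarray
    q2: float | None = None
    sep: float | None = None
    r2_ncv: float | None = None
    see: float | None = None
    f_value: float | None = None
    field_contributions: dict[str, float] | None = None

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_center + (X - self.x_center) @ self.coefficients


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a centered NIPALS PLS1 model with exactly ``n_components``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2D with one row per activity")
    if len(y) < 2:
        raise ValueError("need at least two training rows")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    if n_components > min(len(y) - 1, X.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)"
        )
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    B = _nipals_coefficients(X - x_center, y - y_center, n_components)
    if B.shape[1] < n_components:
        raise ValueError(
            f"descriptor rank supports only {B.shape[1]} components, "
            f"{n_components} requested"
        )
    return PLSModel(
        n_components=n_components,
        x_center=x_center,
        y_center=y_center,
        coefficients=B[:, n_components - 1],
    )


@dataclass
class LooResult:
    q2: np.ndarray  # per component count 1..max
    sep: np.ndarray
    optimal_n: int

    @property
    def best_q2(self) -> float:
        return float(self.q2[self.optimal_n - 1])


def loo_q2(X: np.ndarray, y: np.ndarray, max_components: int = 20) -> LooResult:
    """Leave-one-out cross-validation over candidate component counts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if n < 3:
        raise ValueError("leave-one-out needs at least three rows")
    A = min(max_components, n - 2, X.shape[1])
    press = np.zeros(A)
    counts = np.zeros(A, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        xc = Xi.mean(axis=0)
        yc = float(yi.mean())
        B = _nipals_coefficients(Xi - xc, yi - yc, A)
        preds = yc + (X[i] - xc) @ B  # one prediction per component count
        a_eff = B.shape[1]
        press[:a_eff] += (y[i] - preds) ** 2
        counts[:a_eff] += 1
    valid = counts == n
    if not valid.any():
        raise ValueError("no component count achievable on every LOO fold")
    press = press[valid]
    A = int(valid.sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    comps = np.arange(1, A + 1)
    sep = np.sqrt(press / np.maximum(n - comps - 1, 1))
    optimal = int(np.argmax(q2)) + 1  # argmax takes the first (smallest c) on ties
    return LooResult(q2=q2, sep=sep, optimal_n=optimal)


def model_stats(
    model: PLSModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Non-cross-validated r2, SEE and the F statistic of a fitted model."""
    y = np.asarray(y, dtype=float)
    n, c = len(y), model.n_components
    if n <= c + 1:
        raise ValueError("model statistics require n > n_components + 1")
    resid = y - model.predict_rows(X)
    rss = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot
    see = float(np.sqrt(rss / (n - c - 1)))
    if rss == 0.0 or r2 >= 1.0:
        f_value = float("inf")
    else:
        f_value = (r2 / c) / ((1.0 - r2) / (n - c - 1))
    model.r2_ncv, model.see, model.f_value = r2, see, f_value
    return r2, see, f_value


def f_statistic(r2: float, n: int, c: int) -> float:
    """F-test value from a non-cross-validated r2 with c components."""
    if n <= c + 1:
        raise ValueError("requires n > c + 1")
    if r2 >= 1.0:
        return float("inf")
    return (r2 / c) / ((1.0 - r2) / (n - c - 1))


def field_contributions(
    model: PLSModel, matrix: DescriptorMatrix, training_rows: Sequence[int]
) -> dict[str, float]:
    """Normalized per-field share of sum |coefficient| * training column sd.

    ``model.coefficients`` lives in the retained-column space of
    ``matrix``; contributions are normalized across the matrix's fields
    to sum to one.
    """
    mask = matrix.mask if matrix.mask is not None else np.ones(matrix.n_columns, bool)
    sd = (
        matrix.train_sd
        if matrix.train_sd is not None
        else matrix.values[list(training_rows)].std(axis=0, ddof=0)
    )
    kinds = matrix.field_kinds[mask]
    weight = np.abs(model.coefficients) * sd[mask]
    total = weight.sum()
    contribs = {}
    for kind in matrix.config.fields:
        share = float(weight[kinds == kind].sum())
        contribs[kind] = share / total if total > 0 else 0.0
    model.field_contributions = contribs
    return contribs


# ---------------------------------------------------------------------------
# High-level model on molecules


@dataclass
class ComsiaModel:
    """A PLS model bound to its lattice, pruning mask and provenance."""

    pls: PLSModel
    matrix: DescriptorMatrix
    training_ids: list[str]
    charge_provider: str = "file"
    scheme: str = "default"
    seed: int | None = None

    def predict(self, molecules: Sequence[Molecule]) -> np.ndarray:
        """Predict pIC50 for aligned, parameterized molecules."""
        new = assemble_descriptor_matrix(
            molecules, lattice=self.matrix.lattice, config=self.matrix.config
        )
        if new.n_columns != self.matrix.n_columns:
            raise ValueError("descriptor layout mismatch with the model lattice")
        mask = (
            self.matrix.mask
            if self.matrix.mask is not None
            else np.ones(self.matrix.n_columns, bool)
        )
        return self.pls.predict_rows(new.values[:, mask])


def training_rows(molecules: Sequence[Molecule]) -> list[int]:
    """Rows usable for fitting: activity present and not flagged test."""
    return [
        i
        for i, m in enumerate(molecules)
        if m.activity is not None and m.subset != "test"
    ]


def train_model(
    molecules: Sequence[Molecule],
    config: FieldConfig | None = None,
    max_components: int = 20,
    n_components: int | None = None,
    min_sigma: float | None = None,
    charge_provider: str = "file",
    seed: int | None = None,
) -> ComsiaModel:
    """Assemble descriptors, prune, select N by LOO, and fit the final model."""
    config = config or FieldConfig()
    rows = training_rows(molecules)
    if len(rows) < 3:
        raise ValueError("need at least three training molecules with activities")
    matrix = assemble_descriptor_matrix(molecules, config=config)
    matrix = prune_columns(matrix, rows, min_sigma)
    X = matrix.retained()[rows]
    y = np.array([molecules[i].activity for i in rows])
    loo = loo_q2(X, y, max_components)
    n_comp = n_components or loo.optimal_n
    model = fit_pls(X, y, n_comp)
    model.q2 = float(loo.q2[n_comp - 1])
    model.sep = float(loo.sep[n_comp - 1])
    model_stats(model, X, y)
    field_contributions(model, matrix, rows)
    return ComsiaModel(
        pls=model,
        matrix=matrix,
        training_ids=[molecules[i].id for i in rows],
        charge_provider=charge_provider,
        seed=seed,
    )


def scan_field_combinations(
    molecules: Sequence[Molecule],
    config: FieldConfig | None = None,
    max_components: int = 20,
    min_sigma: float | None = None,
) -> pd.DataFrame:
    """Fit every non-empty field subset; one report row per subset.

    Rows are labeled canonically in S, E, H, D, A order and carry q2, N,
    SEP, SEE, r2_ncv, F and per-field contributions.  A subset whose fit
    fails is recorded with ``failed=True`` instead of aborting the scan.
    """
    config = config or FieldConfig()
    rows = training_rows(molecules)
    if len(rows) < 3:
        raise ValueError("need at least three training molecules")
    full = assemble_descriptor_matrix(molecules, config=config)
    y = np.array([molecules[i].activity for i in rows])
    labels = _subset_labels(config.fields)
    records = []
    for label in labels:
        rec: dict = {"model": label, "failed": False}
        try:
            sub = full.subset_fields(label)
            sub = prune_columns(sub, rows, min_sigma)
            X = sub.retained()[rows]
            loo = loo_q2(X, y, max_components)
            model = fit_pls(X, y, loo.optimal_n)
            r2, see, f_value = model_stats(model, X, y)
            contribs = field_contributions(model, sub, rows)
            rec.update(
                q2=loo.best_q2,
                N=loo.optimal_n,
                SEP=loo.sep[loo.optimal_n - 1],
                SEE=see,
                r2_ncv=r2,
                F=f_value,
            )
            for kind in FIELD_ORDER:
                rec[kind] = contribs.get(kind, np.nan)
        except Exception as exc:
            rec.update(failed=True, error=str(exc))
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("model")


def _subset_labels(fields: str) -> list[str]:
    """All non-empty subsets of the configured fields, canonically labeled,
    ordered by subset size then canonical position."""
    fields = "".join(k for k in FIELD_ORDER if k in set(fields))
    labels = []
    for bits in range(1, 2 ** len(fields)):
        label = "".join(f for i, f in enumerate(fields) if bits >> i & 1)
        labels.append(label)
    labels.sort(key=lambda s: (len(s), [fields.index(c) for c in s]))
    return labels


# ---------------------------------------------------------------------------
# Model archive: a zip of JSON metadata + text-encoded arrays


def save_model(model: ComsiaModel, path) -> None:
    meta = {
        "n_components": model.pls.n_components,
        "y_center": model.pls.y_center,
        "q2": model.pls.q2,
        "sep": model.pls.sep,
        "r2_ncv": model.pls.r2_ncv,
        "see": model.pls.see,
        "f_value": model.pls.f_value,
        "field_contributions": model.pls.field_contributions,
        "training_ids": model.training_ids,
        "charge_provider": model.charge_provider,
        "scheme": model.scheme,
        "seed": model.seed,
        "ids": model.matrix.ids,
        "lattice": {
            "origin": model.matrix.lattice.origin.tolist(),
            "spacing": model.matrix.lattice.spacing,
            "counts": list(model.matrix.lattice.counts),
        },
        "config": {
            "spacing": model.matrix.config.spacing,
            "margin": model.matrix.config.margin,
            "alpha": model.matrix.config.alpha,
            "fields": model.matrix.config.fields,
            "probe": model.matrix.config.probe,
            "min_sigma": model.matrix.config.min_sigma,
        },
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, arr in [
            ("x_center", model.pls.x_center),
            ("coefficients", model.pls.coefficients),
            ("values", model.matrix.values),
            ("mask", model.matrix.mask),
            ("train_sd", model.matrix.train_sd),
            ("field_kinds", model.matrix.field_kinds),
            ("grid_indices", model.matrix.grid_indices),
        ]:
            if arr is None:
                continue
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(name + ".npy", buf.getvalue())


def load_model(path) -> ComsiaModel:
    from .fields import Lattice

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))

        def arr(name):
            if name + ".npy" not in zf.namelist():
                return None
            return np.load(io.BytesIO(zf.read(name + ".npy")), allow_pickle=False)

        pls = PLSModel(
            n_components=meta["n_components"],
            x_center=arr("x_center"),
            y_center=meta["y_center"],
            coefficients=arr("coefficients"),
            q2=meta["q2"],
            sep=meta["sep"],
            r2_ncv=meta["r2_ncv"],
            see=meta["see"],
            f_value=meta["f_value"],
            field_contributions=meta["field_contributions"],
        )
        matrix = DescriptorMatrix(
            ids=meta["ids"],
            field_kinds=arr("field_kinds"),
            grid_indices=arr("grid_indices"),
            values=arr("values"),
            lattice=Lattice(
                origin=np.array(meta["lattice"]["origin"]),
                spacing=meta["lattice"]["spacing"],
                counts=tuple(meta["lattice"]["counts"]),
            ),
            config=FieldConfig(**meta["config"]),
            mask=arr("mask"),
            train_sd=arr("train_sd"),
        )
    return ComsiaModel(
        pls=pls,
        matrix=matrix,
        training_ids=meta["training_ids"],
        charge_provider=meta["charge_provider"],
        scheme=meta["scheme"],
        seed=meta["seed"],
    )
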