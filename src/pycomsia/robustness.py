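"""Model robustness checks: Y-randomization and applicability domain.

Y-randomization refits the full PLS pipeline after permuting the
activity vector; a real structure–activity relationship must collapse
(q2 near or below zero) under permutation.  The applicability domain
uses the descriptor-standardization rule: a query compound is inside
the domain when its standardized descriptor magnitudes
``s_k = |x_k - mean_k(train)| / sd_k(train)`` stay within three
training standard deviations, with the 90th-percentile escape clause
``mean(s) + 1.28 * sd(s) <= 3`` for rows that straddle the border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pls import fit_pls, loo_q2, model_stats


@dataclass
class YRandomizationReport:
    reference_q2: float
    reference_r2: float
    iterations: pd.DataFrame  # columns: iteration, seed, q2, r2_ncv

    def to_file(self, path) -> None:
        self.iterations.to_csv(path, sep="\t", index=False)


def y_randomize(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 10,
    base_seed: int = 0,
    max_components: int = 20,
    include_identity: bool = False,
) -> YRandomizationReport:
    """Refit after seeded permutations of the response.

    Each iteration draws an independent permutation from a seed spawned
    deterministically off ``base_seed``, re-selects the component count
    by leave-one-out, and records q2 and r2_ncv.  With
    ``include_identity`` the identity permutation is injected as
    iteration 0, reproducing the reference statistics exactly (a
    diagnostic that the randomized pipeline matches the reference one).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def fit_stats(y_perm: np.ndarray) -> tuple[float, float]:
        loo = loo_q2(X, y_perm, max_components)
        model = fit_pls(X, y_perm, loo.optimal_n)
        r2, _, _ = model_stats(model, X, y_perm)
        return loo.best_q2, r2

    ref_q2, ref_r2 = fit_stats(y)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_iter)
    records = []
    if include_identity:
        records.append(
            {"iteration": 0, "seed": -1, "q2": ref_q2, "r2_ncv": ref_r2}
        )
    for it, seed in enumerate(seeds, start=1):
        rng = np.random.default_rng(int(seed))
        perm = rng.permutation(len(y))
        q2, r2 = fit_stats(y[perm])
        records.append(
            {"iteration": it, "seed": int(seed), "q2": q2, "r2_ncv": r2}
        )
    return YRandomizationReport(
        reference_q2=ref_q2,
        reference_r2=ref_r2,
        iterations=pd.DataFrame.from_records(records),
    )


# ---------------------------------------------------------------------------
# Applicability domain


def standardize_descriptors(
    train: np.ndarray, query: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized descriptor magnitudes of query rows w.r.t. training rows.

    Returns ``(s, retained)`` where ``s[i, k] = |x_ik - mean_k| / sd_k``
    over the training columns with nonzero variance, and ``retained`` is
    the boolean column filter that was applied (constant training
    columns carry no domain information and are dropped with notice).
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if train.shape[1] != query.shape[1]:
        raise ValueError("train and query must share columns")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    retained = sd > 0
    if not retained.any():
        raise ValueError("no non-constant training columns for standardization")
    s = np.abs(query[:, retained] - mean[retained]) / sd[retained]
    return s, retained


@dataclass
class ADReport:
    table: pd.DataFrame  # id, s_max, s_min, s_mean, s_sd, decision
    threshold: float

    def to_file(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ad_decide(
    s: np.ndarray,
    ids: Sequence[str] | None = None,
    threshold: float = 3.0,
) -> ADReport:
    """Inside/outside verdicts from a standardized-magnitude matrix.

    Per compound: inside if every s <= threshold; outside if every
    s > threshold; otherwise inside iff mean(s) + 1.28*sd(s) <= threshold.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("standardized matrix must be finite")
    if ids is None:
        ids = [str(i + 1) for i in range(len(s))]
    rows = []
    for cid, row in zip(ids, s):
        s_max, s_min = float(row.max()), float(row.min())
        s_mean, s_sd = float(row.mean()), float(row.std(ddof=0))
        if s_max <= threshold:
            inside = True
        elif s_min > threshold:
            inside = False
        else:
            inside = s_mean + 1.28 * s_sd <= threshold
        rows.append(
            {
                "id": cid,
                "s_max": s_max,
                "s_min": s_min,
                "s_mean": s_mean,
                "s_sd": s_sd,
                "decision": "inside" if inside else "outside",
            }
        )
    return ADReport(table=pd.DataFrame.from_records(rows), threshold=threshold)


def applicability_domain(
    train: np.ndarray,
    query: np.ndarray,
    ids: Sequence[str] | None = None,
    threshold: float = 3.0,
) -> ADReport:
    """Standardize query rows against training rows and decide the domain."""
    s, _ = standardize_descriptors(train, query)
    return ad_decide(s, ids=ids, threshold=threshold)
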