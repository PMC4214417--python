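"""Feature-grouped all-subsets regression for biomass and leaf-area traits.

Candidate models come in four families built around projected area ``A``:

- ``A``   — area alone;
- ``AM``  — area plus one morphological descriptor;
- ``AT``  — area plus one texture descriptor;
- ``ATM`` — area plus one morphological and one texture descriptor.

Every candidate in a family is fitted by ordinary least squares and scored
with AIC, adjusted R² and the PRESS statistic; the final model must beat
smaller families by configurable margins ("noticeably better").
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CandidateModel",
    "SelectionReport",
    "EvalMetrics",
    "fit_linear_model",
    "press_statistic",
    "model_aic",
    "all_subsets_search",
    "select_best_model",
    "evaluate_predictions",
    "split_train_test",
    "cross_validate",
]

Family = Literal["A", "AM", "AT", "ATM"]

FAMILY_ARITY = {"A": 1, "AM": 2, "AT": 2, "ATM": 3}


@dataclasses.dataclass
class CandidateModel:
    family: Family
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    n: int
    p: int
    rss: float
    r2: float
    adj_r2: float
    aic: float
    press: float

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.predictors)
        return X @ self.coefficients


@dataclasses.dataclass
class SelectionReport:
    family_best: dict[str, CandidateModel]
    chosen: CandidateModel
    criteria: pd.DataFrame
    rel_press_margin: float
    abs_adj_r2_margin: float


@dataclasses.dataclass
class EvalMetrics:
    r2_test: float
    mape_pct: float
    n_test: int


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(table))] + [table[name].to_numpy(dtype=float) for name in predictors]
    )
    return X


def model_aic(n: int, rss: float, p: int) -> float:
    """Gaussian-OLS AIC: ``n ln(rss/n) + 2 (p + 2)``.

    ``p`` counts slope terms; the ``+2`` accounts for intercept and error
    variance.  Additive constants are dropped — only differences matter.
    A perfect fit (``rss == 0``) returns ``-inf``.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * (p + 2)


def fit_linear_model(
    table: pd.DataFrame,
    trait: str,
    predictors: Sequence[str],
    family: Family | None = None,
) -> CandidateModel:
    """OLS fit of ``trait ~ 1 + predictors`` with criteria attached."""
    predictors = tuple(predictors)
    p = len(predictors)
    n = len(table)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    y = table[trait].to_numpy(dtype=float)
    X = _design(table, predictors)
    q, r = np.linalg.qr(X)
    if np.abs(np.diag(r)).min() < 1e-10 * max(1.0, np.abs(np.diag(r)).max()):
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        warnings.warn("zero response variance; r2 set to 0", RuntimeWarning)
        r2 = 0.0
        adj_r2 = 0.0
    else:
        r2 = 1.0 - rss / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    leverage = (q**2).sum(axis=1)
    if np.any(leverage >= 1.0 - 1e-12):
        raise np.linalg.LinAlgError("leverage of 1: a point is interpolated exactly")
    press = float(((resid / (1.0 - leverage)) ** 2).sum())
    return CandidateModel(
        family=family or ("A" if predictors == ("projected_area_px",) else "custom"),  # type: ignore[arg-type]
        predictors=predictors,
        coefficients=beta,
        n=n,
        p=p,
        rss=rss,
        r2=r2,
        adj_r2=adj_r2,
        aic=model_aic(n, rss, p),
        press=press,
    )


def press_statistic(model: CandidateModel, table: pd.DataFrame, trait: str) -> float:
    """PRESS via the hat-matrix identity ``sum (e_i / (1 - h_ii))^2``.

    Algebraically identical to refitting with each row left out and summing
    the squared out-of-sample residuals.
    """
    y = table[trait].to_numpy(dtype=float)
    X = _design(table, model.predictors)
    q, _ = np.linalg.qr(X)
    leverage = (q**2).sum(axis=1)
    if np.any(leverage >= 1.0 - 1e-12):
        raise np.linalg.LinAlgError("leverage of 1: a point is interpolated exactly")
    resid = y - model.predict(table)
    return float(((resid / (1.0 - leverage)) ** 2).sum())


def _family_candidates(
    family: Family,
    area: str,
    morph_pool: Sequence[str],
    texture_pool: Sequence[str],
) -> list[tuple[str, ...]]:
    if family == "A":
        return [(area,)]
    if family == "AM":
        if not morph_pool:
            raise ValueError("empty morphological pool")
        return [(area, m) for m in morph_pool]
    if family == "AT":
        if not texture_pool:
            raise ValueError("empty texture pool")
        return [(area, t) for t in texture_pool]
    if family == "ATM":
        if not morph_pool or not texture_pool:
            raise ValueError("empty descriptor pool")
        return [(area, m, t) for m, t in itertools.product(morph_pool, texture_pool)]
    raise ValueError(f"unknown family {family!r}")


def all_subsets_search(
    table: pd.DataFrame,
    trait: str,
    family: Family,
    morph_pool: Sequence[str],
    texture_pool: Sequence[str],
    area: str = "projected_area_px",
) -> list[CandidateModel]:
    """Fit every candidate of ``family`` and rank by PRESS, AIC, names."""
    models = []
    for preds in _family_candidates(family, area, morph_pool, texture_pool):
        try:
            m = fit_linear_model(table, trait, preds, family=family)
        except np.linalg.LinAlgError:
            continue  # collinear or interpolating candidate: unrankable, drop
        models.append(m)
    if not models:
        raise ValueError(f"no fittable candidate in family {family}")
    models.sort(key=lambda m: (m.press, m.aic, m.predictors))
    return models


def select_best_model(
    family_best: dict[str, CandidateModel],
    rel_press_margin: float = 0.05,
    abs_adj_r2_margin: float = 0.01,
) -> SelectionReport:
    """Pick the final model under the "noticeably better" rule.

    Starting from family ``A``, a larger family replaces the incumbent only
    if its PRESS is at least ``rel_press_margin`` relatively smaller AND its
    adjusted R² is at least ``abs_adj_r2_margin`` larger.  The partial order
    is ``A < {AM, AT} < ATM``; ties favour the smaller family.
    """
    for fam in ("A", "AM", "AT", "ATM"):
        if fam not in family_best:
            raise ValueError(f"missing family best for {fam}")

    def noticeably_better(challenger: CandidateModel, incumbent: CandidateModel) -> bool:
        press_ok = challenger.press <= (1.0 - rel_press_margin) * incumbent.press
        adj_ok = challenger.adj_r2 >= incumbent.adj_r2 + abs_adj_r2_margin
        return press_ok and adj_ok

    incumbent = family_best["A"]
    qualifiers = [
        family_best[f]
        for f in ("AM", "AT")
        if noticeably_better(family_best[f], incumbent)
    ]
    if qualifiers:
        incumbent = min(qualifiers, key=lambda m: (m.press, m.aic))
    # ATM must beat the two-predictor incumbent; when no two-predictor
    # family qualified it has to beat A noticeably instead.
    if noticeably_better(family_best["ATM"], incumbent):
        incumbent = family_best["ATM"]

    criteria = pd.DataFrame(
        [
            {
                "family": fam,
                "predictors": "+".join(m.predictors),
                "aic": m.aic,
                "adj_r2": m.adj_r2,
                "press": m.press,
            }
            for fam, m in family_best.items()
        ]
    )
    return SelectionReport(
        family_best=family_best,
        chosen=incumbent,
        criteria=criteria,
        rel_press_margin=rel_press_margin,
        abs_adj_r2_margin=abs_adj_r2_margin,
    )


def run_selection(
    table: pd.DataFrame,
    trait: str,
    morph_pool: Sequence[str],
    texture_pool: Sequence[str],
    area: str = "projected_area_px",
    rel_press_margin: float = 0.05,
    abs_adj_r2_margin: float = 0.01,
) -> SelectionReport:
    """Convenience: per-family searches followed by cross-family selection."""
    family_best = {
        fam: all_subsets_search(table, trait, fam, morph_pool, texture_pool, area)[0]
        for fam in ("A", "AM", "AT", "ATM")
    }
    return select_best_model(family_best, rel_press_margin, abs_adj_r2_margin)


def evaluate_predictions(
    model: CandidateModel, test: pd.DataFrame, trait: str
) -> EvalMetrics:
    """Test-set R² and mean absolute percentage error."""
    y = test[trait].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("MAPE requires strictly positive truth")
    yhat = model.predict(test)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero test variance")
    sse = float(((y - yhat) ** 2).sum())
    mape = float(100.0 * np.mean(np.abs(yhat - y) / y))
    return EvalMetrics(r2_test=1.0 - sse / sst, mape_pct=mape, n_test=len(y))


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split; train gets ``floor(n * fraction)`` rows."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(math.floor(n * fraction))
    return table.iloc[np.sort(order[:n_train])], table.iloc[np.sort(order[n_train:])]


def cross_validate(
    table: pd.DataFrame,
    trait: str,
    predictors: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> EvalMetrics:
    """k-fold CV with pooled out-of-fold predictions."""
    n = len(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k may not exceed n")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    yhat = np.empty(n)
    for fold in folds:
        train_idx = np.setdiff1d(order, fold)
        m = fit_linear_model(table.iloc[train_idx], trait, predictors)
        yhat[fold] = m.predict(table.iloc[fold])
    y = table[trait].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("MAPE requires strictly positive truth")
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    mape = float(100.0 * np.mean(np.abs(yhat - y) / y))
    return EvalMetrics(r2_test=1.0 - sse / sst if sst > 0 else 0.0, mape_pct=mape, n_test=n)
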