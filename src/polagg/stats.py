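"""Statistical layer: linear diameter-growth fit, AIC model comparison,
binned summaries, and two-sample tests.

Model comparison follows an information-theoretic protocol: every
candidate model is fitted to the same data, ranked by AIC, and a model is
flagged as *substantially better supported* only when its AIC undercuts
the runner-up by more than 2.  Candidate models are additive: linear
terms, factor terms, penalized B-spline smooths, and optional
tensor-product interactions of two smooths, under a Gaussian or a
negative-binomial (identity link) error family -- the latter for
fluorescence responses, which are non-negative counts of camera units
with variance growing faster than the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "ModelFitResult",
    "ModelSpec",
    "BinnedSummary",
    "fit_diameter_growth",
    "compare_models",
    "binned_summary",
    "ks_two_sample",
    "welch_t",
]

logger = logging.getLogger(__name__)

DELTA_AIC_SUPPORT = 2.0  # ΔAIC beyond which support counts as substantial


@dataclass
class ModelFitResult:
    """One fitted model within a comparison set."""

    model_id: str
    coefficients: Dict[str, float]
    aic: float
    deviance_explained: float
    r_squared: float = float("nan")
    p_values: Dict[str, float] = field(default_factory=dict)
    delta_aic: float = float("nan")  # vs the best model in the set
    substantially_better: bool = False
    n_obs: int = 0
    notes: str = ""

    def predict_linear(self, x: float) -> float:
        """Evaluate an intercept+slope fit at ``x`` (linear fits only)."""
        if set(self.coefficients) != {"intercept", "slope"}:
            raise ValueError("predict_linear applies to simple linear fits")
        return self.coefficients["intercept"] + self.coefficients["slope"] * x


@dataclass
class ModelSpec:
    """Declarative additive-model specification.

    ``smooth_terms`` maps a column name to the basis dimension of its
    penalized B-spline smooth; ``tensor_terms`` lists pairs of columns
    whose marginal spline bases are crossed into a tensor-product
    interaction surface.  ``family`` is ``"gaussian"`` or
    ``"nb_identity"`` (negative binomial, identity link).
    """

    model_id: str
    response: str
    linear_terms: Sequence[str] = ()
    factor_terms: Sequence[str] = ()
    smooth_terms: Dict[str, int] = field(default_factory=dict)
    tensor_terms: Sequence[Tuple[str, str]] = ()
    family: str = "gaussian"
    alpha: float = 1.0  # smoothing penalty weight for each spline term


def fit_diameter_growth(
    points: Sequence[Tuple[float, float]] | pd.DataFrame,
    time_cutoff: Optional[float] = 40.0,
) -> ModelFitResult:
    """OLS of aggregate diameter (µm) on time (h), restricted to t ≤ cutoff.

    Aggregate diameters widen linearly while they remain smaller than the
    cell width, so a straight line is the model of interest; the default
    cutoff discards the late, non-linear regime (diameters at the width
    ceiling).  Returns slope (µm/h), intercept (µm), R², and the slope's
    two-sided p-value.  A two-point fit is mathematically exact (R² = 1)
    and flagged ``low_n``.
    """
    if isinstance(points, pd.DataFrame):
        t = points.iloc[:, 0].to_numpy(dtype=float)
        d = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        t, d = arr[:, 0], arr[:, 1]
    if time_cutoff is not None:
        keep = t <= time_cutoff
        t, d = t[keep], d[keep]
    if t.size < 2:
        raise ValueError("diameter-growth fit needs >= 2 points within the cutoff")
    if np.ptp(t) == 0.0:
        raise np.linalg.LinAlgError("singular design: all time points equal")
    X = sm.add_constant(t)
    res = sm.OLS(d, X).fit()
    notes = "low_n" if t.size < 3 else ""
    return ModelFitResult(
        model_id="diameter~time",
        coefficients={"intercept": float(res.params[0]), "slope": float(res.params[1])},
        aic=float(res.aic),
        deviance_explained=float(res.rsquared) if t.size > 2 else 1.0,
        r_squared=float(res.rsquared) if t.size > 2 else 1.0,
        p_values={"slope": float(res.pvalues[1])},
        n_obs=int(t.size),
        notes=notes,
    )


def _tensor_basis(u: np.ndarray, v: np.ndarray, df: int = 4) -> np.ndarray:
    """Tensor-product interaction basis from two marginal B-spline bases.

    Marginal main effects are left to the additive terms of the model, so
    the product basis is centered column-wise to represent the pure
    interaction surface.
    """
    bu = BSplines(u, df=[df], degree=[3]).basis
    bv = BSplines(v, df=[df], degree=[3]).basis
    cols = [bu[:, i] * bv[:, j] for i in range(bu.shape[1]) for j in range(bv.shape[1])]
    basis = np.column_stack(cols)
    return basis - basis.mean(axis=0)


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Parametric design matrix, smoother object, and term names for a spec."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.linear_terms:
        cols.append(data[term].to_numpy(dtype=float))
        names.append(term)
    for term in spec.factor_terms:
        dummies = pd.get_dummies(data[term], prefix=term, drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(c)
    for u, v in spec.tensor_terms:
        basis = _tensor_basis(
            data[u].to_numpy(dtype=float), data[v].to_numpy(dtype=float)
        )
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"ti({u},{v})[{j}]")
    X = np.column_stack(cols)

    smoother = None
    if spec.smooth_terms:
        svars = list(spec.smooth_terms)
        sdata = data[svars].to_numpy(dtype=float)
        smoother = BSplines(
            sdata,
            df=[spec.smooth_terms[v] for v in svars],
            degree=[3] * len(svars),
            include_intercept=False,
        )
    return X, names, smoother


def _make_family(family: str):
    if family == "gaussian":
        return sm.families.Gaussian()
    if family == "nb_identity":
        return sm.families.NegativeBinomial(link=sm.families.links.Identity())
    raise ValueError(f"unknown family {family!r}")


def _null_deviance(y: np.ndarray, family) -> float:
    res = sm.GLM(y, np.ones((y.size, 1)), family=family).fit()
    return float(res.null_deviance)


def _fit_one(data: pd.DataFrame, spec: ModelSpec) -> ModelFitResult:
    y = data[spec.response].to_numpy(dtype=float)
    X, names, smoother = _design(data, spec)
    family = _make_family(spec.family)
    notes = ""
    try:
        res = _fit_glm(y, X, smoother, family, spec)
    except Exception as exc:  # NB identity-link fits can fail to converge
        if spec.family == "nb_identity":
            logger.warning(
                "model %s: %s family failed (%s); falling back to gaussian",
                spec.model_id, spec.family, exc,
            )
            notes = f"family fallback to gaussian ({exc})"
            family = _make_family("gaussian")
            res = _fit_glm(y, X, smoother, family, spec)
        else:
            raise
    coefs = {nm: float(b) for nm, b in zip(names, res.params[: len(names)])}
    pvals = {nm: float(p) for nm, p in zip(names, res.pvalues[: len(names)])}
    null_dev = _null_deviance(y, family)
    dev_expl = 1.0 - float(res.deviance) / null_dev if null_dev > 0 else 0.0
    return ModelFitResult(
        model_id=spec.model_id,
        coefficients=coefs,
        aic=float(res.aic),
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        p_values=pvals,
        n_obs=int(y.size),
        notes=notes,
    )


def _fit_glm(y, X, smoother, family, spec: ModelSpec):
    if smoother is None:
        return sm.GLM(y, X, family=family).fit()
    model = GLMGam(
        y, exog=X, smoother=smoother,
        alpha=[spec.alpha] * len(smoother.smoothers), family=family,
    )
    return model.fit()


def compare_models(data: pd.DataFrame, specs: Sequence[ModelSpec]) -> List[ModelFitResult]:
    """Fit every spec to ``data`` and rank by AIC.

    Returns results sorted by ascending AIC with ``delta_aic`` relative to
    the best model.  The best model is flagged ``substantially_better``
    only when the runner-up trails by more than ``DELTA_AIC_SUPPORT`` (=2)
    AIC units; ties (ΔAIC = 0, e.g. duplicated specs) are never flagged.
    Non-nested specs are allowed.  A model that fails to fit under the
    negative-binomial family is refitted under the Gaussian family and the
    fallback is recorded in its ``notes``.
    """
    if not specs:
        raise ValueError("compare_models needs at least one model spec")
    results = [_fit_one(data, spec) for spec in specs]
    results.sort(key=lambda r: r.aic)
    best = results[0].aic
    for r in results:
        r.delta_aic = r.aic - best
    if len(results) > 1 and results[1].delta_aic > DELTA_AIC_SUPPORT:
        results[0].substantially_better = True
    return results


@dataclass
class BinnedSummary:
    """Fixed-width binned mean ± SD, small bins suppressed.

    ``frame`` has one row per emitted bin (``bin_center``, ``mean``,
    ``sd``, ``n``); bins with fewer than ``min_n`` points are dropped but
    their point count is retained in ``n_dropped`` so that emitted + dropped
    always equals the input size.
    """

    frame: pd.DataFrame
    bin_width: float
    min_n: int
    n_dropped: int

    @property
    def n_total(self) -> int:
        return int(self.frame["n"].sum()) + self.n_dropped


def binned_summary(
    x: Sequence[float], y: Sequence[float], bin_width: float, min_n: int = 10
) -> BinnedSummary:
    """Mean ± SD of ``y`` in fixed-width bins of ``x`` anchored at min(x).

    Bins holding fewer than ``min_n`` points are excluded from the output
    (their counts are reported in ``n_dropped``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("binned_summary requires finite values")
    if x.size == 0:
        return BinnedSummary(
            frame=pd.DataFrame(columns=["bin_center", "mean", "sd", "n"]),
            bin_width=bin_width, min_n=min_n, n_dropped=0,
        )
    idx = np.floor((x - x.min()) / bin_width).astype(int)
    rows = []
    n_dropped = 0
    for b in np.unique(idx):
        sel = idx == b
        n = int(sel.sum())
        if n < min_n:
            n_dropped += n
            continue
        rows.append(
            {
                "bin_center": x.min() + (b + 0.5) * bin_width,
                "mean": float(y[sel].mean()),
                "sd": float(y[sel].std(ddof=1)) if n > 1 else 0.0,
                "n": n,
            }
        )
    frame = pd.DataFrame(rows, columns=["bin_center", "mean", "sd", "n"])
    return BinnedSummary(frame=frame, bin_width=bin_width, min_n=min_n, n_dropped=n_dropped)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test: (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = scipy.stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def welch_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch's unequal-variance t test, two-sided: (t, p).

    Degenerate input with zero variance in both samples and equal means
    returns t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
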