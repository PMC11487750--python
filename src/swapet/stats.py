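"""Association models between slow-wave features and amyloid accumulation.

The statistical core is an ordinary least-squares model of annualized amyloid
accumulation (ΔPiB(log)/year or CL/year, global or per ROI) on per-SD
standardized slow-wave features plus covariates (baseline age, APOE ε4,
baseline PiB status, scan intervals...).  It is exposed statsmodels-style: a
:class:`SlowWaveAmyloidModel` is built from a cohort DataFrame and ``fit()``
returns an :class:`AssociationResults` carrying coefficients, 95% CIs,
p-values, per-term VIFs, adjusted R² and a ``summary()`` table.  Backward
elimination of covariates (probability of F for removal 0.1, exposures always
forced in), subgroup refits by amyloid status, paired diagnostic-vs-titration
comparisons with Cohen's d, correlations, and predictions at feature
quantiles complete the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scs
import statsmodels.api as sm

__all__ = [
    "standardize",
    "fit_ols",
    "backward_eliminate",
    "correlate",
    "paired_compare",
    "effect_size_from_ci",
    "PairedComparison",
    "AssociationResults",
    "SlowWaveAmyloidModel",
]

P_REMOVE_DEFAULT = 0.1


def standardize(x) -> tuple[np.ndarray, float]:
    """Z-score with sample SD (n−1); returns (z, SD) for back-conversion."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardize a constant column")
    sd = float(np.std(x, ddof=1))
    return (x - x.mean()) / sd, sd


class AssociationResults:
    """OLS fit results: estimates, uncertainty, collinearity diagnostics.

    Attributes
    ----------
    params, bse, pvalues : pandas.Series indexed by term (incl. ``const``)
    conf_int : DataFrame with columns ``lower``/``upper`` (95%, t-based)
    vif : Series of variance inflation factors for non-intercept terms
    rsquared, rsquared_adj : float
    nobs : int
    removal_trace : list of (term, p_at_removal) from backward elimination
    exposure_sds : dict of the SDs used to standardize exposures
    """

    def __init__(self, sm_results, data: pd.DataFrame, outcome: str, terms: list[str],
                 removal_trace=None, exposure_sds=None):
        self._res = sm_results
        self.data = data
        self.outcome = outcome
        self.terms = list(terms)
        self.removal_trace = removal_trace or []
        self.exposure_sds = exposure_sds or {}
        ci = sm_results.conf_int(alpha=0.05)
        ci.columns = ["lower", "upper"]
        self.conf_int = ci
        self.params = sm_results.params
        self.bse = sm_results.bse
        self.pvalues = sm_results.pvalues
        self.rsquared = float(sm_results.rsquared)
        self.rsquared_adj = float(sm_results.rsquared_adj)
        self.nobs = int(sm_results.nobs)
        self.vif = self._compute_vif()

    def _compute_vif(self) -> pd.Series:
        X = self.data[self.terms]
        if len(self.terms) < 2:
            return pd.Series(1.0, index=self.terms)
        vals = {}
        Xc = sm.add_constant(X.to_numpy(dtype=float))
        for j, t in enumerate(self.terms):
            y = Xc[:, j + 1]
            others = np.delete(Xc, j + 1, axis=1)
            r2 = sm.OLS(y, others).fit().rsquared
            vals[t] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
        return pd.Series(vals)

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(exog[self.terms].to_numpy(dtype=float), has_constant="add")
        return X @ self.params.to_numpy()

    def predict_at_quantiles(self, feature: str, quantiles, profile: dict | None = None):
        """Linear predictor at the feature's sample quantiles.

        The feature column is set to its observed quantile values; every other
        term is held at the supplied ``profile`` value, defaulting to its
        sample mean.  Returns ``{q: prediction}``.
        """
        if feature not in self.terms:
            raise ValueError(f"{feature!r} is not a model term: {self.terms}")
        qs = np.atleast_1d(np.asarray(quantiles, dtype=float))
        if np.any((qs <= 0) | (qs >= 1)):
            raise ValueError("quantiles must lie strictly inside (0, 1)")
        profile = profile or {}
        base = {t: float(profile.get(t, self.data[t].mean())) for t in self.terms}
        out = {}
        for q in qs:
            row = dict(base)
            row[feature] = float(self.data[feature].quantile(q))
            out[float(q)] = float(self.predict(pd.DataFrame([row]))[0])
        return out

    def tidy(self) -> pd.DataFrame:
        """Coefficient table (one row per term) for CSV export."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "beta": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_lower": self.conf_int["lower"].to_numpy(),
                "ci_upper": self.conf_int["upper"].to_numpy(),
                "p": self.pvalues.to_numpy(),
                "vif": [self.vif.get(t, np.nan) for t in self.params.index],
                "adj_r2": self.rsquared_adj,
                "n": self.nobs,
                "outcome": self.outcome,
            }
        )

    def summary(self):
        return self._res.summary()

    def __repr__(self):
        return (
            f"<AssociationResults outcome={self.outcome!r} n={self.nobs} "
            f"terms={self.terms} adj_r2={self.rsquared_adj:.3f}>"
        )


def fit_ols(data: pd.DataFrame, outcome: str, terms: list[str]) -> AssociationResults:
    """OLS of ``outcome`` on ``terms`` plus intercept, with classical SEs.

    Raises on rank-deficient designs, naming the aliased terms.
    """
    df = data[[outcome, *terms]].dropna()
    if len(df) <= len(terms) + 1:
        raise ValueError(f"n={len(df)} too small for {len(terms)} terms")
    X = df[terms].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < len(terms) + 1:
        # identify aliased columns by incremental rank
        aliased = []
        cols = [np.ones(len(X))]
        for j, t in enumerate(terms):
            cand = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(cand) == len(cols):
                aliased.append(t)
            else:
                cols.append(X[:, j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    exog = sm.add_constant(pd.DataFrame(X, columns=terms, index=df.index))
    res = sm.OLS(df[outcome], exog).fit()
    return AssociationResults(res, df, outcome, terms)


def backward_eliminate(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    forced_in: list[str] | None = None,
    p_remove: float = P_REMOVE_DEFAULT,
) -> AssociationResults:
    """Backward selection: drop the worst removable term while its p > p_remove.

    The partial-F p-value of a single term equals its two-sided t-test
    p-value, which is what is compared against the removal threshold.  Terms
    in ``forced_in`` are never removed.  The returned results carry the
    ordered ``removal_trace``.
    """
    forced = set(forced_in or [])
    unknown = forced - set(terms)
    if unknown:
        raise ValueError(f"forced_in terms not among terms: {sorted(unknown)}")
    current = list(terms)
    trace = []
    while True:
        res = fit_ols(data, outcome, current)
        removable = [t for t in current if t not in forced]
        if not removable:
            break
        worst = max(removable, key=lambda t: res.pvalues[t])
        if res.pvalues[worst] > p_remove:
            trace.append((worst, float(res.pvalues[worst])))
            current.remove(worst)
        else:
            break
    res = fit_ols(data, outcome, current)
    res.removal_trace = trace
    return res


def correlate(x, y, method: str = "pearson", transform: str | None = None):
    """Pearson r or Spearman rs with two-sided p; optional log transform.

    ``transform`` may be ``"x"``, ``"y"`` or ``"both"`` to log-transform the
    corresponding variable(s) first (natural log, values must be positive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if transform in ("x", "both"):
        x = np.log(x)
    if transform in ("y", "both"):
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        r, p = scs.pearsonr(x, y)
    elif method == "spearman":
        r, p = scs.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class PairedComparison:
    """Paired t-test with Cohen's d for paired samples.

    ``d`` uses the SD of the paired differences, which equals
    sqrt(s_a² + s_b² − 2·r·s_a·s_b) — the between-condition SD adjusted by
    the correlation between measures.
    """

    n: int
    mean_diff: float
    sd_diff: float
    ci_lower: float
    ci_upper: float
    t: float
    p: float
    d: float


def paired_compare(a, b) -> PairedComparison:
    """Compare paired samples: mean difference a−b, 95% CI, p, Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired vectors must be equal-length with n >= 3")
    diff = a - b
    n = len(diff)
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        raise ValueError("Cohen's d undefined: paired differences have zero variance")
    m = float(diff.mean())
    se = sd / np.sqrt(n)
    tcrit = scs.t.ppf(0.975, n - 1)
    tstat = m / se
    p = 2 * scs.t.sf(abs(tstat), n - 1)
    return PairedComparison(
        n=n,
        mean_diff=m,
        sd_diff=sd,
        ci_lower=m - tcrit * se,
        ci_upper=m + tcrit * se,
        t=float(tstat),
        p=float(p),
        d=m / sd,
    )


def effect_size_from_ci(mean_diff: float, ci_lower: float, ci_upper: float, n: int) -> float:
    """Cohen's d for paired samples reconstructed from a printed mean and 95% CI.

    The CI half-width equals t(0.975, n−1)·SD(diff)/√n, so
    SD(diff) = half-width/t · √n and d = mean/SD(diff).
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    half = (ci_upper - ci_lower) / 2.0
    if half <= 0:
        raise ValueError("CI must have positive width")
    sd = half / scs.t.ppf(0.975, n - 1) * np.sqrt(n)
    return float(mean_diff / sd)


class SlowWaveAmyloidModel:
    """Linear model of annualized amyloid accumulation on slow-wave features.

    Parameters
    ----------
    data : DataFrame
        One row per participant (the cohort table).
    outcome : str
        Outcome column, e.g. ``"dpib_log_yr"`` or ``"dpib_cl_yr"``.
    exposures : list of str
        Slow-wave feature columns; standardized to per-SD units (sample SD)
        unless ``standardize_exposures=False``.  Always forced into the model
        during backward elimination.
    covariates : list of str
        Adjustment terms entered untransformed (e.g. baseline age, APOE ε4,
        baseline PiB status); eligible for backward removal.

    Examples
    --------
    >>> model = SlowWaveAmyloidModel.from_dataframe(
    ...     cohort, outcome="dpib_log_yr",
    ...     exposures=["so_slope", "delta_slope"],
    ...     covariates=["age_baseline", "apoe4", "pib_positive"])
    >>> res = model.fit()
    >>> res.params["so_slope"]  # change per 1 SD of SO-slope   # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, outcome: str, exposures: list[str],
                 covariates: list[str] | None = None, standardize_exposures: bool = True):
        covariates = covariates or []
        cols = [outcome, *exposures, *covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        self.raw = data[cols].dropna().reset_index(drop=True)
        self.outcome = outcome
        self.exposures = list(exposures)
        self.covariates = list(covariates)
        self.exposure_sds: dict[str, float] = {}
        df = self.raw.copy()
        if standardize_exposures:
            for e in exposures:
                z, sd = standardize(df[e])
                df[e] = z
                self.exposure_sds[e] = sd
        self.data = df

    @classmethod
    def from_dataframe(cls, data, outcome, exposures, covariates=None, **kw):
        return cls(data, outcome, exposures, covariates, **kw)

    @property
    def terms(self) -> list[str]:
        return [*self.exposures, *self.covariates]

    def fit(self, backward: bool = False, p_remove: float = P_REMOVE_DEFAULT,
            subgroup: pd.Series | None = None) -> AssociationResults:
        """Fit the model, optionally after backward elimination of covariates.

        ``subgroup`` is a boolean mask over rows for plain subgroup refits
        (e.g. split by baseline amyloid status); no interaction terms are
        added.
        """
        data = self.data if subgroup is None else self.data[np.asarray(subgroup)]
        if backward:
            res = backward_eliminate(data, self.outcome, self.terms,
                                     forced_in=self.exposures, p_remove=p_remove)
        else:
            res = fit_ols(data, self.outcome, self.terms)
        res.exposure_sds = dict(self.exposure_sds)
        return res

    def fit_by_group(self, group_col: str, backward: bool = False) -> dict:
        """Refit per level of ``group_col`` in the raw data (subgroup analysis)."""
        if group_col not in self.raw.columns:
            raise ValueError(f"{group_col!r} not among model columns")
        out = {}
        for level in sorted(self.raw[group_col].unique()):
            mask = (self.raw[group_col] == level).to_numpy()
            terms = [t for t in self.terms if t != group_col]
            data = self.data[mask]
            if backward:
                res = backward_eliminate(data, self.outcome, terms, forced_in=self.exposures)
            else:
                res = fit_ols(data, self.outcome, terms)
            res.exposure_sds = dict(self.exposure_sds)
            out[level] = res
        return out
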