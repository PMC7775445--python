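"""Covariate-adjusted correlation battery and auxiliary statistics.

The battery relates an ADHD Index sum score to behavioral and ERP measures
via partial correlations controlling for age, sex and intelligence (SPM raw
score).  Per variable pair: outliers (> 3 SD from the full-sample mean of
either analyzed variable, single pass) are removed first; Pearson partial
correlation is used unless the Shapiro-Wilk test flags either variable as
non-normal (p < .05), in which case a Spearman (rank) partial correlation is
used.  Significance is evaluated both at alpha and at the Bonferroni
threshold alpha/m with m = 4 tests per ERP component (amplitude, latency and
the two variability measures).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "iq_raw")


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    method: str  # 'pearson_partial' or 'spearman_partial'
    coefficient: float
    p_value: float
    n_after_exclusion: int
    n_outliers_removed: int
    shapiro_p: dict = field(default_factory=dict)


def exclude_outliers(values: np.ndarray) -> np.ndarray:
    """Keep-mask removing points > 3 SD from the full-sample mean.

    Single pass: mean/SD come from the full sample, no re-iteration.  With
    zero variance nothing is excluded.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        logger.info("zero variance: no outlier exclusion possible")
        return np.ones(values.size, dtype=bool)
    z = (values - values.mean()) / sd
    return np.abs(z) <= 3.0


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        logger.info("constant input: Shapiro-Wilk undefined, treating as non-normal")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def choose_method(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple:
    """('pearson'|'spearman', {'x': p, 'y': p}) via the Shapiro-Wilk gate."""
    px, py = _shapiro_p(np.asarray(x, float)), _shapiro_p(np.asarray(y, float))
    method = "spearman" if (px < alpha or py < alpha) else "pearson"
    return method, {"x": px, "y": py}


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design (collinear column)")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    method: str = "pearson",
) -> tuple:
    """Partial correlation of x and y given covariates.

    Pearson: correlate the residuals of x and y after linear regression on
    the covariates (with intercept).  Spearman: rank-transform all variables
    first, then the same residual procedure.  Two-tailed p from a
    t-distribution with df = n - 2 - k.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    covariates = np.atleast_2d(np.asarray(covariates, float))
    if covariates.shape[0] != len(x):
        covariates = covariates.T
    n, k = covariates.shape
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")

    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        covariates = np.column_stack([sps.rankdata(c) for c in covariates.T])
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    # a variable fully explained by the covariates leaves numerical dust as
    # residual; its partial correlation is 0 by definition
    for v, rv in ((x, rx), (y, ry)):
        vc = v - v.mean()
        if (rv @ rv) <= 1e-24 * max(vc @ vc, 1.0):
            return 0.0, 1.0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(rx @ ry / denom) if denom > 0 else float("nan")
    r = min(max(r, -1.0), 1.0)
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def gated_partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
    alpha_gate: float = 0.05,
) -> CorrelationResult:
    """Outlier exclusion -> Shapiro-Wilk method gate -> partial correlation.

    Records with a missing (non-finite) value on either analyzed variable are
    dropped first (pairwise deletion, logged).  Outliers are then flagged on
    the raw analyzed variables (never on the covariates); a subject flagged
    on either variable is removed from the pair's analysis.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    covariates = np.atleast_2d(np.asarray(covariates, float))
    if covariates.shape[0] != len(x):
        covariates = covariates.T
    finite = np.isfinite(x) & np.isfinite(y)
    if not finite.all():
        logger.warning(
            "%s ~ %s: dropping %d record(s) with missing values",
            x_name, y_name, int((~finite).sum()),
        )
    x, y, covariates = x[finite], y[finite], covariates[finite]
    keep = exclude_outliers(x) & exclude_outliers(y)
    xk, yk, ck = x[keep], y[keep], covariates[keep]
    method, gate = choose_method(xk, yk, alpha_gate)
    r, p = partial_correlation(xk, yk, ck, method)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        method=f"{method}_partial",
        coefficient=r,
        p_value=p,
        n_after_exclusion=int(keep.sum()),
        n_outliers_removed=int((~keep).sum()),
        shapiro_p=gate,
    )


def one_sample_t(values: np.ndarray, mu: float = 0.0, gate_alpha: float = 0.05) -> dict:
    """Two-tailed one-sample t-test with 95% CI and Cohen's d.

    The Shapiro-Wilk gate is informational: a violation is logged as a
    caveat (``normality_ok`` in the result), the test still runs.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sw_p = _shapiro_p(values)
    if sw_p < gate_alpha:
        logger.warning("one_sample_t: normality violated (Shapiro-Wilk p=%.4f)", sw_p)
    sd = values.std(ddof=1)
    if sd == 0:
        diff = float(values.mean() - mu)
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return {
            "t": t,
            "df": int(values.size - 1),
            "p": 1.0 if diff == 0 else 0.0,
            "mean_diff": diff,
            "ci95": (float(values.mean()), float(values.mean())),
            "cohens_d": 0.0 if diff == 0 else math.copysign(math.inf, diff),
            "normality_ok": sw_p >= gate_alpha,
            "shapiro_p": sw_p,
        }
    res = sps.ttest_1samp(values, mu)
    ci = res.confidence_interval(0.95)
    return {
        "t": float(res.statistic),
        "df": int(values.size - 1),
        "p": float(res.pvalue),
        "mean_diff": float(values.mean() - mu),
        "ci95": (float(ci.low), float(ci.high)),
        "cohens_d": float((values.mean() - mu) / sd) if sd > 0 else float("inf"),
        "normality_ok": sw_p >= gate_alpha,
        "shapiro_p": sw_p,
    }


def extreme_groups(records: pd.DataFrame, score: str = "adhd_index") -> tuple:
    """Upper and lower tercile index arrays of the score distribution.

    Ties are broken deterministically by a stable sort on ``subject_id``
    (or row order without one); group sizes are n // 3 each.
    """
    if len(records) < 6:
        raise ValueError("need at least 6 records for tercile groups")
    df = records.reset_index(drop=True)
    by = ["subject_id"] if "subject_id" in df.columns else []
    order = df.sort_values(by=[score] + by, kind="stable").index.to_numpy()
    k = len(df) // 3
    return order[-k:], order[:k]


def independent_t_extreme_groups(
    records: pd.DataFrame, variable: str, score: str = "adhd_index",
    levene_alpha: float = 0.05,
) -> dict:
    """Student t-test comparing upper vs lower tercile of the score.

    Pooled-variance t when Levene's test does not reject homoskedasticity;
    Welch fallback (logged) otherwise.
    """
    hi, lo = extreme_groups(records, score)
    a = records.iloc[hi][variable].to_numpy(dtype=float)
    b = records.iloc[lo][variable].to_numpy(dtype=float)
    lev_p = float(sps.levene(a, b).pvalue) if (np.ptp(a) > 0 or np.ptp(b) > 0) else 1.0
    equal_var = lev_p > levene_alpha
    if not equal_var:
        logger.warning("Levene p=%.4f: falling back to Welch t-test", lev_p)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "mean_diff": float(a.mean() - b.mean()),
        "ci95": (float(ci.low), float(ci.high)),
        "cohens_d": float((a.mean() - b.mean()) / sp) if sp > 0 else float("inf"),
        "levene_p": lev_p,
        "equal_var": equal_var,
        "n": (na, nb),
    }


def polynomial_fit_r2(x: np.ndarray, y: np.ndarray, form: str) -> float:
    """R^2 of a least-squares logarithmic, quadratic or cubic fit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if form == "log":
        shift = 0.0
        if x.min() <= 0:
            shift = 1.0 - x.min()
            logger.info("log fit: shifting x by %+g to make it positive", shift)
        design = np.column_stack([np.ones_like(x), np.log(x + shift)])
    elif form == "linear":
        design = np.column_stack([np.ones_like(x), x])
    elif form == "quadratic":
        design = np.column_stack([np.ones_like(x), x, x**2])
    elif form == "cubic":
        design = np.column_stack([np.ones_like(x), x, x**2, x**3])
    else:
        raise ValueError(f"unknown form {form!r}")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("degenerate design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid @ resid) / ss_tot)


def bonferroni_threshold(alpha: float = 0.05, m: int = 4) -> float:
    """Corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest correlation detectable with the given power (Fisher-z).

    r = tanh((z_{1-alpha/2} + z_{power}) / sqrt(n - 3)), two-tailed.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    return float(np.tanh(z / np.sqrt(n - 3)))


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

MEASURES = ("amp", "lat", "amp_sd", "lat_sd")

#: (component, site) pairs: primary sites plus the Pz replications.
PRIMARY_SITES = (("inhibition_P3", "POz"), ("salience_P3", "POz"), ("salience_N2", "Fz"))
REPLICATION_SITES = (("inhibition_P3", "Pz"), ("salience_P3", "Pz"))


def battery_targets(include_replication: bool = True) -> list:
    """Default (component, site, measure, column) tuples of the battery."""
    sites = PRIMARY_SITES + (REPLICATION_SITES if include_replication else ())
    return [
        (comp, site, meas, f"{comp}_{site}_{meas}")
        for comp, site in sites
        for meas in MEASURES
    ]


def run_correlation_battery(
    records: pd.DataFrame,
    targets: list | None = None,
    score: str = "adhd_index",
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    m_per_component: int = 4,
) -> pd.DataFrame:
    """Normality-gated partial-correlation battery over the component measures.

    One row per (component, site, measure): outlier exclusion per pair,
    Shapiro-Wilk method gate, partial correlation controlling for the
    covariates, and significance flags at ``alpha`` (sig_unc) and at the
    Bonferroni-corrected threshold ``alpha / m_per_component`` (sig_bonf).
    """
    if targets is None:
        targets = battery_targets()
    thresh = bonferroni_threshold(alpha, m_per_component)
    cov = records.loc[:, list(covariates)].to_numpy(dtype=float)
    x = records[score].to_numpy(dtype=float)

    rows = []
    for comp, site, meas, column in targets:
        res = gated_partial_correlation(
            x, records[column].to_numpy(dtype=float), cov,
            x_name=score, y_name=column,
        )
        rows.append(
            {
                "component": comp,
                "site": site,
                "measure": meas,
                "method": res.method,
                "coefficient": res.coefficient,
                "p": res.p_value,
                "sig_unc": res.p_value < alpha,
                "sig_bonf": res.p_value < thresh,
                "n": res.n_after_exclusion,
                "n_outliers": res.n_outliers_removed,
                "shapiro_x": res.shapiro_p["x"],
                "shapiro_y": res.shapiro_p["y"],
            }
        )
    return pd.DataFrame(rows)
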