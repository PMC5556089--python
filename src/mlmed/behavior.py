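"""Behavioral analyses: random-intercept mixed model and paired contrasts.

The rating model regresses experienced pleasantness on trial number (1..36
within wine), wine, price and payment plus all listed two-way interactions and
the trial x price x payment three-way term (12 fixed effects including the
intercept), with a random intercept per subject, estimated by maximum
likelihood.  All regressors are z-scored across trials within subject before
fitting; interactions are products of the z-scored main effects.  Fixed-effect
p-values and CIs use t statistics on residual degrees of freedom
df = n_obs - n_fixed_effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

FIXED_TERMS = (
    "trial", "wine", "price", "payment",
    "trial:wine", "trial:price", "trial:payment",
    "wine:price", "wine:payment", "price:payment",
    "trial:price:payment",
)


@dataclass
class LmmFit:
    """Summary of the random-intercept mixed model."""

    fixed: pd.DataFrame          # term, beta, se, t, df, p, ci_lo, ci_hi
    random_intercept_sd: float
    residual_sd: float
    aic: float
    bic: float
    loglik: float
    n_obs: int

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.fixed)


def zscore_within_subject(values, subjects) -> np.ndarray:
    """Standardise a per-trial regressor to mean 0, sd 1 within each subject.

    Uses the sample (n-1) standard deviation.  Raises when the regressor is
    constant within any subject.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    out = np.empty_like(values)
    for s in np.unique(subjects):
        mask = subjects == s
        v = values[mask]
        if len(v) < 2:
            raise ValueError(f"subject {s}: need at least 2 trials to z-score")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"subject {s}: regressor is constant, cannot z-score")
        out[mask] = (v - v.mean()) / sd
    return out


def add_trial_number(table: pd.DataFrame) -> pd.DataFrame:
    """Trial number coded 1..n within each (subject, wine) in tasting order."""
    table = table.copy()
    order = table.sort_values("trial_index").groupby(["subject", "wine"]).cumcount() + 1
    table["trial"] = order.sort_index()
    return table


def build_lmm_design(table: pd.DataFrame) -> pd.DataFrame:
    """Z-scored main effects and their interaction products, per subject."""
    table = add_trial_number(table)
    subj = table["subject"].to_numpy()
    design = pd.DataFrame({"subject": subj, "rating": table["rating"].to_numpy()})
    for term in ("trial", "wine", "price", "payment"):
        design[term] = zscore_within_subject(table[term].to_numpy(), subj)
    for term in FIXED_TERMS[4:]:
        parts = term.split(":")
        col = np.ones(len(design))
        for p in parts:
            col = col * design[p].to_numpy()
        design[term] = col
    return design


def fit_random_intercept_lmm(table: pd.DataFrame) -> LmmFit:
    """ML fit of the rating model with a random intercept per subject.

    ``table`` needs columns subject, trial_index, wine, price, payment,
    rating.  Raises on non-convergence with the optimizer diagnostics.
    """
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    design = build_lmm_design(table)
    exog = sm.add_constant(design[list(FIXED_TERMS)])
    model = MixedLM(design["rating"], exog, groups=design["subject"])
    result = model.fit(reml=False)
    if not result.converged or not np.isfinite(result.llf):
        raise RuntimeError(f"mixed model did not converge: {result.summary()}")

    k = exog.shape[1]
    n_obs = len(design)
    df = n_obs - k
    beta = result.fe_params.to_numpy()
    se = result.bse_fe.to_numpy()
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    fixed = pd.DataFrame({
        "term": ["intercept"] + list(FIXED_TERMS),
        "beta": beta, "se": se, "t": t, "df": df, "p": p,
        "ci_lo": beta - half, "ci_hi": beta + half,
    })
    return LmmFit(
        fixed=fixed,
        random_intercept_sd=float(np.sqrt(result.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(result.scale)),
        aic=float(result.aic),
        bic=float(result.bic),
        loglik=float(result.llf),
        n_obs=n_obs,
    )


def paired_contrast(informed_means, blind_means) -> dict:
    """Paired two-tailed t-test on per-subject mean differences.

    Equivalent to a one-sample t on the differences with df = n - 1.
    Zero-variance differences are flagged degenerate (t = 0, p = 1 when the
    differences are all zero).
    """
    a = np.asarray(informed_means, dtype=float)
    b = np.asarray(blind_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = a - b
    n = len(d)
    if d.std(ddof=1) == 0:
        return {"mean_diff": float(d.mean()), "t": 0.0 if d.mean() == 0 else np.inf,
                "df": n - 1, "p": 1.0 if d.mean() == 0 else 0.0, "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"mean_diff": float(d.mean()), "t": float(t), "df": n - 1,
            "p": float(p), "degenerate": False}
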