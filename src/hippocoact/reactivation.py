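"""Theta -> offline reactivation via linear mixed models.

The reactivation statistic asks whether cell pairs that co-fired in
waking theta cycles also co-fire in the offline events (DS or SWR) of
the following sleep, beyond what their pre-experience offline coactivity
predicts.  Per cell pair the three coactivity weights (theta, pre-sleep
event, post-sleep event) enter the mixed model

    post ~ b0 + b_theta * theta + b_pre * pre + u_mouse + e      (forward)
    pre  ~ b0 + b_theta * theta + b_post * post + u_mouse + e    (reverse)

with a mouse random intercept, fit by restricted maximum likelihood.
Reactivation shows as forward b_theta exceeding reverse b_theta and
exceeding a null distribution built by shuffling cell-pair identity
(theta weights permuted across pairs, within mouse by default to
preserve the random-effect structure) and refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coactivity import CoactivityMatrix

PAIR_COLUMNS = ["mouse_id", "unit_i", "unit_j", "theta", "pre", "post"]


def assemble_pair_table(
    pre: CoactivityMatrix,
    theta: CoactivityMatrix,
    post: CoactivityMatrix,
    mouse_id: str,
) -> pd.DataFrame:
    """Long-form table of upper-triangle weights aligned across conditions."""
    if not (pre.unit_ids == theta.unit_ids == post.unit_ids):
        raise ValueError("coactivity matrices must share the unit roster")
    n = pre.n
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                (mouse_id, pre.unit_ids[i], pre.unit_ids[j],
                 theta.A[i, j], pre.A[i, j], post.A[i, j])
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


@dataclass
class LmmResult:
    """Fixed-effect estimates of one reactivation mixed model."""

    beta_theta: float
    se_theta: float
    ci_theta: tuple[float, float]
    t_theta: float
    df_resid: float
    direction: str
    params: dict
    fit_method: str = "reml"
    singular: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci_theta
        if not (lo <= self.beta_theta <= hi):
            raise ValueError("confidence interval must bracket the estimate")


def fit_reactivation_lmm(table: pd.DataFrame, direction: str = "forward") -> LmmResult:
    """Fit the forward or reverse reactivation mixed model.

    Forward regresses post-sleep event coactivity on theta and pre-sleep
    coactivity; reverse swaps pre and post.  Mouse identity is the random
    intercept (REML).  With a single mouse, falls back to ordinary least
    squares with a warning.  The t degrees of freedom use the residual
    method (n_obs - n_fixed_params).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if direction == "forward":
        formula, control = "post ~ theta + pre", "pre"
    elif direction == "reverse":
        formula, control = "pre ~ theta + post", "post"
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")

    n_mice = table["mouse_id"].nunique()
    singular = False
    if n_mice < 2:
        warnings.warn("single mouse: fitting plain regression (no random intercept)")
        fit = smf.ols(formula, data=table).fit()
        fit_method = "ols"
    else:
        model = smf.mixedlm(formula, data=table, groups=table["mouse_id"])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = model.fit(reml=True, method="lbfgs")
        # report, never absorb, a singular random-effect covariance (the
        # mouse variance sitting on the zero boundary); fixed-effect
        # estimates remain valid in that case
        singular = any("singular" in str(w.message).lower() for w in caught)
        fit_method = "reml"

    beta = float(fit.params["theta"])
    se = float(fit.bse["theta"])
    df_resid = float(len(table) - 3)  # intercept + theta + control
    from scipy.stats import t as tdist

    tval = beta / se if se > 0 else np.inf
    half = tdist.ppf(0.975, df_resid) * se
    return LmmResult(
        beta_theta=beta,
        se_theta=se,
        ci_theta=(beta - half, beta + half),
        t_theta=float(tval),
        df_resid=df_resid,
        direction=direction,
        params={k: float(v) for k, v in fit.params.items() if k != "Group Var"},
        fit_method=fit_method,
        singular=singular,
    )


def shuffle_null(
    table: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
    direction: str = "forward",
    within_mouse: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Cell-pair-shuffle null for the theta coefficient.

    Per shuffle the theta weights are permuted across cell pairs (within
    mouse unless ``within_mouse=False``), the model is refit, and the
    theta coefficient recorded.  Returns (null betas, observed beta,
    empirical two-sided p = fraction of |null| >= |observed|).
    """
    rng = np.random.default_rng(seed)
    observed = fit_reactivation_lmm(table, direction).beta_theta
    null = np.empty(n_shuffles)
    work = table.copy()
    groups = list(table.groupby("mouse_id").indices.values()) if within_mouse else [np.arange(len(table))]
    theta0 = table["theta"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_shuffles):
            shuffled = theta0.copy()
            for idx in groups:
                idx = np.asarray(idx)
                shuffled[idx] = theta0[idx][rng.permutation(len(idx))]
            work["theta"] = shuffled
            null[k] = fit_reactivation_lmm(work, direction).beta_theta
    p = float(np.mean(np.abs(null) >= abs(observed)))
    return null, observed, p
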