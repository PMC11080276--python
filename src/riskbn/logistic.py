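"""Binary logistic regression with forward stepwise selection by
likelihood ratio.

The fitter is straight Newton/IRLS maximum likelihood with the covariance
taken as the inverse observed information.  Categorical predictors are
reference-coded (one indicator per non-reference level) and enter or leave
the stepwise model as whole blocks, tested with a block likelihood-ratio
chi-square — the classic "Forward: LR" procedure with default entry/removal
thresholds 0.05/0.10.  Continuous predictors stay on their raw scale, so
odds ratios are per unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import CATEGORICAL, GROUP_COLUMN, Codebook
from .screening import TestResult

Z_95 = 1.959964  # two-sided 95% normal quantile

MAX_ITER = 50
SCORE_TOL = 1e-8
LL_RTOL = 1e-10
SEPARATION_BETA = 15.0


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation: diverging coefficients."""


class RankDeficientError(ValueError):
    """Design matrix is not full column rank."""


@dataclass
class DesignMatrix:
    """Outcome vector plus named predictor columns grouped into terms.

    ``terms`` maps a variable name to the list of its column names, so a
    categorical variable's indicator block can be tested jointly.
    """

    y: np.ndarray
    X: pd.DataFrame
    terms: dict[str, list[str]]

    def subset(self, variables: list[str]) -> "DesignMatrix":
        cols = [c for v in variables for c in self.terms[v]]
        return DesignMatrix(
            y=self.y,
            X=self.X[cols],
            terms={v: list(self.terms[v]) for v in variables},
        )


def build_design(
    cohort: pd.DataFrame,
    case_group: str,
    variables: list[str],
    codebook: Codebook,
) -> DesignMatrix:
    """Reference-coded design matrix for case-vs-control regression."""
    sub = cohort[cohort[GROUP_COLUMN].isin(["control", case_group])]
    y = (sub[GROUP_COLUMN] == case_group).to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    terms: dict[str, list[str]] = {}
    for var in variables:
        spec = codebook[var]
        x = sub[var].to_numpy()
        if spec.kind == CATEGORICAL:
            code_to_label = {c: lab for lab, c in spec.states.items()}
            block = []
            for code in sorted(spec.states.values()):
                if code == spec.reference_code:
                    continue
                if not np.any(x == code):  # level absent in these two groups
                    continue
                name = f"{var}[{code_to_label[code]}]"
                cols[name] = (x == code).astype(float)
                block.append(name)
            terms[var] = block
        else:
            cols[var] = x.astype(float)
            terms[var] = [var]
    return DesignMatrix(y=y, X=pd.DataFrame(cols, index=sub.index), terms=terms)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit."""

    params: pd.Series  # includes "intercept"
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool
    n_iter: int
    n_obs: int
    separable_terms: list[str] = field(default_factory=list)

    @property
    def wald_chi2(self) -> pd.Series:
        return (self.params / self.bse) ** 2

    @property
    def p_values(self) -> pd.Series:
        return pd.Series(
            stats.chi2.sf(self.wald_chi2, df=1), index=self.params.index
        )

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        """Per-term Beta, SE, Wald chi-square, P, OR and CI (Table 4 layout)."""
        z = stats.norm.ppf(1 - (1 - level) / 2)
        out = pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "wald_chi2": self.wald_chi2,
                "p_value": self.p_values,
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
            }
        )
        return out


def fit_logistic(design: DesignMatrix) -> LogisticFit:
    """Newton/IRLS maximum likelihood for binary logistic regression.

    Converges when the score's max absolute entry drops below 1e-8 or the
    relative log-likelihood change below 1e-10.  Raises
    :class:`RankDeficientError` naming collinear columns and flags
    separation (|beta| > 15 or 50 iterations without convergence).
    """
    y = np.asarray(design.y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome needs at least one event and one non-event")
    names = ["intercept"] + list(design.X.columns)
    X = np.column_stack([np.ones(len(y)), design.X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR localizes the dependent columns
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, pivoting=True)
        bad = [names[piv[j]] for j in range(rank, X.shape[1])]
        raise RankDeficientError(f"collinear columns: {bad}")

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        score = X.T @ (y - mu)
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if np.max(np.abs(score)) < SCORE_TOL or (
            np.isfinite(ll_old)
            and abs(ll - ll_old) < LL_RTOL * (abs(ll_old) + 1.0)
        ):
            converged = True
            break
        ll_old = ll
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from None
        # damped Newton: halve until the likelihood does not decrease
        for _ in range(30):
            cand = beta + step
            mu_c = np.clip(1.0 / (1.0 + np.exp(-(X @ cand))), 1e-12, 1 - 1e-12)
            ll_c = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    separable = [
        names[j] for j in range(len(beta)) if abs(beta[j]) > SEPARATION_BETA
    ]
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=llf,
        converged=converged and not separable,
        n_iter=it,
        n_obs=len(y),
        separable_terms=separable,
    )


def lr_test(full: LogisticFit, reduced: LogisticFit) -> TestResult:
    """Likelihood-ratio chi-square between nested fits on the same rows."""
    full_terms = set(full.params.index)
    red_terms = set(reduced.params.index)
    if not red_terms <= full_terms or full.n_obs != reduced.n_obs:
        raise ValueError("models are not nested on the same data")
    df = len(full_terms) - len(red_terms)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return TestResult("chi2", chi2, p, df=float(df))


@dataclass(frozen=True)
class StepwiseStep:
    step: int
    action: str  # "enter" or "remove"
    variable: str
    lr_chi2: float
    df: float
    p_value: float


def stepwise_forward_lr(
    design: DesignMatrix,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> tuple[LogisticFit, list[StepwiseStep]]:
    """Forward stepwise selection by likelihood-ratio criterion.

    At each step the candidate with the smallest block-LR p-value below
    ``p_enter`` enters (ties broken by candidate order, then name); after
    every entry, included variables whose removal LR p exceeds ``p_remove``
    are dropped (worst first).  Stops when no move is possible; an
    intercept-only model is a legal result.
    """
    candidates = list(design.terms)
    included: list[str] = []
    trace: list[StepwiseStep] = []
    current = fit_logistic(design.subset([]))
    seen_models = {frozenset()}
    step_no = 0
    while True:
        # --- entry ---
        best = None
        for var in candidates:
            if var in included or not design.terms[var]:
                continue
            trial = fit_logistic(design.subset(included + [var]))
            res = lr_test(trial, current)
            key = (res.p_value, candidates.index(var), var)
            if best is None or key < best[0]:
                best = (key, var, trial, res)
        if best is None or best[3].p_value >= p_enter:
            break
        step_no += 1
        _, var, current, res = best
        included.append(var)
        trace.append(
            StepwiseStep(step_no, "enter", var, res.statistic, res.df,
                         res.p_value)
        )
        # --- removal sweep ---
        while len(included) > 1:
            worst = None
            for var in included:
                reduced = fit_logistic(
                    design.subset([v for v in included if v != var])
                )
                res = lr_test(current, reduced)
                if worst is None or res.p_value > worst[1].p_value:
                    worst = (var, res, reduced)
            if worst is None or worst[1].p_value <= p_remove:
                break
            step_no += 1
            var, res, current = worst[0], worst[1], worst[2]
            included.remove(var)
            trace.append(
                StepwiseStep(step_no, "remove", var, res.statistic, res.df,
                             res.p_value)
            )
        state = frozenset(included)
        if state in seen_models:  # cycling guard
            break
        seen_models.add(state)
    return current, trace


def odds_ratios(fit: LogisticFit, level: float = 0.95) -> pd.DataFrame:
    """Per-term odds ratios with a Wald confidence interval."""
    return fit.summary_frame(level=level)[["or", "ci_low", "ci_high"]]
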