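"""Conditional logistic regression for 1:m matched case-control sets.

The conditional likelihood for a matched set with one case and m controls
is the probability that the case is the member with the observed
covariates, given that exactly one member is a case:

    L_s(beta) = exp(beta' x_case) / sum_j exp(beta' x_j)

so the log-likelihood is ``sum_s [beta' x_case - logsumexp_j beta' x_j]``.
Conditioning eliminates every set-level term, which is what controls for
the matching variables.  The maximiser is found by Newton-Raphson with
step halving; Wald standard errors come from the inverse observed
information.  Covariates that never vary within a set (e.g. a variable
matched exactly) carry no information and are dropped with a note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "MatchedData",
    "ClogitResult",
    "conditional_loglik",
    "fit_clogit",
    "score_test",
    "analyze_all",
    "NonIdentifiableError",
]

SEPARATION_BETA = 15.0


class NonIdentifiableError(ValueError):
    """No covariate varies within any matched set: the likelihood is flat."""


@dataclass
class MatchedData:
    """Stacked representation of matched sets.

    ``x`` is (n_members, n_covariates); ``group`` maps each member to its
    set; ``is_case`` marks exactly one member per set.
    """

    x: np.ndarray
    group: np.ndarray
    is_case: np.ndarray
    terms: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.group = np.asarray(self.group)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.x.ndim != 2 or len(self.group) != len(self.x) or len(self.is_case) != len(self.x):
            raise ValueError("x, group and is_case must have matching first dimension")
        for g in np.unique(self.group):
            n_cases = self.is_case[self.group == g].sum()
            if n_cases != 1:
                raise ValueError(f"matched set {g!r} has {n_cases} cases; expected exactly 1")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, terms: list[str], set_col: str = "set_id", case_col: str = "is_case"
    ) -> "MatchedData":
        return cls(
            x=df[terms].to_numpy(dtype=float),
            group=df[set_col].to_numpy(),
            is_case=df[case_col].to_numpy(dtype=bool),
            terms=list(terms),
        )


def _set_slices(group: np.ndarray) -> list[np.ndarray]:
    order = {}
    for i, g in enumerate(group):
        order.setdefault(g, []).append(i)
    return [np.asarray(ix) for ix in order.values()]


def conditional_loglik(
    data: MatchedData, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Conditional log-likelihood with analytic gradient and Hessian.

    Per set: ``ll = beta'x_case - logsumexp_j(beta'x_j)``; gradient is
    ``x_case - sum_j w_j x_j`` and the Hessian is minus the softmax-weighted
    covariance of the member covariates, with weights
    ``w_j = softmax(beta'x_j)``.  Computed with log-sum-exp for stability.
    """
    beta = np.asarray(beta, dtype=float)
    eta = data.x @ beta
    ll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((beta.size, beta.size))
    for ix in _set_slices(data.group):
        eta_s = eta[ix]
        x_s = data.x[ix]
        case = data.is_case[ix]
        lse = logsumexp(eta_s)
        w = np.exp(eta_s - lse)
        xbar = w @ x_s
        ll += float(eta_s[case][0] - lse)
        grad += x_s[case][0] - xbar
        centered = x_s - xbar
        hess -= (centered * w[:, None]).T @ centered
    return ll, grad, hess


@dataclass
class ClogitResult:
    """Point estimates with Wald inference for one conditional-logit fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_sets: int
    n_members: int
    message: str = ""
    dropped_terms: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def conf_int(self) -> np.ndarray:
        z = norm.ppf(1 - self.alpha / 2)
        return np.exp(
            np.column_stack([self.beta - z * self.se, self.beta + z * self.se])
        )

    @property
    def p_values(self) -> np.ndarray:
        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan), where=self.se > 0)
        return 2 * norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "or": self.odds_ratio,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p_values,
                "converged": self.converged,
            }
        )


def _drop_constant_within_sets(data: MatchedData) -> tuple[MatchedData, list[str]]:
    keep, dropped = [], []
    for j, term in enumerate(data.terms):
        varies = any(
            np.ptp(data.x[ix, j]) > 0 for ix in _set_slices(data.group)
        )
        (keep if varies else dropped).append(j)
    if not keep:
        raise NonIdentifiableError(
            "no covariate varies within any matched set; the conditional "
            "likelihood carries no information"
        )
    sub = MatchedData(
        x=data.x[:, keep],
        group=data.group,
        is_case=data.is_case,
        terms=[data.terms[j] for j in keep],
    )
    return sub, [data.terms[j] for j in dropped]


def fit_clogit(
    data: MatchedData,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
) -> ClogitResult:
    """Newton-Raphson maximiser of the conditional likelihood from beta = 0.

    Convergence when the largest score component is below ``score_tol`` or
    the Newton step is below ``step_tol``.  Estimates drifting past
    ``|beta| > 15`` are flagged as non-converged (complete or
    quasi-separation) and no inference is reported for them.
    """
    data, dropped = _drop_constant_within_sets(data)
    p = data.x.shape[1]
    beta = np.zeros(p)
    converged = False
    message = "max iterations reached"
    ll, grad, hess = conditional_loglik(data, beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # Step-halving line search on the log-likelihood.
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new, grad_new, hess_new = conditional_loglik(data, candidate)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = candidate, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            message = "possible complete or quasi-separation (|beta| > 15)"
            break
        if np.max(np.abs(grad)) < score_tol or np.linalg.norm(scale * step) < step_tol:
            converged = True
            message = "converged"
            break
    if converged:
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            converged = False
            message = "singular information at optimum"
            se = np.full(p, np.nan)
    else:
        se = np.full(p, np.nan)
        beta = np.full(p, np.nan) if "separation" in message else beta
    n_sets = len(np.unique(data.group))
    return ClogitResult(
        terms=data.terms,
        beta=beta,
        se=se,
        loglik=ll,
        converged=converged,
        n_sets=n_sets,
        n_members=len(data.x),
        message=message,
        dropped_terms=dropped,
    )


def score_test(data: MatchedData, term_index: int = 0, max_iter: int = 50) -> float:
    """Score (Rao) test p-value for one term at zero, profiling the others.

    The nuisance coefficients are maximised with the tested term fixed at
    zero; the statistic is the squared efficient score over the partial
    information, referred to chi-square(1).  Unlike the Wald test it is
    defined under complete or quasi-separation and is close to nominal at
    small numbers of matched sets, where the Wald test is conservative.
    """
    p = data.x.shape[1]
    beta = np.zeros(p)
    nuisance = [j for j in range(p) if j != term_index]
    if nuisance:
        for _ in range(max_iter):
            _, grad, hess = conditional_loglik(data, beta)
            sub_h = hess[np.ix_(nuisance, nuisance)]
            try:
                step = np.linalg.solve(sub_h, -grad[nuisance])
            except np.linalg.LinAlgError:
                return float("nan")
            beta[nuisance] += step
            if np.max(np.abs(grad[nuisance])) < 1e-8:
                break
    _, grad, hess = conditional_loglik(data, beta)
    i00 = -hess[term_index, term_index]
    if nuisance:
        i01 = -hess[term_index, nuisance]
        i11 = -hess[np.ix_(nuisance, nuisance)]
        try:
            i00 = i00 - i01 @ np.linalg.solve(i11, i01)
        except np.linalg.LinAlgError:
            return float("nan")
    if i00 <= 0:
        return float("nan")
    from scipy.stats import chi2

    return float(chi2.sf(grad[term_index] ** 2 / i00, 1))


def build_matched_data(
    calls: pd.DataFrame,
    participants: pd.DataFrame,
    method: str,
    week: int,
    drug: str,
    adjust: tuple[str, ...] = ("weight_kg", "sex"),
) -> MatchedData | None:
    """Assemble matched sets for one (method, week, drug) analysis cell.

    The exposure is the non-adherence indicator.  Sets whose case lacks a
    call at this week (missing sample) are dropped whole; sets keep any
    controls that do have calls.  Returns ``None`` when no set remains.
    """
    cell = calls[
        (calls["method"] == method) & (calls["week"] == week) & (calls["drug"] == drug)
    ]
    if cell.empty:
        return None
    merged = cell.merge(participants, on="participant_id", how="left")
    merged = merged.assign(
        non_adherent=(merged["status"] == "non-adherent").astype(float),
        is_case=merged["group"] == "case",
        sex_male=(merged["sex"] == "male").astype(float),
    )
    keep_sets = merged.groupby("set_id")["is_case"].any()
    merged = merged[merged["set_id"].map(keep_sets)]
    # also need at least one control per retained set
    n_controls = merged.groupby("set_id")["is_case"].apply(lambda s: (~s).sum())
    merged = merged[merged["set_id"].map(n_controls) >= 1]
    if merged.empty:
        return None
    terms = ["non_adherent"] + [
        "sex_male" if t == "sex" else t for t in adjust
    ]
    return MatchedData.from_frame(merged, terms)


def analyze_all(
    calls: pd.DataFrame,
    participants: pd.DataFrame,
    methods: list[str] | None = None,
    weeks: tuple[int, ...] = (2, 4, 8),
    drugs: tuple[str, ...] | None = None,
    adjust: tuple[str, ...] = ("weight_kg", "sex"),
) -> pd.DataFrame:
    """One conditional-logit fit per (drug, method, week) analysis cell.

    Failures in one cell (non-identifiability, separation, no informative
    calls) are recorded in that cell's rows without aborting the others.
    Returns a tidy results frame with one row per term per cell.
    """
    methods = methods or sorted(calls["method"].unique())
    drugs = drugs or tuple(sorted(calls["drug"].unique()))
    rows = []
    for drug in drugs:
        for method in methods:
            for week in weeks:
                base = {"drug": drug, "method": method, "week": week}
                data = build_matched_data(calls, participants, method, week, drug, adjust)
                if data is None:
                    rows.append({**base, "term": "non_adherent", "status": "uninformative"})
                    continue
                try:
                    res = fit_clogit(data)
                except NonIdentifiableError as err:
                    rows.append(
                        {**base, "term": "non_adherent", "status": f"non-identifiable: {err}"}
                    )
                    continue
                if "non_adherent" in res.dropped_terms:
                    # weight may still vary within sets, but a fit without the
                    # exposure answers no adherence question
                    rows.append(
                        {
                            **base,
                            "term": "non_adherent",
                            "status": "non-identifiable: non-adherence constant within every set",
                        }
                    )
                    continue
                reduced, _ = _drop_constant_within_sets(data)
                p_score = score_test(reduced, reduced.terms.index("non_adherent"))
                frame = res.summary_frame()
                for rec in frame.to_dict("records"):
                    rows.append(
                        {
                            **base,
                            **rec,
                            "p_score": p_score if rec["term"] == "non_adherent" else np.nan,
                            "status": res.message,
                            "n_sets": res.n_sets,
                        }
                    )
    return pd.DataFrame(rows)
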