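"""Directional risk score, median dichotomization, and Firth logistic fits.

The risk score is a linear combination of the concordant candidate genes
in which up-regulated genes enter with a plus sign and down-regulated
genes enter as ``offset - expression``, where the offset is the smallest
integer strictly greater than the gene's maximum observed log2 value
across all cohorts (so every term increases with PE risk and stays
positive).  The score is split at its per-cohort median and its
association with case status is quantified by a logistic regression with
Firth's Jeffreys-prior penalty, which keeps estimates finite even under
complete separation.  On a saturated 2x2 design the Firth fit coincides
with the classical half-count-corrected odds ratio, which this module
also exposes as an independent closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import ExpressionMatrix, ValidationError, normalize_gene


@dataclass(frozen=True)
class ScoreDefinition:
    """Directional linear score: sum of up-genes plus (offset - gene) terms."""

    up_genes: tuple[str, ...] = ()
    down_genes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        up = tuple(normalize_gene(g) for g in self.up_genes)
        down = {normalize_gene(g): o for g, o in dict(self.down_genes).items()}
        for gene, offset in down.items():
            if int(offset) != offset:
                raise ValueError(f"offset for {gene} must be an integer, got {offset!r}")
        overlap = set(up) & set(down)
        if overlap:
            raise ValueError(f"genes cannot be both up and down: {sorted(overlap)}")
        if len(set(up)) != len(up):
            raise ValueError("duplicate up-genes")
        if not up and not down:
            raise ValueError("score definition has no genes")
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", {g: int(o) for g, o in down.items()})

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up_genes + tuple(self.down_genes)


def compute_offsets(
    expr_by_cohort: Sequence[ExpressionMatrix], down_genes: Sequence[str]
) -> dict[str, int]:
    """Smallest integer strictly above each gene's maximum across cohorts."""
    offsets: dict[str, int] = {}
    for gene in (normalize_gene(g) for g in down_genes):
        maxima = []
        for expr in expr_by_cohort:
            expr.require_genes([gene])
            maxima.append(float(expr.values.loc[gene].max()))
        observed = max(maxima)
        offsets[gene] = int(math.floor(observed)) + 1  # strict: 9.0 -> 10
    return offsets


def compute_score(expr: ExpressionMatrix, definition: ScoreDefinition) -> pd.Series:
    """Per-sample risk score (log2-expression units)."""
    expr.require_genes(definition.genes)
    score = pd.Series(0.0, index=expr.values.columns, name="risk_score")
    for gene in definition.up_genes:
        score += expr.values.loc[gene]
    for gene, offset in definition.down_genes.items():
        score += offset - expr.values.loc[gene]
    return score


@dataclass
class RiskScoreResult:
    """Per-sample scores with the per-cohort median split."""

    scores: pd.Series
    median: float
    group: pd.Series  # "low" / "high" per sample

    @property
    def n_low(self) -> int:
        return int((self.group == "low").sum())

    @property
    def n_high(self) -> int:
        return int((self.group == "high").sum())


def dichotomize(scores: pd.Series, tie: str = "high") -> RiskScoreResult:
    """Split scores at the cohort median.

    Samples strictly below the median are "low" and strictly above are
    "high"; a sample exactly at the median goes to the group named by
    ``tie``.  The default ``tie="high"`` reproduces the published 78/79
    low/high split for 157 distinct scores (odd n puts the middle sample
    in the high row).
    """
    if tie not in ("low", "high"):
        raise ValueError("tie must be 'low' or 'high'")
    scores = pd.Series(scores).astype(float)
    if scores.size < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    med = float(scores.median())
    if tie == "high":
        group = pd.Series(np.where(scores < med, "low", "high"), index=scores.index)
    else:
        group = pd.Series(np.where(scores <= med, "low", "high"), index=scores.index)
    group.name = "score_group"
    return RiskScoreResult(scores=scores, median=med, group=group)


@dataclass
class FirthFit:
    """Penalized-likelihood logistic fit for one covariate."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    n_iter: int
    intercept: float = 0.0

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def firth_logistic(
    y, x, max_iter: int = 25, tol: float = 1e-9
) -> FirthFit:
    """Firth-penalized logistic regression of binary ``y`` on one covariate.

    Maximizes l(b) + 0.5 log det I(b) by Newton iteration on the modified
    score U*(b) = X'(y - p + h (0.5 - p)), where h are the hat-matrix
    diagonals; step-halving guards against penalized-likelihood decreases.
    Convergence requires max |U*| < ``tol``.  The Wald 95% CI is
    exp(beta +/- 1.96 se) with se from the penalized information.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome contains a single class; association undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)

    def penalized_loglik(b: np.ndarray) -> float:
        eta = X @ b
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll + 0.5 * logdet

    ll_old = penalized_loglik(beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X.T @ (X * w[:, None])
        inv_info = np.linalg.inv(info)
        # hat diagonals of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        h = np.einsum("ij,jk,ik->i", X, inv_info, X) * w
        u_star = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(u_star)) < tol:
            converged = True
            break
        step = inv_info @ u_star
        new_beta = beta + step
        ll_new = penalized_loglik(new_beta)
        halvings = 0
        while ll_new < ll_old and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            ll_new = penalized_loglik(new_beta)
            halvings += 1
        beta = new_beta
        ll_old = ll_new
    else:
        # final score check after exhausting iterations
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X.T @ (X * w[:, None])
        inv_info = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, inv_info, X) * w
        u_star = X.T @ (y - p + h * (0.5 - p))
        converged = bool(np.max(np.abs(u_star)) < tol)

    p_fit = expit(X @ beta)
    w = np.clip(p_fit * (1 - p_fit), 1e-12, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z = b / se if se > 0 else math.inf * np.sign(b)
    p_value = 2.0 * float(stats.norm.sf(abs(z)))
    return FirthFit(
        beta=b,
        se=se,
        or_=math.exp(b),
        ci_low=math.exp(b - 1.96 * se),
        ci_high=math.exp(b + 1.96 * se),
        p=min(p_value, 1.0),
        converged=converged,
        n_iter=n_iter,
        intercept=float(beta[0]),
    )


def odds_ratio_closed_form(
    control_low: int, case_low: int, control_high: int, case_high: int
) -> float:
    """Half-count-corrected odds ratio of a 2x2 table.

    ((a + 1/2)(d + 1/2)) / ((b + 1/2)(c + 1/2)) with a = controls in the
    low group, b = cases low, c = controls high, d = cases high.  The
    correction keeps the estimate finite with zero cells and is the exact
    Firth estimate for the saturated 2x2 logistic model.
    """
    a, b, c, d = control_low, case_low, control_high, case_high
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def expand_2x2(
    control_low: int, case_low: int, control_high: int, case_high: int
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level (y, x) arrays from 2x2 counts (x = 1 for high score)."""
    y = np.concatenate([
        np.zeros(control_low), np.ones(case_low),
        np.zeros(control_high), np.ones(case_high),
    ])
    x = np.concatenate([
        np.zeros(control_low + case_low), np.ones(control_high + case_high),
    ])
    return y, x


def firth_from_counts(
    control_low: int, case_low: int, control_high: int, case_high: int, **kwargs
) -> FirthFit:
    """Firth fit of case status on the high/low indicator from 2x2 counts."""
    y, x = expand_2x2(control_low, case_low, control_high, case_high)
    return firth_logistic(y, x, **kwargs)


def association_table(
    risk: RiskScoreResult, condition: pd.Series
) -> pd.DataFrame:
    """2x2 summary (counts and row percentages) of score group vs condition."""
    condition = condition.reindex(risk.group.index)
    if condition.isna().any():
        raise ValidationError("condition missing for some scored samples")
    rows = []
    for grp in ("low", "high"):
        in_grp = risk.group == grp
        n = int(in_grp.sum())
        n_case = int((condition[in_grp] == "PE").sum())
        n_ctrl = n - n_case
        rows.append(
            {
                "score_group": grp,
                "n": n,
                "n_non_pe": n_ctrl,
                "pct_non_pe": 100.0 * n_ctrl / n if n else float("nan"),
                "n_pe": n_case,
                "pct_pe": 100.0 * n_case / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("score_group")
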