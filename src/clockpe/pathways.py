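"""Differential pathway testing and risk-score/pathway correlations.

Two complementary views of the pathway-score matrix: an empirical-Bayes
moderated t-test between conditions (per-set variances shrunk toward a
pooled prior estimated by closed-form method of moments on log s^2), and
Pearson correlation of every pathway's per-sample score with the
continuous clock-gene risk score, with Fisher-z 95% confidence intervals.
Both use the same Benjamini–Hochberg adjustment and the dual p < 0.05 /
adjusted p < 0.10 filter, and two cohorts' retained pathways are
intersected requiring a concordant correlation sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .diffexpr import SignificanceThresholds, bh_adjust
from .io import PhenotypeTable, ValidationError


def _trigamma(x):
    return polygamma(1, x)


def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton on 1/trigamma."""
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for scaled-inverse-chi2 variances.

    Matches the mean and variance of log s^2 to the theoretical moments:
    e_g = log(s2_g) - digamma(df/2) + log(df/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2).  When
    the observed variance of e is no larger than trigamma(df/2), d0 is
    infinite and every variance shrinks to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("variance prior estimation needs >= 2 sets")
    e = np.log(np.clip(s2, 1e-300, None)) - float(digamma(df / 2)) + math.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(_trigamma(df / 2))
    if excess <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(digamma(d0 / 2)) - math.log(d0 / 2))
    return d0, s0_sq


def moderated_t(
    scores: pd.DataFrame,
    pheno: PhenotypeTable,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t-test per pathway.

    ``scores`` is sets x samples.  Residual variances pool the two groups
    (d = nA + nB - 2 per set); the prior (d0, s0^2) is estimated across
    sets unless supplied.  ``prior_df=0`` recovers the ordinary t-test;
    ``prior_df=inf`` uses the common variance everywhere.
    """
    ctrl_ids = [s for s in scores.columns if s in set(pheno.samples_with("non-PE"))]
    case_ids = [s for s in scores.columns if s in set(pheno.samples_with("PE"))]
    n1, n2 = len(ctrl_ids), len(case_ids)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each condition needs >= 2 samples")
    if scores.shape[0] < 2 and prior_df is None:
        raise ValidationError("variance pooling needs >= 2 pathways")
    a = scores[ctrl_ids].to_numpy()
    b = scores[case_ids].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    df_resid = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df_resid

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_var) if prior_var is not None else float(np.mean(s2))

    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    diff = mean_b - mean_a  # case minus control
    with np.errstate(divide="ignore", invalid="ignore"):
        t_tilde = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_tilde))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_tilde), df_total)
    p = np.minimum(p, 1.0)
    out = pd.DataFrame(
        {
            "mean_control": mean_a,
            "mean_case": mean_b,
            "t": t_tilde,
            "df": df_total,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=scores.index,
    )
    out["direction"] = np.where(diff > 0, "up_in_case", np.where(diff < 0, "down_in_case", "none"))
    out["significant"] = (out["p"] < thresholds.alpha_p) & (out["adj_p"] < thresholds.alpha_q)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


@dataclass
class CorrelationRecord:
    """Pearson correlation with a Fisher-z 95% confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def pearson_with_ci(x, y) -> CorrelationRecord:
    """Pearson r, two-sided p from the t transform, and Fisher-z 95% CI.

    CI = tanh(atanh(r) +/- 1.96 / sqrt(n - 3)).  |r| = 1 degenerates to a
    zero-width interval and p = 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have the same length")
    if n < 4:
        raise ValueError("need n >= 4 for a correlation CI")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return CorrelationRecord(r=r, ci_low=r, ci_high=r, p=0.0, n=n)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    half = 1.96 / math.sqrt(n - 3)
    zr = math.atanh(r)
    return CorrelationRecord(
        r=r,
        ci_low=math.tanh(zr - half),
        ci_high=math.tanh(zr + half),
        p=min(p, 1.0),
        n=n,
    )


def score_pathway_table(
    scores: pd.DataFrame,
    risk_scores: pd.Series,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> pd.DataFrame:
    """Correlate every pathway's scores with the continuous risk score.

    Returns a table of r, CI, p, and BH q per set plus a ``significant``
    flag for the dual p < alpha_p / q < alpha_q filter.  Sample ids of
    the two inputs must match exactly.
    """
    if set(scores.columns) != set(risk_scores.index):
        raise ValidationError("sample ids of pathway scores and risk scores differ")
    risk = risk_scores[list(scores.columns)].to_numpy()
    rows = []
    for name in scores.index:
        rec = pearson_with_ci(risk, scores.loc[name].to_numpy())
        rows.append(
            {"pathway": name, "r": rec.r, "ci_low": rec.ci_low,
             "ci_high": rec.ci_high, "p": rec.p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "r", "ci_low", "ci_high", "p", "q", "significant"]
        ).set_index("pathway")
    out = pd.DataFrame(rows).set_index("pathway")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p"] < thresholds.alpha_p) & (out["q"] < thresholds.alpha_q)
    return out


@dataclass
class PathwayOverlap:
    """Cross-cohort intersection of retained pathways, split by sign."""

    decreased: pd.DataFrame
    increased: pd.DataFrame
    discordant: list[str]

    @property
    def n_common(self) -> int:
        return len(self.decreased) + len(self.increased)


def overlap_pathways(table_a: pd.DataFrame, table_b: pd.DataFrame) -> PathwayOverlap:
    """Intersect two retained-pathway correlation tables by name.

    Only pathways flagged significant in both cohorts are considered;
    concordant-sign pathways are partitioned into decreased (r < 0) and
    increased (r > 0); discordant ones are excluded and listed.
    """
    sig_a = table_a[table_a["significant"]] if "significant" in table_a else table_a
    sig_b = table_b[table_b["significant"]] if "significant" in table_b else table_b
    common = sorted(set(sig_a.index) & set(sig_b.index))
    rows = []
    discordant: list[str] = []
    for name in common:
        ra, rb = float(sig_a.loc[name, "r"]), float(sig_b.loc[name, "r"])
        if ra * rb > 0:
            rows.append({"pathway": name, "r_a": ra, "r_b": rb})
        else:
            discordant.append(name)
    merged = pd.DataFrame(rows, columns=["pathway", "r_a", "r_b"]).set_index("pathway")
    return PathwayOverlap(
        decreased=merged[merged["r_a"] < 0],
        increased=merged[merged["r_a"] > 0],
        discordant=discordant,
    )
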