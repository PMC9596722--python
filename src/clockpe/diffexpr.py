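"""Per-gene two-group testing, FDR adjustment, and cross-cohort overlap.

The candidate-gene stage of the pipeline: for every gene, a two-sample
two-tailed t-test between the PE and non-PE groups, Benjamini–Hochberg
adjustment across the candidate list, a signed percent-change summary of
the group means, significance filtering (p < 0.05 and q < 0.10 by
default), and the intersection of the significant genes of two cohorts
with direction concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PhenotypeTable, ValidationError, normalize_gene

UP = "up_in_case"
DOWN = "down_in_case"
NONE = "none"


@dataclass(frozen=True)
class SignificanceThresholds:
    """Dual cut-off: raw p-value and BH-adjusted q-value."""

    alpha_p: float = 0.05
    alpha_q: float = 0.10

    def __post_init__(self) -> None:
        for name, v in (("alpha_p", self.alpha_p), ("alpha_q", self.alpha_q)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def two_sample_t(
    x: np.ndarray, y: np.ndarray, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample two-sided t-test of x (group 1) vs y (group 2).

    Returns ``(t, df, p)`` with ``t`` based on ``mean(x) - mean(y)``.
    ``variant`` is ``"pooled"`` (Student, common variance) or ``"welch"``
    (Satterthwaite degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return summary_t(
        x.size, x.mean(), x.std(ddof=1), y.size, y.mean(), y.std(ddof=1), variant
    )


def summary_t(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Same statistic as :func:`two_sample_t`, from group summaries.

    Working from (n, mean, SD) triples lets the test be verified directly
    against published descriptive tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        if v1 + v2 == 0.0:
            df = float(n1 + n2 - 2)
        else:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    diff = m1 - m2
    if se == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0  # identical degenerate groups
        t = math.inf if diff > 0 else -math.inf
        return t, df, 0.0
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values,
    mapped back to the original positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def percent_change(mean_control: float, mean_case: float) -> float:
    """Signed percent change of the case mean relative to the control mean."""
    if mean_control == 0.0:
        raise ValueError("control mean is zero; percent change undefined")
    return (mean_case - mean_control) / mean_control * 100.0


def _direction(mean_control: float, mean_case: float) -> str:
    if mean_case > mean_control:
        return UP
    if mean_case < mean_control:
        return DOWN
    return NONE


def gene_stats_from_summaries(
    summaries: dict[str, tuple[int, float, float, int, float, float]],
    variant: str = "pooled",
) -> pd.DataFrame:
    """Build the per-gene statistics table from (n, mean, SD) group triples.

    ``summaries`` maps gene -> (n_control, mean_control, sd_control,
    n_case, mean_case, sd_case).  BH adjustment runs across the supplied
    gene list (the candidate list defines m).
    """
    rows = []
    for gene, (n1, m1, s1, n2, m2, s2) in summaries.items():
        t, df, p = summary_t(n1, m1, s1, n2, m2, s2, variant)
        rows.append(
            {
                "gene": normalize_gene(gene),
                "n_control": n1, "mean_control": m1, "sd_control": s1,
                "n_case": n2, "mean_case": m2, "sd_case": s2,
                "t": t, "df": df, "p": p,
                "pct_change": percent_change(m1, m2),
                "direction": _direction(m1, m2),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def differential_expression(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    genes=None,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-gene two-group statistics for one cohort.

    Restricts to ``genes`` when given (the candidate list; BH m equals its
    length), otherwise tests every gene in the matrix.
    """
    pheno.check_matches(expr)
    if genes is None:
        genes = expr.gene_ids
    genes = [normalize_gene(g) for g in genes]
    expr.require_genes(genes)
    control_ids = [s for s in expr.sample_ids if s in set(pheno.samples_with("non-PE"))]
    case_ids = [s for s in expr.sample_ids if s in set(pheno.samples_with("PE"))]
    if len(control_ids) < 2 or len(case_ids) < 2:
        raise ValidationError("each condition needs at least 2 samples")
    ctrl = expr.values.loc[genes, control_ids].to_numpy()
    case = expr.values.loc[genes, case_ids].to_numpy()
    summaries = {
        g: (
            ctrl.shape[1], float(ctrl[i].mean()), float(ctrl[i].std(ddof=1)),
            case.shape[1], float(case[i].mean()), float(case[i].std(ddof=1)),
        )
        for i, g in enumerate(genes)
    }
    return gene_stats_from_summaries(summaries, variant=variant)


def significant_genes(
    stats_table: pd.DataFrame,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> dict[str, str]:
    """Genes passing p < alpha_p AND q < alpha_q, with their direction."""
    if stats_table.empty:
        return {}
    keep = (stats_table["p"] < thresholds.alpha_p) & (
        stats_table["q"] < thresholds.alpha_q
    )
    return dict(stats_table.loc[keep, "direction"])


@dataclass
class OverlapResult:
    """Cross-cohort intersection of significant genes.

    ``common`` maps each concordant gene to its shared direction;
    ``discordant`` lists genes significant in both cohorts but with
    opposite directions (excluded from ``common`` by default).
    """

    common: dict[str, str] = field(default_factory=dict)
    discordant: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.common)


def overlap_datasets(
    sig_a: dict[str, str],
    sig_b: dict[str, str],
    allow_discordant: bool = False,
) -> OverlapResult:
    """Intersect two significant-gene maps, requiring direction concordance."""
    result = OverlapResult()
    for gene in sorted(set(sig_a) & set(sig_b)):
        if sig_a[gene] == sig_b[gene]:
            result.common[gene] = sig_a[gene]
        else:
            result.discordant.append(gene)
            if allow_discordant:
                result.common[gene] = NONE
    return result
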