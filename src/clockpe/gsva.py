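"""Single-sample gene-set variation scoring (the GSVA statistic).

Three steps, all deterministic:

1. Per gene, a Gaussian-kernel-smoothed empirical CDF evaluated at each
   sample: ``z_ij = mean_k Phi((x_ij - x_ik) / h_i)`` with per-gene
   bandwidth ``h_i = sd_i / bandwidth_divisor``.
2. Per sample, genes are ranked by decreasing z and given the symmetric
   rank weight ``|N/2 - rank|`` (largest in the tails).
3. Per set and sample, a weighted Kolmogorov–Smirnov-like random walk
   down the ranked list; the enrichment score is either the difference
   between the largest positive and largest negative deviation ("diff")
   or the signed largest deviation ("maxdev"), and always lies in
   [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ExpressionMatrix, GeneSetCollection, ValidationError


@dataclass(frozen=True)
class GsvaParams:
    tau: float = 1.0
    bandwidth_divisor: float = 4.0
    es_mode: str = "diff"  # "diff" or "maxdev"
    min_set_size: int = 5
    max_set_size: int = 500

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.bandwidth_divisor <= 0:
            raise ValueError("bandwidth_divisor must be > 0")
        if self.es_mode not in ("diff", "maxdev"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must be <= max_set_size")


def expression_statistic(
    expr: ExpressionMatrix, params: GsvaParams = GsvaParams()
) -> pd.DataFrame:
    """Kernel-CDF statistic z (genes x samples), strictly increasing per gene.

    A zero-variance gene degenerates to the tie-sharing ECDF limit (every
    sample gets the same value); a warning is emitted.
    """
    X = expr.values.to_numpy()
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValidationError("kernel density statistic needs >= 3 samples")
    sd = X.std(axis=1, ddof=1)
    z = np.empty_like(X)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); statistic set to the "
            "tied-ECDF limit",
            stacklevel=2,
        )
        z[flat] = 0.5
    h = sd / params.bandwidth_divisor
    for i in np.flatnonzero(~flat):
        diffs = (X[i][:, None] - X[i][None, :]) / h[i]
        z[i] = norm.cdf(diffs).mean(axis=1)
    return pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)


def rank_statistic(z_column: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending ranks and symmetric rank weights for one sample.

    Returns ``(order, weights)``: ``order`` lists gene positions from the
    highest to the lowest z (ties broken by input position, stable), and
    ``weights[k]`` is ``|N/2 - (k+1)|``, the weight of the gene at walk
    step ``k+1``.  Weights peak at both tails of the ranking.
    """
    z = np.asarray(z_column, dtype=float)
    n = z.size
    order = np.argsort(-z, kind="stable")
    ranks = np.arange(1, n + 1)
    weights = np.abs(n / 2.0 - ranks)
    return order, weights


def random_walk_es(
    in_set: np.ndarray,
    weights: np.ndarray,
    params: GsvaParams = GsvaParams(),
) -> float:
    """Enrichment score of one set for one sample's ranked gene list.

    ``in_set`` is a boolean vector over the ranked list (True where the
    gene at that walk position belongs to the set); ``weights`` are the
    rank weights at each position.  The walk gains normalized weight at
    member positions and loses 1/(N - |S|) elsewhere.
    """
    in_set = np.asarray(in_set, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    n = in_set.size
    size = int(in_set.sum())
    if size == 0:
        raise ValidationError("gene set has empty intersection with the ranked list")
    if size == n:
        raise ValidationError("gene set equals the whole gene universe")
    w = weights**params.tau
    gain = np.where(in_set, w, 0.0)
    total = gain.sum()
    if total == 0.0:  # all member weights zero (possible when tau > 0)
        gain_cum = np.zeros(n)
    else:
        gain_cum = np.cumsum(gain) / total
    loss_cum = np.cumsum(~in_set) / (n - size)
    v = gain_cum - loss_cum
    max_pos = max(float(v.max()), 0.0)
    max_neg = min(float(v.min()), 0.0)
    if params.es_mode == "diff":
        return max_pos + max_neg
    return max_pos if max_pos >= -max_neg else max_neg


def gsva_scores(
    expr: ExpressionMatrix,
    genesets: GeneSetCollection,
    params: GsvaParams = GsvaParams(),
) -> pd.DataFrame:
    """Pathway x sample enrichment-score matrix.

    Sets are intersected with the matrix's genes and filtered to
    [min_set_size, max_set_size] before scoring; an error is raised when
    no set survives.
    """
    usable = genesets.restricted_to(
        expr.gene_ids, min_size=params.min_set_size, max_size=params.max_set_size
    )
    if len(usable) == 0:
        raise ValidationError("no gene sets survive the size filter")
    z = expression_statistic(expr, params).to_numpy()
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    n_genes, n_samples = z.shape
    membership = np.zeros((len(usable), n_genes), dtype=bool)
    for s_idx, name in enumerate(usable.names):
        for g in usable.genes(name):
            membership[s_idx, gene_pos[g]] = True
    scores = np.empty((len(usable), n_samples))
    for j in range(n_samples):
        order, weights = rank_statistic(z[:, j])
        ordered_membership = membership[:, order]
        for s_idx in range(len(usable)):
            scores[s_idx, j] = random_walk_es(
                ordered_membership[s_idx], weights, params
            )
    return pd.DataFrame(scores, index=usable.names, columns=expr.values.columns)
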