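"""End-to-end orchestration of the two-cohort analysis.

Stage order: per-cohort candidate-gene differential expression ->
cross-cohort overlap with direction concordance -> directional risk score
(offsets derived from the data) -> per-cohort median dichotomization and
Firth logistic association -> single-sample pathway scoring -> moderated-t
differential pathways and risk-score/pathway Pearson correlations per
cohort -> cross-cohort pathway overlap.  The term-subgroup variant drops
preterm samples from one cohort and reruns the same stages with the
CLOCK/NR1D2/PER3-based score.

Every stage's inputs and outputs are plain pandas objects so stages can
be rerun in isolation; ``outdir`` persists each intermediate table with a
config-hash header for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr, gsva, pathways, reference, risk
from .diffexpr import SignificanceThresholds
from .gsva import GsvaParams
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
    read_expression,
    read_gmt,
    read_phenotypes,
    write_results,
)
from .simulate import (
    CohortSimConfig,
    ConfigError,
    planted_genesets,
    simulate_cohort,
    simulate_genesets,
    table1_defaults,
)


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: loaded from TSV files or simulated from a config."""

    expression_path: str | None = None
    phenotype_path: str | None = None
    sim: CohortSimConfig | None = None
    label: str = ""

    def __post_init__(self) -> None:
        from_files = self.expression_path is not None and self.phenotype_path is not None
        if from_files == (self.sim is not None):
            raise ConfigError(
                "cohort needs either expression+phenotype paths or a simulation config"
            )

    def materialize(self) -> tuple[ExpressionMatrix, PhenotypeTable]:
        if self.sim is not None:
            return simulate_cohort(self.sim)
        expr = read_expression(self.expression_path, cohort_label=self.label or str(self.expression_path))
        pheno = read_phenotypes(self.phenotype_path)
        return expr, pheno


@dataclass(frozen=True)
class PipelineConfig:
    cohort_a: CohortSpec
    cohort_b: CohortSpec | None = None
    candidate_genes: tuple[str, ...] = reference.CIRCADIAN_GENES
    thresholds: SignificanceThresholds = SignificanceThresholds()
    pathway_thresholds: SignificanceThresholds = SignificanceThresholds()
    gsva_params: GsvaParams = GsvaParams()
    gmt_path: str | None = None
    n_random_sets: int = 20
    random_set_size: tuple[int, int] = (10, 30)
    ttest_variant: str = "pooled"
    seed: int = 0
    outdir: str | None = None


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the analysis configuration, for output headers.

    The output directory is excluded: where results are written does not
    change what was computed.
    """
    payload = _jsonable(config)
    payload.pop("outdir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class CohortResult:
    label: str
    de_table: pd.DataFrame
    significant: dict[str, str]
    scores: pd.Series | None = None
    risk_result: risk.RiskScoreResult | None = None
    firth: risk.FirthFit | None = None
    assoc_counts: pd.DataFrame | None = None
    pathway_scores: pd.DataFrame | None = None
    pathway_diff: pd.DataFrame | None = None
    pathway_corr: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    config_hash: str
    cohorts: list[CohortResult]
    overlap: diffexpr.OverlapResult | None = None
    score_definition: risk.ScoreDefinition | None = None
    pathway_overlap: pathways.PathwayOverlap | None = None
    report: str = ""
    log: list[str] = field(default_factory=list)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def _load_genesets(config: PipelineConfig, exprs: list[ExpressionMatrix]) -> GeneSetCollection:
    if config.gmt_path is not None:
        return read_gmt(config.gmt_path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for spec in (config.cohort_a, config.cohort_b):
        if spec is not None and spec.sim is not None:
            for name, item in planted_genesets(spec.sim).items():
                sets.setdefault(name, item)
    shared = sorted(set(exprs[0].gene_ids).intersection(*[e.gene_ids for e in exprs[1:]]))
    if config.n_random_sets > 0:
        hi = min(config.random_set_size[1], len(shared))
        lo = min(config.random_set_size[0], hi)
        rand = simulate_genesets(
            config.n_random_sets, (lo, hi), shared, seed=config.seed + 7919
        )
        for name, item in rand.items():
            sets.setdefault(name, item)
    return GeneSetCollection(sets)


def _score_definition_from_overlap(
    overlap: diffexpr.OverlapResult, exprs: list[ExpressionMatrix]
) -> risk.ScoreDefinition:
    up = tuple(g for g, d in overlap.common.items() if d == diffexpr.UP)
    down_genes = [g for g, d in overlap.common.items() if d == diffexpr.DOWN]
    offsets = risk.compute_offsets(exprs, down_genes) if down_genes else {}
    return risk.ScoreDefinition(up_genes=up, down_genes=offsets)


def _run_cohort_association(
    result: CohortResult,
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    definition: risk.ScoreDefinition,
    genesets: GeneSetCollection,
    config: PipelineConfig,
    log: list[str],
) -> None:
    with _stage(f"risk_score[{result.label}]"):
        result.scores = risk.compute_score(expr, definition)
        result.risk_result = risk.dichotomize(result.scores)
        condition = pheno.table["condition"].reindex(result.scores.index)
        result.assoc_counts = risk.association_table(result.risk_result, condition)
        tab = result.assoc_counts
        result.firth = risk.firth_from_counts(
            int(tab.loc["low", "n_non_pe"]), int(tab.loc["low", "n_pe"]),
            int(tab.loc["high", "n_non_pe"]), int(tab.loc["high", "n_pe"]),
        )
        log.append(
            f"{result.label}: score split low/high = "
            f"{result.risk_result.n_low}/{result.risk_result.n_high}, "
            f"OR = {result.firth.or_:.2f} "
            f"({result.firth.ci_low:.2f}, {result.firth.ci_high:.2f})"
        )
    with _stage(f"gsva[{result.label}]"):
        result.pathway_scores = gsva.gsva_scores(expr, genesets, config.gsva_params)
    with _stage(f"pathway_assoc[{result.label}]"):
        result.pathway_diff = pathways.moderated_t(
            result.pathway_scores, pheno, config.pathway_thresholds
        )
        result.pathway_corr = pathways.score_pathway_table(
            result.pathway_scores, result.scores, config.pathway_thresholds
        )
        # retained pathways must be both differential between conditions
        # and correlated with the score
        keep = result.pathway_corr["significant"] & result.pathway_diff[
            "significant"
        ].reindex(result.pathway_corr.index, fill_value=False)
        result.pathway_corr = result.pathway_corr.assign(significant=keep)
        log.append(
            f"{result.label}: {int(keep.sum())} pathway(s) pass the dual filter"
        )


def run_overall(config: PipelineConfig) -> PipelineResult:
    """Run the full two-cohort pipeline."""
    if config.cohort_b is None:
        raise ConfigError("run_overall needs exactly two cohorts")
    chash = config_hash(config)
    log: list[str] = [f"config_hash {chash}", f"seed {config.seed}"]
    cohorts: list[CohortResult] = []
    exprs: list[ExpressionMatrix] = []
    phenos: list[PhenotypeTable] = []
    for i, spec in enumerate((config.cohort_a, config.cohort_b)):
        with _stage(f"load[{i}]"):
            expr, pheno = spec.materialize()
            label = spec.label or expr.cohort_label or f"cohort{i}"
            pheno.check_matches(expr)
        with _stage(f"diffexpr[{label}]"):
            de = diffexpr.differential_expression(
                expr, pheno, genes=config.candidate_genes, variant=config.ttest_variant
            )
            sig = diffexpr.significant_genes(de, config.thresholds)
            log.append(
                f"{label}: n = {int(de.iloc[0]['n_control'])} non-PE / "
                f"{int(de.iloc[0]['n_case'])} PE; {len(sig)} significant gene(s): "
                f"{sorted(sig)}"
            )
        cohorts.append(CohortResult(label=label, de_table=de, significant=sig))
        exprs.append(expr)
        phenos.append(pheno)

    with _stage("overlap"):
        overlap = diffexpr.overlap_datasets(cohorts[0].significant, cohorts[1].significant)
        log.append(
            f"overlap: {len(overlap.common)} concordant gene(s) {overlap.genes}; "
            f"discordant excluded: {overlap.discordant}"
        )
        if not overlap.common:
            raise PipelineStageError(
                "stage 'overlap': no concordant significant genes; no risk score "
                "can be formed"
            )
        definition = _score_definition_from_overlap(overlap, exprs)
        log.append(
            f"score: up {list(definition.up_genes)}, "
            f"down offsets {definition.down_genes}"
        )

    genesets = _load_genesets(config, exprs)
    log.append(f"gene sets: {len(genesets)}")
    for result, expr, pheno in zip(cohorts, exprs, phenos):
        _run_cohort_association(result, expr, pheno, definition, genesets, config, log)

    with _stage("pathway_overlap"):
        pw_overlap = pathways.overlap_pathways(
            cohorts[0].pathway_corr, cohorts[1].pathway_corr
        )
        log.append(
            f"pathway overlap: {pw_overlap.n_common} common "
            f"({len(pw_overlap.decreased)} decreased, {len(pw_overlap.increased)} "
            f"increased); discordant {pw_overlap.discordant}"
        )

    result = PipelineResult(
        config_hash=chash,
        cohorts=cohorts,
        overlap=overlap,
        score_definition=definition,
        pathway_overlap=pw_overlap,
        log=log,
    )
    result.report = _render_report(result, config)
    if config.outdir is not None:
        _persist(result, config)
    return result


def run_term_subgroup(
    config: PipelineConfig, cohort_index: int = 0
) -> PipelineResult:
    """Single-cohort rerun on term samples only (preterm births removed).

    Uses the term score variant: every gene enters as (offset - gene),
    built from the subgroup's own significant down-regulated genes with
    data-derived offsets; up-regulated significant genes enter with a
    plus sign as in the overall score.
    """
    spec = (config.cohort_a, config.cohort_b)[cohort_index]
    if spec is None:
        raise ConfigError(f"no cohort at index {cohort_index}")
    chash = config_hash(config)
    log: list[str] = [f"config_hash {chash}", f"seed {config.seed}", "variant term-subgroup"]
    with _stage("load"):
        expr, pheno = spec.materialize()
        label = (spec.label or expr.cohort_label or "cohort") + "-term"
    with _stage("term_filter"):
        term_pheno = pheno.term_subset()
        dropped = len(pheno.sample_ids) - len(term_pheno.sample_ids)
        term_expr = expr.subset_samples(term_pheno.sample_ids)
        n_ctrl = len(term_pheno.samples_with("non-PE"))
        n_case = len(term_pheno.samples_with("PE"))
        log.append(f"{label}: dropped {dropped} preterm sample(s); n = {n_ctrl}/{n_case}")
        if n_ctrl < 2 or n_case < 2:
            raise PipelineStageError(
                "stage 'term_filter': fewer than 2 samples per condition after "
                "removing preterm births"
            )
    with _stage("diffexpr"):
        de = diffexpr.differential_expression(
            term_expr, term_pheno, genes=config.candidate_genes,
            variant=config.ttest_variant,
        )
        sig = diffexpr.significant_genes(de, config.thresholds)
        log.append(f"{label}: {len(sig)} significant gene(s): {sorted(sig)}")
    cohort = CohortResult(label=label, de_table=de, significant=sig)
    if not sig:
        raise PipelineStageError(
            "stage 'diffexpr': no significant genes in the term subgroup"
        )
    with _stage("score_definition"):
        overlap = diffexpr.OverlapResult(common=dict(sig))
        definition = _score_definition_from_overlap(overlap, [term_expr])
        log.append(
            f"score: up {list(definition.up_genes)}, down offsets {definition.down_genes}"
        )
    genesets = _load_genesets(config, [term_expr])
    log.append(f"gene sets: {len(genesets)}")
    _run_cohort_association(cohort, term_expr, term_pheno, definition, genesets, config, log)
    result = PipelineResult(
        config_hash=chash,
        cohorts=[cohort],
        overlap=overlap,
        score_definition=definition,
        log=log,
    )
    result.report = _render_report(result, config)
    if config.outdir is not None:
        _persist(result, config)
    return result


def _render_report(result: PipelineResult, config: PipelineConfig) -> str:
    lines = [
        "# clockpe pipeline report",
        "",
        f"- config hash: `{result.config_hash}`",
        f"- seed: {config.seed}",
        f"- thresholds: p < {config.thresholds.alpha_p}, q < {config.thresholds.alpha_q} "
        f"(genes); p < {config.pathway_thresholds.alpha_p}, "
        f"q < {config.pathway_thresholds.alpha_q} (pathways)",
        "",
        "## Stages",
        "",
    ]
    lines += [f"- {entry}" for entry in result.log]
    if result.score_definition is not None:
        lines += [
            "",
            "## Risk score",
            "",
            f"- up genes: {list(result.score_definition.up_genes)}",
            f"- down genes (offsets): {result.score_definition.down_genes}",
        ]
    for cohort in result.cohorts:
        if cohort.firth is None:
            continue
        lines += [
            "",
            f"## Association ({cohort.label})",
            "",
            f"- OR = {cohort.firth.or_:.2f} "
            f"({cohort.firth.ci_low:.2f}, {cohort.firth.ci_high:.2f}), "
            f"p = {cohort.firth.p:.2e}",
        ]
    if result.pathway_overlap is not None:
        po = result.pathway_overlap
        lines += [
            "",
            "## Common pathways",
            "",
            f"- {po.n_common} concordant ({len(po.decreased)} decreased, "
            f"{len(po.increased)} increased in PE)",
        ]
    return "\n".join(lines) + "\n"


def _persist(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash {result.config_hash}", f"seed {config.seed}"]
    for cohort in result.cohorts:
        tag = cohort.label.replace("/", "_")
        write_results(
            cohort.de_table.reset_index(), outdir / f"stats_{tag}.tsv",
            header_lines=header,
        )
        if cohort.scores is not None:
            score_df = pd.DataFrame(
                {
                    "sample_id": cohort.scores.index,
                    "risk_score": cohort.scores.to_numpy(),
                    "score_group": cohort.risk_result.group.to_numpy(),
                }
            )
            write_results(
                score_df, outdir / f"score_{tag}.tsv",
                float_formats={"risk_score": "%.6f"}, header_lines=header,
            )
        if cohort.pathway_corr is not None:
            write_results(
                cohort.pathway_corr.reset_index(), outdir / f"pathways_{tag}.tsv",
                header_lines=header,
            )
        if cohort.pathway_diff is not None:
            write_results(
                cohort.pathway_diff.reset_index(), outdir / f"pathway_diff_{tag}.tsv",
                header_lines=header,
            )
    assoc_rows = []
    for cohort in result.cohorts:
        if cohort.firth is None:
            continue
        assoc_rows.append(
            {
                "cohort": cohort.label,
                "n_low": cohort.risk_result.n_low,
                "n_high": cohort.risk_result.n_high,
                "or": cohort.firth.or_,
                "ci_low": cohort.firth.ci_low,
                "ci_high": cohort.firth.ci_high,
                "p": cohort.firth.p,
            }
        )
    if assoc_rows:
        write_results(pd.DataFrame(assoc_rows), outdir / "assoc.tsv", header_lines=header)
    if result.pathway_overlap is not None:
        po = result.pathway_overlap
        common = pd.concat([po.decreased, po.increased])
        write_results(
            common.reset_index(), outdir / "pathways_common.tsv", header_lines=header
        )
    (outdir / "report.md").write_text(result.report)


def two_cohort_default_config(
    seed: int = 0,
    n_background_genes: int = 150,
    outdir: str | None = None,
    **overrides,
) -> PipelineConfig:
    """Paired synthetic cohorts emulating the two published datasets."""
    return PipelineConfig(
        cohort_a=CohortSpec(sim=table1_defaults(
            "157", seed=(seed * 2 + 1) % 2**31, n_background_genes=n_background_genes
        )),
        cohort_b=CohortSpec(sim=table1_defaults(
            "173", seed=(seed * 2 + 2) % 2**31, n_background_genes=n_background_genes
        )),
        seed=seed,
        outdir=outdir,
        **overrides,
    )
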