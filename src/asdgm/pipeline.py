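"""End-to-end orchestration of the stratified microbiota analysis.

For each neuropsychological variable (CSS, CBCL_INT, CBCL_EXT, CBCL_TOT,
IQ_DQ) the pipeline stratifies the cohort, filters the ASV table, rarefies
for diversity analyses, CSS-normalises for models, computes alpha/beta
diversity with group tests, the per-subject dysbiosis index against the
control cohort, and the dual-method biomarker consensus.  Failure of one
variable's analysis is recorded and does not abort the others.  All
stochastic stages take explicit seeds derived from a single run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import cohort as cohort_mod
from . import diversity as div
from . import mdi as mdi_mod
from .features import (
    FeatureTable,
    FilterConfig,
    TaxonomyMap,
    aggregate_at_rank,
    css_normalize,
    filter_features,
    rarefy,
)

__all__ = ["RunConfig", "RunReport", "run_all", "confounder_check"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run."""

    strat: cohort_mod.StratConfig = cohort_mod.StratConfig()
    filter: FilterConfig = FilterConfig()
    lefse: bm.LefseConfig = bm.LefseConfig()
    mdi_ranks: tuple[str, ...] = mdi_mod.DEFAULT_RANKS
    biomarker_rank: str = "genus"
    variables: tuple[str, ...] = cohort_mod.VARIABLES
    age_split: float = 6.0
    permutations: int = 999
    depth_floor: int = 1000
    seed: int = 0
    out_dir: str | None = None


@dataclass
class VariableResult:
    variable: str
    subgroup_summary: pd.DataFrame | None = None
    alpha_tests: dict = field(default_factory=dict)
    beta_permanova: div.PermanovaResult | None = None
    mdi_compare: pd.DataFrame | None = None
    biomarker_report: pd.DataFrame | None = None
    error: str | None = None


@dataclass
class RunReport:
    config: RunConfig
    labels: pd.DataFrame
    removal_log: pd.DataFrame
    confounders: dict
    alpha: pd.DataFrame
    mdi: pd.DataFrame
    variables: dict
    failed: list


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ("rarefy", "permanova", "lefse", "confounder")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def confounder_check(
    table: FeatureTable,
    clinical: cohort_mod.ClinicalTable,
    age_split: float = 6.0,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """PERMANOVA screens for age-class and gender as confounders.

    Age is binned into two classes at ``age_split`` years.  A factor is
    flagged as a confounder when group membership explains composition
    (PERMANOVA p below ``alpha``).  Checks that would be degenerate (one
    class only) are skipped with a note.
    """
    dm = div.bray_curtis(table)
    sample_ids = [s for s in table.sample_ids if s in clinical.subject_ids]
    results = {}
    age = clinical.data["age"].reindex(sample_ids)
    age_class = pd.Series(
        np.where(age <= age_split, f"<={age_split:g}y", f">{age_split:g}y"),
        index=sample_ids,
    )
    for factor, labels in (
        ("age", age_class),
        ("gender", clinical.data["gender"].reindex(sample_ids)),
    ):
        if labels.nunique() < 2:
            results[factor] = {"skipped": True, "reason": "single class"}
            continue
        res = div.permanova(dm, labels, n_permutations=permutations, seed=seed)
        results[factor] = {
            "skipped": False,
            "pseudo_f": res.pseudo_f,
            "p_value": res.p_value,
            "confounder": res.p_value < alpha,
        }
    return results


def _analyse_variable(
    variable: str,
    labels: pd.Series,
    rarefied: FeatureTable,
    normalized_at_rank: FeatureTable,
    alpha_df: pd.DataFrame,
    mdi_df: pd.DataFrame,
    clinical: cohort_mod.ClinicalTable,
    cfg: RunConfig,
    seeds: dict,
) -> VariableResult:
    result = VariableResult(variable=variable)
    result.subgroup_summary = cohort_mod.cohort_summary(labels)
    for index in alpha_df.columns:
        try:
            result.alpha_tests[index] = div.alpha_group_test(alpha_df[index], labels)
        except ValueError as exc:
            result.alpha_tests[index] = str(exc)
    dm = div.bray_curtis(rarefied)
    result.beta_permanova = div.permanova(
        dm, labels, n_permutations=cfg.permutations, seed=seeds["permanova"]
    )
    result.mdi_compare = mdi_mod.mdi_group_compare(mdi_df, labels)
    covariates = clinical.data[["age", "gender"]].reindex(
        [s for s in normalized_at_rank.sample_ids]
    )
    lefse_cfg = bm.LefseConfig(
        kw_alpha=cfg.lefse.kw_alpha,
        lda_min=cfg.lefse.lda_min,
        n_boot=cfg.lefse.n_boot,
        boot_fraction=cfg.lefse.boot_fraction,
        seed=seeds["lefse"],
        rescale_total=cfg.lefse.rescale_total,
    )
    result.biomarker_report = bm.run_consensus(
        normalized_at_rank, labels, covariates, lefse_cfg
    )
    return result


def run_all(
    case_table: FeatureTable,
    control_table: FeatureTable,
    taxonomy: TaxonomyMap,
    clinical: cohort_mod.ClinicalTable,
    cfg: RunConfig = RunConfig(),
) -> RunReport:
    """Execute the full stratified analysis.

    Stage order: quality floor and filtering on counts; rarefaction feeds
    alpha/beta diversity; CSS normalisation feeds the dysbiosis index
    models and biomarker discovery.  Each stratification variable is
    analysed independently and failures are collected, not raised.
    """
    seeds = _stage_seeds(cfg.seed)

    # drop samples under the sequencing-depth quality floor before anything else
    totals = case_table.sample_totals()
    deep_enough = totals.index[totals >= cfg.depth_floor]
    if len(deep_enough) < case_table.shape[1]:
        shallow = sorted(set(case_table.sample_ids) - set(deep_enough))
        log.info("dropping %d samples below %d reads: %s", len(shallow), cfg.depth_floor, shallow)
        case_table = FeatureTable(case_table.data[deep_enough], mode="counts")

    labels = pd.DataFrame(
        {v: cohort_mod.stratify(clinical, v, cfg.strat) for v in cfg.variables}
    )

    filtered, removal_log = filter_features(case_table, cfg.filter)
    rarefied = rarefy(filtered, depth="min", seed=seeds["rarefy"])
    normalized = css_normalize(filtered)
    normalized_at_rank = aggregate_at_rank(normalized, taxonomy, cfg.biomarker_rank)

    alpha_df = div.alpha_diversity(rarefied)
    mdi_df = mdi_mod.cohort_mdi(filtered, control_table, taxonomy, ranks=cfg.mdi_ranks)
    confounders = confounder_check(
        rarefied, clinical, age_split=cfg.age_split,
        permutations=cfg.permutations, seed=seeds["confounder"],
    )

    variables: dict = {}
    failed: list = []
    for variable in cfg.variables:
        var_labels = labels[variable].reindex(rarefied.sample_ids)
        try:
            variables[variable] = _analyse_variable(
                variable, var_labels, rarefied, normalized_at_rank,
                alpha_df, mdi_df, clinical, cfg, seeds,
            )
        except (ValueError, KeyError) as exc:
            log.warning("variable %s failed: %s", variable, exc)
            variables[variable] = VariableResult(variable=variable, error=str(exc))
            failed.append(variable)

    report = RunReport(
        config=cfg,
        labels=labels,
        removal_log=removal_log,
        confounders=confounders,
        alpha=alpha_df,
        mdi=mdi_df,
        variables=variables,
        failed=failed,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir))
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    """Write the stage outputs as TSVs under the output directory."""
    out_dir.mkdir(parents=True, exist_ok=True)
    report.labels.to_csv(out_dir / "subgroup_labels.tsv", sep="\t")
    report.removal_log.to_csv(out_dir / "feature_removal_log.tsv", sep="\t", index=False)
    report.alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
    report.mdi.to_csv(out_dir / "mdi_per_subject.tsv", sep="\t")
    pd.DataFrame(report.confounders).T.to_csv(out_dir / "confounder_check.tsv", sep="\t")
    for variable, res in report.variables.items():
        if res.error is not None:
            continue
        vdir = out_dir / variable.lower()
        vdir.mkdir(exist_ok=True)
        res.subgroup_summary.to_csv(vdir / "subgroups.tsv", sep="\t")
        res.mdi_compare.to_csv(vdir / "mdi_compare.tsv", sep="\t", index=False)
        res.biomarker_report.to_csv(vdir / "biomarkers.tsv", sep="\t")
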