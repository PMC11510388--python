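"""Microbial Dysbiosis Index (MDI).

The MDI quantifies how far a subject's gut-microbiota composition sits
from a healthy reference.  The reference is the coordinate-wise median of
the control cohort's relative-abundance profiles at a taxonomic rank
(renormalised back onto the simplex, since medians of compositions need
not sum to one).  For a case profile f_case and reference f_controls over
the same taxa,

    Z = sqrt(1/2 * sum_t (f_case,t - f_controls,t)^2) * 100

a percentage quadratic dissimilarity: 0 means the case equals the
reference exactly, 100 means the two compositions share no taxa.  Scores
are computed per subject at the phylum, family and genus ranks, with an
unweighted mean across ranks as a composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .features import FeatureTable, TaxonomyMap, aggregate_at_rank, to_relative

__all__ = [
    "ReferenceProfile",
    "build_reference",
    "mdi_score",
    "cohort_mdi",
    "mdi_group_compare",
    "DEFAULT_RANKS",
]

DEFAULT_RANKS = ("phylum", "family", "genus")

_SIMPLEX_TOL = 1e-6


@dataclass
class ReferenceProfile:
    """Median control composition at one rank (taxon -> fraction)."""

    rank: str
    values: pd.Series
    renormalized: bool

    def __post_init__(self) -> None:
        v = self.values
        if ((v < 0) | (v > 1)).any():
            raise ValueError("reference abundances must lie in [0, 1]")
        if self.renormalized and abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("renormalized reference must sum to 1")


def build_reference(
    control_table: FeatureTable,
    tax: TaxonomyMap,
    rank: str,
    renormalize: bool = True,
    min_controls: int = 3,
) -> ReferenceProfile:
    """Median relative-abundance profile of the control cohort at a rank.

    Coordinate-wise medians of compositions generally do not sum to one;
    by default they are rescaled back onto the simplex so the MDI keeps
    its [0, 100] bound.
    """
    if control_table.shape[1] == 0:
        raise ValueError("control table is empty")
    if control_table.shape[1] < min_controls:
        raise ValueError(
            f"need at least {min_controls} control samples for a stable median "
            f"(got {control_table.shape[1]})"
        )
    at_rank = aggregate_at_rank(control_table, tax, rank)
    rel = to_relative(at_rank) if at_rank.mode != "relative" else at_rank
    medians = rel.data.median(axis=1)
    if renormalize:
        total = medians.sum()
        if total <= 0:
            raise ValueError("control medians are all zero; cannot renormalise")
        medians = medians / total
    return ReferenceProfile(rank=rank, values=medians, renormalized=renormalize)


def mdi_score(
    case_profile: pd.Series,
    reference: ReferenceProfile,
    scale: str = "percent",
) -> float:
    """Quadratic dissimilarity Z between a case profile and the reference.

    Taxa are aligned on the union of the two supports with zero-fill; both
    vectors must sum to 1 (otherwise the [0, 100] bound does not hold and
    an error is raised).  ``scale="percent"`` returns Z in [0, 100];
    ``scale="fraction"`` returns Z in [0, 1].
    """
    if scale not in ("percent", "fraction"):
        raise ValueError("scale must be 'percent' or 'fraction'")
    case = pd.Series(case_profile, dtype=float)
    taxa = case.index.union(reference.values.index)
    f_case = case.reindex(taxa, fill_value=0.0).values
    f_ctrl = reference.values.reindex(taxa, fill_value=0.0).values
    for name, vec in (("case", f_case), ("reference", f_ctrl)):
        if abs(vec.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"{name} profile sums to {vec.sum():.6f}, not 1; "
                "renormalise before scoring"
            )
    z = np.sqrt(0.5 * ((f_case - f_ctrl) ** 2).sum())
    return float(z * (100.0 if scale == "percent" else 1.0))


def cohort_mdi(
    case_table: FeatureTable,
    control_table: FeatureTable,
    tax: TaxonomyMap,
    ranks: tuple[str, ...] = DEFAULT_RANKS,
    renormalize: bool = True,
    scale: str = "percent",
) -> pd.DataFrame:
    """Per-subject MDI at each rank plus an unweighted-mean composite.

    Returns a DataFrame indexed by subject with one column per rank and a
    ``composite`` column; cohort mean and SD of the composite are stored in
    ``attrs``.
    """
    references = {
        rank: build_reference(control_table, tax, rank, renormalize=renormalize)
        for rank in ranks
    }
    case_at_rank = {
        rank: to_relative(aggregate_at_rank(case_table, tax, rank)) for rank in ranks
    }
    out = pd.DataFrame(index=case_table.sample_ids, columns=list(ranks), dtype=float)
    for rank in ranks:
        rel = case_at_rank[rank].data
        for subject in rel.columns:
            out.loc[subject, rank] = mdi_score(rel[subject], references[rank], scale=scale)
    out["composite"] = out[list(ranks)].mean(axis=1)
    out.index.name = "subject_id"
    out.attrs["cohort_mean"] = float(out["composite"].mean())
    out.attrs["cohort_sd"] = float(out["composite"].std(ddof=1)) if len(out) > 1 else 0.0
    out.attrs["scale"] = scale
    return out


def mdi_group_compare(
    mdi: pd.DataFrame, labels: pd.Series, column: str = "composite"
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney comparison of MDI across subgroups.

    Returns one row per label pair with group sizes, medians, the U
    statistic and p-value; degenerate pairs (a group with fewer than two
    subjects) are flagged instead of tested.
    """
    joined = pd.DataFrame({"mdi": mdi[column], "label": labels.reindex(mdi.index)}).dropna()
    groups = {g: sub["mdi"].values for g, sub in joined.groupby("label")}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare MDI")
    if sum(len(v) >= 2 for v in groups.values()) < 2:
        raise ValueError("need at least two groups with >=2 subjects")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            med_a, med_b = np.median(groups[a]), np.median(groups[b])
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                rows.append((a, b, len(groups[a]), len(groups[b]), med_a, med_b, np.nan, np.nan, "too_few_subjects"))
                continue
            u, p = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append((a, b, len(groups[a]), len(groups[b]), med_a, med_b, u, p, ""))
    return pd.DataFrame(
        rows,
        columns=["group1", "group2", "n1", "n2", "median1", "median2", "u", "p", "flag"],
    )
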