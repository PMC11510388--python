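"""Feature-table and taxonomy handling for 16S ASV data.

The in-memory container is :class:`FeatureTable`: a features x samples
matrix (pandas DataFrame) plus a mode flag.  ``counts`` tables hold
non-negative integers (sequence counts per ASV per sample); ``relative``
tables hold per-sample proportions summing to one; ``normalized`` tables
hold cumulative-sum-scaled abundances.

Preprocessing follows common amplicon practice: prevalence and
relative-abundance filtering of ASVs, rarefaction (without-replacement
subsampling to a common depth) for diversity analyses, and cumulative sum
scaling (CSS) for differential-abundance models.  Taxonomic lineages allow
collapsing the ASV table to any of the seven canonical ranks.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "FeatureTable",
    "TaxonomyMap",
    "FilterConfig",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "to_relative",
    "filter_features",
    "rarefy",
    "css_normalize",
    "aggregate_at_rank",
]

#: canonical rank order, domain to species
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNASSIGNED = "unassigned"

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class FeatureTable:
    """Features x samples abundance matrix with axis identifiers.

    Parameters
    ----------
    data : DataFrame
        Rows are features (ASVs or taxa), columns are samples.
    mode : {"counts", "relative", "normalized"}
        ``counts`` for raw sequence counts, ``relative`` for per-sample
        proportions (columns sum to 1), ``normalized`` for scaled
        abundances with no sum constraint.
    """

    MODES = ("counts", "relative", "normalized")

    def __init__(self, data: pd.DataFrame, mode: str = "counts"):
        if mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        data = data.astype(float)
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        if (data.values < 0).any():
            raise ValueError("negative abundances are not allowed")
        if mode == "relative":
            sums = data.sum(axis=0)
            if (sums == 0).any():
                raise ValueError("relative-mode table has zero-sum sample columns")
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-mode sample columns must sum to 1")
        self.data = data
        self.mode = mode

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.mode)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        return (
            isinstance(other, FeatureTable)
            and self.mode == other.mode
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.data.values, other.data.values)
        )

    def __repr__(self) -> str:
        f, s = self.shape
        return f"<FeatureTable {f} features x {s} samples, mode={self.mode!r}>"


class TaxonomyMap:
    """Feature -> ordered 7-rank lineage.

    Stored as a DataFrame indexed by feature id with one column per rank;
    empty ranks are the explicit string ``"unassigned"``.  Greengenes-style
    rank prefixes (``g__`` etc.) are stripped on construction; suffix
    disambiguated names (e.g. ``Bacteroides_H``) are kept verbatim.
    """

    def __init__(self, lineages: pd.DataFrame):
        missing = [r for r in RANKS if r not in lineages.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        lineages = lineages[list(RANKS)].copy()
        if lineages.index.has_duplicates:
            raise ValueError("duplicate feature ids in taxonomy")
        for rank in RANKS:
            col = lineages[rank].fillna("").astype(str).str.strip()
            col = col.map(lambda s: _RANK_PREFIX.sub("", s))
            lineages[rank] = col.replace("", UNASSIGNED)
        self.lineages = lineages

    @classmethod
    def from_strings(cls, lineage_strings: pd.Series | dict) -> "TaxonomyMap":
        """Build from semicolon-joined lineage strings (domain;...;species)."""
        s = pd.Series(lineage_strings)
        parts = s.fillna("").astype(str).str.split(";", expand=True)
        parts = parts.reindex(columns=range(len(RANKS)))
        parts.columns = list(RANKS)
        return cls(parts)

    @property
    def feature_ids(self) -> pd.Index:
        return self.lineages.index

    def at_rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineages[rank]

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass(frozen=True)
class FilterConfig:
    """ASV filtering rules.

    A feature is retained iff it is present (nonzero) in at least
    ``ceil(prevalence_min * n_samples)`` samples AND its relative abundance
    exceeds ``rel_abund_min`` under ``rel_abund_rule`` (in at least one
    sample, or on average across samples).
    """

    prevalence_min: float = 0.25
    rel_abund_min: float = 0.01
    rel_abund_rule: str = "any_sample"

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_min <= 1:
            raise ValueError("prevalence_min must lie in [0, 1]")
        if not 0 <= self.rel_abund_min < 1:
            raise ValueError("rel_abund_min must lie in [0, 1)")
        if self.rel_abund_rule not in ("any_sample", "mean_across_samples"):
            raise ValueError("rel_abund_rule must be 'any_sample' or 'mean_across_samples'")


# ---------------------------------------------------------------------------
# I/O


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table from TSV.

    Two layouts are accepted: wide (features as rows, first column the
    feature id, remaining columns samples) and sparse triplets (exactly the
    three columns ``feature_id``, ``sample_id``, ``value``).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if list(raw.columns[:3]) == ["feature_id", "sample_id", "value"] and raw.shape[1] == 3:
        values = pd.to_numeric(raw["value"], errors="raise")
        wide = (
            raw.assign(value=values)
            .pivot_table(index="feature_id", columns="sample_id", values="value", fill_value=0.0)
        )
        wide.index.name = None
        wide.columns.name = None
        return FeatureTable(wide, mode="counts")
    table = raw.set_index(raw.columns[0])
    table.index.name = None
    if table.isna().any().any():
        raise ValueError(f"ragged or empty cells in {path.name}")
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance cell in {path.name}: {exc}") from exc
    return FeatureTable(table, mode="counts")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as wide TSV (features x samples)."""
    out = table.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2-column TSV (feature_id, semicolon-joined lineage)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ValueError("taxonomy file needs feature_id and lineage columns")
    return TaxonomyMap.from_strings(pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values))


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    lineage = tax.lineages.apply(lambda row: ";".join(row), axis=1)
    pd.DataFrame({"feature_id": lineage.index, "lineage": lineage.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Transformations


def to_relative(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample relative abundances (columns sum to 1)."""
    if table.mode == "relative":
        return table.copy()
    totals = table.sample_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cannot normalise zero-total samples: {zero}")
    return FeatureTable(table.data.div(totals, axis=1), mode="relative")


def filter_features(
    table: FeatureTable, cfg: FilterConfig = FilterConfig()
) -> tuple[FeatureTable, pd.DataFrame]:
    """Apply prevalence and relative-abundance filters to a counts table.

    Returns the filtered table (same samples) and a removal log naming the
    rule(s) that removed each dropped feature.  The kept set is the
    intersection of the two rules, so rule order is irrelevant.
    """
    if table.mode != "counts":
        raise ValueError("filter_features expects a counts-mode table")
    n_samples = table.shape[1]
    min_samples = math.ceil(cfg.prevalence_min * n_samples)
    prevalence_ok = (table.data > 0).sum(axis=1) >= min_samples

    rel = to_relative(table).data
    if cfg.rel_abund_rule == "any_sample":
        abundance_ok = (rel > cfg.rel_abund_min).any(axis=1)
    else:
        abundance_ok = rel.mean(axis=1) > cfg.rel_abund_min

    keep = prevalence_ok & abundance_ok
    dropped = table.feature_ids[~keep]
    reasons = []
    for fid in dropped:
        why = []
        if not prevalence_ok[fid]:
            why.append("prevalence")
        if not abundance_ok[fid]:
            why.append("abundance")
        reasons.append("+".join(why))
    log = pd.DataFrame({"feature_id": dropped, "removed_by": reasons}).reset_index(drop=True)
    filtered = FeatureTable(table.data.loc[keep], mode="counts")
    return filtered, log


def rarefy(
    table: FeatureTable,
    depth: int | str = "min",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` uses the smallest sample total.  With an explicit depth,
    samples whose total falls below it are dropped.  Deterministic for a
    fixed seed (multivariate hypergeometric draw per sample).
    """
    if table.mode != "counts":
        raise ValueError("rarefy expects a counts-mode table")
    counts = table.data.round().astype(np.int64)
    totals = counts.sum(axis=0)
    if isinstance(depth, str):
        if depth != "min":
            raise ValueError("depth must be a positive integer or 'min'")
        depth_val = int(totals.min())
    else:
        depth_val = int(depth)
    if depth_val <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = totals.index[totals >= depth_val]
    if rng is None:
        rng = np.random.default_rng(seed)
    out = {}
    for sample in keep:
        col = counts[sample].values
        if col.sum() == depth_val:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth_val)
    result = pd.DataFrame(out, index=counts.index, columns=keep)
    return FeatureTable(result.astype(float), mode="counts")


def css_normalize(
    table: FeatureTable, percentile: float = 0.5, scale: float = 1000.0
) -> FeatureTable:
    """Cumulative sum scaling.

    For each sample the scaling factor is the sum of counts at or below the
    ``percentile``-th quantile of that sample's nonzero counts; each count
    is divided by its sample's factor and multiplied by ``scale``.  Robust
    to a handful of dominant features and invariant to multiplying a sample
    by a positive constant.
    """
    if table.mode != "counts":
        raise ValueError("css_normalize expects a counts-mode table")
    if not 0 < percentile <= 1:
        raise ValueError("percentile must lie in (0, 1]")
    data = table.data
    factors = {}
    for sample in data.columns:
        col = data[sample].values
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts; CSS factor is 0")
        q = np.quantile(nonzero, percentile)
        s = col[col <= q].sum()
        if s <= 0:
            raise ValueError(f"sample {sample!r} yields a zero CSS scaling factor")
        factors[sample] = s
    factors = pd.Series(factors)
    normalized = data.div(factors, axis=1) * scale
    result = FeatureTable(normalized, mode="normalized")
    result.data.attrs["css_factors"] = factors
    return result


def aggregate_at_rank(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Collapse features to taxa at one rank by summing their values.

    Features whose rank label is ``unassigned`` pool into a single explicit
    ``unassigned`` row; per-sample totals are conserved.
    """
    labels = tax.at_rank(rank)
    missing = table.feature_ids.difference(labels.index)
    if len(missing) > 0:
        raise ValueError(f"features without taxonomy lineage: {missing.tolist()}")
    groups = labels.reindex(table.feature_ids)
    collapsed = table.data.groupby(groups).sum()
    collapsed.index.name = None
    return FeatureTable(collapsed, mode=table.mode)
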