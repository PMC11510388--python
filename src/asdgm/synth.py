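"""Synthetic case/control cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
pediatric autism cohort of ~70 subjects (80/20 male/female, ages 3-17,
severity scores on a 1-10 scale with mean ~7), a matched control cohort,
and compositional 16S count tables built hierarchically:

* a random 7-rank taxonomy with realistic fan-out and suffix-disambiguated
  names (to exercise name handling),
* a base composition drawn from a log-normal ranked-abundance curve
  (dominant taxa plus a long tail),
* per-sample compositions drawn from a Dirichlet around the base
  (compositional overdispersion), with subgroup-specific log-fold
  perturbations applied to planted taxa,
* integer counts drawn multinomially at a negative-binomially distributed
  sequencing depth with a 1000-read floor.

Clinical scores are drawn from configured distributions and subgroup
labels are derived from them through the cohort module, so labels and
scores are consistent by construction.  Everything is reproducible from a
single seed, and a :class:`GroundTruth` record carries the planted taxa
for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .features import FeatureTable, TaxonomyMap

__all__ = [
    "PlantedEffect",
    "SynthConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "perturb_for_mdi",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A differential-abundance signal planted into one subgroup.

    ``log_fold`` is a natural-log fold change applied multiplicatively to
    the taxon's base abundance for subjects carrying ``subgroup`` under
    ``variable`` (before renormalisation to the simplex).
    """

    taxon: str
    variable: str
    subgroup: str
    log_fold: float


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 70 cases, 80% male, ages 3-17
    (mean 6.91, SD 3.17), CSS mean 6.98 SD 1.47 on the 1-10 scale, IQ/DQ
    mean 62.9 SD 19.9, CBCL t-score means chosen so all three bands are
    populated, and a small amount of missingness in the score columns.
    """

    n_cases: int = 70
    n_controls: int = 70
    male_fraction: float = 0.8
    age_min: float = 3.0
    age_max: float = 17.0
    age_mean: float = 6.91
    age_sd: float = 3.17
    n_asv: int = 300
    depth_mean: float = 20000.0
    depth_dispersion: float = 5.0
    depth_floor: int = 1000
    base_concentration: float = 50.0
    base_sigma: float = 1.6
    planted_effects: tuple[PlantedEffect, ...] = ()
    css_mean: float = 6.98
    css_sd: float = 1.47
    cbcl_means: dict = field(
        default_factory=lambda: {"cbcl_int": 65.0, "cbcl_ext": 60.0, "cbcl_tot": 64.0}
    )
    cbcl_sd: float = 9.0
    iq_mean: float = 62.9
    iq_sd: float = 19.9
    css_missing: float = 5.0 / 70.0
    cbcl_missing: float = 9.0 / 70.0
    iq_missing: float = 1.0 / 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("male_fraction", "css_missing", "cbcl_missing", "iq_missing"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_asv < len(self.planted_effects):
            raise ValueError("n_asv must be at least the number of planted taxa")
        for eff in self.planted_effects:
            if not np.isfinite(eff.log_fold):
                raise ValueError("planted log-folds must be finite")


@dataclass
class GroundTruth:
    """Record of what was planted, for recovery tests."""

    planted: tuple[PlantedEffect, ...]
    labels: pd.DataFrame  # subject x variable, derived subgroup labels
    base_composition: pd.Series


@dataclass
class SyntheticCohort:
    case_table: FeatureTable
    control_table: FeatureTable
    taxonomy: TaxonomyMap
    clinical: cohort_mod.ClinicalTable
    truth: GroundTruth


def _make_taxonomy(n_asv: int, rng: np.random.Generator) -> TaxonomyMap:
    """Random hierarchical taxonomy with suffixed, prefixed names."""
    n_phyla = max(4, min(10, n_asv // 25))
    suffixes = ["", "", "", "_A", "_B", "_H"]
    rows = []
    for i in range(n_asv):
        phylum = f"Phylum{1 + rng.integers(n_phyla)}"
        cls = f"{phylum}c{1 + rng.integers(2)}"
        order = f"{cls}o{1 + rng.integers(2)}"
        family = f"Family{order}f{1 + rng.integers(3)}"
        genus = f"Genus{family[-4:]}g{1 + rng.integers(4)}{rng.choice(suffixes)}"
        species = f"{genus} sp{i:04d}"
        rows.append(
            {
                "domain": "d__Bacteria",
                "phylum": f"p__{phylum}",
                "class": f"c__{cls}",
                "order": f"o__{order}",
                "family": f"f__{family}",
                "genus": f"g__{genus}",
                "species": f"s__{species}",
            }
        )
    frame = pd.DataFrame(rows, index=[f"ASV{i:04d}" for i in range(n_asv)])
    frame.index.name = None
    return TaxonomyMap(frame)


def _base_composition(n_asv: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    logabund = rng.normal(0.0, sigma, size=n_asv)
    comp = np.exp(logabund)
    return comp / comp.sum()


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _sample_depths(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    # negative binomial parameterised by mean and dispersion (size) parameter
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    depths = rng.negative_binomial(r, p, size=n)
    return np.maximum(depths, cfg.depth_floor)


def _draw_counts(
    comps: np.ndarray, depths: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-multinomial counts; rows = samples."""
    n, k = comps.shape
    counts = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        alpha = np.maximum(concentration * comps[i], 1e-8)
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], p)
    return counts


def _clinical_frame(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases
    n_male = int(round(cfg.male_fraction * n))
    gender = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(gender)
    age = _truncated_normal(cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max, n, rng)
    css = np.clip(np.round(_truncated_normal(cfg.css_mean, cfg.css_sd, 1, 10, n, rng)), 1, 10)
    frame = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "css": css.astype(float),
            "iq_dq": np.clip(rng.normal(cfg.iq_mean, cfg.iq_sd, n), 5, None),
        },
        index=pd.Index([f"ASD{i:03d}" for i in range(n)], name="subject_id"),
    )
    for col, mean in cfg.cbcl_means.items():
        frame[col] = np.clip(rng.normal(mean, cfg.cbcl_sd, n), 0, None)
    # plant missingness in score columns only (age/gender are required)
    for col, rate in (
        ("css", cfg.css_missing),
        ("cbcl_int", cfg.cbcl_missing),
        ("cbcl_ext", cfg.cbcl_missing),
        ("cbcl_tot", cfg.cbcl_missing),
        ("iq_dq", cfg.iq_missing),
    ):
        k = int(round(rate * n))
        if k > 0:
            miss = rng.choice(n, size=k, replace=False)
            frame.iloc[miss, frame.columns.get_loc(col)] = np.nan
    return frame


def generate_cohort(cfg: SynthConfig = SynthConfig()) -> SyntheticCohort:
    """Generate case and control tables, taxonomy, clinical data and truth.

    Planted effects may name explicit ASVs or use the placeholder
    ``"auto:k"`` (k = 0,1,...) to select the k-th most abundant base taxon,
    which guarantees the signal survives prevalence/abundance filtering.
    """
    rng = np.random.default_rng(cfg.seed)
    taxonomy = _make_taxonomy(cfg.n_asv, rng)
    asv_ids = list(taxonomy.feature_ids)
    base = _base_composition(cfg.n_asv, cfg.base_sigma, rng)
    base_s = pd.Series(base, index=asv_ids)

    # resolve auto-placeholders against the abundance ranking
    ranked = base_s.sort_values(ascending=False).index
    resolved = []
    for eff in cfg.planted_effects:
        if eff.taxon.startswith("auto:"):
            k = int(eff.taxon.split(":", 1)[1])
            resolved.append(replace(eff, taxon=ranked[k]))
        elif eff.taxon not in base_s.index:
            raise ValueError(f"planted taxon {eff.taxon!r} not in taxonomy")
        else:
            resolved.append(eff)
    planted = tuple(resolved)

    clinical_frame = _clinical_frame(cfg, rng)
    clinical = cohort_mod.ClinicalTable(clinical_frame)
    labels = pd.DataFrame(
        {v: cohort_mod.stratify(clinical, v) for v in cohort_mod.VARIABLES}
    )

    # per-case composition with subgroup-specific perturbations
    case_ids = list(clinical_frame.index)
    comps = np.tile(base, (cfg.n_cases, 1))
    asv_pos = {a: i for i, a in enumerate(asv_ids)}
    for eff in planted:
        carriers = labels.index[labels[eff.variable] == eff.subgroup]
        rows = [case_ids.index(c) for c in carriers]
        comps[rows, asv_pos[eff.taxon]] *= math.exp(eff.log_fold)
    comps /= comps.sum(axis=1, keepdims=True)

    case_depths = _sample_depths(cfg, cfg.n_cases, rng)
    case_counts = _draw_counts(comps, case_depths, cfg.base_concentration, rng)
    case_table = FeatureTable(
        pd.DataFrame(case_counts.T, index=asv_ids, columns=case_ids).astype(float),
        mode="counts",
    )

    ctrl_ids = [f"CTRL{i:03d}" for i in range(cfg.n_controls)]
    ctrl_comps = np.tile(base, (cfg.n_controls, 1))
    ctrl_depths = _sample_depths(cfg, cfg.n_controls, rng)
    ctrl_counts = _draw_counts(ctrl_comps, ctrl_depths, cfg.base_concentration, rng)
    control_table = FeatureTable(
        pd.DataFrame(ctrl_counts.T, index=asv_ids, columns=ctrl_ids).astype(float),
        mode="counts",
    )

    truth = GroundTruth(planted=planted, labels=labels, base_composition=base_s)
    return SyntheticCohort(
        case_table=case_table,
        control_table=control_table,
        taxonomy=taxonomy,
        clinical=clinical,
        truth=truth,
    )


def perturb_for_mdi(base: pd.Series | np.ndarray, target: float) -> pd.Series:
    """Construct a composition at an exact quadratic dissimilarity from ``base``.

    Moving mass delta from one taxon to another changes the index by
    sqrt(1/2 * (delta^2 + delta^2)) = delta on the fraction scale, so the
    construction moves ``target`` mass from the most abundant taxon to the
    least abundant one.  Raises if the base support cannot donate that
    much mass or the receiver would exceed 1.
    """
    s = pd.Series(base, dtype=float)
    if abs(s.sum() - 1.0) > 1e-9:
        raise ValueError("base must be a composition summing to 1")
    if not 0 <= target < 1:
        raise ValueError("target must lie in [0, 1)")
    if target == 0:
        return s.copy()
    if len(s) < 2:
        raise ValueError("base needs at least two taxa")
    donor = s.idxmax()
    receiver = s.drop(donor).idxmin()
    if s[donor] < target:
        raise ValueError(
            f"target {target} infeasible: largest taxon holds only {s[donor]:.4f}"
        )
    if s[receiver] + target > 1.0:
        raise ValueError("receiver taxon would exceed 1")
    out = s.copy()
    out[donor] -= target
    out[receiver] += target
    return out
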