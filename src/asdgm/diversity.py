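"""Alpha- and beta-diversity ecology.

Alpha diversity: Chao1 (bias-corrected richness estimate), Shannon entropy
(natural log by default) and the Gini-Simpson index, with Kruskal-Wallis
omnibus tests and post-hoc Mann-Whitney pairwise comparisons across
clinical subgroups.

Beta diversity: Bray-Curtis dissimilarity, PERMANOVA with seeded label
permutations, and principal coordinate analysis (classical metric MDS with
negative eigenvalues reported rather than silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu
from skbio import DistanceMatrix

__all__ = [
    "alpha_diversity",
    "chao1",
    "shannon",
    "simpson",
    "AlphaGroupTest",
    "alpha_group_test",
    "bray_curtis",
    "PermanovaResult",
    "permanova",
    "PcoaResult",
    "pcoa",
]

ALPHA_INDICES = ("chao1", "shannon", "simpson")


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy -sum p_i log p_i; natural log unless ``base`` given."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample total must be positive")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p_i^2, in [0, 1 - 1/S_obs]."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample total must be positive")
    p = counts / total
    return float(1.0 - (p**2).sum())


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the numbers of singletons and doubletons; requires
    integer counts.
    """
    counts = np.asarray(counts, dtype=float)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 requires integer counts, not relative abundances")
    counts = np.round(counts).astype(np.int64)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table, indices=ALPHA_INDICES, shannon_base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity for a counts-mode feature table."""
    if "chao1" in indices and table.mode != "counts":
        raise ValueError("chao1 requires a counts-mode table")
    funcs = {
        "chao1": chao1,
        "shannon": lambda c: shannon(c, base=shannon_base),
        "simpson": simpson,
    }
    unknown = set(indices) - set(funcs)
    if unknown:
        raise ValueError(f"unknown alpha indices: {sorted(unknown)}")
    rows = {
        sample: {idx: funcs[idx](table.data[sample].values) for idx in indices}
        for sample in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(indices)]


@dataclass
class AlphaGroupTest:
    """Omnibus Kruskal-Wallis result plus post-hoc pairwise Mann-Whitney."""

    h: float
    p: float
    groups: dict
    pairwise: pd.DataFrame


def alpha_group_test(values: pd.Series, labels: pd.Series) -> AlphaGroupTest:
    """Kruskal-Wallis across subgroups with Mann-Whitney post-hocs.

    ``values`` holds one alpha index per sample; ``labels`` assigns samples
    to subgroups (missing labels are excluded).  Pairs with a group of
    fewer than two samples are flagged rather than tested.
    """
    joined = pd.DataFrame({"value": values, "label": labels}).dropna()
    groups = {g: sub["value"].values for g, sub in joined.groupby("label")}
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least two groups with >=2 samples each")
    pooled = np.concatenate(list(usable.values()))
    if np.ptp(pooled) == 0:  # all observations tied: H is 0 by convention
        h, p = 0.0, 1.0
    else:
        h, p = kruskal(*usable.values())
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                rows.append((a, b, len(groups[a]), len(groups[b]), np.nan, np.nan, "too_few_samples"))
                continue
            u, mp = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append((a, b, len(groups[a]), len(groups[b]), u, mp, ""))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "u", "p", "flag"])
    return AlphaGroupTest(h=float(h), p=float(p), groups={g: len(v) for g, v in groups.items()}, pairwise=pairwise)


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: 1 - 2 sum min / (sum + sum)."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total samples have undefined Bray-Curtis distance: {zero}")
    mat = table.data.T.values  # samples x features
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.sample_ids])


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_samples: int
    n_groups: int


def _permanova_ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_w


def permanova(
    dist: DistanceMatrix,
    labels: pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    The pseudo-F partitions the squared-distance sums within and between
    groups; the p-value is (1 + #{permuted F >= observed}) /
    (1 + n_permutations), deterministic for a fixed seed.
    """
    labels = pd.Series(labels).dropna()
    ids = [i for i in dist.ids if i in set(map(str, labels.index))]
    if len(ids) < len(dist.ids):
        dist = dist.filter(ids)
    codes_s = labels.astype(str)
    codes_s.index = codes_s.index.map(str)
    grouping = codes_s.reindex(dist.ids)
    uniq = sorted(grouping.unique())
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    codes = np.array([uniq.index(g) for g in grouping])
    n = len(codes)
    a = len(uniq)
    d2 = np.asarray(dist.data) ** 2
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _permanova_ss_within(d2, codes, a)
    ss_b = ss_t - ss_w
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ss_w_p = _permanova_ss_within(d2, perm, a)
        f_perm = ((ss_t - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
        if f_perm >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        n_samples=n,
        n_groups=a,
    )


@dataclass
class PcoaResult:
    """Principal coordinates with the full eigenvalue spectrum.

    ``coordinates`` holds one column per positive-eigenvalue axis, ordered
    by decreasing eigenvalue; ``eigenvalues`` keeps the whole spectrum so
    negative eigenvalues (non-Euclidean input) remain visible.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: pd.Series


def pcoa(dist: DistanceMatrix, atol: float = 1e-10) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > atol * max(1.0, abs(evals[0]))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    coordinates = pd.DataFrame(coords, index=list(dist.ids), columns=axes)
    total_pos = evals[pos].sum()
    explained = pd.Series(evals[pos] / total_pos, index=axes)
    return PcoaResult(coordinates=coordinates, eigenvalues=evals, proportion_explained=explained)
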