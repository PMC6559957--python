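"""FPKM computation, differential expression, set analysis and clustering.

Differential expression keeps the study's printed decision rule —
BH-adjusted p <= 0.05 AND |log2 fold change| >= 2 — while the test engine
is a documented Welch two-sample t-test on log2(FPKM + 1) replicate values
(the rule, not the dispersion machinery, is what downstream stages
consume; the engine is deliberately simple and pluggable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .core import FolliscanError, SampleDesign

#: pseudo-count (FPKM units) added before fold-change ratios and log2 transforms
PSEUDOCOUNT = 1.0
#: printed decision thresholds
PADJ_THRESHOLD = 0.05
LFC_THRESHOLD = 2.0
#: default number of k-means clusters
DEFAULT_K = 10
#: fraction of the centroid value range used as the flatness tolerance tau
TAU_FRACTION = 0.1
#: lower bound on the per-feature profile standard deviation used for
#: z-standardization; prevents near-flat profiles from being blown up to
#: pure noise on the unit sphere (log2 units)
STD_FLOOR = 0.25

PATTERN_GROUPS = ("increasing", "decreasing", "fluctuating", "stable")


class ExpressionTable:
    """FPKM matrix (features x samples) tied to a :class:`SampleDesign`."""

    def __init__(self, values: pd.DataFrame, design: SampleDesign, kind: str = "lncRNA"):
        missing = [s for s in design.samples if s not in values.columns]
        if missing:
            raise FolliscanError(f"expression table missing samples: {missing}")
        values = values[design.samples].astype(float)
        if (values.values < 0).any():
            raise FolliscanError("expression values must be non-negative")
        self.values = values
        self.design = design
        self.kind = kind

    @property
    def features(self) -> List[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, features: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(self.values.loc[list(features)], self.design, self.kind)

    def log2p1(self) -> pd.DataFrame:
        return np.log2(self.values + PSEUDOCOUNT)

    def stage_means(self, log: bool = True) -> pd.DataFrame:
        """Per-stage replicate means (of log2(FPKM+1) by default)."""
        mat = self.log2p1() if log else self.values
        cols = {s: self.design.stage_samples(s) for s in self.design.stages}
        return pd.DataFrame(
            {s: mat[c].mean(axis=1) for s, c in cols.items()},
            index=mat.index,
        )[list(self.design.stages)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return (
            self.design == other.design
            and self.values.index.equals(other.values.index)
            and np.allclose(self.values.values, other.values.values)
        )


def compute_fpkm(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """FPKM[f, s] = counts[f, s] / ((length_f / 1e3) * (total_s / 1e6)).

    ``total_s`` is the per-sample column sum of counts.  A zero library
    size is an error naming the sample.
    """
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise FolliscanError("counts must be non-negative")
    missing = [f for f in counts.index if f not in lengths]
    if missing:
        raise FolliscanError(f"no length for features: {missing[:5]}")
    lens = np.array([float(lengths[f]) for f in counts.index])
    if (lens <= 0).any():
        raise FolliscanError("feature lengths must be positive")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise FolliscanError(f"zero library size for sample {zero.index[0]}")
    fpkm = counts.div(lens / 1e3, axis=0).div(totals / 1e6, axis=1)
    return fpkm


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise FolliscanError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Per-feature differential-expression calls for one stage contrast."""

    comparison: Tuple[str, str]
    table: pd.DataFrame  # columns: log2fc, p, padj, de, direction

    @property
    def label(self) -> str:
        return f"{self.comparison[0]}-VS-{self.comparison[1]}"

    @property
    def de_features(self) -> FrozenSet[str]:
        return frozenset(self.table.index[self.table["de"]])

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def differential_expression(
    tab: ExpressionTable,
    comparison: Tuple[str, str],
    padj_threshold: float = PADJ_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> ComparisonResult:
    """Welch test + BH over all features for one (treatment, control) pair.

    log2FC = log2((mean_trt + eps) / (mean_ctl + eps)) on raw FPKM stage
    means with pseudo-count eps; p from Welch's two-sample t-test on
    log2(FPKM + 1) replicate values; a feature is DE iff
    padj <= ``padj_threshold`` and |log2FC| >= ``lfc_threshold``.
    """
    trt, ctl = comparison
    if tab.design.replicates_per_stage < 2:
        raise FolliscanError("differential expression needs >= 2 replicates per stage")
    x = tab.values[tab.design.stage_samples(trt)].values
    y = tab.values[tab.design.stage_samples(ctl)].values

    mean_t, mean_c = x.mean(axis=1), y.mean(axis=1)
    lfc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))

    lx, ly = np.log2(x + PSEUDOCOUNT), np.log2(y + PSEUDOCOUNT)
    with np.errstate(all="ignore"):
        _, p = stats.ttest_ind(lx, ly, axis=1, equal_var=False)
    # degenerate features: zero within-group variance on both sides
    degenerate = (lx.std(axis=1) == 0) & (ly.std(axis=1) == 0)
    equal_means = np.isclose(lx.mean(axis=1), ly.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    # constant-zero features: not testable, flat by definition
    allzero = (x == 0).all(axis=1) & (y == 0).all(axis=1)
    p = np.where(allzero, 1.0, p)
    lfc = np.where(allzero, 0.0, lfc)

    padj = benjamini_hochberg(p)
    de = (padj <= padj_threshold) & (np.abs(lfc) >= lfc_threshold)
    direction = np.where(de, np.where(lfc > 0, "up", "down"), "null")

    table = pd.DataFrame(
        {"log2fc": lfc, "p": p, "padj": padj, "de": de, "direction": direction},
        index=tab.values.index,
    )
    return ComparisonResult(comparison=comparison, table=table)


def run_all_comparisons(tab: ExpressionTable, **kwargs) -> List[ComparisonResult]:
    return [differential_expression(tab, c, **kwargs) for c in tab.design.comparisons]


# ---------------------------------------------------------------------------
# Venn / stage-specific sets
# ---------------------------------------------------------------------------

@dataclass
class VennResult:
    """DE sets, stage-specific subsets and all 2^k - 1 region counts."""

    labels: List[str]
    de_sets: Dict[str, FrozenSet[str]]
    stage_specific: Dict[str, FrozenSet[str]]
    regions: Dict[Tuple[bool, ...], int]

    @property
    def union_size(self) -> int:
        u: set = set()
        for s in self.de_sets.values():
            u |= s
        return len(u)


def venn_stage_specific(results: Sequence[ComparisonResult]) -> VennResult:
    """Region cardinalities and per-comparison stage-specific DE subsets.

    A feature is stage-specific to a comparison when it is DE in that
    comparison and in no other.
    """
    labels = [r.label for r in results]
    de_sets = {r.label: r.de_features for r in results}
    union = sorted(set().union(*de_sets.values())) if de_sets else []

    regions: Dict[Tuple[bool, ...], int] = {}
    for f in union:
        key = tuple(f in de_sets[l] for l in labels)
        regions[key] = regions.get(key, 0) + 1

    specific = {}
    for i, lab in enumerate(labels):
        only = [
            f
            for f in de_sets[lab]
            if all(f not in de_sets[labels[j]] for j in range(len(labels)) if j != i)
        ]
        specific[lab] = frozenset(only)
    return VennResult(labels=labels, de_sets=de_sets, stage_specific=specific, regions=regions)


# ---------------------------------------------------------------------------
# Hierarchical sample clustering
# ---------------------------------------------------------------------------

@dataclass
class SampleDendrogram:
    linkage: np.ndarray
    labels: List[str]  # sample names, in the order used for the linkage
    matrix: pd.DataFrame  # log2(FPKM+1), columns ordered by dendrogram leaves

    def leaf_order(self) -> List[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> Dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def root_split(self) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        groups = self.cut(2)
        a = frozenset(s for s, g in groups.items() if g == 1)
        b = frozenset(s for s, g in groups.items() if g == 2)
        return a, b

    def stage_clades(self, design: SampleDesign) -> Dict[str, bool]:
        """Whether each stage's replicates form a clade in the tree."""
        tree = hierarchy.to_tree(self.linkage)
        clades: List[FrozenSet[str]] = []

        def walk(node) -> FrozenSet[str]:
            if node.is_leaf():
                leaves = frozenset([self.labels[node.id]])
            else:
                leaves = walk(node.left) | walk(node.right)
            clades.append(leaves)
            return leaves

        walk(tree)
        return {
            stage: frozenset(design.stage_samples(stage)) in clades
            for stage in design.stages
        }


def hierarchical_cluster_samples(tab: ExpressionTable) -> SampleDendrogram:
    """Complete-linkage Euclidean clustering of sample columns.

    Operates on log2(FPKM + 1) of the supplied (typically DE-restricted)
    table.  Samples are ordered lexicographically by name before linkage
    so equal-distance merges resolve deterministically.
    """
    if len(tab) < 2:
        raise FolliscanError("sample clustering needs >= 2 features")
    mat = tab.log2p1()
    labels = sorted(mat.columns)
    X = mat[labels].values.T  # samples x features
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return SampleDendrogram(linkage=Z, labels=labels, matrix=mat[order])


# ---------------------------------------------------------------------------
# K-means expression patterns
# ---------------------------------------------------------------------------

def assign_pattern_group(centroid: Sequence[float], tau: float) -> str:
    """Trend class of a six-stage centroid given flatness tolerance ``tau``.

    stable: every successive difference within +-tau; increasing: no
    successive drop beyond tau and at least one rise beyond tau;
    decreasing: the mirror image; anything else fluctuates.
    """
    c = np.asarray(centroid, dtype=float)
    d = np.diff(c)
    if np.all(np.abs(d) <= tau):
        return "stable"
    if np.all(d >= -tau) and np.any(d > tau):
        return "increasing"
    if np.all(d <= tau) and np.any(d < -tau):
        return "decreasing"
    return "fluctuating"


@dataclass
class ClusterAssignment:
    """k-means clusters of standardized stage profiles plus trend labels."""

    assignments: pd.Series  # feature -> cluster id (1..k)
    centroids: pd.DataFrame  # cluster id x stages, standardized units
    pattern_groups: Dict[int, str]  # cluster id -> pattern group
    tau: float

    @property
    def k(self) -> int:
        return len(self.centroids)

    def cluster_sizes(self) -> Dict[int, int]:
        return {int(c): int((self.assignments == c).sum()) for c in self.centroids.index}

    def feature_pattern(self, feature: str) -> str:
        return self.pattern_groups[int(self.assignments[feature])]


def standardize_profiles(profiles: pd.DataFrame, std_floor: float = STD_FLOOR) -> pd.DataFrame:
    """Per-feature z-standardization with a standard-deviation floor.

    Dividing a near-constant profile by its own tiny standard deviation
    would place pure replicate noise on the unit sphere; the floor keeps
    flat profiles near the origin so they cluster together.
    """
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0).clip(lower=std_floor)
    return profiles.sub(mu, axis=0).div(sd, axis=0)


def kmeans_patterns(
    tab: ExpressionTable,
    k: int = DEFAULT_K,
    seed: int = 0,
    tau_fraction: float = TAU_FRACTION,
    std_floor: float = STD_FLOOR,
) -> ClusterAssignment:
    """Cluster per-stage expression profiles with Euclidean k-means.

    Profiles are per-stage replicate means of log2(FPKM + 1), z-standardized
    per feature (see :func:`standardize_profiles`); k-means++ start, fixed
    seed, <= 300 iterations.  Each cluster centroid receives a pattern group
    with tau = ``tau_fraction`` x (max - min) over all centroid values.
    """
    if k < 2:
        raise FolliscanError("k must be >= 2")
    if len(tab) < k:
        raise FolliscanError(
            f"only {len(tab)} features for k={k}; use a smaller k"
        )
    profiles = standardize_profiles(tab.stage_means(log=True), std_floor=std_floor)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(profiles.values)

    assignments = pd.Series(labels + 1, index=profiles.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=profiles.columns
    )
    spread = float(centroids.values.max() - centroids.values.min())
    tau = tau_fraction * spread
    groups = {
        int(cid): assign_pattern_group(centroids.loc[cid].values, tau)
        for cid in centroids.index
    }
    return ClusterAssignment(
        assignments=assignments, centroids=centroids, pattern_groups=groups, tau=tau
    )
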