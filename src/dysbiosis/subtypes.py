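"""Subject subtyping from paired difference profiles.

Each subject is represented by the vector of lesion minus peri-lesion
relative-abundance differences over the prevalent genera (prevalence >= 60%
across all samples by default). Subjects are compared by Pearson correlation
of these profiles, clustered hierarchically on the distance 1 - r, and the
tree is cut at the merge height that maximizes the number of clusters that
are both large enough (>= 3 members) and internally coherent (within-cluster
mean pairwise r >= r_min). Qualifying clusters are labelled C1, C2, ... in
decreasing size order; everyone else lands in the singleton/doublet bucket
Cs. Severity scores are compared across the resulting groups with one-way
ANOVA plus Tukey HSD, and per-genus difference values are tested the same
way with Benjamini-Hochberg adjustment across genera.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .data import PairedDesign
from .profiling import RelAbundanceTable


@dataclass
class SubtypeAssignment:
    """Subject -> cluster labels plus per-cluster coherence diagnostics."""

    labels: dict[str, str]
    cluster_stats: pd.DataFrame  # index label; columns size, mean_r
    cut_height: float
    r_min: float
    min_cluster_size: int
    linkage: str

    def members(self, label: str) -> list[str]:
        return sorted(s for s, lab in self.labels.items() if lab == label)

    @property
    def cluster_labels(self) -> list[str]:
        return [lab for lab in self.cluster_stats.index if lab != "Cs"]


def difference_profiles(
    design: PairedDesign,
    rel: RelAbundanceTable,
    prevalence: float = 0.6,
) -> pd.DataFrame:
    """Subjects x prevalent-genera matrix of paired abundance differences.

    Prevalence is computed across ALL samples (both sites) on the full genus
    table; differences are taken on the full-table relative abundances and
    then column-subset to the qualifying genera.
    """
    frame = rel.to_frame()
    n = len(frame)
    need = math.ceil(prevalence * n)
    prevalent = [g for g in frame.columns if (frame[g] > 0).sum() >= need]
    if len(prevalent) < 2:
        raise ValueError(
            f"only {len(prevalent)} genera pass the {prevalence:.0%} "
            "prevalence filter; need at least 2"
        )
    les = frame.loc[design.lesion_samples].to_numpy()
    per = frame.loc[design.peri_samples].to_numpy()
    full = pd.DataFrame(les - per, index=design.subjects, columns=frame.columns)
    return full[prevalent]


def subject_correlations(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every pair of subject difference profiles.

    Subjects with a constant profile have undefined correlations; these are
    recorded as missing (NaN) with a warning, except the diagonal which is 1
    by convention.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 genus columns to correlate subjects")
    constant = profiles.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"constant difference profiles for {list(profiles.index[constant])}; "
            "their correlations are undefined and recorded as missing"
        )
    corr = profiles.T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _mean_within_r(corr: pd.DataFrame, members: list[str]) -> float:
    sub = corr.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), 1)
    vals = sub[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def cluster_subjects(
    corr: pd.DataFrame,
    linkage: str = "complete",
    r_min: float = 0.6,
    min_cluster_size: int = 3,
) -> SubtypeAssignment:
    """Hierarchical clustering on 1 - r with a coherence-guided cut.

    Every merge height of the dendrogram is a candidate cut; a cluster
    qualifies at a cut if it has size >= ``min_cluster_size`` and
    within-cluster mean pairwise r >= ``r_min``. The chosen cut maximizes
    the number of subjects belonging to qualifying clusters, with ties
    resolved toward the larger height (fewer, coarser clusters) — i.e. the
    tree is cut as high as the coherence floor allows. Maximizing the
    cluster count instead would always favor the finest fragmentation,
    because complete-linkage children of a coherent cluster are at least as
    coherent as their parent. Members of non-qualifying clusters are pooled
    into Cs. Missing correlations enter the distance as 1 (r = 0) but are
    excluded from within-cluster means.
    """
    subjects = list(corr.index)
    n = len(subjects)
    if n == 1:
        return SubtypeAssignment(
            labels={subjects[0]: "Cs"},
            cluster_stats=pd.DataFrame(
                {"size": [1], "mean_r": [float("nan")]}, index=["Cs"]
            ),
            cut_height=0.0,
            r_min=r_min,
            min_cluster_size=min_cluster_size,
            linkage=linkage,
        )
    dist = 1.0 - corr.to_numpy()
    dist = np.where(np.isnan(dist), 1.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = scipy_linkage(squareform(dist, checks=False), method=linkage)

    def evaluate(height):
        flat = fcluster(z, t=height, criterion="distance")
        clusters = [
            [subjects[i] for i in np.flatnonzero(flat == c)]
            for c in np.unique(flat)
        ]
        good = [
            c
            for c in clusters
            if len(c) >= min_cluster_size and _mean_within_r(corr, c) >= r_min
        ]
        return clusters, good

    best_height, best_good, best_cov = 0.0, [], -1
    for height in sorted(set([0.0, *z[:, 2]])):
        _, good = evaluate(height)
        coverage = sum(len(c) for c in good)
        if coverage >= best_cov:  # ties -> larger height wins
            best_height, best_good, best_cov = height, good, coverage

    if not best_good:
        warnings.warn("no cut produced a qualifying cluster; all subjects in Cs")
    ordered = sorted(best_good, key=lambda c: (-len(c), c[0]))
    labels = {s: "Cs" for s in subjects}
    records = []
    for k, members in enumerate(ordered, start=1):
        lab = f"C{k}"
        for s in members:
            labels[s] = lab
        records.append((lab, len(members), _mean_within_r(corr, members)))
    cs_members = [s for s, lab in labels.items() if lab == "Cs"]
    records.append(
        ("Cs", len(cs_members),
         _mean_within_r(corr, cs_members) if len(cs_members) > 1 else float("nan"))
    )
    stats_df = pd.DataFrame(
        records, columns=["label", "size", "mean_r"]
    ).set_index("label")
    return SubtypeAssignment(
        labels=labels,
        cluster_stats=stats_df,
        cut_height=float(best_height),
        r_min=r_min,
        min_cluster_size=min_cluster_size,
        linkage=linkage,
    )


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    groups_used: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def _one_way_anova(values_by_group: dict[str, np.ndarray]) -> AnovaResult:
    used = {g: v for g, v in values_by_group.items() if len(v) >= 2}
    excluded = sorted(set(values_by_group) - set(used))
    if excluded:
        warnings.warn(f"groups of size < 2 excluded from ANOVA: {excluded}")
    if len(used) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    arrays = list(used.values())
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        f, p = (0.0, 1.0) if ss_between == 0 else (float("inf"), 0.0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*arrays)
        f, p = float(f), float(p)
    labels = np.concatenate([[g] * len(a) for g, a in used.items()])
    if ss_within == 0:
        tukey_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p-adj", "lower", "upper", "reject"]
        )
    else:
        res = pairwise_tukeyhsd(pooled, labels)
        pairs = [
            (res.groupsunique[i], res.groupsunique[j])
            for i in range(len(res.groupsunique))
            for j in range(i + 1, len(res.groupsunique))
        ]
        tukey_df = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "meandiff": res.meandiffs,
                "p-adj": res.pvalues,
                "lower": res.confint[:, 0],
                "upper": res.confint[:, 1],
                "reject": res.reject,
            }
        )
    return AnovaResult(f, p, tukey_df, sorted(used), excluded)


def severity_anova(
    assignment: SubtypeAssignment, endpoint_values: pd.Series
) -> AnovaResult:
    """ANOVA of a subject-level endpoint (e.g. mMASI) across subtype groups."""
    groups: dict[str, np.ndarray] = {}
    for label in assignment.cluster_stats.index:
        members = [s for s in assignment.members(label) if s in endpoint_values.index]
        if members:
            groups[label] = endpoint_values[members].to_numpy(dtype=float)
    return _one_way_anova(groups)


def cluster_genus_enrichment(
    assignment: SubtypeAssignment, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-genus ANOVA of difference values across clusters, BH-adjusted.

    Returns one row per genus with F, p, BH q, the cluster where the genus
    difference is largest on average, and the Tukey table is retrievable via
    the ``tukey`` column (stored as a DataFrame per row).
    """
    groups_of = {
        label: assignment.members(label) for label in assignment.cluster_stats.index
    }
    rows = []
    for genus in profiles.columns:
        values = {
            lab: profiles.loc[members, genus].to_numpy(dtype=float)
            for lab, members in groups_of.items()
            if members
        }
        res = _one_way_anova(values)
        means = {lab: v.mean() for lab, v in values.items() if len(v) >= 2}
        top = max(means, key=means.get)
        rows.append((genus, res.f_statistic, res.p_value, top, res.tukey))
    df = pd.DataFrame(rows, columns=["genus", "F", "p", "top_cluster", "tukey"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.set_index("genus")[["F", "p", "q", "top_cluster", "tukey"]]


def top_enriched_per_cluster(
    enrichment: pd.DataFrame, profiles: pd.DataFrame, assignment: SubtypeAssignment
) -> dict[str, str]:
    """For each non-Cs cluster, the genus with the largest mean difference."""
    out = {}
    for label in assignment.cluster_labels:
        members = assignment.members(label)
        means = profiles.loc[members].mean(axis=0)
        out[label] = str(means.idxmax())
    return out


def cohort_homogeneity(corr: pd.DataFrame) -> float:
    """Mean off-diagonal Pearson r (missing entries excluded)."""
    m = corr.to_numpy()
    iu = np.triu_indices(m.shape[0], 1)
    vals = m[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")
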