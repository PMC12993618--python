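"""Community profiling: filters, diversity, core-microbiome sets, paired tests.

All abundance statistics operate on per-sample relative abundances; no
rarefaction is applied (an optional rarefaction helper is provided for
sensitivity analysis). "Presence" of a taxon in a sample means a nonzero
count. Paired site contrasts use the two-sided Wilcoxon signed-rank test —
exact null for <= 25 non-zero differences without ties, normal approximation
with continuity correction otherwise — with Benjamini-Hochberg adjustment
across genera where many taxa are tested.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .data import PairedDesign, TaxonCountTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RelAbundanceTable:
    """Samples x taxa proportions; every row sums to one."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        rowsums = self.values.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValidationError("relative-abundance rows must sum to 1")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValidationError("relative abundances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


@dataclass
class SetPartition:
    """Common / unique split of two taxon sets (e.g. lesion vs peri-lesion)."""

    common: set[str]
    unique_to_a: set[str]
    unique_to_b: set[str]

    @property
    def cardinalities(self) -> tuple[int, int, int]:
        return len(self.common), len(self.unique_to_a), len(self.unique_to_b)


def relative_abundance(table: TaxonCountTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total."""
    totals = table.counts.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValidationError(f"samples with zero total counts: {zero}")
    return RelAbundanceTable(
        list(table.sample_ids),
        list(table.taxon_ids),
        table.counts / totals[:, None],
    )


def prevalence_count_filter(
    table: TaxonCountTable, min_prevalence: float = 0.4, min_total: int = 10
) -> TaxonCountTable:
    """Drop taxa below a prevalence fraction or a grand-total count.

    A taxon is kept iff it is present (count > 0) in at least
    ``ceil(min_prevalence * n_samples)`` samples AND its total count across
    all samples is at least ``min_total``. Samples are never dropped.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    need = math.ceil(min_prevalence * table.n_samples)
    presence = (table.counts > 0).sum(axis=0)
    totals = table.counts.sum(axis=0)
    keep = [
        t
        for t, p, tot in zip(table.taxon_ids, presence, totals)
        if p >= need and tot >= min_total
    ]
    if not keep:
        raise ValidationError(
            "prevalence/count filter removed every taxon; lower min_prevalence "
            f"(={min_prevalence}) or min_total (={min_total})"
        )
    return table.subset_taxa(keep)


def shannon_index(proportions: np.ndarray, base: str | float = "e") -> float:
    """Shannon diversity H = -sum p_i log p_i of one composition row.

    ``base`` is ``"e"`` (nats, default) or ``2`` (bits); zero proportions
    contribute nothing.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base in (2, "2"):
        h /= math.log(2)
    elif base not in ("e",):
        raise ValueError("base must be 'e' or 2")
    return h


def alpha_diversity(rel: RelAbundanceTable, base: str | float = "e") -> pd.Series:
    """Per-sample Shannon index."""
    return pd.Series(
        [shannon_index(row, base=base) for row in rel.values],
        index=rel.sample_ids,
        name="shannon",
    )


def _paired_wilcoxon(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank; zeros dropped; exact when possible."""
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p set to 1")
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def paired_alpha_test(
    design: PairedDesign, diversity: pd.Series
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of lesion vs peri-lesion Shannon indices."""
    if design.n_pairs < 6:
        raise ValueError("need at least 6 complete pairs")
    diffs = (
        diversity[design.lesion_samples].to_numpy()
        - diversity[design.peri_samples].to_numpy()
    )
    return _paired_wilcoxon(diffs)


def core_microbiome(
    table: TaxonCountTable,
    site_samples: list[str],
    prevalence_threshold: float = 0.9,
) -> set[str]:
    """Taxa present in at least the threshold fraction of a site's samples."""
    if not site_samples:
        raise ValueError("site_samples must be non-empty")
    sub = table.subset_samples(site_samples)
    frac = (sub.counts > 0).mean(axis=0)
    return {t for t, f in zip(sub.taxon_ids, frac) if f >= prevalence_threshold}


def set_partition(a: set[str], b: set[str]) -> SetPartition:
    """Split two taxon sets into common / unique-to-A / unique-to-B."""
    a, b = set(a), set(b)
    return SetPartition(common=a & b, unique_to_a=a - b, unique_to_b=b - a)


def observed_taxa(table: TaxonCountTable, samples: list[str]) -> set[str]:
    """Taxa with a nonzero count in any of the given samples."""
    sub = table.subset_samples(samples)
    present = (sub.counts > 0).any(axis=0)
    return {t for t, ok in zip(sub.taxon_ids, present) if ok}


def paired_genus_test(
    design: PairedDesign, rel: RelAbundanceTable, genus: str
) -> tuple[float, float, float]:
    """Paired lesion vs peri-lesion test for one genus.

    Returns (mean paired difference, Wilcoxon statistic, two-sided p).
    """
    if genus not in rel.taxon_ids:
        raise KeyError(f"genus {genus!r} not in table")
    frame = rel.to_frame()
    diffs = (
        frame.loc[design.lesion_samples, genus].to_numpy()
        - frame.loc[design.peri_samples, genus].to_numpy()
    )
    stat, p = _paired_wilcoxon(diffs)
    return float(diffs.mean()), stat, p


def paired_genus_tests(
    design: PairedDesign, rel: RelAbundanceTable, genera: list[str] | None = None
) -> pd.DataFrame:
    """Per-genus paired tests with BH-adjusted q across the tested genera."""
    genera = list(genera) if genera is not None else list(rel.taxon_ids)
    frame = rel.to_frame()
    les = frame.loc[design.lesion_samples, genera].to_numpy()
    per = frame.loc[design.peri_samples, genera].to_numpy()
    rows, degenerate = [], []
    for j, g in enumerate(genera):
        d = les[:, j] - per[:, j]
        if (d == 0).all():
            degenerate.append(g)
            rows.append((g, 0.0, 0.0, 1.0))
            continue
        stat, p = _paired_wilcoxon(d)
        rows.append((g, float(d.mean()), stat, p))
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} genus/genera with all-zero paired differences "
            "(absent from every tested pair); p set to 1 for those"
        )
    df = pd.DataFrame(rows, columns=["genus", "mean_difference", "statistic", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.set_index("genus")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(rel: RelAbundanceTable) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarity on relative abundances."""
    d = squareform(pdist(rel.values, metric="braycurtis"))
    return pd.DataFrame(d, index=rel.sample_ids, columns=rel.sample_ids)


def _pseudo_f(dm: np.ndarray, groups: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a distance matrix and group labels."""
    n = dm.shape[0]
    d2 = dm**2
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    uniq, counts = np.unique(groups, return_counts=True)
    for g, ng in zip(uniq, counts):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(ng, 1)].sum() / ng
    ssa = sst - ssw
    a = len(uniq)
    return (ssa / (a - 1)) / (ssw / (n - a))


def beta_diversity(
    rel: RelAbundanceTable,
    design: PairedDesign,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Bray-Curtis + PERMANOVA on site labels, permuting within subjects.

    The permutation null respects the paired design: each subject's
    (lesion, peri-lesion) labels are swapped or kept independently, so
    exchangeability holds within subject only. Returns
    (distance matrix, pseudo-F, p).
    """
    dm_df = bray_curtis(rel)
    samples = design.lesion_samples + design.peri_samples
    idx = [rel.sample_ids.index(s) for s in samples]
    dm = dm_df.to_numpy()[np.ix_(idx, idx)]
    k = design.n_pairs
    groups = np.array([0] * k + [1] * k)
    f_obs = _pseudo_f(dm, groups)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_permutations):
        flips = rng.integers(0, 2, size=k).astype(bool)
        perm = groups.copy()
        perm[:k][flips] = 1
        perm[k:][flips] = 0
        if _pseudo_f(dm, perm) >= f_obs:
            hits += 1
    p = hits / (n_permutations + 1)
    return dm_df, float(f_obs), float(p)


def rarefy(table: TaxonCountTable, depth: int, seed: int = 0) -> TaxonCountTable:
    """Optional even-depth subsampling without replacement (sensitivity only)."""
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        total = row.sum()
        if total < depth:
            raise ValidationError(
                f"sample {table.sample_ids[i]!r} has {total} < depth {depth}"
            )
        pool = np.repeat(np.arange(table.n_taxa), row)
        picked = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=table.n_taxa)
    return TaxonCountTable(
        list(table.sample_ids), list(table.taxon_ids), out, dict(table.lineages)
    )
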