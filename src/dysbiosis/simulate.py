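"""Synthetic paired lesion/peri-lesion cohorts with planted ground truth.

The generator emulates a 40-subject facial-skin 16S study: each subject
contributes one lesion and one peri-lesion sample. Peri-lesion communities
are drawn from a logistic-normal model — a latent Gaussian with a planted
sparse dependence graph (its precision matrix), pushed through a softmax onto
the simplex and observed as multinomial counts at a realistic read depth.
Lesion communities are the same subject's latent vector plus a
subtype-specific shift: each planted subtype moves its own small set of taxa
by +/- delta on the latent (log) scale, and a fraction of subjects carries no
shift at all (the "unassigned" pool). Clinical endpoints are linearly coupled
to the paired relative-abundance difference of a chosen genus so that the
population Pearson correlation hits a configured target, and the severity
score (mMASI) is drawn subject-level with subtype-specific means.

Everything needed to score recovery — the latent edge set, the subject ->
subtype map and the clinical coupling coefficients — is returned as
:class:`PlantedTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    LESION,
    PERI_LESION,
    ClinicalTable,
    PairedDesign,
    SampleMeta,
    TaxonCountTable,
)

#: real facial-skin genera used to name the top-ranked synthetic taxa
SKIN_GENERA = [
    "Cutibacterium", "Staphylococcus", "Streptococcus", "Corynebacterium",
    "Micrococcus", "Kocuria", "Acinetobacter", "Pseudomonas", "Actinomyces",
    "Rothia", "Veillonella", "Gemella", "Haemophilus", "Fusobacterium",
    "Arthrobacter", "Enterobacter", "Leptotrichia", "Microbacterium",
    "Lachnoanaerobaculum", "Paracoccus", "Deinococcus", "Brevibacterium",
    "Dermacoccus", "Prevotella", "Neisseria", "Sphingomonas",
    "Methylobacterium", "Janibacter", "Enhydrobacter", "Finegoldia",
    "Anaerococcus", "Peptoniphilus", "Lawsonella", "Moraxella", "Kingella",
    "Leptothrix", "Arsenicicoccus", "Dietzia", "Brachybacterium", "Pantoea",
]


@dataclass(frozen=True)
class SubtypeSpec:
    """One planted lesional-shift subtype.

    ``shifted_taxa`` are taxon indices; ``signs`` the per-taxon shift
    direction; ``delta`` the shift magnitude on the latent log scale.
    """

    label: str
    proportion: float
    shifted_taxa: tuple[int, ...]
    delta: float
    signs: tuple[int, ...] | None = None


@dataclass(frozen=True)
class ClinicalSpec:
    """One planted clinical endpoint coupled to a genus difference."""

    endpoint: str
    coupled_genus: str
    target_r: float


def default_subtypes(delta: float = 2.0) -> list[SubtypeSpec]:
    """Three subtypes sized 55% / 17.5% / 17.5% of the cohort.

    At 40 subjects this yields groups of 22, 7 and 7, with the remaining 10%
    (4 subjects) unassigned. Each subtype perturbs five moderately abundant
    taxa with alternating signs; the largest subtype includes the dominant
    genus among its shifted taxa.
    """
    signs = (1, -1, 1, -1, 1)
    return [
        SubtypeSpec("C1", 0.55, (0, 5, 10, 15, 20), delta, signs),
        SubtypeSpec("C2", 0.175, (2, 3, 6, 11, 16), delta, signs),
        SubtypeSpec("C3", 0.175, (1, 7, 12, 17, 22), delta, signs),
    ]


def default_clinical() -> list[ClinicalSpec]:
    return [
        ClinicalSpec("TEWL", "Actinomyces", 0.48),
        ClinicalSpec("L_STAR", "Rothia", -0.40),
        ClinicalSpec("CAT_ACTIVITY", "Gemella", 0.40),
    ]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults reproduce the emulated study: 40 subjects x 2 paired sites,
    150 genera with a skin-like rank-abundance skew (one dominant genus),
    an Erdos-Renyi latent dependence graph, three planted subtypes
    (22/7/7 subjects) plus 4 unassigned, and read depths of 10k-50k.
    """

    n_subjects: int = 40
    n_taxa: int = 150
    graph_type: str = "erdos_renyi"
    graph_density: float = 0.04
    subtypes: list[SubtypeSpec] = field(default_factory=default_subtypes)
    clinical: list[ClinicalSpec] = field(default_factory=default_clinical)
    depth_range: tuple[int, int] = (10_000, 50_000)
    skew_exponent: float = 1.3
    rare_tail_start: int = 40
    rare_tail_rate: float = 0.12
    lesion_noise_sd: float = 0.4
    mmasi_means: dict[str, float] = field(
        default_factory=lambda: {"C1": 7.5, "C2": 8.7, "C3": 9.8, "Cs": 8.2}
    )
    mmasi_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(s.proportion for s in self.subtypes)
        if total > 1.0 + 1e-9:
            raise ValueError(f"subtype proportions sum to {total} > 1")
        if self.depth_range[0] < 1000:
            raise ValueError("minimum read depth must be >= 1000")
        for c in self.clinical:
            if abs(c.target_r) >= 1:
                raise ValueError(f"target |r| must be < 1 ({c.endpoint}: {c.target_r})")
        for s in self.subtypes:
            if not np.isfinite(s.delta):
                raise ValueError(f"subtype {s.label}: delta must be finite")

    @property
    def unassigned_fraction(self) -> float:
        return 1.0 - sum(s.proportion for s in self.subtypes)


def null_config(**overrides) -> SyntheticConfig:
    """A no-effect cohort: delta = 0, flat mMASI means, no clinical coupling."""
    defaults = dict(
        subtypes=default_subtypes(delta=0.0),
        clinical=[ClinicalSpec(c.endpoint, c.coupled_genus, 0.0) for c in default_clinical()],
        mmasi_means={"C1": 8.2, "C2": 8.2, "C3": 8.2, "Cs": 8.2},
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort, for recovery scoring."""

    precision: np.ndarray
    edges: set[tuple[int, int]]
    subtype_of: dict[str, str]
    clinical_coefficients: dict[str, dict[str, float]]
    taxon_ids: list[str] = field(default_factory=list)

    def edge_ids(self) -> set[tuple[str, str]]:
        out = set()
        for i, j in self.edges:
            u, v = self.taxon_ids[i], self.taxon_ids[j]
            out.add((u, v) if u < v else (v, u))
        return out


# ---------------------------------------------------------------------------
# planted dependence graph
# ---------------------------------------------------------------------------

def make_precision_matrix(
    graph_type: str,
    n_taxa: int,
    density: float = 0.1,
    seed: int = 0,
    edge_weight: float = 0.3,
    pd_margin: float = 0.5,
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Build a symmetric positive-definite precision matrix on a planted graph.

    The off-diagonal support is the planted edge set (chain, hub, or
    Erdos-Renyi with the given density) with fixed magnitude ``edge_weight``;
    the diagonal is lifted by the most negative eigenvalue of the off-diagonal
    part plus ``pd_margin`` so the matrix is positive definite by
    construction.
    """
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    if graph_type == "chain":
        edges = {(i, i + 1) for i in range(n_taxa - 1)}
    elif graph_type == "hub":
        edges = {(0, i) for i in range(1, n_taxa)}
    elif graph_type == "erdos_renyi":
        if not 0 < density <= 1:
            raise ValueError("erdos_renyi density must be in (0, 1]")
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                if rng.random() < density:
                    edges.add((i, j))
    else:
        raise ValueError(f"unknown graph type {graph_type!r}")

    omega = np.zeros((n_taxa, n_taxa))
    for i, j in edges:
        omega[i, j] = omega[j, i] = edge_weight
    eigmin = np.linalg.eigvalsh(omega)[0] if edges else 0.0
    np.fill_diagonal(omega, abs(eigmin) + pd_margin)
    if np.linalg.eigvalsh(omega)[0] <= 0:
        raise RuntimeError("precision matrix not positive definite")
    return omega, edges


def _latent_covariance(precision: np.ndarray) -> np.ndarray:
    """Invert the precision and rescale to unit marginal variances."""
    sigma = np.linalg.inv(precision)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _baseline_skew(
    n_taxa: int, exponent: float, tail_start: int = 40, tail_rate: float = 0.12
) -> np.ndarray:
    """Zipf-like latent means with an accelerated rare tail.

    The power-law head gives taxon 1 roughly a third of the reads; beyond
    ``tail_start`` an extra linear decay on the log scale pushes low-ranked
    genera toward the detection limit, so — as in real 16S tables — many
    taxa are absent from a substantial fraction of samples and the
    prevalence filters have something to do.
    """
    ranks = np.arange(1, n_taxa + 1, dtype=float)
    mu = -exponent * np.log(ranks)
    mu -= tail_rate * np.clip(ranks - tail_start, 0, None)
    return mu


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _taxon_names(n_taxa: int) -> tuple[list[str], dict[str, str]]:
    names = list(SKIN_GENERA[:n_taxa])
    for k in range(len(names), n_taxa):
        names.append(f"Genus{k + 1:03d}")
    lineages = {g: f"k__Bacteria;g__{g}" for g in names}
    return names, lineages


def _subject_labels(config: SyntheticConfig) -> list[str]:
    """Deterministic subtype allocation: largest remainder on proportions."""
    n = config.n_subjects
    raw = [s.proportion * n for s in config.subtypes]
    base = [int(np.floor(r)) for r in raw]
    remainder = n - sum(base) - int(round(config.unassigned_fraction * n))
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for k in order[:max(remainder, 0)]:
        base[k] += 1
    labels = []
    for spec, cnt in zip(config.subtypes, base):
        labels.extend([spec.label] * cnt)
    labels.extend(["Cs"] * (n - len(labels)))
    return labels


# ---------------------------------------------------------------------------
# paired count sampling
# ---------------------------------------------------------------------------

def sample_paired_counts(
    config: SyntheticConfig,
) -> tuple[TaxonCountTable, list[SampleMeta], PlantedTruth]:
    """Draw the paired count table plus metadata and planted truth.

    Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    precision, edges = make_precision_matrix(
        config.graph_type, config.n_taxa, config.graph_density,
        seed=int(rng.integers(2**31)),
    )
    cov = _latent_covariance(precision)
    chol = np.linalg.cholesky(cov)
    mu = _baseline_skew(
        config.n_taxa, config.skew_exponent,
        config.rare_tail_start, config.rare_tail_rate,
    )
    taxon_ids, lineages = _taxon_names(config.n_taxa)
    labels = _subject_labels(config)

    shift_of = {"Cs": np.zeros(config.n_taxa)}
    for s in config.subtypes:
        vec = np.zeros(config.n_taxa)
        signs = s.signs or tuple(1 for _ in s.shifted_taxa)
        for idx, sign in zip(s.shifted_taxa, signs):
            vec[idx] = sign * s.delta
        shift_of[s.label] = vec

    subjects = [f"subj{k + 1:02d}" for k in range(config.n_subjects)]
    sample_ids: list[str] = []
    metas: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    lo, hi = config.depth_range
    for subj, label in zip(subjects, labels):
        z = mu + chol @ rng.standard_normal(config.n_taxa)
        z_lesion = (
            z + shift_of[label]
            + config.lesion_noise_sd * rng.standard_normal(config.n_taxa)
        )
        for site, latent in ((LESION, z_lesion), (PERI_LESION, z)):
            depth = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(depth, _softmax(latent))
            sid = f"{subj}{'L' if site == LESION else 'P'}"
            sample_ids.append(sid)
            metas.append(SampleMeta(sid, subj, site))
            rows.append(counts)

    table = TaxonCountTable(
        sample_ids, taxon_ids, np.array(rows, dtype=np.int64), lineages
    )
    truth = PlantedTruth(
        precision=precision,
        edges=edges,
        subtype_of=dict(zip(subjects, labels)),
        clinical_coefficients={},
        taxon_ids=taxon_ids,
    )
    return table, metas, truth


def sample_community_counts(
    n_samples: int,
    precision: np.ndarray,
    seed: int = 0,
    skew_exponent: float = 1.3,
    depth_range: tuple[int, int] = (10_000, 50_000),
) -> np.ndarray:
    """Draw i.i.d. logistic-normal multinomial count rows from a planted graph.

    The latent Gaussian has the given precision matrix (rescaled to unit
    marginal variances) and a Zipf-like mean vector; this is the standard
    benchmark for sparse inverse-covariance co-occurrence inference.
    """
    rng = np.random.default_rng(seed)
    p = precision.shape[0]
    chol = np.linalg.cholesky(_latent_covariance(precision))
    mu = _baseline_skew(p, skew_exponent, tail_start=p + 1)
    lo, hi = depth_range
    out = np.empty((n_samples, p), dtype=np.int64)
    for i in range(n_samples):
        z = mu + chol @ rng.standard_normal(p)
        depth = int(rng.integers(lo, hi + 1))
        out[i] = rng.multinomial(depth, _softmax(z))
    return out


def _difference_profiles(
    table: TaxonCountTable, design: PairedDesign
) -> pd.DataFrame:
    """Subjects x genera lesion - peri-lesion relative-abundance differences."""
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    sidx = {s: i for i, s in enumerate(table.sample_ids)}
    diffs = np.array(
        [rel[sidx[les]] - rel[sidx[per]] for _, les, per in design.pairs]
    )
    return pd.DataFrame(diffs, index=design.subjects, columns=table.taxon_ids)


def plant_clinical(
    config: SyntheticConfig,
    truth: PlantedTruth,
    diff_profiles: pd.DataFrame,
    seed: int | None = None,
) -> ClinicalTable:
    """Generate clinical endpoints coupled to genus differences plus mMASI.

    For each configured endpoint the lesion - peri-lesion difference is
    ``beta * d_g + eps``, with ``beta`` and ``Var(eps)`` solved so the
    population Pearson correlation against the coupled genus difference
    ``d_g`` equals the target r (beta = 0 when the target is 0). mMASI is
    subject-level Gaussian with subtype-specific means.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    subjects = list(diff_profiles.index)
    records = []
    truth.clinical_coefficients = {}
    for spec in config.clinical:
        d = diff_profiles[spec.coupled_genus].to_numpy()
        s = float(np.std(d))
        r = spec.target_r
        if r == 0 or s == 0:
            beta, sigma = 0.0, 1.0
        else:
            beta = np.sign(r) * 1.0
            sigma = abs(beta) * s * np.sqrt(1 - r**2) / abs(r)
        truth.clinical_coefficients[spec.endpoint] = {
            "genus": spec.coupled_genus, "beta": beta, "sigma": sigma,
            "target_r": r,
        }
        peri = 10.0 + rng.standard_normal(len(subjects))
        diff = beta * d + sigma * rng.standard_normal(len(subjects))
        lesion = peri + diff
        for subj, pv, lv in zip(subjects, peri, lesion):
            records.append((subj, spec.endpoint, PERI_LESION, pv))
            records.append((subj, spec.endpoint, LESION, lv))
    for subj in subjects:
        label = truth.subtype_of[subj]
        mean = config.mmasi_means.get(label, 8.2)
        records.append(
            (subj, "mMASI", "subject_level",
             mean + config.mmasi_sd * rng.standard_normal())
        )
    df = pd.DataFrame(records, columns=["subject_id", "endpoint", "site", "value"])
    return ClinicalTable(df)


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulated study produces."""

    table: TaxonCountTable
    metas: list[SampleMeta]
    design: PairedDesign
    clinical: ClinicalTable
    truth: PlantedTruth
    config: SyntheticConfig


def simulate_cohort(config: SyntheticConfig | None = None) -> SimulatedCohort:
    """One-call generator: counts, metadata, paired design, clinical, truth."""
    from .data import build_paired_design

    config = config or SyntheticConfig()
    table, metas, truth = sample_paired_counts(config)
    design = build_paired_design(metas)
    profiles = _difference_profiles(table, design)
    clinical = plant_clinical(config, truth, profiles)
    return SimulatedCohort(table, metas, design, clinical, truth, config)
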