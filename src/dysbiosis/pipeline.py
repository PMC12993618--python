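"""End-to-end pipeline: validate -> profile -> network -> compare -> subtype
-> associate, driven by one serializable configuration.

Every stage writes its artifacts under ``out/<stage>/`` and contributes an
entry (parameter echo, output digests, warnings, wall-clock) to the run
report, so a run is reproducible from the echoed config alone: the same
config, inputs and seed produce byte-identical outputs. A single global seed
is fanned out to the stages that need randomness through a fixed counter
scheme (``stage_seed = (seed * 10007 + k) mod 2**31`` for stage counter k).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import netcompare, network, profiling, subtypes
from .data import (
    LESION,
    PERI_LESION,
    build_paired_design,
    check_meta_coverage,
    read_clinical_table,
    read_count_table,
    read_sample_meta,
)

log = logging.getLogger(__name__)

STAGES = ("validate", "profile", "network", "compare_nets", "subtype", "associate")


@dataclass
class RunConfig:
    """All pipeline knobs in one serializable object."""

    counts: str = ""
    meta: str = ""
    clinical: str = ""
    counts_format: str = "tsv"
    out_dir: str = "out"
    seed: int = 0
    # filters
    network_prevalence: float = 0.4
    network_min_total: int = 10
    profile_prevalence: float = 0.6
    core_prevalence: float = 0.9
    # network inference
    pseudocount: float = 1.0
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_reps: int = 50
    stars_beta: float = 0.05
    mb_rule: str = "or"
    # subtyping
    linkage: str = "complete"
    r_min: float = 0.6
    min_cluster_size: int = 3
    # stats
    alpha: float = 0.05
    log_transform: str = "auto"
    beta_permutations: int = 999

    def __post_init__(self) -> None:
        for name in ("network_prevalence", "profile_prevalence", "core_prevalence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.mb_rule not in ("or", "and"):
            raise ValueError("mb_rule must be 'or' or 'and'")
        if self.linkage not in ("complete", "average", "single"):
            raise ValueError("linkage must be complete/average/single")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def stage_seed(seed: int, k: int) -> int:
    """Deterministic per-stage seed fan-out from the single run seed."""
    return (seed * 10007 + k) % 2**31


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    config: dict
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: dict[str, str], warnings_: list[str],
            elapsed: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": outputs,
                "warnings": warnings_,
                "seconds": round(elapsed, 3),
            }
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_dir(d: Path) -> dict[str, str]:
    return {p.name: _digest(p) for p in sorted(d.iterdir()) if p.is_file()}


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; see module docstring for the contract."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))

    import warnings as _w

    def run_stage(name, fn):
        t0 = time.perf_counter()
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            try:
                fn(stage_dir)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report.add(
            name,
            _digest_dir(stage_dir),
            [str(w.message) for w in caught],
            time.perf_counter() - t0,
        )

    state: dict = {}

    def s_validate(d: Path):
        table = read_count_table(config.counts, config.counts_format)
        metas = read_sample_meta(config.meta)
        check_meta_coverage(table, metas)
        design = build_paired_design(metas)
        state.update(table=table, metas=metas, design=design)
        if config.clinical:
            state["clinical"] = read_clinical_table(config.clinical)
        summary = {
            "n_samples": table.n_samples,
            "n_taxa": table.n_taxa,
            "n_pairs": design.n_pairs,
            "rejects": design.rejects,
        }
        (d / "validation.json").write_text(json.dumps(summary, indent=2))

    def s_profile(d: Path):
        table, design = state["table"], state["design"]
        rel = profiling.relative_abundance(table)
        state["rel"] = rel
        shannon = profiling.alpha_diversity(rel)
        stat, p = profiling.paired_alpha_test(design, shannon)
        _float_csv(shannon.to_frame(), d / "alpha_diversity.tsv")
        genus_tests = profiling.paired_genus_tests(design, rel)
        _float_csv(genus_tests, d / "genus_tests.tsv")
        core_l = profiling.core_microbiome(
            table, design.lesion_samples, config.core_prevalence
        )
        core_p = profiling.core_microbiome(
            table, design.peri_samples, config.core_prevalence
        )
        obs_l = profiling.observed_taxa(table, design.lesion_samples)
        obs_p = profiling.observed_taxa(table, design.peri_samples)
        part = profiling.set_partition(obs_l, obs_p)
        core_part = profiling.set_partition(core_l, core_p)
        _, f_stat, beta_p = profiling.beta_diversity(
            rel, design, config.beta_permutations, stage_seed(config.seed, 1)
        )
        doc = {
            "alpha": {"wilcoxon_statistic": stat, "p": p},
            "beta": {"pseudo_F": f_stat, "p": beta_p},
            "observed_partition": {
                "common": sorted(part.common),
                "unique_to_lesion": sorted(part.unique_to_a),
                "unique_to_peri": sorted(part.unique_to_b),
            },
            "core_partition": {
                "common": sorted(core_part.common),
                "unique_to_lesion": sorted(core_part.unique_to_a),
                "unique_to_peri": sorted(core_part.unique_to_b),
            },
        }
        (d / "profile.json").write_text(json.dumps(doc, indent=2))

    def s_network(d: Path):
        table, design = state["table"], state["design"]
        for site, samples, k in (
            (LESION, design.lesion_samples, 2),
            (PERI_LESION, design.peri_samples, 3),
        ):
            sub = table.subset_samples(samples)
            filtered = profiling.prevalence_count_filter(
                sub, config.network_prevalence, config.network_min_total
            )
            net = network.infer_network(
                filtered,
                pseudocount=config.pseudocount,
                n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
                n_reps=config.stars_reps,
                beta=config.stars_beta,
                seed=stage_seed(config.seed, k),
                rule=config.mb_rule,
            )
            state[f"net_{site}"] = net
            (d / f"network_{site}.json").write_text(
                json.dumps(network_sorted(network.network_to_json(net)), indent=2)
            )
            network.write_graphml(net, d / f"network_{site}.graphml")

    def s_compare(d: Path):
        net_l, net_p = state[f"net_{LESION}"], state[f"net_{PERI_LESION}"]
        rows = []
        for site, net in ((LESION, net_l), (PERI_LESION, net_p)):
            s = netcompare.summarize(net)
            rows.append(
                (site, s.n_nodes, s.n_nodes_total, s.n_edges, s.mean_degree)
            )
        _float_csv(
            pd.DataFrame(
                rows,
                columns=["site", "n_nodes", "n_nodes_total", "n_edges", "mean_degree"],
            ).set_index("site"),
            d / "summary.tsv",
        )
        comp = netcompare.compare_degrees(net_l, net_p)
        _float_csv(comp.table, d / "degree_comparison.tsv")
        for site, net in ((LESION, net_l), (PERI_LESION, net_p)):
            for strategy in ("targeted_degree", "random"):
                try:
                    rc = netcompare.robustness(
                        net, strategy, seed=stage_seed(config.seed, 4)
                    )
                except ValueError:
                    continue
                _float_csv(
                    pd.DataFrame(
                        {
                            "fraction_removed": rc.fractions_removed,
                            "lcc_fraction": rc.lcc_fractions,
                        }
                    ),
                    d / f"robustness_{site}_{strategy}.tsv",
                    index=False,
                )

    def s_subtype(d: Path):
        design, rel = state["design"], state["rel"]
        profiles = subtypes.difference_profiles(
            design, rel, config.profile_prevalence
        )
        state["profiles"] = profiles
        corr = subtypes.subject_correlations(profiles)
        assignment = subtypes.cluster_subjects(
            corr, config.linkage, config.r_min, config.min_cluster_size
        )
        state["assignment"] = assignment
        _float_csv(corr, d / "subject_correlations.tsv")
        _float_csv(
            pd.Series(assignment.labels, name="subtype").rename_axis("subject_id").to_frame(),
            d / "assignment.tsv",
        )
        _float_csv(assignment.cluster_stats, d / "cluster_stats.tsv")
        doc = {
            "cut_height": assignment.cut_height,
            "cohort_mean_r": subtypes.cohort_homogeneity(corr),
        }
        if "clinical" in state:
            mmasi = state["clinical"].subject_values("mMASI", "subject_level")
            if len(mmasi):
                res = subtypes.severity_anova(assignment, mmasi)
                doc["severity_anova"] = {"F": res.f_statistic, "p": res.p_value}
                _float_csv(res.tukey, d / "severity_tukey.tsv", index=False)
        enrich = subtypes.cluster_genus_enrichment(assignment, profiles)
        _float_csv(enrich.drop(columns=["tukey"]), d / "enrichment.tsv")
        (d / "subtype.json").write_text(json.dumps(doc, indent=2))

    def s_associate(d: Path):
        if "clinical" not in state:
            (d / "associations.tsv").write_text(
                "parameter\tgenus\tdirection\tr\tp\tq\n"
            )
            return
        assoc = clin.genus_clinical_correlations(
            state["profiles"], state["clinical"], alpha=config.alpha
        )
        _float_csv(
            assoc[["parameter", "genus", "direction", "r", "p", "q"]],
            d / "associations.tsv",
            index=False,
        )
        contrasts = clin.endpoint_contrasts(
            state["clinical"], config.log_transform
        )
        _float_csv(contrasts, d / "endpoint_contrasts.tsv")

    run_stage("validate", s_validate)
    run_stage("profile", s_profile)
    run_stage("network", s_network)
    run_stage("compare_nets", s_compare)
    run_stage("subtype", s_subtype)
    run_stage("associate", s_associate)

    report.to_json(out / "run_report.json")
    config.to_yaml(out / "config_echo.yaml")
    return report


def network_sorted(doc: dict) -> dict:
    """Round floats and sort keys so network JSON is byte-stable."""
    doc = dict(doc)
    doc["edges"] = [
        {"u": e["u"], "v": e["v"], "stability": round(e["stability"], 10)}
        for e in doc["edges"]
    ]
    return doc
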