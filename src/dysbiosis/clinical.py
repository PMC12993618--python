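"""Clinical endpoint contrasts and clinical-parameter x genus correlations.

Endpoint contrasts compare lesion vs peri-lesion values of each clinical
endpoint. In a balanced two-level within-subject design the mixed model with
a subject random intercept and a site fixed effect reduces exactly to the
paired t-test on per-subject differences, which is what is computed here
(with n - 1 degrees of freedom); skewed, strictly positive endpoints are
log-transformed first. Associations between clinical parameters and genera
are Pearson correlations across subjects — by default against the paired
genus difference profile for site-paired endpoints and against subject-level
values (e.g. mMASI) otherwise — reported with raw p-values and
Benjamini-Hochberg q-values per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import LESION, PERI_LESION, SUBJECT_LEVEL, ClinicalTable


@dataclass
class EndpointContrast:
    """Lesion minus peri-lesion contrast for one endpoint."""

    endpoint: str
    estimate: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    n_pairs: int
    log_transformed: bool


def _maybe_log(lesion: np.ndarray, peri: np.ndarray, policy: str, endpoint: str):
    pooled = np.concatenate([lesion, peri])
    if policy == "off":
        return lesion, peri, False
    if policy == "on":
        if (pooled <= 0).any():
            bad = np.flatnonzero(pooled <= 0)
            raise ValueError(
                f"endpoint {endpoint!r}: log transform requested but "
                f"{bad.size} value(s) are non-positive"
            )
        return np.log(lesion), np.log(peri), True
    if policy == "auto":
        if (pooled > 0).all() and stats.skew(pooled) > 1:
            return np.log(lesion), np.log(peri), True
        return lesion, peri, False
    raise ValueError("log_transform must be 'auto', 'on' or 'off'")


def endpoint_contrast(
    clinical: ClinicalTable, endpoint: str, log_transform: str = "auto"
) -> EndpointContrast:
    """Paired lesion vs peri-lesion contrast with 95% CI.

    With zero-variance differences the t distribution degenerates: p is 1
    when the estimate is 0 and reported as 0 (< 1e-12) otherwise.
    """
    les = clinical.subject_values(endpoint, LESION)
    per = clinical.subject_values(endpoint, PERI_LESION)
    common = les.index.intersection(per.index)
    if len(common) < 3:
        raise ValueError(f"endpoint {endpoint!r}: need paired values for >= 3 subjects")
    lv, pv, logged = _maybe_log(
        les[common].to_numpy(float), per[common].to_numpy(float),
        log_transform, endpoint,
    )
    d = lv - pv
    n = len(d)
    est = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        p = 1.0 if est == 0 else 0.0
        t_stat = 0.0 if est == 0 else float("inf")
        ci = (est, est)
    else:
        se = sd / np.sqrt(n)
        t_stat = est / se
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
        half = stats.t.ppf(0.975, df=n - 1) * se
        ci = (est - half, est + half)
    return EndpointContrast(
        endpoint=endpoint,
        estimate=est,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        t_statistic=float(t_stat),
        p_value=p,
        n_pairs=n,
        log_transformed=logged,
    )


def endpoint_contrasts(
    clinical: ClinicalTable, log_transform: str = "auto"
) -> pd.DataFrame:
    """Contrast every site-paired endpoint in the clinical table."""
    rows = []
    for ep in clinical.endpoints():
        sites = set(clinical.df.loc[clinical.df["endpoint"] == ep, "site"])
        if not {LESION, PERI_LESION} <= sites:
            continue
        c = endpoint_contrast(clinical, ep, log_transform)
        rows.append(
            (c.endpoint, c.estimate, c.ci_low, c.ci_high, c.t_statistic,
             c.p_value, c.n_pairs, c.log_transformed)
        )
    return pd.DataFrame(
        rows,
        columns=["endpoint", "estimate", "ci_low", "ci_high", "t", "p",
                 "n_pairs", "log_transformed"],
    ).set_index("endpoint")


def _parameter_values(
    clinical: ClinicalTable, parameter: str, mode: str
) -> pd.Series:
    sites = set(clinical.df.loc[clinical.df["endpoint"] == parameter, "site"])
    if not sites:
        raise KeyError(f"parameter {parameter!r} not in clinical table")
    if SUBJECT_LEVEL in sites and mode != "subject_level":
        mode = "subject_level"  # endpoints without site are always subject-level
    if mode == "difference":
        les = clinical.subject_values(parameter, LESION)
        per = clinical.subject_values(parameter, PERI_LESION)
        common = les.index.intersection(per.index)
        return (les[common] - per[common]).rename(parameter)
    if mode == "lesional":
        return clinical.subject_values(parameter, LESION).rename(parameter)
    if mode == "subject_level":
        return clinical.subject_values(parameter, SUBJECT_LEVEL).rename(parameter)
    raise ValueError("mode must be 'difference', 'lesional' or 'subject_level'")


def genus_clinical_correlations(
    profiles: pd.DataFrame,
    clinical: ClinicalTable,
    parameters: list[str] | None = None,
    mode: str | dict[str, str] = "difference",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations of clinical parameters against genus differences.

    One row per (parameter, genus) pair with r, two-sided p, BH q within
    parameter, the direction label, and a significance flag at ``alpha``.
    ``mode`` selects which per-subject clinical value is correlated:
    ``difference`` (lesion - peri-lesion), ``lesional``, or
    ``subject_level``; endpoints recorded without a site (e.g. mMASI) use
    subject-level values automatically. Pairs with fewer than 4 complete
    observations are skipped with a warning.
    """
    if parameters is None:
        parameters = clinical.endpoints()
    rows = []
    for param in parameters:
        pmode = mode.get(param, "difference") if isinstance(mode, dict) else mode
        values = _parameter_values(clinical, param, pmode)
        pvals, prows = [], []
        for genus in profiles.columns:
            g = profiles[genus]
            common = values.index.intersection(g.index)
            x = values[common].to_numpy(float)
            y = g[common].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4:
                warnings.warn(
                    f"({param}, {genus}): only {int(ok.sum())} complete "
                    "observations; skipped"
                )
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                warnings.warn(f"({param}, {genus}): constant input; skipped")
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            prows.append((param, genus, float(r), float(p), int(ok.sum())))
            pvals.append(p)
        if not prows:
            continue
        q = multipletests(pvals, method="fdr_bh")[1]
        for (param_, genus, r, p, n), qv in zip(prows, q):
            rows.append(
                (param_, genus,
                 "Positive" if r >= 0 else "Negative",
                 r, p, float(qv), n, p < alpha)
            )
    return pd.DataFrame(
        rows,
        columns=["parameter", "genus", "direction", "r", "p", "q", "n",
                 "significant"],
    )
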