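"""Frequency-stratified enrichment, subset contrasts and rank statistics.

Feature proportions are clonotype-weighted (each unique clonotype counts
once within its frequency class; the classes already encode abundance),
per-replicate proportions are averaged per donor, and group contrasts use
the unpaired two-sided Wilcoxon rank-sum test: the exact null distribution
when both groups are small and untied, otherwise the normal approximation
with midranks, tie correction and continuity correction.  P-values are
reported raw (no multiple-testing correction); a Benjamini-Hochberg column
can be added explicitly as an extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .statistics import (
    FREQUENCY_CLASSES,
    StatisticsError,
    d75,
    shannon_entropy,
)

log = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "TestResult",
    "wilcoxon_rank_sum",
    "enrichment_by_frequency_class",
    "length_distribution_by_class",
    "spearman_correlation_matrix",
    "compare_subsets",
    "sample_metric",
    "benjamini_hochberg",
    "mean_ci_t",
]

#: Feature name -> annotated-table predicate column/derivation.
FEATURES = ("J1_usage", "invT", "hAA5", "germline_encoded", "public")

_EXACT_MAX_N = 16


@dataclass(frozen=True)
class TestResult:
    """Two-sided Wilcoxon rank-sum contrast between two independent groups."""

    group_a: str
    group_b: str
    statistic: float  # rank sum of group a (midranks)
    p_value: float
    median_difference: float  # median(a) - median(b)
    n_a: int
    n_b: int
    method: str  # "exact" or "normal"


def _feature_values(annotated: pd.DataFrame, feature: str) -> pd.Series:
    if feature == "J1_usage":
        return annotated["j_region"].eq("J1").where(annotated["j_region"].notna())
    if feature == "invT":
        return annotated["inv_t"]
    if feature == "hAA5":
        return annotated["is_hAA5"]
    if feature == "germline_encoded":
        return annotated["germline_encoded"]
    if feature == "public":
        if "is_public" not in annotated.columns:
            raise StatisticsError("feature 'public' requires an 'is_public' annotation column")
        return annotated["is_public"]
    raise StatisticsError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float],
                      group_a: str = "a", group_b: str = "b") -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Uses the exact null distribution when n_a + n_b <= 16 and the pooled
    values are tie-free, and the tie- and continuity-corrected normal
    approximation otherwise.  Two identical constant groups give p = 1 by
    convention (with a warning).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticsError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    median_diff = float(np.median(a) - np.median(b))
    if np.all(pooled == pooled[0]):
        log.warning("all values identical across both groups; p = 1 by convention")
        return TestResult(group_a, group_b, w, 1.0, 0.0, a.size, b.size, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size + b.size <= _EXACT_MAX_N:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal"
    return TestResult(
        group_a, group_b, w, float(min(res.pvalue, 1.0)), median_diff, a.size, b.size, method
    )


def enrichment_by_frequency_class(annotated: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-class proportion of unique clonotypes bearing a feature.

    Emits one row per (sample, frequency class) at level ``replicate`` and
    one row per (donor, subset, frequency class) at level ``donor`` (the
    average of the replicate proportions, mirroring lines that connect the
    replicate average per donor).  Clonotypes with an undefined feature
    value (e.g. AA5 features on junctions shorter than 7 aa) are excluded
    with a logged count; empty classes are emitted with a missing
    proportion and excluded from downstream tests.
    """
    df = annotated[annotated["productive"].astype(bool)].copy()
    values = _feature_values(df, feature)
    n_undefined = int(values.isna().sum())
    if n_undefined:
        log.info("feature %s undefined for %d clonotypes (excluded)", feature, n_undefined)
    df = df.assign(_feat=values).dropna(subset=["_feat"])
    rows = []
    for (sample_id, donor, replicate, subset), g in df.groupby(
        ["sample_id", "donor_id", "replicate_id", "subset_label"], sort=True
    ):
        for fclass in FREQUENCY_CLASSES:
            cls = g[g["frequency_class"] == fclass]
            rows.append(
                {
                    "level": "replicate",
                    "sample_id": sample_id,
                    "donor_id": donor,
                    "replicate_id": replicate,
                    "subset_label": subset,
                    "frequency_class": fclass,
                    "feature": feature,
                    "proportion": float(cls["_feat"].astype(bool).mean()) if len(cls) else np.nan,
                    "n_clonotypes": len(cls),
                }
            )
    per_rep = pd.DataFrame(rows)
    donor_rows = []
    for (donor, subset, fclass), g in per_rep.groupby(
        ["donor_id", "subset_label", "frequency_class"], sort=True
    ):
        valid = g.dropna(subset=["proportion"])
        donor_rows.append(
            {
                "level": "donor",
                "sample_id": "",
                "donor_id": donor,
                "replicate_id": "",
                "subset_label": subset,
                "frequency_class": fclass,
                "feature": feature,
                "proportion": float(valid["proportion"].mean()) if len(valid) else np.nan,
                "n_clonotypes": int(g["n_clonotypes"].sum()),
            }
        )
    return pd.concat([per_rep, pd.DataFrame(donor_rows)], ignore_index=True)


def length_distribution_by_class(
    annotated: pd.DataFrame, restrict_to: Optional[str] = None
) -> pd.DataFrame:
    """Mean per-class CDR3 length distribution across samples.

    Within each sample and frequency class, the fraction of unique
    clonotypes at each CDR3 length is computed (distributions sum to 1 per
    class per sample); the table reports the mean of these fractions across
    samples.  ``restrict_to`` limits the analysis to one J region (the
    J1-rearranged subrepertoire in the headline analyses).
    """
    df = annotated[annotated["productive"].astype(bool)].dropna(subset=["cdr3_length"])
    if restrict_to is not None:
        df = df[df["j_region"] == restrict_to]
    per_sample = []
    for (sample_id, fclass), g in df.groupby(["sample_id", "frequency_class"], sort=True):
        frac = g["cdr3_length"].value_counts(normalize=True)
        for length, p in frac.items():
            per_sample.append(
                {
                    "sample_id": sample_id,
                    "frequency_class": fclass,
                    "cdr3_length": int(length),
                    "proportion": float(p),
                }
            )
    long = pd.DataFrame(per_sample)
    if long.empty:
        return pd.DataFrame(columns=["frequency_class", "cdr3_length", "mean_proportion", "n_samples"])
    n_samples = long.groupby("frequency_class")["sample_id"].nunique()
    out = (
        long.groupby(["frequency_class", "cdr3_length"])["proportion"]
        .sum()
        .reset_index()
    )
    out["mean_proportion"] = out.apply(
        lambda r: r["proportion"] / n_samples[r["frequency_class"]], axis=1
    )
    out["n_samples"] = out["frequency_class"].map(n_samples)
    return out.drop(columns="proportion").sort_values(
        ["frequency_class", "cdr3_length"], kind="stable"
    ).reset_index(drop=True)


def spearman_correlation_matrix(phenotype_fractions: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix of per-donor phenotype fractions.

    Midranks for ties; constant columns yield missing entries.  Requires at
    least 3 donors (rows).
    """
    if len(phenotype_fractions) < 3:
        raise StatisticsError("Spearman correlation matrix needs >= 3 donors")
    corr = phenotype_fractions.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def sample_metric(annotated: pd.DataFrame, metric: str,
                  feature: Optional[str] = None,
                  frequency_class: Optional[str] = None) -> pd.Series:
    """One value of ``metric`` per sample_id from an annotated table."""
    df = annotated
    out = {}
    for sample_id, g in df.groupby("sample_id", sort=True):
        counts = g["read_count"].to_numpy()
        if metric == "shannon":
            out[sample_id] = shannon_entropy(counts)
        elif metric == "richness":
            out[sample_id] = float(len(g))
        elif metric == "d75":
            out[sample_id] = d75(counts, g["junction"].tolist())
        elif metric == "mean_cdr3_length":
            out[sample_id] = float(g["cdr3_length"].dropna().astype(float).mean())
        elif metric == "mean_n_insertions":
            out[sample_id] = float(g["n_insertions"].astype(float).mean())
        elif metric == "feature_proportion":
            if feature is None:
                raise StatisticsError("feature_proportion requires a feature name")
            sub = g if frequency_class is None else g[g["frequency_class"] == frequency_class]
            vals = _feature_values(sub, feature).dropna()
            out[sample_id] = float(vals.astype(bool).mean()) if len(vals) else np.nan
        else:
            raise StatisticsError(f"unknown metric {metric!r}")
    return pd.Series(out, name=metric)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (extension; raw p is the default)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def mean_ci_t(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a two-sided t-interval: (mean, lower, upper)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise StatisticsError("t-interval needs >= 2 values")
    mean = float(x.mean())
    half = float(sps.t.ppf(0.5 + level / 2, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size))
    return mean, mean - half, mean + half


def compare_subsets(
    annotated: pd.DataFrame,
    subset_a: str,
    subset_b: str,
    metric: str,
    feature: Optional[str] = None,
    frequency_class: Optional[str] = None,
) -> TestResult:
    """Contrast a per-sample repertoire metric between two sorted subsets.

    The metric is computed per sample and the two subsets' per-sample
    values are compared with the unpaired rank-sum test (donor pairing is
    reflected only upstream, in replicate averaging).
    """
    present = set(annotated["subset_label"].unique())
    missing = {subset_a, subset_b} - present
    if missing:
        raise StatisticsError(f"subset(s) absent from data: {sorted(missing)}")
    values = {}
    for label in (subset_a, subset_b):
        sub = annotated[annotated["subset_label"] == label]
        vals = sample_metric(sub, metric, feature=feature, frequency_class=frequency_class)
        values[label] = vals.dropna().to_numpy()
    return wilcoxon_rank_sum(values[subset_a], values[subset_b], subset_a, subset_b)
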