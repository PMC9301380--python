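"""Frequency classes, publicity and diversity statistics for TRD repertoires.

Frequency classes follow the printed half-open bins: non-expanded
(f < 0.1%), expanded (0.1% <= f < 1%) and hyperexpanded (f >= 1%), with f
the clonotype's share of its sample's post-filter reads.

Publicity is defined at the amino-acid level: an AA clonotype is public
when shared by at least two donors and "highly common" when shared by more
than half the cohort.  To keep low-frequency detection honest, only
nucleotypes detected in at least two samples of the same donor
(replicate-concordant) enter the publicity analysis, and all nucleotypes
encoding one AA sequence are collapsed to a single entry whose read count
is the total of the constituent nucleotype counts.

Diversity of a sample is summarised by Shannon entropy (natural log),
richness (number of distinct clonotypes) and D75 evenness — the percentage
of unique clonotypes that occupy 75% of the sample's reads; low D75 means
a clonally focused repertoire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RepertoireSample

log = logging.getLogger(__name__)

__all__ = [
    "NON_EXPANDED",
    "EXPANDED",
    "HYPEREXPANDED",
    "FREQUENCY_CLASSES",
    "StatisticsError",
    "DiversityMetrics",
    "classify_frequency",
    "shannon_entropy",
    "d75",
    "richness",
    "diversity_metrics",
    "replicate_concordant_nucleotypes",
    "collapse_and_score_publicity",
    "split_subrepertoires",
    "check_equal_cell_numbers",
    "downsample_sample",
]

NON_EXPANDED = "non_expanded"
EXPANDED = "expanded"
HYPEREXPANDED = "hyperexpanded"
FREQUENCY_CLASSES = (NON_EXPANDED, EXPANDED, HYPEREXPANDED)


class StatisticsError(ValueError):
    pass


def classify_frequency(frequency_pct: float) -> str:
    """Bin a clonotype frequency (percent of sample reads) into its class.

    Boundaries are closed on the left: 0.1% is expanded, 1% hyperexpanded.
    """
    if not frequency_pct > 0 or frequency_pct > 100:
        raise StatisticsError(f"frequency must be in (0, 100] percent, got {frequency_pct}")
    if frequency_pct < 0.1:
        return NON_EXPANDED
    if frequency_pct < 1.0:
        return EXPANDED
    return HYPEREXPANDED


def _positive_counts(read_counts: Iterable[float]) -> np.ndarray:
    counts = np.asarray(list(read_counts), dtype=float)
    if counts.size == 0:
        raise StatisticsError("empty repertoire")
    if np.any(counts <= 0):
        raise StatisticsError("read counts must be positive")
    return counts


def shannon_entropy(read_counts: Iterable[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    counts = _positive_counts(read_counts)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def d75(read_counts: Iterable[float], labels: Sequence[str] | None = None) -> float:
    """Percentage of unique clonotypes that occupy 75% of the sample reads.

    Counts are ranked in descending order (ties broken by the clonotype
    label, lexicographically, for determinism); k is the smallest number of
    top clonotypes whose cumulative read share reaches 75%, and the return
    value is 100*k / richness.
    """
    counts = _positive_counts(read_counts)
    if labels is not None:
        if len(labels) != counts.size:
            raise StatisticsError("labels must match counts")
        order = sorted(range(counts.size), key=lambda i: (-counts[i], labels[i]))
        counts = counts[order]
    else:
        counts = np.sort(counts)[::-1]
    share = np.cumsum(counts) / counts.sum()
    k = int(np.searchsorted(share, 0.75 - 1e-12) + 1)
    return 100.0 * k / counts.size


def richness(sample_or_counts) -> int:
    """Number of distinct retained clonotypes."""
    if isinstance(sample_or_counts, RepertoireSample):
        return len(sample_or_counts.clonotypes)
    return len(list(sample_or_counts))


@dataclass(frozen=True)
class DiversityMetrics:
    sample_id: str
    shannon_entropy: float
    richness: int
    d75: float


def diversity_metrics(sample: RepertoireSample) -> DiversityMetrics:
    counts = [c.read_count for c in sample.clonotypes]
    labels = [c.junction_nt for c in sample.clonotypes]
    return DiversityMetrics(
        sample_id=sample.sample_id,
        shannon_entropy=shannon_entropy(counts),
        richness=len(counts),
        d75=d75(counts, labels),
    )


def replicate_concordant_nucleotypes(samples: Sequence[RepertoireSample]) -> pd.DataFrame:
    """Nucleotypes of one donor detected in at least two of its samples.

    ``samples`` must all belong to the same donor and be pre-filtered
    (singletons removed).  Returns one row per concordant nucleotype with
    its total read count across the donor's samples.
    """
    donors = {s.donor_id for s in samples}
    if len(donors) != 1:
        raise StatisticsError(f"samples from a single donor expected, got donors {sorted(donors)}")
    if len(samples) < 2:
        raise StatisticsError(
            "replicate concordance needs >= 2 samples per donor; "
            "skip publicity analysis for this donor"
        )
    rows: dict[tuple, dict] = {}
    for s in samples:
        seen_here = set()
        for c in s.clonotypes:
            key = c.nucleotype_key
            rec = rows.setdefault(
                key,
                {
                    "junction": c.junction_nt,
                    "v_call": c.v_call,
                    "j_call": c.j_call,
                    "junction_aa": c.junction_aa,
                    "read_count": 0,
                    "n_samples_detected": 0,
                },
            )
            rec["read_count"] += c.read_count
            if key not in seen_here:
                rec["n_samples_detected"] += 1
                seen_here.add(key)
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        return pd.DataFrame(
            columns=["junction", "v_call", "j_call", "junction_aa", "read_count", "n_samples_detected"]
        )
    return (
        df[df["n_samples_detected"] >= 2]
        .sort_values(["junction", "v_call", "j_call"], kind="stable")
        .reset_index(drop=True)
    )


def collapse_and_score_publicity(
    concordant_by_donor: Mapping[str, pd.DataFrame],
    cohort_size: int | None = None,
) -> pd.DataFrame:
    """Collapse concordant nucleotypes to AA clonotypes and score sharing.

    ``concordant_by_donor`` maps donor id to that donor's concordant
    nucleotype table (see :func:`replicate_concordant_nucleotypes`).
    Nucleotypes encoding the same AA sequence are collapsed to one record
    whose read count is the total of the constituents; ``n_nucleotypes``
    counts distinct junction nucleotide sequences pooled across donors.
    ``is_public`` requires sharing by >= 2 donors; ``is_highly_common``
    requires sharing by more than half the cohort (strictly > 50%).
    """
    if cohort_size is None:
        cohort_size = len(concordant_by_donor)
    if concordant_by_donor and len(concordant_by_donor) < 2:
        raise StatisticsError("publicity scoring needs >= 2 donors in scope")
    records: dict[str, dict] = {}
    for donor_id in sorted(concordant_by_donor):
        df = concordant_by_donor[donor_id]
        for row in df.itertuples(index=False):
            rec = records.setdefault(
                row.junction_aa,
                {"junction_aa": row.junction_aa, "nucleotypes": set(), "donors": set(), "reads": 0},
            )
            rec["nucleotypes"].add(row.junction)
            rec["donors"].add(donor_id)
            rec["reads"] += int(row.read_count)
    out = [
        {
            "junction_aa": aa,
            "n_donors_sharing": len(rec["donors"]),
            "n_nucleotypes": len(rec["nucleotypes"]),
            "collapsed_read_count": rec["reads"],
            "is_public": len(rec["donors"]) >= 2,
            "is_highly_common": len(rec["donors"]) > cohort_size / 2,
        }
        for aa, rec in records.items()
    ]
    columns = [
        "junction_aa",
        "n_donors_sharing",
        "n_nucleotypes",
        "collapsed_read_count",
        "is_public",
        "is_highly_common",
    ]
    if not out:
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(out, columns=columns)
        .sort_values(["n_donors_sharing", "junction_aa"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def split_subrepertoires(annotated: pd.DataFrame, axis: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition an annotated table along a bias axis.

    ``axis`` is ``"germline_vs_inserted"`` (germline-encoded first) or
    ``"public_vs_private"`` (public first; requires an ``is_public``
    column).  The partition is disjoint and exhaustive, and frequencies are
    NOT renormalised within the splits — they remain fractions of the whole
    sample.
    """
    if axis == "germline_vs_inserted":
        mask = annotated["germline_encoded"].astype(bool)
    elif axis == "public_vs_private":
        if "is_public" not in annotated.columns:
            raise StatisticsError("public_vs_private split requires an 'is_public' annotation")
        mask = annotated["is_public"].astype(bool)
    else:
        raise StatisticsError(f"unknown split axis {axis!r}")
    return annotated[mask].copy(), annotated[~mask].copy()


def check_equal_cell_numbers(
    samples: Sequence[RepertoireSample], allow_unequal: bool = False
) -> None:
    """Enforce the equal-sorted-cell-number contract for head-to-head comparisons."""
    cells = {s.sorted_cell_count for s in samples}
    if len(cells) > 1:
        msg = f"samples differ in sorted cell numbers: {sorted(cells)}"
        if not allow_unequal:
            raise StatisticsError(msg + " (pass allow_unequal to override)")
        log.warning(msg)


def downsample_sample(
    sample: RepertoireSample, depth: int, rng: np.random.Generator
) -> RepertoireSample:
    """Seeded read-downsampling to a common depth (extension utility).

    Draws ``depth`` reads without replacement from the sample's reads and
    rebuilds the clonotype table from the drawn counts.
    """
    from dataclasses import replace

    total = sample.total_reads
    if depth > total:
        raise StatisticsError(f"cannot downsample {total} reads to {depth}")
    counts = np.array([c.read_count for c in sample.clonotypes])
    drawn = rng.multivariate_hypergeometric(counts, depth)
    kept = tuple(
        replace(c, read_count=int(k))
        for c, k in zip(sample.clonotypes, drawn)
        if k > 0
    )
    return replace(sample, clonotypes=kept)
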