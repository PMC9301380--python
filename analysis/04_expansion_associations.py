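#!/usr/bin/env python
"""Frequency-stratified feature enrichment and subset contrasts.

For the CD27pos compartment: per-donor proportions of J1 usage, invT and
hAA5 across the three frequency classes, with the hyperexpanded vs
non-expanded rank-sum contrast; the CDR3 length distribution of the
J1-rearranged subrepertoire per class; and CD27pos vs CD27neg contrasts of
Shannon entropy, richness and D75.
Outputs: results/cohort/{enrichment,length_distribution_J1,comparisons}.tsv
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cdr3delta import (
    annotate_clonotypes,
    compare_subsets,
    enrichment_by_frequency_class,
    filter_singletons,
    length_distribution_by_class,
    load_reference,
    read_repertoire,
    wilcoxon_rank_sum,
    write_table,
)

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    samples = [
        filter_singletons(s)
        for s in read_repertoire(OUTDIR / "repertoire.tsv", OUTDIR / "metadata.tsv")
    ]
    annotated = annotate_clonotypes(samples, load_reference())
    pos = annotated[annotated["subset_label"] == "CD27pos"]

    tables = []
    print("CD27pos, donor-level hyperexpanded vs non-expanded contrasts:")
    for feature in ("J1_usage", "invT", "hAA5"):
        enr = enrichment_by_frequency_class(pos, feature)
        tables.append(enr)
        donor = (
            enr[enr.level == "donor"]
            .pivot(index="donor_id", columns="frequency_class", values="proportion")
            .dropna()
        )
        res = wilcoxon_rank_sum(donor["hyperexpanded"], donor["non_expanded"])
        print(f"  {feature:18s} median {donor['non_expanded'].median():.3f} -> "
              f"{donor['hyperexpanded'].median():.3f}  "
              f"(rank-sum p = {res.p_value:.3g}, median diff = {res.median_difference:+.3f})")
    write_table(
        pd.concat(tables, ignore_index=True),
        OUTDIR / "enrichment.tsv",
        sort_by=["feature", "level", "donor_id", "subset_label", "frequency_class", "sample_id"],
    )

    lengths = length_distribution_by_class(pos, restrict_to="J1")
    write_table(lengths, OUTDIR / "length_distribution_J1.tsv",
                sort_by=["frequency_class", "cdr3_length"])
    mean_len = (
        lengths.assign(w=lengths["cdr3_length"] * lengths["mean_proportion"])
        .groupby("frequency_class")["w"].sum()
    )
    print("\nmean CDR3 length among J1-rearranged clonotypes by class:")
    for cls in ("non_expanded", "expanded", "hyperexpanded"):
        print(f"  {cls:14s} {mean_len[cls]:.2f} aa")

    print("\nCD27pos vs CD27neg repertoire contrasts:")
    rows = []
    for metric in ("shannon", "richness", "d75"):
        res = compare_subsets(annotated, "CD27pos", "CD27neg", metric)
        rows.append({"metric": metric, **dataclasses.asdict(res)})
        print(f"  {metric:9s} median diff = {res.median_difference:+.3f}  "
              f"(rank-sum p = {res.p_value:.3g})")
    write_table(pd.DataFrame(rows), OUTDIR / "comparisons.tsv", sort_by=["metric"])


if __name__ == "__main__":
    main()
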