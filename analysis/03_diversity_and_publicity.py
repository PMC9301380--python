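#!/usr/bin/env python
"""Diversity metrics per sample and amino-acid clonotype publicity.

Computes Shannon entropy, richness and D75 per sorted sample, then runs
the publicity analysis over replicate-concordant nucleotypes: nucleotypes
collapsing to one AA sequence are merged, and sharing across donors is
scored (public: >= 2 donors; highly common: > 50% of the cohort).
Outputs: results/cohort/{diversity,publicity}.tsv
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cdr3delta import (
    diversity_metrics,
    collapse_and_score_publicity,
    filter_singletons,
    read_repertoire,
    replicate_concordant_nucleotypes,
    write_table,
)
from cdr3delta.simulate import PUBLIC_CLONOTYPES

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    samples = [
        filter_singletons(s)
        for s in read_repertoire(OUTDIR / "repertoire.tsv", OUTDIR / "metadata.tsv")
    ]
    meta = {s.sample_id: s.subset_label for s in samples}
    div = pd.DataFrame([dataclasses.asdict(diversity_metrics(s)) for s in samples])
    div["subset_label"] = div["sample_id"].map(meta)
    write_table(div, OUTDIR / "diversity.tsv", sort_by=["sample_id"])
    by_subset = div.groupby("subset_label")[["shannon_entropy", "richness", "d75"]].median()
    print("median diversity by subset:")
    print(by_subset.round(3).to_string())

    by_donor: dict[str, list] = {}
    for s in samples:
        by_donor.setdefault(s.donor_id, []).append(s)
    concordant = {d: replicate_concordant_nucleotypes(ss) for d, ss in by_donor.items()}
    publicity = collapse_and_score_publicity(concordant)
    write_table(publicity, OUTDIR / "publicity.tsv", sort_by=["junction_aa"])
    n_public = int(publicity["is_public"].sum())
    common = publicity[publicity["is_highly_common"]]
    seeded_found = len(set(common["junction_aa"]) & set(PUBLIC_CLONOTYPES))
    print(f"\n{len(publicity)} AA clonotypes scored; {n_public} public; "
          f"{len(common)} highly common (> 50% of donors)")
    print(f"{seeded_found}/{len(PUBLIC_CLONOTYPES)} seeded public clonotypes "
          f"recovered as highly common")
    print("nucleotypes per highly common AA clonotype (median): "
          f"{common['n_nucleotypes'].median():.1f}")


if __name__ == "__main__":
    main()
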