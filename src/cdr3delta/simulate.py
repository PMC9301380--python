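"""Generative TRDV2 repertoire simulator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be validated without sequencing data:

* TRDV2 -> (D) -> TRDJ{1..4} rearrangement with geometric end-trimming and
  Poisson N insertions, rejection-sampled to productive junctions;
* convergent recombination: a pool of public amino-acid sequences (by
  default the fourteen highly common public CDR3delta clonotypes) seeded
  across donors through distinct synonymous nucleotide routes, so the same
  AA clonotype recurs with several nucleotypes;
* clone sizes following a discrete power law (rank-frequency exponent per
  sorted subset), reweighted by a log-linear expansion coupling
  w = base * exp(b_hAA5*hAA5 + b_J1*J1 - b_length*(length-12)),
  so expansion probability is coupled, with configurable effect sizes, to
  J1 usage, hydrophobic AA5 and short CDR3 length;
* multi-donor, multi-replicate, multi-subset multinomial read sampling.

One root seed fully determines the output; per-donor substreams are
spawned from (seed, donor index), so adding a donor does not perturb the
others.  The generator validates the pipeline; it does not claim
biophysical realism (no thymic selection, no sequencing-error model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

from .annotation import HYDROPHOBIC_AA5, classify_j_region_by_suffix
from .germline import GermlineReference, j_region_of, load_reference
from .io import Clonotype, RepertoireSample

__all__ = [
    "SimulationError",
    "SubsetSpec",
    "SimulationConfig",
    "PUBLIC_CLONOTYPES",
    "TCR_TRANSFER_CLONOTYPES",
    "simulate_rearrangement",
    "simulate_cohort",
]

#: Highly common public CDR3delta amino-acid clonotypes (junction strings,
#: C104...F/W118 inclusive) shared by more than half the donors of the
#: adult cohort this package models; used as the default convergent-
#: recombination pool.
PUBLIC_CLONOTYPES: tuple[str, ...] = (
    "CACDTLGDTDKLIF",
    "CACDTLLGDTDKLIF",
    "CACDVLGDTDKLIF",
    "CACDTLGVYTDKLIF",
    "CACDTVGDTDKLIF",
    "CACDTVGEYTDKLIF",
    "CACDTVGGYTDKLIF",
    "CACDILGDTDKLIF",
    "CACDPLGDTDKLIF",
    "CACDTAGGSSWDTRQMFF",
    "CACDTVGGTDKLIF",
    "CACDTVGTYTDKLIF",
    "CACDTWGTDKLIF",
    "CACDTWGYTDKLIF",
)

#: The four public clonotypes used in the TCR gene-transfer experiment.
TCR_TRANSFER_CLONOTYPES: tuple[str, ...] = (
    "CACDTLGDTDKLIF",
    "CACDVLGDTDKLIF",
    "CACDTVGDTDKLIF",
    "CACDTWGYTDKLIF",
)

_SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYNONYMOUS.setdefault(_aa, tuple())
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _SYNONYMOUS[_aa] = _SYNONYMOUS[_aa] + (_codon,)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SubsetSpec:
    """One sorted-subset condition of the simulated cohort.

    ``n_clones`` clones are drawn per donor from the donor's naive pool and
    given rank-frequency power-law base sizes s_r = r^(-exponent); a larger
    exponent yields a steeper, more clonally focused repertoire.
    """

    label: str
    n_clones: int
    clone_size_exponent: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the modelled study: 9 adult donors, sorted CD27pos and
    CD27neg Vd2 subsets in duplicate at 50,000 sorted cells / 50,000 reads
    per sample, a J usage dominated by J1, mostly TRDD3-containing
    rearrangements, and clonal focusing of the CD27neg compartment (a
     10-fold smaller clone pool with a steeper clone-size law).
    """

    seed: int = 0
    n_donors: int = 9
    replicates_per_subset: int = 2
    subsets: tuple[SubsetSpec, ...] = (
        SubsetSpec("CD27pos", n_clones=3000, clone_size_exponent=0.9),
        SubsetSpec("CD27neg", n_clones=300, clone_size_exponent=1.6),
    )
    j_usage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"J1": 0.80, "J2": 0.04, "J3": 0.12, "J4": 0.04}
    )
    d_usage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"none": 0.05, "TRDD1*01": 0.05, "TRDD2*01": 0.10, "TRDD3*01": 0.80}
    )
    trim_geometric_p: float = 0.35  # per segment end; mean trim ~ 1.9 nt
    n_insertion_mean: float = 4.0  # Poisson mean per N block
    beta_haa5: float = 1.5
    beta_j1: float = 1.0
    beta_length: float = 0.15
    n_naive_clones: int = 3000  # donor pool size (>= max subset n_clones)
    reads_per_sample: int = 50_000
    sorted_cell_count: int = 50_000
    public_pool: tuple[str, ...] = PUBLIC_CLONOTYPES
    public_seed_prob: float = 0.7  # chance a public AA is seeded into a donor
    max_rejections: int = 10_000

    def validate(self) -> None:
        for name, probs in (("j_usage_probs", self.j_usage_probs), ("d_usage_probs", self.d_usage_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
                raise SimulationError(f"{name} must be a probability distribution")
        if self.replicates_per_subset < 2:
            raise SimulationError("replicates_per_subset must be >= 2 (replicate concordance)")
        if self.reads_per_sample < 100:
            raise SimulationError("reads_per_sample < 100 is degenerate")
        if max(s.n_clones for s in self.subsets) > self.n_naive_clones:
            raise SimulationError("subset n_clones exceeds the donor naive pool")
        if not 0 < self.trim_geometric_p <= 1:
            raise SimulationError("trim_geometric_p must be in (0, 1]")


def _trim(rng: np.random.Generator, p: float) -> int:
    # geometric number of removed nucleotides, support {0, 1, 2, ...}
    return int(rng.geometric(p) - 1)


def simulate_rearrangement(
    config: SimulationConfig, rng: np.random.Generator, reference: GermlineReference | None = None
) -> dict:
    """Draw one productive TRDV2 rearrangement.

    Chooses D and J per the configured usage, trims segment ends
    geometrically, inserts Poisson-distributed N nucleotides (uniform
    A/C/G/T) at each join, and rejection-samples until the junction is
    in-frame, stop-free and C...F/W anchored.  Returns the junction with
    its true block structure (ground truth for decomposition tests).
    """
    ref = reference if reference is not None else load_reference()
    v_full = ref.v_junction_region()
    j_labels = sorted(config.j_usage_probs)
    j_p = np.array([config.j_usage_probs[j] for j in j_labels])
    d_labels = sorted(config.d_usage_probs)
    d_p = np.array([config.d_usage_probs[d] for d in d_labels])
    nt = "ACGT"

    for _ in range(config.max_rejections):
        j_region = j_labels[rng.choice(len(j_labels), p=j_p)]
        d_id = d_labels[rng.choice(len(d_labels), p=d_p)]
        v_trim = min(_trim(rng, config.trim_geometric_p), len(v_full) - 3)
        v_part = v_full[: len(v_full) - v_trim]
        if d_id == "none":
            d_part = ""
        else:
            d_nt = ref[d_id].nt_sequence
            d5 = _trim(rng, config.trim_geometric_p)
            d3 = _trim(rng, config.trim_geometric_p)
            d_part = d_nt[d5 : len(d_nt) - d3] if d5 + d3 < len(d_nt) else ""
        j_full = ref.j_junction_region(j_region)
        j_trim = min(_trim(rng, config.trim_geometric_p), len(j_full) - 3)
        j_part = j_full[j_trim:]
        n1 = "".join(nt[i] for i in rng.integers(0, 4, rng.poisson(config.n_insertion_mean)))
        n2 = "".join(nt[i] for i in rng.integers(0, 4, rng.poisson(config.n_insertion_mean)))
        if not d_part:
            n1, n2 = n1 + n2, ""
        junction = v_part + n1 + d_part + n2 + j_part
        if len(junction) % 3 != 0 or len(junction) < 12:
            continue
        aa = str(Seq(junction).translate())
        if "*" in aa or not aa.startswith("C") or not aa.endswith(("F", "W")):
            continue
        return {
            "junction": junction,
            "junction_aa": aa,
            "v_call": "TRDV2*01",
            "d_call": d_id if d_part else "",
            "j_call": f"TRDJ{j_region[-1]}*01",
            "true_v_len": len(v_part),
            "true_d_len": len(d_part),
            "true_j_len": len(j_part),
            "true_n": len(n1) + len(n2),
        }
    raise SimulationError(
        f"{config.max_rejections} consecutive nonproductive draws; degenerate parameters"
    )


def _encode_public(aa: str, rng: np.random.Generator, ref: GermlineReference) -> dict:
    """Back-translate a public AA clonotype through a germline-compatible route.

    The V-matching prefix and J-matching suffix use germline codons; the
    remaining middle residues draw synonymous codons at random, emulating
    convergent recombination (distinct nucleotypes for one AA sequence).
    """
    v_nt = ref.v_junction_region()
    v_aa = str(Seq(v_nt).translate())
    m = 0
    while m < min(len(v_aa), len(aa)) and v_aa[m] == aa[m]:
        m += 1
    j_region = classify_j_region_by_suffix(aa, ref) or "J1"
    j_head = ref.j_head_aa(j_region)
    k = 0
    while (
        k < min(len(j_head), len(aa) - m)
        and j_head[len(j_head) - 1 - k] == aa[len(aa) - 1 - k]
    ):
        k += 1
    j_nt_full = ref.j_junction_region(j_region)
    middle = aa[m : len(aa) - k]
    mid_nt = "".join(
        _SYNONYMOUS[res][rng.integers(0, len(_SYNONYMOUS[res]))] for res in middle
    )
    junction = v_nt[: 3 * m] + mid_nt + (j_nt_full[len(j_nt_full) - 3 * k :] if k else "")
    return {
        "junction": junction,
        "junction_aa": aa,
        "v_call": "TRDV2*01",
        "d_call": "",
        "j_call": f"TRDJ{j_region[-1]}*01",
        "true_v_len": 3 * m,
        "true_d_len": 0,
        "true_j_len": 3 * k,
        "true_n": len(mid_nt),
    }


def _clone_weight(config: SimulationConfig, aa: str, j_call: str) -> float:
    is_h = len(aa) >= 7 and aa[5] in HYDROPHOBIC_AA5
    is_j1 = j_region_of(j_call) == "J1"
    length = len(aa) - 2
    return float(
        np.exp(
            config.beta_haa5 * is_h + config.beta_j1 * is_j1 - config.beta_length * (length - 12)
        )
    )


def simulate_cohort(
    config: SimulationConfig, reference: GermlineReference | None = None
) -> tuple[list[RepertoireSample], pd.DataFrame]:
    """Simulate a multi-donor, multi-replicate, multi-subset cohort.

    Returns the samples plus a ground-truth table with one row per
    (donor, subset, clone): the generating route, true expansion weight and
    true clone fraction.  Fully deterministic under ``config.seed``.
    """
    config.validate()
    ref = reference if reference is not None else load_reference()
    samples: list[RepertoireSample] = []
    truth_rows = []
    for donor_idx in range(config.n_donors):
        donor_id = f"D{donor_idx + 1:02d}"
        rng = np.random.default_rng([config.seed, donor_idx])
        pool: dict[str, dict] = {}
        for aa in config.public_pool:
            if rng.random() < config.public_seed_prob:
                clone = _encode_public(aa, rng, ref)
                clone["public_origin"] = True
                pool.setdefault(clone["junction"], clone)
        while len(pool) < config.n_naive_clones:
            clone = simulate_rearrangement(config, rng, ref)
            clone["public_origin"] = False
            pool.setdefault(clone["junction"], clone)
        clones = list(pool.values())
        for c in clones:
            c["weight"] = _clone_weight(config, c["junction_aa"], c["j_call"])

        order = rng.permutation(len(clones))
        for spec in config.subsets:
            chosen = [clones[i] for i in order[: spec.n_clones]]
            ranks = rng.permutation(spec.n_clones) + 1
            base = ranks.astype(float) ** (-spec.clone_size_exponent)
            w = base * np.array([c["weight"] for c in chosen])
            fractions = w / w.sum()
            for rep in range(1, config.replicates_per_subset + 1):
                counts = rng.multinomial(config.reads_per_sample, fractions)
                sample_id = f"{donor_id}_{spec.label}_r{rep}"
                clonotypes = tuple(
                    sorted(
                        (
                            Clonotype(
                                junction_nt=c["junction"],
                                junction_aa=c["junction_aa"],
                                v_call=c["v_call"],
                                j_call=c["j_call"],
                                d_call=c["d_call"],
                                read_count=int(n),
                                sample_id=sample_id,
                                donor_id=donor_id,
                                replicate_id=f"r{rep}",
                                subset_label=spec.label,
                            )
                            for c, n in zip(chosen, counts)
                            if n > 0
                        ),
                        key=lambda c: (c.junction_nt, c.v_call, c.j_call),
                    )
                )
                samples.append(
                    RepertoireSample(
                        sample_id=sample_id,
                        donor_id=donor_id,
                        replicate_id=f"r{rep}",
                        subset_label=spec.label,
                        sorted_cell_count=config.sorted_cell_count,
                        clonotypes=clonotypes,
                    )
                )
            for c, f in zip(chosen, fractions):
                truth_rows.append(
                    {
                        "donor_id": donor_id,
                        "subset_label": spec.label,
                        "junction": c["junction"],
                        "junction_aa": c["junction_aa"],
                        "j_call": c["j_call"],
                        # a 1-2 nt D remnant is indistinguishable from an
                        # insertion under exact matching; labelled separately
                        "route": (
                            "n_inserted"
                            if c["true_n"] > 0
                            else "germline_only"
                            if c["true_d_len"] == 0 or c["true_d_len"] >= 3
                            else "short_d_remnant"
                        ),
                        "public_origin": bool(c["public_origin"]),
                        "true_n": int(c["true_n"]),
                        "expansion_weight": float(c["weight"]),
                        "true_fraction": float(f),
                    }
                )
    truth = pd.DataFrame(truth_rows).sort_values(
        ["donor_id", "subset_label", "junction"], kind="stable"
    ).reset_index(drop=True)
    return samples, truth
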