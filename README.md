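# cdr3delta

Deconstruction of human γ9δ2 T-cell **CDR3δ repertoires**: feature
annotation of TRDV2 clonotypes, clonotype publicity, repertoire
diversity/evenness, and the statistical association analyses that link
repertoire composition to clonal expansion and T-cell phenotype.

γ9δ2 T cells sense phosphoantigen (pAg) accumulation through the
butyrophilins BTN3A1/BTN2A1 rather than peptide–MHC. Reactivity to the
pAg-induced ligand is modulated by the TCRδ chain's third
complementarity-determining region (CDR3δ), and a small set of sequence
determinants recurs across studies: rearrangement to the **J1** region, a
**hydrophobic residue at CDR3 position 5** (hAA5, IMGT position 109; set
{A,V,L,I,P,W,F,M}), the **invariant T** nucleotide at the second position
of the codon encoding that residue (invT, which restricts AA5 to
{F,L,I,M,V}), a **short CDR3δ length**, and few **N insertions**. This
package provides the analysis machinery to quantify how those determinants
concentrate in expanded clones and differ between sorted phenotype
subsets, for anyone working with AIRR-seq clonotype tables of the TRD
locus (immunologists studying γδ T-cell repertoires, and engineers of
γ9δ2TCR-based therapeutics selecting high-affinity receptors).

## What it computes

- **Junction decomposition.** Each junction (C104 … F/W118, inclusive) is
  split into contiguous V / N1 / D / N2 / J blocks by maximising the
  number of germline-attributable nucleotides over exact, end-anchored
  matches; unattributed nucleotides are N insertions, and a junction with
  zero of them is *germline-encoded*.
- **Clonotype frequency classes.** With `f` the clonotype's share of its
  sample's reads (after removing one-read clonotypes):
  non-expanded `f < 0.1 %`, expanded `0.1 % ≤ f < 1 %`, hyperexpanded
  `f ≥ 1 %` (left boundaries closed).
- **Publicity.** Nucleotide clonotypes detected in ≥ 2 samples of a donor
  are collapsed to amino-acid clonotypes (read counts summed); an AA
  clonotype shared by ≥ 2 donors is *public*, and by > 50 % of the cohort
  *highly common*.
- **Diversity.** Shannon entropy `H = −Σ pᵢ ln pᵢ` (nats), richness
  (number of distinct clonotypes) and **D75** — the percentage of unique
  clonotypes occupying 75 % of the sample's reads (low D75 = clonal
  focusing).
- **Associations.** Clonotype-weighted feature proportions per frequency
  class (replicate values averaged per donor), per-class CDR3δ length
  distributions, Spearman phenotype correlations, and two-sided Wilcoxon
  rank-sum contrasts (exact null distribution for small untied groups,
  tie/continuity-corrected normal approximation otherwise).
- **Synthetic cohorts.** A seeded V(D)J rearrangement simulator with known
  ground truth — geometric trimming, Poisson N insertions, power-law clone
  sizes, a log-linear expansion coupling
  `w = base · exp(β_hAA5·hAA5 + β_J1·J1 − β_len·(L−12))`, and convergent-
  recombination seeding of the fourteen highly common public clonotypes —
  so every pipeline stage is testable without sequencing data.

## Worked example

The numbered drivers under `analysis/` run the whole study design on a
simulated nine-donor cohort (duplicate CD27pos/CD27neg sorts, 50,000 reads
per sample) and write their tables under `results/cohort/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_annotate_repertoires.py
python analysis/03_diversity_and_publicity.py
python analysis/04_expansion_associations.py
```

The last two print, for example:

```
median diversity by subset:
              shannon_entropy  richness     d75
CD27neg                 2.373     246.0   2.008
CD27pos                 6.012    2295.5  18.168

17441 AA clonotypes scored; 680 public; 24 highly common (> 50% of donors)
13/14 seeded public clonotypes recovered as highly common

CD27pos, donor-level hyperexpanded vs non-expanded contrasts:
  J1_usage           median 0.870 -> 1.000  (rank-sum p = 0.000498, median diff = +0.130)
  invT               median 0.284 -> 0.610  (rank-sum p = 0.000412, median diff = +0.326)
  hAA5               median 0.480 -> 0.846  (rank-sum p = 0.000412, median diff = +0.367)
```

Reading: the focused CD27neg compartment has far lower entropy, richness
and D75 than CD27pos (clonal focusing with phenotypic maturation); almost
all seeded public clonotypes are recovered as highly common through
replicate-concordant, convergently encoded nucleotypes; and the
pAg-sensing determinants concentrate in the hyperexpanded class, as
programmed into the generator.

The same stages are available as a console tool (`cdr3delta simulate`,
`annotate`, `diversity`, `publicity`, `enrich`, `compare`, `run`) and as a
single `run_pipeline` call that adds provenance: a manifest of content
hashes, exclusion counts, and the resolved YAML config.

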