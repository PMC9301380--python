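# Methods

This note documents the models, conventions and design choices behind
`cdr3delta`, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the validation on synthetic data does and does
not establish.

## Junction conventions

A *junction* runs from the conserved TRDV2 cysteine (C104, IMGT unique
numbering) to the conserved TRDJ phenylalanine/tryptophan (F/W118), both
inclusive; the CDR3 excludes these two anchors, so `cdr3_length =
len(junction_aa) − 2`. This convention is forced by the published
public-clonotype table, which lists 14-residue junction strings at length
12. CDR3 position 5 (IMGT 109) is therefore the **6th** junction residue;
it is undefined for junctions shorter than 7 residues, which are excluded
from AA5/invT analyses (and counted in the exclusion report) but retained
everywhere else. `hAA5` tests membership in {A,V,L,I,P,W,F,M}. `invT` is
operationalised as a template T at the second position of junction codon 6;
because codons with a middle T encode exactly {F,L,I,M,V}, invT implies
hAA5 on every input (a property test asserts this). Whether the T must be
germline D-encoded is genuinely ambiguous in the field's usage; the default
accepts any template T, and a stricter variant
(`detect_inv_t(..., require_germline_origin=True)`) additionally requires
the position to fall inside the decomposition's D block — results from the
variant should be labelled as such.

## Germline reference

The reference ships as in-repo constants: the junction-proximal 3' tail of
TRDV2 (C104 codon onward: `TGTGCCTGTGACACC`, CACDT), the three complete
TRDD segments, and the 5' heads of TRDJ1–4 through the F118 codon, reference
alleles *01 only (the analyses are region-level; allele polymorphism is
irrelevant at this resolution). Coordinates are 0-based half-open, anchor
offsets point at the first nucleotide of the anchor codon, and the V tail +
TRDD3 (frame 2) + TRDJ1 head concatenation reproduces the canonical
germline public clonotype CACDTLGDTDKLIF with zero N insertions — the
internal consistency check that anchors the whole decomposition. No IMGT
release tag is recorded for the fixture; the junction-proximal regions of
the rarely used TRDJ2/TRDJ3/TRDJ4 are curated reference-allele
reconstructions with correct anchors and motif-consistent heads, sufficient
for region-level classification and for the simulator's closed loop, but
absolute N-insertion counts on real data can shift by small constants if a
different reference release is substituted (the FASTA import path exists
for exactly that audit).

## Junction decomposition and N insertions

`decompose_junction` attributes junction nucleotides to contiguous, ordered
V / N1 / D / N2 / J blocks by maximising the germline-attributed total
(score) over: an exact V prefix match (any length up to the V tail), an
optional exact contiguous D substring match of ≥ `min_d_match` nucleotides
(default 3 — shorter matches are indistinguishable from chance), and an
exact J suffix match (best over the four J heads). Ties prefer a longer V
match, then a longer J match, then calling a D over no D, then the
lexicographically smallest D id, then the leftmost placement — fully
deterministic. When no D is called the unattributed nucleotides form one
merged N block. The implementation enumerates (V,J) boundary pairs against
precomputed maximal D-match intervals (any in-window match is a truncation
of a maximal one); the test suite checks its score against a brute-force
oracle that enumerates every placement by direct string comparison, on 500
junctions up to 48 nt.

Two deliberate simplifications: matching is exact (sequencing-error
tolerance belongs upstream), and P (palindromic) nucleotides are not
modelled — they count as insertions. `germline_encoded` therefore means
"decomposable with zero unattributed nucleotides under exact matching",
which slightly understates germline content relative to tools that model P
additions. For the same reason the simulator's recovered insertion count
can sit below the generated one (chance germline matches absorb inserted
nucleotides); the round-trip test requires agreement of the means within
±1 nt.

## Filtering, frequencies, classes

One-read clonotypes are removed per sample before any frequency or
diversity computation ("more than one read per clonotype"); the filter is
idempotent and applied per sample (a donor-pooled variant exists for
sensitivity analyses). Clonotype identity at the nucleotide level is the
tuple (junction, v_call, j_call); D calls are informative only. Frequencies
are shares of the same sample's post-filter reads — self-consistent with
the filtered repertoire, since no denominator is externally defined.
Class boundaries are closed on the left: 0.1 % is *expanded*, 1 % is
*hyperexpanded*.

## Publicity

Publicity is scored at the amino-acid level over replicate-concordant
nucleotypes (detected in ≥ 2 samples of the same donor), which suppresses
the detection noise of rare sequences; donors with a single sample are
excluded with an explicit error. Collapse conserves reads by construction,
sharing counts are monotone under donor addition (both property-tested),
and "highly common" means strictly more than half the cohort.

## Diversity and comparisons

Shannon entropy uses natural logarithms; comparisons are within-study, so
the base is immaterial but fixed for reproducibility. D75 uses the
standard DXX estimator: counts ranked descending (ties broken by junction
sequence for determinism), k = smallest number of top clonotypes reaching a
75 % cumulative read share, D75 = 100·k/richness. Head-to-head diversity
comparisons refuse samples with unequal sorted-cell counts unless
explicitly overridden; a seeded read-downsampling utility is provided as an
extension, not as part of the core procedure.

Group contrasts use the two-sided Wilcoxon rank-sum test, unpaired (donor
pairing enters only through replicate averaging): the exact null
distribution when the pooled sample is ≤ 16 and tie-free, otherwise the
normal approximation with midranks, tie correction and continuity
correction (both routes via scipy's Mann–Whitney machinery; an independent
full-permutation oracle verifies the exact route in the tests). The
reported effect size is the plain difference of group medians. P-values are
raw — the analyses mirror single-comparison reporting — with a
Benjamini–Hochberg helper available as a clearly separate extension, and a
t-based 95 % interval helper for mean summaries. Feature proportions are
clonotype-weighted within frequency classes (the classes already encode
abundance), and empty classes propagate as missing values rather than
zeros.

## The synthetic cohort generator

The simulator emulates the statistical structure the analyses assume; it is
a pipeline-validation instrument, not a biophysical model (no thymic
selection, no TCRγ pairing, no sequencing-error model). Per rearrangement:
V = TRDV2; D and J drawn from configurable usage (defaults J1 0.80 /
J3 0.12 / J2 = J4 0.04, TRDD3-dominant); geometric end-trimming
(p = 0.35, mean ≈ 1.9 nt per end); Poisson N insertions per block (mean
4.0, giving adult-like junction lengths centred near 13–14 aa);
rejection-sampling to productive junctions (in-frame, stop-free, C…F/W).
Convergent recombination is emulated by seeding the fourteen highly common
public AA clonotypes through germline-compatible routes whose middle codons
draw synonymous alternatives, so multiple nucleotypes per public AA
sequence arise naturally; each public sequence enters a donor with
probability 0.7, making ">50 % of donors" sharing typical but not certain.

Clone sizes follow a rank-frequency power law per sorted subset
(`s_r = r^−a`), multiplied by the expansion coupling
`exp(β_hAA5·hAA5 + β_J1·J1 − β_len·(length−12))` with defaults
β_hAA5 = 1.5, β_J1 = 1.0, β_len = 0.15. The cohort defaults mirror the
modelled study design: 9 donors, duplicate sorts, 50,000 reads per sample,
a CD27pos compartment of 3,000 clones (a = 0.9) and a CD27neg compartment
drawn as a 10× smaller sub-pool with a steeper law (a = 1.6), encoding the
focused, oligoclonal late-differentiation phenotype. Reads are drawn
multinomially per replicate. Determinism: one root seed; per-donor
substreams are spawned from (seed, donor index), so adding donors never
perturbs existing ones, and repeated runs are byte-identical at the table
level.

Ground truth labels each clone's generation route; a 1–2 nt D remnant after
trimming is labelled separately (`short_d_remnant`) because exact matching
cannot distinguish it from insertions — only `germline_only` clones carry
the guarantee of decomposing to zero N.

What passing on synthetic data shows: the pipeline's bookkeeping is
correct, programmed effect directions and magnitudes are recovered, and the
test machinery attains its nominal level under the null. What it does not
show: that real repertoires satisfy the generator's assumptions (power-law
clone sizes, independence of features beyond the programmed couplings,
error-free clonotype calls).

## Problem sizes and numerical choices

Simulation-based checks run at reduced but design-preserving sizes chosen
for quick iteration: parameter-recovery cohorts use 10 donors × 1,200
clones × 20,000 reads; the type-I calibration uses 1,000 null cohort pairs
of 8 + 8 donors, whose per-donor entropies come from multinomial read
draws over a fixed power-law clone distribution — the generator's sampling
model with zero coupling — because the exact rank-sum test at 8 + 8
attains level 0.0499 at α = 0.05. Degenerate inputs fail loudly:
empty repertoires, nonpositive frequencies, single-sample donors in
publicity, >10,000 consecutive nonproductive draws in the simulator.
Stable sort orders and explicit tie-breaks (D75 labels, decomposition
candidates, table row order) make every output deterministic and
byte-reproducible.

## Known limitations

- TRD only, TRDV2-centred; no TRG/TRA/TRB, no allele inference.
- N-insertion counts are reference- and convention-dependent (no P
  nucleotides, exact matching); treat cross-study absolute comparisons
  with caution, rank/ordering behaviour is the robust signal.
- Publicity depends on the replicate-concordance universe; cohorts without
  replicates cannot be scored.
- The simulator's clone-size law and coupling form are convenient
  abstractions, not fitted models.
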