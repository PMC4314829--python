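# Methods

This note records the models, parameter choices and numerical conventions
behind `dhqforge`, and what the synthetic data do and do not exercise.

## Homolog screen

Candidate proteins are scored against one type I and one type II seed by
optimal local alignment (Smith–Waterman with affine gaps). The scoring
scheme is BLOSUM62 with gap open 11 and extend 1 — the standard protein
BLAST parameterization — under the BLAST gap convention (a gap of length
L costs `open + extend·L`). Raw scores convert to E-values with the
ungapped Karlin–Altschul formula `E = K·m·n·exp(−λS)` using K = 0.041 and
λ = 0.267 per score unit, applied to the gapped score; this is an
approximation (gapped statistics have slightly different K, λ), which is
acceptable because the screen operates ~40 score units below threshold
for true homologs and ~100 above it for random sequences. `m` is the seed
length and `n` the residue count of the screened proteome; no
database-wide length sum is used, so E-values are directly interpretable
at toy scale. All four constants are configurable on `ScoringScheme`.

Pipeline order: pathway-completeness filter → species de-duplication →
screen → classification → summary. Completeness is judged on the
genome's declared step annotations (`step1`–`step7`), not by re-screening
the other six pathway enzymes. De-duplication keys on the exact binomial
species string and keeps the lexicographically smallest genome id — an
arbitrary but deterministic tie-break. Classification assigns the seed
type with the smaller E-value; exact ties go to type II (the dominant
class among prokaryotic DHQases), and records passing neither threshold
are "none".

Distribution percentages follow the conventions of type I/II survey
tables: genome categories (type-I-only / type-II-only / both) are
percentages of the *bacterial* genome total; sequence-type shares are
percentages of the bacterial sequence total (archaeal sequences, all
type I, are excluded from the denominator). Rounding to one decimal
happens only at reporting.

The residue audit maps reference positions (1-based, e.g. the catalytic
Tyr24/His101 of type II enzymes) through a pairwise global alignment with
the same scoring scheme. A production survey would use a multiple
alignment; pairwise is the supported approximation here and is exact for
the point-substituted and end-inserted variants the tests construct.

## Gene design

**Harmonized weights.** Each host's usage table is reduced to relative
adaptiveness (codon frequency / synonymous-family maximum); the joint
weight of a codon is the geometric mean across hosts. The geometric mean
is chosen over the arithmetic because it penalizes codons that are rare
in *either* host — a codon unusable in one chassis should not be rescued
by popularity in the other. Codons with weight < 0.10 (floor,
configurable) are inadmissible for initial recoding unless their whole
family is below the floor, in which case the family's best codon stays
admissible. Reverse translation takes the admissible argmax per residue,
lexicographically smallest codon on ties, so designs are fully
deterministic. A TAA stop (the majority stop codon in both reference
hosts) is appended and never edited.

**Site curing.** The scrubber removes the seven reserved recognition
sites (NdeI CATATG, XhoI CTCGAG, EcoRI GAATTC, NotI GCGGCCGC, XbaI
TCTAGA, SpeI ACTAGT, PstI CTGCAG — all reverse-complement palindromes, so
single-strand scanning is complete; non-palindromic custom motifs are
additionally scanned on the reverse complement). Strategy: leftmost
motif first; among codons overlapping it, the synonymous replacement with
the least harmonized-weight loss that removes the occurrence without
creating a new site anywhere. If no single substitution helps, an
exhaustive search over the motif window (±1 codon) runs, and for peptides
of ≤10 codons over the entire synonymous space — so on short inputs the
scrubber succeeds exactly when a motif-free encoding exists, and failure
is a proof of unsatisfiability. Iterations are bounded
(`max_scrub_iterations`, default 200). Every change is logged as
(codon index, old, new, reason) and replaying the log onto the initial
argmax ORF reproduces the final ORF exactly. Because edits only ever move
away from the per-family weight optimum, the total harmonized weight of
the ORF is non-increasing; per-host CAI individually need not be
monotone (an edit can favor one host at the other's expense), so QC
reports both hosts' CAI.

**Secondary structure.** mRNA-folding screens in gene synthesis target
stable hairpins near the ribosome entry; here the check is a
deterministic perfect-stem inverted-repeat scan over the first 120 nt:
report maximal stems of ≥8 Watson–Crick pairs with loops of 3–9 nt,
suppressing hairpins nested inside a longer-stemmed one. This replaces a
full minimum-free-energy fold: it is dependency-free, exactly testable,
and catches the hairpins strong enough (≥8 perfect pairs) to matter for
5′ accessibility; G·U wobbles, bulged stems and long-range pairings are
out of scope. Elimination substitutes the least-weight-loss synonymous
codon inside a detected stem, never re-introducing a forbidden motif;
irreducible hairpins are returned as a warning with the residual list
rather than an error, since synthesis may still proceed.

**BioBrick assembly.** The construct is `prefix + ORF + suffix` with the
RFC10 adapter strings. Validation scans the whole construct: site
occurrences entirely inside adapter coordinates are the standard's own
(EcoRI/NotI/XbaI in the prefix at offsets 3/9/18; SpeI/NotI/PstI in the
suffix at 0/7/15); any occurrence overlapping the ORF or a junction is a
violation. Coordinates are 0-based half-open everywhere in the API;
1-based numbers appear only in human-facing audit positions.

**QC metrics.** CAI is the geometric mean of relative adaptiveness over
sense codons (Met/Trp contribute 1; trailing stop ignored; internal stop
is an error). Theoretical mass is the average-isotope protein molecular
weight (Biopython), reported in kDa to one decimal at the boundary.

## Kinetics

The assay model is Beer–Lambert at 234 nm: product concentration
`P = A/(ε·l)·10⁶` µmol/L with ε defaulting to 1.2 × 10⁴ L·mol⁻¹·cm⁻¹
(the classical 3-dehydroshikimate value — it is not printed in plate
protocols, so it is configurable and logged) and path length 0.29 cm
(100 µL in a standard 96-well geometry; also configurable).

**Initial rate.** Candidate fit windows are anchored at the first time
point and end anywhere within the first 20% of substrate conversion (a
window of at least three points is always permitted); the window with
the highest r² wins, the longest on ties. Anchoring at the start avoids
chasing transient high-r² windows later in the curve; the r² criterion
is a bias–variance compromise — longer windows average out read noise
until curvature from substrate depletion degrades linearity. A flat or
decreasing curve yields a flagged zero-rate estimate, not an exception.

**Fitting.** Km and Vmax come from ordinary least squares of 1/v on 1/S:
`Vmax = 1/intercept`, `Km = slope/intercept`. Double-reciprocal OLS is
statistically inferior to a direct nonlinear Michaelis–Menten fit (it
over-weights low-rate points), but it is the classical plate-assay
convention and is kept as the default; `fit_michaelis_menten_nonlinear`
is an opt-in cross-check only. Zero rates are excluded with a warning, at
least three distinct substrate concentrations are required, and a
non-positive intercept is rejected with a hint that the substrate range
likely sits far below Km. The 80–1000 µmol/L 8-point design resolves
Km values across the full library range (≈37–2230 µmol/L) on exact data.

**Derived constants.** kcat = Vmax/[E] (s⁻¹), efficiency = kcat/Km
(L·µmol⁻¹·s⁻¹), and specific activity = v(500 µmol/L) converted to
µmol/min in the well volume per mg protein (U/mg). When [E] or the
protein mass is unknown the dependent quantities are reported as
unavailable rather than guessed. Reporting precision (one decimal for
Km/Vmax, two for kcat, efficiency and specific activity) applies only at
the summary boundary; internals stay full precision.

## Synthetic data

**Cohorts.** Genomes are apportioned among four classes (bacterial
type-I-only / type-II-only / both, archaeal) by largest remainder, so a
391-genome cohort at fractions 0.153/0.783/0.064 contains exactly
60/306/25 genomes. Planted homologs are point-substituted copies of the
seeds at 60% identity by default — inside the 42–72% band typical of
cross-species DHQase homologs and comfortably above the screen's
detection limit. Decoys are i.i.d. uniform random sequences of 120–260
residues; no compositional realism (hydrophobicity patterns, low
complexity, domain structure) is attempted. Passing the recovery tests
therefore shows the pipeline's thresholds and bookkeeping are correct,
not that the screen would separate true homologs from paralogous lyases
in real proteomes. The shipped seed pair is likewise synthetic (random
sequences with Tyr24/His101 planted in the type II seed), so absolute
alignment scores are not comparable to scores against real DHQases.

**Plates.** Progress curves integrate `dP/dt = Vmax·(S₀−P)/(Km+S₀−P)` by
fixed-step Euler (duration/2000 per step) — substrate depletion is
simulated, not assumed negligible, so the 20%-conversion window rule is
genuinely exercised. Readings are sampled at 301 time points over 60 s
(0.2 s interval, a fast kinetic plate read) and perturbed by
multiplicative Gaussian noise with CV 1% by default. With these
defaults the noiseless extraction bias from depletion is < 0.4% of the
true rate at the lowest substrate, and the full pipeline recovers Km
with ≈1.4% median error under 1% noise. The exact-identity regime
(recovery to ≤10⁻⁶ relative) is reached by shrinking the duration until
conversion is negligible (e.g. 10⁻⁴ s at these constants); with
appreciable depletion a secant slope is biased low by roughly half the
window's conversion fraction times Km/(Km+S), which the default
configuration keeps below the half-percent level.

**Tables.** The packaged CSVs (distribution counts, the 38-enzyme
selection, the kinetic-constants table) are verified by SHA-256 at load;
the four enzymes with no detectable activity are carried as missing
values, excluded from summaries and listed as omitted in diversity
reports. Diversity ratios are `100 · value/reference` per parameter with
code 3001 as the default reference.

## Known limitations

- E-values reuse ungapped Karlin–Altschul constants for gapped scores;
  fine for a toy screen with large margins, not for borderline calls.
- The hairpin detector ignores G·U pairs, bulges and free energies; a
  thermodynamic folder can be slotted in where stronger guarantees are
  needed.
- The motif scrubber is greedy with bounded backtracking; global
  optimality of the edit set is only guaranteed on short peptides where
  the exhaustive fallback engages.
- Lineweaver–Burk inherits its classical noise sensitivity; use the
  nonlinear cross-check for low-substrate designs.
- Pairwise residue auditing can mis-map positions around long indels
  where a multiple alignment would not.
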