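# Methods

## Saturation mutagenesis

Given a coding sequence (A/C/G/T, length divisible by 3, 1-based
coordinates throughout), each of the 3L single-nucleotide substitutions is
applied, the affected codon re-translated with the standard genetic code,
and the outcome classified as silent, nonsense, or missense. Silent and
nonsense changes are not analyzed further; missense changes within the
N-terminal mitochondrial leader peptide (default 35 residues for GLDC) are
excluded; the remaining missense changes are deduplicated on
(position, reference residue, alternate residue), keeping the lowest cDNA
position. The census records all five counts and enforces the partition
`total = silent + nonsense + leader_excluded + missense_raw`. Two
conventions are worth noting:

* Substitutions inside a trailing stop codon (stop-retaining or
  read-through) are counted in the silent class — they are not missense and
  would otherwise break the partition.
* Duplicate collapse keys on the protein change alone. All parameters in
  the default registry except codon/tRNA availability are protein-level, so
  cDNA provenance is retained on each record (`collapse=False` keeps every
  route) and can be consulted at scoring time.

A reference sequence containing an internal stop is rejected; a missing
initial ATG warns but does not error, so fragments can be analyzed.

## Cross-species mutation transfer

A pairwise protein alignment is converted to a strictly increasing
one-to-one position map; gap columns map nothing, and an insertion in the
target shifts downstream numbering (the mouse GLDC five-glycine insertion
at residues 43–47 is the motivating case: human position p maps to p for
p ≤ 42 and to p + 5 beyond). A mutation transfers only when the aligned
target residue is *identical* to the source reference residue; similarity
is not accepted. This strict-identity rule is what makes a subset of
clinical mutations unmappable between human and mouse, and it is the rule
that reproduces the published 242-of-255 mapped count. Alignments are
accepted pre-computed (aligned FASTA, e.g. from Clustal Omega); a built-in
Needleman–Wunsch (BLOSUM62, affine gaps 10 open / 0.5 extend, via
Biopython's PairwiseAligner) exists so the module is testable
self-contained, but identical alignments across aligners are not guaranteed
and analyses of real pairs should supply the alignment they trust.

## The parameter registry

The published description names the four indicator categories and several
members but defers the full 18-parameter list to supplementary material
that is not redistributable here. The shipped registry
(`src/gldcscore/data/registry.yaml`) therefore instantiates the categories
with a defensible, fully documented 18-member set:

| category | parameters |
|---|---|
| stability | ΔΔG very destabilizing, destabilizing, stabilizing, very stabilizing |
| position | helix, sheet, dimerization interface, active site |
| conservation | ConSurf grade ≥ 7, ≥ 8, = 9, functional-residue flag |
| property change | proline, size, polarity, charge |
| tolerance | conserved substitution (the single −1-signed parameter) |
| translation | rare mutant codon (tRNA availability) |

The engine is registry-driven and works at any width, so a different
18-member definition drops in as a config change without touching code.
Indicator evaluation is strict: missing underlying data raises
(`ParameterUnavailableError`); a mutation is never silently scored 0.

Numerical conventions:

* **ΔΔG bands** (kcal/mol): very destabilizing (−∞, −5.0); destabilizing
  [−5.0, −1.5) — "destabilizing" is strictly below −1.5, so −1.5 itself is
  neutral and −5.0 exactly is destabilizing (not *very*); neutral
  [−1.5, +1.5]; stabilizing (1.5, 5.0]; very stabilizing (5.0, ∞). Only the
  destabilizing bounds are anchored by the source analysis; the
  stabilizing side mirrors them, a choice recorded here because no printed
  value constrains it.
* **Amino-acid property classes**: size is a three-way side-chain-volume
  class (small AGSCPND / medium TVEQHIL / large MKRFYW), polarity a binary
  class (polar STNQYCDEKRH), charge {+: KRH, −: DE, 0 otherwise}. The
  proline indicator fires when proline is gained or lost. Swapping tables
  is a provider change.
* **Conserved substitution**: BLOSUM62 score ≥ 1 for the exchange,
  i.e. substitutions favored through evolution subtract one point.
* **Active site**: a residue belongs iff any of its atoms lies within the
  cutoff (default 5 Å) of any atom of a center residue — the catalytic
  lysine (K759 in mouse numbering) and, when present in the coordinate
  file, the PLP cofactor or substrate glycine. Implemented with Biopython's
  NeighborSearch (KD-tree); center residues always include themselves.
* **Phi correlations** between indicators use the 2×2 contingency closed
  form, identical to Pearson on 0/1 vectors; a constant indicator has
  undefined phi and is reported as NaN, never coerced.

## Scoring and weight training

MMS is the signed sum of indicators (+1 each, −1 for conserved
substitution); theoretical-mutation tables conventionally floor it at 0
(`clamp=True`), and the severity bins are 0 / 1–2 mild / 3–4 moderate /
≥ 5 severe (negative pre-clamp values fall in the 0 bin). Weights are
ordinary least squares (scikit-learn `LinearRegression` inside the
`WmmsWeightModel` estimator) of COS on the indicator matrix. Decisions that
were genuinely open:

* **Controls at COS 0.** The training set pairs patient mutations having
  outcome scores with benign control polymorphisms whose target value is
  never stated; 0 is the only value consistent with negative WMMS
  predicting reduced pathogenesis.
* **Intercept excluded from the score.** WMMS is described as a summation
  of weighted parameters and negative WMMS values exist, so the fitted
  intercept is stored but not added; `include_intercept=True` enables a
  sensitivity check.
* **Exact collinearity** (duplicate or constant columns) raises a
  `CollinearityError` naming the dependent columns rather than silently
  returning one of infinitely many solutions; `allow_rank_deficient=True`
  opts into the minimum-norm fit.
* **Score concordance** between species means equality of printed values,
  so the comparison rounds to 2 decimals (configurable), the precision at
  which the scores are reported.

## Selection models

*Attenuated ranking*: Score A = (mWMMS − min)/(max − min) over the cohort
(min–max rather than value/max, because the published endpoints put the
lowest-scoring candidate at exactly 0 even when scores are negative);
Score B = 1 − |mWMMS − hWMMS| / max|mWMMS − hWMMS|, cohort-relative because
no absolute scale is stated, and 1 when every difference is zero.
Candidates are ranked by the sum; ties share the better (competition) rank
and are ordered deterministically by label.

*Severe five-criterion model*: one point each for mWMMS ≥ 9.94 (the lead
severe candidate's score, configurable), residue conserved between
species, mWMMS equal to hWMMS (2-decimal equality; forced 0 when
unmappable), substitution not introducing a proline (prolines are so
destabilizing they risk outright lethality), and active-site membership.
Reachability by single-nucleotide substitution is implicit for enumerated
mutations. Double mutations are refused with an explicit message: the
weights are trained on single-point mutants, so a combined score is
undefined.

The active-site vs non-active-site comparison uses Welch's unequal-variance
t-test (two-tailed, Satterthwaite df), since the two groups' variances
differ.

## Outcome model

The line WMMS = slope·COS + intercept is fitted by least squares
(`scipy.stats.linregress`); its value at the clinical cutoff COS = 5 is the
attenuated/severe WMMS threshold (1.3 for the published 0.76·COS − 2.5
line). Classification bands are attenuated [−0.87, threshold] (both edges
inclusive — the validated attenuated anchor must classify attenuated;
a 1e−9 tolerance absorbs floating-point rounding of slope·cutoff),
severe (threshold, 10], out-of-range beyond, because scores above 10 lie
outside the interval validated in animals.

Prenatal lethality from colony counts is 100·(1 − hom-fraction/0.25),
floored at 0. Outcome prediction interpolates prenatal fatality *linearly*
between the validated anchors (−0.87 → 26%, 10 → 90% cap): the disease
scale is stated to be linear in WMMS but no interpolant is printed, so
linearity is this package's modelling assumption, flagged here
prominently. Post-natal hydrocephalus has no supportable interpolant at
all; it is returned as the constant attenuated baseline 31% (34% under
formate) with a caveat flag on every prediction. Formate supplementation
of dams is modelled as a step rescue to 29% fatality / 34% hydrocephalus
irrespective of WMMS. Mendelian colony tests are Pearson goodness-of-fit
chi-square against 1:2:1 with df = 2.

## Synthetic data

No accession is attached to the analyzed cDNAs and the per-mutation tables
are not redistributable, so the test suite runs on synthetic bundles
(`gldcscore.fixtures`). A bundle contains: a random in-frame "human-like"
cDNA (default 60 codons — large enough for every enumeration path, small
enough that the full suite runs in seconds) and a "mouse-like" copy with 6
point substitutions plus one in-frame 15-nt insertion encoding five
glycines after codon 42, echoing the real pair's divergence pattern; a
40 × 18 Bernoulli(0.3) indicator matrix (the training-set scale of the
clinical analysis: tens of homozygous mutations and controls over 18
parameters); planted Normal(0, 1.5) weights; a training response
X·w + N(0, 0.5); and (COS, WMMS) pairs on the 0.76/−2.5 line with the same
noise. Everything is drawn from one seeded generator, and regeneration
with the same seed is byte-identical.

What passing on synthetic data does and does not show: it demonstrates
that enumeration, mapping, scoring, training and the outcome fit are
implemented correctly (oracle-checked against independent brute-force and
closed-form computations) and that parameter recovery behaves as OLS
theory predicts; it does not validate the biological parameter definitions
against the original study's tables, which would require those tables
themselves. The end-to-end tests that need them state this explicitly and
run whenever the files are supplied under `tests/data/reference`.

## Known limitations

* ΔΔG and ConSurf values are consumed, never computed; hydrogen-bond
  reasoning is carried only as free-text annotation.
* The exact published 18-parameter conditions may differ from the shipped
  registry instantiation; the registry file is the single point of change.
* The outcome interpolant is linear by assumption (see above) and the
  hydrocephalus percentage is a baseline, not a function of WMMS.
* One ortholog pair at a time; no orthology detection, no indel or
  multi-nucleotide mutations, no splice effects.
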