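# Methods

This note documents the models, parameter choices and numerical
decisions behind `mimicry_screen`, in the order the pipeline runs.

## Peptide comparison and substitution chemistry

Epitopes are nonamers over the canonical 20-letter alphabet; the data
model accepts other lengths but the scanning and library stages insist
on length 9. Positions are **1-based** everywhere, matching how
immunologists report "a substitution at position 7". Lowercase input is
upper-cased with a warning rather than rejected; any symbol outside the
alphabet is an error that names the offending character.

A substitution is classified against an injectable `ClassScheme`, a
total partition of the alphabet into chemical classes. The default
six-class partition is

| class | residues |
|---|---|
| aliphatic-hydrophobic | A V L I M C |
| aromatic | F W Y |
| polar-uncharged | S T N Q |
| positive | K R H |
| negative | D E |
| special | G P |

chosen because "same chemical property" is not otherwise pinned down by
any single standard; the scheme is serialized into every pair report so
classifications are reproducible, and an alternative rule (BLOSUM62
score ≥ 0) is available as `Blosum62Scheme` for sensitivity analyses.
The two rules mostly agree on the pairs that matter here (e.g. L↔I,
A↔V, V↔L conservative; K↔E, I↔T non-conservative).

The package ships the seven study TAA nonamers (MAGE-A1, -A3, -A3/12,
-A10, -C1, -C2, SSX2) and the eleven mimic sequences printed with them
(`STUDY_TAAS`, `STUDY_MOAS`). One printed mimic, FLWGPKALV, is described
in its source with an inconsistent residue name at position 6; the
comparison here is purely position-based and reports what the sequences
actually contain (R→K at position 6 against FLWGPRALV).

## Homology scanning

BLAST-style heuristics are deliberately replaced by exhaustive
enumeration: with a fixed gap-free nonamer model, every window of every
protein can be checked exactly, so E-values and seeding heuristics add
nothing. The scan is vectorized (integer-encoded sequences, sliding
window view) and returns every window with `n_identical ≥
min_identical`, sorted by (score desc, protein id, offset) for
deterministic output. `min_identical` defaults to 6 — mimic pairs
typically share 6–7 identical residues — but it is a parameter, not a
constant. The score weight for conservative substitutions (0.5) affects
reporting order only, never the gate. Windows containing ambiguity codes
(X, B, Z, U, O, \*) are skipped and counted in a log line, since such
residues have no chemical class.

Sequence logos use raw frequencies (no pseudocounts, no background
correction): with 3–9 sequences per mimic panel, pseudocounts would only
blur the signal, and the display convention is relative frequency. A
Kullback–Leibler background-corrected variant (`build_logo_kl`) exists
for users who want compositional correction. Consensus calling takes the
modal residue per position; exact ties are flagged ambiguous and the
string form takes the alphabetically first residue, so the output is
deterministic.

## Binding filter

Affinity/stability cuts are strict inequalities, read literally from
"< 100 nM" and "> 1 h": a peptide at exactly 100 nM is dropped. The
module consumes prediction TSVs and never invokes a predictor — the
predictors are external trained models and re-running them is out of
scope. `library_summary` reports the mean affinity and the count of
peptides strictly below it.

## Barcode enrichment statistics

The statistical engine follows the established barcoded-multimer
analysis pattern (Barracoda-style), with each choice stated explicitly:

* **Counting layer.** Clonally reduced counts (distinct molecule tags
  per barcode and sample) are used wherever present, falling back to raw
  counts with a warning; read fractions are computed on the same layer.
* **Normalization.** Trimmed mean of M-values with the method's
  canonical trims (30 % on M, 5 % on A) and inverse-variance weights,
  computed on barcodes non-zero in both the sample and the reference
  (the baseline replicate with median total count). The returned factor
  absorbs sequencing depth — factor ∝ column total × composition factor,
  rescaled to geometric mean 1 — so `count / factor` is directly
  comparable across samples. (The edgeR convention separates the two;
  here a single per-sample scale is more convenient because the NB test
  needs sample-scale means.)
* **Test.** One-sided upper tail of a negative binomial with mean equal
  to the (depth-rescaled) mean of normalized baselines and fixed
  dispersion α = 0.1 (variance μ + αμ²; the mean/dispersion
  parameterization is the standard reading of a "fixed dispersion
  parameter"). Enrichment is the only alternative of interest, hence
  one-sided. Tail probabilities are floored at the smallest positive
  double to guard floating-point underflow on extreme spikes.
* **Zero handling.** The fold change uses a pseudocount of 1 in both
  numerator and denominator. The NB mean instead uses a floor of 0.5
  normalized reads: a pseudocount there would bias every test, while a
  floor only prevents a barcode absent from the baseline from becoming
  infinitely significant.
* **Multiplicity.** Benjamini–Hochberg across all (barcode × tested
  sample) pairs of a run — a single global family, logged; a per-sample
  family is available by configuration since the family boundary is a
  convention, not a printed fact.
* **Calls.** Significant ⇔ FDR < 0.1 % ∧ log₂FC > 2 ∧ read fraction
  ≥ 1/1,000 (the read-fraction gate is inclusive; the other two strict).
* **Frequencies.** Responding-cell frequency = read fraction × %
  multimer⁺ CD8⁺ cells; when the percentage was not recorded the
  frequency is reported missing, never zero. Fractions over a sample sum
  to 1, so frequencies conserve the sample's multimer⁺ percentage.
* **Negative control.** Any specificity significant in the non-matched
  control sample is un-called in every sample and listed in the log.

The pipeline is deterministic: identical inputs and configuration give
byte-identical result tables.

## Subject profiles and group comparison

Cross-reactivity is defined operationally at the specificity level: a
(TAA, MoA) pair is cross-reactive in a subject when both are significant
in that subject's double-stained fraction and the MoA belongs to the
TAA's homology group. Class percentages partition each subject's total
response: cross-pair members (double-stained) form the CROSS class,
remaining double-stained TAAs the TAA class, and everything else
(single-stained MoA/viral responses plus unpaired double-stained MoAs)
the MoA class. By default the classes are weighted by estimated
T-cell frequencies; a count-of-specificities mode exists because the
weighting convention of such summary plots is rarely printed. Percentages
sum to 100 whenever any response exists and are reported missing
otherwise.

The group comparison is a two-sided Mann–Whitney U test: exact by full
enumeration of label assignments for combined n ≤ 12 (ties handled by
the ½-count convention), normal approximation with tie correction above
that. The switch point is documented in
`reactivity_profile.EXACT_ENUMERATION_LIMIT`.

## Synthetic data

The generators emulate the screening study's input structure at its real
scale, so the defaults are the study conditions rather than toy sizes:

* **Library**: 7 TAAs + 53 mimics + 64 viral-control barcodes (124
  pMHCs). Mimic panels embed the printed mimic sequences and fill up
  with synthetic mimics at Hamming distance 1–2, with mutated positions
  budgeted so no position is mutated in half or more of a panel — this
  reproduces the reported structure in which the panel consensus equals
  the TAA, and makes consensus recovery a by-construction truth the
  pipeline must reproduce, not a statistical accident.
* **Counts**: baseline barcode abundances are lognormal (μ = 0, σ = 1 on
  the log scale — about a 50-fold 5th-to-95th percentile abundance
  range, typical of pooled multimer libraries); per-sample depth
  defaults to 10⁶ reads; sorted-sample counts are negative binomial with
  dispersion α = 0.1 around the abundance-share mean, times a planted
  fold (default 32, i.e. log₂FC 5) for spiked responses.
* **Baseline noise**: baseline replicates are technical aliquots of one
  multimer pool, so their replicate noise is Poisson
  (`baseline_alpha=None`); the NB dispersion of 0.1 describes how a
  sorted sample varies around the pool composition, which is exactly
  what the test models. (Drawing baselines with α = 0.1 would give the
  estimated baseline mean a coefficient of variation of √(α/3) ≈ 18 %
  that a fixed-dispersion test cannot absorb, and no fixed-dispersion
  pipeline would be calibrated against it; `baseline_alpha` accepts a
  float for users who want to study that regime.)
* **Cohorts**: 10 healthy subjects and 15 patients, each contributing a
  single-stained and a double-stained sorted sample, plus triplicate
  baselines and one negative-control sample. The default planted pattern
  mirrors the screening study's headline readout: every subject reacts
  to a consistent MAGE-C2 mimic plus 1–3 random MoAs; two healthy
  subjects and three patients carry cross-reactive responses, one
  patient with the broad TAA + three-mimic pattern.

All randomness flows from one integer seed through
`numpy.random.default_rng`; a fixed seed reproduces counts, sequences
and truth tables exactly.

### What the simulations do and do not show

Passing the planted-truth checks shows the pipeline's statistics are
calibrated and powerful *under the generative model it assumes*:
independent NB counts, correct homology annotation, no barcode
collisions. The generators do not model PCR chemistry or sequencing
error (clonal reduction is therefore exercised on synthetic tag streams,
not error-corrupted ones), flow-cytometer gating, inter-subject
repertoire correlation, or compositional interference between spiked
barcodes beyond what the fixed depth imposes. Agreement on synthetic
cohorts is therefore evidence about the code and the statistics, not
about any particular biological dataset.

### Measured operating characteristics

With the default generator and the standard gates, measured over ~200k
null barcode tests: the null probability of p < 0.001 is ≈ 0.0017 —
above the nominal 0.001 because the baseline mean is estimated from
three aliquots and the normalization factors are themselves noisy, but
well inside twice nominal; fold-32 spikes at baseline mean ≥ 50 reads
were recovered as significant in every measured run (the test suite
gates this at ≥ 95 %) with no excess calls beyond the BH expectation. `scripts/acceptance.py` recomputes these
numbers (at ~50k null tests, so the rate estimate is stable) on every
run.

## Known limitations

* No gapped alignment or epitope-length flexibility: mimics longer or
  shorter than 9 residues are invisible by design.
* The NB test treats the baseline mean as known; its mild
  anti-conservatism (above) is inherited from the fixed-dispersion
  design, not removable without changing the published procedure.
* Homology groups must be provided (or generated); the package does not
  infer them from sequence similarity at analysis time.
* 3-D conformation, TCR-contact modelling and any flow-cytometry
  processing are out of scope; the pipeline starts at annotated count
  records and prediction tables.
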