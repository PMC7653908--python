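# Methods

## Model

A cohort of `n_g` samples is summarised as a count matrix `A` over `n_t`
mutation-type channels (SBS-96 for single-base substitutions; DBS-78 / ID-83
matrices are consumed pre-computed). The generative picture is `A ≈ W·H`:
`H` (`n_k × n_t`) holds mutational signatures, each row a probability
distribution over channels; `W` (`n_g × n_k`) holds non-negative exposures,
the mutation counts attributed to each signature per sample. Model quality
is always measured by the sample-size-normalised Frobenius cost
`C = ||A − W·H||_F / n_g`.

### SBS-96 classification

A substitution is keyed by its pyrimidine-strand representation: if the
reference base is a purine, the trinucleotide context and the alternate
allele are reverse-complemented before lookup, so each SNV lands in exactly
one of 6 × 16 channels. Channel order is substitution-class major,
context alphabetical, and panels/catalogs are always aligned by channel
*label* with explicit reordering — a mismatched label set is an error, never
an implicit intersection. During matrix generation, records that are not
simple SNVs, records whose VCF REF contradicts the genome base (likely a
build mismatch), and SNVs with ambiguous context (N) are skipped and
counted; the counts are returned with the matrix and logged. Soft-masked
genome bases are uppercased and used.

## Reference refitting and stepwise selection

With `H` fixed, each sample row of `W` is an independent non-negative
least-squares problem, solved exactly by the Lawson–Hanson active-set
algorithm (`scipy.optimize.nnls`). Forward selection grows the model from
empty, at each step refitting every candidate model exactly and adding the
signature with the lowest resulting cost; backward elimination starts from
the full panel and discards the signature whose removal raises the cost
least. Both run to completion so the user sees the whole cost curve; the
implied importance ranking is addition order (forward) or reverse removal
order (backward). Ties in candidate cost (within 1e−12 relative) go to the
earlier panel position, making both procedures deterministic. Candidate
evaluation refits all samples jointly — no incremental approximation — which
is affordable because reference panels are small (tens of signatures).

How many signatures to keep is a user decision. An advisory elbow is
computed as the curve point of maximum perpendicular distance to the chord
joining its endpoints; it is never applied silently.

## Residual and partially-fixed NMF

The residual `A′ = A − W·H` can be negative where the fit overshoots a
channel; since a non-negative factorisation cannot represent that, negative
entries are clamped to zero and the clamped mass is reported (on simulated
data it is a modest fraction of the residual and behaves like a positive
noise floor). The de novo model is `A′ ≈ W′·H′` with `H′` stacking the
`n_k_ref` fitted reference rows (frozen) over `n_k_new` free rows.
Optimisation uses multiplicative Frobenius updates in which all of `W′` but
only the free rows of `H′` move; because the underlying
majorise-minimise argument is elementwise, freezing rows preserves the
monotone non-increase of the objective, which is asserted per iteration in
the tests. Defaults: free `H′` rows initialised Uniform(0,1) then row-
normalised, `W′` Uniform(0, max A′), 10 random restarts (best objective
kept), at most 10,000 iterations, stop when the relative objective change
over a 10-iteration window falls below 1e−8, 1e−12 added to update
denominators. At convergence free rows are renormalised to sum to one with
the scale folded into the matching `W′` columns, and de novo signatures are
labelled `Denovo_1…n` in decreasing order of total attributed mutations.
With `n_k_new = 0` the procedure reduces to an NNLS fit of the fixed panel;
with `n_k_ref = 0` it is pure de novo extraction.

Final reported exposures add the stage-1 (refit) and stage-2 (residual)
attributions for reference signatures and take de novo columns from stage 2;
both addends are retained so either convention is recoverable.

### Choosing the number of de novo signatures

Leave-k-out cross-validation: folds are consecutive blocks of `k` samples in
input order (remainder in the last fold; deterministic), every sample held
out exactly once. Per candidate `n_new` and fold, the NMF is trained on the
retained samples, held-out samples are projected onto the learned `H′` by
NNLS, and both held-out and training reconstruction costs are recorded
(each normalised by its own sample count). The default is leave-one-out
(`k = 1`); the studies below use `k = 5` on 25-sample cohorts, which cuts
the fold count five-fold with indistinguishable curves. A baseline
candidate `n_new = 0` (reference-only projection) anchors the curve. The
suggested elbow is the largest candidate whose mean test cost improves on
its predecessor by at least 5% relative; on null data (no hidden structure)
observed drops stay under 2%, so the rule cleanly separates signal from
noise while remaining advisory.

## Signature similarity

Signatures are distributions, so similarity uses the Hellinger distance
`H(p,q) = (1/√2)·||√p − √q||₂`, bounded in [0,1], zero iff the profiles are
identical, one exactly on disjoint supports; the 1/√2 normaliser is the
unique convention with that range. Inputs must sum to one within 1e−6
(renormalised inside that tolerance, an error beyond it). De novo
signatures are reported with their nearest reference (smallest HDS; ties to
the earlier reference).

## Simulator and synthetic panel

Each simulated sample draws one multinomial of size `n_mutations` with
channel probabilities `wᵀH` — mutations from a mixture of processes with
success probabilities proportional to each process's emission. (A
per-signature draw mode yields integer per-process truths; it is identical
in distribution.) Scenario presets fix the cohort mixture over six panel
signatures: A = one dominant process (0.75 / 5 × 0.05), B = two dominant
(0.375 × 2 / 0.0625 × 4), C = uniform (1/6 each); sample sizes 15/25/50 and
burdens 500–35,000 span the study grid. Optionally, per-sample fractions
are drawn from Dirichlet(κ · fractions) with κ = 50 (≈ ±30% relative
spread), emulating inter-patient heterogeneity of process activity. The de
novo studies always use this option: with literally identical per-sample
mixtures the residual's expectation has rank one, so no method can separate
two hidden signatures — heterogeneity is what makes the factorisation
identifiable, as it is in real cohorts.

The bundled reference panel is fully synthetic and deterministic: sixteen
profiles built from hand-chosen class/context concentrations on smooth
flanking-base tilts, emulating the qualitative character of well-known
processes (CpG-deamination clock, flat HRD-like, broad T>C, alkylation,
oxidative C>A, aristolochic T>A) plus decoys, including deliberately
collinear ones (a CpG C>T overlap of the clock signature; several broad T>C
profiles), because that redundancy — characteristic of published panels —
is precisely what makes signature selection non-trivial and greedy forward
selection fallible. No published probability values are reproduced; real
analyses should load a real panel TSV (COSMIC layout or its transpose,
auto-detected).

What passing simulation tests do *not* show: robustness to mis-specified
trinucleotide background, sequencing artefacts, inter-sample differences in
mutation burden far beyond the Dirichlet spread, or panels whose true
signatures are absent entirely; the simulator draws independent samples
from exactly the assumed model.

## Study problem sizes and observed behaviour

The selection study runs forward and backward over the 16-signature panel on
12 datasets per scenario (15/25/50 samples × 500/1000/2500/5000 mutations).
Backward elimination identifies the dominant signatures nearly always and
calls spurious top-six sets in only ~1–2 of 12 equal-mixture datasets;
forward selection misses a dominant flat signature systematically when a
collinear decoy mimics the cohort blend. The de novo study (25 samples ×
35,000 mutations, two withheld signatures, five replicate cohorts) puts the
modal CV elbow at 2 and recovers both withheld profiles at HDS ≈ 0.3 —
recovery is bounded by the residual's noise floor and by what the fitted
references absorb, so distances well below ~0.4 mark successful recovery,
and near-zero distances are only attainable when the hidden process
overlaps the references minimally. These sizes keep the full suite and the
acceptance script in the low minutes on a single CPU; all quantities quoted
here are recomputed by the tests and `scripts/acceptance.py`, not stored.

## Known limitations

- Clamping negative residual entries biases de novo profiles towards the
  positive noise floor; an alternative (joint NMF on `A` with frozen
  reference rows) would avoid clamping but changes the staged semantics.
- Greedy stepwise selection is exact per step but not globally optimal.
- The Frobenius objective treats all channels homoscedastically; a Poisson
  or KL objective would weight low-count channels differently.
- Selection is cohort-level: a signature kept for the cohort may have zero
  exposure in individual samples, but no per-sample model search is done.
- Transcriptional-strand-aware channel sets and DBS/ID matrix *generation*
  are out of scope; such matrices are consumed pre-computed.
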