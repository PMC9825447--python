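# Methods

`metabrepo` implements the computational core of a *comparable* untargeted
LC–MS metabolome repository: a collection of per-sample peak tables acquired
under one uniform chromatographic/MS protocol, so that any two peaks can be
compared directly by precursor m/z and retention time. This note documents
the models, algorithms, parameter choices and limitations.

## Tolerance semantics

All comparisons are inclusive (`<=`). An m/z tolerance is given in ppm or Da;
ppm tolerances are resolved against the **query-side** mass, not the mean of
the pair, so a search result depends only on the query, never on the hit set.
The asymmetry this introduces is negligible at realistic tolerances (it can
only flip a comparison whose relative deviation lies within ~1 ppm of the
bound) and is covered by an explicit test. RT tolerances are minutes or
percent-of-gradient; the latter resolves against the repository's declared
total elution time. Recommended defaults mirror the two published platform
families: 5 ppm / 1 min for the high-resolution FT platform (107-min
gradient) and 20 ppm / 0.5 min for the Q-ToF platform (42-min gradient).
Positive- and negative-mode peaks are never compared: polarity is a hard
partition throughout.

## Alignment into tentative unique peaks (TUPs)

A TUP is a cross-sample group of peaks with the same or similar precursor
m/z and RT — the row unit of the aligned peak matrix. The upstream vendor
tool's alignment algorithm is not publicly described, so this module uses a
deterministic greedy procedure of its own design:

1. Pool all peaks and order by descending intensity (ties: ascending m/z,
   RT, sample id, peak id).
2. The most intense unassigned peak seeds a TUP.
3. Among unassigned peaks from samples not yet in the TUP that lie within
   both tolerances of the current consensus, repeatedly attach the one
   minimizing `d = (Δmz/mz_tol)² + (Δrt/rt_tol)²`, recomputing the consensus
   (median m/z, median RT over members) after every attachment.
4. When no candidate remains, the TUP is closed; every peak that fits no
   group seeds its own TUP (there is no "unassigned" state).

At most one peak per sample joins a TUP, so per-sample presence/absence is
always well defined; co-eluting duplicates within a sample land in separate
TUPs. Before a TUP is emitted, every member is re-checked against the final
consensus; in the rare case median drift pushed an early member out of
tolerance, the worst offender is ejected back into the pool and seeds its
own group in a later sweep. Two invariants are enforced on every run: the
TUPs partition the input peaks exactly, and every member is within tolerance
of its consensus. The procedure is single-pass by design (no global
reassignment step), which keeps it order-deterministic; a refinement pass is
a possible future extension.

## Specificity statistics

For `N` samples, the **peak share rate** of a TUP detected in `k` samples is
`PSR = k / N`, and the **averaged peak share rate** of a sample is the
unweighted arithmetic mean of the PSRs of the TUPs detected in it. A low
APSR marks a sample rich in sample-specific chemistry. Intensity weighting
is deliberately not applied — the statistic is a plain average over detected
TUPs.

Saturation analysis estimates the expected number of new unique peaks per
added sample in two independent ways:

* **Tail slope** — the TUP accumulation curve is computed over uniform
  random sample subsets without replacement (default: every 25 samples,
  replicates averaged, seeded), and a least-squares line is fit to the
  trailing 25 % of curve points.
* **Singleton estimator** — the number of TUPs detected in exactly one
  sample, divided by `N`.

On share-count distributions following a power law the two agree closely
(the tail slope carries a small positive bias from k ≥ 2 compounds still
entering late subsets; at N = 200, α = 2 this bias is ≈ 3 %). Reported
per-sample integers round half away from zero.

The share-count histogram (number of TUPs detected in exactly `k` samples)
is fit as `count ∝ k^(−α)` by least squares on log₁₀–log₁₀ axes. The fit
weights each bin by its count, so every TUP contributes equally. The naive
unweighted per-bin line is available (`weights="none"`) but is biased low on
sampled data (α ≈ 1.7 recovered for a true α = 2 at 10⁵ draws truncated at
k = 524): sparse tail bins appear only when their count is nonzero, and
dropping the zero bins lifts the tail. Count weighting removes the bias
(α ≈ 1.99 in the same simulation) while leaving exact and flat histograms
unchanged. Maximum-likelihood fitting was considered and rejected as the
default because the quantity of interest downstream is the regression slope
of the displayed distribution.

## Search

* **Precursor search** returns all peaks matching a query m/z (and RT, when
  given) within tolerance; omitting RT searches the whole run and surfaces
  candidate isomers. The index is a sorted m/z array with a binary-search
  window per query; its contract — verified against a brute-force linear
  scan — is exact equivalence.
* **Spectral search** scores the cosine of nominal-mass-binned intensity
  vectors: fragment m/z rounded half-up to integers, intensities summed per
  bin, both vectors scaled to unit length. Raw intensities are used by
  default (no square-root transform); the score is symmetric, bounded in
  [0, 1] and scale-invariant. No global score threshold is imposed — the
  meaningful threshold depends on fragment counts, so the default
  `min_score` is 0 and callers filter. A level filter supports the
  derivative search (MS² query against MS³ library spectra), which finds
  candidate glycosides/derivatives sharing an aglycone fragmentation. The
  precursor m/z is not included as a pseudo-fragment.
* **Neutral-loss search** matches peaks having a fragment at
  `precursor − loss` within an absolute Da tolerance (per-fragment
  definition, not spectrum-to-spectrum shifted matching); 162.0528 Da flags
  hexose conjugates.
* **Cross-repository search** forwards a query to a second platform after
  converting its RT through a fitted RT model, flagging extrapolated
  conversions. Category summaries report, per sample category, the fraction
  of its samples containing at least one hit.

## RT calibration between platforms

Anchors are discovered between two samples (one per platform) as
mutual-nearest unique m/z matches above an optional per-table intensity
quantile; uniqueness suppresses isomer mis-pairs. The source→target RT
mapping is a least-squares polynomial (linear default, quadratic optional)
with one robust trim pass: residuals beyond 3× the median absolute deviation
are dropped once and the curve refit. Iterating the trim was rejected for
stability. The fitted curve must be strictly increasing over the anchor
range — elution order must be preserved for a conversion to be meaningful —
otherwise fitting fails with advice to use the linear form. Conversions
outside the anchor range evaluate the curve as-is but carry an
`extrapolated` flag.

## Co-occurrence mining

TUP presence is collapsed to species level (a species is 1 if any of its
samples contains the TUP) and compared against orthogroup presence profiles
derived from a gene-count table (count ≥ 1 → present). The default
comparison is **exact pattern matching** with a relaxable Hamming mismatch
budget; Jaccard similarity ranks the relaxed matches. Profiles present in
fewer than 2 or more than `n_species − 2` species are excluded by default as
uninformative (all/none patterns match trivially). No statistical
significance machinery is attached: matched counts are reported, and
phylogenetic non-independence of species is acknowledged but not modeled —
shared patterns are leads, not tests.

The flavonoid-candidate miner is a conjunction of per-peak predicates: no
compound-database hit (`db_hit_count == 0`), at least one MS³ spectrum, and
an MS³ aglycone-similarity score at or above 0.5 (inclusive — the lowest
score among published accepted candidates is exactly 0.500). A missing
annotation fails the predicate that requires it. Annotation scores are
consumed as data; their computation is out of scope.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
the chemistry:

* Samples-per-compound counts follow a truncated discrete power law
  `P(k) ∝ k^(−α)` on `{1..n_samples}`, α = 2 by default — the shape
  empirically observed for share counts in large aligned repositories.
* Compound (m/z, RT) positions are rejection-sampled to stay at least twice
  the alignment tolerance apart jointly, so the planted grouping is
  unambiguous and recovery can be scored exactly. Emitted peaks add Gaussian
  jitter (defaults 1 ppm, 0.1 min — well inside the 20 ppm / 0.5 min search
  tolerances) and log-normal intensities.
* Product-ion spectra are attached to 15 % of peaks (typical DDA coverage is
  a small minority of peaks), with random fragments plus a planted
  hexose-loss subset; MS³ spectra follow 30 % of MS² spectra. Spectra are
  structurally plausible, not simulated fragmentation.
* Platform pairs share a configurable fraction of compounds whose target RTs
  are a monotone polynomial warp of the source RTs plus noise; shared
  compounds always appear in the first sample of each platform (a pooled
  reference sample, as a QC mix would be run on both instruments), so anchor
  discovery between the two reference tables sees every shared compound.
* Profile datasets plant exact metabolite/gene pattern pairs with presence
  in `[2, n_species − 2]` among uniform random decoy patterns (resampled if
  they collide with a planted pattern).

Everything is bit-reproducible given the config seed.

What passing tests on this synthetic data do **not** show: robustness to
correlated RT drift across a run, intensity-dependent mass error, in-source
fragments and adduct multiplicity, missing-at-random dropout structure, or
phylogenetic correlation between decoy gene profiles. Real repositories
contain all of these; the generators' defaults describe the clean regime in
which the algorithms are exact, and stress configurations (jitter at the
tolerance boundary, dropout > 0) probe degradation.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run: alignment recovery at 50
samples × 5000 compounds (~14 000 peaks); estimator consistency at 200
samples × 5000 compounds with a 25-sample accumulation grid and 3
replicates; power-law recovery at 10⁵ draws truncated at k = 524; search
oracle equivalence on ≤ 1000 peaks × 100 queries; RT recovery on 300-anchor
platform pairs; co-partition mining at 500 × 500 profiles over 30 species.

## Known limitations

* The alignment is greedy; a pathological intensity ordering can split a
  true group that a global optimizer would keep together. On data whose
  compounds are separated by more than the tolerance this does not occur.
* Percent-of-gradient RT tolerances require the repository's total elution
  time; peak tables loaded without repository metadata can only use minute
  tolerances.
* The cosine uses nominal (integer) bins; isobaric fragments closer than
  0.5 Da merge, which is intended for ion-trap-accuracy data but coarse for
  high-resolution MS/MS.
* `find_copartitioned_pairs` materializes two rectangular integer products;
  at ≫ 10⁴ × 10⁴ profiles a blocked implementation would be needed.
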