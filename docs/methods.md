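# Methods

## The permutation model

A peptide-spectrum match (PSM) pairs one tandem spectrum with one candidate
peptide and is summarized by a vector of match indicators. Under the null
hypothesis of no correct match, the spectrum is treated as having been
produced by an arbitrary residue sequence whose neutral mass lies near the
observed precursor mass; any residue may occupy any position, which
satisfies the exchangeability requirement of a permutation test. The null
distribution of each indicator is therefore estimated by scoring the
spectrum against Monte Carlo draws from the space of sequences: for each
*candidate* peptide (a target-database entry whose neutral mass is within a
12 Da window of an observed precursor mass), k unique sequences of the same
length are drawn with every position sampled i.i.d. uniformly from the
19-letter alphabet in which isoleucine and leucine — identical in neutral
mass — are merged into a single symbol. This is a zero-order Markov model
of peptide sequences.

Draws that equal the candidate, any target entry, or a previously emitted
decoy (all compared after I→L normalization) are rejected and redrawn, so a
finished database holds exactly k × |candidates| unique decoys; the target
database is appended to form the combined search database. Each decoy draws
exactly the current deficit per rejection round — a surplus-then-truncate
scheme would bias the first sequence position toward early alphabet letters
(we observed a chi-square of ~2200 on 18 df before adopting pure
rejection).

The permutation p-value of a target match is the fraction of scored,
collapsed combined-database candidates whose indicator is equal to or
better than the target's, the target's own cluster included — hence never
zero. Its attainable minimum is 1/(collapsed candidates in the precursor
window), which grows linearly with k: detections migrate from the
p < 10⁻² decade at k = 10³ to p < 10⁻⁴ at k = 10⁵.

An important consequence of mass-changing permutation: a decoy's mass
spreads around its length's mean with a standard deviation of roughly
31·√L Da, so for any one spectrum only the decoys (from *all* candidates)
that land inside the 1.5 Da precursor window are comparable. The
per-spectrum denominator is therefore of order (total decoys) × (local mass
density), not k itself, and spectra whose precursor mass falls in a sparse
region of the decoy mass distribution have intrinsically coarser p-values.

## Match indicators

All indicators are computed from +1 b/y fragment ions (water and ammonia
loss variants included for every ion, irrespective of composition; a-, c-,
z- and internal ions are not considered). Fragment matching is a greedy
one-to-one assignment, nearest |Δm/z| first within a 0.3 Da tolerance, ties
broken toward the lower experimental m/z.

* **n_matched** — matched theoretical-ion count (higher better).
* **convolution** — Σ of matched experimental intensities with unit
  theoretical intensities (a dot product). A literal product of intensities
  would be zero whenever any ion misses, so the dot-product form standard in
  X! Tandem is used.
* **hyperscore** — n_b!·n_y!·convolution, the standard two-factorial form.
  Computed with exact integer factorials while the product is representable,
  in log space otherwise; values beyond the double range are reported as
  infinity (they can only belong to near-perfect matches and tie only with
  one another).
* **Sp** — (Σ matched intensities)·(n_matched/n_theoretical)·
  (1 + 0.075·n_consecutive), the classic SEQUEST preliminary score;
  n_consecutive counts adjacent-index matched pairs within one
  (series, loss, charge) ladder.
* **XCorr** — fast cross-correlation: intensities square-rooted, m/z binned
  at 0.3 Da, ten equal windows normalized to 50, background = mean of the
  vector shifted over offsets ±75 bins (offset 0 excluded) subtracted, dot
  product with the unit theoretical vector, scaled by 10⁻⁴.
* **ΔCn** — (XCorr₁ − XCorrᵢ)/XCorr₁ against the best candidate; undefined
  (NaN, flagged missing) when XCorr₁ ≤ 0. Because the best match has
  ΔCn = 0 and worse matches larger values, *lower* is better; its
  permutation p-values then coincide with XCorr's, as expected.
* **λ / Poisson p / E-value** — expected random fragment matches under a
  uniform peak background, λ = n_theoretical_mz · n_peaks_considered ·
  2·tol / (m/z range), clipped below at 10⁻¹²; p = P(X ≥ n_matched) for
  X ~ Poisson(λ); E-value = p × (candidates scored for the spectrum).
  n_peaks_considered is capped at the 40 most intense peaks, a stand-in for
  OMSSA's quartile-based peak filtering. All three are lower-better.

An optional prefilter drops candidates with no theoretical ion within
tolerance of the eight most intense peaks (off by default in the library
pipeline; available for emulating engine behaviour).

## Homeometric collapsing

Distinct database peptides frequently produce indistinguishable matches.
Two records are homeometric when all nine indicators agree after rounding
to 6 *significant* digits and their neutral masses chain within ±1.5 Da
(single linkage; the pairwise definition is made transitive). Each cluster
counts once in the permutation null; a cluster containing a target record
is represented by that target. Significant digits rather than fixed
decimals are essential: Poisson tails span hundreds of orders of magnitude,
and decimal rounding would collapse all of them to zero and tie the target
with unrelated decoys.

## Significance levels

Level t of a result is the largest integer with p < 10⁻ᵗ, pooled at "≥6" —
p = 10⁻³ exactly sits at t = 2. Histograms also report cumulative counts at
the 10⁻² and 10⁻⁴ thresholds.

## Synthetic test-bed

The generator emulates the study system rather than any real acquisition:

* **Target databases** — unique uniform-random sequences over the 19-letter
  decoy alphabet; default lengths lognormal(ln 15, 0.45) clipped to 2–60
  residues, a neuropeptide-like distribution.
* **Ideal uniform spectra** — one peak at every +1 b/y ion including loss
  variants, all intensities equal (100 arbitrary units; the scale cancels
  in rank-based p-values), theoretical m/z values closer than 10⁻⁴ Da
  merged into one peak, precursor set from the peptide.
* **Noisy spectra** — ideal peaks with Gaussian m/z jitter (default
  0.05 Da), a dropped fraction (deterministic rounding of drop_frac·n), and
  uniform-random background peaks with exponential intensities.

What these fixtures do *not* emulate: isotope envelopes, charge-state
errors, chimeric spectra, intensity structure of real fragmentation, or
real neuropeptide sequence composition. Passing tests therefore demonstrate
the statistical correctness and calibration of the permutation machinery,
not identification performance on real acquisitions.

## Reference experiments and problem sizes

* **Decoy-space size** — 19¹⁰ = 6.13×10¹² distinct 10-residue sequences;
  the analytic motivation for Monte Carlo sampling.
* **Database sizes** — 236 synthetic candidates at k = 10³/10⁴/10⁵ give
  exactly 236 000 / 2 360 000 / 23 600 000 decoys. Candidate lengths use
  the lognormal floored at 6 residues: 19⁵ ≈ 2.5×10⁶, so shorter peptides
  cannot supply 10⁵ unique permutations — a hard combinatorial limit of
  the method for very short sequences.
* **Ideal bin shift** — 80 length-12 targets, all used as candidates, five
  spectra generated from the entries with masses nearest the database
  median (representative precursors: decoy coverage near the mass median is
  typical, while tail-mass precursors are exactly the known sparse-decoy
  pathology). At k = 10³ every true peptide reaches p ≤ 10⁻² and at
  k = 10⁵ p ≤ 10⁻⁴ for the counting-family indicators, with modal levels
  t = 2 and t = 4.
* **Null calibration** — 200 spectra generated from random peptides absent
  from a 48-entry database, each assigned the precursor of a database
  peptide; that designated target is exchangeable with the decoys, so its
  permutation p-value is uniform on (0,1]. Uniformity is tested by KS at
  α = 0.001 on the XCorr p-values: XCorr is effectively continuous, whereas
  discrete indicators (n_matched and its Poisson transforms) are calibrated
  only at their attainable atoms — exactly uniform there, super-uniform
  between them — and a continuous-KS test would reject them for reasons
  unrelated to correctness.
* **Composition** — pooled residue counts of ~1.2×10⁶ decoy positions
  tested against uniform(19) by chi-square at α = 0.001.

These sizes keep the complete reference run at a few minutes on one CPU
while leaving order-of-magnitude margins on every acceptance bound.

## Numerical and design choices

* Monoisotopic constants at full reference precision (proton 1.00727646688,
  water 18.0105646863, ammonia 17.0265491015 Da); residue masses from the
  standard monoisotopic table; PTM deltas from standard reference values
  (amidation −0.984016, phosphorylation +79.966331, acetylation +42.010565,
  pyroglutamination of Q −17.026549, methylation +14.015650, sulfation
  +79.956815, oxidation +15.994915 Da).
* Precursor and candidate windows are closed intervals in neutral-mass
  space; spectra with unknown charge are searched at charges 1–4 and
  pooled.
* Variable modifications: at most one per site, at most 3 per peptide
  (max_var, configurable); pyroglutamination only on N-terminal Q,
  amidation only at the C-terminus. With modifications enabled, the
  pre-expansion mass filter widens by the largest total shift any variant
  can carry, then each variant is filtered exactly.
* Product charge default {+1}; configurable.
* MGF dialect: PEPMASS is the precursor m/z (first value used); a missing
  CHARGE defaults to 1+ with a warning. The FASTA reader is strict and
  reports line numbers and offending symbols.
* Determinism: every stochastic step flows from one integer seed through
  numpy Generators; equal seeds give byte-identical FASTA, MGF and TSV
  outputs. Decoy FASTA headers carry candidate id, ordinal and seed.

## Known limitations

* Indicator values are re-implementations of the published scoring forms,
  not bit-compatible reproductions of any engine's output.
* Very short candidates (< 6 residues) cannot support large k; the
  attainable maximum is reported and exceeding it is an error.
* The per-spectrum denominator depends on local decoy mass density;
  precursors in the tails of the decoy mass distribution receive coarser
  p-values (visible in the worked example in the README).
* Single-process execution; the k = 10⁶ scale of the method is supported
  by the data structures but not exercised by the test suite.
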