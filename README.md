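# pepperm

Monte Carlo **k-permuted decoy databases** and **permutation p-values** for
peptide-spectrum matches (PSMs), built for intact-neuropeptide tandem-MS
identification.

## The problem

Neuropeptides are short (typically 3–40 residues) and are detected without
enzymatic digestion. Classic target-decoy FDR estimation struggles here: a
short peptide has few distinct reversals/shuffles, so the null distribution
of decoy scores is coarse and true identifications receive unimpressively
large significance values.

`pepperm` instead treats each PSM as a permutation test. Under the null
hypothesis of no match, the spectrum could have been produced by *any*
residue sequence whose mass is near the observed precursor mass. For every
candidate peptide (a target-database entry within 12 Da of an observed
precursor), the package draws **k unique random sequences of the same
length**, each position sampled i.i.d. uniformly from the 19-letter
isoleucine/leucine-merged alphabet (a zero-order Markov model). The decoys
are pooled, deduplicated against the target database, and the targets are
appended, giving a combined database of exactly `k × |candidates|` decoys
plus targets.

Each spectrum is scored against every combined-database entry within the
1.5 Da precursor window, with re-implementations of the match-indicator
families of the three classic open-source engines:

| family | indicators | direction |
|---|---|---|
| counting / X! Tandem | matched-ion count `n`, convolution `C = Σ I_matched`, hyperscore `H = n_b!·n_y!·C` | higher better |
| SEQUEST / Crux | `Sp = ΣI·(n/n_theo)·(1+0.075·n_consec)`, fast XCorr, ΔCn | higher (ΔCn lower) |
| OMSSA | Poisson mean λ, tail `P(X ≥ n)`, E-value `p·N` | lower better |

Matches indistinguishable across all indicators with masses within ±1.5 Da
("homeometric") are collapsed and counted once. The permutation p-value of
the target match is then

```
p = (# collapsed candidates scoring equal-or-better, target included)
    ─────────────────────────────────────────────────────────────────
                     (# collapsed candidates)
```

which is never zero, and whose attainable minimum shrinks as k grows —
detections migrate from the p < 10⁻² bin at k = 10³ to p < 10⁻⁴ at k = 10⁵.

## Worked example

```sh
pepperm simulate-db --n 200 --length 12 --seed 7 --out target.fasta
pepperm simulate-spectra --db target.fasta --n 3 --seed 7 --out spectra.mgf
pepperm search --db target.fasta --mgf spectra.mgf --k 1000 --seed 7 \
    --truth spectra.truth.tsv --out results.tsv
pepperm report --results results.tsv --indicator n_matched --out hist.tsv
```

The search prints `wrote 27 result rows to results.tsv` (3 spectra × 9
indicators). The matched-ion rows of `results.tsv` read:

```
k     spectrum_id  indicator  n_candidates_collapsed  n_equal_or_better  p_value         t_level
1000  sim_000      n_matched  49                      1                  0.02040816327   1
1000  sim_001      n_matched  187                     1                  0.005347593583  2
1000  sim_002      n_matched  339                     1                  0.002949852507  2
```

and the report prints the significance histogram:

```
   k indicator  t0  t1  t2  t3  t4  t5  t6plus  cum_1e-2  cum_1e-4  total
1000 n_matched   0   1   2   0   0   0       0         2         0      3
```

Every true peptide beat all of its comparable combined-database candidates
(`n_equal_or_better` = 1), so p is exactly one over the collapsed candidate
count. The significance ceiling is set by how many of the k-permuted decoys
land inside each spectrum's 1.5 Da precursor window (49, 187 and 339 here),
not by match quality: `sim_000` sits at t = 1 only because its precursor
mass is in a sparse region of the decoy mass distribution. Raising `--k`
multiplies those denominators and shifts all detections toward smaller
p-values — the defining bin-shift behaviour of the method.

The same machinery is available as a library (`pepperm.score_spectrum`,
`pepperm.spectrum_pvalues`, `pepperm.run_experiment`), and
`pepperm make-decoys` writes combined target+decoy FASTA files usable by
external search engines.

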