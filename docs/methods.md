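# Methods

## 1. Peptide mapping (`histoptm.peptide_map`)

**Coordinates.** All residue positions are 1-based on the mature protein:
the initiator methionine is stripped before digestion, matching the
convention used for histone mark names (H3 K27 is residue 27 of the mature
chain).

**Digestion.** Propionylation of free lysines blocks trypsin at K, so the
effective protease is Arg-C: cleavage after R, suppressed before P.
Peptides with up to `max_missed` (default 2) missed cleavages are
enumerated by concatenating adjacent fully-cleaved segments.

**Mass arithmetic.** Monoisotopic residue masses come from
`pyteomics.mass.std_aa_mass`; water is 18.0105646837 Da. Modification
deltas (Da): ac +42.01057, me1 +14.01565, me2 +28.03130, me3 +42.04695,
ph +79.96633, propionyl +56.02621. Full derivatization adds one propionyl
at the peptide N-terminus and one on every K that is unmodified or
monomethylated (ac/me2/me3 block the ε-amine). `mz(form, z)` uses the
proton mass 1.00727646688.

**Variant discrimination.** The H3 K27–R40 peptide differs between H3.1
(`KSAPATGGVKKPHR`, bare 1432.8263 Da) and H3.3 (`KSAPTTGGVKKPHR`,
1462.8368 Da): a single Ala→Thr replacement, shift 30.0106 Da, identical
modifiable residues — the basis for variant-resolved PTM quantification.

**Protein grouping.** Proteins with identical observable peptide sets are
merged into one group. A group participates in variant quantification only
if it has at least one *unique* peptide (present in no other group). A
truncated variant consisting entirely of shared sequence (the H2A.W.12
situation) is flagged `has_unique_evidence=False` and excluded with a
logged warning rather than silently dropped.

**PSM filtering.** Defaults mirror common search-engine practice: rank 1,
expectation < 0.01, ion score ≥ 30 (boundary inclusive).

## 2. Quantification (`histoptm.quantify`)

Charge states of the same (sample, peptide, modification-set) are summed
(`min_count=1`: a row is missing only if *all* charge states are missing).
Within each sample × peptide-region, form areas are closed to 100%. Missing
cells stay `NaN` through quantification; imputation happens only inside the
statistics layer, where group structure is known.

Variant proportions use unique peptides only, summing over modification
states before averaging, so a variant's share does not depend on how its
PTMs are distributed. Mark-level abundance weights each variant's
within-variant profile by its mixture fraction; a co-modified form (e.g.
`K8ac;K16ac`) counts once toward *each* mark it carries, then mark totals
are renormalized.

## 3. Compositional statistics (`histoptm.compstats`)

**Imputation.** Multiplicative replacement: a missing cell receives
`delta_factor` (default 0.65) × the smallest observed value of that form
within the sample's group, then rows are re-closed. Columns that are
missing everywhere are dropped. Transform functions raise
`MustImputeFirstError` on zeros/NaN — imputation cannot be skipped
accidentally.

**Transforms.** `ilr_transform` uses the sequential-binary-partition basis
(part *i* against all later parts), so for two parts it reduces to
`ln(p/(100−p))/√2`. Inference is invariant to the particular orthonormal
basis (verified by a QR-rotation test). `alr2_log2(p) = log2(p/(100−p))`
is the reporting scale for two-part balances and the scale on which the
generator defines effects.

**Tests.**
- `hotelling_t2`: two-sample Hotelling T² with pooled covariance and the
  exact F reference (df₁ = p, df₂ = nₐ+n_b−1−p). Raises
  `SingularCovarianceError` when the pooled covariance is ill-conditioned
  (cond > 1e12) instead of returning noise. In one dimension it equals the
  squared Student t (verified to 1e-10).
- `anova_tukey`: one-way ANOVA, then Tukey–Kramer HSD implemented directly
  from `scipy.stats.studentized_range` (q = |Δ|/√(MSE/2·(1/n₁+1/n₂)),
  adjusted p = sf(q, k, df_err)); unadjusted p is the Fisher-LSD t test.
  `statsmodels.pairwise_tukeyhsd` is kept as an independent cross-check in
  the test suite (agreement to 1e-6) but is ~4× slower per call, which
  matters for the 1000-replicate calibration tests.
- Compact letter display: build the graph of non-significant pairs and
  letter its maximal cliques (`networkx.find_cliques`), so two groups share
  a letter iff their difference is not significant — the defining property,
  tested exhaustively for 3–5 groups against a brute-force clique cover.

## 4. Compensation model (`histoptm.compensation`)

The pure-exchange null: a mutant's expected abundance of mark *m* on
variant *v* is `f_v(mutant) × WT_profile_v(m)`, where `f_v` comes from the
measured mutant H3.1:H3.3 ratio via `r → (r/(1+r), 1/(1+r))`. Expected
cells close to 100% by construction. `compensation_delta` reports
found − expected with an up/down/none call at `tolerance` (default 0.5
percentage points — a reporting threshold, not a significance test; formal
inference belongs to the log-ratio tests of §3).

## 5. Localization tests (`histoptm.localization`)

Counts are reconstructed from published percentages by rounding
`percent/100 × n` and validated against n. The test is the exact two-sided
*minimum-likelihood* binomial test: p = Σ pmf(j) over all j with
pmf(j) ≤ pmf(k)·(1+1e-7); the relative tolerance guards against floating
tie-breaking and matches `scipy.stats.binomtest` (cross-checked to 1e-9,
plus an exhaustive enumeration oracle for n ≤ 50). The null `p0` is the
*observed* reference-genotype frequency treated as fixed — a convention
recorded in the output's `note` column, since it ignores sampling error in
the reference sample (see Limitations).

Headline values: chromocenter-positive nuclei, k = 5 of n = 31 vs
p0 = 18/22 → p = 3.66e-15; intranucleolar foci, k = 11 of 31 vs p0 = 4/22
→ p = 0.018859.

## 6. Synthetic generator (`histoptm.synthetic_data`)

A compact FASTA of 9 synthetic histone entries preserves the structural
features the pipeline must handle: the H3.1/H3.3 discriminating region,
H2A.Z paralogs with shared flanks and unique cores, H2A.W paralogs
including a truncated entry with *no* unique peptide, and H4.

Ground truth per genotype: variant mixtures (e.g. WT H2A.Z 67/7/25;
H3.1:H3.3 ratios WT 3.0, *fas1* 0.8) and within-variant form profiles that
must close to 100% (`ConfigError` otherwise). Per sample, each form's area
is `scale × variant fraction × form fraction × lognormal(1, cv)`
(σ² = ln(1+cv²) so the noise mean is exactly 1), split over charges 2+
(0.7) and 3+ (0.3), then censored MCAR at `missing_rate` and/or by a
low-area quantile. Treatment effects are *exact* shifts on the alr2-log2
scale, applied sequentially through odds so the target form's balance moves
by precisely the stated amount.

Defaults (cv = 0.2, n = 6, missing = 0.02) were chosen from the generator's
own behavior — noiseless runs reproduce truth to 1e-9, and at these
settings estimator RMSE decreases with replicates as expected — not from
any test threshold.

## 7. Pipeline (`histoptm.workflow`)

A YAML config is validated strictly: unknown keys are rejected by name,
defaults are filled and logged, paths must exist, α ∈ (0,1). Stages
(map → quantify → compare → compensate → localize) write TSVs plus a
`manifest.json` with a config hash and per-stage status/row counts; any
failure writes a `FAILED` marker and the manifest records which stage
failed. Reruns of the same config produce byte-identical outputs.

`compare` uses the genotype design (ANOVA + Tukey on the control arm) or,
with `grouping: treatment`, per-genotype two-condition t tests — both on
imputed, alr2-transformed balances, skipping regions with a single form.

## 8. Acceptance verification

`tests/test_acceptance.py` holds one test (or test class) per headline
property; all oracle values were computed and frozen before implementation:

1. 30.0106 Da H3.1/H3.3 mass shift, stable under shared modifications.
2. Chromocenter depletion binomial p < 0.05 (p = 3.66e-15).
3. Intranucleolar enrichment p = 0.018859 < 0.05.
4. Oracle equivalences: ilr/alr vs closed formulas (1e-10), Hotelling ≡ t²
   in 1-D (1e-10), binomial ≡ exhaustive enumeration for all n ≤ 50,
   Tukey letters ≡ brute-force clique cover.
5. Type-I error of the t, ANOVA+Tukey-family, and Hotelling tests within
   [0.03, 0.07] at α = 0.05 (n = 6/group, 1000 replicates, fixed seeds).
6. Parameter recovery over 200 simulated studies: mean H2A.Z proportions
   within ±2 points, H3.1:H3.3 ratios within ±0.15 of truth.
7. Pure-exchange null: with mutant profiles set equal to WT and cv = 0,
   found = expected to 1e-9 end to end.
8. All compositions close to 100 ± 1e-9; scaling one sample's areas by 10⁶
   changes no percentage and no test p-value.

`scripts/acceptance.py` recomputes targets 2–3 from the published
percentages alone and writes them as JSON.

## Open design decisions

- **Reference frequency as fixed null.** A two-sample exact test
  (Boschloo/Fisher) would propagate reference uncertainty; the fixed-p0
  binomial is used because it matches the original analysis convention and
  is stated in the output.
- **Imputation delta.** 0.65 follows the common multiplicative-replacement
  recommendation; results should be (and in our checks are) insensitive
  within 0.5–1.0.
- **Compensation tolerance.** 0.5 points is a descriptive cutoff for the
  direction call only.

## Limitations

- The generator simulates peak areas *after* identification: search-engine
  errors, co-elution, and isotope interference are out of scope.
- Lognormal noise is independent across forms; real co-eluting forms have
  correlated errors, so calibration on real data may differ.
- The binomial localization test conditions on the reference frequency.
- Missed-cleavage peptides are mapped but the quantifier expects areas
  reported on consistent peptide regions; mixed region definitions across
  samples are rejected, not reconciled.
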