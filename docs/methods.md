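# Methods

## The problem

Label-free spectral counting attributes to each protein, in each LC–MS/MS
run, the number of peptide-spectrum matches it received; this count is a
proxy for abundance. Comparing two species requires (a) deciding which
proteins correspond across the species' sequence databases and (b) a count
model tolerant of the strong overdispersion typical of spectral counts.
`orthospec` implements both for a balanced 2 species × 2 treatments × n
replicates design (default n = 5, matching the well-watered / water-deficit
contrast the package is built around).

## Ortholog mapping

Input is standard 12-column tabular alignment output for both query
directions (every sorghum protein against the maize database and vice
versa). Processing per direction:

- discard hits with bit score < 50 (the floor is inclusive: 50.0 survives;
  "minimum of 50" is read as ≥ 50);
- per query, retain the single highest-scoring survivor. Bit-score ties are
  broken by lower e-value, then lexicographically smaller subject accession.
  Ties are vanishingly rare in real alignment output; the rule exists so
  runs are deterministic.

The two directed maps combine in one of two modes. `directional-union`
(default) accepts a pair named by either direction; `reciprocal` requires
both directions to agree and is the field's stricter convention for
one-to-one orthology. Reciprocal pairs are provably a subset of union pairs,
and the tests enforce that. The union default deliberately tolerates
asymmetric best hits, because those asymmetries are exactly what produces
split rows downstream (next section); the reciprocal option is there for
users who prefer precision over recall.

## Row alignment and split merging

Each species' count table is keyed by its own accessions. A count row is
attached to the map pair that its *own* query direction names (a maize row
follows the forward best hit, a sorghum row the reverse one); among several
same-direction candidates the highest supporting bit score wins. One joint
row per pair results, carrying a maize vector and a sorghum vector; a pair
whose partner contributed no counts is kept one-sided (all-zero partner
vector) and flagged rather than dropped — the ≥10-spectra filter downstream
governs its fate. Rows whose accession appears nowhere in the map are
excluded and tallied.

When the forward and reverse best hits of one biological pair disagree on
the representative accession (a paralog family collapsed differently in the
two species), alignment yields two one-sided rows. `merge_split_rows`
connects rows that share an accession or that a map pair links across, and
combines each connected group by per-sample addition, preserving provenance.
Per-sample totals are invariant under the merge, the operation is
idempotent, and on synthetic fixtures the matched-row gain equals the number
of planted splits exactly. A group containing two rows that each already
carry both species' counts is an ambiguous many-to-many configuration and is
an error, not a silent sum.

Match statistics partition the input rows into: no ortholog named; named in
the map but never matched; matched at alignment; and cross-identified (rows
matched only through a merge). Percentages are integers (round half up) of
the total entry count, and the merge improvement is reported as
round(100·(after − before)/before).

## The count model

Each joint row's 4n counts are modelled as quasi-Poisson:

    log E[y] = β0 + β_species·I[sorghum] + β_treatment·I[WD],  Var[y] = φ·E[y]

- **Estimation.** Poisson log-link maximum likelihood via iteratively
  reweighted least squares; convergence at 1e-8 on the coefficient change,
  at most 100 iterations. No ad-hoc constants are added to the data; a
  complete separation (an all-zero design cell) leaves that contrast without
  a finite MLE and the fit is flagged instead.
- **Dispersion.** φ̂ = Pearson X²/(n − p). It is reported as computed (a
  saturated constant fit legitimately yields φ̂ = 0) and floored at 1e-12
  only inside the standard-error product, to keep SEs finite.
- **Inference.** SE = sqrt(φ̂·[X'WX]⁻¹ diag); two-sided p-values from the t
  distribution with n − p degrees of freedom, the conventional
  quasi-likelihood reference (normal-based p-values would be anti-
  conservative at n = 20).
- **Multiplicity.** Benjamini–Hochberg step-up per term across proteins —
  the species column and the treatment column are adjusted separately,
  mirroring a report with one q-value column per term. Significance is
  strict: q < α (default 0.05); q = α is not a call.
- **Model form.** The model is additive by default (no species×treatment
  interaction; available via `interaction=True`). Consequently the report's
  per-species log2 fold changes are computed descriptively from replicate
  means, log2((mean_WD + c)/(mean_WW + c)) with pseudocount c = 0.5
  (configurable), not from coefficients — one fitted treatment effect cannot
  yield two species-specific fold changes. A species with no identified
  counts gets an undefined (NaN) fold change, never a fabricated zero.
- **Normalisation.** None by default (spectral-count tables from a balanced
  acquisition are typically analysed raw); a log total-count offset per
  sample is available (`offset="total"`).
- **Filtering.** Rows with a grand total below 10 spectra (both species, all
  samples, boundary inclusive) carry too little information for a 3-parameter
  count model and are removed before fitting.

## Physiology

- RWC = 100·(FW − DW)/(TW − DW); TW ≤ DW is an error, FW outside [DW, TW] is
  physically implausible and warns but returns.
- Proline: the standard curve (absorbance = slope·conc + intercept) is fitted
  by OLS on ≥ 3 distinct L-proline concentrations, with a warning below
  r² = 0.98. Content in µmol per g fresh weight is
  (A520 − intercept)/slope · V_toluene · (V_extract/V_aliquot) / m_tissue,
  with defaults from the assay geometry (0.5 mL extract, 0.1 mL aliquot,
  1.0 mL toluene, 0.1 g tissue — a 50-fold overall factor). Every volume and
  the mass are explicit parameters, and the conversion formula is written
  into the output header, because unit-conversion chains are where such
  assays silently go wrong.
- Group comparisons: one-way ANOVA (F, p) plus Tukey–Kramer pairwise tests
  (studentised range, unequal-n form, via `scipy.stats.tukey_hsd`). Letters
  use the standard maximal-clique cover of the non-significance graph,
  cliques ordered by descending group mean, ties by label; groups sharing no
  significant difference share a letter. All-zero within-group variance
  makes the studentised range undefined; the result is flagged degenerate
  and letters fall back to exact mean equality.

## The synthetic-data generator

The generator emulates the study conditions, not arbitrary data:

- **Design.** 2 species × 2 treatments × 5 replicates by default.
- **Counts.** Negative binomial with mean μ from the log-linear model above
  and variance φμ (size μ/(φ−1), success probability 1/φ; φ = 1 degenerates
  to Poisson). The fitted model is quasi-likelihood and agnostic to the
  generative law; NB is the standard overdispersed choice. Defaults:
  baseline mean 8 spectra (a realistic per-protein count for a single-run
  label-free experiment), dispersion φ = 2, species effects
  N(0, 0.5·ln 2) on the natural-log scale, treatment log2 fold change 2 on a
  10% subset.
- **Databases and alignments.** Accessions follow the GRMZM*/Sobic.* styles;
  ortholog partners share mutated copies of one random amino-acid sequence;
  orphans are species-private and draw either no hit or a sub-threshold one
  (bit score < 50); true pairs draw bit scores in (80, 300); optional decoy
  second-best hits score strictly below the true hit, so exact map recovery
  is a testable property.
- **Paralog splits.** A split pair adds one maize paralog accession; the
  forward hit departs from the count-bearing maize accession while the
  reverse hit targets the paralog, which is precisely the asymmetry that
  produces two one-sided rows at alignment. The per-sample sum of the two
  split rows equals the latent joint counts.
- **Physiology.** Planted cell means encode the drought phenotype (maize RWC
  95 → 65% under deficit, sorghum 94 → 88%; proline up ~60%/50%); weights
  are derived from the planted RWC so DW ≤ FW ≤ TW holds by construction,
  and absorbances come from a known standard line (slope 10 per µmol/mL,
  intercept 0.02). A single `noise` scale multiplies every perturbation;
  at 0 the truth round-trips exactly.
- **Seeding.** One seed fans out through fixed `SeedSequence` sub-streams
  per generator function, so each generator is reproducible standalone and
  identical configs give byte-identical output files.

What the generator does *not* emulate — peptide-level identification,
protein inference, shared peptides, run-to-run depth variation, missing-row
mechanisms correlated with abundance — bounds what passing tests show:
they validate the mapping/merging logic, the estimator's calibration, and
FDR control under the stated generative law, not robustness to
identification artefacts in real data.

## Operating characteristics (computed by the suite and the script)

- Empirical FDR: with 2000 proteins per experiment (90% null, 10% at log2FC
  2, φ = 2, n = 5) over 20 seeded repetitions, the mean false-discovery
  proportion among treatment q < 0.05 calls is compared against the nominal
  5% plus two Monte-Carlo standard errors. `scripts/acceptance.py` reports
  this quantity in percent.
- Coefficient recovery: the mean fitted treatment coefficient over planted
  non-null pairs (500 proteins, effect ln 4) is checked within 3 Monte-Carlo
  SE of truth.
- Oracle equivalence: best-hit retention and the BH step-up rule are checked
  against brute-force reimplementations on 1000 random instances each, and
  the quasi-Poisson fit against an independent GLM implementation
  (statsmodels, scale = Pearson X², t reference) — the production code never
  calls it.

Problem sizes in the default test run (thousands of 20-observation fits,
hundreds of small simulations) were chosen so the whole suite completes in
about a minute while leaving the Monte-Carlo checks enough repetitions to be
meaningful.

## Known limitations

- The additive model pools both species in one regression; a genuinely
  species-specific treatment response is only partially captured without the
  interaction term (off by default, available as an option).
- One-sided joint rows are fitted with an all-zero partner side; their
  species contrast is separated and flagged, and they survive only if their
  one-sided total passes the spectra filter.
- BH is applied within each term independently; no cross-term dependency
  adjustment is attempted.
- Quasi-likelihood t-inference at n = 20 is approximate; the FDR simulation
  is the package's evidence that the approximation is adequate at the
  default design size.
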