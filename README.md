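# orthospec

Cross-species differential proteomics from label-free spectral counts.

When two related species (here maize, *Zea mays*, and sorghum, *Sorghum
bicolor*) are profiled by LC–MS/MS under contrasting conditions (well-watered
vs water deficit), their protein identifications live in different sequence
databases and cannot be compared directly. `orthospec` implements the
comparison pipeline for this setting:

1. **Ortholog mapping** — from blastp-style tabular hits in both query
   directions, apply a bit-score floor of 50 and retain, per query, only the
   highest-scoring hit; combine the two directions into a maize↔sorghum
   ortholog map (directional union by default, strict reciprocal best hits
   as an option).
2. **Count-row alignment and merging** — align each species' spectral-count
   rows on the map into joint ortholog rows; when a pair's maize and sorghum
   spectra land in different rows (paralog splits), merge them by per-sample
   addition with provenance; proteins without orthologs are excluded and
   tallied in match statistics.
3. **Differential abundance** — filter rows below 10 total spectra, then fit
   each ortholog's counts y with a quasi-Poisson regression,

   log E[y] = β₀ + β_species·I[sorghum] + β_treatment·I[WD],

   estimated by IRLS with dispersion φ̂ = Pearson X²/(n−p), Wald t-tests
   (df = n−p), Benjamini–Hochberg adjustment per term across proteins, and
   q < 0.05 significance calls; per-species log2 fold changes (WD vs WW, with
   a 0.5 pseudocount) are reported descriptively.
4. **Physiology** — relative water content RWC = 100·(FW−DW)/(TW−DW), proline
   quantification from A520 via an L-proline standard curve and the assay's
   dilution chain, and one-way ANOVA with Tukey–Kramer compact-letter
   groupings.

A seeded synthetic-data generator (`orthospec.synthdata`) emulates the whole
study design — paired protein databases with orphans and paralog splits,
two-direction alignment tables, negative-binomial counts with quasi-Poisson
variance φμ, and physiology tables — with recorded ground truth, so every
stage is testable end to end without external data.

## Worked example

```python
from orthospec.pipeline import PipelineConfig, run_all
from orthospec.synthdata import SimConfig

cfg = PipelineConfig(
    outdir="example_run",
    seed=7,
    sim=SimConfig(n_ortholog_pairs=30, n_paralog_split_pairs=3,
                  n_orphans_per_species=5, frac_treatment_de=0.3, seed=7),
)
print(run_all(cfg).report)
```

prints

```
seed: 7
config_hash: 9e038c6e1fa0

match statistics:
                            category  count  percent
                       total entries     76    100.0
                   no ortholog named     10     13.0
             named in map, unmatched      0      0.0
matched in both species at alignment     60     79.0
      cross-identified via row merge      6      8.0
           matched rows before merge     30      NaN
            matched rows after merge     33      NaN
               merge improvement (%)     10      NaN

orthologs tested (>= 10 spectra): 33
significant for species (q < 0.05): 4
significant for treatment (q < 0.05): 11
significant for both terms: 1

physiology group summary:
 metric      group  n      mean       se letter    anova_F      anova_p
    rwc   maize_WD  5 64.895863 0.708608      c 337.517645 1.136765e-14
    rwc   maize_WW  5 94.440215 0.790329      a 337.517645 1.136765e-14
    rwc sorghum_WD  5 88.414242 0.727697      b 337.517645 1.136765e-14
    rwc sorghum_WW  5 95.611186 0.878704      a 337.517645 1.136765e-14
proline   maize_WD  5  3.282949 0.114523      a  46.467982 4.017561e-08
proline   maize_WW  5  2.032857 0.048780      b  46.467982 4.017561e-08
...
```

Reading the report: of 76 simulated protein entries, 10 (the orphans) had no
ortholog and were excluded; the 3 planted paralog splits were rejoined by the
merge step (30 → 33 matched rows, +10%). Of the 33 tested orthologs, 11 were
called for the treatment term and 1 for both terms at q < 0.05. The
physiology block shows the planted drought phenotype: maize leaf RWC drops
from ~94% to ~65% under deficit (letters a vs c) while sorghum largely holds
(a vs b), and proline rises in both species. The same stages are available on
the command line (`orthospec simulate|orthomap|merge|de|physio|run-all|validate
--config config.yaml`); identical config and seed reproduce every output file
byte for byte.

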