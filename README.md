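# polyqmod

Genetic-modifier analysis of **age at onset (AAO) in polyglutamine
diseases** — Huntington's disease and the spinocerebellar ataxias SCA1, 2,
3, 6, 7 and 17. Longer expanded CAG repeats mean earlier onset, but repeat
length leaves a substantial residual that is partly heritable; candidate
SNPs (e.g. in DNA-repair genes) can be tested as modifiers of that
residual. `polyqmod` is for statistical geneticists who want that analysis
as a reusable, tested pipeline rather than a one-off script.

## What it computes

1. **Onset residualization.** Per disease, OLS of ln(AAO) on the expanded
   repeat length, `ln(AAO) = A + B·CAG`; each subject's residual is
   observed AAO minus the expected onset `exp(A + B·CAG)` (years scale;
   a log-scale option is provided).
2. **Per-SNP association.** Within each of eight disease groups (HD+SCAs,
   HD, all SCAs, SCA1/2/3/6/7), OLS of residual AAO on effect-allele
   dosage, with two-sided and direction-aligned one-sided p-values
   (`p_one = p_two/2` when the slope matches the reference-study
   direction, else `1 − p_two/2`).
3. **LD-aware combination (Brown's method).** Per group, the panel's
   p-values are combined with `X = −2·Σ ln p` referred to a scaled
   chi-square `c·χ²_f` whose moments absorb the covariance between
   correlated tests, `δ(ρ) = 3.263ρ + 0.710ρ² + 0.027ρ³` with
   `ρ_ij = d_i d_j r_ij` (one-sided) or `r²_ij` (two-sided) — Fisher's
   method exactly when the panel is independent. Bonferroni tiers
   `0.05/(SNPs·groups)`, `0.05/SNPs`, `0.05/groups`, plus sensitivity
   re-analyses (drop high-LD proxies with r² > 0.8; drop the top SNP).
4. **QC.** Exact Hardy–Weinberg test on the pooled cohort, exclusion at
   p < 0.001; call rate and MAF reported.
5. **Polygenic onset score.** `S = Σ w_s·dosage_s` with reference-study
   weights in years per allele, quartile summaries of residual AAO, and
   the variance explained (R²).

A **synthetic-cohort generator** reproduces the analysis' assumptions —
seven diseases with their cohort sizes, onset laws and CAG ranges, LD
blocks with proxy pairs at r² > 0.8, assay-realistic missingness, and
optional additive modifier effects — so the whole pipeline is testable
without patient data. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
import numpy as np
from polyqmod import ModifierAnalysis
from polyqmod.simulate import study_config, simulate_cohort

# study-scale cohort (1,505 subjects, 22-SNP panel) with two true
# modifiers: +1.4 and -1.0 years of onset shift per effect allele
eff = np.zeros(22); eff[3] = 1.4; eff[7] = -1.0
cohort = simulate_cohort(study_config(seed=2026, effect_sizes=eff))

res = ModifierAnalysis(cohort.genotypes, cohort.phenotypes, cohort.priors).fit(seed=2026)
print(res.summary())
```

Abridged output:

```
Combined SNP-set association (Brown's method)
group     flavor        k         X       c       f   p_combined  sig@0.05/8
HD+SCAs   one_sided    22    83.140   1.004   43.82     0.000339         yes
HD+SCAs   two_sided    22    67.797   1.244   35.36       0.0209          no
HD        one_sided    22    66.180   1.004   43.82       0.0171          no
...
Single-SNP Bonferroni tiers: p < 0.000284 (all groups), p < 0.00227 (per group)
snp       gene    group          beta      p_two  concordant  tier
snp004    GENE4   HD+SCAs       1.672   1.98e-05        True     1
snp004    GENE4   HD            1.790   0.000793        True     2
...
Polygenic onset score: R^2 = 0.0061 of residual-AAO variance; 1283 imputed dosages
quartile       n   median residual
Q1           377             -0.90
Q4           376              0.53
```

Reading it: pooling every disease, the one-sided (direction-aligned)
combination of all 22 SNPs is significant after correcting for the eight
disease groups (p = 3.4×10⁻⁴ < 0.05/8) while the undirected test is not —
the gain comes from effects pointing the way the reference study said they
would. The injected +1.4-year SNP is recovered with β = 1.67 years/allele
at the strictest single-SNP tier, and subjects in the top score quartile
have onset ~1.4 years later than expected relative to the bottom quartile.

The same run is available from the shell:

```bash
polyq-modifier run --config examples/study_null.yaml --out-dir polyq_run
```

with stage subcommands (`simulate`, `qc`, `residualize`, `assoc`,
`combine`, `score`) operating on the TSV hand-offs in the output
directory, and a `manifest.json` recording config, seed, checksums and
warnings.

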