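# connmanova

Multivariate group inference for parcel-wise brain metrics: does sex,
diagnosis, or their **interaction** shape regional brain structure?

The package implements the complete four-step MANOVA/CCA workflow used in
case-control neuroimaging studies of the sex disparity in autism spectrum
disorder (ASD): five regional metrics (cortical area, thickness, mean
curvature, gray-matter volume and white-matter connectivity density, CD) are
measured over a whole-brain parcel atlas (165 parcels by default) in a 2x2
sex-by-diagnosis cohort, and the question is which metric - and ultimately
which brain regions - carry a sex-by-diagnosis interaction. It ships with a
synthetic multi-site cohort generator so every operating characteristic of
the workflow (type-I error, power, region recovery) can be measured by
simulation, plus demographic comparisons (Welch's t, chi-square) and a CLI.

## The model

For each metric, the subjects x parcels response matrix **Y** (N = 193,
p = 165 by default) is regressed on a fixed-effects design
**X** = [1, sex, dx, sex*dx] with sex and diagnosis coded +/-1, so q = 3
predictors. From the least-squares fit,

    E = (Y - XB)'(Y - XB)          (error SSCP,     v_E = N - q - 1)
    H = T - E                      (hypothesis SSCP, v_H = q)

with T the total SSCP about the column means. The omnibus statistic is
Wilks' Lambda = det(E) / det(E + H), transformed to an approximate F by
Rao's formula

    t  = sqrt((p^2 v_H^2 - 4) / (p^2 + v_H^2 - 5)),
    w  = v_E + v_H - (p + v_H + 1)/2,
    d1 = p v_H,     d2 = w t - (d1 - 2)/2,
    F  = ((1 - L^(1/t)) / L^(1/t)) * d2 / d1,

which at the default dimensions gives the familiar F with (495, 76) df.
The four steps are:

1. **Omnibus** Wilks/Rao test per metric, BH-FDR across the five metrics;
   only rejected metrics advance.
2. **Predictor leave-one-out** (regression frame): partial
   Lambda_j = Lambda(full)/Lambda(without predictor j), converted by the
   exact transform F = ((1-L)/L) (v_E - p + 1)/p with (p, v_E - p + 1) df.
3. **Predictor leave-one-out** (CCA frame): canonical correlations r_k
   between Y and X via whitening + SVD; Lambda = prod(1 - r_k^2) is
   identical to the determinant ratio, so Steps 2 and 3 give the same
   inference by two routes.
4. **Response leave-one-out**: for every parcel, partial
   Lambda = Lambda(p)/Lambda(p-1 without the parcel), converted by
   F = ((1-L)/L) (v_E - p + 1)/v_H with (v_H, v_E - p + 1) df, then BH-FDR
   across parcels - a region-wise map of the interaction.

Before inference, every measure is normalized by the subject's total
intracranial volume (TICV), and age, acquisition site, cognitive ability
(DAS) and their interactions are partialed out. The package accounts for
the error degrees of freedom consumed by that projection (and projects the
predictors accordingly) by default; see `docs/methods.md` for why.

## Worked example

Simulate a study-sized cohort with an interaction of one noise-sd planted
on 22 temporal/parietal parcels of the CD panel, then run the pipeline:

```bash
connmanova simulate --seed 11 --delta 1.0 --out demo/data
connmanova run --data-dir demo/data --out demo/results
# advanced metrics: ['CD']
# wrote 8 files to demo/results
```

`demo/results/step1_omnibus.tsv` shows the omnibus tests (only CD survives
the metric-level FDR):

```
metric      wilks      f       p          p_adj     reject
area        2.3e-04    0.957   0.598      0.598     False
thickness   1.4e-04    1.157   0.321      0.401     False
curvature   1.0e-04    1.286   0.199      0.331     False
volume      2.3e-04    0.961   0.591      0.598     False
CD          2.9e-06    4.345   3.3e-06    1.6e-05   True
```

`step2_predictor_loo_CD.tsv` attributes the CD effect to the interaction,
not to either main effect:

```
predictor    partial_f   df1    df2   p          reject
sex          1.983       165    10    0.115      False
diagnosis    1.202       165    10    0.401      False
interaction  32.312      165    10    7.3e-07    True
```

`step3_cca_loo_CD.tsv` repeats the attribution in the CCA frame (identical
partial Lambdas), and `step4_region_loo_CD.tsv` ranks the 165 parcels by
their partial-F contribution to the interaction. The report directory also
contains the demographics table, the quadratic-age screen, `report.json`
(with provenance: seed, config hash, versions) and a hash manifest; a rerun
with the same seed and config is byte-identical.

The same analyses are available as library calls (`run_pipeline`,
`omnibus_step1`, `predictor_loo_step2/3`, `response_loo_step4`,
`MultivariateManova`, `CanonicalCorrelation`, ...), and the generator as
`default_paper_spec` / `generate_dataset`.

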