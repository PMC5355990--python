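# histotype

Gene-expression classification of invasive lobular (ILC) versus invasive
ductal (IDC) breast carcinoma.

Histopathologic subtyping of breast tumors is imperfect: lobular and ductal
carcinomas overlap morphologically, diagnoses vary between pathologists, and
misclassification matters because the subtypes differ in prognosis and
treatment response. `histotype` implements, as a reusable and fully tested
pipeline, the development and validation of a molecular ILC/IDC classifier
from multi-cohort bulk expression data:

1. **Batch adjustment** — per-gene mean centering within each cohort.
2. **Structure assessment** — consensus clustering (k = 2..7) with
   CDF/delta-area curves to gauge how many stable expression clusters the
   cohorts contain.
3. **Feature reduction** — a nearest shrunken centroid classifier
   (soft-thresholded standardized centroid deviations
   d'_ik = sign(d_ik)·max(|d_ik| − Δ, 0)); cross-validation picks the
   largest Δ whose lobular-class error stays within one standard error of
   the best, yielding the working gene set.
4. **Signature selection** — elastic-net regularized logistic regression
   (penalty λ[α‖β‖₁ + (1−α)/2‖β‖₂²], α = 0.5 by default) on the working
   set; 10-fold cross-validated binomial deviance selects λ; the nonzero
   coefficients are the signature.
5. **Scoring and calibration** — each sample's lobular score is the Pearson
   correlation r between its standardized signature-gene expression and the
   coefficient pattern. The optimal cutoff c* minimizes misclassifications
   over the discovery samples; cutoffs statistically indistinct from c*
   (two-proportion Z test) form a band [c_lo, c_hi]; under the **strict**
   model, samples scoring inside the band are called *indeterminate*.
6. **Evaluation** — concordance with pathology (all calls vs called-only),
   grade cross-tabulation, Kaplan–Meier / logrank / Cox comparison of
   predicted classes, single-marker (CDH1-like) negativity via a
   two-component Gaussian mixture, and correlation of cell-line lobular
   scores with drug sensitivities (−log10 GI50) tested per compound class.

Because the original tumor cohorts are external, the package ships a
synthetic-data generator (`histotype.simulate`) that reproduces the study's
statistical structure — multiple cohorts with batch shifts, ~11% lobular
prevalence, class-informative genes, a bimodal CDH1-like marker (low in 45%
of lobular vs 5% of ductal tumors), class-skewed grades, class-linked
survival, and a cell-line panel with class-coupled drug sensitivities — so
every stage is exercisable end to end.

## Worked example

```python
import histotype as ht

# 3 discovery + 3 validation cohorts, 200 samples each, 11% lobular
spec = ht.SimulationSpec(n_cohorts=6, n_per_cohort=200, seed=7)
X, clinical, truth = ht.simulate_cohorts(spec)

disc = [s for s, c in zip(X.sample_ids, X.cohort)
        if c in ("cohort1", "cohort2", "cohort3")]
val = [s for s in X.sample_ids if s not in set(disc)]
labels = clinical.set_index("sample_id").loc[disc, "histology"].to_numpy()

art = ht.train_classifier(X.subset_samples(disc), labels, ht.RunConfig(seed=7))
clf = art.classifier
print(len(art.working_genes), len(clf.genes))
print(round(clf.cutoff, 3), tuple(round(b, 3) for b in clf.band))

calls = ht.score_cohorts(clf, X.subset_samples(val))
rep = ht.concordance_report(calls, clinical)
print(round(rep.plain_concordance, 4), round(rep.strict_concordance, 4),
      round(rep.indeterminacy_rate, 4))
```

prints

```
28 28
0.458 (0.293, 0.624)
0.9717 0.9963 0.1033
```

The shrunken centroid reduced 2000 genes to a 28-gene working set, all of
which survived the elastic net as the signature. The optimal score cutoff is
0.458 with a strict band of [0.293, 0.624]. Scoring the three held-out
cohorts as measured (batch shifts intact) gives 97.2% concordance with the
simulated histology over all calls, rising to 99.6% when the 10.3% of
samples scoring inside the band are excluded — abstention concentrates on
exactly the samples the score cannot place. See `docs/methods.md` for what
the generator does and does not emulate.

The same classifier can score a simulated cell-line panel and test drug
classes for sensitivity shifts:

```python
panel_X, gi50, classes, _ = ht.simulate_cell_panel(
    60, 1000, 10, coupling=0.8, seed=7, truth=truth)
scores = ht.score_panel(clf, panel_X)
panel = ht.DrugPanel.from_tables(gi50, classes)
shift = ht.class_shift_test(ht.compound_correlations(scores, panel),
                            panel.class_map)
top = shift.iloc[0]
print(top["class"], int(top["n_compounds"]), round(float(top["mean_r"]), 3))
```

prints

```
sensitive_class 20 0.693
```

## Command-line interface

Every stage is also a subcommand: `histotype simulate | simulate-panel |
consensus | reduce | fit | calibrate | score | evaluate | mixture |
drugcorr`, with global `--seed` and `--out` options. For example:

```bash
histotype --seed 7 --out data simulate
histotype --seed 7 --out work reduce data/expression.tsv data/clinical.tsv \
    --cohorts data/cohorts.tsv
histotype --seed 7 --out work fit data/expression.tsv data/clinical.tsv \
    work/working_genes.txt --cohorts data/cohorts.tsv
histotype --seed 7 --out work calibrate work/classifier.json \
    data/expression.tsv data/clinical.tsv --cohorts data/cohorts.tsv
histotype --seed 7 --out work score work/classifier.json data/expression.tsv \
    --cohorts data/cohorts.tsv
histotype --seed 7 --out work evaluate work/scores.tsv data/clinical.tsv
```

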