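# tumorclass

Tools for classifying tumor growth responses in untreated preclinical
cohorts and for building cross-species T cell exhaustion gene signatures.

## The problem

When an immunogenic tumor line (e.g. an ovalbumin-expressing MC38 clone) is
implanted into immunocompetent mice without any treatment, the cohort splits
into three behaviours: tumors that keep growing (**non-responsive**), tumors
that shrink and stay small (**regressing**), and tumors that shrink but then
stall or regrow — the hallmark of T cell **exhaustion** in the tumor. With
no treated/control contrast available, the classification has to be built
from the cohort itself.

`tumorclass` implements that workflow end to end:

1. **Pseudo-control band.** Tumor areas (cm², length × width) are converted
   to mm² (× 100; undetectable tumors floored at 1 mm² so log10 is defined).
   Each animal is ranked by the trapezoid area under its growth curve (AUC),
   and the top quartile — the fastest growers — becomes the pseudo-control
   population. A two-stage model (non-linear mean curve on the log10 scale,
   then empirical residual quantiles) yields a band containing the central
   75% of control observations up to day 17.
2. **Responder rules.** A measurement is a *responder point* when it falls
   strictly below the band's lower bound. An animal with ≥ 3 measurements
   from day 10 is a *responder* when ≥ 2 of those points are responder
   points **and** the final measurement is one; otherwise it is
   non-responsive. Responders split by the OLS slope of log10 area on day
   (day ≥ 10): significantly negative (two-sided t-test, p < 0.05) →
   *regressing*, the rest → *exhausted*.
3. **Exhaustion signatures.** Differential-expression tables for the
   in vitro exhausted-vs-activated and in vivo TIL-vs-activated contrasts
   are thresholded (FDR ≤ 0.01, |log2FC| ≥ 2), intersected by direction
   into the *experimental signature*, mapped to human orthologs, intersected
   with a human exhausted-cluster gene list into the *exhausted signature*,
   and filtered for transcription factors.
4. **Over-representation.** Gene sets (GMT) are scored with the
   hypergeometric upper tail P(X ≥ k) against a fixed universe
   (default N = 42 739, the MSigDB mouse gene total), BH-adjusted at
   FDR 0.01 and ranked by fold enrichment (k/n)/(K/N).
5. **Morphometry.** The circularity shape descriptor used for EM
   quantification: 4π·area/perimeter², exactly 1 for a circle.

A synthetic-data module generates growth cohorts of the three archetypes
and DE/ortholog/TF/GMT fixtures with planted ground truth, so the entire
pipeline is testable without any external downloads.

## Worked example

```python
from tumorclass import TumorResponseClassifier, summarize_cohort
from tumorclass.simulate import simulate_cohort

cohort = simulate_cohort(n=120, seed=1)        # three archetypes, σ=0.05
clf = TumorResponseClassifier().fit(cohort.curves)
print(len(clf.control_ids_), "pseudo-control animals")
print(summarize_cohort(clf.predict_calls(cohort.curves)))
```

prints

```
30 pseudo-control animals
regressing: 57 (47.5%); exhausted: 34 (28.3%); non-responsive: 29 (24.2%); unclassifiable: 0
```

The cohort was generated with mixture weights 0.478 / 0.257 / 0.265, so the
classifier recovers the composition to within a few animals; the 30
pseudo-controls are the top AUC quartile of the 120 mice. The same pipeline
is available from the shell:

```bash
tumorclass simulate --n 120 --seed 1 --out-dir fixtures/
tumorclass classify --measurements fixtures/measurements.tsv --out calls.tsv
tumorclass signature --invitro fixtures/de_invitro.tsv --invivo fixtures/de_invivo.tsv \
    --orthologs fixtures/orthologs.tsv --human-exhausted human.txt \
    --tfs fixtures/tfs.tsv --out-dir sig/
tumorclass enrich --query genes.txt --gmt fixtures/gene_sets.gmt --out enrichment.tsv
tumorclass circularity --in shapes.tsv --out circ.tsv
```

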