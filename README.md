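# paencase

Scoring and statistical evaluation of the relationship between pulmonary
arteries and lung lesions on CT, for differentiating benign from malignant
lesions.

## The problem

On contrast-enhanced multidetector CT the course of a pulmonary artery can be
traced through or around a lung nodule or mass. Radiologists classify the
lesion–artery relationship into five categories: **encasement** (the lesion
envelops the artery and narrows its caliber), **displacement** (the artery is
pushed off its normal course, with or without a notch), **penetration** (the
artery runs through the lesion with unchanged course and caliber), **in the
margin**, and **disconnection** (the last two carry no mass-effect
information and are excluded from analysis). Malignant lesions tend to encase
and displace arteries; benign ones tend to be penetrated. The severity of
encasement is quantified as the **degree of encasement**, the percent luminal
narrowing at the tightest point:

```
degree = (1 − CD / ref) × 100%
```

where `CD` is the narrowest luminal diameter inside the lesion and `ref` is
the expected normal diameter there, chosen by the encasement *type*:

| type | geometry | reference `ref` |
|------|----------|-----------------|
| A | no bifurcation in the encased segment | proximal normal diameter `AB` |
| B | one bifurcation, narrowest point proximal to it | `AB` |
| C | one bifurcation, narrowest point distal to it | distal normal diameter `EF` |
| D | ≥2 bifurcations, narrowest point between them | `CD′ = EF + (EC/EA)·(AB − EF)` |
| amputation | vessel barely visualized | degree ≡ 100% |

`EC` and `EA` are centerline arc distances from the distal normal point to
the narrowest point and to the proximal normal point, so `CD′` interpolates
the expected caliber linearly along a tapering vessel.

The package implements this scoring, the mass-effect relationship resolution
(encasement > displacement > penetration), and the full diagnostic battery:
Fisher exact tests on the relation × diagnosis table, odds ratios with Wald
95% CIs against the penetration baseline, Wilcoxon rank-sum on degrees,
Cohen's kappa for inter-observer agreement, and an empirical ROC with the
Youden-optimal cutoff and confusion metrics. Because no per-patient
measurements are published for this kind of study, a synthetic-cohort
generator (moment-matched amputation/Beta degree mixture, published
relationship frequencies) and geometric vessel phantoms with known ground
truth make every stage testable.

## Worked example

The `reproduce-paper` subcommand recomputes the headline analysis from the
shipped published summary tables:

```
$ paencase reproduce-paper
== Lesion accounting ==
malignant analyzed      74
benign analyzed 20
malignant dual-relationship lesions     15
== Relation x diagnosis ==
Fisher exact P  <0.001
OR encasement vs penetration    18.1 (95% CI: 4.6-71.7) P=1.701e-05
OR displacement vs penetration  33.8 (95% CI: 5.3-213.8)        P=2.719e-05
== Operating point ==
cutoff_pct      44.4
sensitivity     96.6% (56/58)
specificity     62.5% (5/8)
ppv     94.9% (56/59)
npv     71.4% (5/7)
```

Reading: after excluding the 6 lesions with only in-margin/disconnection
arteries, 74 malignant and 20 benign lesions remain (15 malignant lesions
show two relationship types). A lesion encasing a pulmonary artery has
18.1-fold odds of malignancy relative to one penetrated by an artery; at the
44.4% degree cutoff the score detects 56 of 58 encasing malignant lesions
(sensitivity 96.6%) while 3 of 8 benign encasing lesions (tuberculosis with
71–100% encasement) are false positives.

The same analysis runs on any cohort in the package's CSV dialect through
the statsmodels-style interface:

```python
from paencase import EncasementDiagnosticModel, SyntheticConfig, sample_cohort

cohort = sample_cohort(SyntheticConfig(seed=3, n_benign=60, n_malignant=200))
results = EncasementDiagnosticModel(cohort).fit()
print(results.summary())
```

which prints, among other lines,

```
- **malignant: degree of encasement (%)**: 69.8 +/- 19.0
- **Wilcoxon rank-sum P (degrees)**: 0.042
- **AUC (degree of encasement)**: 0.643
- **Inter-observer kappa**: 0.673 (substantial)
```

i.e. on a simulated cohort of this size the degree of encasement separates
the groups (higher in malignancy, AUC > 0.5) and the simulated second
observer reproduces substantial agreement. `simulate`, `score`, `analyze`
and `roc` subcommands expose the individual stages.

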