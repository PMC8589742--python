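# qmrn — quantitative MR neurography biomarkers and their reliability

`qmrn` is a Python package for quantitative magnetic resonance neurography
(MRN) of peripheral nerves. It estimates the biomarkers

* **T2** — transverse relaxation time [ms], from a multi-spin-echo stack by
  fitting `S(TE) = PSD · exp(−TE/T2) + offset` to the ROI-mean signal of
  the even echoes, slice by slice;
* **PSD** — proton spin density [a.u.], the amplitude of that fit, plus a
  scanner-gain-robust **normalized PSD** (nerve PSD / adjacent-muscle PSD);
* **MTR** — magnetization transfer ratio [%],
  `MTR = 100 · (S0 − S1)/S0` from a gradient-echo pair acquired without
  (S0) and with (S1) an off-resonance saturation pulse;
* **CSA** — nerve cross-sectional area [mm²] from the segmentation mask;

and quantifies how reliable those measurements are across repeated scans
(test–retest) and independent readers (interreader):

* **ICC(A,1)** — single-measurement absolute-agreement intraclass
  correlation from a two-way crossed ANOVA, with exact F-based 95%
  confidence intervals (two-way random effects for the interreader design,
  two-way mixed effects per reader for test–retest), classified as
  poor / moderate / good / excellent at 0.5 / 0.75 / 0.9;
* **SEM** — standard error of measurement, `√((MSC − MSE)/n + MSE)`
  (agreement flavour; consistency flavour `√MSE` available);
* **MDD** — minimum detectable difference, `SEM · 1.96 · √2`;
* **Bland–Altman** bias and 95% limits of agreement, with a
  repeated-measures correction for multiple difference pairs per subject.

Because raw human MRN data of this kind is generally not shareable, the
package ships a first-class synthetic-phantom generator
(`qmrn.synthetic`): cohorts with configurable subject/scan/reader variance
components, image rendering with Rician noise, and stochastic ROI-boundary
perturbation that emulates independent manual segmentation. Every stage of
the pipeline is therefore testable against known ground truth.

Intended users: researchers developing or validating quantitative MRN /
muscle MRI protocols, and anyone who needs a well-tested, self-contained
implementation of the ICC/SEM/MDD/Bland–Altman reliability suite.

## Worked example

Simulate a 21-subject cohort, three scans, two readers, with the default
variance components (calibrated to a healthy-volunteer sciatic-nerve
cohort: MTR 26.75 ± 3.5 %, T2 64.54 ± 8.2 ms, PSD 340.93 ± 78.8,
normalized PSD 0.71 ± 0.09), and run the reliability suite:

```python
import qmrn

truth = qmrn.sample_cohort(n_subjects=21, n_scans=3, n_readers=2, seed=1)
df = qmrn.simulate_measurements(truth)
rel, ba, desc = qmrn.analyze_cohort(df)

inter = rel[rel.design == "interreader"]
print(inter[["biomarker", "icc", "ci_low", "ci_high", "icc_class",
             "sem", "mdd"]].round(3).to_string(index=False))
```

prints (for this seed):

```
     biomarker   icc  ci_low  ci_high icc_class    sem    mdd
   mtr_percent 0.765   0.640    0.851      good  1.640  4.546
         t2_ms 0.864   0.785    0.915      good  2.652  7.352
           psd 0.951   0.920    0.970 excellent 16.702 46.295
psd_normalized 0.875   0.801    0.922      good  0.032  0.088
       csa_mm2 0.960   0.935    0.976 excellent  0.992  2.751

grand mean T2  = 65.85 ms (SD 7.15)
grand mean MTR = 27.45 % (SD 3.36)
Bland-Altman T2 interreader: bias 0.488 ms, LoA [-6.88, 7.86]
```

Reading the output: the interreader ICC of T2 is 0.86 ("good"); repeated
T2 measurements scatter around a subject's true value with SEM ≈ 2.7 ms,
so only changes larger than MDD ≈ 7.4 ms between two measurements can be
attributed to true change at 95% confidence. The Bland–Altman bias near
zero shows no systematic offset between the two readers.

The same analysis runs end-to-end from images. The CLI chains dataset
generation (NIfTI volumes + masks + manifest), biomarker fitting, the
reliability suite, and a markdown report with Bland–Altman plots:

```
qmrn run-all --subjects 21 --scans 3 --readers 2 --seed 1 --out results/
```

Individual stages (`qmrn simulate`, `qmrn fit`, `qmrn reliability`,
`qmrn report`) accept a JSON config (`--config`); every artefact records
the configuration hash so that outputs of different runs cannot be mixed.

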