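# brainhmm

Hidden-Markov-model classification of brain MRI cortical structural
complexity, for researchers studying morphological markers of dementia.

Dementia — Alzheimer's disease in particular — alters the irregularity of
the cortical gray-matter (GM) boundary. `brainhmm` turns a
tissue-segmented brain volume (NIfTI-1 or Analyze 7.5, voxels labeled
GM/WM/CSF) into a *sequence* of per-slice complexity summaries and models
that sequence with discrete hidden Markov models:

1. **Distance series** — for each axial slice, the Euclidean distances
   from consecutive outer GM boundary points (Moore-neighbor trace of the
   largest component) to the slice's GM center of mass.
2. **Features** — per slice, a *regularity-dimension* profile (local
   slopes of sample entropy SampEn(m, r) against log(1/r) over a
   tolerance grid r = 1.00 … 0.05) and an experimental *semivariogram*
   γ(h) = (1/2N(h)) Σ (xᵢ − xᵢ₊ₕ)² over index lags h = 1 … 100.
3. **Vector quantization** — LBG codebooks trained on the pooled vectors
   of the two compared groups map regularity profiles to 2 hidden-state
   indices and semivariogram profiles to 32 observable-symbol indices.
4. **HMMs** — one λ = (A, B, π) per group, estimated by supervised
   counting from the (state, symbol) index sequences, π fixed uniform;
   optional Baum-Welch refinement.
5. **Classification** — a held-out subject goes to the group with the
   higher forward log-likelihood P(O|λ), or to the group whose model has
   the smaller symmetrized Monte-Carlo Kullback-Leibler dissimilarity
   1 − exp(D_s) to the subject's own HMM — validated by leave-one-out and
   repeated stratified-split cross-validation with sensitivity,
   specificity and accuracy.

A synthetic-cohort module generates stacks of annular GM masks with
controllable per-group boundary irregularity (harmonic undulation plus
band-limited radial jitter), so the entire chain is testable without any
imaging download.

## Worked example

```python
from brainhmm.synthetic_data import study_spec
from brainhmm.classifier import cohort_features, loo_crossval

# two groups x 12 subjects, 20 slices each, full irregularity gap
dataset = cohort_features(study_spec(n_subjects_per_group=12,
                                     n_slices=20, seed=77))
report = loo_crossval(dataset, rule="likelihood")
print(f"sensitivity={report.sensitivity:.3f} "
      f"specificity={report.specificity:.3f} "
      f"accuracy={report.accuracy:.3f}")
print(report.counts)
```

prints

```
sensitivity=1.000 specificity=1.000 accuracy=1.000
ConfusionCounts(TP=12, TN=12, FP=0, FN=0)
```

i.e. with the default strong irregularity gap every demented subject
(TP = 12) and every control (TN = 12) is classified correctly by the
leave-one-out procedure, in which both LBG codebooks and both group HMMs
are refit in every round without the held-out subject. Shrinking the gap
(`study_spec(..., gap=0.1)`) moves accuracy toward chance.

The same pipeline runs from the shell on a cohort manifest:

```bash
brainhmm simulate --config cohort.yaml --out cohort/
brainhmm crossval --manifest cohort/manifest.csv --scheme loo \
    --rule likelihood --gm-label 1 --out report.json
```

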