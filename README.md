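# icalink

Personality traits are usually analyzed one factor at a time, yet the five
NEO-FFI domains (neuroticism, extraversion, openness, agreeableness,
conscientiousness) are strongly intercorrelated, and resting-state brain
activity is likewise organized into overlapping co-activation networks.
`icalink` is a Python library for researchers who want to relate the two
sides properly: it decomposes five-factor scores into statistically
**independent personality profiles**, decomposes multi-ROI resting-state
time series into **temporal functional modes**, summarizes each subject's
**engagement** of a mode as the variance of their mode time series, and
tests every profile–mode pair with **gender-corrected, family-aware
permutation inference** and FDR control — plus leave-one-out / split-half
reproducibility machinery and a synthetic-data generator with planted
ground truth for end-to-end validation.

## The model in brief

Behavioral side: z-scored factor scores `x ∈ R⁵` are modeled as
`x = A s + ε` with independent non-Gaussian latents `s`; full-rank FastICA
estimates the unmixing `W`, whose rows are the profiles, and `ℓ = W x`
gives each subject's profile loadings.

Imaging side: within-subject z-scored ROI series from 12 regions are
concatenated over subjects and decomposed by full-rank temporal ICA into
12 spatial weight patterns ("temporal modes"); projecting a subject's
series through the unmixing yields mode time series, and
`engagement(i, m) = Var(mode-m series of subject i)`.

Linking: for every profile k and mode m the partial correlation
`r(ℓ_k, engagement_m | gender)` is tested by Freedman–Lane permutation
restricted to family blocks (twins are never split), with
Benjamini–Hochberg correction across the 60 tests.

See `docs/methods.md` for estimation details, the generator's design, and
known limitations.

## Worked example

`examples/03_association.py` plants a coupling of strength ρ = 0.4 between
profile 5's loading and mode 2's engagement in 300 synthetic subjects
(with realistic twin-family structure), runs both decompositions and the
full association, and prints:

```
300 subjects in 226 family blocks (90 MZ and 58 DZ twins); permutations never split a family.

Significant profile-mode cells (BH q < 0.05 over 60 tests):
 profile  mode         r  p_perm  p_fdr  significant
       1     1  0.418326  0.0005 0.0075         True
       1     4 -0.190939  0.0015 0.0180         True
       1     5 -0.210066  0.0005 0.0075         True
       1     6 -0.249994  0.0005 0.0075         True
       1     7 -0.201446  0.0005 0.0075         True

Planted coupling (true profile 5 -> true mode 2) maps to estimated cell (profile 1, mode 1): r = +0.418, FDR-adjusted p = 0.0075
```

The planted coupling is recovered as the strongest cell (ICA orders and
signs components canonically, so "true profile 5" lands at estimated
position 1 here); its partial r of 0.42 reflects the planted ρ = 0.4
after estimation attenuation, and the permutation p sits at the
resolution floor of the 2,000-permutation null. The smaller negative
cells in the same row are compensatory associations induced by
per-subject variance normalization (see `docs/methods.md`).

The other examples cover profile derivation and recovery
(`01_personality_profiles.py`), temporal modes and engagement
(`02_temporal_modes.py`), and LOO / split-half / out-of-sample validation
(`04_validation.py`).

A thin CLI wraps the same pipeline for shell use:

```bash
icalink simulate --n-subjects 200 --n-timepoints 300 --seed 1 --out data/
icalink associate --personality data/personality.tsv --timeseries data/timeseries \
    --n-perm 10000 --out results/
icalink validate --personality data/personality.tsv --scheme split-half --out report.json
```

All artifacts are plain TSV/JSON; a run manifest makes every pipeline run
exactly reproducible.

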