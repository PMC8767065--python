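# excitoq

Quantification of glutamate-excitotoxicity endpoints in cultured neurons:
single-cell calcium-imaging kinetics, mitochondrial-potential recovery,
extracellular-flux respirometry, viability assays and soma morphometry, with
the distribution-gated statistics used to compare treatment groups.

## The problem

A prolonged excitotoxic glutamate exposure evokes a biphasic cytosolic-Ca²⁺
response in cultured neurons: a fast first-phase rise to a plateau, followed
— in a stochastic subpopulation of cells — by **delayed calcium
deregulation (DCD)**, a sustained secondary Ca²⁺ rise that predicts cell
death. Studies of modulators (here: bacterial lipopolysaccharide, LPS, which
slows the post-washout recovery of ion homeostasis) quantify this phenotype
per cell and compare cohorts. `excitoq` implements those estimators as a
tested library:

- **lag-DCD** — the time from glutamate addition to DCD onset, measured
  geometrically as the intersection of two least-squares tangents: one to
  the first-phase plateau, one to the steepest segment of the secondary rise;
- **recovery index** — X = 100 (R_off − R_end)/(R_off − R_base), the percent
  of the glutamate-evoked elevation relaxed by a fixed horizon after
  washout (100 = full return to baseline, 0 = none), with sister-culture
  normalization (control median ≡ 1);
- **ΔΨm recovery** from Rh123 F/F0 traces — the post-washout slope and the
  AUC_FCCP/AUC_post-glutamate ratio of above-baseline areas;
- **respirometry metrics** from well × cycle OCR plates with blank-well
  correction — NOCR, basal, maximal, spare respiratory capacity
  (maximal = basal + SRC identically) and the acute response to each
  injected agent, in two explicit normalization conventions;
- **viability** — the Syto-13/EthD-1 live/dead index and the kinetic MTT
  initial rate (background-corrected A550 slope over the first 10 min);
- **morphometry** — contour-pixel area changes and the spherical conversion
  volume fold = (area fold)^(3/2);
- **statistics** — a normality-gated ladder (D'Agostino–Pearson →
  Mann-Whitney / Kruskal-Wallis+Dunn / ANOVA+Šidák / mixed RM
  ANOVA+Dunnett) with a complete branch-decision audit.

Because no raw dataset accompanies this kind of experiment, the package
ships a first-class synthetic-cohort generator (`excitoq.synth`) that
emulates the data structure — log-normal DCD lags, LPS as a multiplicative
recovery-rate factor, coupled Rh123 traces, a mix/wait/measure flux-plate
protocol, binomial live/dead counts — and returns ground truth alongside
every cohort, so every estimator is scored against known values.

## Worked example

```python
import excitoq as xq

params = xq.preset("cortical", seed=1)          # 288 cells, 15-min Glu
cohort = xq.gen_calcium_cohort(params)
results = xq.analyze_cohort(cohort.traces, cohort.events)
summary = xq.summarize_cohort(results)
```

Running `python examples/01_dcd_lag_and_recovery.py` prints:

```
cells analyzed:        288
DCD fraction:          0.812 (ground truth 0.812)
lag-DCD median (IQR):  181 s (104-300), n=234
  ground-truth median: 183 s
recovery X% median:    90.2% (truth 90.9%)
cells w/o defined recovery: 0
```

i.e. on a cohort calibrated to the cortical phenotype (lag median 180 s) the
tangent-intersection estimator recovers the cohort median within ~1%, and
the classifier reproduces the generator's DCD assignment. The other scripts
in `examples/` walk through the LPS recovery effect, Rh123 metrics, flux
plates, endpoint assays and the gated statistics, each printing the numbers
it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
excitoq simulate --preset cortical --seed 5 --out-dir sim/
excitoq dcd --traces sim/calcium_traces.csv --events sim/events.yaml --out-dir out/
excitoq mito --traces sim/rh123_traces.csv --events sim/events.yaml --out-dir out/
```

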