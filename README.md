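# flimcyte

Phasor-based analysis of label-free NAD(P)H fluorescence-lifetime imaging
(FLIM) for single-cell metabolic profiling, with a synthetic TCSPC data
generator that stands in for the microscope.

## The problem

Two-photon FLIM of NAD(P)H autofluorescence reads out cellular metabolism
without labels: free NAD(P)H has a short lifetime (~0.4 ns), enzyme-bound
NAD(P)H a much longer one, and the fraction of bound NAD(P)H tracks the
NAD(P)+/NAD(P)H redox balance — higher values mean more oxidative
phosphorylation, lower values a shift toward glycolysis, as happens within
minutes when T cells are activated at an immune synapse. `flimcyte` turns
per-pixel photon-arrival histograms into calibrated phasor coordinates,
per-pixel fraction-of-bound-NAD(P)H maps, 3-D single-cell statistics, and
resting-vs-activated group comparisons.

## The method

Each pixel's decay histogram I_k (256 bins over one 80 MHz laser period,
bin centers t_k) is mapped to first-harmonic phasor coordinates

    g = Σ_k I_k cos(ω t_k) / Σ_k I_k ,   s = Σ_k I_k sin(ω t_k) / Σ_k I_k ,

with ω = 2πf.  Mono-exponential decays of lifetime τ fall on the universal
semicircle at g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures fall on chords,
at a position set by the intensity fractions.  The instrument response is
removed by calibrating against fluorescein at pH 9 (single-exponential,
4.04 ns).  The fraction of bound NAD(P)H at a pixel is the Euclidean
distance from its calibrated phasor to the free-NAD(P)H location
(g_f, s_f) on the semicircle:

    f_bound = sqrt((g − g_f)² + (s − s_f)²) .

No bound-species location is assumed (the bound lifetime depends on the
binding enzyme), and the statistic is independent of NAD(P)H
concentration.  Phase and modulation lifetimes are also available:
TauP = (s/g)/ω, TauM = sqrt(1/(g²+s²) − 1)/ω.

Single cells are masked on a maximum-intensity Z-projection of a marker
channel (LifeAct-like) or of the NAD(P)H intensity itself (Gaussian blur,
Otsu threshold, hole filling, connected components); one 2-D mask is
shared by all Z planes, and only pixels strictly above a 5-photon
intensity threshold enter per-plane and whole-volume cell means.  Group
statistics follow the field's conventions: Welch t-tests across cells with
medians + IQR, paired t-tests across donors or between bottom/top planes,
and Pearson/Spearman correlation between cell area and fraction bound.

The `simulate` module generates the whole measurement synthetically:
bi-exponential free/bound decays sampled at bin centers, Poisson photon
noise at 200–300 photons/pixel, 6-plane volumes of disk-shaped cell
phantoms with dim nuclear cores and mitochondria-rich cortices, an
activation effect that lowers the bound fraction, a negative
area–metabolism coupling, synapse-side mitochondrial polarisation, and
dead cells flagged in a viability channel — all with exact ground truth
for recovery testing.

## Worked example

`examples/` holds one short script per capability. The core round trip
(`python examples/01_decay_to_phasor.py`):

```
free NAD(P)H (0.4 ns)     g=0.9611 s=0.1935 TauP=0.401 ns TauM=0.400 ns |semicircle residual|=7.24e-05
bound NAD(P)H (3.2 ns)    g=0.2788 s=0.4484 TauP=3.200 ns TauM=3.200 ns |semicircle residual|=2.10e-05
50/50 mixture             g=0.6199 s=0.3210 TauP=1.030 ns TauM=2.040 ns |semicircle residual|=1.33e-01
```

Pure species sit on the semicircle with TauP = TauM; the mixture sits on
the chord between them, where TauP < TauM flags a multi-exponential decay.

A full resting-vs-activated comparison
(`python examples/04_condition_comparison.py`) simulates both conditions,
segments and quantifies the cells, and prints:

```
t=10 min  control 0.2986 [0.2942, 0.3052] (n=30) vs activated 0.2269 [0.2152, 0.2424] (n=30): p=1.73e-26 ***
t=10 min  area vs fraction bound (pooled): Pearson r=-0.272 (p=0.0356, n=60)
```

The activated median is lower by roughly the imposed glycolytic shift,
and larger (more spread) cells show lower fraction bound.  The same
workflow is scriptable from a shell:

```
flimcyte run-all --config config.yaml --seed 1 --out run/
```

## Layout

- `src/flimcyte/` — `core` (acquisition metadata, decay stacks),
  `simulate` (phantom generator), `phasor` (transform, calibration,
  fraction bound, lifetimes), `segment` (masks, viability filter,
  tracking), `cellmetrics` (per-cell/per-Z/volume statistics), `stats`
  (group comparisons), `io`/`config`/`pipeline`/`cli` (formats,
  validation, orchestration), `plots` (optional figures).
- `tests/` — unit, property and end-to-end recovery tests.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model, conventions, parameter defaults, design
  decisions and limitations.
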