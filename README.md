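# palaeoveg

Quantitative palaeovegetation analysis for long fossil-pollen records, built
for alpine forest–meadow–steppe systems such as the eastern Tibetan Plateau.
The package takes a taxon-by-sample pollen count table from a lake-sediment
core through the complete analysis chain used in quantitative palaeoecology:

1. **count arithmetic & chronology** — percentages on the terrestrial pollen
   sum, concentrations from *Lycopodium* marker spikes
   (conc = count/spike_counted × spike_added / volume), influx
   (conc × sedimentation rate), and piecewise-linear tie-point age–depth
   models with hiatus support;
2. **biomization** — each sample's taxa are mapped to plant functional types
   (PFTs) and PFTs to biomes; a biome's affinity score is
   Σₖ √max(0, pₖ − θ) over its member taxa (θ = 0.5 % by default), the
   best-scoring biome wins (ties → fewer defining PFTs), and biomes merge
   into five megabiomes (forest, meadow, steppe, shrubland, desert-steppe);
3. **diversity** — Hurlbert rarefaction
   E(Sₙ) = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)] and Pielou evenness J = H′/ln S,
   overall and split by growth form;
4. **resilience** — residence time (megabiome persistence between
   transition midpoints) and recovery time (last occurrence → first
   reoccurrence, censored if the megabiome never returns), with LOESS
   trends along time or a climate gradient;
5. **spectral & recurrence diagnostics** — Morlet (ω₀ = 6) continuous
   wavelet transform with AR(1) red-noise significance, 13–250-kyr bandpass
   filtering, and recurrence determinism
   DET = Σ_{l≥l_min} l·P(l) / Σ_{l≥1} l·P(l);
6. **regime shifts** — CONISS (stratigraphically constrained incremental
   sum-of-squares clustering) with broken-stick zone selection,
   multivariate regression trees on age, and PCA ordination of
   square-root-transformed percentages (taxa > 2 % in ≥ 1 sample);
7. **driver attribution & calibration** — recursive standardized path
   models (per-equation OLS on z-scored 1-kyr series; δ¹⁸O sign-flipped so
   low = low ice), Spearman matrices, weighted-averaging climate
   optima/tolerances and kernel-density climate envelopes;
8. **synthetic data** — a generator that emulates a 3.5-Myr record at
   0.7-kyr sampling with 20/41/100-kyr orbital forcing, a long-term cooling
   trend, AR(1) millennial noise and multinomial counting noise, exporting
   exact ground truth so every stage has a parameter-recovery test.

The public face is the importable API plus `examples/` (one short narrative
script per capability).

## Worked example

```bash
python examples/01_simulate_and_biomize.py
```

```
simulated core: 5001 samples, 19 taxa, 3500-0 ka
assignment accuracy vs noise-free truth: 98.0%
trend-driven megabiome transitions at: [1967, 1273] ka

megabiome proportions (% of samples) per interval:
                    forest  meadow  steppe  shrubland  desert-steppe  n_samples
3500-1967.35 ka       84.9     5.1    10.0        0.0            0.0     2190.0
1967.35-1272.95 ka    38.5    39.1    22.4        0.0            0.0      992.0
1272.95-0 ka           8.9    76.5    14.6        0.0            0.0     1819.0
```

The simulated core holds 5,001 samples of 300–600 counted grains each. The
biomization recovers the generator's noise-free megabiome label for 98 % of
samples despite multinomial counting noise. The proportion table shows the
long-term transformation the cooling trend imposes: forest dominance in the
warm early interval collapsing to a meadow-dominated system in the cold late
interval, with the trend-only transition ages printed above. The other
examples cover diversity (`02`), resilience (`03`), wavelet/recurrence
spectra and zonation (`04`) and driver attribution plus modern calibration
(`05`).

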