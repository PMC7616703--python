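# hippocoact

Offline hippocampal network-event analysis: detection and laminar typing of
**dentate spikes** (DS₁/DS₂) and **sharp-wave ripples** (SWRs) from
multichannel LFP, event-nested population-vector statistics, peer-controlled
coactivity graphs, and a mixed-model **reactivation** statistic linking waking
theta co-firing to offline events — together with a synthetic-session
generator that plants ground truth for every stage.

It is written for electrophysiologists analyzing laminar silicon-probe or
tetrode recordings of the dentate gyrus and CA fields during sleep/rest and
exploration, and for methodologists who need a fully verifiable re-implementation
of this analysis chain.

## The analysis chain

1. **Preprocessing** — wide-band signals (20 kHz) are anti-alias filtered
   (8th-order Chebyshev type I) and decimated to 1250 Hz.
2. **Dentate spikes** — the granule-cell-layer LFP is band-passed 1–200 Hz
   (4th-order Butterworth, zero-phase); local maxima above
   `6 × median(|filtered|)` are DS peaks, one event per 50 ms frame.
3. **Sharp-wave ripples** — common-average-referenced pyramidal channels are
   band-passed 80–250 Hz; Hilbert-envelope peaks above `5 × median(envelope)`
   are candidates, accepted only with (i) ≥ 2× the reference ripple power,
   (ii) ≥ 4 ripple cycles, (iii) ≥ 2× the 200–500 Hz band power.
4. **DS typing** — current source density
   `CSD[t]ₙ = −(LFP[t]ₙ₋₁ − 2·LFP[t]ₙ + LFP[t]ₙ₊₁)` localizes each event's
   molecular-layer sink; peak-CSD profiles are projected on two principal
   components and split by a 2-component Gaussian mixture. The class with the
   most superficial sink (outer molecular layer) is DS₁, the class with the
   sink nearer the granule layer is DS₂. A PCA + linear-discriminant
   classifier trained on granule-layer waveforms transfers the typing to
   single-channel recordings.
5. **Population vectors** — per-event spike counts in 50 ms windows
   (±25 ms around the peak), with duration-matched baseline windows that
   avoid ±250 ms of any event. Statistics: Gini sparsity
   `S = Σ(2i−N−1)xᵢ / (N Σxᵢ)`, coactive fraction, logistic DS-vs-SWR
   discriminability, Pearson/Jaccard vector similarity, and PCA
   dimensionality (components for 90 % variance, scaled by cell count).
6. **Coactivity graphs** — per cell pair (i, j), the weight β_ij comes from
   the peer-controlled regression `x_j ~ β·x_i + α·P` on z-scored counts,
   where `P` sums the other N−2 cells; symmetrized into an adjacency matrix
   and summarized by the Onnela signed weighted clustering coefficient
   `Cᵢ = Σ (β̂ᵢⱼ β̂ᵢ_q β̂ⱼ_q)^{1/3} / (kᵢ(kᵢ−1))` and per-node mean strength.
7. **Reactivation** — per pair, theta / pre-sleep / post-sleep coactivity
   enters `post ~ β₀ + β_theta·theta + β_pre·pre + υ_mouse + e` (REML, mouse
   random intercept); the reverse model swaps pre and post, and a null
   distribution comes from refitting with cell-pair identity shuffled.
8. **Estimation** — every group contrast reports a mean difference with a
   5,000-resample percentile-bootstrap CI and a permutation p-value.

## Worked example

```python
from hippocoact import (SynthConfig, generate_session, detect_dentate_spikes,
                        detect_swr, csd_profiles_at_peaks, fit_ds_types)

cfg = SynthConfig(pre_sleep_s=600.0, n_channels=64, seed=1)   # 10 min sleep
lfp, spikes, ledger = generate_session(cfg)

ds  = detect_dentate_spikes(lfp)     # granule-layer amplitude detector
swr = detect_swr(lfp)                # ripple-band envelope detector
print(len(ds), len(swr))             # -> 186 378

profiles, cmap = csd_profiles_at_peaks(lfp, ds.peak_times)
model, labels = fit_ds_types(profiles, lfp.layer_map, cmap.interior_channels)
print(model.sink_channels)           # -> {0: 41, 1: 56}  (om vs im sink)
print((labels == "DS2").mean())      # -> 0.639
```

The 186 detected DS events sit at 0.31 Hz (the generator plants 0.40 Hz and
thins close pairs), the 378 SWRs at 0.63 Hz. The mixture's two classes have
their current sinks at channel 41 (outer molecular layer → DS₁) and channel
56 (inner molecular layer → DS₂), and 63.9 % of events are typed DS₂ —
matching the planted two-thirds DS₂ majority. Against the ledger, typing
accuracy here is 100 %.

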