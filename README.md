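# ffnquant

Quantification of evoked pH-sensitive fluorescent false neurotransmitter
(FFN) transients in brain-slice imaging.

## The problem

Dopamine release in sparsely innervated nuclei such as the external globus
pallidus (GPe) is below the detection limit of carbon-fiber electrochemistry.
pH-sensitive FFNs (e.g. FFN102) offer an optical readout: the dye is loaded
into synaptic vesicles through the dopamine transporter, quenched at acidic
vesicular pH, and brightens on exocytosis into the neutral extracellular
space. Electrical stimulation of a labelled slice therefore produces a
whole-field fluorescence "flash" whose size and kinetics report synaptic
dopamine release — even in fields of view with no resolvable puncta.

`ffnquant` implements the full analysis chain for such experiments, plus a
synthetic-data generator with known ground truth so that every stage is
testable without any raw recordings:

- **%ΔF/F extraction** — per-frame mean intensity, ordinary least-squares
  baseline fit to the 500 ms before stimulation, and
  ΔF/F(t) = (F(t) − B(t)) / B(t) with the fitted line B extrapolated over the
  whole trace (cancelling linear photobleaching exactly).
- **AUC scoring** — trapezoidal integral of %ΔF/F over the stimulus window,
  in %·s (or per frame index).
- **Puncta quantification** — Canny edge mask of the pre-stimulus baseline
  image (thresholds 0.08 / 0.2 on the gradient magnitude normalized to 1)
  and its edge-pixel sum as a proxy for punctate structure.
- **Kinetics** — frame-binned derivative of the transient with 100-ms
  landmark bins (pre-stimulus, first pulse, second pulse), and decay times
  from a log-linear fit (time to fall to 10 % of the post-stimulus peak,
  `τ·ln 10` for an exponential, with the fit's r²).
- **Spatial hotspot analysis** — pairwise distances between fields of view,
  AUC-quartile pair classification, and a permutation test for spatial
  clustering of high-releasing fields.
- **Statistics** — two-tailed paired/unpaired t-tests with t-based CI95,
  one-way repeated-measures ANOVA, and a mixed between-region ×
  within-condition ANOVA.
- **Synthetic data** — stimulus protocols, traces, 64×64 px @ 10 Hz movies
  and multi-field slice sessions, with region presets ("striatum": large
  sustained transients, no facilitation, ~60 s recovery; "GPe": small
  flash-like transients, strong frequency-dependent facilitation, ~10 s
  recovery), Hill-type calcium dependence, photobleaching, and Gaussian or
  Poisson pixel noise.

## Worked example

```python
import numpy as np
from ffnquant import (region_kinetics, make_stimulus_protocol, simulate_movie,
                      extract_dff, auc, decay_metrics, baseline_image,
                      canny_mask, canny_edge_sum)

protocol = make_stimulus_protocol(frequency_hz=10.0, n_pulses=10, onset_s=1.0)
kinetics = region_kinetics("GPe")
movie, truth = simulate_movie(kinetics, protocol, duration_s=10.0,
                              noise_sd=0.5, seed=42)

dff = extract_dff(movie)
score = auc(dff, (protocol.onset_s, protocol.last_pulse_s))
decay = decay_metrics(dff, protocol)
edges = canny_edge_sum(canny_mask(baseline_image(movie)))

print(f"peak dF/F      : {dff.values.max():.2f} %")
print(f"AUC (stimulus) : {score:.2f} %*s")
print(f"decay to 10%   : {decay.decay_time_s:.2f} s  (r^2 = {decay.r_squared:.3f})")
print(f"Canny edge sum : {edges}")
print(f"true per-pulse amplitudes: {np.round(truth.amplitudes_pct, 3)}")
```

prints

```
peak dF/F      : 1.37 %
AUC (stimulus) : 0.66 %*s
decay to 10%   : 2.40 s  (r^2 = 0.999)
Canny edge sum : 169
true per-pulse amplitudes: [0.204 0.218 0.219 0.219 0.219 0.219 0.219 0.219 0.219 0.219]
```

A simulated GPe field stimulated with ten 10 Hz pulses reaches ~1.4 %ΔF/F
(each pulse contributes ~0.2 %, slightly facilitating), integrates to
0.66 %·s over the stimulus second, and decays to 10 % of its peak in about
2.4 s — the brief "flash" characteristic of sparsely innervated tissue.
The punctate baseline image yields a Canny edge sum of 169, which across
many simulated fields is uncorrelated with transient size.

The same stages are available from a shell via the `ffnquant` CLI
(`simulate`, `extract`, `puncta`, `kinetics`, `spatial`, `stats`, `run`);
`ffnquant run` drives the whole pipeline from a YAML config and writes
per-FOV tables, mean traces, statistics and a manifest with the config hash.

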