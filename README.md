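# regsec

Quantification of neuronal regulated secretion from fluorescence
time-lapse imaging and whole-cell patch clamp.

Neurons release signaling molecules from two regulated secretory
organelles: synaptic vesicles (SVs) and dense-core vesicles (DCVs). Both
are commonly studied with pH-sensitive fluorophores (pHluorins) that are
quenched in the acidic vesicle lumen and dequench on fusion with the
plasma membrane, or globally when NH4+ superfusion neutralizes vesicular
pH and reveals the entire labeled pool. `regsec` implements the full
quantification chain for such experiments, for people who analyze these
recordings: cell biologists and electrophysiologists working on synaptic
transmission and neuropeptide secretion.

## What it computes

Traces are normalized as ΔF/F0 with F0 the mean of the first 10 s of
frames, and events are accepted when ΔF/F0 exceeds 3 standard deviations
of the baseline.

* **SV (SypHy) fusion** — synapses are non-mobile puncta with a
  supra-threshold NH4+ response (4×4 px ROIs); per synapse: silent vs
  responsive classification, the fusion fraction
  `max ΔF/F0 during stimulation / max ΔF/F0 during NH4+`, and the
  half-decay time of the stimulation response.
* **DCV (NPY-pHluorin) fusion** — events are puncta appearing upon
  stimulation (3×3 px ROIs); the total DCV pool is counted on the NH4+
  maximum projection with modal-intensity correction: each punctum
  contributes `max(1, round(I / I_modal))` vesicles, where the modal
  punctum intensity is the single-vesicle unit (KDE mode, Silverman
  rule-of-thumb bandwidth). Fusion probability = 100 × events /
  corrected pool. Events with >50% of their ROI pixels inside a synapse-
  marker mask are synaptic.
* **Axonal influx** — kymographs along a photobleached axon segment;
  per-frame peak detection plus nearest-neighbor linking yields track
  velocities (least-squares slope) and the influx in puncta/min.
* **Golgi trafficking kinetics** — after biotin-triggered cargo release,
  the Golgi-region trace gives the ER→Golgi entry slope (least-squares
  fit of the peak-normalized rise, %/min) and the Golgi-exit percentage
  `100 × (peak − value at peak + t) / peak`.
* **Static quantification** — neurite length from a morphological
  skeleton, puncta density per µm, Sholl distributions, mask overlap
  percentages and masked Spearman correlation, intensity histograms.
* **Electrophysiology** — evoked and spontaneous (mEPSC) charge
  transfer, mini detection by filtered threshold crossing, the readily
  releasable pool (RRP) as total charge during hypertonic sucrose,
  release probability = 100 × evoked pC / RRP nC·1000, and the
  paired-pulse ratio.
* **Statistics** — the gated decision procedure: Shapiro (per group) and
  Levene gates choose t-test / one-way ANOVA + Tukey HSD, or
  Mann–Whitney U / Kruskal–Wallis + Holm step-down.
* **Synthetic data** (`regsec.synthgen`) — seeded generators for every
  stage (fusion movies, flux movies, static neurons, current sweeps)
  with full ground-truth logs; these drive the test suite.

## Worked example

```python
import numpy as np
from regsec import synthgen, dcv_fusion

cfg = synthgen.default_dcv_config(n_puncta=20, fusion_probability=0.2,
                                  noise_gaussian_sd=10.0, noise_poisson=True,
                                  seed=3)
movie, truth = synthgen.simulate_dcv_movie(cfg)

events = dcv_fusion.detect_fusion_events(movie)
pool = dcv_fusion.estimate_pool(movie)
print(f"events: {len(events)} (truth {len(truth.events)})")
print(f"pool:   {pool.corrected_pool} vesicles from {pool.raw_puncta} puncta "
      f"(truth {truth.pool_vesicles})")
print(f"fusion probability: "
      f"{dcv_fusion.fusion_probability(len(events), pool):.2f}%")
```

prints

```
events: 7 (truth 7)
pool:   36 vesicles from 20 puncta (truth 36)
fusion probability: 19.44%
```

All seven injected dequenching events are recovered; the 20 detected
puncta expand to 36 vesicles after modal-intensity correction (the raw
punctum count underestimates the pool whenever a punctum holds several
vesicles); and the fusion probability is events over the corrected pool
as a percentage.

The same stages are available from the shell:

```bash
regsec simulate --kind dcv --seed 3 --out sim/
regsec dcv-fusion --stack sim/movie.tif --protocol sim/protocol.txt --out out/
```

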