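# swallowkit

Quantitative analysis of feeding, swallowing, and related oromotor behavior
in mouse models of dysphagia — written for labs that phenotype swallowing
disorders (e.g. the *LgDel* model of 22q11.2 deletion syndrome) with
videofluoroscopy, transoral endoscopy, lung histology, and home-cage video
surveillance.

The package re-implements, as tested and reusable code, the bespoke
computational steps such a study needs:

| stage | module | what it computes |
| --- | --- | --- |
| fluoroscopy | `swallowkit.tracking`, `swallowkit.jaw` | template-matched jaw-marker tracking, mm calibration from a 10 mm bar, lick/mastication cycle detection, and the drinking/eating metric set (lick rate, ILI, swallow rate, ISI, lick–swallow ratio, PTT, jaw velocities) |
| endoscopy | `swallowkit.tracking`, `swallowkit.larynx` | glottal-point geometry (equidistant adjustment about the dorsal commissure), lateral vocal-fold traces, and the laryngeal metric set (MMRR, OCCR, Mcorr, VF angle, respiratory rate) plus LAR duration |
| histology | `swallowkit.histology` | the lung-inflammation pixel pipeline (background removal, red/blue color enhancement, luminance threshold 130, ratio over original pixels) and mandible cardinal-point distances |
| behavior | `swallowkit.behavior` | home-cage event-log binning into 24 h periods, per-class frequency/duration, events/hour and minutes/24 h conversions |
| statistics | `swallowkit.stats` | independent t-tests with mean ± SEM, normality/outlier screening, two-way genotype × side ANOVA, tidy group tables |
| synthesis | `swallowkit.synthetic` | ground-truthed generators for every input (jaw/glottal waveforms, marker videos, H&E-like images, Poisson behavior logs) and whole-cohort simulators |

Because animal studies of this kind rarely deposit raw video, the
`synthetic` module is first-class: every generator emits a `SyntheticTruth`
sidecar (exact event times, marker positions, painted pixel fractions) so
each downstream stage is verified by parameter recovery rather than by
fixture files.

## The measurements, briefly

During drinking, a mouse licks at ~8–9 Hz; the jaw gape trace
`g(t)` (mm, from the distance between upper- and lower-jaw markers) is
cyclic, and the metric layer reduces it to rates and intervals: lick rate
(cycles/s counted per 1 s sub-window and averaged), inter-lick interval
(mean close-to-close spacing), pharyngeal transit time
PTT = (f_esoph − f_rest)/fps from annotated bolus frames, and per-phase
mean slopes for jaw opening/closing velocity. During breathing, the left
and right glottal edges oscillate in anti-phase; with signed lateral
coordinates x_L, x_R about the glottal axis, the motion correlation
coefficient is Mcorr = corr(Δx_L, Δx_R) — near −1 for normal motion, near
+1 for paradoxical (same-direction) motion — while MMRR and OCCR summarize
left/right amplitude and cycle-count symmetry, and the VF angle is
∠(L, C, R) at the dorsal commissure C. Lung inflammation is the fraction
of image pixels whose enhanced luminance falls below 130 (dark red/purple
erythrocyte pools), averaged over five images per mouse.

## Worked example

```python
from swallowkit import SwallowAnnotation, compute_drinking_metrics, detect_jaw_cycles
from swallowkit.synthetic import JawTraceSpec, gen_jaw_trace

spec = JawTraceSpec(lick_rate_hz=8.71, noise_sd_mm=0.04, seed=3)
trace, truth = gen_jaw_trace(spec)          # 2 s drinking clip at 30 fps
events = detect_jaw_cycles(trace)           # open/close extrema
swallows = [SwallowAnnotation(**a) for a in truth.annotations]
m = compute_drinking_metrics(events, swallows, trace, window=(0, 60))
```

prints, via the fields of `m`:

```
lick rate              9.00 /s
inter-lick interval   115.7 ms
swallow rate           2.50 /s
lick-swallow ratio     4.00
pharyngeal transit    100.0 ms
```

The clip was generated at 8.71 Hz with a swallow every fourth lick and a
3-frame bolus transit: the inter-lick interval recovers the true 114.8 ms
up to the 33 ms frame quantization; the lick rate of 9.00 is the
windowed-count statistic (cycles counted in each 1 s sub-window, then
averaged), which sits slightly above 1000/ILI for a train that starts on a
cycle — the reason rate and interval are reported as separate metrics
rather than reciprocals.

## The analysis pipeline

Numbered drivers under `analysis/` run the whole study on simulated
cohorts and write tables under `results/`:

```
python analysis/01_simulate.py      # example raw inputs + truth sidecars
python analysis/02_track.py         # marker video -> calibrated gape trace
python analysis/03_vfss.py          # 22-mouse drinking/eating metric table
python analysis/04_larynx.py        # 22-mouse laryngeal metric table
python analysis/05_histology.py     # inflammation ratios + mandible ANOVA
python analysis/06_behavior.py      # 10-mouse home-cage summary
python analysis/07_stats_report.py  # unblinded group comparisons (t-tests)
```

Genotype labels are stored apart from the measurements and merged only in
step 07, mirroring a blinded workflow.

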