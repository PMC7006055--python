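"""Generate example raw study inputs with ground truth.

Produces one of each synthetic artifact the downstream stages consume —
a 2 s drinking jaw trace, a 10 s glottal breathing clip, an H&E-like lung
image, and a 72 h home-cage log — together with their truth sidecars, under
results/synthetic/. Later scripts regenerate cohorts internally; these
files document the raw formats.

Run from the repository root:  python analysis/01_simulate.py [--seed N]
"""

import argparse
from pathlib import Path

import imageio.v3 as iio

from swallowkit.io import write_behavior_log
from swallowkit.synthetic import (
    BehaviorLogSpec,
    GlottalTraceSpec,
    HistologyImageSpec,
    JawTraceSpec,
    gen_glottal_traces,
    gen_histology_image,
    gen_homecage_log,
    gen_jaw_trace,
)

OUT = Path("results/synthetic")


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    jaw_spec = JawTraceSpec(noise_sd_mm=0.04, seed=seed)
    trace, truth = gen_jaw_trace(jaw_spec)
    trace.to_csv(OUT / "jaw_trace.csv")
    truth.to_json(OUT / "jaw_trace_truth.json")
    print(
        f"jaw trace: {jaw_spec.lick_rate_hz} Hz licking, "
        f"{len(truth.event_times['jaw_close'])} closes, "
        f"{len(truth.annotations)} swallows -> {OUT/'jaw_trace.csv'}"
    )

    gl_spec = GlottalTraceSpec(noise_sd_px=0.3, seed=seed)
    left, right, gl_truth = gen_glottal_traces(gl_spec)
    left.to_csv(OUT / "glottal_left.csv")
    right.to_csv(OUT / "glottal_right.csv")
    gl_truth.to_json(OUT / "glottal_truth.json")
    print(
        f"glottal traces: {gl_spec.respiratory_rate_per_min}/min breathing, "
        f"{gl_truth.true_parameters['n_cycles']} cycles -> {OUT/'glottal_left.csv'}"
    )

    hi_spec = HistologyImageSpec(pool_area_fraction=0.05, seed=seed)
    img, hi_truth = gen_histology_image(hi_spec)
    iio.imwrite(OUT / "lung_section.png", img)
    print(
        f"lung image: true inflamed fraction "
        f"{hi_truth.true_inflamed_fraction:.4f} -> {OUT/'lung_section.png'}"
    )

    log_spec = BehaviorLogSpec(seed=seed)
    log, _ = gen_homecage_log(log_spec)
    write_behavior_log(log, OUT / "homecage_log.csv")
    print(f"home-cage log: {len(log)} events over 72 h -> {OUT/'homecage_log.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
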