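"""Published group summary statistics for the adult LgDel / wild-type cohorts.

These are the reported per-genotype means (and SEMs) from the adult mouse
22q11.2-deletion (LgDel) dysphagia study that this pipeline re-implements.
They serve two roles:

* realistic default parameters for the synthetic-data generators (the
  generators emulate the study conditions, so their defaults are the study's
  wild-type values), and
* inputs to the summary arithmetic (fold changes between genotypes, per-hour
  and per-minute unit conversions) recomputed by ``analysis/`` and
  ``scripts/acceptance.py``.

All values are group means with SEM in parentheses in the original report;
only the pieces the pipeline consumes are kept here.
"""

from __future__ import annotations

# --- Videofluoroscopic swallow study (VFSS), drinking and eating ------------
# Units follow the metric definitions: rates in #/s, intervals in ms
# (drinking) or s (eating), transit time in ms, velocities in mm/s.
VFSS_GROUP_MEANS = {
    "wt": {
        "lick_rate": 8.71,
        "inter_lick_interval": 114.43,
        "swallow_rate": 1.68,
        "inter_swallow_interval": 752.91,
        "lick_swallow_ratio": 4.47,
        "pharyngeal_transit_time": 85.82,
        "jaw_closing_velocity": 14.39,
        "jaw_opening_velocity": 13.71,
        "mastication_rate": 8.26,
        "eating_swallow_rate": 0.31,
        "eating_inter_swallow_interval": 4.01,
    },
    "lgdel": {
        "lick_rate": 8.07,
        "inter_lick_interval": 121.91,
        "swallow_rate": 1.77,
        "inter_swallow_interval": 690.18,
        "lick_swallow_ratio": 3.85,
        "pharyngeal_transit_time": 94.36,
        "jaw_closing_velocity": 13.19,
        "jaw_opening_velocity": 13.55,
        "mastication_rate": 8.167,
        "eating_swallow_rate": 0.27,
        "eating_inter_swallow_interval": 4.17,
    },
}

VFSS_GROUP_SEMS = {
    "wt": {
        "lick_rate": 0.18,
        "inter_lick_interval": 2.30,
        "pharyngeal_transit_time": 1.91,
        "eating_swallow_rate": 0.08,
    },
    "lgdel": {
        "lick_rate": 0.22,
        "inter_lick_interval": 2.65,
        "pharyngeal_transit_time": 2.50,
        "eating_swallow_rate": 0.02,
    },
}

# --- Laryngeal motion during spontaneous breathing (10 s endoscopy clips) ---
LARYNGEAL_GROUP_MEANS = {
    "wt": {
        "mmrr": 0.90,
        "occr": 0.94,
        "mcorr": -0.86,
        "vf_angle": 33.57,
        "respiratory_rate": 165.26,
    },
    "lgdel": {
        "mmrr": 0.77,
        "occr": 1.01,
        "mcorr": -0.85,
        "vf_angle": 30.60,
        "respiratory_rate": 143.61,
    },
}

LARYNGEAL_GROUP_SEMS = {
    "wt": {"mmrr": 0.06, "respiratory_rate": 6.48},
    "lgdel": {"mmrr": 0.07, "respiratory_rate": 10.40},
}

# --- Home-cage behavior (72 h, three 24 h bins) -----------------------------
# Per-bin means: frequency in events / 24 h bin, duration in seconds / bin.
BEHAVIOR_PER_BIN_MEANS = {
    "wt": {
        "drinking": {"frequency": 82.32, "duration_s": 107.40},
        "eating": {"frequency": 456.00, "duration_s": 442.20},
        "grooming": {"frequency": 386.64, "duration_s": 12168.60},
    },
    "lgdel": {
        "drinking": {"frequency": 102.72, "duration_s": 223.2},
        "eating": {"frequency": 1070.88, "duration_s": 1257.60},
        "grooming": {"frequency": 484.56, "duration_s": 11948.40},
    },
}

# Converted units as reported: frequency in events/hour, duration in
# minutes / 24 h.
BEHAVIOR_HOURLY_MEANS = {
    "wt": {
        "drinking": {"frequency_per_h": 3.43, "duration_min": 1.79},
        "eating": {"frequency_per_h": 19.00, "duration_min": 7.37},
        "grooming": {"frequency_per_h": 16.11, "duration_min": 202.81},
    },
    "lgdel": {
        "drinking": {"frequency_per_h": 4.28, "duration_min": 3.72},
        "eating": {"frequency_per_h": 44.63, "duration_min": 20.96},
        "grooming": {"frequency_per_h": 20.19, "duration_min": 199.14},
    },
}

# --- Lung inflammation ratio (percent of image pixels) ----------------------
INFLAMMATION_PERCENT = {"wt": 0.78, "lgdel": 3.93}
INFLAMMATION_SEM_PERCENT = {"wt": 0.13, "lgdel": 0.85}

#: Mean event durations implied by the per-bin values (seconds of behavior
#: per event); used as generator defaults.
def mean_event_duration_s(genotype: str, behavior: str) -> float:
    row = BEHAVIOR_PER_BIN_MEANS[genotype][behavior]
    return row["duration_s"] / row["frequency"]
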