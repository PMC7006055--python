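"""Group statistics over every per-mouse table produced by steps 03-06.

This is the unblinding stage: per-mouse measurements (saved without group
labels) are merged with the separately stored genotype maps only here, then
compared by independent two-sample t-tests with mean +/- SEM. One tidy CSV
per assessment domain is written under results/stats/ with columns
(metric, WT_mean, WT_sem, LgDel_mean, LgDel_sem, p).

Run after 03-06, from the repository root:  python analysis/07_stats_report.py
"""

from pathlib import Path

import pandas as pd

from swallowkit import group_table

DOMAINS = {
    "vfss": ("results/vfss", "per_mouse_metrics.csv"),
    "larynx": ("results/larynx", "per_mouse_metrics.csv"),
    "histology": ("results/histology", "per_mouse_ratios.csv"),
    "behavior": ("results/behavior", "per_mouse_summary.csv"),
}
OUT = Path("results/stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (folder, fname) in DOMAINS.items():
        folder = Path(folder)
        metrics_path = folder / fname
        if not metrics_path.exists():
            print(f"skipping {name}: no {metrics_path}; run the earlier analysis steps first")
            continue
        per_mouse = pd.read_csv(metrics_path, index_col="mouse_id")
        genotypes = pd.read_csv(folder / "genotypes.csv", index_col=0)["genotype"]
        if name == "histology":
            per_mouse = per_mouse[["inflammation_ratio"]]
        table = group_table(per_mouse, genotypes)
        out_path = OUT / f"{name}_group_comparison.csv"
        table.to_csv(out_path, index=False)
        n_sig = int((table["p"] <= 0.05).sum())
        print(f"{name}: {len(table)} metrics compared, {n_sig} significant -> {out_path}")
        for _, row in table[table["p"] <= 0.05].iterrows():
            print(
                f"   {row['metric']}: WT {row['WT_mean']:.3g} ({row['WT_sem']:.2g}) "
                f"vs LgDel {row['LgDel_mean']:.3g} ({row['LgDel_sem']:.2g}), "
                f"p = {row['p']:.3g}"
            )


if __name__ == "__main__":
    main()
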