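"""Independent brute-force recomputations of the metric definitions.

Everything here is written as plain loops straight from the operational
definitions, deliberately sharing no code with the package implementation,
so the test suite can check the vectorized implementations against a second
derivation.
"""

from __future__ import annotations

import math

import numpy as np


def per_second_counts(times, t0, t1):
    eps = 1e-9
    counts = []
    k = 0
    while t0 + k + 1 <= t1 + eps:
        lo, hi = t0 + k, t0 + k + 1
        counts.append(sum(1 for t in times if lo - eps <= t < hi - eps))
        k += 1
    return counts


def oracle_drinking(close_times, open_times, gape_at, fps, swallows, t0, t1):
    """All drinking metrics by explicit loops.

    ``gape_at(t)`` samples the gape trace at the frame nearest t;
    ``swallows`` is a list of (rest_frame, esophagus_entry_frame,
    swallow_frame) triples in clip-local frames.
    """
    eps = 1e-9
    closes = sorted(close_times)
    in_win = [t for t in closes if t0 - eps <= t < t1 - eps]

    counts = per_second_counts(closes, t0, t1)
    lick_rate = sum(counts) / len(counts) if counts else math.nan

    if len(in_win) >= 2:
        diffs = [b - a for a, b in zip(in_win, in_win[1:])]
        ili = 1000.0 * sum(diffs) / len(diffs)
    else:
        ili = math.nan

    s_times = sorted(s[2] / fps for s in swallows)
    s_in = [t for t in s_times if t0 - eps <= t < t1 - eps]
    s_counts = per_second_counts(s_times, t0, t1)
    swallow_rate = sum(s_counts) / len(s_counts) if s_counts else math.nan
    if len(s_in) >= 2:
        diffs = [b - a for a, b in zip(s_in, s_in[1:])]
        isi = 1000.0 * sum(diffs) / len(diffs)
    else:
        isi = math.nan

    if len(s_in) >= 2:
        per_pair = []
        for lo, hi in zip(s_in, s_in[1:]):
            per_pair.append(sum(1 for c in closes if lo + eps < c <= hi + eps))
        ratio = sum(per_pair) / len(per_pair)
    else:
        ratio = math.nan

    if swallows:
        ptt = 1000.0 * sum((e - r) / fps for r, e, _ in swallows) / len(swallows)
    else:
        ptt = math.nan

    merged = sorted(
        [(t, "open") for t in open_times] + [(t, "close") for t in close_times]
    )
    opening, closing = [], []
    for (ta, ka), (tb, kb) in zip(merged, merged[1:]):
        if not (t0 - eps <= tb < t1 - eps) or tb <= ta:
            continue
        slope = abs(gape_at(tb) - gape_at(ta)) / (tb - ta)
        if (ka, kb) == ("close", "open"):
            opening.append(slope)
        elif (ka, kb) == ("open", "close"):
            closing.append(slope)
    v_open = sum(opening) / len(opening) if opening else math.nan
    v_close = sum(closing) / len(closing) if closing else math.nan
    return {
        "lick_rate": lick_rate,
        "inter_lick_interval": ili,
        "swallow_rate": swallow_rate,
        "inter_swallow_interval": isi,
        "lick_swallow_ratio": ratio,
        "pharyngeal_transit_time": ptt,
        "jaw_opening_velocity": v_open,
        "jaw_closing_velocity": v_close,
    }


def oracle_eating(close_times, swallows, rotary_intervals, fps, t0, t1):
    eps = 1e-9
    closes = sorted(close_times)
    rates = []
    for start_f, stop_f in rotary_intervals:
        lo, hi = start_f / fps, stop_f / fps
        n = sum(1 for c in closes if lo - eps <= c < hi - eps)
        rates.append(n / (hi - lo))
    mastication = sum(rates) / len(rates) if rates else math.nan

    s_times = sorted(s[2] / fps for s in swallows)
    s_in = [t for t in s_times if t0 - eps <= t < t1 - eps]
    s_counts = per_second_counts(s_times, t0, t1)
    swallow_rate = sum(s_counts) / len(s_counts) if s_counts else math.nan
    if len(s_in) >= 2:
        diffs = [b - a for a, b in zip(s_in, s_in[1:])]
        isi = sum(diffs) / len(diffs)
    else:
        isi = math.nan
    return {
        "mastication_rate": mastication,
        "swallow_rate": swallow_rate,
        "inter_swallow_interval": isi,
    }


def oracle_laryngeal(amp_pairs, n_left, n_right, left_vals, right_vals, clip_seconds):
    """MMRR / OCCR / Mcorr / respiratory rate by explicit formulas.

    ``amp_pairs`` is the per-width-cycle (left amplitude, right amplitude)
    list; Mcorr is the textbook Pearson correlation of first differences.
    """
    ratios = []
    for al, ar in amp_pairs:
        hi = max(al, ar)
        if hi > 0:
            ratios.append(min(al, ar) / hi)
    mmrr = sum(ratios) / len(ratios) if ratios else math.nan
    occr = n_right / n_left if n_left else math.nan

    dl = [b - a for a, b in zip(left_vals, left_vals[1:])]
    dr = [b - a for a, b in zip(right_vals, right_vals[1:])]
    n = len(dl)
    ml = sum(dl) / n
    mr = sum(dr) / n
    cov = sum((a - ml) * (b - mr) for a, b in zip(dl, dr))
    vl = sum((a - ml) ** 2 for a in dl)
    vr = sum((b - mr) ** 2 for b in dr)
    mcorr = cov / math.sqrt(vl * vr) if vl > 0 and vr > 0 else math.nan
    rate = len(amp_pairs) * 60.0 / clip_seconds
    return {"mmrr": mmrr, "occr": occr, "mcorr": mcorr, "respiratory_rate": rate}


def oracle_ttest(a, b):
    """Equal-variance two-sample t-test from the textbook formulas."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    from scipy.stats import t as tdist

    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def oracle_anova_balanced(table):
    """Two-way ANOVA sums of squares for a balanced layout, by hand.

    ``table[i][j]`` is the list of observations in cell (genotype i, side j);
    all cells must have equal n. Returns (F_geno, F_side, F_inter) with
    their p-values.
    """
    a = len(table)
    b = len(table[0])
    n = len(table[0][0])
    grand = [x for row in table for cell in row for x in cell]
    gm = sum(grand) / len(grand)
    cell_means = [[sum(c) / n for c in row] for row in table]
    row_means = [sum(cell_means[i]) / b for i in range(a)]
    col_means = [sum(cell_means[i][j] for i in range(a)) / a for j in range(b)]

    ss_a = n * b * sum((rm - gm) ** 2 for rm in row_means)
    ss_b = n * a * sum((cm - gm) ** 2 for cm in col_means)
    ss_ab = n * sum(
        (cell_means[i][j] - row_means[i] - col_means[j] + gm) ** 2
        for i in range(a)
        for j in range(b)
    )
    ss_e = sum(
        (x - cell_means[i][j]) ** 2
        for i in range(a)
        for j in range(b)
        for x in table[i][j]
    )
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_e = ss_e / df_e
    from scipy.stats import f as fdist

    f_a = (ss_a / df_a) / ms_e
    f_b = (ss_b / df_b) / ms_e
    f_ab = (ss_ab / df_ab) / ms_e
    return (
        (f_a, fdist.sf(f_a, df_a, df_e)),
        (f_b, fdist.sf(f_b, df_b, df_e)),
        (f_ab, fdist.sf(f_ab, df_ab, df_e)),
    )
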