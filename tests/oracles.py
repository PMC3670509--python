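"""Independent single-expression evaluator for every body-fat method.

Written separately from the package on purpose: each method is one flat
expression over a plain dict of measurements, with all branching inline.
Used to cross-check the battery on random subjects.  No code is shared with
``adipoquant.bodyfat``.
"""

import math


def oracle_percent_fat(method, s):
    male = s["sex"] == "male"
    a = s["age"]
    wt = s["weight"]
    ht = s["height"]
    four = s["biceps"] + s["triceps"] + s["suprailiac"] + s["subscapular"]
    ts = s["triceps"] + s["subscapular"]

    if method == "EQ1":
        if int(a) in (15, 16):
            d = (1.1533 - 0.0643 * math.log10(four)) if male else (1.1369 - 0.0598 * math.log10(four))
        else:
            d = (1.1620 - 0.0630 * math.log10(four)) if male else (1.1549 - 0.0678 * math.log10(four))
        return (4.95 / d - 4.50) * 100.0

    if method == "EQ2":
        return 1.35 * ts - 0.012 * ts * ts + (-4.4 if male else -2.4)

    if method == "EQ3":
        tc = s["triceps"] + s["calf"]
        return (0.735 * tc + 1.0) if male else (0.610 * tc + 5.1)

    if method == "EQ4":
        if ts <= 35.0:
            if male:
                black = s["race"] != "white"
                i = {"prepubescent": (-3.5 if black else -1.7),
                     "pubescent": (-5.2 if black else -3.4),
                     "postpubescent": (-6.8 if black else -5.5)}[s["maturation"]]
                return 1.21 * ts - 0.008 * ts * ts + i
            return 1.33 * ts - 0.013 * ts * ts - 2.5
        return (0.783 * ts + 1.6) if male else (0.546 * ts + 9.7)

    if method == "EQ5":
        if male:
            d = (1.1315 + 0.0018 * (a - 2)) - (0.0719 - 0.0006 * (a - 2)) * math.log10(four)
            return (562 - 4.2 * (a - 2)) / d - (525 - 4.7 * (a - 2))
        d = (1.1350 + 0.0031 * (a - 10)) - (0.0719 - 0.0003 * (a - 2)) * math.log10(four)
        return (553 - 7.3 * (a - 10)) / d - (514 - 8.0 * (a - 10))

    if method == "EQ6":
        if male:
            amc = s["brachial_perimeter"] - math.pi * s["triceps"] / 10.0
            ffm = (0.646 * wt - 0.116 * s["calf"] - 0.375 * s["midaxillary"]
                   + 0.475 * amc + 0.156 * ht * ht / s["resistance"] - 2.932)
        else:
            ffm = (0.682 * wt - 0.185 * s["calf"] - 0.244 * s["triceps"]
                   - 0.202 * s["subscapular"] + 0.182 * ht * ht / s["resistance"] + 4.338)
        return 100.0 * (wt - ffm) / wt

    if method == "EQ7":
        return (18.88 * math.log10(four) - 15.58) if male else (39.02 * math.log10(four) - 43.49)

    if method == "EQ8":
        bmi = wt / (ht / 100.0) ** 2
        if int(a) <= 15:
            return 1.51 * bmi - 0.70 * a - 3.6 * (1 if male else 0) + 1.4
        return 1.2 * bmi + 0.23 * a - 10.8 * (1 if male else 0) - 5.4

    if method in ("EQ9", "BIA1"):
        ffm = 0.61 * ht * ht / s["resistance"] + 0.25 * wt + 1.31
        return 100.0 * (wt - ffm) / wt

    if method == "EQ10":
        white = s["race"] == "white"
        if male:
            f = (0.534 * wt - 1.59 * a + 3.03) if white else (0.594 * wt - 0.381 * ht + 36.0)
        else:
            f = (0.642 * wt - 0.120 * ht - 0.606 * a + 8.98) if white else \
                (0.653 * wt - 0.163 * ht - 0.298 * a + 10.7)
        return 100.0 * f / wt

    if method == "BIA2":
        return s["bia2_percent_fat"]

    raise ValueError(f"unknown method {method}")
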