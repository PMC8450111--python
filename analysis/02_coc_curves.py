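#!/usr/bin/env python
"""Coefficient-of-coincidence curves for the simulated cohorts.

Reads the focus tables written by 01_simulate_focus_data.py, computes the
30-interval CoC curve for each cohort, and prints the two numbers that
summarize interference strength: the CoC at the shortest inter-interval
distance (0 under strong interference) and the mean CoC at distances above
half the axis (1 when interference has decayed).
"""

from pathlib import Path

from meicoc import io
from meicoc.interference import IntervalSpec, coc_curve_binomial_se, coc_pairs

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("poisson", "wt_like", "strong"):
        chroms = io.read_focus_table(RESULTS / f"foci_{name}.tsv")
        pairs = coc_pairs(chroms, IntervalSpec(30))
        curve = coc_curve_binomial_se(pairs, len(chroms))
        out = RESULTS / f"coc_{name}.tsv"
        curve.to_csv(out, sep="\t", index=False, float_format="%.6g")
        near = curve["mean_coc"].iloc[0]
        far = curve.loc[curve["distance"] > 0.5, "mean_coc"].mean()
        print(f"{name:8s} CoC(shortest)={near:6.3f}  CoC(d>0.5)={far:5.3f} -> {out.name}")
    print("\nNo interference keeps the curve flat at 1; interference drives the")
    print("short-distance CoC toward 0 while the long-distance tail stays at 1.")


if __name__ == "__main__":
    main()
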