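#!/usr/bin/env python
"""Gamma-shape interference estimates and the edge-censoring bias study.

Part 1 fits the two-parameter gamma to inter-adjacent focus distances for
each simulated cohort (maximum likelihood; renewal-bootstrap 95% CI).

Part 2 quantifies why the CI method matters: the plain gamma MLE applied to
gaps observed inside a finite axis is biased upward, and the bias grows as
the axis holds fewer foci. The table written here (axis-length/spacing
ratio vs relative bias) documents the package's choice to validate the fit
with the renewal-aware bootstrap rather than the iid percentile bootstrap.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meicoc import io
from meicoc.interference import fit_gamma, inter_focus_distances, gamma_shape_mle
from meicoc.simulate import SimulationConfig, simulate_focus_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20260922


def main() -> None:
    rows = []
    for name in ("poisson", "wt_like", "strong"):
        chroms = io.read_focus_table(RESULTS / f"foci_{name}.tsv")
        for normalized in (True, False):
            fit = fit_gamma(chroms, normalized=normalized, n_boot=300, seed=SEED,
                            ci_method="renewal")
            rows.append(
                {
                    "cohort": name,
                    "units": "normalized" if normalized else "micron",
                    "shape": fit.shape,
                    "scale": fit.scale,
                    "loglik": fit.log_likelihood,
                    "n": fit.n_distances,
                    "shape_lo": fit.shape_ci[0],
                    "shape_hi": fit.shape_ci[1],
                }
            )
            print(f"{name:8s} {'normalized' if normalized else 'micron':10s} "
                  f"shape={fit.shape:6.3f}  95% CI=({fit.shape_ci[0]:.3f}, "
                  f"{fit.shape_ci[1]:.3f})  n_gaps={fit.n_distances}")
    pd.DataFrame(rows).to_csv(RESULTS / "gamma_fits.tsv", sep="\t", index=False,
                              float_format="%.6g")
    print("\nNormalized gaps divide by each axis' own length; when axis lengths")
    print("vary (15% CV here) that scale mixture attenuates large shapes, so the")
    print("micron-unit fit tracks the generating shape more closely.")

    print("\nEdge-censoring bias of the plain MLE (relative error of the shape):")
    bias_rows = []
    for true_shape in (1.0, 5.0):
        for foci_per_axis in (3, 6, 15):
            estimates = []
            for rep in range(6):
                cfg = SimulationConfig(
                    shape=true_shape, mean_spacing=3.0 / foci_per_axis,
                    axis_length_mean=3.0, n_nuclei=3000, seed=SEED + rep,
                )
                gaps = inter_focus_distances(simulate_focus_dataset(cfg))
                estimates.append(gamma_shape_mle(gaps)[0])
            rel_bias = float(np.mean(estimates)) / true_shape - 1.0
            bias_rows.append(
                {"true_shape": true_shape, "foci_per_axis": foci_per_axis,
                 "rel_bias": rel_bias}
            )
            print(f"  shape={true_shape:3g}  ~{foci_per_axis:2d} foci/axis: "
                  f"{rel_bias:+.1%}")
    pd.DataFrame(bias_rows).to_csv(RESULTS / "censoring_bias.tsv", sep="\t",
                                   index=False, float_format="%.4g")


if __name__ == "__main__":
    main()
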