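#!/usr/bin/env python
"""Immunofluorescence quantification on synthetic nuclei with known signal.

Generates spot-on-background nucleus images (the generator records the
noise-free in-mask spot signal), estimates per-nucleus background from
three perpendicular line profiles, computes the background-corrected
integrated intensity, and reports the recovery error against ground truth.
Also writes one example scene (image, mask, line endpoints) as TIFF/TSV so
the ``meicoc quantify`` command can be exercised on files.
"""

from pathlib import Path

import pandas as pd

from meicoc import io
from meicoc.experiments import quantification_scene
from meicoc.quant import quantify_nucleus

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20260922


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for i in range(5):
        sample, lines = quantification_scene(SEED + i)
        res = quantify_nucleus(sample.image, sample.mask, lines,
                               smooth_window=5, slope_frac=0.03)
        err = res.corrected_total / sample.true_signal - 1.0
        rows.append({"nucleus_id": f"n{i}", "background": res.background_per_pixel,
                     "n_above": res.n_pixels_above, "raw_total": res.raw_total,
                     "corrected_total": res.corrected_total,
                     "true_signal": sample.true_signal, "rel_error": err})
        print(f"n{i}: background={res.background_per_pixel:6.1f} "
              f"corrected={res.corrected_total:9.0f} truth={sample.true_signal:9.0f} "
              f"error={err:+.2%}")
        if i == 0:
            io.write_image(sample.image, RESULTS / "example_nucleus.tif")
            io.write_mask(sample.mask, RESULTS / "example_mask.tif")
            pd.DataFrame(lines, columns=["x1", "y1", "x2", "y2"]).to_csv(
                RESULTS / "example_lines.tsv", sep="\t", index=False
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "quantification.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(f"\nworst |error| = {frame['rel_error'].abs().max():.2%} over {len(frame)} nuclei")


if __name__ == "__main__":
    main()
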