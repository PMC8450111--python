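import numpy as np
import pytest

from meicoc.simulate import FocusChromosome

SEED = 20260922


def make_chrom(positions, axis_length=3.0, strain="wt", nucleus="n0", chrom="c0"):
    return FocusChromosome(
        strain=strain,
        nucleus_id=nucleus,
        chromosome_id=chrom,
        axis_length=axis_length,
        focus_positions=np.asarray(positions, dtype=float),
    )


@pytest.fixture
def four_chromosomes():
    """Hand-checkable set: foci in intervals {1,5}, {1}, {5}, {} of a 6-bin
    split of a 3-um axis (bin width 0.5 um)."""
    return [
        make_chrom([0.6, 2.7], nucleus="n0"),
        make_chrom([0.7], nucleus="n1"),
        make_chrom([2.6], nucleus="n2"),
        make_chrom([], nucleus="n3"),
    ]
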