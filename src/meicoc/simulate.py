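"""Synthetic focus-mapping, tetrad, and nucleus-image generators.

The focus simulator places crossover-marker (Zip3-like) foci along a
chromosome axis by a *stationary gamma-renewal process*: inter-focus gaps
are i.i.d. Gamma(shape=nu, mean=mu) and the first focus is drawn from the
equilibrium forward-recurrence distribution, so the point process is
statistically homogeneous along the axis.  nu = 1 reduces to a homogeneous
Poisson process (no interference); larger nu produces more evenly spaced
foci, i.e. stronger crossover interference.

All generators are seeded and bit-reproducible: one root seed spawns one
child stream per nucleus, so regenerating a subset of nuclei reproduces
exactly the same chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "FocusChromosome",
    "TetradPattern",
    "ImageSample",
    "simulate_focus_dataset",
    "simulate_tetrads",
    "simulate_nucleus_image",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the gamma-renewal focus simulator.

    Parameters
    ----------
    shape
        Gamma shape nu of the inter-focus gap distribution. nu = 1 means no
        interference (Poisson); larger nu means stronger interference.
    mean_spacing
        Mean inter-focus distance mu, in micrometres.
    axis_length_mean, axis_length_cv
        Mean and coefficient of variation of the per-nucleus axis length
        (lognormal; cv = 0 gives a fixed length).
    n_nuclei, chromosomes_per_nucleus
        Dataset dimensions. Chromosomes within a nucleus share the nucleus'
        axis length.
    seed
        Root seed of the per-nucleus child streams.
    strain
        Label written into every chromosome record.
    obligate
        If true, chromosomes are redrawn until they carry at least one focus
        (obligatory-crossover enforcement). Off by default: the downstream
        analyses measure the zero-focus frequency.
    """

    shape: float
    mean_spacing: float
    axis_length_mean: float
    axis_length_cv: float = 0.0
    n_nuclei: int = 1
    chromosomes_per_nucleus: int = 1
    seed: int = 0
    strain: str = "sim"
    obligate: bool = False

    def __post_init__(self) -> None:
        if not (self.shape > 0):
            raise ConfigurationError(f"shape must be > 0, got {self.shape}")
        if not (self.mean_spacing > 0):
            raise ConfigurationError(
                f"mean_spacing must be > 0, got {self.mean_spacing}"
            )
        if not (self.axis_length_mean > 0):
            raise ConfigurationError(
                f"axis_length_mean must be > 0, got {self.axis_length_mean}"
            )
        if self.axis_length_cv < 0:
            raise ConfigurationError(
                f"axis_length_cv must be >= 0, got {self.axis_length_cv}"
            )
        if int(self.n_nuclei) < 1 or int(self.chromosomes_per_nucleus) < 1:
            raise ConfigurationError("n_nuclei and chromosomes_per_nucleus must be >= 1")


@dataclass(frozen=True)
class FocusChromosome:
    """One chromosome: axis length and ordered focus positions (um from the
    marked end). An empty position array is a chromosome lacking foci."""

    strain: str
    nucleus_id: str
    chromosome_id: str
    axis_length: float
    focus_positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.focus_positions, dtype=float)
        object.__setattr__(self, "focus_positions", pos)
        if not (self.axis_length > 0):
            raise ValueError(
                f"axis_length must be > 0 ({self.strain}/{self.nucleus_id}/"
                f"{self.chromosome_id})"
            )
        if pos.size:
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"focus positions must be sorted ascending "
                    f"({self.strain}/{self.nucleus_id}/{self.chromosome_id})"
                )
            if pos[0] < 0 or pos[-1] > self.axis_length:
                raise ValueError(
                    f"focus position outside [0, axis_length] "
                    f"({self.strain}/{self.nucleus_id}/{self.chromosome_id})"
                )

    @property
    def n_foci(self) -> int:
        return int(self.focus_positions.size)


@dataclass(frozen=True)
class TetradPattern:
    """Four spore colors of one tetrad; values from {"Y", "R", "N"}."""

    tetrad_id: str
    spore_colors: tuple

    def __post_init__(self) -> None:
        colors = tuple(self.spore_colors)
        object.__setattr__(self, "spore_colors", colors)
        if len(colors) != 4:
            raise ValueError(f"tetrad {self.tetrad_id}: expected 4 spores")
        bad = set(colors) - {"Y", "R", "N"}
        if bad:
            raise ValueError(f"tetrad {self.tetrad_id}: bad colors {sorted(bad)}")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _renewal_positions(
    rng: np.random.Generator, shape: float, mean_spacing: float, lengths: np.ndarray
) -> list[np.ndarray]:
    """Stationary gamma-renewal events on windows [0, L_i], vectorized
    across windows.

    The first event is U * G* with G* ~ Gamma(nu+1) (length-biased gap,
    uniform position within it) — the forward-recurrence distribution of the
    equilibrium renewal process. Subsequent gaps are i.i.d. Gamma(nu).
    """
    theta = mean_spacing / shape
    n = lengths.size
    lmax = float(lengths.max())
    first = rng.uniform(size=n) * rng.gamma(shape + 1.0, theta, size=n)
    expected = lmax / mean_spacing
    k0 = int(expected + 6.0 * math.sqrt(expected + 1.0) + 8.0)
    pos = np.empty((n, k0 + 1))
    pos[:, 0] = first
    gaps = rng.gamma(shape, theta, size=(n, k0))
    pos[:, 1:] = first[:, None] + np.cumsum(gaps, axis=1)
    # extend the rare rows whose last event is still inside the window
    while True:
        unfinished = pos[:, -1] <= lengths
        if not unfinished.any():
            break
        extra = rng.gamma(shape, theta, size=(n, 8))
        block = pos[:, -1][:, None] + np.cumsum(extra, axis=1)
        pos = np.concatenate([pos, block], axis=1)
    out = []
    for i in range(n):
        p = pos[i]
        out.append(p[p <= lengths[i]].copy())
    return out


def simulate_focus_dataset(config: SimulationConfig) -> list[FocusChromosome]:
    """Generate a focus-position dataset under *config*.

    Returns one :class:`FocusChromosome` per (nucleus, chromosome), in
    nucleus-major order, including chromosomes with zero foci.
    """
    root = np.random.SeedSequence(int(config.seed))
    children = root.spawn(int(config.n_nuclei))
    mu_ln, sd_ln = _lognormal_params(config.axis_length_mean, config.axis_length_cv)
    n_chrom = int(config.chromosomes_per_nucleus)
    out: list[FocusChromosome] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        length = (
            config.axis_length_mean
            if config.axis_length_cv == 0
            else float(rng.lognormal(mu_ln, sd_ln))
        )
        lengths = np.full(n_chrom, length)
        positions = _renewal_positions(rng, config.shape, config.mean_spacing, lengths)
        if config.obligate:
            for c in range(n_chrom):
                attempts = 0
                while positions[c].size == 0:
                    attempts += 1
                    if attempts > 1000:
                        raise ConfigurationError(
                            "obligate resampling did not place a focus in 1000 "
                            "attempts; axis is far shorter than mean_spacing"
                        )
                    positions[c] = _renewal_positions(
                        rng, config.shape, config.mean_spacing, lengths[c : c + 1]
                    )[0]
        nucleus_id = f"n{i:05d}"
        for c in range(n_chrom):
            out.append(
                FocusChromosome(
                    strain=config.strain,
                    nucleus_id=nucleus_id,
                    chromosome_id=f"c{c:02d}",
                    axis_length=float(lengths[c]),
                    focus_positions=positions[c],
                )
            )
    return out


_ABERRANT = (
    ("Y", "Y", "Y", "R"),
    ("Y", "R", "R", "R"),
    ("Y", "Y", "Y", "Y"),
    ("R", "R", "R", "R"),
)


def simulate_tetrads(
    n: int, missegregation_rate: float, blank_rate: float, seed: int
) -> list[TetradPattern]:
    """Spore-color patterns for *n* tetrads.

    Faithful segregation gives 2 yellow + 2 red spores; with probability
    ``missegregation_rate`` an aberrant fluorescent pattern is emitted
    instead; independently, with probability ``blank_rate`` the tetrad has
    no fluorescent spores at all (these are excluded downstream).
    """
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    for name, rate in (("missegregation_rate", missegregation_rate), ("blank_rate", blank_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(int(seed))
    out: list[TetradPattern] = []
    for i in range(int(n)):
        if rng.random() < blank_rate:
            colors = ("N", "N", "N", "N")
        else:
            base = (
                _ABERRANT[rng.integers(len(_ABERRANT))]
                if rng.random() < missegregation_rate
                else ("Y", "Y", "R", "R")
            )
            colors = tuple(np.asarray(base)[rng.permutation(4)])
        out.append(TetradPattern(tetrad_id=f"t{i:05d}", spore_colors=colors))
    return out


@dataclass(frozen=True)
class ImageSample:
    """A simulated nucleus image with its mask and ground-truth signal.

    ``true_signal`` is the noise-free integrated spot intensity inside the
    mask — the quantity the quantification module should recover.
    """

    image: np.ndarray
    mask: np.ndarray
    true_signal: float


def simulate_nucleus_image(
    width: int,
    height: int,
    background: float,
    noise_sd: float,
    spots: list[tuple[float, float, float, float]],
    seed: int,
    mask: tuple[float, float, float] | None = None,
) -> ImageSample:
    """Uniform background + Gaussian-profile spots + Gaussian pixel noise.

    Parameters
    ----------
    spots
        List of ``(x, y, amplitude, sigma)``; centers must lie inside the
        raster.
    mask
        Optional ``(cx, cy, radius)`` disk; default is the full frame.
    """
    if width <= 0 or height <= 0:
        raise ConfigurationError("image dimensions must be positive")
    if background < 0 or noise_sd < 0:
        raise ConfigurationError("background and noise_sd must be >= 0")
    for x, y, amp, sig in spots:
        if not (0 <= x < width and 0 <= y < height):
            raise ConfigurationError(f"spot center ({x}, {y}) outside the raster")
        if amp < 0 or sig <= 0:
            raise ConfigurationError("spot amplitude must be >= 0 and sigma > 0")
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    spot_img = np.zeros((height, width))
    for x, y, amp, sig in spots:
        spot_img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sig * sig))
    if mask is None:
        mask_arr = np.ones((height, width), dtype=bool)
    else:
        cx, cy, r = mask
        mask_arr = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    rng = np.random.default_rng(int(seed))
    noise = rng.normal(0.0, noise_sd, size=(height, width)) if noise_sd > 0 else 0.0
    image = np.clip(background + spot_img + noise, 0.0, None)
    return ImageSample(
        image=image, mask=mask_arr, true_signal=float(spot_img[mask_arr].sum())
    )
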