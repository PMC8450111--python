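"""Per-nucleus and per-strain focus/axis summaries, obligatory-crossover and
independence arithmetic, tetrad missegregation scoring, and the two
significance tests used throughout (Welch/Student t for means, pooled
two-proportion z for frequencies)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .simulate import FocusChromosome, TetradPattern

__all__ = [
    "NucleusSummary",
    "StrainComparison",
    "summarize_nuclei",
    "summaries_to_frame",
    "strain_summary",
    "zero_focus_frequencies",
    "expected_under_independence",
    "conditional_fraction",
    "overlap_fraction",
    "missegregation_frequency",
    "two_proportion_z",
    "welch_t",
    "significance_stars",
]


@dataclass(frozen=True)
class NucleusSummary:
    strain: str
    nucleus_id: str
    total_axis_length: float
    total_foci: int
    foci_per_micron: float
    has_focusless_chromosome: bool


@dataclass(frozen=True)
class StrainComparison:
    """Two-sample comparison: group means/proportions, their ratio, and the
    test statistic with its two-sided p-value. ``flagged`` marks degenerate
    inputs where the statistic is undefined by formula and set by convention."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    ratio_b_over_a: float
    test_statistic: float
    p_value: float
    df: float | None = None
    flagged: bool = False


def summarize_nuclei(chroms: list[FocusChromosome]) -> list[NucleusSummary]:
    """Sum axis length and focus counts per (strain, nucleus); flag nuclei
    containing a chromosome without foci."""
    if not chroms:
        raise ValueError("empty chromosome collection")
    seen: set[tuple] = set()
    groups: dict[tuple, list[FocusChromosome]] = {}
    for ch in chroms:
        key = (ch.strain, ch.nucleus_id, ch.chromosome_id)
        if key in seen:
            raise ValueError(f"duplicate chromosome record {key}")
        seen.add(key)
        groups.setdefault((ch.strain, ch.nucleus_id), []).append(ch)
    out = []
    for (strain, nid), members in groups.items():
        total_len = float(sum(ch.axis_length for ch in members))
        total_foci = int(sum(ch.n_foci for ch in members))
        out.append(
            NucleusSummary(
                strain=strain,
                nucleus_id=nid,
                total_axis_length=total_len,
                total_foci=total_foci,
                foci_per_micron=total_foci / total_len,
                has_focusless_chromosome=any(ch.n_foci == 0 for ch in members),
            )
        )
    return out


def summaries_to_frame(summaries: list[NucleusSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def strain_summary(chroms: list[FocusChromosome]) -> pd.DataFrame:
    """Per-strain table: nucleus counts, focus/axis means and SDs, density,
    and the two zero-focus frequencies."""
    nuc = summaries_to_frame(summarize_nuclei(chroms))
    rows = []
    for strain, grp in nuc.groupby("strain", sort=False):
        strain_chroms = [c for c in chroms if c.strain == strain]
        per_chrom, per_nuc = zero_focus_frequencies(strain_chroms)
        rows.append(
            {
                "strain": strain,
                "n_nuclei": len(grp),
                "mean_foci": grp["total_foci"].mean(),
                "sd_foci": grp["total_foci"].std(ddof=1),
                "mean_axis_um": grp["total_axis_length"].mean(),
                "sd_axis": grp["total_axis_length"].std(ddof=1),
                "foci_per_um": grp["total_foci"].sum() / grp["total_axis_length"].sum(),
                "zero_focus_chrom_freq": per_chrom,
                "zero_focus_nucleus_freq": per_nuc,
            }
        )
    return pd.DataFrame(rows)


def zero_focus_frequencies(chroms: list[FocusChromosome]) -> tuple[float, float]:
    """(fraction of chromosomes with 0 foci, fraction of nuclei with >= 1
    such chromosome) — the obligatory-crossover readout."""
    if not chroms:
        raise ValueError("empty chromosome collection")
    empty = np.array([ch.n_foci == 0 for ch in chroms])
    nuclei: dict[tuple, bool] = {}
    for ch, e in zip(chroms, empty):
        key = (ch.strain, ch.nucleus_id)
        nuclei[key] = nuclei.get(key, False) or bool(e)
    return float(empty.mean()), float(np.mean(list(nuclei.values())))


def expected_under_independence(frac_a: float, frac_b: float) -> float:
    """Multiplicative expectation for a double mutant whose two lesions act
    independently, each expressed as a fraction of wild type."""
    for name, v in (("frac_a", frac_a), ("frac_b", frac_b)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return frac_a * frac_b


def conditional_fraction(numerator_pct: float, denominator_pct: float) -> float:
    """Ratio of two percentages, itself as a percentage (e.g. the fraction of
    MII-completing cells that sporulate)."""
    if denominator_pct <= 0:
        raise ValueError("denominator percentage must be > 0")
    return 100.0 * numerator_pct / denominator_pct


def overlap_fraction(n_overlapping: int, n_total: int) -> float:
    """Percentage of foci overlapping a reference signal (exact, unrounded;
    display at two decimals)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_overlapping <= n_total):
        raise ValueError("need 0 <= n_overlapping <= n_total")
    return 100.0 * n_overlapping / n_total


def missegregation_frequency(
    tetrads: list[TetradPattern],
) -> tuple[float, int, int]:
    """Score tetrads for chromosome missegregation.

    2 yellow + 2 red spores is faithful segregation; any other color multiset
    with at least one fluorescent spore counts as missegregated; tetrads with
    no fluorescent spores are excluded from the denominator.

    Returns ``(frequency, n_scored, n_excluded)``.
    """
    if not tetrads:
        raise ValueError("empty tetrad collection")
    n_mis = n_scored = n_excluded = 0
    for t in tetrads:
        counts = {c: t.spore_colors.count(c) for c in ("Y", "R", "N")}
        if counts["Y"] + counts["R"] == 0:
            n_excluded += 1
            continue
        n_scored += 1
        if not (counts["Y"] == 2 and counts["R"] == 2):
            n_mis += 1
    if n_scored == 0:
        raise ValueError("no scoreable tetrads: all lack fluorescent spores")
    return n_mis / n_scored, n_scored, n_excluded


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> StrainComparison:
    """Pooled-variance two-proportion z-test, two-sided."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValueError("need 0 <= x <= n and n > 0 for both samples")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    flagged = pooled in (0.0, 1.0)
    if flagged:
        z, p = float("nan"), 1.0
    else:
        z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return StrainComparison(
        mean_a=p1,
        mean_b=p2,
        sd_a=math.sqrt(p1 * (1 - p1)),
        sd_b=math.sqrt(p2 * (1 - p2)),
        n_a=n1,
        n_b=n2,
        ratio_b_over_a=p2 / p1 if p1 != 0 else float("nan"),
        test_statistic=float(z),
        p_value=float(p),
        flagged=flagged,
    )


def welch_t(samples_a, samples_b, equal_var: bool = False) -> StrainComparison:
    """Two-sided t-test of means (Welch by default; ``equal_var=True`` for
    the classic pooled-variance Student test)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    flagged = va == 0 and vb == 0
    if flagged and a.mean() == b.mean():
        t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return StrainComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
        n_a=int(a.size),
        n_b=int(b.size),
        ratio_b_over_a=float(b.mean() / a.mean()) if a.mean() != 0 else float("nan"),
        test_statistic=t,
        p_value=p,
        df=df,
        flagged=bool(flagged),
    )


def significance_stars(p: float) -> str:
    """n.s. / * / ** / *** at 0.05, 0.01, 0.001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
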