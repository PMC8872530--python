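"""Biological sex estimation from shotgun read counts (the Rx statistic).

For each autosome i, the length-normalised ratio

    r_i = (N_X / L_X) / (N_i / L_i)

compares X-chromosome read density to that autosome's. Rx is the mean of
the 22 ratios; XX samples give Rx ~ 1 and XY samples Rx ~ 0.5 because
males carry a single X. The 95% confidence interval uses the sample
standard deviation of the 22 ratios: half-width 1.96 * SD / sqrt(22).
Assignment thresholds: male iff the CI upper bound is below 0.60, female
iff the CI lower bound is above 0.80, otherwise inconclusive.
Y-chromosome reads play no role in the statistic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import AUTOSOMES

N_AUTOSOMES = 22
MALE_CI_UPPER = 0.60
FEMALE_CI_LOWER = 0.80


@dataclasses.dataclass(frozen=True)
class RxResult:
    ratios: np.ndarray
    rx: float
    sd: float
    ci_half_width: float
    ci_low: float
    ci_high: float
    assignment: str

    def to_dict(self) -> dict:
        return {
            "Rx": self.rx,
            "SD": self.sd,
            "CI": self.ci_half_width,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
            "assignment": self.assignment,
        }


def ci_half_width(sd: float, n: int = N_AUTOSOMES) -> float:
    """Half-width of the 95% CI of the mean of ``n`` ratios: 1.96*sd/sqrt(n)."""
    return 1.96 * sd / math.sqrt(n)


def assign_sex(ci_low, ci_high: float | None = None) -> str:
    """Threshold rule on the Rx confidence interval (strict inequalities).

    Accepts either an :class:`RxResult` or the two CI bounds.
    """
    if ci_high is None:
        ci_low, ci_high = ci_low.ci_low, ci_low.ci_high
    if ci_high < MALE_CI_UPPER:
        return "male"
    if ci_low > FEMALE_CI_LOWER:
        return "female"
    return "inconclusive"


def _normalise_chrom(label) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def compute_rx(counts: pd.DataFrame | Mapping[str, int], lengths: Mapping[str, int] | None = None) -> RxResult:
    """Compute Rx and the sex assignment from per-chromosome read counts.

    ``counts`` is either a table with columns ``chrom, n_reads,
    length_bp`` or a mapping ``chrom -> n_reads`` accompanied by a
    ``lengths`` mapping. Chromosomes 1-22 and X are required ('chr'
    prefixes are accepted); every autosome must have at least one read,
    otherwise its ratio is undefined.
    """
    if isinstance(counts, pd.DataFrame):
        n = {_normalise_chrom(r.chrom): int(r.n_reads) for r in counts.itertuples()}
        length = {_normalise_chrom(r.chrom): int(r.length_bp) for r in counts.itertuples()}
    else:
        if lengths is None:
            raise ValueError("lengths mapping required when counts is a mapping")
        n = {_normalise_chrom(k): int(v) for k, v in counts.items()}
        length = {_normalise_chrom(k): int(v) for k, v in lengths.items()}

    needed = list(AUTOSOMES) + ["X"]
    missing = [c for c in needed if c not in n or c not in length]
    if missing:
        raise ValueError(f"missing chromosomes in counts table: {missing}")
    zero = [c for c in AUTOSOMES if n[c] == 0]
    if zero:
        raise ValueError(f"autosomes with zero reads, ratio undefined: {zero}")
    if any(length[c] <= 0 for c in needed):
        raise ValueError("all chromosome lengths must be positive")

    x_density = n["X"] / length["X"]
    ratios = np.array([x_density / (n[c] / length[c]) for c in AUTOSOMES])
    rx = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    half = ci_half_width(sd)
    lo, hi = rx - half, rx + half
    return RxResult(
        ratios=ratios,
        rx=rx,
        sd=sd,
        ci_half_width=half,
        ci_low=lo,
        ci_high=hi,
        assignment=assign_sex(lo, hi),
    )
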