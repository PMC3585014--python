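"""Fragment length distributions and size-class enrichment statistics.

The "area under the curve" of a unit-normalized length distribution is a
discrete sum over 1-bp length bins: fragment lengths are integers, so
unit-area normalization is exactly sum-to-one.  The nucleosomal class
defaults to 141-250 bp and the supernucleosomal class to 251-428 bp; the
supernucleosomal/nucleosomal AUC ratio of an IP sample divided by that of
its input measures how strongly the IP enriches for long protections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import FragmentSet

log = logging.getLogger(__name__)

NUCLEOSOMAL_RANGE = (141, 250)
SUPERNUCLEOSOMAL_RANGE = (251, 428)


@dataclass
class SizeDistribution:
    """Per-length density over an inclusive integer length range."""

    min_length: int
    max_length: int
    density: np.ndarray  # one value per length in [min_length, max_length]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.max_length - self.min_length + 1,):
            raise ValueError("density length must match the length range")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if self.normalized and abs(self.density.sum() - 1.0) > 1e-9:
            raise ValueError("normalized distribution must sum to 1")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.min_length, self.max_length + 1)

    def at(self, length: int) -> float:
        if not self.min_length <= length <= self.max_length:
            return 0.0
        return float(self.density[length - self.min_length])


@dataclass
class SizeClassStat:
    """AUC in the nucleosomal and supernucleosomal classes and their ratio."""

    nucleosomal_range: tuple[int, int]
    supernucleosomal_range: tuple[int, int]
    nucleosomal_auc: float
    supernucleosomal_auc: float
    ratio: float


def length_histogram(fs: FragmentSet) -> SizeDistribution:
    """Unit-area distribution of fragment lengths: density[L] = n_L / n."""
    if len(fs) == 0:
        raise ValueError("cannot build a size distribution from an empty fragment set")
    lengths = fs.lengths()
    lo, hi = int(lengths.min()), int(lengths.max())
    counts = np.bincount(lengths - lo, minlength=hi - lo + 1)
    return SizeDistribution(lo, hi, counts / counts.sum(), normalized=True)


def class_auc(d: SizeDistribution, lo: int, hi: int) -> float:
    """Summed density over lengths in the inclusive range [lo, hi]."""
    if lo > hi:
        raise ValueError("range lower bound exceeds upper bound")
    if hi < d.min_length or lo > d.max_length:
        log.info(
            "size-class range %d-%d lies outside distribution support %d-%d",
            lo, hi, d.min_length, d.max_length,
        )
        return 0.0
    a = max(lo, d.min_length) - d.min_length
    b = min(hi, d.max_length) - d.min_length
    return float(d.density[a : b + 1].sum())


def size_class_stat(
    d: SizeDistribution,
    nucleosomal: tuple[int, int] = NUCLEOSOMAL_RANGE,
    supernucleosomal: tuple[int, int] = SUPERNUCLEOSOMAL_RANGE,
) -> SizeClassStat:
    if not (nucleosomal[1] < supernucleosomal[0] or supernucleosomal[1] < nucleosomal[0]):
        raise ValueError("size-class ranges must be disjoint")
    nuc = class_auc(d, *nucleosomal)
    sup = class_auc(d, *supernucleosomal)
    if nuc == 0:
        raise ValueError("nucleosomal AUC is zero; ratio undefined")
    return SizeClassStat(nucleosomal, supernucleosomal, nuc, sup, sup / nuc)


def supernuc_ratio(
    d: SizeDistribution,
    nucleosomal: tuple[int, int] = NUCLEOSOMAL_RANGE,
    supernucleosomal: tuple[int, int] = SUPERNUCLEOSOMAL_RANGE,
) -> float:
    """Supernucleosomal AUC divided by nucleosomal AUC."""
    return size_class_stat(d, nucleosomal, supernucleosomal).ratio


def enrichment_ratio(
    chip: SizeDistribution,
    input_: SizeDistribution,
    nucleosomal: tuple[int, int] = NUCLEOSOMAL_RANGE,
    supernucleosomal: tuple[int, int] = SUPERNUCLEOSOMAL_RANGE,
) -> float:
    """Ratio of ratios: the IP's supernucleosomal/nucleosomal AUC ratio
    divided by the input's."""
    denominator = supernuc_ratio(input_, nucleosomal, supernucleosomal)
    if denominator == 0:
        raise ValueError(
            "input has no supernucleosomal mass; enrichment ratio undefined"
        )
    return supernuc_ratio(chip, nucleosomal, supernucleosomal) / denominator


def compare_ratio_groups(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample two-sided t-test on per-sample enrichment ratios.

    Returns (statistic, p-value).  The test assumes unequal variances; it
    is undefined when both groups are constant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two ratio values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups constant; Welch statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
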