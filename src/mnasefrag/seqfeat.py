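"""Sequence composition and local DNA bendability.

Two families of operations live here: position frequency matrices (the
numeric half of a sequence logo, here used to show the extreme A+T content
of budding-yeast point centromeres), and sliding-window trinucleotide
bendability profiles in the style of the bend.it analysis, with a Welch
t-test comparison of two region classes.

A trinucleotide's raw value is anchored to its central base, so positions
0 and L-1 of a sequence carry no raw value; the profile at position p is
the mean of the raw values inside the (odd) smoothing window centered at
p, and positions without a full window are undefined (NaN).
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AnchorSite

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
BASES = "ACGT"
TRINUCLEOTIDES = ["".join(t) for t in itertools.product(BASES, repeat=3)]

DEFAULT_BENDABILITY_WINDOW = 39


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over aligned equal-length windows."""

    counts: np.ndarray  # shape (window_length, 4), columns A, C, G, T
    n_sequences: int
    n_ambiguous: np.ndarray  # per-position count of non-ACGT bases

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_ambiguous = np.asarray(self.n_ambiguous, dtype=np.int64)
        totals = self.counts.sum(axis=1) + self.n_ambiguous
        if self.n_sequences and np.any(totals != self.n_sequences):
            raise ValueError("per-position counts must sum to the sequence count")

    @property
    def at_fraction(self) -> np.ndarray:
        """(A+T)/(A+C+G+T) per position; NaN where all bases ambiguous."""
        acgt = self.counts.sum(axis=1)
        out = np.full(acgt.shape, np.nan)
        at = self.counts[:, 0] + self.counts[:, 3]
        np.divide(at, acgt, out=out, where=acgt > 0)
        return out

    def to_dataframe(self):
        import pandas as pd

        half = self.counts.shape[0] // 2
        return pd.DataFrame(
            self.counts,
            columns=list(BASES),
            index=np.arange(self.counts.shape[0]) - half,
        ).rename_axis("offset")


def pfm_from_anchors(
    sequences: dict[str, str], anchors: list[AnchorSite], flank: int
) -> PositionFrequencyMatrix:
    """Count bases in [anchor-flank, anchor+flank] windows.

    Minus-strand anchors contribute the reverse complement of their
    window, so all windows read in anchor orientation.  Anchors whose
    window runs off the sequence are skipped and counted.
    """
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    ambiguous = np.zeros(width, dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    n_used = n_skipped = 0
    for anchor in anchors:
        seq = sequences[anchor.chrom]
        lo, hi = anchor.position - flank, anchor.position + flank + 1
        if lo < 0 or hi > len(seq):
            n_skipped += 1
            continue
        window = seq[lo:hi].upper()
        if anchor.strand == "-":
            window = reverse_complement(window)
        n_used += 1
        for pos, base in enumerate(window):
            i = base_index.get(base)
            if i is None:
                ambiguous[pos] += 1
            else:
                counts[pos, i] += 1
    if n_skipped:
        log.warning("pfm_from_anchors: skipped %d out-of-bounds anchors", n_skipped)
    return PositionFrequencyMatrix(counts, n_used, ambiguous)


@dataclass
class BendabilityScale:
    """Mapping from each of the 64 trinucleotides to a bendability value."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        keys = {k.upper() for k in self.values}
        if keys != set(TRINUCLEOTIDES):
            missing = sorted(set(TRINUCLEOTIDES) - keys)
            raise ValueError(f"scale must cover all 64 trinucleotides; missing {missing[:5]}...")
        self.values = {k.upper(): float(v) for k, v in self.values.items()}
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("scale values must be finite")

    def __getitem__(self, tri: str) -> float:
        return self.values[tri.upper()]

    def is_strand_symmetric(self, tol: float = 1e-9) -> bool:
        return all(
            abs(self.values[t] - self.values[reverse_complement(t)]) <= tol
            for t in TRINUCLEOTIDES
        )

    def symmetrized(self) -> "BendabilityScale":
        return BendabilityScale(
            {
                t: (self.values[t] + self.values[reverse_complement(t)]) / 2
                for t in TRINUCLEOTIDES
            }
        )

    @classmethod
    def from_tsv(cls, path) -> "BendabilityScale":
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tri, val = line.split("\t")[:2]
                values[tri] = float(val)
        return cls(values)

    @classmethod
    def default(cls) -> "BendabilityScale":
        """The packaged strand-symmetric synthetic scale (see its file
        docstring); swap in any 64-entry TSV for a published table."""
        ref = importlib.resources.files("mnasefrag.data").joinpath(
            "synthetic_bendability_scale.tsv"
        )
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


def raw_trinucleotide_values(seq: str, scale: BendabilityScale) -> np.ndarray:
    """Per-position raw values, NaN at the two ends and wherever the
    centered trinucleotide contains a non-ACGT base."""
    seq = seq.upper()
    out = np.full(len(seq), np.nan)
    for p in range(1, len(seq) - 1):
        tri = seq[p - 1 : p + 2]
        if all(b in BASES for b in tri):
            out[p] = scale[tri]
    return out


def bendability_profile(
    seq: str, scale: BendabilityScale | None = None, window: int = DEFAULT_BENDABILITY_WINDOW
) -> np.ndarray:
    """Window-averaged bendability per position.

    The value at p is the mean of the defined raw trinucleotide values in
    the window of ``window`` bases centered at p; positions without a full
    window are NaN.  Ambiguous-base trinucleotides are simply excluded
    from the window mean.
    """
    if scale is None:
        scale = BendabilityScale.default()
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({len(seq)} < {window})")
    raw = raw_trinucleotide_values(seq, scale)
    half = window // 2
    out = np.full(len(seq), np.nan)
    for p in range(half, len(seq) - half):
        block = raw[p - half : p + half + 1]
        if np.any(~np.isnan(block)):
            out[p] = np.nanmean(block)
    return out


def region_mean_bendability(
    regions: list[str], scale: BendabilityScale | None = None, window: int = DEFAULT_BENDABILITY_WINDOW
) -> np.ndarray:
    """Per-region mean of defined profile values; regions shorter than the
    window are excluded (counted in a log message)."""
    if scale is None:
        scale = BendabilityScale.default()
    means = []
    n_short = 0
    for seq in regions:
        if len(seq) < window:
            n_short += 1
            continue
        profile = bendability_profile(seq, scale, window)
        means.append(float(np.nanmean(profile)))
    if n_short:
        log.warning("region_mean_bendability: excluded %d regions shorter than window", n_short)
    return np.asarray(means)


def compare_region_bendability(
    regions_a: list[str],
    regions_b: list[str],
    scale: BendabilityScale | None = None,
    window: int = DEFAULT_BENDABILITY_WINDOW,
) -> tuple[float, float, float]:
    """Difference in mean bendability between two region classes.

    Returns (mean_a - mean_b, Welch t statistic, two-sided p-value).
    """
    if scale is None:
        scale = BendabilityScale.default()
    a = region_mean_bendability(regions_a, scale, window)
    b = region_mean_bendability(regions_b, scale, window)
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least two regions of window length")
    diff = float(a.mean() - b.mean())
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return diff, 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(res.statistic), float(res.pvalue)


def extract_region_sequences(
    sequences: dict[str, str], features
) -> list[str]:
    """Pull the (strand-oriented) sequence of each interval feature."""
    out = []
    for ft in features:
        seq = sequences[ft.chrom][ft.start : ft.end]
        if getattr(ft, "strand", ".") == "-":
            seq = reverse_complement(seq)
        out.append(seq)
    return out
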