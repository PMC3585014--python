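"""Per-bp genomic tracks and anchor-centered summaries.

A :class:`GenomicTrack` stores one float vector per chromosome at 1-bp
resolution; undefined positions are NaN (the mask).  On top of it sit the
anchor-centered operations: aggregate profiles, quintile grouping, ranked
heatmaps, fixed-window coarsening, and the NDR max-signal/width regression.

Orientation convention: for a minus-strand anchor the offset axis is
flipped, so aggregate profiles and heatmap rows always read in the
direction of transcription (left to right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnchorSite, FragmentSet, IntervalFeature


@dataclass
class GenomicTrack:
    """Per-chromosome per-bp values; NaN marks undefined positions."""

    values: dict[str, np.ndarray]
    semantics: str = "counts/bp"  # "counts/bp" | "log2-ratio" | "metric"

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: v.size for c, v in self.values.items()}

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]


@dataclass
class ProfileResult:
    """Mean track value per offset around a set of anchors."""

    flank: int
    mean: np.ndarray  # length 2*flank + 1; NaN where no anchor contributed
    n_contributing: np.ndarray  # anchors contributing per offset

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


@dataclass
class HeatmapMatrix:
    """Per-anchor signal rows sorted descending by a ranking metric."""

    row_ids: list[str]
    flank: int
    matrix: np.ndarray  # shape (n_anchors, 2*flank + 1)
    metric_name: str = ""
    metric_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


def coverage_track(fs: FragmentSet) -> GenomicTrack:
    """Fragment coverage: value at base b = number of fragments containing b.

    The genome-wide total equals the sum of fragment lengths.
    """
    if not fs.chrom_lengths:
        raise ValueError("coverage requires known chromosome lengths")
    diff = {c: np.zeros(L + 1) for c, L in fs.chrom_lengths.items()}
    for f in fs:
        if f.chrom not in diff:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        if f.end > fs.chrom_lengths[f.chrom]:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} exceeds chromosome end"
            )
        diff[f.chrom][f.start] += f.weight
        diff[f.chrom][f.end] -= f.weight
    return GenomicTrack(
        {c: np.cumsum(d[:-1]) for c, d in diff.items()}, semantics="counts/bp"
    )


def log_ratio_track(
    ip: GenomicTrack, input_: GenomicTrack, pseudocount: float = 0.5
) -> GenomicTrack:
    """Depth-normalized log2(IP/input) per base.

    Both tracks are scaled to the same effective depth (the mean of their
    genome-wide totals) before the ratio; positions where both raw tracks
    are zero are masked as carrying no information.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if ip.chrom_lengths != input_.chrom_lengths:
        raise ValueError("IP and input tracks are on different chromosomes")
    t_ip, t_in = ip.total(), input_.total()
    if t_ip == 0 or t_in == 0:
        raise ValueError("cannot depth-normalize an all-zero track")
    target = (t_ip + t_in) / 2
    out: dict[str, np.ndarray] = {}
    for chrom in ip.values:
        a = ip[chrom] * (target / t_ip)
        b = input_[chrom] * (target / t_in)
        ratio = np.log2((a + pseudocount) / (b + pseudocount))
        ratio[(ip[chrom] == 0) & (input_[chrom] == 0)] = np.nan
        out[chrom] = ratio
    return GenomicTrack(out, semantics="log2-ratio")


def _anchor_window(track: GenomicTrack, anchor: AnchorSite, flank: int) -> np.ndarray:
    """Track slice [anchor-flank, anchor+flank], NaN-padded at chromosome
    edges, reversed for minus-strand anchors."""
    values = track[anchor.chrom]
    window = np.full(2 * flank + 1, np.nan)
    lo = anchor.position - flank
    hi = anchor.position + flank + 1
    src_lo, src_hi = max(lo, 0), min(hi, values.size)
    if src_lo < src_hi:
        window[src_lo - lo : src_hi - lo] = values[src_lo:src_hi]
    if anchor.strand == "-":
        window = window[::-1]
    return window


def aggregate_profile(
    track: GenomicTrack, anchors: list[AnchorSite], flank: int = 1000
) -> ProfileResult:
    """Mean track value at each offset over all anchors; masked and
    out-of-bounds positions are excluded from numerator and denominator."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not anchors:
        raise ValueError("anchor list is empty")
    acc = np.zeros(2 * flank + 1)
    n = np.zeros(2 * flank + 1, dtype=int)
    for anchor in anchors:
        window = _anchor_window(track, anchor, flank)
        ok = ~np.isnan(window)
        acc[ok] += window[ok]
        n += ok
    mean = np.full(acc.shape, np.nan)
    np.divide(acc, n, out=mean, where=n > 0)
    return ProfileResult(flank, mean, n)


def _anchor_scores(
    track: GenomicTrack, anchors: list[AnchorSite], flank: int
) -> np.ndarray:
    scores = np.empty(len(anchors))
    for i, anchor in enumerate(anchors):
        window = _anchor_window(track, anchor, flank)
        scores[i] = np.nanmean(window) if np.any(~np.isnan(window)) else -np.inf
    return scores


def quintile_profiles(
    track: GenomicTrack,
    anchors: list[AnchorSite],
    flank: int = 1000,
    n_groups: int = 5,
) -> list[ProfileResult]:
    """Aggregate profiles for anchors split into quintiles of mean window
    signal (group 0 = highest).  Remainders go to the top groups; ties in
    signal are broken by the anchors' given order (their ids)."""
    if len(anchors) < n_groups:
        raise ValueError(f"need at least {n_groups} anchors for {n_groups} groups")
    scores = _anchor_scores(track, anchors, flank)
    # stable sort on descending score keeps the input (id) order among ties
    order = np.argsort(-scores, kind="stable")
    base, extra = divmod(len(anchors), n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
    profiles = []
    pos = 0
    for size in sizes:
        members = [anchors[i] for i in order[pos : pos + size]]
        pos += size
        profiles.append(aggregate_profile(track, members, flank))
    return profiles


def heatmap_matrix(
    track: GenomicTrack,
    anchors: list[AnchorSite],
    flank: int,
    metrics: pd.DataFrame,
    metric_name: str,
) -> HeatmapMatrix:
    """One strand-oriented signal row per anchor, rows ranked descending by
    the named metric.  Every anchor id must be present in the metric table;
    metric ties are broken by the anchors' given order."""
    if metric_name == "self":
        values = _anchor_scores(track, anchors, flank)
    else:
        missing = [a.name for a in anchors if a.name not in metrics.index]
        if missing:
            raise KeyError(f"anchors missing from metric table: {missing}")
        values = np.array(
            [float(metrics.loc[a.name, metric_name]) for a in anchors]
        )
    order = np.argsort(-values, kind="stable")
    rows = np.stack([_anchor_window(track, anchors[i], flank) for i in order])
    return HeatmapMatrix(
        [anchors[i].name for i in order], flank, rows, metric_name, values[order]
    )


def windowed_track(track: GenomicTrack, window: int) -> GenomicTrack:
    """Coarsen to non-overlapping fixed windows; each window's value is the
    mean of its unmasked bases (all-masked windows stay masked).  The
    coarse value is written across the window's span so the result remains
    a per-bp track."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return GenomicTrack({c: v.copy() for c, v in track.values.items()}, track.semantics)
    out: dict[str, np.ndarray] = {}
    for chrom, values in track.values.items():
        coarse = np.full(values.size, np.nan)
        for start in range(0, values.size, window):
            block = values[start : start + window]
            if np.any(~np.isnan(block)):
                coarse[start : start + block.size] = np.nanmean(block)
        out[chrom] = coarse
    return GenomicTrack(out, track.semantics)


def ndr_correlation(
    track: GenomicTrack, ndrs: list[IntervalFeature]
) -> tuple[float, pd.DataFrame]:
    """Regress each NDR's maximum unmasked signal on its width.

    Returns the OLS R-squared and a per-NDR table (name, width, max
    signal).  A high R-squared would indicate that apparent binding merely
    tracks the amount of exposed DNA.
    """
    records = []
    for ndr in ndrs:
        segment = track[ndr.chrom][ndr.start : ndr.end]
        if segment.size == 0 or np.all(np.isnan(segment)):
            continue
        records.append((ndr.name, ndr.width, float(np.nanmax(segment))))
    if len(records) < 3:
        raise ValueError("need at least 3 NDRs with unmasked signal")
    table = pd.DataFrame(records, columns=["name", "width", "max_signal"])
    res = stats.linregress(table["width"], table["max_signal"])
    return float(res.rvalue**2), table
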