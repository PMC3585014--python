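"""V-plot matrices: 2-D histograms of fragment-midpoint distance from an
anchor (x) versus fragment length (y).

Each (anchor, fragment) pair on the same chromosome contributes one count
when the signed midpoint distance lies within the x half-width and the
fragment length within the y range.  Distances are negated for minus-strand
anchors so that the plot reads in the anchor's orientation.  The percent
normalization divides every bin by the number of contributing fragments,
times 100, so a whole matrix sums to 100.

The default grid is x in [-1000, +1000] at 5-bp bins (401 bins) by 400
1-bp length bins starting at 25 bp, i.e. 160,400 bins.  The y window is an
inference from the published bin total and the smallest recovered fragment
size (~25 bp); both axes are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AnchorSite, Fragment, FragmentSet

DEFAULT_X_HALF_WIDTH = 1000
DEFAULT_X_BIN = 5
DEFAULT_Y_MIN = 25
DEFAULT_Y_MAX = 424
DEFAULT_Y_BIN = 1


@dataclass
class VPlotMatrix:
    x_half_width: int
    x_bin: int
    y_min: int
    y_max: int
    y_bin: int
    matrix: np.ndarray  # shape (n_x_bins, n_y_bins)
    normalization: str = "counts"  # "counts" | "percent"
    n_fragments: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n_x_bins, self.n_y_bins):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match grid "
                f"({self.n_x_bins}, {self.n_y_bins})"
            )
        if np.any(self.matrix < 0):
            raise ValueError("bin values must be non-negative")
        if self.normalization == "percent" and self.n_fragments > 0:
            # tolerance admits 6-decimal file rounding (5e-7 per nonzero bin)
            tol = 1e-6 + 5e-7 * np.count_nonzero(self.matrix)
            if abs(self.matrix.sum() - 100.0) > tol:
                raise ValueError("percent matrix must total 100")

    @property
    def n_x_bins(self) -> int:
        # closed x interval: the +half_width edge is clamped into the last bin
        return (2 * self.x_half_width) // self.x_bin + 1

    @property
    def n_y_bins(self) -> int:
        return (self.y_max - self.y_min) // self.y_bin + 1

    @property
    def x_bin_centers(self) -> np.ndarray:
        left = -self.x_half_width + self.x_bin * np.arange(self.n_x_bins)
        return left + (self.x_bin - 1) / 2

    @property
    def y_bin_starts(self) -> np.ndarray:
        return self.y_min + self.y_bin * np.arange(self.n_y_bins)


def fragment_midpoint(f: Fragment) -> int:
    """Fragment midpoint: start + floor(length / 2)."""
    return f.midpoint


def build_vplot(
    fs: FragmentSet,
    anchors: list[AnchorSite],
    x_half_width: int = DEFAULT_X_HALF_WIDTH,
    x_bin: int = DEFAULT_X_BIN,
    y_min: int = DEFAULT_Y_MIN,
    y_max: int = DEFAULT_Y_MAX,
    y_bin: int = DEFAULT_Y_BIN,
) -> VPlotMatrix:
    """Accumulate the (midpoint distance, length) 2-D histogram.

    A fragment near several anchors contributes once per anchor (pairwise
    counting).  x bin index = floor((d + x_half_width) / x_bin) with d at
    exactly +x_half_width clamped into the last bin.
    """
    if not anchors:
        raise ValueError("anchor list is empty")
    if x_half_width <= 0 or x_bin <= 0 or y_bin <= 0:
        raise ValueError("half-width and bin sizes must be positive")
    if y_min > y_max:
        raise ValueError("y_min must not exceed y_max")

    n_x = (2 * x_half_width) // x_bin + 1
    n_y = (y_max - y_min) // y_bin + 1
    matrix = np.zeros((n_x, n_y))

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fs:
        by_chrom.setdefault(f.chrom, []).append((f.midpoint, f.length))

    total = 0
    for anchor in anchors:
        pairs = by_chrom.get(anchor.chrom)
        if not pairs:
            continue
        arr = np.asarray(pairs)
        mid, length = arr[:, 0], arr[:, 1]
        d = mid - anchor.position
        if anchor.strand == "-":
            d = -d
        keep = (np.abs(d) <= x_half_width) & (length >= y_min) & (length <= y_max)
        xi = np.minimum((d[keep] + x_half_width) // x_bin, n_x - 1)
        yi = (length[keep] - y_min) // y_bin
        np.add.at(matrix, (xi, yi), 1)
        total += int(keep.sum())

    return VPlotMatrix(
        x_half_width, x_bin, y_min, y_max, y_bin, matrix, "counts", total
    )


def normalize_vplot(v: VPlotMatrix) -> VPlotMatrix:
    """Convert counts to percent of contributing fragments per bin."""
    if v.normalization != "counts":
        raise ValueError("expected a counts-normalized matrix")
    if v.n_fragments == 0:
        raise ValueError("cannot normalize a V-plot with zero contributing fragments")
    return replace(v, matrix=100.0 * v.matrix / v.n_fragments, normalization="percent")


def merge_vplots(a: VPlotMatrix, b: VPlotMatrix) -> VPlotMatrix:
    """Elementwise sum of two counts matrices on identical grids."""
    for attr in ("x_half_width", "x_bin", "y_min", "y_max", "y_bin"):
        if getattr(a, attr) != getattr(b, attr):
            raise ValueError(f"grid mismatch on {attr}")
    if a.normalization != "counts" or b.normalization != "counts":
        raise ValueError("only counts matrices can be merged")
    return replace(a, matrix=a.matrix + b.matrix, n_fragments=a.n_fragments + b.n_fragments)


def export_vplot(v: VPlotMatrix, path, image_path=None) -> None:
    """Write the matrix as TSV (the contract); optionally render a raster
    heat image (cosmetic only).

    Layout: a metadata comment, then a header row of y bin starts, then one
    row per x bin: x bin center followed by the bin values (6-decimal fixed
    format for percent matrices).
    """
    fmt = "%.6f" if v.normalization == "percent" else "%g"
    with open(path, "w") as fh:
        fh.write(
            f"# vplot x_half_width={v.x_half_width} x_bin={v.x_bin} "
            f"y_min={v.y_min} y_max={v.y_max} y_bin={v.y_bin} "
            f"normalization={v.normalization} n_fragments={v.n_fragments}\n"
        )
        fh.write("x_center\t" + "\t".join(str(y) for y in v.y_bin_starts) + "\n")
        for xc, row in zip(v.x_bin_centers, v.matrix):
            fh.write(f"{xc:g}\t" + "\t".join(fmt % val for val in row) + "\n")
    if image_path is not None:
        render_vplot(v, image_path)


def read_vplot(path) -> VPlotMatrix:
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("# vplot"):
            raise ValueError(f"{path}: not a V-plot matrix file")
        meta = dict(tok.split("=") for tok in meta_line.split()[2:])
        fh.readline()  # y header
        rows = [
            [float(x) for x in line.rstrip("\n").split("\t")[1:]]
            for line in fh
            if line.strip()
        ]
    return VPlotMatrix(
        int(meta["x_half_width"]),
        int(meta["x_bin"]),
        int(meta["y_min"]),
        int(meta["y_max"]),
        int(meta["y_bin"]),
        np.asarray(rows),
        meta["normalization"],
        int(meta["n_fragments"]),
    )


def render_vplot(v: VPlotMatrix, image_path, cmap: str = "viridis") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    extent = (
        -v.x_half_width,
        -v.x_half_width + v.n_x_bins * v.x_bin,
        v.y_min,
        v.y_min + v.n_y_bins * v.y_bin,
    )
    im = ax.imshow(
        v.matrix.T, origin="lower", aspect="auto", extent=extent, cmap=cmap
    )
    ax.set_xlabel("midpoint distance from anchor (bp)")
    ax.set_ylabel("fragment length (bp)")
    label = "% of fragments" if v.normalization == "percent" else "counts"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
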