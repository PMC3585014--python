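"""Readers and writers for the interval, sequence and table formats the
pipeline touches.

All coordinates are 0-based half-open internally; BED dialects are honored
on disk.  A paired-end fragment is stored as the single protected span
``min(start1, start2)``–``max(end1, end2)`` because every downstream
statistic uses the midpoint and length of that span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AnchorMode = Literal["midpoint", "five_prime", "three_prime"]


@dataclass(frozen=True)
class Fragment:
    """One MNase-protected interval (the span of a read pair)."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid fragment interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint position, floor tie-break for even/odd lengths."""
        return self.start + (self.end - self.start) // 2


@dataclass
class FragmentSet:
    """A collection of fragments with per-sample metadata.

    ``chrom_lengths`` may be empty, in which case bounds against the
    chromosome end are not enforced.  Duplicate fragments are retained:
    recurring MNase protections are biology, not artifacts.  Use
    :meth:`deduplicate` if collapsing is explicitly wanted.
    """

    fragments: list[Fragment]
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    name: str = ""
    role: str = "input"
    digestion_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("IP", "input"):
            raise ValueError(f"sample role must be 'IP' or 'input', got {self.role!r}")
        for f in self.fragments:
            L = self.chrom_lengths.get(f.chrom)
            if L is not None and f.end > L:
                raise ValueError(
                    f"fragment {f.chrom}:{f.start}-{f.end} exceeds chromosome length {L}"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=np.int64)

    def deduplicate(self) -> "FragmentSet":
        seen: dict[tuple, Fragment] = {}
        for f in self.fragments:
            seen.setdefault((f.chrom, f.start, f.end), f)
        return replace(self, fragments=list(seen.values()))


@dataclass(frozen=True)
class AnchorSite:
    """A single reference position used to anchor V-plots and profiles."""

    chrom: str
    position: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("anchor position must be >= 0")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class IntervalFeature:
    """A named, classed genomic interval (ORF, NDR, centromere, TFBS, ...)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    feature_class: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"feature start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


class ParseError(ValueError):
    """Raised for malformed lines; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_fragments(
    path,
    fmt: Literal["BED3", "BEDPE"] = "BED3",
    chrom_lengths: Mapping[str, int] | None = None,
    name: str = "",
    role: str = "input",
) -> FragmentSet:
    """Read fragments from BED3 or BEDPE.

    BEDPE mates are collapsed to the spanning interval.  Mates mapped to
    different chromosomes cannot form a protected span; those records are
    skipped and counted (logged), never silently dropped.
    """
    frags: list[Fragment] = []
    n_cross = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if fmt == "BED3":
                    if len(parts) < 3:
                        raise ValueError("expected >= 3 tab-separated fields")
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    frags.append(Fragment(chrom, start, end))
                elif fmt == "BEDPE":
                    if len(parts) < 6:
                        raise ValueError("expected >= 6 tab-separated fields")
                    c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                    c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
                    if c1 != c2:
                        n_cross += 1
                        continue
                    frags.append(Fragment(c1, min(s1, s2), max(e1, e2)))
                else:
                    raise ValueError(f"unknown fragment format {fmt!r}")
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    if n_cross:
        log.warning("%s: skipped %d cross-chromosome BEDPE records", path, n_cross)
    fs = FragmentSet(
        frags, dict(chrom_lengths or {}), name=name or Path(str(path)).stem, role=role
    )
    fs.n_cross_chromosome_skipped = n_cross  # type: ignore[attr-defined]
    return fs


def write_fragments_bed3(fs: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for f in fs:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def read_fragments_sam_bam(path, name: str = "", role: str = "input") -> FragmentSet:
    """Optional adapter: collapse properly paired SAM/BAM alignments to
    spanning fragments.  Only the leftmost mate of each pair (positive
    template length) is consumed, so each pair yields one fragment."""
    import pysam

    frags: list[Fragment] = []
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(path)) as af:
        lengths = {r: int(l) for r, l in zip(af.references, af.lengths)}
        for aln in af:
            if aln.is_unmapped or not aln.is_paired or aln.is_secondary:
                continue
            tlen = aln.template_length
            if tlen <= 0:
                continue
            frags.append(
                Fragment(aln.reference_name, aln.reference_start, aln.reference_start + tlen)
            )
    return FragmentSet(frags, lengths, name=name, role=role)


def read_features(path, default_class: str = "") -> list[IntervalFeature]:
    """Read interval features from BED6 (BED4/BED3 tolerated; missing
    strand recorded as '.')."""
    feats: list[IntervalFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 3:
                    raise ValueError("expected >= 3 tab-separated fields")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                fname = parts[3] if len(parts) > 3 else ""
                strand = parts[5] if len(parts) > 5 else "."
                feats.append(
                    IntervalFeature(chrom, start, end, strand, fname, default_class)
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return feats


def write_features_bed6(features: Iterable[IntervalFeature], path) -> None:
    with open(path, "w") as fh:
        for ft in features:
            fh.write(
                f"{ft.chrom}\t{ft.start}\t{ft.end}\t{ft.name or ft.feature_class or '.'}"
                f"\t0\t{ft.strand}\n"
            )


def to_anchors(
    features: Iterable[IntervalFeature], mode: AnchorMode = "midpoint"
) -> list[AnchorSite]:
    """Convert interval features to single anchor positions.

    midpoint   : start + floor((end - start) / 2), strand kept
    five_prime : start on '+', end - 1 on '-'
    three_prime: end - 1 on '+', start on '-'
    """
    anchors: list[AnchorSite] = []
    for ft in features:
        if mode == "midpoint":
            pos = ft.midpoint
        elif mode in ("five_prime", "three_prime"):
            if ft.strand not in ("+", "-"):
                raise ValueError(
                    f"mode {mode!r} requires a stranded feature, got {ft!r}"
                )
            if mode == "five_prime":
                pos = ft.start if ft.strand == "+" else ft.end - 1
            else:
                pos = ft.end - 1 if ft.strand == "+" else ft.start
        else:
            raise ValueError(f"unknown anchor mode {mode!r}")
        anchors.append(AnchorSite(ft.chrom, pos, ft.strand, ft.name))
    return anchors


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an upper-cased {name: sequence} map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_track_bedgraph(
    track: Mapping[str, np.ndarray], path, precision: int = 6, header: str | None = None
) -> None:
    """Write per-bp vectors as bedGraph, merging runs of equal value.

    NaN positions (the track mask) are omitted, which bedGraph represents
    naturally as uncovered intervals.
    """
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for chrom in track:
            values = np.asarray(track[chrom], dtype=float)
            if values.size == 0:
                continue
            # run boundaries: value changes or NaN-state changes
            nan = np.isnan(values)
            change = np.empty(values.size, dtype=bool)
            change[0] = True
            same = (values[1:] == values[:-1]) | (nan[1:] & nan[:-1])
            change[1:] = ~same
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], values.size)
            for s, e in zip(starts, ends):
                if nan[s]:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.{precision}g}\n")


def read_track_bedgraph(
    path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-bp vectors; uncovered positions are NaN."""
    track = {
        chrom: np.full(length, np.nan) for chrom, length in chrom_lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end, value = (
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    float(parts[3]),
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if chrom not in track:
                raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
            track[chrom][start:end] = value
    return track


def read_metric_table(path) -> pd.DataFrame:
    """Read a per-gene metric TSV.  A header with a ``gene_id`` column is
    required; all other columns are named metrics."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: metric table must have a 'gene_id' header column")
    return df.set_index("gene_id")


def write_metric_table(df: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=True, index_label="gene_id")
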