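"""Synthetic budding-yeast-like chromatin with full ground truth.

The generator produces, from a single integer seed, (i) a genome sequence
with A+T-rich features (centromeres, NDRs), (ii) a chromatin state of
phased nucleosome arrays flanking TF-bound nucleosome-depleted regions,
(iii) paired-end-style protected fragments for IP and input samples under
a tunable MNase digestion model, and (iv) a per-gene metric table whose
metrics are correlated with the designed IP enrichment.

Model in brief
--------------
Protected units come in three classes: nucleosome cores (147 bp around
each dyad), TF footprints (the TFBS interval), and remodeler-spanning
protections running from a flanking nucleosome across the TFBS — the
source of supernucleosomal (>250 bp) fragments in IP samples.  Each
emitted fragment picks one unit (class-weighted), extends it by an
undigested overhang on each side, and nibbles each end by an
exponentially distributed amount whose scale is the digestion extent;
heavier digestion therefore shifts the nucleosomal length mode downward
(e.g. extent 5 gives a ~175-10 ≈ 170 bp peak region, extent 15 a ~160 bp
one).  A spanning event protects one side of the TFBS only, chosen at
random per event.

Every operation draws from its own ``numpy.random.default_rng([op_id,
seed])`` stream, so identical seeds give byte-identical outputs and the
operations are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import Fragment, FragmentSet, IntervalFeature

CORE_LENGTH = 147
DEFAULT_REPEAT_LENGTH = 165
DEFAULT_NDR_HALF_WIDTH = 90

# per-operation RNG stream ids (documented contract)
_STREAM_GENOME = 1
_STREAM_CHROMATIN = 2
_STREAM_FRAGMENTS_IP = 3
_STREAM_FRAGMENTS_INPUT = 4
_STREAM_METRICS = 5

CLASS_NUCLEOSOME = "nucleosome"
CLASS_TF_FOOTPRINT = "tf_footprint"
CLASS_SPANNING = "spanning"


@dataclass(frozen=True)
class FeaturePlacement:
    """A feature to carve into the synthetic genome."""

    feature_class: str  # TFBS | centromere | CDEI | CDEII | CDEIII | ORF | NDR
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    at_fraction: float | None = None  # None: background composition

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature interval {self.chrom}:{self.start}-{self.end}")
        if self.at_fraction is not None and not 0 <= self.at_fraction <= 1:
            raise ValueError("A+T fraction must lie in [0, 1]")


@dataclass
class GenomeSpec:
    chrom_lengths: dict[str, int]
    features: list[FeaturePlacement] = field(default_factory=list)
    background_gc: float = 0.38  # S. cerevisiae-like

    def validate(self) -> None:
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background GC fraction must lie in [0, 1]")
        by_class: dict[tuple[str, str], list[FeaturePlacement]] = {}
        for ft in self.features:
            if ft.chrom not in self.chrom_lengths:
                raise ValueError(f"feature on unknown chromosome {ft.chrom!r}")
            if ft.end > self.chrom_lengths[ft.chrom]:
                raise ValueError(
                    f"feature {ft.chrom}:{ft.start}-{ft.end} exceeds chromosome bounds"
                )
            by_class.setdefault((ft.chrom, ft.feature_class), []).append(ft)
        for (chrom, cls), feats in by_class.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping {cls} features on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    features: list[IntervalFeature]
    spec: GenomeSpec

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def features_of_class(self, feature_class: str) -> list[IntervalFeature]:
        return [f for f in self.features if f.feature_class == feature_class]


@dataclass(frozen=True)
class RemodelerProtection:
    """Continuous protection from a flanking nucleosome across the TFBS."""

    chrom: str
    start: int
    end: int
    side: str  # "left" | "right" of the TFBS
    occupancy: float = 1.0
    tfbs_name: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("protection side must be 'left' or 'right'")
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy probability must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChromatinState:
    dyads: dict[str, np.ndarray]
    repeat_length: int
    core_length: int
    ndrs: list[IntervalFeature]
    tf_footprints: list[IntervalFeature]
    protections: list[RemodelerProtection]
    arrays: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, dd in self.dyads.items():
            dd = np.sort(np.asarray(dd))
            if np.any(np.diff(dd) < self.core_length):
                raise ValueError(f"adjacent dyads closer than one core on {chrom}")
            self.dyads[chrom] = dd
        for ndr in self.ndrs:
            dd = self.dyads.get(ndr.chrom, np.array([]))
            if np.any((dd >= ndr.start) & (dd < ndr.end)):
                raise ValueError(f"NDR {ndr.chrom}:{ndr.start}-{ndr.end} contains a dyad")

    @property
    def linker_length(self) -> int:
        return self.repeat_length - self.core_length

    def mean_linker_length(self) -> float:
        """Mean within-array inter-dyad gap minus the core length."""
        gaps = [np.diff(dd) for _, dd in self.arrays if dd.size > 1]
        if not gaps:
            raise ValueError("no array with at least two dyads")
        return float(np.concatenate(gaps).mean()) - self.core_length

    def nucleosome_intervals(self) -> list[tuple[str, int, int]]:
        half = self.core_length // 2
        out = []
        for chrom, dd in self.dyads.items():
            for d in dd:
                out.append((chrom, int(d) - half, int(d) - half + self.core_length))
        return out


@dataclass
class DigestionModel:
    """Per-end exponential nibbling of protected fragments.

    ``extent`` is the exponential scale in bp of the trimming at each
    fragment end (larger = more digestion); ``overhang`` is the undigested
    linker DNA initially left on each side of a protected unit.  The
    nucleosomal length mode is core + 2*overhang - mode(total trim).
    """

    extent: float = 5.0
    family: str = "exponential"
    min_length: int = 25
    max_length: int = 500
    overhang: int = 14

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("minimum fragment length must be >= 1")
        if self.extent < 0:
            raise ValueError("trimming scale must be >= 0")
        if self.family != "exponential":
            raise ValueError(f"unsupported trimming family {self.family!r}")

    def trim_pmf(self, max_trim: int) -> np.ndarray:
        """Exact pmf of the total (two-end) trim on {0..max_trim}.

        A single end trims floor(Exp(extent)) bases, i.e. geometric with
        q = exp(-1/extent); the two-end sum is negative binomial:
        P(T=t) = (1-q)^2 (t+1) q^t.
        """
        if self.extent == 0:
            pmf = np.zeros(max_trim + 1)
            pmf[0] = 1.0
            return pmf
        q = np.exp(-1.0 / self.extent)
        t = np.arange(max_trim + 1)
        return (1 - q) ** 2 * (t + 1) * q**t


@dataclass
class EnrichmentModel:
    """Class sampling weights for input and IP fragment emission."""

    input_weights: dict[str, float]
    ip_weights: dict[str, float]

    def __post_init__(self) -> None:
        for weights in (self.input_weights, self.ip_weights):
            for cls, w in weights.items():
                if w < 0:
                    raise ValueError(f"negative weight for class {cls!r}")

    def weights_for(self, role: str) -> dict[str, float]:
        if role == "IP":
            return self.ip_weights
        if role == "input":
            return self.input_weights
        raise ValueError(f"unknown sample role {role!r}")

    @classmethod
    def null(cls) -> "EnrichmentModel":
        w = {CLASS_NUCLEOSOME: 1.0, CLASS_TF_FOOTPRINT: 1.0, CLASS_SPANNING: 1.0}
        return cls(dict(w), dict(w))

    @classmethod
    def with_baseline(
        cls,
        state: ChromatinState,
        baseline_spanning_fraction: float = 0.05,
        tf_weight: float = 1.0,
        ip_spanning_multiplier: float = 1.0,
    ) -> "EnrichmentModel":
        """Weights such that the input sample draws the stated fraction of
        its fragments from spanning protections; the IP multiplies the
        spanning weight by ``ip_spanning_multiplier``."""
        if not 0 < baseline_spanning_fraction < 1:
            raise ValueError("baseline spanning fraction must lie in (0, 1)")
        n_nuc = sum(d.size for d in state.dyads.values())
        n_tf = len(state.tf_footprints)
        n_span = len(state.protections)
        if n_span == 0:
            raise ValueError("state has no spanning protections")
        f = baseline_spanning_fraction
        w_span = f / (1 - f) * (n_nuc * 1.0 + n_tf * tf_weight) / n_span
        input_w = {CLASS_NUCLEOSOME: 1.0, CLASS_TF_FOOTPRINT: tf_weight, CLASS_SPANNING: w_span}
        ip_w = dict(input_w)
        ip_w[CLASS_SPANNING] = w_span * ip_spanning_multiplier
        return cls(input_w, ip_w)


def build_genome(spec: GenomeSpec, seed: int) -> SyntheticGenome:
    """Generate sequences honoring the background GC and per-feature A+T
    enrichment, and emit the feature annotations."""
    spec.validate()
    rng = np.random.default_rng([_STREAM_GENOME, seed])
    bases = np.array(list("ACGT"))

    def probs(at_fraction: float) -> np.ndarray:
        at, gc = at_fraction / 2, (1 - at_fraction) / 2
        return np.array([at, gc, gc, at])

    background = probs(1 - spec.background_gc)
    sequences: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        arrays[chrom] = rng.choice(4, size=length, p=background)
    for ft in spec.features:
        if ft.at_fraction is not None:
            arrays[ft.chrom][ft.start : ft.end] = rng.choice(
                4, size=ft.end - ft.start, p=probs(ft.at_fraction)
            )
    for chrom in arrays:
        sequences[chrom] = "".join(bases[arrays[chrom]])
    features = [
        IntervalFeature(f.chrom, f.start, f.end, f.strand, f.name, f.feature_class)
        for f in spec.features
    ]
    return SyntheticGenome(sequences, features, spec)


def centromere_placements(
    chrom: str, midpoint: int, name: str = "CEN", cdeii_width: int = 84
) -> list[FeaturePlacement]:
    """A point-centromere layout: short CDEI and CDEIII elements flanking
    the highly A+T-rich CDEII, plus the enclosing centromere feature."""
    cdei_w, cdeiii_w = 8, 25
    half = (cdei_w + cdeii_width + cdeiii_w) // 2
    start = midpoint - half
    return [
        FeaturePlacement("centromere", chrom, start, start + cdei_w + cdeii_width + cdeiii_w,
                         name=name, at_fraction=0.9),
        FeaturePlacement("CDEI", chrom, start, start + cdei_w, name=f"{name}_CDEI"),
        FeaturePlacement("CDEII", chrom, start + cdei_w, start + cdei_w + cdeii_width,
                         name=f"{name}_CDEII", at_fraction=0.93),
        FeaturePlacement("CDEIII", chrom, start + cdei_w + cdeii_width,
                         start + cdei_w + cdeii_width + cdeiii_w, name=f"{name}_CDEIII"),
    ]


def place_chromatin(
    genome: SyntheticGenome,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    ndr_half_width: int = DEFAULT_NDR_HALF_WIDTH,
    seed: int = 0,
    ndr_half_width_jitter: int = 0,
) -> ChromatinState:
    """Tile phased nucleosome arrays between NDRs at the stated repeat.

    Every TFBS is centered in an NDR of width 2*ndr_half_width (plus a
    seeded uniform jitter of up to ``ndr_half_width_jitter`` bp per side
    when requested, giving a realistic spread of NDR sizes); explicit NDR
    features are honored as given.  The first nucleosome of each
    NDR-adjacent array abuts the NDR boundary; arrays not bounded by an
    NDR are centered with a half-repeat offset from the span start.
    """
    if repeat_length < CORE_LENGTH:
        raise ValueError(
            f"repeat length {repeat_length} is below the {CORE_LENGTH} bp core"
        )
    core = CORE_LENGTH
    half_up = core - core // 2  # 74: dyad-to-right-edge distance
    rng = np.random.default_rng([_STREAM_CHROMATIN, seed])

    ndrs: list[IntervalFeature] = []
    tf_footprints: list[IntervalFeature] = []
    protections: list[RemodelerProtection] = []
    for tfbs in genome.features_of_class("TFBS"):
        mid = tfbs.midpoint
        half = ndr_half_width
        if ndr_half_width_jitter:
            half += int(rng.integers(-ndr_half_width_jitter, ndr_half_width_jitter + 1))
        ndr = IntervalFeature(
            tfbs.chrom, mid - half, mid + half,
            name=f"NDR_{tfbs.name}", feature_class="NDR",
        )
        ndrs.append(ndr)
        tf_footprints.append(tfbs)
        protections.append(
            RemodelerProtection(tfbs.chrom, ndr.start - core, tfbs.end, "left",
                                tfbs_name=tfbs.name)
        )
        protections.append(
            RemodelerProtection(tfbs.chrom, tfbs.start, ndr.end + core, "right",
                                tfbs_name=tfbs.name)
        )
    ndrs.extend(genome.features_of_class("NDR"))

    dyads: dict[str, np.ndarray] = {}
    arrays: list[tuple[str, np.ndarray]] = []
    for chrom, length in genome.chrom_lengths.items():
        chrom_ndrs = sorted(
            (n for n in ndrs if n.chrom == chrom), key=lambda n: n.start
        )
        bounds = [0] + [x for n in chrom_ndrs for x in (n.start, n.end)] + [length]
        chrom_dyads: list[np.ndarray] = []
        for i in range(0, len(bounds), 2):
            span_start, span_end = bounds[i], bounds[i + 1]
            if span_end - span_start < core:
                continue
            abuts_left = i > 0  # span begins at an NDR 3' boundary
            abuts_right = i + 2 < len(bounds)  # span ends at an NDR 5' boundary
            span_arrays = _tile_span(
                span_start, span_end, repeat_length, core, abuts_left, abuts_right
            )
            for dd in span_arrays:
                if dd.size:
                    chrom_dyads.append(dd)
                    arrays.append((chrom, dd))
        dyads[chrom] = (
            np.sort(np.concatenate(chrom_dyads)) if chrom_dyads else np.array([], dtype=int)
        )
    return ChromatinState(dyads, repeat_length, core, ndrs, tf_footprints, protections, arrays)


def _tile_span(
    span_start: int,
    span_end: int,
    repeat: int,
    core: int,
    abuts_left: bool,
    abuts_right: bool,
) -> list[np.ndarray]:
    """Dyad positions for one inter-NDR span at the stated repeat.

    Arrays are phased off the NDR boundaries they abut: the first
    nucleosome edge coincides with the boundary.  A span bounded by NDRs
    on both sides is tiled inward from both ends, meeting at the center
    with one (possibly irregular) junction gap kept >= core.  A span with
    no NDR boundary (a bare chromosome) is tiled with a half-repeat
    phase offset from its start.
    """
    half_down = core // 2       # dyad-to-left-edge distance (73 for 147)
    half_up = core - half_down  # dyad-to-right-edge distance (74)
    lo = span_start + half_down  # leftmost admissible dyad
    hi = span_end - half_up      # rightmost admissible dyad
    if hi < lo:
        return []
    if abuts_left and abuts_right:
        center = (span_start + span_end) // 2
        fwd = np.arange(lo, hi + 1, repeat)
        fwd = fwd[fwd <= center]
        bwd = hi - repeat * np.arange((hi - lo) // repeat + 1)
        bwd = np.sort(bwd[bwd > center])
        while fwd.size and bwd.size and bwd[0] - fwd[-1] < core:
            fwd = fwd[:-1]
        return [fwd, bwd]
    if abuts_left:
        return [np.arange(lo, hi + 1, repeat)]
    if abuts_right:
        bwd = hi - repeat * np.arange((hi - lo) // repeat + 1)
        return [np.sort(bwd)]
    first = span_start + repeat // 2
    return [np.arange(first, hi + 1, repeat)] if first <= hi else []


@dataclass
class SimulatedFragments:
    """Fragments plus the ground-truth provenance sidecar table."""

    fragments: FragmentSet
    provenance: pd.DataFrame  # unit_class, unit_id, side, source_start, source_end


def _unit_table(
    state: ChromatinState, weights: dict[str, float], apply_occupancy: bool
) -> pd.DataFrame:
    """Protected units with sampling weights.

    Occupancy (the remodeler-bound probability of a spanning protection)
    gates only the IP: the immunoprecipitation can pull a protection down
    only when the remodeler occupies it, whereas the input's residual
    spanning protection is a bulk baseline independent of which gene's
    promoter it sits at.
    """
    rows = []
    for i, (chrom, s, e) in enumerate(state.nucleosome_intervals()):
        rows.append((chrom, s, e, CLASS_NUCLEOSOME, f"nuc_{i}", "", 1.0))
    for i, ft in enumerate(state.tf_footprints):
        rows.append((ft.chrom, ft.start, ft.end, CLASS_TF_FOOTPRINT,
                     ft.name or f"tf_{i}", "", 1.0))
    for i, pr in enumerate(state.protections):
        rows.append((pr.chrom, pr.start, pr.end, CLASS_SPANNING,
                     f"{pr.tfbs_name or i}:{pr.side}", pr.side, pr.occupancy))
    units = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "unit_class", "unit_id", "side", "occupancy"]
    )
    units["weight"] = units["unit_class"].map(weights).fillna(0.0)
    if apply_occupancy:
        units["weight"] *= units["occupancy"]
    return units


def emit_fragments(
    state: ChromatinState,
    digestion: DigestionModel,
    enrichment: EnrichmentModel,
    n_fragments: int,
    sample_role: str,
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
    name: str = "",
) -> SimulatedFragments:
    """Draw fragments from the protected units of a chromatin state.

    Each fragment: pick a unit with probability proportional to its class
    weight (times occupancy), extend by the digestion overhang on each
    side, trim each end by floor(Exp(extent)) bases, and keep the result
    if its length lies in [min_length, max_length] (rejected draws are
    resampled).  Spanning protections already encode their side, so each
    spanning event protects one side of its TFBS.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    units = _unit_table(state, enrichment.weights_for(sample_role),
                        apply_occupancy=sample_role == "IP")
    if units["weight"].sum() <= 0:
        raise ValueError("all unit weights are zero; nothing to emit")
    p = (units["weight"] / units["weight"].sum()).to_numpy()
    starts = units["start"].to_numpy() - digestion.overhang
    ends = units["end"].to_numpy() + digestion.overhang
    chrom_of = units["chrom"].to_numpy()
    bound = {c: L for c, L in (chrom_lengths or {}).items()}

    stream = _STREAM_FRAGMENTS_IP if sample_role == "IP" else _STREAM_FRAGMENTS_INPUT
    rng = np.random.default_rng([stream, seed])

    keep_idx: list[np.ndarray] = []
    keep_start: list[np.ndarray] = []
    keep_end: list[np.ndarray] = []
    n_kept = 0
    while n_kept < n_fragments:
        batch = max(1024, int((n_fragments - n_kept) * 1.2))
        idx = rng.choice(units.shape[0], size=batch, p=p)
        if digestion.extent > 0:
            tl = np.floor(rng.exponential(digestion.extent, size=batch)).astype(int)
            tr = np.floor(rng.exponential(digestion.extent, size=batch)).astype(int)
        else:
            tl = tr = np.zeros(batch, dtype=int)
        fs = starts[idx] + tl
        fe = ends[idx] - tr
        fs = np.maximum(fs, 0)
        if bound:
            lims = np.array([bound.get(c, np.iinfo(np.int64).max) for c in chrom_of[idx]])
            fe = np.minimum(fe, lims)
        ok = (fe - fs >= digestion.min_length) & (fe - fs <= digestion.max_length)
        keep_idx.append(idx[ok])
        keep_start.append(fs[ok])
        keep_end.append(fe[ok])
        n_kept += int(ok.sum())
    idx = np.concatenate(keep_idx)[:n_fragments]
    fs_ = np.concatenate(keep_start)[:n_fragments]
    fe_ = np.concatenate(keep_end)[:n_fragments]

    frags = [
        Fragment(chrom_of[i], int(s), int(e)) for i, s, e in zip(idx, fs_, fe_)
    ]
    fragment_set = FragmentSet(
        frags, dict(chrom_lengths or {}), name=name or f"sim_{sample_role}",
        role=sample_role,
    )
    provenance = pd.DataFrame(
        {
            "unit_class": units["unit_class"].to_numpy()[idx],
            "unit_id": units["unit_id"].to_numpy()[idx],
            "side": units["side"].to_numpy()[idx],
            "source_start": starts[idx],
            "source_end": ends[idx],
        }
    )
    return SimulatedFragments(fragment_set, provenance)


def _class_range_probability(
    extended_length: int, digestion: DigestionModel, lo: int, hi: int
) -> float:
    """Exact P(emitted length in [lo, hi]) for a unit of the given
    extended (pre-trim) length, from the two-end trim pmf."""
    pmf = digestion.trim_pmf(extended_length)
    t_lo = max(extended_length - hi, 0)
    t_hi = extended_length - lo
    if t_hi < 0:
        return 0.0
    return float(pmf[t_lo : t_hi + 1].sum())


def expected_ratio_of_ratios(
    state: ChromatinState,
    digestion: DigestionModel,
    enrichment: EnrichmentModel,
    nucleosomal: tuple[int, int] = (141, 250),
    supernucleosomal: tuple[int, int] = (251, 428),
) -> float:
    """Analytic expectation of the IP/input supernucleosomal-to-nucleosomal
    AUC ratio-of-ratios under the emission model (boundary clipping
    ignored)."""

    def ratio(weights: dict[str, float], apply_occupancy: bool) -> float:
        units = _unit_table(state, weights, apply_occupancy)
        ext = units["end"] - units["start"] + 2 * digestion.overhang
        grouped = units.assign(ext=ext).groupby("ext")["weight"].sum()
        p_nuc = p_sup = 0.0
        for L0, w in grouped.items():
            p_nuc += w * _class_range_probability(int(L0), digestion, *nucleosomal)
            p_sup += w * _class_range_probability(int(L0), digestion, *supernucleosomal)
        if p_nuc == 0:
            raise ValueError("expected nucleosomal mass is zero")
        return p_sup / p_nuc

    return ratio(enrichment.ip_weights, True) / ratio(enrichment.input_weights, False)


def design_enrichment(
    state: ChromatinState,
    digestion: DigestionModel,
    target_ratio_of_ratios: float,
    baseline_spanning_fraction: float = 0.05,
    tf_weight: float = 1.0,
    nucleosomal: tuple[int, int] = (141, 250),
    supernucleosomal: tuple[int, int] = (251, 428),
) -> EnrichmentModel:
    """Solve for the IP spanning-class weight multiplier that makes the
    expected ratio-of-ratios equal the target (analytic, no sampling)."""
    if target_ratio_of_ratios <= 0:
        raise ValueError("target ratio-of-ratios must be positive")

    def objective(log_m: float) -> float:
        model = EnrichmentModel.with_baseline(
            state, baseline_spanning_fraction, tf_weight, float(np.exp(log_m))
        )
        return (
            expected_ratio_of_ratios(state, digestion, model, nucleosomal, supernucleosomal)
            - target_ratio_of_ratios
        )

    log_m = optimize.brentq(objective, -12.0, 12.0, xtol=1e-10)
    return EnrichmentModel.with_baseline(
        state, baseline_spanning_fraction, tf_weight, float(np.exp(log_m))
    )


def designed_fragment_mode_length(unit_length: int, digestion: DigestionModel) -> int:
    """Modal emitted length for a unit of the given protected length."""
    ext = unit_length + 2 * digestion.overhang
    pmf = digestion.trim_pmf(ext)
    return ext - int(np.argmax(pmf))


def designed_flanking_dyad_offsets(state: ChromatinState, tfbs: IntervalFeature) -> tuple[int, int]:
    """Signed offsets from the TFBS midpoint to the dyads of the two
    NDR-abutting nucleosomes (left is negative)."""
    ndr = next(n for n in state.ndrs if n.name == f"NDR_{tfbs.name}")
    half_down = state.core_length // 2
    half_up = state.core_length - half_down
    return (ndr.start - half_up - tfbs.midpoint, ndr.end + half_down - tfbs.midpoint)


def measure_flanking_cluster_offsets(v, state: ChromatinState) -> tuple[float, float]:
    """Locate the NDR-flanking nucleosome clusters in a counts V-plot.

    Sums the nucleosomal band (141-250 bp) over fragment length and finds
    the peak x-bin within one repeat length of each NDR edge — the region
    that can only hold the flanking nucleosome.  Returns the (left, right)
    peak x-bin centers in bp.
    """
    ndr_half = (state.ndrs[0].end - state.ndrs[0].start) // 2
    band = (v.y_bin_starts >= 141) & (v.y_bin_starts <= 250)
    x_marginal = v.matrix[:, band].sum(axis=1)
    centers = v.x_bin_centers
    out = []
    for sign in (-1, 1):
        lo, hi = ndr_half, ndr_half + state.repeat_length
        window = (sign * centers >= lo) & (sign * centers < hi)
        idx = np.flatnonzero(window)
        out.append(float(centers[idx[np.argmax(x_marginal[idx])]]))
    return out[0], out[1]


def measure_supernucleosomal_mode_length(v, min_length: int = 251) -> int:
    """Modal fragment length in the supernucleosomal band of a V-plot."""
    band = v.y_bin_starts >= min_length
    y_marginal = v.matrix[:, band].sum(axis=0)
    return int(v.y_bin_starts[band][np.argmax(y_marginal)])


def simulate_gene_metrics(
    genome: SyntheticGenome,
    coupling: float,
    seed: int,
    metrics: tuple[str, ...] = ("expression", "turnover", "transcription_rate"),
) -> pd.DataFrame:
    """Per-gene metric table with a designed IP enrichment column.

    Each metric is jointly Gaussian with the latent designed enrichment at
    the requested Pearson coupling (units are arbitrary and linear, so the
    realized correlation is an unbiased estimate of the target).
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must lie in [-1, 1]")
    genes = genome.features_of_class("ORF")
    if len(genes) < 10:
        raise ValueError(f"need >= 10 genes for meaningful correlations, got {len(genes)}")
    rng = np.random.default_rng([_STREAM_METRICS, seed])
    n = len(genes)
    z = rng.standard_normal(n)
    table = {"designed_enrichment": 1.0 + 0.5 * z}
    scales = {"expression": (10.0, 3.0), "turnover": (1.0, 0.3), "transcription_rate": (8.0, 4.0)}
    for metric in metrics:
        eps = rng.standard_normal(n)
        latent = coupling * z + np.sqrt(1 - coupling**2) * eps
        mu, sd = scales.get(metric, (0.0, 1.0))
        table[metric] = mu + sd * latent
    df = pd.DataFrame(table, index=pd.Index([g.name or f"gene_{i}" for i, g in enumerate(genes)],
                                            name="gene_id"))
    return df


def demo_genome_spec(
    chrom_length: int = 300_000,
    n_tfbs: int = 12,
    n_orfs: int = 60,
    n_centromeres: int = 1,
    tfbs_width: int = 16,
    orf_length: int = 1_500,
    chrom_name: str = "chrI",
    seed: int = 0,
) -> GenomeSpec:
    """A small single-chromosome layout with evenly spaced TFBSs, ORFs
    downstream of alternate TFBSs, and optional centromeres — enough
    structure for every analysis in the package."""
    features: list[FeaturePlacement] = []
    spacing = chrom_length // (n_tfbs + n_centromeres + 1)
    rng = np.random.default_rng([_STREAM_GENOME, seed, 7])
    pos = spacing
    for i in range(n_tfbs):
        mid = pos
        features.append(
            FeaturePlacement("TFBS", chrom_name, mid - tfbs_width // 2,
                             mid + tfbs_width - tfbs_width // 2,
                             strand="+", name=f"tfbs_{i}")
        )
        pos += spacing
    for i in range(n_centromeres):
        features.extend(centromere_placements(chrom_name, pos, name=f"CEN{i + 1}"))
        pos += spacing
    # ORFs: gene bodies starting just outside TFBS-derived NDRs, alternating strand
    orf_slots = np.linspace(spacing, chrom_length - orf_length - spacing, n_orfs).astype(int)
    jitter = rng.integers(120, 1200, size=n_orfs)
    for i, slot in enumerate(orf_slots):
        start = int(slot + jitter[i]) % (chrom_length - orf_length)
        strand = "+" if i % 2 == 0 else "-"
        features.append(
            FeaturePlacement("ORF", chrom_name, start, start + orf_length,
                             strand=strand, name=f"gene_{i}")
        )
    # promoter TFBS ~200 bp upstream of each ORF 5' end; its NDR-spanning
    # protections are what per-gene enrichment coupling modulates
    for ft in [f for f in features if f.feature_class == "ORF"]:
        pos = ft.start - 200 if ft.strand == "+" else ft.end + 200
        if tfbs_width // 2 <= pos <= chrom_length - tfbs_width:
            features.append(
                FeaturePlacement("TFBS", chrom_name, pos - tfbs_width // 2,
                                 pos + tfbs_width - tfbs_width // 2,
                                 strand=ft.strand, name=f"p_{ft.name}")
            )
    spec = GenomeSpec({chrom_name: chrom_length}, features)
    # drop overlapping same-class features introduced by jitter/promoters
    keep: list[FeaturePlacement] = []
    last_end: dict[str, int] = {}
    for ft in sorted(spec.features, key=lambda f: (f.feature_class, f.start)):
        if ft.start < last_end.get(ft.feature_class, -1):
            continue
        last_end[ft.feature_class] = ft.end
        keep.append(ft)
    spec.features = keep
    spec.validate()
    return spec


def couple_state_to_genes(
    state: ChromatinState,
    metrics: pd.DataFrame,
    min_occupancy: float = 0.05,
) -> ChromatinState:
    """Scale each promoter protection's occupancy by its gene's designed
    enrichment.

    Promoter TFBSs are linked to genes by the ``p_<gene_id>`` naming
    convention; occupancies are the designed enrichments rescaled to
    (0, 1] (so the most-enriched gene's promoter protections are sampled
    at full weight).  Returns a new state; non-promoter protections are
    untouched.
    """
    e = metrics["designed_enrichment"]
    top = float(e.max())
    if top <= 0:
        raise ValueError("designed enrichment must have a positive maximum")
    protections = []
    for pr in state.protections:
        gene = pr.tfbs_name[2:] if pr.tfbs_name.startswith("p_") else None
        if gene is not None and gene in e.index:
            occ = float(np.clip(e.loc[gene] / top, min_occupancy, 1.0))
            pr = RemodelerProtection(pr.chrom, pr.start, pr.end, pr.side, occ,
                                     pr.tfbs_name)
        protections.append(pr)
    return ChromatinState(dict(state.dyads), state.repeat_length, state.core_length,
                          list(state.ndrs), list(state.tf_footprints), protections,
                          list(state.arrays))
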