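"""Config-driven orchestration of the whole analysis suite.

A run takes its data either from the built-in simulator or from user
files (exactly one of the two), executes the enabled analyses, and writes
all outputs into one directory.  Every output records the seed and a hash
of the materialized configuration, so a run is reproducible from its
outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import io as fio
from . import profiles as prof
from . import seqfeat, simulate, sizes, vplot

log = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulatorConfig(_Section):
    chrom_length: int = 300_000
    n_tfbs: int = 12
    n_orfs: int = 60
    n_centromeres: int = 1
    n_fragments: int = 50_000
    repeat_length: int = simulate.DEFAULT_REPEAT_LENGTH
    ndr_half_width: int = simulate.DEFAULT_NDR_HALF_WIDTH
    ndr_half_width_jitter: int = 25
    digestion_extent: float = 5.0
    baseline_spanning_fraction: float = 0.05
    target_enrichment: float = 2.5
    coupling: float = 0.8


class InputPaths(_Section):
    ip_fragments: str
    input_fragments: str
    fragment_format: Literal["BED3", "BEDPE"] = "BED3"
    genome_fasta: Optional[str] = None
    features_bed: Optional[str] = None
    metrics_tsv: Optional[str] = None
    chrom_lengths: dict[str, int] = {}


class SizesConfig(_Section):
    enabled: bool = True
    nucleosomal: tuple[int, int] = sizes.NUCLEOSOMAL_RANGE
    supernucleosomal: tuple[int, int] = sizes.SUPERNUCLEOSOMAL_RANGE


class VPlotConfig(_Section):
    enabled: bool = True
    x_half_width: int = vplot.DEFAULT_X_HALF_WIDTH
    x_bin: int = vplot.DEFAULT_X_BIN
    y_min: int = vplot.DEFAULT_Y_MIN
    y_max: int = vplot.DEFAULT_Y_MAX
    y_bin: int = vplot.DEFAULT_Y_BIN
    anchor_mode: Literal["midpoint", "five_prime", "three_prime"] = "midpoint"


class ProfilesConfig(_Section):
    enabled: bool = True
    flank: int = 1000
    pseudocount: float = 0.5
    quintiles: bool = True


class HeatmapConfig(_Section):
    enabled: bool = True
    flank: int = 1000
    metric: str = "expression"


class NdrConfig(_Section):
    enabled: bool = True


class BendabilityConfig(_Section):
    enabled: bool = True
    window: int = seqfeat.DEFAULT_BENDABILITY_WINDOW
    pfm_flank: int = 200


class AnalysesConfig(_Section):
    sizes: SizesConfig = SizesConfig()
    vplot: VPlotConfig = VPlotConfig()
    profiles: ProfilesConfig = ProfilesConfig()
    heatmap: HeatmapConfig = HeatmapConfig()
    ndr: NdrConfig = NdrConfig()
    bendability: BendabilityConfig = BendabilityConfig()


class RunConfig(_Section):
    seed: int = 0
    output_dir: str = "mnasefrag_out"
    simulator: Optional[SimulatorConfig] = None
    inputs: Optional[InputPaths] = None
    analyses: AnalysesConfig = AnalysesConfig()

    @model_validator(mode="after")
    def _one_data_source(self) -> "RunConfig":
        if (self.simulator is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulator' and 'inputs' must be configured"
            )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; defaults materialized,
    unknown keys rejected, referenced input files checked for existence."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = RunConfig.model_validate(raw)
    if config.inputs is not None:
        for field in ("ip_fragments", "input_fragments", "genome_fasta",
                      "features_bed", "metrics_tsv"):
            value = getattr(config.inputs, field)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"configured {field} not found: {value}")
    return config


class _Stage:
    """Context manager attributing failures and timings to a stage name."""

    def __init__(self, name: str, timings: dict[str, float]):
        self.name, self.timings = name, timings

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = time.perf_counter() - self.t0
        if exc is not None:
            raise RuntimeError(f"stage '{self.name}' failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, self.timings[self.name])


def _write_json(path: Path, payload: dict, provenance: dict) -> None:
    payload = {"_provenance": provenance, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_tsv(path: Path, df: pd.DataFrame, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run(config: RunConfig, output_dir: str | Path | None = None) -> dict[str, Path]:
    """Execute all enabled analyses; returns {output name: path}."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    header = f"config_sha256={config.config_hash()} seed={seed}"
    provenance = {"config_sha256": config.config_hash(), "seed": seed}
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}

    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mnasefrag")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("mnasefrag run: %s", header)
        log.info("python %s on %s", platform.python_version(), platform.platform())
        log.info("numpy %s, pandas %s", np.__version__, pd.__version__)
        log.info("parameters: %s", json.dumps(config.model_dump(mode="json"), sort_keys=True))

        # ---- data source ------------------------------------------------
        genome = metrics = None
        features: list[fio.IntervalFeature] = []
        state = None
        with _Stage("data", timings):
            if config.simulator is not None:
                sim = config.simulator
                spec = simulate.demo_genome_spec(
                    chrom_length=sim.chrom_length, n_tfbs=sim.n_tfbs,
                    n_orfs=sim.n_orfs, n_centromeres=sim.n_centromeres, seed=seed,
                )
                genome = simulate.build_genome(spec, seed)
                features = genome.features
                state = simulate.place_chromatin(
                    genome, sim.repeat_length, sim.ndr_half_width, seed,
                    sim.ndr_half_width_jitter,
                )
                metrics = simulate.simulate_gene_metrics(genome, sim.coupling, seed)
                state = simulate.couple_state_to_genes(state, metrics)
                digestion = simulate.DigestionModel(extent=sim.digestion_extent)
                enrichment = simulate.design_enrichment(
                    state, digestion, sim.target_enrichment,
                    sim.baseline_spanning_fraction,
                )
                ip = simulate.emit_fragments(
                    state, digestion, enrichment, sim.n_fragments, "IP", seed,
                    genome.chrom_lengths,
                ).fragments
                inp = simulate.emit_fragments(
                    state, digestion, enrichment, sim.n_fragments, "input", seed,
                    genome.chrom_lengths,
                ).fragments
                fio.write_fragments_bed3(ip, out / "sim_ip.bed")
                fio.write_fragments_bed3(inp, out / "sim_input.bed")
                fio.write_fasta(genome.sequences, out / "sim_genome.fa")
                fio.write_features_bed6(features, out / "sim_features.bed")
                fio.write_metric_table(metrics, out / "sim_metrics.tsv", header)
                outputs |= {
                    "sim_ip": out / "sim_ip.bed", "sim_input": out / "sim_input.bed",
                    "sim_genome": out / "sim_genome.fa",
                    "sim_features": out / "sim_features.bed",
                    "sim_metrics": out / "sim_metrics.tsv",
                }
            else:
                paths = config.inputs
                lengths = dict(paths.chrom_lengths)
                sequences = fio.read_fasta(paths.genome_fasta) if paths.genome_fasta else None
                if sequences and not lengths:
                    lengths = {c: len(s) for c, s in sequences.items()}
                ip = fio.read_fragments(paths.ip_fragments, paths.fragment_format,
                                        lengths, role="IP")
                inp = fio.read_fragments(paths.input_fragments, paths.fragment_format,
                                         lengths, role="input")
                if paths.features_bed:
                    features = fio.read_features(paths.features_bed)
                metrics = (fio.read_metric_table(paths.metrics_tsv)
                           if paths.metrics_tsv else None)
                if sequences is not None:
                    genome = simulate.SyntheticGenome(
                        sequences, features, simulate.GenomeSpec(lengths)
                    )

        chrom_lengths = ip.chrom_lengths or inp.chrom_lengths
        an = config.analyses

        tfbs_features = [f for f in features if f.feature_class == "TFBS"]
        orf_features = [f for f in features if f.feature_class == "ORF"]
        ndr_features = (state.ndrs if state is not None
                        else [f for f in features if f.feature_class == "NDR"])
        anchor_features = tfbs_features or features

        # ---- size distributions ----------------------------------------
        if an.sizes.enabled:
            with _Stage("sizes", timings):
                d_ip = sizes.length_histogram(ip)
                d_in = sizes.length_histogram(inp)
                stats_block = {}
                for label, dist in (("IP", d_ip), ("input", d_in)):
                    st = sizes.size_class_stat(dist, an.sizes.nucleosomal,
                                               an.sizes.supernucleosomal)
                    stats_block[label] = {
                        "nucleosomal_auc": st.nucleosomal_auc,
                        "supernucleosomal_auc": st.supernucleosomal_auc,
                        "ratio": st.ratio,
                    }
                stats_block["enrichment_ratio"] = sizes.enrichment_ratio(
                    d_ip, d_in, an.sizes.nucleosomal, an.sizes.supernucleosomal
                )
                lo = min(d_ip.min_length, d_in.min_length)
                hi = max(d_ip.max_length, d_in.max_length)
                dens = pd.DataFrame(
                    {
                        "length": np.arange(lo, hi + 1),
                        "IP": [d_ip.at(L) for L in range(lo, hi + 1)],
                        "input": [d_in.at(L) for L in range(lo, hi + 1)],
                    }
                )
                _write_tsv(out / "size_densities.tsv", dens, header, index=False)
                _write_json(out / "size_stats.json", stats_block, provenance)
                outputs |= {"size_densities": out / "size_densities.tsv",
                            "size_stats": out / "size_stats.json"}

        # ---- V-plots ----------------------------------------------------
        if an.vplot.enabled and anchor_features:
            with _Stage("vplot", timings):
                anchors = fio.to_anchors(anchor_features, an.vplot.anchor_mode)
                for label, fs in (("ip", ip), ("input", inp)):
                    v = vplot.build_vplot(
                        fs, anchors, an.vplot.x_half_width, an.vplot.x_bin,
                        an.vplot.y_min, an.vplot.y_max, an.vplot.y_bin,
                    )
                    if v.n_fragments:
                        v = vplot.normalize_vplot(v)
                    path = out / f"vplot_{label}.tsv"
                    vplot.export_vplot(v, path)
                    outputs[f"vplot_{label}"] = path

        # ---- tracks, profiles, heatmap, NDR correlation ----------------
        ratio_track = None
        if chrom_lengths and (an.profiles.enabled or an.heatmap.enabled or an.ndr.enabled):
            with _Stage("ratio_track", timings):
                cov_ip = prof.coverage_track(ip)
                cov_in = prof.coverage_track(inp)
                ratio_track = prof.log_ratio_track(cov_ip, cov_in,
                                                   an.profiles.pseudocount)
                fio.write_track_bedgraph(ratio_track.values,
                                         out / "log2_ratio.bedgraph", header=header)
                outputs["log2_ratio"] = out / "log2_ratio.bedgraph"

        if an.profiles.enabled and ratio_track is not None and anchor_features:
            with _Stage("profiles", timings):
                anchors = fio.to_anchors(anchor_features, "midpoint")
                res = prof.aggregate_profile(ratio_track, anchors, an.profiles.flank)
                df = pd.DataFrame({"offset": res.offsets, "mean_log2_ratio": res.mean,
                                   "n": res.n_contributing})
                _write_tsv(out / "aggregate_profile.tsv", df, header, index=False)
                outputs["aggregate_profile"] = out / "aggregate_profile.tsv"
                if an.profiles.quintiles and len(anchors) >= 5:
                    q = prof.quintile_profiles(ratio_track, anchors, an.profiles.flank)
                    qdf = pd.DataFrame({"offset": q[0].offsets})
                    for g, pr_res in enumerate(q, start=1):
                        qdf[f"quintile_{g}"] = pr_res.mean
                    _write_tsv(out / "quintile_profiles.tsv", qdf, header, index=False)
                    outputs["quintile_profiles"] = out / "quintile_profiles.tsv"

        if (an.heatmap.enabled and ratio_track is not None and metrics is not None
                and orf_features):
            with _Stage("heatmap", timings):
                named = [f for f in orf_features if f.name in metrics.index]
                anchors = fio.to_anchors(named, "five_prime")
                hm = prof.heatmap_matrix(ratio_track, anchors, an.heatmap.flank,
                                         metrics, an.heatmap.metric)
                df = pd.DataFrame(hm.matrix, index=pd.Index(hm.row_ids, name="gene_id"),
                                  columns=hm.offsets)
                _write_tsv(out / "heatmap.tsv", df, header)
                outputs["heatmap"] = out / "heatmap.tsv"

        if an.ndr.enabled and ratio_track is not None and ndr_features:
            with _Stage("ndr", timings):
                r2, table = prof.ndr_correlation(ratio_track, ndr_features)
                _write_tsv(out / "ndr_table.tsv", table, header, index=False)
                _write_json(out / "ndr_correlation.json",
                            {"r_squared": r2, "n_ndrs": int(table.shape[0])}, provenance)
                outputs |= {"ndr_table": out / "ndr_table.tsv",
                            "ndr_correlation": out / "ndr_correlation.json"}

        # ---- sequence features -----------------------------------------
        if an.bendability.enabled and genome is not None and anchor_features:
            with _Stage("bendability", timings):
                scale = seqfeat.BendabilityScale.default()
                anchors = fio.to_anchors(anchor_features, "midpoint")
                pfm = seqfeat.pfm_from_anchors(genome.sequences, anchors,
                                               an.bendability.pfm_flank)
                pfm_df = pfm.to_dataframe()
                pfm_df["at_fraction"] = pfm.at_fraction
                _write_tsv(out / "pfm.tsv", pfm_df, header)
                regions = seqfeat.extract_region_sequences(
                    genome.sequences,
                    [fio.IntervalFeature(a.chrom, max(a.position - 50, 0),
                                         a.position + 50, a.strand, a.name)
                     for a in anchors],
                )
                means = seqfeat.region_mean_bendability(regions, scale,
                                                        an.bendability.window)
                _write_json(out / "bendability.json",
                            {"mean_bendability": float(np.mean(means)),
                             "n_regions": int(means.size),
                             "window": an.bendability.window}, provenance)
                outputs |= {"pfm": out / "pfm.tsv",
                            "bendability": out / "bendability.json"}

        _write_json(out / "run_summary.json",
                    {"timings_s": {k: round(v, 3) for k, v in timings.items()},
                     "outputs": {k: str(v.name) for k, v in outputs.items()}},
                    provenance)
        outputs["run_summary"] = out / "run_summary.json"
        outputs["run_log"] = log_path
    finally:
        root.removeHandler(handler)
        handler.close()
    return outputs


def run_from_file(config_path, output_dir=None) -> dict[str, Path]:
    return run(validate_config(config_path), output_dir)
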