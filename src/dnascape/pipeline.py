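"""End-to-end study pipeline: genome -> maps -> properties -> references ->
profiles -> peaks -> correlations -> influences, driven by one YAML config
and one master seed, with a JSON run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_rng
from .correlation import CorrelationConfig, bootstrap_correlation
from .genome import Genome
from .influence import decompose_peak, partition_dinucleotides
from .maps import (AnnotationSet, Interval, count_dinucleotides, coverage_track,
                   find_tandem_repeats, read_annotations, tandem_repeat_intervals)
from .peaks import call_peak, estimate_baseline, relative_significance
from .profiles import ProfileConfig
from .properties import ModelTable, apply_model, bundled_models, load_model_table
from .references import expected_dinucleotides
from .synthetic import (AnchorFlankSpec, GenomeSpec, RepeatInsertionSpec,
                        generate_genome, insert_repeats, place_anchors)
from .tracks import GenomeTracks, write_bedgraph

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Single-document configuration of a full run; every numeric default of
    the analysis modules can be overridden here."""

    output_dir: str = "dnascape_run"
    seed: int = 0
    resolution: int = 1000
    mode: str = "sum"
    models: list[str] = field(default_factory=lambda: ["Roll(94)", "Twist(1)"])
    model_table: str | None = None
    # input genome: path to FASTA, or synthetic spec
    fasta: str | None = None
    synthetic_genome: dict | None = None
    # anchors: BED path + category, or synthetic flank spec
    anchors_bed: str | None = None
    anchors_category: str | None = None
    synthetic_anchors: dict | None = None
    synthetic_repeats: list[dict] = field(default_factory=list)
    half_width: int = 1_000_000
    discard_threshold: float = 0.5
    baseline_min_distance: int = 800_000
    z_threshold: float = 2.0
    correlation_repetitions: int = 50
    correlation_sample_size: int = 50
    max_tr_classes: int = 10
    write_genome: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.fasta is None and self.synthetic_genome is None:
            raise ValueError("config needs either 'fasta' or 'synthetic_genome'")
        if self.fasta is not None and not Path(self.fasta).exists():
            raise FileNotFoundError(f"FASTA not found: {self.fasta}")
        if self.anchors_bed is not None and not Path(self.anchors_bed).exists():
            raise FileNotFoundError(f"anchor BED not found: {self.anchors_bed}")
        if self.fasta is None and self.anchors_bed is None \
                and self.synthetic_anchors is None:
            raise ValueError("config needs anchors (BED or synthetic)")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_synthetic(cfg: RunConfig) -> tuple[Genome, list[Interval], dict]:
    gspec = GenomeSpec(seed=cfg.seed, resolution=cfg.resolution,
                       **cfg.synthetic_genome)
    genome, truth = generate_genome(gspec)
    anchors: list[Interval] = []
    if cfg.synthetic_anchors:
        aspec = AnchorFlankSpec(**cfg.synthetic_anchors)
        genome, anchors, anchor_truth = place_anchors(
            genome, aspec, cfg.seed, truth_resolution=cfg.resolution)
        truth["anchors"] = anchor_truth
    truth["repeats"] = []
    for i, rdict in enumerate(cfg.synthetic_repeats):
        rdict = dict(rdict)
        if "length" in rdict and isinstance(rdict["length"], list):
            rdict["length"] = tuple(rdict["length"])
        rspec = RepeatInsertionSpec(**rdict)
        genome, inserted = insert_repeats(genome, rspec, cfg.seed + i + 1,
                                          anchors=anchors)
        truth["repeats"].extend(r.__dict__ for r in inserted)
    return genome, anchors, truth


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a result bundle and writes TSV/JSON
    outputs plus a manifest to the configured output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": {k: v for k, v in config.__dict__.items()},
                      "inputs": {}}

    # ----- genome and anchors -------------------------------------------
    truth: dict = {}
    if config.synthetic_genome is not None:
        genome, anchors, truth = _build_synthetic(config)
        if config.write_genome:
            genome.to_fasta(out / "genome.fa")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    else:
        genome = Genome.from_fasta(config.fasta)
        manifest["inputs"][config.fasta] = _sha256(config.fasta)
        anchors = []
    if config.anchors_bed is not None:
        ann = read_annotations(config.anchors_bed, "bed")
        cat = config.anchors_category or ann.names[0]
        anchors = ann[cat]
        manifest["inputs"][config.anchors_bed] = _sha256(config.anchors_bed)
    if not anchors:
        raise ValueError("no anchors available")
    AnnotationSet({"anchor": list(anchors)}).to_bed(out / "anchors.bed")

    # ----- maps ----------------------------------------------------------
    dinucs = {n: count_dinucleotides(genome.chromosomes[n], config.resolution, n)
              for n in genome.names}
    trs = {n: find_tandem_repeats(genome.chromosomes[n], chrom=n)
           for n in genome.names}

    # tandem-repeat classes, largest genome-wide coverage first
    tr_cov: dict[str, int] = {}
    tr_ivs: dict[str, list[Interval]] = {}
    for n, rep in trs.items():
        for cls, ivs in tandem_repeat_intervals(rep).items():
            tr_ivs.setdefault(cls, []).extend(ivs)
            tr_cov[cls] = tr_cov.get(cls, 0) + sum(iv.end - iv.start for iv in ivs)
    keep = sorted(tr_cov, key=tr_cov.get, reverse=True)[:config.max_tr_classes]
    tandem = {cls: tr_ivs[cls] for cls in keep}
    if len(tr_ivs) > len(keep):
        other = [iv for cls in tr_ivs if cls not in keep for iv in tr_ivs[cls]]
        tandem["(TR_other)"] = other

    transposons: dict[str, list[Interval]] = {}
    for r in truth.get("repeats", []):
        if r["kind"] == "transposon":
            transposons.setdefault(r["label"], []).append(
                Interval(r["chrom"], r["start"], r["end"]))

    partitioned = {
        n: partition_dinucleotides(
            genome.chromosomes[n],
            {cls: [iv for iv in ivs if iv.chrom == n] for cls, ivs in tandem.items()},
            {lab: [iv for iv in ivs if iv.chrom == n] for lab, ivs in transposons.items()},
            config.resolution, n)
        for n in genome.names}
    reference = {n: expected_dinucleotides(dinucs[n]) for n in genome.names}

    # ----- models --------------------------------------------------------
    table: ModelTable = (load_model_table(config.model_table)
                         if config.model_table else bundled_models())
    models = [table.get(label) for label in config.models]

    pcfg = ProfileConfig(half_width=config.half_width,
                         discard_threshold=config.discard_threshold)

    anchor_cov: GenomeTracks = {
        n: coverage_track([iv for iv in anchors if iv.chrom == n],
                          genome.length(n), config.resolution, n)
        for n in genome.names}

    peak_rows, corr_rows, influence_frames = [], [], []
    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    corr_seed = int(derive_rng(config.seed, "correlation").integers(2 ** 31))

    for model in models:
        dec = decompose_peak(partitioned, model, anchors, pcfg, mask=None,
                             mode=config.mode,
                             baseline_min_distance=config.baseline_min_distance,
                             z_threshold=config.z_threshold,
                             reference=reference)
        dec.property_profile.to_tsv(profiles_dir / f"{model.name}_{model.id}.tsv")
        sigma_rel = np.nan
        if dec.reference_profile is not None:
            ref_base = estimate_baseline(dec.reference_profile,
                                         config.baseline_min_distance)
            ref_peak = call_peak(dec.reference_profile, ref_base,
                                 config.z_threshold)
            sigma_rel = relative_significance(dec.peak, ref_peak)
        pk = dec.peak
        peak_rows.append({
            "model": model.label, "detected": pk.detected, "sign": pk.sign,
            "height": pk.height, "apex_distance": pk.apex_distance,
            "width_min": pk.width_min, "width_max": pk.width_max,
            "z_center": pk.z_center, "sigma_rel": sigma_rel,
        })
        if pk.detected:
            influence_frames.append(dec.to_frame())

        ptracks: GenomeTracks = {
            n: apply_model(model, dinucs[n], config.mode).track
            for n in genome.names}
        write_bedgraph(ptracks, profiles_dir / f"{model.name}_{model.id}.bedgraph")
        res = bootstrap_correlation(ptracks, anchor_cov, CorrelationConfig(
            config.correlation_repetitions, config.correlation_sample_size,
            corr_seed))
        corr_rows.append({"model": model.label, "annotation": "anchor",
                          "r_mean": res.r_mean, "r_sd": res.r_sd,
                          "null_mean": res.null_mean, "null_sd": res.null_sd,
                          "sigma": res.sigma})

    peaks_df = pd.DataFrame(peak_rows)
    corr_df = pd.DataFrame(corr_rows)
    peaks_df.to_csv(out / "peaks.tsv", sep="\t", index=False)
    corr_df.to_csv(out / "correlations.tsv", sep="\t", index=False)
    if influence_frames:
        influence_df = pd.concat(influence_frames, ignore_index=True)
    else:
        influence_df = pd.DataFrame()
    influence_df.to_csv(out / "influence.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)

    return {"peaks": peaks_df, "correlations": corr_df,
            "influence": influence_df, "truth": truth, "manifest": manifest,
            "output_dir": str(out)}
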