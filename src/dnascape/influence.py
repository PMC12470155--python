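"""Attribution of property-profile peaks to dinucleotides and repeat classes.

A property track is linear in the 16 dinucleotide content tracks, so a
peak's height decomposes exactly: profile the property and all dinucleotide
tracks with shared weights, and the contribution of dinucleotide XY is

    c_XY = m_XY * (f_XY(apex) - f_XY(baseline)),

which sums over XY to the signed peak height.  Restricting the dinucleotide
counts to bases inside tandem-repeat or transposon intervals partitions each
c_XY further into repeat-class contributions plus an "outside" remainder,
again exactly.  Relative influences are reported both normalized by the sum
of absolute dinucleotide contributions (so opposing influences stay
visible and repeat influences are on the same scale) and by the signed peak
height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, DINUCLEOTIDES, N_CODE, revcomp_str
from .maps import AnnotationSet, DinucleotideTrackSet, Interval
from .peaks import BaselineEstimate, PeakCall, call_peak, estimate_baseline
from .profiles import EnvironmentProfile, ProfileConfig, profile_tracks
from .properties import PropertyModel
from .tracks import BinnedTrack

OUTSIDE = "outside"


# ---------------------------------------------------------------------------
# partitioned dinucleotide counts
# ---------------------------------------------------------------------------

@dataclass
class PartitionedDinucleotides:
    """Per-bin dinucleotide counts split by repeat partition for one
    chromosome.  ``counts[label]`` has shape (n_bins, 16); partitions are
    disjoint and sum exactly to the unpartitioned counts."""

    base: DinucleotideTrackSet
    counts: dict[str, np.ndarray]

    @property
    def labels(self) -> list[str]:
        return list(self.counts)


def partition_dinucleotides(sequence: str | np.ndarray,
                            tandem_repeats: Mapping[str, Sequence[Interval]] | None = None,
                            transposons: Mapping[str, Sequence[Interval]] | None = None,
                            resolution: int = 1000,
                            chrom: str = "chr") -> PartitionedDinucleotides:
    """Split binned dinucleotide counts by repeat class.

    A dinucleotide at (i, i+1) belongs to a partition iff both bases lie in
    one of its intervals; per-base overlaps are resolved with precedence
    transposon > tandem repeat > outside.  Counts are conserved exactly.
    """
    from ._seq import encode
    from .maps import count_dinucleotides

    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    base = count_dinucleotides(codes, resolution, chrom)
    L = codes.size
    labels = [OUTSIDE]
    label_of = np.zeros(L, dtype=np.int32)
    for group in (tandem_repeats or {}), (transposons or {}):  # transposons overwrite
        for name, ivs in group.items():
            labels.append(name)
            code = len(labels) - 1
            for iv in ivs:
                if iv.chrom == chrom:
                    label_of[max(0, iv.start):min(L, iv.end)] = code

    nb = base.n_bins
    counts = {name: np.zeros((nb, 16), dtype=np.int64) for name in labels}
    if L >= 2:
        a, b = codes[:-1], codes[1:]
        ok = (a != N_CODE) & (b != N_CODE)
        la, lb = label_of[:-1], label_of[1:]
        pair_label = np.where(la == lb, la, 0)
        bins = np.arange(L - 1) // resolution
        pair = a.astype(np.int64) * 4 + b
        for code, name in enumerate(labels):
            sel = ok & (pair_label == code)
            counts[name] = np.bincount(bins[sel] * 16 + pair[sel],
                                       minlength=nb * 16).reshape(nb, 16)
    return PartitionedDinucleotides(base, counts)


# ---------------------------------------------------------------------------
# influence records
# ---------------------------------------------------------------------------

@dataclass
class InfluenceRecord:
    feature: str
    kind: str                     # "dinucleotide" | "repeat" | "residual"
    contribution: float           # signed, property units
    relative_abs_pct: float       # |c| / sum|c_dinuc| * 100
    relative_height_pct: float    # c / signed peak height * 100


@dataclass
class PeakDecomposition:
    """Full influence analysis of one property peak."""

    peak: PeakCall
    property_profile: EnvironmentProfile
    reference_profile: EnvironmentProfile | None
    dinucleotides: list[InfluenceRecord]
    repeats: list[InfluenceRecord]
    residual: InfluenceRecord
    model_label: str
    mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = [r.__dict__ for r in (*self.dinucleotides, *self.repeats, self.residual)]
        df = pd.DataFrame(rows)
        df.insert(0, "model", self.model_label)
        return df


def group_complements(records: Sequence[InfluenceRecord]) -> list[InfluenceRecord]:
    """Sum signed contributions of complementary dinucleotides (AA/TT etc.);
    grouping commutes with normalization because both are linear."""
    dinucs = [r for r in records if r.kind == "dinucleotide"]
    # recover the shared normalizer sum|c| from any nonzero record
    norm = 0.0
    for r in dinucs:
        if r.relative_abs_pct > 0:
            norm = 100.0 * abs(r.contribution) / r.relative_abs_pct
            break
    grouped: dict[str, list[InfluenceRecord]] = {}
    for rec in dinucs:
        key = "/".join(sorted({rec.feature, revcomp_str(rec.feature)}))
        grouped.setdefault(key, []).append(rec)
    out = []
    for key, recs in grouped.items():
        c = sum(r.contribution for r in recs)
        rel_abs = 100.0 * abs(c) / norm if norm > 0 else 0.0
        rel_h = sum(r.relative_height_pct for r in recs)
        out.append(InfluenceRecord(key, "dinucleotide", c, rel_abs, rel_h))
    out.sort(key=lambda r: -abs(r.contribution))
    return out


def _records_from_deltas(model: PropertyModel, deltas: np.ndarray,
                         norm_abs: float, signed_height: float,
                         features: Sequence[str], kind: str) -> list[InfluenceRecord]:
    contribs = model.values * deltas if kind == "dinucleotide" else deltas
    out = []
    for feat, c in zip(features, contribs):
        rel_abs = 100.0 * abs(c) / norm_abs if norm_abs > 0 else 0.0
        rel_h = 100.0 * c / signed_height if signed_height != 0 else 0.0
        out.append(InfluenceRecord(feat, kind, float(c), float(rel_abs), float(rel_h)))
    out.sort(key=lambda r: -abs(r.contribution))
    return out


def decompose_peak(partitioned: Mapping[str, PartitionedDinucleotides],
                   model: PropertyModel,
                   anchors: Sequence[Interval],
                   cfg: ProfileConfig | None = None,
                   mask: AnnotationSet | Sequence[Interval] | None = None,
                   mode: str = "sum",
                   baseline_min_distance: int = 800_000,
                   z_threshold: float = 2.0,
                   reference: Mapping[str, np.ndarray] | None = None,
                   ) -> PeakDecomposition:
    """Call a property peak around anchors and decompose it exactly.

    ``partitioned`` maps chromosome name to its partitioned dinucleotide
    counts.  In ``sum`` mode features are raw counts; in ``mean`` mode they
    are fractions of the bin's total dinucleotide count (shared denominator,
    so additivity still holds exactly and the residual row is a numerical
    check, not a model term).  ``reference`` optionally maps chromosomes to
    (n_bins, 16) expected dinucleotide counts (e.g. the zero-order null) to
    profile alongside and score the peak against.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    cfg = cfg or ProfileConfig()
    part_labels = next(iter(partitioned.values())).labels

    tracks: dict[str, dict[str, BinnedTrack]] = {"__property__": {}}
    for xy in DINUCLEOTIDES:
        tracks[f"d:{xy}"] = {}
    for lab in part_labels:
        for xy in DINUCLEOTIDES:
            tracks[f"p:{lab}:{xy}"] = {}
    if reference is not None:
        tracks["__reference__"] = {}

    for chrom, part in partitioned.items():
        base = part.base
        total = base.total_dinucs.astype(float)
        valid = base.valid & (total > 0)
        denom = np.where(total > 0, total, 1.0)

        def mk(values: np.ndarray) -> BinnedTrack:
            v = values.astype(float)
            if mode == "mean":
                v = v / denom
            v = np.where(valid, v, np.nan)
            return BinnedTrack(chrom, base.resolution, v, base.valid_fraction)

        tracks["__property__"][chrom] = mk(base.dinuc_counts @ model.values)
        for j, xy in enumerate(DINUCLEOTIDES):
            tracks[f"d:{xy}"][chrom] = mk(base.dinuc_counts[:, j])
        for lab in part_labels:
            cts = part.counts[lab]
            for j, xy in enumerate(DINUCLEOTIDES):
                tracks[f"p:{lab}:{xy}"][chrom] = mk(cts[:, j])
        if reference is not None:
            tracks["__reference__"][chrom] = mk(reference[chrom] @ model.values)

    profiles = profile_tracks(tracks, anchors, cfg, mask)
    prop = profiles["__property__"]
    baseline = estimate_baseline(prop, baseline_min_distance)
    peak = call_peak(prop, baseline, z_threshold)
    ref_profile = profiles.get("__reference__")

    model_label = f"{model.name}({model.id})"
    if not peak.detected:
        warnings.warn(f"no central peak detected for {model_label}; "
                      "influence table is empty", stacklevel=2)
        empty = InfluenceRecord("(residual)", "residual", 0.0, 0.0, 0.0)
        return PeakDecomposition(peak, prop, ref_profile, [], [], empty,
                                 model_label, mode)

    apex = prop.index_of(peak.apex_distance)
    signed_height = peak.signed_height

    d_deltas = np.array([
        profiles[f"d:{xy}"].mean[apex]
        - estimate_baseline(profiles[f"d:{xy}"], baseline_min_distance).mean
        for xy in DINUCLEOTIDES])
    contribs = model.values * d_deltas
    norm_abs = float(np.abs(contribs).sum())
    dinuc_records = _records_from_deltas(model, d_deltas, norm_abs,
                                         signed_height, DINUCLEOTIDES,
                                         "dinucleotide")
    residual = InfluenceRecord("(residual)", "residual",
                               float(signed_height - contribs.sum()), 0.0, 0.0)

    repeat_records: list[InfluenceRecord] = []
    for lab in part_labels:
        deltas = np.array([
            profiles[f"p:{lab}:{xy}"].mean[apex]
            - estimate_baseline(profiles[f"p:{lab}:{xy}"], baseline_min_distance).mean
            for xy in DINUCLEOTIDES])
        c = float((model.values * deltas).sum())
        rel_abs = 100.0 * abs(c) / norm_abs if norm_abs > 0 else 0.0
        rel_h = 100.0 * c / signed_height if signed_height != 0 else 0.0
        repeat_records.append(InfluenceRecord(lab, "repeat", c, rel_abs, rel_h))
    repeat_records.sort(key=lambda r: -abs(r.contribution))

    return PeakDecomposition(peak, prop, ref_profile, dinuc_records,
                             repeat_records, residual, model_label, mode)
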