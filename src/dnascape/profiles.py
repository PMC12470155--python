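"""Anchor-centered environment profiles with interior masking.

For every anchor (e.g. a CTCF site or TAD border) the surrounding track
values are collected as a function of signed distance from the anchor's
reference point.  The interiors of annotations — including the anchors
themselves — are masked, so only the true environment outside annotated
elements contributes; this removes the bias that clustering of annotations
would otherwise introduce.  Bins more than half masked are discarded
entirely; the remainder are weighted by their unmasked fraction.  Per
distance, a weighted mean and variance (reliability weights) are pooled over
all anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maps import AnnotationSet, Interval, coverage_fraction
from .tracks import BinnedTrack, GenomeTracks

_REFERENCE_POINTS = ("midpoint", "start", "end")


@dataclass
class ProfileConfig:
    """Parameters of the environment aggregation.

    ``half_width`` is the maximal distance considered on either side
    (default 1 Mbp, comfortably beyond the far-distance baseline region);
    ``discard_threshold`` is the masked fraction above which a bin is
    discarded (default 0.5).
    """

    half_width: int = 1_000_000
    discard_threshold: float = 0.5
    reference_point: str = "midpoint"
    mask_anchors: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.discard_threshold < 1):
            raise ValueError("discard_threshold must lie in (0, 1)")
        if self.reference_point not in _REFERENCE_POINTS:
            raise ValueError(f"reference_point must be one of {_REFERENCE_POINTS}")


@dataclass
class EnvironmentProfile:
    """Distance-indexed weighted statistics around a set of anchors."""

    distances: np.ndarray       # signed bp, -D..+D step resolution
    mean: np.ndarray
    variance: np.ndarray
    weight: np.ndarray          # sum of unmasked fractions contributing
    n_anchors: np.ndarray       # contributing anchors per distance
    resolution: int
    name: str = ""

    @property
    def se(self) -> np.ndarray:
        """Standard error per distance: sqrt(weighted variance / effective weight)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(self.variance / np.where(self.weight > 0, self.weight, np.nan))

    @property
    def center_index(self) -> int:
        return int(np.argmin(np.abs(self.distances)))

    def index_of(self, distance: int) -> int:
        idx = int(np.argmin(np.abs(self.distances - distance)))
        if self.distances[idx] != distance:
            raise ValueError(f"distance {distance} not on the profile grid")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distances, "mean": self.mean,
            "variance": self.variance, "weight": self.weight,
            "n_anchors": self.n_anchors,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "") -> "EnvironmentProfile":
        df = pd.read_csv(path, sep="\t")
        dist = df["distance"].to_numpy()
        res = int(np.min(np.diff(np.sort(np.unique(dist)))))
        return cls(dist, df["mean"].to_numpy(), df["variance"].to_numpy(),
                   df["weight"].to_numpy(), df["n_anchors"].to_numpy(), res, name)


def _as_genome_tracks(track: BinnedTrack | GenomeTracks) -> GenomeTracks:
    return {track.chrom: track} if isinstance(track, BinnedTrack) else dict(track)


def _reference_bin(iv: Interval, resolution: int, mode: str) -> int:
    if mode == "midpoint":
        pos = (iv.start + iv.end) // 2
    elif mode == "start":
        pos = iv.start
    else:
        pos = max(iv.start, iv.end - 1)
    return pos // resolution


def profile_tracks(tracks: Mapping[str, BinnedTrack | GenomeTracks],
                   anchors: Sequence[Interval],
                   cfg: ProfileConfig | None = None,
                   mask: AnnotationSet | Sequence[Interval] | None = None,
                   ) -> dict[str, EnvironmentProfile]:
    """Profile several tracks around the same anchors with *shared* weights.

    All tracks must share chromosomes and resolution.  A bin contributes only
    if it is valid in every track and not discarded by masking; weights are
    therefore identical across the returned profiles, which makes any linear
    combination of tracks profile exactly to the same linear combination of
    profiles (the influence decomposition relies on this).
    """
    cfg = cfg or ProfileConfig()
    if not tracks:
        raise ValueError("no tracks given")
    genome_tracks = {name: _as_genome_tracks(t) for name, t in tracks.items()}
    first = next(iter(genome_tracks.values()))
    resolution = next(iter(first.values())).resolution
    for gt in genome_tracks.values():
        for t in gt.values():
            if t.resolution != resolution:
                raise ValueError("all tracks must share one resolution")
    if cfg.half_width % resolution:
        raise ValueError("half_width must be a multiple of the track resolution")

    mask_ivs: list[Interval] = []
    if mask is not None:
        mask_ivs.extend(mask.all_intervals() if isinstance(mask, AnnotationSet) else list(mask))
    if cfg.mask_anchors:
        mask_ivs.extend(anchors)

    K = cfg.half_width // resolution
    offsets = np.arange(-K, K + 1)
    n_off = offsets.size
    names = list(genome_tracks)
    S0 = np.zeros(n_off)
    SW2 = np.zeros(n_off)
    S1 = np.zeros((len(names), n_off))
    S2 = np.zeros((len(names), n_off))
    n_anchors = np.zeros(n_off, dtype=np.int64)
    usable_anchors = 0
    max_len = 0

    chroms = sorted({iv.chrom for iv in anchors})
    for chrom in chroms:
        if chrom not in first:
            raise ValueError(f"anchors reference chromosome {chrom!r} absent from the track")
        chrom_tracks = [genome_tracks[name][chrom] for name in names]
        nb = chrom_tracks[0].n_bins
        length = nb * resolution
        max_len = max(max_len, length)
        chrom_mask = [iv for iv in mask_ivs if iv.chrom == chrom]
        masked_frac = (coverage_fraction(chrom_mask, length, resolution)
                       if chrom_mask else np.zeros(nb))
        w = 1.0 - masked_frac
        w[masked_frac > cfg.discard_threshold] = 0.0
        usable = w > 0
        for t in chrom_tracks:
            usable &= t.valid
        w = np.where(usable, w, 0.0)

        centers = np.array([_reference_bin(iv, resolution, cfg.reference_point)
                            for iv in anchors if iv.chrom == chrom])
        if centers.size == 0:
            continue
        usable_anchors += centers.size
        idx = centers[:, None] + offsets[None, :]
        inb = (idx >= 0) & (idx < nb)
        idx_c = np.where(inb, idx, 0)
        wmat = np.where(inb, w[idx_c], 0.0)
        S0 += wmat.sum(axis=0)
        SW2 += (wmat ** 2).sum(axis=0)
        n_anchors += (wmat > 0).sum(axis=0)
        for k, t in enumerate(chrom_tracks):
            v = np.where(inb & (wmat > 0), t.values[idx_c], 0.0)
            S1[k] += (wmat * v).sum(axis=0)
            S2[k] += (wmat * v * v).sum(axis=0)

    if usable_anchors == 0:
        raise ValueError("no usable anchors on the provided tracks")
    if cfg.half_width >= max_len:
        warnings.warn("profile half-width exceeds every chromosome; "
                      "distances beyond chromosome ends contribute nothing",
                      stacklevel=2)

    distances = offsets * resolution
    out: dict[str, EnvironmentProfile] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = S0 - np.where(S0 > 0, SW2 / np.where(S0 > 0, S0, 1), 0.0)
        for k, name in enumerate(names):
            mean = np.where(S0 > 0, S1[k] / np.where(S0 > 0, S0, 1), np.nan)
            ss = S2[k] - np.where(S0 > 0, S0 * mean ** 2, 0.0)
            var = np.where(denom > 1e-12, np.maximum(ss, 0.0) / np.where(denom > 1e-12, denom, 1),
                           np.nan)
            var = np.where(n_anchors >= 2, var, np.nan)
            var = np.where(S0 > 0, var, np.nan)
            out[name] = EnvironmentProfile(distances, mean, var, S0.copy(),
                                           n_anchors.copy(), resolution, name)
    return out


def profile(track: BinnedTrack | GenomeTracks,
            anchors: Sequence[Interval],
            cfg: ProfileConfig | None = None,
            mask: AnnotationSet | Sequence[Interval] | None = None,
            name: str = "") -> EnvironmentProfile:
    """Environment profile of a single track around anchors (see
    :func:`profile_tracks`)."""
    result = profile_tracks({name or "track": track}, anchors, cfg, mask)
    prof = next(iter(result.values()))
    prof.name = name
    return prof
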