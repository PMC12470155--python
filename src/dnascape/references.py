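"""Null-model expectations for dinucleotide and tandem-repeat content.

Two nested references are provided for every binned map:

* a zero-order Markov expectation for dinucleotide counts built from the
  bin's own empirical nucleotide content,
  ``E[n_XY] = n_X * n_Y / L_seq`` — the dinucleotide content expected if the
  bin's bases were randomly shuffled;
* a first-order Markov expectation for tandem-repeat content built from the
  bin's empirical dinucleotide content,
  ``E[n_XY, n>=2] = n_XY^2 * n_YX / (n_X * n_Y)`` — interpreted (and
  validated by simulation) as the expected number of start positions of the
  4-mer XYXY, i.e. of tandem occurrences of at least two XY units.  The
  homopolymer case X == Y degenerates to ``n_XX^3 / n_X^2``.

A third, coarser reference is the genome-wide weighted mean and SD of a
track over all valid bins (the uniform-distribution null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import DinucleotideTrackSet
from .tracks import BinnedTrack


def expected_dinucleotides(dinucs: DinucleotideTrackSet) -> np.ndarray:
    """Zero-order expectation E[n_XY] = n_X n_Y / L_seq per bin.

    Returns an (n_bins, 16) array; bins with no valid bases are NaN.
    For a fully valid bin the 16 expectations sum exactly to L_seq,
    matching the convention that bin-bridging dinucleotides are counted.
    """
    n = dinucs.nuc_counts.astype(float)
    L = dinucs.valid_length.astype(float)
    outer = n[:, :, None] * n[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = outer.reshape(-1, 16) / np.where(L > 0, L, np.nan)[:, None]
    return e


def expected_tandem_repeats(dinucs: DinucleotideTrackSet) -> np.ndarray:
    """First-order expectation of (XY)_{n>=2} start counts per bin.

    Returns an (n_bins, 16) array indexed by the ordered dinucleotide XY:
    entry XY is the expected number of positions where the 4-mer XYXY starts.
    Where ``n_X * n_Y = 0`` the expectation is 0 by continuity when
    ``n_XY = 0``, otherwise NaN.
    """
    d = dinucs.dinuc_counts.astype(float).reshape(-1, 4, 4)
    n = dinucs.nuc_counts.astype(float)
    n_xy = d
    n_yx = np.swapaxes(d, 1, 2)
    denom = n[:, :, None] * n[:, None, :]
    num = n_xy ** 2 * n_yx
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(denom > 0, num / np.where(denom > 0, denom, 1), np.nan)
    e = np.where((denom == 0) & (n_xy == 0), 0.0, e)
    return e.reshape(-1, 16)


@dataclass
class GlobalReference:
    """Genome-wide weighted mean and SD of a track over valid bins."""

    mean: float
    sd: float
    n_bins: int
    weight: float

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n_bins) if self.n_bins else np.nan


def global_reference(tracks: BinnedTrack | dict[str, BinnedTrack]) -> GlobalReference:
    """Valid-fraction-weighted mean and SD over all valid bins of a track."""
    if isinstance(tracks, BinnedTrack):
        tracks = {tracks.chrom: tracks}
    vals = np.concatenate([t.values for t in tracks.values()])
    w = np.concatenate([t.valid_fraction for t in tracks.values()])
    ok = np.isfinite(vals) & (w > 0)
    vals, w = vals[ok], w[ok]
    if vals.size < 2:
        raise ValueError("global reference needs at least 2 valid bins")
    v1 = w.sum()
    mean = float((w * vals).sum() / v1)
    v2 = (w ** 2).sum()
    denom = v1 - v2 / v1
    var = float((w * (vals - mean) ** 2).sum() / denom) if denom > 0 else 0.0
    return GlobalReference(mean, np.sqrt(max(var, 0.0)), int(vals.size), float(v1))
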