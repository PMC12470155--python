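"""Fixed-resolution binned genomic tracks.

A :class:`BinnedTrack` holds one value per bin of a chromosome together with
the fraction of valid (non-ambiguous) bases in each bin.  Invalid bins carry
``NaN`` values — they are flagged, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_RESOLUTION = 1000
#: bins whose valid-base fraction falls below this are flagged invalid
VALID_FRACTION_THRESHOLD = 0.5


def n_bins(length: int, resolution: int) -> int:
    return -(-int(length) // int(resolution))


def bin_lengths(length: int, resolution: int) -> np.ndarray:
    """Actual bp length of each bin (last bin may be short)."""
    nb = n_bins(length, resolution)
    out = np.full(nb, resolution, dtype=np.int64)
    rem = length - (nb - 1) * resolution
    out[-1] = rem
    return out


@dataclass
class BinnedTrack:
    """Per-chromosome value array at fixed resolution with a validity mask."""

    chrom: str
    resolution: int
    values: np.ndarray
    valid_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.valid_fraction is None:
            self.valid_fraction = np.ones_like(self.values)
        else:
            self.valid_fraction = np.asarray(self.valid_fraction, dtype=np.float64)
        if self.values.shape != self.valid_fraction.shape:
            raise ValueError("values and valid_fraction must have equal length")
        if np.any((self.valid_fraction < -1e-12) | (self.valid_fraction > 1 + 1e-12)):
            raise ValueError("valid_fraction must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of usable bins."""
        return np.isfinite(self.values)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.chrom, self.resolution, self.values.copy(),
                           self.valid_fraction.copy())

    def masked(self, threshold: float = VALID_FRACTION_THRESHOLD) -> "BinnedTrack":
        """Return a copy with bins below the valid-fraction threshold invalidated."""
        out = self.copy()
        out.values[out.valid_fraction < threshold] = np.nan
        return out

    def aggregate(self, factor: int, mode: str = "mean") -> "BinnedTrack":
        """Coarsen the track by an integer factor (``mean`` or ``sum`` of fine bins)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        nb = n_bins(self.n_bins, factor)
        pad = nb * factor - self.n_bins
        vals = np.concatenate([self.values, np.full(pad, np.nan)])
        vf = np.concatenate([self.valid_fraction, np.zeros(pad)])
        vals = vals.reshape(nb, factor)
        vf = vf.reshape(nb, factor)
        with np.errstate(invalid="ignore"):
            if mode == "mean":
                out = np.nanmean(vals, axis=1)
            elif mode == "sum":
                out = np.nansum(vals, axis=1)
                out[np.all(~np.isfinite(vals), axis=1)] = np.nan
            else:
                raise ValueError(f"unknown mode {mode!r}")
        return BinnedTrack(self.chrom, self.resolution * factor, out, vf.mean(axis=1))


GenomeTracks = dict[str, BinnedTrack]
"""A genome-wide track: one BinnedTrack per chromosome, keyed by name."""


def write_bedgraph(tracks: GenomeTracks | BinnedTrack, path: str | Path) -> None:
    """Write a track as bedGraph (invalid bins omitted)."""
    if isinstance(tracks, BinnedTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        for chrom, tr in tracks.items():
            res = tr.resolution
            for b in np.nonzero(tr.valid)[0]:
                fh.write(f"{chrom}\t{b * res}\t{(b + 1) * res}\t{tr.values[b]:.10g}\n")


def read_bedgraph(path: str | Path, resolution: int | None = None) -> GenomeTracks:
    """Read a bedGraph written at fixed resolution back into tracks.

    Intervals absent from the file become invalid (NaN) bins.
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            rows.setdefault(chrom, []).append((start, end, value))
    out: GenomeTracks = {}
    for chrom, items in rows.items():
        if resolution is None:
            resolution = min(e - s for s, e, _ in items)
        nb = n_bins(max(e for _, e, _ in items), resolution)
        vals = np.full(nb, np.nan)
        for s, e, v in items:
            vals[s // resolution] = v
        out[chrom] = BinnedTrack(chrom, resolution, vals)
    return out
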