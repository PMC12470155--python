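"""Bootstrap Pearson correlation between genomic maps with a shuffled null.

Whole-map correlations are estimated cheaply and with an honest error bar by
repeated small bootstrap samples: per repetition, K jointly valid bin
positions are drawn genome-wide with replacement, and the Pearson r of the
two K-vectors is computed; the mean and SD over R repetitions summarize the
correlation (defaults R = K = 50).  The null repeats the procedure on copies
of the maps whose bin positions were independently permuted (alignment
destroyed, marginals preserved); the significance is

    sigma = (r_emp - r_null) / sqrt(SD_emp^2 + SD_null^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import BinnedTrack, GenomeTracks, VALID_FRACTION_THRESHOLD

_MAX_RESAMPLE = 100


@dataclass
class CorrelationConfig:
    repetitions: int = 50
    sample_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 2:
            raise ValueError("need at least 2 repetitions")
        if self.sample_size < 3:
            raise ValueError("need at least 3 positions per repetition")


@dataclass
class CorrelationResult:
    r_mean: float
    r_sd: float
    null_mean: float
    null_sd: float

    @property
    def sigma(self) -> float:
        denom = np.sqrt(self.r_sd ** 2 + self.null_sd ** 2)
        if denom == 0:
            return 0.0 if self.r_mean == self.null_mean else np.inf
        return float((self.r_mean - self.null_mean) / denom)


def _flatten(track: BinnedTrack | GenomeTracks | np.ndarray) -> np.ndarray:
    if isinstance(track, np.ndarray):
        return track.astype(float)
    if isinstance(track, BinnedTrack):
        return track.values
    return np.concatenate([track[c].values for c in sorted(track)])


def mask_gaps(track: BinnedTrack | GenomeTracks,
              valid_fraction_threshold: float = VALID_FRACTION_THRESHOLD
              ) -> BinnedTrack | GenomeTracks:
    """Invalidate bins whose valid-base fraction falls below the threshold
    (assembly gaps, centromeric N runs)."""
    if isinstance(track, BinnedTrack):
        return track.masked(valid_fraction_threshold)
    return {c: t.masked(valid_fraction_threshold) for c, t in track.items()}


def _bootstrap_means(a: np.ndarray, b: np.ndarray, cfg: CorrelationConfig,
                     rng: np.random.Generator) -> tuple[float, float]:
    """Mean and SD of Pearson r over bootstrap repetitions of (a, b)."""
    n = a.size
    rs = np.empty(cfg.repetitions)
    for rep in range(cfg.repetitions):
        for _attempt in range(_MAX_RESAMPLE):
            idx = rng.integers(0, n, size=cfg.sample_size)
            x, y = a[idx], b[idx]
            if x.std() > 0 and y.std() > 0:
                if np.array_equal(x, y):        # exact self-correlation
                    rs[rep] = 1.0
                elif np.array_equal(x, -y):
                    rs[rep] = -1.0
                else:
                    rs[rep] = np.corrcoef(x, y)[0, 1]
                break
        else:
            raise ValueError("sampled vectors had zero variance repeatedly; "
                             "maps are (near-)constant")
    return float(rs.mean()), float(rs.std(ddof=0))


def bootstrap_correlation(map_a: BinnedTrack | GenomeTracks | np.ndarray,
                          map_b: BinnedTrack | GenomeTracks | np.ndarray,
                          cfg: CorrelationConfig | None = None) -> CorrelationResult:
    """Bootstrap Pearson correlation of two maps plus a position-shuffled null.

    Maps must share chromosomes and resolution; only bins valid in both maps
    are sampled.
    """
    cfg = cfg or CorrelationConfig()
    a, b = _flatten(map_a), _flatten(map_b)
    if a.size != b.size:
        raise ValueError("maps differ in total bin count")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < cfg.sample_size:
        raise ValueError(f"only {a.size} jointly valid bins; "
                         f"need >= {cfg.sample_size}")
    rng = np.random.default_rng(cfg.seed)
    r_mean, r_sd = _bootstrap_means(a, b, cfg, rng)
    a_shuf = a[rng.permutation(a.size)]
    b_shuf = b[rng.permutation(b.size)]
    null_mean, null_sd = _bootstrap_means(a_shuf, b_shuf, cfg, rng)
    return CorrelationResult(r_mean, r_sd, null_mean, null_sd)
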