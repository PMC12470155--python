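"""Central peak/dip detection in environment profiles.

A far-distance baseline (beyond 800 kbp by default, where anchors are
assumed to have no influence) provides the null level and its uncertainty.
Starting from distance zero, the deviation from the baseline is tested with
a z statistic combining both uncertainties; if significant, the peak is
expanded outward in each direction until the deviation stops being
significant in the apex's direction.  Height is the maximal absolute
deviation over the significant span, width the span bounds.

A peak can additionally be scored against the corresponding peak of a
reference profile (e.g. the zero-order dinucleotide null): the relative
significance is the difference of signed heights in units of the combined
height uncertainties.  This cancels peaks explained purely by local
nucleotide/G+C composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import EnvironmentProfile


@dataclass
class BaselineEstimate:
    """Pooled weighted mean/SD of a profile at far distances."""

    mean: float
    sd: float
    min_distance: int
    n_bins: int
    weight: float

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n_bins) if self.n_bins else np.nan


@dataclass
class PeakCall:
    """A called central peak (or dip) of an environment profile."""

    detected: bool
    sign: int                 # +1 peak, -1 dip, 0 undetected
    height: float             # max |deviation from baseline|, track units
    apex_distance: int        # bp, distance of the maximal deviation
    width_min: int            # bp, left bound of the significant span
    width_max: int            # bp, right bound
    z_center: float
    z_apex: float
    height_se: float          # SE at the apex bin (center bin if undetected)
    baseline: BaselineEstimate

    @property
    def signed_height(self) -> float:
        return self.sign * self.height if self.detected else 0.0

    @property
    def width(self) -> int:
        return self.width_max - self.width_min if self.detected else 0


def estimate_baseline(profile: EnvironmentProfile,
                      min_distance: int = 800_000) -> BaselineEstimate:
    """Pooled weighted mean and SD over all bins with |distance| > min_distance."""
    far = np.abs(profile.distances) > min_distance
    if not far.any():
        raise ValueError("profile does not extend beyond the baseline distance")
    ok = far & np.isfinite(profile.mean) & (profile.weight > 0)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"only {n} far-distance bins available; need >= 10")
    w = profile.weight[ok]
    m = profile.mean[ok]
    v1 = w.sum()
    mean = float((w * m).sum() / v1)
    v2 = (w ** 2).sum()
    denom = v1 - v2 / v1
    var = float((w * (m - mean) ** 2).sum() / denom) if denom > 0 else 0.0
    return BaselineEstimate(mean, float(np.sqrt(max(var, 0.0))),
                            int(min_distance), n, float(v1))


def _z_profile(profile: EnvironmentProfile, baseline: BaselineEstimate) -> np.ndarray:
    se = profile.se
    with np.errstate(invalid="ignore", divide="ignore"):
        return (profile.mean - baseline.mean) / np.sqrt(se ** 2 + baseline.se ** 2)


def call_peak(profile: EnvironmentProfile, baseline: BaselineEstimate,
              z_threshold: float = 2.0, gap_tolerance: int = 0) -> PeakCall:
    """Detect a central peak/dip by outward expansion from distance zero.

    Detection requires |z| > threshold at the center.  Expansion in each
    direction stops at the first bin that is not significantly deviated in
    the apex's direction; ``gap_tolerance`` allows that many consecutive
    non-significant bins to be bridged (default 0, strict).
    """
    c = profile.center_index
    z = _z_profile(profile, baseline)
    dev = profile.mean - baseline.mean
    se = profile.se
    if not np.isfinite(z[c]) or not np.isfinite(se[c]):
        raise ValueError("variance undefined at the profile center")

    z0 = float(z[c])
    if abs(z0) <= z_threshold:
        return PeakCall(False, 0, 0.0, 0, 0, 0, z0, z0, float(se[c]), baseline)

    sign = 1 if dev[c] > 0 else -1

    def expand(step: int) -> int:
        last = c
        gaps = 0
        i = c + step
        while 0 <= i < z.size:
            significant = (np.isfinite(z[i]) and abs(z[i]) > z_threshold
                           and np.sign(dev[i]) == sign)
            if significant:
                last = i
                gaps = 0
            else:
                gaps += 1
                if gaps > gap_tolerance:
                    break
            i += step
        return last

    left, right = expand(-1), expand(+1)
    span = slice(left, right + 1)
    span_dev = np.where(np.isfinite(dev[span]), dev[span], 0.0)
    apex_rel = int(np.argmax(np.abs(span_dev)))
    apex = left + apex_rel
    height = float(abs(dev[apex]))
    return PeakCall(True, sign, height, int(profile.distances[apex]),
                    int(profile.distances[left]), int(profile.distances[right]),
                    z0, float(z[apex]), float(se[apex]), baseline)


def relative_significance(empirical: PeakCall, reference: PeakCall) -> float:
    """Signed significance of the empirical peak height relative to the
    reference peak height: (h_emp - h_ref) / sqrt(u_emp^2 + u_ref^2).

    Undetected peaks contribute height 0 with the uncertainty of their
    center bin.  Heights are signed, so a peak over a flat reference scores
    roughly its own apex z, while a peak fully present in the reference
    scores near zero.
    """
    h_emp = empirical.signed_height
    h_ref = reference.signed_height
    u = np.sqrt(empirical.height_se ** 2 + reference.height_se ** 2)
    if u == 0:
        return 0.0 if h_emp == h_ref else np.inf * np.sign(h_emp - h_ref)
    return float((h_emp - h_ref) / u)
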