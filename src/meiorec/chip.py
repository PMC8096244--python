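"""ChIP-seq / ChIP-qPCR signal arithmetic.

The DSB-specific occupancy of a protein is obtained by mean-normalizing the
ChIP coverage of the tagged strain and of a DSB-deficient (*spo11*) control
strain and subtracting the control, keeping signed residuals.  Downstream
views are a moving-average smoothed browser track, average profiles anchored
on feature midpoints (hotspots, axis peaks, coldspots), region-restricted
Spearman correlation between tracks, and a permutation test for enrichment
of the signal over a feature set.  ChIP-qPCR enrichment uses the double
normalization by a negative control locus and the 0 h time-point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

from .errors import ParameterError
from .simulate import CoverageTrack, FeatureSet


@dataclass(frozen=True)
class MetaProfile:
    """Average signal in bins at fixed offsets around anchor midpoints."""

    offsets: np.ndarray  # bin-center offsets in bp relative to the anchor
    values: np.ndarray  # mean signal per bin across anchors
    n_anchors: int
    n_dropped: int = 0


@dataclass(frozen=True)
class QPCRMeasure:
    """One ChIP-qPCR measurement expressed as percent of input."""

    locus: str
    timepoint: str
    percent_input: float

    def __post_init__(self) -> None:
        if self.percent_input < 0:
            raise ParameterError("percent input must be non-negative")


def normalize_track(track: CoverageTrack) -> CoverageTrack:
    """Scale a track by its genome-wide mean (output mean is 1)."""
    mean = float(np.mean(track.values))
    if mean <= 0:
        raise ParameterError("cannot mean-normalize a track with non-positive mean")
    return track.with_values(track.values / mean, "mean_normalized")


def subtract_control(
    signal: CoverageTrack, control: CoverageTrack, floor: bool = False
) -> CoverageTrack:
    """Elementwise signal minus control on matched, mean-normalized tracks.

    Signed residuals are kept by default so correlations see the full
    distribution; ``floor=True`` clips at zero for display and profiles.
    """
    if signal.values.size != control.values.size or signal.step != control.step:
        raise ParameterError("signal and control tracks are not on the same grid")
    if signal.state != "mean_normalized" or control.state != "mean_normalized":
        raise ParameterError("both tracks must be mean_normalized before subtraction")
    diff = signal.values - control.values
    if floor:
        diff = np.clip(diff, 0.0, None)
    return signal.with_values(diff, "subtracted")


def smooth_track(track: CoverageTrack, window_bp: int) -> CoverageTrack:
    """Centered moving average with an edge-shrinking window.

    The window covers ``window_bp`` of genome (at least one bin); near the
    chromosome ends it shrinks to the available positions, so a constant
    track is exactly preserved.
    """
    if window_bp < track.step:
        raise ParameterError("smoothing window must be at least one step")
    n = track.values.size
    w = max(1, int(round(window_bp / track.step)))
    if w == 1:  # avoid cumsum round-off when the window is a single bin
        return track.with_values(track.values.copy(), f"smoothed({window_bp})")
    if w >= n:
        import warnings

        warnings.warn("smoothing window exceeds the chromosome; returning its mean")
        out = np.full(n, float(np.mean(track.values)))
        return track.with_values(out, f"smoothed({window_bp})")
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(track.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (w - 1 - half), n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return track.with_values(out, f"smoothed({window_bp})")


def meta_profile(
    track: CoverageTrack, anchors: np.ndarray, flank_bp: int, bin_bp: int
) -> MetaProfile:
    """Average signal around anchor midpoints, equal weight per anchor.

    Anchors whose full ±flank window leaves the chromosome are dropped and
    counted; at least one usable anchor is required.
    """
    if bin_bp < track.step or flank_bp < bin_bp:
        raise ParameterError("need bin_bp >= step and flank_bp >= bin_bp")
    anchors = np.asarray(anchors, dtype=np.int64)
    n_bins_side = flank_bp // bin_bp
    per_bin = bin_bp // track.step
    genome = track.genome_length
    usable = anchors[(anchors - flank_bp >= 0) & (anchors + flank_bp <= genome)]
    dropped = anchors.size - usable.size
    if usable.size == 0:
        raise ParameterError("no anchor has a full window inside the chromosome")
    offsets = (np.arange(-n_bins_side, n_bins_side) + 0.5) * bin_bp
    acc = np.zeros(2 * n_bins_side)
    for mid in usable:
        start_bin = (mid - flank_bp) // track.step
        seg = track.values[start_bin : start_bin + 2 * n_bins_side * per_bin]
        acc += seg.reshape(2 * n_bins_side, per_bin).mean(axis=1)
    return MetaProfile(offsets, acc / usable.size, int(usable.size), int(dropped))


def correlate_tracks(
    tracks: list[CoverageTrack],
    regions: FeatureSet,
    window_bp: int = 2000,
    bin_bp: int | None = None,
) -> np.ndarray:
    """Pairwise Spearman correlation of smoothed tracks over a region union.

    Each track is smoothed with ``window_bp``, binned at ``bin_bp`` (default:
    the track step), restricted to bins overlapping the union of the regions,
    and rank-correlated with average ranks for ties.  Returns a symmetric
    matrix with unit diagonal.
    """
    if len(tracks) < 2:
        raise ParameterError("need at least two tracks to correlate")
    n = tracks[0].values.size
    step = tracks[0].step
    if any(t.values.size != n or t.step != step for t in tracks):
        raise ParameterError("tracks are not on the same grid")
    if len(regions) == 0:
        raise ParameterError("empty region union")
    bin_bp = bin_bp or step
    per_bin = max(1, bin_bp // step)
    n_bins = n // per_bin
    mask = np.zeros(n_bins, dtype=bool)
    for f in regions.features:
        lo = f.start // bin_bp
        hi = min(n_bins, -(-f.end // bin_bp))
        mask[lo:hi] = True
    if not mask.any():
        raise ParameterError("region union overlaps no bins")
    binned = []
    for t in tracks:
        sm = smooth_track(t, window_bp).values[: n_bins * per_bin]
        binned.append(sm.reshape(n_bins, per_bin).mean(axis=1)[mask])
    k = len(tracks)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho = sps.spearmanr(binned[i], binned[j]).statistic
            mat[i, j] = mat[j, i] = rho
    return mat


def feature_enrichment(
    track: CoverageTrack,
    features: FeatureSet,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation test of signal enrichment over a feature set.

    The observed statistic is the mean signal across feature bases; the null
    re-places length-matched intervals uniformly in the chromosome ``n_perm``
    times.  The empirical p uses the +1 correction:
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if len(features) == 0:
        raise ParameterError("feature set is empty")
    step = track.step
    n = track.values.size
    genome = track.genome_length
    lengths = []
    obs_vals = []
    for f in features.features:
        if f.end - f.start > genome:
            raise ParameterError(f"feature longer than the chromosome: {f}")
        lo, hi = f.start // step, max(f.start // step + 1, -(-f.end // step))
        obs_vals.append(track.values[lo:hi].mean())
        lengths.append(hi - lo)  # in bins
    observed = float(np.mean(obs_vals))

    rng = np.random.default_rng(seed)
    lengths = np.asarray(lengths)
    csum = np.concatenate([[0.0], np.cumsum(track.values)])
    null = np.empty(n_perm)
    for p in range(n_perm):
        starts = rng.integers(0, n - lengths + 1)
        means = (csum[starts + lengths] - csum[starts]) / lengths
        null[p] = means.mean()
    sd = null.std(ddof=1) if n_perm > 1 else 0.0
    z = float((observed - null.mean()) / sd) if sd > 0 else 0.0
    p_emp = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return {
        "observed_mean": observed,
        "null_mean": float(null.mean()),
        "z": z,
        "p": p_emp,
        "n_perm": n_perm,
        "n_features": len(features),
    }


def qpcr_fold_enrichment(
    target_t: QPCRMeasure,
    control_t: QPCRMeasure,
    target_t0: QPCRMeasure,
    control_t0: QPCRMeasure,
) -> float:
    """Double-normalized ChIP-qPCR fold enrichment.

    The target percent-input is normalized first by the negative-control
    locus at the same time-point and then by the same ratio at 0 h:
    ``fold = (target_t / control_t) / (target_t0 / control_t0)``.
    """
    for m in (control_t, target_t0, control_t0):
        if m.percent_input == 0:
            raise ParameterError(
                f"zero percent-input at locus {m.locus} ({m.timepoint}) in denominator"
            )
    return (target_t.percent_input / control_t.percent_input) / (
        target_t0.percent_input / control_t0.percent_input
    )
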