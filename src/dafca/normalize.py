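"""Site-density normalization of the raw accessibility track.

The fluorescence recorded in a bin depends on how many labeling sites the
bin contains, not only on how open the chromatin is.  The correction uses
two ingredients: the theoretical GATC site-density track of the reference,
and a deproteinized "naked" control in which every site is labelable.  An
ordinary least-squares fit of naked fluorescence on (smoothed) predicted
site count per bin gives ``signal = slope x sites + intercept``; inverting
that relation on the chromatin track converts fluorescence into an
effective labeled-site count, and dividing by the predicted count yields a
fraction-accessible estimate per bin.

The smoothing applied to the theoretical track before both fitting and
division should match the effective optical resolution of the data; the
package both ships the field-standard defaults (see
:class:`~dafca.tracks.SmoothingParams`) and can calibrate the width against
the naked control itself (:func:`calibrate_predicted_smoothing`), which is
how those defaults were chosen in the first place.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .tracks import SmoothingParams, smooth_track
from .types import GenomeTrack, MotifSiteTrack, n_bins

__all__ = [
    "LinearModel",
    "predicted_site_density",
    "fit_naked_model",
    "normalize_track",
    "calibrate_predicted_smoothing",
    "NormalizationResult",
    "build_normalized_track",
]


@dataclass
class LinearModel:
    """Affine map from predicted site count per bin to fluorescence."""

    slope: float
    intercept: float
    r: float
    n_bins: int
    warning: str | None = None

    def predict(self, sites) -> np.ndarray:
        return self.slope * np.asarray(sites, dtype=float) + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"slope": self.slope, "intercept": self.intercept, "r": self.r,
                 "n_bins": self.n_bins, "warning": self.warning},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def predicted_site_density(sites: MotifSiteTrack, bin_size: int = 500) -> GenomeTrack:
    """Motif starts per non-overlapping bin; zero is a real value, not missing."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    values = {}
    for chrom, pos in sites.sites.items():
        nb = n_bins(sites.genome_lengths[chrom], bin_size)
        values[chrom] = np.bincount(pos // bin_size, minlength=nb).astype(float)
    return GenomeTrack(bin_size=bin_size, values=values, label=f"{sites.motif}_sites",
                       chrom_lengths=dict(sites.genome_lengths))


def _paired(a: GenomeTrack, b: GenomeTrack) -> tuple[np.ndarray, np.ndarray]:
    if a.bin_size != b.bin_size:
        raise ValueError("tracks are on different bin grids")
    xs, ys = [], []
    for chrom in a.values:
        if chrom not in b.values:
            continue
        va, vb = a.values[chrom], b.values[chrom]
        m = min(va.size, vb.size)
        ok = ~np.isnan(va[:m]) & ~np.isnan(vb[:m])
        xs.append(va[:m][ok])
        ys.append(vb[:m][ok])
    return np.concatenate(xs), np.concatenate(ys)


def fit_naked_model(naked_binned: GenomeTrack, predicted_smoothed: GenomeTrack) -> LinearModel:
    """OLS of naked fluorescence on predicted site count over shared bins."""
    x, y = _paired(predicted_smoothed, naked_binned)
    if x.size < 2:
        raise ValueError(f"need >= 2 paired non-missing bins, got {x.size}")
    if np.ptp(x) == 0:  # constant regressor: slope 0, intercept = mean signal
        return LinearModel(0.0, float(np.mean(y)), 0.0, int(x.size),
                           warning="constant predictor; slope undefined, set to 0")
    fit = stats.linregress(x, y)
    warning = None
    if fit.slope <= 0:
        warning = f"non-positive slope {fit.slope:.4g}; model unusable for normalization"
    return LinearModel(float(fit.slope), float(fit.intercept), float(fit.rvalue),
                       int(x.size), warning)


def normalize_track(
    chromatin_binned: GenomeTrack,
    model: LinearModel,
    predicted: GenomeTrack,
) -> GenomeTrack:
    """Invert the naked calibration to a fraction-accessible estimate per bin.

    ``effective_sites = max(signal - intercept, 0) / slope``; the normalized
    value is ``effective_sites / predicted_sites`` where the predicted count
    is positive, missing otherwise.  Values may exceed 1 where noise puts the
    effective count above the prediction; they are deliberately not clipped.
    """
    if model.slope <= 0:
        raise ValueError("refusing to normalize with non-positive slope")
    if chromatin_binned.bin_size != predicted.bin_size:
        raise ValueError("tracks are on different bin grids")
    values = {}
    for chrom, sig in chromatin_binned.values.items():
        pred = predicted.values[chrom]
        m = min(sig.size, pred.size)
        eff = np.maximum(sig[:m] - model.intercept, 0.0) / model.slope
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(pred[:m] > 0, eff / pred[:m], np.nan)
        out[np.isnan(sig[:m])] = np.nan
        values[chrom] = out
    return GenomeTrack(bin_size=chromatin_binned.bin_size, values=values,
                       label="normalized_accessibility")


def calibrate_predicted_smoothing(
    naked_binned: GenomeTrack,
    predicted_counts: GenomeTrack,
    candidate_stds: Sequence[float] = (250.0, 350.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0),
    window_to_std: float = 2.0,
) -> tuple[SmoothingParams, float]:
    """Pick the smoothing width that best matches the data's resolution.

    Smooths the theoretical site-count track at each candidate sd (window =
    2 x sd, as in the standard parameter set) and returns the parameters
    maximizing the Pearson correlation with the naked control, together with
    that correlation.
    """
    step = predicted_counts.bin_size
    best: tuple[float, SmoothingParams] | None = None
    for std in candidate_stds:
        params = SmoothingParams(window=max(window_to_std * std, step), std=std, step=step)
        x, y = _paired(smooth_track(predicted_counts, params), naked_binned)
        if x.size < 2 or np.ptp(x) == 0:
            continue
        r = float(stats.pearsonr(x, y).statistic)
        if best is None or r > best[0]:
            best = (r, params)
    if best is None:
        raise ValueError("no candidate smoothing produced a usable fit")
    return best[1], best[0]


@dataclass
class NormalizationResult:
    model: LinearModel
    smoothing: SmoothingParams
    predicted_counts: GenomeTrack
    predicted_smoothed: GenomeTrack
    normalized: GenomeTrack
    effective_sites: GenomeTrack  # (signal - intercept)/slope, before division


def build_normalized_track(
    chromatin_binned: GenomeTrack,
    naked_binned: GenomeTrack,
    gatc_sites: MotifSiteTrack,
    smoothing: SmoothingParams | str | None = "calibrate",
) -> NormalizationResult:
    """Full normalization: predicted density -> smoothing -> fit -> inverse.

    ``smoothing``: explicit :class:`SmoothingParams`, the string
    ``"calibrate"`` (default; width chosen against the naked control), or
    None for the field-standard defaults.
    """
    bin_size = chromatin_binned.bin_size
    predicted = predicted_site_density(gatc_sites, bin_size)
    if smoothing == "calibrate":
        smoothing, _ = calibrate_predicted_smoothing(naked_binned, predicted)
    elif smoothing is None:
        smoothing = SmoothingParams(step=bin_size)
    predicted_smoothed = smooth_track(predicted, smoothing)
    model = fit_naked_model(naked_binned, predicted_smoothed)
    normalized = normalize_track(chromatin_binned, model, predicted_smoothed)
    eff_values = {}
    for chrom, sig in chromatin_binned.values.items():
        eff_values[chrom] = np.maximum(sig - model.intercept, 0.0) / model.slope
    effective = GenomeTrack(bin_size=bin_size, values=eff_values, label="effective_sites")
    return NormalizationResult(model, smoothing, predicted, predicted_smoothed,
                               normalized, effective)
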