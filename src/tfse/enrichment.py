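"""Two-stage slope-1 tangent classification of TF-enriched super-enhancers.

The procedure mirrors the hockey-stick geometry used to call
super-enhancers from ranked ChIP-seq signal, applied twice:

1. all per-base signal depths inside the SE catalog are ranked ascending,
   both axes are min–max scaled to [0, 1], and the *read threshold* is the
   unscaled value at the point where a line of slope 1 is tangent to the
   curve — on a discrete convex curve, exactly ``argmin(y_scaled −
   x_scaled)``;
2. each SE's *binding density* — above-threshold signal per kilobase — is
   ranked and scaled the same way, and SEs lying above the slope-1 tangent
   point of that second curve are classified as TF-enriched.

The cutoff is geometric, not a statistical test: no p-values or
multiple-testing machinery are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genomic_io import ENRICHMENT_COLUMNS, CoverageTrack, SERecord, interval_signal

__all__ = [
    "DegenerateCurveError",
    "RankedCurve",
    "TangentThreshold",
    "EnrichmentConfig",
    "EnrichmentResult",
    "rank_scale",
    "tangent_point",
    "compute_read_threshold",
    "binding_density",
    "classify_enriched",
    "run_enrichment",
]

SignalMode = Literal["depth-positions", "depth-sum"]
ThresholdLevel = Literal["base-depth", "se-total"]


class DegenerateCurveError(ValueError):
    """Fewer than two values, or all values equal: no curve to scale."""


@dataclass(frozen=True)
class RankedCurve:
    """Ascending-sorted values with min–max-scaled rank/value coordinates.

    ``x_scaled[i] = i/(N-1)`` and ``y_scaled[i] = (v[i]-min)/(max-min)``,
    so the endpoints sit exactly at (0, 0) and (1, 1).
    """

    values: np.ndarray
    x_scaled: np.ndarray
    y_scaled: np.ndarray
    tangent_index: int | None = None

    def __len__(self) -> int:
        return len(self.values)


def rank_scale(values: Sequence[float] | np.ndarray) -> RankedCurve:
    """Sort ascending and min–max scale both axes to [0, 1].

    Raises :class:`DegenerateCurveError` for fewer than two values or a
    constant series (zero range).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("expected a 1-D value series")
    if len(v) < 2:
        raise DegenerateCurveError(f"need at least 2 values, got {len(v)}")
    if np.any(~np.isfinite(v)):
        raise ValueError("values must be finite")
    v = np.sort(v, kind="mergesort")
    vmin, vmax = v[0], v[-1]
    if vmax == vmin:
        raise DegenerateCurveError("all values equal: min-max scaling undefined")
    n = len(v)
    x = np.arange(n, dtype=np.float64) / (n - 1)
    y = (v - vmin) / (vmax - vmin)
    return RankedCurve(values=v, x_scaled=x, y_scaled=y)


def tangent_point(
    curve: RankedCurve, smooth_window: int = 1
) -> tuple[int, float]:
    """Index and unscaled value where the slope-1 tangent touches the curve.

    The discrete analogue of tangency for a convex ranked curve: the index
    minimising ``y_scaled − x_scaled`` (the point of largest signed gap
    below the diagonal), ties broken toward the smallest index.
    ``smooth_window`` > 1 applies a centred moving average to y before the
    argmin; the returned threshold is still read off the raw values.
    """
    y = curve.y_scaled
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        # edge-padded so endpoints stay anchored near (0,0)/(1,1)
        y = np.convolve(np.pad(y, smooth_window // 2, mode="edge"), kernel, "valid")
        y = y[: len(curve.y_scaled)]
    diff = y - curve.x_scaled
    idx = int(np.argmin(diff))  # np.argmin returns the first minimum
    return idx, float(curve.values[idx])


class TangentThreshold(BaseEstimator):
    """Slope-1 tangent cutoff on a ranked, min–max-scaled value curve.

    A tiny scikit-learn-style estimator: ``fit(values)`` locates the
    tangent point; ``predict(values)`` flags values strictly above the
    fitted threshold.

    Parameters
    ----------
    smooth_window : int, default 1
        Centred moving-average window applied to the scaled curve before
        the tangent search; 1 disables smoothing.

    Attributes
    ----------
    curve_ : RankedCurve
    tangent_index_ : int
    threshold_ : float
        Unscaled value at the tangent point.
    tangent_xy_ : tuple of float
        Scaled (x, y) coordinates of the tangent point.
    """

    def __init__(self, smooth_window: int = 1):
        self.smooth_window = smooth_window

    def fit(self, values: Sequence[float] | np.ndarray, y: None = None):
        curve = rank_scale(values)
        idx, thr = tangent_point(curve, smooth_window=self.smooth_window)
        self.curve_ = RankedCurve(
            curve.values, curve.x_scaled, curve.y_scaled, tangent_index=idx
        )
        self.tangent_index_ = idx
        self.threshold_ = thr
        self.tangent_xy_ = (
            float(curve.x_scaled[idx]),
            float(curve.y_scaled[idx]),
        )
        return self

    def predict(self, values: Sequence[float] | np.ndarray) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("TangentThreshold is not fitted")
        return np.asarray(values, dtype=np.float64) > self.threshold_


@dataclass(frozen=True)
class EnrichmentConfig:
    """Tunable knobs of the two-stage classification.

    signal_mode
        "depth-positions" (default): binding density counts above-threshold
        base positions per kb.  "depth-sum": sums the depths at those
        positions per kb.
    threshold_level
        "base-depth" (default): stage-1 curve ranks every per-base depth in
        the catalog, so the threshold lives on the per-base signal scale the
        densities are computed on.  "se-total": ranks per-SE total signal
        instead (threshold then lives on the totals scale).
    smooth_window
        Moving-average window for both tangent searches; 1 = off.
    """

    signal_mode: SignalMode = "depth-positions"
    threshold_level: ThresholdLevel = "base-depth"
    smooth_window: int = 1


@dataclass
class EnrichmentResult:
    """Everything the two-stage procedure determined."""

    read_threshold: float
    threshold_xy: tuple[float, float]
    density_tangent_value: float
    density_xy: tuple[float, float]
    table: pd.DataFrame
    config: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    @property
    def enriched_ids(self) -> list[str]:
        return self.table.loc[self.table["enriched"], "se_id"].tolist()

    @property
    def n_enriched(self) -> int:
        return int(self.table["enriched"].sum())

    @property
    def mean_density_enriched(self) -> float:
        d = self.table.loc[self.table["enriched"], "binding_density"]
        return float(d.mean()) if len(d) else float("nan")

    @property
    def mean_density_background(self) -> float:
        d = self.table.loc[~self.table["enriched"], "binding_density"]
        return float(d.mean()) if len(d) else float("nan")

    def report(self) -> dict:
        bg = self.table.loc[~self.table["enriched"], "binding_density"]
        return {
            "read_threshold": self.read_threshold,
            "threshold_xy": list(self.threshold_xy),
            "density_tangent_value": self.density_tangent_value,
            "density_xy": list(self.density_xy),
            "n_se": int(len(self.table)),
            "n_enriched": self.n_enriched,
            "mean_density_enriched": self.mean_density_enriched,
            "mean_density_background": self.mean_density_background,
            "background_density_range": [
                float(bg.min()) if len(bg) else None,
                float(bg.max()) if len(bg) else None,
            ],
            "signal_mode": self.config.signal_mode,
            "threshold_level": self.config.threshold_level,
        }


def compute_read_threshold(
    ses: Sequence[SERecord],
    track: CoverageTrack,
    level: ThresholdLevel = "base-depth",
    smooth_window: int = 1,
) -> tuple[float, tuple[float, float]]:
    """Stage 1: the read threshold from the ranked, scaled signal curve.

    With ``level="base-depth"`` every base position inside the catalog
    contributes one point (the curve ranks pileup depths, and the returned
    threshold is a depth); with ``level="se-total"`` each SE contributes
    its total signal.  Returns ``(threshold, (x, y))`` with the scaled
    tangent coordinates for reporting.
    """
    if len(ses) < 2:
        raise DegenerateCurveError("need at least 2 SEs")
    if level == "base-depth":
        values = np.concatenate([interval_signal(track, se) for se in ses])
    elif level == "se-total":
        values = np.array([interval_signal(track, se).sum() for se in ses])
    else:
        raise ValueError(f"unknown threshold level {level!r}")
    est = TangentThreshold(smooth_window=smooth_window).fit(values)
    return est.threshold_, est.tangent_xy_


def binding_density(
    se: SERecord,
    track: CoverageTrack,
    threshold: float,
    mode: SignalMode = "depth-positions",
) -> float:
    """Above-threshold signal per kilobase for one SE.

    "depth-positions": number of bases with depth strictly above the
    threshold, divided by SE length in kb.  "depth-sum": sum of the depths
    at those bases, divided by length in kb.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    depths = interval_signal(track, se)
    above = depths > threshold
    if mode == "depth-positions":
        signal = float(np.count_nonzero(above))
    elif mode == "depth-sum":
        signal = float(depths[above].sum())
    else:
        raise ValueError(f"unknown signal mode {mode!r}")
    return signal / se.length_kb


def classify_enriched(
    densities: Sequence[float] | np.ndarray, smooth_window: int = 1
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Stage 2: flag SEs whose density lies above the slope-1 tangent point.

    Returns ``(enriched_mask, density_tangent_value, (x, y))`` where the
    mask is aligned with the input order and an SE is enriched iff its
    density is strictly greater than the density at the tangent point.
    """
    d = np.asarray(densities, dtype=np.float64)
    est = TangentThreshold(smooth_window=smooth_window).fit(d)
    return est.predict(d), est.threshold_, est.tangent_xy_


def run_enrichment(
    ses: Sequence[SERecord],
    track: CoverageTrack,
    config: EnrichmentConfig | None = None,
) -> EnrichmentResult:
    """The full deterministic pipeline: threshold → densities → classification.

    Output row order follows ascending binding density (ties broken by
    ``se_id``), with ``rank`` 1 for the lowest density; results are
    invariant to the input order of SEs.
    """
    cfg = config or EnrichmentConfig()
    if len(ses) < 2:
        raise DegenerateCurveError("need at least 2 SEs")
    ids = [se.se_id for se in ses]
    if len(set(ids)) != len(ids):
        raise ValueError("se_id values must be unique within a catalog")

    threshold, thr_xy = compute_read_threshold(
        ses, track, level=cfg.threshold_level, smooth_window=cfg.smooth_window
    )
    totals = np.array([float(interval_signal(track, se).sum()) for se in ses])
    dens = np.array(
        [binding_density(se, track, threshold, mode=cfg.signal_mode) for se in ses]
    )
    enriched, tangent_value, dens_xy = classify_enriched(
        dens, smooth_window=cfg.smooth_window
    )

    table = pd.DataFrame(
        {
            "chrom": [se.chrom for se in ses],
            "start": [se.start for se in ses],
            "end": [se.end for se in ses],
            "se_id": ids,
            "total_signal": totals,
            "binding_density": dens,
            "enriched": enriched,
        }
    )
    table = table.sort_values(
        ["binding_density", "se_id"], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table[ENRICHMENT_COLUMNS]
    return EnrichmentResult(
        read_threshold=threshold,
        threshold_xy=thr_xy,
        density_tangent_value=tangent_value,
        density_xy=dens_xy,
        table=table,
        config=cfg,
    )
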