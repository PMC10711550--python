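"""Equilibrium and kinetic binding analysis, and FRAP recovery fitting.

Three families of measurement are covered:

* **EMSA titrations** — the bound fraction of a DNA probe at each protein
  concentration, ``[1 − free/total] × 100`` per lane, fitted to the Hill
  equation ``f = Bmax · X^h / (KD^h + X^h)`` (Bmax fixed to 1 by default,
  so f is a true fraction and f(KD) = 1/2 for any h).

* **Bio-layer interferometry (BLI)** — 1:1 Langmuir kinetics.  The
  association phase follows ``Y = Y0 + A(1 − e^(−kobs·t))`` and the
  dissociation phase ``Y = Y0 + A·e^(−kd·t)``; the observed rate combines
  both directions, ``kobs = ka·[Analyte] + kd``, so
  ``ka = (kobs − kd)/[Analyte]`` and ``KD = kd/ka``.  A global fit of the
  1:1 model across analyte concentrations (shared ka, kd, Rmax) is
  available as an alternative to the sequential per-phase equations.

* **FRAP** — background-subtracted, reference-corrected recovery traces
  normalised to the pre-bleach mean, fitted to a rising double exponential
  ``F(t) = F0 + A1(1 − e^(−t/τ1)) + A2(1 − e^(−t/τ2))``; the single
  reported τ is the amplitude-weighted mean, and the mobile fraction is
  the recovered amplitude relative to the bleached depth.

All fitters are bounded least squares (scipy) wrapped in small
scikit-learn-style estimators; fits are deterministic (any multi-start is
over a fixed grid of initialisations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "FitConvergenceError",
    "BindingCurve",
    "HillFit",
    "KineticsFit",
    "FrapFit",
    "HillBindingModel",
    "ExponentialPhaseModel",
    "FrapRecoveryModel",
    "fraction_bound",
    "fit_hill",
    "fit_bli_association",
    "fit_bli_dissociation",
    "derive_rate_constants",
    "fit_bli",
    "fit_bli_global",
    "frap_correct",
    "fit_frap",
]


class FitConvergenceError(RuntimeError):
    """Least squares did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


# --------------------------------------------------------------------------
# EMSA: fraction bound + Hill
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingCurve:
    """A titration: protein concentrations (nM) vs fraction bound in [0, 1]."""

    concentration_nm: np.ndarray
    fraction: np.ndarray
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        x = np.asarray(self.concentration_nm, dtype=np.float64)
        f = np.asarray(self.fraction, dtype=np.float64)
        object.__setattr__(self, "concentration_nm", x)
        object.__setattr__(self, "fraction", f)
        if x.shape != f.shape:
            raise ValueError("concentration and fraction lengths differ")
        if np.any(x < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(x) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_intensities(
        cls,
        concentration_nm: Sequence[float],
        free_intensity: Sequence[float],
        replicate: str = "rep1",
    ) -> "BindingCurve":
        """Build a curve from free-band intensities.

        The total DNA amount is read from the free band of the
        zero-protein lane, which must be present.
        """
        x = np.asarray(concentration_nm, dtype=np.float64)
        free = np.asarray(free_intensity, dtype=np.float64)
        zero = np.flatnonzero(x == 0)
        if len(zero) == 0:
            raise ValueError("titration must include a 0-concentration lane")
        total = float(free[zero[0]])
        frac = np.array([fraction_bound(f, total) for f in free]) / 100.0
        return cls(x, frac, replicate=replicate)


def fraction_bound(free_intensity: float, total_intensity: float) -> float:
    """Percent of probe bound: ``[1 − free/total] × 100``.

    ``total`` is the free-band intensity of the zero-protein lane.  Free
    intensities outside [0, total] (gel quantification noise) are clipped
    with a warning rather than rejected.
    """
    if total_intensity <= 0:
        raise ValueError(f"total intensity must be > 0, got {total_intensity}")
    if free_intensity < 0 or free_intensity > total_intensity:
        warnings.warn(
            f"free intensity {free_intensity} outside [0, {total_intensity}]; "
            "clipping",
            stacklevel=2,
        )
        free_intensity = min(max(free_intensity, 0.0), total_intensity)
    return (1.0 - free_intensity / total_intensity) * 100.0


@dataclass(frozen=True)
class HillFit:
    kd_nm: float
    hill_coefficient: float
    bmax: float
    rss: float
    residuals: np.ndarray


def _run_least_squares(fun, x0, bounds, what: str):
    res = least_squares(
        fun, x0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000
    )
    if not res.success:
        raise FitConvergenceError(
            f"{what} fit did not converge: {res.message}", last_iterate=res.x
        )
    return res


class HillBindingModel(BaseEstimator):
    """Hill-equation fit of a fraction-bound titration.

    Parameters
    ----------
    fix_bmax : bool, default True
        Hold the saturating fraction Bmax at 1 (apparent-KD convention for
        titrations quantified as true fractions).

    Attributes
    ----------
    kd_ : float         apparent KD, in the concentration unit of X
    h_ : float          Hill coefficient, bounded to (0.1, 10]
    bmax_ : float       1.0 when fixed
    rss_ : float
    residuals_ : ndarray
    """

    def __init__(self, fix_bmax: bool = True):
        self.fix_bmax = fix_bmax

    @staticmethod
    def _model(x: np.ndarray, kd: float, h: float, bmax: float) -> np.ndarray:
        out = np.zeros_like(x)
        pos = x > 0
        xp = x[pos]
        out[pos] = bmax / (1.0 + (kd / xp) ** h)
        return out

    def fit(self, X: Sequence[float], y: Sequence[float]):
        x = np.asarray(X, dtype=np.float64)
        f = np.asarray(y, dtype=np.float64)
        if len(x) < 3:
            raise ValueError("need at least 3 titration points")
        if not np.any(f > 0):
            raise ValueError("no binding observed (all fractions zero)")
        pos = x > 0
        # initial KD: concentration whose fraction is nearest half-saturation
        kd0 = float(x[pos][np.argmin(np.abs(f[pos] - 0.5))])
        kd0 = max(kd0, 1e-9)
        if self.fix_bmax:
            x0, lo, hi = [np.log(kd0), 1.0], [-60.0, 0.1], [60.0, 10.0]

            def resid(p):
                return self._model(x, np.exp(p[0]), p[1], 1.0) - f

        else:
            b0 = max(float(f.max()), 0.1)
            x0 = [np.log(kd0), 1.0, b0]
            lo, hi = [-60.0, 0.1, 1e-6], [60.0, 10.0, 2.0]

            def resid(p):
                return self._model(x, np.exp(p[0]), p[1], p[2]) - f

        res = _run_least_squares(resid, x0, (lo, hi), "Hill")
        self.kd_ = float(np.exp(res.x[0]))
        self.h_ = float(res.x[1])
        self.bmax_ = 1.0 if self.fix_bmax else float(res.x[2])
        self.residuals_ = res.fun.copy()
        self.rss_ = float(np.sum(res.fun**2))
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        return self._model(
            np.asarray(X, dtype=np.float64), self.kd_, self.h_, self.bmax_
        )


def fit_hill(curve: BindingCurve, fix_bmax: bool = True) -> HillFit:
    """Fit the Hill equation to a titration; Bmax is fixed to 1 by default."""
    m = HillBindingModel(fix_bmax=fix_bmax).fit(curve.concentration_nm, curve.fraction)
    return HillFit(m.kd_, m.h_, m.bmax_, m.rss_, m.residuals_)


# --------------------------------------------------------------------------
# BLI: single-phase exponentials + rate-constant arithmetic + global 1:1
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsFit:
    """Parameters of a sequential 1:1 BLI analysis at one analyte concentration."""

    y0_assoc: float
    a_assoc: float
    kobs: float  # 1/s
    y0_dissoc: float
    a_dissoc: float
    kd: float  # 1/s
    ka: float  # 1/(conc unit * s)
    kd_over_ka: float  # KD, in the analyte concentration unit
    analyte_conc: float
    kd_lower_bound_only: bool = False

    @property
    def KD(self) -> float:
        return self.kd_over_ka


class ExponentialPhaseModel(BaseEstimator):
    """Single-exponential fit of one BLI phase.

    phase="association": ``Y = Y0 + A(1 − e^(−k·t))`` (k is kobs).
    phase="dissociation": ``Y = Y0 + A·e^(−k·t)`` (k is kd; Y0 is the
    plateau and Y0 + A the signal at the start of dissociation).

    Attributes: ``y0_``, ``a_``, ``rate_``, ``rss_``; for dissociation,
    ``rate_lower_bound_only_`` marks traces that decay by less than 1%
    over the observation window (kd is then only bounded from above by the
    data).
    """

    def __init__(self, phase: str = "association"):
        self.phase = phase

    def fit(self, X: Sequence[float], y: Sequence[float]):
        t = np.asarray(X, dtype=np.float64)
        sig = np.asarray(y, dtype=np.float64)
        if len(t) < 5:
            raise ValueError("need at least 5 points")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("time must be nonnegative and strictly increasing")
        if self.phase not in ("association", "dissociation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        span = float(np.ptp(sig))
        if span <= 1e-12 * max(1.0, float(np.max(np.abs(sig)))):
            raise ValueError("flat trace: amplitude unidentifiable")
        t = t - t[0]
        t_span = float(t[-1]) if t[-1] > 0 else 1.0

        if self.phase == "association":
            y0_0, a_0 = float(sig[0]), float(sig[-1] - sig[0])
            target = y0_0 + 0.632 * a_0
            k0 = self._crossing_rate(t, sig, target, t_span)

            def model(p, tt):
                return p[0] + p[1] * (1.0 - np.exp(-p[2] * tt))

            lo = [-np.inf, -np.inf, 1e-12]
        else:
            y0_0, a_0 = float(sig[-1]), float(sig[0] - sig[-1])
            target = y0_0 + a_0 / np.e
            k0 = self._crossing_rate(t, sig, target, t_span)

            def model(p, tt):
                return p[0] + p[1] * np.exp(-p[2] * tt)

            lo = [-np.inf, -np.inf, 0.0]

        def resid(p):
            return model(p, t) - sig

        best = None
        for scale in (1.0, 0.2, 5.0):
            res = _run_least_squares(
                resid, [y0_0, a_0, max(k0 * scale, 1e-9)],
                (lo, [np.inf, np.inf, np.inf]), f"{self.phase} phase",
            )
            if best is None or res.cost < best.cost:
                best = res
        self.y0_ = float(best.x[0])
        self.a_ = float(best.x[1])
        self.rate_ = float(best.x[2])
        self.rss_ = float(2 * best.cost)
        if self.phase == "dissociation":
            self.rate_lower_bound_only_ = bool(self.rate_ * t_span < 0.01)
        return self

    @staticmethod
    def _crossing_rate(t, sig, target, t_span) -> float:
        going_up = sig[-1] >= sig[0]
        idx = np.flatnonzero(sig >= target if going_up else sig <= target)
        t63 = float(t[idx[0]]) if len(idx) and t[idx[0]] > 0 else t_span / 3.0
        return 1.0 / t63

    def predict(self, X: Sequence[float]) -> np.ndarray:
        t = np.asarray(X, dtype=np.float64)
        t = t - t[0]
        if self.phase == "association":
            return self.y0_ + self.a_ * (1.0 - np.exp(-self.rate_ * t))
        return self.y0_ + self.a_ * np.exp(-self.rate_ * t)


def fit_bli_association(
    time_s: Sequence[float], signal: Sequence[float]
) -> tuple[float, float, float]:
    """Fit ``Y = Y0 + A(1 − e^(−kobs t))``; returns (Y0, A, kobs)."""
    m = ExponentialPhaseModel("association").fit(time_s, signal)
    if m.rate_ <= 0:
        raise FitConvergenceError("kobs must be positive")
    return m.y0_, m.a_, m.rate_


def fit_bli_dissociation(
    time_s: Sequence[float], signal: Sequence[float]
) -> tuple[float, float, float]:
    """Fit ``Y = Y0 + A·e^(−kd t)``; returns (Y0, A, kd)."""
    m = ExponentialPhaseModel("dissociation").fit(time_s, signal)
    if getattr(m, "rate_lower_bound_only_", False):
        warnings.warn(
            "dissociation decays by <1% over the window: the fitted kd is a "
            "lower-bound-only estimate and A is confounded with the plateau",
            stacklevel=2,
        )
    return m.y0_, m.a_, m.rate_


def derive_rate_constants(
    kobs: float, kd: float, analyte_conc: float
) -> tuple[float, float]:
    """ka and KD from the observed and dissociation rates.

    ``ka = (kobs − kd)/[Analyte]``; ``KD = kd/ka``.  Units follow the
    analyte concentration (nM in → KD in nM, ka in 1/(nM·s)).
    """
    if analyte_conc <= 0:
        raise ValueError("analyte concentration must be > 0")
    if kobs <= kd:
        raise ValueError(
            f"no net association: kobs ({kobs}) must exceed kd ({kd})"
        )
    ka = (kobs - kd) / analyte_conc
    return ka, kd / ka


def fit_bli(trace: pd.DataFrame, mode: str = "sequential") -> list[KineticsFit] | dict:
    """Analyse a two-phase BLI trace table.

    ``trace`` needs columns ``time_s``, ``signal``, ``phase`` ("assoc" /
    "dissoc") and ``conc_nM``.  Phase times are re-zeroed at each phase
    start.  mode="sequential" applies the per-phase exponentials and the
    rate-constant arithmetic independently at each analyte concentration;
    mode="global" fits one shared (ka, kd, Rmax) across all concentrations.
    """
    required = {"time_s", "signal", "phase", "conc_nM"}
    if not required.issubset(trace.columns):
        raise ValueError(f"trace table needs columns {sorted(required)}")
    if mode == "global":
        return fit_bli_global(trace)
    if mode != "sequential":
        raise ValueError(f"unknown mode {mode!r}")
    fits = []
    for conc, grp in trace.groupby("conc_nM", sort=True):
        assoc = grp[grp["phase"] == "assoc"].sort_values("time_s")
        dissoc = grp[grp["phase"] == "dissoc"].sort_values("time_s")
        if assoc.empty or dissoc.empty:
            raise ValueError(f"concentration {conc}: both phases are required")
        y0a, aa, kobs = fit_bli_association(
            assoc["time_s"].to_numpy(), assoc["signal"].to_numpy()
        )
        dm = ExponentialPhaseModel("dissociation").fit(
            dissoc["time_s"].to_numpy(), dissoc["signal"].to_numpy()
        )
        ka, KD = derive_rate_constants(kobs, dm.rate_, float(conc))
        fits.append(
            KineticsFit(
                y0_assoc=y0a, a_assoc=aa, kobs=kobs,
                y0_dissoc=dm.y0_, a_dissoc=dm.a_, kd=dm.rate_,
                ka=ka, kd_over_ka=KD, analyte_conc=float(conc),
                kd_lower_bound_only=bool(dm.rate_lower_bound_only_),
            )
        )
    return fits


def fit_bli_global(trace: pd.DataFrame) -> dict:
    """Global 1:1 fit across analyte concentrations (shared ka, kd, Rmax).

    Association: ``Y(t) = Req(C)(1 − e^(−(ka·C+kd)t))`` with
    ``Req = Rmax·C/(C + kd/ka)``; dissociation continues from the fitted
    end-of-association level with rate kd.  Returns a dict with ka, kd,
    KD, rmax and rss.
    """
    groups = []
    for conc, grp in trace.groupby("conc_nM", sort=True):
        a = grp[grp["phase"] == "assoc"].sort_values("time_s")
        d = grp[grp["phase"] == "dissoc"].sort_values("time_s")
        if a.empty:
            raise ValueError(f"concentration {conc}: association phase required")
        ta = a["time_s"].to_numpy(float)
        groups.append(
            (
                float(conc),
                ta - ta[0],
                a["signal"].to_numpy(float),
                (d["time_s"].to_numpy(float) - d["time_s"].iloc[0])
                if not d.empty else np.empty(0),
                d["signal"].to_numpy(float) if not d.empty else np.empty(0),
            )
        )
    if not groups:
        raise ValueError("no traces to fit")
    smax = max(float(np.max(ya)) for _, _, ya, _, yd in groups)
    t_span = max(float(ta[-1]) for _, ta, _, _, _ in groups)

    def resid(p):
        ka, kd, rmax = np.exp(p[0]), np.exp(p[1]), np.exp(p[2])
        out = []
        for conc, ta, ya, td, yd in groups:
            kobs = ka * conc + kd
            req = rmax * conc / (conc + kd / ka)
            pred_a = req * (1.0 - np.exp(-kobs * ta))
            out.append(pred_a - ya)
            if len(td):
                y_end = req * (1.0 - np.exp(-kobs * ta[-1]))
                out.append(y_end * np.exp(-kd * td) - yd)
        return np.concatenate(out)

    x0 = [np.log(1.0 / (smax + 1.0) / t_span * 100), np.log(0.1 / t_span),
          np.log(max(smax, 1e-3) * 1.5)]
    best = None
    for dka in (-2.0, 0.0, 2.0):
        for dkd in (-2.0, 0.0, 2.0):
            start = [x0[0] + dka, x0[1] + dkd, x0[2]]
            try:
                res = _run_least_squares(
                    resid, start, ([-60.0] * 3, [60.0] * 3), "global 1:1"
                )
            except FitConvergenceError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise FitConvergenceError("global 1:1 fit did not converge")
    ka, kd, rmax = (float(np.exp(v)) for v in best.x)
    return {
        "ka": ka, "kd": kd, "KD": kd / ka, "rmax": rmax,
        "rss": float(2 * best.cost),
    }


# --------------------------------------------------------------------------
# FRAP
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapFit:
    """Double-exponential recovery parameters of a corrected FRAP trace."""

    f0: float
    a1: float
    tau1_s: float
    a2: float
    tau2_s: float
    tau_s: float  # amplitude-weighted mean of tau1/tau2
    mobile_fraction: float
    n_components: int
    rss: float


def frap_correct(
    roi: Sequence[float],
    reference: Sequence[float],
    background: Sequence[float],
    bleach_index: int,
) -> np.ndarray:
    """Background-subtract, reference-correct and pre-bleach-normalise.

    ``corrected(t) = (ROI − bg)/(ref − bg)`` divided by the pre-bleach mean
    of the same ratio, so the output pre-bleach mean is exactly 1 and any
    acquisition photobleaching captured by the reference region cancels.
    Frames 0..bleach_index-1 are pre-bleach.
    """
    roi_a = np.asarray(roi, dtype=np.float64)
    ref_a = np.asarray(reference, dtype=np.float64)
    bg_a = np.asarray(background, dtype=np.float64)
    if not (roi_a.shape == ref_a.shape == bg_a.shape):
        raise ValueError("ROI/reference/background series must share a length")
    if bleach_index < 1 or bleach_index >= len(roi_a):
        raise ValueError("bleach_index must leave a non-empty pre-bleach segment")
    denom = ref_a - bg_a
    if np.any(denom <= 0):
        bad = int(np.argmax(denom <= 0))
        raise ValueError(
            f"reference <= background at frame {bad}: correction undefined"
        )
    ratio = (roi_a - bg_a) / denom
    pre = float(ratio[:bleach_index].mean())
    if pre <= 0:
        raise ValueError("non-positive pre-bleach mean: cannot normalise")
    return ratio / pre


class FrapRecoveryModel(BaseEstimator):
    """Rising double-exponential fit of a post-bleach recovery trace.

    ``F(t) = F0 + A1(1 − e^(−t/τ1)) + A2(1 − e^(−t/τ2))`` with t re-zeroed
    at the bleach frame.  Components are reported with τ1 ≤ τ2; when the
    smaller amplitude is below 1% of the larger the fit falls back to a
    single exponential.  ``tau_`` is the amplitude-weighted mean τ and
    ``mobile_fraction_ = (A1+A2)/(1 − F0)``.
    """

    def __init__(self, fallback_ratio: float = 0.01):
        self.fallback_ratio = fallback_ratio

    @staticmethod
    def _double(p, t):
        f0, a1, tau1, a2, tau2 = p
        return (
            f0
            + a1 * (1.0 - np.exp(-t / tau1))
            + a2 * (1.0 - np.exp(-t / tau2))
        )

    def fit(self, X: Sequence[float], y: Sequence[float]):
        t = np.asarray(X, dtype=np.float64)
        f = np.asarray(y, dtype=np.float64)
        if len(t) < 10:
            raise ValueError("need at least 10 post-bleach points")
        t = t - t[0]
        f0_0 = float(f[0])
        plateau = float(np.mean(f[max(len(f) - max(len(f) // 10, 3), 1):]))
        a_tot = max(plateau - f0_0, 1e-6)
        half = f0_0 + 0.5 * a_tot
        above = np.flatnonzero(f >= half)
        t_half = float(t[above[0]]) if len(above) and t[above[0]] > 0 else t[-1] / 5
        tau0 = max(t_half / np.log(2.0), 1e-6)

        lo = [-np.inf, 0.0, 1e-9, 0.0, 1e-9]
        hi = [np.inf, np.inf, np.inf, np.inf, np.inf]

        def resid(p):
            return self._double(p, t) - f

        best = None
        for ratio in (2.0, 5.0, 20.0):
            for split in (0.5, 0.8):
                p0 = [f0_0, a_tot * split, tau0, a_tot * (1 - split), tau0 * ratio]
                try:
                    res = _run_least_squares(resid, p0, (lo, hi), "FRAP")
                except FitConvergenceError:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None:
            raise FitConvergenceError("FRAP double-exponential fit did not converge")

        f0, a1, tau1, a2, tau2 = best.x
        if tau2 < tau1:  # report the fast component first
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        self.n_components_ = 2
        if min(a1, a2) < self.fallback_ratio * max(a1, a2):
            # one component carries <1% of the amplitude: refit single
            def resid1(p):
                return p[0] + p[1] * (1.0 - np.exp(-t / p[2])) - f

            res1 = _run_least_squares(
                resid1, [f0_0, a_tot, tau0],
                ([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]), "FRAP single",
            )
            f0, a1, tau1 = res1.x
            a2, tau2 = 0.0, tau1
            best = res1
            self.n_components_ = 1

        self.f0_ = float(f0)
        self.a1_, self.tau1_ = float(a1), float(tau1)
        self.a2_, self.tau2_ = float(a2), float(tau2)
        self.tau_ = float((a1 * tau1 + a2 * tau2) / (a1 + a2))
        depth = 1.0 - self.f0_
        if depth <= 0:
            raise ValueError("no bleach depth: pre-bleach level not exceeded by 1")
        self.mobile_fraction_ = float((a1 + a2) / depth)
        self.rss_ = float(2 * best.cost)
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        t = np.asarray(X, dtype=np.float64)
        t = t - t[0]
        return self._double(
            [self.f0_, self.a1_, self.tau1_, self.a2_, self.tau2_], t
        )


def fit_frap(
    normalized: Sequence[float],
    time_s: Sequence[float],
    bleach_index: int,
) -> FrapFit:
    """Fit the post-bleach segment of a corrected, normalised FRAP trace."""
    f = np.asarray(normalized, dtype=np.float64)
    t = np.asarray(time_s, dtype=np.float64)
    if f.shape != t.shape:
        raise ValueError("series and time lengths differ")
    if len(f) - bleach_index < 10:
        raise ValueError("post-bleach segment must have at least 10 points")
    m = FrapRecoveryModel().fit(t[bleach_index:], f[bleach_index:])
    return FrapFit(
        f0=m.f0_, a1=m.a1_, tau1_s=m.tau1_, a2=m.a2_, tau2_s=m.tau2_,
        tau_s=m.tau_, mobile_fraction=m.mobile_fraction_,
        n_components=m.n_components_, rss=m.rss_,
    )
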