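"""Seeded synthetic-data generators for every pipeline stage.

Each generator emits data *and* its ground truth, in the formats the
analysis stages read, so recovery can be asserted with no external
download.  All randomness flows from one integer seed per call; the same
seed reproduces byte-identical artifacts.

The coverage generator emulates the hockey-stick structure of a ranked
SE-signal plot: a large background population whose per-base depth is
i.i.d. Poisson(λ), plus a small enriched tail in which a contiguous block
covering ``peak_fraction`` of the SE carries Poisson(λ·ratio) depth.  The
default condition (200 background + 31 enriched SEs, λ = 20, ratio 10,
peak fraction 0.3) gives a sharply separated tail; the ratio can be
lowered toward 1 to blur the elbow.  Fragment-level read structure (GC
bias, mappability, fragment length) is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, SERecord, write_bed, write_bedgraph
from .kinetics import BindingCurve

__all__ = [
    "SimulationSpec",
    "SimulatedCoverage",
    "simulate_coverage",
    "simulate_binding_curve",
    "simulate_bli_trace",
    "simulate_frap_trace",
    "simulate_droplet_image",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for the planted-enrichment coverage simulation."""

    seed: int = 1
    n_background_ses: int = 200
    n_enriched_ses: int = 31
    se_length_bp: tuple[int, int] = (800, 3000)
    background_depth: float = 20.0  # Poisson mean per base
    enrichment_ratio: float = 10.0  # depth multiplier inside enriched peaks
    peak_fraction: float = 0.3  # fraction of an enriched SE carrying the peak

    def __post_init__(self) -> None:
        if self.n_background_ses < 0 or self.n_enriched_ses < 0:
            raise ValueError("SE counts must be >= 0")
        if self.n_background_ses + self.n_enriched_ses == 0:
            raise ValueError("need at least one SE")
        if self.enrichment_ratio < 1:
            raise ValueError("enrichment ratio must be >= 1")
        if not (0 < self.peak_fraction <= 1):
            raise ValueError("peak fraction must be in (0, 1]")
        lo, hi = self.se_length_bp
        if lo < 1 or hi < lo:
            raise ValueError("invalid SE length range")
        if self.background_depth <= 0:
            raise ValueError("background depth must be > 0")


@dataclass
class SimulatedCoverage:
    records: list[SERecord]
    track: CoverageTrack
    labels: pd.DataFrame  # se_id, enriched (planted truth)
    spec: SimulationSpec = field(default_factory=SimulationSpec)

    @property
    def enriched_ids(self) -> set[str]:
        return set(self.labels.loc[self.labels["enriched"], "se_id"])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "se_bed": out / "ses.bed",
            "bedgraph": out / "coverage.bedgraph",
            "truth": out / "truth.tsv",
        }
        write_bed(self.records, paths["se_bed"])
        write_bedgraph(self.track, paths["bedgraph"])
        self.labels.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _runs_to_records(chrom: str, offset: int, depths: np.ndarray):
    """Run-length encode a per-base depth vector into bedGraph records."""
    change = np.flatnonzero(np.diff(depths)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depths)]))
    for s, e in zip(starts, ends):
        v = float(depths[s])
        if v != 0:
            yield (chrom, offset + int(s), offset + int(e), v)


def simulate_coverage(
    spec: SimulationSpec, out_dir: str | Path | None = None
) -> SimulatedCoverage:
    """Generate an SE catalog, a coverage track and planted enrichment labels.

    SEs are laid end to end (with uncovered gaps) across a handful of
    synthetic chromosomes; enriched SEs are interleaved at seeded random
    positions of the catalog so recovery cannot exploit ordering.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_background_ses + spec.n_enriched_ses
    enriched_flags = np.zeros(n_total, dtype=bool)
    enriched_flags[
        rng.choice(n_total, size=spec.n_enriched_ses, replace=False)
    ] = True

    lo, hi = spec.se_length_bp
    lengths = rng.integers(lo, hi + 1, size=n_total)
    n_chroms = max(1, min(5, n_total // 10))
    chrom_of = rng.integers(0, n_chroms, size=n_total)

    records: list[SERecord] = []
    cov_records: list[tuple[str, int, int, float]] = []
    cursor = {c: 1000 for c in range(n_chroms)}
    for i in range(n_total):
        chrom = f"chr{chrom_of[i] + 1}"
        start = cursor[chrom_of[i]]
        end = start + int(lengths[i])
        se_id = f"sSE{i + 1:03d}"
        records.append(SERecord(chrom, start, end, se_id))
        depths = rng.poisson(spec.background_depth, size=int(lengths[i])).astype(
            np.float64
        )
        if enriched_flags[i]:
            peak_len = max(1, int(round(spec.peak_fraction * lengths[i])))
            peak_start = int(rng.integers(0, lengths[i] - peak_len + 1))
            depths[peak_start : peak_start + peak_len] = rng.poisson(
                spec.background_depth * spec.enrichment_ratio, size=peak_len
            )
        cov_records.extend(_runs_to_records(chrom, start, depths))
        cursor[chrom_of[i]] = end + int(rng.integers(500, 2000))

    track = CoverageTrack.from_records(cov_records)
    labels = pd.DataFrame(
        {
            "se_id": [r.se_id for r in records],
            "enriched": enriched_flags,
        }
    )
    sim = SimulatedCoverage(records=records, track=track, labels=labels, spec=spec)
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def simulate_binding_curve(
    kd_nm: float = 10.0,
    hill: float = 1.5,
    concentrations_nm: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BindingCurve, dict]:
    """Hill-model fraction-bound titration with known KD and Hill coefficient."""
    x = (
        np.asarray(concentrations_nm, dtype=np.float64)
        if concentrations_nm is not None
        else np.array([1.0, 3.0, 10.0, 30.0, 100.0])
    )
    if x.size == 0:
        raise ValueError("empty concentration grid")
    rng = np.random.default_rng(seed)
    frac = np.zeros_like(x)
    pos = x > 0
    frac[pos] = 1.0 / (1.0 + (kd_nm / x[pos]) ** hill)
    if noise_sd > 0:
        frac = np.clip(frac + rng.normal(0.0, noise_sd, size=frac.shape), 0.0, 1.0)
    return (
        BindingCurve(x, frac),
        {"kd_nm": kd_nm, "hill": hill, "noise_sd": noise_sd},
    )


def simulate_bli_trace(
    ka: float = 8e-5,  # 1/(nM s)
    kd: float = 2e-3,  # 1/s
    analyte_conc_nm: float = 100.0,
    assoc_duration_s: float = 600.0,
    dissoc_duration_s: float = 600.0,
    dt_s: float = 1.0,
    rmax: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-phase 1:1 sensorgram with known rate constants.

    Association rises toward ``Req = Rmax·C/(C + kd/ka)`` at rate
    ``kobs = ka·C + kd``; dissociation decays from the end-of-association
    level at rate kd.  Phase times restart at 0 in the output table.
    """
    rng = np.random.default_rng(seed)
    kobs = ka * analyte_conc_nm + kd
    # Req -> Rmax as KD -> 0 (kd = 0: every encounter sticks)
    req = (
        rmax * analyte_conc_nm / (analyte_conc_nm + kd / ka) if kd > 0 else rmax
    )
    t_a = np.arange(0.0, assoc_duration_s + dt_s / 2, dt_s)
    y_a = req * (1.0 - np.exp(-kobs * t_a))
    t_d = np.arange(0.0, dissoc_duration_s + dt_s / 2, dt_s)
    y_d = y_a[-1] * np.exp(-kd * t_d)
    if noise_sd > 0:
        y_a = y_a + rng.normal(0.0, noise_sd, size=y_a.shape)
        y_d = y_d + rng.normal(0.0, noise_sd, size=y_d.shape)
    trace = pd.DataFrame(
        {
            "time_s": np.concatenate([t_a, t_d]),
            "signal": np.concatenate([y_a, y_d]),
            "phase": ["assoc"] * len(t_a) + ["dissoc"] * len(t_d),
            "conc_nM": analyte_conc_nm,
        }
    )
    truth = {
        "ka": ka,
        "kd": kd,
        "kobs": kobs,
        "KD_nm": kd / ka if ka > 0 else np.inf,
        "analyte_conc_nm": analyte_conc_nm,
        "rmax": rmax,
    }
    return trace, truth


def simulate_frap_trace(
    tau1_s: float = 10.0,
    tau2_s: float = 10.0,
    a1: float = 0.8,
    a2: float = 0.0,
    bleach_depth: float = 0.8,
    drift_per_s: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach: int = 10,
    duration_s: float = 120.0,
    dt_s: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Raw ROI/reference/background FRAP series with known recovery kinetics.

    The underlying normalised trace is 1 pre-bleach, drops to
    ``F0 = 1 − bleach_depth`` at the bleach frame, then recovers as
    ``F0 + a1(1 − e^(−t/τ1)) + a2(1 − e^(−t/τ2))`` (so the mobile fraction
    is (a1+a2)/bleach_depth).  ``drift_per_s`` applies an exponential
    acquisition-photobleaching decay to ROI and reference alike, which the
    correction removes exactly.
    """
    if a1 + a2 > bleach_depth + 1e-12:
        raise ValueError("recovered amplitude cannot exceed the bleach depth")
    if not (0 < bleach_depth <= 1):
        raise ValueError("bleach depth must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_post = int(round(duration_s / dt_s)) + 1
    t_post = np.arange(n_post) * dt_s
    f0 = 1.0 - bleach_depth
    f_post = (
        f0
        + a1 * (1.0 - np.exp(-t_post / tau1_s))
        + a2 * (1.0 - np.exp(-t_post / tau2_s))
    )
    f = np.concatenate([np.ones(n_prebleach), f_post])
    time_s = np.arange(len(f)) * dt_s

    bg = 50.0
    ref0 = 1000.0
    decay = np.exp(-drift_per_s * time_s)
    ref = bg + (ref0 - bg) * decay
    roi = bg + (ref - bg) * f
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd * (ref0 - bg), size=roi.shape)
    trace = pd.DataFrame(
        {
            "time_s": time_s,
            "roi": roi,
            "reference": ref,
            "background": np.full(len(f), bg),
        }
    )
    weighted_tau = (
        (a1 * tau1_s + a2 * tau2_s) / (a1 + a2) if (a1 + a2) > 0 else np.nan
    )
    truth = {
        "tau1_s": tau1_s,
        "tau2_s": tau2_s,
        "a1": a1,
        "a2": a2,
        "tau_s": weighted_tau,
        "mobile_fraction": (a1 + a2) / bleach_depth,
        "bleach_index": n_prebleach,
        "f0": f0,
    }
    return trace, truth


def simulate_droplet_image(
    n_disks: int = 12,
    radius_px: tuple[int, int] = (3, 8),
    intensity: float = 200.0,
    background: float = 10.0,
    size: tuple[int, int] = (256, 256),
    seed: int = 7,
    disjoint: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render disk-shaped droplets on a flat background.

    Returns (image, truth mask, per-disk table with centre/radius/area).
    With ``disjoint=True`` disks are placed by rejection sampling so no
    two touch (guaranteeing particle count = n_disks under 8-connectivity);
    otherwise centres are free and overlapping disks merge.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    img = np.full((h, w), float(background))
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    placed: list[tuple[int, int, int]] = []
    rows = []
    attempts = 0
    while len(placed) < n_disks:
        attempts += 1
        if attempts > 10000 * max(n_disks, 1):
            raise RuntimeError(
                "could not place disjoint disks; reduce n_disks or radii"
            )
        r = int(rng.integers(radius_px[0], radius_px[1] + 1))
        cy = int(rng.integers(r + 1, h - r - 1))
        cx = int(rng.integers(r + 1, w - r - 1))
        if disjoint and any(
            (cy - py) ** 2 + (cx - px) ** 2 <= (r + pr + 2) ** 2
            for py, px, pr in placed
        ):
            continue
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disk] = intensity
        mask |= disk
        placed.append((cy, cx, r))
        rows.append(
            {"row": cy, "col": cx, "radius_px": r, "area_px": int(disk.sum())}
        )
    truth = pd.DataFrame(rows, columns=["row", "col", "radius_px", "area_px"])
    return img, mask, truth
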