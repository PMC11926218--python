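"""Force-curve ingestion and dynamic-force-spectroscopy analysis.

A :class:`ForceCurve` is a time-ordered retract (or approach) trace of
tip-sample distance and force plus instrument metadata. The analysis
chain is: baseline correction -> rupture-event detection (with the
minimum tip-substrate distance filter that guards against non-specific
tip-sample interactions and ensures L_c >> L_p) -> per-event WLC fit
-> instantaneous loading rate r = k_eff * v from the slope of the fit
at rupture -> assembly of the dynamic force spectrum and Bell-Evans
fit of mean rupture force vs. log loading rate.

On-disk format: one UTF-8 TSV per curve with header
``time_s<TAB>distance_nm<TAB>force_pN`` and a JSON sidecar
``<name>.meta.json`` holding ``velocity_um_s``, ``spring_constant_pN_nm``,
``temperature_K`` and ``segment``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .constants import DEFAULT_TEMPERATURE_K, NM_PER_UM, thermal_energy
from .wlc import WLCFitResult, WLCParams, fit_wlc, wlc_stiffness

__all__ = [
    "CurveMetadata",
    "ForceCurve",
    "RuptureEvent",
    "EventCandidate",
    "BellEvansParams",
    "ClusterResult",
    "read_force_curves",
    "write_force_curve",
    "baseline_correct",
    "detect_rupture_events",
    "analyse_event",
    "analyse_curve",
    "loop_length_clusters",
    "fit_bell_evans",
    "bell_evans_mean_force",
    "events_to_dataframe",
    "events_from_dataframe",
]

#: Minimum tip-substrate distance (nm) for an event to be analysed.
MIN_EVENT_DISTANCE_NM = 250.0

#: Default force-drop threshold (pN) for event detection (~5x thermal noise).
DEFAULT_DROP_THRESHOLD_PN = 10.0

_TSV_COLUMNS = ["time_s", "distance_nm", "force_pN"]
_META_KEYS = ["velocity_um_s", "spring_constant_pN_nm", "temperature_K", "segment"]


@dataclass(frozen=True)
class CurveMetadata:
    retract_velocity: float          # um/s
    spring_constant: float           # pN/nm (cantilever)
    temperature: float = DEFAULT_TEMPERATURE_K
    source: str = ""
    segment: str = "retract"

    def __post_init__(self) -> None:
        if self.retract_velocity <= 0:
            raise ValueError("retract_velocity must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ForceCurve:
    """Time-ordered (time, tip-sample distance, force) samples."""

    time: np.ndarray      # s
    distance: np.ndarray  # nm
    force: np.ndarray     # pN
    metadata: CurveMetadata

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = len(self.time)
        if len(self.distance) != n or len(self.force) != n:
            raise ValueError("time, distance, force must have equal length")
        if n == 0:
            raise ValueError(f"curve {self.metadata.source!r} has no samples")
        if np.any(np.diff(self.time) < 0):
            raise ValueError(f"curve {self.metadata.source!r} has non-monotone time")
        if np.any(self.distance < 0):
            raise ValueError(f"curve {self.metadata.source!r} has negative distances")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class EventCandidate:
    """A detected force drop with the preceding stretch segment."""

    rupture_index: int
    rupture_distance: float   # nm
    rupture_force: float      # pN
    drop: float               # pN
    stretch_distance: np.ndarray
    stretch_force: np.ndarray
    metadata: CurveMetadata


@dataclass
class RuptureEvent:
    """A rupture analysed with the WLC model.

    ``loading_rate`` is the instantaneous loading rate r = k_eff * v
    with k_eff the slope of the WLC fit at the rupture point (pN/nm)
    and v the retract velocity.
    """

    rupture_force: float          # pN
    rupture_distance: float       # nm
    wlc_fit: WLCFitResult
    effective_stiffness: float    # pN/nm
    loading_rate: float           # pN/s
    retract_velocity: float       # um/s
    source: str = ""


@dataclass
class BellEvansParams:
    """Bell-Evans dynamic-force-spectrum fit.

    Mean rupture force model: F*(r) = (k_BT/x_beta) * ln(r x_beta / (k_off k_BT)).
    """

    k_off_zero_force: float     # 1/s
    barrier_width: float        # nm
    covariance: np.ndarray      # 2x2, order (k_off, x_beta)
    n_events: int
    k_off_stderr: float = float("nan")
    barrier_width_stderr: float = float("nan")
    converged: bool = True
    bin_table: Optional[pd.DataFrame] = None


@dataclass
class ClusterResult:
    centers: np.ndarray
    labels: np.ndarray
    k: int
    quality: float
    flagged: bool


# ---------------------------------------------------------------------------
# I/O


def write_force_curve(curve: ForceCurve, path) -> Path:
    """Write one curve as TSV + JSON metadata sidecar; returns the TSV path."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    df = pd.DataFrame({
        "time_s": curve.time,
        "distance_nm": curve.distance,
        "force_pN": curve.force,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "velocity_um_s": curve.metadata.retract_velocity,
        "spring_constant_pN_nm": curve.metadata.spring_constant,
        "temperature_K": curve.metadata.temperature,
        "segment": curve.metadata.segment,
        "source": curve.metadata.source,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _read_one(tsv_path: Path) -> ForceCurve:
    meta_path = tsv_path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise KeyError(f"{meta_path}: missing metadata keys {missing}")
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    missing_cols = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{tsv_path}: missing columns {missing_cols}")
    bad = df[df[_TSV_COLUMNS].isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-indexing
        raise ValueError(f"{tsv_path}: malformed rows at lines {lines}")
    metadata = CurveMetadata(
        retract_velocity=float(meta["velocity_um_s"]),
        spring_constant=float(meta["spring_constant_pN_nm"]),
        temperature=float(meta["temperature_K"]),
        segment=str(meta["segment"]),
        source=str(meta.get("source", tsv_path.stem)),
    )
    return ForceCurve(df["time_s"].to_numpy(), df["distance_nm"].to_numpy(),
                      df["force_pN"].to_numpy(), metadata)


def read_force_curves(path) -> List[ForceCurve]:
    """Read one TSV curve file, or every ``*.tsv`` curve in a directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no .tsv curves in {path}")
        return [_read_one(p) for p in files]
    return [_read_one(path)]


# ---------------------------------------------------------------------------
# analysis


def baseline_correct(curve: ForceCurve, tail_fraction: float = 0.1) -> ForceCurve:
    """Subtract a linear baseline fitted to the final part of the retract.

    The last ``tail_fraction`` of samples (far from the surface, after
    all tethers have detached) defines the zero-force baseline and any
    linear drift.
    """
    n = len(curve)
    n_tail = max(int(n * tail_fraction), 2)
    d_tail = curve.distance[-n_tail:]
    f_tail = curve.force[-n_tail:]
    if np.ptp(d_tail) > 0:
        coef = np.polyfit(d_tail, f_tail, 1)
        baseline = np.polyval(coef, curve.distance)
    else:
        baseline = np.full(n, float(np.mean(f_tail)))
    return ForceCurve(curve.time, curve.distance, curve.force - baseline, curve.metadata)


def detect_rupture_events(
    curve: ForceCurve,
    min_distance: float = MIN_EVENT_DISTANCE_NM,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD_PN,
    window_nm: float = 15.0,
) -> List[EventCandidate]:
    """Detect rupture events (sharp force drops) on a retract trace.

    A candidate is a local force maximum followed by a drop of at least
    ``drop_threshold`` completed within ``window_nm``. Candidates at
    tip-substrate distance <= ``min_distance`` are discarded. Each
    candidate carries its preceding stretch segment for WLC fitting.
    An empty list is a valid result.
    """
    d, f = curve.distance, curve.force
    n = len(d)
    if n < 5:
        return []
    fs = medfilt(f, kernel_size=min(5, n - (n + 1) % 2))
    spacing = max(float(np.median(np.diff(d))), 1e-9) if n > 1 else 1.0
    w = max(int(round(window_nm / spacing)), 2)

    # drop ahead of each sample within the window
    ahead_min = np.array([fs[i + 1:i + 1 + w].min() if i + 1 < n else fs[i]
                          for i in range(n)])
    drops = fs - ahead_min
    mask = drops >= drop_threshold

    events: List[EventCandidate] = []
    prev_end = 0
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        k = i + int(np.argmax(fs[seg]))  # rupture = highest point of the run
        drop = float(drops[k])
        if d[k] > min_distance:
            sd, sf = _stretch_segment(d, f, fs, prev_end, k)
            events.append(EventCandidate(
                rupture_index=k,
                rupture_distance=float(d[k]),
                rupture_force=float(fs[k]),
                drop=drop,
                stretch_distance=sd,
                stretch_force=sf,
                metadata=curve.metadata,
            ))
        prev_end = j + 1
        i = j + 1 + w  # skip past the completed drop
    return events


def _stretch_segment(d, f, fs, start: int, rupture: int) -> Tuple[np.ndarray, np.ndarray]:
    """Extract the rising stretch preceding a rupture.

    Starts where the smoothed force last rose above 20% of the rupture
    force (or at the previous event's end), so that the slack region
    does not dominate the WLC fit.
    """
    thresh = 0.2 * fs[rupture]
    lo = start
    for i in range(rupture, start - 1, -1):
        if fs[i] < thresh:
            lo = i + 1
            break
    lo = min(lo, max(rupture - 4, start))  # keep at least 5 samples when possible
    return d[lo:rupture + 1].copy(), f[lo:rupture + 1].copy()


def analyse_event(candidate: EventCandidate,
                  temperature: Optional[float] = None,
                  fix_persistence: Optional[float] = None) -> Optional[RuptureEvent]:
    """WLC-fit an event candidate and compute its instantaneous loading rate.

    Returns None (the event is excluded from spectra) when the WLC fit
    does not converge.
    """
    T = temperature if temperature is not None else candidate.metadata.temperature
    if len(candidate.stretch_distance) < 5:
        return None
    pts = np.column_stack([candidate.stretch_distance, candidate.stretch_force])
    pts = pts[pts[:, 0] > 0]
    if len(pts) < 5:
        return None
    fit = fit_wlc(pts, temperature=T, fix_persistence=fix_persistence)
    if not fit.converged:
        return None
    z = min(candidate.rupture_distance, fit.params.contour_length * (1 - 1e-6))
    k_eff = wlc_stiffness(z, fit.params)
    v = candidate.metadata.retract_velocity
    r = k_eff * v * NM_PER_UM  # pN/nm * nm/s = pN/s
    return RuptureEvent(
        rupture_force=candidate.rupture_force,
        rupture_distance=candidate.rupture_distance,
        wlc_fit=fit,
        effective_stiffness=k_eff,
        loading_rate=r,
        retract_velocity=v,
        source=candidate.metadata.source,
    )


def analyse_curve(curve: ForceCurve,
                  min_distance: float = MIN_EVENT_DISTANCE_NM,
                  drop_threshold: float = DEFAULT_DROP_THRESHOLD_PN,
                  correct_baseline: bool = True) -> List[RuptureEvent]:
    """Full per-curve pipeline: baseline -> detection -> WLC analysis."""
    if correct_baseline:
        curve = baseline_correct(curve)
    out = []
    for cand in detect_rupture_events(curve, min_distance, drop_threshold):
        ev = analyse_event(cand)
        if ev is not None:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# loop-size clustering


def loop_length_clusters(events: Sequence[RuptureEvent],
                         max_k: int = 5,
                         quality_threshold: float = 0.65) -> ClusterResult:
    """Cluster effective contour lengths into discrete loop sizes.

    1-D k-means with k chosen by silhouette over k in {1..max_k};
    k = 1 when the best silhouette falls below ``quality_threshold``
    (the result is then flagged unless the lengths are effectively
    identical).
    """
    if len(events) < 10:
        raise ValueError(f"need >= 10 events for clustering, got {len(events)}")
    values = np.array([e.wlc_fit.effective_contour_length for e in events])
    return _cluster_1d(values, max_k, quality_threshold)


def _cluster_1d(values: np.ndarray, max_k: int, quality_threshold: float) -> ClusterResult:
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    x = values.reshape(-1, 1)
    if np.ptp(values) <= 1e-9 * max(1.0, abs(float(np.mean(values)))):
        return ClusterResult(np.array([float(np.mean(values))]),
                             np.zeros(len(values), dtype=int), 1, 1.0, False)
    best = None
    for k in range(2, min(max_k, len(values) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(x)
        score = silhouette_score(x, km.labels_)
        if best is None or score > best[0]:
            best = (score, k, km)
    score, k, km = best
    if score < quality_threshold:
        return ClusterResult(np.array([float(np.mean(values))]),
                             np.zeros(len(values), dtype=int), 1, float(score), True)
    order = np.argsort(km.cluster_centers_.ravel())
    centers = km.cluster_centers_.ravel()[order]
    relabel = np.empty_like(order)
    relabel[order] = np.arange(k)
    return ClusterResult(centers, relabel[km.labels_], k, float(score), False)


# ---------------------------------------------------------------------------
# Bell-Evans dynamic force spectrum


def bell_evans_mean_force(loading_rate, k_off: float, x_beta: float,
                          temperature: float = DEFAULT_TEMPERATURE_K):
    """Bell-Evans most-probable rupture force F*(r), pN.

    F*(r) = (k_BT/x_beta) * ln(r * x_beta / (k_off * k_BT)); the
    standard model fitted to mean rupture force vs. log loading rate.
    """
    kbt = thermal_energy(temperature)
    f_beta = kbt / x_beta
    return f_beta * np.log(np.asarray(loading_rate, dtype=float) * x_beta / (k_off * kbt))


def fit_bell_evans(events: Sequence[RuptureEvent],
                   rate_bins: Optional[np.ndarray] = None,
                   bins_per_decade: int = 4,
                   temperature: float = DEFAULT_TEMPERATURE_K) -> BellEvansParams:
    """Fit the Bell-Evans model to a dynamic force spectrum.

    Rupture forces are binned in log-spaced loading-rate bins
    (``bins_per_decade`` per decade, matching the semi-log
    presentation); the model, linear in ln r, is fitted to the bin
    means and the parameter covariance propagated by the delta method.
    Events must span at least one decade of loading rate.
    """
    rates = np.array([e.loading_rate for e in events])
    forces = np.array([e.rupture_force for e in events])
    return fit_bell_evans_points(rates, forces, rate_bins, bins_per_decade, temperature)


def fit_bell_evans_points(rates: np.ndarray, forces: np.ndarray,
                          rate_bins: Optional[np.ndarray] = None,
                          bins_per_decade: int = 4,
                          temperature: float = DEFAULT_TEMPERATURE_K) -> BellEvansParams:
    rates = np.asarray(rates, float)
    forces = np.asarray(forces, float)
    if len(rates) < 2:
        raise ValueError("need at least 2 events")
    span = math.log10(rates.max() / rates.min())
    if span < 1.0:
        raise ValueError(f"events span only {span:.2f} decades of loading rate; need >= 1")
    if rate_bins is None:
        lo, hi = math.log10(rates.min()), math.log10(rates.max())
        n_bins = max(int(math.ceil((hi - lo) * bins_per_decade)), 2)
        rate_bins = np.logspace(lo, hi, n_bins + 1)
        rate_bins[-1] *= 1 + 1e-12
    idx = np.digitize(rates, rate_bins) - 1
    rows = []
    for b in range(len(rate_bins) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        rows.append((float(np.exp(np.mean(np.log(rates[sel])))),
                     float(np.mean(forces[sel])),
                     float(np.std(forces[sel])),
                     int(sel.sum())))
    table = pd.DataFrame(rows, columns=["rate_pN_s", "mean_force_pN", "sd_force_pN", "n"])
    if len(table) < 2:
        raise ValueError("fewer than 2 populated loading-rate bins")

    kbt = thermal_energy(temperature)
    x = np.log(table["rate_pN_s"].to_numpy())
    y = table["mean_force_pN"].to_numpy()
    (slope, intercept), cov_lin = np.polyfit(x, y, 1, cov=True)
    if slope <= 0:
        return BellEvansParams(float("nan"), float("nan"), np.full((2, 2), np.nan),
                               len(rates), converged=False, bin_table=table)
    x_beta = kbt / slope                       # nm
    k_off = (x_beta / kbt) * math.exp(-intercept / slope)  # 1/s
    if k_off <= 0 or x_beta <= 0:
        return BellEvansParams(float("nan"), float("nan"), np.full((2, 2), np.nan),
                               len(rates), converged=False, bin_table=table)
    # delta method: theta = (k_off, x_beta) as functions of (slope B, intercept A)
    B, A = slope, intercept
    dxb_dB, dxb_dA = -kbt / B ** 2, 0.0
    dko_dB = k_off * (-1.0 / B + A / B ** 2)
    dko_dA = k_off * (-1.0 / B)
    J = np.array([[dko_dB, dko_dA], [dxb_dB, dxb_dA]])
    cov = J @ cov_lin @ J.T
    cov = 0.5 * (cov + cov.T)
    return BellEvansParams(
        k_off_zero_force=k_off,
        barrier_width=x_beta,
        covariance=cov,
        n_events=len(rates),
        k_off_stderr=float(np.sqrt(max(cov[0, 0], 0.0))),
        barrier_width_stderr=float(np.sqrt(max(cov[1, 1], 0.0))),
        bin_table=table,
    )


# ---------------------------------------------------------------------------
# events table round-trip


_EVENT_COLUMNS = [
    "rupture_force_pN", "rupture_distance_nm", "Lp_eff_nm", "Lc_eff_nm",
    "residual_rms_pN", "k_eff_pN_nm", "loading_rate_pN_s", "velocity_um_s",
    "temperature_K", "source",
]


def events_to_dataframe(events: Sequence[RuptureEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rupture_force_pN": e.rupture_force,
        "rupture_distance_nm": e.rupture_distance,
        "Lp_eff_nm": e.wlc_fit.effective_persistence_length,
        "Lc_eff_nm": e.wlc_fit.effective_contour_length,
        "residual_rms_pN": e.wlc_fit.residual_rms,
        "k_eff_pN_nm": e.effective_stiffness,
        "loading_rate_pN_s": e.loading_rate,
        "velocity_um_s": e.retract_velocity,
        "temperature_K": e.wlc_fit.params.temperature,
        "source": e.source,
    } for e in events], columns=_EVENT_COLUMNS)


def events_from_dataframe(df: pd.DataFrame) -> List[RuptureEvent]:
    out = []
    for _, row in df.iterrows():
        params = WLCParams(row["Lp_eff_nm"], row["Lc_eff_nm"], row["temperature_K"])
        fit = WLCFitResult(params, row["Lp_eff_nm"], row["Lc_eff_nm"],
                           row["residual_rms_pN"], 0)
        out.append(RuptureEvent(
            rupture_force=row["rupture_force_pN"],
            rupture_distance=row["rupture_distance_nm"],
            wlc_fit=fit,
            effective_stiffness=row["k_eff_pN_nm"],
            loading_rate=row["loading_rate_pN_s"],
            retract_velocity=row["velocity_um_s"],
            source=str(row.get("source", "")),
        ))
    return out
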