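"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with
its generating parameters ("truth") returned alongside, so each stage
is testable without instrument data or downloads:

* WLC-shaped stretch-and-rupture force curves (single chains, parallel
  loop segments, multi-event sawtooths) with additive Gaussian
  instrument noise and optional linear drift;
* Bell-model rupture-force samples across loading rates, drawn exactly
  by inverse transform of the analytic first-passage distribution
  (independent of the time-stepping simulator they validate);
* toy multi-frame structures ("trajectories") with planted
  donor-acceptor contacts at specified occupancies, bridging waters of
  specified interaction order, and per-residue fluctuation amplitudes;
* structure pairs related by a known rigid transform plus Gaussian
  coordinate perturbation.

All randomness flows from one seeded generator per plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, NM_PER_UM, thermal_energy
from .curves import CurveMetadata, ForceCurve
from .structure import StructureModel, Trajectory
from .wlc import WLCParams, wlc_force

__all__ = [
    "PlantedEvent",
    "ForceCurvePlan",
    "RuptureSamplePlan",
    "TrajectoryPlan",
    "StructurePairPlan",
    "make_force_curve",
    "make_rupture_sample",
    "make_trajectory",
    "make_structure_pair",
]

#: Default instrument force noise, pN (typical AFM thermal noise scale).
DEFAULT_FORCE_NOISE_PN = 2.0


# ---------------------------------------------------------------------------
# force curves


@dataclass(frozen=True)
class PlantedEvent:
    """One planted stretch-and-rupture event.

    ``n_parallel`` identical WLC segments (persistence length
    ``persistence_length``, contour ``contour_length``) are stretched
    together and all rupture at ``rupture_distance``; the planted
    effective persistence length is persistence_length / n_parallel.
    """

    rupture_distance: float           # nm
    contour_length: float             # nm
    persistence_length: float = 4.1   # nm, single-chain value
    n_parallel: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.rupture_distance < self.contour_length):
            raise ValueError("rupture_distance must lie in (0, contour_length)")
        if self.n_parallel < 1:
            raise ValueError("n_parallel must be >= 1")

    @property
    def effective_persistence_length(self) -> float:
        return self.persistence_length / self.n_parallel


@dataclass(frozen=True)
class ForceCurvePlan:
    kind: str = field(default="force_curve", init=False)
    events: Tuple[PlantedEvent, ...] = ()
    noise_sigma: float = DEFAULT_FORCE_NOISE_PN   # pN
    drift_slope: float = 0.0                      # pN/nm linear drift
    sample_spacing: float = 1.0                   # nm
    max_distance: Optional[float] = None          # nm; default past last event
    retract_velocity: float = 1.0                 # um/s
    spring_constant: float = 10.0                 # pN/nm
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.sample_spacing <= 0:
            raise ValueError("noise_sigma must be >= 0 and sample_spacing > 0")


def make_force_curve(plan: ForceCurvePlan) -> Tuple[ForceCurve, Dict]:
    """Build a retract trace as the sum of planted WLC events plus noise.

    Refuses plans whose rupture positions are closer than five sample
    spacings (events overlapping beyond resolvability).
    """
    events = sorted(plan.events, key=lambda e: e.rupture_distance)
    positions = [e.rupture_distance for e in events]
    if any(b - a < 5 * plan.sample_spacing for a, b in zip(positions, positions[1:])):
        raise ValueError("planted events overlap beyond resolvability "
                         f"(min separation {5 * plan.sample_spacing} nm)")
    max_d = plan.max_distance
    if max_d is None:
        max_d = (positions[-1] * 1.3 + 50.0) if positions else 500.0
    rng = np.random.default_rng(plan.seed)
    d = np.arange(0.0, max_d, plan.sample_spacing)
    f = np.zeros_like(d)
    for e in events:
        params = WLCParams(e.persistence_length, e.contour_length, plan.temperature)
        live = d <= e.rupture_distance
        z = np.clip(d[live], 0.0, e.contour_length * (1 - 1e-9))
        f[live] += e.n_parallel * wlc_force(z, params)
    f += plan.drift_slope * d
    if plan.noise_sigma > 0:
        f += rng.normal(0.0, plan.noise_sigma, size=len(d))
    t = d / (plan.retract_velocity * NM_PER_UM)
    meta = CurveMetadata(plan.retract_velocity, plan.spring_constant,
                         plan.temperature, source=f"synthetic:seed{plan.seed}")
    curve = ForceCurve(t, d, f, meta)
    truth = {
        "events": [{
            "rupture_distance_nm": e.rupture_distance,
            "contour_length_nm": e.contour_length,
            "persistence_length_nm": e.persistence_length,
            "n_parallel": e.n_parallel,
            "effective_persistence_length_nm": e.effective_persistence_length,
            "rupture_force_pN": e.n_parallel * wlc_force(
                min(e.rupture_distance, e.contour_length * (1 - 1e-9)),
                WLCParams(e.persistence_length, e.contour_length, plan.temperature)),
        } for e in events],
        "noise_sigma_pN": plan.noise_sigma,
        "drift_slope_pN_nm": plan.drift_slope,
        "seed": plan.seed,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# Bell rupture-force samples


@dataclass(frozen=True)
class RuptureSamplePlan:
    kind: str = field(default="rupture_sample", init=False)
    k_off: float = 0.002          # 1/s, zero-force off rate
    x_beta: float = 1.2           # nm, barrier width
    rate_min: float = 1e2         # pN/s
    rate_max: float = 1e4         # pN/s
    n: int = 500
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_off, self.x_beta, self.rate_min, self.rate_max) <= 0:
            raise ValueError("rates and barrier width must be positive")
        if self.rate_max < self.rate_min or self.n < 1:
            raise ValueError("invalid rate range or sample count")


def bell_rupture_quantile(u, loading_rate, k_off: float, x_beta: float,
                          temperature: float = DEFAULT_TEMPERATURE_K):
    """Inverse CDF of the first-rupture force of a Bell bond.

    Survival under a constant ramp r: S(F) = exp(-(k_off f_b / r)
    (e^{F/f_b} - 1)) with f_b = k_B T / x_beta; solving S(F) = u gives
    F = f_b ln(1 - r ln u / (k_off f_b)).
    """
    f_b = thermal_energy(temperature) / x_beta
    return f_b * np.log1p(-np.asarray(loading_rate) * np.log(u) / (k_off * f_b))


def bell_mean_rupture_force(loading_rate: float, k_off: float, x_beta: float,
                            temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Exact closed-form mean rupture force: f_b e^a E1(a), a = k_off f_b / r."""
    from scipy.special import exp1
    f_b = thermal_energy(temperature) / x_beta
    a = k_off * f_b / loading_rate
    return float(f_b * math.exp(a) * exp1(a))


def make_rupture_sample(plan: RuptureSamplePlan) -> Tuple[pd.DataFrame, Dict]:
    """Draw (loading rate, rupture force) samples; rates log-uniform."""
    rng = np.random.default_rng(plan.seed)
    rates = np.exp(rng.uniform(math.log(plan.rate_min), math.log(plan.rate_max), plan.n))
    u = rng.uniform(0.0, 1.0, plan.n)
    forces = bell_rupture_quantile(u, rates, plan.k_off, plan.x_beta, plan.temperature)
    df = pd.DataFrame({"loading_rate_pN_s": rates, "rupture_force_pN": forces})
    truth = {"k_off_s": plan.k_off, "x_beta_nm": plan.x_beta, "seed": plan.seed}
    return df, truth


# ---------------------------------------------------------------------------
# toy trajectories


@dataclass(frozen=True)
class PlantedContact:
    """A donor-acceptor contact present in an exact fraction of frames."""
    occupancy: float
    bound_distance: float = 2.9    # A
    unbound_distance: float = 6.5  # A


@dataclass(frozen=True)
class PlantedBridge:
    """A water bridging protein and ligand with per-order occupancies.

    ``order_occupancy`` maps 'binary'/'ternary'/'quaternary' to the
    exact frame fraction in which the water has 2/3/4 simultaneous
    partners (at least one on each side).
    """
    order_occupancy: Dict[str, float]


@dataclass(frozen=True)
class PlantedFluctuation:
    """A residue jittered isotropically with the given sigma per coordinate (A)."""
    sigma: float
    n_atoms: int = 3


@dataclass(frozen=True)
class TrajectoryPlan:
    kind: str = field(default="trajectory", init=False)
    n_frames: int = 100
    contacts: Tuple[PlantedContact, ...] = ()
    bridges: Tuple[PlantedBridge, ...] = ()
    fluctuations: Tuple[PlantedFluctuation, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        for c in self.contacts:
            self._check_occ(c.occupancy)
        for b in self.bridges:
            for occ in b.order_occupancy.values():
                self._check_occ(occ)
            if sum(b.order_occupancy.values()) > 1.0 + 1e-9:
                raise ValueError("bridge order occupancies sum above 1")

    def _check_occ(self, occ: float) -> None:
        if not (0.0 <= occ <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        m = occ * self.n_frames
        if abs(m - round(m)) > 1e-9:
            raise ValueError(
                f"occupancy {occ} is not a multiple of 1/{self.n_frames} frames")


_ORDER_PARTNERS = {"binary": 2, "ternary": 3, "quaternary": 4}
_SITE_SPACING_A = 25.0
_FAR_A = 60.0  # parking distance for atoms switched off in a frame


def make_trajectory(plan: TrajectoryPlan) -> Tuple[Trajectory, Dict]:
    """Build a hydrogen-free toy trajectory with planted ground truth.

    Each planted feature lives in its own spatial site, far from the
    others, so contacts cannot cross-talk. Detection on these fixtures
    uses the distance-only (crystal) hydrogen-bond mode.
    """
    rng = np.random.default_rng(plan.seed)
    el, nm, rn, rs, ch = [], [], [], [], []
    base: List[List[float]] = []

    def add_atom(element, name, resname, resseq, chain, pos):
        el.append(element); nm.append(name); rn.append(resname)
        rs.append(resseq); ch.append(chain); base.append(list(pos))
        return len(base) - 1

    site = 0

    def site_center():
        nonlocal site
        c = [site * _SITE_SPACING_A, 0.0, 0.0]
        site += 1
        return np.array(c)

    # rigid alignment scaffold: four non-coplanar carbons, chain A res 1-4
    scaffold = site_center()
    for i, off in enumerate([(0, 0, 0), (4, 0, 0), (0, 4, 0), (0, 0, 4)]):
        add_atom("C", "CA", "ALA", i + 1, "A", scaffold + np.array(off))

    contact_atoms = []  # (donor_idx, acceptor_idx, frames_present)
    for k, c in enumerate(plan.contacts):
        ctr = site_center()
        di = add_atom("N", "N", "ALA", 10 + k, "A", ctr)
        ai = add_atom("O", f"O{k + 1}", "LIG", 1, "B", ctr + [c.bound_distance, 0, 0])
        m = round(c.occupancy * plan.n_frames)
        present = np.zeros(plan.n_frames, dtype=bool)
        present[rng.permutation(plan.n_frames)[:m]] = True
        contact_atoms.append((di, ai, present, c))

    bridge_atoms = []  # (water_idx, partner_idxs, order schedule per frame)
    for b_i, b in enumerate(plan.bridges):
        ctr = site_center()
        wi = add_atom("O", "O", "HOH", 100 + b_i, "W", ctr)
        # up to 4 partners ~2.9 A from the water, tetrahedral: protein O's
        # and ligand O's alternating so any order >= 2 spans both sides
        dirs = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                        dtype=float) / math.sqrt(3.0)
        partners = []
        for p in range(4):
            pos = ctr + 2.9 * dirs[p]
            if p % 2 == 0:
                idx = add_atom("O", "O", "ALA", 200 + 10 * b_i + p, "A", pos)
            else:
                idx = add_atom("O", f"OB{b_i}{p}", "LIG", 1, "B", pos)
            partners.append(idx)
        # frame schedule: 0 = off, else number of partners in range
        schedule = np.zeros(plan.n_frames, dtype=int)
        free = list(rng.permutation(plan.n_frames))
        for order, occ in b.order_occupancy.items():
            m = round(occ * plan.n_frames)
            take, free = free[:m], free[m:]
            schedule[take] = _ORDER_PARTNERS[order]
        bridge_atoms.append((wi, partners, schedule))

    fluct_atoms = []  # (atom indices, sigma)
    for f_i, fl in enumerate(plan.fluctuations):
        ctr = site_center()
        idxs = [add_atom("C", f"C{a + 1}", "ALA", 500 + f_i, "A",
                         ctr + np.array([0, 2.0 * a, 0]))
                for a in range(fl.n_atoms)]
        fluct_atoms.append((idxs, fl.sigma))

    base = np.asarray(base, dtype=float)
    frames = np.repeat(base[None, :, :], plan.n_frames, axis=0)

    for di, ai, present, c in contact_atoms:
        off = frames[~present, ai, 0] + (c.unbound_distance - c.bound_distance)
        frames[~present, ai, 0] = off
    for wi, partners, schedule in bridge_atoms:
        for fidx in range(plan.n_frames):
            k = schedule[fidx]
            if k == 0:
                frames[fidx, wi, 2] += _FAR_A  # water parked away: no bridge
            else:
                for p in partners[k:]:
                    frames[fidx, p, 2] += _FAR_A  # surplus partners parked
    for idxs, sigma in fluct_atoms:
        if sigma > 0:
            frames[:, idxs, :] += rng.normal(0.0, sigma,
                                             size=(plan.n_frames, len(idxs), 3))

    top = StructureModel(np.array(el), np.array(nm), np.array(rn),
                         np.array(rs, dtype=int), np.array(ch), base)
    traj = Trajectory(top, frames)
    truth = {
        "contacts": [{"donor": di, "acceptor": ai, "occupancy": c.occupancy}
                     for di, ai, _, c in contact_atoms],
        "bridges": [{"water": wi, "order_occupancy": dict(plan.bridges[i].order_occupancy)}
                    for i, (wi, _, _) in enumerate(bridge_atoms)],
        "fluctuations": [{"atoms": idxs, "sigma_A": s, "resseq": 500 + i}
                         for i, (idxs, s) in enumerate(fluct_atoms)],
        "align_mask_size": 4,
        "seed": plan.seed,
    }
    return traj, truth


def scaffold_align_mask(traj: Trajectory) -> np.ndarray:
    """Mask of the rigid scaffold atoms of a generated toy trajectory."""
    top = traj.topology
    return (top.chain == "A") & (top.name == "CA") & (top.resseq <= 4)


# ---------------------------------------------------------------------------
# structure pairs


@dataclass(frozen=True)
class StructurePairPlan:
    kind: str = field(default="structure_pair", init=False)
    n_atoms: int = 500
    coordinate_sigma: float = 0.5   # A, per-coordinate Gaussian perturbation
    box: float = 40.0               # A, extent of the random point cloud
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 3:
            raise ValueError("need at least 3 atoms")
        if self.coordinate_sigma < 0:
            raise ValueError("sigma must be >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_structure_pair(plan: StructurePairPlan
                        ) -> Tuple[StructureModel, StructureModel, Dict]:
    """A point-cloud model and a rigid transform of it plus Gaussian noise.

    The expected post-superposition RMSD is ~ sqrt(3) * sigma for large
    atom counts (exact value best obtained numerically).
    """
    rng = np.random.default_rng(plan.seed)
    a = rng.uniform(0.0, plan.box, size=(plan.n_atoms, 3))
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    b = a @ R.T + t
    if plan.coordinate_sigma > 0:
        b = b + rng.normal(0.0, plan.coordinate_sigma, size=b.shape)

    def as_model(xyz):
        n = plan.n_atoms
        return StructureModel(
            np.full(n, "C"), np.full(n, "CA"), np.full(n, "ALA"),
            np.arange(1, n + 1), np.full(n, "A"), xyz)

    truth = {
        "rotation": R, "translation": t,
        "coordinate_sigma_A": plan.coordinate_sigma,
        "expected_rmsd_A": math.sqrt(3.0) * plan.coordinate_sigma,
        "seed": plan.seed,
    }
    return as_model(a), as_model(b), truth
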