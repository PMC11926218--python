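"""Kinetic Monte Carlo simulation of AFM tip retraction with a polymer
chain engaged by multiple surface receptors.

Two bond modes are supported:

``sliding``
    The chain translates through each receptor binding site in discrete
    steps of one disaccharide (~1 nm) with a zero-force hop rate k, the
    hops biased by the local tension drop across the receptor, and a
    receptor releases only when the chain end passes through it. This
    is the toy reductionist model of the LYVE-1 sliding interaction.

``sticking``
    Each receptor holds the chain in place and ruptures stochastically
    at the Bell rate k_off * exp(F * x_beta / k_B T), as for CD44 and
    conventional receptor-ligand bonds; the retract curve is a sawtooth
    of sequential independent ruptures.

Tension model (sliding): receptors act as serial friction points along
one chain. The tip force is the WLC tension of the segment between the
tip anchor and the innermost engaged receptor; the tension beyond the
outermost engaged receptor (towards the free end) is zero; the total
drop is shared equally across the engaged receptors, so each of the m
engaged receptors feels a bias Delta_T = F_tip / m. At steady state the
biased hop flux of each receptor matches the imposed sliding speed,
which gives the analytic plateau force n * (2 k_B T / delta) *
asinh(v / (2 k delta)) implemented in :func:`sliding_friction_force`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Tuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, NM_PER_UM, thermal_energy
from .curves import CurveMetadata, ForceCurve
from .wlc import WLCParams, wlc_force

__all__ = [
    "BondMode",
    "PullingConfig",
    "ChainState",
    "SimulatedCurve",
    "simulate_retraction",
    "simulate_sticking_ruptures",
    "simulate_constant_rate_ruptures",
    "sliding_friction_force",
]


class BondMode(str, Enum):
    SLIDING = "sliding"
    STICKING = "sticking"


#: Contour length per HA disaccharide, nm.
DISACCHARIDE_NM = 1.0

#: Contour length of an 840 kDa HA chain (~2100 disaccharides), nm.
HA_840KDA_CONTOUR_NM = 2100.0

#: Maximum per-step event probability tolerated by the fixed-step KMC.
MAX_STEP_PROBABILITY = 0.1


@dataclass(frozen=True)
class PullingConfig:
    """Inputs of a single retraction simulation.

    Defaults are the toy-model study conditions: one-disaccharide steps
    on an 840 kDa chain, zero-force hop rate 1e3 /s, 5 engaged
    receptors spaced 20 nm apart, retraction at 1 um/s, ambient
    temperature. ``bias_distance`` is the distance to the hop barrier
    (default half a step, i.e. a symmetric barrier). Sticking mode
    reads ``off_rate_zero_force``/``barrier_width`` instead of the hop
    kinetics.
    """

    bond_mode: BondMode = BondMode.SLIDING
    n_receptors: int = 5
    receptor_spacing: float = 20.0          # nm, rms spacing d_rms,R
    chain_contour: float = HA_840KDA_CONTOUR_NM  # nm
    persistence_length: float = 4.1         # nm, single-chain HA value
    disaccharide_step: float = DISACCHARIDE_NM   # nm
    hop_rate_zero_force: float = 1e3        # 1/s (sliding)
    bias_distance: Optional[float] = None   # nm; None -> step/2
    off_rate_zero_force: float = 0.6        # 1/s (sticking)
    barrier_width: float = 0.4              # nm (sticking)
    retract_velocity: float = 1.0           # um/s
    temperature: float = DEFAULT_TEMPERATURE_K
    threading_depth: Optional[float] = None  # nm of chain past the outermost receptor; None -> contour/2
    time_step: Optional[float] = None       # s; None -> auto
    sample_spacing: float = 2.0             # nm between force samples
    seed: int = 0

    def __post_init__(self) -> None:
        mode = BondMode(self.bond_mode)
        object.__setattr__(self, "bond_mode", mode)
        for name in ("receptor_spacing", "chain_contour", "persistence_length",
                     "disaccharide_step", "hop_rate_zero_force",
                     "off_rate_zero_force", "barrier_width",
                     "retract_velocity", "temperature", "sample_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_receptors < 0:
            raise ValueError("n_receptors must be non-negative")
        if self.disaccharide_step > self.chain_contour:
            raise ValueError("disaccharide_step cannot exceed chain_contour")
        if self.bias_distance is not None and self.bias_distance <= 0:
            raise ValueError("bias_distance must be positive")

    @property
    def effective_bias_distance(self) -> float:
        return self.bias_distance if self.bias_distance is not None else 0.5 * self.disaccharide_step


@dataclass
class ChainState:
    """Evolving simulator state.

    ``registers`` holds, per receptor, the chain contour coordinate
    (nm, measured from the tip anchor) currently clamped by that
    receptor; registers of engaged receptors are strictly increasing
    towards the free end. In sliding mode a receptor whose register
    reaches the chain contour has had the chain end pass through and is
    disengaged permanently.
    """

    registers: List[float]
    engaged: List[bool]
    tip_height: float = 0.0
    time: float = 0.0

    @property
    def n_engaged(self) -> int:
        return sum(self.engaged)

    def engaged_registers(self) -> List[float]:
        return [r for r, e in zip(self.registers, self.engaged) if e]


@dataclass
class SimulatedCurve:
    """A simulated retract trace plus its generating truth and event log.

    ``event_log`` records (time s, receptor index, kind) with kind one
    of ``hop+`` (chain slid one step towards the tip), ``hop-`` (one
    step back), ``release`` (receptor disengaged).
    """

    curve: ForceCurve
    truth: PullingConfig
    event_log: List[Tuple[float, int, str]] = field(default_factory=list)
    rupture_forces: List[float] = field(default_factory=list)


def sliding_friction_force(velocity: float, hop_rate: float, step: float,
                           temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Steady-state friction force (pN) of one sliding receptor.

    The tension drop at which the net biased hop flux of a receptor
    equals an imposed sliding speed v:

        f = (2 k_B T / delta) * asinh( v / (2 k delta) )

    with v in um/s, hop rate k in 1/s and step delta in nm. This is the
    analytic companion of the sliding-mode simulator: with n engaged
    receptors the plateau force is n * f.
    """
    if velocity <= 0 or hop_rate <= 0 or step <= 0 or temperature <= 0:
        raise ValueError("all inputs must be positive")
    v_nm = velocity * NM_PER_UM
    kbt = thermal_energy(temperature)
    return (2.0 * kbt / step) * math.asinh(v_nm / (2.0 * hop_rate * step))


def _auto_time_step(cfg: PullingConfig) -> float:
    """Fixed KMC step keeping per-step hop probability safely below the cap.

    Sized for tension biases up to ~3x the steady-state plateau so that
    stochastic excursions do not push a single step past the cap.
    """
    f_ss = sliding_friction_force(cfg.retract_velocity, cfg.hop_rate_zero_force,
                                  cfg.disaccharide_step, cfg.temperature)
    kbt = thermal_energy(cfg.temperature)
    worst_bias = 3.0 * f_ss * cfg.effective_bias_distance / kbt
    worst_rate = 2.0 * cfg.hop_rate_zero_force * math.exp(worst_bias)
    return 0.5 * MAX_STEP_PROBABILITY / worst_rate


def _initial_state(cfg: PullingConfig) -> ChainState:
    # End-on threading: the free (non-reducing) end docked first and the
    # chain threaded through serial adjacent receptors during the dwell, so
    # at the start of retraction a contour length `threading_depth` has
    # already passed beyond the outermost receptor. Receptors clamp the
    # chain at registers spaced d_rms,R apart.
    n, d, L = cfg.n_receptors, cfg.receptor_spacing, cfg.chain_contour
    depth = cfg.threading_depth if cfg.threading_depth is not None else 0.5 * L
    if not (0 < depth < L):
        raise ValueError("threading_depth must lie in (0, chain_contour)")
    outermost = L - depth
    registers = [outermost - (n - 1 - i) * d for i in range(n)]
    if registers and registers[0] <= 0:
        raise ValueError("receptor span exceeds the threaded chain; reduce "
                         "n_receptors, spacing or threading_depth")
    return ChainState(registers=registers, engaged=[True] * n)


def _tip_tension(height: float, inner_register: float, cfg: PullingConfig) -> float:
    """WLC tension of the tip-anchor -> innermost-receptor segment."""
    if height <= 0:
        return 0.0
    params = WLCParams(cfg.persistence_length, inner_register, cfg.temperature)
    z = min(height, inner_register * (1.0 - 1e-9))
    return wlc_force(z, params)


def simulate_retraction(config: PullingConfig) -> SimulatedCurve:
    """Simulate one retract curve; deterministic for a given config+seed.

    The tip is retracted at constant velocity; the force is sampled on
    a uniform tip-height grid. In sliding mode engagement decays
    monotonically as the chain end passes through successive receptors,
    and the force is identically zero after the last release. In
    sticking mode releases are stochastic Bell-rate ruptures
    (see :func:`simulate_sticking_ruptures` for batches).
    """
    cfg = config
    if cfg.bond_mode is BondMode.STICKING:
        return _simulate_sticking_one(cfg)
    rng = np.random.default_rng(cfg.seed)
    tau = cfg.time_step if cfg.time_step is not None else _auto_time_step(cfg)
    # refuse a user-supplied step that can exceed the per-step probability cap
    min_tau_auto = _auto_time_step(cfg)
    if cfg.time_step is not None and cfg.time_step > 2.0 * min_tau_auto:
        raise ValueError(
            f"time_step {cfg.time_step:g} s is too large: per-step hop probability "
            f"may exceed {MAX_STEP_PROBABILITY}; use <= {2.0 * min_tau_auto:g} s or "
            "leave time_step unset for automatic choice"
        )

    v_nm = cfg.retract_velocity * NM_PER_UM
    kbt = thermal_energy(cfg.temperature)
    delta = cfg.disaccharide_step
    delta_b = cfg.effective_bias_distance
    k0 = cfg.hop_rate_zero_force
    L = cfg.chain_contour

    heights: List[float] = []
    forces: List[float] = []

    if cfg.n_receptors == 0:
        # chain fully slack: flat zero-force retract curve
        import warnings
        warnings.warn("no receptors engaged: chain is fully slack, returning a flat curve")
        grid = np.arange(0.0, L, cfg.sample_spacing)
        return _package_sliding(cfg, grid, np.zeros_like(grid), [])

    state = _initial_state(cfg)
    regs = state.registers
    engaged = state.engaged
    n_rec = cfg.n_receptors

    # total retract distance: a little past full chain extension
    h_max = L * 1.02
    n_steps = int(math.ceil(h_max / (v_nm * tau)))
    next_sample_h = 0.0

    c_force = kbt / cfg.persistence_length  # WLC prefactor, pN
    bias_scale = delta_b / kbt
    chunk = 20000
    u_chunk = rng.random((chunk, n_rec))
    row = 0

    log: List[Tuple[float, int, str]] = []
    eng_idx = [i for i in range(n_rec) if engaged[i]]
    for step_i in range(n_steps):
        t = step_i * tau
        h = v_nm * t
        m = len(eng_idx)
        if m == 0:
            f_tip = 0.0
        else:
            # WLC tension of the tip-anchor -> innermost-receptor segment
            s1 = regs[eng_idx[0]]
            x = h / s1
            if x <= 0.0:
                f_tip = 0.0
            else:
                if x > 1.0 - 1e-9:
                    x = 1.0 - 1e-9
                omx = 1.0 - x
                f_tip = c_force * (0.25 / (omx * omx) + x - 0.25)
        if h >= next_sample_h:
            heights.append(h)
            forces.append(f_tip)
            next_sample_h += cfg.sample_spacing
        if m == 0:
            continue
        bias = f_tip / m  # equal tension drop across each engaged receptor
        arg = bias * bias_scale
        if arg > 50.0:
            arg = 50.0
        e = math.exp(arg)
        p_fwd = k0 * e * tau
        p_bwd = k0 / e * tau
        if row >= chunk:
            u_chunk = rng.random((chunk, n_rec))
            row = 0
        u = u_chunk[row]
        row += 1
        changed = False
        for j in range(m):
            i = eng_idx[j]
            uj = u[i]
            if uj < p_fwd:
                # chain slides one step towards the tip through receptor i
                new_r = regs[i] + delta
                if j + 1 < m and new_r >= regs[eng_idx[j + 1]]:
                    continue  # ordering preserved: hop rejected
                if new_r >= L:
                    # chain end passed through: permanent disengagement
                    regs[i] = L
                    engaged[i] = False
                    changed = True
                    log.append((t, i, "release"))
                else:
                    regs[i] = new_r
                    log.append((t, i, "hop+"))
            elif uj < p_fwd + p_bwd:
                new_r = regs[i] - delta
                if new_r <= 0 or (j > 0 and new_r <= regs[eng_idx[j - 1]]):
                    continue
                regs[i] = new_r
                log.append((t, i, "hop-"))
        if changed:
            eng_idx = [i for i in range(n_rec) if engaged[i]]

    return _package_sliding(cfg, np.asarray(heights), np.asarray(forces), log)


def _package_sliding(cfg: PullingConfig, heights: np.ndarray, forces: np.ndarray,
                     log: List[Tuple[float, int, str]]) -> SimulatedCurve:
    v_nm = cfg.retract_velocity * NM_PER_UM
    times = heights / v_nm
    meta = CurveMetadata(retract_velocity=cfg.retract_velocity,
                         spring_constant=10.0,
                         temperature=cfg.temperature,
                         source=f"simulated:{cfg.bond_mode.value}:seed{cfg.seed}")
    curve = ForceCurve(time=times, distance=heights, force=forces, metadata=meta)
    return SimulatedCurve(curve=curve, truth=cfg, event_log=log)


def peak_force(sim: SimulatedCurve) -> float:
    """Maximum force (pN) of the retract trace."""
    return float(np.max(sim.curve.force))


def plateau_force(sim: SimulatedCurve) -> float:
    """Median force (pN) over the full-engagement sliding plateau.

    The plateau window runs from the first crossing of half the trace
    maximum to the first receptor release; this is the statistic the
    serial-friction steady state n * sliding_friction_force predicts.
    """
    f = sim.curve.force
    t = sim.curve.time
    releases = [e[0] for e in sim.event_log if e[2] == "release"]
    t_end = min(releases) if releases else t[-1]
    i0 = int(np.argmax(f > 0.5 * np.max(f)))
    sel = (t >= t[i0]) & (t < t_end)
    if not np.any(sel):
        return float(np.max(f))
    return float(np.median(f[sel]))


# ---------------------------------------------------------------------------
# sticking mode


def _bell_rate(force: float, k_off: float, x_beta: float, kbt: float) -> float:
    return k_off * math.exp(min(force * x_beta / kbt, 50.0))


def _simulate_sticking_one(cfg: PullingConfig) -> SimulatedCurve:
    rng = np.random.default_rng(cfg.seed)
    kbt = thermal_energy(cfg.temperature)
    v_nm = cfg.retract_velocity * NM_PER_UM

    if cfg.n_receptors == 0:
        grid = np.arange(0.0, cfg.chain_contour * 1.02, cfg.sample_spacing)
        return _package_sliding(cfg, grid, np.zeros_like(grid), [])

    state = _initial_state(cfg)
    regs = state.registers
    engaged = state.engaged

    heights: List[float] = []
    forces: List[float] = []
    log: List[Tuple[float, int, str]] = []
    ruptures: List[float] = []

    h, dt_h = 0.0, cfg.sample_spacing
    # integrate rupture hazard per bond on the sampling grid; the load-bearing
    # bond is the innermost engaged one (shortest tether segment)
    thresholds = {i: rng.exponential(1.0) for i in range(cfg.n_receptors)}
    hazards = {i: 0.0 for i in range(cfg.n_receptors)}
    h_max = cfg.chain_contour * 1.02
    while h < h_max:
        eng_idx = [i for i in range(cfg.n_receptors) if engaged[i]]
        if not eng_idx:
            heights.append(h); forces.append(0.0)
            h += dt_h
            continue
        inner = eng_idx[0]
        f_tip = _tip_tension(h, regs[inner], cfg)
        dt = dt_h / v_nm
        hazards[inner] += _bell_rate(f_tip, cfg.off_rate_zero_force,
                                     cfg.barrier_width, kbt) * dt
        if hazards[inner] >= thresholds[inner]:
            engaged[inner] = False
            log.append((h / v_nm, inner, "release"))
            ruptures.append(f_tip)
            # next bond (longer tether) takes the load at lower force
            eng_idx = eng_idx[1:]
            f_tip = _tip_tension(h, regs[eng_idx[0]], cfg) if eng_idx else 0.0
        heights.append(h)
        forces.append(f_tip)
        h += dt_h
    out = _package_sliding(cfg, np.asarray(heights), np.asarray(forces), log)
    out.rupture_forces = ruptures
    return out


def simulate_sticking_ruptures(config: PullingConfig, n_curves: int) -> List[SimulatedCurve]:
    """Simulate a batch of sticking-mode (sawtooth) retract curves.

    Each curve shows sequential, independent Bell-rate ruptures; between
    ruptures the force follows the WLC tension of the tip-anchor -> bond
    segment. Rupture forces are recorded per curve.
    """
    if BondMode(config.bond_mode) is not BondMode.STICKING:
        raise ValueError("config.bond_mode must be 'sticking'")
    return [_simulate_sticking_one(replace(config, seed=config.seed + i))
            for i in range(n_curves)]


def simulate_constant_rate_ruptures(k_off: float, x_beta: float, loading_rate: float,
                                    n: int, seed: int = 0,
                                    temperature: float = DEFAULT_TEMPERATURE_K,
                                    dt: Optional[float] = None) -> np.ndarray:
    """Rupture forces (pN) of a Bell bond under a constant force ramp.

    Time-stepping validation kernel for the sticking simulator: the
    force grows as F = r*t and the bond ruptures with rate
    k_off * exp(F x_beta / k_B T). Used to check the simulator against
    the closed-form mean rupture force.
    """
    if min(k_off, x_beta, loading_rate) <= 0 or n <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    kbt = thermal_energy(temperature)
    f_beta = kbt / x_beta
    # step small enough that the hazard changes little per step
    dt = dt if dt is not None else 0.01 * f_beta / loading_rate
    out = np.empty(n)
    for j in range(n):
        threshold = rng.exponential(1.0)
        hazard, t = 0.0, 0.0
        while True:
            f = loading_rate * t
            hazard += _bell_rate(f, k_off, x_beta, kbt) * dt
            t += dt
            if hazard >= threshold:
                out[j] = f
                break
    return out
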