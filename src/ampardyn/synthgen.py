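"""Synthetic inputs with the geometric and statistical structure the
analyses assume: rigid two-lobe dimers with prescribed conformational
coordinates, binomial channel-noise sweep ensembles, two-pulse recovery
series, and rectifying I–V ramps.

Every generator is deterministic in (spec, seed); the prescribed ground
truth travels with the spec object so recovery tests are self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .confcoords import LobeDefinition
from .ephys import IVPoints, Sweep, SweepSet, recovery_curve
from .errors import ParameterError
from .structio import Atom, Structure

__all__ = [
    "DimerSpec",
    "ChannelSimSpec",
    "make_two_lobe_dimer",
    "make_dimer_trajectory",
    "make_channel_sweeps",
    "make_decay_trace",
    "popen_desensitizing",
    "make_recovery_series",
    "make_iv_ramp",
]


@dataclass(frozen=True)
class DimerSpec:
    """Geometry of a synthetic two-lobe dimer.

    ``lobe_spacing`` sets both the upper-lobe separation and the vertical
    upper→lower drop (Å); 30 Å is a realistic clamshell-domain scale.
    Torsion and opening are the exact centroid-level coordinates realized
    before per-atom noise.
    """

    residues_per_lobe: int = 60
    lobe_spacing: float = 30.0
    torsion: float = 0.0  # degrees, (-180, 180]
    opening: float = 0.0  # degrees, (-180, 180]
    noise: float = 0.0  # Å, isotropic per-atom s.d.
    seed: int = 0

    def __post_init__(self):
        if self.residues_per_lobe < 3:
            raise ParameterError("need at least 3 residues per lobe")
        if self.noise < 0:
            raise ParameterError("noise must be non-negative")
        for name, val in (("torsion", self.torsion), ("opening", self.opening)):
            if not (-180.0 < val <= 180.0):
                raise ParameterError(f"{name} must lie in (-180, 180], got {val}")

    def lobe_definition(self) -> LobeDefinition:
        """Residue ranges matching the generated numbering (lower 1..n, upper 101..100+n)."""
        n = self.residues_per_lobe
        return LobeDefinition(
            upper_ranges=((101, 100 + n),), lower_ranges=((1, n),)
        )


@dataclass(frozen=True)
class ChannelSimSpec:
    """Binomial-gating ensemble for NSFA: N channels of unitary current i."""

    n_channels: int = 100
    i_unitary: float = -1.0  # pA
    popen: np.ndarray = field(default_factory=lambda: np.full(200, 0.5))
    dt_ms: float = 0.1
    baseline_sd: float = 0.0  # pA
    n_sweeps: int = 60
    holding_potential: float = -60.0  # mV
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "popen", np.asarray(self.popen, dtype=float))
        if self.n_channels < 1 or self.n_sweeps < 1:
            raise ParameterError("n_channels and n_sweeps must be >= 1")
        if np.any(self.popen < 0) or np.any(self.popen > 1):
            raise ParameterError("open probabilities must lie in [0, 1]")


def _lobe_template(rng: np.random.Generator, n: int, sd: float = 5.0) -> np.ndarray:
    """Seeded Gaussian point cloud, exactly mean-centred."""
    pts = rng.normal(0.0, sd, size=(n, 3))
    return pts - pts.mean(axis=0)


def _centroid_frame(spec: DimerSpec) -> dict[str, np.ndarray]:
    """Exact lobe-centroid positions realizing the prescribed coordinates.

    Upper centroids sit at (±d/2, 0, 0).  The lower centroids hang a depth
    m = h·cos(θ/2) below with out-of-plane offsets ∓h·sin(θ/2) realizing
    the torsion θ, and in-plane offsets ±q with q = −m·tan(ψ/2) realizing
    the projected opening ψ (the ghost axis evaluates to −z for this
    layout).  Degenerates only as |θ| or |ψ| approach 180°.
    """
    d = h = spec.lobe_spacing
    th = math.radians(spec.torsion)
    ps = math.radians(spec.opening)
    m = h * math.cos(th / 2.0)
    if m <= 1e-9:
        raise ParameterError("torsion too close to 180 degrees for this construction")
    z = h * math.sin(th / 2.0)
    q = -m * math.tan(ps / 2.0)
    return {
        "com1": np.array([-d / 2.0, 0.0, 0.0]),
        "com3": np.array([d / 2.0, 0.0, 0.0]),
        "com2": np.array([-q, -m, -z]),
        "com4": np.array([q, -m, z]),
    }


def _build_dimer(
    spec: DimerSpec,
    templates: tuple[np.ndarray, np.ndarray],
    noise_rng: np.random.Generator,
) -> Structure:
    coms = _centroid_frame(spec)
    t_upper, t_lower = templates
    n = spec.residues_per_lobe
    atoms: list[Atom] = []
    layout = [
        ("A", coms["com2"], t_lower, 1),
        ("A", coms["com1"], t_upper, 101),
        ("B", coms["com4"], t_lower, 1),
        ("B", coms["com3"], t_upper, 101),
    ]
    for chain, com, template, first_res in layout:
        block = template + com
        if spec.noise > 0:
            block = block + noise_rng.normal(0.0, spec.noise, size=block.shape)
        for k in range(n):
            atoms.append(
                Atom(chain, first_res + k, "ALA", "CA", "C", block[k])
            )
    return Structure(atoms)


def make_two_lobe_dimer(spec: DimerSpec) -> Structure:
    """Two-chain dimer whose lobe centroids realize ``spec`` exactly (pre-noise).

    Chains A and B each carry a lower lobe (residues 1..n) and an upper
    lobe (101..100+n) of n Cα pseudo-atoms drawn once from a seeded
    Gaussian cloud (s.d. 5 Å) and translated onto the exact centroid
    positions; isotropic noise is then added per atom.
    """
    rng = np.random.default_rng(spec.seed)
    templates = (_lobe_template(rng, spec.residues_per_lobe),
                 _lobe_template(rng, spec.residues_per_lobe))
    return _build_dimer(spec, templates, rng)


def make_dimer_trajectory(
    schedule: list[tuple[float, float]],
    base: DimerSpec | None = None,
    noise: float | None = None,
    seed: int | None = None,
) -> list[Structure]:
    """One dimer frame per (torsion, opening) pair, sharing lobe templates.

    ``base`` supplies sizes/noise/seed defaults; per-frame noise draws
    advance a single seeded stream so the whole series is reproducible.
    """
    base = base or DimerSpec()
    if noise is not None:
        base = replace(base, noise=noise)
    if seed is not None:
        base = replace(base, seed=seed)
    rng = np.random.default_rng(base.seed)
    templates = (_lobe_template(rng, base.residues_per_lobe),
                 _lobe_template(rng, base.residues_per_lobe))
    frames = []
    for tor, opn in schedule:
        spec = replace(base, torsion=tor, opening=opn)
        frames.append(_build_dimer(spec, templates, rng))
    return frames


def make_decay_trace(
    tau_f: float = 5.0,
    amp_f: float = -50.0,
    tau_s: float = 50.0,
    amp_s: float = -20.0,
    baseline: float = 0.0,
    dt_ms: float = 0.01,
    duration_ms: float = 250.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sweep:
    """Bi-exponential desensitization-style decay starting at its peak.

    I(t) = baseline + Af·exp(−t/τf) + As·exp(−t/τs) (+ Gaussian noise);
    amplitudes are the t = 0 values.
    """
    t = np.arange(0.0, duration_ms, dt_ms)
    I = baseline + amp_f * np.exp(-t / tau_f) + amp_s * np.exp(-t / tau_s)
    if noise_sd > 0:
        I = I + np.random.default_rng(seed).normal(0.0, noise_sd, size=I.shape)
    return Sweep(t, I)


def popen_desensitizing(
    time_ms: np.ndarray,
    p_peak: float = 0.8,
    tau_rise_ms: float = 0.3,
    tau_des_ms: float = 5.0,
    p_ss: float = 0.05,
) -> np.ndarray:
    """Open-probability time course: fast activation then exponential
    desensitization to a steady-state plateau."""
    t = np.asarray(time_ms, dtype=float)
    rise = 1.0 - np.exp(-t / tau_rise_ms)
    decay = p_ss + (p_peak - p_ss) * np.exp(-t / tau_des_ms)
    return np.clip(rise * decay, 0.0, 1.0)


def make_channel_sweeps(spec: ChannelSimSpec) -> SweepSet:
    """Binomial gating ensemble: per sample, open count ~ B(N, p(t));
    current = count·i + Gaussian baseline noise."""
    rng = np.random.default_rng(spec.seed)
    nt = len(spec.popen)
    time = np.arange(nt) * spec.dt_ms
    counts = rng.binomial(
        spec.n_channels, spec.popen[None, :], size=(spec.n_sweeps, nt)
    )
    I = counts * spec.i_unitary
    if spec.baseline_sd > 0:
        I = I + rng.normal(0.0, spec.baseline_sd, size=I.shape)
    sweeps = [
        Sweep(time, I[k], holding_potential=spec.holding_potential)
        for k in range(spec.n_sweeps)
    ]
    return SweepSet(sweeps, protocol="synthetic-binomial")


def make_recovery_series(
    y0: float = 0.1,
    a1: float = 0.6,
    k1: float = 0.2,
    k2: float = 0.02,
    m1: float = 4.0,
    m2: float = 1.0,
    ymax: float = 1.0,
    intervals: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-pulse recovery amplitudes at the given inter-pulse intervals.

    Default intervals follow the two-pulse protocol: 2 ms steps up to
    40 ms, then 10 ms steps to 400 ms.
    """
    if intervals is None:
        intervals = np.concatenate([np.arange(2.0, 40.0, 2.0), np.arange(40.0, 401.0, 10.0)])
    intervals = np.asarray(intervals, dtype=float)
    if np.any(intervals <= 0) or np.any(np.diff(intervals) <= 0):
        raise ParameterError("intervals must be positive and strictly increasing")
    y = recovery_curve(intervals, y0, a1, k1, k2, m1, m2, ymax)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return pd.DataFrame({"interval_ms": intervals, "amplitude": y})


def boltzmann_block(v_mV: np.ndarray, v_half: float = 10.0, slope: float = 15.0) -> np.ndarray:
    """Voltage-dependent open-pore fraction in [0, 1], blocking at positive
    potentials (intracellular polyamine-style inward rectification)."""
    return 1.0 / (1.0 + np.exp((np.asarray(v_mV, dtype=float) - v_half) / slope))


def make_iv_ramp(
    g_nS: float = 1.0,
    block=None,
    voltages: np.ndarray | None = None,
    reversal_mV: float = 0.0,
) -> tuple[IVPoints, pd.DataFrame]:
    """Ohmic ramp current scaled by a voltage-dependent block factor.

    ``block`` maps voltage (mV) to an open fraction in [0, 1]; ``None``
    means no rectification (block ≡ 1).  Currents are in pA for g in nS
    and V in mV.  Returns the three RI voltages plus the full ramp.
    """
    if voltages is None:
        voltages = np.linspace(-100.0, 100.0, 401)
    voltages = np.asarray(voltages, dtype=float)
    needed = (-60.0, 0.0, 40.0)
    if voltages.min() > min(needed) or voltages.max() < max(needed):
        raise ParameterError("ramp must cover -60, 0 and +40 mV")
    factor = np.ones_like(voltages) if block is None else np.asarray(block(voltages))
    if np.any(factor < 0) or np.any(factor > 1):
        raise ParameterError("block factor must lie in [0, 1]")
    current = g_nS * (voltages - reversal_mV) * factor
    ramp = pd.DataFrame({"voltage_mV": voltages, "current_pA": current})
    i_at = {v: float(np.interp(v, voltages, current)) for v in needed}
    points = IVPoints(I_plus40=i_at[40.0], I_0=i_at[0.0], I_minus60=i_at[-60.0])
    return points, ramp
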