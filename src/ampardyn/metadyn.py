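"""Well-tempered metadynamics: hills logs, bias and free-energy surfaces.

The bias potential is a sum of diagonal 2-D Gaussians deposited along a
trajectory in collective-variable (CV) space.  Under well-tempering the
hill height decays as h0·exp(−V/(kB·ΔT)) where V is the bias already
present at the deposition point and ΔT = (γ−1)·T, so the biased ensemble
converges to a stationary distribution at effective temperature T + ΔT:

    P(s) ∝ exp(−F(s)/(kB(T+ΔT)))

Two reconstruction routes are provided and labelled in
:class:`FESurface.method`:

* ``sum_hills`` — F(s) = −(γ/(γ−1))·V(s, t_final), the standard hill-sum
  estimator;
* ``histogram`` — F(s) = −kB(T+ΔT)·ln ρ̂(s), a (kernel-smoothed) density
  estimate over visited CV samples from the converged biased ensemble.

A toy overdamped-Langevin driver on analytic 2-D potentials exercises the
full deposition/reconstruction loop at desk scale, including shared-bias
multiple walkers and diffusion-based adaptive Gaussian widths (per-CV σ
from the RMS displacement of the CV over a trailing time window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import FormatError, ParameterError, StabilityError

__all__ = [
    "KB",
    "Hill",
    "HillsLog",
    "WTParams",
    "FESurface",
    "ToyPotential",
    "parse_hills",
    "write_hills",
    "bias_at",
    "fes_from_hills",
    "fes_from_histogram",
    "next_hill",
    "run_toy_metad",
    "well_free_energy_difference",
    "double_well_benchmark",
]

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083144621


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: centre, per-CV widths, height, bias factor."""

    time: float  # ps
    center: tuple[float, float]
    sigma: tuple[float, float]
    height: float  # kJ/mol
    bias_factor: float

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma components must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


@dataclass
class HillsLog:
    """Time-ordered hills, optionally from several walkers, with CV metadata."""

    hills: list[Hill]
    walker_ids: list[int] | None = None
    cv_names: tuple[str, str] = ("cv1", "cv2")
    periodic: tuple[bool, bool] = (False, False)
    period: tuple[float, float] = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.hills)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(times, centers (m,2), sigmas (m,2), heights (m,)) as arrays."""
        if not self.hills:
            z = np.zeros(0)
            return z, np.zeros((0, 2)), np.zeros((0, 2)), z
        t = np.array([h.time for h in self.hills])
        c = np.array([h.center for h in self.hills])
        s = np.array([h.sigma for h in self.hills])
        ht = np.array([h.height for h in self.hills])
        return t, c, s, ht


@dataclass(frozen=True)
class WTParams:
    """Well-tempered deposition parameters."""

    T: float = 300.0  # K
    gamma: float = 10.0  # bias factor (T + dT)/T
    h0: float = 1.2  # initial hill height, kJ/mol
    tau_dep: float = 10.0  # deposition interval, ps
    tau_d: float = 10.0  # adaptive-width window, ps
    kb: float = KB

    def __post_init__(self):
        if self.gamma <= 1:
            raise ParameterError("bias factor gamma must exceed 1")
        if self.T <= 0:
            raise ParameterError("temperature must be positive")

    @property
    def delta_T(self) -> float:
        return (self.gamma - 1.0) * self.T


@dataclass
class FESurface:
    """Free energy (kJ/mol) on a rectangular CV grid, min-shifted to zero."""

    s1: np.ndarray
    s2: np.ndarray
    F: np.ndarray  # shape (len(s1), len(s2)); NaN marks unvisited nodes
    method: str

    def to_dataframe(self) -> pd.DataFrame:
        g1, g2 = np.meshgrid(self.s1, self.s2, indexing="ij")
        return pd.DataFrame(
            {"s1": g1.ravel(), "s2": g2.ravel(), "F_kJ_mol": self.F.ravel()}
        )

    def write(self, path: str | Path) -> None:
        """Three-column grid text (s1, s2, F), one node per line."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("# s1 s2 F_kJ_mol\n")
            for _, row in df.iterrows():
                fh.write(f"{row.s1:.6f} {row.s2:.6f} {row.F_kJ_mol:.6f}\n")


# ---------------------------------------------------------------------------
# HILLS text format (PLUMED dialect)


def _parse_period_token(tok: str) -> float:
    t = tok.strip().lower()
    if t == "pi":
        return math.pi
    if t == "-pi":
        return -math.pi
    return float(t)


def parse_hills(
    paths: str | Path | Sequence[str | Path],
    periodic: tuple[bool, bool] | None = None,
    period: tuple[float, float] | None = None,
) -> HillsLog:
    """Parse one or more HILLS text files and merge them time-sorted.

    Each file must start with a ``#! FIELDS`` header naming, in order:
    time, two CV columns, their sigma columns, height and biasf.  Walker id
    is the file index.  ``#! SET min_<cv>``/``max_<cv>`` lines declare
    periodic CVs; explicit ``periodic``/``period`` arguments override.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_hills: list[Hill] = []
    all_walkers: list[int] = []
    cv_names: tuple[str, str] | None = None
    header_periodic = [False, False]
    header_period = [0.0, 0.0]

    for walker, p in enumerate(paths):
        lines = Path(p).read_text().splitlines()
        fields: list[str] | None = None
        bounds: dict[str, list[float | None]] = {}
        for lineno, line in enumerate(lines, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#!"):
                parts = stripped.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    fields = parts[2:]
                elif len(parts) >= 4 and parts[1] == "SET":
                    key, val = parts[2], parts[3]
                    if key.startswith("min_") or key.startswith("max_"):
                        cv = key[4:]
                        bounds.setdefault(cv, [None, None])
                        bounds[cv][0 if key.startswith("min_") else 1] = (
                            _parse_period_token(val)
                        )
                continue
            if fields is None:
                raise FormatError(f"{p}: data before #! FIELDS header")
            cols = stripped.split()
            if len(cols) < len(fields):
                raise FormatError(
                    f"{p}: line {lineno}: expected {len(fields)} columns, got {len(cols)}"
                )
            row = dict(zip(fields, (float(c) for c in cols)))
            if fields is not None and cv_names is None:
                if len(fields) < 6 or fields[0] != "time":
                    raise FormatError(f"{p}: unsupported FIELDS header {fields}")
                cv_names = (fields[1], fields[2])
            assert cv_names is not None
            try:
                hill = Hill(
                    time=row["time"],
                    center=(row[cv_names[0]], row[cv_names[1]]),
                    sigma=(row[f"sigma_{cv_names[0]}"], row[f"sigma_{cv_names[1]}"]),
                    height=row["height"],
                    bias_factor=row.get("biasf", 0.0),
                )
            except KeyError as exc:
                raise FormatError(f"{p}: missing column {exc}") from exc
            all_hills.append(hill)
            all_walkers.append(walker)
        if fields is None:
            raise FormatError(f"{p}: no #! FIELDS header found")
        if cv_names is not None:
            for j, cv in enumerate(cv_names):
                b = bounds.get(cv)
                if b and b[0] is not None and b[1] is not None:
                    header_periodic[j] = True
                    header_period[j] = b[1] - b[0]

    order = np.argsort([h.time for h in all_hills], kind="stable")
    hills = [all_hills[i] for i in order]
    walkers = [all_walkers[i] for i in order]
    return HillsLog(
        hills=hills,
        walker_ids=walkers,
        cv_names=cv_names or ("cv1", "cv2"),
        periodic=tuple(periodic) if periodic is not None else tuple(header_periodic),
        period=tuple(period) if period is not None else tuple(header_period),
    )


def write_hills(log: HillsLog, path: str | Path) -> None:
    """Write a HILLS file readable by :func:`parse_hills` (diagonal Gaussians)."""
    n1, n2 = log.cv_names
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {n1} {n2} sigma_{n1} sigma_{n2} height biasf\n")
        for j, name in enumerate(log.cv_names):
            if log.periodic[j]:
                half = log.period[j] / 2.0
                fh.write(f"#! SET min_{name} {-half:.10g}\n")
                fh.write(f"#! SET max_{name} {half:.10g}\n")
        for h in log.hills:
            fh.write(
                f"{h.time:.6f} {h.center[0]:.10g} {h.center[1]:.10g} "
                f"{h.sigma[0]:.10g} {h.sigma[1]:.10g} {h.height:.10g} "
                f"{h.bias_factor:.6g}\n"
            )


# ---------------------------------------------------------------------------
# bias evaluation


def _min_image(delta: np.ndarray, periodic, period) -> np.ndarray:
    out = np.array(delta, dtype=float, copy=True)
    for j in range(2):
        if periodic[j]:
            out[..., j] -= period[j] * np.round(out[..., j] / period[j])
    return out


def bias_at(
    log: HillsLog, point: np.ndarray, upto_time: float = math.inf
) -> float | np.ndarray:
    """Bias potential V(s) (kJ/mol) from hills with time ≤ ``upto_time``.

    ``point`` may be a single (s1, s2) pair or an array (..., 2); the sum
    uses minimum-image CV differences for periodic CVs.
    """
    pt = np.asarray(point, dtype=float)
    scalar = pt.shape == (2,)
    pts = pt.reshape(-1, 2)
    t, c, s, h = log.arrays()
    mask = t <= upto_time
    c, s, h = c[mask], s[mask], h[mask]
    if len(h) == 0:
        out = np.zeros(len(pts))
    else:
        delta = _min_image(pts[:, None, :] - c[None, :, :], log.periodic, log.period)
        expo = -0.5 * np.sum((delta / s[None, :, :]) ** 2, axis=-1)
        out = np.exp(expo) @ h
    if scalar:
        return float(out[0])
    return out.reshape(pt.shape[:-1])


def _resolve_grid(grid) -> tuple[np.ndarray, np.ndarray]:
    (a, b) = grid
    def axis(g):
        if isinstance(g, tuple) and len(g) == 3:
            lo, hi, n = g
            return np.linspace(lo, hi, int(n))
        return np.asarray(g, dtype=float)
    return axis(a), axis(b)


def fes_from_hills(log: HillsLog, params: WTParams, grid) -> FESurface:
    """Hill-sum estimator F = −(γ/(γ−1))·V(s, t_final), min-shifted to 0.

    ``grid`` is a pair of axes, each either an array of node values or a
    ``(lo, hi, n)`` triple.
    """
    if params.gamma <= 1:
        raise ParameterError("bias factor gamma must exceed 1")
    declared = [h.bias_factor for h in log.hills if h.bias_factor > 0]
    if declared and not math.isclose(declared[0], params.gamma, rel_tol=1e-6):
        raise ParameterError(
            f"hills declare biasf={declared[0]}, params say gamma={params.gamma}"
        )
    s1, s2 = _resolve_grid(grid)
    g1, g2 = np.meshgrid(s1, s2, indexing="ij")
    pts = np.stack([g1, g2], axis=-1)
    V = bias_at(log, pts)
    F = -(params.gamma / (params.gamma - 1.0)) * V
    F -= F.min()
    return FESurface(s1, s2, F, method="sum_hills")


def fes_from_histogram(
    samples: np.ndarray,
    params: WTParams,
    grid,
    kernel_width: tuple[float, float] | float,
    periodic: tuple[bool, bool] = (False, False),
    period: tuple[float, float] = (0.0, 0.0),
    final_bias: HillsLog | None = None,
) -> FESurface:
    """Histogram estimator from biased-run CV samples.

    Default form: F(s) = −kB(T+ΔT)·ln ρ̂(s) + const where ρ̂ is a
    Gaussian-kernel-smoothed histogram of the samples on the grid; this
    inverts the well-tempered stationary distribution
    P(s) ∝ exp(−F(s)/(kB(T+ΔT))).  It is exact only insofar as the bias
    has converged to (1−1/γ)·F; any residual bias error ε(s) enters the
    estimate amplified by γ.

    When ``final_bias`` is given, the samples are taken to come from
    dynamics under that *fixed* bias V, whose ensemble is exactly
    P(s) ∝ exp(−(F(s)+V(s))/(kB·T)); the estimator then inverts that
    relation directly, F(s) = −kB·T·ln ρ̂(s) − V(s) + const, which needs no
    convergence assumption and keeps statistical errors on the physical
    temperature scale.

    Nodes with zero smoothed density are NaN (unvisited); the minimum over
    visited nodes is shifted to zero.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 2)
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    if np.isscalar(kernel_width):
        kernel_width = (float(kernel_width), float(kernel_width))
    if any(k <= 0 for k in kernel_width):
        raise ParameterError("kernel width must be positive")
    s1, s2 = _resolve_grid(grid)
    d1 = s1[1] - s1[0] if len(s1) > 1 else 1.0
    d2 = s2[1] - s2[0] if len(s2) > 1 else 1.0
    edges1 = np.concatenate([s1 - d1 / 2, [s1[-1] + d1 / 2]])
    edges2 = np.concatenate([s2 - d2 / 2, [s2[-1] + d2 / 2]])
    counts, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=(edges1, edges2))
    mode = tuple("wrap" if p else "nearest" for p in periodic)
    rho = gaussian_filter(
        counts, sigma=(kernel_width[0] / d1, kernel_width[1] / d2), mode=mode
    )
    with np.errstate(divide="ignore"):
        if final_bias is None:
            kT_eff = params.kb * (params.T + params.delta_T)
            F = -kT_eff * np.log(rho)
        else:
            g1, g2 = np.meshgrid(s1, s2, indexing="ij")
            V = bias_at(final_bias, np.stack([g1, g2], axis=-1))
            F = -params.kb * params.T * np.log(rho) - V
    F[~np.isfinite(F)] = np.nan
    F -= np.nanmin(F)
    return FESurface(s1, s2, F, method="histogram")


# ---------------------------------------------------------------------------
# deposition rule


def adaptive_sigma(
    history: np.ndarray,
    state: np.ndarray,
    initial_sigma: tuple[float, float],
    floor: float = 0.01,
    cap: float | None = None,
) -> tuple[float, float]:
    """Per-CV width from the RMS displacement of the trailing CV history.

    ``history`` holds the CV values over the adaptive window (k, 2);
    σ_j = sqrt(mean((history_j − state_j)²)) floored at ``floor`` and
    optionally capped.  An empty history falls back to ``initial_sigma``.
    """
    if history is None or len(history) == 0:
        sig = np.asarray(initial_sigma, dtype=float)
    else:
        disp = np.asarray(history, dtype=float) - np.asarray(state, dtype=float)
        sig = np.sqrt(np.mean(disp**2, axis=0))
    sig = np.maximum(sig, floor)
    if cap is not None:
        sig = np.minimum(sig, cap)
    return (float(sig[0]), float(sig[1]))


def next_hill(
    state: np.ndarray,
    log: HillsLog,
    params: WTParams,
    history: np.ndarray | None = None,
    time: float = 0.0,
    initial_sigma: tuple[float, float] = (0.3, 0.3),
    sigma_floor: float = 0.01,
    sigma_cap: float | None = None,
) -> Hill:
    """The well-tempered hill to deposit at ``state``.

    Height follows h0·exp(−V(s)/(kB·ΔT)) with V the bias accumulated so
    far; widths come from :func:`adaptive_sigma` over ``history`` (the CV
    trace spanning the adaptive window), falling back to ``initial_sigma``.
    """
    state = np.asarray(state, dtype=float)
    V = bias_at(log, state)
    height = params.h0 * math.exp(-V / (params.kb * params.delta_T))
    sigma = adaptive_sigma(history, state, initial_sigma, sigma_floor, sigma_cap)
    return Hill(
        time=time,
        center=(float(state[0]), float(state[1])),
        sigma=sigma,
        height=height,
        bias_factor=params.gamma,
    )


# ---------------------------------------------------------------------------
# toy potentials and Langevin driver


@dataclass(frozen=True)
class ToyPotential:
    """Analytic 2-D potential (kJ/mol) with gradient, for the toy driver."""

    form: str
    params: dict = field(default_factory=dict)

    @classmethod
    def double_well(
        cls,
        barrier: float = 10.0,
        x0: float = 1.0,
        tilt: float = 0.0,
        ky: float = 10.0,
    ) -> "ToyPotential":
        """Quartic double well along x (+ optional linear tilt), harmonic in y.

        U = barrier·((x/x0)² − 1)² + tilt·x + ½·ky·y².  ``tilt`` = 0 gives a
        symmetric well pair; a positive tilt lowers the x < 0 well.
        """
        return cls("double_well", dict(barrier=barrier, x0=x0, tilt=tilt, ky=ky))

    @classmethod
    def harmonic(cls, kx: float = 10.0, ky: float = 10.0) -> "ToyPotential":
        return cls("harmonic", dict(kx=kx, ky=ky))

    def energy(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        x, y = s[..., 0], s[..., 1]
        p = self.params
        if self.form == "double_well":
            return (
                p["barrier"] * ((x / p["x0"]) ** 2 - 1.0) ** 2
                + p["tilt"] * x
                + 0.5 * p["ky"] * y**2
            )
        if self.form == "harmonic":
            return 0.5 * p["kx"] * x**2 + 0.5 * p["ky"] * y**2
        raise ValueError(f"unknown potential form {self.form!r}")

    def gradient(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        x, y = s[..., 0], s[..., 1]
        p = self.params
        if self.form == "double_well":
            gx = 4.0 * p["barrier"] * ((x / p["x0"]) ** 2 - 1.0) * x / p["x0"] ** 2 + p["tilt"]
            gy = p["ky"] * y
        elif self.form == "harmonic":
            gx = p["kx"] * x
            gy = p["ky"] * y
        else:
            raise ValueError(f"unknown potential form {self.form!r}")
        return np.stack([gx, gy], axis=-1)


def run_toy_metad(
    potential: ToyPotential,
    params: WTParams,
    langevin: tuple[float, float, float] = (10.0, 0.05, 300.0),
    n_steps: int = 10_000,
    n_walkers: int = 4,
    seed: int = 0,
    x0: np.ndarray | None = None,
    domain: tuple[tuple[float, float], tuple[float, float]] = ((-4.0, 4.0), (-4.0, 4.0)),
    sample_stride: int = 10,
    initial_sigma: tuple[float, float] = (0.3, 0.3),
    sigma_floor: float = 0.05,
    sigma_cap: float | None = 1.0,
    deposition_steps: int | None = None,
) -> tuple[HillsLog, pd.DataFrame]:
    """Multiple-walker well-tempered metadynamics on a toy 2-D potential.

    Overdamped Langevin dynamics: per step of size dt (ps) with friction ξ
    (kJ mol⁻¹ ps Å⁻²) at temperature T,

        s ← s + (dt/ξ)·(−∇U − ∇V) + sqrt(2 kB T dt/ξ)·η,  η ~ N(0, 1).

    All walkers share one bias; every ``tau_dep`` each walker deposits a
    hill by the well-tempered rule with adaptive widths estimated from its
    trailing ``tau_d`` of CV history.  Identical inputs (including seed)
    give bit-identical outputs.  Returns the hills log and a sample table
    (time_ps, walker, cv1, cv2) recorded every ``sample_stride`` steps.

    ``deposition_steps`` stops hill deposition after that many steps while
    the walkers keep moving under the frozen bias.  A *converged*
    well-tempered bias held fixed leaves the stationary distribution
    P(s) ∝ exp(−F(s)/(kB(T+ΔT))) unchanged, so the post-deposition samples
    are the natural input to :func:`fes_from_histogram`.

    Walkers are confined by reflective walls at the ``domain`` edges; an
    excursion larger than the domain itself raises
    :class:`StabilityError` naming the step (timestep too large for the
    local curvature).
    """
    if n_steps <= 0:
        raise ParameterError("n_steps must be positive")
    friction, dt, T_lang = langevin
    rng = np.random.default_rng(seed)
    if x0 is None:
        # stagger walkers across the middle half of the domain along cv1
        frac = (np.arange(n_walkers) + 0.5) / n_walkers
        px = domain[0][0] + (domain[0][1] - domain[0][0]) * (0.25 + 0.5 * frac)
        py = np.full(n_walkers, (domain[1][0] + domain[1][1]) / 2.0)
        pos = np.stack([px, py], axis=1)
    else:
        pos = np.tile(np.asarray(x0, dtype=float), (n_walkers, 1)).astype(float)
        pos = pos + rng.normal(0.0, 0.05, size=pos.shape)

    steps_per_dep = max(1, int(round(params.tau_dep / dt)))
    window_steps = max(1, int(round(params.tau_d / dt)))
    mobility = dt / friction
    noise_amp = math.sqrt(2.0 * KB * T_lang * dt / friction)

    max_hills = n_walkers * (n_steps // steps_per_dep + 1)
    centers = np.zeros((max_hills, 2))
    sigmas = np.ones((max_hills, 2))
    heights = np.zeros(max_hills)
    times = np.zeros(max_hills)
    walker_of = np.zeros(max_hills, dtype=int)
    m = 0  # hills deposited so far

    history = np.zeros((window_steps, n_walkers, 2))
    history[:] = pos[None, :, :]
    hist_ptr = 0
    hist_fill = 0

    lo0, hi0 = domain[0]
    lo1, hi1 = domain[1]
    samples: list[tuple[float, int, float, float]] = []

    def bias_force_and_V(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if m == 0:
            return np.zeros_like(p), np.zeros(len(p))
        delta = p[:, None, :] - centers[None, :m, :]
        inv_s2 = 1.0 / sigmas[:m] ** 2
        e = np.exp(-0.5 * np.sum(delta**2 * inv_s2[None, :, :], axis=-1))
        V = e @ heights[:m]
        f = np.einsum("wm,wmj->wj", e * heights[None, :m], delta * inv_s2[None, :, :])
        return f, V

    for step in range(1, n_steps + 1):
        fb, _ = bias_force_and_V(pos)
        force = -potential.gradient(pos) + fb
        pos = pos + mobility * force + noise_amp * rng.standard_normal(pos.shape)
        # hard-wall confinement: reflect at the domain edges (Brownian
        # dynamics with reflective boundaries); an excursion larger than
        # the domain itself means the integrator diverged
        for j, (lo, hi) in enumerate(((lo0, hi0), (lo1, hi1))):
            width = hi - lo
            if not np.all(np.isfinite(pos[:, j])) or np.any(
                np.abs(pos[:, j] - np.clip(pos[:, j], lo, hi)) > width
            ):
                raise StabilityError(
                    f"walker diverged at step {step}; reduce dt or soften the potential",
                    step=step,
                )
            over = pos[:, j] > hi
            pos[over, j] = 2 * hi - pos[over, j]
            under = pos[:, j] < lo
            pos[under, j] = 2 * lo - pos[under, j]
        history[hist_ptr] = pos
        hist_ptr = (hist_ptr + 1) % window_steps
        hist_fill = min(hist_fill + 1, window_steps)

        depositing = deposition_steps is None or step <= deposition_steps
        if depositing and step % steps_per_dep == 0:
            t_now = step * dt
            for w in range(n_walkers):
                _, Vw = bias_force_and_V(pos[w : w + 1])
                height = params.h0 * math.exp(-Vw[0] / (params.kb * params.delta_T))
                if hist_fill >= window_steps:
                    sig = adaptive_sigma(
                        history[:, w, :], pos[w], initial_sigma, sigma_floor, sigma_cap
                    )
                else:
                    sig = tuple(
                        float(np.clip(s, sigma_floor, sigma_cap or np.inf))
                        for s in initial_sigma
                    )
                centers[m] = pos[w]
                sigmas[m] = sig
                heights[m] = height
                times[m] = t_now
                walker_of[m] = w
                m += 1

        if step % sample_stride == 0:
            t_now = step * dt
            for w in range(n_walkers):
                samples.append((t_now, w, float(pos[w, 0]), float(pos[w, 1])))

    hills = [
        Hill(
            time=float(times[i]),
            center=(float(centers[i, 0]), float(centers[i, 1])),
            sigma=(float(sigmas[i, 0]), float(sigmas[i, 1])),
            height=float(heights[i]),
            bias_factor=params.gamma,
        )
        for i in range(m)
    ]
    log = HillsLog(hills=hills, walker_ids=[int(w) for w in walker_of[:m]])
    frame = pd.DataFrame(samples, columns=["time_ps", "walker", "cv1", "cv2"])
    return log, frame


def double_well_benchmark(seed: int = 1) -> dict[str, float]:
    """Full deposition→reconstruction loop on the canonical tilted double well.

    The benchmark potential is a quartic double well (barrier 6 kJ/mol,
    minima near ±1) with a linear tilt of 2.837 kJ/mol/unit chosen so the
    Boltzmann-quadrature free-energy difference between the two basins is
    5.0 kJ/mol at 300 K, plus a harmonic transverse coordinate
    (k = 30 kJ/mol/unit²).  Four walkers deposit well-tempered hills
    (γ = 10, h0 = 1.2 kJ/mol, every 10 ps, adaptive widths) for 6 ns, then
    sample a further 18 ns under the frozen bias for the histogram route.

    Returns ``delta_f_reference`` (quadrature), ``delta_f_sum_hills`` and
    ``delta_f_histogram`` (kJ/mol), all computed from scratch.
    """
    pot = ToyPotential.double_well(barrier=6.0, tilt=2.837, ky=30.0)
    params = WTParams()
    kT = params.kb * params.T
    domain = ((-1.9, 1.9), (-2.5, 2.5))

    xq = np.linspace(*domain[0], 1521)
    yq = np.linspace(*domain[1], 2001)
    Xq, Yq = np.meshgrid(xq, yq, indexing="ij")
    w = np.exp(-pot.energy(np.stack([Xq, Yq], axis=-1)) / kT)
    ref = float(-kT * np.log(w[xq >= 0].sum()) + kT * np.log(w[xq < 0].sum()))

    log, samples = run_toy_metad(
        pot, params, langevin=(30.0, 0.2, 300.0), n_steps=120_000,
        n_walkers=4, seed=seed, domain=domain, sigma_floor=0.05,
        sigma_cap=0.5, sample_stride=5, deposition_steps=30_000,
    )
    grid = ((-1.9, 1.9, 77), (-1.5, 1.5, 61))
    dF_hills = well_free_energy_difference(fes_from_hills(log, params, grid))
    frozen = samples[samples.time_ps > 30_000 * 0.2]
    fes_hist = fes_from_histogram(
        frozen[["cv1", "cv2"]].to_numpy(), params, grid, 0.12, final_bias=log
    )
    dF_hist = well_free_energy_difference(fes_hist)
    return {
        "delta_f_reference": ref,
        "delta_f_sum_hills": float(dF_hills),
        "delta_f_histogram": float(dF_hist),
        "n_hills": float(len(log)),
    }


def well_free_energy_difference(
    fes: FESurface, split: float = 0.0, axis: int = 0, kT: float = KB * 300.0
) -> float:
    """ΔF (kJ/mol) between the two basins either side of ``split`` on an axis.

    Basin free energies are −kT·ln Σ exp(−F/kT) over each half of the grid
    (Boltzmann-integrated, robust to single-node noise); returns
    F(high side) − F(low side).
    """
    ax_vals = fes.s1 if axis == 0 else fes.s2
    mask_lo = ax_vals < split
    F = np.where(np.isfinite(fes.F), fes.F, np.inf)
    if axis == 0:
        F_lo, F_hi = F[mask_lo, :], F[~mask_lo, :]
    else:
        F_lo, F_hi = F[:, mask_lo], F[:, ~mask_lo]

    def basin(Fpart: np.ndarray) -> float:
        w = np.exp(-(Fpart[np.isfinite(Fpart)]) / kT)
        return -kT * math.log(w.sum())

    return basin(F_hi) - basin(F_lo)
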