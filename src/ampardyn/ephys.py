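"""Patch-clamp kinetics: desensitization, recovery, fluctuation analysis, RI.

The analyses implemented here are the standard macroscopic-current fits for
ligand-gated channels:

* **Desensitization decay** — one or two exponentials fitted from 90% of
  the peak (falling phase) to the steady state; for biexponential fits the
  amplitude-weighted time constant

      τw,des = τf·Af/(Af+As) + τs·As/(Af+As)

* **Recovery from desensitization** — two-pulse amplitude-vs-interval
  series fitted with a sum of two Hodgkin–Huxley terms

      y = y0 + a1·(1−exp(−x·k1))^m1 + (ymax−a1−y0)·(1−exp(−x·k2))^m2

  with slopes fixed (m1 = 4, m2 = 1) and ymax constrained to 1; the
  weighted recovery tau is (τ1·a1 + τ2·(ymax−a1−y0))/(ymax−y0), τi = 1/ki.

* **Non-stationary fluctuation analysis (NSFA)** — ensemble variance vs
  mean over the desensitizing phase, binned into equal-count amplitude
  bins and fitted with the parabola σ² = i·Ī − Ī²/N (+ background term),
  yielding the single-channel current i, channel count N, chord
  conductance γ = i/Vh and peak open probability Popen = Ī_peak/(N·i).

* **Rectification index** — RI = −(I₊₄₀ − I₀)/(I₋₆₀ − I₀) from ramp
  currents at −60, 0 and +40 mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, ParameterError

__all__ = [
    "Sweep",
    "SweepSet",
    "DecayFit",
    "RecoveryFit",
    "NSFAResult",
    "IVPoints",
    "fit_decay",
    "weighted_tau",
    "fit_recovery",
    "recovery_curve",
    "nsfa",
    "rectification_index",
    "train_ratios",
    "read_sweeps_csv",
    "write_sweeps_csv",
]


@dataclass
class Sweep:
    """One current trace on a uniform time grid (ms, pA)."""

    time: np.ndarray
    current: np.ndarray
    holding_potential: float = -60.0  # mV

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.size < 2 or self.time.shape != self.current.shape:
            raise ValueError("a sweep needs >= 2 samples with matching shapes")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sweep time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class SweepSet:
    """Repeated sweeps sharing one time grid."""

    sweeps: list[Sweep]
    protocol: str = ""

    def __post_init__(self):
        t0 = self.sweeps[0].time
        for s in self.sweeps[1:]:
            if s.time.shape != t0.shape or not np.allclose(s.time, t0):
                raise ValueError("all sweeps must share the time grid")

    def __len__(self) -> int:
        return len(self.sweeps)

    @property
    def time(self) -> np.ndarray:
        return self.sweeps[0].time

    def currents(self) -> np.ndarray:
        """(n_sweeps, n_samples) current matrix."""
        return np.array([s.current for s in self.sweeps])


@dataclass
class DecayFit:
    n_components: int
    tau_f: float  # ms
    tau_s: float | None
    amp_f: float  # pA
    amp_s: float | None
    baseline: float  # pA (fitted steady state)
    tau_w_des: float  # ms
    residual_norm: float
    window: tuple[float, float]  # ms


@dataclass
class RecoveryFit:
    y0: float
    a1: float
    ymax: float
    k1: float  # 1/ms
    k2: float  # 1/ms
    m1: float
    m2: float
    residual_norm: float

    @property
    def tau1(self) -> float:
        return 1.0 / self.k1

    @property
    def tau2(self) -> float:
        return 1.0 / self.k2

    @property
    def tau_w_rec(self) -> float:
        return (self.tau1 * self.a1 + self.tau2 * (self.ymax - self.a1 - self.y0)) / (
            self.ymax - self.y0
        )


@dataclass
class NSFAResult:
    i: float  # single-channel current, pA
    N: float  # channel count
    sigma_o2: float  # background variance, pA^2 (sign per convention used)
    gamma_pS: float  # chord conductance, pS
    popen_peak: float
    holding_potential: float  # mV
    table: pd.DataFrame  # binned (mean_pA, var_pA2, n_samples)
    background_sign: int
    warning: str | None = None


@dataclass(frozen=True)
class IVPoints:
    """Sweep-averaged currents at the three RI voltages (pA)."""

    I_plus40: float
    I_0: float
    I_minus60: float


# ---------------------------------------------------------------------------
# decay fitting


def weighted_tau(tau_f: float, amp_f: float, tau_s: float, amp_s: float) -> float:
    """Amplitude-weighted time constant τf·Af/(Af+As) + τs·As/(Af+As)."""
    total = amp_f + amp_s
    if total == 0:
        raise ZeroDivisionError("total amplitude is zero")
    if tau_f <= 0 or tau_s <= 0:
        raise ParameterError("time constants must be positive")
    return tau_f * amp_f / total + tau_s * amp_s / total


def _multi_exp(t, baseline, amps, taus):
    out = np.full_like(t, baseline, dtype=float)
    for a, tau in zip(amps, taus):
        out += a * np.exp(-t / tau)
    return out


def fit_decay(
    sweep: Sweep,
    n_components: int = 2,
    peak_fraction: float = 0.9,
    window_end: float | None = None,
) -> DecayFit:
    """Exponential fit of the current decay from ``peak_fraction`` of peak.

    The peak is the extremum of |I − baseline₀| (baseline₀ from the first
    samples); the window runs from the first post-peak sample at or below
    ``peak_fraction`` of the peak amplitude to ``window_end`` (ms, default
    end of sweep).  Bounded least squares with three deterministic starts.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t, I = sweep.time, sweep.current
    # the trace median tracks the resting/steady level whether or not a
    # pre-stimulus baseline is present
    base0 = float(np.median(I))
    dev = np.abs(I - base0)
    if dev.max() < 1e-12 or np.ptp(I) < 1e-12:
        raise FitError("flat trace: no peak to fit")
    ipk = int(np.argmax(dev))
    peak_amp = I[ipk] - base0
    thresh = abs(peak_amp) * peak_fraction
    post = np.nonzero(dev[ipk:] <= thresh)[0]
    istart = ipk + (int(post[0]) if len(post) else 0)
    iend = len(t) if window_end is None else int(np.searchsorted(t, window_end, "right"))
    if iend - istart < 10:
        raise FitError("decay window contains fewer than 10 samples")
    tw = t[istart:iend] - t[istart]
    Iw = I[istart:iend]
    span = tw[-1] if tw[-1] > 0 else 1.0
    a0 = Iw[0] - Iw[-1]

    def residuals(p):
        if n_components == 1:
            baseline, a1, lt1 = p
            return _multi_exp(tw, baseline, [a1], [np.exp(lt1)]) - Iw
        baseline, a1, a2, lt1, lt2 = p
        return _multi_exp(tw, baseline, [a1, a2], [np.exp(lt1), np.exp(lt2)]) - Iw

    starts = []
    for f1, f2 in ((0.05, 0.5), (0.02, 0.2), (0.1, 0.9)):
        if n_components == 1:
            starts.append([Iw[-1], a0, np.log(span * f1)])
        else:
            starts.append([Iw[-1], 0.7 * a0, 0.3 * a0, np.log(span * f1), np.log(span * f2)])

    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("decay fit did not converge from any start")

    if n_components == 1:
        baseline, a1, lt1 = best.x
        tau1 = float(np.exp(lt1))
        fit = DecayFit(
            1, tau1, None, float(a1), None, float(baseline), tau1,
            float(np.sqrt(2 * best.cost)), (float(t[istart]), float(t[iend - 1])),
        )
        return fit
    baseline, a1, a2, lt1, lt2 = best.x
    tau1, tau2 = float(np.exp(lt1)), float(np.exp(lt2))
    comps = sorted([(tau1, float(a1)), (tau2, float(a2))])
    (tf, af), (ts, asl) = comps
    tw_des = weighted_tau(tf, af, ts, asl)
    return DecayFit(
        2, tf, ts, af, asl, float(baseline), tw_des,
        float(np.sqrt(2 * best.cost)), (float(t[istart]), float(t[iend - 1])),
    )


# ---------------------------------------------------------------------------
# recovery fitting


def recovery_curve(x, y0, a1, k1, k2, m1=4.0, m2=1.0, ymax=1.0):
    """Sum of two Hodgkin–Huxley terms (see module docstring)."""
    x = np.asarray(x, dtype=float)
    return (
        y0
        + a1 * (1.0 - np.exp(-x * k1)) ** m1
        + (ymax - a1 - y0) * (1.0 - np.exp(-x * k2)) ** m2
    )


def fit_recovery(
    points: np.ndarray | pd.DataFrame,
    m1: float = 4.0,
    m2: float = 1.0,
    ymax: float = 1.0,
) -> RecoveryFit:
    """Fit the two-component Hodgkin–Huxley recovery curve.

    ``points`` is an (n, 2) array or DataFrame of (interval ms, normalized
    amplitude); slopes and ymax are fixed (free parameters y0, a1, k1, k2).
    """
    if isinstance(points, pd.DataFrame):
        pts = points.iloc[:, :2].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): interval_ms, amplitude")
    if len(pts) < 6:
        raise InsufficientDataError("recovery fit needs at least 6 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0) or np.any(np.diff(x) <= 0):
        raise ValueError("intervals must be positive and strictly increasing")

    span = x[-1]

    def residuals(p):
        y0, a1, lk1, lk2 = p
        return recovery_curve(x, y0, a1, np.exp(lk1), np.exp(lk2), m1, m2, ymax) - y

    starts = [
        [max(y[0], 0.0), 0.5, np.log(10.0 / span), np.log(1.0 / span)],
        [0.0, 0.8, np.log(30.0 / span), np.log(3.0 / span)],
        [0.2, 0.3, np.log(5.0 / span), np.log(0.5 / span)],
    ]
    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                residuals,
                p0,
                bounds=([0.0, 0.0, -20.0, -20.0], [1.0, 1.0, 20.0, 20.0]),
                max_nfev=10000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("recovery fit did not converge from any start")
    y0, a1, lk1, lk2 = best.x
    return RecoveryFit(
        float(y0), float(a1), float(ymax), float(np.exp(lk1)), float(np.exp(lk2)),
        m1, m2, float(np.sqrt(2 * best.cost)),
    )


# ---------------------------------------------------------------------------
# non-stationary fluctuation analysis


def nsfa(
    sweeps: SweepSet,
    n_bins: int = 10,
    background_window: tuple[float, float] | None = None,
    holding_potential: float | None = None,
    background_sign: int = +1,
    binning: str = "equal-count",
) -> NSFAResult:
    """Parabolic variance–mean fit over the desensitizing current phase.

    Ensemble mean Ī(t) and variance σ²(t) are computed per sample across
    sweeps from the peak of |Ī| to the end of the sweep, grouped into
    ``n_bins`` amplitude bins (equal sample count by default), and fitted
    with σ² = i·Ī − Ī²/N + sgn·σ_b² by linear least squares (the model is
    linear in i, 1/N and σ_b²).  ``background_sign`` +1 treats the
    baseline variance as additive (default); −1 reproduces the printed
    −σo² convention; the fitted curve is identical, only the reported
    σ_b² flips sign.
    """
    if len(sweeps) < 20:
        raise InsufficientDataError(
            f"NSFA needs >= 20 sweeps, got {len(sweeps)}"
        )
    if background_sign not in (+1, -1):
        raise ValueError("background_sign must be +1 or -1")
    t = sweeps.time
    I = sweeps.currents()
    mean = I.mean(axis=0)
    var = I.var(axis=0, ddof=1)
    if float(var.max()) < 1e-15:
        raise FitError("all sweeps identical: zero ensemble variance")
    vh = (
        holding_potential
        if holding_potential is not None
        else sweeps.sweeps[0].holding_potential
    )

    ipk = int(np.argmax(np.abs(mean)))
    sel = slice(ipk, len(t))
    if background_window is not None:
        # subtract the measured baseline variance before fitting
        b0, b1 = background_window
        bmask = (t >= b0) & (t <= b1)
        if not bmask.any():
            raise ValueError("background window contains no samples")
        var = var - float(var[bmask].mean())

    m_sel = mean[sel]
    v_sel = var[sel]

    order = np.argsort(np.abs(m_sel))
    m_sorted, v_sorted = m_sel[order], v_sel[order]
    if binning == "equal-count":
        idx = np.array_split(np.arange(len(m_sorted)), n_bins)
    elif binning == "equal-width":
        edges = np.linspace(np.abs(m_sorted).min(), np.abs(m_sorted).max(), n_bins + 1)
        which = np.clip(np.digitize(np.abs(m_sorted), edges) - 1, 0, n_bins - 1)
        idx = [np.nonzero(which == b)[0] for b in range(n_bins)]
    else:
        raise ValueError("binning must be 'equal-count' or 'equal-width'")
    rows = [
        (float(m_sorted[ii].mean()), float(v_sorted[ii].mean()), len(ii))
        for ii in idx
        if len(ii) > 0
    ]
    table = pd.DataFrame(rows, columns=["mean_pA", "var_pA2", "n_samples"])

    # sigma^2 = i*mean - mean^2 * (1/N) + c  -- linear in (i, 1/N, c)
    A = np.column_stack(
        [table.mean_pA, -table.mean_pA**2, np.ones(len(table))]
    )
    coef, *_ = np.linalg.lstsq(A, table.var_pA2.to_numpy(), rcond=None)
    i_unit, inv_N, c = (float(v) for v in coef)

    warn = None
    if inv_N <= 0:
        warn = "variance-mean relation is not concave: 1/N fitted non-positive"
        N = float("inf")
    else:
        N = 1.0 / inv_N
    sigma_o2 = background_sign * c

    gamma_pS = (i_unit / vh) * 1000.0 if vh != 0 else float("nan")
    peak_mean = float(mean[ipk])
    popen = peak_mean / (N * i_unit) if np.isfinite(N) and i_unit != 0 else float("nan")
    return NSFAResult(
        i=i_unit,
        N=N,
        sigma_o2=float(sigma_o2),
        gamma_pS=float(gamma_pS),
        popen_peak=float(popen),
        holding_potential=float(vh),
        table=table,
        background_sign=background_sign,
        warning=warn,
    )


# ---------------------------------------------------------------------------
# rectification and trains


def rectification_index(iv: IVPoints) -> float:
    """RI = −(I₊₄₀ − I₀)/(I₋₆₀ − I₀)."""
    denom = iv.I_minus60 - iv.I_0
    if denom == 0:
        raise ZeroDivisionError("I(-60 mV) equals I(0 mV): RI undefined")
    return -(iv.I_plus40 - iv.I_0) / denom


def train_ratios(peaks: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Normalize per-pulse peaks to P1 and report Pk/P1 summary ratios.

    Returns the P1-normalized series and a dict with ``P5/P1`` when the
    train has at least five pulses (plus ``Pn/P1`` for the last pulse).
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("a train needs at least 2 pulses")
    if peaks[0] == 0:
        raise ZeroDivisionError("first pulse amplitude is zero")
    norm = peaks / peaks[0]
    ratios: dict[str, float] = {f"P{len(peaks)}/P1": float(norm[-1])}
    if len(peaks) >= 5:
        ratios["P5/P1"] = float(norm[4])
    return norm, ratios


# ---------------------------------------------------------------------------
# CSV I/O


def read_sweeps_csv(path: str | Path, holding_potential: float = -60.0) -> SweepSet:
    """Read sweeps from CSV with columns time_ms, current_pA, sweep_id."""
    df = pd.read_csv(path)
    required = {"time_ms", "current_pA", "sweep_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"sweep CSV needs columns {sorted(required)}")
    sweeps = []
    for _, grp in df.groupby("sweep_id", sort=True):
        sweeps.append(
            Sweep(
                grp.time_ms.to_numpy(),
                grp.current_pA.to_numpy(),
                holding_potential=holding_potential,
            )
        )
    return SweepSet(sweeps)


def write_sweeps_csv(sweeps: SweepSet, path: str | Path) -> None:
    frames = []
    for k, s in enumerate(sweeps.sweeps):
        frames.append(
            pd.DataFrame(
                {"time_ms": s.time, "current_pA": s.current, "sweep_id": k}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
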