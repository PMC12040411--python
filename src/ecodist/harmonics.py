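"""Harmonic regression of seasonal time series and amplitude/phase descriptors.

Each pixel's time series of a seasonal variable is fit by ordinary least
squares in the basis

    S(t) = b0 + b1*t + sum_j [ b2_j cos(w_j t) + b3_j sin(w_j t) ] + e(t)

with t in fractional years and J harmonics. In the default
``per-year-multiples`` frequency convention w_j = 2*pi*j per year (the j-th
harmonic completes j cycles per year, so higher harmonics capture
within-year multi-cycle behaviour such as double cropping). The alternative
``literal-reciprocal`` convention uses w_j = 2*pi/j per year (periods of
j years). Each harmonic yields an amplitude A_j = sqrt(b2_j^2 + b3_j^2) and
a phase P_j = atan2(b3_j, b2_j) in (-pi, pi].

Per-pixel amplitude/phase estimates are averaged to ecoregion level, and
amplitudes are min–max scaled to [0, 1] per variable across ecoregions so
that variables with different units contribute comparably to downstream
dissimilarity indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "HarmonicFit",
    "HarmonicDescriptor",
    "fit_harmonic",
    "amplitude_phase",
    "descriptor_set",
    "descriptor_sets",
    "scale_amplitudes",
    "descriptors_to_frame",
    "frame_to_descriptors",
]

FREQUENCY_MODES = ("per-year-multiples", "literal-reciprocal")


@dataclass(frozen=True)
class HarmonicFit:
    """OLS solution of the harmonic model for one series.

    ``frequencies`` are in cycles per year; ``beta2``/``beta3`` are the
    cosine/sine coefficients per harmonic; ``residual_sd`` is the root mean
    square residual with degrees-of-freedom correction when n allows it.
    """

    beta0: float
    beta1: float
    beta2: np.ndarray
    beta3: np.ndarray
    J: int
    frequencies: np.ndarray
    residual_sd: float
    n_obs: int


@dataclass
class HarmonicDescriptor:
    """Ecoregion-level amplitude/phase summary.

    ``amplitude`` and ``phase`` are (I, J) arrays over I variables and J
    harmonics — I*J*2 scalar descriptors in total. ``scaled`` records
    whether amplitudes have been min–max scaled across ecoregions.
    """

    ecoregion_id: str
    variables: list[str]
    amplitude: np.ndarray
    phase: np.ndarray
    scaled: bool = False

    @property
    def J(self) -> int:
        return self.amplitude.shape[1]

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, float)
        self.phase = np.asarray(self.phase, float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if self.amplitude.shape[0] != len(self.variables):
            raise ValueError("first descriptor axis must match variable list")


def _frequencies(J: int, frequency_mode: str) -> np.ndarray:
    if frequency_mode not in FREQUENCY_MODES:
        raise ValueError(
            f"frequency_mode must be one of {FREQUENCY_MODES}, got {frequency_mode!r}"
        )
    j = np.arange(1, J + 1, dtype=float)
    return j if frequency_mode == "per-year-multiples" else 1.0 / j


def _design(times: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(times), times]
    names = ["intercept", "trend"]
    for j, f in enumerate(freqs, start=1):
        w = 2 * np.pi * f
        cols.append(np.cos(w * times))
        names.append(f"cos(harmonic {j})")
    for j, f in enumerate(freqs, start=1):
        w = 2 * np.pi * f
        cols.append(np.sin(w * times))
        names.append(f"sin(harmonic {j})")
    return np.column_stack(cols), names


def fit_harmonic(
    times,
    values,
    J: int = 2,
    frequency_mode: str = "per-year-multiples",
) -> HarmonicFit:
    """Least-squares harmonic fit of one series.

    ``times`` are fractional years; requires n_obs >= 2 + 2J finite
    observations and a full-rank design (times that alias a harmonic raise
    ``ValueError`` naming the collinear column).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")
    if J < 1:
        raise ValueError("J must be >= 1")
    n_par = 2 + 2 * J
    if t.size < n_par:
        raise ValueError(f"need at least {n_par} observations for J={J}, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("times must not all be equal")

    freqs = _frequencies(J, frequency_mode)
    X, names = _design(t, freqs)

    # QR-based rank check so an aliased harmonic fails loudly, naming itself.
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    bad = np.nonzero(diag < max(tol, 1e-10 * diag.max()))[0]
    if bad.size:
        raise ValueError(
            f"rank-deficient harmonic design: column {names[bad[0]]!r} is "
            "collinear with earlier columns (times alias this term)"
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = t.size - n_par
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return HarmonicFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=beta[2 : 2 + J].copy(),
        beta3=beta[2 + J :].copy(),
        J=J,
        frequencies=freqs,
        residual_sd=residual_sd,
        n_obs=int(t.size),
    )


def amplitude_phase(fit: HarmonicFit) -> list[tuple[float, float]]:
    """Per-harmonic (amplitude, phase) pairs.

    Amplitude is sqrt(b2^2 + b3^2); phase is the quadrant-aware two-argument
    arctangent of (b3, b2) mapped into (-pi, pi], with (0, 0) -> 0.
    """
    out = []
    for b2, b3 in zip(fit.beta2, fit.beta3):
        a = float(np.hypot(b2, b3))
        p = 0.0 if a == 0.0 else float(np.arctan2(b3, b2))
        if p == -np.pi:
            p = np.pi
        out.append((a, p))
    return out


def _circular_mean(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    s = np.sin(angles).mean(axis=axis)
    c = np.cos(angles).mean(axis=axis)
    return np.arctan2(s, c)


def descriptor_set(
    series: pd.DataFrame,
    J: int = 2,
    frequency_mode: str = "per-year-multiples",
    phase_average: str = "arithmetic",
) -> HarmonicDescriptor:
    """Fit every (pixel, variable) series of one ecoregion and average.

    ``series`` is long-form with columns ``ecoregion_id``, ``pixel_id``,
    ``variable``, ``time_years``, ``value`` and a single ecoregion id.
    Amplitudes are averaged arithmetically across pixels; phases are averaged
    arithmetically by default (``phase_average='circular'`` uses the mean
    resultant direction instead). A failing pixel fit re-raises with the
    pixel and variable identified.
    """
    if phase_average not in ("arithmetic", "circular"):
        raise ValueError(f"unknown phase_average {phase_average!r}")
    eco_ids = series["ecoregion_id"].unique()
    if len(eco_ids) != 1:
        raise ValueError(f"expected a single ecoregion, got {sorted(eco_ids)}")
    variables = sorted(series["variable"].unique())
    pixels = sorted(series["pixel_id"].unique())

    amp = np.empty((len(pixels), len(variables), J))
    phs = np.empty_like(amp)
    grouped = dict(iter(series.groupby(["pixel_id", "variable"], sort=False)))
    for pi, px in enumerate(pixels):
        for vi, var in enumerate(variables):
            try:
                grp = grouped[(px, var)]
            except KeyError:
                raise ValueError(f"pixel {px!r} has no series for {var!r}") from None
            try:
                fit = fit_harmonic(
                    grp["time_years"].to_numpy(),
                    grp["value"].to_numpy(),
                    J=J,
                    frequency_mode=frequency_mode,
                )
            except ValueError as err:
                raise ValueError(f"pixel {px!r}, variable {var!r}: {err}") from err
            for j, (a, p) in enumerate(amplitude_phase(fit)):
                amp[pi, vi, j] = a
                phs[pi, vi, j] = p

    mean_amp = amp.mean(axis=0)
    mean_phs = (
        phs.mean(axis=0) if phase_average == "arithmetic" else _circular_mean(phs)
    )
    return HarmonicDescriptor(
        ecoregion_id=str(eco_ids[0]),
        variables=variables,
        amplitude=mean_amp,
        phase=mean_phs,
        scaled=False,
    )


def descriptor_sets(
    series: pd.DataFrame,
    J: int = 2,
    frequency_mode: str = "per-year-multiples",
    phase_average: str = "arithmetic",
) -> list[HarmonicDescriptor]:
    """One :func:`descriptor_set` per ecoregion in a long-form series table."""
    return [
        descriptor_set(grp, J=J, frequency_mode=frequency_mode,
                       phase_average=phase_average)
        for _, grp in series.groupby("ecoregion_id", sort=True)
    ]


def scale_amplitudes(
    descriptors: list[HarmonicDescriptor],
    mode: str = "per-variable",
) -> list[HarmonicDescriptor]:
    """Min–max scale amplitudes to [0, 1] across ecoregions.

    Default pools both harmonics of a variable when computing its min and
    max; ``mode='per-variable-harmonic'`` scales each (variable, harmonic)
    cell separately. A degenerate range (max == min) maps to 0. Phases are
    untouched. Requires at least two descriptors.
    """
    if not descriptors:
        raise ValueError("no descriptors to scale")
    if len(descriptors) < 2:
        raise ValueError("amplitude scaling needs descriptors from >= 2 ecoregions")
    if mode not in ("per-variable", "per-variable-harmonic"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    ref_vars = descriptors[0].variables
    for d in descriptors[1:]:
        if d.variables != ref_vars or d.amplitude.shape != descriptors[0].amplitude.shape:
            raise ValueError("descriptors must share variables and harmonic count")

    stack = np.stack([d.amplitude for d in descriptors])  # (K, I, J)
    if mode == "per-variable":
        lo = stack.min(axis=(0, 2), keepdims=True)
        hi = stack.max(axis=(0, 2), keepdims=True)
    else:
        lo = stack.min(axis=0, keepdims=True)
        hi = stack.max(axis=0, keepdims=True)
    span = hi - lo
    scaled = np.where(span > 0, (stack - lo) / np.where(span > 0, span, 1.0), 0.0)
    return [
        replace(d, amplitude=scaled[i].copy(), phase=d.phase.copy(), scaled=True)
        for i, d in enumerate(descriptors)
    ]


def descriptors_to_frame(
    raw: list[HarmonicDescriptor],
    scaled: list[HarmonicDescriptor] | None = None,
) -> pd.DataFrame:
    """Long-form descriptor table (one row per ecoregion, variable, harmonic)."""
    scaled_by_id = {d.ecoregion_id: d for d in scaled} if scaled else {}
    rows = []
    for d in raw:
        s = scaled_by_id.get(d.ecoregion_id)
        for vi, var in enumerate(d.variables):
            for j in range(d.J):
                rows.append(
                    {
                        "ecoregion_id": d.ecoregion_id,
                        "variable": var,
                        "harmonic": j + 1,
                        "amplitude_raw": d.amplitude[vi, j],
                        "amplitude_scaled": (
                            s.amplitude[vi, j] if s is not None else np.nan
                        ),
                        "phase_radians": d.phase[vi, j],
                    }
                )
    return pd.DataFrame(rows)


def frame_to_descriptors(
    frame: pd.DataFrame, amplitude: str = "amplitude_scaled"
) -> list[HarmonicDescriptor]:
    """Rebuild descriptor objects from a long-form table.

    ``amplitude`` selects which amplitude column to load; loading the scaled
    column marks the descriptors as scaled.
    """
    out = []
    for eco_id, grp in frame.groupby("ecoregion_id", sort=True):
        piv_a = grp.pivot(index="variable", columns="harmonic", values=amplitude)
        piv_p = grp.pivot(index="variable", columns="harmonic", values="phase_radians")
        piv_a = piv_a.sort_index()
        piv_p = piv_p.reindex(piv_a.index)
        out.append(
            HarmonicDescriptor(
                ecoregion_id=str(eco_id),
                variables=list(piv_a.index),
                amplitude=piv_a.to_numpy(float),
                phase=piv_p.to_numpy(float),
                scaled=(amplitude == "amplitude_scaled"),
            )
        )
    return out
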