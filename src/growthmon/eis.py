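"""Equivalent-circuit model of an impedimetric cell-growth sensor.

The sensor (interdigitated electrodes under a thin passivation layer, in a
culture chamber) is modelled as a series resistance for the culture medium,
``R_med``, in series with two parallel RC branches: one lumping the attached
cell monolayer (``R_cell``, ``C_cell``) and one lumping the passivated
electrode (``R_el``, ``C_el``)::

    Z(f) = R_med + R_cell / (1 + i 2*pi*f R_cell C_cell)
                 + R_el  / (1 + i 2*pi*f R_el  C_el)

``C_cell`` grows with the number of attached cells, so its fitted time course
is the impedance-derived growth readout.  Spectra are fitted by complex
nonlinear least squares on the stacked real and imaginary parts, in
log-parameter space (positivity for free), with per-frequency modulus
weighting by default.

Sign convention: ``z.imag`` is stored as the mathematical imaginary part,
which is negative for this capacitive topology.  Presentation layers may
plot ``-Im(Z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FREQ_BAND_HZ",
    "READOUT_FREQUENCIES_HZ",
    "DEFAULT_EXCITATION_V",
    "CircuitParameters",
    "ImpedanceSpectrum",
    "FitOptions",
    "FitResult",
    "SeriesFit",
    "circuit_impedance",
    "spectrum_components",
    "residual_norm",
    "initial_guess",
    "fit_circuit",
    "fit_series",
]

#: Measurement band of the frequency sweep (Hz).  Tens of kHz sit in the
#: beta-dispersion region where intact cell membranes polarize, which is why
#: the band is capped at 100 kHz.
FREQ_BAND_HZ: tuple[float, float] = (5e3, 100e3)

#: Convenience frequencies at which single-frequency readouts are reported.
READOUT_FREQUENCIES_HZ: tuple[float, float, float] = (10e3, 50e3, 90e3)

#: Excitation amplitude of the AC sweep (volts).
DEFAULT_EXCITATION_V: float = 0.01

PARAM_NAMES: tuple[str, ...] = ("r_med", "r_cell", "c_cell", "r_el", "c_el")

#: Resistance (ohm) treated as "branch absent" when a calibration spectrum
#: is fitted without a cell contribution.
NEGLIGIBLE_RESISTANCE_OHM: float = 1e-6


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class CircuitParameters:
    """The five lumped circuit quantities, all strictly positive.

    Resistances in ohm, capacitances in farad.  ``c_cell`` is the growth
    readout; ``r_el``/``c_el`` describe the passivated electrode and are
    physically constant over a cultivation.
    """

    r_med: float
    r_cell: float
    c_cell: float
    r_el: float
    c_el: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            _require_positive(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "CircuitParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def replace(self, **kwargs: float) -> "CircuitParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One frequency sweep: frequencies (Hz) and complex impedance (ohm).

    Points are sorted ascending by frequency on construction, so downstream
    consumers may rely on a strictly increasing grid.  ``timepoint`` is the
    cultivation time in hours, if known.
    """

    frequencies: np.ndarray
    z: np.ndarray
    excitation_amplitude: float = DEFAULT_EXCITATION_V
    timepoint: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if z.shape != f.shape:
            raise ValueError(
                f"z has shape {z.shape} but frequencies has shape {f.shape}"
            )
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValueError("frequencies must all be positive and finite")
        order = np.argsort(f)
        f = f[order]
        z = z[order]
        if np.any(np.diff(f) == 0):
            raise ValueError("frequencies contain duplicates")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def modulus(self) -> np.ndarray:
        """|Z| = sqrt(Re^2 + Im^2)."""
        return np.abs(self.z)

    @property
    def real(self) -> np.ndarray:
        return self.z.real

    @property
    def imag(self) -> np.ndarray:
        return self.z.imag


def circuit_impedance(
    params: CircuitParameters, frequency: float | np.ndarray
) -> complex | np.ndarray:
    """Complex impedance of the three-branch topology at ``frequency`` (Hz).

    Vectorizes over frequency arrays.  Raises ``ValueError`` for non-positive
    frequencies, naming the offending input.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("frequency must be strictly positive and finite")
    jw = 2j * np.pi * f
    z = (
        params.r_med
        + params.r_cell / (1.0 + jw * params.r_cell * params.c_cell)
        + params.r_el / (1.0 + jw * params.r_el * params.c_el)
    )
    if np.isscalar(frequency):
        return complex(z)
    return z


def spectrum_components(
    spectrum: ImpedanceSpectrum,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (|Z|, Re, Im) arrays aligned with ``spectrum.frequencies``."""
    if len(spectrum) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("empty spectrum")
    return spectrum.modulus, spectrum.real, spectrum.imag


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the complex nonlinear least-squares fit.

    ``weighting`` is ``"modulus"`` (each Re/Im pair divided by the measured
    |Z| at that frequency, so all decades of the band contribute comparably)
    or ``"unit"``.
    """

    weighting: str = "modulus"
    tol: float = 1e-10
    max_nfev: int = 5000

    def __post_init__(self) -> None:
        if self.weighting not in ("modulus", "unit"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one spectrum fit."""

    params: CircuitParameters
    residual_norm: float
    per_point_residuals: np.ndarray
    converged: bool
    fixed_mask: tuple[str, ...]
    nfev: int = 0

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed_mask)


def _weights(spectrum: ImpedanceSpectrum, weighting: str) -> np.ndarray:
    if weighting == "modulus":
        mod = spectrum.modulus
        if np.any(mod == 0):
            raise ValueError("modulus weighting undefined: |Z| = 0 at some point")
        return 1.0 / mod
    return np.ones(len(spectrum))


def _stacked_residuals(
    spectrum: ImpedanceSpectrum, params: CircuitParameters, w: np.ndarray
) -> np.ndarray:
    z_model = circuit_impedance(params, spectrum.frequencies)
    return np.concatenate(
        [w * (z_model.real - spectrum.real), w * (z_model.imag - spectrum.imag)]
    )


def residual_norm(
    spectrum: ImpedanceSpectrum,
    params: CircuitParameters,
    weighting: str = "modulus",
) -> float:
    """Euclidean norm of the weighted stacked (Re, Im) residual vector."""
    w = _weights(spectrum, weighting)
    return float(np.linalg.norm(_stacked_residuals(spectrum, params, w)))


def initial_guess(spectrum: ImpedanceSpectrum) -> CircuitParameters:
    """Heuristic starting point when the caller supplies none.

    High-frequency Re approximates ``R_med`` (both capacitors short); the
    low-frequency Re approximates the series total; the branch resistance is
    split 2:1 between cell and electrode; each capacitance is set so that the
    branch corner frequency sits at the frequency of extremal Im.
    """
    re = spectrum.real
    r_med = max(float(re[-1]), 1e-3)
    total = max(float(re[0]), r_med * (1 + 1e-6))
    branch = max(total - r_med, 1e-3)
    r_cell = 2.0 * branch / 3.0
    r_el = branch / 3.0
    f_peak = float(spectrum.frequencies[np.argmax(np.abs(spectrum.imag))])
    c_cell = 1.0 / (2.0 * np.pi * f_peak * r_cell)
    c_el = 1.0 / (2.0 * np.pi * f_peak * r_el)
    return CircuitParameters(r_med, r_cell, c_cell, r_el, c_el)


def fit_circuit(
    spectrum: ImpedanceSpectrum,
    init: CircuitParameters | None = None,
    fixed: Iterable[str] = (),
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the circuit to one spectrum by weighted complex least squares.

    Parameters named in ``fixed`` are held at their ``init`` values.  Free
    parameters are optimized in log space (trust-region reflective), which
    enforces positivity without explicit bounds.  Non-convergence is reported
    through ``converged=False``, never silently.
    """
    options = options or FitOptions()
    fixed = tuple(fixed)
    unknown = set(fixed) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names in fixed: {sorted(unknown)}")
    if init is None:
        init = initial_guess(spectrum)

    free_idx = [i for i, n in enumerate(PARAM_NAMES) if n not in fixed]
    n_points = len(spectrum)
    if n_points < len(free_idx):
        raise ValueError(
            f"{n_points} spectrum points cannot determine {len(free_idx)} free parameters"
        )
    f = spectrum.frequencies
    if len(free_idx) > 0 and f[-1] / f[0] < 10.0 and not (
        f[0] <= FREQ_BAND_HZ[0] * 1.001 and f[-1] >= FREQ_BAND_HZ[1] * 0.999
    ):
        raise ValueError(
            "spectrum must span at least one frequency decade (or the full "
            f"{FREQ_BAND_HZ[0]:.0f}-{FREQ_BAND_HZ[1]:.0f} Hz band) to be fittable"
        )

    w = _weights(spectrum, options.weighting)
    base = init.as_array()

    if not free_idx:
        rn = residual_norm(spectrum, init, options.weighting)
        return FitResult(init, rn, _stacked_residuals(spectrum, init, w), True, fixed)

    def unpack(x_log: np.ndarray) -> CircuitParameters:
        vals = base.copy()
        vals[free_idx] = np.exp(x_log)
        return CircuitParameters.from_array(vals)

    def fun(x_log: np.ndarray) -> np.ndarray:
        return _stacked_residuals(spectrum, unpack(x_log), w)

    x0 = np.log(base[free_idx])
    sol = least_squares(
        fun,
        x0,
        method="trf",
        xtol=options.tol,
        ftol=options.tol,
        gtol=options.tol,
        max_nfev=options.max_nfev,
    )
    fitted = unpack(sol.x)
    res = _stacked_residuals(spectrum, fitted, w)
    init_rn = residual_norm(spectrum, init, options.weighting)
    rn = float(np.linalg.norm(res))
    # Trust-region steps never accept an ascent, but guard against a
    # pathological first evaluation anyway.
    if rn > init_rn:
        fitted, res, rn = init, _stacked_residuals(spectrum, init, w), init_rn
    return FitResult(
        params=fitted,
        residual_norm=rn,
        per_point_residuals=res,
        converged=bool(sol.status > 0),
        fixed_mask=fixed,
        nfev=int(sol.nfev),
    )


@dataclass(frozen=True)
class SeriesFit:
    """Per-timepoint circuit fits with a shared, pinned electrode branch."""

    timepoints: np.ndarray
    results: tuple[FitResult, ...]
    r_el: float
    c_el: float

    def c_cell(self) -> np.ndarray:
        return np.array([r.params.c_cell for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per timepoint."""
        return pd.DataFrame(
            {
                "timepoint_h": self.timepoints,
                "r_med_ohm": [r.params.r_med for r in self.results],
                "r_cell_ohm": [r.params.r_cell for r in self.results],
                "c_cell_f": [r.params.c_cell for r in self.results],
                "r_el_ohm": [r.params.r_el for r in self.results],
                "c_el_f": [r.params.c_el for r in self.results],
                "residual_norm": [r.residual_norm for r in self.results],
                "converged": [r.converged for r in self.results],
            }
        )


def fit_electrode_calibration(
    calibration: ImpedanceSpectrum, options: FitOptions | None = None
) -> tuple[float, float]:
    """Determine (R_el, C_el) from a cell-free calibration sweep.

    The cell branch is pinned to a negligible resistance so the electrode
    branch is identified unambiguously (the two parallel RC branches are
    otherwise exchangeable).
    """
    guess = initial_guess(calibration)
    init = guess.replace(
        r_cell=NEGLIGIBLE_RESISTANCE_OHM,
        # With r_cell negligible the cell branch impedance vanishes for any
        # capacitance; keep a sane value.
        c_cell=guess.c_cell,
        r_el=guess.r_cell + guess.r_el,
    )
    res = fit_circuit(calibration, init=init, fixed=("r_cell", "c_cell"), options=options)
    return res.params.r_el, res.params.c_el


def fit_series(
    spectra: Sequence[ImpedanceSpectrum],
    electrode_calibration: ImpedanceSpectrum | None = None,
    electrode_params: tuple[float, float] | Mapping[str, float] | None = None,
    init: CircuitParameters | None = None,
    options: FitOptions | None = None,
) -> SeriesFit:
    """Fit a time series of sweeps with the electrode branch held constant.

    The passivated electrode does not change over a cultivation, so
    ``R_el``/``C_el`` are determined once — from ``electrode_calibration``
    (a cell-free or 0 h sweep) or supplied directly as ``electrode_params``
    — and fixed for every timepoint, leaving ``R_med``, ``R_cell`` and
    ``C_cell`` free per sweep.  Successive fits are warm-started from the
    previous timepoint.
    """
    if not spectra:
        raise ValueError("fit_series needs at least one spectrum")
    if electrode_params is not None:
        if isinstance(electrode_params, Mapping):
            r_el, c_el = float(electrode_params["r_el"]), float(electrode_params["c_el"])
        else:
            r_el, c_el = map(float, electrode_params)
        _require_positive("r_el", r_el)
        _require_positive("c_el", c_el)
    elif electrode_calibration is not None:
        r_el, c_el = fit_electrode_calibration(electrode_calibration, options)
    else:
        raise ValueError(
            "electrode branch is unconstrained: pass electrode_params=(r_el, c_el) "
            "or electrode_calibration=<cell-free ImpedanceSpectrum>"
        )

    order = sorted(
        range(len(spectra)),
        key=lambda i: (
            spectra[i].timepoint if spectra[i].timepoint is not None else float(i)
        ),
    )
    timepoints = np.array(
        [
            spectra[i].timepoint if spectra[i].timepoint is not None else float(i)
            for i in order
        ]
    )

    results: list[FitResult] = []
    prev: CircuitParameters | None = None
    for i in order:
        sp = spectra[i]
        if prev is not None:
            start = prev
        elif init is not None:
            start = init.replace(r_el=r_el, c_el=c_el)
        else:
            start = initial_guess(sp).replace(r_el=r_el, c_el=c_el)
        res = fit_circuit(sp, init=start, fixed=("r_el", "c_el"), options=options)
        results.append(res)
        prev = res.params
    return SeriesFit(
        timepoints=timepoints, results=tuple(results), r_el=r_el, c_el=c_el
    )
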