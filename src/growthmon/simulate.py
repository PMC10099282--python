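"""Ground-truthed synthetic data for every stage of the monitoring workflow.

Three generators, all bit-reproducible under a fixed seed:

* ``simulate_growth_curve`` — a four-phase adherent-cell capacitance
  trajectory (lag, logistic exponential rise, stationary plateau, exponential
  decline after nutrient exhaustion), continuous at every phase junction.
* ``simulate_spectrum`` — the lumped-circuit forward model with independent
  relative Gaussian noise on the real and imaginary parts.
* ``render_culture_image`` — a grayscale culture image of soft-edged,
  textured elliptical cells (fibroblast-like eccentricity) on a noisy,
  gradient-shaded background, with the true covered-area mask returned
  alongside.  ``debris_mode`` scatters small high-contrast fragments that are
  *not* counted in the truth mask, emulating the detached-cell debris that
  corrupts image-based confluence after the dying phase begins.

``simulate_experiment`` bundles the three into a full cultivation: one noisy
sweep per timepoint driven by the capacitance trajectory with a constant
electrode branch, a cell-free calibration sweep, and replicate rendered
images whose target coverage tracks cell density before the dying onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .eis import (
    FREQ_BAND_HZ,
    CircuitParameters,
    ImpedanceSpectrum,
    circuit_impedance,
)

__all__ = [
    "GrowthSimParams",
    "SpectrumNoise",
    "ImageSimParams",
    "SyntheticExperiment",
    "default_frequencies",
    "simulate_growth_curve",
    "simulate_spectrum",
    "render_culture_image",
    "simulate_experiment",
    "DEFAULT_CIRCUIT",
]

#: Circuit at the stationary plateau.  Corner frequencies of both branches
#: (~16 kHz cell, ~3 kHz electrode) sit in or near the 5-100 kHz sweep band,
#: which is what makes the five parameters identifiable from one sweep.
DEFAULT_CIRCUIT = CircuitParameters(
    r_med=100.0, r_cell=1000.0, c_cell=10e-9, r_el=500.0, c_el=100e-9
)


def default_frequencies(n: int = 30) -> np.ndarray:
    """Log-spaced sweep over the measurement band."""
    return np.logspace(
        math.log10(FREQ_BAND_HZ[0]), math.log10(FREQ_BAND_HZ[1]), n
    )


@dataclass(frozen=True)
class GrowthSimParams:
    """Four-phase capacitance trajectory parameters.

    The defaults describe a 96 h cultivation with limited nutrients: flat
    baseline through a 12 h lag, logistic rise to the plateau by 48 h,
    stationary until the dying onset at 60 h, then exponential decline as
    cells detach.
    """

    c_cell_baseline: float = 2e-9
    c_cell_max: float = 20e-9
    lag_end: float = 12.0
    exp_rate: float = 0.15
    stationary_start: float = 48.0
    dying_onset: float = 60.0
    dying_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.c_cell_baseline < self.c_cell_max:
            raise ValueError("need 0 < c_cell_baseline < c_cell_max")
        if not 0 <= self.lag_end < self.stationary_start < self.dying_onset:
            raise ValueError(
                "phase ordering must satisfy 0 <= lag_end < stationary_start < dying_onset"
            )
        if self.exp_rate <= 0 or self.dying_rate < 0:
            raise ValueError("exp_rate must be > 0 and dying_rate >= 0")


@dataclass(frozen=True)
class SpectrumNoise:
    """Independent relative Gaussian noise on Re and Im, seeded."""

    relative_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")


@dataclass(frozen=True)
class ImageSimParams:
    """Rendering parameters for one synthetic culture image.

    Cells are ellipses with minor semi-axis drawn from ``cell_axis_range``
    (pixels) and aspect ratio from ``cell_eccentricity_range`` (elongated,
    fibroblast-like).  ``cell_contrast`` is the interior intensity offset
    below the background; ``illumination_gradient`` is the peak-to-peak
    fraction of a linear shading ramp.  ``debris_coverage`` only applies when
    ``debris_mode`` is on and controls how much fragment area is scattered
    outside the truth mask.
    """

    size: tuple[int, int] = (256, 256)
    target_coverage: float = 30.0
    cell_axis_range: tuple[float, float] = (10.0, 16.0)
    cell_eccentricity_range: tuple[float, float] = (2.0, 5.0)
    background_level: float = 0.55
    cell_contrast: float = 0.30
    noise_sd: float = 0.005
    illumination_gradient: float = 0.08
    debris_mode: bool = False
    debris_coverage: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_coverage < 100:
            raise ValueError("target_coverage must be in (0, 100)")
        if min(self.size) < 64:
            raise ValueError("image size must be at least 64x64")


def simulate_growth_curve(
    params: GrowthSimParams, timepoints: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """C_cell(t) and normalized cell density over ``timepoints`` (hours).

    Piecewise form, continuous at every junction: baseline through
    ``lag_end``; a logistic segment rescaled to start exactly at baseline and
    reach exactly ``c_cell_max`` at ``stationary_start``; plateau until
    ``dying_onset``; exponential decay toward baseline after.  Density is the
    capacitance excess over baseline, normalized to [0, 1].
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    lo, hi = params.c_cell_baseline, params.c_cell_max
    t_mid = 0.5 * (params.lag_end + params.stationary_start)

    def logistic(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-params.exp_rate * (x - t_mid)))

    l0, l1 = logistic(np.array([params.lag_end, params.stationary_start]))
    c = np.empty_like(t)
    lag = t <= params.lag_end
    rise = (t > params.lag_end) & (t <= params.stationary_start)
    plateau = (t > params.stationary_start) & (t <= params.dying_onset)
    dying = t > params.dying_onset
    c[lag] = lo
    c[rise] = lo + (hi - lo) * (logistic(t[rise]) - l0) / (l1 - l0)
    c[plateau] = hi
    c[dying] = lo + (hi - lo) * np.exp(-params.dying_rate * (t[dying] - params.dying_onset))
    density = (c - lo) / (hi - lo)
    return c, density


def simulate_spectrum(
    params: CircuitParameters,
    frequencies: np.ndarray,
    noise: SpectrumNoise | None = None,
    timepoint: float | None = None,
) -> ImpedanceSpectrum:
    """Forward-model sweep with independent relative Gaussian noise."""
    noise = noise or SpectrumNoise(relative_sd=0.0)
    f = np.asarray(frequencies, dtype=float)
    z = np.asarray(circuit_impedance(params, f))
    if noise.relative_sd > 0:
        rng = np.random.default_rng(noise.seed)
        re = z.real * (1.0 + noise.relative_sd * rng.standard_normal(f.size))
        im = z.imag * (1.0 + noise.relative_sd * rng.standard_normal(f.size))
        z = re + 1j * im
    return ImpedanceSpectrum(frequencies=f, z=z, timepoint=timepoint)


def _ellipse_field(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> tuple[slice, slice, np.ndarray]:
    """Normalized elliptical radius on a bounding window (r <= 1 inside)."""
    cy, cx = center
    a, b = axes  # major, minor semi-axes
    margin = a + 2.0
    y0, y1 = max(int(cy - margin), 0), min(int(cy + margin) + 1, shape[0])
    x0, x1 = max(int(cx - margin), 0), min(int(cx + margin) + 1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return slice(y0, y1), slice(x0, x1), r


def render_culture_image(params: ImageSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one culture image; return (image, ground-truth cell mask).

    Ellipses are placed with an overlap-rejection bias until the mask
    coverage lands within one percentage point of ``target_coverage``.  When
    the remaining gap is small the sampler shrinks the cells so the target is
    not overshot.  If a placement cap is hit first, the achieved coverage is
    reported in the raised error.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.size
    npix = h * w

    # Background: shaded ramp in a random direction plus Gaussian noise.
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(theta) * xx / w + np.sin(theta) * yy / h)
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12) - 0.5
    image = params.background_level + params.illumination_gradient * ramp
    image = image + params.noise_sd * rng.standard_normal((h, w))

    mask = np.zeros((h, w), dtype=bool)
    target = params.target_coverage
    attempts, cap = 0, 20000
    edge_soft = 1.5  # px of soft rim on each cell

    while True:
        cov = 100.0 * mask.sum() / npix
        if abs(cov - target) <= 1.0 or cov > target:
            break
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"placement cap hit: achieved coverage {cov:.2f}% of target {target:.2f}%"
            )
        b_lo, b_hi = params.cell_axis_range
        remaining_px = (target - cov) / 100.0 * npix
        # Shrink cells when little area is left, to avoid overshooting.
        mean_area = np.pi * b_lo * b_hi * np.mean(params.cell_eccentricity_range)
        if remaining_px < 2.0 * mean_area:
            b_hi = max(b_lo, b_hi * 0.6)
        b = rng.uniform(b_lo, b_hi)
        ecc = rng.uniform(*params.cell_eccentricity_range)
        # Cells stay fully inside the frame so every outline is closed; very
        # elongated cells are clamped on small frames to keep placement feasible.
        a = min(b * ecc, 0.25 * min(h, w))
        a = max(a, b)
        cy = rng.uniform(a + 1, h - a - 1)
        cx = rng.uniform(a + 1, w - a - 1)
        angle = rng.uniform(0, np.pi)
        ys, xs, r = _ellipse_field((h, w), (cy, cx), (a, b), angle)
        inside = r <= 1.0
        if inside.sum() == 0:
            continue
        # Overlap bias, relaxed as placements get harder (dense cultures).
        max_overlap = 0.25 + 0.6 * attempts / cap
        overlap = (mask[ys, xs] & inside).sum() / inside.sum()
        if overlap > max_overlap:
            continue
        # Soft-edged intensity profile with interior texture.
        rim = b * (1.0 - r)  # approx. distance into the cell, px
        alpha = np.clip(rim / edge_soft, 0.0, 1.0)
        texture = 0.035 * rng.standard_normal(r.shape)
        cell_level = params.background_level - params.cell_contrast
        patch = image[ys, xs]
        image[ys, xs] = patch * (1 - alpha) + (cell_level + texture) * alpha
        mask[ys, xs] |= inside

    if params.debris_mode and params.debris_coverage > 0:
        debris_px_target = params.debris_coverage / 100.0 * npix
        placed = 0.0
        guard = 0
        # Fragment clumps must be larger than the pipeline's median kernel,
        # or they would be filtered away instead of corrupting the coverage.
        while placed < debris_px_target and guard < 50000:
            guard += 1
            b = rng.uniform(3.0, 7.0)
            a = b * rng.uniform(1.0, 2.5)
            cy = rng.uniform(a, h - a)
            cx = rng.uniform(a, w - a)
            angle = rng.uniform(0, np.pi)
            ys, xs, r = _ellipse_field((h, w), (cy, cx), (a, b), angle)
            inside = r <= 1.0
            alpha = np.clip(b * (1.0 - r) / 1.0, 0.0, 1.0)
            sign = rng.choice([-1.0, 1.0])
            frag_level = params.background_level + sign * (params.cell_contrast + 0.12)
            patch = image[ys, xs]
            image[ys, xs] = patch * (1 - alpha) + frag_level * alpha
            placed += float(inside.sum())

    return np.clip(image, 0.0, 1.0), mask


@dataclass(frozen=True)
class SyntheticExperiment:
    """A full simulated cultivation with its ground truth."""

    timepoints: np.ndarray
    c_cell_true: np.ndarray
    density_true: np.ndarray
    coverage_true: np.ndarray
    spectra: tuple[ImpedanceSpectrum, ...]
    calibration: ImpedanceSpectrum
    images: dict
    masks: dict
    base_circuit: CircuitParameters
    growth: GrowthSimParams

    def truth_dict(self) -> dict:
        return {
            "timepoints_h": self.timepoints.tolist(),
            "c_cell_true_f": self.c_cell_true.tolist(),
            "density_true": self.density_true.tolist(),
            "coverage_true_percent": self.coverage_true.tolist(),
            "base_circuit": {
                "r_med": self.base_circuit.r_med,
                "r_cell": self.base_circuit.r_cell,
                "c_cell": self.base_circuit.c_cell,
                "r_el": self.base_circuit.r_el,
                "c_el": self.base_circuit.c_el,
            },
            "growth": {
                "c_cell_baseline": self.growth.c_cell_baseline,
                "c_cell_max": self.growth.c_cell_max,
                "lag_end": self.growth.lag_end,
                "exp_rate": self.growth.exp_rate,
                "stationary_start": self.growth.stationary_start,
                "dying_onset": self.growth.dying_onset,
                "dying_rate": self.growth.dying_rate,
                "seed": self.growth.seed,
            },
        }


def _coverage_from_density(
    density: np.ndarray, baseline_coverage: float, max_coverage: float
) -> np.ndarray:
    """Linear density -> coverage map, saturating at 90% confluence."""
    cov = baseline_coverage + (max_coverage - baseline_coverage) * density
    return np.minimum(cov, 90.0)


def simulate_experiment(
    growth: GrowthSimParams | None = None,
    base_circuit: CircuitParameters = DEFAULT_CIRCUIT,
    frequencies: np.ndarray | None = None,
    noise: SpectrumNoise | None = None,
    image_params: ImageSimParams | None = None,
    timepoints: np.ndarray | None = None,
    n_images: int = 3,
    baseline_coverage: float = 7.0,
    max_coverage: float = 60.0,
) -> SyntheticExperiment:
    """Simulate the full 96 h cultivation data set.

    Per timepoint: one noisy sweep whose ``C_cell`` follows the growth
    trajectory (all other circuit parameters constant), and ``n_images``
    rendered fields of view whose target coverage tracks cell density.  A
    cell-free calibration sweep (medium + electrode only) is included for
    electrode pinning.  With ``image_params.debris_mode`` on, timepoints
    after the dying onset additionally receive a random amount of scattered
    debris, drawn per timepoint, which is excluded from the truth masks —
    so measured coverage becomes erratic exactly where detached-cell
    fragments corrupt real imaging.
    """
    growth = growth or GrowthSimParams()
    noise = noise or SpectrumNoise()
    image_params = image_params or ImageSimParams()
    if timepoints is None:
        timepoints = np.arange(0.0, 96.0 + 1e-9, 4.0)
    if frequencies is None:
        frequencies = default_frequencies()

    c_cell, density = simulate_growth_curve(growth, timepoints)
    coverage_true = _coverage_from_density(density, baseline_coverage, max_coverage)
    if image_params.debris_mode:
        # Dead cells detach: the attached-cell footprint in images collapses
        # faster than the lumped capacitance declines.  Modelled as decay at
        # three times the dying rate from the onset value toward baseline.
        dying = timepoints > growth.dying_onset
        onset_cov = _coverage_from_density(
            np.array([1.0]), baseline_coverage, max_coverage
        )[0]
        coverage_true = coverage_true.copy()
        coverage_true[dying] = baseline_coverage + (onset_cov - baseline_coverage) * np.exp(
            -3.0 * growth.dying_rate * (timepoints[dying] - growth.dying_onset)
        )

    master = np.random.default_rng(growth.seed)
    spectra = []
    for i, (t, c) in enumerate(zip(timepoints, c_cell)):
        p = base_circuit.replace(c_cell=float(c))
        sub = int(master.integers(0, 2**31 - 1))
        spectra.append(
            simulate_spectrum(
                p, frequencies, replace(noise, seed=sub), timepoint=float(t)
            )
        )

    # Cell-free calibration: medium + electrode only (no cell branch).
    jw = 2j * np.pi * np.asarray(frequencies, dtype=float)
    z_cal = base_circuit.r_med + base_circuit.r_el / (
        1.0 + jw * base_circuit.r_el * base_circuit.c_el
    )
    cal_rng_seed = int(master.integers(0, 2**31 - 1))
    if noise.relative_sd > 0:
        rng = np.random.default_rng(cal_rng_seed)
        z_cal = z_cal.real * (
            1 + noise.relative_sd * rng.standard_normal(z_cal.size)
        ) + 1j * z_cal.imag * (1 + noise.relative_sd * rng.standard_normal(z_cal.size))
    calibration = ImpedanceSpectrum(frequencies=np.asarray(frequencies), z=z_cal)

    images: dict[float, list[np.ndarray]] = {}
    masks: dict[float, list[np.ndarray]] = {}
    for t, cov in zip(timepoints, coverage_true):
        imgs, msks = [], []
        past_dying = image_params.debris_mode and t > growth.dying_onset
        debris_cov = float(master.uniform(5.0, 65.0)) if past_dying else 0.0
        for _ in range(n_images):
            sub = int(master.integers(0, 2**31 - 1))
            p = replace(
                image_params,
                target_coverage=float(max(cov, 0.5)),
                debris_mode=past_dying,
                debris_coverage=debris_cov,
                seed=sub,
            )
            img, msk = render_culture_image(p)
            imgs.append(img)
            msks.append(msk)
        images[float(t)] = imgs
        masks[float(t)] = msks

    return SyntheticExperiment(
        timepoints=np.asarray(timepoints, dtype=float),
        c_cell_true=c_cell,
        density_true=density,
        coverage_true=coverage_true,
        spectra=tuple(spectra),
        calibration=calibration,
        images=images,
        masks=masks,
        base_circuit=base_circuit,
        growth=growth,
    )
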