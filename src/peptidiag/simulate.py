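"""Synthetic serum-peptidome cohort generator with known ground truth.

Emulates a two-class (cancer vs. healthy-control) MALDI-TOF serum peptidome
study: a panel of Gaussian peptide peaks on a uniform m/z grid, a subset of
which carry planted log2 fold changes between classes; smooth exponential
baseline drift; additive detector noise; per-sample multiplicative TIC
variation; per-sample ppm-scale mass-axis drift; and matrix-cluster artifact
peaks confined to the 1,500-2,000 Da region.

The generator is the testing ground for every downstream stage: because the
discriminative m/z values, artifact positions and per-sample drifts are
returned as :class:`GroundTruth`, recovery of planted signal can be measured
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, default_grid

__all__ = [
    "PeakSpec",
    "BaselineSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_spectrum",
    "generate_cohort",
    "default_peak_panel",
    "default_config",
]

#: σ of the Gaussian peak profile as a fraction of m/z, mimicking the
#: roughly constant relative resolution of a linear-mode TOF analyser.
DEFAULT_WIDTH_PPM = 300.0

#: lower bound on σ in Da so that every peak spans several grid points at
#: the default 0.5 Da pitch (an undersampled peak is not a resolvable one).
MIN_WIDTH_DA = 1.5

MATRIX_REGION = (1500.0, 2000.0)


@dataclass
class PeakSpec:
    """One peptide species in the simulated panel.

    Parameters
    ----------
    mz
        Peak centre in Da.
    width_sd
        Gaussian σ in Da; defaults to ``mz * 300e-6`` (300 ppm).
    base_area_mean
        Mean integrated area in the control class (arbitrary intensity·Da).
    area_cv
        Biological coefficient of variation of the area (log-normal).
    log2fc
        Planted log2 fold change of the mean area, cancer over control.
    prevalence
        Fraction of samples in which the peak is present at all.
    """

    mz: float
    base_area_mean: float = 100.0
    width_sd: float | None = None
    area_cv: float = 0.2
    log2fc: float = 0.0
    prevalence: float = 1.0

    def __post_init__(self) -> None:
        if self.width_sd is None:
            self.width_sd = max(self.mz * DEFAULT_WIDTH_PPM * 1e-6, MIN_WIDTH_DA)
        if self.width_sd <= 0:
            raise ValueError("width_sd must be positive")
        if self.base_area_mean <= 0:
            raise ValueError("base_area_mean must be positive")
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in (0, 1]")


@dataclass
class BaselineSpec:
    """Smooth chemical-background drift added under the peaks.

    ``exponential-decay``: A * exp(-(mz - mz_low) / scale), the matrix
    background shape typical of linear-mode MALDI.  ``polynomial``: A *
    polyval(coeffs, x) with x rescaled to [0, 1] over the mass range.
    """

    shape: str = "exponential-decay"
    amplitude: float = 50.0
    scale: float = 1500.0
    coeffs: tuple[float, ...] = (1.0, -1.0, 0.25)

    def __call__(self, mz: np.ndarray, mz_low: float | None = None) -> np.ndarray:
        lo = mz[0] if mz_low is None else mz_low
        if self.shape == "exponential-decay":
            return self.amplitude * np.exp(-(mz - lo) / self.scale)
        if self.shape == "polynomial":
            x = (mz - lo) / max(mz[-1] - lo, 1.0)
            return self.amplitude * np.polyval(self.coeffs, x)
        raise ValueError(f"unknown baseline shape {self.shape!r}")


def zero_baseline() -> BaselineSpec:
    return BaselineSpec(shape="exponential-decay", amplitude=0.0)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    discriminative_mz: tuple[float, ...]
    artifact_mz: tuple[float, ...]
    per_sample_drift_ppm: np.ndarray
    panel_mz: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "discriminative_mz": list(self.discriminative_mz),
            "artifact_mz": list(self.artifact_mz),
            "per_sample_drift_ppm": [float(d) for d in self.per_sample_drift_ppm],
            "panel_mz": list(self.panel_mz),
        }


@dataclass
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the emulated study: 414 cancer (TC) and 430 control (HC)
    sera, spectra over m/z 1,000-10,000 Da at 0.5 Da per point, ~150 panel
    peaks of which 12 carry |log2fc| >= 1, 20% biological CV, 15% TIC CV,
    150 ppm per-sample mass drift, and five matrix-cluster artifacts.
    """

    n_tc: int = 414
    n_hc: int = 430
    mz_range: tuple[float, float] = (1000.0, 10000.0)
    grid_step: float = 0.5
    peak_panel: list[PeakSpec] = field(default_factory=lambda: default_peak_panel())
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    noise_sd: float = 0.5
    tic_cv: float = 0.15
    mass_drift_ppm_sd: float = 150.0
    matrix_artifacts: tuple[float, ...] = field(default_factory=lambda: DEFAULT_ARTIFACT_MZ)
    artifact_area_mean: float = 40.0
    artifact_area_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tc < 0 or self.n_hc < 0:
            raise ValueError("sample counts must be non-negative")
        lo, hi = self.mz_range
        if lo >= hi:
            raise ValueError("mz_range low must be below high")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        for p in self.peak_panel:
            if not (lo <= p.mz <= hi):
                raise ValueError(f"panel peak {p.mz} outside mz_range {self.mz_range}")
        for a in self.matrix_artifacts:
            if not (MATRIX_REGION[0] <= a <= MATRIX_REGION[1]):
                raise ValueError(f"matrix artifact {a} outside {MATRIX_REGION}")

    def grid(self) -> np.ndarray:
        return default_grid(self.mz_range[0], self.mz_range[1], self.grid_step)


def default_peak_panel(
    n_peaks: int = 150,
    n_discriminative: int = 12,
    mz_low: float = 1050.0,
    mz_high: float = 9800.0,
    area_cv: float = 0.2,
) -> list[PeakSpec]:
    """Build the default ~150-peak serum peptide panel.

    Peak centres are evenly spaced (~59 Da apart, i.e. several alignment
    tolerances even at the top of the mass range) with a small fixed jitter,
    so cross-sample alignment is well posed and no mass region is so crowded
    that peak flanks contaminate the local noise estimate.  Twelve peaks,
    spread across the mass range, carry planted log2 fold changes of
    magnitude 1.0-1.6 (both directions); all others are null.  Base areas
    vary log-uniformly over 30-300 to span a realistic dynamic range; a
    minority of null peaks have prevalence 0.8 so that missing-value fill is
    exercised.
    """
    rng_pos = np.random.default_rng(2718)
    sep = (mz_high - mz_low) / (n_peaks - 1)
    centres = np.linspace(mz_low, mz_high, n_peaks) + rng_pos.uniform(
        -0.15 * sep, 0.15 * sep, n_peaks
    )
    centres = np.clip(centres, mz_low, mz_high)
    rng = np.random.default_rng(1812)  # fixed: the panel is part of the design
    areas = 10 ** rng.uniform(math.log10(30.0), math.log10(300.0), n_peaks)
    disc_idx = np.linspace(5, n_peaks - 6, n_discriminative).round().astype(int)
    fcs = [1.0, -1.0, 1.2, -1.2, 1.5, -1.5, 1.0, -1.2, 1.6, 1.2, -1.0, 1.4]
    panel: list[PeakSpec] = []
    null_idx = np.setdiff1d(np.arange(n_peaks), disc_idx)
    n_low_prev = min(15, len(null_idx) // 5)
    low_prev = set(rng.choice(null_idx, n_low_prev, replace=False))
    for i, mz in enumerate(centres):
        lfc = 0.0
        if i in set(disc_idx):
            lfc = fcs[list(disc_idx).index(i) % len(fcs)]
            # plant effects above the detection limit in BOTH classes: the
            # lower-abundance class keeps a mean area of 120
            areas[i] = 120.0 * 2.0 ** max(-lfc, 0.0)
        panel.append(
            PeakSpec(
                mz=float(mz),
                base_area_mean=float(areas[i]),
                area_cv=area_cv,
                log2fc=lfc,
                prevalence=0.8 if i in low_prev else 1.0,
            )
        )
    return panel


def _artifact_positions() -> tuple[float, ...]:
    """Five artifact m/z values inside the matrix-cluster region, each far
    (>3 tolerances) from every default panel peak."""
    panel_mz = np.array([p.mz for p in default_peak_panel()])
    cands = []
    region = panel_mz[(panel_mz > 1400) & (panel_mz < 2100)]
    edges = np.sort(np.concatenate([[1500.0], region, [2000.0]]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        if 1500.0 <= mid <= 2000.0 and (hi - lo) / mid > 0.02:
            cands.append(round(mid, 1))
    return tuple(cands[:5])


DEFAULT_ARTIFACT_MZ: tuple[float, ...] = _artifact_positions()


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study-scale cohort configuration (414 TC / 430 HC)."""
    return CohortConfig(seed=seed, **overrides)


def generate_spectrum(
    panel: list[tuple[float, float, float]] | list[PeakSpec],
    baseline: BaselineSpec,
    noise_sd: float,
    drift_ppm: float,
    tic_scale: float,
    grid: np.ndarray,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
) -> Spectrum:
    """Render one profile-mode spectrum.

    ``panel`` entries are either :class:`PeakSpec` (areas taken at their
    mean) or ``(mz, area, width_sd)`` triples of realized areas.  Intensity
    at each grid point is

        tic_scale * ( Σ_peaks area · N(mz; centre·(1 + drift_ppm·1e-6), σ)
                      + baseline(mz) ) + ε,   ε ~ N(0, noise_sd²),

    clipped at zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty m/z grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if tic_scale < 0:
        raise ValueError("tic_scale must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    signal = np.zeros_like(grid)
    shift = 1.0 + drift_ppm * 1e-6
    for spec in panel:
        if isinstance(spec, PeakSpec):
            centre, area, sd = spec.mz, spec.base_area_mean, spec.width_sd
        else:
            centre, area, sd = spec
        if area <= 0:
            continue
        c = centre * shift
        lo = np.searchsorted(grid, c - 6 * sd)
        hi = np.searchsorted(grid, c + 6 * sd)
        if hi <= lo:
            continue
        x = grid[lo:hi]
        signal[lo:hi] += area / (sd * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((x - c) / sd) ** 2
        )
    signal += baseline(grid, mz_low=grid[0])
    intensity = tic_scale * signal
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, grid.size)
    return Spectrum(mz=grid, intensity=np.clip(intensity, 0.0, None),
                    sample_id=sample_id, stage="raw")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, mean) if size else mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_cohort(config: CohortConfig):
    """Generate the full labelled cohort.

    Returns ``(spectra, labels, truth)`` where ``labels`` is a list of
    ``"TC"`` / ``"HC"`` aligned with ``spectra`` (TC first), and ``truth``
    records the planted discriminative m/z, artifact m/z and realized
    per-sample drifts.  Identical config and seed reproduce the output
    bit-for-bit.
    """
    n = config.n_tc + config.n_hc
    if n == 0:
        raise ValueError("cohort must contain at least one sample")
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    labels = ["TC"] * config.n_tc + ["HC"] * config.n_hc

    drifts = rng.normal(0.0, config.mass_drift_ppm_sd, n)
    tics = _lognormal(rng, 1.0, config.tic_cv, n)

    spectra: list[Spectrum] = []
    for i, label in enumerate(labels):
        realized: list[tuple[float, float, float]] = []
        for p in config.peak_panel:
            if p.prevalence < 1.0 and rng.random() >= p.prevalence:
                continue
            mean = p.base_area_mean * (2.0 ** p.log2fc if label == "TC" else 1.0)
            realized.append((p.mz, float(_lognormal(rng, mean, p.area_cv)), p.width_sd))
        for a_mz in config.matrix_artifacts:
            area = float(_lognormal(rng, config.artifact_area_mean, config.artifact_area_cv))
            realized.append(
                (a_mz, area, max(a_mz * DEFAULT_WIDTH_PPM * 1e-6, MIN_WIDTH_DA))
            )
        spectra.append(
            generate_spectrum(
                realized, config.baseline, config.noise_sd,
                drift_ppm=float(drifts[i]), tic_scale=float(tics[i]),
                grid=grid, seed=rng, sample_id=f"S{i:04d}",
            )
        )
    truth = GroundTruth(
        discriminative_mz=tuple(p.mz for p in config.peak_panel if p.log2fc != 0.0),
        artifact_mz=tuple(config.matrix_artifacts),
        per_sample_drift_ppm=drifts,
        panel_mz=tuple(p.mz for p in config.peak_panel),
    )
    return spectra, labels, truth
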