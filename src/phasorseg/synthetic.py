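"""Synthetic TCSPC decay generation with known ground truth.

Emulates acquisitions with a picosecond pulsed excitation source under
periodic excitation: mono- or multi-exponential decays sampled into the
configured histogram bins, scaled to a target peak count, with optional
Poisson counting noise.  Two-population "interface" maps reproduce the
measurement geometry of scanning across the boundary between two paint
mixtures, with per-pixel ground-truth labels retained for scoring.

The excitation is modelled as an ideal delta pulse: no instrument response
function (IRF) is applied by default, since the lifetimes of interest
(>= 1 ns) dwarf the picosecond pulse width.  An optional Gaussian IRF
convolution is available for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .acquisition import AcquisitionConfig, DecayHistogram, DecayMap, time_axis
from .errors import DomainError

__all__ = [
    "PopulationSpec",
    "expected_decay",
    "simulate_decay",
    "simulate_interface_map",
    "simulate_peak_ladder",
]

NS = 1e-9


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth description of one fluorophore population.

    lifetimes are in nanoseconds; fractions are amplitude fractions and must
    sum to 1.  ``target_peak`` is the *expected* (pre-noise) peak count.
    """

    lifetimes: Tuple[float, ...]
    fractions: Tuple[float, ...] = (1.0,)
    target_peak: float = 500.0
    label: int = 1

    def __post_init__(self) -> None:
        lifetimes = tuple(float(t) for t in np.atleast_1d(self.lifetimes))
        fractions = tuple(float(f) for f in np.atleast_1d(self.fractions))
        object.__setattr__(self, "lifetimes", lifetimes)
        object.__setattr__(self, "fractions", fractions)
        if len(lifetimes) != len(fractions):
            raise DomainError("lifetimes and fractions must have equal length")
        if any(t <= 0 for t in lifetimes):
            raise DomainError("all lifetimes must be > 0")
        if any(f <= 0 for f in fractions):
            raise DomainError("all fractions must be > 0")
        if abs(sum(fractions) - 1.0) > 1e-12:
            raise DomainError("fractions must sum to 1")
        if not (self.target_peak > 0):
            raise DomainError("target_peak must be > 0")


def expected_decay(
    spec: PopulationSpec,
    config: AcquisitionConfig,
    wrap: bool = True,
    irf_fwhm_ns: Optional[float] = None,
) -> np.ndarray:
    """Expected (noise-free) counts per bin, scaled so the maximum equals
    ``target_peak``.

    Under periodic excitation with period T = 1/f, the steady-state decay of
    a component with lifetime tau is the wrapped sum of all previous pulses,

        lambda(t) ∝ exp(-t/tau) / (1 - exp(-T/tau)),

    which for multi-exponential mixtures re-weights the components.  The
    wrap term can be disabled for single-pulse decays.
    """
    t = time_axis(config)
    lam = np.zeros(config.n_bins)
    for tau_ns, frac in zip(spec.lifetimes, spec.fractions):
        tau = tau_ns * NS
        term = frac * np.exp(-t / tau)
        if wrap:
            term = term / (1.0 - np.exp(-config.period / tau))
        lam += term
    if irf_fwhm_ns is not None:
        lam = _convolve_gaussian_irf(lam, config, irf_fwhm_ns)
    peak = lam.max()
    if peak <= 0:
        raise DomainError("degenerate expected decay (zero peak)")
    return lam * (spec.target_peak / peak)


def _convolve_gaussian_irf(
    lam: np.ndarray, config: AcquisitionConfig, fwhm_ns: float
) -> np.ndarray:
    """Circular convolution with a normalized Gaussian IRF (periodic system)."""
    if fwhm_ns <= 0:
        raise DomainError("IRF FWHM must be > 0")
    sigma_bins = fwhm_ns * NS / (2.3548200450309493 * config.bin_width)
    n = config.n_bins
    k = np.arange(n)
    k = np.minimum(k, n - k)  # circular distance
    kernel = np.exp(-0.5 * (k / sigma_bins) ** 2)
    kernel /= kernel.sum()
    return np.real(np.fft.ifft(np.fft.fft(lam) * np.fft.fft(kernel)))


def simulate_decay(
    spec: PopulationSpec,
    config: AcquisitionConfig,
    seed: int = 0,
    noise: str = "poisson",
    wrap: bool = True,
    irf_fwhm_ns: Optional[float] = None,
    pixel: Optional[Tuple[int, int]] = None,
) -> DecayHistogram:
    """Simulate one decay histogram.

    ``noise='poisson'`` draws independent Poisson counts with the expected
    per-bin intensities; ``noise='none'`` rounds the expected counts to the
    nearest integer.  The same seed always yields the same histogram.
    """
    if noise not in ("poisson", "none"):
        raise DomainError(f"noise must be 'poisson' or 'none', got {noise!r}")
    lam = expected_decay(spec, config, wrap=wrap, irf_fwhm_ns=irf_fwhm_ns)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam)
    else:
        counts = np.rint(lam).astype(np.int64)
    return DecayHistogram(counts.astype(np.int64), pixel=pixel)


def _pixel_seed(seed: int, row: int, col: int) -> np.random.SeedSequence:
    # Deterministic per-pixel stream: maps are reproducible even under
    # partial regeneration of a sub-grid.
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(row), int(col)))


def simulate_interface_map(
    pop_a: PopulationSpec,
    pop_b: PopulationSpec,
    shape: Tuple[int, int],
    boundary_col: int,
    config: AcquisitionConfig,
    seed: int = 0,
    noise: str = "poisson",
    wrap: bool = True,
) -> DecayMap:
    """Two-population map split at a vertical boundary.

    Pixels with ``col < boundary_col`` are drawn from ``pop_a``, the rest
    from ``pop_b``; ``labels_truth`` records the population of each pixel.
    """
    rows, cols = shape
    if not (0 < boundary_col < cols):
        raise DomainError(
            f"boundary_col must be inside the grid (0 < {boundary_col} < {cols})"
        )
    lam_a = expected_decay(pop_a, config, wrap=wrap)
    lam_b = expected_decay(pop_b, config, wrap=wrap)
    counts = np.zeros((rows, cols, config.n_bins), dtype=np.int64)
    labels = np.zeros((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            lam = lam_a if c < boundary_col else lam_b
            labels[r, c] = pop_a.label if c < boundary_col else pop_b.label
            if noise == "poisson":
                rng = np.random.default_rng(_pixel_seed(seed, r, c))
                counts[r, c] = rng.poisson(lam)
            elif noise == "none":
                counts[r, c] = np.rint(lam).astype(np.int64)
            else:
                raise DomainError(f"noise must be 'poisson' or 'none', got {noise!r}")
    return DecayMap(counts, config, labels_truth=labels)


def simulate_peak_ladder(
    peaks: Sequence[int], config: AcquisitionConfig, tau_ns: float = 3.7
) -> DecayMap:
    """One noiseless decay per requested peak value, as a 1-row map.

    Useful as an exact fixture for the peak-count threshold: decay j has
    ``peak_count`` equal to ``peaks[j]`` (the peak sits in bin 0, so the
    nearest-integer rounding of the scaled maximum is exact).
    """
    peaks = list(peaks)
    if len(peaks) == 0:
        raise DomainError("peaks must be non-empty")
    if any(p < 0 for p in peaks):
        raise DomainError("peaks must be >= 0")
    counts = np.zeros((1, len(peaks), config.n_bins), dtype=np.int64)
    base = expected_decay(
        PopulationSpec(lifetimes=(tau_ns,), target_peak=1.0), config
    )
    for j, p in enumerate(peaks):
        counts[0, j] = np.rint(base * float(p)).astype(np.int64)
    return DecayMap(counts, config)
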