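"""Domain types for TCSPC acquisitions, decay-map I/O and instrument geometry.

A time-correlated single photon counting (TCSPC) acquisition records, for
each spatial position, a histogram of photon arrival times relative to the
excitation pulse.  The default configuration mirrors a fibre-based
time-resolved fluorescence imaging instrument: a 20 MHz pulsed excitation
source and an acquisition card binning arrivals into 256 bins of 195 ps,
i.e. a 49.92 ns histogram inside the 50 ns excitation period.

Decay maps are stored on disk in a small comma-separated text dialect (one
pixel per line, header carrying the acquisition parameters) or in a zip
archive bundling that text with a key-value config file.
"""

from __future__ import annotations

import io
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError, DomainError, FormatError

__all__ = [
    "AcquisitionConfig",
    "DecayHistogram",
    "DecayMap",
    "time_axis",
    "peak_count",
    "spot_diameter",
    "save_decay_map",
    "load_decay_map",
    "read_config_file",
    "write_config_file",
]

_DIALECT_MAGIC = "phasorseg-decaymap v1"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and instrument parameters of a TCSPC acquisition.

    Parameters
    ----------
    repetition_rate : float
        Pulse repetition rate of the excitation laser in Hz (default 20 MHz).
        This frequency is also the first phasor harmonic.
    n_bins : int
        Number of histogram bins (default 256).
    bin_width : float
        Width of one histogram bin in seconds (default 195 ps).
    emission_band : tuple of float, optional
        Detected emission band (nm, nm); metadata only.
    numerical_aperture : float
        NA of the delivery fibre, used by :func:`spot_diameter`.
    """

    repetition_rate: float = 2.0e7
    n_bins: int = 256
    bin_width: float = 1.95e-10
    emission_band: Optional[Tuple[float, float]] = None
    numerical_aperture: float = 0.22

    def __post_init__(self) -> None:
        if not (self.repetition_rate > 0):
            raise ConfigurationError("repetition_rate must be > 0")
        if not (isinstance(self.n_bins, (int, np.integer)) and self.n_bins >= 2):
            raise ConfigurationError("n_bins must be an integer >= 2")
        if not (self.bin_width > 0):
            raise ConfigurationError("bin_width must be > 0")
        window = self.n_bins * self.bin_width
        period = 1.0 / self.repetition_rate
        if window > period * (1 + 1e-12):
            raise ConfigurationError(
                f"histogram window {window:.4e} s exceeds the excitation "
                f"period {period:.4e} s"
            )

    @property
    def period(self) -> float:
        """Excitation period T = 1/f in seconds."""
        return 1.0 / self.repetition_rate

    @property
    def window(self) -> float:
        """Total histogram span n_bins * bin_width in seconds."""
        return self.n_bins * self.bin_width


@dataclass(frozen=True)
class DecayHistogram:
    """A single per-pixel photon-count decay histogram."""

    counts: np.ndarray
    pixel: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size == 0:
            raise FormatError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
                arr = arr.astype(np.int64)
            else:
                raise FormatError("counts must be integral")
        if np.any(arr < 0):
            raise FormatError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64, copy=False))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


class DecayMap:
    """A dense grid of decay histograms on a regular (row, col) raster.

    Counts are held as one ``(n_rows, n_cols, n_bins)`` integer array.
    ``labels_truth`` optionally carries per-pixel ground-truth cluster labels
    when the map was produced by the simulator.
    """

    def __init__(
        self,
        counts: np.ndarray,
        config: AcquisitionConfig,
        labels_truth: Optional[np.ndarray] = None,
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 3:
            raise FormatError("counts must have shape (n_rows, n_cols, n_bins)")
        if counts.shape[2] != config.n_bins:
            raise FormatError(
                f"histogram length {counts.shape[2]} != config n_bins {config.n_bins}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            raise FormatError("counts must be integral")
        if np.any(counts < 0):
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        self.config = config
        if labels_truth is not None:
            labels_truth = np.asarray(labels_truth)
            if labels_truth.shape != counts.shape[:2]:
                raise FormatError("labels_truth shape must match the grid")
        self.labels_truth = labels_truth

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[0] * self.counts.shape[1]

    def histogram(self, row: int, col: int) -> DecayHistogram:
        return DecayHistogram(self.counts[row, col], pixel=(row, col))

    def __iter__(self) -> Iterator[DecayHistogram]:
        rows, cols = self.shape
        for r in range(rows):
            for c in range(cols):
                yield self.histogram(r, c)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecayMap):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.counts, other.counts)
            and self.config == other.config
        )


def time_axis(config: AcquisitionConfig) -> np.ndarray:
    """Bin-centre times t_k = (k + 0.5) * bin_width, k = 0..n_bins-1.

    Bin centres (rather than left edges) reduce the discretization bias of
    the phasor projections.
    """
    if not isinstance(config, AcquisitionConfig):
        raise ConfigurationError("config must be an AcquisitionConfig")
    return (np.arange(config.n_bins) + 0.5) * config.bin_width


def peak_count(decay: Union[DecayHistogram, np.ndarray]) -> int:
    """Maximum bin value of a decay histogram — the quantity the >100-count
    quality filter thresholds."""
    counts = decay.counts if isinstance(decay, DecayHistogram) else np.asarray(decay)
    if counts.size == 0:
        raise FormatError("empty decay histogram")
    return int(counts.max())


def spot_diameter(distance_mm: float, na: float) -> float:
    """Irradiated spot diameter (mm) at a given fibre-sample distance.

    Models the excitation cone diverging at the fibre's acceptance
    half-angle arcsin(NA): diameter = 2 * d * tan(arcsin(NA)).  With
    NA = 0.22 this gives 0.9 mm at 2 mm and 4.5 mm at 10 mm distance.
    """
    if not (0.0 < na < 1.0):
        raise DomainError(f"numerical aperture must be in (0, 1), got {na}")
    if distance_mm < 0:
        raise DomainError("distance must be >= 0")
    return 2.0 * distance_mm * math.tan(math.asin(na))


# ---------------------------------------------------------------------------
# Decay-map text dialect


def _header_line(decay_map: DecayMap) -> str:
    rows, cols = decay_map.shape
    cfg = decay_map.config
    return (
        f"# {_DIALECT_MAGIC}, rows={rows}, cols={cols}, "
        f"n_bins={cfg.n_bins}, bin_width_s={cfg.bin_width!r}, "
        f"rep_rate_hz={cfg.repetition_rate!r}"
    )


def _format_map(decay_map: DecayMap) -> str:
    lines = [_header_line(decay_map)]
    rows, cols = decay_map.shape
    for r in range(rows):
        for c in range(cols):
            counts = ",".join(str(int(v)) for v in decay_map.counts[r, c])
            lines.append(f"{r},{c},{counts}")
    return "\n".join(lines) + "\n"


def _parse_header(line: str) -> dict:
    body = line.lstrip("#").strip()
    if not body.startswith(_DIALECT_MAGIC):
        raise FormatError("missing 'phasorseg-decaymap v1' header")
    fields = {}
    for part in body[len(_DIALECT_MAGIC):].split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed header field {part!r}")
        key, value = part.split("=", 1)
        fields[key.strip()] = value.strip()
    return fields


def _parse_map(text: str, config: Optional[AcquisitionConfig]) -> DecayMap:
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError("decay-map file must start with a '#' header line")
    header = _parse_header(lines[0])
    try:
        rows = int(header["rows"])
        cols = int(header["cols"])
        n_bins = int(header["n_bins"])
        bin_width = float(header["bin_width_s"])
        rep_rate = float(header["rep_rate_hz"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad decay-map header: {exc}") from exc

    if config is None:
        config = AcquisitionConfig(
            repetition_rate=rep_rate, n_bins=n_bins, bin_width=bin_width
        )
    else:
        if (
            config.n_bins != n_bins
            or not math.isclose(config.bin_width, bin_width, rel_tol=1e-9)
            or not math.isclose(config.repetition_rate, rep_rate, rel_tol=1e-9)
        ):
            raise FormatError("header does not match the supplied config")

    counts = np.zeros((rows, cols, n_bins), dtype=np.int64)
    seen = np.zeros((rows, cols), dtype=bool)
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != n_bins + 2:
            raise FormatError(
                f"row {lineno}: expected {n_bins + 2} fields, got {len(parts)}"
            )
        try:
            r, c = int(parts[0]), int(parts[1])
            values = [int(p) for p in parts[2:]]
        except ValueError as exc:
            raise FormatError(f"row {lineno}: non-integer count ({exc})") from exc
        if not (0 <= r < rows and 0 <= c < cols):
            raise FormatError(f"row {lineno}: pixel ({r},{c}) outside grid")
        if any(v < 0 for v in values):
            raise FormatError(f"row {lineno}: negative count")
        if seen[r, c]:
            raise FormatError(f"row {lineno}: duplicate pixel ({r},{c})")
        seen[r, c] = True
        counts[r, c] = values
    if not seen.all():
        missing = int((~seen).sum())
        raise FormatError(f"{missing} pixel(s) missing from decay-map file")
    return DecayMap(counts, config)


def save_decay_map(decay_map: DecayMap, path: Union[str, Path]) -> None:
    """Write a decay map in the text dialect, or as a zip archive bundling
    the text with a key-value config file when *path* ends in ``.zip``."""
    path = Path(path)
    text = _format_map(decay_map)
    if path.suffix == ".zip":
        cfg = decay_map.config
        cfg_text = (
            f"rep_rate_hz = {cfg.repetition_rate!r}\n"
            f"n_bins = {cfg.n_bins}\n"
            f"bin_width_s = {cfg.bin_width!r}\n"
        )
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("decaymap.csv", text)
            zf.writestr("config.txt", cfg_text)
    else:
        path.write_text(text)


def load_decay_map(
    path: Union[str, Path], config: Optional[AcquisitionConfig] = None
) -> DecayMap:
    """Read a decay map from the text dialect or its zip archive form.

    If *config* is given it is validated against the file header;
    otherwise the header parameters define the configuration.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".zip" or zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            csv_names = [n for n in names if n.endswith(".csv")]
            if not csv_names:
                raise FormatError("archive contains no decay-map csv")
            text = zf.read(csv_names[0]).decode("utf-8")
    else:
        text = path.read_text()
    return _parse_map(text, config)


# ---------------------------------------------------------------------------
# Flat key-value config files

_CONFIG_KEYS = {
    "rep_rate_hz": float,
    "n_bins": int,
    "bin_width_s": float,
    "peak_threshold": int,
    "k_clusters": int,
    "seed": int,
    "tau_color_min_ns": float,
    "tau_color_max_ns": float,
}


def read_config_file(path: Union[str, Path]) -> dict:
    """Parse a flat ``key = value`` run-configuration file."""
    result: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise FormatError(f"line {lineno}: unknown key {key!r}")
        try:
            result[key] = _CONFIG_KEYS[key](value)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad value for {key!r}: {exc}") from exc
    return result


def write_config_file(path: Union[str, Path], values: dict) -> None:
    unknown = set(values) - set(_CONFIG_KEYS)
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    lines = [f"{k} = {values[k]}" for k in _CONFIG_KEYS if k in values]
    Path(path).write_text("\n".join(lines) + "\n")
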