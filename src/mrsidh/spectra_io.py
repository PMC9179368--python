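"""Spectrum and cohort containers, the ppm-axis convention, and on-disk formats.

Every other module works in the chemical-shift (ppm) coordinate defined
here.  A single-voxel ¹H-MR spectrum is stored as a real-valued intensity
vector (arbitrary units, vendor scale) together with the acquisition
metadata needed to place it on a ppm axis: static field strength,
transmitter frequency, spectral width and number of points.

The ppm axis runs high → low (standard NMR plotting orientation); all
window arguments throughout the package are ``(ppm_high, ppm_low)`` pairs.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

#: Proton gyromagnetic ratio in MHz per Tesla, used to derive the
#: transmitter frequency when it is not given explicitly
#: (1.5 T -> 63.864 MHz, 3.0 T -> 127.728 MHz).
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.576

VALID_LABELS = ("mut", "wt", "unknown")

_MANDATORY_KEYS = ("field_strength_T", "spectral_width_Hz", "n_points")


class InvalidParameterError(ValueError):
    """Acquisition parameters are physically or structurally invalid."""


class SpectrumFormatError(ValueError):
    """A spectrum or manifest file violates the documented on-disk format."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata determining the ppm axis of one spectrum.

    Parameters
    ----------
    field_strength_t
        Static magnetic field in Tesla (> 0).
    spectral_width_hz
        Acquisition bandwidth in Hz (> 0).
    n_points
        Number of acquired data points (>= 2).
    transmitter_frequency_mhz
        Proton transmitter frequency in MHz.  If ``None`` it is derived as
        ``42.576 * field_strength_t``; real magnets deviate slightly from
        the nominal field, so the value is user-overridable.
    echo_time_ms
        Echo time in ms; carried as metadata only.
    center_ppm
        Chemical shift at the center of the acquisition window.  Defaults
        to 4.7 ppm (water); absolute placement is irrelevant after choline
        anchoring but a convention is needed for simulation and plotting.
    """

    field_strength_t: float
    spectral_width_hz: float
    n_points: int
    transmitter_frequency_mhz: float | None = None
    echo_time_ms: float | None = None
    center_ppm: float = 4.7

    def __post_init__(self) -> None:
        if not (self.field_strength_t > 0):
            raise InvalidParameterError(
                f"field strength must be > 0 T, got {self.field_strength_t}"
            )
        if not (self.spectral_width_hz > 0):
            raise InvalidParameterError(
                f"spectral width must be > 0 Hz, got {self.spectral_width_hz}"
            )
        if int(self.n_points) != self.n_points or self.n_points < 2:
            raise InvalidParameterError(
                f"n_points must be an integer >= 2, got {self.n_points}"
            )
        object.__setattr__(self, "n_points", int(self.n_points))
        if self.transmitter_frequency_mhz is None:
            object.__setattr__(
                self,
                "transmitter_frequency_mhz",
                GYROMAGNETIC_RATIO_MHZ_PER_T * self.field_strength_t,
            )
        elif not (self.transmitter_frequency_mhz > 0):
            raise InvalidParameterError(
                "transmitter frequency must be > 0 MHz, "
                f"got {self.transmitter_frequency_mhz}"
            )

    @property
    def ppm_span(self) -> float:
        """Width of the acquisition window in ppm: spectral_width / f0."""
        return self.spectral_width_hz / self.transmitter_frequency_mhz

    def to_dict(self) -> dict:
        d = {
            "field_strength_T": self.field_strength_t,
            "transmitter_frequency_MHz": self.transmitter_frequency_mhz,
            "spectral_width_Hz": self.spectral_width_hz,
            "n_points": self.n_points,
            "center_ppm": self.center_ppm,
        }
        if self.echo_time_ms is not None:
            d["echo_time_ms"] = self.echo_time_ms
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(
            field_strength_t=float(d["field_strength_T"]),
            spectral_width_hz=float(d["spectral_width_Hz"]),
            n_points=int(d["n_points"]),
            transmitter_frequency_mhz=(
                float(d["transmitter_frequency_MHz"])
                if d.get("transmitter_frequency_MHz") is not None
                else None
            ),
            echo_time_ms=(
                float(d["echo_time_ms"]) if d.get("echo_time_ms") is not None else None
            ),
            center_ppm=float(d.get("center_ppm", 4.7)),
        )


@dataclass(frozen=True)
class PpmAxis:
    """A uniform, strictly decreasing chemical-shift axis.

    ``values[i] = center + span/2 - i * span/n`` with spacing
    ``span / n_points``; the first point sits at the upper window edge.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise InvalidParameterError("ppm axis needs at least two points")
        steps = np.diff(values)
        if not np.all(steps < 0):
            raise InvalidParameterError("ppm axis must be strictly decreasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Grid spacing in ppm (positive)."""
        return float(self.values[0] - self.values[1])

    @property
    def span(self) -> float:
        return float(self.spacing * len(self))

    def nearest_index(self, ppm: float) -> int:
        return int(np.argmin(np.abs(self.values - ppm)))

    def window_mask(self, ppm_high: float, ppm_low: float) -> np.ndarray:
        """Boolean mask of grid points with ppm_low <= value <= ppm_high."""
        if ppm_high < ppm_low:
            raise InvalidParameterError(
                f"window must be (ppm_high, ppm_low), got ({ppm_high}, {ppm_low})"
            )
        return (self.values >= ppm_low) & (self.values <= ppm_high)


def ppm_axis(params: AcquisitionParams) -> PpmAxis:
    """Chemical-shift axis of a spectrum acquired with ``params``.

    The axis has ``n_points`` uniformly spaced values ordered high → low,
    spans ``spectral_width / transmitter_frequency`` ppm around
    ``center_ppm``, and has spacing ``span / n_points``.
    """
    span = params.ppm_span
    step = span / params.n_points
    top = params.center_ppm + span / 2.0
    values = top - step * np.arange(params.n_points)
    return PpmAxis(values)


@dataclass
class Spectrum:
    """One single-voxel spectrum: intensities plus acquisition metadata.

    Intensities are real absorption-mode values in vendor arbitrary units;
    negative values are permitted (baseline, noise).
    """

    intensities: np.ndarray
    params: AcquisitionParams
    id: str = ""
    label: str = "unknown"
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        if intensities.ndim != 1:
            raise SpectrumFormatError("intensities must be a 1-D vector")
        if intensities.size != self.params.n_points:
            raise SpectrumFormatError(
                f"spectrum '{self.id}' has {intensities.size} intensities "
                f"but n_points={self.params.n_points}"
            )
        if not np.all(np.isfinite(intensities)):
            raise SpectrumFormatError(
                f"spectrum '{self.id}' contains non-finite intensities"
            )
        self.intensities = intensities
        self.label = normalize_label(self.label)

    @property
    def axis(self) -> PpmAxis:
        return ppm_axis(self.params)


def normalize_label(label: str) -> str:
    norm = str(label).strip().lower()
    if norm in ("", "na", "none"):
        norm = "unknown"
    if norm not in VALID_LABELS:
        raise SpectrumFormatError(
            f"label must be one of {VALID_LABELS} (case-insensitive), got {label!r}"
        )
    return norm


@dataclass
class Cohort:
    """Ordered collection of labeled spectra with exclusion bookkeeping.

    ``exclusion_ledger`` maps an exclusion reason to a count; the counts
    sum to (initial size − retained size) after quality gating.
    """

    spectra: list
    name: str = ""
    exclusion_ledger: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SpectrumFormatError(f"duplicate spectrum ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def labels(self) -> list:
        return [s.label for s in self.spectra]


# ---------------------------------------------------------------------------
# Spectrum files: UTF-8 TSV, '#key<TAB>value' header lines followed by one
# intensity per line at full decimal precision.
# ---------------------------------------------------------------------------


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum in the package's TSV format (lossless round trip)."""
    p = spectrum.params
    lines = [
        f"#id\t{spectrum.id}",
        f"#label\t{spectrum.label}",
        f"#field_strength_T\t{p.field_strength_t!r}",
        f"#transmitter_frequency_MHz\t{p.transmitter_frequency_mhz!r}",
        f"#spectral_width_Hz\t{p.spectral_width_hz!r}",
        f"#n_points\t{p.n_points}",
        f"#center_ppm\t{p.center_ppm!r}",
    ]
    if p.echo_time_ms is not None:
        lines.append(f"#echo_time_ms\t{p.echo_time_ms!r}")
    lines.extend(repr(float(v)) for v in spectrum.intensities)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum`.

    Raises
    ------
    SpectrumFormatError
        If a mandatory metadata key is missing, a line cannot be parsed, or
        the number of intensity rows disagrees with ``n_points``.
    """
    path = Path(path)
    meta: dict = {}
    intensities: list = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if len(parts) != 2:
                    raise SpectrumFormatError(
                        f"{path.name}:{lineno}: malformed header line {line!r}"
                    )
                meta[parts[0].strip()] = parts[1].strip()
            else:
                try:
                    intensities.append(float(line))
                except ValueError as exc:
                    raise SpectrumFormatError(
                        f"{path.name}:{lineno}: unparsable intensity {line!r}"
                    ) from exc
    for key in _MANDATORY_KEYS:
        if key not in meta:
            raise SpectrumFormatError(
                f"{path.name}: missing mandatory metadata key '{key}'"
            )
    params = AcquisitionParams(
        field_strength_t=float(meta["field_strength_T"]),
        spectral_width_hz=float(meta["spectral_width_Hz"]),
        n_points=int(meta["n_points"]),
        transmitter_frequency_mhz=(
            float(meta["transmitter_frequency_MHz"])
            if "transmitter_frequency_MHz" in meta
            else None
        ),
        echo_time_ms=float(meta["echo_time_ms"]) if "echo_time_ms" in meta else None,
        center_ppm=float(meta.get("center_ppm", 4.7)),
    )
    if len(intensities) != params.n_points:
        raise SpectrumFormatError(
            f"{path.name}: {len(intensities)} intensity rows but "
            f"n_points={params.n_points}"
        )
    return Spectrum(
        intensities=np.array(intensities, dtype=float),
        params=params,
        id=meta.get("id", path.stem),
        label=meta.get("label", "unknown"),
    )


# ---------------------------------------------------------------------------
# Cohort manifests: TSV with columns path, id, label.  Paths are resolved
# relative to the manifest's directory.
# ---------------------------------------------------------------------------


def read_cohort(manifest_path, name: str = "") -> Cohort:
    """Read a cohort from a manifest; the manifest's id and label win."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    spectra = []
    with manifest_path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"path", "id", "label"} <= set(
            reader.fieldnames
        ):
            raise SpectrumFormatError(
                f"{manifest_path.name}: manifest needs columns path, id, label"
            )
        for row in reader:
            member = base / row["path"]
            if not member.exists():
                raise SpectrumFormatError(
                    f"{manifest_path.name}: unreadable member file {row['path']!r}"
                )
            spec = read_spectrum(member)
            spec.id = row["id"]
            spec.label = normalize_label(row["label"])
            spectra.append(spec)
    return Cohort(spectra=spectra, name=name or manifest_path.stem)


def write_cohort(cohort: Cohort, directory, manifest_name: str = "manifest.tsv"):
    """Write every spectrum plus a manifest into ``directory``.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in cohort:
        fname = f"{spec.id}.tsv"
        write_spectrum(spec, directory / fname)
        rows.append((fname, spec.id, spec.label))
    manifest = directory / manifest_name
    with manifest.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["path", "id", "label"])
        writer.writerows(rows)
    return manifest
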