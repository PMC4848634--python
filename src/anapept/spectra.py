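"""Centroided MS/MS spectrum container, MGF/TSV I/O and peak matching.

Spectra are singly charged positive-mode product-ion scans grouped by
solid-phase-extraction (SPE) fraction label (e.g. "40% MeOH"). The fraction
label travels in the MGF TITLE field as ``FRACTION=<label>`` so files stay
standard-compatible; MGF parsing and writing go through pyteomics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "Tolerance",
    "MGFParseError",
    "read_mgf",
    "write_mgf",
    "read_peaklist_tsv",
    "match_peak",
]


class MGFParseError(ValueError):
    """Raised when an MGF block cannot be interpreted as a spectrum."""


@dataclass(frozen=True)
class Tolerance:
    """Peak-matching tolerance, absolute (Da) or relative (ppm).

    The default across the package is 0.5 Da absolute, reflecting
    integer-level nominal-m/z reporting; ppm mode suits high-accuracy
    synthetic data.
    """

    value: float = 0.5
    mode: Literal["da", "ppm"] = "da"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.mode not in ("da", "ppm"):
            raise ValueError(f"unknown tolerance mode: {self.mode!r}")

    def window(self, target: float) -> float:
        return self.value if self.mode == "da" else target * self.value * 1e-6


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS spectrum with its SPE fraction label."""

    id: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    fraction: str = ""
    charge: int = 1

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.id}: precursor m/z must be positive")
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in peaks):
            raise ValueError(f"{self.id}: negative peak intensity")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


_FRACTION_RE = re.compile(r"FRACTION=(.+)$")


def _title_for(s: Spectrum) -> str:
    title = s.id
    if s.fraction:
        title += f" FRACTION={s.fraction}"
    return title


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.

    The fraction label is recovered from a ``FRACTION=<label>`` suffix in
    the TITLE. A block without PEPMASS raises :class:`MGFParseError`
    identifying the offending block. An empty file yields an empty list.
    """
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = params.get("title", f"spectrum_{i}")
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise MGFParseError(
                    f"{path}: block {i + 1} ({title!r}) has no PEPMASS"
                )
            fraction = ""
            m = _FRACTION_RE.search(title)
            if m:
                fraction = m.group(1).strip()
                title = title[: m.start()].strip()
            charge = 1
            if params.get("charge"):
                charge = int(params["charge"][0])
            peaks = tuple(zip(entry["m/z array"], entry["intensity array"]))
            spectra.append(
                Spectrum(
                    id=title or f"spectrum_{i}",
                    precursor_mz=float(params["pepmass"][0]),
                    peaks=peaks,
                    fraction=fraction,
                    charge=charge,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF, embedding fraction labels in the TITLE."""
    records = [
        {
            "m/z array": s.mz_array,
            "intensity array": s.intensity_array,
            "params": {
                "title": _title_for(s),
                "pepmass": s.precursor_mz,
                "charge": [s.charge],
            },
        }
        for s in spectra
    ]
    with open(path, "w") as fh:
        _mgf.write(records, fh)


def read_peaklist_tsv(
    path: str | Path, precursor_mz: float, spectrum_id: str = "", fraction: str = ""
) -> Spectrum:
    """Read a bare two-column (mz, intensity) TSV peak list."""
    peaks = []
    with open(path) as fh:
        first = fh.readline()
        if not first.lower().startswith("mz"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            mz, inten = line.split("\t")[:2]
            peaks.append((float(mz), float(inten)))
    return Spectrum(
        id=spectrum_id or Path(path).stem,
        precursor_mz=precursor_mz,
        peaks=tuple(peaks),
        fraction=fraction,
    )


def match_peak(
    s: Spectrum, target: float, tol: Tolerance
) -> tuple[float, float] | None:
    """Most intense peak within tolerance of ``target``, or None.

    Ties on intensity are broken toward the smaller m/z so matching is
    deterministic.
    """
    window = tol.window(target)
    best: tuple[float, float] | None = None
    for mz, intensity in s.peaks:
        if abs(mz - target) <= window:
            if best is None or intensity > best[1]:
                best = (mz, intensity)
    return best
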