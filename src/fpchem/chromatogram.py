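"""In-memory containers for detector traces and fingerprint matrices."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .grid import TimeGrid


@dataclass
class Chromatogram:
    """One detector trace with its sample metadata.

    ``absorbance`` is in absorbance units (AU) on ``grid`` (minutes).
    Blanks carry ``blank=True`` and no species label.
    """

    sample_id: str
    species: str | None
    extract_id: str
    replicate: int
    wavelength_nm: int
    grid: TimeGrid
    absorbance: np.ndarray = field(repr=False)
    blank: bool = False

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.grid.n_points,):
            raise ValueError(
                f"absorbance length {self.absorbance.size} does not match "
                f"grid length {self.grid.n_points} for sample {self.sample_id!r}"
            )

    def with_absorbance(self, values: np.ndarray, grid: TimeGrid | None = None) -> "Chromatogram":
        """Copy of this trace with new absorbance values (and optionally grid)."""
        return replace(self, absorbance=np.asarray(values, dtype=float), grid=grid or self.grid)


@dataclass
class ChromatogramSet:
    """An ordered collection of chromatograms with filtering helpers."""

    chromatograms: list[Chromatogram]

    def __len__(self) -> int:
        return len(self.chromatograms)

    def __iter__(self) -> Iterator[Chromatogram]:
        return iter(self.chromatograms)

    def __getitem__(self, i: int) -> Chromatogram:
        return self.chromatograms[i]

    def at_wavelength(self, wavelength_nm: int) -> "ChromatogramSet":
        return ChromatogramSet(
            [c for c in self.chromatograms if c.wavelength_nm == wavelength_nm]
        )

    def wavelengths(self) -> list[int]:
        seen: dict[int, None] = {}
        for c in self.chromatograms:
            seen.setdefault(c.wavelength_nm, None)
        return list(seen)

    def by_extract(self) -> dict[str, list[Chromatogram]]:
        """Group traces by extract id, preserving insertion order."""
        groups: dict[str, list[Chromatogram]] = {}
        for c in self.chromatograms:
            groups.setdefault(c.extract_id, []).append(c)
        return groups

    def by_species(self) -> dict[str, list[Chromatogram]]:
        groups: dict[str, list[Chromatogram]] = {}
        for c in self.chromatograms:
            groups.setdefault(str(c.species), []).append(c)
        return groups


@dataclass
class FingerprintMatrix:
    """Samples x time-points absorbance matrix at one wavelength.

    Row ``i`` of ``X`` is the fingerprint of ``sample_ids[i]``; ``species``
    aligns with rows.  The grid holds the (cropped) analysis window.
    """

    sample_ids: list[str]
    species: list[str]
    wavelength_nm: int
    grid: TimeGrid
    X: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if n != len(self.sample_ids) or n != len(self.species):
            raise ValueError("rows of X must align with sample_ids and species")
        if p != self.grid.n_points:
            raise ValueError("columns of X must align with the grid")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("fingerprint matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]
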