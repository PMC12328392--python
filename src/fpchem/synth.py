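"""Synthetic HPLC-DAD fingerprint datasets with known ground truth.

The raw study chromatograms are not deposited, so this module generates
datasets with the same statistical structure the analysis assumes: two
plant species, twenty methanolic extracts each, duplicate injections at
254/280/330 nm on the 13.2-64.5 min / 7696-point analysis grid.  Traces are
sums of Gaussian peaks (shared peaks plus species-specific ones) on a slow
drifting baseline with i.i.d. detector noise; duplicate injections of one
extract share the extract-level peak amplitudes and differ only by noise and
a small injection-scale factor, which calibrates the duplicate Pearson
correlation well above the r > 0.93 reproducibility gate.

A subset of peaks placed in the 20-35 min region is flagged *active*: a
latent antioxidant level is defined as the sum of their extract-level
amplitudes, and the four assay readouts are affine maps of that latent level
plus method noise.  The ground truth (latent level, active peak ids,
species effect) supports parameter-recovery tests of the downstream
chemometrics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import ASSAY_COLUMNS, AssayPanel
from .chromatogram import Chromatogram, ChromatogramSet
from .grid import TimeGrid, default_grid

#: Species labels; the last one is the planted high-antioxidant species.
DEFAULT_SPECIES: tuple[str, str] = ("species_a", "species_b")

#: Compound names assigned to active peaks in the standards table, cycled in
#: order.  Shared active peaks emulate the vitexin region (330 nm); the
#: high-species-specific ones emulate tannic and chlorogenic acid (280 nm).
_SHARED_STANDARDS = ("vitexin", "isovitexin", "orientin")
_SPECIFIC_STANDARDS = ("tannic acid", "chlorogenic acid", "neochlorogenic acid")

#: Affine map (offset, slope) from the latent antioxidant level to each
#: assay column, on realistic mg-equivalents-per-g-DW scales.
_ASSAY_MAPS: dict[str, tuple[float, float]] = {
    "tp_mg_gae_g": (60.0, 30.0),
    "dpph_mg_te_g": (25.0, 12.0),
    "abts_mg_te_g": (35.0, 15.0),
    "frap_mg_te_g": (30.0, 14.0),
}

_ACTIVE_WINDOW_MIN: tuple[float, float] = (20.0, 35.0)


@dataclass(frozen=True)
class Peak:
    id: str
    retention_min: float
    width_sigma_min: float
    amplitude_by_species: Mapping[str, float]
    active: bool = False


@dataclass(frozen=True)
class PeakLibrary:
    peaks: tuple[Peak, ...]
    species: tuple[str, ...]

    def active_peaks(self) -> list[Peak]:
        return [p for p in self.peaks if p.active]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.peaks)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults reproduce the study layout: 2 species x 20 extracts x duplicate
    injections (80 chromatograms per wavelength) at 254/280/330 nm.
    ``seed`` fixes every random draw in this module.
    """

    n_species: int = 2
    n_extracts_per_species: int = 20
    n_injection_replicates: int = 2
    wavelengths_nm: tuple[int, ...] = (254, 280, 330)
    noise_sd: float = 0.002  # AU, detector noise
    drift_amplitude: float = 0.05  # AU, ~5% of max peak height
    drift_curvature: float = 0.6  # quadratic share of the drift shape
    assay_noise_fraction: float = 0.10  # method noise, fraction of sd(latent)
    extract_log_sd: float = 0.2  # lognormal sd of extract-level amplitudes
    injection_scale_sd: float = 0.01  # per-injection global scale factor sd
    n_shared_peaks: int = 10
    n_specific_peaks_per_species: int = 5
    n_active_peaks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_extracts_per_species, self.n_injection_replicates) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.assay_noise_fraction < 0:
            raise ValueError("noise and drift parameters must be non-negative")

    def species_labels(self) -> tuple[str, ...]:
        if self.n_species <= len(DEFAULT_SPECIES):
            return DEFAULT_SPECIES[: self.n_species]
        return tuple(f"species_{chr(ord('a') + i)}" for i in range(self.n_species))


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities enabling parameter-recovery tests."""

    latent_activity: dict[str, float]  # extract id -> latent level
    active_peak_ids: frozenset[str]
    species_effect: float  # mean latent difference, high minus low species


@dataclass
class SimulatedDataset:
    """Everything one study run produces, plus the generator internals."""

    chromatograms: ChromatogramSet
    blanks: list[Chromatogram]
    panel: AssayPanel
    standards: pd.DataFrame  # columns: compound, retention_min, wavelength_nm
    truth: GroundTruth
    library: PeakLibrary
    grid: TimeGrid


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf8"))


def simulate_peak_library(
    seed: int,
    n_shared: int = 10,
    n_specific_per_species: int = 5,
    n_active: int = 3,
    window: TimeGrid | None = None,
    species: Sequence[str] = DEFAULT_SPECIES,
) -> PeakLibrary:
    """Draw a deterministic peak library.

    Shared peaks have equal amplitude in every species; species-specific
    peaks have zero amplitude elsewhere.  Active peaks (those that drive the
    latent antioxidant level) are re-placed inside the 20-35 min region: the
    first is a shared peak, the rest are specific to the high-activity
    (last) species, overflowing back to shared peaks if needed.
    """
    window = window or default_grid()
    species = tuple(species)
    if n_active > n_shared + n_specific_per_species:
        raise ValueError("n_active cannot exceed n_shared + n_specific_per_species")
    lo, hi = _ACTIVE_WINDOW_MIN
    if n_active > 0 and (window.start_min > lo or window.end_min < hi):
        raise ValueError(
            f"window [{window.start_min}, {window.end_min}] min does not cover "
            f"the {lo}-{hi} min active-peak region"
        )
    rng = np.random.default_rng(seed)
    t0, t1 = window.start_min + 0.5, window.end_min - 0.5

    def draw_retention(taken: list[float], low: float, high: float) -> float:
        # rejection with a minimum 0.8 min separation keeps peaks resolvable
        for _ in range(200):
            r = float(rng.uniform(low, high))
            if all(abs(r - t) > 0.8 for t in taken):
                return r
        return float(rng.uniform(low, high))  # pragma: no cover - dense fallback

    taken: list[float] = []
    peaks: list[Peak] = []
    for i in range(n_shared):
        r = draw_retention(taken, t0, t1)
        taken.append(r)
        amp = float(rng.uniform(0.2, 1.0))
        peaks.append(
            Peak(
                id=f"shared_{i + 1:02d}",
                retention_min=r,
                width_sigma_min=float(rng.uniform(0.08, 0.25)),
                amplitude_by_species={sp: amp for sp in species},
                active=False,
            )
        )
    for sp in species:
        for i in range(n_specific_per_species):
            r = draw_retention(taken, t0, t1)
            taken.append(r)
            amp = float(rng.uniform(0.7, 1.3))
            peaks.append(
                Peak(
                    id=f"{sp}_spec_{i + 1:02d}",
                    retention_min=r,
                    width_sigma_min=float(rng.uniform(0.08, 0.25)),
                    amplitude_by_species={s: (amp if s == sp else 0.0) for s in species},
                    active=False,
                )
            )

    # pick active peaks: one shared, then high-species specific, then shared
    high = species[-1]
    shared_ids = [p.id for p in peaks if p.id.startswith("shared_")]
    specific_ids = [p.id for p in peaks if p.id.startswith(f"{high}_spec_")]
    order: list[str] = []
    if n_shared >= 1 and n_active >= 1:
        order.append(shared_ids[0])
    order += specific_ids[: max(0, n_active - len(order))]
    order += [pid for pid in shared_ids[1:] if len(order) < n_active][
        : max(0, n_active - len(order))
    ]
    active_ids = set(order[:n_active])

    # re-place active peaks inside 20-35 min, stratified so they spread out,
    # and kept >= 0.8 min from every other peak so apexes stay resolvable
    placements: dict[str, float] = {}
    others = [p.retention_min for p in peaks if p.id not in active_ids]
    for k, pid in enumerate(order[:n_active]):
        left = lo + 0.5 + (hi - lo - 1.0) * k / max(1, n_active)
        right = lo + 0.5 + (hi - lo - 1.0) * (k + 0.8) / max(1, n_active)
        r = draw_retention(others + list(placements.values()), left, right)
        placements[pid] = r

    final: list[Peak] = []
    for p in peaks:
        if p.id in active_ids:
            amp = float(rng.uniform(0.6, 1.0))
            if p.id.startswith("shared_"):
                amps = {sp: amp for sp in species}
            else:
                amps = {sp: (amp if sp == high else 0.0) for sp in species}
            final.append(
                Peak(
                    id=p.id,
                    retention_min=placements[p.id],
                    width_sigma_min=p.width_sigma_min,
                    amplitude_by_species=amps,
                    active=True,
                )
            )
        else:
            final.append(p)
    return PeakLibrary(peaks=tuple(final), species=species)


def _extract_factors(library: PeakLibrary, extract_id: str, cfg: SimConfig) -> dict[str, float]:
    """Extract-level lognormal amplitude factors, one per peak."""
    rng = np.random.default_rng([cfg.seed, _crc(extract_id), 4201])
    return {
        p.id: float(np.exp(rng.normal(0.0, cfg.extract_log_sd))) for p in library.peaks
    }


def _wavelength_factor(peak_id: str, wavelength_nm: int) -> float:
    """Fixed per-compound detector response relative to 280 nm."""
    if wavelength_nm == 280:
        return 1.0
    rng = np.random.default_rng([_crc(peak_id), wavelength_nm, 6301])
    return float(np.exp(rng.normal(0.0, 0.3)))


def _drift(grid: TimeGrid, wavelength_nm: int, cfg: SimConfig) -> np.ndarray:
    """Deterministic slow baseline drift shared by samples and blanks."""
    if cfg.drift_amplitude == 0:
        return np.zeros(grid.n_points)
    rng = np.random.default_rng([cfg.seed, wavelength_nm, 7001])
    t = grid.points
    x = (t - t[0]) / (t[-1] - t[0])
    phase = rng.uniform(0.0, 2.0 * np.pi)
    period = rng.uniform(35.0, 55.0)  # min; slow relative to the window
    lin = rng.uniform(-0.4, 0.4)
    shape = (
        0.5 * np.sin(2.0 * np.pi * (t - t[0]) / period + phase)
        + lin * x
        + cfg.drift_curvature * (x - 0.5) ** 2
    )
    return cfg.drift_amplitude * shape


def _peak_profile(
    grid: TimeGrid,
    library: PeakLibrary,
    species: str,
    factors: Mapping[str, float],
    wavelength_nm: int,
) -> np.ndarray:
    t = grid.points
    y = np.zeros_like(t)
    for p in library.peaks:
        amp = p.amplitude_by_species[species] * factors[p.id]
        amp *= _wavelength_factor(p.id, wavelength_nm)
        if amp == 0.0:
            continue
        lo = np.searchsorted(t, p.retention_min - 6.0 * p.width_sigma_min)
        hi = np.searchsorted(t, p.retention_min + 6.0 * p.width_sigma_min)
        seg = t[lo:hi]
        y[lo:hi] += amp * np.exp(-0.5 * ((seg - p.retention_min) / p.width_sigma_min) ** 2)
    return y


def simulate_chromatogram(
    library: PeakLibrary,
    species: str,
    extract_id: str,
    replicate: int,
    grid: TimeGrid,
    cfg: SimConfig,
    wavelength_nm: int = 280,
    extract_factors: Mapping[str, float] | None = None,
) -> Chromatogram:
    """Simulate one injection of one extract at one wavelength.

    Replicate injections of the same extract share the extract-level peak
    amplitudes and differ only in detector noise and a small injection-scale
    factor.
    """
    for p in library.peaks:
        if species not in p.amplitude_by_species:
            raise ValueError(f"species {species!r} absent from peak {p.id} amplitude map")
    factors = dict(extract_factors) if extract_factors else _extract_factors(library, extract_id, cfg)
    signal = _peak_profile(grid, library, species, factors, wavelength_nm)
    rng = np.random.default_rng([cfg.seed, wavelength_nm, _crc(extract_id), replicate + 1, 11])
    inj = 1.0 + rng.normal(0.0, cfg.injection_scale_sd) if cfg.injection_scale_sd > 0 else 1.0
    noise = rng.normal(0.0, cfg.noise_sd, grid.n_points) if cfg.noise_sd > 0 else 0.0
    absorbance = inj * signal + _drift(grid, wavelength_nm, cfg) + noise
    return Chromatogram(
        sample_id=f"{extract_id}_r{replicate}",
        species=species,
        extract_id=extract_id,
        replicate=replicate,
        wavelength_nm=wavelength_nm,
        grid=grid,
        absorbance=absorbance,
        blank=False,
    )


def simulate_blank(
    grid: TimeGrid,
    cfg: SimConfig,
    wavelength_nm: int = 280,
    index: int = 0,
) -> Chromatogram:
    """A blank injection: drift plus noise only, flagged ``blank=True``."""
    rng = np.random.default_rng([cfg.seed, wavelength_nm, 999, index])
    noise = rng.normal(0.0, cfg.noise_sd, grid.n_points) if cfg.noise_sd > 0 else 0.0
    return Chromatogram(
        sample_id=f"blank_{wavelength_nm}_{index}",
        species=None,
        extract_id=f"blank_{index}",
        replicate=index,
        wavelength_nm=wavelength_nm,
        grid=grid,
        absorbance=_drift(grid, wavelength_nm, cfg) + noise,
        blank=True,
    )


def make_ground_truth(
    library: PeakLibrary,
    factors_by_extract: Mapping[str, Mapping[str, float]],
    species_of: Mapping[str, str],
) -> GroundTruth:
    """Latent antioxidant level: unit-weight sum of active-peak amplitudes."""
    actives = library.active_peaks()
    latent = {
        ext: float(
            sum(p.amplitude_by_species[species_of[ext]] * f[p.id] for p in actives)
        )
        for ext, f in factors_by_extract.items()
    }
    high = library.species[-1]
    hi_vals = [v for e, v in latent.items() if species_of[e] == high]
    lo_vals = [v for e, v in latent.items() if species_of[e] != high]
    effect = float(np.mean(hi_vals) - np.mean(lo_vals)) if hi_vals and lo_vals else 0.0
    return GroundTruth(
        latent_activity=latent,
        active_peak_ids=frozenset(p.id for p in actives),
        species_effect=effect,
    )


def simulate_assay_panel(
    truth: GroundTruth,
    cfg: SimConfig,
    species_of: Mapping[str, str] | None = None,
) -> AssayPanel:
    """Four assay columns as affine maps of the latent level plus noise.

    Method noise has sd ``assay_noise_fraction * sd(latent)`` on the latent
    scale, independently per assay, so all four columns are noisy affine
    views of the same underlying antioxidant capacity.
    """
    extracts = list(truth.latent_activity)
    latent = np.array([truth.latent_activity[e] for e in extracts])
    if species_of is None:
        species_of = {e: e.rsplit("_e", 1)[0] for e in extracts}
    sd_latent = float(latent.std(ddof=1)) if latent.size > 1 else 0.0
    # degenerate truth (no active peaks): pure method noise on a unit
    # latent scale, so the panel is still a valid, non-constant readout
    noise_sd = cfg.assay_noise_fraction * (sd_latent if sd_latent > 0 else 1.0)
    rng = np.random.default_rng([cfg.seed, 555])
    cols = {}
    for name in ASSAY_COLUMNS:
        offset, slope = _ASSAY_MAPS[name]
        eps = rng.normal(0.0, noise_sd, latent.size) if noise_sd > 0 else 0.0
        cols[name] = offset + slope * (latent + eps)
    data = pd.DataFrame(cols, index=extracts)[list(ASSAY_COLUMNS)]
    return AssayPanel(
        sample_ids=extracts,
        species=[species_of[e] for e in extracts],
        data=data,
    )


def _standards_table(library: PeakLibrary) -> pd.DataFrame:
    """Name the active peaks after phenolic standards with true retentions."""
    rows = []
    shared_i = specific_i = 0
    high = library.species[-1]
    for p in library.active_peaks():
        if p.amplitude_by_species[high] and all(
            p.amplitude_by_species[s] for s in library.species
        ):
            name = _SHARED_STANDARDS[shared_i % len(_SHARED_STANDARDS)]
            shared_i += 1
            wl = 330
        else:
            name = _SPECIFIC_STANDARDS[specific_i % len(_SPECIFIC_STANDARDS)]
            specific_i += 1
            wl = 280
        rows.append({"compound": name, "retention_min": p.retention_min, "wavelength_nm": wl})
    return pd.DataFrame(rows, columns=["compound", "retention_min", "wavelength_nm"])


def simulate_dataset(cfg: SimConfig, grid: TimeGrid | None = None) -> SimulatedDataset:
    """Generate a full study dataset under ``cfg``.

    Produces ``n_species * n_extracts * n_replicates`` chromatograms per
    wavelength, one blank per wavelength, the assay panel driven by the
    planted latent level, and the standards retention-time table.
    """
    grid = grid or default_grid()
    species = cfg.species_labels()
    library = simulate_peak_library(
        cfg.seed,
        cfg.n_shared_peaks,
        cfg.n_specific_peaks_per_species,
        cfg.n_active_peaks,
        window=grid,
        species=species,
    )
    extracts: list[tuple[str, str]] = []  # (extract_id, species)
    for sp in species:
        for i in range(cfg.n_extracts_per_species):
            extracts.append((f"{sp}_e{i + 1:02d}", sp))
    factors = {ext: _extract_factors(library, ext, cfg) for ext, _ in extracts}
    species_of = dict(extracts)
    truth = make_ground_truth(library, factors, species_of)

    chroms: list[Chromatogram] = []
    for wl in cfg.wavelengths_nm:
        for ext, sp in extracts:
            for rep in range(1, cfg.n_injection_replicates + 1):
                chroms.append(
                    simulate_chromatogram(
                        library, sp, ext, rep, grid, cfg,
                        wavelength_nm=wl, extract_factors=factors[ext],
                    )
                )
    blanks = [simulate_blank(grid, cfg, wavelength_nm=wl) for wl in cfg.wavelengths_nm]
    panel = simulate_assay_panel(truth, cfg, species_of)
    return SimulatedDataset(
        chromatograms=ChromatogramSet(chroms),
        blanks=blanks,
        panel=panel,
        standards=_standards_table(library),
        truth=truth,
        library=library,
        grid=grid,
    )
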