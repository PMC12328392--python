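"""Raw chromatograms to analysis-ready fingerprint matrices.

The pipeline follows standard fingerprinting practice for liquid
chromatography: subtract the blank injection, check duplicate-injection
reproducibility with Pearson's r (a gate at r >= 0.93; alignment is never
performed — a high replicate correlation removes the need for it),
consolidate replicates into one trace per extract, correct the baseline and
crop to the analysis window.

Baseline correction uses an iterative local-suppression estimator in the
spirit of the R ``baseline::fillPeaks`` method: each point is repeatedly
replaced by the minimum of its current value and a symmetric interpolation
of its neighbourhood, over window half-widths that shrink geometrically.
The interpolation uses the four-point stencil
``(4*(b[i-m] + b[i+m]) - (b[i-2m] + b[i+2m])) / 6``, which is exact for
cubic backgrounds, so slow curved drift is tracked without the systematic
undershoot a plain two-point average suffers, while peaks (narrow relative
to the largest window) are cut down to the interpolated background.
Savitzky-Golay smoothing (quadratic, edge-exact) is applied before the
suppression, to keep detector noise out of the minimum envelope, and after
it, to return a smooth baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.signal import savgol_filter

from .chromatogram import Chromatogram, ChromatogramSet, FingerprintMatrix
from .grid import DEFAULT_WINDOW_MIN, TimeGrid

#: Duplicate-injection reproducibility gate on Pearson's r.
REPRODUCIBILITY_THRESHOLD: float = 0.93


@dataclass
class BaselineResult:
    """Baseline estimate and the corrected (input minus baseline) trace."""

    baseline: np.ndarray = field(repr=False)
    corrected: np.ndarray = field(repr=False)
    params: dict


def subtract_blank(chrom: Chromatogram, blank: Chromatogram) -> Chromatogram:
    """Elementwise blank subtraction; negative values are retained."""
    if not blank.blank:
        raise ValueError(f"{blank.sample_id!r} is not flagged as a blank")
    if chrom.wavelength_nm != blank.wavelength_nm:
        raise ValueError(
            f"wavelength mismatch: {chrom.wavelength_nm} vs {blank.wavelength_nm} nm"
        )
    if not chrom.grid.isclose(blank.grid):
        raise ValueError(
            f"grid mismatch: {chrom.grid.n_points} vs {blank.grid.n_points} points"
        )
    return chrom.with_absorbance(chrom.absorbance - blank.absorbance)


def _pearson(a: np.ndarray, b: np.ndarray, name_a: str, name_b: str) -> float:
    if np.ptp(a) == 0:
        raise ValueError(f"constant trace for sample {name_a!r}; correlation undefined")
    if np.ptp(b) == 0:
        raise ValueError(f"constant trace for sample {name_b!r}; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def replicate_correlation(
    cset: ChromatogramSet, wavelength_nm: int | None = None
) -> dict[str, float]:
    """Minimum pairwise Pearson r between replicate traces, per extract."""
    if wavelength_nm is not None:
        cset = cset.at_wavelength(wavelength_nm)
    out: dict[str, float] = {}
    for ext, traces in cset.by_extract().items():
        if len(traces) < 2:
            raise ValueError(f"extract {ext!r} has fewer than 2 replicates")
        rs = [
            _pearson(a.absorbance, b.absorbance, a.sample_id, b.sample_id)
            for a, b in combinations(traces, 2)
        ]
        out[ext] = min(rs)
    return out


def gate_reproducibility(
    rs: dict[str, float], threshold: float = REPRODUCIBILITY_THRESHOLD
) -> tuple[set[str], set[str]]:
    """Partition extracts by the r >= threshold reproducibility gate.

    Failures trigger a warning (not an error); no alignment is attempted in
    either case.
    """
    passed = {e for e, r in rs.items() if r >= threshold}
    failed = set(rs) - passed
    if failed:
        warnings.warn(
            f"{len(failed)} extract(s) below the r >= {threshold:g} "
            f"reproducibility gate: {sorted(failed)}",
            stacklevel=2,
        )
    return passed, failed


def consolidate_replicates(cset: ChromatogramSet, method: str = "mean") -> ChromatogramSet:
    """One trace per extract: pointwise mean (default) or median."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    reducer = np.mean if method == "mean" else np.median
    out: list[Chromatogram] = []
    for ext, traces in cset.by_extract().items():
        g = traces[0].grid
        for t in traces[1:]:
            if not t.grid.isclose(g):
                raise ValueError(f"replicates of extract {ext!r} are on different grids")
        stacked = np.vstack([t.absorbance for t in traces])
        proto = traces[0]
        out.append(
            Chromatogram(
                sample_id=ext,
                species=proto.species,
                extract_id=ext,
                replicate=0,
                wavelength_nm=proto.wavelength_nm,
                grid=g,
                absorbance=reducer(stacked, axis=0),
                blank=proto.blank,
            )
        )
    return ChromatogramSet(out)


def group_median(cset: ChromatogramSet, by: str = "species") -> dict[str, Chromatogram]:
    """Pointwise median trace per group (default grouping: species)."""
    if by != "species":
        raise ValueError("only grouping by species is supported")
    out: dict[str, Chromatogram] = {}
    for label, traces in cset.by_species().items():
        if not traces:
            raise ValueError(f"empty group {label!r}")
        g = traces[0].grid
        stacked = np.vstack([t.absorbance for t in traces])
        out[label] = Chromatogram(
            sample_id=f"median_{label}",
            species=traces[0].species,
            extract_id=f"median_{label}",
            replicate=0,
            wavelength_nm=traces[0].wavelength_nm,
            grid=g,
            absorbance=np.median(stacked, axis=0),
            blank=False,
        )
    return out


def _odd_window(n_points: int, minimum: int = 5) -> int:
    w = max(minimum, n_points)
    return w + 1 if w % 2 == 0 else w


def estimate_baseline(
    chrom: Chromatogram,
    half_window_min: float = 2.0,
    iterations: int = 8,
    smooth_window_min: float = 0.2,
) -> BaselineResult:
    """Iterative local-suppression baseline estimate.

    ``half_window_min`` is the largest suppression half-width (must comfortably
    exceed the widest peak), shrinking geometrically to ``smooth_window_min``
    over ``iterations`` passes.  The corrected trace is ``input - baseline``,
    not clipped at zero.
    """
    if half_window_min <= 0:
        raise ValueError("half_window_min must be positive")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = chrom.absorbance
    n = y.size
    dt = chrom.grid.spacing_min
    m0 = int(round(half_window_min / dt))
    if 2 * m0 + 1 > n:
        raise ValueError(
            f"suppression window ({2 * m0 + 1} points) wider than trace ({n} points)"
        )
    m_min = max(1, int(round(smooth_window_min / dt)))
    ms = np.unique(
        np.round(np.geomspace(m0, m_min, iterations)).astype(int)
    )[::-1]

    sw = _odd_window(int(round(smooth_window_min / dt)))
    b = savgol_filter(y, sw, 2, mode="interp") if n > sw else y.copy()

    idx = np.arange(n)
    for m in ms:
        mi = np.minimum(np.minimum(idx, n - 1 - idx) // 2, m)
        avg2 = 0.5 * (b[idx - mi] + b[idx + mi])
        avg4 = (4.0 * (b[idx - mi] + b[idx + mi]) - (b[idx - 2 * mi] + b[idx + 2 * mi])) / 6.0
        # avg4 is exact for cubic backgrounds but its negative lobe digs in
        # when a peak sits 2m away; avg2 never does, so take the larger
        b = np.minimum(b, np.maximum(avg2, avg4))
    if n > sw:
        b = savgol_filter(b, sw, 2, mode="interp")
    return BaselineResult(
        baseline=b,
        corrected=y - b,
        params={
            "half_window_min": half_window_min,
            "iterations": iterations,
            "smooth_window_min": smooth_window_min,
        },
    )


def correct_baseline(chrom: Chromatogram, **kwargs) -> Chromatogram:
    """Convenience wrapper returning the baseline-corrected chromatogram."""
    return chrom.with_absorbance(estimate_baseline(chrom, **kwargs).corrected)


def crop_window(
    chrom: Chromatogram,
    start_min: float = DEFAULT_WINDOW_MIN[0],
    end_min: float = DEFAULT_WINDOW_MIN[1],
) -> Chromatogram:
    """Keep points with ``start_min <= t <= end_min`` (inclusive)."""
    t = chrom.grid.points
    mask = (t >= start_min - 1e-12) & (t <= end_min + 1e-12)
    if not mask.any():
        raise ValueError(f"crop window [{start_min}, {end_min}] min is empty")
    pts = t[mask]
    new_grid = TimeGrid(
        start_min=float(pts[0]),
        end_min=float(pts[-1]),
        spacing_s=chrom.grid.spacing_s,
        points=pts,
    )
    return chrom.with_absorbance(chrom.absorbance[mask], grid=new_grid)


def build_fingerprint_matrix(
    cset: ChromatogramSet,
    wavelength_nm: int,
    window: tuple[float, float] | None = None,
) -> FingerprintMatrix:
    """Stack consolidated traces into a samples x time matrix.

    Rows are ordered by sample id; species labels are carried through.
    Traces must already share a common grid (resample externally supplied
    data first).
    """
    traces = sorted(
        cset.at_wavelength(wavelength_nm).chromatograms, key=lambda c: c.sample_id
    )
    if not traces:
        raise ValueError(f"no traces at {wavelength_nm} nm")
    if window is not None:
        traces = [crop_window(c, *window) for c in traces]
    g = traces[0].grid
    for c in traces[1:]:
        if not c.grid.isclose(g):
            raise ValueError(
                "heterogeneous grids in fingerprint input; resample traces to a "
                "common grid (see resample_to_grid) before building the matrix"
            )
    return FingerprintMatrix(
        sample_ids=[c.sample_id for c in traces],
        species=[str(c.species) for c in traces],
        wavelength_nm=wavelength_nm,
        grid=g,
        X=np.vstack([c.absorbance for c in traces]),
    )


def resample_to_grid(chrom: Chromatogram, grid: TimeGrid) -> Chromatogram:
    """Linear interpolation onto a target grid (for external data only)."""
    if grid.start_min < chrom.grid.start_min - 1e-9 or grid.end_min > chrom.grid.end_min + 1e-9:
        raise ValueError("target grid extends beyond the measured span")
    values = np.interp(grid.points, chrom.grid.points, chrom.absorbance)
    return chrom.with_absorbance(values, grid=grid)


def preprocess_wavelength(
    cset: ChromatogramSet,
    blank: Chromatogram,
    wavelength_nm: int,
    threshold: float = REPRODUCIBILITY_THRESHOLD,
    window: tuple[float, float] = DEFAULT_WINDOW_MIN,
    baseline_kwargs: dict | None = None,
) -> tuple[FingerprintMatrix, dict[str, float]]:
    """Full pipeline at one wavelength: blank -> gate -> consolidate ->
    baseline -> crop -> matrix.  Returns the matrix and the replicate
    correlations (the gate warns on failures but keeps all extracts).
    """
    traces = [
        subtract_blank(c, blank)
        for c in cset.at_wavelength(wavelength_nm)
        if not c.blank
    ]
    subtracted = ChromatogramSet(traces)
    rs = replicate_correlation(subtracted)
    gate_reproducibility(rs, threshold)
    consolidated = consolidate_replicates(subtracted, method="mean")
    corrected = ChromatogramSet(
        [correct_baseline(c, **(baseline_kwargs or {})) for c in consolidated]
    )
    cropped = ChromatogramSet([crop_window(c, *window) for c in corrected])
    return build_fingerprint_matrix(cropped, wavelength_nm), rs
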