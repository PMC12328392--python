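"""Antioxidant-capacity calibration and composite indices.

Four in-vitro assays are carried: total polyphenols (Folin-Ciocalteu,
expressed as mg gallic-acid equivalents per g dry weight) and the DPPH, ABTS
and FRAP radical/reducing assays (mg Trolox equivalents per g dry weight).
Because the assays differ in chemistry and scale, samples are compared
through a Relative Antioxidant Capacity Index (RACI): the mean of the
per-assay standard scores.  An alternative index uses the sample scores on
the first principal component of the z-scored assay matrix; when the assays
are strongly and equally intercorrelated the two indices agree essentially
exactly, while the PC1 variant additionally reports per-assay loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical assay column order: total polyphenols, DPPH, ABTS, FRAP.
ASSAY_COLUMNS: tuple[str, ...] = (
    "tp_mg_gae_g",
    "dpph_mg_te_g",
    "abts_mg_te_g",
    "frap_mg_te_g",
)


@dataclass
class CalibrationCurve:
    """Ordinary-least-squares standard curve (response vs concentration)."""

    standard_name: str
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass
class AssayPanel:
    """Per-sample assay equivalents (columns :data:`ASSAY_COLUMNS`)."""

    sample_ids: list[str]
    species: list[str]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(ASSAY_COLUMNS):
            raise ValueError(f"assay panel columns must be {ASSAY_COLUMNS}")
        if len(self.data) != len(self.sample_ids) or len(self.species) != len(self.sample_ids):
            raise ValueError("panel rows must align with sample_ids and species")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("assay panel contains missing or non-finite values")

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class AntioxidantIndex:
    """RACI in both forms plus their agreement.

    ``raci_mean`` is the row mean of the z-score matrix; ``pc1_scores`` are
    the sample scores on the first principal component of the same matrix,
    with unit-norm loadings oriented to a positive sum.
    """

    sample_ids: list[str]
    z_matrix: np.ndarray
    raci_mean: np.ndarray
    pc1_scores: np.ndarray
    pc1_loadings: np.ndarray
    r_squared_mean_vs_pc1: float


class SpeciesContrast(NamedTuple):
    mean_high: float
    mean_low: float
    direction_correct: bool


def fit_calibration(
    concentrations: Sequence[float],
    responses: Sequence[float],
    standard_name: str = "standard",
) -> CalibrationCurve:
    """Fit an OLS calibration line of response on concentration."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size != resp.size or conc.size < 3:
        raise ValueError("calibration needs >= 3 matched points")
    if np.ptp(conc) == 0:
        raise ValueError("calibration concentrations are constant")
    res = stats.linregress(conc, resp)
    return CalibrationCurve(
        standard_name=standard_name,
        concentrations=conc,
        responses=resp,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def to_equivalents(
    raw_response: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
    dry_weight_g_per_mL: float = 1.0,
) -> float:
    """Convert a raw assay response to mg equivalents per g dry weight.

    Inverts the calibration line and scales by the dilution factor and the
    dry-drug concentration of the assayed solution.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    if dry_weight_g_per_mL <= 0:
        raise ValueError("dry weight must be positive")
    conc = (raw_response - curve.intercept) / curve.slope
    return conc * dilution_factor / dry_weight_g_per_mL


def zscore_matrix(panel: AssayPanel) -> np.ndarray:
    """Column-wise standard scores, sample (n-1) standard deviation."""
    x = panel.values()
    if x.shape[0] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [ASSAY_COLUMNS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant assay column(s): {bad}")
    return (x - x.mean(axis=0)) / sd


def raci_mean(z: np.ndarray) -> np.ndarray:
    """RACI as the row mean of the standard-score matrix."""
    z = np.asarray(z, dtype=float)
    return z.mean(axis=1)


def raci_pc1(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PC1-score antioxidant index of the z-matrix.

    Returns ``(scores, loadings)`` where loadings are the first right
    singular vector of ``z`` (unit norm, oriented so the loading sum is
    positive) and ``scores = z @ loadings``.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] <= z.shape[1]:
        raise ValueError("PC1 index needs more samples than assays")
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-0 z-matrix")
    loadings = vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    return z @ loadings, loadings


def compare_indices(raci: np.ndarray, pc1: np.ndarray) -> float:
    """R-squared of the OLS regression of the PC1 index on the mean RACI."""
    raci = np.asarray(raci, dtype=float)
    pc1 = np.asarray(pc1, dtype=float)
    if raci.size != pc1.size or raci.size < 3:
        raise ValueError("indices must have equal length >= 3")
    if np.ptp(raci) == 0 or np.ptp(pc1) == 0:
        raise ValueError("constant index; R^2 undefined")
    return float(stats.linregress(raci, pc1).rvalue ** 2)


def antioxidant_index(panel: AssayPanel) -> AntioxidantIndex:
    """Compute both RACI variants and their agreement for a panel."""
    z = zscore_matrix(panel)
    mean_idx = raci_mean(z)
    pc1, loadings = raci_pc1(z)
    return AntioxidantIndex(
        sample_ids=list(panel.sample_ids),
        z_matrix=z,
        raci_mean=mean_idx,
        pc1_scores=pc1,
        pc1_loadings=loadings,
        r_squared_mean_vs_pc1=compare_indices(mean_idx, pc1),
    )


def compute_der(drug_mass_g: float, extract_mass_g: float) -> float:
    """Drug-extract ratio, the X in "X:1" (dried drug mass per extract mass)."""
    if drug_mass_g <= 0 or extract_mass_g <= 0:
        raise ValueError("masses must be positive")
    return drug_mass_g / extract_mass_g


def species_contrast(
    index: np.ndarray,
    species: Sequence[str],
    high_label: str | None = None,
) -> SpeciesContrast:
    """Group means of an index for a two-species design.

    ``direction_correct`` reports whether ``high_label`` (the species
    expected to be more active, if known) indeed has the higher mean.
    """
    index = np.asarray(index, dtype=float)
    labels = np.asarray(list(species))
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("species_contrast needs exactly 2 species labels")
    means = {lab: float(index[labels == lab].mean()) for lab in uniq}
    for lab in uniq:
        if np.sum(labels == lab) < 2:
            raise ValueError(f"species {lab!r} has fewer than 2 samples")
    hi = max(means, key=means.get)
    lo = min(means, key=means.get)
    direction = True if high_label is None else means[high_label] >= means[hi]
    return SpeciesContrast(means[hi], means[lo], bool(direction))
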