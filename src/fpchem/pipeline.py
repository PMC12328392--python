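"""End-to-end orchestration: simulate -> preprocess -> cluster -> index ->
model -> markers, plus the chromatographic gradient-program bookkeeping.

``run_pipeline`` executes the whole analysis at the configured wavelengths
(default 280 and 330 nm; 254 nm is recorded metadata only) and returns a
machine-readable report in which every number is reproducible from the
configuration and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .activity import antioxidant_index, species_contrast
from .chemometrics import (
    MarkerReport,
    find_marker_intervals,
    fit_fingerprint_model,
    fit_metrics,
    loo_cv,
    match_standards,
    regression_coefficients,
)
from .grid import DEFAULT_WINDOW_MIN
from .preprocess import REPRODUCIBILITY_THRESHOLD, preprocess_wavelength
from .similarity import cut_clusters, validate_clustering
from .synth import SimConfig, simulate_dataset

logger = logging.getLogger("fpchem")

#: The study's elution program: ratio A/B nodes (time_min, %A, %B), 15 min
#: re-equilibration, 0.75 mL/min on a C18 column at 30 degC.
STUDY_GRADIENT_SEGMENTS: tuple[tuple[float, float, float], ...] = (
    (0.0, 100.0, 0.0),
    (5.0, 100.0, 0.0),
    (55.0, 50.0, 50.0),
    (90.0, 0.0, 100.0),
    (95.0, 100.0, 0.0),
)


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear binary gradient with explicit hold nodes."""

    segments: tuple[tuple[float, float, float], ...]
    re_equilibration_min: float = 0.0
    flow_mL_min: float = 0.75
    column: str = "C18 250x4 mm, 5 um"
    temperature_c: float = 30.0

    def __post_init__(self) -> None:
        times = [s[0] for s in self.segments]
        if not self.segments or times[0] != 0.0:
            raise ValueError("gradient must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("gradient node times must be strictly increasing")
        for t, a, b in self.segments:
            if abs(a + b - 100.0) > 1e-9:
                raise ValueError(f"composition at {t} min does not sum to 100%")


def study_gradient() -> GradientProgram:
    return GradientProgram(segments=STUDY_GRADIENT_SEGMENTS, re_equilibration_min=15.0)


def total_runtime(g: GradientProgram) -> float:
    """Last gradient node plus re-equilibration, in minutes."""
    return g.segments[-1][0] + g.re_equilibration_min


def composition_at(g: GradientProgram, t_min: float) -> tuple[float, float]:
    """Mobile-phase composition (%A, %B) at time t by linear interpolation."""
    times = np.array([s[0] for s in g.segments])
    pa = np.array([s[1] for s in g.segments])
    if t_min < times[0] or t_min > times[-1]:
        raise ValueError(f"t={t_min} min outside the gradient span [0, {times[-1]}]")
    a = float(np.interp(t_min, times, pa))
    return a, 100.0 - a


@dataclass
class RunReport:
    """Machine-readable end-to-end result."""

    seed: int
    version: str
    config: dict
    raci: dict
    per_wavelength: dict
    def to_dict(self) -> dict:
        return asdict(self)


_DEFAULT_CONFIG: dict = {
    "simulate": {"seed": 1},
    "preprocess": {
        "wavelengths_nm": [280, 330],
        "window_min": list(DEFAULT_WINDOW_MIN),
        "threshold": REPRODUCIBILITY_THRESHOLD,
        "baseline": {"half_window_min": 2.0, "iterations": 8},
    },
    "cluster": {"sqrt": True, "k": 2},
    "model": {"pls_components": 2, "opls_orthogonal": 1, "cv": "loo"},
    "markers": {"rel_threshold": 0.1, "min_width_min": 0.1, "tolerance_min": 0.5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(source) -> dict:
    """Accepts a YAML/JSON path or a dict; fills in defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    if not isinstance(source, dict):
        raise ValueError("config must be a mapping or a path to one")
    return _merge(_DEFAULT_CONFIG, source)


def _marker_dict(report: MarkerReport) -> dict:
    return {
        "intervals": [asdict(iv) for iv in report.intervals],
        "matches": [
            {
                "compound": m.compound,
                "retention_min": m.retention_min,
                "apex_min": m.interval.apex_min,
                "delta_min": m.delta_min,
            }
            for m in report.matches
        ],
    }


def run_pipeline(config, out_dir=None, seed: int | None = None) -> RunReport:
    """Run the full analysis; any stage error aborts with stage context.

    ``seed`` overrides ``config["simulate"]["seed"]``.  When ``out_dir`` is
    given, intermediate CSVs and the JSON report are written there.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["simulate"]["seed"] = int(seed)
    sim_kwargs = dict(cfg["simulate"])
    sim = SimConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in sim_kwargs.items()})

    logger.info("simulating dataset (seed=%d)", sim.seed)
    ds = simulate_dataset(sim)

    idx = antioxidant_index(ds.panel)
    contrast = species_contrast(
        idx.raci_mean, ds.panel.species, high_label=sim.species_labels()[-1]
    )
    raci_summary = {
        "sample_ids": idx.sample_ids,
        "raci_mean": idx.raci_mean.tolist(),
        "pc1_scores": idx.pc1_scores.tolist(),
        "pc1_loadings": idx.pc1_loadings.tolist(),
        "r_squared_mean_vs_pc1": idx.r_squared_mean_vs_pc1,
        "species_means": {"high": contrast.mean_high, "low": contrast.mean_low},
        "direction_correct": contrast.direction_correct,
    }

    pp = cfg["preprocess"]
    per_wl: dict[str, dict] = {}
    for wl in pp["wavelengths_nm"]:
        stage = f"preprocess@{wl}nm"
        try:
            blank = next(b for b in ds.blanks if b.wavelength_nm == wl)
            F, rs = preprocess_wavelength(
                ds.chromatograms,
                blank,
                wl,
                threshold=pp["threshold"],
                window=tuple(pp["window_min"]),
                baseline_kwargs=pp["baseline"],
            )
            gate_min = min(rs.values())
            logger.info("%s: min replicate r = %.4f (gate %.2f)", stage, gate_min, pp["threshold"])

            stage = f"cluster@{wl}nm"
            val, tree, _ = validate_clustering(F, use_sqrt=cfg["cluster"]["sqrt"], seed=sim.seed)
            labels = cut_clusters(tree, k=cfg["cluster"]["k"])

            stage = f"model@{wl}nm"
            y = np.array([idx.raci_mean[idx.sample_ids.index(s)] for s in F.sample_ids])
            results = {}
            for kind in ("pls", "opls"):
                model = fit_fingerprint_model(
                    F,
                    y,
                    kind=kind,
                    n_components=cfg["model"]["pls_components"],
                    n_orthogonal=cfg["model"]["opls_orthogonal"],
                )
                cv = loo_cv(
                    F.X,
                    y,
                    kind=kind,
                    n_components=cfg["model"]["pls_components"],
                    n_orthogonal=cfg["model"]["opls_orthogonal"],
                )
                met = fit_metrics(model, F.X, y, cv)
                results[kind] = {
                    "metrics": {
                        "r2x_per_component": met.r2x_per_component.tolist(),
                        "r2x_total": met.r2x_total,
                        "r2y": met.r2y,
                        "msec": met.msec,
                        "rmsec": met.rmsec,
                        "rpd_cal": met.rpd_cal,
                        "msecv": met.msecv,
                        "rmsecv": met.rmsecv,
                        "q2": met.q2,
                        "rpd_cv": met.rpd_cv,
                    }
                }
                if kind == "pls":
                    stage = f"markers@{wl}nm"
                    time_axis, B = regression_coefficients(model)
                    report = find_marker_intervals(
                        time_axis,
                        B,
                        rel_threshold=cfg["markers"]["rel_threshold"],
                        min_width_min=cfg["markers"]["min_width_min"],
                        wavelength_nm=wl,
                    )
                    report = match_standards(
                        report, ds.standards, tolerance_min=cfg["markers"]["tolerance_min"]
                    )
                    results["markers"] = _marker_dict(report)
            per_wl[str(wl)] = {
                "replicate_r_min": gate_min,
                "ccc": val.ccc,
                "hopkins": val.hopkins,
                "cluster_labels": labels,
                **results,
            }
        except Exception as exc:  # re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        seed=sim.seed,
        version=__version__,
        config=cfg,
        raci=raci_summary,
        per_wavelength=per_wl,
    )
    if out_dir is not None:
        _write_outputs(report, ds, cfg, Path(out_dir))
    return report


def _write_outputs(report: RunReport, ds, cfg, out_dir: Path) -> None:
    from . import io as fio

    out_dir.mkdir(parents=True, exist_ok=True)
    for wl in cfg["preprocess"]["wavelengths_nm"]:
        fio.write_chromatograms(
            ds.chromatograms.at_wavelength(wl), out_dir / f"chromatograms_{wl}nm.csv"
        )
    fio.write_assay_panel(ds.panel, out_dir / "assay_panel.csv")
    fio.write_standards(ds.standards, out_dir / "standards.csv")
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))


def summarize(report: RunReport) -> str:
    """Three-significant-digit human summary of a run report."""
    lines = [f"fpchem {report.version} run (seed {report.seed})"]
    lines.append(
        f"  RACI mean-vs-PC1 R^2 = {report.raci['r_squared_mean_vs_pc1']:.6f}; "
        f"loadings {['%.3g' % v for v in report.raci['pc1_loadings']]}"
    )
    for wl, res in report.per_wavelength.items():
        lines.append(
            f"  {wl} nm: min replicate r {res['replicate_r_min']:.4f}, "
            f"CCC {res['ccc']:.3g}, Hopkins {res['hopkins']:.3g}, "
            f"PLS RPDcal {res['pls']['metrics']['rpd_cal']:.3g}, "
            f"{len(res['markers']['intervals'])} marker interval(s)"
        )
    return "\n".join(lines)
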