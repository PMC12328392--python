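"""CSV/JSON dialects for chromatograms, assay panels and standards.

Chromatograms at one wavelength travel as a wide CSV (first column
``time_min``, one column per sample id) with a JSON sidecar carrying the
per-sample metadata (species, extract_id, replicate, wavelength_nm, blank).
The assay panel is ``sample_id`` plus the four equivalents columns; the
standards table is ``compound, retention_min, wavelength_nm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import ASSAY_COLUMNS, AssayPanel
from .chromatogram import Chromatogram, ChromatogramSet
from .grid import TimeGrid, make_time_grid


def write_chromatograms(cset: ChromatogramSet | list, csv_path, sidecar_path=None) -> None:
    """Write a single-wavelength set as wide CSV + JSON metadata sidecar."""
    traces = list(cset)
    if not traces:
        raise ValueError("nothing to write")
    wls = {c.wavelength_nm for c in traces}
    if len(wls) != 1:
        raise ValueError("one file per wavelength; filter the set first")
    g = traces[0].grid
    for c in traces[1:]:
        if not c.grid.isclose(g):
            raise ValueError("traces must share a grid to be written together")
    csv_path = Path(csv_path)
    data = {"time_min": g.points}
    meta = []
    for c in traces:
        data[c.sample_id] = c.absorbance
        meta.append(
            {
                "sample_id": c.sample_id,
                "species": c.species,
                "extract_id": c.extract_id,
                "replicate": c.replicate,
                "wavelength_nm": c.wavelength_nm,
                "blank": c.blank,
            }
        )
    pd.DataFrame(data).to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_chromatograms(csv_path, sidecar_path=None) -> ChromatogramSet:
    """Read the wide CSV + sidecar dialect back into a ChromatogramSet."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if "time_min" not in df.columns:
        raise ValueError("wide chromatogram CSV must have a time_min column")
    t = df["time_min"].to_numpy(dtype=float)
    spacing_s = float(np.median(np.diff(t)) * 60.0)
    grid = make_time_grid(float(t[0]), float(t[-1]), spacing_s)
    if not np.allclose(grid.points, t, atol=1e-6):
        raise ValueError("time_min column is not a uniform grid")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".meta.json")
    meta = {m["sample_id"]: m for m in json.loads(sidecar.read_text())}
    traces = []
    for col in df.columns:
        if col == "time_min":
            continue
        m = meta.get(col, {})
        traces.append(
            Chromatogram(
                sample_id=col,
                species=m.get("species"),
                extract_id=m.get("extract_id", col),
                replicate=int(m.get("replicate", 0)),
                wavelength_nm=int(m.get("wavelength_nm", 0)),
                grid=grid,
                absorbance=df[col].to_numpy(dtype=float),
                blank=bool(m.get("blank", False)),
            )
        )
    return ChromatogramSet(traces)


def write_assay_panel(panel: AssayPanel, path) -> None:
    df = panel.data.copy()
    df.insert(0, "sample_id", panel.sample_ids)
    df.insert(1, "species", panel.species)
    df.to_csv(path, index=False)


def read_assay_panel(path) -> AssayPanel:
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay panel CSV missing columns: {missing}")
    ids = df["sample_id"].astype(str).tolist()
    if "species" in df.columns:
        species = df["species"].astype(str).tolist()
    else:
        species = [s.rsplit("_e", 1)[0] for s in ids]
    data = df[list(ASSAY_COLUMNS)].copy()
    data.index = ids
    return AssayPanel(sample_ids=ids, species=species, data=data)


def write_standards(standards: pd.DataFrame, path) -> None:
    standards.to_csv(path, index=False)


def read_standards(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"compound", "retention_min", "wavelength_nm"}
    if not needed.issubset(df.columns):
        raise ValueError(f"standards CSV must have columns {sorted(needed)}")
    return df
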