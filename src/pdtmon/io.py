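"""Readers and writers for the plain-text and TIFF formats the pipeline uses.

Formats:

* tissue CSV - ``layer,thickness_mm,n,mua_per_mm,musp_per_mm``, one row per
  layer, top first;
* series CSV - ``dose_Jcm2,excitation_nm,intensity`` (long format, both
  excitation channels in one file);
* dose-profile CSV - ``z_mm,absorbed_per_mm``;
* image sessions - 16-bit grayscale TIFF frames, each with a JSON sidecar
  ``{"excitation_nm": ..., "cumulative_dose_Jcm2": ...}``, listed in dose
  order by a manifest CSV;
* grades CSV - ``regime,timepoint,grade``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fluor_kinetics import DoseSeries, FluorescenceFrame
from .layered_mc import OpticalLayer, TissueModel, TransportResult
from .synthetic_data import EdemaGrade, grades_to_frame

__all__ = [
    "read_grades_csv",
    "read_series_csv",
    "read_session",
    "read_tissue_csv",
    "write_dose_profile",
    "write_grades_csv",
    "write_series_csv",
    "write_session",
    "write_tissue_csv",
]

TISSUE_COLUMNS = ["layer", "thickness_mm", "n", "mua_per_mm", "musp_per_mm"]


def read_tissue_csv(path) -> TissueModel:
    df = pd.read_csv(path)
    missing = set(TISSUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tissue CSV {path} is missing columns {sorted(missing)}")
    layers = tuple(
        OpticalLayer(
            name=str(row.layer),
            thickness_mm=float(row.thickness_mm),
            n=float(row.n),
            mua=float(row.mua_per_mm),
            musp=float(row.musp_per_mm),
        )
        for row in df.itertuples()
    )
    return TissueModel(layers)


def write_tissue_csv(model: TissueModel, path) -> None:
    pd.DataFrame(
        [
            {
                "layer": l.name,
                "thickness_mm": l.thickness_mm,
                "n": l.n,
                "mua_per_mm": l.mua,
                "musp_per_mm": l.musp,
            }
            for l in model.layers
        ]
    ).to_csv(path, index=False)


def read_series_csv(path) -> dict[int, DoseSeries]:
    """Dose-intensity series per excitation wavelength from a long-format CSV."""
    df = pd.read_csv(path)
    out = {}
    for exc, grp in df.groupby("excitation_nm"):
        grp = grp.sort_values("dose_Jcm2")
        out[int(exc)] = DoseSeries(
            doses=grp["dose_Jcm2"].to_numpy(float),
            intensities=grp["intensity"].to_numpy(float),
            excitation_nm=int(exc),
        )
    if not out:
        raise ValueError(f"series CSV {path} contains no rows")
    return out


def write_series_csv(series: dict[int, DoseSeries] | list[DoseSeries], path) -> None:
    if isinstance(series, dict):
        series = list(series.values())
    rows = []
    for s in series:
        for d, i in zip(s.doses, s.intensities):
            rows.append(
                {"dose_Jcm2": d, "excitation_nm": s.excitation_nm, "intensity": i}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dose_profile(result: TransportResult, prefix) -> None:
    """Dose-profile CSV plus a JSON summary of the energy fractions."""
    prefix = Path(prefix)
    pd.DataFrame(
        {"z_mm": result.z_centers, "absorbed_per_mm": result.absorbed_density}
    ).to_csv(prefix.with_suffix(".csv"), index=False)
    summary = {
        "r_specular": result.r_specular,
        "r_diffuse": result.r_diffuse,
        "transmitted": result.transmitted,
        "absorbed_total": result.absorbed_total,
        "n_photons": result.n_photons,
        "z_bin_mm": result.z_bin,
        "seed": result.seed,
    }
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def write_session(
    frames: list[FluorescenceFrame],
    manifest: pd.DataFrame,
    outdir,
    counts_per_au: float = 1.0,
) -> Path:
    """Write a session as 16-bit TIFFs with JSON sidecars and a manifest CSV.

    counts_per_au scales arbitrary intensity units to camera counts before
    quantization to uint16.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for frame, fname in zip(frames, manifest["file"], strict=True):
        counts = np.clip(np.round(frame.pixels * counts_per_au), 0, 65535)
        tifffile.imwrite(outdir / fname, counts.astype(np.uint16))
        sidecar = {
            "excitation_nm": frame.excitation_nm,
            "cumulative_dose_Jcm2": frame.cumulative_dose,
            "counts_per_au": counts_per_au,
        }
        (outdir / fname).with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2)
        )
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_session(manifest_path) -> list[FluorescenceFrame]:
    """Load a session's frames (in manifest order) from TIFF + sidecar pairs.

    The sidecar JSON is the source of truth for excitation wavelength and
    cumulative dose; intensities are rescaled back to arbitrary units when
    the sidecar records the counts_per_au gain."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"session manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    frames = []
    for fname in df["file"]:
        tif = manifest_path.parent / fname
        sidecar = json.loads(tif.with_suffix(".json").read_text())
        pixels = tifffile.imread(tif).astype(float)
        gain = float(sidecar.get("counts_per_au", 1.0))
        frames.append(
            FluorescenceFrame(
                pixels=pixels / gain,
                excitation_nm=int(sidecar["excitation_nm"]),
                cumulative_dose=float(sidecar["cumulative_dose_Jcm2"]),
            )
        )
    return frames


def write_grades_csv(records: list[EdemaGrade], path) -> None:
    grades_to_frame(records).to_csv(path, index=False)


def read_grades_csv(path) -> list[EdemaGrade]:
    df = pd.read_csv(path)
    return [
        EdemaGrade(regime=str(r.regime), timepoint=str(r.timepoint), level=int(r.grade))
        for r in df.itertuples()
    ]
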