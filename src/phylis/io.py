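"""File formats and configuration: spectrum CSV, dataset CSV, YAML config.

Spectrum files are plain CSV with the header ``position,wavelength_nm,
intensity`` and exactly 1000 data rows; ``#``-prefixed lines before the
header carry provenance metadata (source image, configuration) and are
ignored on read.  Dataset files have one row per spectrum with columns
``group_id, crop[, system][, <soil properties>], v0001..v1000``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .errors import MalformedFile, SchemaError
from .calibration import LabeledSpectrumSet
from .image_extraction import N_POINTS, Spectrum, position_to_wavelength
from .reference import SOIL_PROPERTIES

SPECTRUM_HEADER = ["position", "wavelength_nm", "intensity"]
_VCOLS = [f"v{i:04d}" for i in range(1, N_POINTS + 1)]


def write_spectrum_csv(spectrum: Spectrum, path, metadata: dict | None = None) -> None:
    """Write a spectrum as CSV, with optional ``#``-prefixed metadata lines.

    ``path`` may be a filesystem path or an open text stream.
    """
    def _emit(fh) -> None:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write(",".join(SPECTRUM_HEADER) + "\n")
        for p, v in zip(spectrum.positions, spectrum.values):
            fh.write(f"{p},{position_to_wavelength(int(p)):.6f},{v:.6f}\n")

    if hasattr(path, "write"):
        _emit(path)
    else:
        with open(path, "w", newline="") as fh:
            _emit(fh)


def read_spectrum_csv(path) -> Spectrum:
    """Read a spectrum CSV written by :func:`write_spectrum_csv`.

    Raises :class:`MalformedFile` (with an approximate line number) on a
    wrong header, wrong row count or non-numeric intensities.
    """
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                         skipinitialspace=True)
    except Exception as exc:  # pandas parse failure
        raise MalformedFile(f"{path}: {exc}") from exc
    if list(df.columns) != SPECTRUM_HEADER:
        raise MalformedFile(
            f"{path}: header line must be '{','.join(SPECTRUM_HEADER)}', "
            f"got {list(df.columns)}")
    if len(df) != N_POINTS:
        raise MalformedFile(
            f"{path}: expected {N_POINTS} data rows, found {len(df)} "
            f"(last data line {len(df) + 1})")
    intensities = pd.to_numeric(df["intensity"], errors="coerce")
    if intensities.isna().any():
        bad = int(intensities.isna().idxmax()) + 2
        raise MalformedFile(f"{path}: non-numeric intensity near line {bad}")
    order = pd.to_numeric(df["position"], errors="coerce")
    if order.isna().any() or sorted(order) != list(range(1, N_POINTS + 1)):
        raise MalformedFile(f"{path}: position column must be 1..{N_POINTS}")
    return Spectrum(values=intensities.to_numpy()[np.argsort(order.to_numpy())])


def write_dataset_csv(dataset: LabeledSpectrumSet, path) -> None:
    """Write a labelled spectrum set in the one-row-per-spectrum schema."""
    data = {"group_id": dataset.group_ids, "crop": dataset.crop}
    if dataset.system is not None:
        data["system"] = dataset.system
    df = pd.DataFrame(data)
    if dataset.soil is not None:
        df = pd.concat([df, dataset.soil.reset_index(drop=True)], axis=1)
    spec_df = pd.DataFrame(dataset.spectra, columns=_VCOLS)
    pd.concat([df, spec_df], axis=1).to_csv(path, index=False)


def read_dataset_csv(path) -> LabeledSpectrumSet:
    """Read a dataset CSV back into a :class:`LabeledSpectrumSet`.

    ``group_id``, ``crop`` and the 1000 ``vNNNN`` columns are required;
    ``system`` and soil-property columns are optional.  A ``group_id``
    spanning two different crops triggers a warning (likely labelling
    error — twins come from one plant at one location).
    """
    df = pd.read_csv(path)
    for col in ("group_id", "crop"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    missing_v = [c for c in _VCOLS if c not in df.columns]
    if missing_v:
        raise SchemaError(f"{path}: missing spectrum column '{missing_v[0]}' "
                          f"(and {len(missing_v) - 1} more)")
    crops_per_group = df.groupby("group_id")["crop"].nunique()
    if (crops_per_group > 1).any():
        bad = crops_per_group[crops_per_group > 1].index.tolist()
        warnings.warn(f"group_id(s) {bad} span multiple crops; "
                      "check for labelling errors", stacklevel=2)
    soil_cols = [c for c in SOIL_PROPERTIES if c in df.columns]
    return LabeledSpectrumSet(
        spectra=df[_VCOLS].to_numpy(dtype=float),
        crop=df["crop"].astype(str).tolist(),
        group_ids=df["group_id"].astype(str).tolist(),
        system=df["system"].astype(str).tolist() if "system" in df.columns else None,
        soil=df[soil_cols].astype(float) if soil_cols else None,
    )


class ExtractionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold_frac: float = 0.2
    use_otsu: bool = False
    band_x_frac: float = 0.8
    band_y_frac: float = 0.1
    flip: bool = False


class PreprocessSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "none"
    window_subtract: bool = False
    window_radius: int = 20
    savgol_window: int = 11


class MLPSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden: tuple[int, int] = (20, 20)
    learning_rate: float = 0.05
    epochs: int = 5000


class CVSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 10
    seed: int = 0


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    extraction: ExtractionSettings = ExtractionSettings()
    preprocess: PreprocessSettings = PreprocessSettings()
    linkage: str = "average"
    mlp: MLPSettings = MLPSettings()
    cv: CVSettings = CVSettings()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
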