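"""Synthetic photographs and labelled spectral datasets for end-to-end testing.

No raw data from the device's field campaigns was ever deposited, so every
pipeline stage is exercised against synthetic inputs with known ground truth:

* :func:`render_photograph` is a forward model of the camera image — a dark
  frame, a bright circular aperture (whose centre and radius jitter between
  shots, as when the camera is re-seated), and a horizontal spectrum band of
  700–800 columns whose summed-RGB column intensities encode a known
  reflectance curve scaled by an illumination level.  The slit-wheel
  behaviour is emulated exactly: illumination scales intensity without
  reshaping the curve.
* :func:`generate_crop_dataset` draws replicate spectra around smooth
  class-mean curves, with controllable within-class variation, optional
  twinned pairs sharing a sample-location effect, and cropping-system labels.
* :func:`generate_soil_dataset` samples the eighteen soil properties within
  their observed field ranges and imprints a configurable subset of them
  onto the spectra as smooth spectral signatures (the uncoupled remainder
  emulates properties that leave no visible-range trace in the crop).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import LabeledSpectrumSet
from .image_extraction import (
    MAX_RGB_SUM,
    N_POINTS,
    ExtractionConfig,
    position_to_wavelength,
)
from .reference import SOIL_PROPERTIES, SOIL_PROPERTY_RANGES

#: Properties coupled to the spectrum by default — the nutrient set a crop
#: canopy plausibly reflects; the complement stays uncoupled (no signal).
DEFAULT_COUPLED = ("NO3", "available_N", "Mn", "P", "Mg", "S", "Cu", "Fe", "NH3")


# ---------------------------------------------------------------------------
# smooth curve construction
# ---------------------------------------------------------------------------

def gaussian_bump(center_nm: float, width_nm: float, amplitude: float = 1.0) -> np.ndarray:
    """A Gaussian feature on the 390–700 nm axis, as a 1000-point array."""
    wl = position_to_wavelength(np.arange(1, N_POINTS + 1))
    return amplitude * np.exp(-0.5 * ((wl - center_nm) / width_nm) ** 2)


def smooth_random_curve(rng: np.random.Generator, n_bumps: int = 4,
                        amplitude: float = 1.0) -> np.ndarray:
    """Random smooth zero-baseline curve: a few Gaussian bumps of mixed sign."""
    curve = np.zeros(N_POINTS)
    for _ in range(n_bumps):
        center = rng.uniform(400, 690)
        width = rng.uniform(15, 60)
        amp = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
        curve += gaussian_bump(center, width, amp)
    m = np.max(np.abs(curve))
    return curve * (amplitude / m) if m > 0 else curve


def make_class_curve(rng: np.random.Generator, baseline: float = 0.35,
                     amplitude: float = 0.3) -> np.ndarray:
    """A plausible reflectance-like class mean curve, bounded in (0, 1)."""
    curve = baseline + amplitude * smooth_random_curve(rng, n_bumps=3)
    return np.clip(curve, 0.02, 0.98)


# ---------------------------------------------------------------------------
# photograph rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderSpec:
    """Geometry, illumination and noise settings for one rendered photograph.

    The default geometry puts a radius-470 px aperture in a 1400 × 1100
    frame; with the default band geometry (half-width 0.8 r) that yields a
    spectrum band of ≈ 750 columns, matching the real device's 700–800.
    ``center_offset`` shifts the aperture from frame centre (the camera
    re-seating jitter); ``illumination`` multiplies intensity only and never
    reshapes the curve, like the slit wheel.
    """

    width: int = 1400
    height: int = 1100
    center_offset: tuple[float, float] = (0.0, 0.0)
    radius: float = 470.0
    illumination: float = 1.0
    noise_sd: float = 2.0
    background: float = 3.0     # per-channel background level
    circle_fill: float = 70.0   # per-channel aperture brightness
    band_x_frac: float = 0.8
    band_y_frac: float = 0.1
    tint: float = 0.6           # 0 = neutral grey band, 1 = full hue map

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2 + self.center_offset[0],
                self.height / 2 + self.center_offset[1])


def _rgb_fractions(wavelengths_nm: np.ndarray, tint: float) -> np.ndarray:
    """Per-wavelength RGB split fractions, columns summing to exactly 1."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    r = np.interp(wl, [390, 440, 510, 580, 645, 700], [0.3, 0.1, 0.0, 0.8, 1.0, 1.0])
    g = np.interp(wl, [390, 490, 540, 580, 645, 700], [0.0, 0.3, 1.0, 0.9, 0.1, 0.0])
    b = np.interp(wl, [390, 450, 510, 560, 700], [0.9, 1.0, 0.3, 0.0, 0.0])
    F = np.vstack([r, g, b])
    F = F / F.sum(axis=0, keepdims=True)
    return (1.0 - tint) / 3.0 + tint * F


def _split_channels(totals: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Split summed-RGB totals (≤ 765) into three 8-bit-range channels.

    Channels are first allocated by the hue fractions; any allocation beyond
    the 255 per-channel ceiling is redistributed to channels with headroom,
    so the channel sum always equals the requested total.
    """
    v = np.minimum(totals * fractions, 255.0)
    for _ in range(3):
        deficit = totals - v.sum(axis=0)
        if np.all(deficit <= 1e-9):
            break
        head = 255.0 - v
        tot_head = head.sum(axis=0)
        share = np.where(tot_head > 0, deficit / np.maximum(tot_head, 1e-12), 0.0)
        v = np.minimum(v + head * share, 255.0)
    return v


def render_photograph(curve: np.ndarray, spec: RenderSpec | None = None,
                      seed: int | None = 0) -> np.ndarray:
    """Render a synthetic camera photograph encoding a known reflectance curve.

    ``curve`` is a 1000-point ground-truth reflectance in [0, 1].  The band's
    column summed-RGB intensities equal ``curve × illumination × 765``,
    sampled at exactly the scale positions the extraction stage will assign
    to each column, so extraction round-trips the curve up to quantisation
    and noise.  Returns an (H, W, 3) uint8 array.
    """
    spec = spec or RenderSpec()
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (N_POINTS,):
        raise ValueError(f"curve must have {N_POINTS} points")
    if np.any(curve < 0) or np.any(curve > 1):
        raise ValueError("curve values must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    img = np.full((spec.height, spec.width, 3), spec.background, dtype=float)
    cx, cy = spec.center
    r = spec.radius
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
    img[inside] = spec.circle_fill

    # band box, same convention as the extraction stage
    left = int(round(cx - spec.band_x_frac * r))
    right = int(round(cx + spec.band_x_frac * r))
    top = int(round(cy - spec.band_y_frac * r))
    bottom = int(round(cy + spec.band_y_frac * r))
    n_cols = right - left
    # sample the curve at the scale positions extraction assigns to columns
    scale_pos = 1 + np.arange(n_cols) * (N_POINTS - 1) / (n_cols - 1)
    col_curve = np.interp(scale_pos, np.arange(1, N_POINTS + 1), curve)
    totals = np.clip(col_curve * spec.illumination, 0.0, 1.0) * MAX_RGB_SUM
    fractions = _rgb_fractions(position_to_wavelength(scale_pos), spec.tint)
    channels = _split_channels(totals, fractions)  # (3, n_cols)
    img[top:bottom, left:right, :] = channels.T[np.newaxis, :, :]

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def extraction_config_for(spec: RenderSpec) -> ExtractionConfig:
    """Extraction configuration matching a render geometry's band placement."""
    return ExtractionConfig(band_x_frac=spec.band_x_frac, band_y_frac=spec.band_y_frac)


# ---------------------------------------------------------------------------
# labelled crop datasets
# ---------------------------------------------------------------------------

@dataclass
class ClassModel:
    """Per-class generative model: mean curve plus within-class variation."""

    name: str
    curve: np.ndarray
    within_sd: float = 0.01

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.shape != (N_POINTS,):
            raise ValueError(f"class curve must have {N_POINTS} points")
        if np.any(self.curve < 0) or np.any(self.curve > 1):
            raise ValueError("class curves must lie in [0, 1]")


def _perturbation(rng: np.random.Generator, norm: float) -> np.ndarray:
    """Smooth random curve rescaled to a fixed Euclidean norm."""
    p = smooth_random_curve(rng, n_bumps=3)
    n = np.linalg.norm(p)
    return p * (norm / n) if n > 0 else p


def generate_crop_dataset(classes: list[ClassModel], n_per_class: int,
                          twins: bool = False, seed: int = 0,
                          location_sd: float = 0.0,
                          systems: tuple[str, str] | None = None) -> LabeledSpectrumSet:
    """Replicate spectra around class means, optionally in twinned pairs.

    Each replicate is ``class mean + smooth perturbation`` with perturbation
    norm ``within_sd × sqrt(1000)`` (so ``within_sd`` is an RMS amplitude).
    With ``twins=True``, ``n_per_class`` must be even: consecutive pairs
    share a ``group_id`` and a common location-effect curve of RMS
    ``location_sd``.  ``systems`` assigns the two cropping-system labels to
    alternating groups (no spectral effect — system is not encoded in the
    synthetic spectra, mirroring how weakly the real systems separate).
    """
    if twins and n_per_class % 2:
        raise ValueError("twinned designs need an even n_per_class")
    rng = np.random.default_rng(seed)
    spectra, crop, group_ids, system = [], [], [], []
    group_counter = 0
    for cm in classes:
        members_per_group = 2 if twins else 1
        n_groups = n_per_class // members_per_group
        for g in range(n_groups):
            gid = f"loc{group_counter:03d}"
            group_counter += 1
            loc_effect = (_perturbation(rng, location_sd * np.sqrt(N_POINTS))
                          if location_sd > 0 else 0.0)
            for _ in range(members_per_group):
                pert = (_perturbation(rng, cm.within_sd * np.sqrt(N_POINTS))
                        if cm.within_sd > 0 else 0.0)
                spectra.append(np.clip(cm.curve + loc_effect + pert, 0.0, 1.0))
                crop.append(cm.name)
                group_ids.append(gid)
                if systems is not None:
                    system.append(systems[group_counter % 2])
    return LabeledSpectrumSet(
        spectra=np.vstack(spectra), crop=crop, group_ids=group_ids,
        system=system if systems is not None else None,
    )


def vegetable_garden_design(seed: int = 0, n_classes: int = 12,
                            n_replicates: int = 2,
                            separation_ratio: float = 5.0) -> LabeledSpectrumSet:
    """The community-garden survey design: 12 crops × 2 replicate spectra.

    Class curves are drawn at random; within-class perturbations are scaled
    so the minimum between-class curve distance exceeds the within-class
    replicate distance by at least ``separation_ratio``, guaranteeing
    recoverable clustering structure at ratios ≥ 5.
    """
    rng = np.random.default_rng(seed)
    curves = [make_class_curve(rng) for _ in range(n_classes)]
    dists = [np.linalg.norm(curves[i] - curves[j])
             for i in range(n_classes) for j in range(i + 1, n_classes)]
    min_between = min(dists)
    # replicate-to-replicate distance is at most twice the perturbation norm
    pert_norm = min_between / (2.0 * separation_ratio)
    classes = [ClassModel(name=f"crop{i:02d}", curve=c,
                          within_sd=pert_norm / np.sqrt(N_POINTS))
               for i, c in enumerate(curves)]
    return generate_crop_dataset(classes, n_per_class=n_replicates,
                                 twins=False, seed=seed + 1)


def balruddery_design(seed: int = 0, n_per_class: int = 24,
                      within_sd: float = 0.015, location_sd: float = 0.02,
                      grain_identical: bool = True) -> LabeledSpectrumSet:
    """The agricultural field design: 4 crops × 24 spectra in 48 twin pairs.

    Beans and potatoes get distinct mean curves; the two grain crops (barley,
    wheat) share one mean curve when ``grain_identical`` — spectrally
    indistinguishable classes whose confusion the classifier should
    concentrate on, while the three superclasses stay separable.  Cropping
    systems alternate between groups with no spectral effect.
    """
    rng = np.random.default_rng(seed)
    bean_curve = make_class_curve(rng)
    potato_curve = make_class_curve(rng)
    grain_curve = make_class_curve(rng)
    wheat_curve = grain_curve if grain_identical else make_class_curve(rng)
    # enforce separation between the three superclass curves
    superclass = [bean_curve, potato_curve, grain_curve]
    min_d = min(np.linalg.norm(a - b)
                for i, a in enumerate(superclass) for b in superclass[i + 1:])
    scale = max(1.0, 5.0 * (within_sd + location_sd) * np.sqrt(N_POINTS) / min_d)
    if scale > 1.0:  # widen separation by pushing curves apart around their mean
        center = np.mean(superclass, axis=0)
        bean_curve, potato_curve, grain_curve = (
            np.clip(center + scale * (c - center), 0.0, 1.0) for c in superclass)
        wheat_curve = grain_curve if grain_identical else wheat_curve
    classes = [
        ClassModel("beans", bean_curve, within_sd),
        ClassModel("potatoes", potato_curve, within_sd),
        ClassModel("barley", grain_curve, within_sd),
        ClassModel("wheat", wheat_curve, within_sd),
    ]
    return generate_crop_dataset(classes, n_per_class=n_per_class, twins=True,
                                 seed=seed, location_sd=location_sd,
                                 systems=("sustainable", "conventional"))


# ---------------------------------------------------------------------------
# soil-property datasets
# ---------------------------------------------------------------------------

@dataclass
class SoilCouplingModel:
    """How each soil property imprints on the crop spectrum.

    Coupled properties add ``amplitude × (scaled value − 0.5) × signature``
    to the spectrum, where the signature is a smooth unit-RMS curve specific
    to the property; uncoupled properties add nothing and are therefore
    unrecoverable from the spectrum by construction.  Property values are
    sampled uniformly within the observed field ranges.
    """

    ranges: pd.DataFrame = field(default_factory=lambda: SOIL_PROPERTY_RANGES.copy())
    coupled: tuple[str, ...] = DEFAULT_COUPLED
    amplitude: float = 0.08
    noise_sd: float = 0.0  # RMS of additional uncorrelated smooth noise

    def __post_init__(self) -> None:
        unknown = set(self.coupled) - set(self.ranges.index)
        if unknown:
            raise ValueError(f"coupled properties not in range table: {unknown}")


def generate_soil_dataset(coupling: SoilCouplingModel | None = None,
                          n: int = 96, seed: int = 0,
                          twins: bool = True) -> LabeledSpectrumSet:
    """Spectra carrying soil-property signal, with properties in field ranges.

    With ``twins=True`` (the field design), samples come in pairs sharing a
    location: both twins carry the same soil-property record and nearly the
    same spectrum.
    """
    coupling = coupling or SoilCouplingModel()
    if twins and n % 2:
        raise ValueError("twinned designs need an even n")
    rng = np.random.default_rng(seed)
    base = make_class_curve(rng)
    signatures = {}
    for p in coupling.coupled:  # smooth unit-RMS signature per property
        s = smooth_random_curve(rng, n_bumps=3)
        signatures[p] = s / np.sqrt(np.mean(s ** 2))

    n_groups = n // 2 if twins else n
    members = 2 if twins else 1
    rows, spectra, group_ids = [], [], []
    for g in range(n_groups):
        record = {}
        for p in coupling.ranges.index:
            lo, hi = coupling.ranges.loc[p, "minimum"], coupling.ranges.loc[p, "maximum"]
            record[p] = rng.uniform(lo, hi)
        signal = np.zeros(N_POINTS)
        for p in coupling.coupled:
            lo, hi = coupling.ranges.loc[p, "minimum"], coupling.ranges.loc[p, "maximum"]
            z = (record[p] - lo) / (hi - lo) - 0.5
            signal += coupling.amplitude * z * signatures[p]
        for _ in range(members):
            noise = (_perturbation(rng, coupling.noise_sd * np.sqrt(N_POINTS))
                     if coupling.noise_sd > 0 else 0.0)
            spectra.append(np.clip(base + signal + noise, 0.0, 1.0))
            rows.append(record)
            group_ids.append(f"loc{g:03d}")
    soil = pd.DataFrame(rows)[list(coupling.ranges.index)]
    return LabeledSpectrumSet(
        spectra=np.vstack(spectra), crop=["crop"] * len(spectra),
        group_ids=group_ids, soil=soil,
    )


def generate_leaky_soil_dataset(n_groups: int = 24, seed: int = 0,
                                fingerprint_sd: float = 0.15,
                                property_name: str = "NO3") -> LabeledSpectrumSet:
    """A deliberately leaky twin design for cross-validation ablations.

    Each location gets a strong idiosyncratic spectral fingerprint and an
    *independent* random property value: the property is unpredictable from
    any generalisable spectrum–property relationship, but a model that sees
    one twin in training can reproduce its target for the held-out twin.
    Pair-preserving folds therefore score near zero here, while pair-splitting
    folds score spuriously high — the leakage the grouped design prevents.
    """
    rng = np.random.default_rng(seed)
    base = make_class_curve(rng)
    lo, hi = (SOIL_PROPERTY_RANGES.loc[property_name, "minimum"],
              SOIL_PROPERTY_RANGES.loc[property_name, "maximum"])
    spectra, values, group_ids = [], [], []
    for g in range(n_groups):
        fingerprint = _perturbation(rng, fingerprint_sd * np.sqrt(N_POINTS))
        value = rng.uniform(lo, hi)
        for _ in range(2):
            spectra.append(np.clip(base + fingerprint, 0.0, 1.0))
            values.append(value)
            group_ids.append(f"loc{g:03d}")
    soil = pd.DataFrame({property_name: values})
    return LabeledSpectrumSet(spectra=np.vstack(spectra),
                              crop=["crop"] * len(spectra),
                              group_ids=group_ids, soil=soil)
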