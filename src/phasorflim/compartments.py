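"""Compartment aggregation, bleaching correction and intensity normalization.

Fluorescence intensity depends on the product of fluorophore concentration
and lifetime (quantum yield), so relative NAD(P)H concentration is estimated
as intensity divided by the amplitude-weighted mean lifetime.  Intensities
are first corrected for photobleaching over the acquisition (factor b = mean
frame intensity / first frame intensity) and normalized to same-replicate
vehicle-control fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .io import (
    LABEL_BACKGROUND,
    LABEL_CYTOPLASM,
    LABEL_NUCLEUS,
    DecayCube,
    MaskSet,
)

__all__ = [
    "BleachingSeries",
    "background_mask",
    "bleaching_factor",
    "corrected_intensity",
    "normalize_to_control",
    "concentration_proxy",
    "summarize_regions",
]

COMPARTMENT_NAMES = {LABEL_NUCLEUS: "nucleus", LABEL_CYTOPLASM: "cytoplasm"}


@dataclass(frozen=True)
class BleachingSeries:
    """Per-frame mean intensities and the derived correction factor b."""

    frame_means: tuple
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("bleaching factor must be positive")


class PairingError(KeyError):
    """No vehicle control available for the requested replicate."""


def background_mask(intensity: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
    """True where total counts fall below the background threshold.

    With ``threshold=None`` an Otsu threshold on the intensity image is
    used; the threshold is otherwise an explicit photon-count value.
    """
    intensity = np.asarray(intensity)
    if threshold is None:
        threshold = threshold_otsu(intensity.astype(float))
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return intensity < threshold


def bleaching_factor(frame_means: Sequence[float]) -> BleachingSeries:
    """b = mean of the per-frame intensities over the first frame's.

    For a monotonically bleaching acquisition b <= 1 and dividing by it
    restores the initial-intensity scale; a single frame gives b = 1.
    """
    fm = tuple(float(v) for v in frame_means)
    if not fm:
        raise ValueError("need at least one frame")
    if fm[0] <= 0:
        raise ValueError("first-frame intensity must be positive")
    return BleachingSeries(frame_means=fm, factor=float(np.mean(fm) / fm[0]))


def corrected_intensity(raw: float, bleach: BleachingSeries | float) -> float:
    b = bleach.factor if isinstance(bleach, BleachingSeries) else float(bleach)
    if b <= 0:
        raise ValueError("bleaching factor must be positive")
    return raw / b


def normalize_to_control(treated: float, control: float) -> float:
    """Ratio of a treated field's corrected intensity to its same-replicate
    vehicle control's."""
    if control <= 0:
        raise ValueError("control intensity must be positive")
    return treated / control


def concentration_proxy(corrected: float, mean_tau_m: float) -> float:
    """Relative concentration estimate: intensity / mean lifetime (a.u.)."""
    if mean_tau_m <= 0:
        raise ValueError("mean lifetime must be positive")
    return corrected / mean_tau_m


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def summarize_regions(
    cube: DecayCube,
    masks: MaskSet,
    tau_m_map: Optional[np.ndarray] = None,
    fraction_map: Optional[np.ndarray] = None,
    bleach: Optional[BleachingSeries] = None,
    control_intensity: Optional[float] = None,
    field_id: Optional[str] = None,
    treatment: Optional[str] = None,
) -> pd.DataFrame:
    """Aggregate per-compartment means into result-table rows.

    Produces one row per non-empty compartment (nucleus, cytoplasm) plus a
    whole-cell row whose means are pixel-count-weighted combinations of the
    two.  ``raw_intensity`` is mean photons per (unbinned) pixel; NaN pixels
    in the lifetime/fraction maps (ungated, failed fits) are excluded from
    those means but not from the intensity.
    """
    intensity = cube.intensity_image().astype(float)
    if masks.labels.shape != intensity.shape:
        raise ValueError("masks and cube are not spatially aligned")
    b = bleach if bleach is not None else (
        bleaching_factor(cube.frame_intensity) if cube.frame_intensity
        else BleachingSeries((1.0,), 1.0))
    field_id = field_id if field_id is not None else cube.meta.field_id
    treatment = treatment if treatment is not None else cube.meta.treatment

    rows = []
    compartment_masks = {
        "nucleus": masks.pixels(LABEL_NUCLEUS),
        "cytoplasm": masks.pixels(LABEL_CYTOPLASM),
        "whole-cell": masks.labels != LABEL_BACKGROUND,
    }
    for name, sel in compartment_masks.items():
        n_pix = int(sel.sum())
        if n_pix == 0:
            import warnings

            warnings.warn(f"compartment {name!r} is empty; omitted")
            continue
        raw = float(intensity[sel].mean())
        corr = corrected_intensity(raw, b)
        tau_vals = (tau_m_map[sel] if tau_m_map is not None
                    else np.array([np.nan]))
        tau_vals = tau_vals[np.isfinite(tau_vals)]
        mean_tau = float(tau_vals.mean()) if tau_vals.size else float("nan")
        f_vals = (fraction_map[sel] if fraction_map is not None
                  else np.array([np.nan]))
        f_vals = f_vals[np.isfinite(f_vals)]
        mean_f = float(f_vals.mean()) if f_vals.size else float("nan")
        norm = (normalize_to_control(corr, control_intensity)
                if control_intensity is not None else float("nan"))
        proxy = (concentration_proxy(corr, mean_tau)
                 if np.isfinite(mean_tau) and mean_tau > 0 else float("nan"))
        rows.append({
            "field_id": field_id,
            "compartment": name,
            "treatment": treatment,
            "mean_lifetime": mean_tau,
            "bound_fraction": mean_f,
            "raw_intensity": raw,
            "corrected_intensity": corr,
            "normalized_intensity": norm,
            "concentration_proxy": proxy,
            "n_pixels": n_pix,
            "sem_lifetime": _sem(tau_m_map[sel]) if tau_m_map is not None else float("nan"),
            "sem_bound_fraction": _sem(fraction_map[sel]) if fraction_map is not None else float("nan"),
            "sem_intensity": _sem(intensity[sel]),
        })
    return pd.DataFrame(rows)
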