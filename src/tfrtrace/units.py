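"""Dose and cell-count arithmetic for the experimental protocol layer.

These helpers validate the unit conversions behind the in-silico protocols:
diphtheria-toxin dosing per body weight, the tamoxifen gavage dose, and the
cell number delivered in a bone-marrow transfer injection.
"""

from __future__ import annotations

__all__ = ["dose_per_kg", "gavage_dose_mg", "cells_transferred"]


def dose_per_kg(dose_ug: float, body_weight_g: float) -> float:
    """Dose in µg/kg implied by a dose in µg and a body weight in grams."""
    if dose_ug < 0:
        raise ValueError("dose must be non-negative")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    return dose_ug / (body_weight_g / 1000.0)


def gavage_dose_mg(volume_ml: float, concentration_mg_per_ml: float) -> float:
    """Total dose in mg delivered by a gavage volume at a given concentration."""
    if volume_ml < 0 or concentration_mg_per_ml < 0:
        raise ValueError("volume and concentration must be non-negative")
    return volume_ml * concentration_mg_per_ml


def cells_transferred(volume_ul: float, cells_per_ml: float) -> float:
    """Number of cells in an injected volume (µL) at a given density (cells/mL)."""
    if volume_ul < 0 or cells_per_ml < 0:
        raise ValueError("volume and density must be non-negative")
    return volume_ul / 1000.0 * cells_per_ml
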