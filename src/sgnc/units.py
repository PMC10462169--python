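"""Conversions among binding free energy (ΔG), Ki, and IC50.

Binding affinities are carried as Gibbs free energies in kcal/mol (more
negative = tighter binding). The Ki↔ΔG relation used throughout is

    ΔG ≈ 1.3633 × log10(Ki)   [kcal/mol, Ki in molar]

i.e. ΔG = −RT·ln(Ki) evaluated with the composite factor 1.3633 that the
field conventionally prints at R = 1.987 cal/mol·K, T = 298.15 K. The
composite factor is used verbatim: it is what makes the two standard
activity cut-offs come out as −9.54 kcal/mol (Ki = 0.1 μM, "tight binder")
and −8.18 kcal/mol (Ki = 1 μM, the hERG safety margin) after rounding to
two decimals. Recomputing RT·ln10 from the constants gives ≈1.3641 and
shifts both thresholds in the third decimal, so the printed factor is
authoritative here.

IC50 is related to Ki by the flat competitive/uncompetitive approximation
Ki = IC50 / 2 (Kalliokoski), with no inhibition-mode switch.
"""

from __future__ import annotations

import math

from sgnc.exceptions import DomainError

#: Gas constant, cal/(mol·K) — documented context for the composite factor.
GAS_CONSTANT_CAL = 1.987
#: Absolute temperature, K, at which the conversion is quoted.
TEMPERATURE_K = 298.15
#: Composite factor: ΔG [kcal/mol] = KI_TO_KCAL * log10(Ki [M]).
KI_TO_KCAL = 1.3633

#: Recognized concentration unit strings and their factor to molar.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def ki_to_delta_g(ki: float) -> float:
    """Convert an inhibition constant Ki (molar) to ΔG in kcal/mol.

    Parameters
    ----------
    ki : float
        Inhibition constant in molar. Must be positive and finite.

    Returns
    -------
    float
        Binding free energy in kcal/mol; negative for sub-molar Ki.

    Raises
    ------
    DomainError
        If ``ki`` is not a positive finite number.
    """
    if not (isinstance(ki, (int, float)) and math.isfinite(ki)) or ki <= 0:
        raise DomainError(f"Ki must be a positive finite molar concentration, got {ki!r}")
    return KI_TO_KCAL * math.log10(ki)


def delta_g_to_ki(delta_g: float) -> float:
    """Invert :func:`ki_to_delta_g`: ΔG in kcal/mol → Ki in molar."""
    if not (isinstance(delta_g, (int, float)) and math.isfinite(delta_g)):
        raise DomainError(f"delta_g must be finite, got {delta_g!r}")
    return 10.0 ** (delta_g / KI_TO_KCAL)


def ic50_to_ki(ic50: float) -> float:
    """Convert IC50 (molar) to Ki (molar) via Ki = IC50 / 2."""
    if not (isinstance(ic50, (int, float)) and math.isfinite(ic50)) or ic50 <= 0:
        raise DomainError(f"IC50 must be a positive finite molar concentration, got {ic50!r}")
    return ic50 / 2.0


def concentration_to_molar(value: float, unit: str) -> float:
    """Normalize a concentration with a unit tag ("M", "mM", "uM", "nM", "pM") to molar."""
    try:
        factor = _UNIT_TO_MOLAR[unit]
    except KeyError:
        raise DomainError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}"
        ) from None
    if not math.isfinite(value) or value <= 0:
        raise DomainError(f"concentration must be positive and finite, got {value!r}")
    return value * factor
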