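"""Small unit conversions for the induction protocol."""

from __future__ import annotations

from ._rounding import round_half_up

TAMOXIFEN_MW_G_PER_MOL = 371.52  # free base


def dose_umol_per_kg(dose_mg_per_kg: float, mw_g_per_mol: float, ndigits: int = 1) -> float:
    """Convert a mg/kg dose to µmol/kg given the molar mass (g/mol).

    µmol/kg = mg/kg ÷ (g/mol) × 1000; rounded half-up to ``ndigits``.
    """
    if dose_mg_per_kg < 0 or mw_g_per_mol <= 0:
        raise ValueError("dose must be nonnegative and molar mass positive")
    return round_half_up(dose_mg_per_kg / mw_g_per_mol * 1000.0, ndigits)
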