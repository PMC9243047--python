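"""Reference condensation step energies for the ten nucleotides.

Published standard Gibbs energies (kcal/mol, DFT B3LYP/6-31G(d,p); aqueous
values from IEFPCM continuum solvation) for the two condensation steps of
each pathway — classic a+b (sugar+base first, phosphate second) and
alternative c+d (phosphate first, base second) — for the α and β anomers
of the five DNA and five RNA nucleoside 5′-monophosphates in vacuum and in
water. ``printed_total`` and ``printed_ddg`` are the one-decimal totals and
β−α pathway differences as printed in the source table; a handful of rows
are internally inconsistent at the last decimal because the printed steps
are themselves rounded from unrounded intermediates — consistency per row
can be checked with :func:`row_is_self_consistent`.

These numbers serve as ledger inputs and cross-checks; the package never
attempts to recompute the underlying electronic-structure energies.
"""

from __future__ import annotations

import pandas as pd

from .ledger import round_half_away

__all__ = [
    "reference_step_energies",
    "reference_steps",
    "reference_ddg",
    "row_is_self_consistent",
]

# nucleotide, pathway, phase, anomer → (ΔG step i, ΔG step j, printed total, printed ΔΔG)
_ROWS: list[tuple[str, str, str, str, float, float, float, float]] = [
    # classic path, vacuum
    ("dAMP", "a+b", "vacuum", "alpha", 2.5, -6.2, -3.7, -9.1),
    ("dAMP", "a+b", "vacuum", "beta", 2.1, -14.9, -12.8, -9.1),
    ("dGMP", "a+b", "vacuum", "alpha", 4.6, -8.8, -4.3, -18.6),
    ("dGMP", "a+b", "vacuum", "beta", 2.6, -25.4, -22.8, -18.6),
    ("dCMP", "a+b", "vacuum", "alpha", 6.5, -14.8, -8.3, 1.9),
    ("dCMP", "a+b", "vacuum", "beta", 4.8, -11.3, -6.4, 1.9),
    ("dTMP", "a+b", "vacuum", "alpha", 8.1, -19.7, -11.7, 4.9),
    ("dTMP", "a+b", "vacuum", "beta", 6.9, -13.7, -6.7, 4.9),
    ("dUMP", "a+b", "vacuum", "alpha", 7.8, -20.2, -12.3, 5.2),
    ("dUMP", "a+b", "vacuum", "beta", 7.0, -14.2, -7.2, 5.2),
    ("AMP", "a+b", "vacuum", "alpha", 2.3, -6.9, -4.6, -12.6),
    ("AMP", "a+b", "vacuum", "beta", 1.0, -18.3, -17.3, -12.6),
    ("GMP", "a+b", "vacuum", "alpha", 6.2, -9.8, -3.6, -9.5),
    ("GMP", "a+b", "vacuum", "beta", 1.9, -15.1, -13.1, -9.5),
    ("CMP", "a+b", "vacuum", "alpha", 1.9, -5.4, -3.5, -11.8),
    ("CMP", "a+b", "vacuum", "beta", 3.4, -18.8, -15.3, -11.8),
    ("TMP", "a+b", "vacuum", "alpha", 6.7, -8.9, -2.2, -5.3),
    ("TMP", "a+b", "vacuum", "beta", 5.7, -13.2, -7.5, -5.3),
    ("UMP", "a+b", "vacuum", "alpha", 6.8, -9.5, -2.7, -15.2),
    ("UMP", "a+b", "vacuum", "beta", 5.8, -23.8, -18.0, -15.2),
    # classic path, aqueous
    ("dAMP", "a+b", "aqueous", "alpha", 4.5, 0.6, 5.0, -0.8),
    ("dAMP", "a+b", "aqueous", "beta", 2.6, 1.6, 4.2, -0.8),
    ("dGMP", "a+b", "aqueous", "alpha", 4.3, 0.6, 4.9, -1.5),
    ("dGMP", "a+b", "aqueous", "beta", 3.0, 0.4, 3.4, -1.5),
    ("dCMP", "a+b", "aqueous", "alpha", 5.9, 2.6, 8.5, -3.9),
    ("dCMP", "a+b", "aqueous", "beta", 4.5, 0.1, 4.6, -3.9),
    ("dTMP", "a+b", "aqueous", "alpha", 6.3, 2.1, 8.3, -2.9),
    ("dTMP", "a+b", "aqueous", "beta", 4.9, 0.5, 5.4, -2.9),
    ("dUMP", "a+b", "aqueous", "alpha", 6.3, 2.2, 8.5, -4.0),
    ("dUMP", "a+b", "aqueous", "beta", 5.0, -0.5, 4.6, -4.0),
    ("AMP", "a+b", "aqueous", "alpha", 3.7, 2.4, 6.1, -0.4),
    ("AMP", "a+b", "aqueous", "beta", 3.9, 1.8, 5.7, -0.4),
    ("GMP", "a+b", "aqueous", "alpha", 4.3, 3.4, 7.7, -2.8),
    ("GMP", "a+b", "aqueous", "beta", 4.4, 0.6, 4.9, -2.8),
    ("CMP", "a+b", "aqueous", "alpha", 3.5, 3.1, 8.6, -5.1),
    ("CMP", "a+b", "aqueous", "beta", 2.7, 0.8, 3.5, -5.1),
    ("TMP", "a+b", "aqueous", "alpha", 7.7, 2.8, 10.5, -4.7),
    ("TMP", "a+b", "aqueous", "beta", 5.9, -0.1, 5.8, -4.7),
    ("UMP", "a+b", "aqueous", "alpha", 6.9, 2.6, 9.5, -4.1),
    ("UMP", "a+b", "aqueous", "beta", 5.8, -0.4, 5.4, -4.1),
    # alternative path, vacuum
    ("dAMP", "c+d", "vacuum", "alpha", -3.1, -3.7, -6.8, 2.9),
    ("dAMP", "c+d", "vacuum", "beta", -8.5, 4.6, -3.9, 2.9),
    ("dGMP", "c+d", "vacuum", "alpha", -3.1, -3.2, -6.3, -5.7),
    ("dGMP", "c+d", "vacuum", "beta", -8.5, -3.5, -12.0, -5.7),
    ("dCMP", "c+d", "vacuum", "alpha", -3.1, 4.7, 1.5, -14.3),
    ("dCMP", "c+d", "vacuum", "beta", -8.5, -4.2, -12.7, -14.3),
    ("dTMP", "c+d", "vacuum", "alpha", -3.1, 1.4, -1.7, -12.0),
    ("dTMP", "c+d", "vacuum", "beta", -8.5, -5.2, -13.7, -12.0),
    ("dUMP", "c+d", "vacuum", "alpha", -3.1, 0.7, -2.4, -12.4),
    ("dUMP", "c+d", "vacuum", "beta", -8.5, -6.3, -14.8, -12.4),
    ("AMP", "c+d", "vacuum", "alpha", -5.2, 0.8, -4.4, -0.2),
    ("AMP", "c+d", "vacuum", "beta", -9.8, 5.1, -4.6, -0.2),
    ("GMP", "c+d", "vacuum", "alpha", -5.2, -7.1, -12.3, -1.8),
    ("GMP", "c+d", "vacuum", "beta", -9.8, -4.4, -14.1, -1.8),
    ("CMP", "c+d", "vacuum", "alpha", -5.2, 2.8, -2.4, -4.4),
    ("CMP", "c+d", "vacuum", "beta", -9.8, 3.0, -6.8, -4.4),
    ("TMP", "c+d", "vacuum", "alpha", -5.2, -8.4, -13.6, 4.8),
    ("TMP", "c+d", "vacuum", "beta", -9.8, 1.0, -8.8, 4.8),
    ("UMP", "c+d", "vacuum", "alpha", -5.2, -9.2, -14.4, 8.4),
    ("UMP", "c+d", "vacuum", "beta", -9.8, 3.7, -6.0, 8.4),
    # alternative path, aqueous
    ("dAMP", "c+d", "aqueous", "alpha", 2.0, 5.0, 7.0, -1.7),
    ("dAMP", "c+d", "aqueous", "beta", -2.3, 7.6, 5.3, -1.7),
    ("dGMP", "c+d", "aqueous", "alpha", 2.0, 4.6, 6.6, -2.0),
    ("dGMP", "c+d", "aqueous", "beta", -2.3, 6.9, 4.6, -2.0),
    ("dCMP", "c+d", "aqueous", "alpha", 2.0, 6.2, 8.2, -2.5),
    ("dCMP", "c+d", "aqueous", "beta", -2.3, 7.9, 5.6, -2.5),
    ("dTMP", "c+d", "aqueous", "alpha", 2.0, 6.7, 8.7, -1.6),
    ("dTMP", "c+d", "aqueous", "beta", -2.3, 9.4, 7.1, -1.6),
    ("dUMP", "c+d", "aqueous", "alpha", 2.0, 6.4, 8.4, -1.9),
    ("dUMP", "c+d", "aqueous", "beta", -2.3, 8.7, 6.4, -1.9),
    ("AMP", "c+d", "aqueous", "alpha", 1.8, 5.7, 7.5, -2.8),
    ("AMP", "c+d", "aqueous", "beta", -0.9, 5.7, 4.8, -2.8),
    ("GMP", "c+d", "aqueous", "alpha", 1.8, 6.0, 7.9, -2.1),
    ("GMP", "c+d", "aqueous", "beta", -0.9, 6.6, 5.7, -2.1),
    ("CMP", "c+d", "aqueous", "alpha", 1.8, 5.5, 7.3, -2.2),
    ("CMP", "c+d", "aqueous", "beta", -0.9, 6.0, 5.1, -2.2),
    ("TMP", "c+d", "aqueous", "alpha", 1.8, 8.4, 10.3, -1.8),
    ("TMP", "c+d", "aqueous", "beta", -0.9, 9.4, 8.5, -1.8),
    ("UMP", "c+d", "aqueous", "alpha", 1.8, 8.1, 9.9, -3.8),
    ("UMP", "c+d", "aqueous", "beta", -0.9, 7.0, 6.1, -3.8),
]

_COLUMNS = [
    "nucleotide", "pathway", "phase", "anomer",
    "dg_step_i", "dg_step_j", "printed_total", "printed_ddg",
]


def reference_step_energies() -> pd.DataFrame:
    """The full 80-row reference grid as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def reference_steps(nucleotide: str, pathway: str, phase: str, anomer: str) -> tuple[float, float]:
    """(ΔG step i, ΔG step j) for one pathway/anomer/phase of one nucleotide."""
    for row in _ROWS:
        if row[:4] == (nucleotide, pathway, phase, anomer):
            return row[4], row[5]
    raise KeyError(f"no reference row for {(nucleotide, pathway, phase, anomer)}")


def reference_ddg(nucleotide: str, pathway: str, phase: str) -> float:
    """The printed β−α pathway ΔΔG for one nucleotide/pathway/phase."""
    for row in _ROWS:
        if row[:3] == (nucleotide, pathway, phase):
            return row[7]
    raise KeyError(f"no reference row for {(nucleotide, pathway, phase)}")


def row_is_self_consistent(nucleotide: str, pathway: str, phase: str, anomer: str) -> bool:
    """True when the printed steps re-sum to the printed total at one decimal."""
    i, j = reference_steps(nucleotide, pathway, phase, anomer)
    for row in _ROWS:
        if row[:4] == (nucleotide, pathway, phase, anomer):
            return round_half_away(i + j, 1) == row[6]
    raise KeyError(f"no reference row for {(nucleotide, pathway, phase, anomer)}")
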