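"""Monoisotopic mass constants and the residue mass table.

All masses are in daltons (Da) and monoisotopic.  The residue masses come
from pyteomics' standard table; the constants below are spelled out because
ion m/z arithmetic throughout the package depends on them to sub-ppm
precision.
"""
from __future__ import annotations

from pyteomics import mass as _pmass

#: Mass of a water molecule (added to residue masses for a neutral peptide).
WATER = 18.0105646863

#: Mass of a proton (charge carrier in positive-mode ESI).
PROTON = 1.00727646688

#: Carbon monoxide, lost when converting a b-ion to an a-ion.
CO = 27.994915

#: Ammonia neutral loss.
NH3 = 17.026549

#: Water neutral loss (fragment-side; same molecule as WATER at lower precision).
H2O = 18.010565

#: The 20 canonical amino-acid letters.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity/non-standard codes excluded from the search space.
AMBIGUOUS = frozenset("BJOUXZ")

#: Monoisotopic residue masses for the canonical alphabet.
AA_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in CANONICAL}


def format_delta(delta: float) -> str:
    """Canonical text form of a modification mass delta, e.g. ``+57.02146``.

    Used everywhere a modified residue is rendered as a token or a peptide
    as a modified-sequence string, so that string identity is stable across
    modules.
    """
    text = f"{delta:+.6f}"
    text = text.rstrip("0").rstrip(".")
    return text
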