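"""Packaged reference data.

Random-coil Cα/Cβ chemical shifts are standard tabulated per-residue-type
values (ppm, referenced to DSS); they serve as the default subtraction
reference and are always overridable by a user-supplied table. The
sequence-dependent neighbour-correction machinery of dedicated random-coil
predictors is deliberately not reimplemented — such corrections enter this
package only through externally supplied tables.

The fixture peptide sequence is a SYNTHETIC stand-in for a 29-residue
transcription-factor construct numbered 244–272: the residues named in the
analyses (V261, D262, L264, L265, R266, D267) sit at their stated positions,
the remainder are plausible filler. It exists so the demonstration study and
tests run without any measured data.
"""

from __future__ import annotations

import numpy as np

from .containers import RandomCoilTable

__all__ = [
    "RANDOM_COIL_CA",
    "RANDOM_COIL_CB",
    "FIXTURE_SEQUENCE",
    "FIXTURE_FIRST_RESIDUE",
    "random_coil_for_sequence",
]

#: Random-coil Cα shifts (ppm) per one-letter residue type.
RANDOM_COIL_CA = {
    "A": 52.5, "R": 56.0, "N": 53.1, "D": 54.2, "C": 58.2,
    "Q": 55.7, "E": 56.6, "G": 45.1, "H": 55.0, "I": 61.1,
    "L": 55.1, "K": 56.2, "M": 55.4, "F": 57.7, "P": 63.3,
    "S": 58.3, "T": 61.8, "W": 57.5, "Y": 57.9, "V": 62.2,
}

#: Random-coil Cβ shifts (ppm); glycine has none and maps to NaN.
RANDOM_COIL_CB = {
    "A": 19.1, "R": 30.9, "N": 38.9, "D": 41.1, "C": 28.0,
    "Q": 29.4, "E": 29.9, "G": float("nan"), "H": 29.0, "I": 38.8,
    "L": 42.4, "K": 33.1, "M": 32.9, "F": 39.6, "P": 31.9,
    "S": 63.8, "T": 69.8, "W": 29.6, "Y": 38.8, "V": 32.9,
}

#: Synthetic stand-in sequence, residues 244-272 (see module docstring).
FIXTURE_SEQUENCE = "SEDGSAPKEESGNEDAAVDELLRDLNQEG"
FIXTURE_FIRST_RESIDUE = 244


def random_coil_for_sequence(
    sequence: str, first_residue: int = FIXTURE_FIRST_RESIDUE
) -> RandomCoilTable:
    """Random-coil reference table for a one-letter sequence.

    Residue numbering starts at ``first_residue`` (full-protein numbering).
    """
    seq = sequence.upper()
    unknown = sorted(set(seq) - set(RANDOM_COIL_CA))
    if unknown:
        raise ValueError(f"unknown residue type(s): {', '.join(unknown)}")
    numbers = np.arange(first_residue, first_residue + len(seq))
    ca = np.array([RANDOM_COIL_CA[a] for a in seq])
    cb = np.array([RANDOM_COIL_CB[a] for a in seq])
    return RandomCoilTable(residue_number=numbers, rc_ca_ppm=ca, rc_cb_ppm=cb)
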