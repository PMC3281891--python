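"""Shared amino-acid constants: alphabet order, background composition,
transmembrane-helix composition and the Kyte-Doolittle hydropathy scale.

All probability vectors are indexed in ``AMINO_ACIDS`` order.
"""
from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"

# Average composition of well-annotated protein databases (fractions, UniProt-like).
_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0685,
}

BACKGROUND_FREQS = np.array([_BACKGROUND[a] for a in AMINO_ACIDS])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
KD_VECTOR = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS])
# Unknown residues score at the background-average hydropathy.
KD_UNKNOWN = float(BACKGROUND_FREQS @ KD_VECTOR)

# Transmembrane-helix residue distribution used by the synthetic generator.
# 85% of the mass sits on the Kyte-Doolittle-positive residues, dominated by
# the aliphatic trio I/L/V as in real bitopic/polytopic TM segments; the
# remaining 15% is small/polar (G,S,T,P...) with only traces of charged
# residues, which are rare inside membranes.
_HELIX = {
    "I": 0.330, "L": 0.270, "V": 0.250, "F": 0.015, "A": 0.010,
    "M": 0.010, "C": 0.005, "W": 0.0025, "Y": 0.0025,
    # 15% non-hydrophobic remainder, dominated by small residues; serine is
    # kept sparse so near-invariant helix columns are overwhelmingly planted
    "G": 0.058, "S": 0.020, "T": 0.048, "P": 0.008, "N": 0.005,
    "Q": 0.005, "H": 0.002, "D": 0.001, "E": 0.001, "K": 0.001,
    "R": 0.001,
}
HELIX_FREQS = np.array([_HELIX[a] for a in AMINO_ACIDS])
HELIX_FREQS = HELIX_FREQS / HELIX_FREQS.sum()
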