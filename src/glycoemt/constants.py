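"""Physical constants for peptide mass and m/z arithmetic.

All masses are monoisotopic and in daltons. Residue masses are the
standard 5-decimal table (free amino acid minus one water); a peptide's
monoisotopic mass is the residue sum plus one water.
"""

from __future__ import annotations

import hashlib
import json

# Monoisotopic residue masses, 20 standard amino acids (Da).
RESIDUE_MONO_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

# Monoisotopic mass of water added on peptide-bond hydrolysis (Da).
WATER_MONO_MASS: float = 18.010565

# Proton mass for charge-state arithmetic (Da).
PROTON_MASS: float = 1.00727646

# Exact monoisotopic Asn -> Asp shift on deamidation / PNGase F
# de-glycosylation (Da): -NH2 +OH. Nominally "one mass unit".
DEAMIDATION_DELTA: float = 0.984016

# Non-glycosylated PD-L1 tryptic peptides used to normalize protein
# amount among samples, with the charge states that reproduce their
# published m/z (843.4570 at 2+ and 586.3003 at 3+).
REFERENCE_PEPTIDES: dict[str, int] = {
    "DQLSLGNAALQITDVK": 2,
    "AEVIWTSSDHQVLSGK": 3,
}

# Default XIC mass-accuracy window (parts per million).
DEFAULT_PPM_TOL: float = 10.0


def constants_hash() -> str:
    """Short SHA-256 digest of the constants table, for run-log provenance."""
    payload = json.dumps(
        {
            "residues": RESIDUE_MONO_MASS,
            "water": WATER_MONO_MASS,
            "proton": PROTON_MASS,
            "deamidation": DEAMIDATION_DELTA,
            "references": REFERENCE_PEPTIDES,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
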