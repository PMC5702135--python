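"""Published reference growth rates for genome-reduced C. glutamicum strains.

Literature rates (mean over replicates, 1/h) for a library of genome-reduced
strains derived from the ATCC13032 wild type or the lysine producer DM1933,
alongside the rates this automated method yields on the same BioLector raw
data set. Used to benchmark the automated exponential-phase detection
against manually curated fits via the scale-free deviation
``|1 - mu_auto / mu_lit| * 100`` (%).

The WT entry appears once; its two growth duplicates gave the same rounded
rate (0.46 1/h).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["genome_reduced_strain_rates"]

# strain, literature mu (1/h), automated mu (1/h)
_ROWS = [
    ("DM1933", 0.32, 0.30),
    ("DM1933 dCGP1", 0.30, 0.30),
    ("DM1933 dCGP2", 0.31, 0.32),
    ("DM1933 dCGP3", 0.31, 0.32),
    ("DM1933 dCGP123", 0.33, 0.33),
    ("GRLP16", 0.31, 0.35),
    ("GRLP23", 0.33, 0.31),
    ("GRLP41", 0.31, 0.29),
    ("GRLP42", 0.36, 0.30),
    ("GRLP46", 0.30, 0.32),
    ("GRS37", 0.45, 0.51),
    ("GRS40", 0.44, 0.50),
    ("GRS41", 0.41, 0.47),
    ("GRS42", 0.39, 0.47),
    ("GRS46", 0.43, 0.50),
    ("GRS45", 0.31, 0.34),
    ("GRS47", 0.41, 0.48),
    ("GRS48", 0.45, 0.49),
    ("GRS53", 0.44, 0.47),
    ("MB001", 0.43, 0.48),
    ("GRS16", 0.44, 0.49),
    ("GRS23", 0.46, 0.47),
    ("WT", 0.43, 0.46),
]


def genome_reduced_strain_rates() -> pd.DataFrame:
    """Reference table: columns ``strain``, ``mu_lit``, ``mu_auto`` (1/h)."""
    return pd.DataFrame(_ROWS, columns=["strain", "mu_lit", "mu_auto"])
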