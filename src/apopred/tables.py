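"""Built-in physicochemical property tables.

Two versioned tables ship with the package:

* ``PSEAAC_PROPERTIES`` — nine per-residue numeric scales (hydrophobicity,
  hydrophilicity, side-chain mass, pK1 of the alpha-carboxyl group, pK2 of
  the alpha-amino group, isoelectric point at 25 degC, rigidity,
  irreplaceability, flexibility) used for the sequence-order correlation
  factors of pseudo-amino-acid composition. Values are compiled from
  standard amino-acid index collections; each scale is standardised to zero
  mean and unit variance over the 20 residues before use, so only relative
  values matter.
* ``CTD_GROUPS`` — eight three-group partitions of the alphabet used by the
  composition/transition/distribution (188D) encoder.

Users may register alternative tables keyed by a ``property_table_id``.
"""

from __future__ import annotations

import numpy as np

from .sequence_io import AMINO_ACIDS

# residue order everywhere: ACDEFGHIKLMNPQRSTVWY
_SCALES: dict[str, list[float]] = {
    "hydrophobicity": [0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38,
                       -1.50, 1.06, 0.64, -0.78, 0.12, -0.85, -2.53, -0.18,
                       -0.05, 1.08, 0.81, 0.26],
    "hydrophilicity": [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0,
                       -1.8, -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5,
                       -3.4, -2.3],
    "mass": [15.0, 47.0, 59.0, 73.0, 91.0, 1.0, 82.0, 57.0, 73.0, 57.0,
             75.0, 58.0, 42.0, 72.0, 101.0, 31.0, 45.0, 43.0, 130.0, 107.0],
    "pK1": [2.35, 1.71, 1.88, 2.19, 2.58, 2.34, 1.78, 2.32, 2.20, 2.36,
            2.28, 2.18, 1.99, 2.17, 2.17, 2.21, 2.15, 2.29, 2.38, 2.20],
    "pK2": [9.87, 10.78, 9.60, 9.67, 9.24, 9.60, 8.97, 9.76, 8.90, 9.60,
            9.21, 9.09, 10.60, 9.13, 9.04, 9.15, 9.12, 9.72, 9.39, 9.11],
    "pI": [6.11, 5.02, 2.98, 3.08, 5.91, 6.06, 7.64, 6.04, 9.47, 6.04,
           5.74, 5.41, 6.30, 5.65, 10.76, 5.68, 5.60, 6.02, 5.88, 5.63],
    "rigidity": [0.984, 0.906, 1.068, 1.094, 0.915, 1.031, 0.950, 0.927,
                 1.102, 0.935, 0.952, 1.048, 1.049, 1.037, 1.008, 1.046,
                 0.997, 0.931, 0.904, 0.929],
    "irreplaceability": [0.61, 1.12, 0.87, 0.81, 0.92, 0.88, 0.79, 0.74,
                         0.78, 0.62, 1.05, 0.76, 0.83, 0.72, 0.68, 0.65,
                         0.70, 0.67, 1.32, 0.95],
    "flexibility": [0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462,
                    0.466, 0.365, 0.295, 0.463, 0.509, 0.493, 0.529, 0.507,
                    0.444, 0.386, 0.305, 0.420],
}

#: canonical order of the nine properties (property-minor index within a tier)
PSEAAC_PROPERTY_NAMES = tuple(_SCALES)

#: table id -> {property name -> raw length-20 value array}
PROPERTY_TABLES: dict[str, dict[str, np.ndarray]] = {
    "builtin-v1": {name: np.asarray(vals, dtype=float) for name, vals in _SCALES.items()}
}


def standardized_properties(table_id: str = "builtin-v1") -> dict[str, np.ndarray]:
    """Return each scale standardised to mean 0, variance 1 over the 20 residues."""
    try:
        table = PROPERTY_TABLES[table_id]
    except KeyError:
        raise KeyError(f"unknown property table {table_id!r}") from None
    out = {}
    for name, vals in table.items():
        out[name] = (vals - vals.mean()) / vals.std()
    return out


# Standard CTD three-group partitions of the 20 residues, one per
# physicochemical attribute; groups are given low/medium/high (or the
# conventional class order for categorical attributes such as charge).
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
    "surface_tension": ("GQDNAHR", "KTSEC", "ILMFPWYV"),
}

for _name, _groups in CTD_GROUPS.items():
    assert sorted("".join(_groups)) == sorted(AMINO_ACIDS), _name
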