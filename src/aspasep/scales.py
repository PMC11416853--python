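"""Residue property scales.

A :class:`PropertyScale` is a named mapping from the 20 standard amino
acids to numbers (hydropathy, mass, ...).  Dipeptide scales map ordered
residue pairs instead (400 entries).  Scales that are standard reference
data (Kyte-Doolittle hydropathy, the DIWV instability weights, average
residue masses) are taken from Biopython's curated tables; the three
coupling scales of pseudo amino acid composition are shipped as a JSON
data file with literature provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV, kd

#: Canonical one-letter alphabet, alphabetical order (fixed column order
#: for compositions and feature matrices).
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

WATER_MASS = 18.015  # Da, one water per peptide chain

# pKa sets for the Henderson-Hasselbalch net-charge model.  "bjellqvist"
# reproduces the Expasy ProtParam convention; "emboss" the iep tool.
PKA_SETS: dict[str, dict[str, float]] = {
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}

# Bjellqvist terminal pKa values depend on the terminal residue; these
# overrides make the "bjellqvist" set reproduce Expasy ProtParam.
PKA_NTERM_OVERRIDES: dict[str, dict[str, float]] = {
    "bjellqvist": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                   "T": 6.82, "V": 7.44, "E": 7.7},
    "emboss": {},
}
PKA_CTERM_OVERRIDES: dict[str, dict[str, float]] = {
    "bjellqvist": {"D": 4.55, "E": 4.75},
    "emboss": {},
}

# Ikai aliphatic-index coefficients: relative volumes of Val and Ile/Leu
# side chains versus Ala.
ALIPHATIC_COEF_VAL = 2.9
ALIPHATIC_COEF_ILE_LEU = 3.9


@dataclass(frozen=True)
class PropertyScale:
    """A named residue -> value mapping over the 20 standard amino acids."""

    name: str
    values: dict[str, float]
    unit: str = "dimensionless"
    source: str = ""
    pair_values: dict[str, dict[str, float]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pair_values is not None:
            n = sum(len(row) for row in self.pair_values.values())
            if n != 400:
                raise ValueError(
                    f"dipeptide scale {self.name!r} has {n} entries, expected 400"
                )
        elif set(self.values) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.values)
            extra = set(self.values) - set(AMINO_ACIDS)
            raise ValueError(
                f"scale {self.name!r}: missing {sorted(missing)}, extra {sorted(extra)}"
            )

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def as_vector(self) -> list[float]:
        """Values in fixed alphabetical residue order."""
        return [self.values[aa] for aa in AMINO_ACIDS]

    def normalized(self) -> "PropertyScale":
        """Standard-convert to mean 0 / population s.d. 1 over the 20 residues.

        This is the conversion step PseAAC applies to every coupling scale
        before computing sequence-order correlation factors.
        """
        vals = self.as_vector()
        mean = sum(vals) / 20.0
        var = sum((v - mean) ** 2 for v in vals) / 20.0
        if var == 0.0:
            raise ValueError(f"scale {self.name!r} is constant; cannot standardize")
        sd = math.sqrt(var)
        if abs(mean) < 1e-12 and abs(sd - 1.0) < 1e-12:
            return self
        return PropertyScale(
            name=f"{self.name}_normalized",
            values={aa: (self.values[aa] - mean) / sd for aa in AMINO_ACIDS},
            unit="dimensionless",
            source=self.source,
        )


def _load_packaged_scales() -> dict[str, PropertyScale]:
    text = resources.files("aspasep.data").joinpath("pseaac_scales.json").read_text()
    payload = json.loads(text)
    out = {}
    for name, entry in payload["scales"].items():
        out[name] = PropertyScale(
            name=name,
            values={aa: float(v) for aa, v in entry["values"].items()},
            unit=entry.get("unit", "dimensionless"),
            source=entry.get("source", ""),
        )
    return out


_PACKAGED = _load_packaged_scales()

#: Average residue masses (full amino acid minus one water), ProtParam style.
RESIDUE_MASS = PropertyScale(
    name="average_residue_mass",
    values={aa: protein_weights[aa] - WATER_MASS for aa in AMINO_ACIDS},
    unit="Da",
    source="Biopython IUPACData average amino-acid masses",
)

KYTE_DOOLITTLE = PropertyScale(
    name="kyte_doolittle",
    values={aa: kd[aa] for aa in AMINO_ACIDS},
    unit="dimensionless",
    source="Kyte J., Doolittle R.F. (1982) J Mol Biol 157:105-132",
)

#: Dipeptide instability weight values of Guruprasad et al.
DIWV_SCALE = PropertyScale(
    name="diwv",
    values={},
    unit="dimensionless",
    source="Guruprasad K. et al. (1990) Protein Eng 4:155-161",
    pair_values={a: dict(DIWV[a]) for a in AMINO_ACIDS},
)

CHOU_HYDROPHOBICITY = _PACKAGED["chou_hydrophobicity"]
CHOU_HYDROPHILICITY = _PACKAGED["chou_hydrophilicity"]
SIDE_CHAIN_MASS = _PACKAGED["side_chain_mass"]

_REGISTRY: dict[str, PropertyScale] = {
    s.name: s
    for s in (
        RESIDUE_MASS,
        KYTE_DOOLITTLE,
        DIWV_SCALE,
        CHOU_HYDROPHOBICITY,
        CHOU_HYDROPHILICITY,
        SIDE_CHAIN_MASS,
    )
}


def get_scale(name: str) -> PropertyScale:
    """Look up a shipped scale by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_scales() -> list[str]:
    return sorted(_REGISTRY)
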