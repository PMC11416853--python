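"""ProtParam-style per-sequence physicochemical descriptors.

Computes, for each protein sequence: length, molecular weight,
theoretical pI, instability index (with the <40 stability call),
aliphatic index, GRAVY, charged-residue counts and the 20 amino-acid
frequencies.  Conventions follow the Expasy ProtParam tool: average
residue masses, Bjellqvist pKa values, Kyte-Doolittle hydropathy, the
Guruprasad DIWV dipeptide weights, and Ikai's aliphatic coefficients.

GRAVY follows the standard Kyte-Doolittle sign convention: positive
values indicate hydrophobic character.

"Positively charged" counts Arg + Lys by default (His excluded, the
ProtParam convention); pass ``include_his=True`` to count His as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scales import (
    ALIPHATIC_COEF_ILE_LEU,
    ALIPHATIC_COEF_VAL,
    AMINO_ACIDS,
    DIWV_SCALE,
    KYTE_DOOLITTLE,
    PKA_CTERM_OVERRIDES,
    PKA_NTERM_OVERRIDES,
    PKA_SETS,
    RESIDUE_MASS,
    WATER_MASS,
)
from .seq_io import LabeledDataset, ProteinRecord

INSTABILITY_STABLE_BELOW = 40.0

DESCRIPTOR_COLUMNS = [
    "length",
    "molecular_weight",
    "theoretical_pi",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "n_positive",
    "n_negative",
]


def _check(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    _check(seq)
    return sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def gravy(seq: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value."""
    _check(seq)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu),
    with X in mole percent."""
    _check(seq)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return (
        x["A"]
        + ALIPHATIC_COEF_VAL * x["V"]
        + ALIPHATIC_COEF_ILE_LEU * (x["I"] + x["L"])
    )


def instability_index(seq: str) -> tuple[float, str]:
    """Guruprasad instability index and its stability call.

    (10/L) times the sum of DIWV weights over the L-1 consecutive
    dipeptides; the protein is called "stable" iff the index is < 40.
    """
    _check(seq)
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    pairs = DIWV_SCALE.pair_values
    total = sum(pairs[a][b] for a, b in zip(seq, seq[1:]))
    index = 10.0 / len(seq) * total
    return index, ("stable" if index < INSTABILITY_STABLE_BELOW else "unstable")


def net_charge(seq: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Positive groups: N-terminus, K, R, H; negative groups: C-terminus,
    D, E, C, Y.  Under the Bjellqvist set the terminal pKa values are
    adjusted for the terminal residue, as in ProtParam.
    """
    _check(seq)
    pka = PKA_SETS[pka_set]
    nterm_pka = PKA_NTERM_OVERRIDES[pka_set].get(seq[0], pka["Nterm"])
    cterm_pka = PKA_CTERM_OVERRIDES[pka_set].get(seq[-1], pka["Cterm"])
    pos = [(pka["K"], seq.count("K")), (pka["R"], seq.count("R")),
           (pka["H"], seq.count("H")), (nterm_pka, 1)]
    neg = [(pka["D"], seq.count("D")), (pka["E"], seq.count("E")),
           (pka["C"], seq.count("C")), (pka["Y"], seq.count("Y")), (cterm_pka, 1)]
    charge = 0.0
    for pk, n in pos:
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pk))
    for pk, n in neg:
        if n:
            charge -= n / (1.0 + 10.0 ** (pk - ph))
    return charge


def theoretical_pi(seq: str, pka_set: str = "bjellqvist", tol: float = 0.002) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The termini guarantee the charge is positive at pH 0 and negative at
    pH 14, so a root always exists; net charge is monotone decreasing in
    pH, so it is unique.
    """
    _check(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charged_counts(seq: str, include_his: bool = False) -> tuple[int, int]:
    """(n_positive, n_negative): Arg+Lys (optionally +His) and Asp+Glu."""
    _check(seq)
    n_pos = seq.count("R") + seq.count("K")
    if include_his:
        n_pos += seq.count("H")
    return n_pos, seq.count("D") + seq.count("E")


def aa_frequencies(seq: str) -> dict[str, float]:
    """Residue frequencies (counts/L) in fixed alphabetical order."""
    _check(seq)
    n = len(seq)
    return {aa: seq.count(aa) / n for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class DescriptorRow:
    """All descriptors for one sequence."""

    id: str
    label: str | None
    length: int
    molecular_weight: float
    theoretical_pi: float
    instability_index: float
    stability_call: str
    aliphatic_index: float
    gravy: float
    n_positive: int
    n_negative: int
    aa_freq: dict[str, float]


def describe(record: ProteinRecord, pka_set: str = "bjellqvist",
             include_his: bool = False) -> DescriptorRow:
    seq = record.sequence
    instab, call = instability_index(seq)
    n_pos, n_neg = charged_counts(seq, include_his=include_his)
    return DescriptorRow(
        id=record.id,
        label=record.label,
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        theoretical_pi=theoretical_pi(seq, pka_set=pka_set),
        instability_index=instab,
        stability_call=call,
        aliphatic_index=aliphatic_index(seq),
        gravy=gravy(seq),
        n_positive=n_pos,
        n_negative=n_neg,
        aa_freq=aa_frequencies(seq),
    )


def descriptor_table(
    dataset: LabeledDataset | Iterable[ProteinRecord],
    pka_set: str = "bjellqvist",
    include_his: bool = False,
) -> pd.DataFrame:
    """One row per sequence: id, label, the named descriptors, and the
    20 per-residue frequency columns (``freq_A`` ... ``freq_Y``).

    Column names are stable and consumed directly by the ROC stage.
    """
    rows = []
    for rec in dataset:
        d = describe(rec, pka_set=pka_set, include_his=include_his)
        row = {
            "id": d.id,
            "label": d.label,
            "length": d.length,
            "molecular_weight": d.molecular_weight,
            "theoretical_pi": d.theoretical_pi,
            "instability_index": d.instability_index,
            "aliphatic_index": d.aliphatic_index,
            "gravy": d.gravy,
            "n_positive": d.n_positive,
            "n_negative": d.n_negative,
        }
        row.update({f"freq_{aa}": d.aa_freq[aa] for aa in AMINO_ACIDS})
        rows.append(row)
    if not rows:
        raise ValueError("no records to describe")
    return pd.DataFrame(rows)


def write_descriptor_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
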