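"""Type-I pseudo amino acid composition (PseAAC).

A sequence of length L is converted into 20 + lambda features: the 20
amino-acid composition components plus lambda sequence-order correlation
factors theta_1 ... theta_lambda.  Tier k couples residues k positions
apart through three standard-converted property scales (hydrophobicity,
hydrophilicity, side-chain mass):

    theta_k = (1/(L-k)) * sum_i Theta(R_i, R_{i+k})
    Theta(a, b) = (1/3) * [(H1_a-H1_b)^2 + (H2_a-H2_b)^2 + (M_a-M_b)^2]

and the feature vector is

    x_u = f_u / (sum_v f_v + w * sum_k theta_k)          u = 1..20
    x_{20+k} = w * theta_k / (same denominator)          k = 1..lambda

with f_u the relative residue frequencies and w the weight balancing
order factors against composition.  Components are non-negative and sum
to 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .scales import (
    AMINO_ACIDS,
    CHOU_HYDROPHILICITY,
    CHOU_HYDROPHOBICITY,
    SIDE_CHAIN_MASS,
    PropertyScale,
)
from .seq_io import LabeledDataset, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_SCALES = (CHOU_HYDROPHOBICITY, CHOU_HYDROPHILICITY, SIDE_CHAIN_MASS)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class SequenceTooShortError(ValueError):
    """Sequence length must exceed lambda to define all theta tiers."""


@dataclass(frozen=True)
class PseAACConfig:
    """Parameters of the featurization.

    lambda_ is the number of correlation tiers (must stay below the
    length of every sequence); weight is Chou's w balancing the order
    factors against composition.  Defaults: lambda 5, w 0.05.
    """

    lambda_: int = 5
    weight: float = 0.05
    scales: tuple[PropertyScale, ...] = DEFAULT_SCALES
    on_short: str = "error"  # or "drop"

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lambda_}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if len(self.scales) == 0:
            raise ValueError("at least one property scale is required")
        if self.on_short not in ("error", "drop"):
            raise ValueError(f"on_short must be 'error' or 'drop', got {self.on_short}")

    def feature_names(self) -> list[str]:
        return [f"comp_{aa}" for aa in AMINO_ACIDS] + [
            f"theta_{k}" for k in range(1, self.lambda_ + 1)
        ]

    def metadata(self) -> dict:
        return {
            "lambda": self.lambda_,
            "weight": self.weight,
            "scales": [s.name for s in self.scales],
        }


def normalize_scale(raw: PropertyScale) -> PropertyScale:
    """Standard conversion: mean 0, population s.d. 1 over the 20 residues.

    Idempotent; a constant scale is an error.
    """
    return raw.normalized()


def _normalized_scale_matrix(scales: Iterable[PropertyScale]) -> np.ndarray:
    """Rows = scales (standard-converted), columns = residues in fixed order."""
    return np.array([s.normalized().as_vector() for s in scales])


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[aa] for aa in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None


def correlation_factor(
    seq: str, k: int, scales: Iterable[PropertyScale] = DEFAULT_SCALES
) -> float:
    """theta_k: mean squared-difference coupling of residues k apart,
    averaged over the standard-converted scales."""
    if not 1 <= k <= len(seq) - 1:
        raise SequenceTooShortError(
            f"tier k={k} needs sequence length > k, got {len(seq)}"
        )
    mat = _normalized_scale_matrix(scales)
    idx = _encode(seq)
    diffs = mat[:, idx[:-k]] - mat[:, idx[k:]]  # scales x (L-k)
    return float(np.mean(diffs**2, axis=0).mean())


def pseaac_vector(seq: str, config: PseAACConfig = PseAACConfig()) -> np.ndarray:
    """The 20+lambda PseAAC components for one sequence."""
    if len(seq) <= config.lambda_:
        raise SequenceTooShortError(
            f"sequence length {len(seq)} must exceed lambda={config.lambda_}"
        )
    idx = _encode(seq)
    freqs = np.bincount(idx, minlength=20) / len(seq)
    mat = _normalized_scale_matrix(config.scales)
    vals = mat[:, idx]  # scales x L
    thetas = np.empty(config.lambda_)
    for k in range(1, config.lambda_ + 1):
        diffs = vals[:, :-k] - vals[:, k:]
        thetas[k - 1] = np.mean(diffs**2, axis=0).mean()
    denom = freqs.sum() + config.weight * thetas.sum()
    return np.concatenate([freqs, config.weight * thetas]) / denom


def featurize_dataset(
    dataset: LabeledDataset | Iterable[ProteinRecord],
    config: PseAACConfig = PseAACConfig(),
) -> pd.DataFrame:
    """PseAAC feature matrix: id, label, then 20+lambda named columns.

    Row order matches dataset order.  Sequences not longer than lambda
    are an error by default, or dropped with a log line when the config
    says ``on_short="drop"``.
    """
    names = config.feature_names()
    rows = []
    ids = []
    labels = []
    n_dropped = 0
    for rec in dataset:
        if len(rec.sequence) <= config.lambda_:
            if config.on_short == "drop":
                logger.warning(
                    "record %s: dropped (length %d <= lambda %d)",
                    rec.id, len(rec.sequence), config.lambda_,
                )
                n_dropped += 1
                continue
            raise SequenceTooShortError(
                f"record {rec.id!r}: length {len(rec.sequence)} <= lambda {config.lambda_}"
            )
        rows.append(pseaac_vector(rec.sequence, config))
        ids.append(rec.id)
        labels.append(rec.label)
    if not rows:
        raise SequenceTooShortError("no sequence is longer than lambda")
    if n_dropped:
        logger.warning("featurize_dataset: dropped %d short sequences", n_dropped)
    out = pd.DataFrame(np.vstack(rows), columns=names)
    out.insert(0, "label", labels)
    out.insert(0, "id", ids)
    return out


def write_feature_matrix(
    matrix: pd.DataFrame, path: str | Path, config: PseAACConfig | None = None
) -> None:
    """TSV feature matrix plus a JSON sidecar with lambda/w/scale names."""
    path = Path(path)
    matrix.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(config.metadata(), indent=2, sort_keys=True) + "\n")
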