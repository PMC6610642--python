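"""Drug–drug and cell-line–cell-line similarity matrices.

Drugs are compared through the Jaccard coefficient of their binary
substructure fingerprints (e.g. PubChem fingerprints); cell lines through
the Pearson correlation of their gene-expression profiles.  Both routines
return a :class:`SimilarityMatrix` that is exactly symmetric with unit
diagonal, ready for p-nearest-neighbor sparsification and Laplacian
construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FeatureTable",
    "SimilarityMatrix",
    "jaccard_similarity",
    "pearson_similarity",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class FeatureTable:
    """Entities (drugs or cell lines) described by a numeric feature grid.

    Parameters
    ----------
    entity_ids
        Unique identifiers, one per row of ``values``.
    values
        ``(n_entities, n_features)`` array.  For binary fingerprints every
        entry must be exactly 0 or 1.
    feature_kind
        ``"binary_fingerprint"`` or ``"continuous_profile"``.
    """

    entity_ids: list[str]
    values: np.ndarray
    feature_kind: Literal["binary_fingerprint", "continuous_profile"]

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be a 2-D grid")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValidationError("entity_ids must be unique")
        if self.values.shape[0] != len(self.entity_ids):
            raise ValidationError(
                f"row count {self.values.shape[0]} does not match "
                f"{len(self.entity_ids)} entity ids"
            )
        if self.feature_kind == "binary_fingerprint":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValidationError("binary fingerprints must contain only 0/1")
        elif self.feature_kind == "continuous_profile":
            if np.isnan(self.values).any():
                bad = [
                    self.entity_ids[i]
                    for i in np.nonzero(np.isnan(self.values).any(axis=1))[0]
                ]
                raise ValidationError(
                    f"missing values in profiles for {bad}; impute or drop first"
                )
        else:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityMatrix:
    """A symmetric, unit-diagonal similarity matrix with labeled axes."""

    entity_ids: list[str]
    S: np.ndarray
    kind: Literal["drug", "cell_line"] = field(default="drug")

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.entity_ids)
        if self.S.shape != (n, n):
            raise ValidationError(
                f"similarity grid {self.S.shape} does not match {n} entities"
            )
        if not np.array_equal(self.S, self.S.T):
            raise ValidationError("similarity matrix must be exactly symmetric")

    @property
    def n(self) -> int:
        return self.S.shape[0]


def _symmetrize(S: np.ndarray) -> np.ndarray:
    # exact symmetry so downstream Laplacian code can rely on it
    return (S + S.T) / 2.0


def jaccard_similarity(fingerprints: FeatureTable) -> SimilarityMatrix:
    """Jaccard coefficient between binary fingerprint rows.

    S(i, j) = |bits_i ∩ bits_j| / |bits_i ∪ bits_j|, diagonal forced to 1.
    An entity with no set bits has an undefined self-similarity (0/0) and is
    rejected.
    """
    if fingerprints.feature_kind != "binary_fingerprint":
        raise ValidationError("jaccard_similarity requires binary fingerprints")
    if fingerprints.n_entities < 2:
        raise ValidationError("need at least 2 entities")
    V = fingerprints.values
    popcount = V.sum(axis=1)
    if (popcount == 0).any():
        bad = [fingerprints.entity_ids[i] for i in np.nonzero(popcount == 0)[0]]
        raise ValidationError(f"all-zero fingerprint for {bad}; Jaccard undefined")
    inter = V @ V.T
    union = popcount[:, None] + popcount[None, :] - inter
    S = inter / union
    S = _symmetrize(S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(fingerprints.entity_ids, S, kind="drug")


def pearson_similarity(
    profiles: FeatureTable, clip_negative: bool = False
) -> SimilarityMatrix:
    """Pearson correlation between continuous profile rows.

    Negative correlations are kept by default; set ``clip_negative`` to
    truncate them at 0 before graph construction.
    """
    if profiles.feature_kind != "continuous_profile":
        raise ValidationError("pearson_similarity requires continuous profiles")
    if profiles.n_entities < 2:
        raise ValidationError("need at least 2 entities")
    V = profiles.values
    if V.shape[1] < 2:
        raise ValidationError("need at least 2 features for a correlation")
    sd = V.std(axis=1)
    if (sd == 0).any():
        bad = [profiles.entity_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance profile for {bad}; PCC undefined")
    S = np.corrcoef(V)
    if clip_negative:
        S = np.clip(S, 0.0, None)
    S = _symmetrize(np.clip(S, -1.0, 1.0))
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(profiles.entity_ids, S, kind="cell_line")
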