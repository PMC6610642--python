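"""Synthetic fixtures with the statistical structure the factorization assumes.

A dataset is generated from rank-k Gaussian truth factors: R = A Bᵀ plus
Gaussian noise, a uniform missingness mask at an exact configurable rate,
and drug/cell-line similarity matrices derived from the truth factors
themselves (cosine similarity mapped to [0, 1]).  Because similarities come
from the generating factors, entities close in similarity space really are
close in the latent space — the local-invariance assumption that graph
regularization exploits holds by construction, so these fixtures isolate
solver correctness from similarity quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import FeatureTable, SimilarityMatrix, ValidationError
from .solver import ResponseMatrix

__all__ = ["SyntheticDataset", "generate", "fingerprints_from_factors"]


@dataclass
class SyntheticDataset:
    """A generated fixture plus its ground truth."""

    rm: ResponseMatrix
    Sd: SimilarityMatrix
    Sc: SimilarityMatrix
    truth_A: np.ndarray
    truth_B: np.ndarray
    truth_R: np.ndarray
    gen_params: dict

    def masked_entries(self) -> np.ndarray:
        """(row, col) index pairs hidden by the missingness mask."""
        return np.argwhere(self.rm.W == 0)


def _cosine_unit_interval(F: np.ndarray, ids: list[str], kind: str) -> SimilarityMatrix:
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = F / norms
    C = np.clip(U @ U.T, -1.0, 1.0)
    S = (C + 1.0) / 2.0  # map [-1, 1] -> [0, 1]
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix([str(i) for i in ids], S, kind=kind)


def generate(
    n: int = 25,
    m: int = 40,
    k_true: int = 2,
    noise_sd: float = 0.1,
    missing_fraction: float = 0.2,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a rank-``k_true`` drug-response fixture.

    Parameters
    ----------
    n, m
        Number of drugs and cell lines.
    k_true
        Rank of the generating factors (standard Gaussian entries).
    noise_sd
        Noise scale as a fraction of sd(truth_R); the observation noise is
        N(0, (noise_sd · sd(truth_R))²).
    missing_fraction
        Fraction of entries hidden, masked exactly: round(missing_fraction
        · n · m) entries chosen uniformly without replacement.
    seed
        Seed for all randomness; identical seeds give identical datasets.
    """
    if k_true > min(n, m):
        raise ValidationError(f"k_true={k_true} exceeds min(n, m)={min(n, m)}")
    if not (0 <= missing_fraction < 1):
        raise ValidationError("missing_fraction must be in [0, 1)")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, k_true))
    B = rng.standard_normal((m, k_true))
    truth_R = A @ B.T
    scale = noise_sd * truth_R.std()
    R = truth_R + rng.normal(0.0, scale, size=(n, m)) if scale > 0 else truth_R.copy()

    W = np.ones((n, m))
    n_hide = int(round(missing_fraction * n * m))
    if n_hide:
        flat = rng.choice(n * m, size=n_hide, replace=False)
        W.flat[flat] = 0.0

    drug_ids = [f"drug{i:03d}" for i in range(n)]
    cell_ids = [f"cell{j:03d}" for j in range(m)]
    rm = ResponseMatrix(drug_ids, cell_ids, R, W)
    Sd = _cosine_unit_interval(A, drug_ids, "drug")
    Sc = _cosine_unit_interval(B, cell_ids, "cell_line")
    return SyntheticDataset(
        rm=rm, Sd=Sd, Sc=Sc, truth_A=A, truth_B=B, truth_R=truth_R,
        gen_params={"n": n, "m": m, "k_true": k_true, "noise_sd": noise_sd,
                    "missing_fraction": missing_fraction, "seed": seed},
    )


def fingerprints_from_factors(
    factors: np.ndarray, ids: list[str], n_bits: int = 64, seed: int = 0
) -> FeatureTable:
    """Emulate binary fingerprints by thresholding Gaussian feature loadings.

    Bits are sign indicators of random projections of the latent factors —
    a convenience for exercising the Jaccard path end-to-end, not a model
    of real chemical fingerprints.  Rows that come out all-zero get their
    first bit set so Jaccard stays defined.
    """
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((factors.shape[1], n_bits))
    bits = (factors @ G > 0).astype(float)
    empty = bits.sum(axis=1) == 0
    bits[empty, 0] = 1.0
    return FeatureTable([str(i) for i in ids], bits, "binary_fingerprint")
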