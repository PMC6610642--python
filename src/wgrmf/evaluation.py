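"""Per-drug evaluation metrics and repeated entry-wise cross-validation.

Prediction quality is summarized per drug by the Pearson correlation (PCC)
and root-mean-square error (RMSE) between predicted and observed responses,
optionally restricted to each drug's most sensitive and most resistant
cell-line quartiles (PCCsr / RMSEsr).  Cross-validation masks observed
*entries* (not whole rows or columns): per repeat the observed set is
partitioned into near-equal folds, the model is refit with each fold hidden
and its predictions collected, so every observed entry is predicted exactly
once per repeat.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix, ValidationError
from .solver import HyperParams, LatentFactors, ResponseMatrix, fit, predict

__all__ = [
    "CVResult",
    "pcc",
    "rmse",
    "sensitive_resistant_subset",
    "kfold_cv",
    "grid_search",
]

logger = logging.getLogger(__name__)

Orientation = Literal["lower", "higher"]
METRICS = ("pcc", "rmse", "pcc_sr", "rmse_sr")


def pcc(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation coefficient between observed and predicted values.

    Returns NaN (an undefined marker, excluded from averages) when either
    sequence has zero variance.
    """
    r = np.asarray(observed, dtype=float)
    rh = np.asarray(predicted, dtype=float)
    if r.shape != rh.shape:
        raise ValidationError(f"length mismatch: {r.shape} vs {rh.shape}")
    if r.size < 2:
        raise ValidationError("PCC needs at least 2 paired values")
    rc = r - r.mean()
    rhc = rh - rh.mean()
    denom = np.sqrt(np.sum(rc**2) * np.sum(rhc**2))
    if denom == 0:
        return float("nan")
    return float(np.clip(np.sum(rc * rhc) / denom, -1.0, 1.0))


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error between observed and predicted values."""
    r = np.asarray(observed, dtype=float)
    rh = np.asarray(predicted, dtype=float)
    if r.shape != rh.shape:
        raise ValidationError(f"length mismatch: {r.shape} vs {rh.shape}")
    if r.size < 1:
        raise ValidationError("RMSE needs at least 1 paired value")
    return float(np.sqrt(np.mean((r - rh) ** 2)))


def sensitive_resistant_subset(
    drug_responses: pd.Series | dict[str, float],
    orientation: Orientation = "lower",
) -> tuple[list[str], list[str]]:
    """Split one drug's observed responses into sensitive/resistant quartiles.

    Cell lines are ranked by response; the extreme quartiles (size
    floor(nd/4) each, middle remainder discarded) are returned as
    (sensitive_ids, resistant_ids).  ``orientation="lower"`` means lower
    values indicate sensitivity (IC50 semantics); ``"higher"`` the reverse
    (activity-area semantics).  Ties are broken by identifier order.
    """
    s = pd.Series(drug_responses, dtype=float)
    nd = len(s)
    if nd < 4:
        raise ValidationError(f"need at least 4 responses for quartiles, got {nd}")
    ids = list(s.index.astype(str))
    order = sorted(range(nd), key=lambda i: (s.iloc[i], i))
    q = nd // 4
    low = [ids[i] for i in order[:q]]
    high = [ids[i] for i in order[-q:]]
    if orientation == "lower":
        return low, high
    return high, low


def _per_drug_metrics(
    rm: ResponseMatrix,
    pred: np.ndarray,
    orientation: Orientation,
) -> pd.DataFrame:
    """Assemble per-drug PCC/RMSE (all cells and sr quartiles) from a full
    predicted grid aligned with the observed entries of ``rm``."""
    rows = []
    cells = np.array(rm.cell_ids)
    for i, drug in enumerate(rm.drug_ids):
        mask = rm.W[i] == 1
        nd = int(mask.sum())
        if nd < 2:
            logger.info("drug %s has %d observed responses; metrics skipped", drug, nd)
            continue
        obs = rm.R[i, mask]
        est = pred[i, mask]
        rec = {"drug": drug, "pcc": pcc(obs, est), "rmse": rmse(obs, est),
               "pcc_sr": float("nan"), "rmse_sr": float("nan")}
        if nd >= 4:
            series = pd.Series(obs, index=cells[mask])
            sens, resist = sensitive_resistant_subset(series, orientation)
            keep = series.index.isin(sens + resist)
            if keep.sum() >= 2:
                rec["pcc_sr"] = pcc(obs[keep], est[keep])
                rec["rmse_sr"] = rmse(obs[keep], est[keep])
        else:
            logger.info("drug %s excluded from sr metrics (nd=%d < 4)", drug, nd)
        rows.append(rec)
    return pd.DataFrame(rows)


def _fold_partition(
    obs_idx: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    perm = rng.permutation(len(obs_idx))
    return [obs_idx[chunk] for chunk in np.array_split(perm, n_folds)]


@dataclass
class CVResult:
    """Repeated cross-validation output.

    ``per_drug`` is tidy (drug, repeat, metric, value); ``summary`` holds the
    drug-averaged mean ± sd of each metric; ``fold_assignments`` records the
    entry partition of every repeat for reproducibility.
    """

    per_drug: pd.DataFrame
    summary: pd.DataFrame
    fold_assignments: list[list[np.ndarray]]
    hp_used: HyperParams
    n_undefined: int = 0

    def drug_averages(self) -> pd.Series:
        """Mean over drugs of the per-drug metric means across repeats."""
        wide = self.per_drug.pivot_table(
            index="drug", columns="metric", values="value", aggfunc="mean"
        )
        return wide.mean(axis=0)


def _summarize(per_drug: pd.DataFrame) -> pd.DataFrame:
    wide = per_drug.pivot_table(
        index="drug", columns="metric", values="value", aggfunc="mean"
    )
    return pd.DataFrame({"mean": wide.mean(axis=0), "sd": wide.std(axis=0, ddof=1)})


def kfold_cv(
    rm: ResponseMatrix,
    Sd: SimilarityMatrix,
    Sc: SimilarityMatrix,
    hp: HyperParams,
    n_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    orientation: Orientation = "lower",
) -> CVResult:
    """Entry-wise k-fold cross-validation, repeated with derived seeds.

    Per repeat the observed entries are partitioned into ``n_folds``
    near-equal subsets; each fold is masked out, the model refit on the
    rest and its held-out predictions collected.  Per-drug metrics are then
    computed from the assembled predicted-vs-observed pairs.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    obs_idx = np.argwhere(rm.W == 1)
    if len(obs_idx) < n_folds:
        raise ValidationError(
            f"{len(obs_idx)} observed entries cannot fill {n_folds} folds"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_repeats)

    records = []
    assignments: list[list[np.ndarray]] = []
    n_undefined = 0
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        folds = _fold_partition(obs_idx, n_folds, rng)
        assignments.append(folds)
        pred = np.full(rm.shape, np.nan)
        for fold in folds:
            train = rm.masked_copy(fold)
            if train.n_observed() == 0:
                raise ValidationError("a fold left zero training entries")
            lf = fit(train, Sd, Sc, hp)
            full = lf.A @ lf.B.T
            pred[fold[:, 0], fold[:, 1]] = full[fold[:, 0], fold[:, 1]]
        metrics = _per_drug_metrics(rm, pred, orientation)
        n_undefined += int(metrics["pcc"].isna().sum())
        for _, row in metrics.iterrows():
            for metric in METRICS:
                records.append(
                    {"drug": row["drug"], "repeat": rep,
                     "metric": metric, "value": row[metric]}
                )

    per_drug = pd.DataFrame(records)
    if n_undefined:
        logger.warning("%d undefined per-drug PCC values excluded", n_undefined)
    return CVResult(
        per_drug=per_drug,
        summary=_summarize(per_drug),
        fold_assignments=assignments,
        hp_used=hp,
        n_undefined=n_undefined,
    )


def grid_search(
    rm: ResponseMatrix,
    Sd: SimilarityMatrix,
    Sc: SimilarityMatrix,
    grids: dict[str, Sequence],
    n_folds: int = 3,
    seed: int = 0,
    base: HyperParams | None = None,
    orientation: Orientation = "lower",
) -> HyperParams:
    """Exhaustive hyperparameter search by inner cross-validation.

    ``grids`` maps :class:`HyperParams` field names to candidate values;
    the Cartesian product is scored by drug-averaged PCC on ``rm`` (call on
    training data only for a nested, leak-free protocol).  Ties prefer a
    larger ``lambda_l`` then a smaller ``k`` (stronger regularization).
    Combinations where the solver fails are skipped.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValidationError("grids must be non-empty")
    base = base or HyperParams()
    keys = list(grids)
    best: tuple[float, float, float] | None = None
    best_hp: HyperParams | None = None
    for combo in itertools.product(*(grids[k] for k in keys)):
        hp = replace(base, **dict(zip(keys, combo)))
        try:
            res = kfold_cv(rm, Sd, Sc, hp, n_folds=n_folds, n_repeats=1,
                           seed=seed, orientation=orientation)
            score = float(res.drug_averages()["pcc"])
        except (ValidationError, np.linalg.LinAlgError) as exc:
            logger.warning("grid cell %s failed: %s", dict(zip(keys, combo)), exc)
            continue
        if np.isnan(score):
            continue
        key = (score, hp.lambda_l, -hp.k)
        if best is None or key > best:
            best = key
            best_hp = hp
    if best_hp is None:
        raise ValidationError("every grid combination failed")
    return best_hp
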