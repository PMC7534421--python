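"""Cross-validation designs and accuracy metrics for genomic prediction.

Three folding schemes mirror increasing training-validation separation:

* ``random``           10 folds, sizes differing by at most one tree;
* ``balanced_family``  5 folds, each family's trees dealt as evenly as
                       possible across folds (every fold validates >=20%
                       of each sufficiently large family);
* ``family``           one fold per family (>= 8 trees), withholding the
                       entire family from training, so accuracy reflects
                       marker-QTL linkage disequilibrium rather than
                       captured relationships.

Metrics per fold: predictive ability (Pearson correlation of adjusted
phenotypes with cross-validation predictions) and prediction accuracy
(correlation of full-data predictions with cross-validation predictions),
summarised across folds as mean and SE = SD/sqrt(n_folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ADDITIVE, DOMINANCE, BLUPModel, BLUPResults, ConvergenceError

SCHEMES = ("random", "balanced_family", "family")
MIN_FAMILY_SIZE = 8  # families smaller than this are not validated in family folding


def theoretical_accuracy(pev, sigma2_a: float, F) -> pd.Series:
    """Per-individual accuracy r_i = sqrt(1 - PEV_i / (sigma2_a (1 + F_i))).

    PEV is the prediction error variance from the mixed-model equations and
    F_i the inbreeding coefficient.  Radicands below -1e-10 raise; small
    negative values from roundoff are clipped to zero.
    """
    pev = pd.Series(pev, dtype=float)
    F = pd.Series(F, dtype=float).reindex(pev.index)
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    denom = sigma2_a * (1.0 + F)
    radicand = 1.0 - pev / denom
    if (radicand < -1e-10).any():
        bad = radicand[radicand < -1e-10]
        raise ValueError(f"negative accuracy radicand for {list(bad.index[:5])}")
    return np.sqrt(radicand.clip(lower=0.0)).rename("accuracy")


@dataclass
class FoldAssignment:
    """Partition of the evaluation set into validation folds."""

    scheme: str
    n_folds: int
    membership: dict  # individual id -> fold index
    seed: int
    excluded: list = field(default_factory=list)

    def fold_ids(self, fold: int) -> list:
        return [i for i, f in self.membership.items() if f == fold]

    @property
    def fold_sizes(self) -> list[int]:
        counts = pd.Series(self.membership).value_counts()
        return [int(counts.get(f, 0)) for f in range(self.n_folds)]


def make_folds(scheme: str, ids, family_of: dict | None = None, seed: int = 0,
               n_folds: int | None = None) -> FoldAssignment:
    """Deterministic fold assignment for a given (scheme, ids, seed)."""
    ids = list(ids)
    rng = np.random.default_rng(seed)
    if scheme == "random":
        k = n_folds or 10
        perm = [ids[i] for i in rng.permutation(len(ids))]
        membership = {}
        for fold, chunk in enumerate(np.array_split(np.arange(len(ids)), k)):
            for j in chunk:
                membership[perm[j]] = fold
        return FoldAssignment(scheme, k, membership, seed)

    if family_of is None:
        raise ValueError(f"scheme {scheme!r} requires family_of")
    families: dict[str, list] = {}
    for i in ids:
        families.setdefault(family_of[i], []).append(i)

    if scheme == "balanced_family":
        k = n_folds or 5
        membership = {}
        for fam in sorted(families):
            members = families[fam]
            perm = [members[i] for i in rng.permutation(len(members))]
            offset = int(rng.integers(k))
            for j, ind in enumerate(perm):
                membership[ind] = (j + offset) % k
        return FoldAssignment(scheme, k, membership, seed)

    if scheme == "family":
        eligible = [f for f in sorted(families) if len(families[f]) >= MIN_FAMILY_SIZE]
        excluded = [f for f in sorted(families) if f not in eligible]
        if not eligible:
            raise ValueError(
                f"no family with >= {MIN_FAMILY_SIZE} trees for family folding")
        membership = {}
        for fold, fam in enumerate(eligible):
            for ind in families[fam]:
                membership[ind] = fold
        return FoldAssignment(scheme, len(eligible), membership, seed,
                              excluded=excluded)

    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def predictive_ability(adjusted_pheno: pd.Series, cv_predictions: pd.Series) -> float:
    """Pearson correlation of adjusted phenotypes with CV predictions
    (one fold); NaN when undefined (zero variance or < 3 pairs)."""
    common = adjusted_pheno.index.intersection(cv_predictions.index)
    paired = pd.DataFrame({"y": adjusted_pheno.loc[common],
                           "p": cv_predictions.loc[common]}).dropna()
    return _pearson(paired["y"].to_numpy(), paired["p"].to_numpy())


def prediction_accuracy(full_fit_values: pd.Series, cv_predictions: pd.Series) -> float:
    """Pearson correlation of full-data predictions with CV predictions."""
    return predictive_ability(full_fit_values, cv_predictions)


@dataclass
class CVResult:
    """Fold-wise metrics plus across-fold summaries per prediction type."""

    scheme: str
    folds_frame: pd.DataFrame  # columns: fold, type, n_val, pa, accuracy
    failed_folds: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for (ptype,), grp in self.folds_frame.groupby(["type"]):
            for metric in ("pa", "accuracy"):
                vals = grp[metric].dropna()
                rows.append({
                    "type": ptype, "metric": metric, "n_folds": len(vals),
                    "mean": vals.mean(), "sd": vals.std(ddof=1),
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) else np.nan,
                })
        return pd.DataFrame(rows)


def _predictions(res: BLUPResults) -> dict[str, pd.Series]:
    preds = {res.additive_name: res.ranef(ADDITIVE)}
    if DOMINANCE in res.labels:
        preds["MGV"] = res.mgv
    return preds


def run_cross_validation(y: pd.Series, terms, folds: FoldAssignment,
                         full_results: BLUPResults | None = None,
                         fixed_vc: dict | None = None,
                         fit_kwargs: dict | None = None) -> CVResult:
    """Cross-validate a BLUP model specification.

    Parameters
    ----------
    y : pd.Series
        Adjusted phenotypes indexed by individual id (training pool =
        everything not in the current validation fold).
    terms : sequence of (label, RelationshipMatrix)
        Model terms; relationship matrices cover all individuals, so
        masking a fold's phenotypes leaves the matrices unchanged.
    folds : FoldAssignment
        Validation folds over (a subset of) the phenotyped individuals.
    full_results : BLUPResults, optional
        Full-data fit providing the reference values for prediction
        accuracy; fitted here when omitted.
    fixed_vc : dict, optional
        Variance components to reuse in every fold instead of
        re-estimating by REML.
    """
    fit_kwargs = fit_kwargs or {}
    additive_K = dict(terms)[ADDITIVE]
    if additive_K.kind == "A" and folds.scheme == "family":
        warnings.warn("family folding with a pedigree-only model predicts the "
                      "family mean; results are not informative", stacklevel=2)
    if full_results is None:
        full_results = BLUPModel(y.to_numpy(), y.index.to_numpy(), terms).fit(**fit_kwargs)
    full_preds = _predictions(full_results)

    rows, failed = [], []
    for fold in range(folds.n_folds):
        val_ids = folds.fold_ids(fold)
        train = y.drop(index=val_ids)
        model = BLUPModel(train.to_numpy(), train.index.to_numpy(), terms)
        try:
            res = model.evaluate(fixed_vc) if fixed_vc else model.fit(**fit_kwargs)
        except ConvergenceError as err:
            failed.append((fold, str(err)))
            continue
        for ptype, pred in _predictions(res).items():
            val_pred = pred.loc[[i for i in val_ids if i in pred.index]]
            rows.append({
                "fold": fold, "type": ptype, "n_val": len(val_pred),
                "pa": predictive_ability(y, val_pred),
                "accuracy": prediction_accuracy(full_preds[ptype], val_pred),
            })
    return CVResult(folds.scheme, pd.DataFrame(rows), failed)
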