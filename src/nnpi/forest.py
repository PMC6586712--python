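"""Class-balanced random forest for combined NNPI status (LM vs HVH).

The response at most survey sites is low-moderate, so every tree is grown
on a downsampled balanced bootstrap: the same number of cases drawn (with
replacement) from each class, equal to the minority-class size.  Out-of-bag
(OOB) votes give cross-validated performance (percent correctly classified
overall and per class, majority vote with ties resolved to HVH), variable
importance is the per-tree mean decrease in OOB accuracy after permuting a
predictor, and partial dependence curves show the HVH vote fraction as a
single predictor sweeps its observed range.

Trees are CART classifiers with ``mtry = floor(sqrt(p))`` features examined
per split; categorical predictors are one-hot encoded, and permutation
importance permutes all encoded columns of a categorical jointly so
importance is reported per original predictor.  Survey weights are not
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

CLASSES = ("LM", "HVH")


@dataclass
class ForestConfig:
    """Forest hyperparameters; ``mtry`` defaults to floor(sqrt(p))."""

    n_trees: int = 1000
    mtry: Optional[int] = None
    seed: int = 0


@dataclass
class ForestReport:
    """OOB performance, per-predictor importance, and metadata."""

    pcc_all: float
    pcc_lm: float
    pcc_hvh: float
    importance: dict[str, float]
    n_trees: int
    mtry: int
    per_class_bootstrap: int
    encoding: str = "one-hot"


class BalancedRandomForest:
    """Downsampled-balanced bagged CART ensemble with OOB bookkeeping.

    Parameters
    ----------
    config:
        Number of trees, features per split, and the master seed (which
        fixes bootstraps, tree induction, and permutation draws).
    """

    def __init__(self, config: ForestConfig | None = None):
        self.config = config or ForestConfig()
        self._fitted = False

    # -- encoding -----------------------------------------------------------

    @staticmethod
    def encode(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
        """One-hot encode object/categorical columns.

        Returns the numeric design matrix and a map original predictor ->
        encoded column names (identity for numeric predictors).
        """
        groups: dict[str, list[str]] = {}
        pieces = []
        for col in X.columns:
            s = X[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                d = pd.get_dummies(s, prefix=col, dtype=float)
                groups[col] = list(d.columns)
                pieces.append(d)
            else:
                groups[col] = [col]
                pieces.append(s.astype(float).to_frame())
        return pd.concat(pieces, axis=1), groups

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "BalancedRandomForest":
        """Fit the ensemble; ``y`` holds 'LM'/'HVH' labels.

        Raises ``ValueError`` when predictors contain missing values or a
        class has fewer than 2 members.
        """
        y = np.asarray(y)
        bad = set(y) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class label(s) {sorted(bad)}")
        if X.isna().any().any():
            raise ValueError("predictor table contains missing values")
        Xe, self.feature_groups_ = self.encode(X)
        self.feature_names_ = list(Xe.columns)
        Xm = Xe.to_numpy(dtype=float)
        n, p = Xm.shape
        class_idx = {c: np.flatnonzero(y == c) for c in CLASSES}
        counts = {c: len(v) for c, v in class_idx.items()}
        if min(counts.values()) < 2:
            raise ValueError(f"each class needs >= 2 members; got {counts}")
        n_per_class = min(counts.values())

        mtry = self.config.mtry or max(1, int(np.floor(np.sqrt(p))))
        rng = np.random.default_rng(self.config.seed)

        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_indices_: list[np.ndarray] = []
        self.inbag_counts_ = np.zeros((self.config.n_trees, n), dtype=np.int32)
        vote_hvh = np.zeros(n, dtype=np.int64)
        vote_total = np.zeros(n, dtype=np.int64)

        for t in range(self.config.n_trees):
            boot = np.concatenate(
                [rng.choice(class_idx[c], size=n_per_class, replace=True) for c in CLASSES]
            )
            oob = np.flatnonzero(~np.isin(np.arange(n), boot))
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xm[boot], y[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
            np.add.at(self.inbag_counts_[t], boot, 1)
            if len(oob):
                pred = tree.predict(Xm[oob])
                vote_hvh[oob] += pred == "HVH"
                vote_total[oob] += 1

        self.X_ = Xm
        self.y_ = y
        self.mtry_ = mtry
        self.n_per_class_ = n_per_class
        self.oob_vote_hvh_ = vote_hvh
        self.oob_vote_total_ = vote_total
        self._fitted = True
        return self

    # -- OOB performance ----------------------------------------------------

    def oob_predictions(self) -> np.ndarray:
        """Majority-vote OOB class per site; ties go to HVH (the
        stress-conservative call).  Sites never OOB yield ''."""
        self._check_fitted()
        out = np.full(len(self.y_), "", dtype=object)
        seen = self.oob_vote_total_ > 0
        hvh = self.oob_vote_hvh_[seen] * 2 >= self.oob_vote_total_[seen]
        out[seen] = np.where(hvh, "HVH", "LM")
        return out

    def oob_probability_hvh(self) -> np.ndarray:
        """OOB predicted probability of HVH (vote fraction); NaN if never
        OOB."""
        self._check_fitted()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.oob_vote_total_ > 0,
                self.oob_vote_hvh_ / self.oob_vote_total_,
                np.nan,
            )

    def oob_performance(self) -> tuple[float, float, float]:
        """Percent correctly classified: overall, LM, and HVH.

        Sites never out of bag are excluded (with essentially no effect at
        typical tree counts); an empty vote set raises.
        """
        self._check_fitted()
        pred = self.oob_predictions()
        seen = pred != ""
        if not seen.any():
            raise ValueError("no OOB votes recorded")
        return oob_performance(pred[seen], self.y_[seen])

    # -- permutation importance --------------------------------------------

    def permutation_importance(self) -> dict[str, float]:
        """Mean decrease in OOB accuracy per original predictor.

        For each tree, its OOB accuracy is compared with the accuracy after
        permuting one predictor's values (all one-hot columns of a
        categorical permuted jointly, preserving the rows' category draws)
        within the OOB rows; the decreases are averaged over trees.
        """
        self._check_fitted()
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 1]))
        drops = {name: [] for name in self.feature_groups_}
        col_pos = {c: i for i, c in enumerate(self.feature_names_)}
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if len(oob) < 2:
                continue
            Xo = self.X_[oob]
            yo = self.y_[oob]
            base = np.mean(tree.predict(Xo) == yo)
            perm = rng.permutation(len(oob))
            used = set(tree.tree_.feature[tree.tree_.feature >= 0])
            for name, cols in self.feature_groups_.items():
                pos = [col_pos[c] for c in cols]
                if not used.intersection(pos):
                    drops[name].append(0.0)  # unused predictor: exactly no change
                    continue
                Xp = Xo.copy()
                Xp[:, pos] = Xo[perm][:, pos]
                acc = np.mean(tree.predict(Xp) == yo)
                drops[name].append(base - acc)
        return {name: float(np.mean(v)) if v else float("nan") for name, v in drops.items()}

    # -- partial dependence --------------------------------------------------

    def partial_dependence(
        self,
        predictor: str,
        grid: np.ndarray | Sequence | None = None,
        n_grid: int = 25,
    ) -> pd.DataFrame:
        """HVH vote fraction as *predictor* sweeps a grid.

        For each grid value v the predictor column is set to v for every
        site and the mean fraction of HVH votes across all trees and sites
        is recorded, averaging out the other predictors empirically.  The
        default grid is ``n_grid`` equally spaced points between the 1st
        and 99th percentiles of the observed values (numeric predictors)
        or the observed categories (categorical predictors).
        """
        self._check_fitted()
        if predictor not in self.feature_groups_:
            raise ValueError(f"unknown predictor {predictor!r}")
        cols = self.feature_groups_[predictor]
        pos = [self.feature_names_.index(c) for c in cols]
        categorical = len(cols) > 1 or cols[0] != predictor
        if grid is None:
            if categorical:
                grid = [c[len(predictor) + 1:] for c in cols]
            else:
                v = self.X_[:, pos[0]]
                lo, hi = np.percentile(v, [1, 99])
                grid = np.linspace(lo, hi, n_grid)
        grid = list(grid)
        if len(grid) == 0:
            raise ValueError("partial dependence grid is empty")
        probs = []
        for v in grid:
            Xg = self.X_.copy()
            if categorical:
                col = f"{predictor}_{v}"
                if col not in cols:
                    raise ValueError(f"unknown category {v!r} for {predictor}")
                Xg[:, pos] = 0.0
                Xg[:, self.feature_names_.index(col)] = 1.0
            else:
                Xg[:, pos[0]] = float(v)
            hvh = np.zeros(len(Xg))
            for tree in self.trees_:
                hvh += tree.predict(Xg) == "HVH"
            probs.append(float(np.mean(hvh / len(self.trees_))))
        return pd.DataFrame({"value": grid, "prob_hvh": probs})

    # -- reporting ----------------------------------------------------------

    def report(self) -> ForestReport:
        pcc_all, pcc_lm, pcc_hvh = self.oob_performance()
        return ForestReport(
            pcc_all=pcc_all,
            pcc_lm=pcc_lm,
            pcc_hvh=pcc_hvh,
            importance=self.permutation_importance(),
            n_trees=self.config.n_trees,
            mtry=self.mtry_,
            per_class_bootstrap=self.n_per_class_,
        )

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("forest is not fitted")


def oob_performance(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Percent correct overall and per class from predictions vs labels."""
    pred = np.asarray(pred)
    labels = np.asarray(labels)
    if len(pred) == 0:
        raise ValueError("empty prediction set")
    correct = pred == labels
    pcc_all = float(correct.mean() * 100.0)
    out = [pcc_all]
    for c in CLASSES:
        mask = labels == c
        out.append(float(correct[mask].mean() * 100.0) if mask.any() else float("nan"))
    return tuple(out)  # type: ignore[return-value]
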