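"""Gradient-boosted-tree model for S-palmitoyl site classification.

Organised in the model/results idiom: :class:`PalmSiteModel` holds the
labeled feature table and hyperparameters; its :meth:`~PalmSiteModel.fit`
runs stratified cross-validation, fits the final booster on all rows and
returns a :class:`PalmSiteResults` carrying the fitted classifier, CV
diagnostics, feature importances and every downstream operation —
scoring, evaluation, ranking, serialization and in-silico Cys-scanning
mutagenesis.

Hyperparameters mirror the classical gradient-boosting knobs:
interaction depth (tree depth), number of trees, shrinkage (learning
rate) and minimum observations per terminal node.  The shipped defaults
are depth 18, 2000 trees, shrinkage 0.08 and 5 observations per node
with 10-fold CV.  The backend is xgboost configured single-threaded on
the exact histogram method, so a fixed seed gives bit-identical
predictions across runs.

A results object records a hash of its ordered feature roster and
refuses to score tables built under a different registry — a silent
column permutation would corrupt every prediction.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from . import metrics as _metrics
from .curation import LabeledDataset
from .features import (
    FEATURE_NAMES,
    FeaturizeResult,
    SiteIneligible,
    feature_registry_hash,
    featurize_proteome,
    featurize_site,
)
from .topology import ProteinRecord

__all__ = ["Hyperparams", "PalmSiteModel", "PalmSiteResults"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperparams:
    """Gradient-boosting knobs in the classical naming.

    interaction_depth maps to tree depth, shrinkage to the learning
    rate, min_obs_per_node to the minimum child weight.
    """

    interaction_depth: int = 18
    n_trees: int = 2000
    shrinkage: float = 0.08
    min_obs_per_node: int = 5
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.interaction_depth, self.n_trees, self.min_obs_per_node) < 1:
            raise ValueError("tree hyperparameters must be positive")
        if self.shrinkage <= 0:
            raise ValueError("shrinkage must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")

    def to_xgb_kwargs(self) -> dict:
        return dict(
            max_depth=self.interaction_depth,
            n_estimators=self.n_trees,
            learning_rate=self.shrinkage,
            min_child_weight=self.min_obs_per_node,
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="exact",
            n_jobs=1,
            random_state=self.seed,
            base_score=0.5,
        )


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{context}: both classes must be present")


class PalmSiteModel:
    """Labeled site features plus hyperparameters, ready to fit.

    Parameters
    ----------
    X : feature table with exactly the registry columns, in order.
    y : binary labels aligned with ``X`` (1 = S-palmitoyl).
    sites : optional (accession, position) frame aligned with ``X``,
        kept so downstream rank tables stay keyed to real sites.
    hyperparams : boosting configuration; defaults above.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[int],
        sites: Optional[pd.DataFrame] = None,
        hyperparams: Optional[Hyperparams] = None,
        feature_names: Sequence[str] = FEATURE_NAMES,
    ) -> None:
        self.feature_names = tuple(feature_names)
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        self.X = X[list(self.feature_names)].reset_index(drop=True)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must align")
        self.sites = (
            sites.reset_index(drop=True) if sites is not None else None
        )
        self.hyperparams = hyperparams or Hyperparams()

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_dataset(
        cls,
        dataset: LabeledDataset,
        hyperparams: Optional[Hyperparams] = None,
    ) -> "PalmSiteModel":
        table = dataset.table
        return cls(
            X=table,
            y=table["label"].to_numpy(),
            sites=table[["accession", "position"]],
            hyperparams=hyperparams,
            feature_names=dataset.feature_names,
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_col: str = "label",
        hyperparams: Optional[Hyperparams] = None,
    ) -> "PalmSiteModel":
        sites = (
            frame[["accession", "position"]]
            if {"accession", "position"}.issubset(frame.columns)
            else None
        )
        return cls(
            X=frame,
            y=frame[label_col].to_numpy(),
            sites=sites,
            hyperparams=hyperparams,
        )

    # ------------------------------------------------------------------
    # cross-validation and fitting
    # ------------------------------------------------------------------
    def _cv_aucs(self, params: Hyperparams) -> List[float]:
        _check_two_classes(self.y, "cross-validation")
        folds = StratifiedKFold(
            n_splits=params.cv_folds, shuffle=True, random_state=params.seed
        )
        aucs: List[float] = []
        for train_idx, test_idx in folds.split(self.X, self.y):
            y_train, y_test = self.y[train_idx], self.y[test_idx]
            if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
                raise ValueError(
                    "a CV fold contains a single class; increase the data "
                    "or reduce cv_folds"
                )
            booster = XGBClassifier(**params.to_xgb_kwargs())
            booster.fit(self.X.iloc[train_idx], y_train)
            scores = booster.predict_proba(self.X.iloc[test_idx])[:, 1]
            aucs.append(float(roc_auc_score(y_test, scores)))
        return aucs

    def tune(
        self,
        grid: Dict[str, Sequence],
        cv_folds: Optional[int] = None,
        seed: Optional[int] = None,
    ) -> Tuple[Hyperparams, pd.DataFrame]:
        """Grid search ranked by mean CV ROC AUC.

        ``grid`` maps hyperparameter field names (interaction_depth,
        n_trees, shrinkage, ...) to candidate values.  Deterministic
        given the seed: ties in mean AUC resolve to the first grid point
        in iteration order.
        """
        base = self.hyperparams
        if cv_folds is not None:
            base = replace(base, cv_folds=cv_folds)
        if seed is not None:
            base = replace(base, seed=seed)
        names = list(grid)
        rows = []
        best: Tuple[float, int] | None = None
        best_params = base
        for i, combo in enumerate(itertools.product(*(grid[n] for n in names))):
            params = replace(base, **dict(zip(names, combo)))
            aucs = self._cv_aucs(params)
            mean_auc = float(np.mean(aucs))
            rows.append(
                {
                    **dict(zip(names, combo)),
                    "cv_auc_mean": mean_auc,
                    "cv_auc_sd": float(np.std(aucs, ddof=1)),
                }
            )
            # -i makes earlier grid points win ties
            key = (mean_auc, -i)
            if best is None or key > best:
                best, best_params = key, params
        return best_params, pd.DataFrame(rows)

    def fit(self, hyperparams: Optional[Hyperparams] = None) -> "PalmSiteResults":
        """Cross-validate, then fit the final booster on all rows."""
        params = hyperparams or self.hyperparams
        _check_two_classes(self.y, "training")
        cv_aucs = self._cv_aucs(params)
        booster = XGBClassifier(**params.to_xgb_kwargs())
        booster.fit(self.X, self.y)
        importances = pd.Series(
            booster.feature_importances_, index=list(self.feature_names)
        ).sort_values(ascending=False)
        return PalmSiteResults(
            booster=booster,
            hyperparams=params,
            feature_names=self.feature_names,
            registry_hash=feature_registry_hash(self.feature_names),
            cv_aucs=tuple(cv_aucs),
            feature_importances_=importances,
            n_train=len(self.y),
            n_positive=int(self.y.sum()),
        )


@dataclass
class PalmSiteResults:
    """A fitted S-palmitoyl classifier plus its training diagnostics."""

    booster: XGBClassifier
    hyperparams: Hyperparams
    feature_names: Tuple[str, ...]
    registry_hash: str
    cv_aucs: Tuple[float, ...]
    feature_importances_: pd.Series
    n_train: int
    n_positive: int

    @property
    def cv_auc_mean(self) -> float:
        return float(np.mean(self.cv_aucs))

    @property
    def cv_auc_sd(self) -> float:
        return float(np.std(self.cv_aucs, ddof=1))

    # ------------------------------------------------------------------
    # scoring
    # ------------------------------------------------------------------
    def _check_registry(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in table.columns if c in set(self.feature_names)]
        if tuple(cols) != self.feature_names:
            raise ValueError(
                "feature registry mismatch: the table's feature columns "
                "must match the model's roster exactly and in order "
                f"(model hash {self.registry_hash})"
            )
        return table[list(self.feature_names)]

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """S-palmitoyl probability per row of a registry-matched table."""
        X = self._check_registry(features)
        return self.booster.predict_proba(X)[:, 1].astype(float)

    def score_sites(self, featurized: FeaturizeResult) -> pd.DataFrame:
        """Score a featurized proteome → accession, position, score."""
        feats = featurized.features
        out = feats[["accession", "position"]].copy()
        out["score"] = self.predict_proba(feats)
        return out

    def score_proteome(
        self, proteins: Iterable[ProteinRecord]
    ) -> pd.DataFrame:
        return self.score_sites(featurize_proteome(proteins))

    # ------------------------------------------------------------------
    # evaluation / ranking
    # ------------------------------------------------------------------
    def evaluate(
        self,
        features: pd.DataFrame,
        labels: Sequence[int],
        thresholds: Sequence[float] = _metrics.DEFAULT_THRESHOLDS,
    ) -> _metrics.MetricReport:
        scores = self.predict_proba(features)
        return _metrics.evaluate(scores, labels, thresholds)

    def rank_and_threshold(
        self,
        scored_sites: pd.DataFrame,
        thresholds: Sequence[float] = _metrics.DEFAULT_THRESHOLDS,
        known_sites: Set[Tuple[str, int]] | None = None,
    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
        return _metrics.rank_and_threshold(
            scored_sites, thresholds, known_sites
        )

    # ------------------------------------------------------------------
    # in-silico Cys scanning
    # ------------------------------------------------------------------
    def cys_scan(self, protein: ProteinRecord) -> pd.DataFrame:
        """Score a Cys substitution at every eligible position.

        Each position outside signal/intramembrane segments is mutated
        to Cys (native cysteines scored as-is), re-featurized in the
        mutated sequence and scored.  Returns one row per position with
        the score, whether the residue is a native Cys, and — for
        ineligible positions — the reason no score is offered (score
        NaN).  The landscape guides rational S-palmitoyl site design:
        peaks mark positions where an introduced Cys is predicted to be
        palmitoylated.
        """
        rows: List[dict] = []
        feat_rows: List[dict] = []
        scored_idx: List[int] = []
        for position in range(1, len(protein.sequence) + 1):
            native = protein.sequence[position - 1]
            if native == "C":
                mutant = protein
            else:
                seq = (
                    protein.sequence[: position - 1]
                    + "C"
                    + protein.sequence[position:]
                )
                mutant = dataclasses.replace(protein, sequence=seq)
            row = {
                "accession": protein.accession,
                "position": position,
                "native_residue": native,
                "is_native_cys": native == "C",
                "score": np.nan,
                "reason": "",
            }
            try:
                feats = featurize_site(mutant, position)
            except SiteIneligible as err:
                row["reason"] = err.reason
                rows.append(row)
                continue
            feat_rows.append(feats)
            scored_idx.append(len(rows))
            rows.append(row)
        if feat_rows:
            table = pd.DataFrame(feat_rows, columns=list(self.feature_names))
            scores = self.predict_proba(table)
            for i, s in zip(scored_idx, scores):
                rows[i]["score"] = float(s)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    # reporting / persistence
    # ------------------------------------------------------------------
    def summary(self) -> str:
        p = self.hyperparams
        top = self.feature_importances_.head(8)
        lines = [
            "S-palmitoyl site gradient-boosted tree",
            "=" * 46,
            f"training sites:        {self.n_train} "
            f"({self.n_positive} positive)",
            f"class imbalance:       "
            f"{self.n_train / self.n_positive:.2f}:1"
            if self.n_positive
            else "class imbalance:       n/a",
            f"interaction depth:     {p.interaction_depth}",
            f"trees:                 {p.n_trees}",
            f"shrinkage:             {p.shrinkage}",
            f"min obs per node:      {p.min_obs_per_node}",
            f"CV ({p.cv_folds}-fold) ROC AUC: "
            f"{self.cv_auc_mean:.4f} ± {self.cv_auc_sd:.4f}",
            f"feature registry:      {self.registry_hash}",
            "",
            "top feature importances (gain):",
            top.to_string(float_format="%.4f"),
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize to a directory: booster dump + self-describing meta."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        # dump the raw booster: the sklearn wrapper's own save path is not
        # stable across xgboost/scikit-learn combinations
        self.booster.get_booster().save_model(path / "booster.json")
        meta = {
            "format_version": _FORMAT_VERSION,
            "feature_names": list(self.feature_names),
            "registry_hash": self.registry_hash,
            "hyperparams": dataclasses.asdict(self.hyperparams),
            "cv_aucs": list(self.cv_aucs),
            "feature_importances": {
                k: float(v) for k, v in self.feature_importances_.items()
            },
            "n_train": self.n_train,
            "n_positive": self.n_positive,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PalmSiteResults":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {meta['format_version']}"
            )
        names = tuple(meta["feature_names"])
        if feature_registry_hash(names) != meta["registry_hash"]:
            raise ValueError("stored registry hash does not match roster")
        hp = Hyperparams(**meta["hyperparams"])
        import xgboost as xgb

        raw = xgb.Booster()
        raw.load_model(path / "booster.json")
        booster = XGBClassifier(**hp.to_xgb_kwargs())
        booster._Booster = raw
        booster.n_classes_ = 2
        return cls(
            booster=booster,
            hyperparams=hp,
            feature_names=names,
            registry_hash=meta["registry_hash"],
            cv_aucs=tuple(meta["cv_aucs"]),
            feature_importances_=pd.Series(meta["feature_importances"]),
            n_train=meta["n_train"],
            n_positive=meta["n_positive"],
        )

    def plot_rank_order(self, scored_sites: pd.DataFrame, ax=None):
        """Rank-order plot of scores with the three threshold lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ordered = np.sort(scored_sites["score"].to_numpy())[::-1]
        ax.plot(np.arange(1, len(ordered) + 1), ordered, lw=1)
        for t in _metrics.DEFAULT_THRESHOLDS:
            ax.axhline(t, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("site rank")
        ax.set_ylabel("S-palmitoyl probability")
        return ax
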