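"""Feature assembly and the random-forest ΔΔG predictor.

A random forest regressor combines the 13 interface-profile features with
optional sequence features and external potential columns.  Two
cross-validation schemes are provided: repeated k-fold (the optimistic,
record-level estimate) and leave-one-protein-out, which holds out every
mutant of the tested complex and therefore measures cross-protein
generalization — the realistic deployment scenario, where no mutant of
the target protein has been seen in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import LeaveOneGroupOut, RepeatedKFold

from .dataset import CuratedDataset
from .profiles import ProfileFeatureSet
from .seqfeatures import pharmacophore_deltas

META_COLUMNS = ("complex_id", "mutations", "ddg_exp")

MTRY_GRID = (2, 4, 6, 8)   # plus p//3, deduplicated and clipped to p


@dataclass
class RFConfig:
    n_trees: int = 500
    seed: int = 0
    max_features: int | None = None   # None -> tune on the test split
    test_fraction: float = 0.2        # internal tuning split when none given


@dataclass
class TrainedModel:
    forest: RandomForestRegressor
    schema: list[str]
    config: RFConfig
    importances: pd.DataFrame | None = None
    cv: "CVSummary | None" = None

    def save(self, path) -> None:
        joblib.dump({"forest": self.forest, "schema": self.schema,
                     "config": self.config}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = joblib.load(path)
        return cls(forest=d["forest"], schema=d["schema"], config=d["config"])


@dataclass
class CVSummary:
    scheme: str
    pearson_mean: float
    pearson_sd: float
    rmse: float                       # standard error of prediction, kcal/mol
    per_repeat: list[float] = field(default_factory=list)
    per_protein: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def assemble_features(dataset: CuratedDataset,
                      profile_featurizer=None,
                      include_sequence: bool = False,
                      external: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """One feature row per curated mutation record.

    ``profile_featurizer(record) -> ProfileFeatureSet`` supplies the 13
    profile features; records it cannot resolve (raising ``ValueError`` or
    returning None) are listed in the exclusion report, never silently
    dropped.  ``external`` is positionally aligned extra columns (one row
    per record, e.g. residue- or atomic-level potential scores).
    """
    rows, exclusions = [], []
    for i, rec in enumerate(dataset.records):
        muts = ";".join(f"{s.chain}:{s.wt}{s.position}{s.mut}"
                        for s in rec.substitutions)
        row: dict[str, float] = {"complex_id": rec.complex_id,
                                 "mutations": muts, "ddg_exp": rec.ddg_exp}
        if profile_featurizer is not None:
            try:
                feats = profile_featurizer(rec)
            except ValueError as exc:
                exclusions.append((muts, str(exc)))
                continue
            if feats is None:
                exclusions.append((muts, "no profile available"))
                continue
            row.update(feats.as_dict())
        if include_sequence:
            row.update(pharmacophore_deltas(rec).as_dict())
        if external is not None:
            for col in external.columns:
                row[col] = float(external.iloc[i][col])
        rows.append(row)
    columns = list(META_COLUMNS)
    if profile_featurizer is not None:
        columns += list(ProfileFeatureSet.FIELDS)
    if include_sequence:
        from .seqfeatures import SequenceFeatureSet
        columns += list(SequenceFeatureSet.FIELDS)
    if external is not None:
        columns += list(external.columns)
    table = pd.DataFrame(rows, columns=columns)
    return table, exclusions


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _xy(table: pd.DataFrame, schema: list[str] | None = None):
    cols = schema or feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["ddg_exp"].to_numpy(dtype=float)
    return X, y, cols


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _mtry_candidates(p: int) -> list[int]:
    grid = {m for m in MTRY_GRID if m <= p}
    grid.add(max(1, p // 3))
    return sorted(grid)


def train_rf(table: pd.DataFrame, config: RFConfig | None = None,
             test_table: pd.DataFrame | None = None) -> TrainedModel:
    """Fit the forest, tuning variables-per-split on a testing split.

    When ``test_table`` is given it is used for tuning and the final model
    is refit on both tables; otherwise an internal split of
    ``config.test_fraction`` is carved out for tuning and the final model
    is refit on the full table.
    """
    config = config or RFConfig()
    X, y, cols = _xy(table)
    if len(y) < 2 or np.allclose(y, y[0]):
        raise ValueError("target is constant: nothing to learn")

    if config.max_features is not None:
        best_mtry = config.max_features
    else:
        if test_table is not None:
            X_tr, y_tr = X, y
            X_te, y_te, _ = _xy(test_table, cols)
        else:
            rng = np.random.default_rng(config.seed)
            order = rng.permutation(len(y))
            n_te = max(1, int(round(config.test_fraction * len(y))))
            te, tr = order[:n_te], order[n_te:]
            X_tr, y_tr, X_te, y_te = X[tr], y[tr], X[te], y[te]
        best_mtry, best_score = None, -np.inf
        for m in _mtry_candidates(X.shape[1]):
            f = RandomForestRegressor(n_estimators=config.n_trees,
                                      max_features=m,
                                      random_state=config.seed)
            f.fit(X_tr, y_tr)
            pred = f.predict(X_te)
            score = _safe_pearson(y_te, pred)
            if score > best_score:
                best_mtry, best_score = m, score

    X_all, y_all = X, y
    if test_table is not None:
        X_te, y_te, _ = _xy(test_table, cols)
        X_all = np.vstack([X, X_te])
        y_all = np.concatenate([y, y_te])
    forest = RandomForestRegressor(n_estimators=config.n_trees,
                                   max_features=best_mtry,
                                   random_state=config.seed,
                                   oob_score=True, bootstrap=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(X_all, y_all)
    imp = feature_importances(forest, X_all, y_all, cols, seed=config.seed)
    cfg = RFConfig(n_trees=config.n_trees, seed=config.seed,
                   max_features=best_mtry,
                   test_fraction=config.test_fraction)
    return TrainedModel(forest=forest, schema=cols, config=cfg,
                        importances=imp)


def feature_importances(forest, X, y, cols, seed: int = 0,
                        n_repeats: int = 5) -> pd.DataFrame:
    """Importance by residual-error increase (permutation) and by node
    purity (impurity decrease), both per feature."""
    perm = permutation_importance(forest, X, y, n_repeats=n_repeats,
                                  random_state=seed)
    return pd.DataFrame({
        "feature": cols,
        "residual_error_increase": perm.importances_mean,
        "node_purity": forest.feature_importances_,
    }).sort_values("residual_error_increase",
                   ascending=False).reset_index(drop=True)


def _safe_pearson(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(table: pd.DataFrame, scheme: str = "kfold_repeated",
                  k: int = 10, repeats: int = 3,
                  config: RFConfig | None = None,
                  report_min_mutants: int = 10) -> CVSummary:
    """Cross-validated accuracy of the forest.

    kfold_repeated: Pearson c on pooled out-of-fold predictions per
    repeat, reported as mean ± sd over repeats, plus the pooled RMSE of
    prediction.  leave_one_protein_out: every record of one complex is
    held out at a time; per-protein RMSE is reported for proteins with
    more than ``report_min_mutants`` mutants.
    """
    config = config or RFConfig()
    X, y, cols = _xy(table)
    if scheme == "kfold_repeated":
        cv = RepeatedKFold(n_splits=k, n_repeats=repeats,
                           random_state=config.seed)
        oof = np.zeros((repeats, len(y)))
        for split_i, (tr, te) in enumerate(cv.split(X)):
            rep = split_i // k
            f = _fit(X[tr], y[tr], config)
            oof[rep, te] = f.predict(X[te])
        per_repeat = [_safe_pearson(y, oof[r]) for r in range(repeats)]
        resid = (oof - y[None, :]).ravel()
        return CVSummary(scheme=scheme,
                         pearson_mean=float(np.mean(per_repeat)),
                         pearson_sd=float(np.std(per_repeat)),
                         rmse=float(np.sqrt(np.mean(resid ** 2))),
                         per_repeat=per_repeat)
    if scheme == "leave_one_protein_out":
        groups = table["complex_id"].to_numpy()
        logo = LeaveOneGroupOut()
        oof = np.zeros(len(y))
        for tr, te in logo.split(X, y, groups):
            f = _fit(X[tr], y[tr], config)
            oof[te] = f.predict(X[te])
        rows = []
        for prot in pd.unique(groups):
            mask = groups == prot
            rows.append({"complex_id": prot, "n_mutants": int(mask.sum()),
                         "rmse": float(np.sqrt(np.mean((oof[mask] - y[mask]) ** 2)))})
        per_protein = pd.DataFrame(rows)
        per_protein["reported_separately"] = (
            per_protein["n_mutants"] > report_min_mutants)
        return CVSummary(
            scheme=scheme,
            pearson_mean=_safe_pearson(y, oof),
            pearson_sd=0.0,
            rmse=float(np.sqrt(np.mean((oof - y) ** 2))),
            per_protein=per_protein,
        )
    raise ValueError(f"unknown cross-validation scheme {scheme!r}")


def _fit(X, y, config: RFConfig) -> RandomForestRegressor:
    mtry = config.max_features or max(1, X.shape[1] // 3)
    f = RandomForestRegressor(n_estimators=config.n_trees, max_features=mtry,
                              random_state=config.seed)
    f.fit(X, y)
    return f


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Predict ΔΔG (kcal/mol) for assembled feature rows (schema-checked)."""
    available = set(features.columns)
    missing = [c for c in model.schema if c not in available]
    extra = [c for c in available - set(model.schema) - set(META_COLUMNS)]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing {missing}, "
                         f"unexpected {sorted(extra)}")
    if len(features) == 0:
        return np.zeros(0)
    X = features[model.schema].to_numpy(dtype=float)
    out = model.forest.predict(X)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite prediction")
    return out
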