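"""Random-Forest activity model building: curation, balanced downsampling,
training, importance averaging, backward feature selection and final model
packaging.

The procedure mirrors how site-level cleavage assays are curated into a
classifier: detected sites are active (or, for concentration-resolved
assays, active at or below a standard 64 nM enzyme concentration); the much
larger undetected pool is downsampled to the actives' per-mismatch-count
histogram, independently 10 times; one forest is trained per repeat, feature
importance is averaged across repeats, backward selection removes the
currently least-important feature one step at a time scoring each step by
out-of-bag (OOB) error, and the best-OOB repeat retrained on the selected
features becomes the final model.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .scoring import SCHEMAS, feature_matrix

DEFAULT_CONCENTRATION_THRESHOLD_NM = 64
N_REPEATS = 10
N_TREES = 500
N_TREES_SELECTION = 150  # lighter forests keep the per-step OOB loop fast


class SamplingShortfall(UserWarning):
    """A mismatch bin of the inactive pool was smaller than its demand."""


class TrainingError(RuntimeError):
    """Training is impossible (e.g. a single-class dataset)."""


@dataclass
class ActivityModel:
    """A trained forest plus everything needed to reproduce it."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    schema: str = "v1"
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        import joblib

        joblib.dump({
            "forest": self.forest,
            "feature_names": self.feature_names,
            "schema": self.schema,
            "metadata": self.metadata,
        }, path)

    @classmethod
    def load(cls, path) -> "ActivityModel":
        import joblib

        raw = joblib.load(path)
        return cls(forest=raw["forest"],
                   feature_names=tuple(raw["feature_names"]),
                   schema=raw["schema"], metadata=raw["metadata"])


def read_training_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"on_target", "off_target", "n_mismatches"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"training table lacks columns: {sorted(missing)}")
    return df


def label_by_concentration(
    df: pd.DataFrame,
    threshold_nM: float = DEFAULT_CONCENTRATION_THRESHOLD_NM,
) -> pd.DataFrame:
    """Label sites active iff detected at <= threshold nM; undetected sites
    (missing concentration) are inactive."""
    conc = pd.to_numeric(df["min_active_conc_nM"], errors="coerce")
    out = df.copy()
    out["label"] = np.where(conc.notna() & (conc <= threshold_nM),
                            "active", "inactive")
    return out


def filter_canonical_pam(df: pd.DataFrame, pam: str = "GG") -> pd.DataFrame:
    """Keep off-targets whose PAM ends in the canonical dinucleotide."""
    return df[df["off_target"].str[-2:] == pam].reset_index(drop=True)


def sample_inactive(
    active: pd.DataFrame,
    pool: pd.DataFrame,
    n_repeats: int = N_REPEATS,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Mismatch-distribution-weighted downsampling of the inactive pool.

    Each repeat independently draws, without replacement, inactive sites
    whose per-mismatch-count histogram equals the actives' histogram.  Bins
    with too few pool members are filled to availability and the shortfall
    is reported as a warning.  Returns one balanced active+inactive dataset
    per repeat; sampled row indices and shortfalls are stored in
    ``df.attrs``.
    """
    demand = active["n_mismatches"].value_counts().to_dict()
    datasets = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        chosen_idx: list[int] = []
        shortfalls: dict[int, int] = {}
        for mm, want in sorted(demand.items()):
            bin_idx = pool.index[pool["n_mismatches"] == mm].to_numpy()
            take = min(want, len(bin_idx))
            if take < want:
                shortfalls[int(mm)] = want - take
            chosen_idx.extend(rng.choice(bin_idx, size=take, replace=False))
        if shortfalls:
            warnings.warn(
                f"repeat {rep}: inactive pool shortfall per mismatch bin: "
                f"{shortfalls}", SamplingShortfall)
        sampled = pool.loc[sorted(chosen_idx)]
        ds = pd.concat([active, sampled], ignore_index=True)
        ds.attrs["repeat"] = rep
        ds.attrs["sampled_pool_indices"] = sorted(int(i) for i in chosen_idx)
        ds.attrs["shortfalls"] = shortfalls
        datasets.append(ds)
    return datasets


def _featurize(df: pd.DataFrame, schema: str) -> tuple[pd.DataFrame, np.ndarray]:
    X = feature_matrix(df["on_target"], df["off_target"], schema)
    y = (df["label"] == "active").to_numpy().astype(int)
    return X, y


def _fit_forest(X, y, n_estimators: int, seed: int) -> RandomForestClassifier:
    if len(np.unique(y)) < 2:
        raise TrainingError("training dataset contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny OOB folds can miss a class
        rf.fit(X, y)
    return rf


def train_models(
    datasets: list[pd.DataFrame],
    schema: str = "v1",
    n_estimators: int = N_TREES,
    seed: int = 0,
) -> list[tuple[RandomForestClassifier, pd.Series, float]]:
    """One forest per balanced dataset; returns (model, importances,
    OOB error) triples."""
    triples = []
    for rep, ds in enumerate(datasets):
        X, y = _featurize(ds, schema)
        rf = _fit_forest(X, y, n_estimators, seed + rep)
        importances = pd.Series(rf.feature_importances_, index=X.columns)
        triples.append((rf, importances, 1.0 - rf.oob_score_))
    return triples


def average_importance(triples) -> pd.DataFrame:
    """Mean per-feature importance across repeats, ranked descending
    (ties broken by feature name)."""
    if not triples:
        raise ValueError("need at least one trained model")
    imp = pd.concat([t[1] for t in triples], axis=1).mean(axis=1)
    df = pd.DataFrame({"feature": imp.index, "importance": imp.to_numpy()})
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def backward_select(
    datasets: list[pd.DataFrame],
    ranking: pd.DataFrame,
    schema: str = "v1",
    n_estimators: int = N_TREES_SELECTION,
    seed: int = 0,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Backward feature selection by OOB error.

    Starting from all ranked features, repeatedly retrain on the current set,
    record the OOB error, and drop the feature the current model deems least
    important (ties broken by the supplied averaged ranking, then by name).
    Selection runs on the first dataset (one representative repeat) to keep
    the per-step loop tractable; the caller refits all repeats on the
    selected set.  Returns the feature set with minimum OOB error (ties go
    to the smaller set) and the full error curve.
    """
    features = list(ranking["feature"])
    missing = set(SCHEMAS[schema]) - set(features)
    if missing:
        raise ValueError("ranking must cover all schema features")
    X_full, y = _featurize(datasets[0], schema)
    rank_order = {f: i for i, f in enumerate(ranking["feature"])}
    curve_rows = []
    best: tuple[float, int, tuple[str, ...]] | None = None
    step = 0
    while features:
        rf = _fit_forest(X_full[features], y, n_estimators, seed + step)
        oob = 1.0 - rf.oob_score_
        curve_rows.append((step, len(features), oob))
        cand = (oob, -len(features), tuple(features))
        if best is None or cand < best:
            best = cand
        if len(features) == 1:
            break
        imp = pd.Series(rf.feature_importances_, index=features)
        drop = min(features,
                   key=lambda f: (imp[f], -rank_order.get(f, 0), f))
        features.remove(drop)
        step += 1
    curve = pd.DataFrame(curve_rows, columns=["step", "n_features", "oob_error"])
    return best[2], curve


def select_final_model(
    datasets: list[pd.DataFrame],
    selected_features: tuple[str, ...],
    schema: str = "v1",
    n_estimators: int = N_TREES,
    seed: int = 0,
) -> ActivityModel:
    """Retrain every repeat on the selected features and keep the repeat
    with the lowest OOB error (ties -> lowest repeat index)."""
    oob_errors = []
    forests = []
    for rep, ds in enumerate(datasets):
        X, y = _featurize(ds, schema)
        rf = _fit_forest(X[list(selected_features)], y, n_estimators,
                         seed + rep)
        forests.append(rf)
        oob_errors.append(1.0 - rf.oob_score_)
    best = int(np.argmin(oob_errors))
    return ActivityModel(
        forest=forests[best],
        feature_names=tuple(selected_features),
        schema=schema,
        metadata={
            "seed": seed,
            "n_estimators": n_estimators,
            "chosen_repeat": best,
            "oob_errors": [float(e) for e in oob_errors],
            "n_schema_features": len(SCHEMAS[schema]),
        },
    )


def concentration_correlation(model, df: pd.DataFrame) -> pd.Series:
    """Mean predicted activity probability per minimal-active-concentration
    tier (undetected sites are excluded); tiers with no sites are omitted."""
    from .scoring import predict_activity

    conc = pd.to_numeric(df["min_active_conc_nM"], errors="coerce")
    tiered = df[conc.notna()].copy()
    if tiered.empty:
        return pd.Series(dtype=float, name="mean_probability")
    X = feature_matrix(tiered["on_target"], tiered["off_target"], model.schema)
    tiered["probability"] = predict_activity(model, X)
    out = tiered.groupby(conc[conc.notna()].astype(int))["probability"].mean()
    out.name = "mean_probability"
    out.index.name = "min_active_conc_nM"
    return out.sort_index()


def run_training_pipeline(
    table: pd.DataFrame,
    schema: str = "v1",
    seed: int = 0,
    n_repeats: int = N_REPEATS,
    canonical_pam_only: bool = True,
    n_estimators: int = N_TREES,
    n_estimators_selection: int = N_TREES_SELECTION,
) -> tuple[ActivityModel, dict]:
    """Full model-building procedure on a labeled table; returns the final
    model and a report (importance table, OOB curve, selected features)."""
    df = table
    if canonical_pam_only:
        df = filter_canonical_pam(df)
    df = df[df["n_mismatches"] <= 8].reset_index(drop=True)
    active = df[df["label"] == "active"].reset_index(drop=True)
    pool = df[df["label"] == "inactive"].reset_index(drop=True)
    if active.empty or pool.empty:
        raise TrainingError("need both active and inactive sites")
    datasets = sample_inactive(active, pool, n_repeats=n_repeats, seed=seed)
    triples = train_models(datasets, schema, n_estimators, seed)
    ranking = average_importance(triples)
    selected, curve = backward_select(datasets, ranking, schema,
                                      n_estimators_selection, seed)
    model = select_final_model(datasets, selected, schema, n_estimators, seed)
    report = {
        "importance": ranking,
        "oob_curve": curve,
        "selected_features": list(selected),
        "repeat_oob_errors": [t[2] for t in triples],
        "n_active": int(len(active)),
        "n_pool": int(len(pool)),
    }
    return model, report
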