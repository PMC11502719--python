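"""Supervised population-assignment track.

Mirrors the machine-learning route to stock identification: classifiers are
trained on mean-imputed dosage vectors of the baseline, evaluated by
Monte-Carlo and stratified K-fold cross-validation, and used to predict
mixture membership with posterior-like probabilities.  Four model kinds are
available (linear discriminant analysis, Gaussian naive Bayes, a
probability-calibrated support-vector classifier, and a random forest); the
support-vector classifier is the default for mixture prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .core import BaselineDefinition, GenotypeTable, population_grouping
from .simulate import derive_rng

MODEL_KINDS = ("linear-discriminant", "naive-bayes", "support-vector", "random-forest")

_ALIASES = {
    "lda": "linear-discriminant",
    "svm": "support-vector",
    "nb": "naive-bayes",
    "rf": "random-forest",
}


def _make_estimator(kind: str, seed: int):
    kind = _ALIASES.get(kind, kind)
    if kind == "linear-discriminant":
        return LinearDiscriminantAnalysis()
    if kind == "naive-bayes":
        return GaussianNB()
    if kind == "support-vector":
        return SVC(probability=True, random_state=seed)
    if kind == "random-forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown model kind: {kind!r}")


@dataclass
class ClassifierModel:
    model_kind: str
    estimator: object
    populations: list[str]
    locus_ids: list[str]
    impute_means: np.ndarray
    training_sizes: dict[str, int]
    seed: int

    def features(self, table: GenotypeTable) -> np.ndarray:
        if table.panel.informative_ids != self.locus_ids:
            raise ValueError("mixture loci do not match training loci")
        X = table.dosage(informative_only=True)
        idx = np.where(np.isnan(X))
        X[idx] = self.impute_means[idx[1]]
        return X


def _features_and_labels(table: GenotypeTable, basedef: BaselineDefinition):
    grouping = population_grouping(table, basedef)
    X = table.dosage(informative_only=True)
    means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    means = np.where(np.isnan(means), 1.0, means)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    y = np.array([grouping[ind] for ind in table.individuals])
    return X, y, means


def train_classifier(
    table: GenotypeTable,
    basedef: BaselineDefinition,
    model_kind: str = "support-vector",
    seed: int = 0,
) -> ClassifierModel:
    """Fit a classifier on the baseline (features: mean-imputed dosages)."""
    X, y, means = _features_and_labels(table, basedef)
    pops = sorted(set(y))
    if len(pops) < 2:
        raise ValueError("need at least two populations to train")
    sizes = {p: int((y == p).sum()) for p in pops}
    if min(sizes.values()) < 2:
        small = [p for p, n in sizes.items() if n < 2]
        raise ValueError(f"populations with fewer than two individuals: {small}")
    est = _make_estimator(model_kind, seed)
    est.fit(X, y)
    return ClassifierModel(
        model_kind=_ALIASES.get(model_kind, model_kind),
        estimator=est,
        populations=list(est.classes_),
        locus_ids=table.panel.informative_ids,
        impute_means=means,
        training_sizes=sizes,
        seed=seed,
    )


@dataclass
class CvReport:
    scheme: str  # "monte-carlo" or "k-fold"
    settings: dict
    overall: dict  # setting value -> overall accuracy (%)
    per_population: pd.DataFrame  # rows: population, cols: setting value
    detail: pd.DataFrame


def monte_carlo_cv(
    table: GenotypeTable,
    basedef: BaselineDefinition,
    model_kind: str = "support-vector",
    train_props: Sequence[float] = (0.5, 0.7, 0.9),
    n_iter: int = 100,
    seed: int = 0,
) -> CvReport:
    """Monte-Carlo cross-validation with per-population stratified splits.

    For each training proportion, a fixed share of every population is drawn
    into the training set (``floor(prop * n)``, at least one train and one
    test individual required) and accuracy on the complement is averaged
    over ``n_iter`` random splits.
    """
    grouping = population_grouping(table, basedef)
    y_all = np.array([grouping[i] for i in table.individuals])
    pops = sorted(set(y_all))
    rng = derive_rng(seed, "monte_carlo_cv")
    records = []
    for prop in train_props:
        for p in pops:
            n = int((y_all == p).sum())
            n_train = int(prop * n)
            if n_train < 1 or n - n_train < 1:
                raise ValueError(
                    f"population {p!r} (n={n}) too small for train proportion {prop}"
                )
        for it in range(n_iter):
            train_rows, test_rows = [], []
            for p in pops:
                rows = np.where(y_all == p)[0]
                rows = rng.permutation(rows)
                n_train = int(prop * len(rows))
                train_rows.extend(rows[:n_train])
                test_rows.extend(rows[n_train:])
            rec = _fit_eval(
                table, basedef, model_kind, train_rows, test_rows,
                seed=int(rng.integers(2**31 - 1)),
            )
            for p, acc, n_test in rec:
                records.append(
                    {"train_prop": prop, "iteration": it, "population": p,
                     "accuracy": acc, "n_test": n_test}
                )
    detail = pd.DataFrame(records)
    return _summarise_cv("monte-carlo", {"train_props": list(train_props), "n_iter": n_iter},
                         detail, "train_prop")


def kfold_cv(
    table: GenotypeTable,
    basedef: BaselineDefinition,
    model_kind: str = "support-vector",
    k_values: Sequence[int] = (3, 4, 5, 15),
    seed: int = 0,
) -> CvReport:
    """Stratified K-fold cross-validation: every individual is tested exactly
    once per value of K."""
    from sklearn.model_selection import StratifiedKFold

    grouping = population_grouping(table, basedef)
    y_all = np.array([grouping[i] for i in table.individuals])
    pops = sorted(set(y_all))
    min_pop = min(int((y_all == p).sum()) for p in pops)
    rng = derive_rng(seed, "kfold_cv")
    records = []
    for k in k_values:
        if k > min_pop:
            raise ValueError(f"k={k} exceeds smallest population size ({min_pop})")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        for fold, (train_rows, test_rows) in enumerate(skf.split(np.zeros(len(y_all)), y_all)):
            rec = _fit_eval(
                table, basedef, model_kind, list(train_rows), list(test_rows),
                seed=int(rng.integers(2**31 - 1)),
            )
            for p, acc, n_test in rec:
                records.append(
                    {"k": k, "fold": fold, "population": p, "accuracy": acc,
                     "n_test": n_test,
                     "test_individuals": ";".join(table.individuals[i] for i in test_rows)}
                )
    detail = pd.DataFrame(records)
    return _summarise_cv("k-fold", {"k_values": list(k_values)}, detail, "k")


def _fit_eval(table, basedef, model_kind, train_rows, test_rows, seed):
    train = table.subset([table.individuals[i] for i in train_rows])
    test = table.subset([table.individuals[i] for i in test_rows])
    model = train_classifier(train, basedef, model_kind, seed=seed)
    pred = predict_membership(model, test)
    grouping = population_grouping(test, basedef)
    truth = np.array([grouping[i] for i in test.individuals])
    correct = pred["map_population"].to_numpy() == truth
    out = []
    for p in sorted(set(truth)):
        m = truth == p
        out.append((p, 100.0 * float(correct[m].mean()), int(m.sum())))
    out.append(("__overall__", 100.0 * float(correct.mean()), len(truth)))
    return out


def _summarise_cv(scheme, settings, detail, key):
    overall_rows = detail[detail["population"] == "__overall__"]
    overall = {
        val: float(grp["accuracy"].mean())
        for val, grp in overall_rows.groupby(key)
    }
    pop_rows = detail[detail["population"] != "__overall__"]
    per_pop = pop_rows.pivot_table(index="population", columns=key, values="accuracy", aggfunc="mean")
    return CvReport(scheme, settings, overall, per_pop, detail)


def predict_membership(model: ClassifierModel, table: GenotypeTable) -> pd.DataFrame:
    """Per-individual predicted population and membership probabilities.

    Individuals with no genotyped locus are predicted from the imputed
    training means and flagged ``low_information``.
    """
    Xraw = table.dosage(informative_only=True)
    all_missing = np.isnan(Xraw).all(axis=1)
    X = model.features(table)
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    map_idx = np.argmax(proba, axis=1)
    out = pd.DataFrame(
        {
            "individual": table.individuals,
            "sample_id": table.meta["sample_id"].to_numpy(),
            "map_population": [classes[i] for i in map_idx],
            "map_posterior": proba[np.arange(len(map_idx)), map_idx],
            "n_missing": np.isnan(Xraw).sum(axis=1).astype(int),
            "low_information": all_missing,
        }
    )
    for k, p in enumerate(classes):
        out[f"posterior_{p}"] = proba[:, k]
    return out


def method_agreement(assignments_a: Sequence[str], assignments_b: Sequence[str]) -> float:
    """Fraction of individuals on which two assignment methods agree."""
    a = np.asarray(assignments_a)
    b = np.asarray(assignments_b)
    if a.shape != b.shape:
        raise ValueError("assignment vectors differ in length")
    if a.size == 0:
        raise ValueError("empty assignment vectors")
    return float((a == b).mean())
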