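"""Evaluation of microbiome-to-metabolite change prediction.

A pluggable per-metabolite predictor (any callable mapping a composition
matrix to metabolite values, or a serialized linear map) is applied to the
pre- and the post-intervention microbiome compositions; the two prediction
sets are subtracted to give predicted change, which is scored against the
observed change. Metabolites are stratified by the predictor's training R^2
at 0.05 — a metabolite the model could predict in its training cohort is
"well predicted" — and within each stratum the Pearson correlation between
the per-metabolite mean observed change and mean predicted change is
reported along with the variance explained, ``100 * r^2``.

The externally trained predictor itself is out of scope here; only its
evaluation harness is implemented, with a synthetic linear map as the test
predictor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DeltaEvaluation
from .exceptions import InvalidArgumentError

R2_THRESHOLD = 0.05


@dataclass
class LinearPredictor:
    """A linear microbiome -> metabolite map ``Y = X @ weights + intercept``.

    ``weights`` is features x metabolites, indexed for alignment-by-name
    with the composition table's columns.
    """

    weights: pd.DataFrame
    intercept: pd.Series

    def __call__(self, composition: pd.DataFrame) -> pd.DataFrame:
        X = composition[self.weights.index]
        return X @ self.weights + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.weights.index),
            "metabolites": list(self.weights.columns),
            "weights": self.weights.to_numpy().tolist(),
            "intercept": self.intercept.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LinearPredictor":
        with open(path) as fh:
            payload = json.load(fh)
        weights = pd.DataFrame(
            payload["weights"],
            index=payload["features"],
            columns=payload["metabolites"],
        )
        intercept = pd.Series(payload["intercept"], index=payload["metabolites"])
        return cls(weights, intercept)


def predict_change(
    predictor, pre_table: pd.DataFrame, post_table: pd.DataFrame
) -> pd.DataFrame:
    """Predicted change = predict(post) - predict(pre), per participant.

    Both tables are participant-indexed composition matrices; participants
    missing from either table are skipped with a warning.
    """
    common = pre_table.index.intersection(post_table.index)
    dropped = set(pre_table.index.symmetric_difference(post_table.index))
    if dropped:
        warnings.warn(
            f"skipping {len(dropped)} unpaired participant(s)", stacklevel=2
        )
    pred_pre = pd.DataFrame(predictor(pre_table.loc[common]), index=common)
    pred_post = pd.DataFrame(predictor(post_table.loc[common]), index=common)
    return pred_post - pred_pre


def evaluate_change(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    training_r2: pd.Series,
    r2_threshold: float = R2_THRESHOLD,
    arms: pd.Series | None = None,
    mode: str = "metabolite_means",
    min_metabolites: int = 3,
) -> list[DeltaEvaluation]:
    """Score predicted against observed change per stratum (and per arm).

    ``observed`` and ``predicted`` are participants x metabolites change
    matrices; ``training_r2`` gives each metabolite's coefficient of
    determination in the predictor's training cohort. In the default
    ``metabolite_means`` mode the correlation is computed across metabolites
    between mean observed and mean predicted change (the axes of the
    published evaluation); ``participant_points`` pools all participant x
    metabolite points instead. Strata with fewer than ``min_metabolites``
    metabolites are skipped.
    """
    if mode not in ("metabolite_means", "participant_points"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    metabolites = observed.columns.intersection(predicted.columns)
    observed = observed[metabolites]
    predicted = predicted[metabolites]
    r2 = training_r2.reindex(metabolites)

    groups = {"both": observed.index}
    if arms is not None:
        arms = arms.reindex(observed.index)
        for arm in arms.dropna().unique():
            groups[str(arm)] = observed.index[arms == arm]

    strata = {
        "well_predicted": metabolites[r2 > r2_threshold],
        "poorly_predicted": metabolites[r2 <= r2_threshold],
    }
    out = []
    for stratum, cols in strata.items():
        if len(cols) < min_metabolites:
            continue
        for arm, rows in groups.items():
            obs = observed.loc[rows, cols]
            pred = predicted.loc[rows, cols]
            if mode == "metabolite_means":
                x = obs.mean(axis=0)
                y = pred.mean(axis=0)
            else:
                x = obs.to_numpy().ravel()
                y = pred.to_numpy().ravel()
                keep = ~(np.isnan(x) | np.isnan(y))
                x, y = x[keep], y[keep]
            r, p = stats.pearsonr(x, y)
            out.append(
                DeltaEvaluation(
                    stratum=stratum,
                    arm=arm,
                    pearson_r=float(r),
                    p=float(p),
                    variance_explained_percent=float(100.0 * r**2),
                    n_metabolites=int(len(cols)),
                )
            )
    return out


def variance_explained(r: float) -> float:
    """Variance explained, in percent: ``100 * r^2`` (12.25 for r = 0.35)."""
    return float(100.0 * r**2)
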