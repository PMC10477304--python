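"""Covariate-adjusted bootstrap mediation over change triplets.

For a triplet (predictor X, mediator M, outcome Y) two ordinary-least-squares
regressions are fitted:

* ``M ~ X + covariates``          -> path a (coefficient of X)
* ``Y ~ X + M + covariates``      -> paths b (coefficient of M) and c'
  (coefficient of X)

Case-resampling bootstrap (default 500 resamples, seed 42) yields two-sided
percentile p-values for a, b and the indirect effect a*b, each computed as
``2 * min(frac of draws <= 0, frac of draws >= 0)`` floored at ``1/n_boot``.
A trajectory is significant only under the two-path rule: p_a < alpha AND
p_b < alpha. For unsigned mediators such as strain dissimilarity the
``absolute_change`` mode takes |X|, |M|, |Y| before fitting.

Covariates default to baseline age, sex (0/1) and BMI. No multiplicity
correction is applied across trajectories unless requested.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import MediationResult
from .exceptions import DegenerateInputError, InvalidArgumentError


def _fit_paths(X, M, Y, C):
    """Point estimates (a, b, c_prime) from the two OLS regressions."""
    n = X.size
    ones = np.ones((n, 1))
    dm = np.concatenate([ones, X[:, None], C], axis=1)
    a = _batched_ols(dm, M)[1]
    dy = np.concatenate([ones, X[:, None], M[:, None], C], axis=1)
    coef_y = _batched_ols(dy, Y)
    return a, coef_y[2], coef_y[1]


def _batched_ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients via normal equations, batched over leading axes.

    Falls back to lstsq for (near-)singular systems.
    """
    xtx = design.swapaxes(-1, -2) @ design[..., :, :]
    xty = (design * y[..., :, None]).sum(axis=-2)
    try:
        return np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        flat_d = design.reshape(-1, *design.shape[-2:])
        flat_y = y.reshape(-1, y.shape[-1])
        out = np.stack(
            [np.linalg.lstsq(d, v, rcond=None)[0] for d, v in zip(flat_d, flat_y)]
        )
        return out.reshape(*design.shape[:-2], design.shape[-1])


def _bootstrap_p(draws: np.ndarray, n_boot: int) -> float:
    p = 2.0 * min(float(np.mean(draws <= 0)), float(np.mean(draws >= 0)))
    return float(min(1.0, max(p, 1.0 / n_boot)))


def fit_mediation(
    X,
    M,
    Y,
    covariates=None,
    n_boot: int = 500,
    seed: int = 42,
    mode: str = "signed_change",
    alpha: float = 0.05,
    predictor_id: str = "X",
    mediator_id: str = "M",
    outcome_id: str = "Y",
    keep_draws: bool = False,
) -> MediationResult:
    """Fit one covariate-adjusted bootstrap mediation triplet.

    Requires equal-length vectors with at least 10 complete cases; rows with
    any missing value among X, M, Y or the covariates are dropped. Raises
    :class:`DegenerateInputError` if X or M has zero variance.
    """
    if mode not in ("signed_change", "absolute_change"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (X.shape == M.shape == Y.shape):
        raise InvalidArgumentError("X, M, Y must have equal length")
    if covariates is None:
        C = np.empty((X.size, 0))
    else:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
    complete = ~(
        np.isnan(X) | np.isnan(M) | np.isnan(Y) | np.isnan(C).any(axis=1)
    )
    X, M, Y, C = X[complete], M[complete], Y[complete], C[complete]
    n = X.size
    if n < 10:
        raise InvalidArgumentError("need >= 10 complete cases")
    if mode == "absolute_change":
        X, M, Y = np.abs(X), np.abs(M), np.abs(Y)
    if np.ptp(X) == 0 or np.ptp(M) == 0:
        raise DegenerateInputError("X and M must vary")

    a_hat, b_hat, c_hat = _fit_paths(X, M, Y, C)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_dr, b_dr, _ = _fit_paths_resampled(X, M, Y, C, idx)
    ab_dr = a_dr * b_dr

    result = MediationResult(
        predictor_id=predictor_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        a=float(a_hat),
        b=float(b_hat),
        c_prime=float(c_hat),
        indirect=float(a_hat * b_hat),
        p_a=_bootstrap_p(a_dr, n_boot),
        p_b=_bootstrap_p(b_dr, n_boot),
        p_indirect=_bootstrap_p(ab_dr, n_boot),
        significant=False,
        mode=mode,
        n=int(n),
        draws=(
            {"a": a_dr, "b": b_dr, "indirect": ab_dr} if keep_draws else None
        ),
    )
    result.significant = bool(result.p_a < alpha and result.p_b < alpha)
    return result


def _fit_paths_resampled(X, M, Y, C, idx):
    """Batched path fits where each bootstrap row resamples cases jointly."""
    Xb, Mb, Yb = X[idx], M[idx], Y[idx]
    Cb = C[idx] if C.shape[1] else np.empty(idx.shape + (0,))
    n = X.size
    ones = np.ones(idx.shape + (1,))
    dm = np.concatenate([ones, Xb[..., None], Cb], axis=-1)
    a = _batched_ols(dm, Mb)[..., 1]
    dy = np.concatenate([ones, Xb[..., None], Mb[..., None], Cb], axis=-1)
    coef_y = _batched_ols(dy, Yb)
    return a, coef_y[..., 2], coef_y[..., 1]


def screen_trajectories(
    diet_changes: pd.DataFrame,
    mediator_changes: pd.DataFrame,
    outcome_changes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 500,
    seed: int = 42,
    mode: str = "signed_change",
    alpha: float = 0.05,
    significant_only: bool = False,
) -> list[MediationResult]:
    """Fit every predictor x mediator x outcome combination.

    The inputs are participant-indexed change tables whose columns are the
    candidate features — by design only features already flagged as
    significantly changed upstream. Empty candidate sets yield an empty list.
    Triplets that are degenerate (constant X or M) are skipped.
    """
    results = []
    combos = itertools.product(
        diet_changes.columns, mediator_changes.columns, outcome_changes.columns
    )
    for x_id, m_id, y_id in combos:
        try:
            res = fit_mediation(
                diet_changes[x_id].to_numpy(),
                mediator_changes[m_id].to_numpy(),
                outcome_changes[y_id].to_numpy(),
                covariates,
                n_boot=n_boot,
                seed=seed,
                mode=mode,
                alpha=alpha,
                predictor_id=str(x_id),
                mediator_id=str(m_id),
                outcome_id=str(y_id),
            )
        except DegenerateInputError:
            continue
        if res.significant or not significant_only:
            results.append(res)
    return results


def select_strain_mediators(
    dissim_by_species: pd.DataFrame,
    species_rates: pd.Series,
    top_k: int = 10,
    min_participants: int = 50,
) -> list[str]:
    """Top-``top_k`` most-replaced species among those present in strictly
    more than ``min_participants`` participants.

    ``dissim_by_species`` is participants x species intra-person
    dissimilarity (NaN where the species was not comparable for that
    participant); ``species_rates`` is percent-of-carriers-replaced per
    species. A species present in exactly ``min_participants`` participants
    is excluded.
    """
    carriers = dissim_by_species.notna().sum(axis=0)
    qualifying = carriers[carriers > min_participants].index
    ranked = species_rates.reindex(qualifying).dropna().sort_values(
        ascending=False, kind="stable"
    )
    return list(ranked.index[:top_k])


def strain_mediation_screen(
    diet_changes: pd.DataFrame,
    dissim_by_species: pd.DataFrame,
    outcome_changes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    species_rates: pd.Series | None = None,
    top_k: int = 10,
    min_participants: int = 50,
    n_boot: int = 500,
    seed: int = 42,
    alpha: float = 0.05,
) -> list[MediationResult]:
    """Mediation screen with strain dissimilarity as the mediator.

    Both diet arms are pooled; mediators are the ``top_k`` most-replaced
    species among those present in more than ``min_participants``
    participants; absolute changes are used throughout because dissimilarity
    is unsigned. ``species_rates`` (percent replaced per species) may be
    given directly or derived from a replacement-call table ``calls``.
    """
    if species_rates is None:
        if calls is None:
            raise InvalidArgumentError("provide species_rates or calls")
        from .strains import species_replacement_rate

        species_rates = species_replacement_rate(calls)
    mediators = select_strain_mediators(
        dissim_by_species, species_rates, top_k, min_participants
    )
    if not mediators:
        return []
    return screen_trajectories(
        diet_changes,
        dissim_by_species[mediators],
        outcome_changes,
        covariates,
        n_boot=n_boot,
        seed=seed,
        mode="absolute_change",
        alpha=alpha,
    )
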