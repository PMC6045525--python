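"""Likelihood, EM estimation and posterior machinery for latent class models.

The model is a ``C``-class finite mixture of independent Bernoulli items:
conditional on latent class ``c`` the ``J`` binary indicators are independent
with item-response probabilities ``rho[c, j]``, and class membership follows
the probabilities ``gamma``.  The probability of a response pattern ``x`` is

    P(x) = sum_c gamma_c * prod_{j observed} rho_cj^x_j (1 - rho_cj)^(1 - x_j)

with missing items marginalised out (missing-at-random).  Estimation is by
multi-start EM; the convergence index is the maximum absolute deviation (MAD)
of any parameter between successive iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .data import ResponseMatrix

__all__ = [
    "LCAParameters",
    "PosteriorMatrix",
    "EMConfig",
    "FitResult",
    "pattern_log_probability",
    "log_likelihood",
    "posterior_probabilities",
    "fit_em",
    "model_implied_marginals",
    "align_classes",
    "sort_classes_by_severity",
]


@dataclass
class LCAParameters:
    """Class membership probabilities ``gamma`` and item-response
    probabilities ``rho`` (``rho[c, j]`` = P(item j = 1 | class c))."""

    gamma: np.ndarray
    rho: np.ndarray
    item_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float).ravel()
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if self.rho.shape[0] != self.gamma.size:
            raise ValueError("rho must have one row per class")
        if (self.gamma < -1e-12).any() or abs(self.gamma.sum() - 1.0) > 1e-10:
            raise ValueError("gamma must be a probability vector summing to 1")
        if (self.rho < -1e-12).any() or (self.rho > 1 + 1e-12).any():
            raise ValueError("rho entries must lie in [0, 1]")
        self.rho = np.clip(self.rho, 0.0, 1.0)
        self.gamma = np.clip(self.gamma, 0.0, 1.0)
        if self.item_names is not None:
            self.item_names = tuple(self.item_names)
            if len(self.item_names) != self.rho.shape[1]:
                raise ValueError("item_names length must equal number of items")

    @property
    def n_classes(self) -> int:
        return self.gamma.size

    @property
    def n_items(self) -> int:
        return self.rho.shape[1]


@dataclass
class PosteriorMatrix:
    """Per-record posterior class probabilities and hard assignments.

    ``assigned`` is 1-based and ties break toward the lowest class index.
    """

    probs: np.ndarray
    assigned: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        self.assigned = np.asarray(self.assigned, dtype=int)


@dataclass
class EMConfig:
    """Multi-start EM settings.  ``seed`` is mandatory so every fit is
    reproducible; ``mad_tol`` is the maximum-absolute-deviation convergence
    threshold on the full parameter vector."""

    seed: int
    n_starts: int = 20
    max_iter: int = 5000
    mad_tol: float = 1e-8
    rho_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be positive")
        if not self.mad_tol > 0:
            raise ValueError("mad_tol must be positive")
        if not 0 < self.rho_floor < 0.5:
            raise ValueError("rho_floor must lie in (0, 0.5)")


@dataclass
class FitResult:
    """One fitted latent class model with its fit statistics.

    ``aic``/``bic`` follow the G-squared convention (``gsq`` plus penalty);
    ``aic_loglik``/``bic_loglik`` are the usual -2*loglik forms, reported for
    transparency but not used by model selection.
    """

    params: object
    loglik: float
    n_params: int
    gsq: float
    xsq: float
    df: int
    aic: float
    bic: float
    converged: bool
    best_start_seed: int
    final_mad: float
    n_used: int
    gof_p: float | None = None
    aic_loglik: float = float("nan")
    bic_loglik: float = float("nan")
    n_iter: int = 0


# --------------------------------------------------------------- likelihood


def _encode_patterns(items: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse records to unique response patterns with counts.

    Returns (patterns, counts) where patterns is int8 with -1 for missing.
    Collapsing makes EM cost scale with the number of distinct patterns
    (at most 3^J) rather than n.
    """
    coded = np.where(np.isnan(items), -1, items).astype(np.int8)
    patterns, counts = np.unique(coded, axis=0, return_counts=True)
    return patterns, counts


def _log_component_terms(
    patterns: np.ndarray, rho: np.ndarray, rho_floor: float
) -> np.ndarray:
    """(P, C) array of log P(pattern | class), missing items marginalised.

    rho is clamped to [rho_floor, 1 - rho_floor] inside the evaluation only,
    so boundary estimates never produce -inf for the wrong reason.
    """
    # keep both logs finite: a -inf multiplied by a zero weight in the
    # einsum would poison the sum with NaN
    lo = max(rho_floor, 1e-300)
    hi = 1.0 - max(rho_floor, 1e-16)
    r = np.clip(rho, lo, hi)
    obs = patterns >= 0
    x = np.clip(patterns, 0, 1).astype(float)
    log_r = np.log(r)
    log_1mr = np.log1p(-r)
    # terms[p, c] = sum_j obs * (x log rho + (1-x) log(1-rho))
    return np.einsum(
        "pj,cj->pc", obs * x, log_r
    ) + np.einsum("pj,cj->pc", obs * (1.0 - x), log_1mr)


def _pattern_logprobs(
    patterns: np.ndarray, params: LCAParameters, rho_floor: float = 1e-12
) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_gamma = np.log(params.gamma)
    terms = _log_component_terms(patterns, params.rho, rho_floor)
    return logsumexp(log_gamma[None, :] + terms, axis=1)


def pattern_log_probability(params: LCAParameters, pattern) -> float:
    """Log mixture probability of a single response pattern.

    Missing items (NaN or None) are marginalised out, so a fully missing
    pattern has probability 1 (log-probability 0).
    """
    arr = np.array(
        [np.nan if (v is None or (isinstance(v, float) and np.isnan(v))) else float(v)
         for v in pattern],
        dtype=float,
    )
    if arr.size != params.n_items:
        raise ValueError(f"pattern length {arr.size} != {params.n_items} items")
    coded = np.where(np.isnan(arr), -1, arr).astype(np.int8)[None, :]
    return float(_pattern_logprobs(coded, params)[0])


def log_likelihood(params: LCAParameters, data: ResponseMatrix) -> float:
    """Observed-data log-likelihood; all-missing records contribute 0."""
    if data.n == 0:
        warnings.warn("log-likelihood of an empty dataset is 0", stacklevel=2)
        return 0.0
    if data.n_items != params.n_items:
        raise ValueError("data and params disagree on the number of items")
    patterns, counts = _encode_patterns(data.items)
    return float(counts @ _pattern_logprobs(patterns, params))


def posterior_probabilities(
    params: LCAParameters, data: ResponseMatrix
) -> PosteriorMatrix:
    """Bayes-posterior class probabilities per record and modal assignment."""
    if data.n_items != params.n_items:
        raise ValueError("data and params disagree on the number of items")
    coded = np.where(np.isnan(data.items), -1, data.items).astype(np.int8)
    with np.errstate(divide="ignore"):
        log_gamma = np.log(params.gamma)
    joint = log_gamma[None, :] + _log_component_terms(coded, params.rho, 1e-12)
    norm = logsumexp(joint, axis=1)
    if not np.isfinite(norm).all():
        bad = int(np.flatnonzero(~np.isfinite(norm))[0])
        raise ValueError(f"record {bad} has zero probability under every class")
    probs = np.exp(joint - norm[:, None])
    assigned = probs.argmax(axis=1) + 1  # argmax takes the lowest index on ties
    return PosteriorMatrix(probs=probs, assigned=assigned)


# ----------------------------------------------------------------------- EM


def _em_single_start(
    patterns: np.ndarray,
    counts: np.ndarray,
    n_classes: int,
    config: EMConfig,
    rng: np.random.Generator,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool, float, int]:
    """Run EM from one random start on the collapsed pattern table.

    Returns (gamma, rho, loglik, converged, final_mad, n_iter).
    """
    n = counts.sum()
    obs = patterns >= 0
    x = np.clip(patterns, 0, 1).astype(float)
    if init is not None:
        gamma, rho = init
    else:
        gamma = rng.dirichlet(np.ones(n_classes))
        rho = rng.uniform(0.1, 0.9, size=(n_classes, patterns.shape[1]))

    final_mad = np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step
        with np.errstate(divide="ignore"):
            log_gamma = np.log(np.maximum(gamma, 1e-300))
        joint = log_gamma[None, :] + _log_component_terms(
            patterns, rho, config.rho_floor
        )
        norm = logsumexp(joint, axis=1)
        post = np.exp(joint - norm[:, None])  # (P, C)
        # M-step on pattern counts
        resp = post * counts[:, None]  # expected class counts per pattern
        new_gamma = resp.sum(axis=0) / n
        num = np.einsum("pc,pj->cj", resp, obs * x)
        den = np.einsum("pc,pj->cj", resp, obs.astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            new_rho = np.where(den > 0, num / np.maximum(den, 1e-300), rho)
        final_mad = max(
            np.abs(new_gamma - gamma).max(), np.abs(new_rho - rho).max()
        )
        gamma, rho = new_gamma, new_rho
        if final_mad < config.mad_tol:
            converged = True
            break
    with np.errstate(divide="ignore"):
        log_gamma = np.log(np.maximum(gamma, 1e-300))
    loglik = float(
        counts
        @ logsumexp(
            log_gamma[None, :]
            + _log_component_terms(patterns, rho, config.rho_floor),
            axis=1,
        )
    )
    return gamma, rho, loglik, converged, float(final_mad), it


def fit_em(
    data: ResponseMatrix,
    n_classes: int,
    config: EMConfig,
    sort_classes: bool = True,
) -> FitResult:
    """Fit a ``n_classes``-class model by multi-start EM.

    Records with every item missing are excluded (they carry no information
    about the items).  The best start by log-likelihood is returned; classes
    are sorted by ascending mean item-response probability so class 1 is the
    least symptomatic ("minor") and class C the most ("major").
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    keep = data.any_observed_rows()
    used = data.subset(keep)
    if used.n == 0:
        raise ValueError("no records with at least one observed item")
    patterns, counts = _encode_patterns(used.items)
    if n_classes > len(patterns):
        warnings.warn(
            f"{n_classes} classes requested but only {len(patterns)} distinct "
            "observed patterns; the model is not identifiable",
            stacklevel=2,
        )

    best = None
    for s in range(config.n_starts):
        rng = np.random.default_rng([config.seed, s])
        gamma, rho, ll, conv, mad, n_iter = _em_single_start(
            patterns, counts, n_classes, config, rng
        )
        if best is None or ll > best[2]:
            best = (gamma, rho, ll, conv, mad, s, n_iter)
    gamma, rho, loglik, converged, final_mad, start, n_iter = best
    if not converged:
        warnings.warn("EM did not reach the MAD tolerance in any best run",
                      stacklevel=2)
    params = LCAParameters(
        gamma=gamma / gamma.sum(), rho=rho, item_names=used.item_names
    )
    if sort_classes:
        params = sort_classes_by_severity(params)

    # goodness of fit and information criteria (complete cases only)
    from . import selection  # local import to avoid a module cycle

    table = selection.PatternTable.from_data(used)
    n_params = selection.count_free_parameters(
        n_classes, used.n_items, n_groups=1, rho_invariant=True
    )
    gsq, xsq, df, p = selection.goodness_of_fit(params, table, n_params=n_params)
    aic, bic = selection.information_criteria(gsq, n_params, used.n)
    return FitResult(
        params=params,
        loglik=loglik,
        n_params=n_params,
        gsq=gsq,
        xsq=xsq,
        df=df,
        aic=aic,
        bic=bic,
        converged=converged,
        best_start_seed=start,
        final_mad=final_mad,
        n_used=used.n,
        gof_p=p,
        aic_loglik=-2 * loglik + 2 * n_params,
        bic_loglik=-2 * loglik + np.log(used.n) * n_params,
        n_iter=n_iter,
    )


# ----------------------------------------------------------------- reporting


def model_implied_marginals(params: LCAParameters) -> np.ndarray:
    """Marginal endorsement probability of each item: ``gamma @ rho``."""
    return params.gamma @ params.rho


def align_classes(params: LCAParameters, reference: LCAParameters) -> LCAParameters:
    """Permute classes to best match a reference (label-switching fix).

    Minimises the total absolute difference between ``rho`` rows; exhaustive
    over all permutations for up to 6 classes, Hungarian assignment beyond.
    Deterministic.
    """
    if params.n_classes != reference.n_classes or params.n_items != reference.n_items:
        raise ValueError("params and reference must share dimensions")
    C = params.n_classes
    cost = np.abs(params.rho[:, None, :] - reference.rho[None, :, :]).sum(axis=2)
    if C <= 6:
        from itertools import permutations

        best_perm, best_cost = None, np.inf
        for perm in permutations(range(C)):
            c = sum(cost[perm[k], k] for k in range(C))
            if c < best_cost - 1e-15:
                best_cost, best_perm = c, perm
        order = np.array(best_perm)
    else:
        row_ind, col_ind = linear_sum_assignment(cost)
        order = row_ind[np.argsort(col_ind)]
    return LCAParameters(
        gamma=params.gamma[order], rho=params.rho[order], item_names=params.item_names
    )


def sort_classes_by_severity(params: LCAParameters) -> LCAParameters:
    """Order classes by ascending mean item-response probability.

    Matches the minor / moderate / major labelling convention for pain
    classes.  Ties preserve the incoming order (stable sort).
    """
    order = np.argsort(params.rho.mean(axis=1), kind="stable")
    return LCAParameters(
        gamma=params.gamma[order], rho=params.rho[order], item_names=params.item_names
    )
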