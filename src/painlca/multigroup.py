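"""Grouped latent class models and the measurement-invariance test.

Multigroup models keep class membership probabilities group-specific
(each gender / age stratum has its own ``gamma``) while the item-response
probabilities ``rho`` are either shared across groups (the *invariant* or
constrained model) or free per group.  Measurement invariance — the same
item-response profile in every group — is tested by the chi-square
difference between the constrained and free fits, on
``(G - 1) * C * J`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import (
    EMConfig,
    FitResult,
    LCAParameters,
    _encode_patterns,
    _log_component_terms,
    align_classes,
    fit_em,
)
from .data import ResponseMatrix
from .selection import (
    PatternTable,
    _gof_statistics,
    chi_square_tail,
    count_free_parameters,
    goodness_of_fit,
    information_criteria,
    _pattern_logprobs,
)

__all__ = [
    "MultigroupParameters",
    "InvarianceResult",
    "fit_multigroup",
    "invariance_df",
    "invariance_test",
]


@dataclass
class MultigroupParameters:
    """Per-group membership probabilities with shared or free response probs.

    ``gamma`` is ``G x C``; ``rho`` is ``C x J`` when ``rho_invariant`` else
    ``G x C x J``.
    """

    group_names: tuple[str, ...]
    gamma: np.ndarray
    rho: np.ndarray
    rho_invariant: bool
    item_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.group_names = tuple(str(g) for g in self.group_names)
        if len(set(self.group_names)) != len(self.group_names):
            raise ValueError("group names must be distinct")
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)
        G, C = self.gamma.shape
        if G != len(self.group_names):
            raise ValueError("gamma must have one row per group")
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each gamma row must sum to 1")
        expected_ndim = 2 if self.rho_invariant else 3
        if self.rho.ndim != expected_ndim:
            raise ValueError(
                f"rho must be {expected_ndim}-D for rho_invariant={self.rho_invariant}"
            )
        if (self.rho < -1e-12).any() or (self.rho > 1 + 1e-12).any():
            raise ValueError("rho entries must lie in [0, 1]")
        self.rho = np.clip(self.rho, 0.0, 1.0)
        if self.item_names is not None:
            self.item_names = tuple(self.item_names)

    @property
    def n_groups(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_classes(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_items(self) -> int:
        return self.rho.shape[-1]

    def group_params(self, g: int) -> LCAParameters:
        """Single-group view: that group's gamma with its (or the shared) rho."""
        rho = self.rho if self.rho_invariant else self.rho[g]
        return LCAParameters(
            gamma=self.gamma[g] / self.gamma[g].sum(),
            rho=rho,
            item_names=self.item_names,
        )


@dataclass
class InvarianceResult:
    """Chi-square difference test of equal item-response probabilities."""

    chisq_diff: float
    df_diff: int
    p_value: float
    free_fit: FitResult
    constrained_fit: FitResult


def invariance_df(C: int, J: int, G: int) -> int:
    """Parameter-count difference between free-rho and invariant-rho models:
    ``(G - 1) * C * J``."""
    if G < 1:
        raise ValueError("G must be >= 1")
    return (G - 1) * C * J


def _grouped_gof(
    params: MultigroupParameters, grouped: dict[str, ResponseMatrix]
) -> tuple[float, float]:
    """G2 and X2 summed over per-group complete-pattern tables."""
    gsq_total = xsq_total = 0.0
    for g, name in enumerate(params.group_names):
        table = PatternTable.from_data(grouped[name])
        if table.n_complete == 0:
            continue
        all_pats, obs = table.full_table()
        probs = np.exp(_pattern_logprobs(all_pats, params.group_params(g)))
        gsq, xsq = _gof_statistics(obs, table.n_complete * probs)
        gsq_total += gsq
        xsq_total += xsq
    return gsq_total, xsq_total


def _fit_invariant_em(
    grouped_patterns: list[tuple[np.ndarray, np.ndarray]],
    n_classes: int,
    config: EMConfig,
) -> tuple[np.ndarray, np.ndarray, float, bool, float]:
    """Joint EM with group-specific gamma and a shared rho matrix."""
    G = len(grouped_patterns)
    J = grouped_patterns[0][0].shape[1]
    n_per_group = np.array([c.sum() for _, c in grouped_patterns], dtype=float)

    best = None
    for s in range(config.n_starts):
        rng = np.random.default_rng([config.seed, s])
        gamma = np.stack([rng.dirichlet(np.ones(n_classes)) for _ in range(G)])
        rho = rng.uniform(0.1, 0.9, size=(n_classes, J))
        converged = False
        final_mad = np.inf
        for _ in range(config.max_iter):
            num = np.zeros((n_classes, J))
            den = np.zeros((n_classes, J))
            new_gamma = np.zeros_like(gamma)
            for g, (pats, counts) in enumerate(grouped_patterns):
                obs = pats >= 0
                x = np.clip(pats, 0, 1).astype(float)
                with np.errstate(divide="ignore"):
                    lg = np.log(np.maximum(gamma[g], 1e-300))
                joint = lg[None, :] + _log_component_terms(pats, rho, config.rho_floor)
                post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
                resp = post * counts[:, None]
                new_gamma[g] = resp.sum(axis=0) / n_per_group[g]
                num += np.einsum("pc,pj->cj", resp, obs * x)
                den += np.einsum("pc,pj->cj", resp, obs.astype(float))
            with np.errstate(invalid="ignore", divide="ignore"):
                new_rho = np.where(den > 0, num / np.maximum(den, 1e-300), rho)
            final_mad = max(
                np.abs(new_gamma - gamma).max(), np.abs(new_rho - rho).max()
            )
            gamma, rho = new_gamma, new_rho
            if final_mad < config.mad_tol:
                converged = True
                break
        ll = 0.0
        for g, (pats, counts) in enumerate(grouped_patterns):
            with np.errstate(divide="ignore"):
                lg = np.log(np.maximum(gamma[g], 1e-300))
            ll += float(
                counts
                @ logsumexp(
                    lg[None, :] + _log_component_terms(pats, rho, config.rho_floor),
                    axis=1,
                )
            )
        if best is None or ll > best[2]:
            best = (gamma, rho, ll, converged, float(final_mad))
    return best


def fit_multigroup(
    data: ResponseMatrix,
    n_classes: int,
    config: EMConfig,
    rho_invariant: bool = True,
) -> FitResult:
    """Fit a grouped latent class model.

    Records without a group label are eliminated first.  The free model
    (group-specific rho) factorises over groups and is fitted as independent
    per-group EMs; the invariant model is fitted by joint EM whose rho M-step
    pools posterior-weighted counts across groups.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    grouped = data.drop_missing_group().split_by_group()
    if not grouped:
        raise ValueError("no records with a group label")
    for name, sub in grouped.items():
        if not sub.any_observed_rows().any():
            raise ValueError(f"group {name!r} has no usable records")
    group_names = tuple(grouped)
    G = len(group_names)
    J = data.n_items
    # restrict to records contributing to the likelihood
    grouped = {k: v.subset(v.any_observed_rows()) for k, v in grouped.items()}
    n_used = sum(v.n for v in grouped.values())

    if rho_invariant:
        grouped_patterns = [_encode_patterns(grouped[g].items) for g in group_names]
        gamma, rho, loglik, converged, final_mad = _fit_invariant_em(
            grouped_patterns, n_classes, config
        )
        order = np.argsort(rho.mean(axis=1), kind="stable")
        params = MultigroupParameters(
            group_names=group_names,
            gamma=(gamma / gamma.sum(axis=1, keepdims=True))[:, order],
            rho=rho[order],
            rho_invariant=True,
            item_names=data.item_names,
        )
        start_seed = config.seed
    else:
        sub_fits = []
        for gi, g in enumerate(group_names):
            cfg = EMConfig(
                seed=int(np.random.default_rng([config.seed, gi]).integers(2**31)),
                n_starts=config.n_starts,
                max_iter=config.max_iter,
                mad_tol=config.mad_tol,
                rho_floor=config.rho_floor,
            )
            sub_fits.append(fit_em(grouped[g], n_classes, cfg))
        loglik = sum(f.loglik for f in sub_fits)
        converged = all(f.converged for f in sub_fits)
        final_mad = max(f.final_mad for f in sub_fits)
        params = MultigroupParameters(
            group_names=group_names,
            gamma=np.stack([f.params.gamma for f in sub_fits]),
            rho=np.stack([f.params.rho for f in sub_fits]),
            rho_invariant=False,
            item_names=data.item_names,
        )
        start_seed = config.seed
    if not converged:
        warnings.warn("multigroup EM did not reach the MAD tolerance", stacklevel=2)

    n_params = count_free_parameters(n_classes, J, G, rho_invariant)
    gsq, xsq = _grouped_gof(params, grouped)
    df = G * (2**J - 1) - n_params
    p = chi_square_tail(max(gsq, 0.0), df) if df >= 1 else None
    aic, bic = information_criteria(gsq, n_params, n_used)
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
        best_start_seed=start_seed,
        final_mad=final_mad,
        n_used=n_used,
        gof_p=p,
        aic_loglik=-2 * loglik + 2 * n_params,
        bic_loglik=-2 * loglik + np.log(n_used) * n_params,
    )


def invariance_test(
    data: ResponseMatrix, n_classes: int, config: EMConfig
) -> InvarianceResult:
    """Chi-square difference test of measurement invariance across groups.

    Fits the rho-invariant (constrained) and free models, aligns each free
    group's classes to the constrained solution's shared rho, and compares
    twice the log-likelihood gain — equivalently the G2 difference — to a
    chi-square with ``(G - 1) * C * J`` degrees of freedom.
    """
    constrained = fit_multigroup(data, n_classes, config, rho_invariant=True)
    free = fit_multigroup(data, n_classes, config, rho_invariant=False)
    if not (constrained.converged and free.converged):
        warnings.warn(
            "invariance test based on a non-converged fit; interpret with care",
            stacklevel=2,
        )

    # align each free group's labels to the constrained shared profile
    ref = LCAParameters(
        gamma=np.full(n_classes, 1.0 / n_classes),
        rho=constrained.params.rho,
        item_names=constrained.params.item_names,
    )
    fp = free.params
    aligned_gamma = np.empty_like(fp.gamma)
    aligned_rho = np.empty_like(fp.rho)
    for g in range(fp.n_groups):
        aligned = align_classes(fp.group_params(g), ref)
        aligned_gamma[g] = aligned.gamma
        aligned_rho[g] = aligned.rho
    free.params = MultigroupParameters(
        group_names=fp.group_names,
        gamma=aligned_gamma,
        rho=aligned_rho,
        rho_invariant=False,
        item_names=fp.item_names,
    )

    chisq = max(constrained.gsq - free.gsq, 0.0)
    df = invariance_df(n_classes, data.n_items, fp.n_groups)
    p = chi_square_tail(chisq, df)
    return InvarianceResult(
        chisq_diff=chisq,
        df_diff=df,
        p_value=p,
        free_fit=free,
        constrained_fit=constrained,
    )
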