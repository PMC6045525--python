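"""Goodness of fit, information criteria, and class enumeration.

Fit is judged on the table of complete response patterns: the likelihood-ratio
statistic G2 = 2 * sum obs * ln(obs/exp) and the Pearson X2, both against the
model-implied pattern probabilities.  AIC and BIC follow the G2-based
convention (G2 plus penalty), and the number of classes is chosen by a forward
sweep that only accepts a larger model when both criteria drop by at least 5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import EMConfig, FitResult, LCAParameters, _pattern_logprobs, fit_em
from .data import ResponseMatrix

__all__ = [
    "PatternTable",
    "SelectionReport",
    "count_free_parameters",
    "goodness_of_fit",
    "information_criteria",
    "chi_square_tail",
    "select_classes",
]


@dataclass
class PatternTable:
    """Observed frequencies of complete response patterns.

    ``patterns`` holds distinct 0/1 ``J``-vectors; ``counts`` their observed
    frequencies among complete-case records (``n_complete`` in total).
    """

    patterns: np.ndarray
    counts: np.ndarray
    n_complete: int

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=np.int8))
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("pattern counts must be non-negative")
        if abs(self.counts.sum() - self.n_complete) > 1e-9:
            raise ValueError("counts must sum to n_complete")

    @classmethod
    def from_data(cls, data: ResponseMatrix) -> "PatternTable":
        complete = data.subset(data.complete_rows())
        if complete.n == 0:
            return cls(
                patterns=np.empty((0, data.n_items), dtype=np.int8),
                counts=np.empty(0),
                n_complete=0,
            )
        pats, counts = np.unique(
            complete.items.astype(np.int8), axis=0, return_counts=True
        )
        return cls(patterns=pats, counts=counts, n_complete=int(counts.sum()))

    def full_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All 2^J complete patterns with observed counts (zeros included)."""
        J = self.patterns.shape[1]
        all_pats = np.array(
            [[(i >> (J - 1 - j)) & 1 for j in range(J)] for i in range(2**J)],
            dtype=np.int8,
        )
        counts = np.zeros(2**J)
        index = {tuple(p): k for k, p in enumerate(all_pats)}
        for p, c in zip(self.patterns, self.counts):
            counts[index[tuple(p)]] = c
        return all_pats, counts


@dataclass
class SelectionReport:
    """Candidate fits across a class range plus the deterministic rule trace."""

    candidate_fits: dict[int, FitResult]
    selected_C: int
    rule_trace: list[dict] = field(default_factory=list)

    def criteria_table(self) -> list[dict]:
        rows = []
        for C, fit in sorted(self.candidate_fits.items()):
            rows.append(
                {
                    "n_classes": C,
                    "loglik": fit.loglik,
                    "gsq": fit.gsq,
                    "df": fit.df,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "gof_p": fit.gof_p,
                    "converged": fit.converged,
                    "selected": C == self.selected_C,
                }
            )
        return rows

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_C": self.selected_C,
                "candidates": self.criteria_table(),
                "rule_trace": self.rule_trace,
            },
            indent=2,
            default=float,
        )


def count_free_parameters(
    C: int, J: int, n_groups: int = 1, rho_invariant: bool = True
) -> int:
    """Free-parameter count of a (multigroup) latent class model.

    Membership probabilities are always group-specific: ``G * (C - 1)``.
    Item-response probabilities contribute ``C * J`` when shared across
    groups, ``G * C * J`` when free.
    """
    if C < 1 or J < 1 or n_groups < 1:
        raise ValueError("C, J and n_groups must be positive")
    rho_params = C * J if rho_invariant else n_groups * C * J
    return n_groups * (C - 1) + rho_params


def chi_square_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(stats.chi2.sf(x, df))


def _gof_statistics(
    observed: np.ndarray, expected: np.ndarray
) -> tuple[float, float]:
    """G2 and Pearson X2 from matched observed counts and expected counts."""
    pos = observed > 0
    if (expected[pos] <= 0).any():
        raise ValueError("expected count of 0 with positive observed count")
    gsq = 2.0 * float(
        np.sum(observed[pos] * np.log(observed[pos] / expected[pos]))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        xsq_terms = np.where(
            expected > 0, (observed - expected) ** 2 / np.maximum(expected, 1e-300), 0.0
        )
    return gsq, float(np.sum(xsq_terms))


def goodness_of_fit(
    params: LCAParameters, table: PatternTable, n_params: int | None = None
) -> tuple[float, float, int, float | None]:
    """G2, Pearson X2, residual df and the G2 tail probability.

    Expected counts come from the model-implied probabilities of all 2^J
    complete patterns; df = 2^J - 1 - n_params.  When df <= 0 the model is
    saturated (or over-parameterised) and p is None.
    """
    J = params.n_items
    if n_params is None:
        n_params = count_free_parameters(params.n_classes, J)
    all_pats, obs = table.full_table()
    probs = np.exp(_pattern_logprobs(all_pats, params))
    expected = table.n_complete * probs
    gsq, xsq = _gof_statistics(obs, expected)
    df = 2**J - 1 - n_params
    p = chi_square_tail(max(gsq, 0.0), df) if df >= 1 else None
    return gsq, xsq, df, p


def information_criteria(
    gsq: float, n_params: int, n_used: int
) -> tuple[float, float]:
    """G2-based AIC and BIC: ``gsq + 2p`` and ``gsq + ln(n) p``."""
    if n_used < 1:
        raise ValueError("n_used must be >= 1")
    return gsq + 2.0 * n_params, gsq + float(np.log(n_used)) * n_params


def select_classes(
    data: ResponseMatrix,
    c_min: int,
    c_max: int,
    config: EMConfig,
    decrease: float = 0.05,
    gof_alpha: float = 0.05,
) -> SelectionReport:
    """Choose the number of classes by the 5%-decrease rule on AIC and BIC.

    Every candidate C in [c_min, c_max] is fitted (shared base seed; each C
    uses its own derived seed stream).  A successful fit requires GOF
    p > ``gof_alpha`` (saturated models, df <= 0, count as adequate).
    Starting from c_min, the sweep advances to the next candidate when the
    current model is not a successful fit and the candidate is, or when both
    AIC and BIC decrease by at least ``decrease`` relative to the current
    model.  Non-converged candidates are flagged and skipped by the rule.
    """
    if c_min < 1 or c_max < c_min:
        raise ValueError("need 1 <= c_min <= c_max")
    fits: dict[int, FitResult] = {}
    for C in range(c_min, c_max + 1):
        cfg = EMConfig(
            seed=int(np.random.default_rng([config.seed, C]).integers(2**31)),
            n_starts=config.n_starts,
            max_iter=config.max_iter,
            mad_tol=config.mad_tol,
            rho_floor=config.rho_floor,
        )
        fits[C] = fit_em(data, C, cfg)

    trace: list[dict] = []
    current = None
    for C in range(c_min, c_max + 1):
        fit = fits[C]
        step = {
            "n_classes": C,
            "aic": fit.aic,
            "bic": fit.bic,
            "gof_p": fit.gof_p,
            "gof_adequate": (fit.gof_p is None) or (fit.gof_p > gof_alpha),
            "converged": fit.converged,
        }
        if not fit.converged:
            step["action"] = "skipped (not converged)"
            trace.append(step)
            continue
        if current is None:
            step["action"] = "baseline"
            current = C
            trace.append(step)
            continue
        ref = fits[current]
        aic_drop = (ref.aic - fit.aic) / abs(ref.aic) if ref.aic != 0 else np.inf
        bic_drop = (ref.bic - fit.bic) / abs(ref.bic) if ref.bic != 0 else np.inf
        step["aic_rel_decrease"] = aic_drop
        step["bic_rel_decrease"] = bic_drop
        ref_adequate = (ref.gof_p is None) or (ref.gof_p > gof_alpha)
        if not ref_adequate and step["gof_adequate"]:
            step["action"] = (
                f"accepted over {current} (model {current} failed GOF "
                f"p > {gof_alpha:g}; this model fits)"
            )
            current = C
        elif aic_drop >= decrease and bic_drop >= decrease:
            step["action"] = f"accepted over {current} (both criteria fell >= {decrease:.0%})"
            current = C
        else:
            step["action"] = f"rejected (kept {current})"
        trace.append(step)
    if current is None:
        # no candidate converged: fall back to the best-BIC candidate,
        # clearly flagged, rather than refusing to report anything
        current = min(fits, key=lambda C: fits[C].bic)
        trace.append(
            {"action": f"fallback: no candidate converged; best BIC is C={current}"}
        )
    return SelectionReport(candidate_fits=fits, selected_C=current, rule_trace=trace)
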