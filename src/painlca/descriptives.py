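"""Descriptive prevalence statistics across gender-age strata.

Covers the standard epidemiological table of per-group symptom prevalence:
Wilson score confidence intervals, chi-square homogeneity tests (asymptotic
or seeded Monte Carlo with fixed margins), pairwise column-proportion
comparisons rendered as a compact letter display, and an inclusion-exclusion
utility mapping "pain in any of these sites" union probabilities back to the
joint distribution over response patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GroupCounts",
    "LetterDisplay",
    "prevalence_with_ci",
    "homogeneity_test",
    "pairwise_letter_display",
    "joint_from_subset_unions",
    "unions_from_joint",
]


@dataclass
class GroupCounts:
    """Successes / totals per group for one binary outcome."""

    group_names: tuple[str, ...]
    successes: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.group_names = tuple(self.group_names)
        self.successes = np.asarray(self.successes, dtype=int)
        self.totals = np.asarray(self.totals, dtype=int)
        if (self.totals < 1).any():
            raise ValueError("every group total must be >= 1")
        if (self.successes < 0).any() or (self.successes > self.totals).any():
            raise ValueError("successes must lie in [0, total] per group")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def proportions(self) -> np.ndarray:
        return self.successes / self.totals


@dataclass
class LetterDisplay:
    """Compact letter display: groups sharing a letter do not differ
    significantly in pairwise comparisons at the adjusted level."""

    letters: tuple[frozenset, ...]
    alpha: float

    def formatted(self) -> tuple[str, ...]:
        return tuple("".join(sorted(ls)) for ls in self.letters)


def prevalence_with_ci(
    successes: int, total: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Point prevalence with a Wilson score confidence interval."""
    if not 0 <= successes <= total or total < 1:
        raise ValueError("need 0 <= successes <= total, total >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    lower, upper = proportion_confint(successes, total, alpha=1 - level, method="wilson")
    # the Wilson bounds are exactly 0 at zero successes and exactly 1 at
    # zero failures; guard against floating-point residue from statsmodels
    lower = 0.0 if successes == 0 else min(float(lower), successes / total)
    upper = 1.0 if successes == total else max(float(upper), successes / total)
    return successes / total, lower, upper


def _pearson_statistic(successes: np.ndarray, totals: np.ndarray) -> float:
    """Pearson chi-square on the G x 2 (success, failure) table."""
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    p_pool = successes.sum() / totals.sum()
    if p_pool in (0.0, 1.0):
        return 0.0
    expected_s = totals * p_pool
    expected_f = totals * (1 - p_pool)
    return float(
        np.sum((successes - expected_s) ** 2 / expected_s)
        + np.sum(((totals - successes) - expected_f) ** 2 / expected_f)
    )


def homogeneity_test(
    counts: GroupCounts,
    method: str = "asymptotic",
    seed: int | None = None,
    n_rep: int = 100_000,
) -> tuple[float, float]:
    """Chi-square test of equal proportions across groups.

    ``method='asymptotic'`` uses the chi-square reference with ``G - 1`` df.
    ``method='monte_carlo'`` resamples ``n_rep`` tables with both margins
    fixed (multivariate hypergeometric) and reports the add-one permutation
    p-value ``(1 + #{stat* >= stat}) / (n_rep + 1)``; seeded and reproducible.
    """
    if counts.n_groups < 2:
        raise ValueError("need at least two groups")
    statistic = _pearson_statistic(counts.successes, counts.totals)
    if method == "asymptotic":
        p = float(stats.chi2.sf(statistic, counts.n_groups - 1))
    elif method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo method requires a seed")
        rng = np.random.default_rng(seed)
        total_s = int(counts.successes.sum())
        draws = rng.multivariate_hypergeometric(
            counts.totals, total_s, size=n_rep
        )  # (n_rep, G) successes with fixed margins
        totals = counts.totals.astype(float)
        p_pool = total_s / totals.sum()
        es = totals * p_pool
        ef = totals * (1 - p_pool)
        if p_pool in (0.0, 1.0):
            stats_star = np.zeros(n_rep)
        else:
            stats_star = ((draws - es) ** 2 / es).sum(axis=1) + (
                ((totals - draws) - ef) ** 2 / ef
            ).sum(axis=1)
        p = float((1 + np.sum(stats_star >= statistic - 1e-12)) / (n_rep + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return statistic, p


def _two_proportion_z_p(s1: int, n1: int, s2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test p-value."""
    p_pool = (s1 + s2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (s1 / n1 - s2 / n2) / se
    return float(2 * stats.norm.sf(abs(z)))


def pairwise_letter_display(counts: GroupCounts, alpha: float = 0.05) -> LetterDisplay:
    """Compact letter display over Bonferroni-adjusted pairwise z-tests.

    All G(G-1)/2 two-proportion z-tests are performed; a pair differs when
    its p-value is below ``alpha / n_pairs``.  Letters are assigned with the
    insert-and-absorb procedure over the non-significance graph, so two
    groups share a letter iff their comparison is non-significant.
    """
    G = counts.n_groups
    if G < 2:
        raise ValueError("need at least two groups")
    n_pairs = G * (G - 1) // 2
    adj_alpha = alpha / n_pairs
    differs = np.zeros((G, G), dtype=bool)
    for i, j in combinations(range(G), 2):
        p = _two_proportion_z_p(
            counts.successes[i], counts.totals[i], counts.successes[j], counts.totals[j]
        )
        differs[i, j] = differs[j, i] = p < adj_alpha

    # insert-and-absorb: each letter is a maximal clique of the
    # non-significance graph covering every non-significant pair
    letter_sets: list[set] = [set(range(G))]
    for i, j in combinations(range(G), 2):
        if not differs[i, j]:
            continue
        for ls in [s for s in letter_sets if i in s and j in s]:
            letter_sets.remove(ls)
            a, b = ls - {j}, ls - {i}
            for cand in (a, b):
                # absorb: keep only sets not contained in an existing one
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    # every group needs at least one letter
    for g in range(G):
        if not any(g in s for s in letter_sets):
            letter_sets.append({g})
    # deterministic ordering: by smallest member then size
    letter_sets.sort(key=lambda s: (min(s), -len(s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = [set() for _ in range(G)]
    for k, s in enumerate(letter_sets):
        for g in s:
            letters[g].add(alphabet[k])
    return LetterDisplay(letters=tuple(frozenset(s) for s in letters), alpha=alpha)


# -------------------------------------------------- inclusion-exclusion


def _subset_iter(J: int):
    for mask in range(1, 2**J):
        yield frozenset(j for j in range(J) if mask >> j & 1)


def unions_from_joint(joint: np.ndarray) -> dict[frozenset, float]:
    """Forward map: P(any item in S endorsed) for every non-empty subset S.

    ``joint[k]`` is the probability of the pattern whose bit ``j`` of ``k``
    is item ``j``'s value.
    """
    joint = np.asarray(joint, dtype=float)
    J = int(np.log2(joint.size))
    if 2**J != joint.size:
        raise ValueError("joint length must be a power of 2")
    unions = {}
    for S in _subset_iter(J):
        mask = sum(1 << j for j in S)
        all_zero = sum(joint[k] for k in range(2**J) if k & mask == 0)
        unions[S] = 1.0 - all_zero
    return unions


def joint_from_subset_unions(
    union_probs: dict[frozenset, float], tol: float = 1e-9
) -> np.ndarray:
    """Recover the joint pattern distribution from all subset union
    probabilities by Mobius inversion.

    ``union_probs`` must give P(any item in S = 1) for every non-empty
    subset S of items; items are indexed 0..J-1.  Returns the length-2^J
    joint with pattern ``k`` encoding item ``j`` in bit ``j``.  Raises when
    the implied joint has entries outside [-tol, 1 + tol] (infeasible union
    system) rather than silently clipping.
    """
    union_probs = {frozenset(k): float(v) for k, v in union_probs.items()}
    items = sorted(set().union(*union_probs)) if union_probs else []
    if not union_probs:
        raise ValueError("union_probs must be non-empty")
    J = max(items) + 1
    for S in _subset_iter(J):
        if S not in union_probs:
            raise ValueError(f"missing union probability for subset {sorted(S)}")
        if not 0 <= union_probs[S] <= 1:
            raise ValueError(f"union probability of {sorted(S)} outside [0, 1]")
    # z(T) = P(all items in T are 0) = 1 - union(T);  z(empty) = 1
    z = np.empty(2**J)
    z[0] = 1.0
    for T in _subset_iter(J):
        z[sum(1 << j for j in T)] = 1.0 - union_probs[T]
    # P(pattern x) = sum_{T >= zeroset(x)} (-1)^{|T| - |zeroset(x)|} z(T)
    joint = np.zeros(2**J)
    for k in range(2**J):
        zero_mask = (2**J - 1) ^ k
        acc = 0.0
        sub = zero_mask
        # iterate supersets T of zero_mask
        comp = k  # bits free to add
        t = 0
        while True:
            T = zero_mask | t
            acc += (-1) ** (bin(T).count("1") - bin(zero_mask).count("1")) * z[T]
            if t == comp:
                break
            t = (t - comp) & comp  # next subset of comp
        joint[k] = acc
    bad = np.flatnonzero((joint < -tol) | (joint > 1 + tol))
    if bad.size:
        cells = {int(k): float(joint[k]) for k in bad}
        raise ValueError(f"infeasible union system; out-of-range joint cells: {cells}")
    return joint
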