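"""Seeded generator of subject-level pain datasets from packaged parameter sets.

The packaged fixtures encode published three-class parameter sets for four
binary pain items (neck, shoulder, upper back, low back): a pooled model, a
gender-specific model, an age-specific model, and a gender-age model with
four strata.  ``simulate`` draws a stratum for each subject, a latent class
from that stratum's membership probabilities, and items independently from
the class's item-response probabilities — exactly the generative model the
latent class likelihood assumes — with optional missing-at-random item
blanking.  Hidden true-class labels are retained for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .data import ResponseMatrix
from .multigroup import MultigroupParameters

__all__ = ["Fixture", "GeneratorConfig", "load_fixture", "available_fixtures",
           "simulate", "inject_missing_mar"]

FIXTURE_NAMES = ("table2", "table3_gender", "table4_age", "table5_gender_age")


@dataclass
class Fixture:
    """A named parameter set: per-group class memberships, item-response
    probabilities, stratum fractions, and the design sample size."""

    name: str
    params: MultigroupParameters
    group_fractions: np.ndarray
    default_n: int = 1611
    class_names: tuple[str, ...] = ("minor", "moderate", "major")
    anomalies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.group_fractions = np.asarray(self.group_fractions, dtype=float)
        if abs(self.group_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if self.group_fractions.size != self.params.n_groups:
            raise ValueError("one fraction per group required")


@dataclass
class GeneratorConfig:
    """Simulation settings.  ``missing_rate`` applies independently per item
    cell (missing-at-random given the stratum); the 0.02 default mirrors the
    mild item non-response typical of classroom questionnaire surveys."""

    n_total: int = 1611
    seed: int = 0
    missing_rate: float | np.ndarray = 0.02

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        rates = np.asarray(self.missing_rate, dtype=float)
        if (rates < 0).any() or (rates >= 1).any():
            raise ValueError("missing rates must lie in [0, 1)")


def available_fixtures() -> tuple[str, ...]:
    return FIXTURE_NAMES


def load_fixture(name: str) -> Fixture:
    """Load a packaged parameter fixture by name.

    Values are stored exactly as published, with entries printed as
    "< 0.01" encoded as 0.0 (this encoding reproduces the published
    model-implied marginal prevalences).  Membership rows are renormalised
    to sum to 1 where printed percentages round to 100.1%.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    text = (resources.files("painlca") / "fixtures" / f"{name}.json").read_text()
    doc = json.loads(text)
    gamma = np.asarray(doc["gamma"], dtype=float)
    gamma = gamma / gamma.sum(axis=1, keepdims=True)
    params = MultigroupParameters(
        group_names=tuple(doc["group_names"]),
        gamma=gamma,
        rho=np.asarray(doc["rho"], dtype=float),
        rho_invariant=False,
        item_names=tuple(doc["item_names"]),
    )
    return Fixture(
        name=doc["name"],
        params=params,
        group_fractions=np.asarray(doc["group_fractions"], dtype=float),
        default_n=int(doc.get("default_n", 1611)),
        class_names=tuple(doc.get("class_names", ("minor", "moderate", "major"))),
        anomalies=tuple(doc.get("anomalies", ())),
    )


def simulate(fixture: Fixture, config: GeneratorConfig) -> ResponseMatrix:
    """Draw a subject-level dataset from a fixture's generative model.

    Deterministic given ``config.seed``.  Group labels are attached whenever
    the fixture has more than one stratum; hidden 1-based true classes are
    always attached (estimation never reads them).
    """
    rng = np.random.default_rng(config.seed)
    p = fixture.params
    n, G, C, J = config.n_total, p.n_groups, p.n_classes, p.n_items

    item_names = p.item_names or tuple(f"item_{j}" for j in range(J))
    group_idx = rng.choice(G, size=n, p=fixture.group_fractions)
    # class per subject from the subject's stratum membership probabilities
    u = rng.random(n)
    cum = np.cumsum(p.gamma, axis=1)  # (G, C)
    class_idx = (u[:, None] > cum[group_idx]).sum(axis=1)
    probs = p.rho[group_idx, class_idx]  # (n, J)
    items = (rng.random((n, J)) < probs).astype(float)

    data = ResponseMatrix(
        items=items,
        item_names=item_names,
        group=(
            np.array([p.group_names[g] for g in group_idx], dtype=object)
            if G > 1
            else None
        ),
        true_class=class_idx + 1,
    )
    rates = np.broadcast_to(
        np.asarray(config.missing_rate, dtype=float), (J,)
    )
    if (rates > 0).any():
        data = inject_missing_mar(
            data, rates, seed=int(rng.integers(2**31))
        )
    return data


def inject_missing_mar(
    data: ResponseMatrix, rates, seed: int
) -> ResponseMatrix:
    """Blank item cells independently at the given per-item rates (MAR).

    Group labels and hidden true classes are never blanked.  Reproducible
    given the seed.
    """
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (data.n_items,))
    if (rates < 0).any() or (rates >= 1).any():
        raise ValueError("missing rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(data.items.shape) < rates[None, :]
    items = data.items.copy()
    items[mask] = np.nan
    return ResponseMatrix(
        items=items,
        item_names=data.item_names,
        group=data.group,
        true_class=data.true_class,
    )
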