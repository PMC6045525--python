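"""End-to-end analysis pipeline and report rendering.

Ties the stages together: ingest (or simulate) subject-level data, build
per-stratum descriptives, enumerate the number of classes on the pooled
data, then for each grouping variable fit the invariant and free multigroup
models and test measurement invariance.  Reports mirror the shape of
published latent class tables: class columns labelled minor / moderate /
major, probabilities printed to two decimals with values below 0.01
rendered as "< 0.01", and the invariance test as a table footnote.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import EMConfig, FitResult
from .data import DEFAULT_ITEMS, ResponseMatrix
from .descriptives import GroupCounts, homogeneity_test, pairwise_letter_display
from .multigroup import InvarianceResult, fit_multigroup, invariance_test
from .selection import SelectionReport, select_classes
from .synthetic import FIXTURE_NAMES, GeneratorConfig, load_fixture, simulate

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "read_subject_table",
    "run_analysis",
    "render_reports",
    "STRATUM_GROUPINGS",
]

# how the four gender-age strata collapse into coarser grouping variables
STRATUM_GROUPINGS: dict[str, dict[str, str]] = {
    "gender": {
        "girls_le13": "girl", "girls_ge14": "girl",
        "boys_le13": "boy", "boys_ge14": "boy",
    },
    "age": {
        "girls_le13": "le13", "boys_le13": "le13",
        "girls_ge14": "ge14", "boys_ge14": "ge14",
    },
    "gender_age": {
        "girls_le13": "girls_le13", "girls_ge14": "girls_ge14",
        "boys_le13": "boys_le13", "boys_ge14": "boys_ge14",
    },
}


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one pipeline run bit-for-bit."""

    source: str  # packaged fixture name or path to a subject-level CSV
    seed: int
    item_names: tuple[str, ...] = DEFAULT_ITEMS
    group_column: str = "group"
    groupings: dict[str, dict[str, str]] | None = None  # name -> stratum map
    c_min: int = 2
    c_max: int = 4
    n_total: int = 1611
    missing_rate: float = 0.02
    n_starts: int = 20
    max_iter: int = 5000
    mad_tol: float = 1e-8
    alpha: float = 0.05

    def em_config(self, salt: int = 0) -> EMConfig:
        seed = int(np.random.default_rng([self.seed, salt]).integers(2**31))
        return EMConfig(
            seed=seed, n_starts=self.n_starts, max_iter=self.max_iter,
            mad_tol=self.mad_tol,
        )


@dataclass
class ReportBundle:
    """All tables and fits from one run, regenerable from the stored objects."""

    config: AnalysisConfig
    descriptives: pd.DataFrame
    selection: SelectionReport
    grouped_fits: dict[str, FitResult]
    invariance: dict[str, InvarianceResult]
    metadata: dict = field(default_factory=dict)


def read_subject_table(
    path: str | Path,
    item_names: tuple[str, ...] = DEFAULT_ITEMS,
    group_column: str | None = None,
) -> ResponseMatrix:
    """Parse a delimited subject-level table (0/1 items, blank or NA missing)."""
    return ResponseMatrix.read_csv(path, item_names=item_names, group_column=group_column)


def _load_input(config: AnalysisConfig) -> ResponseMatrix:
    if config.source in FIXTURE_NAMES:
        fixture = load_fixture(config.source)
        return simulate(
            fixture,
            GeneratorConfig(
                n_total=config.n_total,
                seed=config.seed,
                missing_rate=config.missing_rate,
            ),
        )
    return read_subject_table(
        config.source, item_names=config.item_names, group_column=config.group_column
    )


def _relabel(data: ResponseMatrix, mapping: dict[str, str]) -> ResponseMatrix:
    out = data.drop_missing_group()
    group = np.array([mapping.get(str(g)) for g in out.group], dtype=object)
    return ResponseMatrix(
        items=out.items, item_names=out.item_names, group=group,
        true_class=out.true_class,
    ).drop_missing_group()


def _descriptives_table(data: ResponseMatrix, alpha: float) -> pd.DataFrame:
    """Per-stratum prevalence of each item with the homogeneity test and
    compact letter display."""
    grouped = data.split_by_group()
    names = list(grouped)
    rows = []
    for j, item in enumerate(data.item_names):
        succ, tot = [], []
        for g in names:
            col = grouped[g].items[:, j]
            obs = col[~np.isnan(col)]
            succ.append(int(obs.sum()))
            tot.append(max(len(obs), 1))
        counts = GroupCounts(tuple(names), np.array(succ), np.array(tot))
        stat, p = homogeneity_test(counts, method="asymptotic")
        letters = pairwise_letter_display(counts, alpha=alpha).formatted()
        row: dict = {"item": item}
        for g, s, t, let in zip(names, succ, tot, letters):
            row[g] = f"{s} ({100 * s / t:.1f}%)^{let}"
        row["chisq"] = stat
        row["p_value"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline, deterministically given the config seed.

    Steps: eliminate records lacking a group label, per-stratum descriptives,
    class enumeration on the pooled data over the candidate range, then per
    grouping variable an invariant-rho multigroup fit and the invariance
    test at the selected number of classes (a single selected C is reused
    for every grouping).
    """
    t0 = time.perf_counter()
    data = _load_input(config)
    if data.group is not None:
        data = data.drop_missing_group()

    descriptives = (
        _descriptives_table(data, config.alpha)
        if data.group is not None
        else pd.DataFrame()
    )

    selection = select_classes(data, config.c_min, config.c_max, config.em_config(salt=1))
    C = selection.selected_C

    groupings = config.groupings
    if groupings is None and data.group is not None:
        levels = set(map(str, data.group_levels()))
        if levels == set(STRATUM_GROUPINGS["gender_age"]):
            groupings = STRATUM_GROUPINGS
        else:
            groupings = {"group": {lvl: lvl for lvl in levels}}
    groupings = groupings or {}

    grouped_fits: dict[str, FitResult] = {}
    invariance: dict[str, InvarianceResult] = {}
    for salt, (name, mapping) in enumerate(groupings.items(), start=2):
        regrouped = _relabel(data, mapping)
        cfg = config.em_config(salt=salt)
        grouped_fits[name] = fit_multigroup(regrouped, C, cfg, rho_invariant=True)
        invariance[name] = invariance_test(regrouped, C, cfg)

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "source": config.source,
        "n_records": int(data.n),
        "selected_C": C,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return ReportBundle(
        config=config,
        descriptives=descriptives,
        selection=selection,
        grouped_fits=grouped_fits,
        invariance=invariance,
        metadata=metadata,
    )


# ------------------------------------------------------------- rendering


def format_probability(p: float) -> str:
    """Two-decimal probability with the "< 0.01" convention for tiny values."""
    if 0 < p < 0.005 or (0 <= p < 0.01 and p != 0):
        return "< 0.01"
    if p == 0:
        return "< 0.01"
    return f"{p:.2f}"


def _params_table(fit: FitResult, class_names: tuple[str, ...]) -> pd.DataFrame:
    """Tabulate a multigroup fit: membership row block then one row per
    item, columns = class (x group when rho is free)."""
    p = fit.params
    rows = []
    for g, gname in enumerate(p.group_names):
        row = {"row": f"membership ({gname})"}
        gp = p.group_params(g)
        for c, cname in enumerate(class_names[: gp.n_classes]):
            row[cname] = f"{100 * gp.gamma[c]:.1f}%"
        rows.append(row)
    item_names = p.item_names or tuple(
        f"item_{j}" for j in range(p.n_items)
    )
    for j, item in enumerate(item_names):
        for g, gname in enumerate(p.group_names):
            gp = p.group_params(g)
            row = {"row": f"{item} ({gname})"}
            for c, cname in enumerate(class_names[: gp.n_classes]):
                row[cname] = format_probability(gp.rho[c, j])
            rows.append(row)
            if p.rho_invariant:
                break  # one shared rho row per item
    return pd.DataFrame(rows)


def render_reports(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write delimited and formatted-text versions of every table.

    Returns the list of files written.  Empty sections are omitted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    class_names = ("minor", "moderate", "major", "class4", "class5", "class6")

    if len(bundle.descriptives):
        path = outdir / "descriptives.csv"
        bundle.descriptives.to_csv(path, index=False)
        written.append(path)

    path = outdir / "selection.json"
    path.write_text(bundle.selection.to_json())
    written.append(path)

    for name, fit in bundle.grouped_fits.items():
        table = _params_table(fit, class_names)
        path = outdir / f"params_{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
        inv = bundle.invariance.get(name)
        txt = table.to_string(index=False)
        if inv is not None:
            txt += (
                f"\n\nInvariance across {name} groups: "
                f"Chi2_dif({inv.df_diff}) = {inv.chisq_diff:.2f}, "
                f"P-value = {inv.p_value:.3f}\n"
            )
        path = outdir / f"params_{name}.txt"
        path.write_text(txt)
        written.append(path)

    meta = dict(bundle.metadata)
    meta["files"] = [p.name for p in written]
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, default=str))
    written.append(path)
    return written
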