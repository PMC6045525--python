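"""Subject-level response data for latent class models of binary symptom items.

The observed data are an ``n x J`` table of binary indicators (pain at each
anatomic site, 0 = no, 1 = yes) with item-level missingness allowed, plus
optional categorical group labels (gender, age band, gender-age stratum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_ITEMS = ("neck", "shoulder", "upper_back", "low_back")

__all__ = ["ResponseMatrix", "DEFAULT_ITEMS"]


@dataclass
class ResponseMatrix:
    """``n x J`` binary items with missing cells, plus optional group labels.

    Parameters
    ----------
    items
        Float array of shape ``(n, J)`` with entries 0.0, 1.0, or NaN (missing).
    item_names
        ``J`` item labels.
    group
        Optional length-``n`` array of categorical group labels; ``None``
        entries mark a missing group label.
    true_class
        Optional hidden 1-based class labels retained by the synthetic
        generator for recovery testing; never used by estimation.
    """

    items: np.ndarray
    item_names: tuple[str, ...] = DEFAULT_ITEMS
    group: np.ndarray | None = None
    true_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        if self.items.ndim != 2:
            raise ValueError("items must be a 2-D array")
        self.item_names = tuple(self.item_names)
        if len(self.item_names) != self.items.shape[1]:
            raise ValueError(
                f"{len(self.item_names)} item names for {self.items.shape[1]} columns"
            )
        observed = self.items[~np.isnan(self.items)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0))]
            raise ValueError(f"non-binary item values present: {np.unique(bad)}")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (self.items.shape[0],):
                raise ValueError("group labels must match the number of records")
        if self.true_class is not None:
            self.true_class = np.asarray(self.true_class)

    @property
    def n(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean observedness mask, True where the cell is non-missing."""
        return ~np.isnan(self.items)

    def complete_rows(self) -> np.ndarray:
        """Boolean index of records with every item observed."""
        return self.mask.all(axis=1)

    def any_observed_rows(self) -> np.ndarray:
        """Boolean index of records with at least one observed item."""
        return self.mask.any(axis=1)

    def group_levels(self) -> list:
        """Distinct non-missing group labels in first-appearance order."""
        if self.group is None:
            raise ValueError("no group labels attached")
        seen: dict = {}
        for g in self.group:
            if g is not None and g == g and g not in seen:  # g==g filters NaN
                seen[g] = None
        return list(seen)

    def drop_missing_group(self) -> "ResponseMatrix":
        """Eliminate records lacking a group label, as grouped fits require."""
        if self.group is None:
            raise ValueError("no group labels attached")
        keep = np.array([g is not None and g == g for g in self.group])
        return self.subset(keep)

    def subset(self, index: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            items=self.items[index],
            item_names=self.item_names,
            group=None if self.group is None else self.group[index],
            true_class=None if self.true_class is None else self.true_class[index],
        )

    def split_by_group(self) -> dict:
        """Mapping group label -> ResponseMatrix of that group's records."""
        data = self.drop_missing_group()
        return {
            lvl: data.subset(np.array([g == lvl for g in data.group]))
            for lvl in data.group_levels()
        }

    # ------------------------------------------------------------------ I/O

    def to_dataframe(self, include_truth: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.items, columns=list(self.item_names))
        # keep 0/1 readable while allowing missing cells
        df = df.astype("Int64")
        if self.group is not None:
            df["group"] = self.group
        if include_truth and self.true_class is not None:
            df["true_class"] = self.true_class
        return df

    def write_csv(self, path: str | Path, include_truth: bool = False) -> None:
        self.to_dataframe(include_truth=include_truth).to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        item_names: tuple[str, ...] = DEFAULT_ITEMS,
        group_column: str | None = None,
    ) -> "ResponseMatrix":
        missing = [c for c in item_names if c not in df.columns]
        if missing:
            raise ValueError(f"missing declared item columns: {missing}")
        items = np.full((len(df), len(item_names)), np.nan)
        for j, name in enumerate(item_names):
            col = pd.to_numeric(df[name], errors="coerce")
            raw = df[name]
            # a value that is neither parseable nor blank/NA is a coding error
            bad = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "") \
                & (raw.astype(str).str.upper() != "NA")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"non-binary value {raw.iloc[row]!r} in column {name!r}, row {row}")
            vals = col.to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.any() and not np.isin(vals[ok], (0.0, 1.0)).all():
                row = int(np.flatnonzero(ok & ~np.isin(vals, (0.0, 1.0)))[0])
                raise ValueError(f"non-binary value {vals[row]} in column {name!r}, row {row}")
            items[:, j] = vals
        group = None
        if group_column is not None:
            if group_column not in df.columns:
                raise ValueError(f"missing group column {group_column!r}")
            group = np.array(
                [None if (pd.isna(g) or str(g).strip() == "") else str(g) for g in df[group_column]],
                dtype=object,
            )
        true_class = df["true_class"].to_numpy() if "true_class" in df.columns else None
        return cls(items=items, item_names=tuple(item_names), group=group, true_class=true_class)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        item_names: tuple[str, ...] = DEFAULT_ITEMS,
        group_column: str | None = None,
    ) -> "ResponseMatrix":
        df = pd.read_csv(path, keep_default_na=True, na_values=["", "NA"])
        return cls.from_dataframe(df, item_names=item_names, group_column=group_column)
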