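"""Pedigree container with validation and topological ordering.

A pedigree record carries an individual id, its mother and father (either may
be unknown), a provenance label, an open-pollinated family label, and an
optional bulk-seed-lot label.  Bulk-lot trees come from provenance seed
collections without family identity: both parents are unknown and they are
treated downstream as unrelated founders with a lot-level random effect.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COLUMNS = ["id", "mother", "father", "provenance", "family", "bulk_lot"]


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (duplicates, cycles, orphans)."""


def _norm(value) -> str | None:
    """Normalise an id-ish cell: '', '0', NA -> None (unknown)."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "0", "NA", "nan", "None"):
        return None
    return s


class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    Parameters
    ----------
    table
        DataFrame with columns id, mother, father, provenance, family,
        bulk_lot.  Unknown parents/labels are empty, "0" or NA.  Rows may be
        in any order; the constructor validates and topologically sorts them.
    """

    def __init__(self, table: pd.DataFrame):
        t = table.copy()
        missing_cols = [c for c in COLUMNS if c not in t.columns]
        if missing_cols:
            raise PedigreeError(f"pedigree table lacks columns: {missing_cols}")
        t = t[COLUMNS].reset_index(drop=True)
        for c in COLUMNS:
            t[c] = [_norm(v) for v in t[c]]
        if t["id"].isna().any():
            raise PedigreeError("pedigree contains a record with empty id")
        dup = t["id"][t["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate pedigree ids: {sorted(set(dup))[:5]}")
        known = set(t["id"])
        for col in ("mother", "father"):
            bad = [
                (i, p) for i, p in zip(t["id"], t[col])
                if p is not None and p not in known
            ]
            if bad:
                raise PedigreeError(
                    f"record {bad[0][0]!r} references unknown {col} {bad[0][1]!r}"
                )
        bulk_bad = t[(t["bulk_lot"].notna())
                     & (t["mother"].notna() | t["father"].notna())]
        if len(bulk_bad):
            raise PedigreeError(
                f"bulk-lot record {bulk_bad['id'].iloc[0]!r} has a known parent"
            )
        self.table = self._toposort(t)
        self._index = {i: k for k, i in enumerate(self.table["id"])}

    @staticmethod
    def _toposort(t: pd.DataFrame) -> pd.DataFrame:
        order: list[int] = []
        placed: set[str] = set()
        pending = list(t.index)
        while pending:
            progressed = False
            nxt = []
            for row in pending:
                m, f = t.at[row, "mother"], t.at[row, "father"]
                if (m is None or m in placed) and (f is None or f in placed):
                    order.append(row)
                    placed.add(t.at[row, "id"])
                    progressed = True
                else:
                    nxt.append(row)
            if not progressed:
                cyc = [t.at[r, "id"] for r in nxt[:6]]
                raise PedigreeError(
                    f"pedigree contains a cycle involving ids {cyc}"
                )
            pending = nxt
        return t.loc[order].reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self._index[i] for i in ids], dtype=int)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer indices of mother and father per record; -1 = unknown."""
        m = np.array(
            [self._index[p] if p is not None else -1 for p in self.table["mother"]],
            dtype=int,
        )
        f = np.array(
            [self._index[p] if p is not None else -1 for p in self.table["father"]],
            dtype=int,
        )
        return m, f

    @property
    def is_bulk(self) -> np.ndarray:
        return self.table["bulk_lot"].notna().to_numpy()

    @property
    def provenance(self) -> pd.Series:
        return self.table["provenance"]

    @property
    def family(self) -> pd.Series:
        return self.table["family"]

    @property
    def bulk_lot(self) -> pd.Series:
        return self.table["bulk_lot"]

    def founders(self) -> list[str]:
        t = self.table
        mask = t["mother"].isna() & t["father"].isna()
        return list(t.loc[mask, "id"])

    def with_family(self, ids: Sequence[str], new_families: Sequence[str],
                    new_mothers: Sequence[str] | None = None) -> "Pedigree":
        """Copy with family labels (and optionally mothers) of `ids` replaced
        — the reassignment step of pedigree correction."""
        t = self.table.copy()
        pos = self.index_of(ids)
        t.loc[pos, "family"] = list(new_families)
        if new_mothers is not None:
            t.loc[pos, "mother"] = list(new_mothers)
        return Pedigree(t)

    def drop(self, ids: Iterable[str]) -> "Pedigree":
        """Copy with `ids` removed; fails if a removed id is someone's parent."""
        drop = set(ids)
        t = self.table
        used = set(t["mother"].dropna()) | set(t["father"].dropna())
        conflict = drop & used
        if conflict:
            raise PedigreeError(
                f"cannot drop ids still referenced as parents: {sorted(conflict)[:5]}"
            )
        return Pedigree(t[~t["id"].isin(drop)])

    def __repr__(self) -> str:  # pragma: no cover
        nb = int(self.is_bulk.sum())
        return (f"Pedigree(n={len(self)}, founders={len(self.founders())}, "
                f"bulk={nb})")
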