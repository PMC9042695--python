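"""Hypergeometric over-representation analysis against GMT gene-set collections.

A query gene list (a DEG set or a perturbation category) is tested
against each named set of a collection: with a universe of N genes, m of
which belong to the set, and a query of n genes overlapping it in k, the
one-sided upper-tail p is P(X >= k) for X ~ Hypergeometric(N, m, n).
BH-adjusted FDRs are computed across the tested sets.  A three-way
provenance labelling compares enrichments across the three contrasts of
the study design (significant in a vs-NT contrast, in both, or only in
the λ4-vs-λ3 contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_p",
    "run_ora",
    "compare_contrast_enrichments",
]


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = set(members)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{collection.descriptions.get(name, '')}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_p(k: int, m: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n).

    k: overlap, m: set size within the universe, n: query size, N:
    universe size.
    """
    if not (0 <= k <= min(m, n) <= N) or m > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds k={k}, m={m}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def run_ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Test every collection set against the query; BH-adjust across sets.

    Sets are restricted to the universe; only sets whose universe-restricted
    size is positive and whose overlap with the query reaches
    ``min_overlap`` are reported.  Rows are ordered by p-value with the
    set name as tiebreak.
    """
    q = set(query)
    u = set(universe)
    if not q <= u:
        extra = sorted(q - u)[:5]
        raise ValueError(f"query is not a subset of the universe (e.g. {extra})")

    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & u
        m = len(members)
        if m == 0:
            continue
        k = len(members & q)
        if k < min_overlap:
            continue
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "overlap": k,
                "set_size": m,
                "query_size": len(q),
                "universe_size": len(u),
                "p_value": hypergeom_p(k, m, len(q), len(u)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set", "description", "overlap", "set_size",
                "query_size", "universe_size", "p_value", "fdr",
            ]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "set"], kind="mergesort").reset_index(drop=True)


def compare_contrast_enrichments(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    rows_c: pd.DataFrame,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Label sets significant anywhere by their contrast provenance.

    a / b are the two vs-NT contrasts, c the λ4-vs-λ3 contrast.  A set
    significant (FDR < fdr_thresh) in both a and b is "both"; in a or b
    (but not both) is "A-or-B"; significant only in c is "unique-to-C".
    """
    def sig_sets(rows: pd.DataFrame) -> set[str]:
        if rows.empty:
            return set()
        return set(rows.loc[rows["fdr"] < fdr_thresh, "set"])

    universes = {
        int(u) for r in (rows_a, rows_b, rows_c) if not r.empty
        for u in r["universe_size"].unique()
    }
    if len(universes) > 1:
        raise ValueError(
            f"enrichment results come from mismatched universes: {sorted(universes)}"
        )

    in_a, in_b, in_c = sig_sets(rows_a), sig_sets(rows_b), sig_sets(rows_c)
    records = []
    for name in sorted(in_a | in_b | in_c):
        if name in in_a and name in in_b:
            label = "both"
        elif name in in_a or name in in_b:
            label = "A-or-B"
        else:
            label = "unique-to-C"
        records.append({"set": name, "label": label})
    return pd.DataFrame(records, columns=["set", "label"])
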