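"""Hypergeometric gene-set over-representation with BH FDR control.

Used for asking whether a query gene list (CNV genes, miRNA target sets)
is over-represented in named sets (pathways, a disease gene list) drawn
from a common gene universe (the background annotation package in the
original analyses).  The test is the upper tail P(X >= k) of the
hypergeometric distribution; multiple sets are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from cghcnv.errors import CghCnvError, StructuralError


def hypergeom_overrep(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail p-value P(X >= k), X ~ Hypergeometric(N, K, n).

    N: universe size, K: set size, n: query size, k: overlap.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and min(N, K, n) >= 0):
        raise CghCnvError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CghCnvError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneSetCollection:
    """A gene universe plus named gene-id sets restricted to it."""

    universe: set[str]
    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise CghCnvError("empty gene universe")
        if len(self.sets) != len(set(self.sets)):
            raise StructuralError("duplicate set names")
        self.sets = {name: set(s) & self.universe for name, s in self.sets.items()}

    def combine(self, names: list[str], new_name: str) -> None:
        """Union several sets under one name (e.g. the target sets of the
        mature forms of one miRNA, combined before testing)."""
        union: set[str] = set()
        for name in names:
            union |= self.sets[name]
        for name in names:
            del self.sets[name]
        self.sets[new_name] = union

    # ------------------------------------------------------------- GMT I/O

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("universe\tall background genes\t" + "\t".join(sorted(self.universe)) + "\n")
            for name in self.sets:
                fh.write(f"{name}\tna\t" + "\t".join(sorted(self.sets[name])) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        universe: set[str] = set()
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, _desc, *members = parts
                if name == "universe":
                    universe = set(members)
                else:
                    sets[name] = set(members)
        if not universe:
            universe = set().union(*sets.values()) if sets else set()
        return cls(universe=universe, sets=sets)

    @classmethod
    def read_two_column_tsv(
        cls, path: str | Path, universe: set[str] | None = None
    ) -> "GeneSetCollection":
        """Read (set_name, gene_id) pairs; universe defaults to all genes seen."""
        df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene_id"],
                         dtype=str, comment="#")
        sets: dict[str, set[str]] = {}
        for name, sub in df.groupby("set_name"):
            sets[str(name)] = set(sub["gene_id"])
        if universe is None:
            universe = set(df["gene_id"])
        return cls(universe=universe, sets=sets)


def enrich_sets(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in every named set.

    Query genes outside the universe are dropped with a warning.  Returns
    one row per set: set_name, N, K, n, k, p_value, fdr, sorted by fdr
    then p.
    """
    query = set(query)
    dropped = query - collection.universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside universe dropped", stacklevel=2)
    query &= collection.universe
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        rows.append((name, N, K, n, k, hypergeom_overrep(N, K, n, k)))
    out = pd.DataFrame(rows, columns=["set_name", "N", "K", "n", "k", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["fdr", "p_value", "set_name"]).reset_index(drop=True)
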