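"""Hypergeometric gene-set over-representation with BH control.

For a query list of n genes and a gene set with K members in a universe of
N genes, the overlap k is scored with the hypergeometric upper tail
P(X ≥ k) (computed in log space). p-values are adjusted across all tested
sets by Benjamini–Hochberg; sets passing the FDR cut (default 0.01) are
ranked by fold enrichment (k/n)/(K/N). The default universe size of 42 739
is the MSigDB mouse gene total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
]

#: MSigDB mouse total gene count, the default over-representation universe.
DEFAULT_UNIVERSE_SIZE = 42739


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (as read from GMT) plus per-set descriptions."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str]

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene set(s): {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members... per tab-separated line).

    Duplicate members within a set are deduplicated with a warning;
    duplicate set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = frozenset(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has duplicate members; "
                    "deduplicated", stacklevel=2)
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Evaluated via the log survival function for numerical stability in the
    far tail.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap statistics for one gene set."""

    set_name: str
    k: int  # overlap
    n: int  # query size (within universe)
    K: int  # set size (within universe)
    N: int  # universe size
    p: float
    q: float
    fold_enrichment: float


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    fdr: float = 0.01,
    *,
    universe: Iterable[str] | None = None,
    significant_only: bool = True,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in every set of ``collection``.

    Parameters
    ----------
    query
        Gene symbols of interest.
    universe_size
        Total genes N when only a size constant is known (default: the
        MSigDB mouse total, 42 739). Ignored when ``universe`` is given.
    universe
        Explicit universe gene list; memberships and the query are then
        intersected with it and N is its cardinality.
    fdr
        BH threshold; with ``significant_only`` (default) only sets with
        q ≤ fdr are returned.

    Returns
    -------
    list of EnrichmentResult
        Ranked by descending fold enrichment, then ascending p, then name.
    """
    query_set = frozenset(str(g) for g in query)
    if not query_set:
        raise ValueError("empty query gene list")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")

    if universe is not None:
        universe_set = frozenset(str(g) for g in universe)
        N = len(universe_set)
        query_set = query_set & universe_set
        restrict = lambda s: s & universe_set
    else:
        N = int(universe_size)
        membership_union = collection.all_members() | query_set
        if N < len(membership_union):
            raise ValueError(
                f"universe_size={N} smaller than the {len(membership_union)} "
                "distinct symbols observed")
        restrict = lambda s: s

    n = len(query_set)
    if n == 0:
        raise ValueError("query has no genes inside the universe")

    names = sorted(collection.sets)
    rows = []
    for name in names:
        members = restrict(collection.sets[name])
        K = len(members)
        k = len(query_set & members)
        p = hypergeom_upper_tail(k, n, K, N) if K else 1.0
        fe = (k / n) / (K / N) if K else 0.0
        rows.append((name, k, K, p, fe))

    qvals = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(set_name=name, k=k, n=n, K=K, N=N, p=p,
                         q=float(qv), fold_enrichment=fe)
        for (name, k, K, p, fe), qv in zip(rows, qvals)
    ]
    if significant_only:
        results = [r for r in results if r.q <= fdr]
    results.sort(key=lambda r: (-r.fold_enrichment, r.p, r.set_name))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["set_name", "k", "K", "n", "N", "p", "q", "fold_enrichment"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols)
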