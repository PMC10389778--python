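"""Hypergeometric gene-set enrichment with Bonferroni adjustment.

Given a query gene list (e.g. the stimulation-induced or the
dependent genes), a collection of signature gene sets (GMT format) and
a universe, the enrichment p-value for a set of size K is the upper
hypergeometric tail

    p = P(X >= k) = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, n the query size and k the overlap, all
computed after intersecting query and sets with the universe.  p-values
are Bonferroni-adjusted across the sets actually tested, matching the
convention of reporting Bonferroni-adjusted hypergeometric p-values for
signature enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ("set_name", "N", "K", "n", "k", "p_value", "bonferroni_p")


@dataclass(frozen=True)
class GeneSet:
    """A named signature: unique member gene ids plus a free-text description."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if k < 0:
        raise ValueError(f"overlap k must be >= 0, got {k}")
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test every set in the collection against the query.

    Query genes and set members outside the universe are dropped (the
    drop count is logged and stored in ``attrs["n_query_outside"]``).
    Results are sorted by p-value, ties broken by set name; the
    Bonferroni factor is the number of sets tested.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    names = [gs.name for gs in collection]
    if len(set(names)) != len(names):
        raise ValueError("gene-set names must be unique within a collection")

    query_list = set(query)
    query_in = query_list & universe_set
    n_outside = len(query_list) - len(query_in)
    if n_outside:
        log.warning("%d query genes outside the universe were dropped", n_outside)

    N = len(universe_set)
    n = len(query_in)
    m = len(collection)
    rows = []
    for gs in collection:
        members = gs.members & universe_set
        K = len(members)
        k = len(members & query_in)
        p = hypergeom_upper_tail(k, N, K, n) if n else 1.0
        rows.append((gs.name, N, K, n, k, p, min(1.0, m * p)))
    result = pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS))
    result = result.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    result.attrs["n_query_outside"] = n_outside
    if not query_in:
        result = result.iloc[0:0]
        result.attrs["n_query_outside"] = n_outside
    return result


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a Broad-style GMT file (name TAB description TAB member...)."""
    sets: list[GeneSet] = []
    names_seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected name, description and >=1 member")
            name, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                log.warning("%s: line %d: %d duplicate members collapsed", path, lineno, len(members) - len(unique))
            if name in names_seen:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            names_seen.add(name)
            sets.append(GeneSet(name=name, description=description, members=frozenset(unique)))
    return sets


def write_gmt(collection: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in collection:
            members = "\t".join(sorted(gs.members))
            handle.write(f"{gs.name}\t{gs.description}\t{members}\n")


def write_enrichment_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.loc[:, list(ENRICHMENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")
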