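"""Gene-set over-representation of candidate genes.

Candidates from the screen are tested against user-supplied gene sets (GMT)
with the hypergeometric upper tail: for a universe of N genes containing K
members of a set, drawing n hits, the p-value is P(X >= k) where k is the
observed overlap.  The universe defaults to the genes the library actually
interrogates — a kinome screen should never be tested against a genome-wide
background, which inflates significance.  Rows are flagged at unadjusted
p < alpha (the screen-literature convention) and at Benjamini-Hochberg
q < alpha; both are reported so the difference is visible.

``export_network`` writes node/edge tables (edges weighted by the Jaccard
index of overlap gene lists) loadable by standard network viewers, in the
style of enrichment-map figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_upper",
    "enrich",
    "export_network",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with upper-cased symbols; no set may be empty."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], source: str = ""
    ) -> "GeneSetCollection":
        return cls(
            sets={
                name: frozenset(g.strip().upper() for g in members)
                for name, members in sets.items()
            },
            source=source,
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            members = frozenset(
                g.strip().upper() for g in fields[2:] if g.strip()
            )
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(
            f"overlap k={k} outside [{max(0, n + K - N)}, {min(n, K)}] "
            f"for K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    gsc: GeneSetCollection,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    Hits outside the universe are dropped with a warning.  One row per gene
    set with at least one universe member; BH q-values are computed across
    the tested sets.  ``significant_p`` uses the unadjusted threshold,
    ``significant_q`` the BH-adjusted one.
    """
    universe_set = {g.strip().upper() for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    hit_set = {g.strip().upper() for g in hits}
    outside = hit_set - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} hit gene(s) not in universe dropped: "
            f"{sorted(outside)[:10]}",
            stacklevel=2,
        )
        hit_set &= universe_set

    N = len(universe_set)
    n = len(hit_set)
    rows = []
    for name, members in gsc.sets.items():
        in_universe = members & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        overlap = sorted(hit_set & in_universe)
        k = len(overlap)
        rows.append(
            {
                "set": name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": hypergeom_upper(k, K, n, N),
                "overlap": ",".join(overlap),
            }
        )
    result = pd.DataFrame(
        rows, columns=["set", "N", "K", "n", "k", "p", "overlap"]
    )
    if len(result):
        _, q, _, _ = multipletests(result["p"].to_numpy(), method="fdr_bh")
        result["q"] = np.maximum(q, result["p"])  # guard fp round-off; q >= p
        result["significant_p"] = result["p"] < alpha
        result["significant_q"] = result["q"] < alpha
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant_p"] = pd.Series(dtype=bool)
        result["significant_q"] = pd.Series(dtype=bool)
    return result[
        ["set", "N", "K", "n", "k", "p", "q", "significant_p", "significant_q",
         "overlap"]
    ]


def _jaccard(a: set[str], b: set[str]) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def export_network(
    results: pd.DataFrame,
    outdir: str | Path | None = None,
    edge_threshold: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for an enrichment map.

    Nodes: one per tested set with its overlap size and p/q.  Edges: pairs of
    sets whose overlap gene lists have Jaccard index >= ``edge_threshold``.
    If ``outdir`` is given, writes ``em_nodes.tsv`` and ``em_edges.tsv``.
    """
    nodes = results[["set", "k", "p", "q"]].copy()
    overlaps = {
        row.set: set(row.overlap.split(",")) if row.overlap else set()
        for row in results.itertuples(index=False)
    }
    names = list(overlaps)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            w = _jaccard(overlaps[a], overlaps[b])
            if w >= edge_threshold and w > 0:
                edges.append({"set_i": a, "set_j": b, "jaccard": w})
    edge_df = pd.DataFrame(edges, columns=["set_i", "set_j", "jaccard"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nodes.to_csv(outdir / "em_nodes.tsv", sep="\t", index=False,
                     float_format="%.6g", lineterminator="\n")
        edge_df.to_csv(outdir / "em_edges.tsv", sep="\t", index=False,
                       float_format="%.6g", lineterminator="\n")
    return nodes, edge_df
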