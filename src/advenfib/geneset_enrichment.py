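"""Cross-species gene-set mapping and hypergeometric overlap testing.

Trajectory gene sets derived in mouse are translated to human symbols via
a static ortholog table (rows with one-to-many or many-to-one mappings are
dropped entirely so the map stays bijective), then tested for overlap with
a target list — e.g. GWAS coronary-artery-disease genes — inside an
explicit gene universe.  Significance is the upper hypergeometric tail
P(X >= k) for drawing n query genes from a universe of N containing K
targets and observing k in the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OrthologMap:
    """Validated one-to-one mouse -> human symbol map.

    Built from a two-column table; every mouse or human symbol appearing
    in more than one row is ambiguous and all its rows are dropped, with
    counts recorded.
    """

    mapping: dict[str, str]
    n_ambiguous_dropped: int

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "OrthologMap":
        if table.empty:
            raise ValueError("empty ortholog table")
        cols = {"mouse_symbol", "human_symbol"}
        if not cols.issubset(table.columns):
            raise ValueError(f"ortholog table needs columns {sorted(cols)}")
        t = table[["mouse_symbol", "human_symbol"]].drop_duplicates()
        mouse_multi = t["mouse_symbol"].duplicated(keep=False)
        human_multi = t["human_symbol"].duplicated(keep=False)
        bad = mouse_multi | human_multi
        kept = t[~bad]
        return cls(
            mapping=dict(zip(kept["mouse_symbol"], kept["human_symbol"])),
            n_ambiguous_dropped=int(bad.sum()),
        )

    @property
    def ambiguous_mouse(self) -> set[str]:
        return set()  # ambiguity already resolved at construction


@dataclass
class MappingReport:
    mapped: list[str]
    unmapped: list[str]


def map_orthologs(genes, omap: OrthologMap) -> MappingReport:
    """Translate mouse symbols through a validated one-to-one map.

    Output is deduplicated, input order preserved; genes without a
    (unambiguous) map entry land in the ``unmapped`` bucket.
    """
    if not omap.mapping:
        raise ValueError("ortholog map is empty after ambiguity filtering")
    mapped, unmapped, seen = [], [], set()
    for g in genes:
        h = omap.mapping.get(g)
        if h is None:
            unmapped.append(g)
        elif h not in seen:
            seen.add(h)
            mapped.append(h)
    return MappingReport(mapped=mapped, unmapped=unmapped)


@dataclass(frozen=True)
class HypergeomResult:
    """Upper-tail hypergeometric overlap test.

    N genes in the universe, K of them targets, n in the query set, k in
    the overlap; ``p_value`` = P(X >= k), ``fold_enrichment`` =
    (k/n)/(K/N).
    """

    N: int
    K: int
    n: int
    k: int
    p_value: float
    fold_enrichment: float


def hypergeometric_test(k: int, K: int, n: int, N: int) -> HypergeomResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space
    via the survival function for numerical stability."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"overlap k={k} outside feasible range "
            f"[{max(0, K + n - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return HypergeomResult(N=N, K=K, n=n, k=k, p_value=p, fold_enrichment=fold)


def enrich_trajectory(
    trajectory_genes,
    target_list,
    universe,
    omap: OrthologMap | None = None,
) -> HypergeomResult:
    """Overlap test of a trajectory gene set against a target list.

    The trajectory set is ortholog-mapped first when a map is given; both
    sets are then restricted to the universe before counting N, K, n, k.
    An empty trajectory-universe intersection is an error (nothing to
    test), an empty target intersection is a legitimate k=0 outcome.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = list(trajectory_genes)
    if omap is not None:
        query = map_orthologs(query, omap).mapped
    q = set(query) & uni
    if not q:
        raise ValueError("trajectory gene set does not intersect the universe")
    t = set(target_list) & uni
    return hypergeometric_test(k=len(q & t), K=len(t), n=len(q), N=len(uni))
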