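"""Binomial over-representation of gene sets among top-correlated genes.

The top-k genes by |r| (default k = 1000) from a target's correlation
table form the *pool*. For each annotation set, ``found`` is the number of
set members in the pool and ``mu`` the per-gene background rate — the
fraction of the whole analyzable universe carrying the annotation. The
p-value is the binomial upper tail

    p = P(X > found),  X ~ Binomial(k, mu),

i.e. one minus the CDF *at* found (deliberately P(X > n), not
P(X >= n) — the published convention, kept as-is). The ``expected``
column is the smallest count that would reach p < 0.05 at that mu, a
reader's yardstick for how far above background a found count sits.

No multiplicity correction is applied by default (rows are sorted by raw
binomial p); a BH q column is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CorrelationTable, GeneSetCollection
from .cytoband import top_k_by_abs_r
from .enrichment import benjamini_hochberg
from .errors import SizeError

DEFAULT_POOL_SIZE = 1000
DEFAULT_ALPHA = 0.05


def top_pool(table: CorrelationTable, k: int = DEFAULT_POOL_SIZE) -> set[str]:
    """The k genes with the highest |r| (lexicographic tie-break)."""
    return set(top_k_by_abs_r(table, k))


def set_frequency_mu(
    collection: GeneSetCollection, universe: set[str]
) -> dict[str, float]:
    """Background rate of each set: |members ∩ universe| / |universe|.

    Each gene counts once per set (set semantics). A set disjoint from the
    universe gets mu = 0, which downstream flags rather than tests.
    """
    if not universe:
        raise SizeError("universe is empty")
    universe = set(universe)
    n = len(universe)
    return {
        set_id: len(collection[set_id].members & universe) / n
        for set_id in collection
    }


def binomial_tail_p(found: int, pool_size: int = DEFAULT_POOL_SIZE, mu: float = 0.0) -> float:
    """Upper-tail binomial p = P(X > found), X ~ Binomial(pool_size, mu)."""
    if not 0 <= found <= pool_size:
        raise ValueError(f"found={found} outside [0, {pool_size}]")
    if not 0 <= mu <= 1:
        raise ValueError(f"mu={mu} outside [0, 1]")
    return float(stats.binom.sf(found, pool_size, mu))


def expected_min_count(
    mu: float, pool_size: int = DEFAULT_POOL_SIZE, alpha: float = DEFAULT_ALPHA
) -> int:
    """Smallest count n with binomial_tail_p(n, pool_size, mu) < alpha."""
    if not 0 < mu < 1:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    counts = np.arange(0, pool_size + 1)
    tail = stats.binom.sf(counts, pool_size, mu)
    below = np.flatnonzero(tail < alpha)
    return int(counts[below[0]])


def ora_table(
    table: CorrelationTable,
    collection: GeneSetCollection,
    k: int = DEFAULT_POOL_SIZE,
    add_bh_q: bool = False,
) -> pd.DataFrame:
    """Over-representation of every set among the top-k |r| genes.

    The universe is the correlation table's own gene list (the target is
    excluded by construction). Returns one row per set — columns rank,
    set_id, name, found, expected, p, mu — stably sorted by (p, set_id).
    Sets disjoint from the universe carry mu = 0, p = NaN and expected
    NaN (flagged, not tested). ``add_bh_q`` appends a BH q column over the
    tested sets.
    """
    universe = set(table.features)
    pool = top_pool(table, k)
    mu_by_set = set_frequency_mu(collection, universe)
    rows = []
    for set_id in collection:
        gene_set = collection[set_id]
        mu = mu_by_set[set_id]
        found = len(gene_set.members & pool)
        if mu == 0:
            p, expected = float("nan"), float("nan")
        else:
            p = binomial_tail_p(found, k, mu)
            expected = expected_min_count(mu, k) if mu < 1 else float("nan")
        rows.append(
            {
                "set_id": set_id,
                "name": gene_set.name,
                "found": found,
                "expected": expected,
                "p": p,
                "mu": mu,
            }
        )
    result = pd.DataFrame(rows)
    result = result.sort_values(
        ["p", "set_id"], ascending=[True, True], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    if add_bh_q:
        tested = result["p"].notna()
        q = np.full(len(result), np.nan)
        q[tested.to_numpy()] = benjamini_hochberg(result.loc[tested, "p"].to_numpy())
        result["q"] = q
    result.insert(0, "rank", np.arange(1, len(result) + 1))
    return result
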