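"""Chromosomal cis-effect enrichment around a target gene's TSS.

For a target gene, the *hit pool* Gi collects the genes whose TSS lies
within a window (default 1 Mbp, closed interval on |ΔTSS|) of the target's
TSS on the same chromosome; the *null pool* Go collects the remaining
same-chromosome genes. The target's correlation ranking (its own r = 1 row
removed) is walked with the running-sum enrichment score of Gi; the null
is the ES of Nh = |Gi| genes drawn without replacement from Go, repeated
``n_perm`` times, and the p-value is the one-sided upper tail of a normal
fitted to that null. A genome-wide scan repeats the test with every
annotated gene as target and applies Benjamini–Hochberg FDR across
probes.

A large ES here says the target's strongest co-expression partners are
disproportionately its physical chromosomal neighbours — the signature of
a dominant cis effect (e.g. co-amplification) rather than shared function.
Strand is ignored for the TSS distance and coordinates are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CorrelationTable, ExpressionMatrix
from .correlation import build_correlation_table
from .enrichment import (
    RankedList,
    _as_rng,
    benjamini_hochberg,
    permutation_null,
    rank_by_correlation,
    running_score,
    set_p_value,
)
from .errors import (
    DegenerateWindowError,
    InsufficientNullPoolError,
    MissingFeatureError,
)

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class CisPools:
    """Hit pool (gi, within the window) and null pool (go, same chromosome
    outside the window) around one target gene."""

    target: str
    gi: frozenset[str]
    go: frozenset[str]

    @property
    def nh(self) -> int:
        return len(self.gi)


@dataclass(frozen=True)
class CisEnrichmentResult:
    target: str
    nh: int
    es: float
    null_mean: float
    null_sd: float
    p: float
    q: float = float("nan")


def build_cis_pools(
    annotations: pd.DataFrame,
    target: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    universe=None,
) -> CisPools:
    """Split the target's chromosome into window (gi) and control (go) pools.

    ``universe`` restricts both pools to the genes actually present in the
    correlation ranking (filtered matrix); pass the correlation table's
    feature set. The window is closed: |TSS - target TSS| <= window_bp.
    """
    ann = annotations.set_index("gene")
    if target not in ann.index:
        raise MissingFeatureError(f"target {target!r} not annotated")
    chrom = ann.at[target, "chromosome"]
    tss = int(ann.at[target, "tss_bp"])
    same = annotations[
        (annotations["chromosome"] == chrom) & (annotations["gene"] != target)
    ]
    if universe is not None:
        universe = set(universe)
        same = same[same["gene"].isin(universe)]
    near = (same["tss_bp"] - tss).abs() <= window_bp
    gi = frozenset(same.loc[near, "gene"])
    go = frozenset(same.loc[~near, "gene"])
    if not gi:
        raise DegenerateWindowError(
            f"no gene within {window_bp} bp of {target!r} on chromosome {chrom}"
        )
    if len(go) < len(gi):
        raise InsufficientNullPoolError(
            f"null pool ({len(go)}) smaller than hit pool ({len(gi)}) for {target!r}"
        )
    return CisPools(target=target, gi=gi, go=go)


def _go_positions(ranked: RankedList, go: frozenset[str]) -> np.ndarray:
    mask = np.fromiter((f in go for f in ranked.features), dtype=bool, count=len(ranked))
    return np.flatnonzero(mask)


def cis_es_test(
    table: CorrelationTable,
    pools: CisPools,
    n_perm: int = 1000,
    seed=0,
    weight_exponent: float = 1.0,
    direction: str = "r_desc",
    mode: str = "normal_approx",
) -> CisEnrichmentResult:
    """Enrichment of the cis window genes in the target's own ranking.

    The null draws Nh genes from the same-chromosome outside-window pool
    Go only, so chromosome-wide expression trends cancel and the test is
    specific to the window.
    """
    if table.target_id != pools.target:
        raise ValueError(
            f"table target {table.target_id!r} != pools target {pools.target!r}"
        )
    ranked = rank_by_correlation(table, direction)
    score = running_score(ranked, pools.gi, weight_exponent)
    pool_positions = _go_positions(ranked, pools.go)
    null_mean, null_sd, samples = permutation_null(
        ranked,
        score.nh,
        n_perm=n_perm,
        seed=seed,
        weight_exponent=weight_exponent,
        pool_positions=pool_positions,
    )
    p = set_p_value(score.es, null_mean, null_sd, mode=mode, null_samples=samples)
    return CisEnrichmentResult(
        target=pools.target,
        nh=score.nh,
        es=score.es,
        null_mean=null_mean,
        null_sd=null_sd,
        p=p,
    )


def genomewide_cis_scan(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    n_perm: int = 1000,
    seed=0,
    probe_genes: list[str] | None = None,
    weight_exponent: float = 1.0,
    direction: str = "r_desc",
    mode: str = "normal_approx",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the cis test with every annotated gene as target.

    Each probe gets its own correlation ranking (built on the fly from the
    matrix) and pools; Benjamini–Hochberg q is computed across all probes
    that could be tested. Probes whose pools are degenerate (empty window,
    null pool smaller than the window pool, missing from the matrix,
    constant expression) are reported in the second returned frame with
    the reason — never silently dropped.

    Cost is O(G^2 * S) over the probe list; pass ``probe_genes`` to
    subset.
    """
    present = set(matrix.feature_ids)
    if probe_genes is None:
        probe_genes = [g for g in annotations["gene"] if g in present]
    rng = _as_rng(seed)
    rows: list[dict] = []
    skipped: list[dict] = []
    for probe in probe_genes:
        try:
            table = build_correlation_table(matrix, probe, sort="unsorted")
            pools = build_cis_pools(
                annotations, probe, window_bp=window_bp,
                universe=table.features,
            )
            res = cis_es_test(
                table,
                pools,
                n_perm=n_perm,
                seed=rng,
                weight_exponent=weight_exponent,
                direction=direction,
                mode=mode,
            )
        except Exception as exc:  # noqa: BLE001 - each probe reports its failure
            skipped.append({"target": probe, "reason": str(exc)})
            continue
        rows.append(
            {
                "target": res.target,
                "nh": res.nh,
                "es": res.es,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "p": res.p,
            }
        )
    results = pd.DataFrame(rows)
    if len(results):
        results["q"] = benjamini_hochberg(results["p"].to_numpy())
    if skipped:
        log.info("genomewide_cis_scan: %d probes skipped", len(skipped))
    return results, pd.DataFrame(skipped, columns=["target", "reason"])
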