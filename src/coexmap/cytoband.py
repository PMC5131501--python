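"""Cytoband string parsing and chromosome-position point sets.

A cytoband label ``ApB.N`` / ``AqB.N`` (chromosome A, arm p/q, band B.N)
maps to the scalar plot coordinate ``A - B.N/100`` (p arm) or
``A + B.N/100`` (q arm): ``8p11.2`` -> 7.888, ``8q11.2`` -> 8.112. X and Y
map to chromosome number 23 and share one axis column. The coordinate is
monotone within an arm — larger band numbers land strictly farther from
the chromosome integer — which places each point on the correct side of
its centromere on a 1-D axis.

Caveat of the formula as written: multi-digit sub-bands use the full
decimal, so ``12p13.31`` -> 12 - 13.31/100 = 11.8669, which sorts 13.31
*past* 13.9 within the arm. This matches the published conversion and is
accepted as a plotting convention, not a genomic ordering.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .containers import CorrelationTable
from .errors import FormatError, MissingFeatureError, SizeError

_CYTOBAND_RE = re.compile(
    r"^(?P<chrom>\d{1,2}|XY|X|Y)(?P<arm>[pq])(?P<band>\d+(?:\.\d+)?)$"
)

#: Numeric axis code for the combined X/Y column.
XY_CODE = 23


def cytoband_to_float(band: str) -> float:
    """Convert a cytoband string to its scalar plot coordinate.

    Bands without a sub-band decimal ("8q13") are read as B.N = 13, giving
    8.13. Raises :class:`FormatError` echoing any unparseable input.
    """
    m = _CYTOBAND_RE.match(band.strip())
    if m is None:
        raise FormatError(f"unparseable cytoband string: {band!r}")
    chrom_label = m.group("chrom")
    chrom = XY_CODE if chrom_label in ("X", "Y", "XY") else int(chrom_label)
    if chrom < 1 or chrom > 23:
        raise FormatError(f"chromosome out of range in cytoband: {band!r}")
    offset = float(m.group("band")) / 100.0
    return chrom - offset if m.group("arm") == "p" else chrom + offset


def top_k_by_abs_r(table: CorrelationTable, k: int = 500) -> list[str]:
    """The k features with the largest |r|, lexicographic tie-break."""
    if k > table.n_rows:
        raise SizeError(f"k={k} exceeds table size {table.n_rows}")
    if k < 1:
        raise SizeError("k must be >= 1")
    frame = table.frame
    order = (
        frame.assign(_abs=frame["r"].abs())
        .sort_values(["_abs", "feature"], ascending=[False, True], kind="mergesort")
    )
    return list(order["feature"].iloc[:k])


def build_cytoband_points(
    table: CorrelationTable,
    annotations: pd.DataFrame,
    k: int = 500,
    signed: bool = True,
) -> pd.DataFrame:
    """Chromosome-coordinate points for the top-k |r| genes.

    Returns a plot-ready DataFrame with columns ``feature``, ``cytoband``,
    ``chrom_float``, ``r`` (signed r by default; ``signed=False`` plots
    |r|). Every top-k gene must be annotated.
    """
    top = top_k_by_abs_r(table, k)
    ann = annotations.set_index("gene")
    missing = [g for g in top if g not in ann.index]
    if missing:
        raise MissingFeatureError(f"no annotation for gene {missing[0]!r}")
    r_by_gene = table.frame.set_index("feature")["r"]
    rows = []
    for g in top:
        band = ann.at[g, "cytoband"]
        r = float(r_by_gene[g])
        rows.append(
            {
                "feature": g,
                "cytoband": band,
                "chrom_float": cytoband_to_float(band),
                "r": r if signed else abs(r),
            }
        )
    return pd.DataFrame(rows)


def plot_cytoband_points(points: pd.DataFrame, path: str) -> None:
    """Minimal scatter of (chrom_float, r) for a cytoband point set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.scatter(points["chrom_float"], points["r"], s=8, alpha=0.6)
    max_chrom = int(np.ceil(points["chrom_float"].max()))
    ax.set_xticks(range(1, max_chrom + 1))
    ax.set_xlabel("chromosome (cytoband coordinate)")
    ax.set_ylabel("r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
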