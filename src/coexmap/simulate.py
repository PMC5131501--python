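"""Synthetic paired normal/tumor expression studies with planted structure.

The generator emulates the correlation structure the pipeline is built to
detect, without any external download:

* a *trans module*: a COP9-like group of co-regulated genes scattered over
  several chromosomes that share a latent factor with the target gene in
  the **normal** condition (pairwise log-scale correlation ``rho_module``);
* a *cis block*: genes on the target's chromosome placed as two runs of
  consecutive TSS positions near the edges of the target's window (every
  block gene within ``cis_window_bp`` of the target, the two flanks more
  than a window apart from each other), which couple to the target in the
  **tumor** condition while the trans-module coupling is removed — the
  "cis-effect takes over" contrast. The flanked layout makes the target
  the unique peak of the planted cis structure: the target's window holds
  the whole block, while each block gene's own window holds only its
  flank and the target.

Log expression of gene g in sample s is a single-latent-factor Gaussian,

    y_gs = base_log_mean + a_g * f_s + sqrt(1 - a_g^2) * eps_gs,

with ``f`` shared within a planted group and ``eps`` iid standard normal
(a_g = 0 outside planted groups). In the normal condition the target and
module genes all carry loading sqrt(rho_module), giving every planted
pair correlation ``rho_module``. In the tumor condition the target is the
*hub* of the cis factor — loading ``rho_cis**0.25`` against
``rho_cis**0.75`` for block genes — so each target-block pair has
correlation exactly ``rho_cis`` while block-block pairs sit lower at
``rho_cis**1.5``; the target is therefore the most cis-enriched gene of
its own neighbourhood, as a dominant driver (e.g. a focal amplification
peaking on the target) would produce. Linear-scale expression is
``exp(log_sigma * y)`` rescaled so the population grand mean equals
``exp(base_log_mean)``; each value is then independently zeroed with
probability ``dropout_rate`` so the >5%-zeros expression filter has true
positives by construction.

Every operation draws from its own generator seeded from ``spec.seed``
plus a fixed per-operation offset, so each output is individually
reproducible and identical spec+seed always yields identical data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection
from .errors import ConfigurationError

_RNG_OFFSETS = {
    "annotations": 11,
    "normal": 12,
    "tumor": 13,
    "gene_sets": 14,
    "metadata": 15,
}

_SITES = ("oral cavity", "oral tongue", "larynx")
_SMOKING = ("current", "former", "never")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic paired expression study.

    Defaults mirror the study design the pipeline targets: 42 matched
    normal/tumor pairs, a 9-gene trans module at rho 0.8 in normal tissue,
    an 8-gene cis block (spacing 100 kbp, so the whole block sits inside
    the 1-Mbp window) at rho 0.7 in tumor tissue, and 2,000 genes over 10
    chromosomes — the test-scale stand-in for a ~1.4e4-gene transcriptome.
    """

    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 10
    tss_spacing_bp: int = 100_000
    n_samples_per_condition: int = 42
    target_gene: str = "GENE00000"
    module_size: int = 9
    rho_module: float = 0.8
    cis_window_bp: int = 1_000_000
    cis_block_size: int = 8
    rho_cis: float = 0.7
    log_sigma: float = 0.4
    base_log_mean: float = 7.0
    dropout_rate: float = 0.0
    planted_set_id: str = "planted_module"
    n_decoy_sets: int = 50

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_chromosomes < 1:
            raise ConfigurationError("need n_genes >= 2 and n_chromosomes >= 1")
        if self.n_chromosomes > 22:
            raise ConfigurationError("n_chromosomes must be <= 22")
        if self.module_size + self.cis_block_size > self.n_genes:
            raise ConfigurationError("module_size + cis_block_size exceeds n_genes")
        for name in ("rho_module", "rho_cis", "dropout_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if self.log_sigma <= 0 or self.tss_spacing_bp <= 0 or self.cis_window_bp <= 0:
            raise ConfigurationError("log_sigma, tss_spacing_bp, cis_window_bp must be positive")
        w = self.cis_window_bp // self.tss_spacing_bp
        if w < 1:
            raise ConfigurationError("cis window smaller than the TSS spacing")
        if max(self.cis_block_size // 2, self.cis_block_size - self.cis_block_size // 2) > w:
            raise ConfigurationError("cis block flanks do not fit inside the cis window")
        if self.cis_block_size and self.n_genes < self.n_chromosomes * (2 * w + 1):
            raise ConfigurationError(
                "target chromosome too short to hold the cis window layout; "
                "increase n_genes or shrink cis_window_bp/tss_spacing_bp"
            )
        if self.n_samples_per_condition < 3:
            raise ConfigurationError("need at least 3 samples per condition")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown spec fields: {sorted(unknown)}")
        return cls(**d)


def _rng(spec: SyntheticSpec, op: str) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), _RNG_OFFSETS[op]])


def gene_symbols(spec: SyntheticSpec) -> list[str]:
    """Deterministic gene symbols GENE00000..; index 0 is the target."""
    symbols = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    symbols[0] = spec.target_gene
    return symbols


def module_genes(spec: SyntheticSpec) -> list[str]:
    """The planted trans-module genes (all off the target's chromosome)."""
    symbols = gene_symbols(spec)
    picked: list[str] = []
    i = 1
    while len(picked) < spec.module_size:
        if spec.n_chromosomes == 1 or i % spec.n_chromosomes != 0:
            picked.append(symbols[i])
        i += 1
        if i >= spec.n_genes:
            raise ConfigurationError("not enough genes off the target chromosome")
    return picked


def cis_block_genes(spec: SyntheticSpec) -> list[str]:
    """The planted cis-block genes (round-robin indices 1*C, 2*C, ...),
    laid out by :func:`generate_annotations` as two flanks near the edges
    of the target's cis window."""
    symbols = gene_symbols(spec)
    return [symbols[k * spec.n_chromosomes] for k in range(1, spec.cis_block_size + 1)]


def _target_chromosome_order(spec: SyntheticSpec, chrom_genes: list[str]) -> list[str]:
    """TSS order of the target's chromosome: left flank of the cis block,
    filler, target (window centre), filler, right flank, rest."""
    block = cis_block_genes(spec)
    if not block:
        return chrom_genes
    w = spec.cis_window_bp // spec.tss_spacing_bp
    half = len(block) // 2
    left, right = block[:half], block[half:]
    filler = [g for g in chrom_genes if g != spec.target_gene and g not in set(block)]
    n_left_fill = w - len(left)       # positions between left flank and target
    n_right_fill = w - len(right)     # positions between target and right flank
    order = [
        *left,
        *filler[:n_left_fill],
        spec.target_gene,
        *filler[n_left_fill:n_left_fill + n_right_fill],
        *right,
        *filler[n_left_fill + n_right_fill:],
    ]
    return order


def generate_annotations(spec: SyntheticSpec) -> pd.DataFrame:
    """Gene annotations: round-robin chromosomes, gridded TSS, cytobands.

    Gene i sits on chromosome ``i % n_chromosomes + 1``; TSS positions are
    consecutive multiples of ``tss_spacing_bp`` along each chromosome in
    gene-index order, except on the target's chromosome where the cis
    block is split into two flanks near the edges of the target's window
    (see :func:`_target_chromosome_order`). Cytoband strings put the
    first half of each chromosome on the
    p arm and the second on the q arm with band numbers increasing away
    from the centromere, so the cytoband float coordinate is strictly
    increasing in TSS along a chromosome.
    """
    symbols = gene_symbols(spec)
    by_chrom: dict[int, list[str]] = {c: [] for c in range(1, spec.n_chromosomes + 1)}
    for i, sym in enumerate(symbols):
        by_chrom[i % spec.n_chromosomes + 1].append(sym)

    by_chrom[1] = _target_chromosome_order(spec, by_chrom[1])

    rows = []
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        m = len(genes)
        half_arm = (m + 1) // 2
        for j, sym in enumerate(genes):
            if j < half_arm:
                arm, band = "p", half_arm - j
            else:
                arm, band = "q", j - half_arm + 1
            rows.append(
                {
                    "gene": sym,
                    "chromosome": str(chrom),
                    "cytoband": f"{chrom}{arm}{band}",
                    "tss_bp": (j + 1) * spec.tss_spacing_bp,
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "chromosome", "cytoband", "tss_bp"])
    # keep gene-index (symbol) order stable for readers
    order = {sym: i for i, sym in enumerate(symbols)}
    return out.sort_values("gene", key=lambda s: s.map(order)).reset_index(drop=True)


def _sample_ids(spec: SyntheticSpec, condition: str) -> list[str]:
    suffix = "11A" if condition == "normal" else "01A"
    return [
        f"TCGA-SY-{i:04d}-{suffix}" for i in range(1, spec.n_samples_per_condition + 1)
    ]


def generate_expression_condition(
    spec: SyntheticSpec, condition: str
) -> ExpressionMatrix:
    """One condition's gene-by-sample matrix under the latent-factor model.

    ``normal``: target + trans module share a factor, every pair at
    ``rho_module``; cis-block genes are independent. ``tumor``: the module
    decouples and the target + cis block share a factor with the target as
    hub — target-block pairs at exactly ``rho_cis``, block-block pairs at
    ``rho_cis**1.5``.
    """
    if condition not in ("normal", "tumor"):
        raise ConfigurationError(f"condition must be 'normal' or 'tumor', got {condition!r}")
    rng = _rng(spec, condition)
    symbols = gene_symbols(spec)
    index_of = {sym: i for i, sym in enumerate(symbols)}
    G, S = spec.n_genes, spec.n_samples_per_condition

    factor = rng.standard_normal(S)
    eps = rng.standard_normal((G, S))

    if condition == "normal":
        group = [spec.target_gene, *module_genes(spec)]
        loadings = np.full(len(group), np.sqrt(spec.rho_module))
    else:
        group = [spec.target_gene, *cis_block_genes(spec)]
        loadings = np.full(len(group), spec.rho_cis**0.75)
        loadings[0] = spec.rho_cis**0.25
    idx = [index_of[g] for g in group]

    y = eps
    a = loadings[:, None]
    y[idx] = a * factor + np.sqrt(1.0 - a**2) * eps[idx]
    y = spec.base_log_mean + y

    # exp(log_sigma * y), rescaled so the population grand mean is
    # exp(base_log_mean)
    scale = np.exp(
        spec.base_log_mean - spec.log_sigma * spec.base_log_mean - spec.log_sigma**2 / 2
    )
    values = scale * np.exp(spec.log_sigma * y)

    if spec.dropout_rate > 0:
        mask = rng.random((G, S)) < spec.dropout_rate
        values[mask] = 0.0

    df = pd.DataFrame(values, index=symbols, columns=_sample_ids(spec, condition))
    df.index.name = "gene"
    return ExpressionMatrix(df)


def generate_gene_sets(spec: SyntheticSpec) -> GeneSetCollection:
    """The planted set (exactly the module genes) plus random decoy sets.

    Decoy sizes are uniform on [10, 200]; members are drawn uniformly from
    all genes, so the target appears in decoys only at background rate.
    """
    rng = _rng(spec, "gene_sets")
    symbols = np.array(gene_symbols(spec))
    sets = [
        GeneSet(spec.planted_set_id, "planted co-expression module",
                frozenset(module_genes(spec)))
    ]
    for d in range(spec.n_decoy_sets):
        size = int(rng.integers(10, 201))
        size = min(size, spec.n_genes)
        members = rng.choice(symbols, size=size, replace=False)
        sets.append(GeneSet(f"decoy{d:03d}", f"random decoy set {d}", frozenset(members)))
    return GeneSetCollection(sets)


def generate_metadata(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample metadata for both conditions; paired samples share the
    participant tag and clinical attributes."""
    rng = _rng(spec, "metadata")
    S = spec.n_samples_per_condition
    sites = rng.choice(_SITES, size=S)
    smoking = rng.choice(_SMOKING, size=S)
    ages = rng.integers(35, 85, size=S)
    rows = []
    for condition in ("normal", "tumor"):
        for i, sid in enumerate(_sample_ids(spec, condition)):
            rows.append(
                {
                    "sample_id": sid,
                    "participant_tag": f"TCGA-SY-{i + 1:04d}",
                    "condition": condition,
                    "site": sites[i],
                    "smoking": smoking[i],
                    "age": int(ages[i]),
                }
            )
    return pd.DataFrame(rows)


def generate_paired_study(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Full paired study: normal matrix, tumor matrix, sample metadata."""
    normal = generate_expression_condition(spec, "normal")
    tumor = generate_expression_condition(spec, "tumor")
    metadata = generate_metadata(spec)
    return normal, tumor, metadata
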