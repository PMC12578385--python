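"""Synthetic snRNA-seq count generator with planted differential expression.

Counts are negative binomial per gene with log-normal baseline means shared
across populations; a population is one (cell type, group) combination. Planted
effects come in three kinds:

``shift``
    every cell of the target population has its NB mean multiplied by
    ``magnitude`` — a homogeneous mean change, visible to fold change and to
    any location test.
``subpop_shift``
    only a pre-drawn random subset of ``ceil(affected_fraction * n)`` cells is
    shifted — the heterogeneous change a distribution statistic (EMD) captures
    while the fold change of means is attenuated.
``scale``
    the mean is unchanged and the NB dispersion is divided by ``magnitude`` — a
    pure spread change with |EMD| > 0 but log2FC ~ 0.

Mitochondrial genes (the last ``n_mito_genes``, named with an ``mt-`` prefix)
have their baseline means rescaled so their expected share of a cell's library
equals ``mito_fraction_mean``. Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

EFFECT_KINDS = ("shift", "subpop_shift", "scale")


@dataclass(frozen=True)
class EffectSpec:
    """One planted effect on one gene in one (cell type, group) population."""

    gene: int
    cell_type: str
    group: str
    kind: str
    magnitude: float
    affected_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if not (0 < self.affected_fraction <= 1):
            raise ValueError("affected_fraction must be in (0, 1]")


@dataclass
class SimConfig:
    n_genes: int = 1000
    n_mito_genes: int = 13
    cell_types: tuple = ("neuron",)
    groups: tuple = ("WT", "MUT")
    cells_per_population: dict = None  # (cell_type, group) -> count; or int for all
    baseline_logmean_mu: float = 0.0
    baseline_logmean_sigma: float = 1.0
    nb_dispersion: float = 10.0
    mito_fraction_mean: float = 0.02
    effects: tuple = field(default_factory=tuple)
    doublet_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.cell_types = tuple(self.cell_types)
        self.groups = tuple(self.groups)
        if not self.cell_types or not self.groups:
            raise ValueError("cell_types and groups must be non-empty")
        if self.n_genes <= 0 or self.n_mito_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be < n_genes")
        if not (0 < self.mito_fraction_mean < 1):
            raise ValueError("mito_fraction_mean must be strictly in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.cells_per_population is None:
            self.cells_per_population = 100
        if isinstance(self.cells_per_population, int):
            n = self.cells_per_population
            self.cells_per_population = {
                (ct, g): n for ct in self.cell_types for g in self.groups
            }
        for (ct, g), n in self.cells_per_population.items():
            if n <= 0:
                raise ValueError(f"population ({ct}, {g}) has non-positive size")
            if ct not in self.cell_types or g not in self.groups:
                raise ValueError(f"population ({ct}, {g}) not in config labels")
        self.effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects
        )
        for e in self.effects:
            if not (0 <= e.gene < self.n_genes):
                raise ValueError(f"effect gene index {e.gene} out of range")
            if e.cell_type not in self.cell_types or e.group not in self.groups:
                raise ValueError(
                    f"effect targets unknown population ({e.cell_type}, {e.group})"
                )

    @property
    def populations(self):
        """Populations in deterministic (cell_type, group) order."""
        return [
            (ct, g)
            for ct in self.cell_types
            for g in self.groups
            if (ct, g) in self.cells_per_population
        ]


def sample_nb_counts(mean: float, dispersion: float, n: int, rng) -> np.ndarray:
    """``n`` negative-binomial draws with E[X]=mean, Var[X]=mean + mean^2/dispersion."""
    if mean <= 0 or dispersion <= 0:
        raise ValueError("mean and dispersion must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def subpop_members(effect: EffectSpec, n_population: int, rng) -> np.ndarray:
    """Membership mask for a subpop_shift effect: exactly ceil(f*n) affected cells.

    Drawn once per (effect, population), before any count sampling, so power
    analyses can condition on the realized membership.
    """
    m = math.ceil(effect.affected_fraction * n_population)
    members = rng.choice(n_population, size=m, replace=False)
    mask = np.zeros(n_population, dtype=bool)
    mask[members] = True
    return mask


def planted_means(base_mean, effect: EffectSpec, n_population: int, rng):
    """Per-cell NB means and the dispersion divisor for one effect.

    Returns ``(means, dispersion_divisor, mask)`` where ``means`` has length
    ``n_population`` and ``mask`` marks the affected cells.
    """
    means = np.full(n_population, float(base_mean))
    disp_div = 1.0
    if effect.kind == "shift":
        mask = np.ones(n_population, dtype=bool)
        means *= effect.magnitude
    elif effect.kind == "subpop_shift":
        mask = subpop_members(effect, n_population, rng)
        means[mask] *= effect.magnitude
    else:  # scale: spread-only
        mask = np.ones(n_population, dtype=bool)
        disp_div = effect.magnitude
    return means, disp_div, mask


def apply_effect(base_mean, effect: EffectSpec, cell_index: int,
                 n_population: int, rng) -> float:
    """NB mean for one cell under an effect (membership pre-drawn from ``rng``)."""
    means, _, _ = planted_means(base_mean, effect, n_population, rng)
    return float(means[cell_index])


def _gene_labels(config: SimConfig):
    n, nm = config.n_genes, config.n_mito_genes
    names = np.array([f"Gene{i:05d}" for i in range(n)], dtype=object)
    for j in range(n - nm, n):
        names[j] = f"mt-Gene{j:05d}"
    ids = np.array([f"ENSSIM{i:011d}" for i in range(n)], dtype=object)
    return ids, names


def generate_dataset(config: SimConfig):
    """Generate (CountMatrix, metadata DataFrame, truth DataFrame) from a config.

    The truth table has one row per planted effect with columns
    ``gene_index, gene_id, gene_name, cell_type, group, kind, magnitude,
    affected_fraction, n_affected, direction``.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, gene_names = _gene_labels(config)
    n_genes = config.n_genes
    mito = np.zeros(n_genes, dtype=bool)
    mito[n_genes - config.n_mito_genes:] = True

    base = rng.lognormal(config.baseline_logmean_mu,
                         config.baseline_logmean_sigma, size=n_genes)
    if config.n_mito_genes:
        f = config.mito_fraction_mean
        m_sum, nm_sum = base[mito].sum(), base[~mito].sum()
        base[mito] *= f * nm_sum / ((1.0 - f) * m_sum)

    blocks, meta_rows, truth_rows = [], [], []
    cell_counter = 0
    for ct, g in config.populations:
        n_cells = config.cells_per_population[(ct, g)]
        means = np.tile(base, (n_cells, 1))
        disp = np.full(n_genes, float(config.nb_dispersion))
        for e in config.effects:
            if e.cell_type != ct or e.group != g:
                continue
            col, div, mask = planted_means(base[e.gene], e, n_cells, rng)
            means[:, e.gene] = col
            disp[e.gene] /= div
            direction = "none" if e.kind == "scale" else (
                "up" if e.magnitude > 1 else "down")
            truth_rows.append({
                "gene_index": e.gene,
                "gene_id": gene_ids[e.gene],
                "gene_name": gene_names[e.gene],
                "cell_type": ct,
                "group": g,
                "kind": e.kind,
                "magnitude": e.magnitude,
                "affected_fraction": e.affected_fraction,
                "n_affected": int(mask.sum()),
                "direction": direction,
            })
        if config.doublet_rate > 0:
            n_dbl = int(round(config.doublet_rate * n_cells))
            if n_dbl:
                pairs = rng.choice(n_cells, size=(n_dbl, 2))
                tgt = rng.choice(n_cells, size=n_dbl, replace=False)
                means[tgt] = 0.5 * (means[pairs[:, 0]] + means[pairs[:, 1]])
        p = disp / (disp + means)
        counts = rng.negative_binomial(disp, p, size=(n_cells, n_genes))
        blocks.append(sp.csr_matrix(counts))
        for _ in range(n_cells):
            meta_rows.append({
                "barcode": f"CELL{cell_counter:07d}-1",
                "cell_type": ct,
                "group": g,
                "sample": g,
            })
            cell_counter += 1

    counts = sp.vstack(blocks).tocsr()
    metadata = pd.DataFrame(meta_rows)
    cm = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        gene_names=gene_names,
        cell_barcodes=metadata["barcode"].to_numpy(dtype=object),
        is_mito=mito,
    )
    truth_cols = ["gene_index", "gene_id", "gene_name", "cell_type", "group",
                  "kind", "magnitude", "affected_fraction", "n_affected",
                  "direction"]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return cm, metadata, truth


def truth_for_contrast(truth: pd.DataFrame, cell_type: str,
                       group_ref: str, group_alt: str) -> pd.DataFrame:
    """Truth rows relevant to one contrast, with direction flipped for effects
    planted in the reference group."""
    sel = truth[(truth["cell_type"] == cell_type)
                & truth["group"].isin([group_ref, group_alt])].copy()
    flip = {"up": "down", "down": "up", "none": "none"}
    in_ref = sel["group"] == group_ref
    sel.loc[in_ref, "direction"] = sel.loc[in_ref, "direction"].map(flip)
    return sel.reset_index(drop=True)
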