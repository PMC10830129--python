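"""Ground-truthed synthetic inputs for every stage of the scheme.

The generator emulates the structure the scoring scheme assumes: multi-tissue
UMI count matrices (negative binomial, gene-specific means) in which each
cell type carries a block of exclusive marker genes with elevated expression,
and each disease's genes are preferentially expressed in a designated "true"
affected cell type of the disease's tissue. Two pseudo-species share the
planted structure through an ortholog map, and literature record sets can be
sampled so that planted pairs co-appear with elevated odds.

The planted elevation is parameterised on the preferential-expression Z
scale (``effect_z``) and realised by multiplying the negative-binomial mean
in the affected cell type by ``1 + effect_z**2``. For a gene elevated in a
single cell type, the realised Z saturates at sqrt(C-1) for C cell types per
tissue; the default C=10 therefore makes the default target effect_z=3
attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datasets import DiseaseCatalog, ExpressionDataset
from .matching import OrthologMap
from .validation import GoldPairs, RecordSets


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults give two tissues of ten cell types, 50 cells per type, 400
    genes (10 exclusive markers per cell type at 5-fold elevation), and ten
    diseases of 3-10 genes planted at a target preferential-expression Z of 3
    in one cell type each. Counts are negative binomial with gene-specific
    means (log-normal around ``base_mean``) and dispersion 2 — UMI-like
    overdispersion calibrated so the expressed-gene filter retains roughly
    30-70% of genes.
    """

    seed: int = 0
    tissues: int = 2
    cell_types_per_tissue: int = 10
    cells_per_type: int = 50
    genes: int = 400
    markers_per_type: int = 10
    marker_fold: float = 5.0
    diseases: int = 10
    genes_per_disease: tuple[int, int] = (3, 10)
    effect_z: float = 3.0
    base_mean: float = 0.05
    dispersion: float = 2.0
    mean_sigma: float = 2.0          # log-normal sd of per-gene base means
    planted_mean_sigma: float = 0.5  # tighter spread for marker/disease genes
    ortholog_noise: float = 0.0
    multi_context_diseases: int = 0  # diseases split into ligand/receptor contexts

    def __post_init__(self):
        for name in ("tissues", "cell_types_per_tissue", "cells_per_type",
                     "genes", "markers_per_type", "diseases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ortholog_noise < 0.5:
            raise ValueError("ortholog_noise must be in [0, 0.5)")
        lo, hi = self.genes_per_disease
        if not 1 <= lo <= hi:
            raise ValueError("genes_per_disease must be an increasing range >= 1")
        n_marker = self.tissues * self.cell_types_per_tissue * self.markers_per_type
        n_disease_max = self.diseases * hi
        if n_marker + n_disease_max > self.genes:
            raise ValueError(
                f"{self.genes} genes cannot host {n_marker} markers plus up to "
                f"{n_disease_max} disease genes")
        if self.multi_context_diseases > self.diseases:
            raise ValueError("multi_context_diseases exceeds diseases")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genes_per_disease" in raw:
            raw["genes_per_disease"] = tuple(raw["genes_per_disease"])
        return cls(**raw)

    @property
    def disease_fold(self) -> float:
        return 1.0 + self.effect_z ** 2

    def tissue_names(self) -> list[str]:
        return [f"tissue{t}" for t in range(self.tissues)]

    def cell_type_names(self) -> list[str]:
        return [f"type{c:02d}" for c in range(self.cell_types_per_tissue)]


@dataclass
class GroundTruth:
    """What was planted: disease triples, marker sets, gene assignments."""

    triples: list = field(default_factory=list)       # (disease_id, tissue, cell_type)
    markers: dict = field(default_factory=dict)       # (tissue, cell_type) -> set
    disease_genes: list = field(default_factory=list) # rows (disease_id, gene_id, tissue, cell_type, function_label)
    ortholog_pairs: list = field(default_factory=list)

    def catalog(self, gene_map: Optional[dict] = None) -> DiseaseCatalog:
        """Disease catalog for the scoring stage (optionally through a 1:1
        gene translation, e.g. into the second species' gene space)."""
        rows = []
        for d, g, t, _, lab in self.disease_genes:
            gg = gene_map[g] if gene_map else g
            rows.append((d, gg, t, lab))
        return DiseaseCatalog(pd.DataFrame(
            rows, columns=["disease_id", "gene_id", "tissue", "function_label"]))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.disease_genes,
                     columns=["disease_id", "gene_id", "tissue", "cell_type",
                              "function_label"]).to_csv(path, sep="\t", index=False)

    def gold_pairs(self) -> GoldPairs:
        return GoldPairs.from_triples((d, c, t) for d, t, c in self.triples)


def _plan(config: SimulationConfig, rng: np.random.Generator):
    """Gene means and planted assignments (shared between species)."""
    G = config.genes
    gene_ids = [f"g{i:04d}" for i in range(G)]
    mu = config.base_mean * np.exp(config.mean_sigma * rng.standard_normal(G))

    truth = GroundTruth()
    tissues = config.tissue_names()
    types = config.cell_type_names()
    pool = rng.permutation(G)
    cursor = 0

    def take(k):
        nonlocal cursor
        sel = pool[cursor:cursor + k]
        cursor += k
        return sel

    # planted genes get a tighter mean spread (detectable in their tissue)
    for (t, ct) in [(t, c) for t in tissues for c in types]:
        idx = take(config.markers_per_type)
        mu[idx] = config.base_mean * np.exp(
            config.planted_mean_sigma * rng.standard_normal(len(idx)))
        truth.markers[(t, ct)] = {gene_ids[i] for i in idx}

    lo, hi = config.genes_per_disease
    for d in range(config.diseases):
        disease = f"disease{d:03d}"
        tissue = tissues[d % config.tissues]
        n_genes = int(rng.integers(lo, hi + 1))
        idx = take(n_genes)
        mu[idx] = config.base_mean * np.exp(
            config.planted_mean_sigma * rng.standard_normal(len(idx)))
        if d < config.multi_context_diseases and config.cell_types_per_tissue >= 2:
            c1, c2 = rng.choice(config.cell_types_per_tissue, size=2, replace=False)
            half = max(1, n_genes // 2)
            assign = ([(types[c1], "ligand")] * half
                      + [(types[c2], "receptor")] * (n_genes - half))
        else:
            c = int(rng.integers(config.cell_types_per_tissue))
            assign = [(types[c], "")] * n_genes
        for i, (ct, lab) in zip(idx, assign):
            truth.disease_genes.append((disease, gene_ids[i], tissue, ct, lab))
        for ct in {ct for ct, _ in assign}:
            truth.triples.append((disease, tissue, ct))
    return gene_ids, mu, truth


def _sample_counts(config: SimulationConfig, gene_ids, mu, truth: GroundTruth,
                   rng: np.random.Generator, species: str,
                   gene_prefix: str = "") -> ExpressionDataset:
    """Draw negative-binomial counts with the planted elevations applied."""
    theta = config.dispersion
    tissues = config.tissue_names()
    types = config.cell_type_names()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    planted_by_tc: dict[tuple[str, str], list[int]] = {}
    for _, g, t, ct, _ in truth.disease_genes:
        planted_by_tc.setdefault((t, ct), []).append(gene_pos[g])

    blocks, obs_rows, cell_ids = [], [], []
    for t in tissues:
        for ct in types:
            mean = mu.copy()
            m_idx = [gene_pos[g] for g in truth.markers[(t, ct)]]
            mean[m_idx] *= config.marker_fold
            for i in planted_by_tc.get((t, ct), []):
                mean[i] *= config.disease_fold
            shape = (config.cells_per_type, config.genes)
            p = theta / (theta + mean)
            counts = rng.negative_binomial(theta, p[None, :], size=shape)
            blocks.append(counts)
            sample = f"{species}_{t}_s0"
            for i in range(config.cells_per_type):
                cell_ids.append(f"{species}.{t}.{ct}.{i:03d}")
                obs_rows.append((t, ct, sample))
    cells = pd.DataFrame(obs_rows, columns=["tissue", "cell_type", "sample"],
                         index=pd.Index(cell_ids, name="cell_id"))
    out_ids = [gene_prefix + g for g in gene_ids]
    return ExpressionDataset(np.vstack(blocks).astype(float), cells, out_ids,
                             species=species)


def generate_dataset(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[ExpressionDataset, GroundTruth]:
    """One pseudo-species count matrix plus its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gene_ids, mu, truth = _plan(config, rng)
    data = _sample_counts(config, gene_ids, mu, truth, rng, species="speciesA")
    return data, truth


def generate_species_pair(config: SimulationConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[ExpressionDataset, ExpressionDataset,
                                     OrthologMap, GroundTruth]:
    """Two pseudo-species sharing the planted structure, plus an ortholog map
    of which ``ortholog_noise`` of the entries are scrambled."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gene_ids, mu, truth = _plan(config, rng)
    data_a = _sample_counts(config, gene_ids, mu, truth, rng, species="speciesA")
    data_b = _sample_counts(config, gene_ids, mu, truth, rng, species="speciesB",
                            gene_prefix="m.")
    true_pairs = [(g, "m." + g) for g in gene_ids]
    truth.ortholog_pairs = list(true_pairs)
    pairs = true_pairs.copy()
    k = int(round(config.ortholog_noise * len(pairs)))
    if k >= 2:
        which = rng.choice(len(pairs), size=k, replace=False)
        targets = [pairs[i][1] for i in which]
        rolled = targets[1:] + targets[:1]  # cyclic shift: no fixed points
        for i, b in zip(which, rolled):
            pairs[i] = (pairs[i][0], b)
    return data_a, data_b, OrthologMap.from_pairs(pairs), truth


def generate_literature(truth: GroundTruth, n_records: int = 500,
                        signal: float = 20.0, p0: float = 0.05,
                        seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None,
                        cell_types: Optional[list[str]] = None
                        ) -> tuple[RecordSets, GoldPairs]:
    """Literature record sets in which planted pairs co-appear with elevated
    odds.

    Every disease and cell type of a tissue cites each of the tissue's
    ``n_records`` records independently with probability ``p0``; for each
    planted pair, ``round(3 * (signal - 1))`` extra records are added to both
    sides, so ``signal=1`` is an exact null.
    """
    if signal < 1:
        raise ValueError("signal must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    records = RecordSets()
    tissues = sorted({t for _, t, _ in truth.triples})
    if cell_types is None:
        cell_types = sorted({ct for (_, ct) in truth.markers})
    n_boost = min(n_records, int(round(3 * (signal - 1))))
    for t in tissues:
        univ = [f"{t}:r{i:04d}" for i in range(n_records)]
        diseases = sorted({d for d, tt, _ in truth.triples if tt == t})
        for d in diseases:
            mask = rng.random(n_records) < p0
            records.diseases[(t, d)] = {univ[i] for i in np.flatnonzero(mask)}
        for c in cell_types:
            mask = rng.random(n_records) < p0
            records.cell_types[(t, c)] = {univ[i] for i in np.flatnonzero(mask)}
        for d, tt, c in truth.triples:
            if tt != t or n_boost == 0:
                continue
            extra = {univ[i] for i in rng.choice(n_records, size=n_boost,
                                                 replace=False)}
            records.diseases[(t, d)] |= extra
            records.cell_types[(t, c)] |= extra
    return records, truth.gold_pairs()
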