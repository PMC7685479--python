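"""Multi-cohort synthetic datasets with planted driver structure.

The generator emulates the statistical situation the discovery pipeline
assumes: several tumor cohorts share a pool of mutated genes; a subset of
that pool ("planted drivers") shifts the expression of a fixed set of target
genes in mutated samples, while the rest of the pool ("pool passengers") is
mutated just as often but leaves expression untouched. Genes outside the
pool acquire sporadic background mutations per (gene, sample). Expression is
Gaussian around a per-gene baseline; downstream z-scoring removes baselines,
so no count model is needed.

Every draw is derived from the config seed, making outputs byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (TRUNCATING_CLASSES, GeneCatalog, VariantRecord,
                         write_expression, write_maf)
from .matrices import ExpressionMatrix, MutationMatrix

logger = logging.getLogger(__name__)

#: Default pathogenic-class composition of generated records.
DEFAULT_VARIANT_CLASS_MIX: dict[str, float] = {
    "Missense_Mutation": 0.70,
    "Nonsense_Mutation": 0.08,
    "Frame_Shift_Del": 0.05,
    "Frame_Shift_Ins": 0.04,
    "Splice_Site": 0.05,
    "In_Frame_Del": 0.04,
    "In_Frame_Ins": 0.02,
    "Nonstop_Mutation": 0.01,
    "Translation_Start_Site": 0.01,
}

_PROTEIN_LEN = 800  # residue range for random protein positions


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one multi-cohort simulation.

    ``driver_mutation_frequency`` applies to every shared-pool gene (drivers
    and pool passengers alike), so passengers are testable negatives;
    ``passenger_mutation_frequency`` is the per-(gene, sample) rate of
    sporadic background mutations outside the pool. ``effect_size_delta`` is
    the expression shift in units of ``noise_sd``.
    """

    n_cohorts: int = 3
    n_samples: int = 150
    n_genes: int = 500
    n_shared_mutated_genes: int = 100
    n_planted_drivers: int = 20
    driver_mutation_frequency: float = 0.2
    passenger_mutation_frequency: float = 0.005
    targets_per_driver: int = 30
    effect_size_delta: float = 1.5
    noise_sd: float = 1.0
    known_gene_fraction: float = 0.1
    variant_class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_CLASS_MIX))
    hotspot_concentration: float = 0.0
    min_group_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("driver_mutation_frequency", "passenger_mutation_frequency",
                     "known_gene_fraction", "hotspot_concentration"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.variant_class_mix.values()) - 1.0) > 1e-12:
            raise ValueError("variant_class_mix probabilities must sum to 1")
        if not (self.n_planted_drivers <= self.n_shared_mutated_genes <= self.n_genes):
            raise ValueError("need n_planted_drivers <= n_shared_mutated_genes <= n_genes")
        if self.driver_mutation_frequency * self.n_samples < self.min_group_size:
            raise ValueError(
                "driver_mutation_frequency x n_samples = "
                f"{self.driver_mutation_frequency * self.n_samples:.2f} below the "
                f"minimum mutated-group size {self.min_group_size}")
        if self.targets_per_driver > self.n_genes - 1:
            raise ValueError("targets_per_driver exceeds available target genes")


@dataclass
class PlantedTruth:
    """Ground truth of one simulation, for recovery checks."""

    config: SimulationConfig
    gene_universe: tuple[str, ...]
    shared_pool: tuple[str, ...]            # drivers first
    driver_genes: tuple[str, ...]
    target_map: dict[str, tuple[str, ...]]
    effect_sign: dict[tuple[str, str], int]  # (driver, target) -> +1/-1
    known_genes: frozenset[str]
    # cohort index -> pool gene -> mutated sample names
    pool_mutated_samples: dict[int, dict[str, tuple[str, ...]]]

    @property
    def passenger_pool(self) -> tuple[str, ...]:
        drivers = set(self.driver_genes)
        return tuple(g for g in self.shared_pool if g not in drivers)

    def mutated_samples(self, cohort_index: int, driver: str) -> tuple[str, ...]:
        return self.pool_mutated_samples[cohort_index][driver]


def gene_name(i: int) -> str:
    return f"G{i:05d}"


def sample_name(cohort_index: int, j: int) -> str:
    return f"C{cohort_index + 1}-S{j:04d}"


def make_truth(config: SimulationConfig) -> PlantedTruth:
    """Draw the shared planted structure (genes, targets, signs, carriers)."""
    rng = np.random.default_rng((config.seed,))
    universe = tuple(gene_name(i) for i in range(config.n_genes))
    pool_idx = rng.choice(config.n_genes, size=config.n_shared_mutated_genes, replace=False)
    pool = tuple(universe[i] for i in pool_idx)
    drivers = pool[:config.n_planted_drivers]
    # reorder pool so drivers come first (they already do by construction)
    target_map: dict[str, tuple[str, ...]] = {}
    effect_sign: dict[tuple[str, str], int] = {}
    for d in drivers:
        eligible = [g for g in universe if g != d]
        targets = tuple(rng.choice(eligible, size=config.targets_per_driver, replace=False))
        target_map[d] = targets
        for t in targets:
            effect_sign[(d, t)] = 1 if rng.random() < 0.5 else -1
    n_known = int(np.round(config.known_gene_fraction * config.n_genes))
    known = frozenset(rng.choice(universe, size=n_known, replace=False)) if n_known else frozenset()
    pool_mutated: dict[int, dict[str, tuple[str, ...]]] = {}
    for c in range(config.n_cohorts):
        per_gene: dict[str, tuple[str, ...]] = {}
        for g in pool:
            k = int(rng.binomial(config.n_samples, config.driver_mutation_frequency))
            k = max(k, 1)  # every pool gene appears mutated in every cohort
            idx = rng.choice(config.n_samples, size=k, replace=False)
            per_gene[g] = tuple(sample_name(c, j) for j in sorted(idx))
        pool_mutated[c] = per_gene
    return PlantedTruth(config=config, gene_universe=universe, shared_pool=pool,
                        driver_genes=drivers, target_map=target_map,
                        effect_sign=effect_sign, known_genes=known,
                        pool_mutated_samples=pool_mutated)


def _check_truth(config: SimulationConfig, truth: PlantedTruth, cohort_index: int) -> None:
    if truth.config != config:
        raise ValueError("truth was drawn for a different configuration")
    if not (0 <= cohort_index < config.n_cohorts):
        raise ValueError(f"cohort_index {cohort_index} outside 0..{config.n_cohorts - 1}")
    if cohort_index not in truth.pool_mutated_samples:
        raise ValueError(f"truth lacks mutated-sample draws for cohort {cohort_index}")


def _emit_records(rng: np.random.Generator, gene: str, samples: Sequence[str],
                  mix_classes: list[str], mix_probs: np.ndarray,
                  hotspot_concentration: float) -> list[VariantRecord]:
    """One record per (gene, sample); classes from the mix; missense hotspots."""
    classes = rng.choice(len(mix_classes), size=len(samples), p=mix_probs)
    positions = rng.integers(1, _PROTEIN_LEN + 1, size=len(samples))
    records = []
    missense_idx = [i for i, c in enumerate(classes) if mix_classes[c] == "Missense_Mutation"]
    if hotspot_concentration > 0 and missense_idx:
        n_hot = int(np.round(hotspot_concentration * len(missense_idx)))
        hot_pos = int(rng.integers(1, _PROTEIN_LEN + 1))
        for i in missense_idx[:n_hot]:
            positions[i] = hot_pos
    for i, s in enumerate(samples):
        records.append(VariantRecord(gene=gene, sample=s,
                                     classification=mix_classes[classes[i]],
                                     protein_position=int(positions[i])))
    return records


def simulate_cohort(config: SimulationConfig, cohort_index: int, truth: PlantedTruth,
                    ) -> tuple[MutationMatrix, ExpressionMatrix, list[VariantRecord]]:
    """Generate one cohort consistent with the shared planted truth.

    Expression for gene t in sample s is baseline mu_t + Normal(0, noise_sd^2)
    noise, plus sign(d,t) * effect_size_delta * noise_sd for every driver d
    mutated in s with t among its targets. The mutation matrix is the
    indicator of the emitted records. Returned expression is raw
    (``normalized=False``); z-scoring is a downstream step.
    """
    _check_truth(config, truth, cohort_index)
    rng = np.random.default_rng((config.seed, cohort_index))
    samples = [sample_name(cohort_index, j) for j in range(config.n_samples)]
    sample_pos = {s: j for j, s in enumerate(samples)}
    mix_classes = list(config.variant_class_mix.keys())
    mix_probs = np.asarray(list(config.variant_class_mix.values()), dtype=float)
    mix_probs = mix_probs / mix_probs.sum()

    records: list[VariantRecord] = []
    for g in truth.shared_pool:
        carriers = truth.pool_mutated_samples[cohort_index][g]
        records.extend(_emit_records(rng, g, carriers, mix_classes, mix_probs,
                                     config.hotspot_concentration))
    pool_set = set(truth.shared_pool)
    background = [g for g in truth.gene_universe if g not in pool_set]
    if config.passenger_mutation_frequency > 0:
        hits = rng.random((len(background), config.n_samples)) < config.passenger_mutation_frequency
        for gi, g in enumerate(background):
            carriers = [samples[j] for j in np.flatnonzero(hits[gi])]
            if carriers:
                records.extend(_emit_records(rng, g, carriers, mix_classes, mix_probs,
                                             config.hotspot_concentration))

    mutated: dict[str, set[int]] = {}
    for r in records:
        mutated.setdefault(r.gene, set()).add(sample_pos[r.sample])
    genes_mut = sorted(mutated)
    arr = np.zeros((len(genes_mut), config.n_samples), dtype=np.int8)
    for i, g in enumerate(genes_mut):
        arr[i, sorted(mutated[g])] = 1
    mut = MutationMatrix(pd.DataFrame(arr, index=genes_mut, columns=samples))

    baselines = rng.normal(0.0, 1.0, size=config.n_genes)
    x = baselines[:, None] + rng.normal(0.0, config.noise_sd,
                                        size=(config.n_genes, config.n_samples))
    gene_pos = {g: i for i, g in enumerate(truth.gene_universe)}
    for d in truth.driver_genes:
        carrier_idx = [sample_pos[s] for s in truth.pool_mutated_samples[cohort_index][d]]
        for t in truth.target_map[d]:
            sign = truth.effect_sign[(d, t)]
            x[gene_pos[t], carrier_idx] += sign * config.effect_size_delta * config.noise_sd
    expr = ExpressionMatrix(pd.DataFrame(x, index=list(truth.gene_universe),
                                         columns=samples), normalized=False)
    return mut, expr, records


def simulate_multi_cancer(config: SimulationConfig,
                          ) -> tuple[list[tuple[MutationMatrix, ExpressionMatrix, list[VariantRecord]]],
                                     PlantedTruth]:
    """All cohorts of one study under a single shared :class:`PlantedTruth`."""
    if config.n_cohorts < 2:
        raise ValueError("a multi-cancer study needs n_cohorts >= 2")
    truth = make_truth(config)
    cohorts = [simulate_cohort(config, c, truth) for c in range(config.n_cohorts)]
    return cohorts, truth


def simulate_maf_for_2020(n_mutations: int, missense_fraction: float,
                          truncating_fraction: float, hotspot_concentration: float,
                          seed: int, gene: str = "GENE1") -> list[VariantRecord]:
    """Single-gene record list with controlled 20/20-rule composition.

    round(n x missense_fraction) missense records, of which
    round(hotspot x n_missense) share one protein position;
    round(n x truncating_fraction) truncating records; the remainder are
    other non-silent classes (in-frame indels). Round-half-even throughout.
    """
    if missense_fraction + truncating_fraction > 1 + 1e-12:
        raise ValueError("missense_fraction + truncating_fraction must be <= 1")
    n_missense = int(np.round(n_mutations * missense_fraction))
    n_truncating = int(np.round(n_mutations * truncating_fraction))
    if n_missense + n_truncating > n_mutations:
        raise ValueError("rounded category counts exceed n_mutations")
    n_hot = int(np.round(hotspot_concentration * n_missense))
    rng = np.random.default_rng(seed)
    truncating_classes = sorted(TRUNCATING_CLASSES)
    hot_pos = int(rng.integers(1, _PROTEIN_LEN + 1))
    records: list[VariantRecord] = []
    used = {hot_pos}

    def fresh_pos() -> int:
        while True:
            p = int(rng.integers(1, _PROTEIN_LEN + 1))
            if p not in used:
                used.add(p)
                return p

    for i in range(n_missense):
        pos = hot_pos if i < n_hot else fresh_pos()
        records.append(VariantRecord(gene=gene, sample=f"S{len(records):04d}",
                                     classification="Missense_Mutation",
                                     protein_position=pos))
    for i in range(n_truncating):
        records.append(VariantRecord(gene=gene, sample=f"S{len(records):04d}",
                                     classification=truncating_classes[int(rng.integers(len(truncating_classes)))],
                                     protein_position=fresh_pos()))
    while len(records) < n_mutations:
        records.append(VariantRecord(gene=gene, sample=f"S{len(records):04d}",
                                     classification="In_Frame_Del",
                                     protein_position=fresh_pos()))
    return records


def simulate_gene_catalog(truth: PlantedTruth, seed: int = 0) -> GeneCatalog:
    """Synthetic annotation catalog: known flags from the truth, lognormal
    lengths with driver genes drawn longer (emulating the conservation
    surrogate that real cancer genes tend to be large)."""
    rng = np.random.default_rng((seed, 7))
    rows = []
    drivers = set(truth.driver_genes)
    for g in truth.gene_universe:
        scale = 1.0 if g in drivers or g in truth.known_genes else 0.0
        gene_len = float(np.round(np.exp(rng.normal(9.5 + scale, 0.6))))
        protein_len = float(np.round(np.exp(rng.normal(6.2 + 0.5 * scale, 0.5))))
        rows.append({"gene": g, "known_cancer_gene": g in truth.known_genes,
                     "gene_length": max(gene_len, 100.0),
                     "protein_length": max(protein_len, 50.0)})
    return GeneCatalog(pd.DataFrame(rows).set_index("gene"))


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Documented key-value text dump of the planted truth."""
    lines = [
        "# driverscan synthetic truth, one key per line",
        f"seed\t{truth.config.seed}",
        f"n_cohorts\t{truth.config.n_cohorts}",
        "driver_genes\t" + ",".join(truth.driver_genes),
        "shared_pool\t" + ",".join(truth.shared_pool),
        "known_genes\t" + ",".join(sorted(truth.known_genes)),
    ]
    for d, targets in truth.target_map.items():
        signed = [f"{t}:{'+' if truth.effect_sign[(d, t)] > 0 else '-'}" for t in targets]
        lines.append(f"targets\t{d}\t" + ",".join(signed))
    for c, per_gene in truth.pool_mutated_samples.items():
        for g, ss in per_gene.items():
            lines.append(f"mutated_samples\t{c}\t{g}\t" + ",".join(ss))
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(outdir: str | Path, name: str, mut: MutationMatrix,
                 expr: ExpressionMatrix, records: Sequence[VariantRecord]) -> dict[str, Path]:
    """Write one cohort's MAF and expression TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maf_path = outdir / f"{name}.maf"
    expr_path = outdir / f"{name}.expression.tsv"
    write_maf(records, maf_path)
    write_expression(expr.values, expr_path)
    return {"maf": maf_path, "expression": expr_path}
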