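"""The discovery procedure: pre-selection, per-gene SAM testing, candidate
selection, and the known-gene-free patient subset re-analysis.

A gene is pre-selected if it carries at least one retained (pathogenic)
mutation in every cohort. Each pre-selected gene is then tested in each
cohort: samples are split into carriers / non-carriers of a mutation in that
gene and the whole expression matrix is screened with SAM at the target FDR;
the counts of significantly over- and under-expressed *other* genes are
recorded and normalized by the cohort's gene count. A gene is a candidate
driver if it is testable and perturbs expression in every cohort. The same
machinery re-runs on the subset of samples carrying no mutation in any known
cancer gene, to rule out hitchhiking on known drivers.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrices import CancerDataset, MutationMatrix, zscore_normalize
from .sam import SamConfig, UntestableGroup, run_sam

logger = logging.getLogger(__name__)


class NoEligibleSamples(Exception):
    """Every sample carries a known-gene mutation; the subset is empty."""


@dataclass
class GeneEffect:
    """Effect of one mutated gene on the transcriptome of one cohort."""

    cohort: str
    gene: str
    testable: bool
    n_mutated_samples: int
    n_up: int | None = None
    n_down: int | None = None
    prop_up: float | None = None
    prop_down: float | None = None
    fdr_used: float | None = None
    delta_used: float | None = None
    n_genes_total: int | None = None

    @property
    def n_affected(self) -> int:
        return (self.n_up or 0) + (self.n_down or 0)


@dataclass
class CandidateDecision:
    """Cross-cohort verdict for one pre-selected gene."""

    gene: str
    effects: dict[str, GeneEffect]
    is_candidate: bool
    known_cancer_gene: bool = False

    @property
    def total_affected_proportion(self) -> float:
        return sum((e.prop_up or 0.0) + (e.prop_down or 0.0)
                   for e in self.effects.values())


def derive_sam_seed(run_seed: int, cohort: str, gene: str) -> tuple[int, int, int]:
    """Stable per-(run, cohort, gene) seed so test order never matters."""
    return (int(run_seed),
            zlib.crc32(cohort.encode()),
            zlib.crc32(gene.encode()))


def preselect_genes(datasets: Sequence[CancerDataset]) -> list[str]:
    """Sorted intersection of the cohorts' mutated-gene sets."""
    if len(datasets) < 2:
        raise ValueError("pre-selection needs at least 2 cohorts")
    sets = [set(d.mutation.mutated_genes()) for d in datasets]
    common = set.intersection(*sets)
    if not common:
        logger.warning("preselect_genes: empty cross-cohort intersection")
    return sorted(common)


def test_gene_effect(dataset: CancerDataset, gene: str, config: SamConfig,
                     run_seed: int | None = None) -> GeneEffect:
    """SAM screen of the whole expression matrix against one gene's status.

    The tested gene itself is removed from both significant sets before
    counting ("other genes"); proportions are normalized by the cohort's
    normalized-expression gene count.
    """
    if gene not in dataset.mutation.values.index:
        raise KeyError(f"gene {gene} not in mutation matrix of {dataset.name}")
    labels = dataset.mutation.labels_for(gene)
    n_mut = int(labels.sum())
    if run_seed is not None:
        config = replace(config, seed=derive_sam_seed(run_seed, dataset.name, gene))
    try:
        call = run_sam(dataset.expression, labels, config)
    except UntestableGroup:
        return GeneEffect(cohort=dataset.name, gene=gene, testable=False,
                          n_mutated_samples=n_mut)
    up = [g for g in call.significant_up if g != gene]
    down = [g for g in call.significant_down if g != gene]
    total = len(dataset.expression.genes)
    return GeneEffect(cohort=dataset.name, gene=gene, testable=True,
                      n_mutated_samples=n_mut, n_up=len(up), n_down=len(down),
                      prop_up=len(up) / total, prop_down=len(down) / total,
                      fdr_used=call.fdr_estimate, delta_used=call.delta,
                      n_genes_total=total)


def select_candidates(effects: Mapping[str, Mapping[str, GeneEffect]],
                      min_affected: int = 1,
                      known_genes: Iterable[str] = ()) -> list[CandidateDecision]:
    """Candidate iff testable in every cohort and >= min_affected other genes
    significantly perturbed (either direction) in every cohort."""
    known = set(known_genes)
    decisions = []
    for gene, per_cohort in effects.items():
        ok = all(e.testable and e.n_affected >= min_affected
                 for e in per_cohort.values())
        decisions.append(CandidateDecision(gene=gene, effects=dict(per_cohort),
                                           is_candidate=ok,
                                           known_cancer_gene=gene in known))
    decisions.sort(key=lambda d: (-d.total_affected_proportion, d.gene))
    return decisions


def cosmic_free_subset(dataset: CancerDataset, known_genes: Iterable[str]) -> CancerDataset:
    """Restrict a cohort to samples with zero retained mutations in every
    known cancer gene; re-z-score expression over the subset and drop genes
    left without mutated samples."""
    known_present = [g for g in set(known_genes) if g in dataset.mutation.values.index]
    mut = dataset.mutation.values
    if known_present:
        carrier = mut.loc[known_present].sum(axis=0) > 0
        eligible = [s for s in dataset.samples if not carrier[s]]
    else:
        eligible = list(dataset.samples)
    if not eligible:
        raise NoEligibleSamples(f"dataset {dataset.name}: every sample carries a known-gene mutation")
    logger.info("cosmic_free_subset %s: %d / %d samples eligible",
                dataset.name, len(eligible), len(dataset.samples))
    sub_mut = mut[eligible]
    sub_mut = sub_mut.loc[sub_mut.sum(axis=1) > 0]
    # per-gene z-scoring is affine-invariant per gene, so re-normalizing the
    # already-normalized matrix over the subset equals normalizing the raw one
    sub_expr = zscore_normalize(dataset.expression.values[eligible])
    return CancerDataset(name=f"{dataset.name}:cosmic-free",
                         mutation=MutationMatrix(sub_mut),
                         expression=sub_expr)


def _effects_table(effects: Mapping[str, Mapping[str, GeneEffect]]) -> pd.DataFrame:
    rows = []
    for gene, per_cohort in effects.items():
        for cohort, e in per_cohort.items():
            rows.append({
                "gene": gene, "cohort": cohort, "testable": e.testable,
                "n_mutated_samples": e.n_mutated_samples,
                "n_up": e.n_up, "n_down": e.n_down,
                "prop_up": e.prop_up, "prop_down": e.prop_down,
                "fdr_used": e.fdr_used, "delta_used": e.delta_used,
                "n_genes_total": e.n_genes_total,
            })
    return pd.DataFrame(rows).sort_values(["gene", "cohort"]).reset_index(drop=True)


def _candidates_table(decisions: Sequence[CandidateDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        row = {"gene": d.gene, "is_candidate": d.is_candidate,
               "known_cancer_gene": d.known_cancer_gene,
               "total_affected_proportion": d.total_affected_proportion}
        for cohort, e in sorted(d.effects.items()):
            row[f"n_affected[{cohort}]"] = e.n_affected if e.testable else None
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Everything one discovery run produces."""

    effects: dict[str, dict[str, GeneEffect]]
    decisions: list[CandidateDecision]
    subset_effects: dict[str, dict[str, GeneEffect]] | None
    subset_decisions: list[CandidateDecision] | None
    report: dict

    @property
    def candidates(self) -> list[str]:
        return [d.gene for d in self.decisions if d.is_candidate]

    @property
    def subset_candidates(self) -> list[str]:
        if self.subset_decisions is None:
            return []
        return [d.gene for d in self.subset_decisions if d.is_candidate]


def _analyse(datasets: Sequence[CancerDataset], sam_config: SamConfig,
             min_affected: int, known_genes: frozenset[str], run_seed: int,
             ) -> tuple[list[str], dict[str, dict[str, GeneEffect]], list[CandidateDecision]]:
    preselected = preselect_genes(datasets)
    effects: dict[str, dict[str, GeneEffect]] = {}
    for gene in preselected:
        effects[gene] = {ds.name: test_gene_effect(ds, gene, sam_config, run_seed=run_seed)
                         for ds in datasets}
    decisions = select_candidates(effects, min_affected=min_affected,
                                  known_genes=known_genes)
    return preselected, effects, decisions


def run_full_pipeline(datasets: Sequence[CancerDataset],
                      known_genes: Iterable[str] = (),
                      sam_config: SamConfig | None = None,
                      min_affected: int = 1,
                      run_seed: int = 0,
                      with_subset: bool = True,
                      outdir: str | Path | None = None) -> PipelineResult:
    """Full discovery run, optionally repeated on known-gene-free subsets.

    Emits ``gene_effects.tsv``, ``candidates.tsv``,
    ``cosmic_free_candidates.tsv`` and ``run_report.json`` under ``outdir``
    when given. Fully reproducible from the datasets + ``run_seed``.
    """
    sam_config = sam_config or SamConfig()
    known = frozenset(known_genes)
    preselected, effects, decisions = _analyse(datasets, sam_config, min_affected,
                                               known, run_seed)
    candidates = [d.gene for d in decisions if d.is_candidate]
    report: dict = {
        "seed": run_seed,
        "min_affected": min_affected,
        "sam": {"n_permutations": sam_config.n_permutations,
                "target_fdr": sam_config.target_fdr,
                "min_group_size": sam_config.min_group_size,
                "s0_mode": sam_config.s0_mode},
        "denominator": "genes in the cohort's normalized expression matrix",
        "note": "FDR is controlled within each per-gene SAM run; no correction across runs",
        "cohorts": {ds.name: {
            "n_samples": len(ds.samples),
            "n_mutated_genes": len(ds.mutation.mutated_genes()),
            "n_expression_genes": len(ds.expression.genes),
        } for ds in datasets},
        "n_preselected": len(preselected),
        "n_testable": sum(1 for g in preselected
                          if all(effects[g][ds.name].testable for ds in datasets)),
        "n_candidates": len(candidates),
        "n_candidates_known": sum(1 for d in decisions if d.is_candidate and d.known_cancer_gene),
        "candidates": candidates,
    }

    subset_effects = subset_decisions = None
    if with_subset and known:
        try:
            subsets = [cosmic_free_subset(ds, known) for ds in datasets]
        except NoEligibleSamples as exc:
            logger.warning("subset analysis skipped: %s", exc)
            report["subset"] = {"skipped": str(exc)}
        else:
            sub_pre, subset_effects, subset_decisions = _analyse(
                subsets, sam_config, min_affected, known, run_seed)
            report["subset"] = {
                "n_samples": {s.name: len(s.samples) for s in subsets},
                "n_preselected": len(sub_pre),
                "n_candidates": sum(1 for d in subset_decisions if d.is_candidate),
                "candidates": [d.gene for d in subset_decisions if d.is_candidate],
            }

    result = PipelineResult(effects=effects, decisions=decisions,
                            subset_effects=subset_effects,
                            subset_decisions=subset_decisions, report=report)
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _effects_table(result.effects).to_csv(outdir / "gene_effects.tsv", sep="\t", index=False)
    _candidates_table(result.decisions).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    if result.subset_decisions is not None:
        _candidates_table(result.subset_decisions).to_csv(
            outdir / "cosmic_free_candidates.tsv", sep="\t", index=False)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
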