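"""Per-cohort analysis matrices.

A cohort enters the analysis as two aligned gene × sample matrices: a binary
mutation-status matrix (1 = the sample carries at least one retained mutation
in the gene) and an expression matrix standardized per gene to z-scores.
The analysis sample set is the intersection of the two matrices' barcodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantRecord, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class MutationMatrix:
    """Binary gene × sample mutation indicator matrix."""

    values: pd.DataFrame  # int8 in {0,1}, index=genes, columns=samples

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("mutation matrix has duplicate genes or samples")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def mutated_genes(self) -> list[str]:
        """Genes with at least one mutated sample, sorted."""
        sums = self.values.sum(axis=1)
        return sorted(sums.index[sums > 0])

    def labels_for(self, gene: str) -> np.ndarray:
        """Boolean mutated/not-mutated vector over samples for one gene."""
        return self.values.loc[gene].to_numpy().astype(bool)


@dataclass
class ExpressionMatrix:
    """Real-valued gene × sample matrix; ``normalized`` marks per-gene z-scores."""

    values: pd.DataFrame
    normalized: bool = False
    dropped_genes: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CancerDataset:
    """One cohort ready for analysis: aligned mutation and expression matrices."""

    name: str
    mutation: MutationMatrix
    expression: ExpressionMatrix

    def __post_init__(self) -> None:
        if list(self.mutation.values.columns) != list(self.expression.values.columns):
            raise ValueError(f"dataset {self.name}: mutation/expression samples differ")
        if len(self.samples) == 0:
            raise ValueError(f"dataset {self.name}: empty shared sample set")

    @property
    def samples(self) -> list[str]:
        return list(self.mutation.values.columns)


def build_mutation_matrix(records: Sequence[VariantRecord],
                          samples: Sequence[str] | None = None) -> MutationMatrix:
    """Indicator matrix over (gene, sample) pairs with >=1 record.

    Duplicate records for a pair collapse to a single 1. Genes are sorted
    lexicographically; samples keep the given order, or are sorted when
    inferred from the records. Records are expected to be already
    pathogenicity-filtered by the caller.
    """
    if not records and samples is None:
        raise ValueError("no records and no sample list: cannot define matrix dimensions")
    if samples is None:
        samples = sorted({r.sample for r in records})
    else:
        samples = list(samples)
    sample_pos = {s: j for j, s in enumerate(samples)}
    genes = sorted({r.gene for r in records})
    gene_pos = {g: i for i, g in enumerate(genes)}
    arr = np.zeros((len(genes), len(samples)), dtype=np.int8)
    outside = 0
    for r in records:
        j = sample_pos.get(r.sample)
        if j is None:
            outside += 1
            continue
        arr[gene_pos[r.gene], j] = 1
    if outside:
        logger.info("build_mutation_matrix: %d record(s) for samples outside the sample list", outside)
    return MutationMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def zscore_normalize(raw: pd.DataFrame | ExpressionMatrix,
                     sd_policy: str = "drop") -> ExpressionMatrix:
    """Standardize each gene row to mean 0, SD 1 (sample SD, denominator n-1).

    Zero-variance rows are handled per ``sd_policy``: "drop" (default,
    logged) or "error". Raises if every row is zero-variance.
    """
    table = raw.values if isinstance(raw, ExpressionMatrix) else raw
    if table.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    arr = table.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if flat.all():
        raise ValueError("all gene rows have zero variance")
    if flat.any():
        if sd_policy == "drop":
            logger.info("zscore_normalize: dropping %d zero-variance gene row(s)", int(flat.sum()))
        elif sd_policy == "error":
            raise ValueError(f"{int(flat.sum())} zero-variance gene row(s)")
        else:
            raise ValueError(f"unknown sd_policy {sd_policy!r}")
    keep = ~flat
    z = (arr[keep] - mean[keep]) / sd[keep]
    out = pd.DataFrame(z, index=table.index[keep], columns=table.columns)
    return ExpressionMatrix(out, normalized=True,
                            dropped_genes=tuple(table.index[flat]))


def harmonize_barcodes(mutation_samples: Sequence[str],
                       expression_samples: Sequence[str]) -> dict[str, str]:
    """Map mutation barcodes onto expression barcodes by prefix truncation.

    TCGA mutation barcodes are often longer (more fields) than expression
    barcodes; when an expression barcode is a prefix of a mutation barcode
    the two are matched. Returns a mapping mutation barcode -> expression
    barcode for every match (direct equality included).
    """
    expr_set = set(expression_samples)
    lengths = sorted({len(s) for s in expression_samples}, reverse=True)
    mapping: dict[str, str] = {}
    for mb in mutation_samples:
        if mb in expr_set:
            mapping[mb] = mb
            continue
        for L in lengths:
            if len(mb) > L and mb[:L] in expr_set:
                mapping[mb] = mb[:L]
                break
    return mapping


def build_dataset(name: str,
                  mutation: MutationMatrix,
                  expression_raw: pd.DataFrame,
                  harmonize: bool = True,
                  sd_policy: str = "drop") -> CancerDataset:
    """Align a cohort's matrices on the barcode intersection and z-score.

    Unmatched samples on either side are discarded (counts logged).
    """
    mut = mutation.values
    if harmonize:
        mapping = harmonize_barcodes(mut.columns, expression_raw.columns)
        renamed = mut.rename(columns=mapping)
        if renamed.columns.has_duplicates:  # two mutation barcodes collapsing: OR them
            renamed = renamed.T.groupby(level=0, sort=False).max().T
        mut = renamed
    shared = [s for s in expression_raw.columns if s in set(mut.columns)]
    if not shared:
        raise ValueError(f"dataset {name}: no shared samples between mutation and expression")
    n_drop_mut = mut.shape[1] - len(shared)
    n_drop_expr = expression_raw.shape[1] - len(shared)
    if n_drop_mut or n_drop_expr:
        logger.info("build_dataset %s: discarded %d mutation-only and %d expression-only sample(s)",
                    name, n_drop_mut, n_drop_expr)
    expr = zscore_normalize(expression_raw[shared], sd_policy=sd_policy)
    return CancerDataset(name=name,
                         mutation=MutationMatrix(mut[shared]),
                         expression=expr)


def select_expression_source(candidates: Sequence[pd.DataFrame],
                             mutation: MutationMatrix,
                             control_genes: Iterable[str],
                             sam_config) -> tuple[int, pd.DataFrame]:
    """Choose among candidate expression tables via a control experiment.

    For each candidate, z-score it, run the SAM test against the mutation
    status of each control gene (well-established cancer genes such as
    BRCA1/BRCA2/TP53), and sum the significant-gene counts. The candidate
    with the largest total effect wins; ties go to the first by input order.
    Returns ``(best_index, score_table)``.
    """
    from .sam import UntestableGroup, run_sam  # local import to avoid a cycle

    if not candidates:
        raise ValueError("no candidate expression tables")
    control = [normalize_symbol(g) for g in control_genes]
    rows = []
    any_testable = False
    for idx, table in enumerate(candidates):
        dataset = build_dataset(f"candidate{idx}", mutation, table)
        total = 0
        tested = 0
        for gene in control:
            if gene not in dataset.mutation.values.index:
                continue
            labels = dataset.mutation.labels_for(gene)
            try:
                call = run_sam(dataset.expression, labels, sam_config)
            except UntestableGroup:
                continue
            tested += 1
            up = set(call.significant_up) - {gene}
            down = set(call.significant_down) - {gene}
            total += len(up) + len(down)
        any_testable = any_testable or tested > 0
        rows.append({"candidate": idx, "n_control_genes_tested": tested,
                     "total_significant": total})
    if not any_testable:
        raise ValueError("no control gene testable in any candidate expression table")
    scores = pd.DataFrame(rows).set_index("candidate")
    best = int(scores["total_significant"].idxmax())  # idxmax -> first max (tie rule)
    logger.info("select_expression_source: chose candidate %d of %d", best, len(candidates))
    return best, scores


def write_matrix_tsv(matrix: MutationMatrix | ExpressionMatrix, path: str | Path,
                     provenance: str | None = None) -> None:
    """Serialize a matrix as TSV (genes as rows); optional provenance sidecar."""
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if provenance is not None:
        Path(str(path) + ".provenance.txt").write_text(provenance)
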