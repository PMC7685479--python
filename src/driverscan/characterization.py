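"""Post-hoc characterization of candidate genes.

Covers the 20/20 rule (oncogene: >20% of a gene's mutations are missense at
a recurrent protein position; tumor suppressor: >20% truncating), gene- and
protein-length comparisons between gene groups (Kolmogorov-Smirnov) as a
conservation surrogate, 2x2 chi-square tests, and hypergeometric gene-set
over-representation with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import TRUNCATING_CLASSES, GeneCatalog, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class TwentyTwentyResult:
    """20/20-rule classification of one gene in one cohort."""

    gene: str
    cohort: str | None
    n_mutations: int
    recurrent_missense_fraction: float
    truncating_fraction: float
    oncogene_flag: bool
    tsg_flag: bool
    classified: bool
    combined_label: str  # "oncogene" | "tsg" | "unclassified"


def classify_20_20(records: Sequence[VariantRecord], min_mutations: int = 5,
                   cohort: str | None = None) -> TwentyTwentyResult:
    """Apply the 20/20 rule to one gene's (already filtered) records.

    ``recurrent_missense_fraction`` is the share of ALL the gene's retained
    mutations that are missense at a protein position carrying >= 2 of the
    gene's missense mutations ("same locus"); when no missense record has a
    protein position, genomic start positions are used as the locus fallback.
    Flags use the strict > 0.20 rule; genes with fewer than ``min_mutations``
    records keep their computed flags but are labeled "unclassified". When
    both flags fire the combined label is "tsg" (truncating evidence
    dominates).
    """
    if not records:
        raise ValueError("classify_20_20 requires at least one record")
    genes = {r.gene for r in records}
    if len(genes) != 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    (gene,) = genes
    n = len(records)
    missense = [r for r in records if r.classification == "Missense_Mutation"]
    loci = [r.protein_position for r in missense if r.protein_position is not None]
    if missense and not loci:
        loci = [r.start for r in missense if r.start is not None]
        if loci:
            logger.info("classify_20_20 %s: no protein positions, using genomic starts", gene)
    n_missing = len(missense) - len(loci)
    if n_missing:
        logger.info("classify_20_20 %s: %d missense record(s) without a locus "
                    "count toward the denominator only", gene, n_missing)
    counts = Counter(loci)
    recurrent = sum(c for c in counts.values() if c >= 2)
    recurrent_fraction = recurrent / n
    truncating = sum(1 for r in records if r.classification in TRUNCATING_CLASSES)
    truncating_fraction = truncating / n
    oncogene_flag = recurrent_fraction > 0.20
    tsg_flag = truncating_fraction > 0.20
    classified = n >= min_mutations
    if not classified:
        label = "unclassified"
    elif tsg_flag:
        label = "tsg"
    elif oncogene_flag:
        label = "oncogene"
    else:
        label = "unclassified"
    return TwentyTwentyResult(gene=gene, cohort=cohort, n_mutations=n,
                              recurrent_missense_fraction=recurrent_fraction,
                              truncating_fraction=truncating_fraction,
                              oncogene_flag=oncogene_flag, tsg_flag=tsg_flag,
                              classified=classified, combined_label=label)


def classify_20_20_by_gene(records: Sequence[VariantRecord], min_mutations: int = 5,
                           cohort: str | None = None) -> dict[str, TwentyTwentyResult]:
    """Classify every gene present in a record list."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    return {g: classify_20_20(rs, min_mutations=min_mutations, cohort=cohort)
            for g, rs in by_gene.items()}


def compare_lengths(groups: Mapping[str, Iterable[str]],
                    catalog: GeneCatalog) -> pd.DataFrame:
    """Pairwise two-sample K-S tests on gene and protein lengths.

    Genes lacking the relevant length are excluded (counts reported); pairs
    where either group has fewer than 2 measurable genes are skipped with a
    warning.
    """
    rows = []
    for length_type, getter in (("gene_length", catalog.gene_length),
                                ("protein_length", catalog.protein_length)):
        measured = {name: np.array([v for g in genes
                                    if (v := getter(g)) is not None])
                    for name, genes in groups.items()}
        for a, b in combinations(groups.keys(), 2):
            xa, xb = measured[a], measured[b]
            if len(xa) < 2 or len(xb) < 2:
                logger.warning("compare_lengths: skipping %s %s vs %s (<2 measurable genes)",
                               length_type, a, b)
                continue
            ks = stats.ks_2samp(xa, xb)
            rows.append({"length_type": length_type, "group_a": a, "group_b": b,
                         "n_a": len(xa), "n_b": len(xb),
                         "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
                         "ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue)})
    return pd.DataFrame(rows)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (df = 1, upper-tail p).

    Continuity correction is off by default; a zero row or column margin is
    an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


@dataclass
class EnrichmentRow:
    """One gene set's over-representation result."""

    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float
    overlap_genes: tuple[str, ...] = ()


def enrich_gene_sets(query: Iterable[str], universe: Iterable[str],
                     sets: Mapping[str, Iterable[str]],
                     min_overlap: int = 1) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` within each gene set.

    Sets are intersected with the universe; query genes outside the universe
    are dropped (logged). p is the upper tail P(overlap >= observed) for
    (universe_size, set_size, query_size); BH adjustment is applied across
    the reported rows (those with overlap >= min_overlap).
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    query_set = frozenset(query)
    dropped = query_set - universe_set
    if dropped:
        logger.info("enrich_gene_sets: %d query gene(s) outside the universe dropped", len(dropped))
    query_set &= universe_set
    rows = []
    for name, members in sets.items():
        member_set = frozenset(members) & universe_set
        overlap_genes = tuple(sorted(query_set & member_set))
        k = len(overlap_genes)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, len(universe_set), len(member_set), len(query_set)))
        rows.append(EnrichmentRow(set_name=name, overlap=k, set_size=len(member_set),
                                  query_size=len(query_set),
                                  universe_size=len(universe_set),
                                  p_value=min(p, 1.0), adjusted_p=1.0,
                                  overlap_genes=overlap_genes))
    if rows:
        _, adj, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, a in zip(rows, adj):
            r.adjusted_p = float(a)
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
        "query_size": r.query_size, "universe_size": r.universe_size,
        "p_value": r.p_value, "adjusted_p": r.adjusted_p,
        "overlap_genes": ",".join(r.overlap_genes),
    } for r in rows])


def oncogene_tsg_rates(groups: Mapping[str, Iterable[str]],
                       results: Mapping[str, TwentyTwentyResult],
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group oncogene/TSG rates and pairwise 2x2 chi-square tests.

    A gene counts as flagged only when classified (enough mutations); the
    unclassified count is reported separately but stays in the denominator.
    """
    rates = []
    flagged: dict[str, dict[str, np.ndarray]] = {}
    for name, genes in groups.items():
        genes = list(genes)
        onc = np.array([g in results and results[g].classified and results[g].oncogene_flag
                        for g in genes])
        tsg = np.array([g in results and results[g].classified and results[g].tsg_flag
                        for g in genes])
        unclassified = sum(1 for g in genes
                           if g not in results or not results[g].classified)
        flagged[name] = {"oncogene": onc, "tsg": tsg}
        rates.append({"group": name, "n_genes": len(genes),
                      "n_unclassified": unclassified,
                      "oncogene_rate": float(onc.mean()) if len(genes) else float("nan"),
                      "tsg_rate": float(tsg.mean()) if len(genes) else float("nan")})
    tests = []
    for a, b in combinations(groups.keys(), 2):
        for kind in ("oncogene", "tsg"):
            fa, fb = flagged[a][kind], flagged[b][kind]
            table = [[int(fa.sum()), int((~fa).sum())],
                     [int(fb.sum()), int((~fb).sum())]]
            try:
                stat, p = chi_square_2x2(table)
            except ValueError:
                stat, p = float("nan"), float("nan")
            tests.append({"group_a": a, "group_b": b, "flag": kind,
                          "chi2": stat, "p": p})
    return pd.DataFrame(rates), pd.DataFrame(tests)


def functional_impact_summary(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabulate SIFT/PolyPhen verdicts already present in the MAF (no API calls)."""
    rows = []
    for col in ("sift", "polyphen"):
        counts = Counter(getattr(r, col) for r in records if getattr(r, col))
        for verdict, n in sorted(counts.items()):
            rows.append({"annotation": col, "verdict": verdict, "n": n})
    return pd.DataFrame(rows)
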