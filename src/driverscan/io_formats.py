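"""Readers and writers for the tabular formats the pipeline consumes.

Covers MAF somatic mutation tables, gene × sample expression TSVs, GMT
gene-set collections, plain gene lists, and the gene annotation catalog,
plus the variant-classification (pathogenicity) filter applied before any
mutation matrix is built. All readers transparently accept gzip-compressed
files and normalize gene symbols to uppercase, stripped form.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# MAF Variant_Classification controlled vocabulary.
MAF_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site", "Silent", "Intron",
    "3'UTR", "5'UTR", "3'Flank", "5'Flank", "RNA", "IGR", "Targeted_Region",
})

#: Classes retained by default as potentially pathogenic: the standard
#: non-synonymous MAF convention (everything expected to alter the protein).
DEFAULT_RETAINED_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
})

#: Classes counted as protein-truncating by the 20/20 classifier.
TRUNCATING_CLASSES = frozenset({
    "Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins",
    "Splice_Site", "Nonstop_Mutation", "Translation_Start_Site",
})

_PROTEIN_POS_RE = re.compile(r"p\.[^\d]*(\d+)")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene symbol form: uppercase, surrounding whitespace stripped."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class VariantRecord:
    """One somatic mutation call.

    ``protein_position`` is the integer residue parsed from a
    ``Protein_Change``/``HGVSp_Short`` string such as ``p.R175H`` (-> 175).
    ``sift``/``polyphen`` carry functional-impact verdicts when the source
    MAF provides those columns; they are never computed here.
    """

    gene: str
    sample: str
    classification: str
    protein_position: int | None = None
    chromosome: str | None = None
    start: int | None = None  # 1-based inclusive, MAF convention
    sift: str | None = None
    polyphen: str | None = None


@dataclass
class GeneCatalog:
    """Per-gene annotation: known-cancer-gene flag and optional lengths (bp/aa)."""

    table: pd.DataFrame  # index: symbol; columns: known_cancer_gene, gene_length, protein_length

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate catalog symbols: {dups}")

    @property
    def known_genes(self) -> frozenset[str]:
        if "known_cancer_gene" not in self.table.columns:
            return frozenset()
        flag = self.table["known_cancer_gene"].fillna(False).astype(bool)
        return frozenset(self.table.index[flag])

    def is_known(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.known_genes

    def _length(self, gene: str, column: str) -> float | None:
        gene = normalize_symbol(gene)
        if column not in self.table.columns or gene not in self.table.index:
            return None
        value = self.table.at[gene, column]
        return None if pd.isna(value) else float(value)

    def gene_length(self, gene: str) -> float | None:
        return self._length(gene, "gene_length")

    def protein_length(self, gene: str) -> float | None:
        return self._length(gene, "protein_length")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_protein_position(change: str | None) -> int | None:
    """Extract the residue number from an HGVS-style protein change string."""
    if not change:
        return None
    m = _PROTEIN_POS_RE.search(change)
    if m is None:
        return None
    pos = int(m.group(1))
    return pos if pos >= 1 else None


_MAF_MANDATORY = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a MAF (tab-separated) file into :class:`VariantRecord` objects.

    Comment lines starting with ``#`` are skipped; unknown columns are
    ignored; missing mandatory columns raise a ``ValueError`` naming them.
    """
    with _open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] < len(_MAF_MANDATORY)):
        logger.warning("MAF file %s is empty", path)
        return []
    missing = [c for c in _MAF_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} lacks mandatory column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("MAF file %s has a header but no records", path)
        return []

    protein_col = next((c for c in ("Protein_Change", "HGVSp_Short") if c in df.columns), None)
    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        start = rowd.get("Start_Position") or None
        records.append(VariantRecord(
            gene=normalize_symbol(rowd["Hugo_Symbol"]),
            sample=rowd["Tumor_Sample_Barcode"].strip(),
            classification=rowd["Variant_Classification"].strip(),
            protein_position=parse_protein_position(rowd.get(protein_col) if protein_col else None),
            chromosome=(rowd.get("Chromosome") or None),
            start=int(start) if start else None,
            sift=(rowd.get("SIFT") or None),
            polyphen=(rowd.get("PolyPhen") or None),
        ))
    return records


def write_maf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a standard MAF TSV (mandatory + optional columns)."""
    columns = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
               "Protein_Change", "Chromosome", "Start_Position", "SIFT", "PolyPhen"]
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            writer.writerow([
                r.gene, r.sample, r.classification,
                f"p.X{r.protein_position}X" if r.protein_position is not None else "",
                r.chromosome or "", r.start if r.start is not None else "",
                r.sift or "", r.polyphen or "",
            ])


def filter_pathogenic(records: Sequence[VariantRecord],
                      retained_classes: Iterable[str] = DEFAULT_RETAINED_CLASSES,
                      ) -> list[VariantRecord]:
    """Keep only records whose classification is in ``retained_classes``.

    Order-preserving and idempotent; records with classifications outside the
    MAF vocabulary are dropped and counted in the log.
    """
    retained = frozenset(retained_classes)
    if not retained:
        raise ValueError("retained_classes must be non-empty")
    kept = [r for r in records if r.classification in retained]
    unknown = sum(1 for r in records if r.classification not in MAF_CLASSES)
    if unknown:
        logger.info("filter_pathogenic: %d record(s) with unknown classification dropped", unknown)
    logger.info("filter_pathogenic: kept %d / %d records", len(kept), len(records))
    return kept


def read_expression(path: str | Path, collapse: str = "mean") -> pd.DataFrame:
    """Read a gene × sample expression TSV (first column = gene symbol).

    Values are parsed as floats; empty cells become missing (NaN); any other
    non-numeric cell raises with its (gene, sample) coordinates; ragged rows
    raise with their line number. Duplicate gene rows are collapsed by
    ``collapse`` ("mean", "first" or "max").
    """
    with _open_text(path) as handle:
        lines = [line.rstrip("\n") for line in handle if line.strip() != ""]
    if not lines:
        raise ValueError(f"expression file {path} is empty")
    header = lines[0].split("\t")
    samples = [s.strip() for s in header[1:]]
    if len(set(samples)) != len(samples):
        raise ValueError(f"expression file {path} has duplicate sample columns")
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"expression file {path}: row {lineno} has {len(parts)} fields, expected {len(header)}")
        gene = normalize_symbol(parts[0])
        values = []
        for sample, cell in zip(samples, parts[1:]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                values.append(float("nan"))
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"expression file {path}: non-numeric value {cell!r} at gene {gene}, sample {sample}"
                ) from None
        genes.append(gene)
        rows.append(values)
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=samples)
    if df.index.has_duplicates:
        if collapse not in ("mean", "first", "max"):
            raise ValueError(f"unknown duplicate-collapse rule {collapse!r}")
        n_dup = int(df.index.duplicated().sum())
        logger.info("read_expression: collapsing %d duplicate gene row(s) by %s", n_dup, collapse)
        grouped = df.groupby(level=0, sort=False)
        df = getattr(grouped, collapse)()
    return df


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    """Write a gene × sample table as TSV with the gene symbol as first column."""
    with _open_text(path, "wt") as handle:
        table.to_csv(handle, sep="\t", index_label="gene")


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: dict[str, frozenset[str]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT {path}: line {lineno} has fewer than 3 fields")
            name = parts[0].strip()
            if name in sets:
                raise ValueError(f"GMT {path}: duplicate set name {name!r} at line {lineno}")
            members = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
            sets[name] = members
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene symbol per line; duplicates collapse into the returned set."""
    with _open_text(path) as handle:
        return frozenset(normalize_symbol(line) for line in handle if line.strip())


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for g in sorted(set(genes)):
            handle.write(g + "\n")


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a CSV/TSV gene catalog (symbol, known_cancer_gene, optional lengths)."""
    with _open_text(path) as handle:
        first = handle.readline()
        sep = "\t" if "\t" in first else ","
        df = pd.read_csv(io.StringIO(first + handle.read()), sep=sep)
    symbol_col = next((c for c in ("gene", "symbol", "Hugo_Symbol") if c in df.columns), None)
    if symbol_col is None:
        raise ValueError(f"catalog {path} lacks a gene/symbol column")
    df[symbol_col] = df[symbol_col].map(normalize_symbol)
    if df[symbol_col].duplicated().any():
        dups = df.loc[df[symbol_col].duplicated(), symbol_col].tolist()
        raise ValueError(f"catalog {path}: duplicate symbol(s) {dups}")
    df = df.set_index(symbol_col)
    if "known_cancer_gene" in df.columns:
        df["known_cancer_gene"] = (
            df["known_cancer_gene"].astype(str).str.strip().str.lower()
            .isin({"1", "true", "yes", "y"}))
    for col in ("gene_length", "protein_length"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
            if (df[col].dropna() <= 0).any():
                raise ValueError(f"catalog {path}: non-positive {col}")
    return GeneCatalog(df)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        catalog.table.to_csv(handle, index_label="gene")
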