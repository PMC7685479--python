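#!/usr/bin/env python
"""Characterize the discovered candidates: 20/20 rule, lengths, enrichment.

Classifies every candidate's mutation pattern per cohort with the 20/20
rule, compares gene/protein lengths of candidates vs known vs other genes
(K-S tests), and tests over-representation of the candidate list in gene
sets built from the planted driver-target structure plus random decoys.
Writes tables under results/characterization/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from driverscan.characterization import (classify_20_20_by_gene,
                                         compare_lengths, enrich_gene_sets,
                                         enrichment_table, oncogene_tsg_rates)
from driverscan.io_formats import (filter_pathogenic, read_gene_catalog,
                                   read_gene_list, read_maf)
from driverscan.synthetic_data import SimulationConfig, make_truth

SEED = 20257
ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    sim_dir, disc_dir = SCRATCH / "sim", ROOT / "discovery"
    if not disc_dir.exists():
        print("run analysis/02_discover.py first", file=sys.stderr)
        return 1
    out = ROOT / "characterization"
    out.mkdir(parents=True, exist_ok=True)
    truth = make_truth(SimulationConfig(seed=SEED))
    candidates = pd.read_csv(disc_dir / "candidates.tsv", sep="\t")
    candidate_genes = set(candidates.loc[candidates.is_candidate, "gene"])
    known = read_gene_list(sim_dir / "known_genes.txt")
    catalog = read_gene_catalog(sim_dir / "catalog.csv")
    universe = set(truth.gene_universe)

    # 20/20 rule per cohort, restricted to candidates
    rows = []
    results_pooled = {}
    for c in range(3):
        records = filter_pathogenic(read_maf(sim_dir / f"cohort{c + 1}.maf"))
        per_gene = classify_20_20_by_gene(records, cohort=f"cohort{c + 1}")
        results_pooled.update({g: r for g, r in per_gene.items()
                               if g not in results_pooled})
        for g in sorted(candidate_genes):
            if g in per_gene:
                r = per_gene[g]
                rows.append({"gene": g, "cohort": r.cohort,
                             "n_mutations": r.n_mutations,
                             "recurrent_missense_fraction": round(r.recurrent_missense_fraction, 4),
                             "truncating_fraction": round(r.truncating_fraction, 4),
                             "label": r.combined_label})
    pd.DataFrame(rows).to_csv(out / "twenty_twenty.tsv", sep="\t", index=False)
    labels = pd.DataFrame(rows)["label"].value_counts().to_dict() if rows else {}
    print(f"20/20 labels over candidate x cohort pairs: {labels}")

    groups = {"candidate": sorted(candidate_genes),
              "known": sorted(known - candidate_genes),
              "other": sorted(universe - candidate_genes - known)}
    lengths = compare_lengths(groups, catalog)
    lengths.to_csv(out / "length_comparison.tsv", sep="\t", index=False)
    for _, r in lengths[lengths.length_type == "gene_length"].iterrows():
        print(f"gene length {r.group_a} (mean {r.mean_a:.0f} bp) vs {r.group_b} "
              f"(mean {r.mean_b:.0f} bp): K-S D={r.ks_statistic:.3f}, p={r.ks_p:.2e}")

    rates, tests = oncogene_tsg_rates(groups, results_pooled)
    rates.to_csv(out / "oncogene_tsg_rates.tsv", sep="\t", index=False)
    tests.to_csv(out / "oncogene_tsg_tests.tsv", sep="\t", index=False)

    # gene sets: "pathway" sets seeded with planted drivers, plus random decoys
    rng = np.random.default_rng(SEED)
    drivers = list(truth.driver_genes)
    sets = {}
    for j in range(8):
        seeded = rng.choice(drivers, size=5, replace=False)
        padding = rng.choice(sorted(universe - set(drivers)), size=25, replace=False)
        sets[f"PATHWAY_{j}"] = set(seeded) | set(padding)
    for j in range(20):
        sets[f"RANDOM_{j}"] = set(rng.choice(sorted(universe), size=30, replace=False))
    enr = enrich_gene_sets(candidate_genes, universe, sets)
    enrichment_table(enr).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    top = [r for r in enr if r.adjusted_p < 0.05]
    if top:
        print(f"{len(top)} gene sets enriched at BH-adjusted p < 0.05 "
              f"(top: {top[0].set_name}, p={top[0].p_value:.3g})")
    else:
        print("no gene set enriched at BH-adjusted p < 0.05")
    print(f"tables in {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
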