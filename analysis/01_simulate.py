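#!/usr/bin/env python
"""Generate the synthetic multi-cohort study used by the downstream steps.

Three cohorts of 150 tumor samples share a pool of 100 mutated genes; 20 of
those are planted drivers that shift the expression of 30 target genes each
by 1.5 noise SDs in carrier samples, and 80 are expression-silent passengers
mutated at the same frequency. Writes per-cohort MAF + expression TSVs, the
planted truth, the known-gene list and a synthetic annotation catalog under
results/sim/.
"""

import sys
from pathlib import Path

from driverscan.io_formats import write_gene_catalog, write_gene_list
from driverscan.synthetic_data import (SimulationConfig, simulate_gene_catalog,
                                       simulate_multi_cancer, write_cohort,
                                       write_truth)

SEED = 20257
OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    cohorts, truth = simulate_multi_cancer(config)
    OUT.mkdir(parents=True, exist_ok=True)
    for c, (mut, expr, records) in enumerate(cohorts):
        paths = write_cohort(OUT, f"cohort{c + 1}", mut, expr, records)
        print(f"cohort{c + 1}: {len(records)} mutation records, "
              f"{expr.values.shape[0]} x {expr.values.shape[1]} expression -> "
              f"{paths['maf'].name}, {paths['expression'].name}")
    write_truth(truth, OUT / "truth.txt")
    write_gene_list(truth.known_genes, OUT / "known_genes.txt")
    write_gene_catalog(simulate_gene_catalog(truth, seed=SEED), OUT / "catalog.csv")
    print(f"planted {len(truth.driver_genes)} drivers and "
          f"{len(truth.passenger_pool)} pool passengers; "
          f"{len(truth.known_genes)} genes labeled known cancer genes")
    print(f"wrote study to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
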