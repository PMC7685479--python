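"""Run configuration: a YAML file naming inputs and parameters.

Either ``cohorts`` (per-cohort MAF + expression paths) or ``simulate``
(a synthetic-study block) must be present. Unknown keys are errors — a typo
must never silently fall back to a default — and every filled default is
recorded with its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .io_formats import DEFAULT_RETAINED_CLASSES
from .sam import SamConfig
from .synthetic_data import SimulationConfig


@dataclass
class CohortSpec:
    name: str
    maf: str
    expression: list[str]  # >= 1 candidate table; >1 triggers the control experiment


@dataclass
class RunConfig:
    cohorts: list[CohortSpec] = field(default_factory=list)
    simulate: SimulationConfig | None = None
    known_genes: str | None = None
    catalog: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    control_genes: list[str] = field(default_factory=lambda: ["BRCA1", "BRCA2", "TP53"])
    sam: SamConfig = field(default_factory=SamConfig)
    min_affected: int = 1
    retained_classes: frozenset[str] = DEFAULT_RETAINED_CLASSES
    output_dir: str = "results"
    seed: int = 0
    default_provenance: dict[str, str] = field(default_factory=dict)


_TOP_KEYS = {"cohorts", "simulate", "known_genes", "catalog", "gene_sets",
             "control_genes", "sam", "min_affected", "retained_classes",
             "output_dir", "seed"}
_SAM_KEYS = {f.name for f in fields(SamConfig)}
_SIM_KEYS = {f.name for f in fields(SimulationConfig)}
_COHORT_KEYS = {"name", "maf", "expression"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {', '.join(unknown)}")


def validate_config(path: str | Path) -> RunConfig:
    """Parse, validate and default-fill a run configuration file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a key-value mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    provenance: dict[str, str] = {}

    cohorts = []
    for i, spec in enumerate(raw.get("cohorts") or []):
        _check_keys(spec, _COHORT_KEYS, f"cohorts[{i}]")
        expr = spec["expression"]
        cohorts.append(CohortSpec(name=spec["name"], maf=spec["maf"],
                                  expression=[expr] if isinstance(expr, str) else list(expr)))
    simulate = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim = dict(raw["simulate"])
        _check_keys(sim, _SIM_KEYS, "simulate")
        simulate = SimulationConfig(**sim)
    if not cohorts and simulate is None:
        raise ValueError("config must name either 'cohorts' or a 'simulate' block")

    sam_raw = dict(raw.get("sam") or {})
    _check_keys(sam_raw, _SAM_KEYS, "sam")
    for f in fields(SamConfig):
        if f.name not in sam_raw:
            provenance[f"sam.{f.name}"] = "default"
    sam = SamConfig(**sam_raw)

    for key, default in (("min_affected", 1), ("output_dir", "results"), ("seed", 0)):
        if key not in raw:
            provenance[key] = "default"
    retained = raw.get("retained_classes")
    if retained is None:
        provenance["retained_classes"] = "default (standard non-synonymous classes)"
        retained = DEFAULT_RETAINED_CLASSES

    config = RunConfig(
        cohorts=cohorts, simulate=simulate,
        known_genes=raw.get("known_genes"), catalog=raw.get("catalog"),
        gene_sets=list(raw.get("gene_sets") or []),
        control_genes=list(raw.get("control_genes") or ["BRCA1", "BRCA2", "TP53"]),
        sam=sam, min_affected=int(raw.get("min_affected", 1)),
        retained_classes=frozenset(retained),
        output_dir=str(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
        default_provenance=provenance,
    )

    missing: list[str] = []
    for spec in config.cohorts:
        for p in [spec.maf, *spec.expression]:
            if not Path(p).exists():
                missing.append(p)
    for p in [config.known_genes, config.catalog, *config.gene_sets]:
        if p is not None and not Path(p).exists():
            missing.append(p)
    if missing:
        raise FileNotFoundError("missing input file(s): " + ", ".join(missing))
    return config


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through validate_config)."""
    doc: dict = {
        "min_affected": config.min_affected,
        "output_dir": config.output_dir,
        "seed": config.seed,
        "retained_classes": sorted(config.retained_classes),
        "control_genes": list(config.control_genes),
        "sam": {"n_permutations": config.sam.n_permutations,
                "target_fdr": config.sam.target_fdr,
                "s0_mode": config.sam.s0_mode,
                "min_group_size": config.sam.min_group_size,
                "n_delta": config.sam.n_delta},
    }
    if config.cohorts:
        doc["cohorts"] = [{"name": c.name, "maf": c.maf, "expression": c.expression}
                          for c in config.cohorts]
    if config.simulate is not None:
        sim = {f.name: getattr(config.simulate, f.name) for f in fields(SimulationConfig)}
        sim["variant_class_mix"] = dict(sim["variant_class_mix"])
        doc["simulate"] = sim
    for key in ("known_genes", "catalog"):
        if getattr(config, key):
            doc[key] = getattr(config, key)
    if config.gene_sets:
        doc["gene_sets"] = list(config.gene_sets)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
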