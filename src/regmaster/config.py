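"""Pipeline configuration (YAML) with the standard defaults baked in."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineParams", "CohortSpec", "SurvivalSpec", "PipelineConfig"]

DEFAULT_SEED = 20190910


@dataclass
class PipelineParams:
    """Every downstream tunable with its standard default."""

    n_perm: int = 1000            # network permutation count
    p_cut: float = 0.001          # adjusted-p cutoff for network edges
    n_boot: int = 100             # bootstrap resamples
    support_min: float = 0.95     # bootstrap consensus fraction
    dpi_tolerance: float = 0.0
    null_pairs_per_perm: int = 200
    deg_fdr: float = 0.05
    deg_lfc: float = 1.0
    mra_fdr: float = 0.05
    consensus_frac: float = 0.8   # >=80% of case-control studies
    min_regulon_size: int = 51    # regulon size > 50
    gsea_n_perm: int = 1000
    gsea_fdr: float = 0.05
    gsea_rank_by: str = "logFC"
    gsva_mode_handling: str = "whole"
    survival_frac: float = 0.5    # >=50% of survival studies
    survival_p: float = 0.05
    cmap_n_perm: int = 1000
    cmap_fdr: float = 0.05
    min_tags: int = 10


@dataclass
class CohortSpec:
    id: str
    expression: str
    labels: str | None = None


@dataclass
class SurvivalSpec:
    id: str
    expression: str
    clinical: str


@dataclass
class PipelineConfig:
    reference_cohorts: list[CohortSpec]
    case_control: list[CohortSpec]
    tfs: str
    outdir: str = "regmaster_out"
    survival: list[SurvivalSpec] = field(default_factory=list)
    drug_reference: str | None = None
    seed: int = DEFAULT_SEED
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if not self.reference_cohorts:
            raise ValueError("at least one reference cohort is required")
        if not self.case_control:
            raise ValueError("at least one case-control study is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            reference_cohorts=[CohortSpec(**c) for c in raw["reference_cohorts"]],
            case_control=[CohortSpec(**c) for c in raw["case_control"]],
            tfs=raw["tfs"],
            outdir=raw.get("outdir", "regmaster_out"),
            survival=[SurvivalSpec(**c) for c in raw.get("survival", [])],
            drug_reference=raw.get("drug_reference"),
            seed=raw.get("seed", DEFAULT_SEED),
            params=PipelineParams(**raw.get("params", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "reference_cohorts": [dataclasses.asdict(c)
                                  for c in self.reference_cohorts],
            "case_control": [dataclasses.asdict(c) for c in self.case_control],
            "tfs": self.tfs,
            "outdir": self.outdir,
            "survival": [dataclasses.asdict(c) for c in self.survival],
            "drug_reference": self.drug_reference,
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
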