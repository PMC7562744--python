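"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

ALL_STAGES = ("simulate", "scale", "decompose", "cluster", "model", "states", "atac")


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    # synthetic inputs
    n_genes: int = Field(300, ge=0)
    n_enhancers: int = Field(100, ge=0)
    depth: int = Field(200_000, gt=0)
    dispersion: float = Field(0.05, ge=0)

    # analysis thresholds
    window_preset: str = "quantify"
    tau_log2: float = Field(0.25, gt=0)
    delta_log2: float = Field(0.5, gt=0)
    padj_de: float = Field(0.05, gt=0, lt=1)
    padj_differentiation: float = Field(0.01, gt=0, lt=1)
    pseudocount: float = Field(0.0, ge=0)
    count_pseudocount: float = Field(1.0, ge=0)
    mark_cutoff_log2: float = 0.5  # gene counts as H3K79me2-marked above this
    k_clusters: int = Field(5, ge=2)

    # posterior sampling
    chains: int = Field(4, ge=1)
    draws: int = Field(2000, ge=100)
    warmup: int = Field(1000, ge=100)

    # accessibility
    atac_component: int = Field(1, ge=1)
    atac_top_n: int = Field(200, ge=1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)
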