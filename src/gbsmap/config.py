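"""Pipeline configuration: every numeric threshold in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds for read processing, variant calling and mapping.

    Defaults follow the published pipeline settings for polyploid wheat GBS
    data; fields without a published value are documented where they are
    used and are deliberate, overridable choices.
    """

    # read processing
    q_min: int = 15
    max_lowq_frac: float = 0.20
    min_read_len: int = 30  # tags shorter than this cannot be clustered reliably

    # reference construction / alignment
    snp_identity: float = 0.96
    pa_identity: float = 1.00
    snp_max_mismatch: int = 3
    pa_max_mismatch: int = 1
    merge_max_mismatch: int = 3
    pa_merge_max_mismatch: int = 0  # PA reference keeps divergent alleles separate
    pa_min_parent_depth: int = 2  # parental read support required for a PA reference entry
    min_overlap: int = 30

    # SNP genotype calling and post-filters
    min_depth: int = 1
    max_nonparental_frac: float = 0.02
    max_missing_frac: float = 0.80
    ratio_alpha: float = 0.01
    expected_variant_fraction: float = 1 / 3  # 1/n_subgenomes for collapsed-homeolog tags

    # presence/absence calling
    min_presence: int = 10
    pa_pvalue: float = 0.001

    # genetic mapping
    max_r: float = 0.10
    lod_reference: float = 6.0
    lod_denovo: float = 8.0
    max_dist_cM: float = 20.0
    denovo_max_missing: float = 0.20
    denovo_max_het: float = 0.05
    mapping_function: str = "haldane"  # or "kosambi"

    def __post_init__(self):
        for name in (
            "max_lowq_frac",
            "snp_identity",
            "pa_identity",
            "max_nonparental_frac",
            "max_missing_frac",
            "ratio_alpha",
            "expected_variant_fraction",
            "pa_pvalue",
            "max_r",
            "denovo_max_missing",
            "denovo_max_het",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("q_min", "min_read_len", "snp_max_mismatch", "pa_max_mismatch",
                     "merge_max_mismatch", "min_depth", "min_presence", "min_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mapping_function not in ("haldane", "kosambi"):
            raise ValueError("mapping_function must be 'haldane' or 'kosambi'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d.get("pipeline", d))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
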