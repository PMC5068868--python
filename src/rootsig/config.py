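"""Pipeline configuration: a flat, validated YAML-serializable record."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every stage parameter of the end-to-end analysis.

    Unknown keys in a YAML file are rejected; each run writes the resolved
    config next to its outputs so results can be regenerated bit-for-bit.
    """

    # I/O
    outdir: str = "rootsig_out"
    gene_lists: str | None = None  # GMT path; None -> simulate a corpus
    # simulation (used when gene_lists is None)
    n_experiments: int = 9
    biosets_per_experiment: int = 3
    universe_size: int = 2000
    baseline_inclusion_prob: float = 0.05
    experiment_specific_genes: int = 60
    experiment_share_prob: float = 0.7
    signature_size: int = 0
    signature_biosets: list[str] | None = None
    signature_inclusion_prob: float = 0.95
    # DE selection
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.2
    t_test_variant: str = "welch"
    paired: bool = False
    # clustering
    linkage: str = "average"
    k: int = 14
    mds_dims: int = 2
    # bootstrap stability
    B: int = 1000
    robust_threshold: float = 0.6
    dissolved_threshold: float = 0.5
    # root analysis
    min_support: float = 1.0
    root_cluster_members: list[str] | None = None  # None -> most stable cluster
    reference_lists: dict[str, str] | None = None  # name -> txt path
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
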