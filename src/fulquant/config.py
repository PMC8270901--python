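"""Pipeline configuration with the published default parameterization.

Every threshold defaults to the constant of the reference protocol, so an
empty override section reproduces the published analysis: qscore cutoff 6,
ISPCR adapter, polyA >= 10 bases with one mismatch, 200-bp end windows,
soft-clip limit 30, junction-insertion limit 5, clustering constants
HFWINSIZE=5 / DISTHRES=8 / PTHRESHOLD=3 / SUMHOLD=5, transcript filters
(count > 3, > 40% full-length, polyA distance 10, strand required), locus
rules (> 3% of the maximum, 25% truncation rescue), NMD distance 55,
co-association alpha 0.001, usage alpha 0.005, DE prefilter > 10 counts.
The minimap2 invocation of the reference protocol is recorded for
provenance only; alignment itself is out of scope.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from .preprocess import ISPCR_ADAPTER

MINIMAP2_PROVENANCE = "-K500m -secondary=no -a -x splice -splice-flank=yes"


@dataclass
class SampleSpec:
    sample_id: str
    condition: str = ""
    build_annotation: bool = True
    fastq: Optional[str] = None
    bam: Optional[str] = None


@dataclass
class PipelineConfig:
    # preprocess
    qscore_cutoff: float = 6.0
    adapter: str = ISPCR_ADAPTER
    end_window: int = 200
    adapter_min_identity: float = 0.7
    polya_min_length: int = 10
    polya_max_mismatch: int = 1
    min_read_length: int = 50
    # alignment filters
    max_softclip: int = 30
    max_junction_insert: int = 5
    junction_insert_window: int = 10
    # splice-site clustering
    hfwinsize: int = 5
    disthres: int = 8
    pthreshold: int = 3
    sumhold: int = 5
    # transcript filters
    min_read_count: int = 3  # strict >
    min_full_length_fraction: float = 0.40  # strict >
    polya_distance: int = 10
    # locus rules
    locus_min_fraction: float = 0.03  # strict >
    truncation_rescue_fraction: float = 0.25  # strict >
    misalignment_check: bool = True
    # downstream statistics
    nmd_distance: int = 55  # strict >
    coassociation_alpha: float = 0.001
    usage_alpha: float = 0.005
    de_prefilter_min_total: int = 10  # strict >
    # inputs
    genome_fasta: Optional[str] = None
    reference_gtf: Optional[str] = None
    repeats_bed: Optional[str] = None
    samples: List[SampleSpec] = field(default_factory=list)
    aligner_provenance: str = MINIMAP2_PROVENANCE

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        samples = [SampleSpec(**s) for s in data.pop("samples", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(samples=samples, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
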