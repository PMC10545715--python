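"""Run configuration for the synthetic dual RNA-seq study.

The defaults emulate a desk-scale version of a mixed host/pathogen
time-course experiment: two genomes of very unequal read share (the
pathogen contributes only a few reads in 10^5, rising over four time
points), a host strain that diverges from its reference assembly by
substitutions and short indels, triplicate libraries per time point, and
a temporal expression program with planted co-expressed gene clusters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

DEFAULT_TIMEPOINTS = ("3h", "12h", "48h", "72h")
# Per-time-point pathogen read share: 0.002% rising to 0.0063%.
DEFAULT_PATHOGEN_FRACTIONS = (2.0e-5, 3.0e-5, 4.5e-5, 6.3e-5)


@dataclass(frozen=True)
class QualityModel:
    """Two-state Phred model: a high-quality body plus an optional
    low-quality 3' tail, so sliding-window trimming has something to act on.

    Per-base error probabilities drive both error injection and the Phred
    string, i.e. qualities are calibrated: Q = -10*log10(p_error), capped.
    """

    tail_prob: float = 0.15       # fraction of reads carrying a low-quality tail
    tail_len: int = 12            # tail length in bases
    tail_error_rate: float = 0.05 # per-base error rate inside the tail (Q13)
    max_phred: int = 40

    def validate(self) -> None:
        if not 0.0 <= self.tail_prob <= 1.0:
            raise ValueError("tail_prob must be in [0, 1]")
        if self.tail_len < 0:
            raise ValueError("tail_len must be >= 0")
        if not 0.0 <= self.tail_error_rate <= 1.0:
            raise ValueError("tail_error_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    pathogen_genome_len: int = 50_000
    host_genome_len: int = 100_000
    gc_content: float = 0.5

    # Host strain divergence from the host reference assembly.
    snp_divergence_rate: float = 0.005
    indel_divergence_rate: float = 2.0e-4
    indel_max_len: int = 8
    # Placement of substitutions: a fraction is concentrated in a few dense
    # hotspots (overdispersed strain divergence); the rest is uniform.
    snp_hotspot_fraction: float = 0.12
    n_snp_hotspots: int = 3
    snp_hotspot_density: float = 0.06  # substitutions per bp inside a hotspot

    # Library structure.
    read_len: int = 100
    fragment_mean: int = 300
    fragment_sd: int = 30
    base_error_rate: float = 1.0e-3
    quality_model: QualityModel = field(default_factory=QualityModel)
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 3
    reads_per_sample: int = 50_000  # read PAIRS per library
    pathogen_read_fraction: tuple[float, ...] = DEFAULT_PATHOGEN_FRACTIONS

    # Gene and expression structure.
    n_genes_host: int = 200
    n_genes_pathogen: int = 100
    min_gene_len: int = 400
    gene_flank: int = 0  # bp of flank around a gene available to fragments
    n_clusters: int = 8
    cluster_profile_sd: float = 0.2      # within-cluster noise, log2 units
    cluster_profile_amplitude: float = 1.5  # SD of centroid coordinates, log2
    cluster_min_separation: float = 10.0    # min centroid distance, in units of SD
    abundance_sigma: float = 1.0         # lognormal spread of basal gene abundance

    def validate(self) -> None:
        rates = {
            "gc_content": self.gc_content,
            "snp_divergence_rate": self.snp_divergence_rate,
            "indel_divergence_rate": self.indel_divergence_rate,
            "base_error_rate": self.base_error_rate,
            "snp_hotspot_fraction": self.snp_hotspot_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.fragment_mean < self.read_len:
            raise ValueError("fragment_mean must be >= read_len")
        if len(self.pathogen_read_fraction) != len(self.timepoints):
            raise ValueError(
                "pathogen_read_fraction must have one entry per timepoint"
            )
        for f in self.pathogen_read_fraction:
            if not 0.0 <= f <= 1.0:
                raise ValueError("pathogen read fractions must be in [0, 1]")
        if self.indel_max_len < 1:
            raise ValueError("indel_max_len must be >= 1")
        if self.read_len < 1 or self.reads_per_sample < 0:
            raise ValueError("read_len and reads_per_sample must be positive")
        if self.n_genes_host < 1 or self.n_genes_pathogen < 1:
            raise ValueError("need at least one gene per organism")
        if self.min_gene_len < self.read_len:
            raise ValueError("min_gene_len must be >= read_len")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        self.quality_model.validate()

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "SimulationConfig":
        if "{" not in source:
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        qm = payload.pop("quality_model", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in payload.items()})
        if qm is not None:
            cfg = replace(cfg, quality_model=QualityModel(**qm))
        cfg.validate()
        return cfg
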