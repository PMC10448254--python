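"""Pipeline configuration.

All thresholds of the annotation pipeline live here so that a run is fully
described by (reference set, input genome, Config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class Config:
    """Tunable parameters of the annotation pipeline.

    k               : k-mer size of the graph; edges are (k+1)-mers.
    min_gene_length : shortest gene typically present in the clade (nt);
                      fragments of one donor annotation closer than this
                      are merged.
    rel_dist_max    : upper bound on the relative distance between input
                      and database seeding-trail gaps (Step 1 filter).
    evalue_max      : E-value acceptance threshold for bridge alignments.
    align_*         : local alignment scoring; a gap of length l costs
                      align_gap_open + l * align_gap_extend.
    g0_bridge       : initial search-extent multiplier g0 for bridging.
    rfd_retrieval_min : minimal max-RFD for a cluster to yield a prediction.
    rfd_cum_t       : cumulative RFD mass defining the merge quality t.
    noncoding_cum_min : masking threshold on the cumulative RFD of the two
                      best-scoring genes at a position.
    overlap_eval_min : prediction-side shared-position fraction required
                      for a benchmark correspondence.
    rng_seed        : seed for the (rare) random tie-break in clustering.
    """

    k: int = 16
    min_gene_length: int = 70
    rel_dist_max: float = 0.2
    evalue_max: float = 1e-3
    align_match: int = 1
    align_mismatch: int = -2
    align_gap_open: int = -2
    align_gap_extend: int = -2
    g0_bridge: int = 2
    rfd_retrieval_min: float = 0.7
    rfd_cum_t: float = 0.95
    noncoding_cum_min: float = 0.8
    overlap_eval_min: float = 0.75
    rng_seed: int = 0
    skip_ambiguous: bool = True  # exclude windows with non-ACGT from k-mer enumeration
    tiebreak_weighted_score: bool = True  # tie-break (1) uses weighted scores

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for name in ("rel_dist_max", "rfd_retrieval_min", "rfd_cum_t",
                     "noncoding_cum_min", "overlap_eval_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.g0_bridge < 2:
            raise ValueError("g0_bridge must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read a flat ``key = value`` text file ('#' starts a comment)."""
        kv: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        known = {f.name: f.type for f in fields(cls)}
        args = {}
        for key, val in kv.items():
            if key not in known:
                raise ValueError(f"unknown config key: {key}")
            typ = known[key]
            if "bool" in str(typ):
                args[key] = val.lower() in ("1", "true", "yes", "on")
            elif "int" in str(typ):
                args[key] = int(val)
            else:
                args[key] = float(val)
        return cls(**args)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_CONFIG = Config()
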