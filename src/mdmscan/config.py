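"""Central pipeline configuration.

Every numeric decision threshold used by a pipeline stage is defined here,
once, with the value the methodology prescribes.  Stage modules take these
as keyword defaults drawn from :class:`PipelineConfig` (or the module-level
constants below) and never hard-code them, so a single config object fully
determines the behaviour of a run.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Any

import yaml

# --- alignment-based unassigned detection -------------------------------
ALIGN_THRESHOLD_LOW = 75.0    # minimum identity to include a sequence in an alignment
ALIGN_THRESHOLD_HIGH = 90.0   # minimum identity to call a database match a hit
ASSIGN_MIN_IDENTITY = 90.0    # below this best identity an OTU is "unassigned"
CLASSIFY_MIN_COVERAGE = 50.0  # percent of query an alignment must span to count as a hit

# --- taxonomic novelty bands (canonical 16S rank identity floors) -------
GENUS_THRESHOLD = 94.5
FAMILY_THRESHOLD = 86.5
ORDER_THRESHOLD = 82.0
CLASS_THRESHOLD = 78.5
PHYLUM_THRESHOLD = 75.0
ARTIFACT_FLOOR = 60.0         # below this, a hit is more likely artifact than phylum-level novelty

# --- OTU-table triage ---------------------------------------------------
MIN_TOTAL_READS = 50          # minimum total observation count to retain an OTU
ABUNDANCE_CUTOFF = 0.5        # percent; candidates need abundance summary strictly above this
ABUNDANCE_SUMMARY_MODE = "sum"

# --- chimera (bimera) scan ----------------------------------------------
CHIMERA_MIN_DELTA = 2.0       # percentage points the two-parent model must gain
CHIMERA_MIN_SEGMENT = 50      # bases each side of the breakpoint
CHIMERA_TOP_K_PARENTS = 8

# --- existence verification ---------------------------------------------
VERIFY_MIN_IDENTITY = 95.0    # re-sequenced amplicon vs original, strict >
VERIFY_REVIEW_IDENTITY = 94.5 # (review, pass] flagged for manual review: same-genus relevance
VERIFY_REQUIRED_COVER = 100.0 # full query cover required
PCR_MAX_MISMATCHES = 2
PCR_THREE_PRIME_EXACT = 3
PRIMER_GC_MIN = 40.0
PRIMER_GC_MAX = 60.0
PRIMER_TM_MIN = 57.0
PRIMER_TM_MAX = 63.0
PRIMER_MAX_TM_DIFF = 3.0
PRIMER_MAX_SELF_DIMER = 8

# --- MAG cross-validation ------------------------------------------------
MAG_MIN_IDENTITY = 96.0       # strict >
BIN_MIN_COMPLETENESS = 50.0
BIN_MAX_CONTAMINATION = 10.0
MAG_LOW_COVER_FRACTION = 0.5  # overlap below this fraction of the MDMS length -> LOW_COVER flag
MAG_MIN_OVERLAP = 100         # bp; shorter local hits are noise at 16S scale, not reported

# --- phylogenetic placement ----------------------------------------------
GAP_THRESHOLD = 0.70          # drop alignment columns with gap fraction above this
MIN_SHARED_COLUMNS = 50       # fewer shared columns -> distance imputed, pair flagged

# --- alignment engine -----------------------------------------------------
KMER_SIZE = 8
MIN_SHARED_KMERS = 1
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -2
GAP_EXTEND = -1
LOCAL_FULL_DP_MAX_LEN = 20_000


@dataclass
class PipelineConfig:
    """All tunable thresholds of the MDMS pipeline, with prescribed defaults."""

    align_threshold_low: float = ALIGN_THRESHOLD_LOW
    align_threshold_high: float = ALIGN_THRESHOLD_HIGH
    assign_min_identity: float = ASSIGN_MIN_IDENTITY
    classify_min_coverage: float = CLASSIFY_MIN_COVERAGE

    genus_threshold: float = GENUS_THRESHOLD
    family_threshold: float = FAMILY_THRESHOLD
    order_threshold: float = ORDER_THRESHOLD
    class_threshold: float = CLASS_THRESHOLD
    phylum_threshold: float = PHYLUM_THRESHOLD
    artifact_floor: float = ARTIFACT_FLOOR

    min_total_reads: int = MIN_TOTAL_READS
    abundance_cutoff: float = ABUNDANCE_CUTOFF
    abundance_summary_mode: str = ABUNDANCE_SUMMARY_MODE

    chimera_min_delta: float = CHIMERA_MIN_DELTA
    chimera_min_segment: int = CHIMERA_MIN_SEGMENT
    chimera_top_k_parents: int = CHIMERA_TOP_K_PARENTS

    verify_min_identity: float = VERIFY_MIN_IDENTITY
    verify_review_identity: float = VERIFY_REVIEW_IDENTITY
    verify_required_cover: float = VERIFY_REQUIRED_COVER
    pcr_max_mismatches: int = PCR_MAX_MISMATCHES
    pcr_three_prime_exact: int = PCR_THREE_PRIME_EXACT
    primer_gc_min: float = PRIMER_GC_MIN
    primer_gc_max: float = PRIMER_GC_MAX
    primer_tm_min: float = PRIMER_TM_MIN
    primer_tm_max: float = PRIMER_TM_MAX
    primer_max_tm_diff: float = PRIMER_MAX_TM_DIFF
    primer_max_self_dimer: int = PRIMER_MAX_SELF_DIMER

    mag_min_identity: float = MAG_MIN_IDENTITY
    bin_min_completeness: float = BIN_MIN_COMPLETENESS
    bin_max_contamination: float = BIN_MAX_CONTAMINATION
    mag_low_cover_fraction: float = MAG_LOW_COVER_FRACTION
    mag_min_overlap: int = MAG_MIN_OVERLAP

    gap_threshold: float = GAP_THRESHOLD
    min_shared_columns: int = MIN_SHARED_COLUMNS

    kmer_size: int = KMER_SIZE
    min_shared_kmers: int = MIN_SHARED_KMERS
    match_score: int = MATCH_SCORE
    mismatch_score: int = MISMATCH_SCORE
    gap_open: int = GAP_OPEN
    gap_extend: int = GAP_EXTEND

    def __post_init__(self) -> None:
        bands = (
            self.genus_threshold,
            self.family_threshold,
            self.order_threshold,
            self.class_threshold,
            self.phylum_threshold,
        )
        if not all(a > b for a, b in zip(bands, bands[1:])):
            raise ValueError(f"novelty-rank thresholds must strictly decrease, got {bands}")
        if not (0 <= self.gap_threshold <= 1):
            raise ValueError("gap_threshold must be a fraction in [0, 1]")
        if self.min_total_reads < 0 or self.abundance_cutoff < 0:
            raise ValueError("count/abundance cutoffs must be non-negative")
        if self.abundance_summary_mode not in ("sum", "mean", "max"):
            raise ValueError(f"unknown abundance summary mode {self.abundance_summary_mode!r}")

    @classmethod
    def from_yaml(cls, path_or_stream: Any) -> "PipelineConfig":
        """Load a flat-YAML config; unknown keys are an error."""
        if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
            with open(path_or_stream) as fh:
                data = yaml.safe_load(fh) or {}
        else:
            data = yaml.safe_load(path_or_stream) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs: Any) -> "PipelineConfig":
        """Return a copy with the given keys replaced (CLI flags beat file values)."""
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    def to_yaml(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump(dataclasses.asdict(self), buf, sort_keys=True)
        return buf.getvalue()


DEFAULT_CONFIG = PipelineConfig()
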