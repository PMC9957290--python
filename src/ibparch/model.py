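"""Shared data model for the DUF3494 ice-binding-protein (IBP) pipeline.

Every stage of the pipeline exchanges the plain dataclasses defined here.
Coordinates are 1-based inclusive throughout (GFF3 convention), both on the
genome (base pairs) and on proteins (amino acids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Closed vocabulary of sampling environments, ordered from the ice interior
#: down the water column.
ENVIRONMENTS: tuple[str, ...] = (
    "interior_ice",
    "sea_ice_interface",
    "epipelagic",
    "meso_bathypelagic",
)

#: Default target domain: DUF3494, the domain that defines the dominant
#: microbial ice-binding protein family.
TARGET_PFAM = "pfam11999"

#: Localization classes derived from signal-peptide / transmembrane topology.
LOCALIZATION_CLASSES: tuple[str, ...] = ("none", "sp_only", "tmd_only", "both")

#: Taxonomic ranks accepted by breakdown operations.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Label used for the eukaryote domain in taxonomy tables.
EUKARYOTE_LABEL = "Eukaryota"


@dataclass(frozen=True)
class GeneRecord:
    """One called gene on one contig of one sample assembly."""

    gene_id: str
    contig_id: str
    sample_id: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive, end >= start
    strand: str  # "+" or "-"
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.read_count < 0:
            raise ValueError(f"gene {self.gene_id}: negative read_count")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One Pfam model hit on one protein (envelope coordinates)."""

    protein_id: str
    pfam_acc: str  # normalized, "pfamNNNNN"
    env_start: int  # aa, 1-based inclusive
    env_end: int  # aa, >= env_start
    bit_score: float
    i_evalue: float

    def __post_init__(self) -> None:
        if self.env_end < self.env_start:
            raise ValueError(
                f"hit {self.pfam_acc} on {self.protein_id}: "
                f"env_end ({self.env_end}) < env_start ({self.env_start})"
            )
        if self.i_evalue < 0:
            raise ValueError(f"hit on {self.protein_id}: negative i_evalue")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class TopologyAnnotation:
    """Signal-peptide and transmembrane-domain annotation for one protein."""

    protein_id: str
    has_sp: bool
    n_tmd: int

    def __post_init__(self) -> None:
        if self.n_tmd < 0:
            raise ValueError(f"{self.protein_id}: negative n_tmd")


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic assignment of a gene or contig (ranks domain -> genus)."""

    subject_id: str
    ranks: dict[str, str | None] = field(default_factory=dict)
    is_eukaryote: bool = False

    def __post_init__(self) -> None:
        if self.is_eukaryote:
            dom = self.ranks.get("domain")
            if dom is not None and dom != EUKARYOTE_LABEL:
                raise ValueError(
                    f"{self.subject_id}: is_eukaryote set but domain rank is {dom!r}"
                )

    def rank(self, name: str) -> str | None:
        return self.ranks.get(name)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: environment class and the RPKM denominator."""

    sample_id: str
    environment: str
    total_mapped_reads: int
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"sample {self.sample_id}: environment {self.environment!r} "
                f"not in {ENVIRONMENTS}"
            )
        if self.total_mapped_reads <= 0:
            raise ValueError(f"sample {self.sample_id}: total_mapped_reads must be > 0")


@dataclass
class Architecture:
    """Ordered domain architecture of one target-domain protein.

    ``arch_string`` is the field's standard notation: lowercase Pfam
    accessions joined with underscores in N->C order, e.g.
    ``pfam11999_pfam16130``. Signal peptides and TMDs are overlay
    classifiers, never part of the string.
    """

    gene_id: str
    domain_order: list[str]
    arch_string: str
    n_target: int
    n_nterm: int
    n_cterm: int
    has_sp: bool
    n_tmd: int
    localization_class: str
    is_diverse: bool = False
    sample_id: str | None = None
    functions: list[tuple[str, str, str, bool]] = field(default_factory=list)
    # (pfam_acc, family_name, broad_function, ig_like) per non-target domain


@dataclass
class AbundanceRecord:
    """Per-architecture abundance (summed RPKM) and prevalence (gene count)."""

    arch_string: str
    rpkm_total: float
    pct_abundance: float
    n_genes: int
    pct_prevalence: float
    env_counts: dict[str, int] = field(default_factory=dict)
    env_pcts: dict[str, float] = field(default_factory=dict)
    order_counts: dict[str, int] = field(default_factory=dict)
    loc_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class NeighborRecord:
    """Nearest flanking gene of one target gene on a MAG contig.

    ``direction`` is strand-aware relative to the target gene; a target on
    the minus strand has its upstream neighbour at higher coordinates.
    ``distance_bp`` is the inter-gene gap (exclusive of both genes; 0 when
    abutting or overlapping). Neighbour fields are None iff the target gene
    is first/last on its contig in that direction (``at_contig_edge``).
    """

    mag_id: str
    ibp_gene_id: str
    direction: str  # "upstream" | "downstream"
    neighbor_gene_id: str | None
    distance_bp: int | None
    neighbor_arch: str | None
    at_contig_edge: bool

    def __post_init__(self) -> None:
        if self.direction not in ("upstream", "downstream"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.at_contig_edge != (self.neighbor_gene_id is None):
            raise ValueError(
                f"{self.ibp_gene_id}: neighbour fields must be absent iff at_contig_edge"
            )


@dataclass
class TandemCluster:
    """Run of >=2 target-domain genes on one contig with bounded gaps."""

    mag_id: str
    contig_id: str
    gene_ids: list[str]
    intervening_counts: list[int]  # per gap between consecutive members

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("a tandem cluster needs >= 2 members")
        if len(self.intervening_counts) != len(self.gene_ids) - 1:
            raise ValueError("need one intervening count per gap")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA result on a dissimilarity matrix."""

    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        # R2 = SS_between / SS_total; with semimetric dissimilarities
        # (Bray–Curtis) SS_between can dip slightly below zero under the
        # null, so only the upper bound is hard.
        if not (-1.0 <= self.R2 <= 1.0):
            raise ValueError(f"R2 out of range: {self.R2}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0,1]: {self.p_value}")


@dataclass
class LeafAnnotation:
    """Per-leaf annotation ring values for tree export."""

    leaf_id: str
    environment: str | None = None
    localization_class: str | None = None
    phylum: str | None = None
    order: str | None = None
    arch_class: str | None = None  # single|double|triple|duf4842|pep_cterm|other
    abundance_rpkm: float = 0.0


#: Closed vocabulary for the tree annotation architecture ring.
ARCH_CLASSES: tuple[str, ...] = (
    "single",
    "double",
    "triple",
    "duf4842",
    "pep_cterm",
    "other",
)


def arch_class_of(arch_string: str, target: str = TARGET_PFAM) -> str:
    """Map an architecture string onto the coarse tree-ring vocabulary."""
    domains = arch_string.split("_") if arch_string else []
    n_target = sum(d == target for d in domains)
    if domains == [target]:
        return "single"
    if domains == [target, target]:
        return "double"
    if domains == [target, target, target]:
        return "triple"
    if n_target == 1 and "pfam16130" in domains and len(domains) == 2:
        return "duf4842"
    if n_target == 1 and "pfam07589" in domains and len(domains) == 2:
        return "pep_cterm"
    return "other"
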