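"""Domain-architecture construction and architecture-level classifiers.

A protein's architecture is the ordered list of its Pfam domains along the
chain, written as lowercase accessions joined with underscores
(``pfam11999_pfam16130``). Overlapping hits are resolved greedily by bit
score before the order is read off. Signal peptides and transmembrane
domains never enter the architecture string — they are overlay classifiers
(the localization class).

The N/C-terminal companion split is anchored at the FIRST target-domain
copy: companions before it are N-terminal, everything after it (including
domains interleaved between target copies) counts as C-terminal.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .model import Architecture, DomainHit, TopologyAnnotation, TARGET_PFAM

logger = logging.getLogger(__name__)

#: Fraction of the shorter envelope above which two hits are "overlapping".
DEFAULT_OVERLAP_FRACTION = 0.5

#: The two published definitions of a "diverse" architecture.
DIVERSE_MODES = ("methods", "results")


@dataclass(frozen=True)
class FunctionEntry:
    family_name: str
    broad_function: str
    ig_like: bool


class FunctionMap:
    """Pfam accession -> (family name, broad functional grouping, Ig-likeness).

    The shipped default map covers every accession appearing in the abundant
    ice-binding-protein architectures; unknown accessions resolve to
    ``unmapped`` rather than being dropped.
    """

    def __init__(self, entries: Mapping[str, FunctionEntry]):
        self._entries = dict(entries)

    @classmethod
    def default(cls) -> "FunctionMap":
        ref = resources.files("ibparch").joinpath("data/function_map.tsv")
        with ref.open(encoding="utf-8") as fh:
            return cls._from_handle(fh)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FunctionMap":
        with open(path, encoding="utf-8") as fh:
            return cls._from_handle(fh)

    @classmethod
    def _from_handle(cls, fh) -> "FunctionMap":
        reader = csv.DictReader(fh, delimiter="\t")
        entries = {}
        for row in reader:
            entries[row["pfam_acc"]] = FunctionEntry(
                family_name=row["family_name"],
                broad_function=row["broad_function"],
                ig_like=row["ig_like"].strip().lower() == "true",
            )
        return cls(entries)

    def __contains__(self, acc: str) -> bool:
        return acc in self._entries

    def lookup(self, acc: str) -> FunctionEntry:
        """Resolve an accession; unknown accessions map to 'unmapped'."""
        return self._entries.get(
            acc, FunctionEntry(family_name=acc, broad_function="unmapped", ig_like=False)
        )

    def accessions(self) -> list[str]:
        return sorted(self._entries)


def resolve_overlaps(
    hits: Iterable[DomainHit],
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> list[DomainHit]:
    """Resolve overlapping Pfam hits on one protein, greedily by bit score.

    Hits are considered in descending bit-score order (ties broken by lower
    env_start, then lexicographic accession); a hit is discarded when its
    envelope overlaps an already-kept hit by more than ``overlap_fraction``
    of the shorter envelope. The result is returned sorted by env_start.
    """
    hits = list(hits)
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"resolve_overlaps expects hits on one protein, got {sorted(proteins)}")
    ranked = sorted(hits, key=lambda h: (-h.bit_score, h.env_start, h.pfam_acc))
    kept: list[DomainHit] = []
    for h in ranked:
        if all(not _conflict(h, k, overlap_fraction) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.env_start, h.env_end, h.pfam_acc))
    return kept


def _conflict(a: DomainHit, b: DomainHit, overlap_fraction: float) -> bool:
    ov = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
    if ov <= 0:
        return False
    shorter = min(a.env_length, b.env_length)
    return ov > overlap_fraction * shorter


def build_architecture(
    hits: Iterable[DomainHit],
    topology: TopologyAnnotation | None = None,
    target: str = TARGET_PFAM,
) -> Architecture:
    """Build the Architecture of one protein from its overlap-resolved hits.

    ``hits`` must contain at least one target-domain hit; callers pre-filter
    to target-domain proteins. An absent topology record is interpreted as
    no signal peptide and no TMD (and logged): topology prediction covers
    only a subset of proteins in practice.
    """
    hits = sorted(hits, key=lambda h: (h.env_start, h.env_end, h.pfam_acc))
    if not hits:
        raise ValueError("no hits given")
    gene_id = hits[0].protein_id
    order = [h.pfam_acc.lower() for h in hits]
    n_target = sum(d == target for d in order)
    if n_target == 0:
        raise ValueError(f"protein {gene_id}: no {target} hit; caller must pre-filter")
    first_t = order.index(target)
    n_nterm = sum(d != target for d in order[:first_t])
    n_cterm = sum(d != target for d in order[first_t:])
    if topology is None:
        logger.debug("protein %s: no topology record, assuming no SP/TMD", gene_id)
        has_sp, n_tmd = False, 0
    else:
        has_sp, n_tmd = topology.has_sp, topology.n_tmd
    return Architecture(
        gene_id=gene_id,
        domain_order=order,
        arch_string="_".join(order),
        n_target=n_target,
        n_nterm=n_nterm,
        n_cterm=n_cterm,
        has_sp=has_sp,
        n_tmd=n_tmd,
        localization_class=localization_class(has_sp, n_tmd),
    )


def localization_class(has_sp: bool, n_tmd: int) -> str:
    if has_sp and n_tmd > 0:
        return "both"
    if has_sp:
        return "sp_only"
    if n_tmd > 0:
        return "tmd_only"
    return "none"


def classify_diverse(arch: Architecture, mode: str = "results") -> bool:
    """Classify an architecture as "diverse" under one of two definitions.

    ``results`` (default): more than one domain in the protein, of any
    family (including extra target-domain copies). ``methods``: more than
    one domain OR the presence of a signal peptide and/or TMD. The two
    definitions differ for single-domain proteins with SP/TMD; both are
    kept because both are in use.
    """
    if mode not in DIVERSE_MODES:
        raise ValueError(f"unknown diverse-architecture mode {mode!r}; use one of {DIVERSE_MODES}")
    multi = len(arch.domain_order) > 1
    if mode == "results":
        return multi
    return multi or arch.has_sp or arch.n_tmd > 0


def annotate_function(arch: Architecture, function_map: FunctionMap) -> Architecture:
    """Label each non-target domain with its broad function and Ig-likeness.

    Unknown accessions are labelled ``unmapped``, never dropped — dropping
    them would silently merge distinct architectures.
    """
    functions = []
    target = TARGET_PFAM
    for acc in arch.domain_order:
        if acc == target:
            continue
        entry = function_map.lookup(acc)
        functions.append((acc, entry.family_name, entry.broad_function, entry.ig_like))
    arch.functions = functions
    return arch


def build_catalogue(
    hits_by_protein: Mapping[str, list[DomainHit]],
    topologies: Mapping[str, TopologyAnnotation],
    target: str = TARGET_PFAM,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    diverse_mode: str = "results",
    function_map: FunctionMap | None = None,
) -> list[Architecture]:
    """Architecture catalogue over every protein with >= 1 retained target hit.

    Resolves overlaps per protein, keeps proteins whose resolved hit list
    still contains the target domain, and derives every classifier.
    Returned sorted by gene_id for determinism.
    """
    fmap = function_map or FunctionMap.default()
    out: list[Architecture] = []
    for protein_id in sorted(hits_by_protein):
        resolved = resolve_overlaps(hits_by_protein[protein_id], overlap_fraction)
        if not any(h.pfam_acc == target for h in resolved):
            continue
        arch = build_architecture(resolved, topologies.get(protein_id), target=target)
        arch.is_diverse = classify_diverse(arch, mode=diverse_mode)
        annotate_function(arch, fmap)
        out.append(arch)
    return out


def group_hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return grouped
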