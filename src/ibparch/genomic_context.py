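"""Gene-neighbourhood (synteny) analysis of target-domain genes in MAGs.

For each target gene on a MAG contig we record its nearest upstream and
downstream genes, the inter-gene gap in base pairs, and the neighbour's
domain architecture; runs of adjacent target genes become tandem clusters.

Conventions (applied in this module only, so they cannot drift):

* **upstream/downstream are strand-aware** relative to the target gene — a
  minus-strand gene's upstream neighbour lies at higher coordinates. Pass
  ``strand_aware=False`` to reproduce pure left/right coordinate order.
* **distance** is the gap between the facing gene boundaries, exclusive of
  both genes (abutting genes are 0 apart); overlapping gene calls are
  floored at 0.
* a target gene that is first/last on its contig yields an edge record with
  neighbour fields absent.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import GeneRecord, NeighborRecord, TandemCluster

logger = logging.getLogger(__name__)


def _check_sorted(genes: Sequence[GeneRecord]) -> None:
    for a, b in zip(genes, genes[1:]):
        if a.contig_id != b.contig_id:
            raise ValueError("scan expects genes from a single contig at a time")
        if b.start < a.start:
            raise ValueError(
                f"genes not sorted by start: {a.gene_id} ({a.start}) before "
                f"{b.gene_id} ({b.start})"
            )


def gap_bp(left: GeneRecord, right: GeneRecord) -> int:
    """Inter-gene gap in bp between two genes in coordinate order (>= 0)."""
    return max(0, right.start - left.end - 1)


def scan_neighbors(
    genes_on_contig: Sequence[GeneRecord],
    target_gene_ids: Iterable[str],
    mag_id: str = "",
    arch_by_gene: Mapping[str, str] | None = None,
    strand_aware: bool = True,
) -> list[NeighborRecord]:
    """Nearest-flanking-gene records for every target gene on one contig.

    ``arch_by_gene`` maps any gene id to its architecture-style domain
    string; genes with no Pfam hits get the empty string (a "no-domain"
    neighbour class, never dropped).
    """
    genes = list(genes_on_contig)
    _check_sorted(genes)
    targets = set(target_gene_ids)
    arch_by_gene = arch_by_gene or {}
    records: list[NeighborRecord] = []
    for i, g in enumerate(genes):
        if g.gene_id not in targets:
            continue
        left = genes[i - 1] if i > 0 else None
        right = genes[i + 1] if i + 1 < len(genes) else None
        if strand_aware and g.strand == "-":
            oriented = (("upstream", right), ("downstream", left))
        else:
            oriented = (("upstream", left), ("downstream", right))
        for direction, nb in oriented:
            if nb is None:
                records.append(
                    NeighborRecord(
                        mag_id=mag_id,
                        ibp_gene_id=g.gene_id,
                        direction=direction,
                        neighbor_gene_id=None,
                        distance_bp=None,
                        neighbor_arch=None,
                        at_contig_edge=True,
                    )
                )
            else:
                dist = gap_bp(nb, g) if nb.start <= g.start else gap_bp(g, nb)
                records.append(
                    NeighborRecord(
                        mag_id=mag_id,
                        ibp_gene_id=g.gene_id,
                        direction=direction,
                        neighbor_gene_id=nb.gene_id,
                        distance_bp=dist,
                        neighbor_arch=arch_by_gene.get(nb.gene_id, ""),
                        at_contig_edge=False,
                    )
                )
    return records


def flanking_frequencies(
    neighbor_records: Iterable[NeighborRecord],
) -> dict[str, pd.DataFrame]:
    """Ranked flanking frequencies, by whole architecture and by domain.

    Returns four tables keyed ``{direction}_{unit}`` with unit in
    {``architecture``, ``domain``}. A neighbour with k domains contributes
    k rows to the domain table and one to the architecture table. Percents
    are given over non-edge slots (``pct``) and, since the right denominator
    is a judgement call, also over all slots including contig edges
    (``pct_all_slots``). Neighbours without Pfam hits rank as the
    ``(no domain)`` class.
    """
    recs = list(neighbor_records)
    out: dict[str, pd.DataFrame] = {}
    for direction in ("upstream", "downstream"):
        dir_recs = [r for r in recs if r.direction == direction]
        non_edge = [r for r in dir_recs if not r.at_contig_edge]
        n_all, n_ne = len(dir_recs), len(non_edge)
        if n_ne == 0:
            logger.warning("flanking_frequencies: no non-edge %s neighbours", direction)
        arch_counts: dict[str, int] = {}
        dom_counts: dict[str, int] = {}
        for r in non_edge:
            arch = r.neighbor_arch or ""
            key = arch if arch else "(no domain)"
            arch_counts[key] = arch_counts.get(key, 0) + 1
            if arch:
                for d in arch.split("_"):
                    dom_counts[d] = dom_counts.get(d, 0) + 1
            else:
                dom_counts["(no domain)"] = dom_counts.get("(no domain)", 0) + 1
        for unit, counts in (("architecture", arch_counts), ("domain", dom_counts)):
            denom_dom = sum(counts.values()) if unit == "domain" else n_ne
            rows = [
                {
                    "key": k,
                    "count": c,
                    "pct": 100.0 * c / denom_dom if denom_dom else 0.0,
                    "pct_all_slots": 100.0 * c / n_all if n_all else 0.0,
                }
                for k, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            ]
            out[f"{direction}_{unit}"] = pd.DataFrame(
                rows, columns=["key", "count", "pct", "pct_all_slots"]
            )
    return out


def find_tandem_clusters(
    genes_on_contig: Sequence[GeneRecord],
    target_gene_ids: Iterable[str],
    max_intervening: int = 0,
    mag_id: str = "",
) -> list[TandemCluster]:
    """Maximal runs of target genes with bounded intervening non-target genes.

    Two consecutive target genes belong to the same cluster when at most
    ``max_intervening`` non-target genes lie between them (0 = strictly
    adjacent). Singletons are not emitted.
    """
    genes = list(genes_on_contig)
    _check_sorted(genes)
    targets = set(target_gene_ids)
    idx = [i for i, g in enumerate(genes) if g.gene_id in targets]
    clusters: list[TandemCluster] = []
    run: list[int] = []
    for i in idx:
        if run and (i - run[-1] - 1) <= max_intervening:
            run.append(i)
        else:
            if len(run) >= 2:
                clusters.append(_make_cluster(genes, run, mag_id))
            run = [i]
    if len(run) >= 2:
        clusters.append(_make_cluster(genes, run, mag_id))
    return clusters


def _make_cluster(genes: Sequence[GeneRecord], run: list[int], mag_id: str) -> TandemCluster:
    return TandemCluster(
        mag_id=mag_id,
        contig_id=genes[run[0]].contig_id,
        gene_ids=[genes[i].gene_id for i in run],
        intervening_counts=[b - a - 1 for a, b in zip(run, run[1:])],
    )


def mag_summary(target_counts_by_mag: Mapping[str, int]) -> dict[str, int]:
    """Per-MAG accounting: totals, multi-target MAG count, maximum per MAG."""
    counts = list(target_counts_by_mag.values())
    return {
        "n_mags": len(counts),
        "n_target_genes": sum(counts),
        "n_multi_target_mags": sum(c > 1 for c in counts),
        "max_per_mag": max(counts) if counts else 0,
    }


def neighbors_table(records: Iterable[NeighborRecord]) -> pd.DataFrame:
    rows = [
        {
            "mag_id": r.mag_id,
            "ibp_gene_id": r.ibp_gene_id,
            "direction": r.direction,
            "neighbor_gene_id": r.neighbor_gene_id if r.neighbor_gene_id else "",
            "distance_bp": r.distance_bp if r.distance_bp is not None else "",
            "neighbor_arch": r.neighbor_arch if r.neighbor_arch else "",
            "at_contig_edge": r.at_contig_edge,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id", "ibp_gene_id", "direction", "neighbor_gene_id",
            "distance_bp", "neighbor_arch", "at_contig_edge",
        ],
    )


def clusters_table(clusters: Iterable[TandemCluster]) -> pd.DataFrame:
    rows = [
        {
            "mag_id": c.mag_id,
            "contig_id": c.contig_id,
            "size": c.size,
            "gene_ids": ";".join(c.gene_ids),
            "intervening_counts": ";".join(map(str, c.intervening_counts)),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows, columns=["mag_id", "contig_id", "size", "gene_ids", "intervening_counts"]
    )
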