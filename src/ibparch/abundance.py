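"""RPKM abundance and prevalence accounting per domain architecture.

Two deliberately distinct statistics run through this module:

* **abundance** — an architecture's share of the grand-total RPKM (reads per
  kilobase of gene per million mapped reads), summed over genes and samples;
* **prevalence** — its share of the total *count* of target-domain genes.

A single highly covered gene can make an architecture abundant without
making it prevalent; both columns are always reported. RPKM is summed
across samples with no between-sample renormalization; per-sample
denominators come from the sample metadata (``total_mapped_reads`` by
default).

All percentages are computed at full precision; rounding to two decimals
happens only at rendering. Ranking always uses full precision.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    LOCALIZATION_CLASSES,
    AbundanceRecord,
    Architecture,
    GeneRecord,
    SampleMeta,
    TaxonomyRecord,
)

logger = logging.getLogger(__name__)

BREAKDOWN_RANKS = ("phylum", "order", "genus")


def rpkm(read_count: float, gene_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of gene per million mapped reads.

    rpkm = read_count / (gene_length_bp / 1000) / (total_mapped_reads / 1e6)
    """
    if gene_length_bp <= 0:
        raise ValueError(f"gene_length_bp must be >= 1, got {gene_length_bp}")
    if total_mapped_reads <= 0:
        raise ValueError(f"total_mapped_reads must be >= 1, got {total_mapped_reads}")
    if read_count < 0:
        raise ValueError(f"negative read_count {read_count}")
    return read_count / (gene_length_bp / 1000.0) / (total_mapped_reads / 1e6)


def rpkm_by_gene(
    genes: Iterable[GeneRecord],
    samples: Mapping[str, SampleMeta],
    denominator: str = "total_mapped_reads",
) -> dict[str, float]:
    """Per-gene RPKM using each gene's own sample's read total.

    ``denominator`` names the SampleMeta attribute used as the per-million
    denominator (the published analyses do not pin down which read total was
    used; total mapped reads is the default).
    """
    out: dict[str, float] = {}
    for g in genes:
        meta = samples.get(g.sample_id)
        if meta is None:
            raise KeyError(f"gene {g.gene_id}: sample {g.sample_id!r} not in metadata")
        total = getattr(meta, denominator)
        out[g.gene_id] = rpkm(g.read_count, g.length_bp, total)
    return out


def aggregate_architectures(
    architectures: Sequence[Architecture],
    rpkm_values: Mapping[str, float],
    env_by_gene: Mapping[str, str] | None = None,
    taxonomy_by_gene: Mapping[str, TaxonomyRecord] | None = None,
) -> list[AbundanceRecord]:
    """Aggregate per-gene RPKM into per-architecture abundance records.

    Grand totals (RPKM and gene count) are computed over ALL architectures.
    Records are sorted by rpkm_total descending, ties broken by arch_string
    so the ranking is stable.
    """
    missing = sorted(a.gene_id for a in architectures if a.gene_id not in rpkm_values)
    if missing:
        raise KeyError(f"genes missing from rpkm table: {missing}")

    by_arch: dict[str, list[Architecture]] = {}
    for a in architectures:
        by_arch.setdefault(a.arch_string, []).append(a)

    grand_rpkm = sum(rpkm_values[a.gene_id] for a in architectures)
    grand_n = len(architectures)
    records: list[AbundanceRecord] = []
    for arch_string, members in by_arch.items():
        total = sum(rpkm_values[a.gene_id] for a in members)
        env_counts: dict[str, int] = {}
        order_counts: dict[str, int] = {}
        loc_counts: dict[str, int] = {c: 0 for c in LOCALIZATION_CLASSES}
        for a in members:
            loc_counts[a.localization_class] += 1
            if env_by_gene is not None:
                env = env_by_gene.get(a.gene_id)
                if env is not None:
                    env_counts[env] = env_counts.get(env, 0) + 1
            if taxonomy_by_gene is not None:
                rec = taxonomy_by_gene.get(a.gene_id)
                order = rec.rank("order") if rec is not None else None
                key = order if order is not None else "unclassified"
                order_counts[key] = order_counts.get(key, 0) + 1
        env_total = sum(env_counts.values())
        env_pcts = (
            {e: 100.0 * c / env_total for e, c in env_counts.items()} if env_total else {}
        )
        records.append(
            AbundanceRecord(
                arch_string=arch_string,
                rpkm_total=total,
                pct_abundance=100.0 * total / grand_rpkm if grand_rpkm > 0 else 0.0,
                n_genes=len(members),
                pct_prevalence=100.0 * len(members) / grand_n,
                env_counts=env_counts,
                env_pcts=env_pcts,
                order_counts=order_counts,
                loc_counts=loc_counts,
            )
        )
    records.sort(key=lambda r: (-r.rpkm_total, r.arch_string))
    return records


def environment_breakdown(counts_by_environment: Mapping[str, int]) -> dict[str, float]:
    """Percent of genes per environment: 100 * count / total, full precision.

    Raises on an all-zero table. Render with two decimals for reporting;
    rounded percentages sum to 100 within 0.02.
    """
    total = sum(counts_by_environment.values())
    if total <= 0:
        raise ValueError("all-zero environment counts")
    if any(c < 0 for c in counts_by_environment.values()):
        raise ValueError("negative environment count")
    return {env: 100.0 * c / total for env, c in counts_by_environment.items()}


def localization_breakdown(
    architectures: Sequence[Architecture],
    subset: str | None = None,
    predicate=None,
) -> pd.DataFrame:
    """SP/TMD class percentages and the TMD-count spectrum over a subset.

    ``subset`` selects by exact arch_string; ``predicate`` (Architecture ->
    bool) selects arbitrarily; both None means everything. Returns a
    one-row-per-statistic table: the four localization classes, the TMD
    spectrum (0, 1, 2, 3, 4+), percent with both SP and >= 1 TMD, and
    percent with neither.
    """
    sel = list(architectures)
    if subset is not None:
        sel = [a for a in sel if a.arch_string == subset]
    if predicate is not None:
        sel = [a for a in sel if predicate(a)]
    if not sel:
        logger.warning("localization_breakdown: empty subset")
        return pd.DataFrame(columns=["statistic", "count", "percent"])
    n = len(sel)
    rows = []
    for cls in LOCALIZATION_CLASSES:
        c = sum(a.localization_class == cls for a in sel)
        rows.append(("class_" + cls, c, 100.0 * c / n))
    for k in (0, 1, 2, 3):
        c = sum(a.n_tmd == k for a in sel)
        rows.append((f"tmd_{k}", c, 100.0 * c / n))
    c4 = sum(a.n_tmd >= 4 for a in sel)
    rows.append(("tmd_4plus", c4, 100.0 * c4 / n))
    c_sp = sum(a.has_sp for a in sel)
    rows.append(("sp_any", c_sp, 100.0 * c_sp / n))
    c_both = sum(a.has_sp and a.n_tmd >= 1 for a in sel)
    rows.append(("sp_and_tmd", c_both, 100.0 * c_both / n))
    c_neither = sum((not a.has_sp) and a.n_tmd == 0 for a in sel)
    rows.append(("neither", c_neither, 100.0 * c_neither / n))
    return pd.DataFrame(rows, columns=["statistic", "count", "percent"])


def taxon_breakdown(
    architectures: Sequence[Architecture],
    rank: str,
    taxonomy_by_gene: Mapping[str, TaxonomyRecord],
    subset: str | None = None,
) -> pd.DataFrame:
    """Counts and percents per taxon at a rank, unclassified tallied apart.

    Percentages are over the whole subset; the classified share is reported
    as a separate summary row (``__classified__``). Counts sum to the
    subset size.
    """
    if rank not in BREAKDOWN_RANKS:
        raise ValueError(f"unknown rank {rank!r}; use one of {BREAKDOWN_RANKS}")
    sel = [a for a in architectures if subset is None or a.arch_string == subset]
    n = len(sel)
    counts: dict[str, int] = {}
    n_classified = 0
    for a in sel:
        rec = taxonomy_by_gene.get(a.gene_id)
        label = rec.rank(rank) if rec is not None else None
        if label is None:
            counts["unclassified"] = counts.get("unclassified", 0) + 1
        else:
            n_classified += 1
            counts[label] = counts.get(label, 0) + 1
    rows = [
        (taxon, c, 100.0 * c / n if n else 0.0)
        for taxon, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    rows.append(("__classified__", n_classified, 100.0 * n_classified / n if n else 0.0))
    return pd.DataFrame(rows, columns=["taxon", "count", "percent"])


def abundance_table(
    records: Sequence[AbundanceRecord], function_map=None
) -> pd.DataFrame:
    """Render abundance records as the standard catalogue table.

    Columns mirror the published layout: architecture, family names, broad
    functions, summed RPKM, percent abundance, gene count, percent
    prevalence.
    """
    rows = []
    for r in records:
        names, funcs = [], []
        if function_map is not None:
            from .model import TARGET_PFAM

            for acc in r.arch_string.split("_"):
                if acc == TARGET_PFAM:
                    continue
                e = function_map.lookup(acc)
                if e.family_name not in names:
                    names.append(e.family_name)
                    funcs.append(e.broad_function)
            if not names:  # target-only architectures
                e = function_map.lookup(TARGET_PFAM)
                names, funcs = [e.family_name], [e.broad_function]
        rows.append(
            {
                "arch_string": r.arch_string,
                "family_names": ";".join(names),
                "broad_functions": ";".join(funcs),
                "rpkm_total": r.rpkm_total,
                "pct_abundance": r.pct_abundance,
                "n_genes": r.n_genes,
                "pct_prevalence": r.pct_prevalence,
            }
        )
    return pd.DataFrame(rows)
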