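"""Readers, writers and record-level filters for all external file formats.

All readers validate into the dataclasses of :mod:`ibparch.model`; all
writers emit TSV with a commented header line recording the tool version and
a configuration hash. Genomic coordinates stay 1-based inclusive end to end.

The GFF3 and HMMER domtblout readers are deliberately direct column parsers:
their error contracts name the offending line number, which the generic
library parsers do not surface. The domtblout reader is cross-checked against
Bio.SearchIO in the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .model import (
    EUKARYOTE_LABEL,
    RANKS,
    DomainHit,
    GeneRecord,
    SampleMeta,
    TaxonomyRecord,
    TopologyAnnotation,
)

logger = logging.getLogger(__name__)

TOOL_VERSION = "ibparch 0.1.0"

_PFAM_RE = re.compile(r"^(?:PF|pfam)(\d{5})(?:\.\d+)?$")

#: GFF3 feature types treated as gene calls.
_GENE_FEATURES = {"gene", "CDS"}


def normalize_pfam(acc: str) -> str:
    """Normalize a Pfam accession: ``PF11999.6`` -> ``pfam11999``.

    Raises ValueError for anything that is not a Pfam accession.
    """
    m = _PFAM_RE.match(acc.strip())
    if not m:
        raise ValueError(f"not a Pfam accession: {acc!r}")
    return f"pfam{m.group(1)}"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path, sample_id: str | None = None) -> list[GeneRecord]:
    """Read gene calls from a GFF3 file.

    Only ``gene``/``CDS`` features are consumed; each must carry an ``ID``
    attribute. Records are returned sorted by (contig_id, start). Read counts
    are not part of GFF3; they default to 0 and are attached later from the
    counts table (:func:`attach_read_counts`).

    ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    genes: list[GeneRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line "
                    f"({len(fields)} columns, expected 9)"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in _GENE_FEATURES:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: zero/negative-length feature (end {end} < start {start})"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            gene_id = _gff_attribute(attrs, "ID")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: feature has no ID attribute")
            if gene_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen_ids.add(gene_id)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=seqid,
                    sample_id=sample_id,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))
    return genes


def _gff_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Collect contig lengths from ``##sequence-region`` pragmas of a GFF3."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3]) - int(parts[2]) + 1
    return lengths


# ---------------------------------------------------------------------------
# HMMER domtblout
# ---------------------------------------------------------------------------

def read_domtblout(
    path: str | Path, max_i_evalue: float = 1e-5
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (hmmscan orientation).

    Accessions are normalized (``PF11999.6`` -> ``pfam11999``); rows whose
    independent E-value exceeds ``max_i_evalue`` are dropped and the dropped
    count logged. Rows whose target accession is not a Pfam accession are
    skipped (non-Pfam profile libraries may share the file).
    """
    path = Path(path)
    hits: list[DomainHit] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: malformed domtblout row ({len(fields)} columns)"
                )
            target_acc = fields[1]
            protein_id = fields[3]
            try:
                i_evalue = float(fields[12])
                bit_score = float(fields[13])
                env_start = int(fields[19])
                env_end = int(fields[20])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score/evalue/coordinate field"
                ) from None
            try:
                pfam_acc = normalize_pfam(target_acc)
            except ValueError:
                logger.debug("%s:%d: skipping non-Pfam target %r", path, lineno, target_acc)
                continue
            if i_evalue > max_i_evalue:
                n_dropped += 1
                continue
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    pfam_acc=pfam_acc,
                    env_start=env_start,
                    env_end=env_end,
                    bit_score=bit_score,
                    i_evalue=i_evalue,
                )
            )
    logger.info(
        "read_domtblout(%s): kept %d hits, dropped %d at i_evalue > %g",
        path.name, len(hits), n_dropped, max_i_evalue,
    )
    return hits


# ---------------------------------------------------------------------------
# Plain TSV tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_topology(path: str | Path) -> dict[str, TopologyAnnotation]:
    """Read a Phobius-short-style topology table (protein_id, has_sp, n_tmd).

    Proteins with more than four predicted TMDs are permitted but flagged
    with a warning: larger counts are rare among ice-binding proteins and
    usually indicate a mis-joined gene call.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["protein_id", "has_sp", "n_tmd"], path)
    out: dict[str, TopologyAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = TopologyAnnotation(
            protein_id=str(row.protein_id),
            has_sp=_as_bool(row.has_sp),
            n_tmd=int(row.n_tmd),
        )
        if ann.n_tmd > 4:
            logger.warning(
                "protein %s has %d TMDs (> 4): unusual, flagged", ann.protein_id, ann.n_tmd
            )
        out[ann.protein_id] = ann
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read per-gene read counts: columns gene_id, sample_id, read_count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["gene_id", "sample_id", "read_count"], path)
    if (df["read_count"] < 0).any():
        bad = df.loc[df["read_count"] < 0, "gene_id"].tolist()
        raise ValueError(f"{path}: negative read counts for genes {bad}")
    return df


def attach_read_counts(
    genes: Iterable[GeneRecord], counts: pd.DataFrame
) -> list[GeneRecord]:
    """Return genes with read_count filled from the counts table.

    A gene absent from the table keeps read_count 0. The count used is the
    gene's count in its own sample.
    """
    lookup = {
        (str(r.gene_id), str(r.sample_id)): int(r.read_count)
        for r in counts.itertuples(index=False)
    }
    out = []
    for g in genes:
        rc = lookup.get((g.gene_id, g.sample_id), 0)
        out.append(
            GeneRecord(
                gene_id=g.gene_id,
                contig_id=g.contig_id,
                sample_id=g.sample_id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                read_count=rc,
            )
        )
    return out


def assign_samples(
    genes: Iterable[GeneRecord], contig_to_sample: Mapping[str, str]
) -> list[GeneRecord]:
    """Re-key each gene's sample_id from a contig -> sample mapping.

    Used when one GFF carries every sample's contigs; a contig without a
    mapping is an error.
    """
    out = []
    for g in genes:
        sid = contig_to_sample.get(g.contig_id)
        if sid is None:
            raise KeyError(f"contig {g.contig_id} has no sample assignment")
        out.append(
            GeneRecord(
                gene_id=g.gene_id, contig_id=g.contig_id, sample_id=sid,
                start=g.start, end=g.end, strand=g.strand, read_count=g.read_count,
            )
        )
    return out


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read sample metadata: sample_id, environment, total_mapped_reads, pooled."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["sample_id", "environment", "total_mapped_reads"], path)
    out: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            environment=str(row.environment),
            total_mapped_reads=int(row.total_mapped_reads),
            pooled=_as_bool(getattr(row, "pooled", False)),
        )
        out[meta.sample_id] = meta
    return out


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    """Read taxonomy assignments keyed by gene or contig id.

    Columns: subject_id plus any of domain/phylum/class/order/family/genus
    (empty cells mean unassigned at that rank). A subject is eukaryotic when
    its domain rank equals the eukaryote label.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, ["subject_id"], path)
    rank_cols = [r for r in RANKS if r in df.columns]
    out: dict[str, TaxonomyRecord] = {}
    for row in df.itertuples(index=False):
        ranks: dict[str, str | None] = {}
        for r in rank_cols:
            val = getattr(row, r)
            ranks[r] = None if (val is None or pd.isna(val) or val == "") else str(val)
        rec = TaxonomyRecord(
            subject_id=str(row.subject_id),
            ranks=ranks,
            is_eukaryote=ranks.get("domain") == EUKARYOTE_LABEL,
        )
        out[rec.subject_id] = rec
    return out


def read_mag_membership(path: str | Path) -> pd.DataFrame:
    """Read MAG membership (mag_id, contig_id, completeness, contamination, taxonomy).

    Completeness/contamination are pass-through metadata; no QC is applied.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["mag_id", "contig_id"], path)
    return df


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _as_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


# ---------------------------------------------------------------------------
# Record-level filters
# ---------------------------------------------------------------------------

def filter_contigs(
    genes: Iterable[GeneRecord],
    contig_lengths: Mapping[str, int],
    min_len: int = 500,
) -> list[GeneRecord]:
    """Drop genes on contigs shorter than ``min_len`` base pairs (inclusive).

    Short contigs carry unreliable gene calls; the default keeps contigs of
    at least 500 bp. Every contig present in ``genes`` must have a recorded
    length.
    """
    genes = list(genes)
    missing = sorted({g.contig_id for g in genes} - set(contig_lengths))
    if missing:
        raise ValueError(f"contigs without recorded length: {missing}")
    return [g for g in genes if contig_lengths[g.contig_id] >= min_len]


def drop_eukaryotes(
    genes: Iterable[GeneRecord],
    taxonomy: Mapping[str, TaxonomyRecord],
) -> list[GeneRecord]:
    """Remove genes classified as eukaryotic (gene- or contig-level).

    A gene-level taxonomy record overrides a contig-level one (finer evidence
    wins). Genes with no taxonomy record at either level are retained and
    counted as unclassified in the log.
    """
    kept: list[GeneRecord] = []
    n_unclassified = 0
    n_removed = 0
    for g in genes:
        rec = taxonomy.get(g.gene_id)
        if rec is None:
            rec = taxonomy.get(g.contig_id)
        if rec is None:
            n_unclassified += 1
            kept.append(g)
        elif rec.is_eukaryote:
            n_removed += 1
        else:
            kept.append(g)
    logger.info(
        "drop_eukaryotes: removed %d eukaryotic genes, %d unclassified retained",
        n_removed, n_unclassified,
    )
    return kept


# ---------------------------------------------------------------------------
# Result-table writers
# ---------------------------------------------------------------------------

def config_hash(config: Mapping | None) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, config: Mapping | None = None
) -> None:
    """Write a result table as TSV with a commented provenance header.

    Reals are written with 6 significant figures, which the round-trip
    contract guarantees to reproduce; integers are exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_VERSION} config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")


def format_percent(x: float) -> str:
    """Render a percentage to 2 decimals (display only; never for ranking)."""
    if math.isnan(x):
        return "nan"
    return f"{x:.2f}"
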