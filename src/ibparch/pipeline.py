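"""End-to-end orchestration: filters -> architectures -> abundance ->
genomic context -> composition statistics -> tree-input preparation.

Every stage is a pure function of (inputs, configuration);
:func:`compute_all` runs them in memory, :func:`run_all` writes every
result table. Outputs carry the configuration hash in their commented
header so reruns are verifiable by content hashing (no timestamps are
written; identical config + dataset gives byte-identical outputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import architectures as ar
from . import community_stats as cs
from . import genomic_context as gc
from . import io as fio
from . import tree_tools as tt
from .model import TARGET_PFAM, TaxonomyRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run over a dataset directory."""

    dataset_dir: str
    out_dir: str
    target_pfam: str = TARGET_PFAM
    max_i_evalue: float = 1e-5
    min_contig_len: int = 500
    overlap_fraction: float = 0.5
    diverse_mode: str = "results"  # or "methods"
    strand_aware: bool = True
    max_intervening: int = 0
    rank: str = "order"
    denominator: str = "total_mapped_reads"
    include_pooled: bool = True
    n_permutations: int = 999
    seed: int = cs.DEFAULT_SEED

    def __post_init__(self) -> None:
        if not re.fullmatch(r"pfam\d{5}", self.target_pfam):
            raise ValueError(
                f"target_pfam {self.target_pfam!r} does not match 'pfamNNNNN'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def compute_all(config: RunConfig) -> dict:
    """Run every stage in memory; returns a dict of intermediate results.

    Keys: genes, samples, taxonomy_by_gene, env_by_gene, catalogue, grouped,
    rpkms, records (abundance), tables (name -> DataFrame), neighbor_records,
    clusters, mag_summary, permanova, domain_fasta.
    """
    ds = Path(config.dataset_dir)
    # the provenance hash covers the analysis parameters, not the output
    # location, so a rerun into a different directory stays byte-identical
    cfg = {k: v for k, v in config.as_dict().items() if k != "out_dir"}
    ctx: dict = {"config": cfg}

    # ------------------------------------------------------------ read inputs
    try:
        genes = fio.read_gff(ds / "genes.gff", sample_id="NA")
        contig_df = pd.read_csv(ds / "contig_samples.tsv", sep="\t", comment="#")
        contig_to_sample = dict(
            zip(contig_df["contig_id"].astype(str), contig_df["sample_id"].astype(str))
        )
        contig_lengths = dict(
            zip(contig_df["contig_id"].astype(str), contig_df["length_bp"].astype(int))
        )
        genes = fio.assign_samples(genes, contig_to_sample)
        counts = fio.read_counts(ds / "counts.tsv")
        genes = fio.attach_read_counts(genes, counts)
        samples = fio.read_sample_meta(ds / "samples.tsv")
        taxonomy = fio.read_taxonomy(ds / "taxonomy.tsv")
        topology = fio.read_topology(ds / "topology.tsv")
        mags = fio.read_mag_membership(ds / "mags.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("read_inputs", e) from e

    if not config.include_pooled:
        pooled = {s for s, m in samples.items() if m.pooled}
        genes = [g for g in genes if g.sample_id not in pooled]

    # ----------------------------------------------------------------- filter
    try:
        genes = fio.filter_contigs(genes, contig_lengths, config.min_contig_len)
        genes = fio.drop_eukaryotes(genes, taxonomy)
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    gene_ids = {g.gene_id for g in genes}
    gene_by_id = {g.gene_id: g for g in genes}
    ctx["genes"] = genes
    ctx["samples"] = samples

    # ---------------------------------------------------------- architectures
    try:
        hits = fio.read_domtblout(ds / "domains.domtblout", config.max_i_evalue)
        hits = [h for h in hits if h.protein_id in gene_ids]
        grouped = ar.group_hits_by_protein(hits)
        catalogue = ar.build_catalogue(
            grouped,
            topology,
            target=config.target_pfam,
            overlap_fraction=config.overlap_fraction,
            diverse_mode=config.diverse_mode,
        )
        if not catalogue:
            logger.warning(
                "no proteins carry the target domain %s: emitting empty catalogue",
                config.target_pfam,
            )
        for a in catalogue:
            a.sample_id = gene_by_id[a.gene_id].sample_id
    except Exception as e:  # noqa: BLE001
        raise StageError("architectures", e) from e

    taxonomy_by_gene: dict[str, TaxonomyRecord] = {}
    for g in genes:
        rec = taxonomy.get(g.gene_id) or taxonomy.get(g.contig_id)
        if rec is not None:
            taxonomy_by_gene[g.gene_id] = rec
    env_by_gene = {g.gene_id: samples[g.sample_id].environment for g in genes}
    ctx.update(
        catalogue=catalogue, grouped=grouped,
        taxonomy_by_gene=taxonomy_by_gene, env_by_gene=env_by_gene,
    )

    # -------------------------------------------------------------- abundance
    tables: dict[str, pd.DataFrame] = {}
    try:
        rpkms = ab.rpkm_by_gene(genes, samples, config.denominator)
        records = ab.aggregate_architectures(
            catalogue, rpkms, env_by_gene, taxonomy_by_gene
        )
        fmap = ar.FunctionMap.default()
        tables["abundance"] = ab.abundance_table(records, fmap)
        tables["architectures"] = _architecture_table(catalogue, taxonomy_by_gene)
        env_counts: dict[str, int] = {}
        for a in catalogue:
            env = env_by_gene[a.gene_id]
            env_counts[env] = env_counts.get(env, 0) + 1
        if env_counts:
            env_pcts = ab.environment_breakdown(env_counts)
            tables["environment_breakdown"] = pd.DataFrame(
                [
                    {"environment": e, "count": env_counts[e], "percent": env_pcts[e]}
                    for e in sorted(env_counts)
                ]
            )
        tables["localization"] = ab.localization_breakdown(catalogue)
        if catalogue:
            tables["taxon_breakdown"] = ab.taxon_breakdown(
                catalogue, config.rank, taxonomy_by_gene
            )
        ctx.update(rpkms=rpkms, records=records, env_counts=env_counts)
    except Exception as e:  # noqa: BLE001
        raise StageError("abundance", e) from e

    # -------------------------------------------------------- genomic context
    try:
        mag_of_contig = dict(
            zip(mags["contig_id"].astype(str), mags["mag_id"].astype(str))
        )
        target_ids = {a.gene_id for a in catalogue}
        arch_by_gene = {
            gid: "_".join(
                h.pfam_acc
                for h in ar.resolve_overlaps(grouped[gid], config.overlap_fraction)
            )
            for gid in sorted(grouped)
        }
        by_contig: dict[str, list] = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        neighbor_records, clusters = [], []
        mag_target_counts: dict[str, int] = {}
        for contig_id in sorted(by_contig):
            mag_id = mag_of_contig.get(contig_id)
            if mag_id is None:
                continue
            contig_genes = sorted(by_contig[contig_id], key=lambda g: g.start)
            n_t = sum(g.gene_id in target_ids for g in contig_genes)
            if n_t:
                mag_target_counts[mag_id] = mag_target_counts.get(mag_id, 0) + n_t
            neighbor_records.extend(
                gc.scan_neighbors(
                    contig_genes, target_ids, mag_id, arch_by_gene,
                    strand_aware=config.strand_aware,
                )
            )
            clusters.extend(
                gc.find_tandem_clusters(
                    contig_genes, target_ids, config.max_intervening, mag_id
                )
            )
        tables["neighbors"] = gc.neighbors_table(neighbor_records)
        tables["tandem_clusters"] = gc.clusters_table(clusters)
        for key, df in gc.flanking_frequencies(neighbor_records).items():
            tables[f"flanking_{key}"] = df
        ctx.update(
            neighbor_records=neighbor_records, clusters=clusters,
            mag_summary=gc.mag_summary(mag_target_counts),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("genomic_context", e) from e

    # -------------------------------------------------------- community stats
    try:
        perma: dict = {}
        if catalogue:
            target_genes = [gene_by_id[a.gene_id] for a in catalogue]
            mat, grouping = cs.composition_matrix(
                target_genes, taxonomy_by_gene, samples, rank=config.rank
            )
            mat = mat[mat.sum(axis=1) > 0]
            grouping = {s: grouping[s] for s in mat.index}
            tables["composition_ibp"] = mat.reset_index(names="sample_id")
            n_groups = len(set(grouping.values()))
            if n_groups >= 2 and mat.shape[0] - n_groups >= 1:
                d = cs.bray_curtis(mat)
                res = cs.permanova(
                    d, grouping,
                    n_permutations=config.n_permutations, seed=config.seed,
                )
                perma = dataclasses.asdict(res)
        ctx["permanova"] = perma
    except Exception as e:  # noqa: BLE001
        raise StageError("community_stats", e) from e

    # -------------------------------------------------------------- tree prep
    try:
        sequences = fio.read_fasta(ds / "proteins.faa")
        target_hits = [
            h
            for a in catalogue
            for h in ar.resolve_overlaps(grouped[a.gene_id], config.overlap_fraction)
            if h.pfam_acc == config.target_pfam
        ]
        ctx["domain_fasta"] = tt.excise_domains(
            sequences, target_hits, config.target_pfam
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("tree_prep", e) from e

    ctx["tables"] = tables
    return ctx


def _architecture_table(catalogue, taxonomy_by_gene) -> pd.DataFrame:
    rows = []
    for a in catalogue:
        rec = taxonomy_by_gene.get(a.gene_id)
        rows.append(
            {
                "gene_id": a.gene_id,
                "sample_id": a.sample_id,
                "arch_string": a.arch_string,
                "n_target": a.n_target,
                "n_nterm": a.n_nterm,
                "n_cterm": a.n_cterm,
                "has_sp": a.has_sp,
                "n_tmd": a.n_tmd,
                "localization_class": a.localization_class,
                "is_diverse": a.is_diverse,
                "order": rec.rank("order") if rec is not None else None,
                "phylum": rec.rank("phylum") if rec is not None else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample_id", "arch_string", "n_target", "n_nterm",
            "n_cterm", "has_sp", "n_tmd", "localization_class", "is_diverse",
            "order", "phylum",
        ],
    )


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write all output tables; returns out_dir."""
    ctx = compute_all(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ctx["config"]
    for name, df in sorted(ctx["tables"].items()):
        fio.write_table(df, out / f"{name}.tsv", cfg)
    with open(out / "permanova.json", "w") as fh:
        json.dump(ctx["permanova"], fh, indent=2, sort_keys=True)
    tt.write_fasta(ctx["domain_fasta"], out / "target_domains.faa")
    run_summary = {
        "config_hash": fio.config_hash(cfg),
        "n_genes": len(ctx["genes"]),
        "n_target_genes": len(ctx["catalogue"]),
        "n_architectures": len({a.arch_string for a in ctx["catalogue"]}),
        "mag_summary": ctx["mag_summary"],
        "permanova": ctx["permanova"],
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
    return out
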