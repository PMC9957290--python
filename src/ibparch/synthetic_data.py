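"""Ground-truthed synthetic metagenome datasets for the IBP pipeline.

The generator emulates the statistical structure the analysis assumes —
contigs carrying genes with planted domain architectures (1–3 DUF3494
copies plus companion domains such as pfam16130 and pfam07589), planted
signal-peptide/TMD flags, tandem target-gene clusters, per-environment
read-count enrichment of target genes, and order-level taxonomy skews —
and writes every file format the pipeline reads, alongside truth tables.

It does NOT emulate sequence-level realism: protein sequences are random
strings with planted hit envelopes (they exist to exercise domain
excision), and read counts are per-gene negative-binomial draws as if read
mapping had already happened. Defaults mirror the gross proportions of an
Arctic winter sea-ice survey: ~70% single-domain and ~12% double-domain
prevalence, interior-ice read enrichment, Flavobacteriales/Alteromonadales-
dominated taxonomy.

Everything is deterministic given the seed: two runs with the same config
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ENVIRONMENTS, TARGET_PFAM

logger = logging.getLogger(__name__)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Companion-domain pool for non-target genes (frequent IBP neighbours).
OTHER_PFAMS = (
    "pfam07690", "pfam00072", "pfam04397", "pfam00578", "pfam01131",
    "pfam01663", "pfam03050", "pfam00155", "pfam03781", "pfam11251",
    "pfam11617", "pfam07676", "pfam14903", "pfam00132",
)

ORDER_TO_PHYLUM = {
    "Flavobacteriales": "Bacteroidetes",
    "Cytophagales": "Bacteroidetes",
    "Saprospirales": "Bacteroidetes",
    "Alteromonadales": "Gammaproteobacteria",
    "Oceanospirillales": "Gammaproteobacteria",
    "Cellvibrionales": "Gammaproteobacteria",
    "Vibrionales": "Gammaproteobacteria",
    "Thiotrichales": "Gammaproteobacteria",
    "Methylococcales": "Gammaproteobacteria",
    "Burkholderiales": "Betaproteobacteria",
    "Rhodobacterales": "Alphaproteobacteria",
    "Acidimicrobiales": "Actinobacteria",
    "Micrococcales": "Actinobacteria",
    "Streptomycetales": "Actinobacteria",
    "Verrucomicrobiales": "Verrucomicrobia",
}

_DEFAULT_SPECTRUM = {
    "pfam11999": 0.70,
    "pfam11999_pfam11999": 0.12,
    "pfam11999_pfam16130": 0.05,
    "pfam11999_pfam07589": 0.05,
    "pfam11999_pfam11999_pfam11999": 0.03,
    "pfam11999_pfam02010": 0.05,
}

_DEFAULT_P_SP = {
    "pfam11999": 0.40,
    "pfam11999_pfam11999": 0.58,
    "pfam11999_pfam16130": 0.37,
    "pfam11999_pfam07589": 0.53,
    "pfam11999_pfam11999_pfam11999": 0.41,
    "pfam11999_pfam02010": 0.45,
}

_DEFAULT_P_TMD = {
    "pfam11999": 0.09,
    "pfam11999_pfam11999": 0.04,
    "pfam11999_pfam16130": 0.20,
    "pfam11999_pfam07589": 0.65,
    "pfam11999_pfam11999_pfam11999": 0.06,
    "pfam11999_pfam02010": 0.10,
}

_DEFAULT_TAXONOMY_POOL = {
    "pfam11999": (("Flavobacteriales", 0.45), ("Alteromonadales", 0.29),
                  ("Burkholderiales", 0.05), ("Oceanospirillales", 0.03),
                  ("Acidimicrobiales", 0.02), ("Rhodobacterales", 0.16)),
    "pfam11999_pfam16130": (("Alteromonadales", 0.68), ("Flavobacteriales", 0.23),
                            ("Cellvibrionales", 0.08), ("Vibrionales", 0.01)),
    "pfam11999_pfam07589": (("Alteromonadales", 0.78), ("Oceanospirillales", 0.09),
                            ("Verrucomicrobiales", 0.07), ("Methylococcales", 0.02),
                            ("Rhodobacterales", 0.04)),
    "default": (("Flavobacteriales", 0.50), ("Alteromonadales", 0.25),
                ("Cytophagales", 0.10), ("Micrococcales", 0.08),
                ("Thiotrichales", 0.07)),
}


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study-like conditions.

    ``enrichment`` multiplies the expected read count of target genes per
    environment; with a fixed per-sample read total the expected RPKM of a
    target gene is ``base_read_rate * enrichment[env]``, giving a closed
    form for per-environment abundance shares.
    """

    seed: int = 0
    n_samples: dict[str, int] = field(
        default_factory=lambda: {
            "interior_ice": 4, "sea_ice_interface": 3,
            "epipelagic": 6, "meso_bathypelagic": 2,
        }
    )
    n_contigs_per_sample: tuple[int, int] = (6, 10)
    genes_per_contig: tuple[int, int] = (6, 14)
    target_gene_fraction: float = 0.08
    tandem_rate: float = 0.30
    architecture_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPECTRUM)
    )
    p_sp: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_P_SP))
    p_tmd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_P_TMD))
    enrichment: dict[str, float] = field(
        default_factory=lambda: {
            "interior_ice": 40.0, "sea_ice_interface": 8.0,
            "epipelagic": 1.0, "meso_bathypelagic": 0.2,
        }
    )
    base_read_rate: float = 50.0  # expected reads per kb at enrichment 1
    nb_size: float = 5.0  # negative-binomial dispersion (size parameter)
    total_mapped_reads: int = 1_000_000  # per sample (fixed denominator)
    p_classified: float = 0.857  # order-level taxonomy coverage of target genes
    taxonomy_pool: dict[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_TAXONOMY_POOL)
    )
    eukaryote_contig_fraction: float = 0.05
    short_contig_fraction: float = 0.05
    mag_fraction: float = 0.6  # fraction of prokaryotic contigs binned into MAGs
    decoy_hit_rate: float = 0.10  # extra overlapping / high-E-value decoy rows

    def validate(self) -> None:
        s = sum(self.architecture_spectrum.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"architecture_spectrum sums to {s}, not 1")
        for name, probs in (("p_sp", self.p_sp), ("p_tmd", self.p_tmd)):
            for k, v in probs.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}[{k}] = {v} outside [0,1]")
        if any(v <= 0 for v in self.enrichment.values()):
            raise ValueError("enrichment factors must be > 0")
        for env in self.n_samples:
            if env not in ENVIRONMENTS:
                raise ValueError(f"unknown environment {env!r}")


@dataclass
class GroundTruth:
    """Planted truth accompanying one simulated dataset."""

    genes: pd.DataFrame  # one row per gene with all planted attributes
    clusters: pd.DataFrame  # planted tandem clusters (adjacent target runs)
    arch_counts: dict[str, int]
    expected_env_rpkm_share: dict[str, float]
    config: SimConfig


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AA_ALPHABET, size=n))


def _draw_order(rng: np.random.Generator, pool: tuple) -> str:
    orders = [o for o, _w in pool]
    w = np.array([w for _o, w in pool], dtype=float)
    return str(rng.choice(orders, p=w / w.sum()))


def simulate(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Generate a complete dataset directory plus its ground truth.

    Emits genes.gff (with ``##sequence-region`` pragmas), domains.domtblout,
    topology.tsv, taxonomy.tsv, counts.tsv, samples.tsv, mags.tsv,
    contig_samples.tsv, proteins.faa, and a truth/ subdirectory.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    arch_names = sorted(config.architecture_spectrum)
    arch_probs = np.array([config.architecture_spectrum[a] for a in arch_names])
    arch_probs = arch_probs / arch_probs.sum()

    gene_rows = []  # truth rows
    gff_lines: list[str] = []
    region_lines: list[str] = []
    contig_sample_rows = []
    domt_rows: list[str] = []
    topo_rows = []
    tax_rows = []
    count_rows = []
    fasta_records: list[tuple[str, str]] = []
    mag_rows = []
    cluster_rows = []

    sample_ids: list[tuple[str, str]] = []  # (sample_id, env)
    for env in ENVIRONMENTS:
        for i in range(config.n_samples.get(env, 0)):
            abbrev = {"interior_ice": "II", "sea_ice_interface": "SII",
                      "epipelagic": "EPI", "meso_bathypelagic": "BaMe"}[env]
            sample_ids.append((f"{abbrev}_{i + 1}", env))

    mag_counter = 0
    for sample_id, env in sample_ids:
        n_contigs = int(rng.integers(config.n_contigs_per_sample[0],
                                     config.n_contigs_per_sample[1] + 1))
        enrich = config.enrichment[env]
        # decide MAG membership up front: consecutive prokaryotic contigs
        # are grouped 2-4 per MAG
        contig_plan = []
        for ci in range(n_contigs):
            contig_id = f"{sample_id}_c{ci + 1:03d}"
            u = rng.random()
            kind = "eukaryote" if u < config.eukaryote_contig_fraction else (
                "short" if u < config.eukaryote_contig_fraction + config.short_contig_fraction
                else "normal"
            )
            contig_plan.append((contig_id, kind))

        prok_contigs = [c for c, k in contig_plan if k == "normal"]
        mag_of_contig: dict[str, str] = {}
        i = 0
        while i < len(prok_contigs):
            if rng.random() < config.mag_fraction:
                mag_counter += 1
                mag_id = f"MAG_{mag_counter:04d}"
                size = int(rng.integers(2, 5))
                members = prok_contigs[i : i + size]
                for c in members:
                    mag_of_contig[c] = mag_id
                mag_rows.append(
                    {
                        "mag_id": mag_id,
                        "completeness": round(float(rng.uniform(50, 100)), 2),
                        "contamination": round(float(rng.uniform(0, 10)), 2),
                        "members": members,
                    }
                )
                i += size
            else:
                i += 1

        for contig_id, kind in contig_plan:
            if kind == "short":
                length = int(rng.integers(200, 500))
                gene_len = int(rng.integers(90, length - 20))
                start = int(rng.integers(1, length - gene_len))
                _emit_gene(
                    rng, config, gene_rows, gff_lines, domt_rows, topo_rows,
                    tax_rows, count_rows, fasta_records,
                    contig_id=contig_id, sample_id=sample_id, env=env,
                    gene_index=1, start=start, is_target=False,
                    fixed_len=gene_len, mag_id=mag_of_contig.get(contig_id, ""),
                    enrich=enrich,
                )
                region_lines.append(f"##sequence-region {contig_id} 1 {length}")
                contig_sample_rows.append((contig_id, sample_id, length))
                continue

            n_genes = int(rng.integers(config.genes_per_contig[0],
                                       config.genes_per_contig[1] + 1))
            # plant the target/non-target sequence with tandem correlation
            is_target_seq: list[bool] = []
            for gi in range(n_genes):
                if kind == "eukaryote":
                    is_target_seq.append(False)
                elif gi > 0 and is_target_seq[-1]:
                    is_target_seq.append(rng.random() < config.tandem_rate)
                else:
                    is_target_seq.append(rng.random() < config.target_gene_fraction)
            pos = 1
            run: list[str] = []
            for gi, is_t in enumerate(is_target_seq):
                gap = int(rng.integers(50, 301)) if gi > 0 else int(rng.integers(1, 100))
                start = pos + gap
                gene_id, gene_len = _emit_gene(
                    rng, config, gene_rows, gff_lines, domt_rows, topo_rows,
                    tax_rows, count_rows, fasta_records,
                    contig_id=contig_id, sample_id=sample_id, env=env,
                    gene_index=gi + 1, start=start, is_target=is_t,
                    fixed_len=None, mag_id=mag_of_contig.get(contig_id, ""),
                    enrich=enrich, eukaryote=(kind == "eukaryote"),
                )
                pos = start + gene_len - 1
                if is_t:
                    run.append(gene_id)
                else:
                    if len(run) >= 2:
                        cluster_rows.append(
                            {"contig_id": contig_id,
                             "mag_id": mag_of_contig.get(contig_id, ""),
                             "gene_ids": ";".join(run), "size": len(run)}
                        )
                    run = []
            if len(run) >= 2:
                cluster_rows.append(
                    {"contig_id": contig_id, "mag_id": mag_of_contig.get(contig_id, ""),
                     "gene_ids": ";".join(run), "size": len(run)}
                )
            length = pos + int(rng.integers(1, 200))
            region_lines.append(f"##sequence-region {contig_id} 1 {length}")
            contig_sample_rows.append((contig_id, sample_id, length))
            if kind == "eukaryote":
                tax_rows.append(
                    {"subject_id": contig_id, "domain": "Eukaryota",
                     "phylum": "", "order": ""}
                )

    genes_df = pd.DataFrame(gene_rows)
    clusters_df = pd.DataFrame(
        cluster_rows, columns=["contig_id", "mag_id", "gene_ids", "size"]
    )

    # ------------------------------------------------------------------ files
    with open(out_dir / "genes.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        for line in region_lines:
            fh.write(line + "\n")
        for line in gff_lines:
            fh.write(line + "\n")

    with open(out_dir / "domains.domtblout", "w") as fh:
        fh.write("#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord\n")
        fh.write("# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
        for line in domt_rows:
            fh.write(line + "\n")

    pd.DataFrame(topo_rows, columns=["protein_id", "has_sp", "n_tmd"]).to_csv(
        out_dir / "topology.tsv", sep="\t", index=False
    )
    pd.DataFrame(tax_rows, columns=["subject_id", "domain", "phylum", "order"]).to_csv(
        out_dir / "taxonomy.tsv", sep="\t", index=False
    )
    pd.DataFrame(count_rows, columns=["gene_id", "sample_id", "read_count"]).to_csv(
        out_dir / "counts.tsv", sep="\t", index=False
    )
    sample_meta = pd.DataFrame(
        [
            {
                "sample_id": s, "environment": e,
                "total_mapped_reads": config.total_mapped_reads,
                "pooled": e == "epipelagic" and s.endswith(("5", "6")),
            }
            for s, e in sample_ids
        ]
    )
    sample_meta.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        contig_sample_rows, columns=["contig_id", "sample_id", "length_bp"]
    ).to_csv(out_dir / "contig_samples.tsv", sep="\t", index=False)

    mag_records = []
    for m in mag_rows:
        for c in m["members"]:
            mag_records.append(
                {
                    "mag_id": m["mag_id"], "contig_id": c,
                    "completeness": m["completeness"],
                    "contamination": m["contamination"],
                    "taxonomy": "",
                }
            )
    pd.DataFrame(
        mag_records,
        columns=["mag_id", "contig_id", "completeness", "contamination", "taxonomy"],
    ).to_csv(out_dir / "mags.tsv", sep="\t", index=False)

    with open(out_dir / "proteins.faa", "w") as fh:
        for rid, seq in fasta_records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    # ------------------------------------------------------------------ truth
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    genes_df.to_csv(truth_dir / "genes_truth.tsv", sep="\t", index=False)
    clusters_df.to_csv(truth_dir / "clusters_truth.tsv", sep="\t", index=False)

    target_truth = genes_df[genes_df["is_target"] & ~genes_df["is_eukaryote"]]
    arch_counts = target_truth["arch_string"].value_counts().to_dict()
    env_weight = {
        env: float(
            (target_truth["environment"] == env).sum() * config.enrichment[env]
        )
        for env in ENVIRONMENTS
    }
    wsum = sum(env_weight.values())
    expected_share = {
        env: (w / wsum if wsum > 0 else 0.0) for env, w in env_weight.items()
    }
    summary = {
        "seed": config.seed,
        "n_genes": int(len(genes_df)),
        "n_target_genes": int(len(target_truth)),
        "arch_counts": {k: int(v) for k, v in sorted(arch_counts.items())},
        "n_tandem_clusters": int(len(clusters_df)),
        "expected_env_rpkm_share": expected_share,
        "p_sp": config.p_sp,
    }
    with open(truth_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    logger.info(
        "simulated %d genes (%d target) on %d contigs into %s",
        len(genes_df), len(target_truth), len(contig_sample_rows), out_dir,
    )
    return GroundTruth(
        genes=genes_df,
        clusters=clusters_df,
        arch_counts={k: int(v) for k, v in arch_counts.items()},
        expected_env_rpkm_share=expected_share,
        config=config,
    )


def _emit_gene(
    rng, config, gene_rows, gff_lines, domt_rows, topo_rows, tax_rows,
    count_rows, fasta_records, *, contig_id, sample_id, env, gene_index,
    start, is_target, fixed_len, mag_id, enrich, eukaryote=False,
):
    """Emit one gene everywhere it appears; returns (gene_id, gene_len_bp)."""
    gene_id = f"{contig_id}_g{gene_index:03d}"
    arch = ""
    has_sp, n_tmd = False, 0
    order, phylum = "", ""

    if is_target:
        arch_names = sorted(config.architecture_spectrum)
        probs = np.array([config.architecture_spectrum[a] for a in arch_names])
        arch = str(rng.choice(arch_names, p=probs / probs.sum()))
        domains = arch.split("_")
        has_sp = bool(rng.random() < config.p_sp.get(arch, 0.4))
        if rng.random() < config.p_tmd.get(arch, 0.1):
            n_tmd = int(rng.choice([1, 2, 3], p=[0.85, 0.12, 0.03]))
        pool = config.taxonomy_pool.get(arch, config.taxonomy_pool["default"])
        if rng.random() < config.p_classified:
            order = _draw_order(rng, pool)
            phylum = ORDER_TO_PHYLUM.get(order, "Bacteria_unclassified")
    elif fixed_len is not None:
        domains = []  # short-contig filler genes carry no domains
    else:
        n_other = int(rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15]))
        domains = sorted(rng.choice(OTHER_PFAMS, size=n_other, replace=False)) if n_other else []
        arch = "_".join(domains)

    # protein layout: envelopes laid left to right with linkers
    envelopes = []
    pos_aa = int(rng.integers(10, 41))
    for d in (arch.split("_") if arch else []):
        dlen = int(rng.integers(180, 221)) if d == TARGET_PFAM else int(rng.integers(50, 121))
        envelopes.append((d, pos_aa, pos_aa + dlen - 1))
        pos_aa += dlen + int(rng.integers(5, 31))
    prot_len = max(pos_aa + int(rng.integers(10, 31)),
                   (fixed_len // 3 - 1) if fixed_len else 0, 60)
    gene_len = fixed_len if fixed_len else 3 * prot_len + 3
    prot_len = (gene_len - 3) // 3
    end = start + gene_len - 1
    strand = "+" if rng.random() < 0.5 else "-"

    gff_lines.append(
        "\t".join(
            [contig_id, "ibparch_sim", "CDS", str(start), str(end), ".",
             strand, "0", f"ID={gene_id}"]
        )
    )

    seq = _rand_seq(rng, prot_len)
    fasta_records.append((gene_id, seq))

    for d, a, b in envelopes:
        score = float(rng.uniform(80, 400))
        ieval = 10.0 ** float(rng.uniform(-40, -10))
        domt_rows.append(_domt_row(d, gene_id, prot_len, a, b, score, ieval))
        if rng.random() < config.decoy_hit_rate:
            # overlapping lower-score duplicate: removed by overlap resolution
            domt_rows.append(
                _domt_row(d, gene_id, prot_len, a, b, score / 2.0, ieval * 10)
            )
        if rng.random() < config.decoy_hit_rate:
            # weak spurious hit: removed by the E-value threshold
            decoy = str(rng.choice(OTHER_PFAMS))
            domt_rows.append(
                _domt_row(decoy, gene_id, prot_len, a, b, 12.0, 1.0)
            )

    if is_target:
        topo_rows.append(
            {"protein_id": gene_id, "has_sp": str(has_sp).lower(), "n_tmd": n_tmd}
        )
        if order:
            tax_rows.append(
                {"subject_id": gene_id, "domain": "Bacteria",
                 "phylum": phylum, "order": order}
            )
    elif not eukaryote and rng.random() < 0.7:
        pool = config.taxonomy_pool["default"]
        o = _draw_order(rng, pool)
        tax_rows.append(
            {"subject_id": gene_id, "domain": "Bacteria",
             "phylum": ORDER_TO_PHYLUM.get(o, ""), "order": o}
        )

    mean = config.base_read_rate * (gene_len / 1000.0) * (enrich if is_target else 1.0)
    p = config.nb_size / (config.nb_size + mean)
    reads = int(rng.negative_binomial(config.nb_size, p))
    count_rows.append({"gene_id": gene_id, "sample_id": sample_id, "read_count": reads})

    gene_rows.append(
        {
            "gene_id": gene_id, "contig_id": contig_id, "sample_id": sample_id,
            "environment": env, "mag_id": mag_id, "start": start, "end": end,
            "strand": strand, "gene_len_bp": gene_len, "is_target": bool(is_target),
            "is_eukaryote": bool(eukaryote), "arch_string": arch,
            "has_sp": bool(has_sp), "n_tmd": int(n_tmd),
            "order": order, "phylum": phylum, "read_count": reads,
        }
    )
    return gene_id, gene_len


def _domt_row(pfam: str, protein: str, prot_len: int, env_a: int, env_b: int,
              score: float, ievalue: float) -> str:
    acc = "PF" + pfam[4:] + ".1"
    cols = [
        pfam, acc, str(env_b - env_a + 1), protein, "-", str(prot_len),
        f"{ievalue:.2g}", f"{score:.1f}", "0.0", "1", "1",
        f"{ievalue:.2g}", f"{ievalue:.2g}", f"{score:.1f}", "0.0",
        "1", str(env_b - env_a + 1), str(env_a), str(env_b),
        str(env_a), str(env_b), "0.95", "-",
    ]
    return " ".join(cols)


# ---------------------------------------------------------------------------
# Composition simulator (for the PERMANOVA suites)
# ---------------------------------------------------------------------------

def simulate_compositions(
    group_alphas: Mapping[str, np.ndarray],
    n_per_group: int,
    n_reads: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Samples x taxa count matrix with Dirichlet-multinomial groups.

    Each group's samples draw proportions from Dirichlet(alpha_g) and then
    counts from a multinomial; identical alphas across groups give a true
    null, distinct means a planted effect.
    """
    rng = np.random.default_rng(seed)
    rows, index, grouping = [], [], {}
    for g in sorted(group_alphas):
        alpha = np.asarray(group_alphas[g], dtype=float)
        for i in range(n_per_group):
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(n_reads, p))
            sid = f"{g}_{i + 1}"
            index.append(sid)
            grouping[sid] = g
    k = len(rows[0])
    mat = pd.DataFrame(rows, index=index, columns=[f"taxon_{j + 1}" for j in range(k)])
    return mat, grouping


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

def audit(dataset_dir: str | Path, truth: GroundTruth | None = None) -> dict:
    """Self-consistency audit of a simulated dataset directory.

    Checks: every GFF gene has a read-count row; every (non-eukaryotic)
    target gene in the truth has at least one pfam11999 row in the
    domtblout; gene coordinates lie inside their contig; topology covers
    every target gene. Failures are report content, not exceptions.
    """
    from . import io as fio

    dataset_dir = Path(dataset_dir)
    problems: list[str] = []
    genes = fio.read_gff(dataset_dir / "genes.gff", sample_id="NA")
    lengths = fio.read_contig_lengths(dataset_dir / "genes.gff")
    counts = fio.read_counts(dataset_dir / "counts.tsv")
    counted = set(counts["gene_id"].astype(str))
    for g in genes:
        if g.gene_id not in counted:
            problems.append(f"gene {g.gene_id} has no read-count row")
        clen = lengths.get(g.contig_id)
        if clen is None:
            problems.append(f"contig {g.contig_id} has no sequence-region pragma")
        elif g.end > clen:
            problems.append(f"gene {g.gene_id} ends beyond contig length {clen}")

    hits = fio.read_domtblout(dataset_dir / "domains.domtblout", max_i_evalue=float("inf"))
    hit_proteins = {h.protein_id for h in hits if h.pfam_acc == TARGET_PFAM}
    topo = fio.read_topology(dataset_dir / "topology.tsv")
    if truth is not None:
        tt = truth.genes[truth.genes["is_target"] & ~truth.genes["is_eukaryote"]]
        for gid in tt["gene_id"]:
            if gid not in hit_proteins:
                problems.append(f"target gene {gid} has no {TARGET_PFAM} hit")
            if gid not in topo:
                problems.append(f"target gene {gid} has no topology record")
    return {"pass": not problems, "problems": problems}
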