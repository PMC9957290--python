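"""Tree-input preparation, rooting, and per-leaf annotation export.

Gene trees over the excised target-domain (DUF3494) subsequences are
inferred externally (alignment, trimming and inference are standard tools
with no project-specific behaviour); this module prepares their input FASTA,
roots the resulting newick trees, and exports iTOL annotation rings.

Rooting rule: trees with fewer than ``min_leaves_for_outgroup`` leaves (60
by default) or with an empty outgroup set are rooted at their midpoint —
halfway along the longest leaf-to-leaf path. Larger trees are rooted on the
edge subtending the smallest clade containing all outgroup leaves; the
outgroup need not be monophyletic, in which case the smallest spanning
clade is used and a warning emitted. Rooting never changes the leaf set,
the total branch length, or any leaf-to-leaf path length.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .model import DomainHit, LeafAnnotation, TARGET_PFAM

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEAVES_FOR_OUTGROUP = 60

# Ring colours for the closed vocabularies (environment ring follows the
# published greyscale: interior ice darkest, open water lightest).
ENVIRONMENT_COLORS = {
    "interior_ice": "#000000",
    "sea_ice_interface": "#555555",
    "epipelagic": "#BBBBBB",
    "meso_bathypelagic": "#FFFFFF",
}
LOCALIZATION_COLORS = {
    "none": "#FFFFFF",
    "sp_only": "#E41A1C",
    "tmd_only": "#8B0000",
    "both": "#000000",
}
ARCH_CLASS_COLORS = {
    "single": "#FFFFFF",
    "double": "#808080",
    "triple": "#377EB8",
    "duf4842": "#2CA25F",
    "pep_cterm": "#F781BF",
    "other": "#000000",
}
#: Deterministic qualitative palette for open vocabularies (phylum, order).
PALETTE = (
    "#66C2A5", "#FC8D62", "#8DA0CB", "#E78AC3", "#A6D854", "#FFD92F",
    "#E5C494", "#B3B3B3", "#1B9E77", "#D95F02", "#7570B3", "#E7298A",
    "#66A61E", "#E6AB02", "#A6761D", "#666666",
)
UNKNOWN_COLOR = "#FFFFFF"


# ---------------------------------------------------------------------------
# Domain excision
# ---------------------------------------------------------------------------

def excise_domains(
    protein_sequences: Mapping[str, str],
    hits: Iterable[DomainHit],
    target: str = TARGET_PFAM,
) -> list[tuple[str, str]]:
    """Cut target-domain envelope subsequences out of their proteins.

    One record per retained target-domain hit, id
    ``gene_id/env_start-env_end`` — multi-copy proteins yield one record per
    copy. Envelope coordinates are 1-based inclusive; an envelope reaching
    beyond the sequence end is an error.
    """
    out: list[tuple[str, str]] = []
    for h in sorted(hits, key=lambda h: (h.protein_id, h.env_start, h.env_end)):
        if h.pfam_acc != target:
            continue
        seq = protein_sequences.get(h.protein_id)
        if seq is None:
            raise KeyError(f"protein {h.protein_id} not in sequence set")
        if h.env_end > len(seq):
            raise ValueError(
                f"hit envelope {h.env_start}-{h.env_end} exceeds protein "
                f"{h.protein_id} length {len(seq)}"
            )
        out.append(
            (f"{h.protein_id}/{h.env_start}-{h.env_end}", seq[h.env_start - 1 : h.env_end])
        )
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def load_tree(source: str | Path) -> dendropy.Tree:
    """Load a newick tree from a path or a newick string."""
    s = str(source)
    if s.lstrip().startswith("("):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def root_tree(
    tree: dendropy.Tree,
    outgroup_leaf_ids: Iterable[str] = (),
    min_leaves_for_outgroup: int = DEFAULT_MIN_LEAVES_FOR_OUTGROUP,
    mode: str = "auto",
) -> dendropy.Tree:
    """Root a tree by the midpoint/outgroup rule (see module docstring).

    ``mode``: ``auto`` applies the leaf-count rule; ``midpoint`` and
    ``outgroup`` force one strategy. Requesting outgroup rooting with
    outgroup leaves absent from the tree is an error listing the missing
    ids. The input tree is modified in place and also returned.
    """
    if mode not in ("auto", "midpoint", "outgroup"):
        raise ValueError(f"unknown rooting mode {mode!r}")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    outgroup = sorted(set(outgroup_leaf_ids))
    if mode == "midpoint" or (mode == "auto" and (len(leaves) < min_leaves_for_outgroup or not outgroup)):
        tree.is_rooted = True
        if not _is_midpoint_rooted(tree):
            tree.reroot_at_midpoint(update_bipartitions=False)
        return tree
    missing = sorted(set(outgroup) - set(leaves))
    if missing:
        raise ValueError(f"outgroup leaves absent from tree: {missing}")
    return _root_on_outgroup(tree, outgroup)


def _root_on_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    tree.is_rooted = True
    og_set = set(outgroup)
    # Anchor the rooting at an ingroup leaf so the outgroup cannot span the
    # root, then take the MRCA of the outgroup under that rooting.
    ingroup_leaves = sorted(
        (lf for lf in tree.leaf_node_iter() if lf.taxon.label not in og_set),
        key=lambda lf: lf.taxon.label,
    )
    if not ingroup_leaves:
        raise ValueError("outgroup covers every leaf; cannot root")
    anchor = ingroup_leaves[0]
    el = anchor.edge.length or 0.0
    tree.reroot_at_edge(anchor.edge, length1=el / 2, length2=el / 2, update_bipartitions=False)
    taxa = [tx for tx in tree.taxon_namespace if tx.label in og_set]
    mrca = tree.mrca(taxa=taxa)
    clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
    if clade_leaves != og_set:
        logger.warning(
            "outgroup is not monophyletic: smallest spanning clade has %d leaves "
            "(%d requested)", len(clade_leaves), len(og_set),
        )
    el = mrca.edge.length or 0.0
    tree.reroot_at_edge(mrca.edge, length1=el / 2, length2=el / 2, update_bipartitions=False)
    return tree


def _is_midpoint_rooted(tree: dendropy.Tree) -> bool:
    """True when the current root already sits at the tree midpoint.

    Guard for idempotent midpoint rooting: rerooting is skipped when the
    root is bifurcating, the two deepest root-adjacent subtrees tie, and
    the root's depth equals half the tree diameter.
    """
    children = tree.seed_node.child_nodes()
    if len(children) != 2:
        return False
    if root_balance(tree) > 1e-9:
        return False
    depths = []
    for lf in tree.leaf_node_iter():
        d, node = 0.0, lf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    diameter = max(
        (pdist for pdist in leaf_distance_matrix(tree).values()), default=0.0
    )
    return abs(max(depths, default=0.0) - diameter / 2.0) <= 1e-9


def root_balance(tree: dendropy.Tree) -> float:
    """Difference between the two root-adjacent subtree depths.

    Depth of a root child = its edge length plus the maximum leaf distance
    below it. Zero (to numerical tolerance) for a midpoint-rooted tree,
    unless the midpoint falls exactly on an internal node.
    """
    depths = []
    for child in tree.seed_node.child_nodes():
        m = 0.0
        for lf in child.leaf_iter():
            d = 0.0
            node = lf
            while node is not child:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(None)
            m = max(m, d)
        depths[-1] = m + (child.edge.length or 0.0)
    depths = [d for d in depths if d is not None]
    if len(depths) < 2:
        return 0.0
    depths.sort(reverse=True)
    return depths[0] - depths[1]


def leaf_distance_matrix(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Pairwise leaf-to-leaf path lengths keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = sorted(tree.taxon_namespace, key=lambda tx: tx.label)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# iTOL annotation rings
# ---------------------------------------------------------------------------

def _categorical_colors(values: Iterable[str], fixed: Mapping[str, str] | None) -> dict[str, str]:
    if fixed is not None:
        return dict(fixed)
    cats = sorted({v for v in values if v is not None})
    return {c: PALETTE[i % len(PALETTE)] for i, c in enumerate(cats)}


def export_itol_rings(
    tree: dendropy.Tree,
    annotations: Sequence[LeafAnnotation],
    out_dir: str | Path,
    color_map: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, Path]:
    """Write one iTOL dataset file per annotation ring.

    Colour strips for the categorical rings (environment, localization,
    phylum, order, architecture class) and a simple bar chart for RPKM
    abundance. Colour assignment is deterministic: closed vocabularies use
    the shipped maps, open ones (phylum/order) take palette colours in
    sorted category order. Leaves without an annotation get the explicit
    unknown colour (white). Duplicate leaf ids in the annotations are an
    error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    ann_by_leaf: dict[str, LeafAnnotation] = {}
    for a in annotations:
        if a.leaf_id in ann_by_leaf:
            raise ValueError(f"duplicate leaf id in annotations: {a.leaf_id}")
        ann_by_leaf[a.leaf_id] = a

    color_map = color_map or {}
    rings: list[tuple[str, str, Mapping[str, str] | None]] = [
        ("environment", "environment", ENVIRONMENT_COLORS),
        ("localization_class", "localization", LOCALIZATION_COLORS),
        ("phylum", "phylum", None),
        ("order", "order", None),
        ("arch_class", "architecture", ARCH_CLASS_COLORS),
    ]
    paths: dict[str, Path] = {}
    for attr, label, fixed in rings:
        values = [getattr(ann_by_leaf.get(l), attr, None) if l in ann_by_leaf else None for l in leaf_ids]
        colors = _categorical_colors(values, color_map.get(label, fixed))
        p = out_dir / f"{label}_strip.txt"
        with open(p, "w") as fh:
            fh.write("DATASET_COLORSTRIP\nSEPARATOR TAB\n")
            fh.write(f"DATASET_LABEL\t{label}\nCOLOR\t#000000\n")
            fh.write("DATA\n")
            for leaf, v in zip(leaf_ids, values):
                color = colors.get(v, UNKNOWN_COLOR) if v is not None else UNKNOWN_COLOR
                fh.write(f"{leaf}\t{color}\t{v if v is not None else 'unknown'}\n")
        paths[label] = p

    p = out_dir / "abundance_bar.txt"
    with open(p, "w") as fh:
        fh.write("DATASET_SIMPLEBAR\nSEPARATOR TAB\n")
        fh.write("DATASET_LABEL\tabundance_rpkm\nCOLOR\t#377EB8\n")
        fh.write("DATA\n")
        for leaf in leaf_ids:
            a = ann_by_leaf.get(leaf)
            fh.write(f"{leaf}\t{a.abundance_rpkm if a is not None else 0.0}\n")
    paths["abundance"] = p
    return paths
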