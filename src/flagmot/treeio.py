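"""Reading, writing, and pruning of trees and of the pipeline's tabular formats.

Trees are handled as :class:`dendropy.Tree` objects (Newick or Nexus, rooted
as given — no re-rooting is ever applied). Tabular inputs and outputs are
tab-separated with a header row; lines beginning with ``#`` are ignored so
that HMMER ``--tblout``-style files pass through unchanged. Taxon names are
matched by exact string after whitespace trimming.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: marker accepted in trait tables for "state unknown"
MISSING_STATE = "-"

HIT_COLUMNS = ["genome_id", "query_protein", "e_value", "subject_length", "subject_id"]


class TreeError(ValueError):
    """A tree violates the pipeline's structural requirements."""


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Check tip-label uniqueness and non-negative branch lengths.

    Returns the tree unchanged on success; raises :class:`TreeError` otherwise.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        seen, dups = set(), set()
        for lab in labels:
            (dups if lab in seen else seen).add(lab)
        raise TreeError(f"duplicate tip labels: {sorted(dups)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length} on edge to "
                            f"{edge.head_node}")
    return tree


def read_tree(path: str | Path, format: str = "newick") -> dendropy.Tree:
    """Read a rooted phylogeny from a Newick or Nexus file.

    Parameters
    ----------
    path : path to the tree file.
    format : ``"newick"`` or ``"nexus"``.

    The tree is treated as rooted with the root placed as written. Underscores
    in labels are preserved literally.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=format, preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except dendropy.utility.error.DataParseError as exc:
        if "Duplicate" in str(exc) or "duplicate" in str(exc):
            raise TreeError(f"duplicate tip labels in {path}") from exc
        raise
    tree.is_rooted = True
    validate_tree(tree)
    logger.info("read %d-tip tree from %s", sum(1 for _ in tree.leaf_node_iter()), path)
    return tree


def parse_tree(newick: str, format: str = "newick") -> dendropy.Tree:
    """Parse a tree from a string (same validation as :func:`read_tree`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema=format, preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except dendropy.utility.error.DataParseError as exc:
        if "uplicate" in str(exc):
            raise TreeError("duplicate tip labels") from exc
        raise
    tree.is_rooted = True
    return validate_tree(tree)


def write_tree(tree: dendropy.Tree, path: str | Path, format: str = "newick") -> None:
    """Write a phylogeny to Newick or Nexus; round-trips through :func:`read_tree`."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    tree.write(path=str(path), schema=format, unquoted_underscores=True,
               suppress_rooting=False)


def tree_to_string(tree: dendropy.Tree, format: str = "newick") -> str:
    return tree.as_string(schema=format, unquoted_underscores=True,
                          suppress_rooting=True)


def prune_tree_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to a taxon subset, preserving patristic distances.

    Unary internal nodes created by the pruning are suppressed with their
    branch lengths summed, so path lengths between kept tips are unchanged.
    The input tree is not modified.
    """
    keep = {str(k).strip() for k in keep}
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    unknown = keep - tip_labels
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)[:10]}")
    if len(keep) < 2:
        raise TreeError(f"need at least 2 surviving taxa, got {len(keep)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    # dendropy can leave the root unifurcating; merge that edge downward.
    root = pruned.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        for grandchild in list(child.child_nodes()):
            child.remove_child(grandchild)
            root.add_child(grandchild)
            if grandchild.edge.length is not None and child.edge.length is not None:
                grandchild.edge.length += child.edge.length
        root.remove_child(child)
    pruned.update_bipartitions(suppress_unifurcations=True)
    return validate_tree(pruned)


def _read_table(path: str | Path) -> tuple[pd.DataFrame, int]:
    """TSV with header; '#'-prefixed lines skipped. Returns (frame, n_comments)."""
    text = Path(path).read_text()
    kept, n_comments = [], 0
    for line in text.splitlines():
        if line.startswith("#"):
            n_comments += 1
        elif line.strip():
            kept.append(line)
    if not kept:
        raise ValueError(f"{path}: no data rows")
    frame = pd.read_csv(io.StringIO("\n".join(kept)), sep="\t", dtype=str)
    frame.columns = [c.strip() for c in frame.columns]
    if n_comments:
        logger.info("%s: skipped %d comment line(s)", path, n_comments)
    return frame, n_comments


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a homology hit table (TSV, tblout-style ``#`` comments tolerated).

    Required columns: genome_id, query_protein, e_value, subject_length;
    subject_id is optional. Malformed rows raise with their line numbers.
    """
    frame, _ = _read_table(path)
    required = ["genome_id", "query_protein", "e_value", "subject_length"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "subject_id" not in frame.columns:
        frame["subject_id"] = ""
    bad_lines = []
    e_value = pd.to_numeric(frame["e_value"], errors="coerce")
    length = pd.to_numeric(frame["subject_length"], errors="coerce")
    for idx in frame.index[e_value.isna() | length.isna() | (e_value <= 0) | (length < 1)]:
        bad_lines.append(idx + 2)  # header is line 1
    if bad_lines:
        raise ValueError(f"{path}: malformed rows at line(s) {bad_lines[:20]} "
                         "(need e_value > 0, subject_length >= 1)")
    frame = frame.assign(e_value=e_value, subject_length=length.astype(int))
    frame["genome_id"] = frame["genome_id"].str.strip()
    frame["query_protein"] = frame["query_protein"].str.strip()
    return frame[HIT_COLUMNS]


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path,
                     alphabet: Sequence[str] = ("0", "1")) -> pd.DataFrame:
    """Read a taxon/state table; states must come from ``alphabet`` or be missing.

    Returns a frame with columns ``taxon`` and ``state`` (strings); the missing
    marker ``-`` is preserved as-is.
    """
    frame, _ = _read_table(path)
    if "taxon" not in frame.columns or "state" not in frame.columns:
        raise ValueError(f"{path}: trait table needs 'taxon' and 'state' columns")
    frame["taxon"] = frame["taxon"].str.strip()
    frame["state"] = frame["state"].str.strip()
    allowed = set(alphabet) | {MISSING_STATE}
    bad = frame.loc[~frame["state"].isin(allowed)]
    if len(bad):
        raise ValueError(f"{path}: states outside alphabet {list(alphabet)}: "
                         f"{sorted(bad['state'].unique())[:10]}")
    if frame["taxon"].duplicated().any():
        dups = frame.loc[frame["taxon"].duplicated(), "taxon"].tolist()
        raise ValueError(f"{path}: duplicate taxa {dups[:10]}")
    return frame[["taxon", "state"]]


def write_trait_table(traits: pd.DataFrame | dict, path: str | Path) -> None:
    if isinstance(traits, dict):
        traits = pd.DataFrame({"taxon": list(traits), "state": list(traits.values())})
    traits.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a presence/absence matrix (rows = genomes, columns = proteins)."""
    frame, _ = _read_table(path)
    frame = frame.set_index(frame.columns[0])
    frame.index.name = "genome_id"
    mat = frame.apply(pd.to_numeric)
    if not mat.isin([0, 1]).all().all():
        raise ValueError(f"{path}: matrix entries must be 0/1")
    return mat.astype(np.int8)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read observed-motility phenotypes: columns taxon, phenotype."""
    frame, _ = _read_table(path)
    if "taxon" not in frame.columns or "phenotype" not in frame.columns:
        raise ValueError(f"{path}: phenotype table needs 'taxon' and 'phenotype'")
    frame["taxon"] = frame["taxon"].str.strip()
    frame["phenotype"] = frame["phenotype"].str.strip().str.lower()
    allowed = {"motile", "non-motile"}
    bad = set(frame["phenotype"]) - allowed
    if bad:
        raise ValueError(f"{path}: phenotypes must be in {allowed}, got {sorted(bad)}")
    return frame[["taxon", "phenotype"]]
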