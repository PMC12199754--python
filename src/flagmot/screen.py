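"""Homolog-screen filtering: e-value and length filters, PCA-outlier pick,
structural-verdict propagation through sequence clusters, and binarization
into the presence/absence matrix.

The screen assumes the homology search itself (jackhmmer), the 90%-identity
clustering, structure prediction, and the structural comparisons have already
run; their outputs — hit tables, cluster assignments, per-structure
probabilities, reduced-space coordinates — are the inputs here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .registry import QueryProteinSpec, default_protein_names, default_query_specs

logger = logging.getLogger(__name__)

LENGTH_RULES = ("above_max_only", "outside_range")


@dataclass
class ScreenConfig:
    """Filter thresholds for the homolog screen.

    evalue_max: hits with e-value above this are discarded (inclusive keep).
    n_outliers: how many most-distant points to pick for structural checking.
    foldseek_accept_prob: structural verdicts below this probability reject.
    length_rule: drop only over-length hits, or anything outside the range.
    """

    evalue_max: float = 1e-10
    n_outliers: int = 10
    foldseek_accept_prob: float = 1.0
    length_rule: str = "above_max_only"

    def __post_init__(self):
        if not self.evalue_max > 0:
            raise ValueError("evalue_max must be positive")
        if not 0 < self.foldseek_accept_prob <= 1:
            raise ValueError("foldseek_accept_prob must be in (0, 1]")
        if self.length_rule not in LENGTH_RULES:
            raise ValueError(f"length_rule must be one of {LENGTH_RULES}")


def _removals_by_protein(before: pd.DataFrame, after: pd.DataFrame) -> dict[str, int]:
    b = before["query_protein"].value_counts()
    a = after["query_protein"].value_counts()
    removed = (b - a.reindex(b.index, fill_value=0)).astype(int)
    return {p: int(n) for p, n in removed.items() if n > 0}


def filter_hits_by_evalue(hits: pd.DataFrame,
                          config: ScreenConfig | None = None) -> pd.DataFrame:
    """Keep hits with e_value <= evalue_max (threshold inclusive)."""
    config = config or ScreenConfig()
    kept = hits.loc[hits["e_value"] <= config.evalue_max].copy()
    removed = _removals_by_protein(hits, kept)
    if removed:
        logger.info("e-value filter removed %d hit(s): %s",
                    len(hits) - len(kept), removed)
    return kept


def filter_hits_by_length(hits: pd.DataFrame,
                          specs: dict[str, QueryProteinSpec] | None = None,
                          config: ScreenConfig | None = None) -> pd.DataFrame:
    """Drop hits outside each query protein's representative length range.

    Under ``above_max_only`` (default) only over-length subjects are removed;
    under ``outside_range`` under-length subjects are removed too. Boundary
    lengths are kept.
    """
    config = config or ScreenConfig()
    specs = specs or default_query_specs()
    missing = set(hits["query_protein"]) - set(specs)
    if missing:
        raise KeyError(f"no length spec for protein(s): {sorted(missing)}")
    lo = hits["query_protein"].map(lambda p: specs[p].length_min)
    hi = hits["query_protein"].map(lambda p: specs[p].length_max)
    keep = hits["subject_length"] <= hi
    if config.length_rule == "outside_range":
        keep &= hits["subject_length"] >= lo
    kept = hits.loc[keep].copy()
    removed = _removals_by_protein(hits, kept)
    if removed:
        fractions = {p: n / int((hits["query_protein"] == p).sum())
                     for p, n in removed.items()}
        logger.info("length filter removed %d hit(s); per-protein fractions: %s",
                    len(hits) - len(kept),
                    {p: round(f, 3) for p, f in fractions.items()})
    return kept


def select_pca_outliers(coordinates: pd.DataFrame, k: int = 10) -> list:
    """The ``k`` point ids farthest (Euclidean) from the coordinate-wise mean.

    Ties are broken by ascending id; with fewer than ``k`` points, all ids
    are returned (farthest first).
    """
    if len(coordinates) == 0:
        raise ValueError("no points given")
    X = coordinates.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("coordinates contain NaN/inf")
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    order = sorted(range(len(d)), key=lambda i: (-d[i], coordinates.index[i]))
    return [coordinates.index[i] for i in order[: min(k, len(d))]]


def apply_structural_verdicts(hits: pd.DataFrame, clusters: pd.DataFrame,
                              verdicts: pd.DataFrame,
                              config: ScreenConfig | None = None) -> pd.DataFrame:
    """Propagate structural accept/reject decisions through sequence clusters.

    ``clusters`` maps sequence_id -> cluster_id (tidy, one row per sequence);
    ``verdicts`` carries a ``foldseek_probability`` per ``sequence_id`` or per
    ``cluster_id``. A verdict below the acceptance probability rejects the
    sequence and, with it, every member of its CD-HIT cluster. Sequences in
    clusters that received no verdict are untouched.
    """
    config = config or ScreenConfig()
    seq_to_cluster = dict(zip(clusters["sequence_id"], clusters["cluster_id"]))
    known_clusters = set(clusters["cluster_id"])

    rejected_clusters: set = set()
    rejected_sequences: set = set()
    for _, row in verdicts.iterrows():
        prob = float(row["foldseek_probability"])
        if not 0 <= prob <= 1:
            raise ValueError(f"foldseek probability {prob} outside [0, 1]")
        accepted = prob >= config.foldseek_accept_prob
        if accepted:
            continue
        if "cluster_id" in verdicts.columns and pd.notna(row.get("cluster_id")):
            cid = row["cluster_id"]
            if cid not in known_clusters:
                raise KeyError(f"verdict references unknown cluster {cid!r}")
            rejected_clusters.add(cid)
        else:
            sid = row["sequence_id"]
            if sid not in seq_to_cluster:
                raise KeyError(f"verdict references unknown sequence {sid!r}")
            rejected_sequences.add(sid)
            rejected_clusters.add(seq_to_cluster[sid])

    bad_seqs = {s for s, c in seq_to_cluster.items()
                if c in rejected_clusters} | rejected_sequences
    kept = hits.loc[~hits["subject_id"].isin(bad_seqs)].copy()
    removed = _removals_by_protein(hits, kept)
    if removed:
        logger.info("structural verdicts removed %d hit(s): %s",
                    len(hits) - len(kept), removed)
    return kept


def build_presence_absence(hits: pd.DataFrame, genome_universe=None,
                           protein_set=None) -> pd.DataFrame:
    """Binarize surviving hits: entry (g, p) = 1 iff any hit remains.

    Genomes in ``genome_universe`` without hits appear as all-zero rows;
    columns follow ``protein_set`` (default: the built-in 54-protein set).
    """
    proteins = list(protein_set) if protein_set is not None else default_protein_names()
    genomes = (list(genome_universe) if genome_universe is not None
               else sorted(hits["genome_id"].unique()))
    matrix = pd.DataFrame(0, index=pd.Index(genomes, name="genome_id"),
                          columns=proteins, dtype=np.int8)
    relevant = hits.loc[hits["genome_id"].isin(set(genomes))
                        & hits["query_protein"].isin(set(proteins))]
    for gid, prot in zip(relevant["genome_id"], relevant["query_protein"]):
        matrix.loc[gid, prot] = 1
    return matrix


class HomologScreen(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer chaining the screen's filters in fixed order.

    ``transform`` maps a raw hit table to the filtered hit table
    (e-value -> length -> structural verdicts); ``presence_absence`` then
    binarizes. Stage-wise removal counts are recorded in ``report_``.

    Parameters mirror :class:`ScreenConfig`; ``specs`` defaults to the
    built-in 54-protein registry; ``clusters``/``verdicts`` are optional —
    without them the structural stage is a no-op.
    """

    def __init__(self, evalue_max: float = 1e-10, n_outliers: int = 10,
                 foldseek_accept_prob: float = 1.0,
                 length_rule: str = "above_max_only",
                 specs: dict | None = None,
                 clusters: pd.DataFrame | None = None,
                 verdicts: pd.DataFrame | None = None):
        self.evalue_max = evalue_max
        self.n_outliers = n_outliers
        self.foldseek_accept_prob = foldseek_accept_prob
        self.length_rule = length_rule
        self.specs = specs
        self.clusters = clusters
        self.verdicts = verdicts

    def _config(self) -> ScreenConfig:
        return ScreenConfig(evalue_max=self.evalue_max,
                            n_outliers=self.n_outliers,
                            foldseek_accept_prob=self.foldseek_accept_prob,
                            length_rule=self.length_rule)

    def fit(self, X: pd.DataFrame, y=None):
        self._config()  # validates parameters
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        config = self._config()
        report = {"input": len(X)}
        out = filter_hits_by_evalue(X, config)
        report["after_evalue"] = len(out)
        out = filter_hits_by_length(out, self.specs, config)
        report["after_length"] = len(out)
        if self.clusters is not None and self.verdicts is not None:
            out = apply_structural_verdicts(out, self.clusters, self.verdicts,
                                            config)
        report["after_structure"] = len(out)
        self.report_ = report
        return out

    def presence_absence(self, X: pd.DataFrame, genome_universe=None,
                         protein_set=None) -> pd.DataFrame:
        filtered = self.transform(X)
        if protein_set is None and self.specs is not None:
            protein_set = list(self.specs)
        return build_presence_absence(filtered, genome_universe, protein_set)
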