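"""Motility calling from flagellar-protein counts, phenotype validation, and
normalized functional-class abundance summaries.

The classifier's single feature is N_FP, the number of distinct query
proteins with at least one surviving hit in a genome. Genomes with
N_FP <= 15 are called non-motile, N_FP >= 32 motile, and anything between is
a "partial" flagellar protein set — thresholds read off the valley of the
strongly bimodal N_FP distribution, and configurable here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, ClassifierMixin

LABELS = ("non-motile", "partial", "motile")


def count_flagellar_proteins(matrix_row) -> int:
    """N_FP of one genome: the row sum of its binary presence vector."""
    row = np.asarray(matrix_row)
    if not np.isin(row, (0, 1)).all():
        raise ValueError("presence row must be binary")
    return int(row.sum())


def classify_motility(n_fp: int, nonmotile_max: int = 15,
                      motile_min: int = 32) -> str:
    """Threshold rule: <=nonmotile_max non-motile, >=motile_min motile, else partial."""
    if n_fp < 0:
        raise ValueError("negative protein count")
    if nonmotile_max >= motile_min:
        raise ValueError("nonmotile_max must be below motile_min")
    if n_fp <= nonmotile_max:
        return "non-motile"
    if n_fp >= motile_min:
        return "motile"
    return "partial"


def classify_by_flic(matrix_row: pd.Series) -> str:
    """Single-protein proxy: motile iff flagellin (FliC) is present."""
    if "FliC" not in matrix_row.index:
        raise KeyError("row has no FliC column")
    return "motile" if int(matrix_row["FliC"]) == 1 else "non-motile"


class MotilityClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier over presence/absence matrices (or N_FP vectors).

    Stateless in the statistical sense — ``fit`` only validates thresholds and
    records feature count — so it slots into sklearn pipelines downstream of
    :class:`flagmot.screen.HomologScreen`.

    Parameters
    ----------
    nonmotile_max : largest N_FP still called non-motile (default 15).
    motile_min : smallest N_FP called motile (default 32).
    """

    def __init__(self, nonmotile_max: int = 15, motile_min: int = 32):
        self.nonmotile_max = nonmotile_max
        self.motile_min = motile_min

    def fit(self, X, y=None):
        if self.nonmotile_max >= self.motile_min:
            raise ValueError("nonmotile_max must be below motile_min")
        X = self._counts(X)
        self.classes_ = np.array(sorted(LABELS))
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _counts(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy().sum(axis=1)
        X = np.asarray(X)
        if X.ndim == 2:
            return X.sum(axis=1)
        return X

    def predict(self, X) -> np.ndarray:
        counts = self._counts(X)
        return np.array([classify_motility(int(c), self.nonmotile_max,
                                           self.motile_min) for c in counts])

    def calls(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Full calls table: genome_id, N_FP, label."""
        counts = matrix.to_numpy().sum(axis=1)
        labels = [classify_motility(int(c), self.nonmotile_max, self.motile_min)
                  for c in counts]
        return pd.DataFrame({"genome_id": matrix.index, "N_FP": counts,
                             "label": labels}).reset_index(drop=True)


def find_histogram_valley(n_fp_values, max_count: int = 54,
                          sigma: float = 2.0) -> int:
    """Optional helper: the minimum of a smoothed N_FP histogram between the
    two largest modes. Never overrides configured thresholds implicitly."""
    counts = np.bincount(np.asarray(n_fp_values, dtype=int),
                         minlength=max_count + 1)
    smooth = gaussian_filter1d(counts.astype(float), sigma=sigma)
    lo_mode = int(np.argmax(smooth[: max_count // 2]))
    hi_mode = int(np.argmax(smooth[max_count // 2:])) + max_count // 2
    return lo_mode + int(np.argmin(smooth[lo_mode:hi_mode + 1]))


@dataclass
class ValidationReport:
    """Confusion counts and rates for calls vs observed phenotypes.

    "Motile" is the positive class; partial calls and taxa without a
    phenotype are excluded from the confusion matrix but counted. Because the
    orientation of a mismatch count can be read either way, the report also
    carries the reversed-orientation rates.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    excluded_partial: int
    excluded_unmatched: int

    @property
    def n_decided(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        return round(100.0 * (self.TP + self.TN) / self.n_decided, 1)

    @property
    def sensitivity(self) -> float:
        return round(100.0 * self.TP / (self.TP + self.FN), 1)

    @property
    def specificity(self) -> float:
        return round(100.0 * self.TN / (self.TN + self.FP), 1)

    @property
    def sensitivity_reversed(self) -> float:
        """Sensitivity with non-motile treated as the positive class."""
        return round(100.0 * self.TN / (self.TN + self.FP), 1)

    @property
    def specificity_reversed(self) -> float:
        return round(100.0 * self.TP / (self.TP + self.FN), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "excluded_partial": self.excluded_partial,
            "excluded_unmatched": self.excluded_unmatched,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }])


def validate_predictions(calls: pd.DataFrame,
                         phenotypes: pd.DataFrame) -> ValidationReport:
    """Confront motility calls with observed phenotypes.

    ``calls`` needs genome_id + label; ``phenotypes`` needs taxon + phenotype
    in {motile, non-motile}. Taxa are matched by exact id.
    """
    merged = calls.merge(phenotypes, left_on="genome_id", right_on="taxon",
                         how="inner")
    excluded_unmatched = len(phenotypes) - len(merged)
    partial = merged["label"] == "partial"
    excluded_partial = int(partial.sum())
    decided = merged.loc[~partial]
    if len(decided) == 0:
        raise ValueError("no overlapping taxa with decided calls")
    pred_motile = decided["label"] == "motile"
    obs_motile = decided["phenotype"] == "motile"
    return ValidationReport(
        TP=int((pred_motile & obs_motile).sum()),
        TN=int((~pred_motile & ~obs_motile).sum()),
        FP=int((pred_motile & ~obs_motile).sum()),
        FN=int((~pred_motile & obs_motile).sum()),
        excluded_partial=excluded_partial,
        excluded_unmatched=excluded_unmatched,
    )


def normalize_class_abundance(matrix: pd.DataFrame, grouping,
                              class_map: dict[str, str]) -> pd.DataFrame:
    """Doubly-normalized functional-class abundance per group.

    value(group, class) = total presences / (members(group) x proteins(class)),
    i.e. normalized by both the number of genomes in the group and the number
    of proteins in the class, hence always in [0, 1]. ``grouping`` maps
    genome_id -> group (a dict or Series); long-format output.
    """
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series)
                         else grouping)
    unmapped = set(matrix.columns) - set(class_map)
    if unmapped:
        raise KeyError(f"proteins without a class: {sorted(unmapped)}")
    missing_group = set(matrix.index) - set(grouping.index)
    if missing_group:
        raise KeyError(f"genomes without a group: {sorted(missing_group)[:10]}")
    class_sizes = pd.Series(class_map).value_counts()
    rows = []
    for group, members in matrix.groupby(grouping.reindex(matrix.index)):
        if len(members) == 0:
            raise ValueError(f"empty group {group!r}")
        class_totals = members.T.groupby(pd.Series(class_map)).sum().sum(axis=1)
        for cls, total in class_totals.items():
            value = total / (len(members) * class_sizes[cls])
            rows.append((group, cls, float(value)))
    return pd.DataFrame(rows, columns=["group", "functional_class", "value"])


def aggregate_strains_to_species(matrix: pd.DataFrame,
                                 species_map) -> pd.DataFrame:
    """Species-level presence = mean over that species' strains (in [0, 1])."""
    species_map = pd.Series(dict(species_map) if not isinstance(species_map, pd.Series)
                            else species_map)
    return matrix.groupby(species_map.reindex(matrix.index)).mean()


def summarize_group_composition(matrix: pd.DataFrame, calls: pd.DataFrame,
                                class_map: dict[str, str]) -> pd.DataFrame:
    """Per functional class: the share of presences in motile vs non-motile
    genomes (partial calls excluded), as percentages summing to 100.

    Classes with no presences in either group get NaN shares.
    """
    labels = calls.set_index("genome_id")["label"].reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("calls missing for some genomes")
    class_series = pd.Series(class_map).reindex(matrix.columns)
    rows = []
    for cls in class_series.dropna().unique():
        cols = class_series.index[class_series == cls]
        motile_total = int(matrix.loc[labels == "motile", cols].to_numpy().sum())
        nonmotile_total = int(matrix.loc[labels == "non-motile", cols].to_numpy().sum())
        total = motile_total + nonmotile_total
        if total == 0:
            rows.append((cls, np.nan, np.nan, 0))
        else:
            rows.append((cls, 100.0 * motile_total / total,
                         100.0 * nonmotile_total / total, total))
    return pd.DataFrame(rows, columns=["functional_class", "motile_pct",
                                       "nonmotile_pct", "n_presences"])
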