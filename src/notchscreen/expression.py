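"""One-colour microarray screening: percentile normalization and signed fold change.

The screen is fold-change based: arrays are scaled so every chip has the same
reference percentile (the per-chip 50th-percentile method), per-gene ratios of
condition means are folded into signed fold changes (GeneSpring convention:
ratio r reported as r if r >= 1 else -1/r) and genes are partitioned by an
inclusive absolute-fold-change cutoff, 1.3 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TREATED = "treated"

DEFAULT_CUTOFF = 1.3


@dataclass
class ExpressionMatrix:
    """Gene-by-sample intensity matrix with condition labels.

    Parameters
    ----------
    intensities
        Non-negative fluorescence intensities, genes as rows (unique index),
        samples as columns.
    conditions
        Mapping of sample id to ``"control"`` or ``"treated"``, covering every
        column.
    """

    intensities: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        self.intensities = pd.DataFrame(self.intensities).astype(float)
        self.conditions = pd.Series(self.conditions, dtype=object)
        if self.intensities.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        missing = set(self.intensities.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        bad = set(self.conditions) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for cond in (CONTROL, TREATED):
            if not self.samples(cond):
                raise ValueError(f"at least one {cond} sample is required")

    def samples(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label, in column order."""
        labelled = {s for s, c in self.conditions.items() if c == condition}
        return [s for s in self.intensities.columns if s in labelled]

    @property
    def genes(self) -> pd.Index:
        return self.intensities.index


@dataclass
class FoldChangeResult:
    """Signed fold changes plus per-gene diagnostics for rejected genes."""

    fc_signed: pd.Series
    rejected: dict[str, str] = field(default_factory=dict)


def normalize_percentile(matrix: ExpressionMatrix, percentile: float = 50.0) -> ExpressionMatrix:
    """Scale each array so its `percentile`-th intensity equals 1.

    With the default percentile of 50 this is per-chip median normalization:
    every chip is divided by its own median, removing global scale (labelling,
    scanning) differences between arrays.

    Raises
    ------
    ValueError
        If the percentile is outside (0, 100] or any array's reference
        percentile is not positive (e.g. an all-zero array).
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    scales = np.percentile(matrix.intensities.to_numpy(), percentile, axis=0)
    for sample, scale in zip(matrix.intensities.columns, scales):
        if scale <= 0:
            raise ValueError(
                f"array {sample!r} has non-positive {percentile}th percentile; cannot normalize"
            )
    return ExpressionMatrix(matrix.intensities / scales, matrix.conditions)


def fold_change(matrix: ExpressionMatrix) -> FoldChangeResult:
    """Per-gene signed fold change between treated and control means.

    The ratio r = mean(treated)/mean(control) of (normalized) linear
    intensities is folded into the signed convention r if r >= 1 else -1/r,
    so magnitudes are always >= 1 and the sign is the direction.

    Genes whose control mean is zero cannot be given a ratio; they are
    excluded from ``fc_signed`` and reported in ``rejected`` with a
    diagnostic, never silently dropped.
    """
    ctrl = matrix.intensities[matrix.samples(CONTROL)].mean(axis=1)
    trt = matrix.intensities[matrix.samples(TREATED)].mean(axis=1)
    rejected = {g: "zero control mean" for g in ctrl.index[ctrl == 0]}
    keep = ctrl > 0
    r = trt[keep] / ctrl[keep]
    fc = pd.Series(np.where(r >= 1, r, -1.0 / np.where(r > 0, r, np.nan)), index=r.index)
    # a zero treated mean gives ratio 0: direction is down, magnitude unbounded
    fc[r == 0] = -np.inf
    return FoldChangeResult(fc_signed=fc, rejected=rejected)


def classify(fc_signed: pd.Series, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Attach direction and cutoff flags to signed fold changes.

    direction is ``up`` iff fc >= cutoff, ``down`` iff fc <= -cutoff
    (inclusive comparison), else ``unchanged``.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    direction = np.where(
        fc_signed >= cutoff, "up", np.where(fc_signed <= -cutoff, "down", "unchanged")
    )
    return pd.DataFrame(
        {
            "gene": fc_signed.index,
            "fc_signed": fc_signed.to_numpy(),
            "direction": direction,
            "passes_cutoff": direction != "unchanged",
        }
    ).reset_index(drop=True)


def partition_by_cutoff(
    results: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (up, down, unchanged), each sorted deterministically.

    Ordering within each partition is by |fc| descending with ties broken by
    gene identifier. `results` needs ``gene`` and ``fc_signed`` columns; the
    direction is (re)derived at the given cutoff so the three partitions are
    disjoint and cover the input.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    table = classify(results.set_index("gene")["fc_signed"], cutoff)
    table = table.assign(_abs=table["fc_signed"].abs())
    table = table.sort_values(["_abs", "gene"], ascending=[False, True]).drop(columns="_abs")
    parts = tuple(
        table[table["direction"] == d].reset_index(drop=True)
        for d in ("up", "down", "unchanged")
    )
    return parts  # type: ignore[return-value]


def collapse_probes(probe_intensities: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level rows to gene level by the per-gene median.

    Needed only for real array data where several probes map to one gene
    symbol; probes without a gene assignment are dropped.
    """
    mapped = probe_intensities.join(probe_to_gene.rename("gene"), how="inner")
    return mapped.groupby("gene").median()
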