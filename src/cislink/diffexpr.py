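"""Expression matrices, TPM conversion, and differential-expression calls.

Differential expression is a threshold classification over a per-feature
statistics table (log2 fold change and FDR): a feature is ``up`` when
FDR < alpha (strict) and log2FC >= tau, ``down`` when FDR < alpha and
log2FC <= -tau, and ``not_de`` otherwise; defaults alpha = 0.05,
tau = 1.  The statistics table normally comes from an external DE tool;
``naive_de_test`` provides a deliberately simple built-in alternative
(Welch t-test on log2(TPM+1) with Benjamini-Hochberg correction) so that
fully synthetic runs need no external input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONDITIONS = ("case", "control")
DE_STATUSES = ("up", "down", "not_de")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with a two-group design.

    ``values`` is a DataFrame indexed by feature_id with sample columns;
    ``condition`` maps each sample to ``case`` or ``control``; ``unit`` is
    ``TPM`` or ``counts``.
    """

    values: pd.DataFrame
    condition: Mapping[str, str]
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "counts"):
            raise ValueError(f"unit must be TPM or counts, got {self.unit!r}")
        missing = set(self.values.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        bad = {s: c for s, c in self.condition.items() if c not in CONDITIONS}
        if bad:
            raise ValueError(f"conditions must be case/control, got {bad}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate feature ids: {dups}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], dict(self.condition), self.unit
        )


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression call."""

    feature_id: str
    log2fc: float
    fdr: float
    de_status: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.feature_id!r}: fdr {self.fdr} outside [0, 1]")
        if self.de_status not in DE_STATUSES:
            raise ValueError(f"{self.feature_id!r}: bad de_status {self.de_status!r}")


def counts_to_tpm(
    matrix: ExpressionMatrix, lengths: Mapping[str, int]
) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-feature transcript lengths (nt).

    TPM_i = 1e6 * (count_i / length_kb_i) / sum_j(count_j / length_kb_j),
    so every sample column with any signal sums to one million.  An
    all-zero sample column stays all-zero (with a warning).
    """
    if matrix.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {matrix.unit!r}")
    missing = set(matrix.feature_ids) - set(lengths)
    if missing:
        raise KeyError(f"no length for features: {sorted(missing)[:5]}")
    len_kb = np.array([lengths[f] for f in matrix.feature_ids], dtype=float) / 1e3
    if (len_kb <= 0).any():
        raise ValueError("all feature lengths must be >= 1 nt")
    rate = matrix.values.to_numpy(dtype=float) / len_kb[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample columns left as zero TPM: %s",
            [s for s, z in zip(matrix.sample_ids, zero_cols) if z],
        )
        colsum = np.where(zero_cols, 1.0, colsum)
    tpm = 1e6 * rate / colsum
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=matrix.values.index, columns=matrix.values.columns),
        dict(matrix.condition),
        unit="TPM",
    )


def classify_de(
    stats_table: Iterable[tuple[str, float, float]] | pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> list[DERecord]:
    """Assign up/down/not_de from (feature_id, log2fc, fdr) rows.

    ``FDR < alpha`` is strict; ``|log2FC| >= min_abs_log2fc`` is inclusive.
    Every feature receives exactly one status.
    """
    if isinstance(stats_table, pd.DataFrame):
        rows = list(
            stats_table[["feature_id", "log2fc", "fdr"]].itertuples(index=False, name=None)
        )
    else:
        rows = list(stats_table)
    seen: set[str] = set()
    records = []
    for feature_id, log2fc, fdr in rows:
        if feature_id in seen:
            raise ValueError(f"duplicated feature_id in stats table: {feature_id!r}")
        seen.add(feature_id)
        if fdr < alpha and log2fc >= min_abs_log2fc:
            status = "up"
        elif fdr < alpha and log2fc <= -min_abs_log2fc:
            status = "down"
        else:
            status = "not_de"
        records.append(DERecord(feature_id, float(log2fc), float(fdr), status))
    n_up = sum(r.de_status == "up" for r in records)
    n_down = sum(r.de_status == "down" for r in records)
    logger.info(
        "DE classification: %d up, %d down, %d not DE",
        n_up, n_down, len(records) - n_up - n_down,
    )
    return records


def naive_de_test(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Simple two-group DE statistics on a TPM matrix.

    log2FC = log2((mean_case + c) / (mean_control + c)) with pseudo-count
    c = 1; p-values from a two-sided Welch t-test on log2(TPM + 1); FDR by
    Benjamini-Hochberg over all features.  A feature with zero variance in
    both groups and equal means gets p = 1.  This is a stand-in for a full
    count-model DE analysis, intended for synthetic end-to-end runs.
    """
    if matrix.unit != "TPM":
        raise ValueError("naive_de_test expects a TPM matrix")
    case = matrix.samples_of("case")
    control = matrix.samples_of("control")
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 samples per condition")
    x = matrix.values[case].to_numpy(dtype=float)
    y = matrix.values[control].to_numpy(dtype=float)
    log2fc = np.log2((x.mean(axis=1) + pseudocount) / (y.mean(axis=1) + pseudocount))
    lx, ly = np.log2(x + 1.0), np.log2(y + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(lx, ly, axis=1, equal_var=False)
    # degenerate features (no variance, equal means) yield nan -> null p
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
        }
    )


def read_stats_table(path: str | Path) -> pd.DataFrame:
    """Read an external DE statistics TSV (feature_id, log2fc, fdr)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"feature_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"stats table {path} lacks columns {sorted(missing)}")
    return df


def read_expression_table(
    path: str | Path, condition: Mapping[str, str], unit: str = "TPM"
) -> ExpressionMatrix:
    """Read an expression TSV (first column feature_id, then samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, dict(condition), unit=unit)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
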