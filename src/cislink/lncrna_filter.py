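"""lncRNA candidate selection.

Two filters are applied, in order: a strict length criterion (transcripts
must exceed 200 nt) and a consensus coding-potential vote over the four
predictors CPC2, CNCI, Pfam and FEElnc, retaining transcripts called
non-coding by at least ``min_votes`` (default 3) of them.  A ``missing``
verdict never counts toward the non-coding tally: unassessed transcripts
are not promoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from cislink.annotation_io import FeatureSet

PREDICTORS = ("CPC2", "CNCI", "Pfam", "FEElnc")
VERDICTS = {"noncoding", "coding", "missing"}

#: cell spellings accepted in verdict tables
_VERDICT_ALIASES = {
    "nc": "noncoding",
    "noncoding": "noncoding",
    "non-coding": "noncoding",
    "c": "coding",
    "coding": "coding",
    "na": "missing",
    ".": "missing",
    "": "missing",
    "missing": "missing",
}


@dataclass(frozen=True)
class CodingCallRecord:
    """Per-transcript verdicts from the four coding-potential predictors."""

    feature_id: str
    verdicts: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tool, verdict in self.verdicts.items():
            if tool not in PREDICTORS:
                raise ValueError(
                    f"{self.feature_id!r}: unknown predictor {tool!r} "
                    f"(expected one of {PREDICTORS})"
                )
            if verdict not in VERDICTS:
                raise ValueError(f"{self.feature_id!r}: unknown verdict {verdict!r}")

    @property
    def n_noncoding(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == "noncoding")


def filter_by_length(features: FeatureSet, min_exclusive_nt: int = 200) -> FeatureSet:
    """Retain features with ``length_nt`` strictly greater than the cutoff.

    The boundary is exclusive: a 200 nt transcript is removed, a 201 nt one
    kept.  Input order is preserved.
    """
    return FeatureSet(
        (f for f in features if f.length_nt > min_exclusive_nt),
        genome_name=features.genome_name,
    )


def consensus_noncoding(
    calls: Iterable[CodingCallRecord], min_votes: int = 3
) -> set[str]:
    """Feature ids with at least ``min_votes`` non-coding verdicts."""
    if not 1 <= min_votes <= len(PREDICTORS):
        raise ValueError(f"min_votes must be in [1, {len(PREDICTORS)}], got {min_votes}")
    return {c.feature_id for c in calls if c.n_noncoding >= min_votes}


def select_lncrna_candidates(
    features: FeatureSet,
    calls: Iterable[CodingCallRecord],
    min_exclusive_nt: int = 200,
    min_votes: int = 3,
) -> FeatureSet:
    """Length filter followed by the consensus vote.

    Features absent from the verdict table are dropped (no evidence of
    non-coding status).
    """
    long_enough = filter_by_length(features, min_exclusive_nt)
    voted = consensus_noncoding(calls, min_votes)
    return FeatureSet(
        (f for f in long_enough if f.feature_id in voted),
        genome_name=features.genome_name,
    )


def read_coding_calls(path: str | Path) -> list[CodingCallRecord]:
    """Read a verdict TSV with columns feature_id, CPC2, CNCI, Pfam, FEElnc.

    Cells are NC / C / NA (case-insensitive; ``.`` and blank count as NA).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = {"feature_id", *PREDICTORS} - set(df.columns)
    if missing_cols:
        raise ValueError(f"verdict table {path} lacks columns {sorted(missing_cols)}")
    records = []
    for row in df.itertuples(index=False):
        verdicts = {}
        for tool in PREDICTORS:
            raw = str(getattr(row, tool)).strip().lower()
            if raw not in _VERDICT_ALIASES:
                raise ValueError(
                    f"verdict table {path}: feature {row.feature_id!r}, "
                    f"predictor {tool}: unknown cell value {raw!r}"
                )
            verdicts[tool] = _VERDICT_ALIASES[raw]
        records.append(CodingCallRecord(feature_id=row.feature_id, verdicts=verdicts))
    return records


def write_coding_calls(calls: Iterable[CodingCallRecord], path: str | Path) -> None:
    back = {"noncoding": "NC", "coding": "C", "missing": "NA"}
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(PREDICTORS) + "\n")
        for c in calls:
            cells = [back[c.verdicts.get(t, "missing")] for t in PREDICTORS]
            fh.write(c.feature_id + "\t" + "\t".join(cells) + "\n")
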