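"""Result-surface summaries and planted-truth recovery scoring.

``summarize`` reduces an annotated pair list to the counters a cis-target
analysis reports: window pairs, both-DE pairs, significant pairs, the
positive/negative split, direction-concordance counts among significant
pairs, and the unique-gene rollup of the concordantly upregulated subset
(lncRNAs and mRNAs pooled into one set).  ``score_recovery`` compares the
significant set against the couplings a synthetic dataset planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from cislink.cis_pairing import CisPair


@dataclass(frozen=True)
class PairSummary:
    n_pairs_window: int
    n_pairs_both_de: int
    n_significant: int
    n_positive: int
    n_negative: int
    n_both_up: int
    n_both_down: int
    n_discordant: int
    n_unique_genes_both_up: int
    positive_fraction: float  # nan when no pair is significant

    @property
    def positive_percent(self) -> float:
        """positive_fraction as a rounded whole percentage (97 for 0.974)."""
        if math.isnan(self.positive_fraction):
            return float("nan")
        return round(100.0 * self.positive_fraction)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["positive_fraction"] = (
            None if math.isnan(self.positive_fraction) else round(self.positive_fraction, 3)
        )
        d["positive_percent"] = (
            None if math.isnan(self.positive_fraction) else self.positive_percent
        )
        return d

    def to_text(self) -> str:
        pf = "NA" if math.isnan(self.positive_fraction) else f"{self.positive_fraction:.3f}"
        pp = "NA" if math.isnan(self.positive_fraction) else f"{self.positive_percent:.0f}%"
        return (
            f"window pairs:              {self.n_pairs_window}\n"
            f"pairs with both members DE: {self.n_pairs_both_de}\n"
            f"significant pairs:         {self.n_significant}\n"
            f"  positively correlated:   {self.n_positive} ({pf} = {pp})\n"
            f"  negatively correlated:   {self.n_negative}\n"
            f"  both up:                 {self.n_both_up}\n"
            f"  both down:               {self.n_both_down}\n"
            f"  discordant:              {self.n_discordant}\n"
            f"unique genes in both-up set: {self.n_unique_genes_both_up}\n"
        )


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery of planted couplings by the significance screen."""

    sensitivity: float
    false_discovery_rate: float  # nan when nothing is significant
    n_planted: int
    n_recovered: int
    n_significant: int

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isnan(self.false_discovery_rate):
            d["false_discovery_rate"] = None
        return d


def summarize(pairs: Sequence[CisPair]) -> PairSummary:
    """Compute the full counter set over an annotated pair list.

    Concordance counters (`both_up`, `both_down`, `discordant`) are taken
    over significant pairs whose members are both DE, mirroring the order
    of the analysis (window -> DE restriction -> correlation screen).
    """
    sig = [p for p in pairs if p.significant]
    n_positive = sum(1 for p in sig if p.sign == "positive")
    n_negative = sum(1 for p in sig if p.sign == "negative")
    both_up = [p for p in sig if p.concordance == "both_up"]
    uniq: set[str] = set()
    for p in both_up:
        uniq.add(p.lncrna_id)
        uniq.add(p.mrna_id)
    return PairSummary(
        n_pairs_window=len(pairs),
        n_pairs_both_de=sum(1 for p in pairs if p.concordance != "not_both_de"),
        n_significant=len(sig),
        n_positive=n_positive,
        n_negative=n_negative,
        n_both_up=len(both_up),
        n_both_down=sum(1 for p in sig if p.concordance == "both_down"),
        n_discordant=sum(1 for p in sig if p.concordance == "discordant"),
        n_unique_genes_both_up=len(uniq),
        positive_fraction=(n_positive / len(sig)) if sig else float("nan"),
    )


def score_recovery(pairs: Sequence[CisPair], truth) -> RecoveryReport:
    """Score the significant set against planted couplings.

    sensitivity = recovered planted pairs / planted pairs;
    FDR = significant non-planted pairs / all significant pairs (NA when
    nothing is significant).  ``truth`` is a
    :class:`cislink.synthetic.SyntheticTruth` or anything with a
    ``planted_pairs`` attribute of (lncrna_id, mrna_id, ...) entries.
    """
    planted = {(p[0], p[1]) for p in getattr(truth, "planted_pairs")}
    known_ids = getattr(truth, "feature_ids", None)
    if known_ids:  # only when the truth declares its feature universe
        unknown = {i for pair in planted for i in pair} - set(known_ids)
        if unknown:
            raise KeyError(f"truth references unknown feature ids: {sorted(unknown)[:5]}")
    sig = {p.key for p in pairs if p.significant}
    recovered = planted & sig
    fdr = (len(sig - planted) / len(sig)) if sig else float("nan")
    return RecoveryReport(
        sensitivity=(len(recovered) / len(planted)) if planted else float("nan"),
        false_discovery_rate=fdr,
        n_planted=len(planted),
        n_recovered=len(recovered),
        n_significant=len(sig),
    )


def write_summary(summary: PairSummary, json_path: str | Path, text_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
    if text_path is not None:
        Path(text_path).write_text(summary.to_text())


def write_recovery(report: RecoveryReport, json_path: str | Path) -> None:
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
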