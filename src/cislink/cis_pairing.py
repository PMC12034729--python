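"""Genomic-window enumeration of candidate cis lncRNA-mRNA pairs.

A pair is emitted when both loci sit on the same chromosome and the
closest-edge gap between the two gene-body intervals is at most the
window (default 100 kb), with overlapping intervals at distance 0.
Strand is ignored: the window extends both upstream and downstream, so
orientation cannot change membership.  An optional TSS anchor measures
the distance between transcription start sites instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from cislink.annotation_io import FeatureSet, GenomicFeature
from cislink.diffexpr import DERecord

SIGNS = ("positive", "negative", "undefined")
CONCORDANCES = ("both_up", "both_down", "discordant", "not_both_de")


@dataclass(frozen=True)
class CisPair:
    """One lncRNA-mRNA candidate pair with its screen annotations.

    ``r``/``p_value`` stay ``None`` until the correlation screen runs;
    ``sign`` is the sign of r; ``concordance`` reflects the DE directions
    of the two members.
    """

    lncrna_id: str
    mrna_id: str
    chrom: str
    distance_bp: int
    r: float | None = None
    p_value: float | None = None
    significant: bool = False
    sign: str = "undefined"
    concordance: str = "not_both_de"

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError(f"negative distance for pair {self.key}")
        if self.sign not in SIGNS:
            raise ValueError(f"bad sign {self.sign!r}")
        if self.concordance not in CONCORDANCES:
            raise ValueError(f"bad concordance {self.concordance!r}")
        if self.significant and (self.r is None or self.p_value is None):
            raise ValueError(f"significant pair {self.key} lacks r or p")

    @property
    def key(self) -> tuple[str, str]:
        return (self.lncrna_id, self.mrna_id)


def gap_bp(a: GenomicFeature, b: GenomicFeature) -> int:
    """Closest-edge gap between two closed intervals; 0 when they overlap."""
    return max(0, a.start - b.end, b.start - a.end)


def _tss(f: GenomicFeature) -> int:
    return f.end if f.strand == "-" else f.start


def find_cis_pairs(
    lncrnas: FeatureSet,
    mrnas: FeatureSet,
    window_bp: int = 100_000,
    anchor: str = "gene_body",
) -> list[CisPair]:
    """Enumerate same-chromosome pairs with gap <= ``window_bp``.

    Many-to-many pairs are allowed; output order is deterministic
    (chrom, lncRNA start, mRNA start).  ``anchor="tss"`` measures the
    absolute distance between transcription start sites instead of the
    closest-edge gene-body gap.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if anchor not in ("gene_body", "tss"):
        raise ValueError(f"anchor must be gene_body or tss, got {anchor!r}")

    pairs: list[CisPair] = []
    chroms = sorted(set(lncrnas.chromosomes()) & set(mrnas.chromosomes()))
    for chrom in chroms:
        ms = mrnas.by_chromosome(chrom)
        if not ms:
            continue
        # interval index over mRNA bodies; query expands the lncRNA locus
        # by the window so tree overlap == closest-edge gap <= window
        tree = IntervalTree()
        for i, m in enumerate(ms):
            tree.addi(m.start, m.end + 1, i)
        for l in lncrnas.by_chromosome(chrom):
            if anchor == "gene_body":
                hits = tree.overlap(l.start - window_bp, l.end + window_bp + 1)
                cands = sorted(iv.data for iv in hits)
            else:
                cands = [i for i, m in enumerate(ms) if abs(_tss(l) - _tss(m)) <= window_bp]
            for i in cands:
                m = ms[i]
                d = gap_bp(l, m) if anchor == "gene_body" else abs(_tss(l) - _tss(m))
                if d <= window_bp:
                    pairs.append(
                        CisPair(
                            lncrna_id=l.feature_id,
                            mrna_id=m.feature_id,
                            chrom=chrom,
                            distance_bp=d,
                        )
                    )
    return pairs


def _de_index(de: Iterable[DERecord]) -> Mapping[str, DERecord]:
    return {r.feature_id: r for r in de}


def _concordance(lnc: DERecord, m: DERecord) -> str:
    if lnc.de_status == "not_de" or m.de_status == "not_de":
        return "not_both_de"
    if lnc.de_status == m.de_status:
        return "both_up" if lnc.de_status == "up" else "both_down"
    return "discordant"


def annotate_concordance(
    pairs: Sequence[CisPair], de: Iterable[DERecord]
) -> list[CisPair]:
    """Set each pair's concordance from the members' DE directions.

    Unlike :func:`restrict_to_de` no pair is dropped; pairs whose members
    are not both DE keep ``not_both_de``.
    """
    idx = _de_index(de)
    out = []
    for p in pairs:
        for fid in (p.lncrna_id, p.mrna_id):
            if fid not in idx:
                raise KeyError(f"no DE record for pair member {fid!r}")
        out.append(replace(p, concordance=_concordance(idx[p.lncrna_id], idx[p.mrna_id])))
    return out


def restrict_to_de(pairs: Sequence[CisPair], de: Iterable[DERecord]) -> list[CisPair]:
    """Keep pairs whose lncRNA and mRNA are both differentially expressed."""
    annotated = annotate_concordance(pairs, de)
    return [p for p in annotated if p.concordance != "not_both_de"]
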