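"""Genomic annotation and tabular I/O.

Internal coordinates are 1-based, fully closed (GTF convention).  BED input
(0-based, half-open) is converted on read with ``start + 1`` and converted
back on write, so a BED -> internal -> BED round trip reproduces the
original line.  Pairing downstream operates on gene-level loci: when a GTF
carries only transcript records, multi-transcript genes are collapsed to
the union interval (min start, max end) and the length of the longest
isoform (exon-summed where exons are present).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from gffutils.feature import feature_from_line

VALID_STRANDS = {"+", "-", "."}
VALID_BIOTYPES = {"lncRNA", "mRNA", "candidate", "other"}

#: GTF/Ensembl biotype spellings normalised to the internal vocabulary.
_BIOTYPE_ALIASES = {
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
    "mrna": "mRNA",
    "protein_coding": "mRNA",
    "candidate": "candidate",
}


class AnnotationError(ValueError):
    """Raised on malformed annotation input."""


@dataclass(frozen=True)
class GenomicFeature:
    """A gene-level locus.

    ``start``/``end`` are 1-based inclusive genomic coordinates;
    ``length_nt`` is the transcript length in nucleotides used by the
    lncRNA length filter and TPM normalisation (it may be shorter than the
    genomic span when exon structure is known).
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "other"
    length_nt: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"feature {self.feature_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise AnnotationError(f"feature {self.feature_id!r}: start must be >= 1")
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if self.biotype not in VALID_BIOTYPES:
            raise AnnotationError(f"feature {self.feature_id!r}: bad biotype {self.biotype!r}")
        if self.length_nt is None:
            object.__setattr__(self, "length_nt", self.span_bp)
        elif self.length_nt < 1:
            raise AnnotationError(f"feature {self.feature_id!r}: length_nt must be >= 1")

    @property
    def span_bp(self) -> int:
        """Genomic span in bp (closed-interval width)."""
        return self.end - self.start + 1


class FeatureSet:
    """An ordered collection of :class:`GenomicFeature` with unique ids."""

    def __init__(self, features: Iterable[GenomicFeature] = (), genome_name: str = "custom"):
        self.genome_name = genome_name
        self._features: dict[str, GenomicFeature] = {}
        for f in features:
            self.add(f)

    def add(self, feature: GenomicFeature) -> None:
        if feature.feature_id in self._features:
            raise AnnotationError(f"duplicate feature_id {feature.feature_id!r}")
        self._features[feature.feature_id] = feature

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __getitem__(self, feature_id: str) -> GenomicFeature:
        return self._features[feature_id]

    def ids(self) -> list[str]:
        return list(self._features)

    def chromosomes(self) -> list[str]:
        return sorted({f.chrom for f in self})

    def by_chromosome(self, chrom: str) -> list[GenomicFeature]:
        """Features on ``chrom`` in coordinate-sorted order."""
        feats = [f for f in self if f.chrom == chrom]
        feats.sort(key=lambda f: (f.start, f.end, f.feature_id))
        return feats

    def subset(self, feature_ids: Iterable[str]) -> "FeatureSet":
        wanted = set(feature_ids)
        missing = wanted - set(self._features)
        if missing:
            raise KeyError(f"unknown feature ids: {sorted(missing)[:5]}")
        return FeatureSet(
            (f for f in self if f.feature_id in wanted), genome_name=self.genome_name
        )

    def with_biotype(self, biotype: str) -> "FeatureSet":
        return FeatureSet(
            (f for f in self if f.biotype == biotype), genome_name=self.genome_name
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.feature_id, f.chrom, f.start, f.end, f.strand, f.biotype, f.length_nt)
                for f in self
            ],
            columns=["feature_id", "chrom", "start", "end", "strand", "biotype", "length_nt"],
        )


def _normalise_biotype(raw: str | None) -> str:
    if raw is None:
        return "other"
    return _BIOTYPE_ALIASES.get(raw.strip().lower(), "other" if raw not in VALID_BIOTYPES else raw)


def _read_biotype_table(path: str | Path) -> dict[str, str]:
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "biotype"} <= set(tbl.columns):
        raise AnnotationError(f"biotype table {path} needs columns feature_id, biotype")
    return {row.feature_id: _normalise_biotype(row.biotype) for row in tbl.itertuples()}


def read_annotation(
    path: str | Path,
    format: str = "GTF",
    biotype_table: str | Path | None = None,
    genome_name: str | None = None,
) -> FeatureSet:
    """Read a GTF or BED6 annotation into gene-level loci.

    Biotype precedence: explicit sidecar ``biotype_table`` (TSV with
    feature_id, biotype) > GTF ``gene_biotype``/``transcript_biotype``
    attribute > ``"other"``.  Malformed lines raise
    :class:`AnnotationError` naming the line number.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "GTF":
        feats = _read_gtf(path)
    elif fmt == "BED":
        feats = _read_bed(path)
    else:
        raise AnnotationError(f"unknown annotation format {format!r} (use GTF or BED)")

    sidecar = _read_biotype_table(biotype_table) if biotype_table is not None else {}
    if sidecar:
        feats = [
            replace(f, biotype=sidecar[f.feature_id]) if f.feature_id in sidecar else f
            for f in feats
        ]
    return FeatureSet(feats, genome_name=genome_name or path.stem)


def _read_bed(path: Path) -> list[GenomicFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise AnnotationError(f"{path}:{lineno}: BED line has fewer than 4 columns")
            try:
                chrom, start0, end0, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = cols[5] if len(cols) >= 6 else "."
            try:
                # BED is 0-based half-open; internal is 1-based closed.
                feats.append(
                    GenomicFeature(
                        feature_id=name, chrom=chrom, start=start0 + 1, end=end0, strand=strand
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return feats


def write_bed(features: FeatureSet | Iterable[GenomicFeature], path: str | Path) -> None:
    """Write BED6 (0-based half-open), inverting the read-time conversion."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")


def _read_gtf(path: Path) -> list[GenomicFeature]:
    genes: dict[str, dict] = {}  # insertion-ordered: first appearance wins
    tx_exon_len: dict[str, int] = {}
    tx_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                rec = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if rec.featuretype not in ("gene", "transcript", "exon"):
                continue
            attrs = rec.attributes
            gene_id = (attrs.get("gene_id") or [None])[0]
            if gene_id is None:
                raise AnnotationError(f"{path}:{lineno}: record lacks gene_id attribute")
            if rec.end < rec.start:
                raise AnnotationError(
                    f"{path}:{lineno}: end ({rec.end}) < start ({rec.start}) for {gene_id!r}"
                )
            biotype_raw = (
                attrs.get("gene_biotype") or attrs.get("transcript_biotype") or [None]
            )[0]

            if rec.featuretype == "exon":
                tx_id = (attrs.get("transcript_id") or [None])[0]
                if tx_id is not None:
                    tx_exon_len[tx_id] = tx_exon_len.get(tx_id, 0) + (rec.end - rec.start + 1)
                    tx_gene.setdefault(tx_id, gene_id)
                continue

            if rec.featuretype == "transcript":
                tx_id = (attrs.get("transcript_id") or [None])[0]
                if tx_id is not None:
                    tx_gene.setdefault(tx_id, gene_id)

            entry = genes.get(gene_id)
            if entry is None:
                genes[gene_id] = {
                    "chrom": rec.seqid,
                    "start": rec.start,
                    "end": rec.end,
                    "strand": rec.strand if rec.strand in VALID_STRANDS else ".",
                    "biotype": _normalise_biotype(biotype_raw),
                    "from_gene_record": rec.featuretype == "gene",
                    "lineno": lineno,
                }
            else:
                if rec.featuretype == "gene" and entry["from_gene_record"]:
                    raise AnnotationError(
                        f"{path}:{lineno}: duplicate gene record for id {gene_id!r}"
                    )
                if rec.seqid != entry["chrom"]:
                    raise AnnotationError(
                        f"{path}:{lineno}: gene {gene_id!r} spans chromosomes"
                    )
                # union interval across records of the same gene
                entry["start"] = min(entry["start"], rec.start)
                entry["end"] = max(entry["end"], rec.end)
                if entry["biotype"] == "other":
                    entry["biotype"] = _normalise_biotype(biotype_raw)
                entry["from_gene_record"] |= rec.featuretype == "gene"

    # longest exon-summed isoform per gene, where exon structure exists
    gene_tx_len: dict[str, int] = {}
    for tx_id, exlen in tx_exon_len.items():
        gid = tx_gene.get(tx_id)
        if gid is not None:
            gene_tx_len[gid] = max(gene_tx_len.get(gid, 0), exlen)

    feats = []
    for gene_id, e in genes.items():
        feats.append(
            GenomicFeature(
                feature_id=gene_id,
                chrom=e["chrom"],
                start=e["start"],
                end=e["end"],
                strand=e["strand"],
                biotype=e["biotype"],
                length_nt=gene_tx_len.get(gene_id),
            )
        )
    return feats


def write_gtf(features: FeatureSet | Iterable[GenomicFeature], path: str | Path) -> None:
    """Write gene-level records as GTF 2.2."""
    biotype_out = {"lncRNA": "lncRNA", "mRNA": "protein_coding", "candidate": "candidate"}
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for f in features:
            bt = biotype_out.get(f.biotype, "other")
            attrs = f'gene_id "{f.feature_id}"; gene_biotype "{bt}"; length_nt "{f.length_nt}";'
            fh.write(
                f"{f.chrom}\tcislink\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


_PAIR_COLUMNS = [
    "lncrna_id",
    "mrna_id",
    "chrom",
    "distance_bp",
    "r",
    "p_value",
    "significant",
    "sign",
    "concordance",
]


def write_pairs_table(pairs, path: str | Path) -> None:
    """Write cis pairs as a TSV (``.`` for undefined r/p), round-trippable."""

    def cell(v) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "."
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    cell(getattr(p, c)) for c in _PAIR_COLUMNS
                )
                + "\n"
            )


def read_pairs_table(path: str | Path):
    """Read a pairs TSV written by :func:`write_pairs_table`."""
    from cislink.cis_pairing import CisPair  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"pairs table {path} lacks columns {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            CisPair(
                lncrna_id=row.lncrna_id,
                mrna_id=row.mrna_id,
                chrom=row.chrom,
                distance_bp=int(row.distance_bp),
                r=None if row.r == "." else float(row.r),
                p_value=None if row.p_value == "." else float(row.p_value),
                significant=row.significant == "true",
                sign=row.sign,
                concordance=row.concordance,
            )
        )
    return pairs
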