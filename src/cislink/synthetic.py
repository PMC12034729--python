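"""Synthetic two-condition RNA-seq data with planted cis couplings.

The generator emulates the statistical structure the cis-target screen
assumes: a genome where designated lncRNA-mRNA pairs lie within the
pairing window (closest-edge gap drawn uniformly in [0, window]) while all
other inter-gene gaps exceed the window; negative-binomial counts with a
per-feature baseline and a case/control log2 fold-change for planted DE
features; and a Gaussian copula that couples the two members of a planted
pair at latent correlation rho (the NB marginals attenuate the observable
Pearson r slightly below rho).  Three pair classes are planted:

* ``planted_pairs`` — in-window, expression-coupled at rho, and DE in the
  case group (both up, or both down for a minority), i.e. true cis links;
* ``null_pairs`` — in-window geometry but independent, non-DE expression:
  decoys that the correlation screen should reject;
* ``far_pairs`` — expression-coupled but separated by more than twice the
  window: trans-like controls that the geometric filter should exclude.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import ndtr

from cislink.annotation_io import FeatureSet, GenomicFeature, write_gtf
from cislink.diffexpr import ExpressionMatrix, write_expression_table
from cislink.lncrna_filter import PREDICTORS, CodingCallRecord, write_coding_calls


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small two-condition exosome-style experiment:
    5 vs 5 samples, two 50 Mb chromosomes, 200 lncRNAs and 600 mRNAs of
    which 100 lncRNA-mRNA pairs are coupled cis links (latent rho = 0.9,
    both members DE at |log2FC| = 2) and 100 are in-window decoys.
    ``baseline_mean_log2_range`` bounds the per-feature baseline mean
    count on the log2 scale (3..9, i.e. 8..512 counts).
    """

    n_case: int = 5
    n_control: int = 5
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_lncrna: int = 200
    n_mrna: int = 600
    n_planted_pairs: int = 100
    n_null_pairs: int = 100
    n_far_pairs: int = 0
    window_bp: int = 100_000
    rho: float = 0.9
    de_log2fc: float = 2.0
    frac_pairs_up: float = 0.9
    frac_extra_de: float = 0.3
    nb_dispersion: float = 0.1
    baseline_mean_log2_range: tuple[float, float] = (3.0, 9.0)
    lncrna_length_range: tuple[int, int] = (300, 3_000)
    mrna_length_range: tuple[int, int] = (1_000, 5_000)
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per condition")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        n_paired = self.n_planted_pairs + self.n_null_pairs + self.n_far_pairs
        if n_paired > self.n_lncrna:
            raise ValueError(
                f"{n_paired} designated pairs need {n_paired} lncRNAs, have {self.n_lncrna}"
            )
        if n_paired > self.n_mrna:
            raise ValueError(
                f"{n_paired} designated pairs need {n_paired} mRNAs, have {self.n_mrna}"
            )
        if not 0.0 <= self.frac_pairs_up <= 1.0:
            raise ValueError("frac_pairs_up must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``planted_pairs`` entries are (lncrna_id, mrna_id, rho_target,
    both_up); ``planted_de`` maps feature ids to their true log2 fold
    change (case over control).
    """

    planted_pairs: list[tuple[str, str, float, bool]] = field(default_factory=list)
    null_pairs: list[tuple[str, str]] = field(default_factory=list)
    far_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_de: dict[str, float] = field(default_factory=dict)
    layout: dict[str, GenomicFeature] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.layout)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "null_pairs": [list(p) for p in self.null_pairs],
            "far_pairs": [list(p) for p in self.far_pairs],
            "planted_de": self.planted_de,
            "layout": {
                fid: [f.chrom, f.start, f.end, f.strand, f.biotype, f.length_nt]
                for fid, f in self.layout.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_pairs=[
                (a, b, float(r), bool(u)) for a, b, r, u in payload["planted_pairs"]
            ],
            null_pairs=[tuple(p) for p in payload["null_pairs"]],
            far_pairs=[(a, b, float(r)) for a, b, r in payload["far_pairs"]],
            planted_de={k: float(v) for k, v in payload["planted_de"].items()},
            layout={
                fid: GenomicFeature(fid, c, s, e, st, bt, ln)
                for fid, (c, s, e, st, bt, ln) in payload["layout"].items()
            },
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_layout(cfg: SimConfig) -> tuple[FeatureSet, SyntheticTruth]:
    """Place gene intervals and decide the planted truth.

    Features are packed into atomic blocks — a designated pair with its
    internal gap, or a single gene — separated by more than one window, so
    no unintended in-window pair can arise; far-pair blocks carry an
    internal gap above 2x the window.  Raises when the chromosomes cannot
    hold the requested features (use longer chromosomes).
    """
    rng = _rng(cfg.seed, 0)
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(cfg.n_mrna)]

    def lnc_len() -> int:
        return int(rng.integers(cfg.lncrna_length_range[0], cfg.lncrna_length_range[1] + 1))

    def mrna_len() -> int:
        return int(rng.integers(cfg.mrna_length_range[0], cfg.mrna_length_range[1] + 1))

    truth = SyntheticTruth()
    # blocks: ("pair", lnc_id, lnc_len, gap, m_id, m_len) or ("single", id, len, biotype)
    blocks: list[tuple] = []
    li = mi = 0
    for _ in range(cfg.n_planted_pairs):
        gap = int(rng.integers(0, cfg.window_bp + 1))
        both_up = bool(rng.random() < cfg.frac_pairs_up)
        truth.planted_pairs.append((lnc_ids[li], mrna_ids[mi], cfg.rho, both_up))
        fc = cfg.de_log2fc if both_up else -cfg.de_log2fc
        truth.planted_de[lnc_ids[li]] = fc
        truth.planted_de[mrna_ids[mi]] = fc
        blocks.append(("pair", lnc_ids[li], lnc_len(), gap, mrna_ids[mi], mrna_len()))
        li += 1
        mi += 1
    for _ in range(cfg.n_null_pairs):
        gap = int(rng.integers(0, cfg.window_bp + 1))
        truth.null_pairs.append((lnc_ids[li], mrna_ids[mi]))
        blocks.append(("pair", lnc_ids[li], lnc_len(), gap, mrna_ids[mi], mrna_len()))
        li += 1
        mi += 1
    for _ in range(cfg.n_far_pairs):
        gap = int(rng.integers(2 * cfg.window_bp + 1, 3 * cfg.window_bp + 1))
        truth.far_pairs.append((lnc_ids[li], mrna_ids[mi], cfg.rho))
        blocks.append(("pair", lnc_ids[li], lnc_len(), gap, mrna_ids[mi], mrna_len()))
        li += 1
        mi += 1
    singles: list[tuple] = []
    for fid in lnc_ids[li:]:
        singles.append(("single", fid, lnc_len(), "lncRNA"))
    for fid in mrna_ids[mi:]:
        singles.append(("single", fid, mrna_len(), "mRNA"))
    # extra DE among unpaired features, random direction
    for blk in singles:
        if rng.random() < cfg.frac_extra_de:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.planted_de[blk[1]] = sign * cfg.de_log2fc
    blocks.extend(singles)
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    features: list[GenomicFeature] = []
    chrom_idx = 0
    cursor = 1 + int(rng.integers(0, 10_000))

    def place(fid: str, length: int, biotype: str, start: int) -> GenomicFeature:
        f = GenomicFeature(
            feature_id=fid,
            chrom=f"chr{chrom_idx + 1}",
            start=start,
            end=start + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
            biotype=biotype,
            length_nt=length,
        )
        features.append(f)
        truth.layout[fid] = f
        return f

    for blk in blocks:
        span = blk[2] + blk[3] + blk[5] if blk[0] == "pair" else blk[2]
        while cursor + span - 1 > cfg.chrom_length_bp:
            chrom_idx += 1
            if chrom_idx >= cfg.n_chromosomes:
                raise ValueError(
                    "cannot pack the requested features onto the configured "
                    "chromosomes; increase chrom_length_bp or n_chromosomes"
                )
            cursor = 1 + int(rng.integers(0, 10_000))
        if blk[0] == "pair":
            _, lid, llen, gap, mid, mlen = blk
            l = place(lid, llen, "lncRNA", cursor)
            # closest-edge gap of closed intervals is mRNA.start - lncRNA.end
            # (0 when they overlap), so this start yields exactly `gap`
            place(mid, mlen, "mRNA", l.end + gap if gap > 0 else l.end)
        else:
            _, fid, length, biotype = blk
            place(fid, length, biotype, cursor)
        # inter-block margin strictly above one window
        cursor += span + cfg.window_bp + 1 + int(rng.integers(0, 20_000))

    return FeatureSet(features, genome_name="synthetic"), truth


def simulate_expression(
    features: FeatureSet, truth: SyntheticTruth, cfg: SimConfig
) -> ExpressionMatrix:
    """Draw negative-binomial counts with Gaussian-copula couplings.

    Per feature, a baseline mean is drawn log2-uniformly; planted DE
    features have their case-group mean multiplied by 2**log2fc.  Counts
    come from inverting the NB CDF at correlated Gaussian quantiles, so a
    coupled pair shares latent correlation rho while keeping exact NB
    marginals.
    """
    if not -1.0 < cfg.rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {cfg.rho}")
    rng = _rng(cfg.seed, 1)
    fids = [f.feature_id for f in features]
    pos = {fid: i for i, fid in enumerate(fids)}
    n_feat = len(fids)
    samples = [f"case_{i + 1}" for i in range(cfg.n_case)] + [
        f"control_{i + 1}" for i in range(cfg.n_control)
    ]
    condition = {s: ("case" if s.startswith("case") else "control") for s in samples}
    n_samp = len(samples)

    lo, hi = cfg.baseline_mean_log2_range
    base_mu = 2.0 ** rng.uniform(lo, hi, size=n_feat)
    mu = np.tile(base_mu[:, None], (1, n_samp))
    case_cols = np.arange(cfg.n_case)
    for fid, log2fc in truth.planted_de.items():
        if fid in pos:
            mu[pos[fid], case_cols] *= 2.0**log2fc

    z = rng.standard_normal((n_feat, n_samp))
    couplings = [(a, b, r) for a, b, r, _ in truth.planted_pairs]
    couplings += list(truth.far_pairs)
    for lnc_id, m_id, rho in couplings:
        if lnc_id in pos and m_id in pos:
            i, j = pos[lnc_id], pos[m_id]
            z[j] = rho * z[i] + np.sqrt(1.0 - rho * rho) * z[j]

    u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    size = 1.0 / cfg.nb_dispersion
    p_nb = size / (size + mu)
    counts = stats.nbinom.ppf(u, size, p_nb).astype(np.int64)

    return ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(fids, name="feature_id"), columns=samples),
        condition,
        unit="counts",
    )


def simulate_coding_calls(
    features: FeatureSet,
    truth: SyntheticTruth,
    flip_prob: float = 0.0,
    seed: int | None = None,
) -> list[CodingCallRecord]:
    """Emulate the 4-predictor verdict table.

    Each tool votes independently: a true lncRNA is called non-coding with
    probability 1 - flip_prob, a true mRNA the mirror image.
    """
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    rng = _rng(seed if seed is not None else 0, 2)
    records = []
    for f in features:
        is_lnc = f.biotype in ("lncRNA", "candidate")
        verdicts = {}
        for tool in PREDICTORS:
            truthful = rng.random() >= flip_prob
            noncoding = is_lnc if truthful else not is_lnc
            verdicts[tool] = "noncoding" if noncoding else "coding"
        records.append(CodingCallRecord(feature_id=f.feature_id, verdicts=verdicts))
    return records


@dataclass
class SimulatedDataset:
    config: SimConfig
    features: FeatureSet
    truth: SyntheticTruth
    counts: ExpressionMatrix
    coding_calls: list[CodingCallRecord]


def simulate_dataset(
    cfg: SimConfig | None = None,
    out_dir: str | Path | None = None,
    coding_flip_prob: float = 0.0,
) -> SimulatedDataset:
    """Run the full generator; optionally write all pipeline input files.

    When ``out_dir`` is given, writes annotation.gtf, counts.tsv,
    conditions.yaml, coding_calls.tsv and truth.json.
    """
    cfg = cfg or SimConfig()
    features, truth = simulate_layout(cfg)
    counts = simulate_expression(features, truth, cfg)
    calls = simulate_coding_calls(features, truth, coding_flip_prob, seed=cfg.seed)
    ds = SimulatedDataset(cfg, features, truth, counts, calls)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(features, out / "annotation.gtf")
        write_expression_table(counts, out / "counts.tsv")
        write_coding_calls(calls, out / "coding_calls.tsv")
        truth.to_json(out / "truth.json")
        (out / "conditions.yaml").write_text(
            yaml.safe_dump(
                {
                    "unit": "counts",
                    "condition": dict(counts.condition),
                    "truth": "truth.json",
                },
                sort_keys=True,
            )
        )
    return ds
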