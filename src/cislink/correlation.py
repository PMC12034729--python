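"""Pearson co-expression screen for candidate cis pairs.

Each pair is scored by the Pearson correlation of the two members' TPM
profiles across samples and declared significant when |r| >= 0.80 and the
two-sided p-value is below 0.05 (raw p; no multiple-testing correction by
default, with an optional Benjamini-Hochberg switch).  The p-value comes
from the exact t-transform t = r * sqrt(n-2) / sqrt(1-r^2) with n-2
degrees of freedom; a permutation alternative is available for very small
sample numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cislink.cis_pairing import CisPair
from cislink.diffexpr import ExpressionMatrix


@dataclass(frozen=True)
class CorrelationConfig:
    """Screen thresholds and scoring options.

    ``sample_scope="per_condition"`` centres each condition's samples
    before correlating, removing the between-group mean shift so r
    reflects within-condition covariation only; the default pools all
    samples raw.  ``transform="log2p1"`` correlates log2(TPM+1) profiles.
    """

    min_abs_r: float = 0.80
    alpha: float = 0.05
    sample_scope: str = "all_samples"
    transform: str = "none"
    fdr_correct: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_abs_r <= 1.0:
            raise ValueError("min_abs_r must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.sample_scope not in ("all_samples", "per_condition"):
            raise ValueError(f"bad sample_scope {self.sample_scope!r}")
        if self.transform not in ("none", "log2p1"):
            raise ValueError(f"bad transform {self.transform!r}")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient, clamped to [-1, 1].

    Returns ``nan`` when either vector has zero variance; such pairs are
    flagged undefined downstream rather than silently dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r at sample size n.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) against Student's t with n-2 degrees
    of freedom; |r| = 1 gives p = 0 exactly.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(r):
        return float("nan")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r = {r} outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def permutation_p(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for |r| with the add-one estimator.

    Shuffles y relative to x ``n_permutations`` times; p = (1 + #{|r_perm|
    >= |r_obs|}) / (1 + n_permutations).  Useful when n is too small to
    trust the t approximation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson_r(x, y)
    if np.isnan(r_obs):
        return float("nan")
    n = x.size
    dx = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    yp = y[perms]
    dyp = yp - yp.mean(axis=1, keepdims=True)
    denom = np.sqrt((dyp**2).sum(axis=1))
    r_perm = (dyp @ dx) / denom
    exceed = int(np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    return (1 + exceed) / (1 + n_permutations)


def _prepare(matrix: ExpressionMatrix, cfg: CorrelationConfig, samples: list[str]) -> np.ndarray:
    vals = matrix.values[samples].to_numpy(dtype=float)
    if cfg.transform == "log2p1":
        vals = np.log2(vals + 1.0)
    if cfg.sample_scope == "per_condition":
        for cond in ("case", "control"):
            cols = [i for i, s in enumerate(samples) if matrix.condition[s] == cond]
            if cols:
                vals[:, cols] -= vals[:, cols].mean(axis=1, keepdims=True)
    return vals


def screen_pairs(
    pairs: Sequence[CisPair],
    matrix_lnc: ExpressionMatrix,
    matrix_mrna: ExpressionMatrix,
    cfg: CorrelationConfig | None = None,
) -> list[CisPair]:
    """Annotate each pair with r, p, sign and the significance call.

    ``significant`` requires both |r| >= ``min_abs_r`` and p < ``alpha``
    (BH-adjusted p when ``fdr_correct`` is on).  Pairs with a
    zero-variance member get undefined r/p and are never significant.
    """
    cfg = cfg or CorrelationConfig()
    if list(matrix_lnc.sample_ids) != list(matrix_mrna.sample_ids):
        raise ValueError("sample columns of the two matrices are not aligned")
    samples = list(matrix_lnc.sample_ids)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for the correlation screen")
    if not pairs:
        return []

    lnc_pos = {f: i for i, f in enumerate(matrix_lnc.feature_ids)}
    m_pos = {f: i for i, f in enumerate(matrix_mrna.feature_ids)}
    for p in pairs:
        if p.lncrna_id not in lnc_pos:
            raise KeyError(f"pair member {p.lncrna_id!r} missing from lncRNA matrix")
        if p.mrna_id not in m_pos:
            raise KeyError(f"pair member {p.mrna_id!r} missing from mRNA matrix")

    lv = _prepare(matrix_lnc, cfg, samples)
    mv = _prepare(matrix_mrna, cfg, samples)
    x = lv[[lnc_pos[p.lncrna_id] for p in pairs]]
    y = mv[[m_pos[p.mrna_id] for p in pairs]]

    dx = x - x.mean(axis=1, keepdims=True)
    dy = y - y.mean(axis=1, keepdims=True)
    sxx = (dx**2).sum(axis=1)
    syy = (dy**2).sum(axis=1)
    defined = (sxx > 0) & (syy > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((dx * dy).sum(axis=1) / np.sqrt(sxx * syy), -1.0, 1.0)
    r[~defined] = np.nan

    pvals = np.array([pearson_p(ri, n) if np.isfinite(ri) else np.nan for ri in r])
    p_screen = pvals.copy()
    if cfg.fdr_correct:
        ok = np.isfinite(pvals)
        if ok.any():
            _, adj, _, _ = multipletests(pvals[ok], method="fdr_bh")
            p_screen[ok] = adj

    out = []
    for i, pair in enumerate(pairs):
        if not defined[i]:
            out.append(
                replace(pair, r=None, p_value=None, significant=False, sign="undefined")
            )
            continue
        sig = bool(abs(r[i]) >= cfg.min_abs_r and p_screen[i] < cfg.alpha)
        sign = "positive" if r[i] > 0 else ("negative" if r[i] < 0 else "undefined")
        out.append(
            replace(
                pair,
                r=float(r[i]),
                p_value=float(pvals[i]),
                significant=sig,
                sign=sign,
            )
        )
    return out
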