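"""Per-tissue differential expression between CR and control diets.

A two-group negative-binomial model with log link is fit per gene on
size-factor-normalised counts: the Wald statistic tests the log ratio of the
CR group mean to the control group mean, with the NB variance
Var = mu + phi mu^2 propagated to the log-ratio scale by the delta method.
P-values use the standard-normal reference; multiplicity is handled by
Benjamini-Hochberg step-up within each tissue. Fold changes are reported in
the signed convention common in differential-expression tables: a ratio r is
printed as r when r >= 1 and as -1/r when r < 1 (negative = downregulated
under CR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix

STATUS_TESTED = "tested"
STATUS_NOT_EXPRESSED = "not_expressed"

#: significance-star thresholds (p <= t) used in report tables
STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean pseudo-reference.

    Genes with a zero count in any sample are excluded from the reference.
    Falls back to upper-quartile normalisation (factors scaled to geometric
    mean 1) when no gene is everywhere-nonzero; an all-zero matrix is an
    error.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("cannot compute size factors for an all-zero matrix")
    everywhere = (counts > 0).all(axis=1)
    if everywhere.any():
        sub = counts[everywhere]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    else:
        uq = np.array([np.quantile(c[c > 0], 0.75) if (c > 0).any() else np.nan
                       for c in counts.T])
        if np.isnan(uq).any():
            raise ValueError("sample(s) with all-zero counts; cannot normalise")
        factors = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def estimate_dispersion(y: np.ndarray, factors: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion, pooled within groups.

    For each group g with mean m_g and variance s_g^2 of the normalised
    counts, the moment estimate (s_g^2 - m_g) / m_g^2 is formed; estimates
    are pooled with (n_g - 1) weights and floored at zero. Groups with zero
    mean or fewer than two samples contribute nothing.
    """
    y = np.asarray(y, dtype=float)
    yn = y / np.asarray(factors, dtype=float)
    num = den = 0.0
    for g in np.unique(groups):
        v = yn[groups == g]
        if v.size < 2:
            continue
        m = v.mean()
        if m <= 0:
            continue
        s2 = v.var(ddof=1)
        num += (v.size - 1) * (s2 - m) / m**2
        den += v.size - 1
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def nb_wald_test(
    y: np.ndarray,
    is_cr: np.ndarray,
    factors: np.ndarray,
    phi: float,
) -> tuple[float, float, float]:
    """Wald test of the CR/control log mean ratio under the NB model.

    Returns ``(log_ratio, se, p)``. The log ratio is log(m_CR / m_control) of
    normalised group means; its variance is the delta-method NB variance

        SE^2 = sum_{i in CR} (1/(m_CR s_i) + phi) / n_CR^2
             + sum_{i in ctl} (1/(m_ctl s_i) + phi) / n_ctl^2.

    If either group mean is zero, 0.5 pseudo-counts (normalised scale) are
    added to both group means before forming the ratio.
    """
    y = np.asarray(y, dtype=float)
    is_cr = np.asarray(is_cr, dtype=bool)
    s = np.asarray(factors, dtype=float)
    if not is_cr.any() or is_cr.all():
        raise ValueError("both diet groups must be present")
    yn = y / s
    m_cr, m_ct = yn[is_cr].mean(), yn[~is_cr].mean()
    n_cr, n_ct = int(is_cr.sum()), int((~is_cr).sum())
    if m_cr == 0 or m_ct == 0:
        # pseudo-count keeps the statistic finite for one-group-all-zero genes
        pc = 0.5 / max(n_cr, n_ct)
        m_cr, m_ct = m_cr + pc, m_ct + pc
    beta = np.log(m_cr / m_ct)
    se2 = np.sum(1.0 / (m_cr * s[is_cr]) + phi) / n_cr**2
    se2 += np.sum(1.0 / (m_ct * s[~is_cr]) + phi) / n_ct**2
    se = float(np.sqrt(se2))
    if beta == 0.0:
        return 0.0, se, 1.0
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta), se, p


def signed_fold_change(ratio: float) -> float:
    """Signed fold-change convention: r >= 1 -> r, r < 1 -> -1/r."""
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_stars(p: float, thresholds=STAR_THRESHOLDS) -> str:
    if np.isnan(p):
        return ""
    return "*" * sum(p <= t for t in thresholds)


@dataclass
class DEOptions:
    shared_dispersion: bool = False  # one pooled phi across genes instead of per-gene


def run_de(
    cm: CountMatrix,
    meta: pd.DataFrame,
    tissue: str,
    options: DEOptions | None = None,
) -> pd.DataFrame:
    """Differential expression CR vs control within one tissue.

    Returns a frame indexed by gene with columns ``tissue, ratio, signed_fc,
    wald_p, fdr_q, status, stars``. Genes with zero counts in every sample of
    the tissue are reported as ``not_expressed`` and excluded from testing and
    FDR correction.
    """
    options = options or DEOptions()
    samples = meta.loc[meta["tissue"] == tissue, "sample_id"].tolist()
    if not samples:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = cm.subset_samples(samples)
    diets = meta.set_index("sample_id").loc[samples, "diet"]
    is_cr = (diets == "CR").to_numpy()
    if not is_cr.any() or is_cr.all():
        raise ValueError(f"tissue {tissue!r} lacks one diet group")
    factors = size_factors(sub).to_numpy()
    counts = sub.counts.to_numpy(dtype=float)

    expressed = counts.sum(axis=1) > 0
    phis = np.array([
        estimate_dispersion(counts[i], factors, is_cr) if expressed[i] else np.nan
        for i in range(counts.shape[0])
    ])
    if options.shared_dispersion and expressed.any():
        phis[expressed] = np.nanmedian(phis[expressed])

    rows = []
    for i, gene in enumerate(sub.gene_ids):
        if not expressed[i]:
            rows.append((gene, tissue, np.nan, np.nan, np.nan, STATUS_NOT_EXPRESSED))
            continue
        beta, _se, p = nb_wald_test(counts[i], is_cr, factors, phis[i])
        ratio = float(np.exp(beta))
        rows.append((gene, tissue, ratio, signed_fold_change(ratio), p, STATUS_TESTED))
    de = pd.DataFrame(
        rows, columns=["gene_id", "tissue", "ratio", "signed_fc", "wald_p", "status"]
    ).set_index("gene_id")
    tested = de["status"] == STATUS_TESTED
    de["fdr_q"] = np.nan
    if tested.any():
        de.loc[tested, "fdr_q"] = bh_fdr(de.loc[tested, "wald_p"].to_numpy())
    de["stars"] = de["wald_p"].map(significance_stars)
    return de[["tissue", "ratio", "signed_fc", "wald_p", "fdr_q", "status", "stars"]]


def run_de_all_tissues(
    cm: CountMatrix, meta: pd.DataFrame, options: DEOptions | None = None
) -> pd.DataFrame:
    """Concatenated per-tissue DE results (long format, one row per gene x tissue)."""
    frames = [run_de(cm, meta, t, options) for t in meta["tissue"].unique()]
    return pd.concat(frames).reset_index().set_index(["gene_id", "tissue"])


def fold_change_wide(de_long: pd.DataFrame) -> pd.DataFrame:
    """Genes x tissues table of signed fold changes (report layout)."""
    return de_long["signed_fc"].unstack("tissue")
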