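"""Two-group negative-binomial differential expression for miRNA counts.

A deliberately transparent re-implementation of the DESeq2-style skeleton:
median-of-ratios size factors, gene-wise method-of-moments NB dispersion,
and a Wald test on the log2 ratio of group means with a delta-method
standard error. Dispersion-trend shrinkage, Cook's distance filtering and
independent filtering are intentionally omitted; the fold-change sign
convention is log2(mean_SFH / mean_FH), so positive = higher in the
subfertile (SFH) group.

Features are called differentially expressed (DEMIs) at p <= p_thresh and
|log2FC| >= fc_thresh, thresholds inclusive; raw p-values are thresholded
(a Benjamini-Hochberg adjusted p is reported but not used for the call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mircornet.containers import CountMatrix

#: |log2FC| assigned when one group has zero counts for a feature.
LFC_SENTINEL = 30.0

_DISP_FLOOR = 1e-8


@dataclass
class DERecord:
    feature_id: str
    base_mean: float
    log2fc: float
    p_value: float
    status: str = "not_significant"
    p_adj: float = float("nan")
    flagged: bool = False


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    The geometric mean per feature is taken over samples; features with a
    zero count in any sample are excluded; each sample's factor is the
    median over the remaining features of count / geometric mean.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "apply the prevalence filter first"
        )
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def _group_stats(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean with +0.5 pseudo-mean guard, and unbiased variance, per feature."""
    n = q.shape[1]
    mean = (q.sum(axis=1) + 0.5) / n
    var = q.var(axis=1, ddof=1)
    return mean, var


def nb_wald_test(m: CountMatrix, factors: pd.Series | None = None) -> list[DERecord]:
    """Per-feature NB Wald test of SFH vs FH group means.

    Normalized counts q = counts / size_factor. Group means carry a +0.5
    pseudo-count guard against log(0). The gene-wise dispersion alpha is the
    average over groups of the method-of-moments estimate
    (var - mean) / mean^2, floored at 1e-8. The Wald statistic is
    log2FC / SE with SE^2 = sum over groups of
    (mu_g + alpha mu_g^2) / (n_g mu_g^2 ln(2)^2); the two-sided p-value is
    referred to a t distribution with n1 + n2 - 2 degrees of freedom (the
    dispersion is estimated from that many residual degrees of freedom, and
    a normal reference is anti-conservative at these group sizes).
    """
    if factors is None:
        factors = size_factors(m)
    fh = m.samples_in("FH")
    sfh = m.samples_in("SFH")
    if len(fh) < 3 or len(sfh) < 3:
        raise ValueError("each group needs at least 3 samples")

    q = m.counts.to_numpy(dtype=float) / factors.loc[m.sample_ids].to_numpy()
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    q_fh = q[:, [cols[s] for s in fh]]
    q_sfh = q[:, [cols[s] for s in sfh]]

    mu_fh, var_fh = _group_stats(q_fh)
    mu_sfh, var_sfh = _group_stats(q_sfh)
    base_mean = q.mean(axis=1)

    alpha_fh = (var_fh - mu_fh) / mu_fh**2
    alpha_sfh = (var_sfh - mu_sfh) / mu_sfh**2
    alpha = np.maximum((alpha_fh + alpha_sfh) / 2.0, _DISP_FLOOR)

    log2fc = np.log2(mu_sfh / mu_fh)
    ln2sq = np.log(2.0) ** 2
    se2 = (mu_fh + alpha * mu_fh**2) / (len(fh) * mu_fh**2 * ln2sq) + (
        mu_sfh + alpha * mu_sfh**2
    ) / (len(sfh) * mu_sfh**2 * ln2sq)
    wald = log2fc / np.sqrt(se2)
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=len(fh) + len(sfh) - 2)

    # one group entirely zero: direction is certain, magnitude is not
    zero_fh = q_fh.sum(axis=1) == 0
    zero_sfh = q_sfh.sum(axis=1) == 0
    flagged = (zero_fh | zero_sfh) & ~(zero_fh & zero_sfh)
    log2fc = np.where(zero_fh & ~zero_sfh, LFC_SENTINEL, log2fc)
    log2fc = np.where(zero_sfh & ~zero_fh, -LFC_SENTINEL, log2fc)

    padj = multipletests(pvals, method="fdr_bh")[1]
    return [
        DERecord(
            feature_id=fid,
            base_mean=float(base_mean[i]),
            log2fc=float(log2fc[i]),
            p_value=float(pvals[i]),
            p_adj=float(padj[i]),
            flagged=bool(flagged[i]),
        )
        for i, fid in enumerate(m.feature_ids)
    ]


def classify_demis(
    records: list[DERecord], p_thresh: float = 0.05, fc_thresh: float = 0.5
) -> list[DERecord]:
    """Assign up/down/not_significant status (thresholds inclusive).

    "up" means upregulated in the SFH group (log2FC >= fc_thresh).
    """
    for rec in records:
        if rec.p_value <= p_thresh and rec.log2fc >= fc_thresh:
            rec.status = "up"
        elif rec.p_value <= p_thresh and rec.log2fc <= -fc_thresh:
            rec.status = "down"
        else:
            rec.status = "not_significant"
    return records


def volcano_table(records: list[DERecord]) -> pd.DataFrame:
    """log2FC and -log10(p) per feature, for external volcano plotting."""
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in records],
            "log2FC": [r.log2fc for r in records],
            "neg_log10_p": [-np.log10(max(r.p_value, 1e-300)) for r in records],
            "status": [r.status for r in records],
        }
    )


def de_table(records: list[DERecord]) -> pd.DataFrame:
    """DE results as a DataFrame (one row per feature, input order)."""
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in records],
            "baseMean": [r.base_mean for r in records],
            "log2FC": [r.log2fc for r in records],
            "p": [r.p_value for r in records],
            "p_adj": [r.p_adj for r in records],
            "status": [r.status for r in records],
            "flagged": [r.flagged for r in records],
        }
    )
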