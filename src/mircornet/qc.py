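"""Count-matrix quality control: zero filtering, CPM transform, prevalence filter.

The filtering convention follows standard small RNA-seq practice: features
that are zero in every sample are dropped first, counts are scaled to counts
per million (CPM) of the library, and a feature is retained only if it
reaches at least ``min_cpm`` in at least ``min_frac`` of all samples (both
groups pooled). CPM for the prevalence decision is computed ONCE, on the
zero-filtered matrix's column totals, so the filter does not feed back into
its own normalization.
"""

from __future__ import annotations

import logging

from mircornet.containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


def drop_zero_features(m: CountMatrix) -> CountMatrix:
    """Remove features whose counts are zero in all samples."""
    nonzero = m.counts.sum(axis=1) > 0
    if not nonzero.any():
        raise ValueError("all features have zero counts in every sample")
    kept = m.counts.loc[nonzero]
    logger.info(
        "drop_zero_features: %d -> %d features", len(m.counts), len(kept)
    )
    return CountMatrix(kept, m.groups, m.feature_kind)


def cpm(m: CountMatrix) -> NormalizedMatrix:
    """Counts-per-million: counts[f, s] / library_size[s] * 1e6."""
    totals = m.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return NormalizedMatrix(m.counts / totals * 1e6, m.groups, m.feature_kind)


def prevalence_filter(
    m: CountMatrix, min_cpm: float = 1.0, min_frac: float = 0.5, totals=None
) -> CountMatrix:
    """Keep features with CPM >= min_cpm in at least min_frac of all samples.

    Returns raw counts (the filter is decided on CPM but downstream DE wants
    counts). Both groups are pooled for the prevalence fraction. ``totals``
    optionally fixes the per-sample library sizes the CPM is computed
    against (by default the input matrix's own column totals); under fixed
    totals the filter is idempotent.
    """
    if not 0.0 < min_frac <= 1.0:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if totals is None:
        cpm_vals = cpm(m).cpm
    else:
        totals = totals.loc[m.counts.columns]
        if (totals == 0).any():
            raise ValueError("zero library size in supplied totals")
        cpm_vals = m.counts / totals * 1e6
    frac_ok = (cpm_vals >= min_cpm).mean(axis=1)
    kept = m.counts.loc[frac_ok >= min_frac]
    if kept.empty:
        raise ValueError("prevalence filter removed every feature")
    logger.info(
        "prevalence_filter(min_cpm=%g, min_frac=%g): %d -> %d features",
        min_cpm,
        min_frac,
        len(m.counts),
        len(kept),
    )
    return CountMatrix(kept, m.groups, m.feature_kind)
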