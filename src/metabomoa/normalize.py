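"""Two-stage normalization: pool-reference ratios, within-sample median, log10.

Stage 1 divides every value by the median of the pool reference samples for
that metabolite (compensating instrument drift between and within runs).
Stage 2 divides every value in a sample by that sample's median over a
declared metabolite subset (compensating differences in cell number per
dish): ``X_med[i, j] = X[i, j] / median(X[i, .])``.  Stage 3 is an
elementwise log10 for the downstream statistics.

Missing values are excluded from every median and propagate as missing
through ratios and logs; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AbundanceMatrix, ValidationError


@dataclass
class NormalizationReport:
    pool_medians: pd.Series | None = None  # per metabolite
    sample_medians: pd.Series | None = None  # per sample, median(X[i, .])
    n_missing_excluded: int = 0


def pool_normalize(m: AbundanceMatrix) -> tuple[AbundanceMatrix, NormalizationReport]:
    """Divide each value by the pool-sample median of its metabolite.

    Pool samples themselves are normalized too (their post-normalization
    spread is the technical variability estimate).
    """
    if m.scale != "raw":
        raise ValidationError(f"pool_normalize expects scale 'raw', got {m.scale!r}")
    pool_ids = m.sample_ids(role="pool")
    if len(pool_ids) < 2:
        raise ValidationError(f"need >=2 pool samples, found {len(pool_ids)}")
    pool_med = m.values.loc[pool_ids].median(axis=0, skipna=True)
    bad = pool_med.index[~(pool_med > 0)].tolist()
    if bad:
        raise ValidationError(f"zero/missing pool median for metabolites: {bad[:10]}")
    out = m.values.div(pool_med, axis=1)
    report = NormalizationReport(
        pool_medians=pool_med,
        n_missing_excluded=int(m.values.loc[pool_ids].isna().sum().sum()),
    )
    return m.replace_values(out, "pool_ratio"), report


def median_normalize(
    m: AbundanceMatrix, median_panel: list[str] | None = None
) -> tuple[AbundanceMatrix, NormalizationReport]:
    """Divide each sample row by its median over ``median_panel``.

    The median subset defaults to the full panel (the platform computes it
    from all known and unknown analytes of the compartment); the ratio is
    applied to every metabolite, including ones outside the subset.
    """
    if m.scale not in ("raw", "pool_ratio"):
        raise ValidationError(f"median_normalize expects a linear scale, got {m.scale!r}")
    subset = list(median_panel) if median_panel is not None else m.panel.metabolite_ids
    missing_cols = set(subset) - set(m.values.columns)
    if missing_cols:
        raise ValidationError(f"median subset not in matrix: {sorted(missing_cols)[:10]}")
    sub = m.values[subset]
    sample_med = sub.median(axis=1, skipna=True)
    all_missing = sample_med.index[sample_med.isna()].tolist()
    if all_missing:
        raise ValidationError(
            f"samples with all-missing median subset: {all_missing[:10]}"
        )
    nonpos = sample_med.index[sample_med <= 0].tolist()
    if nonpos:
        raise ValidationError(f"non-positive sample medians for: {nonpos[:10]}")
    out = m.values.div(sample_med, axis=0)
    report = NormalizationReport(
        sample_medians=sample_med,
        n_missing_excluded=int(sub.isna().sum().sum()),
    )
    return m.replace_values(out, "median_ratio"), report


def log_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log10 of a ratio-scale matrix; zeros/negatives are errors."""
    if m.scale not in ("raw", "pool_ratio", "median_ratio"):
        raise ValidationError(f"log_transform expects a linear scale, got {m.scale!r}")
    arr = m.values.to_numpy(dtype=float)
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        rows, cols = np.where(bad)
        loc = [(m.values.index[r], m.values.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValidationError(f"non-positive values cannot be log-transformed: {loc}")
    out = pd.DataFrame(np.log10(arr), index=m.values.index, columns=m.values.columns)
    return m.replace_values(out, "log10")


def normalize_pipeline(
    m: AbundanceMatrix, median_panel: list[str] | None = None
) -> tuple[AbundanceMatrix, NormalizationReport]:
    """Convenience: pool-normalize, median-normalize, log10 in one call."""
    pooled, rep1 = pool_normalize(m)
    med, rep2 = median_normalize(pooled, median_panel=median_panel)
    logged = log_transform(med)
    report = NormalizationReport(
        pool_medians=rep1.pool_medians,
        sample_medians=rep2.sample_medians,
        n_missing_excluded=rep1.n_missing_excluded + rep2.n_missing_excluded,
    )
    return logged, report
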