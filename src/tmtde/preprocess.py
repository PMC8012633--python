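"""Missing-value filtering and cyclic LOESS normalization.

Two preprocessing stages applied before differential-abundance analysis:

1. A replicate-zero exclusion filter in the Perseus style: a protein is
   removed when too many of its replicates are unquantified (zero or
   missing) in too many experimental groups.  The default thresholds read
   "more than two replicates with zero values in more than one group" as
   ">= 3 unquantified replicates in >= 2 groups"; both are parameters.

2. Cyclic LOESS normalization on log2 intensities: for every unordered
   sample pair, the log-ratio M is regressed on the average log-intensity A
   with a locally weighted smoother and half the fitted trend is moved from
   one sample to the other, cycling over all pairs for a fixed number of
   iterations.  This removes smooth intensity-dependent (channel) bias
   while leaving the missingness pattern untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .quant_io import LINEAR, LOG2, QuantTable, StudyDesign

logger = logging.getLogger(__name__)

MIN_SHARED_OBS = 10  # sample pairs sharing fewer co-observed proteins are skipped


@dataclass
class FilterReport:
    n_input: int
    n_removed: int
    removed_ids: list[str]
    min_zeros_per_group: int
    min_groups: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class NormalizationReport:
    span: float
    iterations: int
    pre_medians: dict[str, float]
    post_medians: dict[str, float]
    max_trend_pre: float
    max_trend_post: float
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def filter_low_observation(
    q: QuantTable,
    d: StudyDesign,
    min_zeros_per_group: int = 3,
    min_groups: int = 2,
) -> tuple[QuantTable, FilterReport]:
    """Remove proteins unquantified in too many replicates of too many groups.

    A cell counts as unquantified when it is zero or missing.  A protein is
    removed iff the number of groups in which it has at least
    ``min_zeros_per_group`` unquantified cells is at least ``min_groups``.
    The sample set is unchanged.
    """
    if q.scale != LINEAR:
        raise ValueError("filter operates on the linear scale")
    d.validate_against(q)

    warnings: list[str] = []
    for g, size in d.group_sizes().items():
        if size < min_zeros_per_group:
            msg = (f"group {g!r} has {size} samples < min_zeros_per_group="
                   f"{min_zeros_per_group}; rule can never trigger for it")
            warnings.append(msg)
            logger.warning(msg)

    unquant = q.values.isna() | (q.values == 0)
    groups_hit = pd.Series(0, index=q.values.index)
    for g in d.groups:
        cols = d.samples_in(g)
        groups_hit += (unquant[cols].sum(axis=1) >= min_zeros_per_group).astype(int)
    removed_mask = groups_hit >= min_groups
    removed_ids = list(q.values.index[removed_mask])

    kept = q.subset(q.values.index[~removed_mask])
    report = FilterReport(
        n_input=q.n_proteins,
        n_removed=len(removed_ids),
        removed_ids=removed_ids,
        min_zeros_per_group=min_zeros_per_group,
        min_groups=min_groups,
        warnings=warnings,
    )
    logger.info("filter: removed %d of %d proteins", report.n_removed, report.n_input)
    return kept, report


def to_log2(q: QuantTable) -> QuantTable:
    """log2-transform a linear table; zeros become missing."""
    if q.scale != LINEAR:
        raise ValueError("to_log2 expects a linear-scale table")
    arr = q.values.to_numpy(dtype=float)
    if (arr[~np.isnan(arr)] < 0).any():
        raise ValueError("negative intensity")
    with np.errstate(divide="ignore"):
        out = np.log2(arr)
    out[~np.isfinite(out)] = np.nan
    return QuantTable(pd.DataFrame(out, index=q.values.index, columns=q.values.columns),
                      q.gene_symbols.copy(), scale=LOG2)


def back_to_linear(q: QuantTable) -> QuantTable:
    """Invert :func:`to_log2` on observed cells; missing stays missing."""
    if q.scale != LOG2:
        raise ValueError("back_to_linear expects a log2-scale table")
    out = np.power(2.0, q.values.to_numpy(dtype=float))
    return QuantTable(pd.DataFrame(out, index=q.values.index, columns=q.values.columns),
                      q.gene_symbols.copy(), scale=LINEAR)


def _ma_trend(x_i: np.ndarray, x_j: np.ndarray, trim: float = 0.05) -> float:
    """Smooth |M(A)| trend magnitude for one sample pair.

    A trimmed least-squares quadratic of M on A (the largest-deviation
    fraction ``trim`` is discarded first, so a few genuinely regulated
    proteins do not masquerade as channel bias), evaluated over the central
    96% of the A range; returns the maximum absolute fitted value.
    """
    shared = ~np.isnan(x_i) & ~np.isnan(x_j)
    if shared.sum() < MIN_SHARED_OBS:
        return np.nan
    m = x_i[shared] - x_j[shared]
    a = (x_i[shared] + x_j[shared]) / 2.0
    dev = np.abs(m - np.median(m))
    keep = dev <= np.quantile(dev, 1.0 - trim)
    m, a = m[keep], a[keep]
    if a.size < MIN_SHARED_OBS or np.ptp(a) == 0:
        return np.nan
    coef = np.polyfit(a, m, deg=2)
    grid = np.linspace(np.quantile(a, 0.02), np.quantile(a, 0.98), 50)
    return float(np.max(np.abs(np.polyval(coef, grid))))


def max_ma_trend(q: QuantTable) -> float:
    """Maximum smooth |M(A)| trend over all sample pairs of a log2 table."""
    arr = q.values.to_numpy(dtype=float)
    n = arr.shape[1]
    stats = [
        _ma_trend(arr[:, i], arr[:, j])
        for i in range(n) for j in range(i + 1, n)
    ]
    stats = [s for s in stats if np.isfinite(s)]
    return float(max(stats)) if stats else np.nan


def cyclic_loess_normalize(
    q: QuantTable,
    span: float = 0.7,
    iterations: int = 3,
) -> tuple[QuantTable, NormalizationReport]:
    """Cyclic LOESS normalization of a log2-scale table.

    For each unordered sample pair (i, j): over co-observed proteins compute
    M = x_i - x_j and A = (x_i + x_j)/2, and fit a degree-1 locally weighted
    regression of M on A with fraction ``span``.  All pair fits within one
    cycle use the matrix as it stood at the start of the cycle, and each
    pair's fitted trend is split evenly between its two samples with the
    per-sample corrections averaged over all n samples (for n = 2 this is
    exactly "move half the fitted value from one sample to the other").
    The simultaneous update makes the result independent of sample order
    and removes any constant between-sample offset in a single cycle; the
    cycle runs ``iterations`` times.  Pairs sharing fewer than 10
    co-observed proteins are skipped with a warning.  Missing cells are
    untouched.
    """
    if q.scale != LOG2:
        raise ValueError("cyclic LOESS expects a log2-scale table")
    if q.n_samples < 2:
        raise ValueError("need at least 2 samples to normalize")
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    arr = q.values.to_numpy(dtype=float).copy()
    n = arr.shape[1]
    samples = q.sample_ids
    pre_medians = {s: float(np.nanmedian(arr[:, k])) for k, s in enumerate(samples)}
    max_trend_pre = max_ma_trend(q)

    skipped: set[tuple[str, str]] = set()
    for _ in range(iterations):
        adjust = np.zeros_like(arr)
        for i in range(n - 1):
            for j in range(i + 1, n):
                shared = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
                if shared.sum() < MIN_SHARED_OBS:
                    skipped.add((samples[i], samples[j]))
                    continue
                m = arr[shared, i] - arr[shared, j]
                a = (arr[shared, i] + arr[shared, j]) / 2.0
                # delta > 0 collapses near-duplicate abscissae; large speedup,
                # negligible effect at this data scale
                delta = 0.01 * (a.max() - a.min())
                fitted = lowess(m, a, frac=span, it=3, delta=delta,
                                return_sorted=False)
                adjust[shared, i] -= fitted
                adjust[shared, j] += fitted
        arr += adjust / n

    for pair in skipped:
        logger.warning("pair %s shares < %d observations; skipped", pair, MIN_SHARED_OBS)

    out = QuantTable(
        pd.DataFrame(arr, index=q.values.index, columns=q.values.columns),
        q.gene_symbols.copy(), scale=LOG2,
    )
    report = NormalizationReport(
        span=span,
        iterations=iterations,
        pre_medians=pre_medians,
        post_medians={s: float(np.nanmedian(arr[:, k])) for k, s in enumerate(samples)},
        max_trend_pre=max_trend_pre,
        max_trend_post=max_ma_trend(out),
        skipped_pairs=sorted(skipped),
    )
    logger.info("cyclic LOESS: max |M(A)| trend %.4f -> %.4f",
                report.max_trend_pre, report.max_trend_post)
    return out, report


def median_center(q: QuantTable) -> QuantTable:
    """Median-centering baseline normalization (used as a test oracle only)."""
    if q.scale != LOG2:
        raise ValueError("median_center expects a log2-scale table")
    med = q.values.median(axis=0, skipna=True)
    centered = q.values - (med - med.mean())
    return QuantTable(centered, q.gene_symbols.copy(), scale=LOG2)
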