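"""Differential abundance by Tukey-fence outlier calling on log2 group ratios.

The calling procedure treats each contrast's distribution of per-protein
log2 ratios as one boxplot: quartiles Q1/Q3 are estimated from the finite
ratios, fences are placed at Q1 - k*IQR and Q3 + k*IQR (k = 1.5 by
convention), and a protein is called up or down when its ratio lies
strictly outside a fence.  There is no replicate-level hypothesis test:
significance is distribution-of-ratios outlier detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant_io import LINEAR, Contrast, QuantTable, StudyDesign

QUANTILE_LINEAR = "linear"
QUANTILE_HINGES = "hinges"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"
STATUS_UNDEFINED = "undefined"


@dataclass(frozen=True)
class FencePair:
    """Tukey fences: [q1 - k*(q3-q1), q3 + k*(q3-q1)] with provenance."""

    lower: float
    upper: float
    k: float
    quantile_method: str
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower fence exceeds upper fence")


@dataclass(frozen=True)
class DERecord:
    protein_id: str
    gene_symbol: str
    log2_ratio: float  # NaN when undefined
    status: str


@dataclass
class DEResultSet:
    """All per-protein calls for one contrast, with the fences that made them."""

    contrast: Contrast
    fences: FencePair
    records: list[DERecord]

    @property
    def counts(self) -> dict[str, int]:
        c = {STATUS_UP: 0, STATUS_DOWN: 0, STATUS_NS: 0, STATUS_UNDEFINED: 0}
        for r in self.records:
            c[r.status] += 1
        return c

    def ids_with_status(self, status: str) -> set[str]:
        return {r.protein_id for r in self.records if r.status == status}

    @property
    def up_ids(self) -> set[str]:
        return self.ids_with_status(STATUS_UP)

    @property
    def down_ids(self) -> set[str]:
        return self.ids_with_status(STATUS_DOWN)

    @property
    def protein_ids(self) -> set[str]:
        return {r.protein_id for r in self.records}

    def ratios(self) -> pd.Series:
        return pd.Series({r.protein_id: r.log2_ratio for r in self.records})


@dataclass
class GroupMeans:
    """Per-group arithmetic means (linear scale) with observed-cell counts."""

    means: pd.DataFrame      # proteins x groups; NaN = undefined (no observed cell)
    n_observed: pd.DataFrame # proteins x groups, int


def group_means(q: QuantTable, d: StudyDesign) -> GroupMeans:
    """Arithmetic mean per group over observed cells on the linear scale.

    A group mean is undefined (NaN) when every cell of that group is
    missing.  Zeros are legitimate observed values at this stage.
    """
    if q.scale != LINEAR:
        raise ValueError("group means are taken on the linear scale")
    d.validate_against(q)
    means, counts = {}, {}
    for g in d.groups:
        cols = d.samples_in(g)
        block = q.values[cols]
        means[g] = block.mean(axis=1, skipna=True)
        counts[g] = block.notna().sum(axis=1)
    return GroupMeans(pd.DataFrame(means), pd.DataFrame(counts))


def contrast_log2_ratio(means: GroupMeans, c: Contrast) -> pd.Series:
    """log2(mean_numerator / mean_denominator) per protein.

    Undefined (NaN) when either mean is undefined, the denominator mean is
    zero, or the ratio is otherwise non-finite (numerator mean zero).
    """
    for g in (c.numerator, c.denominator):
        if g not in means.means.columns:
            raise ValueError(f"group {g!r} missing from computed means")
    num = means.means[c.numerator]
    den = means.means[c.denominator]
    # log2(num) - log2(den) rather than log2(num/den): mathematically equal
    # but exactly antisymmetric under contrast reversal in floating point
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(num.to_numpy()) - np.log2(den.to_numpy())
    ratio[~np.isfinite(ratio)] = np.nan
    return pd.Series(ratio, index=means.means.index, name=c.name)


def _tukey_hinges(sorted_vals: np.ndarray) -> tuple[float, float]:
    """Classic Tukey hinges: medians of the two halves, halves sharing the
    middle observation when n is odd."""
    n = sorted_vals.size
    d = (np.floor((n + 1) / 2) + 1) / 2  # hinge depth
    lo = int(np.floor(d)) - 1
    hi = int(np.ceil(d)) - 1
    q1 = (sorted_vals[lo] + sorted_vals[hi]) / 2.0
    q3 = (sorted_vals[n - 1 - lo] + sorted_vals[n - 1 - hi]) / 2.0
    return float(q1), float(q3)


def tukey_fences(
    values,
    k: float = 1.5,
    quantile_method: str = QUANTILE_LINEAR,
) -> FencePair:
    """Boxplot whisker fences from a vector of finite log2 ratios.

    ``quantile_method`` is ``"linear"`` (linear interpolation of order
    statistics, the R ``quantile`` type-7 default) or ``"hinges"`` (classic
    Tukey hinges).  Requires at least 4 finite values; non-finite input is
    an error because fences must be computed from exactly the ratios being
    classified.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in fence input")
    if arr.size < 4:
        raise ValueError(f"need >= 4 finite values to place fences, got {arr.size}")
    if quantile_method == QUANTILE_LINEAR:
        q1, q3 = np.percentile(arr, [25.0, 75.0], method="linear")
    elif quantile_method == QUANTILE_HINGES:
        q1, q3 = _tukey_hinges(np.sort(arr))
    else:
        raise ValueError(f"unknown quantile method {quantile_method!r}")
    iqr = q3 - q1
    return FencePair(
        lower=float(q1 - k * iqr),
        upper=float(q3 + k * iqr),
        k=k,
        quantile_method=quantile_method,
        q1=float(q1),
        q3=float(q3),
    )


def call_de(
    ratios: pd.Series,
    fences: FencePair,
    contrast: Contrast,
    gene_symbols: pd.Series | None = None,
) -> DEResultSet:
    """Classify every protein against the fences.

    Strict inequalities: a ratio exactly on a fence is not significant.
    NaN ratios (unavailable group mean) get status ``undefined``.
    """
    if gene_symbols is None:
        gene_symbols = pd.Series("", index=ratios.index, dtype=object)
    records = []
    for pid, r in ratios.items():
        if not np.isfinite(r):
            status, r = STATUS_UNDEFINED, float("nan")
        elif r > fences.upper:
            status = STATUS_UP
        elif r < fences.lower:
            status = STATUS_DOWN
        else:
            status = STATUS_NS
        records.append(DERecord(str(pid), str(gene_symbols.get(pid, "")), float(r), status))
    return DEResultSet(contrast=contrast, fences=fences, records=records)


def differential_abundance(
    q_linear: QuantTable,
    d: StudyDesign,
    contrast: Contrast,
    k: float = 1.5,
    quantile_method: str = QUANTILE_LINEAR,
    mean_scale: str = LINEAR,
) -> DEResultSet:
    """Means -> ratio -> log2 -> fences -> calls for one contrast.

    ``mean_scale="linear"`` (default) averages normalized intensities on the
    linear scale before taking the ratio; ``"log2"`` averages log2 values
    instead (equivalent to a geometric-mean ratio).
    """
    contrast.validate_against(d)
    if mean_scale == LINEAR:
        gm = group_means(q_linear, d)
        ratios = contrast_log2_ratio(gm, contrast)
    elif mean_scale == "log2":
        from .preprocess import to_log2  # local import avoids a cycle

        logt = to_log2(q_linear)
        means = {
            g: logt.values[d.samples_in(g)].mean(axis=1, skipna=True)
            for g in (contrast.numerator, contrast.denominator)
        }
        ratios = means[contrast.numerator] - means[contrast.denominator]
        ratios[~np.isfinite(ratios)] = np.nan
        ratios.name = contrast.name
    else:
        raise ValueError(f"unknown mean_scale {mean_scale!r}")
    finite = ratios[np.isfinite(ratios)]
    fences = tukey_fences(finite.to_numpy(), k=k, quantile_method=quantile_method)
    return call_de(ratios, fences, contrast, q_linear.gene_symbols)
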