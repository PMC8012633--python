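"""Synthetic TMT-like quantification data with known ground truth.

Emulates the study design the pipeline targets: four groups (naive and
lesioned tissue, each sedentary and exercising) of four pooled samples,
log-normal protein abundances, a small fixed fraction of proteins with
true exercise effects per contrast, smooth per-channel intensity-dependent
bias (the distortion cyclic LOESS removes), and missing values from both a
random (MCAR) and an intensity-dependent (MNAR) mechanism.  Missing cells
are written as zeros in the linear output table, matching the raw-table
convention that a zero reporter intensity means "not quantified".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .de_analysis import DEResultSet, STATUS_DOWN, STATUS_UP
from .quant_io import LINEAR, Contrast, QuantTable, StudyDesign

DEFAULT_GROUPS = ("naive_sed", "naive_ex", "lpc_sed", "lpc_ex")
DEFAULT_CONTRASTS = (("naive_ex", "naive_sed"), ("lpc_ex", "lpc_sed"))

MISS_NONE = ""
MISS_MCAR = "mcar"
MISS_MNAR = "mnar"


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the reference study conditions.

    log2 baselines ~ Normal(baseline_mean, baseline_sd); per-contrast true
    effects are drawn uniformly from ``effect_range`` in magnitude with
    balanced signs and applied to the numerator (exercise) group; channel
    bias is a random quadratic in standardized baseline with maximum
    amplitude ``bias_amplitude`` log2 units; MNAR dropout probability is
    logistic((mnar_theta - log2 value) / mnar_tau), with an extra MCAR rate
    on top.
    """

    n_proteins: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    reps_per_group: int = 4
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    de_fraction: float = 0.05
    effect_range: tuple[float, float] = (0.8, 2.0)
    residual_sd: float = 0.25
    bias_amplitude: float = 0.5
    mcar_rate: float = 0.02
    mnar_theta: float = 16.0
    mnar_tau: float = 1.0
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.reps_per_group < 1:
            raise ValueError("n_proteins and reps_per_group must be >= 1")
        if not (0 <= self.de_fraction <= 1 and 0 <= self.mcar_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.effect_range
        if not (0 < lo <= hi):
            raise ValueError("effect_range must be positive and ordered")
        if self.baseline_sd < 0 or self.residual_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.mnar_tau <= 0:
            raise ValueError("mnar_tau must be > 0")
        for num, den in self.contrasts:
            if num not in self.groups or den not in self.groups:
                raise ValueError(f"contrast ({num}, {den}) references unknown group")

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_proteins)

    def contrast_objects(self) -> list[Contrast]:
        return [Contrast(num, den) for num, den in self.contrasts]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    baselines: pd.Series                 # true log2 baseline per protein
    effects: pd.DataFrame                # proteins x contrast names, 0 = null
    bias: pd.DataFrame                   # applied bias per cell (log2 units)
    missing_cause: pd.DataFrame          # "", "mcar" or "mnar" per cell
    config: SimConfig = field(repr=False, default=None)

    def is_de(self, contrast_name: str) -> pd.Series:
        return self.effects[contrast_name] != 0

    def de_ids(self, contrast_name: str) -> set[str]:
        return set(self.effects.index[self.is_de(contrast_name)])


def _sample_bias(rng: np.random.Generator, z: np.ndarray, amplitude: float) -> np.ndarray:
    """One channel's smooth bias curve: random quadratic in standardized
    baseline, rescaled so its maximum |value| is a random fraction
    (0.5..1) of ``amplitude``."""
    if amplitude == 0:
        return np.zeros_like(z)
    coef = rng.uniform(-1, 1, size=3)
    raw = coef[0] + coef[1] * z + coef[2] * z**2
    peak = np.max(np.abs(raw))
    if peak == 0:
        return np.zeros_like(z)
    return raw * (amplitude * rng.uniform(0.5, 1.0) / peak)


def simulate_dataset(cfg: SimConfig) -> tuple[QuantTable, StudyDesign, SimTruth]:
    """Generate a linear-scale quantification table, design and ground truth.

    Deterministic for a fixed ``cfg.seed``.  The returned table stores a
    zero for every missing cell; the truth records whether the dropout was
    random (MCAR) or intensity-dependent (MNAR).
    """
    rng = np.random.default_rng(cfg.seed)
    n_p = cfg.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n_p)]
    gene_symbols = pd.Series([f"Gene{i}" for i in range(n_p)], index=protein_ids)

    samples: list[str] = []
    mapping: dict[str, str] = {}
    for g in cfg.groups:
        for r in range(1, cfg.reps_per_group + 1):
            s = f"{g}_{r}"
            samples.append(s)
            mapping[s] = g
    design = StudyDesign(mapping, tissue="synthetic")
    n_s = len(samples)

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_p)

    # fixed number of DE proteins per contrast, balanced signs
    contrast_names = [Contrast(num, den).name for num, den in cfg.contrasts]
    effects = pd.DataFrame(0.0, index=protein_ids, columns=contrast_names)
    group_effect = {g: np.zeros(n_p) for g in cfg.groups}
    for (num, _den), cname in zip(cfg.contrasts, contrast_names):
        idx = rng.choice(n_p, size=cfg.n_de, replace=False)
        mags = rng.uniform(*cfg.effect_range, size=cfg.n_de)
        signs = np.ones(cfg.n_de)
        signs[: cfg.n_de // 2] = -1.0
        rng.shuffle(signs)
        eff = mags * signs
        effects.iloc[idx, effects.columns.get_loc(cname)] = eff
        group_effect[num][idx] += eff  # effect carried by the numerator group

    z = (baselines - cfg.baseline_mean) / max(cfg.baseline_sd, 1e-12)
    bias = np.column_stack(
        [_sample_bias(rng, z, cfg.bias_amplitude) for _ in range(n_s)]
    )

    log2_vals = (
        baselines[:, None]
        + np.column_stack([group_effect[mapping[s]] for s in samples])
        + bias
        + rng.normal(0.0, cfg.residual_sd, size=(n_p, n_s))
    )

    p_mnar = expit((cfg.mnar_theta - log2_vals) / cfg.mnar_tau)
    mnar = rng.random((n_p, n_s)) < p_mnar
    mcar = rng.random((n_p, n_s)) < cfg.mcar_rate
    cause = np.full((n_p, n_s), MISS_NONE, dtype=object)
    cause[mcar] = MISS_MCAR
    cause[mnar & ~mcar] = MISS_MNAR
    missing = mnar | mcar

    linear = np.power(2.0, log2_vals)
    linear[missing] = 0.0

    table = QuantTable(
        pd.DataFrame(linear, index=protein_ids, columns=samples),
        gene_symbols, scale=LINEAR,
    )
    truth = SimTruth(
        baselines=pd.Series(baselines, index=protein_ids),
        effects=effects,
        bias=pd.DataFrame(bias, index=protein_ids, columns=samples),
        missing_cause=pd.DataFrame(cause, index=protein_ids, columns=samples),
        config=cfg,
    )
    return table, design, truth


@dataclass
class RecoveryMetrics:
    """Spike-in recovery of a DE caller against simulation truth."""

    sensitivity: float               # direction-correct calls among true DE
    fdp: float                       # false calls among all calls (0 if none)
    n_true: int
    n_called: int
    n_true_positive: int
    recall_by_effect: pd.DataFrame   # bins of |true effect| with recall each

    def sensitivity_at(self, min_abs_effect: float) -> float:
        sel = self.recall_by_effect[
            self.recall_by_effect["min_abs_effect"] >= min_abs_effect
        ]
        n = sel["n_true"].sum()
        return float(sel["n_recovered"].sum() / n) if n else float("nan")


def spike_report(
    truth: SimTruth,
    results: DEResultSet,
    effect_bins=(0.8, 1.2, 1.5, 2.0),
) -> RecoveryMetrics:
    """Compare one contrast's calls to ground truth by exact id matching.

    A true DE protein counts as recovered only when called in the direction
    of its true effect.  Proteins in the results but absent from the truth
    are an error (id mismatch).
    """
    cname = results.contrast.name
    if cname not in truth.effects.columns:
        raise ValueError(f"truth has no contrast {cname!r}")
    stray = results.protein_ids - set(truth.effects.index)
    if stray:
        raise ValueError(f"result proteins unknown to truth: {sorted(stray)[:5]}")

    eff = truth.effects[cname]
    called_up, called_down = results.up_ids, results.down_ids
    called = called_up | called_down
    true_ids = truth.de_ids(cname)

    tp = {p for p in called_up if eff[p] > 0} | {p for p in called_down if eff[p] < 0}
    fp = {p for p in called if eff[p] == 0}

    edges = list(effect_bins) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ids = {p for p in true_ids if lo <= abs(eff[p]) < hi}
        rows.append({
            "min_abs_effect": lo,
            "max_abs_effect": hi,
            "n_true": len(ids),
            "n_recovered": len(ids & tp),
            "recall": len(ids & tp) / len(ids) if ids else float("nan"),
        })

    return RecoveryMetrics(
        sensitivity=len(tp) / len(true_ids) if true_ids else float("nan"),
        fdp=len(fp) / len(called) if called else 0.0,
        n_true=len(true_ids),
        n_called=len(called),
        n_true_positive=len(tp),
        recall_by_effect=pd.DataFrame(rows),
    )
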