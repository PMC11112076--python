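"""Cleaning-performance evaluation: relative error, the condition grid, and
the two-way fixed-effects ANOVA with eta-squared effect sizes.

The relative error for one trial is the energy ratio

    RE_i = sum_c sum_{t in window} (y~ - y)^2 / sum_c sum_{t in window} y^2,

and the dataset score is the mean over trials (a fraction; multiply by 100
for percent).  The Monte-Carlo grid crosses 11 inter-trial-variability
levels with 11 topography (conductivity-contrast) levels; every cell draws
one of the 9 artifact dipoles at random per repetition, corrupts the ground
truth, cleans with each method and records windowed errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import artifact_sim, ground_truth, headmodel, ica_clean, ssp_sir
from .epochs import EpochedData

__all__ = [
    "REResult",
    "AnovaTable",
    "relative_error",
    "log10_re",
    "run_grid",
    "two_way_anova",
]

EARLY_WINDOW_MS = (0.0, 50.0)
LATE_WINDOW_MS = (50.0, 100.0)


@dataclass(frozen=True)
class REResult:
    per_trial_re: np.ndarray
    mean_re: float
    window_ms: tuple[float, float]
    method: str = ""

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.per_trial_re) < 0):
            raise ValueError("relative errors must be non-negative")


def relative_error(
    cleaned: EpochedData,
    truth: EpochedData,
    window_ms: tuple[float, float] = EARLY_WINDOW_MS,
    method: str = "",
    root: bool = False,
) -> REResult:
    """Trial-wise energy-ratio error between cleaned data and ground truth.

    ``root=True`` returns the square root of each trial's ratio instead
    (the alternative reading of the error metric).
    """
    if cleaned.data.shape != truth.data.shape:
        raise ValueError("cleaned and truth shapes differ")
    mask = truth.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    diff = cleaned.data[:, mask, :] - truth.data[:, mask, :]
    num = np.sum(diff**2, axis=(0, 1))
    den = np.sum(truth.data[:, mask, :] ** 2, axis=(0, 1))
    if np.any(den == 0):
        raise ValueError("ground truth has zero energy in the window")
    re = num / den
    if root:
        re = np.sqrt(re)
    return REResult(re, float(re.mean()), tuple(window_ms), method)


def log10_re(re: float, floor: float = 1e-12) -> float:
    """log10 of the relative error expressed in units of 100%.

    RE = 1.0 (i.e. 100%) maps to 0; 10.0 (1000%) to 1; 0.1 (10%) to -1.
    Zero errors are floored with a warning.
    """
    if re < 0:
        raise ValueError("relative error must be non-negative")
    if re == 0:
        warnings.warn(f"zero relative error floored at {floor}")
        re = floor
    return float(np.log10(re))


def _derived_seed(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master, spawn_key=key))


def run_grid(
    gt_config: ground_truth.GroundTruthConfig,
    amplitude_uv: float = 250.0,
    n_reps: int = 10,
    methods: tuple[str, ...] = ("ssp_sir", "ica"),
    seed: int = 0,
    alphas: tuple[float, ...] = artifact_sim.ALPHA_GRID,
    contrasts: tuple[float, ...] = headmodel.CONTRASTS,
    bank: artifact_sim.ArtifactTopographyBank | None = None,
    sir_leadfield: headmodel.LeadField | None = None,
    ica_kwargs: dict | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo sweep over the full condition grid.

    Every (alpha, contrast, rep) cell derives its own random stream from the
    master seed, so any cell can be recomputed in isolation.  Failed cells
    are recorded with ``error`` set rather than dropped.
    """
    gt = ground_truth.generate_ground_truth(gt_config)
    if bank is None:
        bank = artifact_sim.ArtifactTopographyBank(n_channels=gt_config.n_channels)
    if sir_leadfield is None:
        montage = headmodel.build_montage_1020(gt_config.n_channels)
        sir_leadfield = headmodel.compute_leadfield(
            ground_truth.neuronal_head_model(),
            headmodel.shell_source_space(),
            montage,
        )
    ica_kwargs = dict(ica_kwargs or {})

    angle_by_contrast = {
        c: artifact_sim.median_minimum_angle(gt, c, bank) for c in contrasts
    }

    rows = []
    for ia, alpha in enumerate(alphas):
        for ic, contrast in enumerate(contrasts):
            for rep in range(n_reps):
                rng = _derived_seed(seed, ia, ic, rep)
                cond = artifact_sim.ArtifactCondition(
                    alpha=alpha, contrast=contrast, amplitude_uv=amplitude_uv,
                    seed=seed,
                )
                realization = artifact_sim.simulate_realization(
                    cond, gt.times, gt.fs, gt.n_trials, bank=bank, rng=rng
                )
                corrupted = artifact_sim.superpose(gt, realization)
                topo = realization.topography
                for method in methods:
                    row = {
                        "alpha": alpha,
                        "contrast": contrast,
                        "angle_summary_deg": angle_by_contrast[contrast],
                        "amplitude_uv": amplitude_uv,
                        "rep": rep,
                        "method": method,
                        "seed": seed,
                        "source_index": realization.source_index,
                        "error": "",
                    }
                    try:
                        if method == "ssp_sir":
                            res = ssp_sir.clean_dataset_ssp_sir(
                                corrupted, sir_leadfield, known_topography=topo
                            )
                        elif method == "ica":
                            ica_seed = int(rng.integers(0, 2**31 - 1))
                            res = ica_clean.clean_dataset_ica(
                                corrupted, topo, seed=ica_seed, **ica_kwargs
                            )
                        else:
                            raise ValueError(f"unknown method {method!r}")
                        early = relative_error(res.data, gt, EARLY_WINDOW_MS)
                        late = relative_error(res.data, gt, LATE_WINDOW_MS)
                        row.update(
                            re_0_50=early.mean_re,
                            re_50_100=late.mean_re,
                            log10_re=log10_re(max(early.mean_re, 1e-12)),
                        )
                    except Exception as exc:  # record, do not drop
                        row.update(
                            re_0_50=np.nan, re_50_100=np.nan, log10_re=np.nan,
                            error=f"{type(exc).__name__}: {exc}",
                        )
                    rows.append(row)
            if progress:
                print(f"grid: alpha={alpha:.1f} contrast=1/{1/contrast:.0f} done",
                      flush=True)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaTable:
    """Two-way fixed-effects ANOVA with interaction and eta-squared."""

    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    bonferroni_factor: int
    response: str

    def eta_squared(self, effect: str) -> float:
        return float(self.table.loc[effect, "eta_sq"])

    def p_value(self, effect: str, corrected: bool = True) -> float:
        col = "p_bonferroni" if corrected else "p"
        return float(self.table.loc[effect, col])


def two_way_anova(
    grid: pd.DataFrame,
    response: str = "log10_re",
    factor_a: str = "alpha",
    factor_b: str = "contrast",
    bonferroni_factor: int = 3,
) -> AnovaTable:
    """Balanced two-way ANOVA by direct sums-of-squares decomposition.

    eta^2 = SS_effect / SS_total.  p-values are Bonferroni-multiplied by the
    number of amplitude conditions tested (default 3) and capped at 1.
    Unbalanced or incomplete grids raise.
    """
    df = grid.dropna(subset=[response])
    if len(df) != len(grid):
        raise ValueError("grid contains failed cells; cannot run ANOVA")
    counts = df.groupby([factor_a, factor_b], sort=True).size()
    a_levels = df[factor_a].nunique()
    b_levels = df[factor_b].nunique()
    if len(counts) != a_levels * b_levels or counts.nunique() != 1:
        raise ValueError("design must be balanced with no missing cells")

    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    def _ss(group_cols) -> float:
        g = df.groupby(group_cols, sort=True)[response]
        return float((g.count() * (g.mean() - grand) ** 2).sum())

    ss_a = _ss(factor_a)
    ss_b = _ss(factor_b)
    ss_cells = _ss([factor_a, factor_b])
    ss_int = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells

    n = len(df)
    df_a = a_levels - 1
    df_b = b_levels - 1
    df_int = df_a * df_b
    df_err = n - a_levels * b_levels
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom (need replicates)")

    rows = {}
    ms_err = ss_err / df_err
    for name, ss, dof in (
        ("variability", ss_a, df_a),
        ("similarity", ss_b, df_b),
        ("interaction", ss_int, df_int),
    ):
        F = (ss / dof) / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(F, dof, df_err))
        rows[name] = dict(
            ss=ss, df=dof, F=F, p=p,
            p_bonferroni=min(1.0, p * bonferroni_factor),
            eta_sq=ss / ss_total if ss_total > 0 else 0.0,
        )
    rows["residual"] = dict(
        ss=ss_err, df=df_err, F=np.nan, p=np.nan, p_bonferroni=np.nan,
        eta_sq=ss_err / ss_total if ss_total > 0 else 0.0,
    )
    table = pd.DataFrame(rows).T
    assert abs(ss_a + ss_b + ss_int + ss_err - ss_total) <= 1e-6 * max(ss_total, 1.0)
    return AnovaTable(table, bonferroni_factor, response)
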