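"""Variation-factor (VF) statistics and the VIP/VF integration.

VF is the percent change of a hormone's treated-group mean concentration
relative to the control-group mean:

    VF = (mean_treated − mean_control) / mean_control × 100

Significance of each dose-vs-control difference comes from a one-way ANOVA
across all dose groups followed by Tukey's HSD multiple comparison; the
Tukey-adjusted p-value for each dose-vs-control pair is reported.

A hormone is called *altered* for a contrast when all three printed criteria
hold simultaneously (strict inequalities):

    VIP > 1,   |VF| > 25%,   p < 0.05

and the modified VIP is then the VIP signed by the direction of change,
vip_m = sign(VF) × VIP; otherwise vip_m = 0 and the class is "none".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicationError, UndefinedBaselineError
from .io_tables import HormoneDataset
from .plsda import compute_q2, compute_vip, fit_plsda, loo_folds, validate_model

ALTERATION_POSITIVE = "positive"
ALTERATION_NEGATIVE = "negative"
ALTERATION_NONE = "none"


@dataclass(frozen=True)
class SelectionThresholds:
    """Gating thresholds for the VIP/VF integration (all strict)."""

    vip_min: float = 1.0
    vf_min: float = 25.0  # percent
    alpha: float = 0.05


def compute_vf(control_mean: float, treated_mean: float) -> float:
    """Percent change of the treated-group mean relative to control."""
    if not control_mean > 0:
        raise UndefinedBaselineError(
            f"control mean must be positive to define VF, got {control_mean}"
        )
    return (treated_mean - control_mean) / control_mean * 100.0


def test_group_difference(
    control_reps: np.ndarray, treatment_reps: dict[float, np.ndarray]
) -> dict[float, float]:
    """Tukey-HSD-adjusted p-values for each dose-vs-control comparison.

    One omnibus comparison spans the control and all dose groups: the pooled
    within-group mean square from the one-way ANOVA feeds the studentized
    range statistic for every dose-vs-control pair,

        q = |mean_d − mean_0| / sqrt(MSE/2 · (1/n_d + 1/n_0)),

    whose p-value comes from the studentized range distribution with k
    groups and N−k error degrees of freedom — identical to the full Tukey
    HSD, evaluated only for the pairs involving the control.
    """
    control_reps = np.asarray(control_reps, dtype=float)
    groups = [control_reps] + [np.asarray(v, dtype=float) for v in treatment_reps.values()]
    for g in groups:
        if len(g) < 2:
            raise InsufficientReplicationError(
                f"every group needs >=2 replicates, got {len(g)}"
            )
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df_err = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err
    if mse == 0:
        # degenerate: no within-group variance; any difference is significant
        return {
            dose: 0.0 if not np.isclose(np.mean(v), control_reps.mean()) else 1.0
            for dose, v in treatment_reps.items()
        }
    m0, n0 = control_reps.mean(), len(control_reps)
    out = {}
    for dose, v in treatment_reps.items():
        v = np.asarray(v, dtype=float)
        se = np.sqrt(mse / 2.0 * (1.0 / len(v) + 1.0 / n0))
        q = abs(v.mean() - m0) / se
        out[dose] = float(stats.studentized_range.sf(q, k, df_err))
    return out


def integrate_vip_vf(
    vip: float,
    vf_percent: float,
    p_value: float,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> tuple[float, str]:
    """Apply the three-way gate and return (vip_m, alteration class)."""
    if not all(np.isfinite([vip, vf_percent, p_value])):
        raise ValueError("VIP, VF, and p must be finite")
    if (
        vip > thresholds.vip_min
        and abs(vf_percent) > thresholds.vf_min
        and p_value < thresholds.alpha
    ):
        if vf_percent > 0:
            return vip, ALTERATION_POSITIVE
        return -vip, ALTERATION_NEGATIVE
    return 0.0, ALTERATION_NONE


def select_altered_hormones(
    ds: HormoneDataset,
    n_components: int = 2,
    thresholds: SelectionThresholds = SelectionThresholds(),
    validity_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full per-contrast selection over a hormone dataset.

    For every (tissue, dose-vs-control) contrast: fit PLS-DA on the 2-group
    concentration submatrix, compute leave-one-out Q² and VIP, compute VF on
    group means, take Tukey-adjusted p-values across all dose groups, and
    apply the VIP/VF gate.

    Returns
    -------
    records : DataFrame
        One row per (hormone, tissue, dose): vip, vf_percent, p_value,
        vip_m, alteration.
    model_summary : DataFrame
        One row per (tissue, dose): r2x, r2y, q2, validity pass flag.
    """
    rec_rows = []
    model_rows = []
    for tissue in sorted(set(ds.samples["tissue"])):
        means = ds.group_means(tissue)
        control_mean = means.loc[0.0]
        # Tukey across all dose groups, once per hormone
        tukey_p: dict[str, dict[float, float]] = {}
        for hormone in ds.hormone_names:
            ctrl = ds.replicate_values(tissue, 0.0, hormone)
            treats = {
                d: ds.replicate_values(tissue, d, hormone) for d in ds.treatment_doses
            }
            tukey_p[hormone] = test_group_difference(ctrl, treats)
        for dose in ds.treatment_doses:
            sub = ds.subset(tissue, [0.0, dose])
            y = (sub.samples["dose_mg_L"] > 0).astype(float).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_plsda(sub.concentrations, y, n_components)
                q2 = compute_q2(
                    sub.concentrations, y, n_components, loo_folds(len(y))
                )
                vip = compute_vip(model)
            verdict = validate_model(model.r2x, model.r2y, q2, validity_threshold)
            model_rows.append(
                {
                    "tissue": tissue,
                    "dose_mg_L": dose,
                    "r2x": model.r2x,
                    "r2y": model.r2y,
                    "q2": q2,
                    "valid": verdict.passed,
                }
            )
            for j, hormone in enumerate(ds.hormone_names):
                vf = compute_vf(float(control_mean[hormone]), float(means.loc[dose, hormone]))
                p = tukey_p[hormone][dose]
                vip_m, alteration = integrate_vip_vf(float(vip[j]), vf, p, thresholds)
                rec_rows.append(
                    {
                        "hormone": hormone,
                        "tissue": tissue,
                        "dose_mg_L": dose,
                        "vip": float(vip[j]),
                        "vf_percent": vf,
                        "p_value": p,
                        "vip_m": vip_m,
                        "alteration": alteration,
                    }
                )
    records = pd.DataFrame(rec_rows)
    model_summary = pd.DataFrame(model_rows)
    return records, model_summary
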