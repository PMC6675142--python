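"""Link expression dynamics to protein divergence.

Protein divergence is measured as K_A, the rate of nonsynonymous substitution
per nonsynonymous site between orthologs (K_S is saturated between
C. elegans and C. briggsae, so K_A/K_S is computed but not reported by
default). This module summarises K_A by coexpression module, groups genes by
peak-expression timepoint mapped onto developmental stages, averages K_A on
the log scale (geometric mean, with zeros replaced by 0.001 before logging),
computes the expression-weighted transcriptome divergence index (TDI), and
regresses log K_A on the four cubic shape metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .shape_metrics import COEF_NAMES

#: Default threshold below which K_A counts as "near zero" (separates the
#: hyper-conserved histone-like mode from the rest of a module).
NEAR_ZERO_KA = 0.005

#: Value substituted for K_A = 0 before log-transforming.
ZERO_KA_SUB = 0.001


def minutes_of(t: int) -> float:
    """Minutes after the start of the embryonic series; NaN for postembryonic points."""
    if not 1 <= t <= 30:
        raise ValueError(f"timepoint {t} out of range 1..30")
    return float((t - 1) * 30) if t <= 25 else float("nan")


def stage_of(t: int) -> str:
    """Developmental stage of timepoint t.

    Embryonic points 1..25 are spaced at 30-minute intervals: EE up to
    120 min, ME up to 390 min, LE up to 720 min. Points 26-28 are larval
    L1-L3, 29 is L4 and 30 is young adult (YA).
    """
    if not 1 <= t <= 30:
        raise ValueError(f"timepoint {t} out of range 1..30")
    if t <= 25:
        m = (t - 1) * 30
        if m <= 120:
            return "EE"
        if m <= 390:
            return "ME"
        return "LE"
    return {26: "L1", 27: "L2", 28: "L3", 29: "L4", 30: "YA"}[t]


def stage_map(T: int = 30) -> pd.DataFrame:
    """Timepoint -> (minutes, stage) table for the 30-point series."""
    rows = [{"timepoint": t, "minutes": minutes_of(t), "stage": stage_of(t)}
            for t in range(1, T + 1)]
    return pd.DataFrame(rows).set_index("timepoint")


def peak_timepoint(values: pd.DataFrame) -> pd.Series:
    """Per-gene timepoint (1-based) of maximal expression; ties -> earliest."""
    return pd.Series(values.to_numpy().argmax(axis=1) + 1, index=values.index,
                     name="peak_timepoint")


def module_ka_summary(labels: pd.Series, ann: pd.DataFrame,
                      near_zero_threshold: float = NEAR_ZERO_KA) -> pd.DataFrame:
    """Per-module K_A median, IQR, near-zero fraction and ortholog fraction.

    Median/IQR/near-zero use member genes with a K_A value; the ortholog
    fraction is over all module members. Modules without divergence data get
    an NA row.
    """
    genes = labels.index.intersection(ann.index)
    ann = ann.loc[genes]
    lab = labels.loc[genes]
    rows = {}
    for m in sorted(lab.unique()):
        members = ann.loc[lab == m]
        ka = members["ka"].dropna().astype(float)
        row = {"n_genes": len(members), "n_ka": len(ka),
               "ortholog_fraction": float(members["has_ortholog"].mean())
               if "has_ortholog" in members else np.nan}
        if len(ka):
            row.update(ka_median=float(ka.median()),
                       ka_q25=float(ka.quantile(0.25)),
                       ka_q75=float(ka.quantile(0.75)),
                       near_zero_fraction=float((ka < near_zero_threshold).mean()))
        else:
            row.update(ka_median=np.nan, ka_q25=np.nan, ka_q75=np.nan,
                       near_zero_fraction=np.nan)
        rows[m] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def geometric_mean_ka(ka, zero_value: float = ZERO_KA_SUB) -> float:
    """Back-transformed mean of log10 K_A; zeros replaced by ``zero_value``."""
    ka = np.asarray(ka, dtype=float)
    ka = ka[~np.isnan(ka)]
    if len(ka) == 0:
        return float("nan")
    ka = np.where(ka <= 0, zero_value, ka)
    return float(10 ** np.mean(np.log10(ka)))


def stage_ka_average(peaks: pd.Series, ann: pd.DataFrame,
                     zero_value: float = ZERO_KA_SUB) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Geometric-mean K_A per peak-expression timepoint and per stage.

    Stage averages pool genes by the stage of their peak timepoint. Returns
    (per-timepoint frame, per-stage frame).
    """
    genes = peaks.index.intersection(ann.index)
    ka = ann.loc[genes, "ka"].astype(float)
    ok = ka.notna()
    genes = genes[ok]
    ka = ka[ok]
    pk = peaks.loc[genes]
    tps = sorted(pk.unique())
    per_tp = pd.DataFrame(
        {"n_genes": [int((pk == t).sum()) for t in tps],
         "mean_ka": [geometric_mean_ka(ka[pk == t], zero_value) for t in tps]},
        index=pd.Index(tps, name="timepoint"))
    per_tp["stage"] = [stage_of(int(t)) for t in per_tp.index]
    stages = pk.map(lambda t: stage_of(int(t)))
    per_stage = pd.DataFrame({
        "n_genes": stages.value_counts(),
        "mean_ka": [geometric_mean_ka(ka[stages == s], zero_value)
                    for s in stages.value_counts().index],
    })
    order = [s for s in ("EE", "ME", "LE", "L1", "L2", "L3", "L4", "YA")
             if s in per_stage.index]
    per_stage = per_stage.loc[order]
    per_stage.index.name = "stage"
    return per_tp, per_stage


@dataclass
class TDIProfile:
    """Per-timepoint expression-weighted mean K_A.

    TDI_t = sum_i w_it K_A,i / sum_i w_it over the genes with divergence
    data, with w_it the linear-scale expression of gene i at timepoint t.
    """

    values: pd.Series
    n_genes: int
    log_weights: bool = False


def tdi(values: pd.DataFrame, ann: pd.DataFrame, log_weights: bool = False) -> TDIProfile:
    """Transcriptome divergence index across the time series.

    Weights are linear-scale expression recovered from log2-CPM
    (w = 2^value); ``log_weights`` instead weights by the log-CPM values
    directly (provided for sensitivity checks; log weights compress the
    index). Timepoints with zero total weight yield NaN.
    """
    genes = values.index.intersection(ann.index)
    ka = ann.loc[genes, "ka"].astype(float)
    genes = genes[ka.notna()]
    if len(genes) == 0:
        raise ValueError("no genes with K_A values")
    ka = ka.loc[genes].to_numpy()
    expr = values.loc[genes].to_numpy(dtype=float)
    w = expr if log_weights else 2.0**expr
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(tot != 0, (w * ka[:, None]).sum(axis=0) / tot, np.nan)
    return TDIProfile(values=pd.Series(prof, index=values.columns, name="tdi"),
                      n_genes=len(genes), log_weights=log_weights)


@dataclass
class ShapeRegression:
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    n: int
    coefficients: pd.Series


def ka_shape_regression(params: pd.DataFrame, ann: pd.DataFrame) -> ShapeRegression:
    """OLS of log10 K_A on (alpha, beta1, beta2, beta3) + intercept.

    Restricted to genes with both a shape fit and K_A > 0. Reports R-squared
    and the overall F test on (4, n-5) df.
    """
    genes = params.index.intersection(ann.index)
    ka = ann.loc[genes, "ka"].astype(float)
    genes = genes[ka.notna() & (ka > 0)]
    if len(genes) <= 5:
        raise ValueError("need more than 5 genes with positive K_A")
    y = np.log10(ann.loc[genes, "ka"].astype(float).to_numpy())
    X = sm.add_constant(params.loc[genes, list(COEF_NAMES)].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    return ShapeRegression(
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        n=len(genes),
        coefficients=pd.Series(fit.params, index=["intercept", *COEF_NAMES]),
    )
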