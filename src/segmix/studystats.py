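"""Tabular study statistics: epiboly staging, ΔΔCT, mean comparisons.

* :func:`normalize_epiboly` aligns repeats on the standard dome reference
  (4.33 h): whatever offset the wild-type dome time shows in a repeat is
  subtracted from every record of that repeat, both genotypes.
* :func:`epiboly_anova` fits a balanced fixed-effects two-way ANOVA
  (genotype x stage) from the sum-of-squares decomposition and runs
  Bonferroni-corrected per-stage genotype contrasts on the pooled residual
  error (the family is the post-dome stages).
* :func:`ddct` is relative qPCR quantification: per sample,
  ΔCT = mean CT(gene) − mean CT(housekeeping); ΔΔCT subtracts the
  calibrator sample's ΔCT; RQ = efficiency^(−ΔΔCT) with efficiency 2
  (perfect doubling) by default.
* :func:`compare_means` is the generic unpaired two-sided t-test used for
  body length, cell shape, proliferation and densitometry style endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segstats import GroupComparison
from .synthgen import STAGE_ORDER

__all__ = [
    "RelativeQuantity",
    "normalize_epiboly",
    "epiboly_anova",
    "ddct",
    "ddct_per_sample",
    "compare_means",
    "DOME_REFERENCE_H",
]

DOME_REFERENCE_H = 4.33


@dataclass
class RelativeQuantity:
    gene: str
    group: str
    rq: float
    log2_rq: float
    sem: float


# ---------------------------------------------------------------------------
# epiboly
# ---------------------------------------------------------------------------

def normalize_epiboly(
    records: pd.DataFrame, dome_reference_h: float = DOME_REFERENCE_H
) -> pd.DataFrame:
    """Shift each repeat so its wild-type dome time equals the reference.

    The per-repeat shift (observed wt dome time − reference) is subtracted
    from all records of that repeat, both genotypes; idempotent by
    construction. Raises if a repeat lacks a wt dome record, naming it.
    """
    df = records.copy()
    for rep, sub in df.groupby("repeat"):
        wt_dome = sub[(sub["genotype"] == "wt") & (sub["stage"] == "dome")]
        if wt_dome.empty:
            raise ValueError(f"repeat {rep!r} has no wild-type dome record")
        shift = float(wt_dome["time_h"].mean()) - dome_reference_h
        df.loc[df["repeat"] == rep, "time_h"] -= shift
    return df


def epiboly_anova(records: pd.DataFrame) -> dict:
    """Balanced two-way ANOVA (genotype, stage, interaction) + post-hoc.

    Returns genotype/stage/interaction F and p, the sum-of-squares table,
    and Bonferroni-corrected per-stage wt-vs-mut p-values for the post-dome
    stages (pooled residual MS, correction factor = number of post-dome
    stages, capped at 1). A fully degenerate genotype effect (zero SS) is
    reported as F = 0, p = 1.

    The dome stage, when present, is excluded from the model: it is the
    normalization anchor (the wild-type dome time is pinned to the
    reference exactly, with zero variance), not a measurement, and the
    genotype delay is defined at the stages after it.
    """
    df = records.copy()
    if "dome" in set(df["stage"]):
        df = df[df["stage"] != "dome"]
    stages = [s for s in STAGE_ORDER if s in set(df["stage"])]
    genotypes = sorted(set(df["genotype"]))
    counts = df.groupby(["genotype", "stage"])["time_h"].count()
    if counts.nunique() != 1 or len(counts) != len(stages) * len(genotypes):
        raise ValueError("unbalanced design: every genotype x stage cell needs equal n")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need >= 2 repeats per genotype x stage cell")

    y = df["time_h"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    mean_g = df.groupby("genotype")["time_h"].mean()
    mean_s = df.groupby("stage")["time_h"].mean()
    mean_gs = df.groupby(["genotype", "stage"])["time_h"].mean()
    a, b = len(genotypes), len(stages)
    ss_g = float(n * b * ((mean_g - grand) ** 2).sum())
    ss_s = float(n * a * ((mean_s - grand) ** 2).sum())
    ss_cells = float(n * ((mean_gs - grand) ** 2).sum())
    ss_gs = ss_cells - ss_g - ss_s
    ss_res = ss_total - ss_cells
    df_g, df_s = a - 1, b - 1
    df_gs = df_g * df_s
    df_res = a * b * (n - 1)
    ms_res = ss_res / df_res

    def f_and_p(ss: float, dof: int) -> tuple[float, float]:
        if ss <= 1e-12:
            return 0.0, 1.0
        if ms_res <= 1e-12:
            return float("inf"), 0.0
        f = (ss / dof) / ms_res
        return float(f), float(stats.f.sf(f, dof, df_res))

    geno_f, geno_p = f_and_p(ss_g, df_g)
    stage_f, stage_p = f_and_p(ss_s, df_s)
    inter_f, inter_p = f_and_p(ss_gs, df_gs)

    post_dome = stages  # dome itself is excluded above
    per_stage: dict[str, float] = {}
    for stage in post_dome:
        m = [float(mean_gs[(g, stage)]) for g in genotypes]
        diff = m[1] - m[0] if genotypes == ["mut", "wt"] else m[0] - m[1]
        if ms_res <= 1e-12:
            p = 1.0 if abs(diff) <= 1e-12 else 0.0
        else:
            t = diff / np.sqrt(ms_res * 2.0 / n)
            p = 2.0 * float(stats.t.sf(abs(t), df_res))
        per_stage[stage] = min(1.0, p * len(post_dome))

    return {
        "genotype_F": geno_f,
        "genotype_p": geno_p,
        "stage_F": stage_f,
        "stage_p": stage_p,
        "interaction_F": inter_f,
        "interaction_p": inter_p,
        "per_stage": per_stage,
        "ss": {
            "genotype": ss_g,
            "stage": ss_s,
            "interaction": ss_gs,
            "residual": ss_res,
            "total": ss_total,
        },
        "df_residual": df_res,
    }


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def _mean_ct(df: pd.DataFrame) -> pd.Series:
    cts = df[["ct1", "ct2", "ct3"]].to_numpy(dtype=float)
    return pd.Series(cts.mean(axis=1), index=df.index)


def ddct_per_sample(
    measurements: pd.DataFrame,
    housekeeping_gene: str,
    calibrator_sample: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-sample ΔCT, ΔΔCT and RQ for every non-housekeeping gene."""
    df = measurements.copy()
    df["mean_ct"] = _mean_ct(df)
    hk = df[df["gene"] == housekeeping_gene].set_index("sample")["mean_ct"]
    missing = set(df["sample"]) - set(hk.index)
    if missing:
        raise ValueError(f"housekeeping gene missing for samples: {sorted(missing)}")
    if calibrator_sample not in set(df["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")
    out = df[df["gene"] != housekeeping_gene].copy()
    out["delta_ct"] = out["mean_ct"] - out["sample"].map(hk).to_numpy()
    cal = out[out["sample"] == calibrator_sample].set_index("gene")["delta_ct"]
    out["delta_delta_ct"] = out["delta_ct"] - out["gene"].map(cal).to_numpy()
    if out["delta_delta_ct"].isna().any():
        bad = sorted(out.loc[out["delta_delta_ct"].isna(), "gene"].unique())
        raise ValueError(f"calibrator sample lacks genes: {bad}")
    out["rq"] = efficiency ** (-out["delta_delta_ct"])
    return out[["sample", "genotype", "gene", "delta_ct", "delta_delta_ct", "rq"]]


def ddct(
    measurements: pd.DataFrame,
    housekeeping_gene: str = "actb1",
    calibrator_sample: str = "wt_1",
    efficiency: float = 2.0,
) -> list[RelativeQuantity]:
    """Group-level relative quantities: mean RQ ± SEM per gene x genotype."""
    per_sample = ddct_per_sample(
        measurements, housekeeping_gene, calibrator_sample, efficiency
    )
    out = []
    for (gene, group), sub in per_sample.groupby(["gene", "genotype"], sort=True):
        rqs = sub["rq"].to_numpy(dtype=float)
        rq = float(rqs.mean())
        sem = float(rqs.std(ddof=1) / np.sqrt(len(rqs))) if len(rqs) > 1 else 0.0
        out.append(
            RelativeQuantity(
                gene=str(gene), group=str(group), rq=rq, log2_rq=float(np.log2(rq)), sem=sem
            )
        )
    return out


# ---------------------------------------------------------------------------
# generic comparisons
# ---------------------------------------------------------------------------

def compare_means(a, b, welch: bool = False) -> GroupComparison:
    """Two-sided unpaired t-test between two samples of measurements."""
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("compare_means needs n >= 2 per group")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if xa.mean() == xb.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if xa.mean() > xb.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return GroupComparison(
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_a=int(xa.size),
        n_b=int(xb.size),
    )
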