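"""Ct → efficiency-corrected relative quantities.

The amplification efficiency E of each primer pair (per-cycle template
multiplication factor, ideally 2) is estimated from its dilution curve by
ordinary least squares of Ct on log10(dilution): E = 10**(-1/slope). A
reaction's relative template abundance then follows from its Ct as
log-quantity = -Ct * ln(E), on an arbitrary per-assay scale that cancels in
any within-assay ratio (IP/input). Technical replicates are aggregated in
log space (equivalently, mean Ct), because Ct noise is approximately
additive in cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

#: efficiency range outside which an assay is flagged (not rejected)
EFFICIENCY_RANGE = (1.5, 2.3)

#: QC defaults: post-preamplification Ct ceiling and replicate-scatter ceiling
DEFAULT_MAX_CT = 28.0
DEFAULT_MAX_TECH_SD = 0.5


@dataclass(frozen=True)
class AssayEfficiency:
    """Fitted amplification efficiency of one primer pair."""

    assay_id: str
    efficiency: float          # amplification factor per cycle
    slope: float               # cycles per log10 dilution (negative)
    r_squared: float
    n_points: int

    @property
    def flagged_out_of_range(self) -> bool:
        lo, hi = EFFICIENCY_RANGE
        return not (lo <= self.efficiency <= hi)


@dataclass(frozen=True)
class Quantity:
    """Efficiency-corrected relative abundance of one sample x assay group."""

    sample_id: str
    assay_id: str
    log_quantity: float        # natural-log relative abundance, per-assay scale
    se_log: float
    n_tech: int


def estimate_efficiency(points: pd.DataFrame, assay_id: str | None = None) -> AssayEfficiency:
    """Fit E = 10**(-1/slope) from a dilution curve for one assay.

    Parameters
    ----------
    points
        Rows of one assay's dilution series with columns ``dilution`` and
        ``ct`` (missing Cts are dropped). At least 3 distinct dilution
        levels are required; the fitted slope must be negative (more
        template must lower the Ct).
    """
    pts = points.dropna(subset=["ct"])
    if assay_id is None:
        ids = pts["assay_id"].unique() if "assay_id" in pts.columns else ["?"]
        if len(ids) != 1:
            raise ValueError(f"dilution points span multiple assays: {sorted(ids)}")
        assay_id = str(ids[0])
    levels = pts["dilution"].nunique()
    if levels < 3:
        raise ValueError(f"assay '{assay_id}': need >=3 distinct dilution levels, got {levels}")

    x = np.log10(pts["dilution"].to_numpy(float))
    y = pts["ct"].to_numpy(float)
    fit = scipy.stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"assay '{assay_id}': non-negative dilution-curve slope ({fit.slope:.3g}); "
            "amplification must reduce Ct with template concentration"
        )
    eff = 10.0 ** (-1.0 / fit.slope)
    return AssayEfficiency(
        assay_id=assay_id,
        efficiency=float(eff),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        n_points=int(len(y)),
    )


def estimate_efficiencies(dilution: pd.DataFrame) -> dict[str, AssayEfficiency]:
    """Fit every assay present in a dilution-series table."""
    return {
        str(assay): estimate_efficiency(grp, assay_id=str(assay))
        for assay, grp in dilution.groupby("assay_id", sort=True)
    }


def qc_filter(
    records: pd.DataFrame,
    max_ct: float = DEFAULT_MAX_CT,
    max_tech_sd: float = DEFAULT_MAX_TECH_SD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unusable reactions and unreliable sample x assay groups.

    Individual reactions that are flagged or have a missing Ct are dropped
    first; then whole groups are dropped when their technical-replicate Ct
    standard deviation exceeds ``max_tech_sd`` or their mean Ct exceeds
    ``max_ct`` (too close to the no-template noise floor). Returns the kept
    records plus a QC report with one row per dropped group and the rule
    that fired (``missing``, ``tech_sd`` or ``max_ct``). Filtering is total:
    an empty result is legal.
    """
    usable = records[~records["flagged"] & records["ct"].notna()]
    report_rows = []

    kept_groups = []
    all_keys = records.groupby(["sample_id", "assay_id"], sort=True)
    usable_by_key = dict(iter(usable.groupby(["sample_id", "assay_id"], sort=True)))
    for key, _ in all_keys:
        grp = usable_by_key.get(key)
        if grp is None or grp.empty:
            report_rows.append((*key, "missing", 0, np.nan, np.nan))
            continue
        mean_ct = grp["ct"].mean()
        sd_ct = grp["ct"].std(ddof=1) if len(grp) > 1 else 0.0
        if sd_ct > max_tech_sd:
            report_rows.append((*key, "tech_sd", len(grp), mean_ct, sd_ct))
        elif mean_ct > max_ct:
            report_rows.append((*key, "max_ct", len(grp), mean_ct, sd_ct))
        else:
            kept_groups.append(grp)

    kept = pd.concat(kept_groups, ignore_index=True) if kept_groups else usable.iloc[0:0].copy()
    report = pd.DataFrame(
        report_rows, columns=["sample_id", "assay_id", "rule", "n_usable", "mean_ct", "sd_ct"]
    )
    return kept, report


def relative_quantity(ct_group: pd.DataFrame, eff: AssayEfficiency) -> Quantity:
    """Efficiency-corrected relative abundance for one sample x assay group.

    Per reaction, log-quantity = -Ct * ln(E); the group value is the mean
    over technical replicates with se = sd/sqrt(n). The scale is arbitrary
    per assay and is anchored only by ratios between samples.
    """
    if eff.efficiency <= 1:
        raise ValueError(f"assay '{eff.assay_id}': efficiency must exceed 1, got {eff.efficiency}")
    cts = ct_group["ct"].dropna().to_numpy(float)
    if cts.size == 0:
        raise ValueError("relative_quantity: no usable Ct values in group")
    log_e = np.log(eff.efficiency)
    logq = -cts * log_e
    se = float(np.std(logq, ddof=1) / np.sqrt(len(logq))) if len(logq) > 1 else np.nan
    return Quantity(
        sample_id=str(ct_group["sample_id"].iloc[0]),
        assay_id=str(ct_group["assay_id"].iloc[0]),
        log_quantity=float(np.mean(logq)),
        se_log=se,
        n_tech=int(len(logq)),
    )


def quantify_table(
    kept: pd.DataFrame, efficiencies: dict[str, AssayEfficiency]
) -> pd.DataFrame:
    """Apply :func:`relative_quantity` to every sample x assay group.

    Groups whose assay lacks a fitted efficiency are skipped (they cannot be
    corrected); the result is a tidy table of log quantities.
    """
    rows = []
    for (sample, assay), grp in kept.groupby(["sample_id", "assay_id"], sort=True):
        eff = efficiencies.get(str(assay))
        if eff is None:
            continue
        q = relative_quantity(grp, eff)
        rows.append((q.sample_id, q.assay_id, q.log_quantity, q.se_log, q.n_tech, eff.flagged_out_of_range))
    return pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "log_quantity", "se_log", "n_tech", "eff_flagged"]
    )


def technical_ci(q: Quantity, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval on the natural scale.

    exp(log_quantity ± t_{1-α/2, n-1} · se); asymmetric on the natural scale.
    Undefined (NaN, NaN) for a single technical replicate.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if q.n_tech < 2 or not np.isfinite(q.se_log):
        return (np.nan, np.nan)
    tq = scipy.stats.t.ppf(0.5 + level / 2, df=q.n_tech - 1)
    half = tq * q.se_log
    return (float(np.exp(q.log_quantity - half)), float(np.exp(q.log_quantity + half)))
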