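"""The closed-loop index: a lower bound on cap-to-tail loop prevalence.

In the closed-loop model of translation initiation, eIF4E (bound to the 5'
cap), eIF4G and PAB1 (bound to the 3' poly(A) tail) bridge the two ends of
an mRNA. After controlled RNase digestion, pulling down a tagged factor
retains only the mRNA fragments physically attached to its complex: the
factor's own end (the *proximal* end: 5' for eIF4E/eIF4G, 3' for PAB1) is
always retained, while the *opposite* (distal) end co-purifies only if the
molecule was in the looped configuration — and then only with the bridging
complex's co-capture efficiency.

The index is therefore

    index = (distal-end enrichment) / (proximal-end enrichment)

and is a *lower bound* on the fraction of factor-engaged molecules in the
closed loop: incomplete co-capture and fragmentation losses can only shrink
the distal signal. An index above 1 carries no extra biological meaning and
is flagged rather than truncated.

This module also hosts the comparative statistics: biological-replicate
aggregation, condition comparisons with multiple-testing correction, the
between-transcript fold range, a variance-explained regression, and
covariate correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .enrichment import REFERENCE_END, region_class_means

_OPPOSITE = {"five_prime": "three_prime", "three_prime": "five_prime"}


def closed_loop_index(profile: pd.DataFrame, background_subtract: bool = False) -> dict:
    """Distal/proximal end-enrichment ratio for one profile.

    ``profile`` holds one transcript x factor x condition x bio_rep worth of
    enrichment rows (columns ``region_class``, ``raw`` and/or
    ``normalized``). Both end classes must be present. With
    ``background_subtract`` the mean internal-amplicon enrichment is
    removed from both ends first ((distal - internal)/(proximal -
    internal)); off by default because internal amplicons serve as a visual
    baseline, not a stated correction.
    """
    factor = str(profile["factor"].iloc[0])
    transcript = str(profile["transcript_id"].iloc[0])
    proximal_class = REFERENCE_END.get(factor)
    if proximal_class is None:
        raise ValueError(f"transcript '{transcript}': unknown factor '{factor}'")
    distal_class = _OPPOSITE[proximal_class]

    value = "normalized" if "normalized" in profile.columns else "raw"
    means = region_class_means(profile, value=value)
    for cls in (proximal_class, distal_class):
        if cls not in means.index:
            raise ValueError(f"transcript '{transcript}': missing {cls} assay, cannot form index")
    proximal = float(means[proximal_class])
    distal = float(means[distal_class])
    if background_subtract:
        if "internal" not in means.index:
            raise ValueError(f"transcript '{transcript}': no internal assay for background subtraction")
        bg = float(means["internal"])
        proximal, distal = proximal - bg, distal - bg
    if proximal <= 0 or distal <= 0:
        raise ValueError(
            f"transcript '{transcript}': nonpositive end enrichment (proximal={proximal:.4g}, "
            f"distal={distal:.4g}); index undefined"
        )

    # log-scale propagation from the per-amplicon log standard errors
    se_log = np.nan
    if "se_log" in profile.columns:
        parts = []
        for cls in (proximal_class, distal_class):
            sub = profile[profile["region_class"] == cls]
            if sub["se_log"].notna().all():
                parts.append((sub["se_log"] ** 2).mean() / len(sub))
        if len(parts) == 2:
            se_log = float(np.sqrt(sum(parts)))

    return {
        "transcript_id": transcript,
        "factor": factor,
        "condition": str(profile["condition"].iloc[0]),
        "bio_rep": int(profile["bio_rep"].iloc[0]),
        "index": distal / proximal,
        "se_log": se_log,
        "proximal": proximal,
        "distal": distal,
    }


def index_table(enr: pd.DataFrame, background_subtract: bool = False) -> pd.DataFrame:
    """Closed-loop index for every profile in an enrichment table.

    Profiles that lack an end class are skipped (they cannot support the
    estimator); everything else is one row per transcript x factor x
    condition x biological replicate.
    """
    rows = []
    for _, grp in enr.groupby(["transcript_id", "factor", "condition", "bio_rep"], sort=True):
        try:
            rows.append(closed_loop_index(grp, background_subtract=background_subtract))
        except ValueError:
            continue
    return pd.DataFrame(rows)


def aggregate_biological(indices: pd.DataFrame) -> pd.DataFrame:
    """Mean index and SEM over biological replicates.

    One output row per transcript x factor x condition with the replicate
    mean, sem = sd/sqrt(n) (missing for a single replicate), the replicate
    count, and the prevalence lower bound: the index as a fraction, with an
    ``over_unity`` flag instead of truncation when sampling noise pushes it
    above 1.
    """
    rows = []
    for (transcript, factor, condition), grp in indices.groupby(
        ["transcript_id", "factor", "condition"], sort=True
    ):
        vals = grp["index"].to_numpy(float)
        mean = float(vals.mean())
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(
            {
                "transcript_id": transcript,
                "factor": factor,
                "condition": condition,
                "index": mean,
                "sem": sem,
                "n_bio": len(vals),
                "prevalence_lower_bound": mean,
                "over_unity": mean > 1,
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    indices: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    factor: str | None = None,
    correction: str = "holm",
) -> tuple[dict, pd.DataFrame]:
    """Condition comparison: global paired shift plus per-transcript tests.

    Global test: one-tailed paired t-test across transcripts on the
    replicate-mean indices, direction B > A; refused below 3 common
    transcripts. Per-transcript: Welch two-sample t-test on biological
    replicates (needs >=2 per side), with p-values corrected across
    transcripts (Holm by default, ``correction='fdr_bh'`` for
    Benjamini-Hochberg).
    """
    idx = indices if factor is None else indices[indices["factor"] == factor]
    a = idx[idx["condition"] == condition_a]
    b = idx[idx["condition"] == condition_b]
    common = sorted(set(a["transcript_id"]) & set(b["transcript_id"]))
    if len(common) < 3:
        raise ValueError(
            f"global shift test refused: only {len(common)} transcript(s) measured in both "
            f"'{condition_a}' and '{condition_b}' (need >=3)"
        )

    mean_a = a.groupby("transcript_id")["index"].mean().loc[common]
    mean_b = b.groupby("transcript_id")["index"].mean().loc[common]
    diffs = (mean_b - mean_a).to_numpy(float)
    if np.allclose(diffs.std(ddof=1), 0.0):
        # degenerate: identical shifts carry no evidence either way
        t_stat, p_global = 0.0, 0.5
        if not np.allclose(diffs.mean(), 0.0):
            t_stat = np.inf * np.sign(diffs.mean())
            p_global = 0.0 if diffs.mean() > 0 else 1.0
    else:
        t_stat, p_global = scipy.stats.ttest_rel(mean_b, mean_a, alternative="greater")
    global_test = {
        "condition_a": condition_a,
        "condition_b": condition_b,
        "t": float(t_stat),
        "p": float(p_global),
        "n_transcripts": len(common),
        "direction": f"{condition_b} > {condition_a}",
    }

    rows = []
    for transcript in common:
        xa = a.loc[a["transcript_id"] == transcript, "index"].to_numpy(float)
        xb = b.loc[b["transcript_id"] == transcript, "index"].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            continue
        va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
        if va + vb > 0:
            t, p = scipy.stats.ttest_ind(xb, xa, equal_var=False)
            # Welch-Satterthwaite degrees of freedom
            df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
        else:
            # degenerate replicates: no within-condition variance
            equal = np.isclose(xa.mean(), xb.mean())
            t = 0.0 if equal else np.inf * np.sign(xb.mean() - xa.mean())
            p = 1.0 if equal else 0.0
            df = len(xa) + len(xb) - 2
        rows.append((transcript, float(t), float(df), float(p)))
    per_transcript = pd.DataFrame(rows, columns=["transcript_id", "t", "df", "p_raw"])
    if len(per_transcript):
        _, corrected, _, _ = multipletests(per_transcript["p_raw"], method=correction)
        per_transcript["p_corrected"] = corrected
    else:
        per_transcript["p_corrected"] = []
    per_transcript["method"] = correction
    return global_test, per_transcript


def fold_range(estimates: pd.DataFrame) -> tuple[str, str, float]:
    """Span of replicate-mean indices: (max transcript, min transcript, ratio)."""
    if len(estimates) < 2:
        raise ValueError("fold_range needs >=2 transcripts")
    if (estimates["index"] <= 0).any():
        raise ValueError("fold_range: nonpositive mean index")
    by = estimates.set_index("transcript_id")["index"]
    hi, lo = by.idxmax(), by.idxmin()
    return str(hi), str(lo), float(by[hi] / by[lo])


def variance_explained(x: pd.Series, y: pd.Series) -> dict:
    """How much of y's between-transcript variance does x explain?

    Simple least squares of y on x over paired transcripts; reports R²,
    the residual share 1-R², slope and intercept. Used to ask whether
    PAB1 3'-end recovery (a proxy for poly(A)-proximity artefacts) accounts
    for the spread of eIF4E 3'-end enrichment.
    """
    pair = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    if len(pair) < 3:
        raise ValueError(f"variance_explained needs >=3 paired transcripts, got {len(pair)}")
    if np.isclose(pair["x"].var(ddof=0), 0):
        raise ValueError("variance_explained: zero variance in x")
    fit = scipy.stats.linregress(pair["x"], pair["y"])
    r2 = float(fit.rvalue**2)
    return {
        "r_squared": r2,
        "residual_share": 1 - r2,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(pair)),
    }


def covariate_correlation(
    estimates: pd.DataFrame, covariates: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Correlate the per-transcript index with each numeric covariate.

    Spearman by default (monotone association, robust to the index's skew),
    Pearson available. Missing covariate cells are pairwise-deleted; the
    overlap n is reported per covariate. At least 3 overlapping transcripts
    are required overall.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method '{method}'")
    idx = estimates.set_index("transcript_id")["index"]
    cov = covariates.set_index("transcript_id")
    common = idx.index.intersection(cov.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} transcript(s) overlap between estimates and covariates")
    rows = []
    for col in cov.columns:
        pair = pd.concat([idx.loc[common], cov.loc[common, col]], axis=1).dropna()
        if len(pair) < 3:
            rows.append((col, np.nan, np.nan, len(pair)))
            continue
        if method == "spearman":
            rho, p = scipy.stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        else:
            rho, p = scipy.stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append((col, float(rho), float(p), len(pair)))
    return pd.DataFrame(rows, columns=["covariate", "correlation", "p", "n"])
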