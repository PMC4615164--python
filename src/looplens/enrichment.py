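"""IP/Input enrichment per amplicon and the two normalization schemes.

A positional enrichment profile asks: which parts of a transcript co-purify
with a tagged factor? The raw statistic per amplicon is the IP/Input
abundance ratio, which cancels the arbitrary per-assay scale exactly.
Two normalizations make profiles comparable:

``within_transcript``
    each amplicon's ratio divided by the arithmetic mean ratio over all of
    that transcript's amplicons (one divisor per transcript x factor x
    condition x biological replicate). The normalized profile of every
    transcript then averages to exactly 1.

``cross_transcript``
    all ratios divided by the mean *reference-end* ratio across transcripts
    (3' end for PAB1, 5' end for eIF4E/eIF4G; one divisor per factor x
    condition x biological replicate). This preserves between-transcript
    differences in end enrichment while anchoring the factor's own binding
    site at 1 on average.

Both schemes divide a profile by a scalar, so any within-transcript ratio
(in particular the 3'/5' closed-loop index) is identical under either mode.
Uncertainty is propagated on the log scale and converted to the natural
scale only for reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

#: the amplicon class at the factor's own binding site (the proximal end)
REFERENCE_END = {"eIF4E": "five_prime", "eIF4G": "five_prime", "PAB1": "three_prime"}

NORMALIZATION_MODES = ("within_transcript", "cross_transcript")


def ip_input_ratio(log_q_ip: float, log_q_input: float,
                   se_ip: float = np.nan, se_input: float = np.nan) -> tuple[float, float]:
    """Raw enrichment of one assay: exp(log difference), se on log scale.

    The per-assay quantity scale cancels exactly in the difference. Standard
    errors combine in quadrature on the log scale.
    """
    ratio = float(np.exp(log_q_ip - log_q_input))
    se = float(np.sqrt(np.nan_to_num(se_ip) ** 2 + np.nan_to_num(se_input) ** 2))
    return ratio, se


def enrichment_table(
    quantities: pd.DataFrame,
    samples: pd.DataFrame,
    assays: pd.DataFrame,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Raw IP/Input enrichment for every IP sample x assay with a usable input.

    Joins each IP sample's quantities to its matched input sample (the
    retained aliquot of the same digestion) on ``assay_id``, so the per-assay
    scale cancels. Assays measured in the IP but missing from the matched
    input (or vice versa) are dropped. Confidence bounds use a normal
    quantile on the log scale.
    """
    meta = samples.set_index("sample_id")
    anno = assays.set_index("assay_id")
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2)

    q_by_sample = dict(iter(quantities.groupby("sample_id")))
    rows = []
    for _, ip in samples[samples["fraction"] == "IP"].iterrows():
        qi = q_by_sample.get(ip["sample_id"])
        qn = q_by_sample.get(ip["input_pair"])
        if qi is None or qn is None:
            continue
        merged = qi.merge(qn, on="assay_id", suffixes=("_ip", "_in"))
        for _, r in merged.iterrows():
            ratio, se = ip_input_ratio(
                r["log_quantity_ip"], r["log_quantity_in"], r["se_log_ip"], r["se_log_in"]
            )
            a = anno.loc[r["assay_id"]]
            log_ratio = np.log(ratio)
            rows.append(
                (
                    a["transcript_id"], ip["factor"], ip["condition"], int(ip["bio_rep"]),
                    r["assay_id"], a["region_class"], ratio, se,
                    float(np.exp(log_ratio - z * se)), float(np.exp(log_ratio + z * se)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "factor", "condition", "bio_rep",
            "assay_id", "region_class", "raw", "se_log", "ci_low", "ci_high",
        ],
    )


_PROFILE_KEY = ["transcript_id", "factor", "condition", "bio_rep"]


def normalize_within_transcript(enr: pd.DataFrame) -> pd.DataFrame:
    """Divide each profile by the arithmetic mean of its own amplicon ratios.

    Requires >=2 assays per profile and strictly positive raw ratios. The
    normalized values of each profile average to 1 by construction.
    """
    if (enr["raw"] <= 0).any():
        bad = enr.loc[enr["raw"] <= 0, "assay_id"].tolist()
        raise ValueError(f"nonpositive raw enrichment for assay(s) {bad}")
    out = enr.copy()
    divisor = out.groupby(_PROFILE_KEY)["raw"].transform("mean")
    counts = out.groupby(_PROFILE_KEY)["raw"].transform("size")
    if (counts < 2).any():
        bad = out.loc[counts < 2, "transcript_id"].unique().tolist()
        raise ValueError(f"within-transcript normalization needs >=2 assays; transcript(s) {bad}")
    out["normalized"] = out["raw"] / divisor
    out["ci_low"] = out["ci_low"] / divisor
    out["ci_high"] = out["ci_high"] / divisor
    out["normalization_mode"] = "within_transcript"
    return out


def normalize_across_transcripts(enr: pd.DataFrame, geometric: bool = False) -> pd.DataFrame:
    """Divide all profiles of a factor by the mean reference-end ratio.

    The divisor is the arithmetic mean (geometric if requested) over
    transcripts of the factor's reference-end raw enrichment, computed
    separately per factor x condition x biological replicate. Transcripts
    lacking a reference-end assay are excluded with a warning. When a
    transcript has several reference-end amplicons, their mean enters the
    divisor once.
    """
    import warnings

    if (enr["raw"] <= 0).any():
        raise ValueError("nonpositive raw enrichment")
    parts = []
    for (factor, condition, bio_rep), grp in enr.groupby(["factor", "condition", "bio_rep"], sort=True):
        ref_class = REFERENCE_END.get(factor)
        if ref_class is None:
            raise ValueError(f"no reference end defined for factor '{factor}'")
        ref = grp[grp["region_class"] == ref_class]
        have_ref = set(ref["transcript_id"])
        lacking = set(grp["transcript_id"]) - have_ref
        if lacking:
            warnings.warn(
                f"{factor}/{condition}/rep{bio_rep}: transcript(s) {sorted(lacking)} lack a "
                f"{ref_class} assay and are excluded from cross-transcript normalization"
            )
            grp = grp[grp["transcript_id"].isin(have_ref)]
        per_transcript = ref.groupby("transcript_id")["raw"].mean()
        divisor = float(scipy.stats.gmean(per_transcript)) if geometric else float(per_transcript.mean())
        sub = grp.copy()
        sub["normalized"] = sub["raw"] / divisor
        sub["ci_low"] = sub["ci_low"] / divisor
        sub["ci_high"] = sub["ci_high"] / divisor
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True) if parts else enr.iloc[0:0].copy()
    out["normalization_mode"] = "cross_transcript"
    return out


def region_class_means(profile: pd.DataFrame, value: str = "normalized") -> pd.Series:
    """Collapse one profile's amplicons to per-region-class mean values.

    A transcript's ends are summarized as single quantities even when probed
    by several amplicons of the same class.
    """
    return profile.groupby("region_class")[value].mean()
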