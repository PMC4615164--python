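"""End-to-end orchestration: quantify → enrichment → closed-loop statistics.

The pipeline consumes the five interchange tables (Ct table, dilution
series, assay annotations, sample sheet, optional covariates), either from
a directory on disk or as in-memory DataFrames, and produces tidy result
tables plus a JSON run manifest recording every analysis choice.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass
from datetime import datetime, timezone

import pandas as pd

from . import __version__, closedloop, enrichment, qpcr_io, quantify

#: file names of the interchange tables inside a dataset directory
DATASET_FILES = {
    "ct": "ct_table.csv",
    "dilution": "dilution_series.csv",
    "assays": "assay_annotation.csv",
    "samples": "sample_sheet.csv",
    "covariates": "covariates.csv",   # optional
    "truth": "truth.csv",             # optional (simulated data only)
    "expected": "expected_enrichment.csv",
}


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis choices recorded in the run manifest."""

    max_ct: float = quantify.DEFAULT_MAX_CT
    max_tech_sd: float = quantify.DEFAULT_MAX_TECH_SD
    ci_level: float = 0.95
    normalization: str = "within_transcript"   # or "cross_transcript"
    correction: str = "holm"                   # or "fdr_bh"
    background_subtract: bool = False
    efficiency_mode: str = "fitted"            # or "ideal" (assume E = 2)
    baseline_condition: str | None = None      # reference for condition comparisons


def write_dataset(tables: dict[str, pd.DataFrame], outdir: str | os.PathLike) -> None:
    """Write simulator output tables in the interchange formats."""
    os.makedirs(outdir, exist_ok=True)
    for key, df in tables.items():
        fname = DATASET_FILES.get(key, f"{key}.csv")
        qpcr_io.write_results(df, os.path.join(outdir, fname))


def read_dataset(indir: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read the interchange tables of a dataset directory (validated)."""
    p = lambda name: os.path.join(indir, DATASET_FILES[name])
    tables = {
        "ct": qpcr_io.read_ct_table(p("ct")),
        "dilution": qpcr_io.read_dilution_series(p("dilution")),
        "assays": qpcr_io.read_assay_annotation(p("assays")),
        "samples": qpcr_io.read_sample_sheet(p("samples")),
    }
    if os.path.exists(p("covariates")):
        tables["covariates"] = qpcr_io.read_covariates(p("covariates"))
    return tables


def analyze_tables(
    tables: dict[str, pd.DataFrame], options: AnalysisOptions = AnalysisOptions()
) -> dict:
    """Run the full analysis on in-memory tables.

    Returns a dict with ``efficiencies``, ``qc_report``, ``quantities``,
    ``profiles`` (normalized enrichment), ``indices`` (per biological
    replicate), ``results`` (aggregated closed-loop estimates),
    ``global_tests``/``tests`` (condition comparisons, when >=2 conditions),
    and ``summary`` (fold range, variance explained, covariate correlations).
    """
    ct, samples, assays = tables["ct"], tables["samples"], tables["assays"]
    if not (samples["fraction"] == "IP").any():
        raise ValueError("no IP samples in sample sheet")

    # 1. per-assay amplification efficiency
    if options.efficiency_mode == "fitted":
        effs = quantify.estimate_efficiencies(tables["dilution"])
    elif options.efficiency_mode == "ideal":
        effs = {
            str(a): quantify.AssayEfficiency(str(a), 2.0, -1.0 / 0.3010299956639812, 1.0, 0)
            for a in assays["assay_id"]
        }
    else:
        raise ValueError(f"unknown efficiency_mode '{options.efficiency_mode}'")
    eff_df = pd.DataFrame(
        [
            (e.assay_id, e.efficiency, e.slope, e.r_squared, e.n_points, e.flagged_out_of_range)
            for e in effs.values()
        ],
        columns=["assay_id", "efficiency", "slope", "r_squared", "n_points", "flagged_out_of_range"],
    )

    # 2. reaction QC and efficiency-corrected quantities
    kept, qc_report = quantify.qc_filter(ct, max_ct=options.max_ct, max_tech_sd=options.max_tech_sd)
    if kept.empty:
        raise ValueError("no reactions left after QC filtering")
    quantities = quantify.quantify_table(kept, effs)

    # 3. IP/input enrichment and normalization
    raw_enr = enrichment.enrichment_table(quantities, samples, assays, ci_level=options.ci_level)
    if raw_enr.empty:
        raise ValueError("no IP/input pairs with shared assays after QC")
    if options.normalization == "within_transcript":
        profiles = enrichment.normalize_within_transcript(raw_enr)
    elif options.normalization == "cross_transcript":
        profiles = enrichment.normalize_across_transcripts(raw_enr)
    else:
        raise ValueError(f"unknown normalization '{options.normalization}'")

    # 4. closed-loop index per replicate, then biological aggregation
    indices = closedloop.index_table(profiles, background_subtract=options.background_subtract)
    if indices.empty:
        raise ValueError("no transcript provided both end assays; closed-loop index undefined")
    results = closedloop.aggregate_biological(indices)

    out: dict = {
        "efficiencies": eff_df,
        "qc_report": qc_report,
        "quantities": quantities,
        "profiles": profiles,
        "indices": indices,
        "results": results,
    }

    # 5. condition comparisons (per factor, against the baseline condition)
    conditions = list(dict.fromkeys(samples["condition"]))
    if len(conditions) >= 2:
        baseline = options.baseline_condition or conditions[0]
        glob_rows, per_parts = [], []
        for factor in indices["factor"].unique():
            for cond in conditions:
                if cond == baseline:
                    continue
                try:
                    glob, per = closedloop.compare_conditions(
                        indices, baseline, cond, factor=factor, correction=options.correction
                    )
                except ValueError:
                    continue
                glob["factor"] = factor
                glob_rows.append(glob)
                per.insert(0, "factor", factor)
                per.insert(1, "condition", cond)
                per_parts.append(per)
        if glob_rows:
            out["global_tests"] = pd.DataFrame(glob_rows)
        if per_parts:
            out["tests"] = pd.concat(per_parts, ignore_index=True)

    # 6. cross-sectional summaries
    summary: dict = {}
    for (factor, cond), grp in results.groupby(["factor", "condition"]):
        if len(grp) >= 2 and (grp["index"] > 0).all():
            hi, lo, ratio = closedloop.fold_range(grp)
            summary.setdefault("fold_range", []).append(
                {"factor": factor, "condition": cond, "max_transcript": hi,
                 "min_transcript": lo, "ratio": ratio}
            )

    # does PAB1 3'-end recovery explain the spread of cap-side 3' enrichment?
    end3 = (
        profiles[profiles["region_class"] == "three_prime"]
        .groupby(["transcript_id", "factor"])["normalized"].mean().unstack("factor")
    )
    cap = next((f for f in ("eIF4E", "eIF4G") if f in end3.columns), None)
    if cap is not None and "PAB1" in end3.columns:
        try:
            summary["variance_explained"] = closedloop.variance_explained(
                end3["PAB1"], end3[cap]
            )
        except ValueError:
            pass

    if "covariates" in tables:
        cap_est = results[results["factor"].isin(("eIF4E", "eIF4G"))]
        if len(cap_est):
            try:
                summary["covariate_correlation"] = closedloop.covariate_correlation(
                    cap_est.groupby("transcript_id", as_index=False)["index"].mean(),
                    tables["covariates"],
                ).to_dict(orient="records")
            except ValueError:
                pass
    out["summary"] = summary
    return out


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    indir: str | os.PathLike,
    outdir: str | os.PathLike,
    options: AnalysisOptions = AnalysisOptions(),
    seed: int | None = None,
    timestamp: bool = True,
) -> dict:
    """Read a dataset directory, analyze it, write results and a manifest."""
    tables = read_dataset(indir)
    out = analyze_tables(tables, options)

    os.makedirs(outdir, exist_ok=True)
    written = {}
    for key in ("efficiencies", "qc_report", "quantities", "profiles", "indices",
                "results", "global_tests", "tests"):
        if key in out:
            path = os.path.join(outdir, f"{key}.csv")
            qpcr_io.write_results(out[key], path)
            written[key] = f"{key}.csv"
    qpcr_io.write_manifest(out["summary"], os.path.join(outdir, "summary.json"))

    manifest = {
        "version": __version__,
        "seed": seed,
        "options": asdict(options),
        "inputs": {
            name: _digest(os.path.join(indir, fname))
            for name, fname in DATASET_FILES.items()
            if os.path.exists(os.path.join(indir, fname))
        },
        "outputs": written,
    }
    if timestamp:
        manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    qpcr_io.write_manifest(manifest, os.path.join(outdir, "manifest.json"))
    return out
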