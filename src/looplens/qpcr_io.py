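"""Readers and writers for the tabular interchange formats of the pipeline.

All tables are tidy UTF-8 CSV/TSV (dialect sniffed from the file extension,
overridable). Columns and conventions:

``ct table``
    ``sample_id, assay_id, tech_rep, ct[, flagged]`` — one qPCR reaction per
    row. A missing Ct is an empty cell (never a sentinel cycle number such as
    0 or 40). ``flagged`` marks reactions that failed upstream instrument QC;
    the column is optional because instrument exports differ.

``assay annotation``
    ``assay_id, transcript_id, start, end, region_class, transcript_length``
    — one amplicon per row. Coordinates are 0-based half-open on the mature
    transcript (5'→3'); ``region_class`` is one of ``five_prime``,
    ``internal``, ``three_prime``. ``dist_to_polyA`` is derived as
    ``transcript_length - end``.

``sample sheet``
    ``sample_id, factor, fraction, condition, bio_rep, input_pair`` — one
    RNA sample per row. ``fraction`` is ``IP`` or ``input``; every IP sample
    must name its matched digested-lysate input in ``input_pair``.

``dilution series``
    ``assay_id, dilution, tech_rep, ct`` — standard-curve reactions, with
    ``dilution`` the relative template concentration (1, 0.25, ...).

``covariates``
    ``transcript_id`` plus arbitrary numeric columns (half-life, ORF length,
    poly(A) length, translational efficiency, ...); missing cells allowed.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REGION_CLASSES = ("five_prime", "internal", "three_prime")
FACTORS = ("eIF4E", "eIF4G", "PAB1", "none")
FRACTIONS = ("IP", "input")

#: maximum amplicon span (nt) in the assay design; exceeding it warns only
MAX_AMPLICON_SPAN = 75


class SchemaError(ValueError):
    """A table violates its declared schema or an invariant."""


@dataclass(frozen=True)
class AssayAnnotation:
    """An amplicon on a transcript, in 0-based half-open coordinates."""

    assay_id: str
    transcript_id: str
    start: int
    end: int
    region_class: str
    transcript_length: int

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def dist_to_polyA(self) -> int:
        """Distance (nt) from the amplicon 3' edge to the transcript end."""
        return self.transcript_length - self.end


def _sniff_sep(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")


def read_ct_table(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read a long-format Ct table.

    Returns a DataFrame with columns ``sample_id, assay_id, tech_rep, ct,
    flagged``. Unparseable Ct cells become missing with ``flagged=True`` (and
    are reported via a warning); empty cells become missing with
    ``flagged=False``. Duplicate ``(sample_id, assay_id, tech_rep)`` keys are
    a hard error.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path, delimiter), dtype=str, keep_default_na=False)
    _require_columns(df, ("sample_id", "assay_id", "tech_rep", "ct"), "ct table")

    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].str.strip(),
            "assay_id": df["assay_id"].str.strip(),
            "tech_rep": pd.to_numeric(df["tech_rep"], errors="raise").astype(int),
        }
    )
    raw_ct = df["ct"].str.strip()
    ct = pd.to_numeric(raw_ct, errors="coerce")
    unparseable = ct.isna() & (raw_ct != "") & ~raw_ct.str.lower().isin(("na", "nan"))
    if unparseable.any():
        rows = (unparseable[unparseable].index + 2).tolist()  # 1-based incl. header
        warnings.warn(f"ct table: {int(unparseable.sum())} unparseable Ct cell(s) flagged (file rows {rows})")
    bad = ct.notna() & ((ct <= 0) | ~np.isfinite(ct))
    if bad.any():
        raise SchemaError(f"ct table: {int(bad.sum())} Ct value(s) are non-positive or non-finite")
    out["ct"] = ct

    if "flagged" in df.columns:
        flagged = df["flagged"].str.strip().str.lower().isin(("1", "true", "yes", "fail"))
    else:
        flagged = pd.Series(False, index=df.index)
    out["flagged"] = (flagged | unparseable).to_numpy()

    dup = out.duplicated(["sample_id", "assay_id", "tech_rep"], keep=False)
    if dup.any():
        key = out.loc[dup, ["sample_id", "assay_id", "tech_rep"]].iloc[0].tolist()
        raise SchemaError(f"ct table: duplicated (sample_id, assay_id, tech_rep) key {tuple(key)}")
    if (out["tech_rep"] < 1).any():
        raise SchemaError("ct table: tech_rep must be a positive integer")
    return out


def read_assay_annotation(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read amplicon annotations and derive ``dist_to_polyA``.

    Enforces 0 <= start < end <= transcript_length and the region-class
    vocabulary; an amplicon spanning more than 75 bp is accepted with a
    warning (the assay-design rule is a guideline, not a file invariant).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path, delimiter))
    _require_columns(
        df,
        ("assay_id", "transcript_id", "start", "end", "region_class", "transcript_length"),
        "assay annotation",
    )
    df = df.copy()
    for col in ("start", "end", "transcript_length"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)

    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "assay_id"].tolist()
        raise SchemaError(f"assay annotation: start >= end for assay(s) {bad}")
    if (df["start"] < 0).any() or (df["end"] > df["transcript_length"]).any():
        raise SchemaError("assay annotation: amplicon coordinates outside [0, transcript_length]")
    unknown = set(df["region_class"]) - set(REGION_CLASSES)
    if unknown:
        raise SchemaError(f"assay annotation: unknown region_class {sorted(unknown)}; expected {REGION_CLASSES}")
    dup = df["assay_id"].duplicated(keep=False)
    if dup.any():
        raise SchemaError(f"assay annotation: duplicated assay_id {sorted(set(df.loc[dup, 'assay_id']))}")

    span = df["end"] - df["start"]
    wide = span > MAX_AMPLICON_SPAN
    if wide.any():
        names = df.loc[wide, "assay_id"].tolist()
        warnings.warn(
            f"assay annotation: amplicon(s) {names} span more than {MAX_AMPLICON_SPAN} bp "
            "(design rule: each amplicon spans no more than 75 bp)"
        )
    df["dist_to_polyA"] = df["transcript_length"] - df["end"]
    return df


def read_sample_sheet(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read the sample sheet and resolve IP → input pairings.

    Every IP sample's ``input_pair`` must name an existing input sample with
    the same condition and biological replicate; a dangling or mismatched
    pairing is a hard error.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path, delimiter), dtype=str, keep_default_na=False)
    _require_columns(df, ("sample_id", "factor", "fraction", "condition", "bio_rep"), "sample sheet")
    df = df.copy()
    df["bio_rep"] = pd.to_numeric(df["bio_rep"], errors="raise").astype(int)
    if "input_pair" not in df.columns:
        df["input_pair"] = ""
    df["input_pair"] = df["input_pair"].str.strip()

    unknown = set(df["factor"]) - set(FACTORS)
    if unknown:
        raise SchemaError(f"sample sheet: unknown factor {sorted(unknown)}; expected {FACTORS}")
    unknown = set(df["fraction"]) - set(FRACTIONS)
    if unknown:
        raise SchemaError(f"sample sheet: unknown fraction {sorted(unknown)}; expected {FRACTIONS}")
    if df["sample_id"].duplicated().any():
        raise SchemaError("sample sheet: duplicated sample_id")
    if (df["bio_rep"] < 1).any():
        raise SchemaError("sample sheet: bio_rep must be a positive integer")

    by_id = df.set_index("sample_id")
    for _, row in df[df["fraction"] == "IP"].iterrows():
        pair = row["input_pair"]
        if not pair:
            raise SchemaError(f"sample sheet: IP sample '{row['sample_id']}' has no input_pair")
        if pair not in by_id.index:
            raise SchemaError(f"sample sheet: IP sample '{row['sample_id']}' references absent input '{pair}'")
        ref = by_id.loc[pair]
        if ref["fraction"] != "input":
            raise SchemaError(f"sample sheet: input_pair '{pair}' of '{row['sample_id']}' is not an input sample")
        if ref["condition"] != row["condition"] or int(ref["bio_rep"]) != int(row["bio_rep"]):
            raise SchemaError(
                f"sample sheet: IP sample '{row['sample_id']}' paired with input '{pair}' "
                "from a different condition or biological replicate"
            )
    return df


def read_dilution_series(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read standard-curve reactions (``assay_id, dilution, tech_rep, ct``)."""
    df = pd.read_csv(path, sep=_sniff_sep(path, delimiter))
    _require_columns(df, ("assay_id", "dilution", "tech_rep", "ct"), "dilution series")
    df = df.copy()
    df["dilution"] = pd.to_numeric(df["dilution"], errors="raise")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if (df["dilution"] <= 0).any():
        raise SchemaError("dilution series: dilution must be > 0")
    return df


def read_covariates(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read a per-transcript covariate table; missing cells stay missing."""
    df = pd.read_csv(path, sep=_sniff_sep(path, delimiter))
    _require_columns(df, ("transcript_id",), "covariate table")
    if df["transcript_id"].duplicated().any():
        raise SchemaError("covariate table: duplicated transcript_id")
    for col in df.columns:
        if col != "transcript_id":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_results(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a tidy result table as CSV (round-trip safe for text fields)."""
    df.to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
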