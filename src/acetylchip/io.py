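"""Reading and writing the pipeline's TSV tables and BED tracks.

All tables are tab-delimited with a single header row and "." for missing
values. Writers prepend ``# key=value`` comment lines recording the run
configuration (thresholds, seed) so any output can be traced to the exact
parameters that produced it; readers skip and return those lines. Re-running
a stage with the same config and seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

import io as _io
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import Condition, FormatError, ProbeType, TableParseError

logger = logging.getLogger(__name__)

PROBE_KEY_COLUMNS = ["probe_id", "gene_id", "chromosome", "start", "end", "probe_type"]
ANNOTATION_COLUMNS = ["gene_id", "chromosome", "strand", "tss", "tes"]

_SIGNAL_RE = re.compile(r"^signal_(wt|tg)_(\d+)$")
_PVALUE_RE = re.compile(r"^pvalue_(wt|tg)$")
_CHROM_RE = re.compile(r"^chr(\d+|X|Y|M)$")


def signal_columns(df: pd.DataFrame, condition: Condition) -> list:
    """Replicate log2(IP/WCE) signal columns for a condition, in order."""
    cond = condition.value.lower()
    cols = [c for c in df.columns if _SIGNAL_RE.match(c) and c.split("_")[1] == cond]
    return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))


def pvalue_column(condition: Condition) -> str:
    return f"pvalue_{condition.value.lower()}"


def write_table(df: pd.DataFrame, path, meta: Optional[Dict] = None) -> None:
    """Write a TSV with ``# key=value`` header comments, '.' for missing.

    Float columns are rendered with the shortest round-trip representation so
    a write/read cycle reproduces values bit-exactly.
    """
    path = Path(path)
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = [None if pd.isna(v) else repr(float(v)) for v in df[col]]
    with open(path, "w", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_table(path) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, meta)."""
    path = Path(path)
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["."], keep_default_na=False,
                         dtype=str)
    meta["_n_meta_lines"] = str(len(meta))
    return df, meta


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s): {', '.join(missing)}")


def _to_numeric(df: pd.DataFrame, column: str, n_meta: int, *,
                bounds: Optional[Tuple[float, float]] = None) -> pd.Series:
    """Coerce a column to float; report the file line of the first bad cell."""
    raw = df[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bounds is not None:
        lo, hi = bounds
        bad |= values.notna() & ((values < lo) | (values > hi))
    if bad.any():
        pos = int(np.flatnonzero(bad.to_numpy())[0])
        # meta lines + header line + 1-based data row
        line = n_meta + 2 + pos
        raise TableParseError(
            f"column {column!r}: invalid value {raw.iloc[pos]!r}", line=line)
    # astype parses round-trip exactly (to_numeric does not)
    return raw.astype(float)


def read_probe_table(path) -> pd.DataFrame:
    """Read and validate a probe-level ChIP-chip results table.

    Required columns: probe_id, gene_id, chromosome, start, end, probe_type,
    at least one ``signal_<cond>_<rep>`` column and a ``pvalue_<cond>``
    column per condition. Duplicate probe_ids are rejected; unrecognised
    probe_type strings map to Unknown with a logged warning; p-values must
    lie in [0, 1].
    """
    df, meta = read_table(path)
    n_meta = int(meta["_n_meta_lines"])
    _require_columns(df, PROBE_KEY_COLUMNS, "probe table")

    dup = df["probe_id"].duplicated()
    if dup.any():
        dups = df.loc[dup, "probe_id"].unique()[:5]
        raise FormatError(f"probe table: duplicate probe_id(s): {', '.join(dups)}")

    sig_cols = [c for c in df.columns if _SIGNAL_RE.match(c)]
    pv_cols = [c for c in df.columns if _PVALUE_RE.match(c)]
    if not sig_cols:
        raise FormatError("probe table: missing required column(s): signal_<cond>_<rep>")
    if not pv_cols:
        raise FormatError("probe table: missing required column(s): pvalue_<cond>")

    for col in ("start", "end"):
        df[col] = _to_numeric(df, col, n_meta).astype(int)
    for col in sig_cols:
        df[col] = _to_numeric(df, col, n_meta)
    for col in pv_cols:
        df[col] = _to_numeric(df, col, n_meta, bounds=(0.0, 1.0))

    valid_types = {t.value for t in ProbeType}
    unknown_mask = ~df["probe_type"].isin(valid_types)
    if unknown_mask.any():
        logger.warning("probe table: %d probe(s) with unrecognised probe_type "
                       "mapped to Unknown", int(unknown_mask.sum()))
        df.loc[unknown_mask, "probe_type"] = ProbeType.UNKNOWN.value
    df["gene_id"] = df["gene_id"].where(df["gene_id"].notna(), None)
    return df.reset_index(drop=True)


def write_probe_table(df: pd.DataFrame, path, meta: Optional[Dict] = None) -> None:
    write_table(df, path, meta)


def read_annotation(path) -> pd.DataFrame:
    """Read gene annotation; normalizes coordinates to transcription order.

    Accepts minus-strand genes written either orientation: if strand is '-'
    and tss < tes the two are swapped so tss is always the transcriptional
    start.
    """
    df, meta = read_table(path)
    n_meta = int(meta["_n_meta_lines"])
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    for col in ("tss", "tes"):
        df[col] = _to_numeric(df, col, n_meta).astype(int)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        pos = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise TableParseError(f"annotation: invalid strand {df['strand'].iloc[pos]!r}",
                              line=n_meta + 2 + pos)
    flip = (df["strand"] == "-") & (df["tss"] < df["tes"])
    if flip.any():
        tss = df.loc[flip, "tes"].copy()
        df.loc[flip, "tes"] = df.loc[flip, "tss"]
        df.loc[flip, "tss"] = tss
    if df["gene_id"].duplicated().any():
        raise FormatError("annotation: duplicate gene_id(s)")
    return df.reset_index(drop=True)


def write_annotation(df: pd.DataFrame, path, meta: Optional[Dict] = None) -> None:
    write_table(df[ANNOTATION_COLUMNS], path, meta)


def read_expression_table(path) -> pd.DataFrame:
    """Read a probeset-level expression table.

    Columns: gene_id, probeset_id, then per-sample value columns named
    ``wt_<i>`` and ``tg_<i>``.
    """
    df, meta = read_table(path)
    n_meta = int(meta["_n_meta_lines"])
    _require_columns(df, ["gene_id", "probeset_id"], "expression table")
    sample_cols = [c for c in df.columns
                   if re.match(r"^(wt|tg)_\d+$", c)]
    if not sample_cols:
        raise FormatError("expression table: missing required column(s): "
                          "wt_<i>/tg_<i> sample columns")
    for col in sample_cols:
        df[col] = _to_numeric(df, col, n_meta)
    return df.reset_index(drop=True)


def expression_sample_columns(df: pd.DataFrame, condition: Condition) -> list:
    cond = condition.value.lower()
    cols = [c for c in df.columns if re.match(rf"^{cond}_\d+$", c)]
    return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))


def chromosome_sort_key(name: str) -> Tuple[int, int]:
    m = _CHROM_RE.match(name)
    if not m:
        raise FormatError(f"unsortable chromosome name: {name!r}")
    token = m.group(1)
    if token == "X":
        return (1, 0)
    if token == "Y":
        return (2, 0)
    if token == "M":
        return (3, 0)
    return (0, int(token))


def sort_chromosomes(names: Iterable[str]) -> list:
    names = list(names)
    bad = []
    for n in names:
        try:
            chromosome_sort_key(n)
        except FormatError:
            bad.append(n)
    if bad:
        raise FormatError(f"unsortable chromosome name(s): {', '.join(sorted(set(bad)))}")
    return sorted(names, key=chromosome_sort_key)


def write_bed(probes: pd.DataFrame, bound_probe_ids: Iterable[str],
              condition: Condition, path, meta: Optional[Dict] = None) -> None:
    """Write bound probes for one condition as a BED6 track.

    Coordinates are 0-based half-open. The score column maps the
    replicate-mean log2(IP/WCE) ratio onto 0..1000 as
    round(1000 * min(1, ratio / 3)), clamped below at 0 as BED requires.
    """
    bound = probes[probes["probe_id"].isin(set(bound_probe_ids))].copy()
    sort_chromosomes(probes["chromosome"].unique())
    cols = signal_columns(probes, condition)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write(f'track name="AcH3_bound_{condition.value}" '
                 f'description="AcH3-bound probes ({condition.value})"\n')
        if bound.empty:
            return
        mean_sig = bound[cols].mean(axis=1)
        score = (1000 * np.minimum(1.0, mean_sig / 3.0)).clip(lower=0).round().astype(int)
        bound = bound.assign(score=score, key=bound["chromosome"].map(chromosome_sort_key))
        bound = bound.sort_values(["key", "start"], kind="mergesort")
        for chrom, start, end, pid, sc in zip(
                bound["chromosome"], bound["start"], bound["end"],
                bound["probe_id"], bound["score"]):
            fh.write(f"{chrom}\t{start}\t{end}\t{pid}\t{sc}\t.\n")


def read_truth_table(path) -> pd.DataFrame:
    df, meta = read_table(path)
    n_meta = int(meta["_n_meta_lines"])
    _require_columns(df, ["gene_id", "truly_bound_wt", "truly_bound_tg",
                          "truly_expressed_wt", "truly_expressed_tg"], "truth table")
    for col in ("truly_bound_wt", "truly_bound_tg",
                "truly_expressed_wt", "truly_expressed_tg"):
        df[col] = _to_numeric(df, col, n_meta).astype(bool)
    return df.reset_index(drop=True)
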