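"""Readers and writers for the tabular formats.

Inputs
------
* dot table — one homologous gene pair per row (TSV or CSV, header
  ``target_chr, x, ref_chr, y, ks``); thousands separators such as
  ``"1,089"`` are accepted in numeric fields.
* WGDI blockinfo CSV — per-block rows whose ``block1``/``block2``/``ks``
  columns hold comma-separated aligned lists; expanded to one dot per pair.
* len file — two-column table of chromosome name and length in gene-rank
  units (extra columns, e.g. WGDI's base-pair column, are ignored).

Outputs
-------
``cluster.csv``, ``combine.csv`` and ``result.csv`` with the fixed column
layouts used throughout the package (the two box dialects differ only in
the header of the last two columns).  Numbers are always written as plain
integers, never with thousands separators.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .errors import FormatError, ParameterError
from .model import (
    ChromosomeLengths,
    ClusterBox,
    CombinationRound,
    HomologDot,
    natural_key,
)

__all__ = [
    "read_dot_table",
    "write_dot_table",
    "read_blockinfo",
    "read_len_file",
    "read_box_table",
    "write_box_table",
    "write_result_table",
]

DOT_COLUMNS = ("target_chr", "x", "ref_chr", "y", "ks")
BOX_COLUMNS = ("chr1", "chr2", "id", "l_x", "l_y", "num", "r_x", "r_y")
#: trailing column pair per box-table dialect
DIALECT_TAILS = {"cluster": ("y1-y2", "x1-x2"), "combine": ("∆y", "∆x")}
RESULT_COLUMNS = BOX_COLUMNS + ("Sumy", "Δy", "Δx", "Comro")

# header aliases so any of the three dialects can be read back
_TAIL_ALIASES = {
    "y1-y2": "dy", "x1-x2": "dx",
    "∆y": "dy", "∆x": "dx",  # increment sign
    "Δy": "dy", "Δx": "dx",  # Greek capital delta
    "dy": "dy", "dx": "dx",
    "sumy": "sumy", "comro": "comro",
}


def _as_text(source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8")
    return source.read()


def _sniff_sep(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    return "\t" if "\t" in header else ","


def _ensure_stream(dest):
    """Return (text stream, close_after) for a path or file-like destination."""
    if isinstance(dest, (str, Path)):
        return open(dest, "w", encoding="utf-8", newline=""), True
    return dest, False


def _strip_thousands(series: pd.Series) -> pd.Series:
    return series.astype(str).str.replace(",", "", regex=False).str.strip()


def _numeric_column(df: pd.DataFrame, col: str, kind: str) -> pd.Series:
    """Convert a string column to numbers, reporting the first bad line."""
    cleaned = _strip_thousands(df[col])
    if kind == "float":
        # element-wise float() keeps full precision (pandas' fast parser
        # is not correctly rounded for 17-digit decimals)
        out = []
        for idx, s in enumerate(cleaned):
            try:
                out.append(float(s))
            except ValueError:
                raise FormatError(
                    f"column {col!r}: non-numeric value {df[col].iloc[idx]!r} "
                    f"on line {idx + 2}"
                ) from None
        return pd.Series(out, index=df.index)
    values = pd.to_numeric(cleaned, errors="coerce")
    bad = values.isna() & (cleaned != "")
    if bad.any() or (cleaned == "").any():
        idx = int((bad | (cleaned == "")).idxmax())
        raise FormatError(
            f"column {col!r}: non-numeric value {df[col].iloc[idx]!r} "
            f"on line {idx + 2}"
        )
    if kind == "int":
        as_int = values.round().astype("int64")
        if (as_int != values).any():
            idx = int((as_int != values).idxmax())
            raise FormatError(
                f"column {col!r}: expected integer rank, got "
                f"{df[col].iloc[idx]!r} on line {idx + 2}"
            )
        return as_int
    return values.astype(float)


def read_dot_table(source) -> list[HomologDot]:
    """Read a homolog dot table (CSV or TSV, auto-detected) into dots.

    Row order is preserved.  Raises :class:`FormatError` naming a missing
    column or the line of the first non-numeric rank/Ks value.
    """
    text = _as_text(source)
    df = pd.read_csv(_io.StringIO(text), sep=_sniff_sep(text), dtype=str,
                     keep_default_na=False, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    for col in DOT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"dot table is missing required column {col!r}")
    if df.empty:
        return []
    xs = _numeric_column(df, "x", "int")
    ys = _numeric_column(df, "y", "int")
    ks = _numeric_column(df, "ks", "float")
    return [
        HomologDot(str(t).strip(), int(x), str(r).strip(), int(y), float(k))
        for t, x, r, y, k in zip(df["target_chr"], xs, df["ref_chr"], ys, ks)
    ]


def write_dot_table(dots: Iterable[HomologDot], dest, sep: str = "\t") -> None:
    stream, close = _ensure_stream(dest)
    try:
        stream.write(sep.join(DOT_COLUMNS) + "\n")
        for d in dots:
            stream.write(
                sep.join((d.target_chr, str(d.x), d.ref_chr, str(d.y),
                          repr(d.ks))) + "\n"
            )
    finally:
        if close:
            stream.close()


def read_blockinfo(source) -> list[HomologDot]:
    """Expand a WGDI-style blockinfo CSV into one dot per aligned gene pair.

    Only the ``chr1``/``chr2``/``block1``/``block2``/``ks`` columns are
    used; pairs whose Ks is WGDI's missing marker (-1) are dropped.
    """
    text = _as_text(source)
    df = pd.read_csv(_io.StringIO(text), dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("chr1", "chr2", "block1", "block2", "ks"):
        if col not in df.columns:
            raise FormatError(f"blockinfo is missing required column {col!r}")
    dots: list[HomologDot] = []
    for idx, row in df.iterrows():
        block_id = row["id"] if "id" in df.columns else str(idx + 1)
        b1 = [s for s in str(row["block1"]).split(",") if s.strip()]
        b2 = [s for s in str(row["block2"]).split(",") if s.strip()]
        kk = [s for s in str(row["ks"]).split(",") if s.strip()]
        if not (len(b1) == len(b2) == len(kk)):
            raise FormatError(
                f"block {block_id}: block1/block2/ks lengths differ "
                f"({len(b1)}/{len(b2)}/{len(kk)})"
            )
        for x, y, k in zip(b1, b2, kk):
            ks = float(k)
            if ks == -1:
                continue
            dots.append(
                HomologDot(str(row["chr1"]).strip(), int(x),
                           str(row["chr2"]).strip(), int(y), ks)
            )
    return dots


def read_len_file(source, species: str | None = None) -> ChromosomeLengths:
    """Read a chromosome-length ("len") file.

    Expects rows of (chromosome name, length in gene-rank units); any
    further columns are ignored.  A header row is skipped if its second
    field is non-numeric.
    """
    text = _as_text(source)
    entries: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = [f.strip() for f in line.replace("\t", ",").split(",") if f.strip()]
        if len(fields) < 2:
            raise FormatError(f"len file line {lineno}: expected >= 2 columns")
        name, raw_len = fields[0], fields[1].replace(",", "")
        try:
            length = int(float(raw_len))
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise FormatError(
                f"len file line {lineno}: non-numeric length {fields[1]!r}"
            ) from None
        if length <= 0:
            raise FormatError(
                f"len file line {lineno}: chromosome {name!r} has "
                f"non-positive length {length}"
            )
        if name in entries:
            raise FormatError(f"len file: duplicate chromosome {name!r}")
        entries[name] = length
    return ChromosomeLengths(entries, species=species)


def read_box_table(source) -> list[ClusterBox]:
    """Read any of the box-table dialects (cluster/combine/result) back.

    The delta columns (and, for result.csv, Sumy/Comro) are ignored on
    input; deltas are always recomputed from the corners.
    """
    text = _as_text(source)
    df = pd.read_csv(_io.StringIO(text), sep=_sniff_sep(text), dtype=str,
                     keep_default_na=False, skipinitialspace=True)
    df.columns = [
        _TAIL_ALIASES.get(str(c).strip(), _TAIL_ALIASES.get(str(c).strip().lower(),
                                                            str(c).strip()))
        for c in df.columns
    ]
    for col in BOX_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"box table is missing required column {col!r}")
    if df.empty:
        return []
    numeric = {
        col: _numeric_column(df, col, "int")
        for col in ("id", "l_x", "l_y", "num", "r_x", "r_y")
    }
    return [
        ClusterBox(
            chr1=str(df["chr1"].iloc[i]).strip(),
            chr2=str(df["chr2"].iloc[i]).strip(),
            id=int(numeric["id"].iloc[i]),
            l_x=int(numeric["l_x"].iloc[i]),
            l_y=int(numeric["l_y"].iloc[i]),
            r_x=int(numeric["r_x"].iloc[i]),
            r_y=int(numeric["r_y"].iloc[i]),
            num=int(numeric["num"].iloc[i]),
        )
        for i in range(len(df))
    ]


def _box_sort_key(box: ClusterBox):
    return (natural_key(box.chr2), natural_key(box.chr1), box.id)


def write_box_table(boxes: Sequence[ClusterBox], dest,
                    dialect: str = "cluster") -> None:
    """Write cluster.csv / combine.csv (rows sorted by chr2, chr1, id)."""
    if dialect not in DIALECT_TAILS:
        raise ParameterError(f"unknown box-table dialect {dialect!r}")
    stream, close = _ensure_stream(dest)
    try:
        stream.write(",".join(BOX_COLUMNS + DIALECT_TAILS[dialect]) + "\n")
        for b in sorted(boxes, key=_box_sort_key):
            stream.write(
                f"{b.chr1},{b.chr2},{b.id},{b.l_x},{b.l_y},{b.num},"
                f"{b.r_x},{b.r_y},{b.delta_y},{b.delta_x}\n"
            )
    finally:
        if close:
            stream.close()


def write_result_table(rounds: Sequence[CombinationRound], dest) -> None:
    """Write result.csv: one row per member box, rounds in comro order.

    Within a round rows are sorted by box length (delta_y) descending.
    """
    stream, close = _ensure_stream(dest)
    try:
        stream.write(",".join(RESULT_COLUMNS) + "\n")
        for rnd in rounds:
            for b in sorted(rnd.members, key=lambda b: -b.delta_y):
                stream.write(
                    f"{b.chr1},{b.chr2},{b.id},{b.l_x},{b.l_y},{b.num},"
                    f"{b.r_x},{b.r_y},{rnd.sumy},{b.delta_y},{b.delta_x},"
                    f"{rnd.comro}\n"
                )
    finally:
        if close:
            stream.close()
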