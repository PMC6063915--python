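"""Readers and writers for the plain-text formats used across the pipeline.

Supported formats: GCT 1.2 and plain TSV expression matrices, CLS class
label files, GMT gene set collections, and 3-column interaction edge lists.
All parsers raise :class:`ParseError` with the offending file and line.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd


class ParseError(ValueError):
    """Raised when a text file does not conform to its declared format."""

    def __init__(self, path, line_no: int | None, message: str):
        self.path = str(path)
        self.line_no = line_no
        where = f"{self.path}" if line_no is None else f"{self.path}:{line_no}"
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix into a DataFrame (rows x samples).

    The Description column is dropped. Duplicate row or sample identifiers
    and declared-dimension mismatches are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(path, None, "GCT file must have at least 3 lines")
    if lines[0].strip() != "#1.2":
        raise ParseError(path, 1, f"expected version line '#1.2', got {lines[0]!r}")
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise ParseError(path, 2, "expected '<n_rows>\\t<n_samples>'")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except ValueError:
        raise ParseError(path, 2, f"non-integer dimensions {lines[1]!r}") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0].lower() != "name":
        raise ParseError(path, 3, "header must start with 'Name\\tDescription\\t...'")
    sample_ids = header[2:]
    if len(sample_ids) != n_cols:
        raise ParseError(
            path, 3, f"declared {n_cols} samples but header has {len(sample_ids)}"
        )
    if len(set(sample_ids)) != len(sample_ids):
        dup = _first_duplicate(sample_ids)
        raise ParseError(path, 3, f"duplicate sample id {dup!r}")
    body = lines[3:]
    # trailing blank lines are tolerated
    while body and not body[-1].strip():
        body.pop()
    if len(body) != n_rows:
        raise ParseError(
            path, None, f"declared {n_rows} rows but body has {len(body)}"
        )
    ids, rows = [], []
    for i, line in enumerate(body, start=4):
        parts = line.split("\t")
        if len(parts) != n_cols + 2:
            raise ParseError(path, i, f"expected {n_cols + 2} fields, got {len(parts)}")
        ids.append(parts[0])
        try:
            rows.append([float(x) for x in parts[2:]])
        except ValueError as exc:
            raise ParseError(path, i, f"non-numeric cell: {exc}") from None
    if len(set(ids)) != len(ids):
        dup = _first_duplicate(ids)
        raise ParseError(path, None, f"duplicate row id {dup!r}")
    return pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)


def write_gct(values: pd.DataFrame, path, descriptions=None) -> None:
    path = Path(path)
    desc = descriptions if descriptions is not None else {r: "na" for r in values.index}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        for row_id, row in values.iterrows():
            cells = "\t".join(repr(float(v)) for v in row.to_numpy())
            fh.write(f"{row_id}\t{desc.get(row_id, 'na')}\t{cells}\n")


# ---------------------------------------------------------------------------
# TSV matrix (first column = row id, header = sample ids)
# ---------------------------------------------------------------------------

def read_tsv_matrix(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(path, None, f"cannot parse TSV matrix: {exc}") from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(path, None, f"duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(path, None, f"duplicate sample id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(path, None, f"non-numeric cell: {exc}") from None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_tsv_matrix(values: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, values.columns)) + "\n")
        for row_id, row in values.iterrows():
            fh.write(str(row_id) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# CLS (categorical class labels)
# ---------------------------------------------------------------------------

def read_cls(path) -> tuple[list[str], list[str]]:
    """Read a CLS file; returns (class_names, per-sample labels)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != 3:
        raise ParseError(path, None, f"CLS file must have 3 non-blank lines, got {len(lines)}")
    head = lines[0].split()
    if len(head) != 3:
        raise ParseError(path, 1, "expected '<n_samples> <n_classes> 1'")
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except ValueError:
        raise ParseError(path, 1, f"non-integer counts {lines[0]!r}") from None
    if not lines[1].startswith("#"):
        raise ParseError(path, 2, "class-name line must start with '#'")
    class_names = lines[1][1:].split()
    if len(class_names) != n_classes:
        raise ParseError(path, 2, f"declared {n_classes} classes but found {len(class_names)}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ParseError(path, 3, f"declared {n_samples} samples but found {len(tokens)}")
    labels = []
    for tok in tokens:
        if tok in class_names:
            labels.append(tok)
        elif tok.isdigit() and int(tok) < n_classes:
            labels.append(class_names[int(tok)])
        else:
            raise ParseError(path, 3, f"unknown class label {tok!r}")
    return class_names, labels


def write_cls(class_names: list[str], labels: list[str], path) -> None:
    for lab in labels:
        if lab not in class_names:
            raise ValueError(f"label {lab!r} not among classes {class_names}")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(class_names)} 1\n")
        fh.write("# " + " ".join(class_names) + "\n")
        fh.write(" ".join(labels) + "\n")


# ---------------------------------------------------------------------------
# GMT (gene sets)
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[tuple[str, str, tuple[str, ...]]]:
    """Read GMT rows as (name, description, members)."""
    path = Path(path)
    out, seen = [], set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, "GMT row needs name, description and >=1 member")
            name, desc = parts[0], parts[1]
            members = tuple(g for g in parts[2:] if g)
            if not members:
                raise ParseError(path, i, f"gene set {name!r} has no members")
            if name in seen:
                raise ParseError(path, i, f"duplicate gene set name {name!r}")
            seen.add(name)
            out.append((name, desc, members))
    return out


def write_gmt(sets: list[tuple[str, str, tuple[str, ...]]], path) -> None:
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Interaction edge lists (gene_a, gene_b, score)
# ---------------------------------------------------------------------------

def read_edge_rows(path) -> list[tuple[str, str, int]]:
    """Parse a 3-column TSV edge list; no filtering, errors name the line."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(path, i, f"expected 3 tab-separated fields, got {len(parts)}")
            a, b, raw = parts
            try:
                score = int(raw)
            except ValueError:
                raise ParseError(path, i, f"non-integer score {raw!r}") from None
            rows.append((a, b, score))
    return rows


def write_edge_rows(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b, score in edges:
            fh.write(f"{a}\t{b}\t{int(score)}\n")


def read_alias_map(path) -> dict[str, str]:
    """Optional 2-column TSV mapping foreign ids to gene symbols."""
    path = Path(path)
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(path, i, "alias rows need exactly 2 fields")
            out[parts[0]] = parts[1]
    return out


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
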