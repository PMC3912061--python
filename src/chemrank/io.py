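"""Readers and writers for interaction tables, label tables and descriptor matrices.

The interaction dialect is the STITCH detailed-links table: one row per
directed compound pair with five score channels (``similarity``,
``experimental``, ``database``, ``textmining``, ``combined_score``).  Column
names are matched case-insensitively; both tab- and whitespace-separated files
parse.  All readers stream line-by-line and log row counts.
"""

from __future__ import annotations

import csv
import logging
import os
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .types import DescriptorMatrix, InteractionNetwork, LabelCatalog, LabelledDrugSet

logger = logging.getLogger(__name__)

__all__ = [
    "STITCH_CHANNELS",
    "load_stitch_tsv",
    "write_stitch_tsv",
    "load_labels",
    "write_labels",
    "load_descriptors",
    "write_descriptors",
    "load_id_mapping",
    "infer_catalog",
]

#: Score channels of the STITCH detailed-links dialect, canonical lower-case.
STITCH_CHANNELS = (
    "similarity",
    "experimental",
    "database",
    "textmining",
    "combined_score",
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def _split_line(line: str, sep: str | None) -> list[str]:
    line = line.rstrip("\n").rstrip("\r")
    return line.split("\t") if sep == "\t" else line.split()


def _sniff_sep(header_line: str) -> str | None:
    return "\t" if "\t" in header_line else None


def load_id_mapping(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (raw_id, canonical_id) delimited table into a dict.

    Used to translate database compound identifiers (e.g. STITCH CIDs) to the
    drug codes used in a label table; no prefix logic is hard-coded.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            return mapping
        sep = _sniff_sep(first)
        rows = [first] + fh.readlines()
    start = 0
    head = _split_line(rows[0], sep)
    if head and head[0].lower() in {"raw", "raw_id", "from", "source"}:
        start = 1
    for lineno, line in enumerate(rows[start:], start=start + 1):
        if not line.strip():
            continue
        parts = _split_line(line, sep)
        if len(parts) < 2:
            raise FormatError(f"id-mapping line {lineno}: expected two columns")
        mapping[parts[0]] = parts[1]
    return mapping


def load_stitch_tsv(
    path: str | os.PathLike,
    score_channel: str = "combined_score",
    id_filter: Iterable[str] | None = None,
    id_map: Mapping[str, str] | None = None,
) -> InteractionNetwork:
    """Load an interaction network from a STITCH detailed-links table.

    Rows whose chosen channel score is greater than zero become edges (the
    interactivity rule); zero-score rows are excluded.  Duplicate unordered
    pairs keep the maximum score with a logged warning.  ``id_filter``
    restricts the network to edges with both endpoints in the given set,
    applied after the optional ``id_map`` identifier translation.

    Raises
    ------
    FormatError
        If the requested channel column is missing (the message names the
        available columns) or a score fails to parse (the message carries the
        line number).
    """
    channel = score_channel.lower()
    wanted = set(id_filter) if id_filter is not None else None
    net = InteractionNetwork()
    n_rows = 0
    with open(path, newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file, expected a header line")
        sep = _sniff_sep(header_line)
        header = [h.lower() for h in _split_line(header_line, sep)]
        if len(header) < 3:
            raise FormatError(
                f"{path}: header must name two id columns and score channels, got {header}"
            )
        try:
            col = header.index(channel)
        except ValueError:
            raise FormatError(
                f"{path}: no channel column {score_channel!r}; available: {header[2:]}"
            ) from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = _split_line(line, sep)
            if len(parts) <= col:
                raise FormatError(f"{path} line {lineno}: expected {len(header)} columns")
            a, b = parts[0], parts[1]
            if id_map is not None:
                a = id_map.get(a, a)
                b = id_map.get(b, b)
            try:
                q = float(parts[col])
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-numeric {score_channel!r} value {parts[col]!r}"
                ) from None
            n_rows += 1
            if q <= 0:
                continue
            if wanted is not None and (a not in wanted or b not in wanted):
                continue
            net.add_edge(a, b, q)
    logger.info(
        "%s: %d data rows, %d unordered interactive pairs (channel=%s)",
        path, n_rows, net.n_edges, channel,
    )
    return net


def write_stitch_tsv(net: InteractionNetwork, path: str | os.PathLike) -> None:
    """Write a network as a STITCH-dialect table with the score in ``combined_score``.

    The four sub-channel columns are emitted as 0: only the combined channel is
    modelled by :class:`InteractionNetwork`.
    """
    with open(path, "w", newline="") as fh:
        fh.write(
            "chemical1\tchemical2\tsimilarity\texperimental\tdatabase\ttextmining\tcombined_score\n"
        )
        for a, b, q in sorted(net.edges()):
            qs = f"{int(q)}" if float(q).is_integer() else f"{q!r}"
            fh.write(f"{a}\t{b}\t0\t0\t0\t0\t{qs}\n")


def _read_delimited(path: str | os.PathLike) -> tuple[list[str], list[list[str]]]:
    """Read a CSV/TSV file; returns (header, rows). Delimiter sniffed from header."""
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            return [], []
        delim = "\t" if "\t" in first else ","
        reader = csv.reader([first] + fh.readlines(), delimiter=delim)
        rows = [row for row in reader if any(cell.strip() for cell in row)]
    return rows[0], rows[1:]


def infer_catalog(path: str | os.PathLike) -> LabelCatalog:
    """Infer a category catalogue from a label file.

    Wide files (multi-column header of tags) yield the header order; long
    files yield first-appearance order of the tags.  Used by the CLI when no
    explicit catalogue is given; explicit ordering is preferred since the
    catalogue order is the tie-breaking order.
    """
    header, rows = _read_delimited(path)
    if not header:
        raise FormatError(f"{path}: cannot infer a catalog from an empty file")
    # wide form iff every data cell after the id column is a 0/1 indicator
    wide = (
        len(header) >= 2
        and rows
        and all(cell.strip() in {"0", "1"} for row in rows for cell in row[1:])
    )
    if wide:
        return LabelCatalog(header[1:])
    seen: list[str] = []
    for row in rows:
        for cell in row[1:]:
            if cell.strip() and cell not in seen:
                seen.append(cell)
    if not seen:
        raise FormatError(f"{path}: no category tags found")
    return LabelCatalog(seen)


def load_labels(path: str | os.PathLike, catalog: LabelCatalog) -> LabelledDrugSet:
    """Load a drug-label table as a :class:`LabelledDrugSet`.

    Two layouts are auto-detected from the header:

    * **wide** — first column is the drug id and every remaining header cell is
      a catalogue tag; cells are 0/1 indicators.
    * **long** — each data row is a drug id followed by one or more catalogue
      tags (the header content is ignored beyond layout detection).

    Unknown tags are rejected with a message listing the catalogue; a drug with
    zero labels is a validation error.  An empty file yields an empty (valid)
    set, flagged in the log.
    """
    header, rows = _read_delimited(path)
    if not header:
        logger.warning("%s: empty label file, returning empty drug set", path)
        return LabelledDrugSet(catalog, [], np.zeros((0, len(catalog)), np.int8))
    wide = len(header) >= 2 and all(tag in catalog for tag in header[1:])
    if wide:
        ids: list[str] = []
        mat: list[list[int]] = []
        cols = [catalog.index(tag) for tag in header[1:]]
        for row in rows:
            if len(row) != len(header):
                raise FormatError(f"{path}: wide row {row!r} does not match header")
            vec = [0] * len(catalog)
            for tag_col, cell in zip(cols, row[1:]):
                v = int(cell)
                if v not in (0, 1):
                    raise FormatError(f"{path}: wide cells must be 0/1, got {cell!r}")
                vec[tag_col] = v
            if sum(vec) == 0:
                raise ValueError(f"{path}: drug {row[0]!r} has zero labels")
            ids.append(row[0])
            mat.append(vec)
        out = LabelledDrugSet(catalog, ids, np.array(mat, np.int8).reshape(len(ids), -1))
    else:
        pairs: list[tuple[str, str]] = []
        for row in rows:
            drug, tags = row[0], [t for t in row[1:] if t.strip()]
            if not tags:
                raise ValueError(f"{path}: drug {drug!r} has zero labels")
            for tag in tags:
                if tag not in catalog:
                    raise ValueError(
                        f"{path}: unknown category {tag!r} for drug {drug!r}; "
                        f"catalog is {list(catalog)}"
                    )
                pairs.append((drug, tag))
        out = LabelledDrugSet.from_pairs(catalog, pairs)
    if len(out) == 0:
        logger.warning("%s: label file contains a header but no drugs", path)
    logger.info("%s: %d drugs, %d label pairs", path, len(out), out.n_label_pairs)
    return out


def write_labels(
    data: LabelledDrugSet, path: str | os.PathLike, form: str = "long"
) -> None:
    """Write a label table in long (drug,category rows) or wide (binary) form."""
    delim = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        if form == "long":
            w.writerow(["drug_id", "category"])
            for d in data.drug_ids:
                for k in np.flatnonzero(data.label_vector(d)):
                    w.writerow([d, data.catalog[k]])
        elif form == "wide":
            w.writerow(["drug_id", *data.catalog])
            for d in data.drug_ids:
                w.writerow([d, *map(int, data.label_vector(d))])
        else:
            raise ValueError(f"unknown label form {form!r}")


def load_descriptors(path: str | os.PathLike) -> DescriptorMatrix:
    """Load a numeric descriptor matrix, dropping any column with missing values.

    The first column is the drug identifier.  Empty cells, ``NA`` and ``NaN``
    count as missing; the retained dimension is logged.  If every descriptor
    column is dropped the file is unusable and an error is raised.
    """
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    n_before = frame.shape[1]
    frame = frame.apply(pd.to_numeric, errors="coerce")
    frame = frame.dropna(axis="columns", how="any")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no usable descriptors (all columns had missing values)")
    if frame.shape[1] < n_before:
        logger.info(
            "%s: dropped %d descriptor columns with missing values, retained %d",
            path, n_before - frame.shape[1], frame.shape[1],
        )
    logger.info("%s: %d drugs x %d descriptors", path, *frame.shape)
    frame.index = frame.index.astype(str)
    return DescriptorMatrix(frame)


def write_descriptors(desc: DescriptorMatrix, path: str | os.PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    desc.frame.to_csv(path, sep=sep, index_label="drug_id")
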