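"""Reading GEO series-matrix files and writing result tables.

The series-matrix dialect handled here is the text format GEO distributes for
each series: metadata lines prefixed with ``!``, and a tab-separated data block
delimited by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
whose first header cell is ``"ID_REF"``.  Fields may be double-quoted; files
may be gzip-compressed.

Condition and time metadata are never inferred from sample titles (those are
accession-specific); they come from a sidecar annotation TSV with columns
``sample_id``, ``condition`` and ``time_h``.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("treated", "control")

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"

_MISSING_TOKENS = {"", "null", "NULL", "NA", "na", "NaN", "nan"}


class SeriesMatrixParseError(ValueError):
    """Raised when a series-matrix file violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with per-sample metadata.

    Attributes
    ----------
    values : numpy.ndarray
        Real matrix of shape (n_probes, n_samples), in whatever units the
        source file stores.
    probe_ids : list of str
        Unique row identifiers, in row order.
    sample_ids : list of str
        Unique column identifiers, in column order.
    condition : list of str
        Per-sample label, each either ``"treated"`` or ``"control"``.
    time_h : numpy.ndarray
        Per-sample time in hours, finite and nonnegative.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    condition: list[str]
    time_h: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.condition = list(self.condition)
        self.time_h = np.asarray(self.time_h, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError(
                f"{len(self.probe_ids)} probe ids for {n_probes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} matrix columns"
            )
        if len(set(self.probe_ids)) != n_probes:
            raise ValueError("probe ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample ids must be unique")
        if len(self.condition) != n_samples or self.time_h.size != n_samples:
            raise ValueError("condition and time_h must have one entry per sample")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.time_h)) or np.any(self.time_h < 0):
            raise ValueError("time_h must be finite and nonnegative")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def take_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """New matrix restricted to the given sample columns, order preserved."""
        idx = list(indices)
        return ExpressionMatrix(
            values=self.values[:, idx],
            probe_ids=self.probe_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            condition=[self.condition[i] for i in idx],
            time_h=self.time_h[idx],
        )


@dataclass
class SampleAnnotation:
    """Sidecar table assigning each sample a condition and a time in hours."""

    condition: dict[str, str] = field(default_factory=dict)
    time_h: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, cond in self.condition.items():
            if cond not in CONDITIONS:
                raise ValueError(
                    f"sample {sid!r}: condition must be one of {CONDITIONS}, got {cond!r}"
                )
        for sid, t in self.time_h.items():
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"sample {sid!r}: time_h must be finite and >= 0")
        if set(self.condition) != set(self.time_h):
            raise ValueError("condition and time_h must cover the same sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.condition)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, float]]) -> "SampleAnnotation":
        condition: dict[str, str] = {}
        time_h: dict[str, float] = {}
        for sid, cond, t in rows:
            if sid in condition:
                raise ValueError(f"duplicate sample id in annotation: {sid!r}")
            condition[sid] = cond
            time_h[sid] = float(t)
        return cls(condition=condition, time_h=time_h)


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample-annotation TSV (``sample_id<TAB>condition<TAB>time_h``)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "time_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return SampleAnnotation.from_rows(
        (row.sample_id, row.condition, float(row.time_h)) for row in df.itertuples()
    )


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\ttime_h\n")
        for sid in annotation.sample_ids:
            fh.write(f"{sid}\t{annotation.condition[sid]}\t{annotation.time_h[sid]:g}\n")


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _unquote(cell: str) -> str:
    cell = cell.strip()
    if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
        return cell[1:-1]
    return cell


def read_series_matrix(
    path: str | Path, annotation: SampleAnnotation
) -> ExpressionMatrix:
    """Parse a GEO series-matrix file into an :class:`ExpressionMatrix`.

    The returned matrix keeps the file's sample order restricted to the
    annotated samples.  Rows whose values are all missing are dropped (with a
    log line); a missing value inside an otherwise present row is an error,
    because the downstream decomposition has no missing-data handling.

    Raises
    ------
    SeriesMatrixParseError
        If the table delimiters are malformed, an annotated sample is absent
        from the file, or a cell is non-numeric.
    """
    header: list[str] | None = None
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    n_dropped = 0
    in_table = False
    saw_end = False

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not in_table:
                if line.strip() == TABLE_BEGIN:
                    in_table = True
                continue
            if line.strip() == TABLE_END:
                saw_end = True
                break
            cells = [_unquote(c) for c in line.split("\t")]
            if header is None:
                if not cells or cells[0] != "ID_REF":
                    raise SeriesMatrixParseError(
                        f"line {lineno}: expected header starting with ID_REF, "
                        f"got {cells[0]!r}"
                    )
                header = cells[1:]
                if len(set(header)) != len(header):
                    raise SeriesMatrixParseError(
                        f"line {lineno}: duplicate sample columns in header"
                    )
                continue
            if len(cells) != len(header) + 1:
                raise SeriesMatrixParseError(
                    f"line {lineno}: expected {len(header) + 1} fields, "
                    f"got {len(cells)}"
                )
            probe_id = cells[0]
            parsed: list[float] = []
            n_missing = 0
            for col, cell in enumerate(cells[1:], start=1):
                if cell in _MISSING_TOKENS:
                    parsed.append(np.nan)
                    n_missing += 1
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise SeriesMatrixParseError(
                        f"line {lineno}, column {col + 1} (sample "
                        f"{header[col - 1]!r}): non-numeric value {cell!r}"
                    ) from None
            if n_missing == len(header):
                n_dropped += 1
                continue
            probe_ids.append(probe_id)
            rows.append(parsed)

    if not in_table:
        raise SeriesMatrixParseError(
            f"{path}: no {TABLE_BEGIN} line found"
        )
    if not saw_end:
        raise SeriesMatrixParseError(
            f"{path}: table not terminated by {TABLE_END}"
        )
    if header is None:
        raise SeriesMatrixParseError(f"{path}: data block has no header line")
    if n_dropped:
        logger.info("dropped %d all-missing probe rows from %s", n_dropped, path)

    annotated = set(annotation.sample_ids)
    missing_samples = sorted(annotated - set(header))
    if missing_samples:
        raise SeriesMatrixParseError(
            f"annotated samples absent from file: {missing_samples}"
        )
    keep = [j for j, sid in enumerate(header) if sid in annotated]
    if not keep:
        raise SeriesMatrixParseError("annotation retains no sample column")

    values = np.asarray(rows, dtype=np.float64)
    if values.size == 0:
        raise SeriesMatrixParseError(f"{path}: data block contains no probe rows")
    values = values[:, keep]
    nan_rows, nan_cols = np.nonzero(np.isnan(values))
    if nan_rows.size:
        i, j = int(nan_rows[0]), int(nan_cols[0])
        raise SeriesMatrixParseError(
            f"missing value for probe {probe_ids[i]!r} in sample "
            f"{header[keep[j]]!r}; partial missingness is not supported"
        )
    sample_ids = [header[j] for j in keep]
    return ExpressionMatrix(
        values=values,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        condition=[annotation.condition[s] for s in sample_ids],
        time_h=np.array([annotation.time_h[s] for s in sample_ids]),
    )


def build_annotation_from_headers(
    path: str | Path,
    control_pattern: str = r"control",
    time_pattern: str = r"(\d+(?:\.\d+)?)\s*(?:h\b|hr\b|hrs\b|hour)",
) -> SampleAnnotation:
    """Derive a :class:`SampleAnnotation` from series-matrix header lines.

    Scans the ``!Sample_geo_accession``, ``!Sample_title`` and
    ``!Sample_characteristics*`` metadata lines above the data block.  A
    sample is labeled ``control`` when any of its metadata fields matches
    ``control_pattern`` (case-insensitive), ``treated`` otherwise; its time in
    hours is the first match of ``time_pattern``.  Errors if any sample lacks
    a parsable time.  Heuristic by nature — callers should cross-check the
    result against the known design (see ``scripts/build_gse6432_annotation``).
    """
    import re

    accessions: list[str] = []
    meta_rows: list[list[str]] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if line.strip() == TABLE_BEGIN:
                break
            if not line.startswith("!Sample_"):
                continue
            cells = [_unquote(c) for c in line.split("\t")]
            key, fields = cells[0], cells[1:]
            if key == "!Sample_geo_accession":
                accessions = fields
            elif key == "!Sample_title" or key.startswith("!Sample_characteristics"):
                meta_rows.append(fields)
    if not accessions:
        raise SeriesMatrixParseError(
            f"{path}: no !Sample_geo_accession header line found"
        )
    control_re = re.compile(control_pattern, re.IGNORECASE)
    time_re = re.compile(time_pattern, re.IGNORECASE)
    rows: list[tuple[str, str, float]] = []
    for j, sid in enumerate(accessions):
        fields = [row[j] for row in meta_rows if j < len(row)]
        blob = " | ".join(fields)
        match = time_re.search(blob)
        if match is None:
            raise ValueError(
                f"sample {sid}: no time in hours found in metadata {blob!r}"
            )
        condition = "control" if control_re.search(blob) else "treated"
        rows.append((sid, condition, float(match.group(1))))
    return SampleAnnotation.from_rows(rows)


def write_series_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the series-matrix dialect (used by the simulator).

    Emits a minimal header, the quoted ``"ID_REF"`` data block and the
    begin/end delimiters, so files written here exercise the same reader as
    GEO downloads.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!Series_title\t\"synthetic expression matrix\"\n")
        fh.write(f"{TABLE_BEGIN}\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in m.sample_ids]) + "\n")
        for i, pid in enumerate(m.probe_ids):
            row = "\t".join(f"{v:.17g}" for v in m.values[i])
            fh.write(f'"{pid}"\t{row}\n')
        fh.write(f"{TABLE_END}\n")


def split_by_condition(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition sample columns into (treated, control) sub-matrices."""
    treated = select_condition(m, "treated")
    control = select_condition(m, "control")
    return treated, control


def select_condition(m: ExpressionMatrix, condition: str) -> ExpressionMatrix:
    """Sub-matrix of one condition; errors if that condition has no samples."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    idx = [j for j, c in enumerate(m.condition) if c == condition]
    if not idx:
        raise ValueError(f"no samples with condition {condition!r}")
    return m.take_samples(idx)


def write_probe_report(
    scores,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a probe score table as TSV.

    Columns: ``probe_id``, ``statistic``, ``p_value``, ``adjusted_p``,
    ``selected``; one row per probe in input order.  Optional metadata is
    embedded as ``# key: value`` comment lines so each report records the
    thresholds that produced it.
    """
    probe_ids = list(scores.probe_ids)
    if not probe_ids:
        raise ValueError("refusing to write an empty probe report")
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("probe_id\tstatistic\tp_value\tadjusted_p\tselected\n")
        for i, pid in enumerate(probe_ids):
            fh.write(
                f"{pid}\t{scores.statistic[i]:.17g}\t{scores.p_value[i]:.17g}\t"
                f"{scores.adjusted_p[i]:.17g}\t{bool(scores.selected[i])}\n"
            )


def read_probe_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_probe_report`."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_probe_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column ``probe_id<TAB>symbol`` mapping table.

    A header line is accepted (and detected by its first cell being one of the
    usual column titles) but not required, matching GPL annotation exports.
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            cells = [_unquote(c) for c in line.split("\t")]
            if len(cells) < 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns")
            if lineno == 1 and cells[0].lower() in {"probe_id", "id", "id_ref"}:
                continue
            mapping[cells[0]] = cells[1]
    return mapping


def export_gene_list(
    scores,
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
) -> list[str]:
    """Write selected probes as a one-symbol-per-line text file.

    With a probe-to-symbol mapping, duplicates are collapsed (first occurrence
    wins) and unmapped probes are logged and skipped; without one, probe ids
    are emitted.  Returns the list of written lines.
    """
    selected = [
        pid for pid, sel in zip(scores.probe_ids, scores.selected) if bool(sel)
    ]
    lines: list[str] = []
    if not selected:
        logger.warning("no probes selected; writing empty gene list to %s", path)
    elif mapping is None:
        lines = list(selected)
    else:
        seen: set[str] = set()
        for pid in selected:
            symbol = mapping.get(pid)
            if symbol is None or symbol == "":
                logger.info("probe %s has no symbol mapping; skipped", pid)
                continue
            if symbol not in seen:
                seen.add(symbol)
                lines.append(symbol)
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
    return lines
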