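"""Readers and writers for every external format the suite touches.

Dialects
--------
SampleMatrix
    Tab-delimited text. The first column is reserved for row identifiers,
    the remaining columns hold one numeric value per sample. An optional
    first line of sample labels is auto-detected: a first row whose non-ID
    cells are not all numeric is treated as a header. Decimal point only,
    UTF-8, ``\\n`` or ``\\r\\n`` line endings, empty cells rejected.

Spectra
    Two dialects behind one reader:

    ``plain-grid``
        Documented text dialect used throughout the test fixtures.
        1D: one ``ppm<TAB>intensity`` pair per line (the first column is
        the ppm axis). 2D: the first row is ``ppm`` followed by the F2
        (1H) ppm axis; each following row starts with an F1 (13C) ppm
        coordinate followed by that row's intensities.

    ``nmrpipe``
        Single-file nmrPipe binary spectra (512 float32 header words
        followed by float32 intensities). Only the header fields needed
        to reconstruct ppm axes are interpreted (OBS, SW, ORIG, sizes);
        ppm of point ``i`` on an axis of ``N`` points is
        ``(ORIG + SW * (N - 1 - i) / N) / OBS``, descending from point 0.

Hit tables
    BLAST tabular output (outfmt 6), 12 tab-separated columns, one HSP
    per line, ``#`` comment lines ignored.

Taxonomy / CBM metadata
    Two-column TSV ``subject_id<TAB>annotation`` where the annotation is
    either a semicolon-separated lineage (domain;phylum;class;order;family,
    missing ranks written ``unclassified``) or one or more comma-separated
    CBM family labels such as ``CBM2``.

Axes are stored strictly monotone descending (downfield first); ascending
input is flipped on read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import FormatError

__all__ = [
    "SampleMatrix",
    "SpectrumGrid",
    "HitRecord",
    "HitTable",
    "TaxonomyTable",
    "read_sample_matrix",
    "write_sample_matrix",
    "read_spectrum",
    "write_spectrum",
    "read_hit_table",
    "write_hit_table",
    "read_taxonomy_table",
    "write_taxonomy_table",
]

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleMatrix:
    """A row-ID x sample table: the universal exchange type of the suite.

    Parameters
    ----------
    row_ids
        Unique identifier per row (e.g. gene names, DGGE band ids, bin
        positions).
    sample_labels
        One label per value column.
    values
        Real-valued array of shape ``(len(row_ids), len(sample_labels))``.
    block_label
        Optional name of the omics layer this matrix belongs to
        (metagenome, metabolome, ...). Used to prefix row labels when
        several matrices are concatenated into one correlation map.
    """

    row_ids: list[str]
    sample_labels: list[str]
    values: np.ndarray
    block_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.row_ids)} row ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_labels)} sample labels for "
                f"{self.values.shape[1]} value columns"
            )
        dupes = _duplicates(self.row_ids)
        if dupes:
            raise ValueError(f"duplicate row ids: {sorted(dupes)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectrumGrid:
    """A 1D or 2D NMR spectrum on a regular ppm grid.

    ``axes`` holds one ppm vector per dimension, each strictly monotone
    and stored descending (downfield first). For 2D spectra ``axes[0]``
    is the F1 (indirect, typically 13C) axis indexing rows of
    ``intensities`` and ``axes[1]`` the F2 (direct, 1H) axis indexing
    columns. Ascending input axes are flipped (together with the matching
    intensity dimension) at construction.
    """

    axes: list[np.ndarray]
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.axes) not in (1, 2):
            raise ValueError("spectra must be 1D or 2D")
        if self.intensities.ndim != len(self.axes):
            raise ValueError("intensity dimensionality does not match axes")
        axes = []
        for dim, ax in enumerate(self.axes):
            ax = np.asarray(ax, dtype=float)
            if ax.ndim != 1 or ax.size != self.intensities.shape[dim]:
                raise ValueError(
                    f"axis {dim} length {ax.size} does not match intensity "
                    f"dimension {self.intensities.shape[dim]}"
                )
            diffs = np.diff(ax)
            if ax.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise FormatError(f"ppm axis {dim} is not strictly monotone")
            if ax.size > 1 and diffs[0] > 0:  # ascending -> store downfield first
                ax = ax[::-1]
                self.intensities = np.flip(self.intensities, axis=dim)
            axes.append(ax)
        self.axes = axes

    @property
    def ndim(self) -> int:
        return len(self.axes)


@dataclass(frozen=True)
class HitRecord:
    """One alignment HSP from a BLAST tabular line."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float


@dataclass
class HitTable:
    """A parsed BLAST tabular file: one :class:`HitRecord` per HSP line."""

    records: list[HitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.e_value < 0:
                raise ValueError(f"negative E-value {rec.e_value!r} for {rec.query_id}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def query_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.query_id, None)
        return list(seen)


@dataclass
class TaxonomyTable:
    """Subject metadata: either a taxonomic lineage or CBM family labels.

    ``lineages`` maps subject_id to a dict over the five ranks
    (domain..family) with missing ranks stored as ``"unclassified"``;
    ``cbm_families`` maps subject_id to a tuple of CBM labels (a subject
    with several carbohydrate-binding domains lists several).
    """

    lineages: dict[str, dict[str, str]] = field(default_factory=dict)
    cbm_families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.lineages or subject_id in self.cbm_families


# ---------------------------------------------------------------------------
# SampleMatrix I/O
# ---------------------------------------------------------------------------


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_sample_matrix(
    path: str | Path,
    block_label: str | None = None,
    *,
    has_header: bool | None = None,
) -> SampleMatrix:
    """Read a tab-delimited sample matrix (first column = row IDs).

    ``has_header=None`` auto-detects: a first row whose non-ID cells are
    not all numeric is taken as the sample-label header. Pass
    ``has_header=False`` to force a fully numeric first row to be data.
    """
    path = Path(path)
    lines = [
        (lineno, line.rstrip("\r\n"))
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1)
        if line.strip() != ""
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")

    rows = [(lineno, line.split("\t")) for lineno, line in lines]
    width = len(rows[0][1])
    if width < 2:
        raise FormatError(f"{path}: line {rows[0][0]}: need an ID column plus >=1 value column")
    for lineno, cells in rows:
        if len(cells) != width:
            raise FormatError(
                f"{path}: line {lineno}: ragged row ({len(cells)} columns, expected {width})"
            )

    first_cells = rows[0][1]
    if has_header is None:
        has_header = not all(_is_number(c) for c in first_cells[1:])
    if has_header:
        sample_labels = [c.strip() for c in first_cells[1:]]
        data_rows = rows[1:]
    else:
        sample_labels = [f"S{i + 1}" for i in range(width - 1)]
        data_rows = rows
    if not data_rows:
        raise FormatError(f"{path}: header but no data rows")

    row_ids: list[str] = []
    values = np.empty((len(data_rows), width - 1), dtype=float)
    for r, (lineno, cells) in enumerate(data_rows):
        row_ids.append(cells[0].strip())
        for c, token in enumerate(cells[1:], start=2):
            token = token.strip()
            if token == "" or not _is_number(token):
                raise FormatError(
                    f"{path}: line {lineno}, column {c}: non-numeric value {token!r}"
                )
            values[r, c - 2] = float(token)

    dupes = _duplicates(row_ids)
    if dupes:
        raise FormatError(f"{path}: duplicate row ids: {sorted(dupes)}")
    return SampleMatrix(row_ids, sample_labels, values, block_label=block_label)


def write_sample_matrix(matrix: SampleMatrix, path: str | Path, *, id_header: str = "id") -> None:
    """Write a sample matrix as tab-delimited text at full precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(id_header + "\t" + "\t".join(matrix.sample_labels) + "\n")
        for row_id, row in zip(matrix.row_ids, matrix.values):
            fh.write(row_id + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------

# nmrPipe header word indices (512-word float32 header).
_FDMAGIC = 0
_FDFLTFORMAT = 1
_FDFLTORDER = 2
_FDDIMCOUNT = 9
_FDSIZE = 99  # F2 (direct) points
_FDF2SW = 100
_FDF2ORIG = 101
_FDF2OBS = 119
_FDF1OBS = 218
_FDSPECNUM = 219  # F1 (indirect) points
_FDF2FTFLAG = 220
_FDTRANSPOSED = 221
_FDF1FTFLAG = 222
_FDF1SW = 229
_FDF1ORIG = 249
_FLTORDER_VALUE = 2.345  # byte-order sentinel


def _pipe_ppm_axis(obs: float, sw: float, orig: float, size: int) -> np.ndarray:
    """Descending ppm axis from nmrPipe calibration (point 0 = downfield)."""
    if obs == 0:
        raise FormatError("nmrPipe header has zero observe frequency")
    idx = np.arange(size)
    hz = orig + sw * (size - 1 - idx) / size
    return hz / obs


def read_spectrum(
    path: str | Path, dialect: str = "plain-grid", *, label: str | None = None
) -> SpectrumGrid:
    """Read a spectrum in the ``plain-grid`` or ``nmrpipe`` dialect."""
    path = Path(path)
    if label is None:
        label = path.stem
    if dialect == "plain-grid":
        return _read_plain_grid(path, label)
    if dialect == "nmrpipe":
        return _read_nmrpipe(path, label)
    raise FormatError(f"unknown spectrum dialect {dialect!r}")


def _read_plain_grid(path: Path, label: str) -> SpectrumGrid:
    lines = [
        ln.rstrip("\r\n") for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    if not lines:
        raise FormatError(f"{path}: empty spectrum file")
    first = lines[0].split("\t")
    is_2d = len(first) > 2 or (first and not _is_number(first[0]))
    def _floats(cells: list[str], lineno: int) -> list[float]:
        try:
            return [float(c) for c in cells]
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric value") from None

    if not is_2d:
        ppm, inten = [], []
        for lineno, ln in enumerate(lines, 1):
            cells = ln.split("\t")
            if len(cells) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 'ppm<TAB>intensity'")
            p, v = _floats(cells, lineno)
            ppm.append(p)
            inten.append(v)
        return SpectrumGrid([np.array(ppm)], np.array(inten), label=label)
    # 2D: first row = corner token + F2 axis; rows = F1 ppm + intensities
    f2 = np.array(_floats(first[1:], 1))
    f1, grid = [], []
    for lineno, ln in enumerate(lines[1:], 2):
        cells = ln.split("\t")
        if len(cells) != len(first):
            raise FormatError(
                f"{path}: line {lineno}: ragged row ({len(cells)} columns, expected {len(first)})"
            )
        row = _floats(cells, lineno)
        f1.append(row[0])
        grid.append(row[1:])
    return SpectrumGrid([np.array(f1), f2], np.array(grid), label=label)


def _read_nmrpipe(path: Path, label: str) -> SpectrumGrid:
    raw = path.read_bytes()
    if len(raw) < 512 * 4:
        raise FormatError(f"{path}: too short for an nmrPipe header")
    header = np.frombuffer(raw[: 512 * 4], dtype="<f4").astype(float)
    if abs(header[_FDFLTORDER] - _FLTORDER_VALUE) > 1e-3:
        header = np.frombuffer(raw[: 512 * 4], dtype=">f4").astype(float)
        data_dtype = ">f4"
        if abs(header[_FDFLTORDER] - _FLTORDER_VALUE) > 1e-3:
            raise FormatError(f"{path}: not an nmrPipe file (bad FDFLTORDER)")
    else:
        data_dtype = "<f4"
    ndim = int(round(header[_FDDIMCOUNT]))
    n_f2 = int(round(header[_FDSIZE]))
    data = np.frombuffer(raw[512 * 4 :], dtype=data_dtype).astype(float)
    f2_axis = _pipe_ppm_axis(header[_FDF2OBS], header[_FDF2SW], header[_FDF2ORIG], n_f2)
    if ndim == 1:
        if data.size != n_f2:
            raise FormatError(f"{path}: expected {n_f2} points, found {data.size}")
        return SpectrumGrid([f2_axis], data, label=label)
    if ndim == 2:
        n_f1 = int(round(header[_FDSPECNUM]))
        if data.size != n_f1 * n_f2:
            raise FormatError(f"{path}: expected {n_f1}x{n_f2} points, found {data.size}")
        f1_axis = _pipe_ppm_axis(header[_FDF1OBS], header[_FDF1SW], header[_FDF1ORIG], n_f1)
        return SpectrumGrid([f1_axis, f2_axis], data.reshape(n_f1, n_f2), label=label)
    raise FormatError(f"{path}: unsupported dimension count {ndim}")


def write_spectrum(spectrum: SpectrumGrid, path: str | Path, dialect: str = "plain-grid") -> None:
    """Write a spectrum in either dialect (used by the fixtures and tests)."""
    path = Path(path)
    if dialect == "plain-grid":
        _write_plain_grid(spectrum, path)
    elif dialect == "nmrpipe":
        _write_nmrpipe(spectrum, path)
    else:
        raise FormatError(f"unknown spectrum dialect {dialect!r}")


def _write_plain_grid(spectrum: SpectrumGrid, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        if spectrum.ndim == 1:
            for p, v in zip(spectrum.axes[0], spectrum.intensities):
                fh.write(f"{p:.17g}\t{v:.17g}\n")
        else:
            fh.write("ppm\t" + "\t".join(f"{p:.17g}" for p in spectrum.axes[1]) + "\n")
            for p, row in zip(spectrum.axes[0], spectrum.intensities):
                fh.write(f"{p:.17g}\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def _axis_calibration(ax: np.ndarray, obs: float = 500.0) -> tuple[float, float, float]:
    """(obs, sw, orig) reproducing a descending regular ppm axis."""
    n = ax.size
    if n < 2:
        return obs, 1.0, float(ax[0]) * obs if n else 0.0
    step_ppm = float(ax[0] - ax[1])
    sw = step_ppm * obs * n
    orig = float(ax[-1]) * obs  # last (most upfield) point's Hz
    return obs, sw, orig


def _write_nmrpipe(spectrum: SpectrumGrid, path: Path) -> None:
    header = np.zeros(512, dtype="<f4")
    header[_FDMAGIC] = 0.0
    header[_FDFLTFORMAT] = struct.unpack("<f", struct.pack("<I", 0xEEEEEEEE))[0]
    header[_FDFLTORDER] = _FLTORDER_VALUE
    header[_FDDIMCOUNT] = spectrum.ndim
    header[_FDF2FTFLAG] = 1.0
    header[_FDTRANSPOSED] = 0.0
    if spectrum.ndim == 1:
        obs, sw, orig = _axis_calibration(spectrum.axes[0])
        header[_FDSIZE] = spectrum.axes[0].size
        header[_FDF2OBS], header[_FDF2SW], header[_FDF2ORIG] = obs, sw, orig
        data = spectrum.intensities
    else:
        obs2, sw2, orig2 = _axis_calibration(spectrum.axes[1])
        obs1, sw1, orig1 = _axis_calibration(spectrum.axes[0], obs=125.0)
        header[_FDSIZE] = spectrum.axes[1].size
        header[_FDSPECNUM] = spectrum.axes[0].size
        header[_FDF1FTFLAG] = 1.0
        header[_FDF2OBS], header[_FDF2SW], header[_FDF2ORIG] = obs2, sw2, orig2
        header[_FDF1OBS], header[_FDF1SW], header[_FDF1ORIG] = obs1, sw1, orig1
        data = spectrum.intensities.ravel()
    with Path(path).open("wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.asarray(data, dtype="<f4").tobytes())


# ---------------------------------------------------------------------------
# BLAST tabular I/O
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> HitTable:
    """Read a 12-column BLAST tabular (outfmt 6) hit table."""
    path = Path(path)
    records: list[HitRecord] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 12:
            raise FormatError(
                f"{path}: line {lineno}: {len(cells)} columns, expected 12 (BLAST outfmt 6)"
            )
        try:
            e_value = float(cells[10])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: unparsable E-value {cells[10]!r}") from None
        try:
            rec = HitRecord(
                query_id=cells[0],
                subject_id=cells[1],
                percent_identity=float(cells[2]),
                alignment_length=int(cells[3]),
                e_value=e_value,
                bit_score=float(cells[11]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        records.append(rec)
    return HitTable(records)


def write_hit_table(hits: HitTable, path: str | Path) -> None:
    """Write hits back out in the 12-column tabular layout.

    The four unmodelled columns (mismatches, gap opens, coordinates) are
    written as zeros/ones; readers of this package ignore them.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in hits:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        format(r.percent_identity, ".3f"),
                        str(r.alignment_length),
                        "0",
                        "0",
                        "1",
                        str(r.alignment_length),
                        "1",
                        str(r.alignment_length),
                        format(r.e_value, ".3g"),
                        format(r.bit_score, ".1f"),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy / CBM metadata I/O
# ---------------------------------------------------------------------------


def read_taxonomy_table(path: str | Path) -> TaxonomyTable:
    """Read subject metadata: lineage (semicolon-separated) or CBM labels."""
    path = Path(path)
    table = TaxonomyTable()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 'subject_id<TAB>annotation'")
        subject, annot = cells[0].strip(), cells[1].strip()
        if subject in table:
            raise FormatError(f"{path}: line {lineno}: duplicate subject id {subject!r}")
        if ";" in annot:
            ranks = [t.strip() or "unclassified" for t in annot.split(";")]
            ranks += ["unclassified"] * (len(TAXONOMIC_RANKS) - len(ranks))
            table.lineages[subject] = dict(zip(TAXONOMIC_RANKS, ranks[: len(TAXONOMIC_RANKS)]))
        elif annot.upper().startswith("CBM"):
            table.cbm_families[subject] = tuple(t.strip() for t in annot.split(",") if t.strip())
        else:
            # single-token lineage: a domain-only classification
            table.lineages[subject] = dict(
                zip(TAXONOMIC_RANKS, [annot] + ["unclassified"] * 4)
            )
    return table


def write_taxonomy_table(table: TaxonomyTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for subject, lineage in table.lineages.items():
            fh.write(subject + "\t" + ";".join(lineage[r] for r in TAXONOMIC_RANKS) + "\n")
        for subject, fams in table.cbm_families.items():
            fh.write(subject + "\t" + ",".join(fams) + "\n")
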