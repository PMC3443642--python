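"""Reading and writing of radiation-hybrid (RH) mapping artifacts.

The raw input of an RH analysis is a binary genotype matrix: rows are RH
lines (plants regenerated after irradiation), columns are markers, and each
cell records whether the marker locus was retained (``1``), deleted (``0``)
or could not be scored (``NA``).  Around that matrix live three small tables:
per-marker metadata (marker class, anchor status, deletion-bin and BAC-contig
assignment), per-bin physical/map sizes, and per-contig physical sizes.

All tables are plain TSV with documented headers; state tokens for the
genotype matrix are configurable because no standard file format exists for
RH panels.  The module also ships reference tables for wheat chromosome 3B
(the 11 cytogenetic deletion bins with their physical, RH-map and genetic-map
sizes, and the 17 multi-marker BAC contigs of known physical size), used by
the metrics layer and as a realistic template for the simulator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Cell states of a genotype matrix (int8 codes).
RETAINED: int = 1
DELETED: int = 0
MISSING: int = -1

MARKER_CLASSES = ("ISBP", "SSR", "DArT", "OTHER")

# Line classes (see rhmap.mapping.classify_lines).
INTACT = "INTACT"
WHOLE_LOSS = "WHOLE_LOSS"
SUPRA_ARM_LOSS = "SUPRA_ARM_LOSS"
INFORMATIVE = "INFORMATIVE"

_DATA_CHECKSUMS = {
    "bins_3b.tsv": "50d3507da55099ff14422048e1c1e929862b75cad599321acde6a6e515d22bce",
    "contigs_3b.tsv": "b931a36a199608bf382a530384fecab8ff6e0c4a73c3228c90336c093c87c30c",
}


class FixtureChecksumError(RuntimeError):
    """Raised when a packaged reference table does not match its checksum."""


@dataclass
class GenotypeMatrix:
    """Lines x markers grid of retention calls.

    ``calls`` is an int8 array with values RETAINED (1), DELETED (0) or
    MISSING (-1); rows follow ``line_ids``, columns follow ``marker_ids``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        for name, ids in (("line", self.line_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes[:5]}")
        bad = ~np.isin(self.calls, (RETAINED, DELETED, MISSING))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"invalid call state {self.calls[r, c]} at line "
                f"{self.line_ids[r]!r}, marker {self.marker_ids[c]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_ids.index(marker_id)]

    def row(self, line_id: str) -> np.ndarray:
        return self.calls[self.line_ids.index(line_id)]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return GenotypeMatrix(list(self.line_ids), list(marker_ids), self.calls[:, idx])


@dataclass(frozen=True)
class MarkerInfo:
    """Per-marker metadata; anchor markers must carry a deletion-bin name."""

    marker_id: str
    marker_class: str = "OTHER"
    is_anchor: bool = False
    bin_name: str | None = None
    contig_id: str | None = None
    physical_bp: int | None = None  # 0-based position within contig

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        if self.is_anchor and self.bin_name is None:
            raise ValueError(f"anchor marker {self.marker_id!r} lacks a bin_name")


@dataclass(frozen=True)
class BinRecord:
    """A cytogenetic deletion bin with physical and map sizes.

    ``frac_start``/``frac_end`` are the arm fractions in the bin's name
    (e.g. 3BS8-0.78-0.87); centromeric bins run from 0.  ``map_cM`` is None
    when the bin had no genetic-map coverage.  The chromosome-total row is
    represented with ``arm=None`` and fractions spanning [0, 1].
    """

    bin_name: str
    arm: str | None
    frac_start: float
    frac_end: float
    size_mb: float
    map_cR: float
    map_cM: float | None = None
    n_markers: int | None = None
    full_name: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in (None, "S", "L"):
            raise ValueError(f"arm must be S, L or None, got {self.arm!r}")
        if not self.frac_start < self.frac_end:
            raise ValueError(f"{self.bin_name}: frac_start must be < frac_end")
        if self.size_mb <= 0:
            raise ValueError(f"{self.bin_name}: size_mb must be > 0")
        if self.map_cR < 0 or (self.map_cM is not None and self.map_cM < 0):
            raise ValueError(f"{self.bin_name}: map spans must be >= 0")


@dataclass(frozen=True)
class ContigRecord:
    """A BAC contig of known (estimated) physical size placed on the map.

    ``size_mb == 0.0`` means the contig is below the resolution of BAC
    fingerprinting, not literally empty.  ``marker_ids`` may be omitted when
    only the marker count is known (as in the packaged reference table);
    ``span_cR`` may carry a pre-computed map span for the same reason.
    """

    contig_id: str
    size_mb: float
    bin_name: str | None = None
    marker_ids: tuple[str, ...] | None = None
    n_markers: int | None = None
    span_cR: float | None = None

    def __post_init__(self) -> None:
        if self.size_mb < 0:
            raise ValueError(f"{self.contig_id}: size_mb must be >= 0")
        if self.marker_ids is not None and len(self.marker_ids) < 1:
            raise ValueError(f"{self.contig_id}: needs at least one marker")

    @property
    def marker_count(self) -> int:
        if self.marker_ids is not None:
            return len(self.marker_ids)
        if self.n_markers is not None:
            return self.n_markers
        return 0


# ---------------------------------------------------------------------------
# Genotype matrix I/O
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    path: str | Path,
    *,
    retained_token: str = "1",
    deleted_token: str = "0",
    missing_token: str = "NA",
    sep: str = "\t",
) -> GenotypeMatrix:
    """Read a delimited genotype matrix (first row marker ids, first column
    line ids).  Raises ``ValueError`` naming the offending cell on any token
    outside the configured three-state alphabet, and on ragged rows."""
    path = Path(path)
    tokens = {retained_token: RETAINED, deleted_token: DELETED, missing_token: MISSING}
    if len(tokens) != 3:
        raise ValueError("state tokens must be distinct")
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
        marker_ids = [m for m in header[1:] if m != ""]
        n_cols = len(marker_ids)
        line_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split(sep)
            if len(fields) - 1 != n_cols:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {n_cols} calls, "
                    f"got {len(fields) - 1} (ragged row)"
                )
            line_ids.append(fields[0])
            row = []
            for j, tok in enumerate(fields[1:]):
                try:
                    row.append(tokens[tok])
                except KeyError:
                    raise ValueError(
                        f"{path.name}:{lineno}: invalid token {tok!r} for line "
                        f"{fields[0]!r}, marker {marker_ids[j]!r}"
                    ) from None
            rows.append(row)
    return GenotypeMatrix(line_ids, marker_ids, np.array(rows, dtype=np.int8))


def write_genotype_matrix(
    matrix: GenotypeMatrix,
    path: str | Path,
    *,
    retained_token: str = "1",
    deleted_token: str = "0",
    missing_token: str = "NA",
    sep: str = "\t",
) -> None:
    """Write a genotype matrix as delimited text (inverse of the reader)."""
    rev = {RETAINED: retained_token, DELETED: deleted_token, MISSING: missing_token}
    with Path(path).open("w") as fh:
        fh.write(sep.join(["line_id", *matrix.marker_ids]) + "\n")
        for i, line_id in enumerate(matrix.line_ids):
            cells = (rev[int(v)] for v in matrix.calls[i])
            fh.write(sep.join([line_id, *cells]) + "\n")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def _none_if_na(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "NA":
        return None
    return value


def read_marker_table(path: str | Path) -> list[MarkerInfo]:
    """TSV with columns marker_id, marker_class, is_anchor, bin_name,
    contig_id, physical_bp (the last three optional / NA-able)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    out = []
    for rec in df.to_dict("records"):
        bp = _none_if_na(rec.get("physical_bp"))
        out.append(
            MarkerInfo(
                marker_id=str(rec["marker_id"]),
                marker_class=str(rec.get("marker_class", "OTHER")),
                is_anchor=bool(rec.get("is_anchor", False)),
                bin_name=_none_if_na(rec.get("bin_name")),
                contig_id=_none_if_na(rec.get("contig_id")),
                physical_bp=None if bp is None else int(bp),
            )
        )
    return out


def write_marker_table(markers: Iterable[MarkerInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "marker_class": m.marker_class,
                "is_anchor": m.is_anchor,
                "bin_name": m.bin_name if m.bin_name is not None else "NA",
                "contig_id": m.contig_id if m.contig_id is not None else "NA",
                "physical_bp": m.physical_bp if m.physical_bp is not None else "NA",
            }
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)


def _bin_from_record(rec: dict) -> BinRecord:
    cm = _none_if_na(rec.get("map_cM"))
    arm = _none_if_na(rec.get("arm"))
    fs, fe = _none_if_na(rec.get("frac_start")), _none_if_na(rec.get("frac_end"))
    return BinRecord(
        bin_name=str(rec["bin_name"]),
        arm=arm,
        frac_start=0.0 if fs is None else float(fs),
        frac_end=1.0 if fe is None else float(fe),
        size_mb=float(rec["size_mb"]),
        map_cR=float(rec["map_cR"]),
        map_cM=None if cm is None else float(cm),
        n_markers=None if _none_if_na(rec.get("n_markers")) is None else int(rec["n_markers"]),
        full_name=_none_if_na(rec.get("full_name")),
    )


def read_bin_table(path: str | Path) -> list[BinRecord]:
    """TSV with columns bin_name, arm, frac_start, frac_end, size_mb,
    map_cR, map_cM (optional: full_name, n_markers)."""
    df = pd.read_csv(path, sep="\t")
    return [_bin_from_record(rec) for rec in df.to_dict("records")]


def write_bin_table(bins: Iterable[BinRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "bin_name": b.bin_name,
                "full_name": b.full_name or b.bin_name,
                "arm": b.arm if b.arm is not None else "NA",
                "frac_start": b.frac_start,
                "frac_end": b.frac_end,
                "n_markers": b.n_markers if b.n_markers is not None else "NA",
                "size_mb": b.size_mb,
                "map_cR": b.map_cR,
                "map_cM": b.map_cM if b.map_cM is not None else "NA",
            }
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)


def read_contig_table(path: str | Path) -> list[ContigRecord]:
    """TSV with columns contig_id, size_mb, span_cR, n_markers, bin_name."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for rec in df.to_dict("records"):
        span = _none_if_na(rec.get("span_cR"))
        nm = _none_if_na(rec.get("n_markers"))
        out.append(
            ContigRecord(
                contig_id=str(rec["contig_id"]),
                size_mb=float(rec["size_mb"]),
                bin_name=_none_if_na(rec.get("bin_name")),
                n_markers=None if nm is None else int(nm),
                span_cR=None if span is None else float(span),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Packaged wheat-3B reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    ref = resources.files("rhmap.data").joinpath(name)
    with resources.as_file(ref) as p:
        data = p.read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != _DATA_CHECKSUMS[name]:
            raise FixtureChecksumError(
                f"packaged table {name} is corrupted "
                f"(sha256 {digest} != {_DATA_CHECKSUMS[name]})"
            )
        return p


def load_reference_tables() -> tuple[list[BinRecord], list[ContigRecord]]:
    """Load the packaged wheat chromosome 3B reference tables.

    Returns 12 BinRecords (the 11 named deletion bins in physical order from
    the 3BS telomere to the 3BL telomere, plus the chromosome-total row named
    ``Chr``) and the 17 multi-marker BAC contigs with known physical size
    (9 with a nonzero RH-map span, 8 with zero span).
    """
    bins = read_bin_table(_data_path("bins_3b.tsv"))
    contigs = read_contig_table(_data_path("contigs_3b.tsv"))
    return bins, contigs


def chromosome_record(bins: Sequence[BinRecord]) -> BinRecord:
    """Return the chromosome-total row (bin_name ``Chr``) of a bin table."""
    for b in bins:
        if b.bin_name == "Chr":
            return b
    raise KeyError("no chromosome-total record (bin_name 'Chr') present")


def named_bins(bins: Sequence[BinRecord]) -> list[BinRecord]:
    """Return the per-bin rows, dropping any chromosome-total record."""
    return [b for b in bins if b.bin_name != "Chr"]
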