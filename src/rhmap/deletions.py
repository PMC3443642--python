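"""Calling, sizing and summarising radiation-induced deletions.

A deletion is a maximal run of consecutively DELETED loci in map order,
bounded by RETAINED loci or the map ends; MISSING loci bridge a run without
extending it.  Because the true breakpoints fall somewhere between the last
deleted and first retained locus on each side, two cR spans bound every
call: the *inner* span (first to last deleted locus) and the *outer* span
(between the flanking retained loci).  The reported size uses the midpoint
convention ``size_cR = (inner + outer) / 2``, unbiased when the true
boundary is uniform within the flanking interval.

centiRay spans are converted to Mb with the per-bin conversion ratio
(resolution, Mb per cR): a span is partitioned by the bin boundaries on the
cR axis, each segment multiplied by its bin's ratio, and the pieces summed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import DELETED, INFORMATIVE, MISSING, RETAINED, GenotypeMatrix
from .mapping import RHMap, _deleted_runs, deletion_frequency


@dataclass(frozen=True)
class DeletionCall:
    line_id: str
    first_deleted_locus: str
    last_deleted_locus: str
    inner_span_cR: float
    outer_span_cR: float
    size_cR: float              # midpoint convention: (inner + outer) / 2
    size_mb: float | None       # None when bin resolutions are unavailable
    bins_touched: tuple[str, ...]
    midpoint_cR: float
    n_deleted_loci: int

    def __post_init__(self) -> None:
        if not (self.inner_span_cR - 1e-9 <= self.size_cR <= self.outer_span_cR + 1e-9):
            raise ValueError("size_cR must lie between inner and outer spans")


@dataclass(frozen=True)
class BinDeletionSummary:
    bin_name: str
    n_deletions: int
    mean_size_mb: float | None
    sd_size_mb: float | None
    mean_deletion_frequency: float | None


def locus_states(matrix: GenotypeMatrix, rh_map: RHMap, line_id: str) -> np.ndarray:
    """Per-locus call for one line in map order: majority over the locus's
    member markers, MISSING on an exact tie or when all members are missing."""
    row = matrix.calls[matrix.line_ids.index(line_id)]
    col = {m: j for j, m in enumerate(matrix.marker_ids)}
    states = np.empty(rh_map.n_loci, dtype=np.int8)
    for i, g in enumerate(rh_map.loci):
        vals = row[[col[m] for m in g.members if m in col]]
        n_ret = int((vals == RETAINED).sum())
        n_del = int((vals == DELETED).sum())
        if n_ret > n_del:
            states[i] = RETAINED
        elif n_del > n_ret:
            states[i] = DELETED
        else:
            states[i] = MISSING
    return states


def cr_to_mb(
    start_cR: float,
    end_cR: float,
    bin_spans: Mapping[str, tuple[float, float]],
    resolutions: Mapping[str, float | None],
) -> float:
    """Convert a cR interval to Mb using per-bin conversion ratios.

    ``bin_spans`` maps bin name to its (start, end) on the cR axis and
    ``resolutions`` to its Mb-per-cR ratio.  Raises when the interval
    overlaps a bin without a defined ratio (e.g. an anchor-less bin)."""
    if end_cR < start_cR:
        raise ValueError("end_cR must be >= start_cR")
    total = 0.0
    covered = 0.0
    for name, (lo, hi) in bin_spans.items():
        seg = min(end_cR, hi) - max(start_cR, lo)
        if seg <= 1e-12:
            continue
        res = resolutions.get(name)
        if res is None:
            raise ValueError(
                f"span [{start_cR}, {end_cR}] overlaps bin {name!r} with no "
                "defined Mb/cR resolution"
            )
        total += seg * res
        covered += seg
    span = end_cR - start_cR
    if span > 0 and covered < span - 1e-6:
        raise ValueError(
            f"span [{start_cR}, {end_cR}] is not fully covered by bin spans"
        )
    return total


def cr_span_to_mb(span_cR: float, resolution_mb_per_cR: float) -> float:
    """Single-bin convenience: Mb = cR span x (Mb per cR)."""
    if span_cR < 0 or resolution_mb_per_cR < 0:
        raise ValueError("span and resolution must be non-negative")
    return span_cR * resolution_mb_per_cR


def call_deletions(
    line_id: str,
    matrix: GenotypeMatrix,
    rh_map: RHMap,
    *,
    bin_spans: Mapping[str, tuple[float, float]] | None = None,
    resolutions: Mapping[str, float | None] | None = None,
    line_class: str | None = None,
) -> list[DeletionCall]:
    """Call per-line deletions on the ordered map.

    When ``line_class`` is given it must be INFORMATIVE (whole-chromosome and
    supra-arm losses are not sized; see classify_lines).  Mb sizes are the
    mean of the inner- and outer-interval conversions, reported only when
    ``bin_spans``/``resolutions`` are supplied.
    """
    if line_class is not None and line_class != INFORMATIVE:
        raise ValueError(
            f"line {line_id!r} is {line_class}; deletions are called only on "
            "INFORMATIVE lines (see classify_lines)"
        )
    states = locus_states(matrix, rh_map, line_id)
    pos = rh_map.positions_cR
    map_start, map_end = float(pos[0]), float(pos[-1])
    calls = []
    for a, b in _deleted_runs(states):
        left = next((j for j in range(a - 1, -1, -1) if states[j] == RETAINED), None)
        right = next((j for j in range(b + 1, len(states)) if states[j] == RETAINED), None)
        inner_lo, inner_hi = float(pos[a]), float(pos[b])
        outer_lo = float(pos[left]) if left is not None else map_start
        outer_hi = float(pos[right]) if right is not None else map_end
        inner = inner_hi - inner_lo
        outer = outer_hi - outer_lo
        size_mb = None
        if bin_spans is not None and resolutions is not None:
            size_mb = 0.5 * (
                cr_to_mb(inner_lo, inner_hi, bin_spans, resolutions)
                + cr_to_mb(outer_lo, outer_hi, bin_spans, resolutions)
            )
        touched = tuple(
            dict.fromkeys(
                rh_map.bins[j]
                for j in range(a, b + 1)
                if rh_map.bins[j] is not None
            )
        )
        calls.append(
            DeletionCall(
                line_id=line_id,
                first_deleted_locus=rh_map.loci[a].rep,
                last_deleted_locus=rh_map.loci[b].rep,
                inner_span_cR=inner,
                outer_span_cR=outer,
                size_cR=0.5 * (inner + outer),
                size_mb=size_mb,
                bins_touched=touched,
                midpoint_cR=0.5 * (inner_lo + inner_hi),
                n_deleted_loci=int((states[a : b + 1] == DELETED).sum()),
            )
        )
    return calls


def _bin_of_midpoint(
    midpoint_cR: float, bin_spans: Mapping[str, tuple[float, float]]
) -> str | None:
    for name, (lo, hi) in bin_spans.items():
        if lo - 1e-9 <= midpoint_cR <= hi + 1e-9:
            return name
    return None


def summarize_deletions(
    calls: Sequence[DeletionCall],
    bin_spans: Mapping[str, tuple[float, float]],
    *,
    matrix: GenotypeMatrix | None = None,
    rh_map: RHMap | None = None,
) -> tuple[dict[str, BinDeletionSummary], dict[str, int], float | None]:
    """Per-bin deletion summaries, per-line deletion counts and the
    chromosome-wide mean deletion size (Mb).

    A deletion is attributed to the bin containing its cR midpoint.  When
    ``matrix`` and an annotated ``rh_map`` are given, each bin also reports
    its mean marker deletion frequency (the column-mean of per-marker
    deletion frequencies over the bin's markers).
    """
    if not calls:
        raise ValueError("no deletion calls to summarise")
    by_bin: dict[str, list[DeletionCall]] = {b: [] for b in bin_spans}
    per_line: dict[str, int] = {}
    for c in calls:
        per_line[c.line_id] = per_line.get(c.line_id, 0) + 1
        b = _bin_of_midpoint(c.midpoint_cR, bin_spans)
        if b is not None:
            by_bin[b].append(c)

    freq_by_bin: dict[str, float | None] = {b: None for b in bin_spans}
    if matrix is not None and rh_map is not None:
        col = {m: j for j, m in enumerate(matrix.marker_ids)}
        markers_by_bin: dict[str, list[int]] = {b: [] for b in bin_spans}
        for g, bin_name in zip(rh_map.loci, rh_map.bins):
            if bin_name in markers_by_bin:
                markers_by_bin[bin_name].extend(col[m] for m in g.members if m in col)
        for b, idx in markers_by_bin.items():
            if idx:
                freq_by_bin[b] = float(
                    np.mean([deletion_frequency(matrix.calls[:, j]) for j in idx])
                )

    summaries = {}
    for b, cs in by_bin.items():
        sizes = [c.size_mb for c in cs if c.size_mb is not None]
        summaries[b] = BinDeletionSummary(
            bin_name=b,
            n_deletions=len(cs),
            mean_size_mb=float(np.mean(sizes)) if sizes else None,
            sd_size_mb=float(np.std(sizes, ddof=1)) if len(sizes) > 1 else None,
            mean_deletion_frequency=freq_by_bin[b],
        )
    all_sizes = [c.size_mb for c in calls if c.size_mb is not None]
    overall = float(np.mean(all_sizes)) if all_sizes else None
    return summaries, per_line, overall
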