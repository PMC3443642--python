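"""Per-bin, per-contig and chromosome-wide map statistics.

For a deletion bin of physical size S (Mb) with RH-map span L_cR and
genetic-map span L_cM:

* saturation          = S / n_markers          (Mb per marker)
* RH resolution       = S / L_cR               (Mb per cR)
* genetic resolution  = S / L_cM               (Mb per cM)
* BR frequency        = (L_cR / 2) / S         (break/repair events per Mb:
  each deletion needs a proximal and a distal break, so cR/2 counts events)
* CO frequency        = L_cM / S               (crossing-overs per Mb)
* map-size ratio      = L_cR / L_cM

Chromosome-wide values are totals-based (total Mb over total map length),
not means of the per-bin values.  Display rounding is half-up to one
decimal, two for ratios of magnitude >= 10, with raw values retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io import BinRecord, ContigRecord, chromosome_record, named_bins
from .mapping import RHMap


def round_display(value: float | None, decimals: int = 1) -> float | None:
    """Half-up rounding to the printed precision."""
    if value is None:
        return None
    q = 10 ** decimals
    return math.floor(value * q + 0.5) / q


@dataclass(frozen=True)
class BinMetrics:
    bin_name: str
    size_mb: float
    map_cR: float
    map_cM: float | None
    n_markers: int | None
    saturation_mb_per_marker: float | None
    resolution_rh_mb_per_cR: float | None
    resolution_gen_mb_per_cM: float | None
    br_freq: float | None
    co_freq: float | None
    ratio_cR_per_cM: float | None

    def display(self) -> dict:
        """Values rounded the way the per-bin table is printed."""
        ratio = self.ratio_cR_per_cM
        return {
            "bin_name": self.bin_name,
            "saturation_mb_per_marker": round_display(self.saturation_mb_per_marker),
            "resolution_rh_mb_per_cR": round_display(self.resolution_rh_mb_per_cR),
            "resolution_gen_mb_per_cM": round_display(self.resolution_gen_mb_per_cM),
            "br_freq": round_display(self.br_freq),
            "co_freq": round_display(self.co_freq),
            "ratio_cR_per_cM": round_display(
                ratio, 2 if ratio is not None and abs(ratio) >= 10 else 1
            ),
        }


@dataclass(frozen=True)
class ContigMetrics:
    contig_id: str
    size_mb: float
    span_cR: float
    n_markers: int
    orientable: bool
    resolution_mb_per_cR: float | None


def _bin_metrics_one(b: BinRecord) -> BinMetrics:
    has_cm = b.map_cM is not None and b.map_cM > 0
    return BinMetrics(
        bin_name=b.bin_name,
        size_mb=b.size_mb,
        map_cR=b.map_cR,
        map_cM=b.map_cM,
        n_markers=b.n_markers,
        saturation_mb_per_marker=(
            b.size_mb / b.n_markers if b.n_markers else None
        ),
        resolution_rh_mb_per_cR=b.size_mb / b.map_cR if b.map_cR > 0 else None,
        resolution_gen_mb_per_cM=b.size_mb / b.map_cM if has_cm else None,
        br_freq=(b.map_cR / 2.0) / b.size_mb,
        co_freq=b.map_cM / b.size_mb if b.map_cM is not None else None,
        ratio_cR_per_cM=b.map_cR / b.map_cM if has_cm else None,
    )


def compute_bin_metrics(
    bin_records: Sequence[BinRecord],
) -> tuple[list[BinMetrics], BinMetrics]:
    """Derived statistics for each bin plus the chromosome-total row.

    When the input carries an explicit chromosome record (bin_name ``Chr``)
    its printed totals are used; otherwise totals are summed over bins.
    Genetic metrics are None for bins without genetic-map coverage.
    """
    bins = named_bins(bin_records)
    if not bins:
        raise ValueError("no bin records given")
    per_bin = [_bin_metrics_one(b) for b in bins]
    try:
        chrom = chromosome_record(bin_records)
    except KeyError:
        chrom = BinRecord(
            bin_name="Chr",
            arm=None,
            frac_start=0.0,
            frac_end=1.0,
            size_mb=sum(b.size_mb for b in bins),
            map_cR=sum(b.map_cR for b in bins),
            map_cM=sum(b.map_cM or 0.0 for b in bins) or None,
            n_markers=sum(b.n_markers or 0 for b in bins) or None,
        )
    return per_bin, _bin_metrics_one(chrom)


def uniformity(values: Sequence[float], average: float) -> float:
    """Maximum fold-deviation of per-bin metric values from the chromosome
    average: ``max over bins of max(v / avg, avg / v)``."""
    vals = [v for v in values if v is not None]
    if len(vals) < 2:
        raise ValueError("need at least 2 bins with the metric defined")
    if average <= 0:
        raise ValueError("average must be positive")
    if min(vals) <= 0:
        raise ValueError("metric values must be positive")
    return max(max(v / average, average / v) for v in vals)


def contig_metrics(
    contig_records: Sequence[ContigRecord],
    rh_map: RHMap | None = None,
) -> list[ContigMetrics]:
    """Per-contig map span, orientability and within-contig resolution.

    The span is the range of the contig's marker positions on the map (or
    the record's stored ``span_cR`` when no map is given, as for the
    packaged reference table).  A contig is orientable when it has two or
    more mapped markers at distinct positions (span > 0).  Contigs with no
    mapped markers are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    positions = rh_map.marker_positions() if rh_map is not None else {}
    out = []
    for rec in contig_records:
        if rh_map is not None and rec.marker_ids is not None:
            mapped = [positions[m] for m in rec.marker_ids if m in positions]
            if not mapped:
                logger.warning("contig %s has no mapped markers; skipped", rec.contig_id)
                continue
            span = max(mapped) - min(mapped)
            n = len(mapped)
        else:
            if rec.span_cR is None:
                logger.warning("contig %s has no span information; skipped", rec.contig_id)
                continue
            span = rec.span_cR
            n = rec.marker_count
        orientable = span > 0 and n >= 2
        out.append(
            ContigMetrics(
                contig_id=rec.contig_id,
                size_mb=rec.size_mb,
                span_cR=span,
                n_markers=n,
                orientable=orientable,
                resolution_mb_per_cR=rec.size_mb / span if orientable else None,
            )
        )
    return out


def marker_density(
    map_length_cR: float, n_markers: int, chromosome_mb: float
) -> tuple[float, float]:
    """Average marker spacing: (cR per marker, Mb per marker)."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return map_length_cR / n_markers, chromosome_mb / n_markers


def placement_error(
    predicted_interval_bp: tuple[float, float],
    true_bp: float,
    chromosome_bp: float,
) -> float:
    """Map placement error as a percentage of the chromosome length.

    Zero when the true position falls inside the predicted interval;
    otherwise the distance to the nearest interval edge, normalised so that
    an error of one full chromosome length is 100%.
    """
    lo, hi = sorted(predicted_interval_bp)
    if lo <= true_bp <= hi:
        return 0.0
    dist = (lo - true_bp) if true_bp < lo else (true_bp - hi)
    return 100.0 * dist / chromosome_bp
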