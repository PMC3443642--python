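"""Synthetic radiation-hybrid panel generator.

The generator emulates a gamma-irradiated RH panel for a single wheat-like
chromosome.  Its ground truth implements the chromatin-openness working
hypothesis: a single per-bin latent factor omega ("openness") drives both
somatic break/repair activity and meiotic crossing-over, so that the
pipeline's ability to recover a BR-CO correlation is a meaningful test.

Generative model, per informative line and deletion bin b (physical size
S_b Mb, openness omega_b):

* number of deletions  K_b ~ Poisson(lam * omega_b * S_b)
* each deletion starts uniformly within the bin and extends toward the
  centromere until it has consumed an Exponential(mu) amount of *openness
  mass* (integral of omega over the traversed chromatin), truncated at the
  arm boundary — within a bin this is an Exponential length of mean
  mu / omega_b

so open regions accumulate more, shorter deletions while compact regions
resist the spread of the repair-mediated loss; the per-marker deletion
probability is exactly 1 - e^(-lam*mu), independent of omega (deletion
frequency is flat across the chromosome even though deletion number and
size are not).
Whole-chromosome-loss lines are entirely deleted, intact lines entirely
retained, and supra-arm-loss lines carry one run covering a whole arm plus a
uniform extension into the other (translocation remnants).  Genotyping noise
mimics duplicate scoring: each call is read twice with per-read error eps;
discordant duplicates become MISSING, concordant errors (probability eps^2)
flip the call.  Genetic map spans are cM_b = rho * omega_b * S_b with
Poisson counting noise over a notional F2 of configurable size.

The default configuration reproduces the study conditions of a 92-line
panel genotyped at ~540 markers over an 891 Mb chromosome of 11 deletion
bins (line-class mix 13 intact : 9 whole-loss : 8 supra-arm : 62
informative), with rates calibrated so replicate means approximate a 0.89
retention frequency among lines retaining chromatin, 2.8 detected deletions
per informative line and a 26.4 Mb mean deletion size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import (
    DELETED,
    INFORMATIVE,
    INTACT,
    MISSING,
    RETAINED,
    SUPRA_ARM_LOSS,
    WHOLE_LOSS,
    BinRecord,
    GenotypeMatrix,
    MarkerInfo,
)

__all__ = [
    "SimBin",
    "SimConfig",
    "SimTruth",
    "SimPanel",
    "simulate_panel",
    "study_preset",
    "adjacent_discordance_expectation",
    "per_line_bin_deletion_fractions",
    "truth_map",
]


@dataclass(frozen=True)
class SimBin:
    """One deletion bin of the simulated chromosome (physical order)."""

    name: str
    arm: str                    # 'S' or 'L'
    frac_start: float
    frac_end: float
    size_mb: float
    openness: float             # omega_b > 0, chromosome mean ~ 1
    n_markers: int | None = None
    cm_override: float | None = None

    def __post_init__(self) -> None:
        if self.openness <= 0:
            raise ValueError(f"bin {self.name}: openness must be > 0")
        if self.size_mb <= 0:
            raise ValueError(f"bin {self.name}: size_mb must be > 0")


# Wheat-3B-like template: 11 bins in physical order from the S telomere to
# the L telomere, with openness proportional to the per-bin break/repair
# activity of the reference chromosome (normalised to a size-weighted mean
# of 1, ~26-fold range between the most open and most compact bin).
_TEMPLATE_BINS: tuple[SimBin, ...] = (
    SimBin("3BS3", "S", 0.87, 1.00, 56.0, 0.7531, 7),
    SimBin("3BS8", "S", 0.78, 0.87, 39.0, 7.7736, 155),
    SimBin("3BS9", "S", 0.57, 0.75, 78.0, 0.4695, 9),
    SimBin("3BS2", "S", 0.56, 0.57, 4.0, 4.8554, 3),
    SimBin("3BS1", "S", 0.33, 0.55, 95.0, 0.6333, 44),
    SimBin("C-3BS1", "S", 0.00, 0.33, 142.0, 0.4308, 28),
    SimBin("C-3BL2", "L", 0.00, 0.22, 124.0, 0.4229, 27),
    SimBin("3BL2", "L", 0.22, 0.28, 33.0, 0.9445, 29),
    SimBin("3BL1", "L", 0.31, 0.50, 39.0, 0.5020, 47),
    SimBin("3BL10", "L", 0.50, 0.63, 73.0, 0.2994, 4),
    SimBin("3BL7", "L", 0.63, 1.00, 208.0, 1.1693, 187),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the panel generator (defaults = study conditions)."""

    seed: int = 0
    n_lines: int = 92
    bins: tuple[SimBin, ...] = _TEMPLATE_BINS
    markers_per_mb: float | None = None   # None: use per-bin marker counts
    anchor_fraction: float = 0.24         # fraction of markers with known bin
    # line-class mix INTACT : WHOLE_LOSS : SUPRA_ARM_LOSS : INFORMATIVE
    class_mix: tuple[float, float, float, float] = (13, 9, 8, 62)
    lam: float = 0.00340      # deletion initiations per Mb per unit openness
    mu: float = 25.0          # deletion length scale, Mb x openness
    rho: float = 0.2009       # crossing-overs (cM) per Mb per unit openness
    eps: float = 0.01         # per-read assay error rate
    missing_rate: float = 0.005
    duplicate_genotyping: bool = True     # discordant duplicates -> MISSING
    f2_size: int = 300        # notional mapping population for cM noise

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix)) == 0:
            raise ValueError("class_mix must have positive mass")
        if min(self.class_mix) < 0:
            raise ValueError("class proportions must be >= 0")
        for rate in (self.lam, self.mu, self.rho, self.eps, self.missing_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SimTruth:
    """Everything the generator knows that the pipeline must re-infer."""

    marker_ids: list[str]                 # true physical order
    positions_mb: np.ndarray              # global physical coordinates
    marker_bins: list[str]
    marker_arms: list[str]
    line_classes: list[str]
    deletions: dict[str, list[tuple[float, float]]]   # per-line intervals
    cm_by_bin: dict[str, float]
    arm_spans: dict[str, tuple[float, float]]
    config: SimConfig


@dataclass
class SimPanel:
    matrix: GenotypeMatrix
    markers: list[MarkerInfo]
    bins: list[BinRecord]
    truth: SimTruth


def _bin_layout(cfg: SimConfig):
    """Global physical offsets of bins and arms (bins are laid end to end,
    S arm first, so coordinate 0 is the S telomere)."""
    offsets = []
    pos = 0.0
    for b in cfg.bins:
        offsets.append((b, pos, pos + b.size_mb))
        pos += b.size_mb
    arm_spans = {}
    for arm in ("S", "L"):
        spans = [(lo, hi) for b, lo, hi in offsets if b.arm == arm]
        if spans:
            arm_spans[arm] = (min(s[0] for s in spans), max(s[1] for s in spans))
    return offsets, arm_spans, pos


def _marker_positions(cfg: SimConfig, offsets) -> tuple[np.ndarray, list[str], list[str]]:
    positions, bins, arms = [], [], []
    for b, lo, hi in offsets:
        if cfg.markers_per_mb is not None:
            n = max(1, round(cfg.markers_per_mb * b.size_mb))
        else:
            n = b.n_markers if b.n_markers else max(1, round(0.6 * b.size_mb))
        step = b.size_mb / n
        for i in range(n):
            positions.append(lo + (i + 0.5) * step)
            bins.append(b.name)
            arms.append(b.arm)
    return np.asarray(positions), bins, arms


def _class_counts(cfg: SimConfig) -> dict[str, int]:
    mix = np.asarray(cfg.class_mix, dtype=float)
    frac = mix / mix.sum()
    raw = frac * cfg.n_lines
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding to hit n_lines exactly
    for i in np.argsort(-(raw - counts))[: cfg.n_lines - counts.sum()]:
        counts[i] += 1
    names = (INTACT, WHOLE_LOSS, SUPRA_ARM_LOSS, INFORMATIVE)
    return dict(zip(names, counts))


class _ArmScale:
    """Openness-scaled coordinates of one arm.

    ``v(x)`` integrates openness from the telomere toward the centromere,
    so one v-unit is one Mb of fully open (omega = 1) chromatin.  In
    v-space the deletion process is homogeneous — starts Poisson with rate
    lam per v-unit, extents Exponential(mu) — which makes the per-point
    deletion probability exactly ``1 - e^(-lam*mu)`` everywhere while the
    local physical length scale is mu/omega_b and per-bin deletion counts
    are Poisson(lam * omega_b * S_b): open regions collect more, shorter
    deletions, compact regions fewer, larger ones.
    """

    def __init__(self, bins_tip_to_cen, arm: str, arm_lo: float, arm_hi: float):
        self.arm = arm
        self.arm_lo, self.arm_hi = arm_lo, arm_hi
        self.phys_edges = [0.0]
        self.v_edges = [0.0]
        self.omegas = []
        for b, lo, hi in bins_tip_to_cen:
            size = hi - lo
            self.phys_edges.append(self.phys_edges[-1] + size)
            self.v_edges.append(self.v_edges[-1] + b.openness * size)
            self.omegas.append(b.openness)
        self.total_v = self.v_edges[-1]
        self.names = [b.name for b, lo, hi in bins_tip_to_cen]

    def u_of_pos(self, pos: float) -> float:
        """Telomere distance (Mb) of a global physical position."""
        return pos - self.arm_lo if self.arm == "S" else self.arm_hi - pos

    def v_of_pos(self, pos: float) -> float:
        u = self.u_of_pos(pos)
        k = int(np.searchsorted(self.phys_edges[1:-1], u, side="right"))
        return self.v_edges[k] + self.omegas[k] * (u - self.phys_edges[k])

    def pos_of_v(self, v: float) -> float:
        v = min(max(v, 0.0), self.total_v)
        k = int(np.searchsorted(self.v_edges[1:-1], v, side="right"))
        u = self.phys_edges[k] + (v - self.v_edges[k]) / self.omegas[k]
        return self.arm_lo + u if self.arm == "S" else self.arm_hi - u

    def v_interval_to_phys(self, v_lo: float, v_hi: float) -> tuple[float, float]:
        a = self.pos_of_v(v_lo)
        b = self.pos_of_v(v_hi)
        return (min(a, b), max(a, b))

    def bin_v_range(self, name: str) -> tuple[float, float]:
        k = self.names.index(name)
        return self.v_edges[k], self.v_edges[k + 1]


def _arm_scales(cfg: SimConfig) -> dict[str, _ArmScale]:
    offsets, arm_spans, _ = _bin_layout(cfg)
    scales = {}
    for arm, (arm_lo, arm_hi) in arm_spans.items():
        bins_in_arm = [(b, lo, hi) for b, lo, hi in offsets if b.arm == arm]
        if arm == "L":
            bins_in_arm = list(reversed(bins_in_arm))   # tip -> centromere
        scales[arm] = _ArmScale(bins_in_arm, arm, arm_lo, arm_hi)
    return scales


def _draw_deletions(cfg: SimConfig, scales: dict[str, _ArmScale], rng) -> list[tuple[float, float]]:
    """Deletion intervals of one informative line (physical coordinates).

    Interstitial deletions start uniformly within their bin's v-range and
    extend toward the centromere with Exponential(mu) v-extents (truncated
    at the centromere); each telomere additionally seeds Poisson(lam*mu)
    *terminal* deletions, the stationary mass entering from the chromosome
    end, so coverage does not sag at the tips.
    """
    out = []
    for arm in sorted(scales):
        sc = scales[arm]
        for name in sc.names:
            v_lo, v_hi = sc.bin_v_range(name)
            k = rng.poisson(cfg.lam * (v_hi - v_lo))
            if k == 0:
                continue
            starts = rng.uniform(v_lo, v_hi, size=k)
            lengths = rng.exponential(cfg.mu, size=k)
            for s, ln in zip(starts, lengths):
                out.append(sc.v_interval_to_phys(s, min(s + ln, sc.total_v)))
        for ln in rng.exponential(cfg.mu, size=rng.poisson(cfg.lam * cfg.mu)):
            out.append(sc.v_interval_to_phys(0.0, min(ln, sc.total_v)))
    return out


def simulate_panel(config: SimConfig) -> SimPanel:
    """Generate one RH panel (genotype matrix, marker metadata, bin table and
    ground truth).  Bit-reproducible for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    offsets, arm_spans, total_mb = _bin_layout(config)
    scales = _arm_scales(config)
    positions, marker_bins, marker_arms = _marker_positions(config, offsets)
    m = len(positions)
    if m < 1:
        raise ValueError("bins too small to hold any marker")
    width = len(str(m))
    marker_ids = [f"M{i + 1:0{width}d}" for i in range(m)]

    counts = _class_counts(config)
    classes = (
        [INTACT] * counts[INTACT]
        + [WHOLE_LOSS] * counts[WHOLE_LOSS]
        + [SUPRA_ARM_LOSS] * counts[SUPRA_ARM_LOSS]
        + [INFORMATIVE] * counts[INFORMATIVE]
    )
    rng.shuffle(classes)
    line_ids = [f"RH{i + 1:03d}" for i in range(config.n_lines)]

    calls = np.full((config.n_lines, m), RETAINED, dtype=np.int8)
    deletions: dict[str, list[tuple[float, float]]] = {}
    for i, (line_id, cls) in enumerate(zip(line_ids, classes)):
        dels: list[tuple[float, float]] = []
        if cls == WHOLE_LOSS:
            dels = [(0.0, total_mb)]
        elif cls == SUPRA_ARM_LOSS:
            lost_arm = "S" if rng.random() < 0.5 else "L"
            other = "L" if lost_arm == "S" else "S"
            a_lo, a_hi = arm_spans[lost_arm]
            o_lo, o_hi = arm_spans[other]
            ext = rng.uniform(0.0, o_hi - o_lo)
            if lost_arm == "S":
                dels = [(a_lo, a_hi + ext)]
            else:
                dels = [(a_hi - (a_hi - a_lo) - ext, a_hi)]
        elif cls == INFORMATIVE:
            dels = _draw_deletions(config, scales, rng)
        deletions[line_id] = dels
        for lo, hi in dels:
            calls[i, (positions >= lo) & (positions <= hi)] = DELETED

    # assay noise: duplicate genotyping with per-read error eps
    if config.eps > 0:
        if config.duplicate_genotyping:
            e1 = rng.random((config.n_lines, m)) < config.eps
            e2 = rng.random((config.n_lines, m)) < config.eps
            flip = e1 & e2
            discord = e1 ^ e2
            calls = np.where(flip, 1 - calls, calls).astype(np.int8)
            calls[discord] = MISSING
        else:
            flip = rng.random((config.n_lines, m)) < config.eps
            calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random((config.n_lines, m)) < config.missing_rate] = MISSING

    matrix = GenotypeMatrix(line_ids, marker_ids, calls)

    # anchor markers: a per-bin subset with known bin assignment
    markers: list[MarkerInfo] = []
    class_probs = {"ISBP": 96 / 541, "SSR": 19 / 541, "DArT": 426 / 541}
    anchor_flags = np.zeros(m, dtype=bool)
    for b, _, _ in offsets:
        idx = [j for j, name in enumerate(marker_bins) if name == b.name]
        k = max(1, round(config.anchor_fraction * len(idx)))
        anchor_flags[rng.choice(idx, size=min(k, len(idx)), replace=False)] = True
    mclasses = rng.choice(
        list(class_probs), size=m, p=np.array(list(class_probs.values()))
    )
    for j in range(m):
        markers.append(
            MarkerInfo(
                marker_id=marker_ids[j],
                marker_class=str(mclasses[j]),
                is_anchor=bool(anchor_flags[j]),
                bin_name=marker_bins[j] if anchor_flags[j] else None,
            )
        )

    # genetic map spans: shared openness driver with Poisson counting noise
    cm_by_bin: dict[str, float] = {}
    for b, _, _ in offsets:
        if b.cm_override is not None:
            cm_by_bin[b.name] = b.cm_override
        else:
            expect = config.rho * b.openness * b.size_mb
            events = rng.poisson(config.f2_size * expect / 100.0)
            cm_by_bin[b.name] = 100.0 * events / config.f2_size

    exp_disc = adjacent_discordance_expectation(config, positions, marker_bins)
    bin_records = []
    for b, lo, hi in offsets:
        idx = [j for j, name in enumerate(marker_bins) if name == b.name]
        inner = [j for j in idx[:-1] if j + 1 in idx]
        bin_records.append(
            BinRecord(
                bin_name=b.name,
                arm=b.arm,
                frac_start=b.frac_start,
                frac_end=b.frac_end,
                size_mb=b.size_mb,
                map_cR=float(100.0 * exp_disc[inner].sum()) if inner else 0.0,
                map_cM=cm_by_bin[b.name],
                n_markers=len(idx),
            )
        )

    truth = SimTruth(
        marker_ids=list(marker_ids),
        positions_mb=positions,
        marker_bins=marker_bins,
        marker_arms=marker_arms,
        line_classes=classes,
        deletions=deletions,
        cm_by_bin=cm_by_bin,
        arm_spans=arm_spans,
        config=config,
    )
    return SimPanel(matrix=matrix, markers=markers, bins=bin_records, truth=truth)


def adjacent_discordance_expectation(
    config: SimConfig,
    positions: np.ndarray,
    marker_bins: Sequence[str],
) -> np.ndarray:
    """Expected panel discordance fraction for each adjacent marker pair.

    In openness-scaled coordinates the deletion process of an informative
    line is a homogeneous Boolean process (rate lam, Exponential(mu)
    extents), so for two markers separated by delta v-units on one arm::

        m1 = lam*mu*(1 - e^(-delta/mu))     # deletions covering one marker
        m2 = lam*mu*e^(-delta/mu)           # deletions covering both
        p_inf = 2*(1 - e^(-m1)) * e^(-m1) * e^(-m2)

    whose first order is the closed form ``2*lam*mu*(1 - e^(-d*omega_b/mu))``
    for physical spacing d within bin b.  Markers on different arms are
    independent (each covered with probability ``1 - e^(-lam*mu)``).
    Supra-arm-loss lines contribute one uniformly placed breakpoint on a
    random arm, intact and whole-loss lines contribute none, and assay
    flips (probability eps^2 per call under duplicate genotyping) mix the
    discordance toward 1/2.  The expectation is the class-mix average,
    every line staying in the denominator.
    """
    by_name = {b.name: b for b in config.bins}
    counts = _class_counts(config)
    n = config.n_lines
    scales = _arm_scales(config)
    arm_len = {a: sc.phys_edges[-1] for a, sc in scales.items()}
    q = config.eps**2 if config.duplicate_genotyping else config.eps
    lm = config.lam * config.mu

    out = np.empty(len(positions) - 1)
    for j in range(len(positions) - 1):
        p_lo, p_hi = float(positions[j]), float(positions[j + 1])
        arm_a = by_name[marker_bins[j]].arm
        arm_b = by_name[marker_bins[j + 1]].arm
        if arm_a == arm_b:
            sc = scales[arm_a]
            delta = abs(sc.v_of_pos(p_hi) - sc.v_of_pos(p_lo))
            m1 = lm * (1.0 - np.exp(-delta / config.mu))
            m2 = lm * np.exp(-delta / config.mu)
            p_inf = float(2.0 * (1.0 - np.exp(-m1)) * np.exp(-m1) * np.exp(-m2))
            p_sup = 0.5 * (p_hi - p_lo) / arm_len[arm_a]
        else:  # centromere-spanning interval: arms are independent
            cov = 1.0 - np.exp(-lm)
            p_inf = float(2.0 * cov * (1.0 - cov))
            # a supra-arm line is discordant here unless its extension into
            # the retained arm swallows the marker across the break
            d_a = scales[arm_a].u_of_pos(p_lo)
            d_b = scales[arm_b].u_of_pos(p_hi)
            p_sup = 0.5 * (
                (arm_len[arm_b] - d_b) / arm_len[arm_b]
                + (arm_len[arm_a] - d_a) / arm_len[arm_a]
            )
        p = (counts[INFORMATIVE] * p_inf + counts[SUPRA_ARM_LOSS] * p_sup) / n
        # independent call flips (prob q each side) mix the discordance
        # towards 1/2: p' = p*(1-w) + (1-p)*w with w = P(exactly one flip)
        w = 2.0 * q * (1.0 - q)
        out[j] = p * (1.0 - w) + (1.0 - p) * w
    return out


def per_line_bin_deletion_fractions(
    matrix: GenotypeMatrix,
    marker_bins: Sequence[str],
    line_mask: Sequence[bool] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Lines x bins array of per-line deleted-marker fractions (NaN where a
    line has no scored marker in a bin) — the replication structure used by
    the deletion-frequency uniformity test."""
    bins = list(dict.fromkeys(marker_bins))
    cols = {b: np.array([j for j, name in enumerate(marker_bins) if name == b]) for b in bins}
    rows = (
        np.flatnonzero(np.asarray(line_mask))
        if line_mask is not None
        else np.arange(matrix.n_lines)
    )
    out = np.full((len(rows), len(bins)), np.nan)
    for bi, b in enumerate(bins):
        sub = matrix.calls[np.ix_(rows, cols[b])]
        scored = (sub != MISSING).sum(axis=1)
        deleted = (sub == DELETED).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, bi] = np.where(scored > 0, deleted / np.maximum(scored, 1), np.nan)
    return out, bins


def truth_map(panel: SimPanel):
    """RH map implied by the generator's ground truth.

    Loci follow the true physical marker order with positions equal to the
    cumulative *expected* adjacent centiRay distances (100 x the expected
    panel discordance of each interval); bin spans are cut midway between
    the last and first markers of consecutive bins and each bin's Mb/cR
    conversion ratio is its physical size over its cR span.  Returns
    ``(rh_map, bin_spans, resolutions)`` ready for deletion calling —
    the reference against which the de-novo-built map is judged.
    """
    from .mapping import LocusGroup, RHMap

    truth = panel.truth
    exp_disc = adjacent_discordance_expectation(
        truth.config, truth.positions_mb, truth.marker_bins
    )
    positions = np.concatenate([[0.0], np.cumsum(100.0 * exp_disc)])
    loci = [LocusGroup(rep=m, members=(m,)) for m in truth.marker_ids]
    rh_map = RHMap(loci, positions, list(truth.marker_bins))
    bin_spans: dict[str, tuple[float, float]] = {}
    bins_seq = list(dict.fromkeys(truth.marker_bins))
    first_last = {
        b: (truth.marker_bins.index(b), len(truth.marker_bins) - 1 - truth.marker_bins[::-1].index(b))
        for b in bins_seq
    }
    edges = [float(positions[0])]
    for b1, b2 in zip(bins_seq, bins_seq[1:]):
        edges.append(0.5 * (positions[first_last[b1][1]] + positions[first_last[b2][0]]))
    edges.append(float(positions[-1]))
    size_of = {b.bin_name: b.size_mb for b in panel.bins}
    resolutions: dict[str, float | None] = {}
    for i, b in enumerate(bins_seq):
        bin_spans[b] = (edges[i], edges[i + 1])
        span = edges[i + 1] - edges[i]
        resolutions[b] = size_of[b] / span if span > 0 else None
    return rh_map, bin_spans, resolutions


def study_preset(seed: int = 0) -> SimConfig:
    """The default study-condition configuration (92 lines, ~540 markers,
    11 bins, calibrated deletion rates); only the seed varies."""
    return SimConfig(seed=seed)
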