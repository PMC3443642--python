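"""Two-point breakage statistics and framework RH map construction.

Model
-----
A radiation-hybrid line retains a marker with probability r and, between two
adjacent loci, radiation breakage decouples their fates with probability
theta.  For a pair of loci scored in the same line the joint cell
probabilities under linkage are::

    P(1,1) = (1-theta)*r + theta*r^2
    P(1,0) = P(0,1) = theta*r*(1-r)
    P(0,0) = (1-theta)*(1-r) + theta*(1-r)^2

i.e. with probability (1-theta) the two loci share one retention event and
with probability theta they are retained independently.  theta = 1 is
independence (product of marginals).  The LOD of a pair is the base-10 log
likelihood ratio of the model at its maximum-likelihood theta against
independence.

Distances are expressed in centiRays with the raw-discordance definition:
one cR is one state difference (deleted vs retained) between two adjacent
loci per 100 lines screened, i.e. ``distance_cR = 100 * D`` with D the
observed discordance fraction.  An optional Cox-style transform
``-100*ln(1-theta_hat)`` is exposed for comparison but is never the default.

Ordering uses a multipoint objective equal to the sum of adjacent-pair
maximised log-likelihoods (a Markov-chain / travelling-salesman criterion):
loci are inserted one at a time into a growing framework order, gated by a
placement LOD (log-10 likelihood gap between the best and second-best
insertion slot) against a decreasing threshold schedule, and finished with a
window-3 ripple pass.  All ties break lexicographically on marker ids so the
build is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

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

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)
DEFAULT_LOD_SCHEDULE = (10.0, 8.0, 6.0, 3.0)

# Retention thresholds used to classify lines: a line is whole-chromosome
# loss below WHOLE_LOSS_RETENTION and intact at exactly 1.0.
WHOLE_LOSS_RETENTION = 0.020


# ---------------------------------------------------------------------------
# Retention / deletion frequencies and line classes
# ---------------------------------------------------------------------------

def retention_frequency(calls: np.ndarray) -> float:
    """Fraction of non-missing calls that are RETAINED (per line or marker)."""
    calls = np.asarray(calls)
    informative = calls != MISSING
    n = int(informative.sum())
    if n == 0:
        raise ValueError("all calls missing; retention frequency undefined")
    return float((calls == RETAINED).sum() / n)


def deletion_frequency(calls: np.ndarray) -> float:
    """Fraction of non-missing calls that are DELETED (complement of
    :func:`retention_frequency` on the same vector)."""
    return 1.0 - retention_frequency(calls)


def _deleted_runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of DELETED entries, bridging (but not extending over)
    MISSING entries.  Returns (first, last) index pairs of deleted entries."""
    runs: list[tuple[int, int]] = []
    start = None
    last_del = None
    for i, s in enumerate(states):
        if s == DELETED:
            if start is None:
                start = i
            last_del = i
        elif s == RETAINED:
            if start is not None:
                runs.append((start, last_del))
                start = None
        # MISSING: neither breaks nor extends the run
    if start is not None:
        runs.append((start, last_del))
    return runs


def classify_lines(matrix: GenotypeMatrix, arms: Sequence[str]) -> list[str]:
    """Classify each line as INTACT, WHOLE_LOSS, SUPRA_ARM_LOSS or
    INFORMATIVE.

    ``arms`` gives the chromosome arm ('S' or 'L') of each matrix column,
    whose order must follow the physical/map order of the markers.  A line is
    INTACT at retention exactly 1.0, WHOLE_LOSS below retention 0.020, and
    SUPRA_ARM_LOSS when one uninterrupted deleted run covers every marker of
    one arm plus at least one marker of the other (a deletion larger than a
    whole arm, in practice a translocation remnant).
    """
    if len(arms) != matrix.n_markers:
        raise ValueError("arms must label every marker column")
    arms = np.asarray(arms)
    arm_idx = {a: np.flatnonzero(arms == a) for a in ("S", "L")}
    classes = []
    for i in range(matrix.n_lines):
        row = matrix.calls[i]
        r = retention_frequency(row)
        if r == 1.0:
            classes.append(INTACT)
            continue
        if r < WHOLE_LOSS_RETENTION:
            classes.append(WHOLE_LOSS)
            continue
        label = INFORMATIVE
        for a, b in _deleted_runs(row):
            covered = np.arange(a, b + 1)
            for arm, idx in arm_idx.items():
                if len(idx) == 0:
                    continue
                whole_arm = np.isin(idx, covered).all()
                other = arm_idx["L" if arm == "S" else "S"]
                beyond = np.isin(other, covered).any()
                if whole_arm and beyond:
                    label = SUPRA_ARM_LOSS
        classes.append(label)
    return classes


# ---------------------------------------------------------------------------
# Two-point estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    n_informative: int
    n_discordant: int
    distance_cR: float
    theta_hat: float | None
    lod: float
    degenerate: bool = False


def _pair_loglik(a, b, c, r, theta):
    """Log-likelihood of the 2x2 retention table (a=both retained,
    b=discordant, c=both deleted) at breakage probability theta."""
    p11 = (1 - theta) * r + theta * r * r
    p10 = theta * r * (1 - r)
    p00 = (1 - theta) * (1 - r) + theta * (1 - r) * (1 - r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(a > 0, a * np.log(p11), 0.0)
        t2 = np.where(b > 0, b * np.log(p10), 0.0)
        t3 = np.where(c > 0, c * np.log(p00), 0.0)
    return t1 + t2 + t3


def _theta_mle(a, b, c, r):
    """Closed-form maximiser of the pair likelihood over theta in [0, 1].

    Setting d/dtheta log L = 0 gives the quadratic
    ``theta^2 r(1-r) n - theta s + b = 0`` with n = a+b+c and
    s = a(1-r) + c r + b; the smaller root is the interior optimum.
    """
    n = a + b + c
    rr = r * (1 - r)
    s = a * (1 - r) + c * r + b
    disc = s * s - 4.0 * rr * n * b
    with np.errstate(invalid="ignore", divide="ignore"):
        root = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * rr * n)
    return np.clip(root, 0.0, 1.0)


def pairwise_statistics(calls: np.ndarray):
    """Vectorised two-point statistics for every column pair.

    Returns dict of m x m arrays: ``n`` (informative lines), ``ndisc``,
    ``dist`` (cR), ``theta`` (moment estimator), ``lod`` and ``pair_ll``
    (maximised joint log-likelihood, the building block of the multipoint
    objective), plus the boolean ``degenerate`` mask where pooled retention
    is 0 or 1 and linkage is unmeasurable.
    """
    calls = np.asarray(calls)
    R = (calls == RETAINED).astype(np.float64)
    D = (calls == DELETED).astype(np.float64)
    a = R.T @ R                      # both retained
    c = D.T @ D                      # both deleted
    rd = R.T @ D
    b = rd + rd.T                    # discordant
    n = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (2.0 * a + b) / (2.0 * n)
        dfrac = b / n
        dist = 100.0 * dfrac
        theta_mm = np.clip(dfrac / (2.0 * r * (1.0 - r)), 0.0, 1.0)
    degenerate = (n == 0) | (r <= 0.0) | (r >= 1.0)
    r_safe = np.where(degenerate, 0.5, r)
    theta_star = _theta_mle(a, b, c, r_safe)
    ll_star = _pair_loglik(a, b, c, r_safe, theta_star)
    ll_ind = _pair_loglik(a, b, c, r_safe, np.ones_like(r_safe))
    lod = np.maximum(ll_star - ll_ind, 0.0) / LN10
    lod = np.where(degenerate, 0.0, lod)
    pair_ll = np.where(degenerate, ll_ind, ll_star)
    theta_mm = np.where(degenerate, np.nan, theta_mm)
    np.fill_diagonal(lod, 0.0)
    return {
        "n": n,
        "ndisc": b,
        "dist": np.where(n > 0, dist, np.nan),
        "theta": theta_mm,
        "lod": lod,
        "pair_ll": pair_ll,
        "degenerate": degenerate,
    }


def two_point(marker_a: str, marker_b: str, matrix: GenotypeMatrix) -> TwoPointEstimate:
    """Two-point estimate for one marker pair (pairwise-complete lines)."""
    cols = matrix.calls[:, [matrix.marker_ids.index(marker_a), matrix.marker_ids.index(marker_b)]]
    st = pairwise_statistics(cols)
    n = int(st["n"][0, 1])
    if n < 1:
        raise ValueError(f"no informative lines for pair ({marker_a}, {marker_b})")
    deg = bool(st["degenerate"][0, 1])
    theta = st["theta"][0, 1]
    return TwoPointEstimate(
        marker_a=marker_a,
        marker_b=marker_b,
        n_informative=n,
        n_discordant=int(st["ndisc"][0, 1]),
        distance_cR=float(st["dist"][0, 1]),
        theta_hat=None if deg else float(theta),
        lod=float(st["lod"][0, 1]),
        degenerate=deg,
    )


# ---------------------------------------------------------------------------
# Co-segregation groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusGroup:
    """A co-segregation group: markers with identical call vectors mapped as
    one locus.  The representative is the lexicographically smallest id."""

    rep: str
    members: tuple[str, ...]
    framework: bool = True

    @property
    def size(self) -> int:
        return len(self.members)


def collapse_cosegregating(
    matrix: GenotypeMatrix, *, missing_wildcard: bool = False
) -> list[LocusGroup]:
    """Group markers with identical call vectors into loci.

    By default MISSING is part of the pattern (exact match).  With
    ``missing_wildcard`` a marker joins the first group (in id order) whose
    per-line consensus it matches on all mutually non-missing lines; the
    group consensus then absorbs its non-missing calls.
    """
    order = sorted(range(matrix.n_markers), key=lambda j: matrix.marker_ids[j])
    groups: list[list[int]] = []
    if not missing_wildcard:
        seen: dict[bytes, int] = {}
        for j in order:
            key = matrix.calls[:, j].tobytes()
            if key in seen:
                groups[seen[key]].append(j)
            else:
                seen[key] = len(groups)
                groups.append([j])
    else:
        consensus: list[np.ndarray] = []
        for j in order:
            col = matrix.calls[:, j]
            placed = False
            for gi, cons in enumerate(consensus):
                both = (col != MISSING) & (cons != MISSING)
                if np.array_equal(col[both], cons[both]):
                    groups[gi].append(j)
                    upd = cons.copy()
                    upd[col != MISSING] = col[col != MISSING]
                    consensus[gi] = upd
                    placed = True
                    break
            if not placed:
                groups.append([j])
                consensus.append(col.copy())
    out = []
    for g in groups:
        members = tuple(sorted(matrix.marker_ids[j] for j in g))
        out.append(LocusGroup(rep=members[0], members=members))
    return sorted(out, key=lambda lg: lg.rep)


# ---------------------------------------------------------------------------
# RH map container
# ---------------------------------------------------------------------------

@dataclass
class RHMap:
    """An ordered RH map: loci (co-segregation groups) with cumulative
    centiRay positions; ``bins`` is filled by :func:`assign_bins`."""

    loci: list[LocusGroup]
    positions_cR: np.ndarray
    bins: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_cR = np.asarray(self.positions_cR, dtype=float)
        if len(self.positions_cR) != len(self.loci):
            raise ValueError("one position per locus required")
        if np.any(np.diff(self.positions_cR) < -1e-9):
            raise ValueError("positions must be non-decreasing")
        if not self.bins:
            self.bins = [None] * len(self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_markers(self) -> int:
        return sum(g.size for g in self.loci)

    @property
    def length_cR(self) -> float:
        return float(self.positions_cR[-1]) if self.n_loci else 0.0

    def marker_order(self) -> list[str]:
        """All marker ids in map order (members alphabetical within locus)."""
        return [m for g in self.loci for m in g.members]

    def marker_positions(self) -> dict[str, float]:
        return {
            m: float(p)
            for g, p in zip(self.loci, self.positions_cR)
            for m in g.members
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, pos, bin_name in zip(self.loci, self.positions_cR, self.bins):
            for m in g.members:
                rows.append(
                    {
                        "marker_id": m,
                        "locus_id": g.rep,
                        "position_cR": round(float(pos), 4),
                        "bin_name": bin_name if bin_name is not None else "NA",
                        "framework": g.framework,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path) -> RHMap:
    df = pd.read_csv(path, sep="\t")
    loci: list[LocusGroup] = []
    positions: list[float] = []
    bins: list[str | None] = []
    for (locus_id, pos), grp in df.groupby(["locus_id", "position_cR"], sort=False):
        members = tuple(sorted(grp["marker_id"].astype(str)))
        loci.append(
            LocusGroup(rep=str(locus_id), members=members, framework=bool(grp["framework"].iloc[0]))
        )
        positions.append(float(pos))
        b = grp["bin_name"].iloc[0]
        bins.append(None if pd.isna(b) or b == "NA" else str(b))
    order = np.argsort(positions, kind="stable")
    return RHMap(
        [loci[i] for i in order],
        np.asarray(positions)[order],
        [bins[i] for i in order],
    )


# ---------------------------------------------------------------------------
# Framework map construction
# ---------------------------------------------------------------------------

def _order_score(order: Sequence[int], pair_ll: np.ndarray) -> float:
    o = np.asarray(order)
    return float(pair_ll[o[:-1], o[1:]].sum())


def _insertion_deltas(order: list[int], unplaced: np.ndarray, pair_ll: np.ndarray) -> np.ndarray:
    """(k+1) x u matrix of objective gains for inserting each unplaced locus
    at each slot of the current order."""
    o = np.asarray(order)
    adj = pair_ll[o[:-1], o[1:]]
    left = pair_ll[np.ix_(o[:-1], unplaced)]
    right = pair_ll[np.ix_(o[1:], unplaced)]
    interior = left + right - adj[:, None]
    first = pair_ll[o[0], unplaced][None, :]
    last = pair_ll[o[-1], unplaced][None, :]
    return np.vstack([first, interior, last])


def _keeps_frozen_order(candidate: Sequence[int], original: Sequence[int], frozen) -> bool:
    if frozen is None:
        return True
    sub_c = [x for x in candidate if frozen[x]]
    sub_o = [x for x in original if frozen[x]]
    return sub_c == sub_o


def _ripple3(
    order: list[int], pair_ll: np.ndarray, max_passes: int = 60, frozen=None
) -> list[int]:
    """Sliding-window ripple: try all permutations of every 3 consecutive
    loci, accept strict improvements, iterate to a fixpoint.  ``frozen``
    loci (the anchor scaffold) never change their relative order."""
    from itertools import permutations

    perms = list(permutations(range(3)))
    order = list(order)
    for _ in range(max_passes):
        improved = False
        for i in range(len(order) - 2):
            window = order[i : i + 3]
            lnb = order[i - 1] if i > 0 else None
            rnb = order[i + 3] if i + 3 < len(order) else None

            def local(w):
                s = pair_ll[w[0], w[1]] + pair_ll[w[1], w[2]]
                if lnb is not None:
                    s += pair_ll[lnb, w[0]]
                if rnb is not None:
                    s += pair_ll[w[2], rnb]
                return s

            base = local(window)
            best, best_w = base, None
            for p in perms[1:]:
                w = [window[p[0]], window[p[1]], window[p[2]]]
                if not _keeps_frozen_order(w, window, frozen):
                    continue
                s = local(w)
                if s > best + 1e-9:
                    best, best_w = s, w
            if best_w is not None:
                order[i : i + 3] = best_w
                improved = True
        if not improved:
            break
    return order


def _two_opt_pass(order: list[int], pair_ll: np.ndarray, frozen=None) -> bool:
    """One deterministic pass of path 2-opt (segment reversals).

    Reversing ``order[i:j+1]`` only swaps the two boundary edges, so each
    candidate costs O(1); for every left edge the best reversal end is
    found vectorised and applied when it strictly improves the objective.
    Segments holding two or more ``frozen`` (anchor-scaffold) loci are
    never reversed.
    """
    m = len(order)
    improved = False

    def frozen_ok(i: int, j: int, arr) -> np.ndarray | bool:
        if frozen is None:
            return True
        counts = np.cumsum(frozen[arr])
        return (counts[j] - (counts[i - 1] if i > 0 else 0)) <= 1

    # prefix reversals (no left neighbour)
    arr = np.asarray(order)
    if m > 2:
        gain = pair_ll[arr[0], arr[1:]] - pair_ll[arr[:-1], arr[1:]]
        if frozen is not None:
            counts = np.cumsum(frozen[arr])
            bad = counts[1:m - 1] > 1
            gain = gain[: m - 2].copy()
            gain[bad] = -np.inf
        else:
            gain = gain[: m - 2]
        k = int(gain.argmax())
        if gain[k] > 1e-9:
            order[0 : k + 2] = order[0 : k + 2][::-1]
            improved = True
    for i in range(1, m - 1):
        arr = np.asarray(order)
        a = arr[i - 1]
        js = np.arange(i, m - 1)
        gain = (
            pair_ll[a, arr[js]]
            + pair_ll[arr[i], arr[js + 1]]
            - pair_ll[a, arr[i]]
            - pair_ll[arr[js], arr[js + 1]]
        )
        tail_gain = pair_ll[a, arr[-1]] - pair_ll[a, arr[i]]
        if frozen is not None:
            counts = np.cumsum(frozen[arr])
            seg_counts = counts[js] - counts[i - 1]
            gain = gain.copy()
            gain[seg_counts > 1] = -np.inf
            if counts[m - 1] - counts[i - 1] > 1:
                tail_gain = -np.inf
        k = int(gain.argmax())
        if tail_gain > gain[k] and tail_gain > 1e-9:
            order[i:] = order[i:][::-1]
            improved = True
        elif gain[k] > 1e-9:
            j = i + k
            order[i : j + 1] = order[i : j + 1][::-1]
            improved = True
    return improved


def _oropt_pass(order: list[int], pair_ll: np.ndarray, frozen=None) -> bool:
    """One deterministic Or-opt pass: relocate segments of 1-3 loci (either
    orientation) to their best slot when that strictly improves the path
    objective.  All deltas are edge-local, O(1) per candidate slot.
    Segments containing a ``frozen`` (anchor-scaffold) locus stay put."""

    def edge(a: int | None, b: int | None) -> float:
        if a is None or b is None:
            return 0.0
        return float(pair_ll[a, b])

    improved = False
    for seg_len in (1, 2, 3):
        i = 0
        while i + seg_len <= len(order):
            m = len(order)
            seg = order[i : i + seg_len]
            if frozen is not None and any(frozen[x] for x in seg):
                i += 1
                continue
            rest = order[:i] + order[i + seg_len :]
            if len(rest) < 2:
                break
            left = order[i - 1] if i > 0 else None
            right = order[i + seg_len] if i + seg_len < m else None
            removal = edge(left, right) - edge(left, seg[0]) - edge(seg[-1], right)
            rarr = np.asarray(rest)
            adj = pair_ll[rarr[:-1], rarr[1:]]
            best_gain, best = 1e-9, None
            for oriented in (seg, seg[::-1]):
                u0, u1 = oriented[0], oriented[-1]
                deltas = np.concatenate(
                    [
                        [pair_ll[u1, rarr[0]]],
                        pair_ll[rarr[:-1], u0] + pair_ll[rarr[1:], u1] - adj,
                        [pair_ll[rarr[-1], u0]],
                    ]
                )
                k = int(deltas.argmax())
                gain = removal + float(deltas[k])
                if gain > best_gain:
                    best_gain, best = gain, rest[:k] + list(oriented) + rest[k:]
            if best is not None:
                order[:] = best
                improved = True
            i += 1
    return improved


def _polish(
    order: list[int], pair_ll: np.ndarray, max_rounds: int = 50, frozen=None
) -> list[int]:
    """Iterate 2-opt, Or-opt and window-3 ripple to a joint fixpoint."""
    order = list(order)
    for _ in range(max_rounds):
        c1 = _two_opt_pass(order, pair_ll, frozen=frozen)
        c2 = _oropt_pass(order, pair_ll, frozen=frozen)
        order = _ripple3(order, pair_ll, frozen=frozen)
        if not (c1 or c2):
            break
    return order


def _likelihood_order(indices: Sequence[int], pair_ll: np.ndarray) -> list[int]:
    """Order a subset of loci by the multipoint objective alone (exhaustive
    for up to 9 loci, greedy best-insertion plus polish beyond)."""
    idx = sorted(indices)
    if len(idx) <= 2:
        return idx
    sub = pair_ll[np.ix_(idx, idx)]
    if len(idx) <= 9:
        local = _exhaustive_order(sub)
        return [idx[i] for i in local]
    sub_lod = sub.copy()
    np.fill_diagonal(sub_lod, -np.inf)
    i, j = np.unravel_index(int(np.argmax(sub_lod)), sub_lod.shape)
    local = [min(i, j), max(i, j)]
    unplaced = sorted(set(range(len(idx))) - set(local))
    while unplaced:
        u = np.asarray(unplaced)
        deltas = _insertion_deltas(local, u, sub)
        best_slot = deltas.argmax(axis=0)
        best = deltas[best_slot, np.arange(len(u))]
        k = int(np.argmax(best))
        local.insert(int(best_slot[k]), int(u[k]))
        unplaced.remove(int(u[k]))
    local = _polish(local, sub)
    return [idx[i] for i in local]


def _orient_chains(chains: Sequence[Sequence[int]], pair_ll: np.ndarray) -> list[int]:
    """Concatenate per-bin anchor chains, choosing each chain's orientation
    by dynamic programming over the junction log-likelihoods."""
    chains = [list(c) for c in chains if c]
    if not chains:
        return []
    n = len(chains)
    if n == 1:
        return chains[0]
    # dp[k][o]: best score up to chain k with orientation o (0 fwd, 1 rev)
    dp = np.zeros((n, 2))
    back = np.zeros((n, 2), dtype=int)
    for k in range(1, n):
        for o in (0, 1):
            head = chains[k][-1] if o else chains[k][0]
            scores = [
                dp[k - 1][po]
                + pair_ll[(chains[k - 1][0] if po else chains[k - 1][-1]), head]
                for po in (0, 1)
            ]
            po = int(np.argmax(scores))
            dp[k][o], back[k][o] = scores[po], po
    o = int(np.argmax(dp[-1]))
    orients = [0] * n
    for k in range(n - 1, -1, -1):
        orients[k] = o
        o = int(back[k][o]) if k > 0 else o
    out: list[int] = []
    for k, c in enumerate(chains):
        out.extend(c[::-1] if orients[k] else c)
    return out


def bin_order_from_records(bins: Iterable[BinRecord]) -> list[str]:
    """Physical bin order from the S-arm telomere to the L-arm telomere:
    S-arm bins by decreasing arm fraction, then L-arm bins increasing."""
    named = [b for b in bins if b.arm in ("S", "L")]
    s = sorted((b for b in named if b.arm == "S"), key=lambda b: -b.frac_end)
    l = sorted((b for b in named if b.arm == "L"), key=lambda b: b.frac_start)
    return [b.bin_name for b in s] + [b.bin_name for b in l]


def _orient(
    order: list[int],
    loci: list[LocusGroup],
    anchor_bins: dict[str, str],
    bin_order: Sequence[str] | None,
) -> list[int]:
    """Orient the order so anchor bins run from the S-distal to the L-distal
    end; without usable anchors, ties break on the terminal marker ids."""
    if bin_order:
        rank = {b: i for i, b in enumerate(bin_order)}
        xs, ys = [], []
        for pos, li in enumerate(order):
            locus_bins = [anchor_bins[m] for m in loci[li].members if m in anchor_bins]
            locus_bins = [b for b in locus_bins if b in rank]
            if locus_bins:
                xs.append(pos)
                ys.append(rank[min(locus_bins, key=lambda b: rank[b])])
        if len(set(ys)) > 1:
            tau = sps.kendalltau(xs, ys).statistic
            if tau is not None and not np.isnan(tau) and tau != 0:
                return order[::-1] if tau < 0 else order
    if loci[order[-1]].rep < loci[order[0]].rep:
        return order[::-1]
    return order


def build_framework_map(
    matrix: GenotypeMatrix,
    marker_info: Sequence[MarkerInfo] | None = None,
    lod_schedule: Sequence[float] = DEFAULT_LOD_SCHEDULE,
    *,
    bin_order: Sequence[str] | None = None,
    missing_wildcard: bool = False,
    cox_transform: bool = False,
    anchor_scaffold: bool = True,
) -> RHMap:
    """Build the iterative framework RH map.

    Markers are first collapsed into co-segregation loci.  With ``bin_order``
    and anchored loci available (the default study setting), the anchors
    first form a fixed scaffold — deletion bins in their known cytogenetic
    order, anchors within each bin ordered by likelihood, chain orientations
    resolved by dynamic programming — because pairwise linkage saturates
    beyond a few tens of cR and cannot identify the chromosome-scale
    arrangement on its own.  Non-anchor loci are then placed by LOD-gated
    insertion against the decreasing ``lod_schedule``; loci never reaching
    the final threshold are attached at their best slot and flagged
    non-framework.  A window-3 ripple pass plus a deterministic 2-opt /
    Or-opt polish (moves that would reorder the scaffold are rejected)
    refine the order to a joint local optimum of the multipoint objective.
    Without usable anchors the order is instead seeded from the
    highest-LOD pair and grown the same way (``anchor_scaffold=False``
    forces this purely likelihood-driven mode).  Maps of at most 9 loci are
    solved exactly by enumeration.  Positions are cumulative adjacent
    raw-discordance distances (or Cox-transformed with ``cox_transform``).
    """
    schedule = list(lod_schedule)
    if any(x < y for x, y in zip(schedule, schedule[1:])):
        raise ValueError("lod_schedule must be decreasing")
    groups = collapse_cosegregating(matrix, missing_wildcard=missing_wildcard)
    if len(groups) < 3:
        raise ValueError("need at least 3 loci after collapsing to build a map")
    reps = [g.rep for g in groups]
    rep_matrix = matrix.subset_markers(reps)
    st = pairwise_statistics(rep_matrix.calls)
    pair_ll, lod = st["pair_ll"], st["lod"]
    m = len(groups)

    anchor_bins: dict[str, str] = {}
    if marker_info is not None:
        for info in marker_info:
            if info.is_anchor and info.bin_name is not None:
                anchor_bins[info.marker_id] = info.bin_name
    anchor_loci = [
        i for i, g in enumerate(groups) if any(mm in anchor_bins for mm in g.members)
    ]

    def best_pair(candidates: Sequence[int]) -> tuple[int, int]:
        cand = np.asarray(sorted(candidates))
        sub = lod[np.ix_(cand, cand)].copy()
        np.fill_diagonal(sub, -np.inf)
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        return int(cand[min(i, j)]), int(cand[max(i, j)])

    if m <= 9:
        # small maps: the global optimum is affordable outright
        order = _exhaustive_order(pair_ll)
        order = _orient(order, groups, anchor_bins, bin_order)
        return _finish_map(order, groups, st, {i: True for i in order}, cox_transform)

    scaffold = (
        anchor_scaffold
        and bin_order is not None
        and len(anchor_loci) >= 2
    )
    if scaffold:
        # anchor skeleton: bins in their known cytogenetic order, anchors
        # ordered within each bin by likelihood, bin chains oriented by a
        # dynamic program over the junction likelihoods
        rank = {b: i for i, b in enumerate(bin_order)}
        locus_bin: dict[int, str] = {}
        for i in anchor_loci:
            labels = sorted(
                (b for mm in groups[i].members if (b := anchor_bins.get(mm)) in rank),
                key=lambda b: rank[b],
            )
            if labels:
                locus_bin[i] = max(set(labels), key=labels.count)
        chains = []
        for b in bin_order:
            members = sorted(i for i, lb in locus_bin.items() if lb == b)
            if members:
                chains.append(_likelihood_order(members, pair_ll))
        order = _orient_chains(chains, pair_ll)
        framework = {i: True for i in order}
        frozen = np.zeros(m, dtype=bool)
        frozen[order] = True
        unplaced = sorted(set(range(m)) - set(order))
    else:
        if len(anchor_loci) >= 2:
            seed = best_pair(anchor_loci)
        else:
            logger.warning(
                "fewer than 2 anchor loci (%d); seeding from the best overall pair",
                len(anchor_loci),
            )
            seed = best_pair(range(m))
        order = list(seed)
        framework = {seed[0]: True, seed[1]: True}
        frozen = np.zeros(m, dtype=bool)
        unplaced = sorted(set(range(m)) - set(order))
        logger.info("seed pair: %s - %s (lod %.2f)", reps[seed[0]], reps[seed[1]], lod[seed])

    ti = 0
    while unplaced:
        u = np.asarray(unplaced)
        deltas = _insertion_deltas(order, u, pair_ll)
        best_slot = deltas.argmax(axis=0)
        best = deltas[best_slot, np.arange(len(u))]
        if deltas.shape[0] >= 2:
            part = np.partition(deltas, -2, axis=0)
            second = part[-2, :]
        else:  # pragma: no cover - an order always has >= 3 slots
            second = np.full(len(u), -np.inf)
        placement_lod = (best - second) / LN10
        k = int(np.argmax(placement_lod))
        if ti < len(schedule) and placement_lod[k] < schedule[ti]:
            ti += 1
            continue
        locus = int(u[k])
        slot = int(best_slot[k])
        order.insert(slot, locus)
        framework[locus] = ti < len(schedule)
        unplaced.remove(locus)
        logger.info(
            "placed %s at slot %d (placement LOD %.2f, stage %s)",
            reps[locus],
            slot,
            placement_lod[k],
            schedule[ti] if ti < len(schedule) else "attach",
        )

    order = _ripple3(order, pair_ll, frozen=frozen)
    order = _polish(order, pair_ll, frozen=frozen)
    if not scaffold:
        order = _orient(order, groups, anchor_bins, bin_order)
    return _finish_map(order, groups, st, framework, cox_transform)


def _exhaustive_order(pair_ll: np.ndarray) -> list[int]:
    """Globally optimal order by enumeration (m <= 9; reverse-duplicates
    skipped, ties resolved to the lexicographically smallest order)."""
    from itertools import permutations

    m = pair_ll.shape[0]
    perms = np.array(
        [p for p in permutations(range(m)) if p[0] <= p[-1]], dtype=np.intp
    )
    scores = pair_ll[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    return [int(x) for x in perms[int(np.argmax(scores))]]


def _finish_map(order, groups, st, framework, cox_transform) -> RHMap:
    order = list(order)
    if cox_transform:
        theta = np.nan_to_num(st["theta"], nan=0.0)
        adj = -100.0 * np.log(np.maximum(1.0 - theta[order[:-1], order[1:]], 1e-12))
    else:
        adj = np.nan_to_num(st["dist"][order[:-1], order[1:]], nan=0.0)
    positions = np.concatenate([[0.0], np.cumsum(adj)])
    placed = [replace(groups[i], framework=framework.get(i, False)) for i in order]
    return RHMap(placed, positions)


def multipoint_loglik(order: Sequence[str], matrix: GenotypeMatrix) -> float:
    """Multipoint objective (sum of adjacent maximised pair log-likelihoods)
    of an explicit marker/locus order — the quantity the builder maximises."""
    sub = matrix.subset_markers(list(order))
    st = pairwise_statistics(sub.calls)
    return _order_score(range(len(order)), st["pair_ll"])


# ---------------------------------------------------------------------------
# Bin assignment
# ---------------------------------------------------------------------------

def assign_bins(
    rh_map: RHMap,
    marker_info: Sequence[MarkerInfo],
    *,
    bin_order: Sequence[str] | None = None,
) -> tuple[RHMap, dict[str, tuple[float, float]]]:
    """Extrapolate deletion-bin assignments from anchor loci to all loci.

    Bin boundaries on the cR axis are placed between consecutive bins'
    anchors: the cut point minimises the number of anchors on the wrong side
    (for cleanly separated bins this is the midpoint between the adjacent
    anchors of the two bins); interleaved anchors trigger a warning and are
    resolved by that same majority rule.  Every locus inherits the bin of its
    interval.  Returns the annotated map and per-bin (start, end) cR spans.
    """
    anchor_bins = {
        info.marker_id: info.bin_name
        for info in marker_info
        if info.is_anchor and info.bin_name is not None
    }
    anchors: list[tuple[float, str]] = []
    for g, pos in zip(rh_map.loci, rh_map.positions_cR):
        labels = sorted({anchor_bins[m] for m in g.members if m in anchor_bins})
        if labels:
            if len(labels) > 1:
                logger.warning(
                    "locus %s carries anchors of multiple bins %s", g.rep, labels
                )
            anchors.append((float(pos), labels[0]))
    if not anchors:
        raise ValueError("no anchor loci on the map; cannot assign bins")
    anchors.sort(key=lambda t: t[0])

    if bin_order is not None:
        present = [b for b in bin_order if any(lbl == b for _, lbl in anchors)]
    else:
        medians: dict[str, float] = {}
        for _, lbl in anchors:
            medians.setdefault(lbl, np.median([p for p, l2 in anchors if l2 == lbl]))
        present = sorted(medians, key=lambda b: medians[b])

    pos_by_bin = {b: np.array([p for p, lbl in anchors if lbl == b]) for b in present}
    boundaries = [rh_map.positions_cR[0] if rh_map.n_loci else 0.0]
    for b1, b2 in zip(present, present[1:]):
        p1, p2 = pos_by_bin[b1], pos_by_bin[b2]
        if p1.max() > p2.min():
            logger.warning(
                "anchors of bins %s and %s interleave; using majority cut", b1, b2
            )
        cand = np.unique(np.concatenate([p1, p2]))
        cuts = (cand[:-1] + cand[1:]) / 2.0
        cuts = np.concatenate([[cand[0] - 1e-9], cuts, [cand[-1] + 1e-9]])
        errs = [
            int((p1 > t).sum() + (p2 < t).sum()) for t in cuts
        ]
        best = int(np.argmin(errs))
        boundary = max(float(cuts[best]), boundaries[-1])
        boundaries.append(boundary)
    boundaries.append(float(rh_map.positions_cR[-1]))

    spans = {
        b: (boundaries[i], boundaries[i + 1]) for i, b in enumerate(present)
    }
    bins: list[str | None] = []
    for pos in rh_map.positions_cR:
        k = int(np.searchsorted(boundaries[1:-1], pos, side="left"))
        bins.append(present[min(k, len(present) - 1)])
    annotated = RHMap(list(rh_map.loci), rh_map.positions_cR.copy(), bins)
    return annotated, spans


# ---------------------------------------------------------------------------
# Order concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderConcordance:
    tau: float          # |Kendall tau| on shared markers
    reversed: bool      # True when the raw tau was negative
    n_shared: int


def order_concordance(order_a: Sequence[str], order_b: Sequence[str]) -> OrderConcordance:
    """Kendall rank concordance of two marker orders on their shared markers,
    reported orientation-free (``max(tau, -tau)`` with a reversal flag)."""
    shared = [m for m in order_a if m in set(order_b)]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared markers")
    rank_b = {m: i for i, m in enumerate(order_b)}
    xs = list(range(len(shared)))
    ys = [rank_b[m] for m in shared]
    tau = float(sps.kendalltau(xs, ys).statistic)
    return OrderConcordance(tau=abs(tau), reversed=tau < 0, n_shared=len(shared))
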