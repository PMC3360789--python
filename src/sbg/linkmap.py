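"""Linkage-map construction from an A/B/H genotype matrix.

Pairwise recombination fractions are estimated by maximum likelihood from
jointly non-missing informative genotype pairs.  In a BC1 the informative
codes are {B, H} and the recombination fraction is the discordance R/N; in a
selfed RIL residual heterozygotes are uninformative for phase (H is treated
as missing), the observed homozygote discordance R/N is corrected for the
accumulation of recombination over the selfing generations with
r = (R/N) / (2 (1 - R/N)), treating the line as fully inbred.  The LOD score
is the binomial log10 likelihood ratio of the estimate against free
recombination (r = 0.5).

Weakly supported long distances (r > 0.4) are re-estimated through a
shortest-path pass over intermediate markers: confident pairs become graph
edges weighted by their Haldane distance, and the path distance is mapped
back to a recombination fraction through the inverse Haldane function.
Markers are grouped by single linkage over confident edges; under heavy
missingness a two-step mode groups low-missingness markers first and anchors
the rest to the group with the unambiguously best-fitting recombination
fraction.  Each group is ordered by seeded multi-start greedy chaining with
2-opt refinement over many candidate orders; the best order minimises the
sum of adjacent recombination fractions (SARF, ties broken by maximal sum of
adjacent LOD), positions accumulate Haldane distances, and per-marker
stability is the fraction of candidate orders that keep the marker within
one rank of its position in the best order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .parentgeno import ABHMatrix, MISSING

RF_CAP = 0.4999


# ---------------------------------------------------------------------------
# Mapping function (Haldane, no interference)
# ---------------------------------------------------------------------------


def haldane_cm(r):
    """Map distance in cM for recombination fraction ``r``: d = -50 ln(1-2r)."""
    r = np.clip(r, 0.0, RF_CAP)
    return -50.0 * np.log(1.0 - 2.0 * r) + 0.0


def haldane_rf(d_cm):
    """Inverse Haldane: r = (1 - e^(-d/50)) / 2 for distance in cM."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


# ---------------------------------------------------------------------------
# Pairwise estimates
# ---------------------------------------------------------------------------


@dataclass
class PairEstimate:
    rf: float
    lod: float
    n_informative: int
    reestimated: bool = False


@dataclass
class MapConfig:
    """Tunable parameters of the mapping stage."""

    reestimate_threshold: float = 0.4
    group_max_rf: float = 0.4
    group_min_lod: float = 4.0
    n_orders: int = 150
    two_step: bool = False
    anchor_primary_missing: float = 0.30
    anchor_ceiling_missing: float = 0.60
    anchor_margin: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for val in (self.reestimate_threshold, self.group_max_rf):
            if not 0 < val <= 0.5:
                raise ValueError("rf thresholds must be in (0, 0.5]")
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")


_CODE = {"A": 0, "H": 1, "B": 2, MISSING: -1}


def encode_abh(abh: ABHMatrix) -> tuple[np.ndarray, list[str]]:
    """Offspring genotype codes as int8 (A=0, H=1, B=2, missing=-1)."""
    off = abh.offspring_frame()
    vals = off.to_numpy()
    out = np.full(vals.shape, -1, dtype=np.int8)
    for code, num in _CODE.items():
        out[vals == code] = num
    return out, list(off.index)


def _binomial_lod(r_obs: np.ndarray, R: np.ndarray, N: np.ndarray) -> np.ndarray:
    """LOD of the MLE against r = 0.5; exactly 0 at r_obs = 0.5."""
    r = np.clip(r_obs, 0.0, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_r = np.where(R > 0, R * np.log10(np.maximum(r, 1e-300)), 0.0)
        term_nr = np.where(N - R > 0, (N - R) * np.log10(np.maximum(1.0 - r, 1e-300)), 0.0)
    lod = term_r + term_nr - N * math.log10(0.5)
    return np.where(N > 0, lod, 0.0)


def rf_matrix(M: np.ndarray, poptype: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs recombination fractions, LOD scores and informative counts.

    ``M`` is markers x individuals with codes A=0, H=1, B=2, missing=-1.
    """
    if poptype == "bc1":
        valid = (M == 1) | (M == 2)
    elif poptype == "ril":
        valid = (M == 0) | (M == 2)
    else:
        raise ValueError(f"unknown poptype {poptype!r}")
    x = ((M == 2) & valid).astype(np.float64)
    v = valid.astype(np.float64)
    y = v - x
    N = v @ v.T
    R = x @ y.T + y @ x.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r_obs = np.where(N > 0, R / np.maximum(N, 1), 0.5)
    lod = _binomial_lod(r_obs, R, N)
    if poptype == "ril":
        rf = r_obs / np.maximum(2.0 * (1.0 - r_obs), 1e-12)
    else:
        rf = r_obs
    rf = np.clip(rf, 0.0, RF_CAP)
    uninformative = N < 2
    rf[uninformative] = 0.5
    lod[uninformative] = 0.0
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    return rf.astype(np.float64), lod.astype(np.float64), N.astype(np.int64)


def pair_rf(g1: Sequence, g2: Sequence, poptype: str = "bc1") -> PairEstimate:
    """Recombination fraction and LOD between two marker genotype rows.

    Rows may contain "A"/"B"/"H"/"-" codes or the integer encoding.
    """

    def _enc(row):
        arr = np.asarray(row)
        if arr.dtype.kind in "US":
            return np.array([_CODE.get(str(v), -1) for v in row], dtype=np.int8)
        return arr.astype(np.int8)

    M = np.stack([_enc(g1), _enc(g2)])
    rf, lod, N = rf_matrix(M, poptype)
    n = int(N[0, 1])
    if n < 2:
        return PairEstimate(0.5, 0.0, n)
    return PairEstimate(float(rf[0, 1]), float(lod[0, 1]), n)


# ---------------------------------------------------------------------------
# Shortest-path re-estimation and grouping
# ---------------------------------------------------------------------------


def reestimate_long(rf: np.ndarray, threshold: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Replace weak long estimates (rf > threshold) by shortest-path values.

    Confident pairs (rf <= threshold) form a graph with Haldane-cM edge
    weights; for every weak pair the path distance is converted back to a
    recombination fraction.  Unreachable pairs keep rf = 0.5.  Returns the
    new matrix and a boolean mask of re-estimated entries.
    """
    n = rf.shape[0]
    edges = rf <= threshold
    np.fill_diagonal(edges, False)
    weights = np.where(edges, haldane_cm(rf), 0.0)
    graph = csr_matrix(weights * edges)
    dist = shortest_path(graph, method="D", directed=False)
    out = rf.copy()
    weak = rf > threshold
    np.fill_diagonal(weak, False)
    reachable = np.isfinite(dist)
    replace = weak & reachable
    out[replace] = haldane_rf(dist[replace])
    out[weak & ~reachable] = 0.5
    out = np.minimum(out, 0.5)
    return out, weak


def group_markers(
    rf: np.ndarray,
    lod: np.ndarray,
    max_rf: float = 0.4,
    min_lod: float = 4.0,
) -> tuple[list[list[int]], list[int]]:
    """Single-linkage components over confident edges.

    Edges require both rf <= ``max_rf`` and LOD >= ``min_lod``.  Singleton
    components are reported as ungrouped.
    """
    n = rf.shape[0]
    adj = (rf <= max_rf) & (lod >= min_lod)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        comps[lab].append(i)
    groups = sorted((c for c in comps if len(c) >= 2), key=len, reverse=True)
    ungrouped = sorted(i for c in comps if len(c) == 1 for i in c)
    return groups, ungrouped


def anchor_assign(
    groups: list[list[int]],
    ungrouped: Sequence[int],
    rf: np.ndarray,
    max_rf: float = 0.4,
    margin: float = 0.10,
) -> tuple[list[list[int]], list[int]]:
    """Assign leftover markers to the anchor group with the best-fitting rf.

    A marker joins a group only when its best (minimum) rf to any group
    member is <= ``max_rf`` and beats the second-best group by at least
    ``margin`` -- otherwise the assignment is ambiguous and the marker stays
    ungrouped.
    """
    if not groups:
        return [list(g) for g in groups], list(ungrouped)
    out_groups = [list(g) for g in groups]
    still: list[int] = []
    for m in ungrouped:
        best = np.array([rf[m, g].min() for g in groups])
        order = np.argsort(best, kind="stable")
        top = float(best[order[0]])
        second = float(best[order[1]]) if len(groups) > 1 else 1.0
        if top <= max_rf and (second - top) >= margin:
            out_groups[int(order[0])].append(m)
        else:
            still.append(m)
    return out_groups, still


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


def _greedy_chain(D: np.ndarray, start: int) -> list[int]:
    """Nearest-neighbour chain over the rf submatrix from a start marker."""
    n = D.shape[0]
    unvisited = np.ones(n, dtype=bool)
    order = [start]
    unvisited[start] = False
    cur = start
    for _ in range(n - 1):
        d = np.where(unvisited, D[cur], np.inf)
        nxt = int(np.argmin(d))
        order.append(nxt)
        unvisited[nxt] = False
        cur = nxt
    return order


def _two_opt_cycle(order: list[int], A: np.ndarray, max_iter: int = 5000) -> list[int]:
    """Vectorised 2-opt on a cycle: repeatedly apply the best improving
    segment reversal until none remains."""
    o = np.array(order)
    n = o.size
    if n < 4:
        return order
    for _ in range(max_iter):
        nxt = np.roll(o, -1)
        cur_w = A[o, nxt]
        E = A[np.ix_(o, o)]
        E1 = A[np.ix_(nxt, nxt)]
        delta = E + E1 - cur_w[:, None] - cur_w[None, :]
        iu = np.triu_indices(n, k=2)
        dvals = delta[iu]
        k = int(np.argmin(dvals))
        if dvals[k] >= -1e-12:
            break
        i, j = int(iu[0][k]), int(iu[1][k])
        if i == 0 and j == n - 1:
            # reversing everything between: no-op on a cycle; mask by picking next best
            dvals[k] = np.inf
            k = int(np.argmin(dvals))
            if dvals[k] >= -1e-12:
                break
            i, j = int(iu[0][k]), int(iu[1][k])
        o[i + 1: j + 1] = o[i + 1: j + 1][::-1]
    return o.tolist()


def _sarf(order: Sequence[int], D: np.ndarray) -> float:
    o = np.asarray(order)
    return float(D[o[:-1], o[1:]].sum())


def _salod(order: Sequence[int], lod: np.ndarray) -> float:
    o = np.asarray(order)
    return float(lod[o[:-1], o[1:]].sum())


def order_group(
    members: Sequence[int],
    rf: np.ndarray,
    lod: np.ndarray,
    n_orders: int = 150,
    seed: int = 0,
    marker_ids: Optional[Sequence[str]] = None,
) -> tuple[list[int], list[list[int]]]:
    """Best marker order of one linkage group plus all candidate orders.

    Generates ``n_orders`` candidates by greedy nearest-neighbour chaining
    from seeded random start markers, each refined by 2-opt (via a dummy
    depot node, so reversals at the path ends are considered).  The best
    order minimises SARF, ties broken by maximal sum of adjacent LOD, and is
    orientation-normalised (first marker id < last marker id).
    """
    members = list(members)
    k = len(members)
    if k == 0:
        raise ValueError("empty group")
    if k == 1:
        return members, [members]
    rng = np.random.default_rng(seed)
    D = rf[np.ix_(members, members)]
    L = lod[np.ix_(members, members)]
    # dummy depot with zero distance to all markers makes the open path cyclic
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = D
    candidates: list[list[int]] = []
    starts = rng.integers(0, k, size=n_orders)
    for s in starts:
        chain = _greedy_chain(D, int(s))
        cyc = _two_opt_cycle(chain + [k], A)
        cut = cyc.index(k)
        path = cyc[cut + 1:] + cyc[:cut]
        candidates.append(path)
    ids = marker_ids if marker_ids is not None else [str(m) for m in members]
    norm = [p if str(ids[p[0]]) <= str(ids[p[-1]]) else p[::-1] for p in candidates]
    scored = [(_sarf(p, D), -_salod(p, L), i) for i, p in enumerate(norm)]
    scored.sort()
    best_local = norm[scored[0][2]]
    best = [members[i] for i in best_local]
    cand_global = [[members[i] for i in p] for p in norm]
    return best, cand_global


def map_positions(order: Sequence[int], rf: np.ndarray) -> np.ndarray:
    """Cumulative Haldane positions (cM) along an order; position 0 first."""
    o = np.asarray(order)
    if o.size == 0:
        return np.array([])
    steps = haldane_cm(rf[o[:-1], o[1:]])
    return np.concatenate(([0.0], np.cumsum(steps)))


def stability(candidates: Sequence[Sequence[int]], best: Sequence[int]) -> np.ndarray:
    """Per-marker fraction of candidate orders that keep the marker within
    one rank of its best-map position (candidates orientation-matched)."""
    if len(candidates) < 2:
        raise ValueError("stability requires at least 2 candidate orders")
    best = list(best)
    rank_best = {m: i for i, m in enumerate(best)}
    hits = np.zeros(len(best))
    for cand in candidates:
        cand = list(cand)
        ranks_f = {m: i for i, m in enumerate(cand)}
        ranks_r = {m: i for i, m in enumerate(cand[::-1])}
        disp_f = sum(abs(ranks_f[m] - rank_best[m]) for m in best)
        disp_r = sum(abs(ranks_r[m] - rank_best[m]) for m in best)
        ranks = ranks_f if disp_f <= disp_r else ranks_r
        for i, m in enumerate(best):
            if abs(ranks[m] - rank_best[m]) <= 1:
                hits[i] += 1
    return hits / len(candidates)


# ---------------------------------------------------------------------------
# Full map construction
# ---------------------------------------------------------------------------


@dataclass
class MapOrder:
    """Ordered markers of one linkage group."""

    group_id: int
    marker_ids: list[str]
    positions: np.ndarray  # cM, non-decreasing from 0
    stability: np.ndarray
    sarf: float
    salod: float

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class MapResult:
    groups: list[MapOrder]
    ungrouped: list[str]
    config: MapConfig
    merge_log: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as f:
            f.write("group\tmarker\tposition_cM\tstability\n")
            for g in self.groups:
                for m, p, s in zip(g.marker_ids, g.positions, g.stability):
                    f.write(f"LG{g.group_id}\t{m}\t{p:.2f}\t{s:.3f}\n")
            for m in self.ungrouped:
                f.write(f"ungrouped\t{m}\tNA\tNA\n")


def _mean_within_lod(groups: list[list[int]], lod: np.ndarray) -> float:
    tot = 0.0
    n = 0
    for g in groups:
        if len(g) < 2:
            continue
        sub = lod[np.ix_(g, g)]
        iu = np.triu_indices(len(g), k=1)
        tot += float(sub[iu].sum())
        n += len(iu[0])
    return tot / n if n else 0.0


def build_map(abh: ABHMatrix, config: MapConfig = MapConfig()) -> MapResult:
    """Run the whole mapping stage on an A/B/H matrix.

    Grouping is re-run at the configured LOD threshold and +/- 1 LOD, and the
    partition with the highest mean within-group LOD is kept (a pragmatic
    merge/split criterion, recorded in ``merge_log``).  In two-step mode only
    markers with offspring missingness up to ``anchor_primary_missing`` form
    the primary groups; markers with missingness up to
    ``anchor_ceiling_missing`` are then anchored to the best-fitting group.
    """
    M, marker_ids = encode_abh(abh)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 markers to build a map")
    rf_raw, lod, _ = rf_matrix(M, abh.poptype)
    rf, _ = reestimate_long(rf_raw, config.reestimate_threshold)

    missing_frac = (M < 0).mean(axis=1)
    if config.two_step:
        primary = np.nonzero(missing_frac <= config.anchor_primary_missing)[0]
        anchorable = np.nonzero(
            (missing_frac > config.anchor_primary_missing)
            & (missing_frac <= config.anchor_ceiling_missing)
        )[0]
    else:
        primary = np.arange(M.shape[0])
        anchorable = np.array([], dtype=int)

    sub = np.ix_(primary, primary)
    merge_log = {}
    best_groups = None
    best_score = -np.inf
    for lod_thr in (config.group_min_lod - 1.0, config.group_min_lod, config.group_min_lod + 1.0):
        g, u = group_markers(rf[sub], lod[sub], config.group_max_rf, max(lod_thr, 0.0))
        score = _mean_within_lod(g, lod[sub])
        merge_log[f"lod={lod_thr:g}"] = {"n_groups": len(g), "mean_within_lod": round(score, 3)}
        if score > best_score:
            best_score = score
            best_groups = (g, u, lod_thr)
    groups_local, ungrouped_local, chosen_thr = best_groups
    merge_log["chosen_lod"] = chosen_thr
    groups = [[int(primary[i]) for i in g] for g in groups_local]
    ungrouped = [int(primary[i]) for i in ungrouped_local]

    if anchorable.size:
        groups, still = anchor_assign(
            groups, anchorable.tolist() + ungrouped, rf,
            config.group_max_rf, config.anchor_margin,
        )
        ungrouped = still

    rng = np.random.default_rng(config.seed)
    out_groups: list[MapOrder] = []
    for gid, members in enumerate(groups, start=1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if len(members) == 1:
            out_groups.append(MapOrder(gid, [marker_ids[members[0]]],
                                       np.array([0.0]), np.array([1.0]), 0.0, 0.0))
            continue
        best, cands = order_group(
            members, rf, lod, config.n_orders, sub_seed,
            marker_ids=[marker_ids[m] for m in members],
        )
        pos = map_positions(best, rf)
        stab = stability(cands, best) if len(cands) >= 2 else np.ones(len(best))
        out_groups.append(
            MapOrder(
                gid,
                [marker_ids[m] for m in best],
                pos,
                stab,
                _sarf(best, rf),
                _salod(best, lod),
            )
        )
    return MapResult(out_groups, [marker_ids[m] for m in ungrouped], config, merge_log)
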