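"""Two-point linkage, grouping, marker ordering and map statistics.

The engine works on *transmission chains*: for every (family, parent) and
every locus at which that parent is heterozygous, each offspring either
reveals which parental allele it received (a resolved meiosis) or not
(missing genotype, or an ambiguous intercross genotype).  Two-point analysis
maximises the joint genotype likelihood over the recombination fraction and
the unknown parental phases.  Ordering maximises a profiled multipoint
likelihood: chain phases are fixed once by a spanning alignment with
majority-vote refinement, every maximal run of consecutively-resolved
transmissions contributes a span observation pooled across chains, and all
spans are scored against composite probabilities built from shared
adjacent-interval rates, so spans that skip loci act as consistency checks
on the order.  The objective collapses to the classical per-interval closed
form on fully observed data.

LOD scores are base-10 likelihood ratios against free recombination
(r = 0.5).  Map distances use the Kosambi function throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations, product

import networkx as nx
import numba
import numpy as np
from scipy.optimize import minimize_scalar

from .genotypes import Family, Marker

__all__ = [
    "kosambi_cm",
    "kosambi_inverse",
    "TwoPointResult",
    "TwoPointTable",
    "twopoint",
    "twopoint_table",
    "group_markers",
    "pool_groups",
    "FamilySet",
    "multipoint_loglik",
    "order_build",
    "flips_refine",
    "LinkageGroup",
    "MapStats",
    "GeneticMap",
    "map_stats",
    "refine_order",
    "build_map",
]

LN10 = math.log(10.0)
#: recombination fractions are capped here when converting to map distance,
#: so that an (effectively unlinked) adjacent pair yields a finite interval
R_CAP = 0.45
#: adjacent markers with r_hat at or above this are effectively unlinked;
#: the threshold sits between the 30 cM maximum credible map interval
#: (r ~ 0.27) and the sampling noise of a truly unlinked junction
#: (r_hat ~ 0.5 +/- 0.07); built groups are split at such junctions
R_SPLIT = 0.35
#: numerical tolerance for "positive support" decisions in ordering
SUPPORT_TOL = 1e-9
BUILD_THRESHOLDS = (3.0, 2.0, 1.0, 0.5, 0.0)


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi_cm(r: float) -> float:
    """Kosambi map distance in cM: d = 25 * ln((1+2r)/(1-2r)), 0 <= r < 0.5."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction out of [0, 0.5): {r}")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Inverse Kosambi: r = tanh(d/50)/2 for a distance in cM."""
    if d_cm < 0:
        raise ValueError(f"negative map distance: {d_cm}")
    return 0.5 * math.tanh(d_cm / 50.0)


# ---------------------------------------------------------------------------
# Numeric family coding and transmission chains
# ---------------------------------------------------------------------------

@dataclass
class _FamilyData:
    family_id: str
    off_ids: list[str]
    par: np.ndarray    # (2, L, 2) parental allele codes, -1 missing
    het: np.ndarray    # (2, L) bool: parent heterozygous (both alleles known)
    off: np.ndarray    # (N, L, 2) offspring allele codes, -1 missing
    T: np.ndarray      # (2, L, N) resolved transmissions: 0/1 slot, -1 unknown
    n_unres: np.ndarray  # (2, L) observed-but-unresolved offspring counts


class FamilySet:
    """Numeric view of a marker list + families, with transmission chains."""

    def __init__(self, markers: list[Marker], families: list[Family]):
        self.markers = list(markers)
        self.ids = [m.id for m in markers]
        self.index = {m.id: i for i, m in enumerate(markers)}
        self._codes = [
            {a: k for k, a in enumerate(m.alleles)} for m in markers
        ]
        self.families = [self._encode(f) for f in families]
        L = len(markers)
        n_inf = np.zeros(L, dtype=np.int32)
        for fd in self.families:
            for p in (0, 1):
                n_inf += np.where(fd.het[p], (fd.T[p] >= 0).sum(axis=1), 0)
        #: resolved informative meioses per marker, summed over chains
        self.informative_meioses = n_inf

    def _encode(self, fam: Family) -> _FamilyData:
        L = len(self.markers)
        par = np.full((2, L, 2), -1, dtype=np.int8)
        off_ids = list(fam.offspring)
        N = len(off_ids)
        off = np.full((N, L, 2), -1, dtype=np.int8)
        for i, m in enumerate(self.markers):
            code = self._codes[i]
            for p, genos in enumerate((fam.sire, fam.dam)):
                g = genos.get(m.id)
                if g is not None:
                    par[p, i, 0], par[p, i, 1] = code[g[0]], code[g[1]]
            for n, oid in enumerate(off_ids):
                g = fam.offspring[oid].get(m.id)
                if g is not None:
                    off[n, i, 0], off[n, i, 1] = code[g[0]], code[g[1]]
        het = (par[:, :, 0] >= 0) & (par[:, :, 0] != par[:, :, 1])

        T = np.full((2, L, N), -1, dtype=np.int8)
        n_unres = np.zeros((2, L), dtype=np.int32)
        for p in (0, 1):
            q = 1 - p
            for i in range(L):
                if not het[p, i]:
                    continue
                p0, p1 = int(par[p, i, 0]), int(par[p, i, 1])
                q_known = par[q, i, 0] >= 0
                q0, q1 = int(par[q, i, 0]), int(par[q, i, 1])
                for n in range(N):
                    x, y = int(off[n, i, 0]), int(off[n, i, 1])
                    if x < 0:
                        continue
                    cands = []
                    for c, ft in ((0, p0), (1, p1)):
                        if x == y:
                            if ft != x:
                                continue
                            z = x
                        elif ft == x:
                            z = y
                        elif ft == y:
                            z = x
                        else:
                            continue
                        if q_known and z != q0 and z != q1:
                            continue
                        cands.append(c)
                    if len(cands) == 1:
                        T[p, i, n] = cands[0]
                    else:
                        n_unres[p, i] += 1
        return _FamilyData(fam.family_id, off_ids, par, het, off, T, n_unres)


# ---------------------------------------------------------------------------
# Two-point analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointResult:
    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int


def _bern_ll(k: float, n: float, p: float) -> float:
    """k*ln p + (n-k)*ln(1-p) with the 0*ln0 convention."""
    ll = 0.0
    if k > 0:
        ll += k * math.log(p)
    if n - k > 0:
        ll += (n - k) * math.log(1.0 - p)
    return ll


def _fast_pair(units: list[tuple[int, int]]) -> tuple[float, float]:
    """Exact two-point MLE for fully resolved chains.

    Each unit is (recombinants, meioses) for one (family, parent) chain under
    an arbitrary phase; the likelihood is maximised jointly over a shared r
    and per-unit phase flips (k <-> n-k).  Returns (r_hat, lod)."""
    units = [(k, n) for k, n in units if n > 0]
    N = sum(n for _, n in units)
    if N == 0:
        return 0.5, 0.0
    best = None
    for flips in product((0, 1), repeat=len(units)):
        K = sum((n - k) if f else k for (k, n), f in zip(units, flips))
        p = min(K / N, 0.5)
        ll = _bern_ll(K, N, p)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, p)
    ll, r_hat = best
    lod = (ll - N * math.log(0.5)) / LN10
    if lod < 1e-12:  # numerically unlinked
        return 0.5, 0.0
    return r_hat, lod


def _pair_class_coeffs(fd: _FamilyData, i: int, j: int):
    """Quadratic-in-r genotype-class likelihood coefficients for one family.

    Returns None when the family carries no linkage information for (i, j),
    else (counts, [coeff matrix per phase combo]); each coefficient matrix is
    (n_classes, 3) over the basis [(1-r)^2, r(1-r), r^2].
    """
    has_chain = any(fd.het[p, i] and fd.het[p, j] for p in (0, 1))
    if not has_chain:
        return None
    if (fd.par[:, (i, j), 0] < 0).any():
        return None  # a parent genotype is missing: family skipped for this pair

    oi, oj = fd.off[:, i, :], fd.off[:, j, :]
    mask = (oi[:, 0] >= 0) & (oj[:, 0] >= 0)
    if not mask.any():
        return None
    gi = np.sort(oi[mask], axis=1)
    gj = np.sort(oj[mask], axis=1)
    keys = ((gi[:, 0].astype(np.int32) * 16 + gi[:, 1]) * 16 + gj[:, 0]) * 16 + gj[:, 1]
    uniq, counts = np.unique(keys, return_counts=True)
    class_alleles = []
    for key in uniq:
        b1 = key % 16; key //= 16
        b0 = key % 16; key //= 16
        a1 = key % 16; key //= 16
        a0 = key
        class_alleles.append((int(a0), int(a1), int(b0), int(b1)))

    s_a = (int(fd.par[0, i, 0]), int(fd.par[0, i, 1]))
    s_b = (int(fd.par[0, j, 0]), int(fd.par[0, j, 1]))
    d_a = (int(fd.par[1, i, 0]), int(fd.par[1, i, 1]))
    d_b = (int(fd.par[1, j, 0]), int(fd.par[1, j, 1]))
    s_phases = [s_b, (s_b[1], s_b[0])] if fd.het[0, i] and fd.het[0, j] else [s_b]
    d_phases = [d_b, (d_b[1], d_b[0])] if fd.het[1, i] and fd.het[1, j] else [d_b]

    coeff_sets = []
    for sb in s_phases:
        for db in d_phases:
            C = np.zeros((len(class_alleles), 3))
            for ci, (a0, a1, b0, b1) in enumerate(class_alleles):
                for si, sj in product((0, 1), repeat=2):
                    for di, dj in product((0, 1), repeat=2):
                        if tuple(sorted((s_a[si], d_a[di]))) != (a0, a1):
                            continue
                        if tuple(sorted((sb[sj], db[dj]))) != (b0, b1):
                            continue
                        C[ci, (si != sj) + (di != dj)] += 1.0
            coeff_sets.append(C)
    return counts.astype(float), coeff_sets


def _curves_loglik(family_terms, r: np.ndarray) -> np.ndarray:
    """Sum over families of the per-family max-over-phase log-likelihood."""
    basis = np.stack([(1 - r) ** 2, r * (1 - r), r ** 2])
    total = np.zeros_like(r)
    for counts, coeff_sets in family_terms:
        best = None
        for C in coeff_sets:
            probs = np.maximum(C @ basis, 1e-300)
            ll = counts @ np.log(probs)
            best = ll if best is None else np.maximum(best, ll)
        total += best
    return total


def _pair_result(fs: FamilySet, i: int, j: int) -> TwoPointResult:
    a_id, b_id = fs.ids[i], fs.ids[j]
    n_inf = 0
    fast = True
    units: list[tuple[int, int]] = []
    any_chain = False
    for fd in fs.families:
        for p in (0, 1):
            if not (fd.het[p, i] and fd.het[p, j]):
                continue
            any_chain = True
            ta, tb = fd.T[p, i], fd.T[p, j]
            valid = (ta >= 0) & (tb >= 0)
            n = int(valid.sum())
            n_inf += n
            if fd.n_unres[p, i] or fd.n_unres[p, j]:
                fast = False
            units.append((int((ta[valid] != tb[valid]).sum()), n))
    if not any_chain or n_inf == 0:
        return TwoPointResult(a_id, b_id, 0.5, 0.0, n_inf)

    if fast:
        r_hat, lod = _fast_pair(units)
        return TwoPointResult(a_id, b_id, r_hat, lod, n_inf)

    family_terms = [
        t for t in (_pair_class_coeffs(fd, i, j) for fd in fs.families)
        if t is not None
    ]
    if not family_terms:
        return TwoPointResult(a_id, b_id, 0.5, 0.0, n_inf)
    grid = np.linspace(0.0, 0.5, 65)
    ll = _curves_loglik(family_terms, grid)
    k = int(np.argmax(ll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda r: -_curves_loglik(family_terms, np.array([r]))[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(np.clip(res.x, 0.0, 0.5))
    ll_hat = _curves_loglik(family_terms, np.array([r_hat]))[0]
    ll_null = _curves_loglik(family_terms, np.array([0.5]))[0]
    if ll_null >= ll_hat:
        r_hat, ll_hat = 0.5, ll_null
    lod = max((ll_hat - ll_null) / LN10, 0.0)
    if lod == 0.0:
        r_hat = 0.5
    return TwoPointResult(a_id, b_id, r_hat, lod, n_inf)


@dataclass
class TwoPointTable:
    """All-pairs two-point results over one marker set."""

    ids: list[str]
    r: np.ndarray      # (L, L), symmetric, diag 0
    lod: np.ndarray    # (L, L), symmetric, diag 0
    n: np.ndarray      # (L, L) informative meioses
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {m: i for i, m in enumerate(self.ids)}

    def pair(self, a: str, b: str) -> TwoPointResult:
        i, j = self.index[a], self.index[b]
        return TwoPointResult(a, b, float(self.r[i, j]), float(self.lod[i, j]),
                              int(self.n[i, j]))


def twopoint(marker_a: Marker, marker_b: Marker, families: list[Family]) -> TwoPointResult:
    """Two-point recombination fraction and LOD for one marker pair."""
    fs = FamilySet([marker_a, marker_b], families)
    return _pair_result(fs, 0, 1)


def twopoint_table(markers: list[Marker], families: list[Family],
                   fs: FamilySet | None = None) -> TwoPointTable:
    """All-pairs two-point analysis (the input to grouping and ordering)."""
    if fs is None:
        fs = FamilySet(markers, families)
    L = len(fs.markers)
    r = np.full((L, L), 0.5)
    np.fill_diagonal(r, 0.0)
    lod = np.zeros((L, L))
    n = np.zeros((L, L), dtype=np.int32)
    for i in range(L):
        for j in range(i + 1, L):
            res = _pair_result(fs, i, j)
            r[i, j] = r[j, i] = res.r_hat
            lod[i, j] = lod[j, i] = res.lod
            n[i, j] = n[j, i] = res.n_informative
    return TwoPointTable(fs.ids, r, lod, n)


# ---------------------------------------------------------------------------
# Grouping and pooling
# ---------------------------------------------------------------------------

def group_markers(tp: TwoPointTable, lod_group: float = 8.0) -> list[list[str]]:
    """Connected components of the marker graph with edges at lod >= lod_group."""
    g = nx.Graph()
    g.add_nodes_from(tp.ids)
    L = len(tp.ids)
    for i in range(L):
        for j in range(i + 1, L):
            if tp.lod[i, j] >= lod_group:
                g.add_edge(tp.ids[i], tp.ids[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def pool_groups(
    groups: list[list[str]],
    tp: TwoPointTable,
    lod_pool: float = 4.0,
    lod_weak: float = 0.5,
    majority: float = 0.5,
    small_max: int = 5,
) -> list[list[str]]:
    """Merge groups joined by a single strong cross pair (lod >= lod_pool) or
    small groups (<= small_max markers) weakly linked (lod >= lod_weak) to a
    majority of another group's markers.

    The weak-majority rule is restricted to small groups because phase
    profiling inflates null LODs enough that two large unlinked groups
    routinely share a majority of cross pairs above 0.5.  Applied iteratively
    to a fixed point; only ever coarsens the partition.
    """
    groups = [sorted(g) for g in groups]
    changed = True
    while changed:
        changed = False
        groups.sort(key=lambda c: (-len(c), c[0]))
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = [tp.index[m] for m in groups[a]]
                ib = [tp.index[m] for m in groups[b]]
                cross = tp.lod[np.ix_(ia, ib)]
                if cross.size == 0:
                    continue
                small = min(len(ia), len(ib)) <= small_max
                if cross.max() >= lod_pool or \
                        (small and (cross >= lod_weak).mean() > majority):
                    groups[a] = sorted(groups[a] + groups[b])
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    groups.sort(key=lambda c: (-len(c), c[0]))
    return groups


# ---------------------------------------------------------------------------
# Multipoint objective (profiled) and ordering
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _accumulate_spans(T, ranks, selective, K, M, K2, M2):  # pragma: no cover
    """Walk one chain's meioses in the given order, accumulating span counts.

    T is (chain loci in current order x meioses), entries 0/1 resolved,
    -1 unknown; ``ranks`` maps rows to positions in the full order.  Every
    maximal pair of consecutively-resolved loci per meiosis adds one
    observation to the (rank_a, rank_b) cell of M (and K when recombinant).

    Loci flagged ``selective`` are resolvable only for offspring whose other
    parent transmitted a matching allele (both parents heterozygous); spans
    with two selective endpoints condition on correlated transmissions in
    both parents, so their recombinant fractions estimate a transformed rate
    and are accumulated separately (K2, M2).
    """
    L, N = T.shape
    for j in range(N):
        last = -1
        lastv = 0
        for i in range(L):
            v = T[i, j]
            if v >= 0:
                if last >= 0:
                    if selective[last] and selective[i]:
                        M2[ranks[last], ranks[i]] += 1
                        if v != lastv:
                            K2[ranks[last], ranks[i]] += 1
                    else:
                        M[ranks[last], ranks[i]] += 1
                        if v != lastv:
                            K[ranks[last], ranks[i]] += 1
                last = i
                lastv = v


_R_MAX = 0.49  # interval rates are clipped here (finite Kosambi distance)


@numba.njit(cache=False)
def _interval_rates(K, M):  # pragma: no cover - numba kernel
    """Adjacent-interval recombination rates from pooled span counts.

    Directly observed intervals take their empirical rate; intervals no
    meiosis observes directly inherit an even composite split of the
    shortest (then deepest) span covering them, which keeps the objective
    invariant to inserting transmission-free loci.
    """
    L = K.shape[0]
    r = np.zeros(L - 1)
    for i in range(L - 1):
        m = M[i, i + 1]
        if m > 0:
            p = K[i, i + 1] / m
            r[i] = min(p, _R_MAX)
        else:
            # pool every covering span of minimal gap (reversal-symmetric)
            bestg = 1 << 30
            for a in range(i + 1):
                for b in range(i + 1, L):
                    if M[a, b] > 0 and b - a < bestg:
                        bestg = b - a
            if bestg < (1 << 30):
                kp = 0
                mp = 0
                for a in range(i + 1):
                    for b in range(i + 1, L):
                        if b - a == bestg and M[a, b] > 0:
                            kp += K[a, b]
                            mp += M[a, b]
                p = min(kp / mp, _R_MAX)
                r[i] = 0.5 * (1.0 - (1.0 - 2.0 * p) ** (1.0 / bestg))
    return r


@numba.njit(cache=False)
def _refine_rates(K, M, K2, M2, r, rounds):  # pragma: no cover - numba
    """Coordinate-wise ML refinement of the interval rates given all spans.

    Each interval rate is optimised in turn against every span covering it
    (composite probabilities; doubly-conditioned spans with per-span phase
    profile).  Skip spans thereby pull zigzag paths back together and fill
    intervals that lack direct observations.
    """
    L = K.shape[0]
    for _ in range(rounds):
        for i in range(L - 1):
            lo, hi = 0.0, _R_MAX
            for _ in range(40):  # ternary search on a smooth 1-D slice
                m1 = lo + (hi - lo) / 3.0
                m2_ = hi - (hi - lo) / 3.0
                v1 = 0.0
                v2 = 0.0
                for a in range(i + 1):
                    for b in range(i + 1, L):
                        m = M[a, b]
                        mm2 = M2[a, b]
                        if m == 0 and mm2 == 0:
                            continue
                        prod = 1.0
                        for j in range(a, b):
                            if j != i:
                                prod *= 1.0 - 2.0 * r[j]
                        for cand in range(2):
                            rc = m1 if cand == 0 else m2_
                            p = 0.5 * (1.0 - prod * (1.0 - 2.0 * rc))
                            v = 0.0
                            if m > 0:
                                v += _bern(K[a, b], m, p)
                            if mm2 > 0:
                                ga = p * p / (p * p + (1.0 - p) * (1.0 - p))
                                best = _bern(K2[a, b], mm2, ga)
                                alt = _bern(K2[a, b], mm2, 0.5)
                                if alt > best:
                                    best = alt
                                alt = _bern(K2[a, b], mm2, 1.0 - ga)
                                if alt > best:
                                    best = alt
                                v += best
                            if cand == 0:
                                v1 += v
                            else:
                                v2 += v
                if v1 < v2:
                    lo = m1
                else:
                    hi = m2_
            r[i] = 0.5 * (lo + hi)
    return r


@numba.njit(cache=False)
def _bern(k, m, p):  # pragma: no cover - numba helper
    if p < 1e-12:
        p = 1e-12
    if p > 1.0 - 1e-12:
        p = 1.0 - 1e-12
    s = 0.0
    if k > 0:
        s += k * np.log(p)
    if m - k > 0:
        s += (m - k) * np.log(1.0 - p)
    return s


@numba.njit(cache=False)
def _composite_loglik(K, M, K2, M2):  # pragma: no cover - numba kernel
    """Multipoint log-likelihood: every span scored against the composite
    recombination probability implied by the shared interval rates.

    Spans that skip loci (missing or ambiguous genotypes marginalized over
    the locus chain) thereby act as consistency checks on the order: a
    transposed block makes the composite probability of its skipping spans
    disagree with their observed recombinant fractions.

    Doubly-conditioned spans (both endpoints resolvable only when the other
    parent transmitted a matching allele) observe a transformed rate that
    depends on the unknown relative parental phase: p^2/(p^2+(1-p)^2) in
    coupling, 1/2 in mixed phase, or its complement in repulsion; the phase
    is profiled per span.
    """
    L = K.shape[0]
    r = _interval_rates(K, M)
    lf = np.zeros(L)  # log prefix products of (1 - 2 r_i), all positive
    for i in range(L - 1):
        lf[i + 1] = lf[i] + np.log(1.0 - 2.0 * r[i])
    s = 0.0
    for a in range(L):
        for b in range(a + 1, L):
            m = M[a, b]
            m2 = M2[a, b]
            if m == 0 and m2 == 0:
                continue
            p = 0.5 * (1.0 - np.exp(lf[b] - lf[a]))
            if m > 0:
                s += _bern(K[a, b], m, p)
            if m2 > 0:
                ga = p * p / (p * p + (1.0 - p) * (1.0 - p))
                k2 = K2[a, b]
                best = _bern(k2, m2, ga)
                alt = _bern(k2, m2, 0.5)
                if alt > best:
                    best = alt
                alt = _bern(k2, m2, 1.0 - ga)
                if alt > best:
                    best = alt
                s += best
    return s


@dataclass
class _Chain:
    loci: np.ndarray  # local indices (into the group member list)
    T: np.ndarray     # (len(loci), N) int8, phases aligned within the chain
    selective: np.ndarray  # bool per locus: resolution conditions on the
    #                        other parent's transmission (both parents het)
    family: int = 0
    parent: int = 0


def _orient_chain(T: np.ndarray, selective: np.ndarray) -> np.ndarray:
    """Fix the parental phase of every chain locus relative to the others.

    Greedy spanning alignment: starting from the locus with the most shared
    meioses, each remaining locus is oriented against its already-oriented
    partner with the largest overlap so that their recombinant fraction is
    <= 1/2 (the two-point phase estimate).  Returns T with rows flipped
    accordingly.
    """
    Lc, _ = T.shape
    obs = (T >= 0).astype(np.int32)
    ones = np.where(T == 1, 1, 0).astype(np.int32)
    both = obs @ obs.T                         # shared meioses
    agree = ones @ ones.T + (obs - ones) @ (obs - ones).T
    mismatch = both - agree                    # recombinants at raw phase
    biased = np.outer(selective, selective)    # doubly-conditioned pairs
    both = np.where(biased, 0, both)
    mismatch = np.where(biased, 0, mismatch)
    # evidence for a shared phase: |n - 2k| is largest for tightly linked
    # (or tightly repulsed) locus pairs and ~0 for unlinked ones
    evidence = np.abs(both - 2 * mismatch)
    order = np.argsort(-both.sum(axis=1), kind="stable")
    flip = np.zeros(Lc, dtype=bool)
    placed = [int(order[0])]
    remaining = [int(i) for i in order[1:]]
    while remaining:
        best = None
        for j in remaining:
            for l in placed:
                key = (int(evidence[j, l]), int(both[j, l]), -j, -l)
                if best is None or key > best[0]:
                    best = (key, j, l)
        _, j, l = best
        n = both[j, l]
        if n > 0:
            k = mismatch[j, l]
            k_eff = (n - k) if flip[l] else k  # mismatches against oriented l
            flip[j] = bool(2 * k_eff > n)
        placed.append(j)
        remaining.remove(j)
    # refine by majority vote over all partners: a locus whose transmissions
    # disagree with the oriented consensus more often than they agree flips
    np.fill_diagonal(both, 0)
    np.fill_diagonal(mismatch, 0)
    for _ in range(2 * Lc + 4):
        sign = np.where(flip[:, None] ^ flip[None, :], -1, 1)
        k_eff = np.where(sign > 0, mismatch, both - mismatch)
        score = (both - 2 * k_eff).sum(axis=1)
        bad = score < 0
        if not bad.any():
            break
        # flip the worst offender only, then re-vote (avoids oscillation)
        j = int(np.argmin(score))
        flip[j] = not flip[j]
    T = T.copy()
    for i in np.nonzero(flip)[0]:
        row = T[i]
        sel = row >= 0
        row[sel] = 1 - row[sel]
    return T


def group_chains(fs: FamilySet, member_ids: list[str]) -> list[_Chain]:
    """Phase-aligned transmission chains restricted to one candidate group."""
    # canonical marker ordering, so phase orientation (and thus the
    # objective) is identical however the caller permutes the member list
    canon = sorted(member_ids, key=lambda m: fs.index[m])
    pos_in_member = {m: i for i, m in enumerate(member_ids)}
    idx = np.array([fs.index[m] for m in canon])
    chains = []
    for fi, fd in enumerate(fs.families):
        for p in (0, 1):
            het_local = fd.het[p][idx]
            rows = np.nonzero(het_local)[0]
            if len(rows) >= 2:
                loci = np.array([pos_in_member[canon[r]] for r in rows])
                T = np.ascontiguousarray(fd.T[p][idx[rows]])
                # fully distinguishable alleles (e.g. ab x cd) resolve every
                # offspring, so conditioning never selects on transmissions
                selective = fd.het[1 - p][idx[rows]] & \
                    (fd.n_unres[p][idx[rows]] > 0)
                chains.append(_Chain(loci, _orient_chain(T, selective),
                                     selective, family=fi, parent=p))
    return chains


def order_objective(chains: list[_Chain], order: np.ndarray,
                    n_total: int | None = None) -> float:
    """Profiled multipoint log-likelihood of a (possibly partial) marker
    order (natural log); loci outside ``order`` are ignored.

    Span counts are pooled across chains (families and parents share the
    recombination rate of a marker interval); the rate of each observed span
    is profiled at its pooled MLE, clipped to [0, 1/2].
    """
    K, M, K2, M2 = _span_counts(chains, order, n_total)
    return float(_composite_loglik(K, M, K2, M2))


def _span_counts(chains: list[_Chain], order: np.ndarray,
                 n_total: int | None = None):
    if n_total is None:
        n_total = len(order)
    Lo = len(order)
    inv = np.full(n_total, -1, dtype=np.int64)
    inv[np.asarray(order, dtype=np.int64)] = np.arange(Lo)
    K = np.zeros((Lo, Lo), dtype=np.int64)
    M = np.zeros((Lo, Lo), dtype=np.int64)
    K2 = np.zeros((Lo, Lo), dtype=np.int64)
    M2 = np.zeros((Lo, Lo), dtype=np.int64)
    for ch in chains:
        ranks = inv[ch.loci]
        sel = ranks >= 0
        if int(sel.sum()) < 2:
            continue
        idx = np.nonzero(sel)[0][np.argsort(ranks[sel], kind="stable")]
        _accumulate_spans(np.ascontiguousarray(ch.T[idx]),
                          np.sort(ranks[sel]).astype(np.int64),
                          ch.selective[idx], K, M, K2, M2)
    return K, M, K2, M2


def interval_support(chains: list[_Chain], order: np.ndarray,
                     n_total: int | None = None) -> np.ndarray:
    """True per interval iff at least one unbiased span covers it.

    An interval no meiosis bridges has no linkage evidence at all; a rate of
    zero there would be an artifact of the estimator's default, so callers
    treat unsupported intervals as unlinked junctions.
    """
    K, M, _, _ = _span_counts(chains, order, n_total)
    L = len(order)
    supported = np.zeros(max(L - 1, 0), dtype=bool)
    for a in range(L):
        for b in range(a + 1, L):
            if M[a, b] > 0:
                supported[a:b] = True
    return supported


def interval_rates(chains: list[_Chain], order: np.ndarray,
                   n_total: int | None = None, refine: bool = False) -> np.ndarray:
    """Pooled adjacent-interval recombination-rate estimates for an order.

    With ``refine`` the single-pass estimates are polished by coordinate-wise
    maximum likelihood over all spans (composite probabilities), which
    de-inflates zigzag paths caused by residual ordering error.
    """
    K, M, K2, M2 = _span_counts(chains, order, n_total)
    r = np.asarray(_interval_rates(K, M))
    if refine and len(order) > 2:
        r = np.asarray(_refine_rates(K, M, K2, M2, r, 3))
    return r


def multipoint_loglik(order: list[Marker], families: list[Family]) -> float:
    """Profiled multipoint log-likelihood of an ordered marker list."""
    fs = FamilySet(list(order), families)
    chains = group_chains(fs, fs.ids)
    return order_objective(chains, np.arange(len(order)))


def _insertion_scores(chains, order: np.ndarray, m: int, n_total: int) -> np.ndarray:
    L = len(order)
    scores = np.empty(L + 1)
    for pos in range(L + 1):
        cand = np.insert(order, pos, m)
        scores[pos] = order_objective(chains, cand, n_total)
    return scores


def final_interval_rates(fs: FamilySet, ordered_ids: list[str],
                         rounds: int = 3) -> np.ndarray:
    """Interval rates for a finished order, refined against the exact
    two-point likelihood of each adjacent pair plus all skipping spans.

    The adjacent-pair genotype likelihood uses every offspring (including
    the intercross configurations whose transmissions are only selectively
    resolvable), while spans that skip loci keep the composite-probability
    consistency role they play in the ordering objective.
    """
    L = len(ordered_ids)
    chains = group_chains(fs, ordered_ids)
    order = np.arange(L)
    K, M, K2, M2 = _span_counts(chains, order)
    r = np.asarray(_interval_rates(K, M))
    if L < 2:
        return r

    pair_terms = []
    for i in range(L - 1):
        gi, gj = fs.index[ordered_ids[i]], fs.index[ordered_ids[i + 1]]
        terms = [
            t for t in (_pair_class_coeffs(fd, gi, gj) for fd in fs.families)
            if t is not None
        ]
        pair_terms.append(terms or None)

    def local_ll(i: int, ri: float) -> float:
        s = 0.0
        if pair_terms[i] is not None:
            s += _curves_loglik(pair_terms[i], np.array([ri]))[0]
        else:
            if M[i, i + 1] > 0:
                s += _bern(K[i, i + 1], M[i, i + 1], ri)
            if M2[i, i + 1] > 0:
                ga = ri * ri / (ri * ri + (1 - ri) ** 2)
                s += max(
                    _bern(K2[i, i + 1], M2[i, i + 1], ga),
                    _bern(K2[i, i + 1], M2[i, i + 1], 0.5),
                    _bern(K2[i, i + 1], M2[i, i + 1], 1 - ga),
                )
        # skipping spans covering interval i
        for a in range(i + 1):
            for b in range(i + 2, L):
                if b - a < 2 or b <= i:
                    continue
                m = M[a, b]
                m2c = M2[a, b]
                if m == 0 and m2c == 0:
                    continue
                prod = 1.0
                for j in range(a, b):
                    prod *= 1.0 - 2.0 * (ri if j == i else r[j])
                p = 0.5 * (1.0 - prod)
                if m > 0:
                    s += _bern(K[a, b], m, p)
                if m2c > 0:
                    ga = p * p / (p * p + (1 - p) ** 2)
                    s += max(
                        _bern(K2[a, b], m2c, ga),
                        _bern(K2[a, b], m2c, 0.5),
                        _bern(K2[a, b], m2c, 1 - ga),
                    )
        return s

    for _ in range(rounds):
        for i in range(L - 1):
            lo, hi = 0.0, _R_MAX
            for _ in range(30):
                m1 = lo + (hi - lo) / 3.0
                m2_ = hi - (hi - lo) / 3.0
                if local_ll(i, m1) < local_ll(i, m2_):
                    lo = m1
                else:
                    hi = m2_
            r[i] = 0.5 * (lo + hi)
    return r


def order_build(
    member_ids: list[str],
    tp: TwoPointTable,
    fs: FamilySet,
    thresholds: tuple[float, ...] = BUILD_THRESHOLDS,
) -> tuple[list[str], list[str]]:
    """Greedy build ordering with stepwise-lowered placement support.

    Seeds with the pair of highest informative-meiosis count; repeatedly
    inserts the unplaced marker whose best insertion position beats its
    second-best by at least the current support threshold (in log10 units),
    lowering the threshold stepwise when no marker qualifies.  Markers that
    never attract positive support are returned unmapped.
    """
    ids = list(member_ids)
    if len(ids) < 2:
        return ids, []
    chains = group_chains(fs, ids)
    gi = {m: k for k, m in enumerate(ids)}
    tpi = [tp.index[m] for m in ids]

    best_pair = None
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            key = (int(tp.n[tpi[a], tpi[b]]), float(tp.lod[tpi[a], tpi[b]]),
                   tuple(sorted((ids[a], ids[b]))))
            if best_pair is None or (key[0], key[1]) > (best_pair[0], best_pair[1]) \
                    or ((key[0], key[1]) == (best_pair[0], best_pair[1])
                        and key[2] < best_pair[2]):
                best_pair = key
    a_id, b_id = best_pair[2]
    order = np.array([gi[a_id], gi[b_id]])
    unplaced = [m for m in ids if m not in (a_id, b_id)]

    for thr in thresholds:
        while unplaced:
            candidates = []
            for m in unplaced:
                scores = _insertion_scores(chains, order, gi[m], len(ids))
                top = np.sort(scores)[::-1]
                support = (top[0] - top[1]) / LN10 if len(top) > 1 else 0.0
                pos = int(np.argmax(scores))
                ok = support > SUPPORT_TOL if thr == 0.0 else support >= thr - 1e-12
                if ok:
                    nm = int(fs.informative_meioses[fs.index[m]])
                    candidates.append((support, nm, m, pos))
            if not candidates:
                break
            candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
            support, _, m, pos = candidates[0]
            order = np.insert(order, pos, gi[m])
            unplaced.remove(m)
    ordered_ids = [ids[k] for k in order]
    return ordered_ids, sorted(unplaced)


def _relocate_refine(ordered_ids: list[str], fs: FamilySet,
                     chains: list[_Chain] | None = None) -> list[str]:
    """Single-marker relocation passes: each marker is removed and reinserted
    at its best position; strictly improving moves are adopted until a full
    pass changes nothing."""
    ids = list(ordered_ids)
    L = len(ids)
    if L < 3:
        return ids
    if chains is None:
        chains = group_chains(fs, ids)
    gi = {m: k for k, m in enumerate(ids)}
    order = np.array([gi[m] for m in ids])
    current = order_objective(chains, order)
    improved = True
    while improved:
        improved = False
        for m in list(ids):
            k = int(np.nonzero(order == gi[m])[0][0])
            rest = np.delete(order, k)
            scores = _insertion_scores(chains, rest, gi[m], L)
            pos = int(np.argmax(scores))
            if scores[pos] > current + SUPPORT_TOL and pos != k:
                order = np.insert(rest, pos, gi[m])
                current = scores[pos]
                improved = True
    return [ids[k] for k in order]


def _reversal_refine(ordered_ids: list[str], fs: FamilySet,
                     chains: list[_Chain] | None = None) -> list[str]:
    """2-opt passes: every contiguous segment reversal is tried and strictly
    improving reversals adopted (best-improvement per pass), escaping the
    inversion-type local optima that windowed permutations cannot reach."""
    ids = list(ordered_ids)
    L = len(ids)
    if L < 4:
        return ids
    if chains is None:
        chains = group_chains(fs, ids)
    gi = {m: k for k, m in enumerate(ids)}
    order = np.array([gi[m] for m in ids])
    current = order_objective(chains, order)
    improved = True
    while improved:
        improved = False
        best = (current, None)
        for i in range(L - 2):
            for j in range(i + 3, L + 1):  # reverse order[i:j], len >= 3
                cand = order.copy()
                cand[i:j] = cand[i:j][::-1]
                obj = order_objective(chains, cand)
                if obj > best[0] + SUPPORT_TOL:
                    best = (obj, (i, j))
        if best[1] is not None:
            i, j = best[1]
            order[i:j] = order[i:j][::-1]
            current = best[0]
            improved = True
    return [ids[k] for k in order]


def flips_refine(
    ordered_ids: list[str],
    fs: FamilySet,
    window: int = 5,
) -> list[str]:
    """Windowed permutation refinement of a marker order.

    Slides a window of ``window`` markers; every within-window permutation is
    evaluated under the profiled multipoint likelihood with the flanks fixed;
    the best is adopted.  Repeats full passes until a pass changes nothing.
    The output objective is never below the input objective.
    """
    ids = list(ordered_ids)
    L = len(ids)
    if L < 3:
        return ids
    chains = group_chains(fs, ids)
    gi = {m: k for k, m in enumerate(ids)}
    order = np.array([gi[m] for m in ids])
    w = min(window, L)
    perms = list(permutations(range(w)))
    current = order_objective(chains, order)
    improved = True
    while improved:
        improved = False
        for start in range(L - w + 1):
            best_perm, best_obj = None, current
            segment = order[start:start + w].copy()
            for p in perms[1:]:
                cand = order.copy()
                cand[start:start + w] = segment[list(p)]
                obj = order_objective(chains, cand)
                if obj > best_obj + SUPPORT_TOL:
                    best_obj, best_perm = obj, p
            if best_perm is not None:
                order[start:start + w] = segment[list(best_perm)]
                current = best_obj
                improved = True
    return [ids[k] for k in order]


# ---------------------------------------------------------------------------
# Linkage groups, maps, statistics
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    group_id: str
    marker_ids: list[str]
    positions: np.ndarray  # cM from the first marker, non-decreasing

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class MapStats:
    total_length_cm: float
    d_av_cm: float
    max_interval_cm: float
    n_mapped: int
    n_groups: int


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    unmapped: list[str]
    stats: MapStats
    contig_of: dict[str, str | None] = field(default_factory=dict)

    def group_of(self) -> dict[str, str]:
        return {m: g.group_id for g in self.groups for m in g.marker_ids}


def _arrange_blocks(blocks: list[list[str]], fs: FamilySet) -> list[str]:
    """Concatenate rigid ordered blocks, choosing the block sequence and
    orientations that maximise the multipoint objective.

    For up to three blocks every arrangement is enumerated; beyond that the
    blocks are chained greedily from the largest one, appending at either
    end in either orientation.  Deterministic tie-breaks (first arrangement
    in enumeration order wins).
    """
    ids = [m for b in blocks for m in b]
    chains = group_chains(fs, ids)
    gi = {m: k for k, m in enumerate(ids)}

    def obj(seq: list[str]) -> float:
        return order_objective(chains, np.array([gi[m] for m in seq]),
                               n_total=len(ids))

    def orientations(block: list[str]):
        yield block
        if len(block) > 1:
            yield block[::-1]

    if len(blocks) <= 3:
        best = None
        for perm in permutations(range(len(blocks))):
            for orient in product(*(range(2 if len(blocks[i]) > 1 else 1)
                                    for i in perm)):
                seq = []
                for bi, flip in zip(perm, orient):
                    seq.extend(blocks[bi][::-1] if flip else blocks[bi])
                val = obj(seq)
                if best is None or val > best[0] + SUPPORT_TOL:
                    best = (val, seq)
        return best[1]

    remaining = sorted(range(len(blocks)), key=lambda i: (-len(blocks[i]),
                                                          blocks[i][0]))
    seq = list(blocks[remaining.pop(0)])
    while remaining:
        best = None
        for ri, bi in enumerate(remaining):
            for variant in orientations(blocks[bi]):
                for cand in (variant + seq, seq + variant):
                    val = obj(cand)
                    if best is None or val > best[0] + SUPPORT_TOL:
                        best = (val, cand, ri)
        seq = best[1]
        remaining.pop(best[2])
    return seq


def refine_order(ordered_ids: list[str], fs: FamilySet,
                 window: int = 5, max_rounds: int = 4) -> list[str]:
    """Full order refinement: windowed permutations (flips), single-marker
    relocation and 2-opt segment reversals, iterated to a joint fixed point.
    Groups of up to 7 markers are ordered exhaustively instead.  The output
    objective is never below the input objective."""
    ordered = list(ordered_ids)
    if 3 <= len(ordered) <= 7:
        chains = group_chains(fs, ordered)
        gi = {m: k for k, m in enumerate(ordered)}
        best = None
        for perm in permutations(ordered):
            if perm > perm[::-1]:
                continue  # the objective is invariant under reversal
            val = order_objective(chains, np.array([gi[m] for m in perm]))
            if best is None or val > best[0] + SUPPORT_TOL:
                best = (val, list(perm))
        start = order_objective(chains,
                                np.array([gi[m] for m in ordered]))
        return best[1] if best[0] > start + SUPPORT_TOL else ordered
    for _ in range(max_rounds):
        before = list(ordered)
        ordered = flips_refine(ordered, fs, window)
        ordered = _relocate_refine(ordered, fs)
        ordered = _reversal_refine(ordered, fs)
        if ordered == before:
            break
    return ordered


def map_stats(groups: list[LinkageGroup], d_av_definition: str = "positions") -> MapStats:
    """Summary statistics: total length, average inter-marker distance and
    largest adjacent gap.  D_av divides total length by (loci - groups) where
    loci counts distinct map positions (``"positions"``, default) or raw
    mapped markers (``"markers"``)."""
    total = sum(g.length_cm for g in groups)
    n_groups = len(groups)
    n_mapped = sum(g.n_markers for g in groups)
    if d_av_definition == "positions":
        n_loci = sum(len(np.unique(np.round(g.positions, 6))) for g in groups)
    elif d_av_definition == "markers":
        n_loci = n_mapped
    else:
        raise ValueError(f"unknown d_av definition {d_av_definition!r}")
    denom = n_loci - n_groups
    d_av = total / denom if denom > 0 else 0.0
    max_gap = 0.0
    for g in groups:
        if g.n_markers >= 2:
            max_gap = max(max_gap, float(np.max(np.diff(g.positions))))
    return MapStats(total, d_av, max_gap, n_mapped, n_groups)


def _positions(ordered_ids: list[str], tp: TwoPointTable) -> np.ndarray:
    pos = [0.0]
    for a, b in zip(ordered_ids, ordered_ids[1:]):
        r = min(tp.r[tp.index[a], tp.index[b]], R_CAP)
        pos.append(pos[-1] + kosambi_cm(r))
    return np.asarray(pos)


def build_map(
    markers: list[Marker],
    families: list[Family],
    lod_group: float = 8.0,
    lod_pool: float = 4.0,
    lod_weak: float = 0.5,
    majority: float = 0.5,
    flips_window: int = 5,
    thresholds: tuple[float, ...] = BUILD_THRESHOLDS,
    d_av_definition: str = "positions",
    tp: TwoPointTable | None = None,
) -> GeneticMap:
    """Full map construction: two-point table, grouping, pooling, build +
    flips ordering, Kosambi positions and summary statistics.

    Groups are numbered LG1, LG2, ... by decreasing map length (ties: marker
    count, then smallest marker id).  Singleton components and markers without
    positive placement support are reported as unmapped.
    """
    fs = FamilySet(markers, families)
    if tp is None:
        tp = twopoint_table(markers, families, fs=fs)
    groups = pool_groups(group_markers(tp, lod_group), tp,
                         lod_pool, lod_weak, majority)
    built: list[LinkageGroup] = []
    unmapped: list[str] = []
    for comp in groups:
        if len(comp) < 2:
            unmapped.extend(comp)
            continue
        # order each strongly-linked (lod >= lod_group) block separately,
        # then arrange the blocks end to end: markers joined only by the
        # weaker pooling evidence must not interleave, or the junctions
        # between them become undetectable
        sub = nx.Graph()
        sub.add_nodes_from(comp)
        for a, b in combinations(comp, 2):
            if tp.lod[tp.index[a], tp.index[b]] >= lod_group:
                sub.add_edge(a, b)
        blocks: list[list[str]] = []
        for part in sorted(nx.connected_components(sub),
                           key=lambda c: (-len(c), min(c))):
            part = sorted(part)
            if len(part) < 2:
                blocks.append(part)
                continue
            ordered, left = order_build(part, tp, fs, thresholds)
            unmapped.extend(left)
            if len(ordered) < 2:
                blocks.append(ordered)
                continue
            blocks.append(refine_order(ordered, fs, flips_window))
        blocks = [b for b in blocks if b]
        if not blocks:
            continue
        # concatenate blocks only along seams with genuine two-point
        # evidence (a cross pair at the strong pooling LOD); seams carried
        # by weak-majority pooling alone are as likely chance as real
        bg = nx.Graph()
        bg.add_nodes_from(range(len(blocks)))
        for i, j in combinations(range(len(blocks)), 2):
            ia = [tp.index[m] for m in blocks[i]]
            ib = [tp.index[m] for m in blocks[j]]
            if tp.lod[np.ix_(ia, ib)].max() >= lod_pool:
                bg.add_edge(i, j)
        for bc in sorted(nx.connected_components(bg),
                         key=lambda c: (-sum(len(blocks[i]) for i in c),
                                        min(c))):
            sub_blocks = [blocks[i] for i in sorted(bc)]
            if len(sub_blocks) > 1:
                ordered = _arrange_blocks(sub_blocks, fs)
            else:
                ordered = sub_blocks[0]
            if len(ordered) < 2:
                unmapped.extend(ordered)
                continue
            chains_f = group_chains(fs, ordered)
            r_vec = interval_rates(chains_f, np.arange(len(ordered)),
                                   refine=True)
            supported = interval_support(chains_f, np.arange(len(ordered)))
            # cut at effectively-unlinked junctions: chance linkage can pool
            # markers that ordering cannot bridge with a credible interval,
            # and an interval no meiosis spans carries no evidence at all
            segments: list[list[str]] = [[ordered[0]]]
            seg_pos: list[list[float]] = [[0.0]]
            for i, b in enumerate(ordered[1:]):
                if r_vec[i] >= R_SPLIT or not supported[i]:
                    segments.append([b])
                    seg_pos.append([0.0])
                else:
                    segments[-1].append(b)
                    seg_pos[-1].append(seg_pos[-1][-1]
                                       + kosambi_cm(float(r_vec[i])))
            for seg, spos in zip(segments, seg_pos):
                if len(seg) < 2:
                    unmapped.extend(seg)
                else:
                    built.append(LinkageGroup("", seg, np.asarray(spos)))
    built.sort(key=lambda g: (-g.length_cm, -g.n_markers, min(g.marker_ids)))
    for k, g in enumerate(built, start=1):
        g.group_id = f"LG{k}"
    contig_of = {m.id: m.contig_id for m in markers}
    return GeneticMap(built, sorted(unmapped), map_stats(built, d_av_definition),
                      contig_of)
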