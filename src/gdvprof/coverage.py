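"""Local sequencing depth and genome-dataset validity (GDV) estimation.

The central quantity is the GDV of a reference genome: the fraction of the
reference for which the sequencing dataset provides evidence. A reference
identical to a sampled organism has GDV near 1; a reference sharing only a
few genes with anything in the sample has GDV near 0.

For references with sequencing depth >= 1x, the per-position coverage-depth
histogram is modelled as a three-component mixture

    f(x | a, lam) = a1 * z(x) + a2 * Pois(x | lam) + a3 * T_lam(x)

where ``z`` is a point mass at zero (genome regions with no counterpart in
the sample), ``Pois`` is the Poisson coverage law in shared regions, and
``T_lam`` is a heavy right tail absorbing repeat pile-ups and other skews.
The tail is the normalized Poisson survival mass, T_lam(x) = Pr(Pois(lam) >=
x) / lam for x >= 1 (its normalizer is exactly lam). The mixture is fitted by
EM; GDV = 1 - a1 and lam is the local sequencing depth.

Below 1x the depth histogram is nearly all zeros and ones and carries no
signal; the model switches to the histogram of distances between consecutive
read start positions, fitted with a three-component geometric mixture. Read
starts inside reference regions shared with a sampled organism form a
(discretized) Poisson process, so their spacings are geometric with success
probability p = 1 - exp(-rho), rho the per-base start rate; spacings that
cross unshared regions are far longer and land in the slower components.
This recovers depth and GDV down to ~0.05x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .alignment_io import AlignmentTable, mapping_error_rate

__all__ = [
    "CoverageHistogram",
    "StartDistanceHistogram",
    "MixtureFit",
    "ReferenceProfile",
    "NoCoverageError",
    "InsufficientReadsError",
    "NonConvergenceError",
    "coverage_histogram",
    "start_distance_histogram",
    "truncate_histogram",
    "fit_poisson_tail_mixture",
    "fit_geometric_mixture",
    "estimate_gdv",
    "ks_homogeneity",
    "estimate_profile",
]

# GDV interpretation bands: > 0.8 almost always marks a highly relevant
# reference; < 0.2 may be a distant relation or spurious mappings.
GDV_HIGH = 0.8
GDV_CAUTION = 0.2

EM_TOL = 1e-8
EM_MAX_ITER = 2000
MIN_DISTANCES = 10
GEOM_MERGE_FACTOR = 5.0


class NoCoverageError(ValueError):
    """The coverage histogram contains no covered positions."""


class InsufficientReadsError(ValueError):
    """Too few read-start distances for the low-coverage model."""


class NonConvergenceError(RuntimeError):
    def __init__(self, n_iter: int):
        super().__init__(f"EM did not converge within {n_iter} iterations")
        self.n_iter = n_iter


@dataclass
class CoverageHistogram:
    """Per-position depth histogram of one organism-grouped reference."""

    counts: dict[int, int]
    genome_length: int

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.array(sorted(self.counts), dtype=np.int64)
        ns = np.array([self.counts[int(x)] for x in xs], dtype=np.float64)
        return xs, ns

    @property
    def mean_depth(self) -> float:
        xs, ns = self.arrays()
        return float((xs * ns).sum() / ns.sum())


@dataclass
class StartDistanceHistogram:
    """Distances between consecutive read starts (pooled over sequences)."""

    counts: dict[int, int]
    n_reads: int
    genome_length: int

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ds = np.array(sorted(self.counts), dtype=np.int64)
        ns = np.array([self.counts[int(d)] for d in ds], dtype=np.float64)
        return ds, ns

    @property
    def n_distances(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class MixtureFit:
    """Fitted mixture parameters.

    For the ``poisson_tail`` variant, ``lam`` is the local sequencing depth
    (x-coverage). For the ``geometric`` variant, ``lam`` is the per-base
    read-start rate inside shared regions; multiply by read length to get
    depth. ``components`` (geometric only) holds (weight, p) pairs sorted by
    decreasing success probability p, i.e. tightest spacing first.
    """

    alpha: tuple[float, float, float]
    lam: float
    variant: str
    loglik: float
    n_iter: int
    converged: bool
    components: tuple[tuple[float, float], ...] = ()
    n_obs: int = 0
    genome_length: int = 0
    loglik_path: tuple[float, ...] = field(default=(), repr=False)


@dataclass
class ReferenceProfile:
    """Per-reference summary feeding core-read extraction and reporting."""

    organism_id: str
    depth: float
    gdv: float
    n_reads: int
    n_unique_reads: int
    error_rate: float
    ks_p: float | None
    quality_band: str
    variant: str = ""
    fit_failed: bool = False


def quality_band(gdv: float) -> str:
    if gdv > GDV_HIGH:
        return "high"
    if gdv >= GDV_CAUTION:
        return "informative"
    return "caution"


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def coverage_histogram(table: AlignmentTable, organism: str) -> CoverageHistogram:
    """Exact per-position depth histogram over all member sequences."""
    recs = table.records_of(organism)
    counts: dict[int, int] = {}
    total_len = 0
    for seq in table.member_sequences(organism):
        length = table.ref_lengths[seq]
        total_len += length
        delta = np.zeros(length + 1, dtype=np.int64)
        for rec in recs:
            if rec.ref_id != seq:
                continue
            start = min(rec.pos, length)
            end = min(rec.pos + rec.aln_len, length)
            delta[start] += 1
            delta[end] -= 1
        depth = np.cumsum(delta[:-1])
        binc = np.bincount(depth)
        for x in np.nonzero(binc)[0]:
            counts[int(x)] = counts.get(int(x), 0) + int(binc[x])
    return CoverageHistogram(counts=counts, genome_length=total_len)


def start_distance_histogram(table: AlignmentTable, organism: str) -> StartDistanceHistogram:
    """Consecutive read-start spacings, computed per member sequence and pooled.

    Duplicate starts (distance 0) are clamped to 1 so every spacing lies in
    the geometric support {1, 2, ...}.
    """
    recs = table.records_of(organism)
    counts: dict[int, int] = {}
    n_reads = 0
    total_len = 0
    for seq in table.member_sequences(organism):
        total_len += table.ref_lengths[seq]
        starts = np.sort(np.array([r.pos for r in recs if r.ref_id == seq]))
        n_reads += starts.size
        if starts.size < 2:
            continue
        dists = np.maximum(np.diff(starts), 1)
        binc = np.bincount(dists)
        for d in np.nonzero(binc)[0]:
            counts[int(d)] = counts.get(int(d), 0) + int(binc[d])
    return StartDistanceHistogram(counts=counts, n_reads=n_reads, genome_length=total_len)


def truncate_histogram(hist: CoverageHistogram, q: float = 0.999) -> CoverageHistogram:
    """Pool depths above the ``q`` quantile into the quantile bin.

    Extreme repeat pile-ups otherwise dominate the tail component and can
    destabilize the fit.
    """
    xs, ns = hist.arrays()
    cum = np.cumsum(ns)
    cut_idx = int(np.searchsorted(cum, q * cum[-1]))
    cut_idx = min(cut_idx, len(xs) - 1)
    cap = int(xs[cut_idx])
    counts: dict[int, int] = {}
    for x, n in zip(xs, ns):
        key = int(min(x, cap))
        counts[key] = counts.get(key, 0) + int(n)
    return CoverageHistogram(counts=counts, genome_length=hist.genome_length)


# ---------------------------------------------------------------------------
# zero-inflated Poisson with tail (depth >= 1x)
# ---------------------------------------------------------------------------

def _log_components_poisson_tail(xs: np.ndarray, lam: float) -> np.ndarray:
    """Log densities of (z, Poisson, tail) at the depth values ``xs``.

    Shape (3, len(xs)); impossible values get -inf. Computed directly from
    gammaln (the EM inner loop evaluates this thousands of times; the
    scipy.stats frozen-distribution machinery is far too slow for that).
    """
    xmax = int(xs.max())
    k = np.arange(xmax + 1, dtype=np.float64)
    logpmf_all = k * math.log(lam) - lam - gammaln(k + 1.0)
    pmf_all = np.exp(logpmf_all)
    cdf_all = np.cumsum(pmf_all)
    logs = np.full((3, xs.size), -np.inf)
    logs[0, xs == 0] = 0.0
    logs[1] = logpmf_all[xs]
    pos = xs >= 1
    # T_lam(x) = Pr(Pois(lam) >= x) / lam; normalizer sum_{x>=1} sf(x-1) = lam
    sf = np.maximum(1.0 - cdf_all[xs[pos] - 1], 1e-300)
    logs[2, pos] = np.log(sf) - math.log(lam)
    return logs


def mixture_loglik(xs: np.ndarray, ns: np.ndarray, alpha: np.ndarray, lam: float) -> float:
    """Total log-likelihood of a depth histogram under the ZIP-with-tail mixture."""
    logcomp = _log_components_poisson_tail(xs, lam)
    with np.errstate(divide="ignore"):
        logw = np.where(alpha > 0, np.log(np.maximum(alpha, 1e-300)), -np.inf)
    ll = logsumexp(logcomp + logw[:, None], axis=0)
    return float((ns * ll).sum())


def fit_poisson_tail_mixture(
    hist: CoverageHistogram,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    truncate: float = 0.999,
) -> MixtureFit:
    """Fit the zero/Poisson/tail mixture to a coverage-depth histogram by EM.

    The M-step for the mixing weights is closed-form; the shared rate ``lam``
    is updated by exact 1-D maximization of the expected complete-data
    log-likelihood over the Poisson and tail components (a generalized EM
    step), so the observed log-likelihood is non-decreasing.
    """
    if truncate is not None:
        hist = truncate_histogram(hist, truncate)
    xs, ns = hist.arrays()
    nonzero = xs > 0
    if not nonzero.any():
        raise NoCoverageError("no coverage evidence: histogram is all zeros")

    n_total = ns.sum()
    zero_frac = float(ns[xs == 0].sum() / n_total)
    alpha = np.array(
        [zero_frac, 0.5 * (1 - zero_frac), 0.5 * (1 - zero_frac)], dtype=float
    )
    alpha = np.maximum(alpha, 1e-6)
    alpha /= alpha.sum()
    lam = float((xs[nonzero] * ns[nonzero]).sum() / ns[nonzero].sum())
    lam_hi = float(xs.max()) * 2.0 + 10.0

    ll = mixture_loglik(xs, ns, alpha, lam)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logcomp = _log_components_poisson_tail(xs, lam)
        with np.errstate(divide="ignore"):
            logw = np.where(alpha > 0, np.log(np.maximum(alpha, 1e-300)), -np.inf)
        logpost = logcomp + logw[:, None]
        logpost -= logsumexp(logpost, axis=0, keepdims=True)
        resp = np.exp(logpost)  # (3, nbins)

        # M-step: weights
        alpha = (resp * ns).sum(axis=1) / n_total
        alpha = np.clip(alpha, 0.0, 1.0)
        alpha /= alpha.sum()

        # M-step: lam by bounded 1-D maximization over Poisson + tail terms
        w2, w3 = resp[1] * ns, resp[2] * ns

        def neg_q(l: float) -> float:
            logc = _log_components_poisson_tail(xs, l)
            t2 = np.where(w2 > 0, w2 * logc[1], 0.0).sum()
            lc2 = np.where(np.isfinite(logc[2]), logc[2], 0.0)
            t3 = np.where(w3 > 0, w3 * lc2, 0.0).sum()
            return -(t2 + t3)

        res = optimize.minimize_scalar(
            neg_q, bounds=(1e-6, lam_hi), method="bounded",
            options={"xatol": 1e-9},
        )
        if res.success and -res.fun >= -neg_q(lam):
            lam = float(res.x)

        new_ll = mixture_loglik(xs, ns, alpha, lam)
        if new_ll < ll - 1e-6 * (abs(ll) + 1):  # pragma: no cover - EM guarantee
            raise RuntimeError("EM log-likelihood decreased")
        path.append(new_ll)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # EM creeps along the ridge between structural and Poisson zeros; a
    # direct simplex polish from the EM point closes the remaining gap to
    # the maximum (accepted only if the likelihood improves).
    alpha, lam, polished_ll = _polish_poisson_tail(xs, ns, alpha, lam, ll)
    if polished_ll > ll:
        ll = polished_ll
        path.append(ll)
        converged = True

    return MixtureFit(
        alpha=tuple(float(a) for a in alpha),
        lam=float(lam),
        variant="poisson_tail",
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        n_obs=int(n_total),
        genome_length=hist.genome_length,
        loglik_path=tuple(path),
    )


def _polish_poisson_tail(
    xs: np.ndarray,
    ns: np.ndarray,
    alpha: np.ndarray,
    lam: float,
    ll: float,
) -> tuple[np.ndarray, float, float]:
    """Nelder-Mead refinement of (a1, Poisson/tail split, lam) on the logit/log scale."""
    eps = 1e-9

    def clip01(v: float) -> float:
        return min(max(v, eps), 1 - eps)

    a1 = clip01(alpha[0])
    rest = max(alpha[1] + alpha[2], eps)
    b = clip01(alpha[1] / rest)
    x0 = np.array(
        [math.log(a1 / (1 - a1)), math.log(b / (1 - b)), math.log(lam)]
    )

    def neg_ll(theta: np.ndarray) -> float:
        t0 = 1.0 / (1.0 + math.exp(-theta[0]))
        t1 = 1.0 / (1.0 + math.exp(-theta[1]))
        l = math.exp(theta[2])
        a = np.array([t0, (1 - t0) * t1, (1 - t0) * (1 - t1)])
        return -mixture_loglik(xs, ns, a, l)

    res = optimize.minimize(
        neg_ll, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-10},
    )
    if -res.fun <= ll:
        return alpha, lam, ll
    t0 = 1.0 / (1.0 + math.exp(-res.x[0]))
    t1 = 1.0 / (1.0 + math.exp(-res.x[1]))
    new_alpha = np.array([t0, (1 - t0) * t1, (1 - t0) * (1 - t1)])
    return new_alpha, float(math.exp(res.x[2])), float(-res.fun)


# ---------------------------------------------------------------------------
# geometric mixture on read-start spacings (depth < 1x)
# ---------------------------------------------------------------------------

def _geom_logpmf(ds: np.ndarray, p: float) -> np.ndarray:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p) + (ds - 1) * math.log1p(-p)


def geometric_mixture_loglik(
    ds: np.ndarray, ns: np.ndarray, weights: np.ndarray, ps: np.ndarray
) -> float:
    logcomp = np.stack([_geom_logpmf(ds, p) for p in ps])
    with np.errstate(divide="ignore"):
        logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
    return float((ns * logsumexp(logcomp + logw[:, None], axis=0)).sum())


def _merged_shared_components(
    components: tuple[tuple[float, float], ...],
    merge_factor: float = GEOM_MERGE_FACTOR,
) -> tuple[float, float]:
    """Pool components describing the within-shared-region spacing regime.

    A single spacing regime often splits its weight across near-identical
    geometric components, and a near-zero-weight component can latch onto a
    handful of coincidentally tight spacings. The pool is therefore anchored
    on the *dominant* (largest-weight) component and takes every component
    whose mean spacing is within ``merge_factor`` of the anchor's, leaving
    out only the far-slower components that describe jumps across unshared
    regions. Returns (total weight, mean spacing) of the pool.
    """
    means = [(w, 1.0 / p) for w, p in components if w > 1e-12]
    base = max(means, key=lambda wm: wm[0])[1]
    pooled = [(w, m) for w, m in means if m <= merge_factor * base]
    w_tot = sum(w for w, _ in pooled)
    mean = sum(w * m for w, m in pooled) / w_tot
    return w_tot, mean


def fit_geometric_mixture(
    hist: StartDistanceHistogram,
    n_components: int = 3,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> MixtureFit:
    """Fit a geometric mixture to read-start spacings by EM.

    Components are reported sorted by decreasing success probability, so
    component 1 is the tight within-shared-region spacing regime. ``lam`` is
    the per-base read-start rate rho = -ln(1 - 1/m) of the pooled shared
    regime with mean spacing m.
    """
    ds, ns = hist.arrays()
    n_total = ns.sum()
    if n_total < MIN_DISTANCES:
        raise InsufficientReadsError(
            f"insufficient reads for low-coverage model "
            f"({int(n_total)} spacings < {MIN_DISTANCES})"
        )

    # spread initial means over the empirical spacing quantiles
    cum = np.cumsum(ns) / n_total
    qs = np.linspace(0.25, 0.95, n_components)
    init_means = [float(ds[np.searchsorted(cum, q)]) for q in qs]
    ps = np.array([1.0 / max(m, 1.0 + 1e-9) for m in init_means])
    ps = np.clip(ps, 1e-9, 1 - 1e-9)
    # nudge apart identical initial components
    for k in range(1, n_components):
        if abs(ps[k] - ps[k - 1]) < 1e-12:
            ps[k] = ps[k - 1] * 0.5
    weights = np.full(n_components, 1.0 / n_components)

    ll = geometric_mixture_loglik(ds, ns, weights, ps)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logcomp = np.stack([_geom_logpmf(ds, p) for p in ps])
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
        logpost = logcomp + logw[:, None]
        logpost -= logsumexp(logpost, axis=0, keepdims=True)
        resp = np.exp(logpost)

        wn = resp * ns
        weights = wn.sum(axis=1) / n_total
        # geometric MLE: p = (sum of weights) / (weighted sum of distances)
        denom = (wn * ds).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ps = np.where(denom > 0, wn.sum(axis=1) / denom, 1 - 1e-9)
        ps = np.clip(ps, 1e-12, 1 - 1e-12)

        new_ll = geometric_mixture_loglik(ds, ns, weights, ps)
        if new_ll < ll - 1e-6 * (abs(ll) + 1):  # pragma: no cover - EM guarantee
            raise RuntimeError("EM log-likelihood decreased")
        path.append(new_ll)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    order = np.argsort(-ps)
    components = tuple((float(weights[k]), float(ps[k])) for k in order)
    _, shared_mean = _merged_shared_components(components)
    p_eff = min(1.0 / shared_mean, 1 - 1e-12)
    rate = float(-math.log1p(-p_eff))

    a = [components[k][0] if k < len(components) else 0.0 for k in range(3)]
    return MixtureFit(
        alpha=(a[0], a[1], a[2]),
        lam=rate,
        variant="geometric",
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        components=components,
        n_obs=int(n_total),
        genome_length=hist.genome_length,
        loglik_path=tuple(path),
    )


# ---------------------------------------------------------------------------
# GDV
# ---------------------------------------------------------------------------

def estimate_gdv(fit: MixtureFit) -> float:
    """Genome-dataset validity from a converged mixture fit.

    poisson_tail: GDV = 1 - a1 (one minus the zero-component weight).
    geometric: expected total span of the within-shared spacing regime over
    the genome length — n_spacings * pooled weight * pooled mean / L.
    """
    if not fit.converged:
        raise NonConvergenceError(fit.n_iter)
    if fit.variant == "poisson_tail":
        return float(min(max(1.0 - fit.alpha[0], 0.0), 1.0))
    if fit.variant == "geometric":
        w, mean = _merged_shared_components(fit.components)
        span = fit.n_obs * w * mean
        return float(min(max(span / fit.genome_length, 0.0), 1.0))
    raise ValueError(f"unknown mixture variant {fit.variant!r}")


# ---------------------------------------------------------------------------
# read-distribution homogeneity
# ---------------------------------------------------------------------------

def ks_homogeneity(table: AlignmentTable, organism: str) -> float | None:
    """One-sample KS test of read-start uniformity over the covered regions.

    Restricting to covered regions makes the test a check of *within-shared*
    homogeneity: a reference whose shared regions are evenly sampled passes
    even when large parts of it have no counterpart in the sample. Returns
    None (not testable) with fewer than 2 reads; p >= 0.05 is read as
    "homogeneously distributed".
    """
    recs = table.records_of(organism)
    if len(recs) < 2:
        return None
    # concatenate member sequences on one axis
    offsets: dict[str, int] = {}
    off = 0
    for seq in table.member_sequences(organism):
        offsets[seq] = off
        off += table.ref_lengths[seq]
    starts = np.array([offsets[r.ref_id] + r.pos for r in recs], dtype=np.int64)
    ends = np.array(
        [offsets[r.ref_id] + r.pos + r.aln_len for r in recs], dtype=np.int64
    )
    order = np.argsort(starts)
    s_sorted, e_sorted = starts[order], ends[order]
    # merge covered intervals
    merged_start, merged_end = [], []
    cur_s, cur_e = int(s_sorted[0]), int(e_sorted[0])
    for s, e in zip(s_sorted[1:], e_sorted[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            merged_start.append(cur_s)
            merged_end.append(cur_e)
            cur_s, cur_e = int(s), int(e)
    merged_start.append(cur_s)
    merged_end.append(cur_e)
    ms = np.array(merged_start)
    me = np.array(merged_end)
    covered_before = np.concatenate([[0], np.cumsum(me - ms)[:-1]])
    total = float((me - ms).sum())
    idx = np.searchsorted(ms, starts, side="right") - 1
    transformed = covered_before[idx] + (starts - ms[idx])
    u = transformed / total
    return float(stats.kstest(u, "uniform").pvalue)


# ---------------------------------------------------------------------------
# per-reference profile
# ---------------------------------------------------------------------------

def estimate_profile(table: AlignmentTable, organism: str) -> ReferenceProfile:
    """Depth, GDV, homogeneity and error statistics for one reference.

    Dispatches on the naive covered-genome depth (total aligned bases over
    genome length): the coverage-histogram model at >= 1x, the start-spacing
    model below. Fit failures (no coverage, too few reads, non-convergence)
    are reported as GDV 0 with ``fit_failed`` set rather than raised.
    """
    recs = table.records_of(organism)
    glen = table.grouping.organism_length[organism]
    naive_depth = sum(r.aln_len for r in recs) / glen
    n_reads = len(table.reads_of(organism))
    n_unique = len(table.unique_reads_of(organism))
    err = mapping_error_rate(table, organism)
    ks_p = ks_homogeneity(table, organism)

    depth = naive_depth
    gdv = 0.0
    failed = False
    variant = ""
    try:
        if naive_depth >= 1.0:
            fit = fit_poisson_tail_mixture(coverage_histogram(table, organism))
            depth = fit.lam
        else:
            fit = fit_geometric_mixture(start_distance_histogram(table, organism))
            mean_read_len = sum(r.aln_len for r in recs) / len(recs)
            depth = fit.lam * mean_read_len
        variant = fit.variant
        gdv = estimate_gdv(fit)
    except (NoCoverageError, InsufficientReadsError, NonConvergenceError):
        failed = True

    return ReferenceProfile(
        organism_id=organism,
        depth=float(depth),
        gdv=float(gdv),
        n_reads=n_reads,
        n_unique_reads=n_unique,
        error_rate=err,
        ks_p=ks_p,
        quality_band="caution" if failed else quality_band(gdv),
        variant=variant,
        fit_failed=failed,
    )
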