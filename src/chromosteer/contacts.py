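"""Significant cis-contact calling: ICE correction, ZiNB fitting, BH selection.

The statistical model: at fixed genomic distance ``delta = |i - j|`` (in
bins), bias-corrected contact counts x are treated as draws from a
zero-inflated negative binomial

    P(0)     = pi + (1 - pi) * NB(0; theta, mu)
    P(k > 0) = (1 - pi) * NB(k; theta, mu)

with NB(k; theta, mu) = Gamma(k + theta) / (Gamma(theta) k!) *
(theta / (theta + mu))**theta * (mu / (theta + mu))**k. Here ``pi`` is the
probability of extra (structural) zeros on top of the NB's own zero mass,
``theta`` the over-dispersion relative to Poisson, and
``p = theta / (theta + mu)`` the probability of not having a 3D contact in
the NB parametrization. Parameters are fitted per distance by maximum
likelihood; each entry's p-value is the upper tail P(X >= x); multiple
testing is corrected per distance with Benjamini-Hochberg at a 1% FDR.
Distances with too few observations are pooled with neighbours into
geometrically growing bins before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConvergenceWarning, DegenerateDataError, FormatError
from .hic import ContactMatrix


# ---------------------------------------------------------------------------
# ICE matrix balancing
# ---------------------------------------------------------------------------

def ice_normalize(matrix: ContactMatrix, max_iter: int = 200,
                  tol: float = 1e-8):
    """Iterative correction: factor out multiplicative per-bin biases.

    Returns ``(corrected, biases, mask)``: a new :class:`ContactMatrix`
    whose unmasked marginals are equal, the per-bin bias vector (NaN on
    masked bins) such that ``raw_ij ~= b_i * b_j * corrected_ij``, and the
    boolean mask of balanced (nonzero-marginal) bins. The corrected matrix
    is rescaled so its total equals the raw total over unmasked bins.
    """
    w = matrix.to_dense()
    if w.sum() == 0:
        raise DegenerateDataError("all-zero matrix cannot be balanced")
    mask = w.sum(axis=1) > 0
    b = np.ones(matrix.n_bins)
    wm = w[np.ix_(mask, mask)].astype(float)
    raw_total = wm.sum()
    bm = np.ones(wm.shape[0])
    converged = False
    for _ in range(max_iter):
        s = wm.sum(axis=1)
        db = s / s.mean()
        wm /= np.outer(db, db)
        bm *= db
        if np.abs(db - 1).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("ICE did not reach tolerance; returning partial result",
                      ConvergenceWarning)
    # equalize scale: keep the total number of (corrected) reads
    scale = raw_total / wm.sum()
    wm *= scale
    bm /= np.sqrt(scale)
    full = np.zeros_like(w)
    full[np.ix_(mask, mask)] = wm
    b[:] = np.nan
    b[mask] = bm
    corrected = ContactMatrix.from_dense(matrix.chrom, matrix.resolution, full)
    corrected.n_bins = matrix.n_bins
    return corrected, b, mask


# ---------------------------------------------------------------------------
# per-distance observation collection
# ---------------------------------------------------------------------------

def collect_by_distance(matrix: ContactMatrix, mask: np.ndarray | None = None,
                        min_delta: int = 1) -> dict[int, np.ndarray]:
    """For each delta >= min_delta, the vector of all entries at that
    separation between unmasked bins -- including structural zeros, which
    are data, not missing values."""
    dense = matrix.to_dense()
    if mask is None:
        mask = np.ones(matrix.n_bins, dtype=bool)
    out: dict[int, np.ndarray] = {}
    n = matrix.n_bins
    for d in range(max(1, min_delta), n):
        i = np.arange(n - d)
        keep = mask[i] & mask[i + d]
        if keep.any():
            out[d] = dense[i[keep], i[keep] + d]
    return out


# ---------------------------------------------------------------------------
# ZiNB fitting
# ---------------------------------------------------------------------------

@dataclass
class ZiNBParams:
    """Fitted ZiNB for one (possibly pooled) distance group."""

    delta_min: int
    delta_max: int
    pi: float
    theta: float
    mu: float
    n_obs: int
    n_nonzero: int
    loglik: float
    status: str  # ok | pooled | degenerate

    @property
    def p(self) -> float:
        """NB probability of not having a 3D contact, theta/(theta + mu)."""
        return self.theta / (self.theta + self.mu)


@dataclass
class ZiNBParamTable:
    rows: list[ZiNBParams] = field(default_factory=list)

    def lookup(self, delta: int) -> ZiNBParams | None:
        for r in self.rows:
            if r.delta_min <= delta <= r.delta_max:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "delta_min": r.delta_min, "delta_max": r.delta_max, "pi": r.pi,
            "theta": r.theta, "mu": r.mu, "p": r.p if r.status != "degenerate" else np.nan,
            "n_obs": r.n_obs, "n_nonzero": r.n_nonzero,
            "loglik": r.loglik, "status": r.status} for r in self.rows])


def _zinb_nll(params, counts, weights, n_censored=0, censor_at=0):
    """Negative log-likelihood on (logit pi, log theta, log mu).

    ``n_censored`` observations optionally enter only through their
    exceedance P(X >= censor_at) (right-censoring).
    """
    a, lt, lm = params
    pi = special.expit(a)
    theta, mu = np.exp(lt), np.exp(lm)
    p = theta / (theta + mu)
    lognb = stats.nbinom.logpmf(counts, theta, p)
    ll = np.where(
        counts == 0,
        np.logaddexp(np.log(pi + 1e-300), np.log1p(-pi) + lognb),
        np.log1p(-pi) + lognb,
    )
    nll = -np.sum(weights * ll)
    if n_censored > 0:
        tail = stats.nbinom.sf(censor_at - 1, theta, p)
        nll -= n_censored * (np.log1p(-pi) + np.log(tail + 1e-300))
    return nll


def zinb_loglik(counts, pi, theta, mu) -> float:
    """Log-likelihood of a ZiNB at the given parameters."""
    counts = np.asarray(counts)
    vals, cnts = np.unique(counts, return_counts=True)
    return -_zinb_nll(
        (special.logit(np.clip(pi, 1e-12, 1 - 1e-12)), np.log(theta), np.log(mu)),
        vals, cnts)


def fit_zinb(observations, min_nonzero: int = 3, n_censored: int = 0,
             censor_at: int = 0) -> ZiNBParams:
    """Maximum-likelihood ZiNB fit of one observation vector.

    Moment-based initialization (excess-zero fraction for pi; mean/variance
    of the nonzero part for theta, mu), then L-BFGS-B on the transformed
    parameters, with a small multi-start fallback. Degenerate data (all
    zeros, or fewer than ``min_nonzero`` positive counts) gets a boundary
    guard fit and no p-values downstream.
    """
    x = np.asarray(observations, dtype=float)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise FormatError("observations must be non-negative integers")
    x = x.astype(np.int64)
    n = len(x)
    nz = x[x > 0]
    if len(nz) < min_nonzero:
        return ZiNBParams(0, 0, 0.999, 1.0, max(x.mean(), 1e-6), n, len(nz),
                          -np.inf, "degenerate")

    f0 = float(np.mean(x == 0))
    m_nz, v_nz = float(nz.mean()), float(nz.var())
    mu0 = max(m_nz, 0.1)
    theta0 = float(np.clip(mu0 ** 2 / max(v_nz - mu0, 1e-3), 0.05, 100.0))
    nb0 = (theta0 / (theta0 + mu0)) ** theta0
    pi0 = float(np.clip((f0 - nb0) / max(1 - nb0, 1e-6), 1e-4, 0.98))

    vals, cnts = np.unique(x, return_counts=True)
    starts = [
        (special.logit(pi0), np.log(theta0), np.log(mu0)),
        (special.logit(max(f0 * 0.5, 1e-3)), np.log(1.0), np.log(max(x.mean(), 0.1))),
        (special.logit(1e-3), np.log(theta0), np.log(mu0)),
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _zinb_nll, s0, args=(vals, cnts, n_censored, censor_at),
            method="L-BFGS-B",
            bounds=[(-12, 12), (np.log(1e-3), np.log(1e4)),
                    (np.log(1e-6), np.log(1e7))],
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    a, lt, lm = best.x
    return ZiNBParams(0, 0, float(special.expit(a)), float(np.exp(lt)),
                      float(np.exp(lm)), n, len(nz), -float(best.fun), "ok")


def fit_zinb_robust(observations, min_nonzero: int = 3,
                    censor_frac: float = 0.15) -> ZiNBParams:
    """Tail-censored ZiNB background fit.

    The background must be estimated in the presence of the very enriched
    pairs the test is meant to find, whose huge counts would otherwise
    drag the dispersion estimate down and fatten the fitted tail. Here the
    top ``censor_frac`` of the nonzero observations are right-censored:
    they enter the likelihood only through their exceedance probability
    P(X >= c) at the censoring point c (the smallest of the censored
    values). This caps the leverage any single large count can exert while
    remaining a consistent estimator on enrichment-free data, where
    censored MLE and plain MLE agree.
    """
    x = np.asarray(observations, dtype=float)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise FormatError("observations must be non-negative integers")
    x = x.astype(np.int64)
    n = len(x)
    nz = x[x > 0]
    n_nz = len(nz)
    k = int(np.ceil(censor_frac * n_nz)) if n_nz > min_nonzero + 1 else 0
    if k == 0:
        return fit_zinb(x, min_nonzero=min_nonzero)
    order = np.argsort(x)
    retained = x[order[:n - k]]
    # censor at just above the top retained value: the censored points
    # enter only as "at least as large as the background maximum", which
    # is true of them regardless of how enriched they are
    censor_at = int(retained.max()) + 1
    if int((retained > 0).sum()) < min_nonzero:
        return fit_zinb(x, min_nonzero=min_nonzero)
    row = fit_zinb(retained, min_nonzero=min_nonzero,
                   n_censored=k, censor_at=censor_at)
    row.n_obs = n
    row.n_nonzero = n_nz
    return row


def fit_zinb_by_distance(obs_by_delta: dict[int, np.ndarray],
                         pool_min_n: int = 50,
                         pool_min_nonzero: int = 10,
                         robust: bool = True) -> ZiNBParamTable:
    """Fit each distance, pooling sparse deltas with neighbours.

    Walking outward in delta, consecutive distances are merged until the
    group has >= pool_min_n observations and >= pool_min_nonzero nonzero
    counts; groups therefore grow geometrically at large separations where
    data thin out. A trailing underfull group is merged into its
    predecessor. With ``robust`` (default) each group's background is
    refined by outlier exclusion (:func:`fit_zinb_robust`).
    """
    fitter = fit_zinb_robust if robust else fit_zinb
    table = ZiNBParamTable()
    deltas = sorted(obs_by_delta)
    group: list[int] = []
    pooled_obs: list[np.ndarray] = []

    def flush():
        obs = np.concatenate(pooled_obs)
        row = fitter(obs)
        row.delta_min, row.delta_max = group[0], group[-1]
        if row.status == "ok" and len(group) > 1:
            row.status = "pooled"
        table.rows.append(row)
        group.clear()
        pooled_obs.clear()

    for d in deltas:
        group.append(d)
        pooled_obs.append(np.asarray(obs_by_delta[d]))
        tot = sum(len(o) for o in pooled_obs)
        nnz = sum(int((o > 0).sum()) for o in pooled_obs)
        if tot >= pool_min_n and nnz >= pool_min_nonzero:
            flush()
    if group:
        # merge the trailing underfull group into the previous one
        if table.rows:
            prev = table.rows.pop()
            lo = prev.delta_min
            obs = np.concatenate(
                [obs_by_delta[d] for d in deltas
                 if lo <= d <= group[-1]])
            row = fitter(obs)
            row.delta_min, row.delta_max = lo, group[-1]
            if row.status == "ok":
                row.status = "pooled" if row.delta_max > row.delta_min else "ok"
            table.rows.append(row)
        else:
            flush()
    return table


# ---------------------------------------------------------------------------
# p-values and BH selection
# ---------------------------------------------------------------------------

def zinb_pvalue(x, params: ZiNBParams):
    """Upper-tail p-value P(X >= x) under the fitted ZiNB.

    Equals 1 - CDF(x - 1); lies in (0, 1] and is monotone non-increasing
    in x. ``x`` may be a scalar or array of non-negative integers.
    """
    if params.status == "degenerate":
        raise DegenerateDataError("no p-values from a degenerate fit")
    x = np.asarray(x)
    if np.any(x < 0):
        raise FormatError("count must be >= 0")
    p = params.theta / (params.theta + params.mu)
    # P(X >= x) = (1 - pi) * P_NB(X >= x) for x >= 1; = 1 at x = 0
    tail = (1.0 - params.pi) * stats.nbinom.sf(x - 1, params.theta, p)
    out = np.where(x == 0, 1.0, tail)
    return float(out) if out.ndim == 0 else out


def bh_select(pvals: pd.DataFrame, alpha: float = 0.01,
              group_col: str = "delta_group") -> pd.DataFrame:
    """Benjamini-Hochberg step-up within each distance group.

    ``pvals`` needs columns [chrom, bin_i, bin_j, delta, p_value] plus the
    grouping column. Returns the significant rows (q <= alpha) with a
    ``q_value`` column, sorted by (chrom, bin_i, bin_j).
    """
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        out = pvals.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    parts = []
    for _, grp in pvals.groupby(group_col, sort=True):
        rej, q, _, _ = multipletests(grp["p_value"].to_numpy(),
                                     alpha=alpha, method="fdr_bh")
        g = grp.copy()
        g["q_value"] = q
        parts.append(g[rej])
    out = pd.concat(parts) if parts else pvals.iloc[:0].copy()
    if "q_value" not in out.columns:
        out["q_value"] = pd.Series(dtype=float)
    return out.sort_values(["chrom", "bin_i", "bin_j"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SignificantContactSet:
    """Called contacts (q <= alpha) and the fitted background."""

    contacts: pd.DataFrame
    params: ZiNBParamTable
    alpha: float

    def __len__(self) -> int:
        return len(self.contacts)

    def to_tsv(self, path) -> None:
        self.contacts.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


def _test_corrected(matrix: ContactMatrix, raw_dense, dense, mask,
                    alpha, min_delta, pool_min_n, pool_min_nonzero):
    """Fit per-delta ZiNB on a rounded corrected matrix and BH-select."""
    rounded = ContactMatrix.from_dense(matrix.chrom, matrix.resolution,
                                       dense.astype(float))
    rounded.n_bins = matrix.n_bins
    obs = collect_by_distance(rounded, mask=mask, min_delta=min_delta)
    table = fit_zinb_by_distance(obs, pool_min_n=pool_min_n,
                                 pool_min_nonzero=pool_min_nonzero)
    rows = []
    n = matrix.n_bins
    for params in table.rows:
        if params.status == "degenerate":
            continue
        for d in range(params.delta_min, params.delta_max + 1):
            if d >= n:
                break
            i = np.arange(n - d)
            keep = mask[i] & mask[i + d]
            i = i[keep]
            x = dense[i, i + d]
            # zeros have p = 1 exactly but remain members of the BH family
            pv = np.atleast_1d(zinb_pvalue(x, params))
            for bi, xx, pp in zip(i, x, pv):
                rows.append((matrix.chrom, int(bi), int(bi + d),
                             float(raw_dense[bi, bi + d]), int(xx), d,
                             f"{params.delta_min}-{params.delta_max}",
                             float(pp)))
    pvals = pd.DataFrame(rows, columns=[
        "chrom", "bin_i", "bin_j", "raw_count", "corrected_count",
        "delta", "delta_group", "p_value"])
    return bh_select(pvals, alpha=alpha), table


def _balance_trimmed(raw_dense: np.ndarray, mask: np.ndarray,
                     trim_frac: float = 0.05, max_iter: int = 200,
                     tol: float = 1e-8) -> np.ndarray:
    """Iterative correction with hotspot-trimmed marginals.

    Matrix balancing forces equal marginals, so on small matrices a handful
    of strongly enriched entries per row leak into the bias vector and
    distort every corrected count. Here each row's marginal is computed
    with its top ``trim_frac`` entries held out, which removes the
    influence of enriched pairs on bias estimation; on enrichment-free data
    the trim is uniform across rows and only rescales. Returns the bias
    vector (NaN on masked bins).
    """
    nm = int(mask.sum())
    k = max(1, int(np.ceil(trim_frac * nm)))
    wm = raw_dense[np.ix_(mask, mask)].astype(float)
    bm = np.ones(nm)
    for _ in range(max_iter):
        part = np.partition(wm, nm - k - 1, axis=1)
        s = wm.sum(axis=1) - part[:, nm - k:].sum(axis=1)
        s = np.where(s > 0, s, wm.sum(axis=1))
        db = s / s.mean()
        wm /= np.outer(db, db)
        bm *= db
        if np.abs(db - 1).max() < tol:
            break
    biases = np.full(raw_dense.shape[0], np.nan)
    biases[mask] = bm
    return biases


def _shrink_biases(raw_dense: np.ndarray, mask: np.ndarray,
                   biases: np.ndarray, trim_frac: float = 0.05) -> np.ndarray:
    """Noise-aware shrinkage of estimated biases toward 1.

    At desk scale (a few hundred bins) the marginal of a row is a noisy
    estimate: its sampling noise would otherwise be imprinted on every
    corrected count as a spurious "bias". The log-biases are shrunk by a
    method-of-moments factor lambda = max(0, 1 - v_noise / v_total), where
    v_total is the observed variance of the log-biases across bins and
    v_noise approximates their sampling variance from per-distance robust
    entry variances. Genuine large biases survive; pure noise is removed.
    """
    nm = int(mask.sum())
    wm = raw_dense[np.ix_(mask, mask)].astype(float)
    lb = np.log(biases[mask])
    lb = lb - lb.mean()
    v_total = float(lb.var())
    if v_total <= 0:
        return np.where(mask, 1.0, np.nan)
    # pure-noise floor: rebalance surrogate matrices whose entries are
    # permuted within each diagonal -- per-distance distributions are
    # preserved, genuine row biases destroyed
    rng = np.random.default_rng(1234)
    v_noise = []
    ones = np.ones(nm, dtype=bool)
    for _ in range(10):
        surr = np.zeros_like(wm)
        for d in range(1, nm):
            vals = np.diagonal(wm, offset=d).copy()
            rng.shuffle(vals)
            idx = np.arange(nm - d)
            surr[idx, idx + d] = vals
            surr[idx + d, idx] = vals
        if surr.sum() == 0:
            continue
        bs = _balance_trimmed(surr, ones, trim_frac=trim_frac)
        ls = np.log(bs)
        v_noise.append(float(np.var(ls - ls.mean())))
    lam = max(0.0, 1.0 - float(np.mean(v_noise)) / v_total) if v_noise else 0.0
    out = np.full(raw_dense.shape[0], np.nan)
    out[mask] = np.exp(lam * lb)
    return out


def estimate_biases(matrix: ContactMatrix, trim_frac: float = 0.05,
                    shrink: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Signal- and noise-robust per-bin biases for contact calling.

    Hotspot-trimmed iterative correction (:func:`_balance_trimmed`)
    followed by noise-aware shrinkage (:func:`_shrink_biases`). Returns
    ``(biases, mask)``.
    """
    raw_dense = matrix.to_dense()
    mask = raw_dense.sum(axis=1) > 0
    if not mask.any():
        raise DegenerateDataError("all-zero matrix")
    biases = _balance_trimmed(raw_dense, mask, trim_frac=trim_frac)
    if shrink:
        biases = _shrink_biases(raw_dense, mask, biases, trim_frac)
    return biases, mask


def call_significant_contacts(matrix: ContactMatrix, alpha: float = 0.01,
                              min_delta: int = 1,
                              pool_min_n: int = 50,
                              pool_min_nonzero: int = 10,
                              ice: bool = True,
                              trim_frac: float = 0.05) -> SignificantContactSet:
    """ICE-correct, fit ZiNB per distance, test every pair, BH-select.

    Corrected (real-valued) entries are rounded to the nearest integer
    before fitting and testing, preserving the discrete model's support.
    Only pairs between unmasked bins are tested; zeros always get p = 1 so
    only observed entries can be selected. Bias estimation is robust to the
    enrichment signal itself (hotspot-trimmed marginals) and to marginal
    sampling noise (shrinkage), see :func:`estimate_biases`.
    """
    raw_dense = matrix.to_dense()
    mask = raw_dense.sum(axis=1) > 0
    if not mask.any():
        raise DegenerateDataError("all-zero matrix")
    if ice:
        biases, mask = estimate_biases(matrix, trim_frac=trim_frac)
        bb = np.outer(biases, biases)
        with np.errstate(invalid="ignore"):
            corrected = np.where(np.isfinite(bb), raw_dense / bb, 0.0)
        dense = np.round(np.nan_to_num(corrected)).astype(np.int64)
    else:
        dense = np.round(raw_dense).astype(np.int64)
    selected, table = _test_corrected(
        matrix, raw_dense, dense, mask, alpha, min_delta,
        pool_min_n, pool_min_nonzero)
    return SignificantContactSet(selected, table, alpha)
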