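"""Dropout search and recovery for peak-by-cell matrices.

Within each cell cluster, the counts of a peak across cells are modelled
as a two-component mixture

    f(x) = lambda * Gamma(x; shape, rate) + (1 - lambda) * Normal(x; mu, sigma)

where the Gamma component (mass near zero) absorbs dropout residuals and
the Normal component the bona fide counts.  Parameters are estimated per
(peak, cluster) stratum by EM; the posterior weight of the Gamma
component at an observed count is its dropout probability.  Entries whose
dropout probability reaches a threshold T are replaced by a candidate
value derived from the sequence model's predicted accessibility; all
other entries are left untouched.

Zeros are given a small pseudo-value (default 0.1) before fitting because
the Gamma density is undefined at 0.

Neighbourhood quality of a matrix is scored by the label score: the mean
fraction of each cell's k nearest neighbours (in a 50-component PCA
projection) that share the cell's label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .annotate import ClusterAssignment
from .sequence_io import PeakCellMatrix

__all__ = [
    "GammaNormalMixture",
    "MixtureResults",
    "MixtureFit",
    "DropoutProbabilities",
    "DenoisedMatrix",
    "fit_mixture",
    "dropout_probability",
    "denoise",
    "denoise_without_search",
    "label_score",
]

_SIGMA_FLOOR = 1e-3
_SHAPE_CAP = 1e4


def _gamma_logpdf(x: np.ndarray, shape: float, rate: float) -> np.ndarray:
    return (shape * math.log(rate) - gammaln(shape)
            + (shape - 1.0) * np.log(x) - rate * x)


def _normal_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * math.log(2 * math.pi) - math.log(sd) \
        - 0.5 * ((x - mean) / sd) ** 2


def _solve_gamma_shape(c: float) -> float:
    """Solve ln(a) - digamma(a) = c by Newton (c > 0)."""
    if c <= 1e-12:
        return _SHAPE_CAP
    a = (3.0 - c + math.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    a = min(max(a, 1e-3), _SHAPE_CAP)
    for _ in range(25):
        f = math.log(a) - digamma(a) - c
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        a_new = min(a_new, _SHAPE_CAP)
        if abs(a_new - a) < 1e-12 * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(min(max(a, 1e-3), _SHAPE_CAP))


@dataclass
class MixtureResults:
    """Fitted Gamma-Normal mixture for one stratum."""

    lam: float
    shape: float
    rate: float
    mean: float
    sd: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def posterior_dropout(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability that each count came from the Gamma
        (dropout) component; exactly 0 / 1 at lambda = 0 / 1."""
        x = np.asarray(x, float)
        if self.lam <= 0.0:
            return np.zeros_like(x)
        if self.lam >= 1.0:
            return np.ones_like(x)
        lg = math.log(self.lam) + _gamma_logpdf(x, self.shape, self.rate)
        ln = math.log(1.0 - self.lam) + _normal_logpdf(x, self.mean, self.sd)
        return 1.0 / (1.0 + np.exp(np.clip(ln - lg, -700, 700)))

    def loglik(self, x: np.ndarray) -> float:
        lg = math.log(max(self.lam, 1e-300)) + _gamma_logpdf(x, self.shape, self.rate)
        ln = math.log(max(1.0 - self.lam, 1e-300)) + _normal_logpdf(x, self.mean, self.sd)
        m = np.maximum(lg, ln)
        return float((m + np.log(np.exp(lg - m) + np.exp(ln - m))).sum())


class GammaNormalMixture:
    """Two-component Gamma + Normal mixture fitted by EM to positive counts.

    Initialisation is a two-quantile split: the lower half of the data
    seeds the Gamma component by moment matching, the upper half the
    Normal component; the mixing weight starts at 0.5.
    """

    def __init__(self, x: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
        x = np.asarray(x, float).ravel()
        if np.any(x <= 0):
            raise ValueError("mixture requires strictly positive counts "
                             "(apply the zero pseudo-value first)")
        self.x = x
        self.tol = tol
        self.max_iter = max_iter

    def _initial(self) -> MixtureResults:
        """Split at the overall mean (low tail seeds the Gamma, high tail the
        Normal); falls back to a median split when one side is near-empty.
        A mean split keeps the pseudo-valued zero atom and the low residual
        counts together on the Gamma side, which avoids a degenerate local
        optimum where the Gamma collapses onto the atom alone."""
        x = np.sort(self.x)
        thr = float(x.mean())
        lo, hi = x[x < thr], x[x >= thr]
        if len(lo) < 2 or len(hi) < 2:
            half = len(x) // 2
            lo, hi = x[:half], x[half:]
        m_lo, v_lo = float(lo.mean()), float(lo.var()) + 1e-6
        shape = min(max(m_lo ** 2 / v_lo, 1e-2), _SHAPE_CAP)
        rate = shape / max(m_lo, 1e-12)
        mean = float(hi.mean())
        sd = max(float(hi.std()), _SIGMA_FLOOR)
        return MixtureResults(0.5, shape, rate, mean, sd)

    def fit(self) -> MixtureResults:
        x = self.x
        res = self._initial()
        prev = -np.inf
        trace: list[float] = []
        for it in range(self.max_iter):
            # E-step
            r = res.posterior_dropout(x)
            wg = r.sum()
            wn = len(x) - wg
            # M-step
            lam = wg / len(x)
            if wn > 1e-10:
                mean = float((1 - r) @ x / wn)
                var = float((1 - r) @ (x - mean) ** 2 / wn)
                sd = max(math.sqrt(max(var, 0.0)), _SIGMA_FLOOR)
            else:
                mean, sd = res.mean, res.sd
            if wg > 1e-10:
                mx = float(r @ x / wg)
                mlog = float(r @ np.log(x) / wg)
                c = max(math.log(mx) - mlog, 0.0)
                shape = _solve_gamma_shape(c)
                rate = shape / mx
            else:
                shape, rate = res.shape, res.rate
            res = MixtureResults(lam, shape, rate, mean, sd)
            ll = res.loglik(x)
            trace.append(ll)
            if it > 0 and abs(ll - prev) < self.tol:
                res.converged = True
                break
            prev = ll
        res.loglik_trace = trace
        res.n_iter = len(trace)
        return res


# ---------------------------------------------------------------------------
# stratified fitting over (peak, cluster)
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Per-(peak, cluster) mixture parameters; ``fitted`` marks strata that
    passed the minimum-size and non-degeneracy rules."""

    lam: np.ndarray               # (peaks, clusters)
    shape: np.ndarray
    rate: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    fitted: np.ndarray            # bool
    cluster_of_cell: np.ndarray   # (cells,)
    pseudo_value: float

    @property
    def n_clusters(self) -> int:
        return self.lam.shape[1]


@dataclass
class DropoutProbabilities:
    """Posterior dropout probabilities, oriented cells x peaks to match
    :class:`PeakCellMatrix`; NaN where no stratum fit exists."""

    values: np.ndarray


@dataclass
class DenoisedMatrix:
    matrix: PeakCellMatrix
    mask: np.ndarray              # cells x peaks; 1 where an entry was replaced
    threshold: float


def fit_mixture(counts: PeakCellMatrix, clusters: ClusterAssignment | np.ndarray,
                min_n: int = 20, pseudo_value: float = 0.1,
                tol: float = 1e-6, max_iter: int = 500) -> MixtureFit:
    """Fit the Gamma-Normal mixture per (peak, cluster) stratum.

    Strata with fewer than ``min_n`` cells or with (near-)identical counts
    are flagged unfitted.  Zeros are replaced by ``pseudo_value`` before
    fitting.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) \
        else np.asarray(clusters)
    if labels.shape[0] != counts.n_cells:
        raise ValueError("cluster labels do not match the cell count")
    X = counts.dense()
    uniq = np.unique(labels)
    cluster_index = {c: i for i, c in enumerate(uniq)}
    P, Kc = counts.n_peaks, len(uniq)
    out = {name: np.full((P, Kc), np.nan) for name in
           ("lam", "shape", "rate", "mean", "sd")}
    fitted = np.zeros((P, Kc), dtype=bool)
    for ci, c in enumerate(uniq):
        rows = labels == c
        if rows.sum() < min_n:
            continue
        block = X[rows, :]
        block = np.where(block == 0, pseudo_value, block)
        for p in range(P):
            x = block[:, p]
            if x.std() < 1e-8:       # degenerate stratum
                continue
            res = GammaNormalMixture(x, tol=tol, max_iter=max_iter).fit()
            # identifiability guard: when the Gamma mean sits inside the
            # Normal bulk the two components describe one population and
            # "dropout" is meaningless — treat the stratum as dropout-free
            if res.shape / res.rate > res.mean - 2.0 * res.sd:
                res.lam = 0.0
            out["lam"][p, ci] = res.lam
            out["shape"][p, ci] = res.shape
            out["rate"][p, ci] = res.rate
            out["mean"][p, ci] = res.mean
            out["sd"][p, ci] = res.sd
            fitted[p, ci] = True
    cluster_of_cell = np.array([cluster_index[c] for c in labels])
    return MixtureFit(out["lam"], out["shape"], out["rate"], out["mean"],
                      out["sd"], fitted, cluster_of_cell, pseudo_value)


def dropout_probability(fit: MixtureFit, counts: PeakCellMatrix
                        ) -> DropoutProbabilities:
    """Posterior dropout probability for every entry with a fitted stratum;
    NaN (never recovered) elsewhere."""
    X = counts.dense()
    X = np.where(X == 0, fit.pseudo_value, X)
    N, P = X.shape
    d = np.full((N, P), np.nan)
    for ci in range(fit.n_clusters):
        rows = fit.cluster_of_cell == ci
        if not rows.any():
            continue
        for p in range(P):
            if not fit.fitted[p, ci]:
                continue
            res = MixtureResults(fit.lam[p, ci], fit.shape[p, ci],
                                 fit.rate[p, ci], fit.mean[p, ci],
                                 fit.sd[p, ci])
            d[rows, p] = res.posterior_dropout(X[rows, p])
    return DropoutProbabilities(d)


def _candidate_matrix(predictions: np.ndarray, fit: MixtureFit,
                      candidate: str) -> np.ndarray:
    """Candidate denoised counts r: predicted probability, optionally scaled
    to the stratum's bona fide (Normal) count scale."""
    predictions = np.asarray(predictions, float)
    if candidate == "raw-probability":
        return predictions
    if candidate != "scaled":
        raise ValueError(f"unknown candidate mode {candidate!r}")
    scale = fit.mean[:, fit.cluster_of_cell].T      # cells x peaks mu-hat
    default = np.nanmean(fit.mean) if np.any(fit.fitted) else 1.0
    scale = np.where(np.isnan(scale), default, scale)
    return predictions * scale


def denoise(counts: PeakCellMatrix, d: DropoutProbabilities,
            predictions: np.ndarray, fit: MixtureFit, T: float = 0.5,
            candidate: str = "scaled") -> DenoisedMatrix:
    """Replace entries whose dropout probability is >= T by the candidate
    value; every other entry is returned untouched."""
    X = counts.dense()
    if predictions.shape != X.shape:
        raise ValueError("predictions must be cells x peaks, same shape as counts")
    if d.values.shape != X.shape:
        raise ValueError("dropout probabilities must match the count matrix")
    with np.errstate(invalid="ignore"):
        mask = (d.values >= T) & ~np.isnan(d.values)
    r = _candidate_matrix(predictions, fit, candidate)
    out = np.where(mask, r, X)
    return DenoisedMatrix(dc_replace(counts, matrix=out),
                          mask.astype(np.int8), float(T))


def denoise_without_search(counts: PeakCellMatrix, predictions: np.ndarray
                           ) -> DenoisedMatrix:
    """Ablation baseline: replace every zero entry indiscriminately.

    Skipping the dropout search means no mixture is fitted, so no stratum
    count scale exists; candidates are the predicted accessibilities scaled
    by each peak's mean non-zero observed count (1.0 for all-zero peaks).
    Non-zero entries — including any dropout residuals — are kept as-is.
    """
    X = counts.dense()
    if predictions.shape != X.shape:
        raise ValueError("predictions must be cells x peaks, same shape as counts")
    nz = (X > 0).sum(axis=0)
    scale = np.where(nz > 0, X.sum(axis=0) / np.maximum(nz, 1), 1.0)
    r = np.asarray(predictions, float) * scale[None, :]
    mask = X == 0
    out = np.where(mask, r, X)
    return DenoisedMatrix(dc_replace(counts, matrix=out),
                          mask.astype(np.int8), float("nan"))


def label_score(matrix: PeakCellMatrix | np.ndarray, labels, k: int = 50,
                n_components: int = 50) -> float:
    """Mean fraction of each cell's k nearest neighbours (Euclidean, in a
    PCA projection with up to ``n_components`` components) sharing the
    cell's label."""
    X = matrix.dense() if isinstance(matrix, PeakCellMatrix) else np.asarray(matrix, float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    n_comp = min(n_components, X.shape[1], n - 1)
    proj = PCA(n_components=n_comp, svd_solver="randomized",
               random_state=0).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(proj)
    _, idx = nn.kneighbors(proj)
    same = labels[idx[:, 1:]] == labels[:, None]
    return float(same.mean())
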