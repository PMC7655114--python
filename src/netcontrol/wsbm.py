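"""Weighted stochastic block model (WSBM) via conjugate variational Bayes.

The model: node i carries a latent community label z_i in {1..K}.  For an
unordered node pair (i, j), an edge exists with probability p_{z_i z_j}
(Bernoulli), and if it exists its weight is drawn from a normal
distribution N(mu_{z_i z_j}, sigma^2_{z_i z_j}).  The log-likelihood mixes
the two parts with a weight alpha:

    alpha * sum_pairs Bernoulli(A_ij > 0 | p)  +
    (1 - alpha) * sum_present_edges Normal(w_ij | mu, sigma^2).

The log-normal weight family applies the normal likelihood to log-weights.

Inference is mean-field variational Bayes with conjugate priors: a
Beta(a, b) prior on each block edge probability and a normal-inverse-gamma
prior on each block (mu, sigma^2).  Label responsibilities are updated one
node at a time (each update is an exact coordinate maximization), so the
evidence lower bound is non-decreasing along every fit trajectory; the
final bound is the model score used for choosing K.

The estimator follows the scikit-learn clustering API (``fit`` on an
adjacency matrix, fitted attributes with trailing underscores, and
``fit_predict`` from :class:`~sklearn.base.ClusterMixin`).
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln, xlogy
from sklearn.base import BaseEstimator, ClusterMixin

from .control import as_matrix

__all__ = [
    "WeightedSBM",
    "wsbm_fit",
    "select_k",
    "wsbm_log_likelihood",
    "variation_of_information",
    "central_partition",
]


def _edge_data(network, weight_family: str):
    """Validated adjacency, binary structure, and (transformed) weight matrix."""
    a = as_matrix(network)
    if np.any(a < 0):
        raise ValueError("adjacency weights must be non-negative")
    np.fill_diagonal(a, 0.0)
    x = (a > 0).astype(float)
    if weight_family == "lognormal":
        w = np.zeros_like(a)
        w[x > 0] = np.log(a[x > 0])
    elif weight_family == "normal":
        w = a.copy()
    else:
        raise ValueError(f"unknown weight family: {weight_family!r}")
    return a, x, w


def wsbm_log_likelihood(
    network,
    labels,
    edge_probability,
    weight_mean,
    weight_var,
    alpha: float = 0.5,
    weight_family: str = "normal",
) -> float:
    """Point log-likelihood of a labeled network under given block parameters.

    Sums alpha-weighted Bernoulli edge-existence terms over all unordered
    node pairs and (1-alpha)-weighted normal weight terms over present
    edges, with block parameters indexed by the endpoint labels.
    """
    _, x, w = _edge_data(network, weight_family)
    labels = np.asarray(labels, dtype=int)
    n = x.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must assign one community per node")
    uniq, z = np.unique(labels, return_inverse=True)
    p = np.asarray(edge_probability, dtype=float)
    mu = np.asarray(weight_mean, dtype=float)
    var = np.asarray(weight_var, dtype=float)
    if p.shape[0] < len(uniq):
        raise ValueError("parameter tables smaller than the number of communities")
    iu, ju = np.triu_indices(n, k=1)
    r, s = z[iu], z[ju]
    xe = x[iu, ju]
    bern = np.sum(xlogy(xe, p[r, s]) + xlogy(1 - xe, 1 - p[r, s]))
    on = xe > 0
    wv = w[iu, ju][on]
    m, v = mu[r[on], s[on]], var[r[on], s[on]]
    wll = np.sum(-0.5 * np.log(2 * np.pi * v) - (wv - m) ** 2 / (2 * v))
    return float(alpha * bern + (1 - alpha) * wll)


class WeightedSBM(BaseEstimator, ClusterMixin):
    """Weighted stochastic block model fit by variational Bayes.

    Parameters
    ----------
    n_communities : int
        Number of blocks K.
    weight_family : {"normal", "lognormal"}
        Edge weight distribution; "lognormal" fits a normal model to
        log-weights (all present edge weights must be positive).
    alpha : float
        Mixing weight between the Bernoulli edge-existence log-likelihood
        (alpha) and the edge-weight log-likelihood (1 - alpha).
    n_restarts : int
        Independent random initializations; the fit with the highest final
        lower bound is kept.
    max_iter, tol : int, float
        Per-restart iteration cap and lower-bound convergence threshold.
    beta_prior : (float, float)
        Beta prior (a, b) on every block edge probability.
    prior_kappa, prior_shape : float
        Normal-inverse-gamma pseudo-counts: kappa0 (mean) and a0 (variance
        shape).  The prior location mu0 and scale b0 default to the mean
        and variance of the observed (transformed) edge weights.
    random_state : int or None
        Seed for the Dirichlet initializations.

    Attributes
    ----------
    labels_ : (n,) int array of hard assignments (1-based).
    responsibilities_ : (n, K) posterior membership probabilities.
    edge_probability_, weight_mean_, weight_var_ : (K, K) posterior-mean
        block parameter tables.
    log_evidence_ : final variational lower bound.
    elbo_trajectory_ : lower bound after each iteration of the best restart.
    """

    def __init__(
        self,
        n_communities: int = 2,
        weight_family: str = "normal",
        alpha: float = 0.5,
        n_restarts: int = 10,
        max_iter: int = 200,
        tol: float = 1e-6,
        beta_prior: tuple = (1.0, 1.0),
        prior_kappa: float = 1.0,
        prior_shape: float = 1.0,
        random_state=None,
    ):
        self.n_communities = n_communities
        self.weight_family = weight_family
        self.alpha = alpha
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.beta_prior = beta_prior
        self.prior_kappa = prior_kappa
        self.prior_shape = prior_shape
        self.random_state = random_state

    # ---- conjugate updates ------------------------------------------------

    @staticmethod
    def _block_stats(tau, x, w):
        """Expected per-block sufficient statistics over unordered node pairs.

        The ordered-pair sum sum_{i != j} tau_ir tau_js already counts every
        unordered pair once for each of the two (r, s) orderings, so for
        r != s it equals the total unordered-pair statistic of block {r, s};
        on-diagonal blocks are counted twice and need halving.
        """
        t = tau.sum(axis=0)
        out = {}
        for key, mat in (
            ("N", np.outer(t, t) - tau.T @ tau),
            ("E", tau.T @ x @ tau),
            ("S1", tau.T @ w @ tau),
            ("S2", tau.T @ (w * w) @ tau),
        ):
            mat = (mat + mat.T) / 2.0
            np.fill_diagonal(mat, 0.5 * np.diag(mat))
            out[key] = mat
        return out

    def _posteriors(self, tau, x, w, prior):
        """Block posterior hyperparameters from expected sufficient statistics."""
        alpha = self.alpha
        stats = self._block_stats(tau, x, w)
        a0, b0 = prior["beta"]
        ba = a0 + alpha * stats["E"]
        bb = b0 + alpha * (stats["N"] - stats["E"])
        mu0, k0, g0, h0 = prior["nig"]  # location, kappa, shape, scale
        m = (1 - alpha) * stats["E"]
        ws1 = (1 - alpha) * stats["S1"]
        ws2 = (1 - alpha) * stats["S2"]
        kap = k0 + m
        loc = (k0 * mu0 + ws1) / kap
        shape = g0 + m / 2.0
        scale = h0 + 0.5 * (ws2 + k0 * mu0**2 - kap * loc**2)
        scale = np.maximum(scale, 1e-12)
        return {"ba": ba, "bb": bb, "kap": kap, "loc": loc, "shape": shape,
                "scale": scale, "stats": stats}

    @staticmethod
    def _expectations(post):
        """Posterior expectations of the log-likelihood natural parameters."""
        ba, bb = post["ba"], post["bb"]
        e_logp = digamma(ba) - digamma(ba + bb)
        e_log1mp = digamma(bb) - digamma(ba + bb)
        kap, loc = post["kap"], post["loc"]
        shape, scale = post["shape"], post["scale"]
        e_prec = shape / scale  # E[1/sigma^2]
        e_mu_prec = loc * e_prec  # E[mu/sigma^2]
        e_mu2_prec = 1.0 / kap + loc**2 * e_prec  # E[mu^2/sigma^2]
        e_logvar = np.log(scale) - digamma(shape)
        # per-edge coefficient tables for the weight likelihood
        c_const = -0.5 * (np.log(2 * np.pi) + e_logvar) - 0.5 * e_mu2_prec
        return {
            "logp": e_logp,
            "log1mp": e_log1mp,
            "c_const": c_const,
            "c_lin": e_mu_prec,
            "c_quad": -0.5 * e_prec,
        }

    def _kl_penalty(self, post, prior):
        """KL(q(theta) || p(theta)) summed over unordered block pairs."""
        a0, b0 = prior["beta"]
        mu0, k0, g0, h0 = prior["nig"]
        ba, bb = post["ba"], post["bb"]
        kl_beta = (
            gammaln(a0) + gammaln(b0) - gammaln(a0 + b0)
            - (gammaln(ba) + gammaln(bb) - gammaln(ba + bb))
            + (ba - a0) * digamma(ba)
            + (bb - b0) * digamma(bb)
            + (a0 + b0 - ba - bb) * digamma(ba + bb)
        )
        kap, loc, shape, scale = post["kap"], post["loc"], post["shape"], post["scale"]
        kl_nig = (
            0.5 * (np.log(kap / k0) + k0 / kap - 1.0)
            + k0 * shape * (loc - mu0) ** 2 / (2.0 * scale)
            + g0 * np.log(scale / h0)
            + gammaln(g0) - gammaln(shape)
            + (shape - g0) * digamma(shape)
            + shape * (h0 - scale) / scale
        )
        total = kl_beta + kl_nig
        iu = np.triu_indices(total.shape[0])
        return float(total[iu].sum())

    def _elbo(self, tau, post, expect, prior):
        st = post["stats"]
        iu = np.triu_indices(self.n_communities)  # one term per unordered block pair
        bern_m = st["E"] * expect["logp"] + (st["N"] - st["E"]) * expect["log1mp"]
        wght_m = (
            st["E"] * expect["c_const"]
            + st["S1"] * expect["c_lin"]
            + st["S2"] * expect["c_quad"]
        )
        bern = bern_m[iu].sum()
        wght = wght_m[iu].sum()
        entropy = -np.sum(xlogy(tau, tau))
        prior_z = -tau.shape[0] * np.log(self.n_communities)
        return (
            self.alpha * bern
            + (1 - self.alpha) * wght
            + entropy
            + prior_z
            - self._kl_penalty(post, prior)
        )

    def _sweep(self, tau, x, w, expect, neighbors):
        """Sequential mean-field update of every node's responsibilities."""
        alpha = self.alpha
        lp, lq = expect["logp"], expect["log1mp"]
        cc, cl, cq = expect["c_const"], expect["c_lin"], expect["c_quad"]
        tcol = tau.sum(axis=0)
        for i in range(tau.shape[0]):
            tcol -= tau[i]
            nb, wv = neighbors[i]
            tw = tau[nb]
            e = tw.sum(axis=0)
            ne = tcol - e
            field = alpha * (lp @ e + lq @ ne)
            if len(nb):
                field += (1 - alpha) * (
                    cc @ e + cl @ (tw.T @ wv) + cq @ (tw.T @ (wv**2))
                )
            field -= field.max()
            ti = np.exp(field)
            tau[i] = ti / ti.sum()
            tcol += tau[i]
        return tau

    @staticmethod
    def _soft_onehot(labels, k, eps=0.05):
        n = len(labels)
        tau = np.full((n, k), eps / max(k - 1, 1))
        tau[np.arange(n), labels] = 1.0 - eps
        return tau / tau.sum(axis=1, keepdims=True)

    def _spectral_init(self, w, k, rng):
        """Near-hard responsibilities from k-means on leading eigenvectors.

        Mean-field coordinate ascent has a large basin of attraction around
        the label-symmetric fixed point, so one restart is seeded from a
        spectral embedding of the weight matrix instead of random draws.
        """
        import scipy.linalg
        from sklearn.cluster import KMeans

        n = w.shape[0]
        top = min(k, n - 1)
        lam, vec = scipy.linalg.eigh(w, subset_by_index=(n - top, n - 1))
        order = np.argsort(np.abs(lam))[::-1]
        emb = vec[:, order]
        km = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31)))
        return self._soft_onehot(km.fit_predict(emb), k)

    def _fit_once(self, x, w, prior, rng, init="dirichlet"):
        n = x.shape[0]
        k = self.n_communities
        if init == "spectral" and k > 1:
            tau = self._spectral_init(w, k, rng)
        else:
            # peaked symmetric Dirichlet: near-uniform draws sit in the basin
            # of the label-symmetric fixed point, so start near-hard
            tau = rng.dirichlet(np.full(k, 0.1), size=n)
            tau = np.clip(tau, 1e-12, None)
            tau /= tau.sum(axis=1, keepdims=True)
        neighbors = []
        for i in range(n):
            nb = np.flatnonzero(x[i])
            neighbors.append((nb, w[i, nb]))
        elbos = []
        prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            post = self._posteriors(tau, x, w, prior)
            expect = self._expectations(post)
            tau = self._sweep(tau, x, w, expect, neighbors)
            post = self._posteriors(tau, x, w, prior)
            expect = self._expectations(post)
            elbo = self._elbo(tau, post, expect, prior)
            elbos.append(elbo)
            if abs(elbo - prev) < self.tol:
                converged = True
                break
            prev = elbo
        return tau, post, np.asarray(elbos), converged

    # ---- public API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the block model to a symmetric non-negative adjacency matrix."""
        a, x, w = _edge_data(X, self.weight_family)
        n = a.shape[0]
        k = int(self.n_communities)
        if k < 1:
            raise ValueError("n_communities must be >= 1")
        if k > n:
            raise ValueError(f"n_communities={k} exceeds node count {n}")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        on = x > 0
        wvals = w[on]
        mu0 = float(wvals.mean()) if wvals.size else 0.0
        h0 = float(wvals.var()) if wvals.size else 1.0
        h0 = max(h0, 1e-6)
        prior = {
            "beta": (float(self.beta_prior[0]), float(self.beta_prior[1])),
            "nig": (mu0, float(self.prior_kappa), float(self.prior_shape), h0),
        }
        ss = np.random.SeedSequence(self.random_state)
        best = None
        n_restarts = max(1, int(self.n_restarts))
        for r, child in enumerate(ss.spawn(n_restarts)):
            rng = np.random.default_rng(child)
            init = "spectral" if r == 0 else "dirichlet"
            tau, post, elbos, converged = self._fit_once(x, w, prior, rng, init=init)
            if best is None or elbos[-1] > best[2][-1]:
                best = (tau, post, elbos, converged)
        tau, post, elbos, converged = best
        self.responsibilities_ = tau
        self.labels_ = tau.argmax(axis=1) + 1
        self.edge_probability_ = post["ba"] / (post["ba"] + post["bb"])
        self.weight_mean_ = post["loc"]
        shape = post["shape"]
        self.weight_var_ = post["scale"] / np.where(shape > 1, shape - 1, shape)
        self.log_evidence_ = float(elbos[-1])
        self.elbo_trajectory_ = elbos
        self.n_iter_ = len(elbos)
        self.converged_ = converged
        self.n_features_in_ = n
        return self


def wsbm_fit(network, n_communities: int, seed=None, **params) -> WeightedSBM:
    """Fit a :class:`WeightedSBM` to a network; returns the fitted estimator."""
    est = WeightedSBM(n_communities=n_communities, random_state=seed, **params)
    return est.fit(as_matrix(network))


def select_k(network, k_grid, seed=None, **params):
    """Fit the WSBM over a grid of K; return (best K, {K: fitted estimator}).

    The K whose best-restart variational lower bound is highest is chosen.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    a = as_matrix(network)
    ss = np.random.SeedSequence(seed)
    fits = {}
    for k, child in zip(k_grid, ss.spawn(len(k_grid))):
        fits[k] = WeightedSBM(
            n_communities=k, random_state=child.generate_state(1)[0], **params
        ).fit(a)
    best_k = max(k_grid, key=lambda k: fits[k].log_evidence_)
    return best_k, fits


def variation_of_information(p1, p2) -> float:
    """VI(p1, p2) = H(p1) + H(p2) - 2 I(p1; p2), in nats.

    A metric distance between partitions; 0 iff the partitions are
    identical up to relabeling of communities.
    """
    l1 = np.asarray(p1, dtype=int)
    l2 = np.asarray(p2, dtype=int)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("partitions must be equal-length 1-D label vectors")
    n = len(l1)
    _, i1 = np.unique(l1, return_inverse=True)
    _, i2 = np.unique(l2, return_inverse=True)
    joint = np.zeros((i1.max() + 1, i2.max() + 1))
    np.add.at(joint, (i1, i2), 1.0)
    joint /= n
    p_r = joint.sum(axis=1)
    p_c = joint.sum(axis=0)
    h1 = -np.sum(xlogy(p_r, p_r))
    h2 = -np.sum(xlogy(p_c, p_c))
    mi = np.sum(xlogy(joint, joint / np.outer(p_r, p_c).clip(1e-300)))
    return float(max(h1 + h2 - 2 * mi, 0.0))


def central_partition(partitions) -> np.ndarray:
    """The member partition minimizing the summed VI distance to all others.

    Ties are broken by lowest index.
    """
    parts = [np.asarray(p, dtype=int) for p in partitions]
    if not parts:
        raise ValueError("need at least one partition")
    m = len(parts)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = variation_of_information(parts[i], parts[j])
    return parts[int(np.argmin(dist.sum(axis=1)))]
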