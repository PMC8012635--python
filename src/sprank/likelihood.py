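"""Tree likelihoods under GTR+I+G and branch-length / model optimization.

Likelihoods are computed with Felsenstein's pruning algorithm over compressed
site patterns.  Rate heterogeneity uses the discrete-gamma approximation
(mean of each quantile interval, 4 categories by default) plus an optional
proportion of invariant sites; with a proportion ``p_inv`` of invariant
sites the variable categories are rescaled by ``1/(1 - p_inv)`` so that the
expected rate over all sites is 1 and branch lengths stay in expected
substitutions per site.

Branch lengths are optimized coordinate-wise: a depth-first sweep visits
every branch, reduces the likelihood to a one-dimensional function of that
branch's length via the eigendecomposition of the rate matrix, and solves it
by bounded scalar search in log branch length.  Partial likelihoods are
rescaled per node to avoid underflow.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .spr import SPRMove, apply_spr
from .tree import Alignment, PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "SubstitutionModel",
    "LikelihoodResult",
    "log_likelihood",
    "optimize_branch_lengths",
    "optimize_model",
    "score_all_neighbors",
    "MIN_BRANCH_LENGTH",
    "MAX_BRANCH_LENGTH",
]

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 100.0

# upper-triangle order of the 6 GTR exchangeabilities
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
RATE_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")


def discrete_gamma_rates(alpha: float, n_cats: int) -> np.ndarray:
    """Mean-of-quantile discrete-gamma category rates (overall mean 1)."""
    if n_cats == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, n_cats + 1), a=alpha, scale=1.0 / alpha)
    cdf = gammainc(alpha + 1.0, edges * alpha)
    return n_cats * np.diff(cdf)


@dataclass(eq=False)
class SubstitutionModel:
    """GTR+I+G nucleotide substitution model.

    ``rates`` are the six symmetric exchangeabilities in order
    AC, AG, AT, CG, CT, GT (GT conventionally 1); ``freqs`` are the
    stationary base frequencies (A, C, G, T).  ``alpha=None`` disables gamma
    rate heterogeneity.  The rate matrix is normalized to one expected
    substitution per site per unit branch length.
    """

    rates: np.ndarray
    freqs: np.ndarray
    p_inv: float = 0.0
    alpha: float | None = None
    n_cats: int = 4
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise ValueError("need 6 positive exchangeability rates")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_cats < 1:
            raise ValueError("need at least one rate category")

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        """Jukes-Cantor: equal rates, equal frequencies, no heterogeneity."""
        return cls(rates=np.ones(6), freqs=np.full(4, 0.25), p_inv=0.0, alpha=None, n_cats=1)

    def q_matrix(self) -> np.ndarray:
        q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIRS):
            q[i, j] = r * self.freqs[j]
            q[j, i] = r * self.freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(self.freqs, np.diag(q)))
        return q / mu

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, left, right) with P(t) = left @ diag(e^{lambda t}) @ right."""
        if self._eigen is None:
            q = self.q_matrix()
            sqp = np.sqrt(self.freqs)
            sym = (sqp[:, None] * q) / sqp[None, :]
            evals, u = np.linalg.eigh((sym + sym.T) / 2.0)
            left = u / sqp[:, None]
            right = u.T * sqp[None, :]
            self._eigen = (evals, left, right)
        return self._eigen

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        evals, left, right = self.eigen()
        p = (left * np.exp(evals * rate * t)[None, :]) @ right
        return np.clip(p, 0.0, None)

    def category_rates_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Variable-category rates and weights (invariant category excluded)."""
        k = self.n_cats if self.alpha is not None else 1
        base = discrete_gamma_rates(self.alpha, k) if self.alpha is not None else np.ones(1)
        scale = 1.0 / (1.0 - self.p_inv) if self.p_inv > 0 else 1.0
        rates = base * scale
        weights = np.full(k, (1.0 - self.p_inv) / k)
        return rates, weights

    def to_dict(self) -> dict:
        return {
            "rates": {n: float(r) for n, r in zip(RATE_NAMES, self.rates)},
            "freqs": {b: float(f) for b, f in zip("ACGT", self.freqs)},
            "p_inv": float(self.p_inv),
            "alpha": None if self.alpha is None else float(self.alpha),
            "n_cats": int(self.n_cats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionModel":
        return cls(
            rates=np.array([d["rates"][n] for n in RATE_NAMES]),
            freqs=np.array([d["freqs"][b] for b in "ACGT"]),
            p_inv=d.get("p_inv", 0.0),
            alpha=d.get("alpha"),
            n_cats=d.get("n_cats", 4),
        )


@dataclass
class LikelihoodResult:
    log_likelihood: float
    tree: PhyloTree


class _PruningKernel:
    """Pruning-algorithm workhorse bound to one (tree, alignment, model).

    Holds compressed patterns, per-node partial likelihood arrays with
    per-(category, pattern) log rescaling factors, and a working copy of the
    branch lengths that branch-length optimization mutates.
    """

    def __init__(self, tree: PhyloTree, aln: Alignment, model: SubstitutionModel):
        if tree.leaves != frozenset(aln.taxa):
            raise ValueError("tree and alignment leaf sets differ")
        self.tree = tree
        self.model = model
        self.evals, self.left, self.right = model.eigen()
        self.rates, self.weights = model.category_rates_weights()
        self.K = len(self.rates)
        codes, self.pat_weights = aln.patterns()
        self.P = codes.shape[1]
        taxon_index = {t: i for i, t in enumerate(aln.taxa)}
        self.freqs = model.freqs

        # leaf partials (P, 4) cached on the alignment; missing data -> 1s
        by_taxon = aln.leaf_partials()
        self.leaf_partials: dict[int, np.ndarray] = {
            nid: by_taxon[label] for nid, label in tree.leaf_nodes.items()
        }

        # invariant-site mixture term: sum of freqs over states compatible
        # with every non-missing character in the pattern
        inv_like = (aln.invariant_compat() * self.freqs[None, :]).sum(axis=1)
        with np.errstate(divide="ignore"):
            self.log_inv = np.log(model.p_inv * inv_like) if model.p_inv > 0 else None

        # rooted scaffold for traversals
        internal = [n for n in tree.nodes if not tree.is_leaf(n)]
        self.root = min(internal) if internal else min(tree.nodes)
        self.postorder = list(tree.traverse_from(self.root))
        self.children: dict[int, list[tuple[int, int]]] = {n: [] for n in tree.nodes}
        for node, parent, bid in self.postorder:
            if parent is not None:
                self.children[parent].append((node, bid))
        self.lengths = tree.branch_lengths
        self.down: dict[int, np.ndarray] = {}
        self.down_scale: dict[int, np.ndarray] = {}

    # --------------------------------------------------------------- messages

    def _edge_probs(self, t: float) -> np.ndarray:
        """(K, 4, 4) transition matrices for one branch across categories."""
        e = np.exp(self.evals[None, :] * (self.rates[:, None] * t))
        return np.matmul(self.left[None, :, :] * e[:, None, :], self.right)

    def _message_raw(self, partial: np.ndarray, t: float) -> np.ndarray:
        """Propagate a conditional-likelihood array across a branch.

        No rescaling: magnitudes stay bounded because inputs are node-scaled
        (max 1 per pattern) and transition probabilities are at most 1; the
        caller rescales once after multiplying messages together.
        """
        return np.matmul(partial, self._edge_probs(t).transpose(0, 2, 1))

    def _rescale(self, part: np.ndarray, scale: np.ndarray):
        m = np.maximum(part.max(axis=2, keepdims=True), 1e-300)
        return part / m, scale + np.log(m[:, :, 0])

    def _combine_children(self, node: int):
        if self.tree.is_leaf(node):
            part = np.broadcast_to(self.leaf_partials[node], (self.K, self.P, 4))
        else:
            part = None
        scale = None
        for child, bid in self.children[node]:
            msg = self._message_raw(self.down[child], self.lengths[bid])
            part = msg if part is None else part * msg
            cs = self.down_scale[child]
            scale = cs if scale is None else scale + cs
        if part is None:
            part = np.ones((self.K, self.P, 4))
        if scale is None:
            scale = np.zeros((self.K, self.P))
        return self._rescale(part, scale)

    def compute_down(self) -> None:
        """Post-order partials of each node's subtree (away from the root)."""
        for node, _parent, _bid in reversed(self.postorder):
            self.down[node], self.down_scale[node] = self._combine_children(node)

    def _site_loglik(self, per_cat: np.ndarray, scale: np.ndarray) -> np.ndarray:
        """Combine per-category site likelihoods (scaled) into site log-likelihoods."""
        per_cat = np.maximum(per_cat, 1e-300)
        m = scale.max(axis=0)
        var = (self.weights[:, None] * np.exp(scale - m[None, :]) * per_cat).sum(axis=0)
        logvar = m + np.log(np.maximum(var, 1e-300))
        if self.log_inv is not None:
            return np.logaddexp(self.log_inv, logvar)
        return logvar

    def full_loglik(self) -> float:
        self.compute_down()
        per_cat = np.einsum("i,kpi->kp", self.freqs, self.down[self.root])
        site = self._site_loglik(per_cat, self.down_scale[self.root])
        return float(self.pat_weights @ site)

    # ---------------------------------------------------- branch optimization

    def _optimize_edge(
        self, a, sa, b, sb, t0: float, grad_tol: float = 1e-6
    ) -> tuple[float, float]:
        """Maximize the likelihood in one branch length.

        With A the conditional likelihoods of the rest of the tree at one
        endpoint and B the subtree partials at the other, the site likelihood
        is A' diag(pi) P(t) B, which via the eigendecomposition reduces to a
        fixed coefficient tensor dotted with exp(lambda * r_k * t).  A
        safeguarded Newton iteration on log t exploits the analytic first
        and second derivatives; bounded golden-section search is the
        fallback.  Never returns a point worse than the current length.

        Assumes downward partials are current for the whole tree.
        """
        acoef = np.einsum("kpi,i,im->kpm", a, self.freqs, self.left)
        bcoef = np.einsum("mj,kpj->kpm", self.right, b)
        stot = sa + sb
        m = stot.max(axis=0)
        # combine the (branch-length-independent) invariant-site term on a
        # shared per-pattern scale so neither mixture part can overflow
        if self.log_inv is not None:
            m2 = np.maximum(m, self.log_inv)
            base = np.exp(m - m2)
            inv_term = np.exp(self.log_inv - m2)
        else:
            m2 = m
            base = 1.0
            inv_term = 0.0
        wexp = base * self.weights[:, None] * np.exp(stot - m[None, :])  # (K, P)
        lam = self.evals[None, :] * self.rates[:, None]  # (K, 4)
        # stacked coefficients for value / first / second derivative, with
        # category weights and scalers folded in; flattening the (category,
        # eigenvalue) axes turns each Newton iteration into one mat-vec
        coef = acoef * bcoef * wexp[:, :, None]
        cstack = np.stack((coef, coef * lam[:, None, :], coef * lam[:, None, :] ** 2))
        cmat = np.ascontiguousarray(cstack.transpose(0, 2, 1, 3)).reshape(3 * self.P, -1)
        P = self.P

        def parts(t: float):
            s = (cmat @ np.exp(lam * t).ravel()).reshape(3, P)
            d = np.maximum(s[0] + inv_term, 1e-300)
            ll = float(self.pat_weights @ (m2 + np.log(d)))
            r1 = s[1] / d
            g = float(self.pat_weights @ r1)  # d ll / d t
            h = float(self.pat_weights @ (s[2] / d - r1 * r1))  # d2 ll / d t2
            return ll, g, h

        def ll_only(t: float) -> float:
            s0 = cmat[:P] @ np.exp(lam * t).ravel()
            d = np.maximum(s0 + inv_term, 1e-300)
            return float(self.pat_weights @ (m2 + np.log(d)))

        lo, hi = math.log(MIN_BRANCH_LENGTH), math.log(MAX_BRANCH_LENGTH)
        t0 = min(max(t0, MIN_BRANCH_LENGTH), MAX_BRANCH_LENGTH)
        ll0 = ll_only(t0)
        u = math.log(t0)
        best_u, best_ll = u, ll0
        converged = False
        for _ in range(25):
            t = math.exp(u)
            ll, g, h = parts(t)
            if ll > best_ll:
                best_ll, best_u = ll, u
            gu = g * t  # chain rule to log-space
            hu = h * t * t + g * t
            if abs(gu) < grad_tol:
                converged = True
                break
            step = -gu / hu if hu < 0 else math.copysign(1.0, gu)
            step = min(max(step, -4.0), 4.0)
            u_new = min(max(u + step, lo), hi)
            if abs(u_new - u) < 1e-9:
                converged = True
                break
            u = u_new
        if not converged:
            res = minimize_scalar(
                lambda x: -ll_only(math.exp(x)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > best_ll:
                best_ll, best_u = -res.fun, res.x
        if best_ll <= ll0:
            return t0, ll0
        return math.exp(best_u), best_ll

    def sweep(self) -> float:
        """One depth-first coordinate-ascent pass over all branches.

        Visits edges in preorder; after a subtree is finished its downward
        partial is refreshed so later siblings always see current lengths
        (exact Gauss-Seidel), which also keeps the downward partials current
        for the next sweep.  Callers must run :meth:`compute_down` once
        before the first sweep.  Returns the log-likelihood after the final
        branch update.
        """
        last_ll = [None]

        def visit(node: int, up: np.ndarray, sup: np.ndarray) -> None:
            kids = self.children[node]
            for child, bid in kids:
                a = up
                sa = sup
                for sib, sbid in kids:
                    if sib == child:
                        continue
                    a = a * self._message_raw(self.down[sib], self.lengths[sbid])
                    sa = sa + self.down_scale[sib]
                if node in self.leaf_partials:
                    a = a * self.leaf_partials[node][None, :, :]
                a, sa = self._rescale(a, sa)
                t_new, ll = self._optimize_edge(
                    a, sa, self.down[child], self.down_scale[child], self.lengths[bid]
                )
                self.lengths[bid] = t_new
                last_ll[0] = ll
                if self.children[child]:
                    visit(child, self._message_raw(a, t_new), sa)
                    self.down[child], self.down_scale[child] = self._combine_children(child)

        ones = np.ones((self.K, self.P, 4))
        zeros = np.zeros((self.K, self.P))
        visit(self.root, ones, zeros)
        return last_ll[0] if last_ll[0] is not None else self.full_loglik_from_down()

    def full_loglik_from_down(self) -> float:
        per_cat = np.einsum("i,kpi->kp", self.freqs, self.down[self.root])
        site = self._site_loglik(per_cat, self.down_scale[self.root])
        return float(self.pat_weights @ site)


# ------------------------------------------------------------------ frontend


def log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel) -> float:
    """Log-likelihood of *tree* given *aln* under *model*."""
    ll = _PruningKernel(tree, aln, model).full_loglik()
    if not math.isfinite(ll):
        raise ArithmeticError(f"non-finite log-likelihood ({ll})")
    return ll


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> LikelihoodResult:
    """Coordinate-wise branch-length optimization with the model held fixed.

    Sweeps over all branches until the per-sweep improvement drops below
    *tol* log-likelihood units or *max_sweeps* is reached.  The returned
    log-likelihood never falls below the input tree's by more than *tol*.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    kernel = _PruningKernel(tree, aln, model)
    kernel.compute_down()
    ll_prev = kernel.full_loglik_from_down()
    ll = ll_prev
    for _ in range(max_sweeps):
        ll = kernel.sweep()
        if ll - ll_prev < tol:
            break
        ll_prev = ll
    else:
        logger.debug("branch-length optimization hit max_sweeps=%d", max_sweeps)
    out = tree.copy()
    for bid, t in kernel.lengths.items():
        out.set_branch_length(bid, max(t, 0.0))
    return LikelihoodResult(log_likelihood=ll, tree=out)


def optimize_model(
    tree: PhyloTree,
    aln: Alignment,
    n_cats: int = 4,
    rounds: int = 2,
) -> SubstitutionModel:
    """Fit GTR+I+G parameters on a fixed topology.

    Base frequencies are empirical counts; exchangeabilities (GT fixed at 1),
    the gamma shape and the invariant proportion are fit by bounded
    quasi-Newton search alternated with branch-length sweeps.  Falls back to
    Jukes-Cantor parameters if the optimizer fails.
    """
    freqs = aln.base_frequencies()

    def make(x: np.ndarray) -> SubstitutionModel:
        rates = np.append(np.exp(x[:5]), 1.0)
        return SubstitutionModel(
            rates=rates, freqs=freqs, p_inv=float(x[6]), alpha=float(np.exp(x[5])), n_cats=n_cats
        )

    x0 = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.01])
    bounds = [(math.log(1e-3), math.log(300.0))] * 5 + [
        (math.log(0.02), math.log(100.0)),
        (0.0, 0.9),
    ]
    try:
        work_tree = tree
        for _ in range(rounds):
            work_tree = optimize_branch_lengths(
                work_tree, aln, make(x0), tol=1e-3, max_sweeps=5
            ).tree

            def neg(x: np.ndarray) -> float:
                # extreme probe points can overflow transiently; the penalty
                # return keeps the optimizer inside the sane region
                try:
                    with np.errstate(all="ignore"):
                        return -log_likelihood(work_tree, aln, make(x))
                except (ArithmeticError, ValueError, FloatingPointError):
                    return 1e12

            res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 60})
            x0 = res.x
        # guard against a poorly converged heterogeneity fit: the returned
        # model is the likelihood-best of the full fit and its nested
        # homogeneous/JC special cases
        candidates = [
            make(x0),
            SubstitutionModel(rates=np.ones(6), freqs=freqs),
            SubstitutionModel.jc(),
        ]
        with np.errstate(all="ignore"):
            lls = [
                optimize_branch_lengths(work_tree, aln, m, tol=1e-3, max_sweeps=5).log_likelihood
                for m in candidates
            ]
        best = int(np.argmax(lls))
        if not math.isfinite(lls[best]):
            raise ArithmeticError("non-finite likelihood at fitted parameters")
        return candidates[best]
    except Exception:
        logger.warning("model optimization failed; falling back to JC parameters")
        return SubstitutionModel.jc()


def score_all_neighbors(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    moves: list[SPRMove],
    tol: float = 1e-4,
    max_sweeps: int = 8,
) -> list[tuple[SPRMove, float]]:
    """True log-likelihood labels for a list of SPR moves.

    Each move is applied and the resulting tree's branch lengths are
    re-optimized with the substitution-model parameters held fixed (they are
    fit once on the starting tree).
    """
    out = []
    for move in moves:
        neighbor = apply_spr(tree, move)
        res = optimize_branch_lengths(neighbor, aln, model, tol=tol, max_sweeps=max_sweeps)
        out.append((move, res.log_likelihood))
    return out
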