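"""Phylogenetic signal and ancestral reconstruction of network traits.

Whole-network parameters (N, K, D, C, L, H, module count M) measured on
one network per taxon become continuous tip traits on a time-calibrated
phylogeny.  Under Brownian motion (BM) a trait accrues independent
normal increments along each branch, so tip values are multivariate
normal with covariance C_ij equal to the shared root-to-MRCA path
length of tips i and j.

Two standard signal statistics are provided:

* **Pagel's lambda** multiplies the off-diagonal entries of C by a
  factor in [0, 1]: lambda = 0 means phylogenetic independence,
  lambda = 1 the full BM expectation.  It is estimated by maximum
  likelihood and tested with a likelihood-ratio test against
  lambda = 0.
* **Blomberg's K** compares the observed ratio of the tip-variance
  around the phylogenetic mean to the GLS mean-square error with its
  BM expectation; K ~ 1 under BM, K ~ 0 without signal.  Significance
  comes from tip-label permutations of the MSE.

Ancestral states at internal nodes are the generalized-least-squares
(equivalently ML / empirical-Bayes under BM) estimates, with 95%
confidence bands, and can be exported as a phenogram — the tree drawn
in (time from root, trait value) coordinates.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "BMFit",
    "PhyloSignalResult",
    "AncestralStates",
    "read_newick",
    "write_newick",
    "normalize_taxon",
    "align_traits",
    "bm_covariance",
    "lambda_transform",
    "fit_bm",
    "fit_pagel_lambda",
    "blomberg_k",
    "ancestral_states",
    "phenogram_export",
]


# ---------------------------------------------------------------------------
# tree I/O and trait alignment
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; branch lengths are required.

    Comments in square brackets are ignored by the parser.  A missing
    branch length on any non-root edge is an error because every
    downstream computation needs path lengths in time units.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a branch without a length")
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def normalize_taxon(name: str) -> str:
    """Case-insensitive, underscore-equals-space taxon name key."""
    return " ".join(name.strip().lower().replace("_", " ").split())


def align_traits(x: Mapping[str, float], tree: dendropy.Tree) -> np.ndarray:
    """Order a taxon → value mapping to the tree's tip order.

    Matching is case-insensitive and treats underscores as spaces; if a
    tip fails to match, a genus-only (first word) match is attempted
    with a warning.  Any remaining mismatch raises.
    """
    table = {normalize_taxon(k): float(v) for k, v in x.items()}
    genus_table: dict[str, list[float]] = {}
    for k, v in x.items():
        genus_table.setdefault(normalize_taxon(k).split()[0], []).append(float(v))

    out = []
    for label in tip_labels(tree):
        key = normalize_taxon(label)
        if key in table:
            out.append(table[key])
            continue
        genus = key.split()[0]
        if genus in genus_table and len(genus_table[genus]) == 1:
            warnings.warn(
                f"tip {label!r} matched trait table by genus only", stacklevel=2
            )
            out.append(genus_table[genus][0])
            continue
        raise KeyError(f"no trait value for tip {label!r}")
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# Brownian-motion covariance
# ---------------------------------------------------------------------------

def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def bm_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip covariance matrix under Brownian motion (unit rate).

    Entry (i, j) is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip distances.  Returns the tip labels in
    matrix order together with the matrix.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    if n == 0:
        raise ValueError("tree has no tips")
    index = {leaf: i for i, leaf in enumerate(leaves)}
    cov = np.zeros((n, n))
    for leaf in leaves:
        cov[index[leaf], index[leaf]] = depths[leaf]

    # postorder: tips of different child subtrees share this node as MRCA
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [index[node]]
            continue
        kids = [below[c] for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        cov[i, j] = cov[j, i] = d
        below[node] = [i for kid in kids for i in kid]
    if max(depths[leaf] for leaf in leaves) <= 0:
        raise ValueError("tree has zero total depth")
    return [leaf.taxon.label for leaf in leaves], cov


def lambda_transform(cov: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's transform: scale off-diagonal covariances by ``lam``."""
    out = cov * lam
    np.fill_diagonal(out, np.diag(cov))
    return out


# ---------------------------------------------------------------------------
# Brownian-motion ML fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BMFit:
    """ML estimates of the BM rate and root state.

    ``sigma2`` is the ML (divide-by-n) rate estimate, ``mu`` the GLS
    root state, ``loglik`` the exact multivariate-normal log-likelihood
    at the optimum.  ``degenerate`` flags a constant trait (sigma2 = 0,
    likelihood unbounded).
    """

    sigma2: float
    mu: float
    loglik: float
    degenerate: bool = False


def fit_bm(x: np.ndarray, cov: np.ndarray) -> BMFit:
    """Closed-form ML fit of Brownian motion given a tip covariance.

    mu_hat = (1' C^-1 x) / (1' C^-1 1);
    sigma2_hat = (x - mu_hat)' C^-1 (x - mu_hat) / n.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 tips")
    try:
        chol = cho_factor(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is singular") from exc
    ones = np.ones(n)
    ci_one = cho_solve(chol, ones)
    ci_x = cho_solve(chol, x)
    mu = float(ones @ ci_x / (ones @ ci_one))
    resid = x - mu
    sigma2 = float(resid @ cho_solve(chol, resid) / n)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    if sigma2 <= 0:
        return BMFit(sigma2=0.0, mu=mu, loglik=np.inf, degenerate=True)
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return BMFit(sigma2=sigma2, mu=mu, loglik=float(loglik))


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloSignalResult:
    """Outcome of a phylogenetic signal test.

    ``method`` is ``"lambda"`` or ``"K"``.  For lambda the p-value is a
    likelihood-ratio test against lambda = 0 and both log-likelihoods
    are kept; for K it is a tip-permutation p-value and the permutation
    count is kept.
    """

    method: str
    estimate: float
    p_value: float
    null_loglik: float | None = None
    alt_loglik: float | None = None
    n_permutations: int | None = None


def _lambda_max(cov: np.ndarray) -> float:
    """Largest lambda keeping every diagonal >= every same-row off-diagonal."""
    n = cov.shape[0]
    off = cov - np.diag(np.diag(cov))
    ratios = []
    for i in range(n):
        m = off[i].max()
        if m > 0:
            ratios.append(cov[i, i] / m)
    return float(min(ratios)) if ratios else 1.0


def fit_pagel_lambda(
    x: Mapping[str, float] | np.ndarray,
    tree: dendropy.Tree,
    allow_above_one: bool = False,
    boundary_mixture: bool = False,
) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio p-value.

    The profile likelihood is maximized over lambda in [0, 1] (or up to
    the largest value keeping the transformed covariance valid when
    ``allow_above_one``) by bounded scalar optimization (tol 1e-8).
    The p-value tests lambda-hat against lambda = 0 with chi-square(1)
    on the likelihood ratio; ``boundary_mixture=True`` instead uses the
    50:50 point-mass/chi-square boundary null.
    """
    labels, cov = bm_covariance(tree)
    xv = align_traits(x, tree) if isinstance(x, Mapping) else np.asarray(x, dtype=float)
    if xv.size != len(labels):
        raise ValueError("trait vector length does not match tip count")
    if xv.size < 3:
        raise ValueError("need at least 3 tips for a lambda test")
    if np.allclose(xv, xv[0]):
        raise ValueError("trait is constant; lambda is unidentifiable")

    upper = min(_lambda_max(cov), 2.0) if allow_above_one else 1.0

    def nll(lam: float) -> float:
        try:
            return -fit_bm(xv, lambda_transform(cov, lam)).loglik
        except ValueError:
            # at the extreme transform the covariance can degenerate
            return np.inf

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, upper), method="bounded", options={"xatol": 1e-8}
    )
    lam_hat = float(res.x)
    # the bounded optimizer never evaluates the exact endpoints; snap to
    # whichever endpoint wins if it beats the interior optimum
    candidates = {lam_hat: float(res.fun), 0.0: nll(0.0), upper: nll(upper)}
    lam_hat = min(candidates, key=lambda lam: (candidates[lam], lam))

    alt_ll = -candidates[lam_hat]
    null_ll = -candidates[0.0]
    lr = max(0.0, 2.0 * (alt_ll - null_ll))
    p = float(stats.chi2.sf(lr, df=1))
    if boundary_mixture:
        p = 0.5 * p if lr > 0 else 1.0
    return PhyloSignalResult(
        method="lambda", estimate=lam_hat, p_value=p,
        null_loglik=null_ll, alt_loglik=alt_ll,
    )


def blomberg_k(
    x: Mapping[str, float] | np.ndarray,
    tree: dendropy.Tree,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Blomberg's K with a tip-label permutation p-value.

    K = (MSE0 / MSE)_observed / (MSE0 / MSE)_expected, where MSE0 is
    the tip variance around the phylogenetic (GLS) mean, MSE the GLS
    mean-square error under the BM covariance C, and the expected ratio
    is (tr C - n / sum(C^-1)) / (n - 1).  The p-value is the fraction
    of tip permutations whose MSE is <= the observed one (signal means
    a small MSE), counting the observed arrangement itself, so
    p >= 1 / (n_perm + 1).
    """
    if seed is None:
        raise ValueError("a permutation seed is required for reproducibility")
    labels, cov = bm_covariance(tree)
    xv = align_traits(x, tree) if isinstance(x, Mapping) else np.asarray(x, dtype=float)
    n = xv.size
    if n != len(labels):
        raise ValueError("trait vector length does not match tip count")
    if np.allclose(xv, xv[0]):
        raise ValueError("trait is constant; K is undefined")

    chol = cho_factor(cov)
    ones = np.ones(n)
    ci_one = cho_solve(chol, ones)
    s1 = float(ones @ ci_one)
    cinv = cho_solve(chol, np.eye(n))

    def mse_pair(v: np.ndarray) -> tuple[float, float]:
        mu = float(ones @ (cinv @ v) / s1)
        r = v - mu
        return float(r @ r / (n - 1)), float(r @ cinv @ r / (n - 1))

    mse0_obs, mse_obs = mse_pair(xv)
    expected = (np.trace(cov) - n / s1) / (n - 1)
    k_stat = (mse0_obs / mse_obs) / expected

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(xv) for _ in range(n_perm)])
    y = perms @ cinv
    qf = np.einsum("ij,ij->i", y, perms)
    sx = y @ ones  # row sums of permuted x' C^-1
    mse_perm = (qf - sx**2 / s1) / (n - 1)
    p = (1 + int(np.sum(mse_perm <= mse_obs + 1e-12))) / (n_perm + 1)
    return PhyloSignalResult(
        method="K", estimate=float(k_stat), p_value=float(p), n_permutations=n_perm
    )


# ---------------------------------------------------------------------------
# ancestral states and phenogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeState:
    """One node of a reconstructed phenogram."""

    id: str
    parent: str | None
    time: float  # distance from root
    estimate: float
    ci_low: float
    ci_high: float
    is_tip: bool


@dataclass(frozen=True)
class AncestralStates:
    """GLS/ML ancestral reconstruction of one trait on one tree.

    ``nodes`` lists every node with its time-from-root coordinate,
    state estimate, and 95% CI (tips carry their observed value with a
    zero-width interval).  ``segments`` yields the phenogram line
    segments connecting each non-root node to its parent.
    """

    nodes: tuple[NodeState, ...]
    fit: BMFit
    trait: str = ""

    def segments(self) -> list[tuple[NodeState, NodeState]]:
        by_id = {n.id: n for n in self.nodes}
        return [(by_id[n.parent], n) for n in self.nodes if n.parent is not None]

    def internal(self) -> list[NodeState]:
        return [n for n in self.nodes if not n.is_tip]


def _node_id(node: dendropy.Node, counter: dict) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    counter["i"] += 1
    return f"node{counter['i']}"


def ancestral_states(
    x: Mapping[str, float] | np.ndarray,
    tree: dendropy.Tree,
    trait: str = "",
) -> AncestralStates:
    """ML ancestral state reconstruction under Brownian motion.

    Each internal node's state is the GLS (BLUP) conditional
    expectation given the tip data, with prediction variance including
    the uncertainty of the estimated root state:

        z_hat(u) = mu_hat + a' C^-1 (x - mu_hat 1)
        var(u) = sigma2 * ( c_uu - a' C^-1 a
                            + (1 - 1' C^-1 a)^2 / (1' C^-1 1) )

    where ``a`` holds the shared-path covariances between node u and
    every tip.  The 95% CI is the estimate +/- 1.96 sqrt(var).
    """
    labels, cov = bm_covariance(tree)
    xv = align_traits(x, tree) if isinstance(x, Mapping) else np.asarray(x, dtype=float)
    fit = fit_bm(xv, cov)
    sigma2 = fit.sigma2

    chol = cho_factor(cov)
    ones = np.ones(xv.size)
    ci_one = cho_solve(chol, ones)
    s1 = float(ones @ ci_one)
    ci_resid = cho_solve(chol, xv - fit.mu)

    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    leaf_index = {leaf: i for i, leaf in enumerate(leaves)}

    # descendant tip sets, for MRCA-by-ascent covariance to the tips
    below: dict[dendropy.Node, set] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {leaf_index[node]}
        else:
            below[node] = set().union(*(below[c] for c in node.child_nodes()))

    counter = {"i": 0}
    ids: dict[dendropy.Node, str] = {}
    records: list[NodeState] = []
    for node in tree.preorder_node_iter():
        ids[node] = _node_id(node, counter)
        parent = ids[node.parent_node] if node.parent_node is not None else None
        time = depths[node]
        if node.is_leaf():
            val = xv[leaf_index[node]]
            records.append(NodeState(ids[node], parent, time, float(val),
                                     float(val), float(val), True))
            continue
        # cov between this node and each tip: depth of their MRCA, found
        # by ascending from the node until the tip is among descendants
        a = np.empty(xv.size)
        for leaf, i in leaf_index.items():
            anc = node
            while i not in below[anc]:
                anc = anc.parent_node
            a[i] = depths[anc]
        est = float(fit.mu + a @ ci_resid)
        ci_a = cho_solve(chol, a)
        var = sigma2 * (depths[node] - float(a @ ci_a)
                        + (1.0 - float(ones @ ci_a)) ** 2 / s1)
        var = max(var, 0.0)
        half = 1.96 * np.sqrt(var)
        records.append(NodeState(ids[node], parent, time, est,
                                 est - half, est + half, False))
    return AncestralStates(nodes=tuple(records), fit=fit, trait=trait)


def phenogram_export(
    anc: AncestralStates,
    path: str | Path,
    figure_path: str | Path | None = None,
) -> None:
    """Write phenogram line segments as CSV, optionally with a figure.

    One row per non-root node: the segment from the parent's
    (time, state) point to the node's, with the node's 95% CI.  A
    companion ``*_quartiles.csv`` records the tip-value distribution
    (min, quartiles, max) used for the marginal box plot.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["node", "parent", "t0", "t1", "y0", "y1", "ci_low", "ci_high"])
        for parent, node in anc.segments():
            writer.writerow([
                node.id, parent.id,
                f"{parent.time:.10g}", f"{node.time:.10g}",
                f"{parent.estimate:.10g}", f"{node.estimate:.10g}",
                f"{node.ci_low:.10g}", f"{node.ci_high:.10g}",
            ])

    tips = np.array([n.estimate for n in anc.nodes if n.is_tip])
    qpath = path.with_name(path.stem + "_quartiles.csv")
    with open(qpath, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["stat", "value"])
        for name, q in zip(
            ["min", "q1", "median", "q3", "max"],
            np.quantile(tips, [0.0, 0.25, 0.5, 0.75, 1.0]),
        ):
            writer.writerow([name, f"{q:.10g}"])

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for parent, node in anc.segments():
            ax.plot([parent.time, node.time], [parent.estimate, node.estimate],
                    color="steelblue", lw=1)
            if not node.is_tip:
                ax.fill_between([parent.time, node.time],
                                [parent.ci_low, node.ci_low],
                                [parent.ci_high, node.ci_high],
                                color="steelblue", alpha=0.15, lw=0)
        ax.set_xlabel("time from root")
        ax.set_ylabel(anc.trait or "trait")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
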