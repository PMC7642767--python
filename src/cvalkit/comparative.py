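"""Phylogenetic signal in continuous traits (genome size on a tree).

Under Brownian motion, tip trait values are multivariate normal with a
covariance C whose entry C_ij is the shared root-to-tip path length of
tips i and j.  Two standard signal statistics are implemented:

* Pagel's lambda — a multiplier on the off-diagonal of C, profiled over
  [0, 1] by maximum likelihood (closed-form GLS for root state and rate
  at each lambda).  lambda = 1 means full Brownian dependence on the
  tree, lambda = 0 phylogenetic independence.
* Blomberg's K — the ratio of observed to Brownian-expected trait
  "mean squared error" contrast; K = 1 matches Brownian expectation,
  K > 1 means relatives are more similar than Brownian motion predicts.
  Significance comes from permuting tip-to-value assignments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import (
    EstimationError,
    LambdaUnidentifiableError,
    ValidationError,
)

ZERO_BRANCH_FRACTION = 1e-8   # perturbation for zero-length tip branches
CHOLESKY_JITTER = 1e-10       # diagonal jitter fallback for near-singular C
LAMBDA_XATOL = 1e-6


@dataclass
class LambdaFit:
    lambda_hat: float
    sigma2_hat: float
    root_hat: float
    logl_max: float
    logl_lambda0: float
    logl_lambda1: float
    p_vs_lambda0: float
    p_vs_lambda1: float


@dataclass
class KResult:
    k: float
    p_perm: float
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def load_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree (path or string) with branch lengths."""
    def _is_path(s) -> bool:
        try:
            return Path(str(s)).exists()
        except OSError:  # e.g. a long newick string
            return False

    try:
        if isinstance(source, dendropy.Tree):
            tree = source
        elif isinstance(source, (str, Path)) and _is_path(source):
            tree = dendropy.Tree.get(path=str(source), schema="newick")
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        raise ValidationError(f"tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValidationError("tree: at least 2 tips required")
    if len(set(labels)) != len(labels):
        raise ValidationError("tree: duplicate tip labels")
    return tree


def vcv(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Shared-path-length (Brownian) covariance matrix and tip labels.

    C_ij is the root-to-MRCA depth of tips i and j; C_ii the root-to-tip
    distance.  Zero-length terminal branches are perturbed by
    1e-8 * tree depth with a warning so C stays non-singular.
    """
    tree = load_tree(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(leaves)

    # depth of every node from the root; a stem edge above the root is
    # ignored (its covariance is shared by all tips and confounded with
    # the root state — the standard comparative-methods convention)
    depth: dict = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        if edge < 0:
            raise ValidationError("tree: negative branch length")
        depth[node] = (depth[node.parent_node] + edge
                       if node.parent_node else 0.0)
    tree_depth = max(depth[l] for l in leaves)
    for leaf in leaves:
        if (leaf.edge.length or 0.0) == 0.0:
            warnings.warn("zero-length terminal branch perturbed by "
                          f"{ZERO_BRANCH_FRACTION} * tree depth", stacklevel=2)
            depth[leaf] += ZERO_BRANCH_FRACTION * (tree_depth or 1.0)

    index = {leaf: i for i, leaf in enumerate(leaves)}
    C = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        C[i, i] = depth[leaf]
    # tips in different child subtrees of a node share that node's depth
    for node in tree.postorder_internal_node_iter():
        child_tipsets = [[index[l] for l in ch.leaf_iter()]
                         for ch in node.child_nodes()]
        d = depth[node]
        for a in range(len(child_tipsets)):
            for b_ in range(a + 1, len(child_tipsets)):
                for i in child_tipsets[a]:
                    for j in child_tipsets[b_]:
                        C[i, j] = C[j, i] = d
    return C, labels


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal entries of C by lambda, keeping the diagonal."""
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def align_trait(traits: dict[str, float], labels: Sequence[str],
                normalize: bool = True) -> np.ndarray:
    """Order a species -> value mapping to match the tip labels.

    With ``normalize`` set, underscores and spaces in names are treated
    as interchangeable.
    """
    def norm(s: str) -> str:
        return s.replace("_", " ") if normalize else s

    lookup = {norm(k): float(v) for k, v in traits.items()}
    missing = [lab for lab in labels if norm(lab) not in lookup]
    if missing:
        raise ValidationError(f"trait values missing for tips: {missing}")
    x = np.array([lookup[norm(lab)] for lab in labels])
    if not np.all(np.isfinite(x)):
        raise ValidationError("trait values must be finite")
    return x


def read_trait_csv(path) -> dict[str, float]:
    import pandas as pd

    df = pd.read_csv(path)
    cols = list(df.columns)
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _chol(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn(f"covariance nearly singular; adding {CHOLESKY_JITTER} "
                      "diagonal jitter", stacklevel=2)
        try:
            return cho_factor(C + CHOLESKY_JITTER * np.eye(len(C)), lower=True)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                "covariance matrix is singular (identical root-to-tip "
                "paths for two or more tips?)") from exc


def bm_loglik(x: np.ndarray, C: np.ndarray, sigma2: float, root: float) -> float:
    """Multivariate-normal log density of tip values under Brownian motion.

    Mean root * 1, covariance sigma2 * C; computed via a Cholesky
    factorization, never an explicit inverse.
    """
    if sigma2 <= 0:
        raise ValidationError("sigma2: must be > 0")
    x = np.asarray(x, float)
    n = x.size
    cf = _chol(C)
    resid = x - root
    quad = float(resid @ cho_solve(cf, resid)) / sigma2
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0])))) + n * math.log(sigma2)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def _profile(x: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Closed-form GLS root and ML sigma2 for a fixed covariance structure.

    Returns (logL, sigma2_hat, root_hat).
    """
    n = x.size
    cf = _chol(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    root = float(ones @ cho_solve(cf, x)) / float(ones @ Ci1)
    resid = x - root
    sigma2 = float(resid @ cho_solve(cf, resid)) / n
    if sigma2 <= 0:
        raise EstimationError("trait variance is zero under the model")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    logl = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return logl, sigma2, root


def fit_lambda(tree, traits: dict[str, float]) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda on [0, 1].

    For each lambda the root state and rate have closed-form GLS/ML
    solutions, so the likelihood is profiled over a single bounded
    scalar; endpoint likelihood-ratio tests (chi-squared, 1 df) compare
    the optimum against lambda = 0 and lambda = 1.
    """
    C, labels = vcv(tree)
    if len(labels) < 4:
        raise ValidationError("fit_lambda: at least 4 tips required")
    off = C[~np.eye(len(labels), dtype=bool)]
    if np.allclose(off, 0.0):
        raise LambdaUnidentifiableError(
            "star phylogeny: lambda has no effect on the covariance")
    x = align_trait(traits, labels)

    def neg(lam: float) -> float:
        return -_profile(x, lambda_transform(C, lam))[0]

    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": LAMBDA_XATOL})
    logl0 = _profile(x, lambda_transform(C, 0.0))[0]
    logl1, s2_1, root_1 = _profile(x, lambda_transform(C, 1.0))
    cands = [(logl0, 0.0), (logl1, 1.0), (-res.fun, float(res.x))]
    logl_max, lam_hat = max(cands, key=lambda t: t[0])
    _, sigma2_hat, root_hat = _profile(x, lambda_transform(C, lam_hat))
    p0 = float(chi2.sf(2.0 * (logl_max - logl0), 1))
    p1 = float(chi2.sf(2.0 * (logl_max - logl1), 1))
    return LambdaFit(lambda_hat=lam_hat, sigma2_hat=sigma2_hat,
                     root_hat=root_hat, logl_max=logl_max,
                     logl_lambda0=logl0, logl_lambda1=logl1,
                     p_vs_lambda0=p0, p_vs_lambda1=p1)


def _k_statistic(x: np.ndarray, C: np.ndarray) -> float:
    n = x.size
    cf = _chol(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    denom_1C1 = float(ones @ Ci1)
    a_hat = float(ones @ cho_solve(cf, x)) / denom_1C1
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ cho_solve(cf, resid)) / (n - 1)
    if mse == 0:
        raise EstimationError("constant trait: K undefined")
    expected = (float(np.trace(C)) - n / denom_1C1) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree, traits: dict[str, float]) -> float:
    """Blomberg's K: observed / Brownian-expected similarity ratio."""
    C, labels = vcv(tree)
    if len(labels) < 4:
        raise ValidationError("blomberg_k: at least 4 tips required")
    x = align_trait(traits, labels)
    return _k_statistic(x, C)


def k_permutation_p(tree, traits: dict[str, float], n_perm: int = 999,
                    seed: int = 0) -> KResult:
    """Permutation p-value for Blomberg's K (add-one estimator).

    Tip-to-value assignments are shuffled with a seeded generator;
    p = (1 + #{permuted K >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("n_perm: must be >= 99")
    C, labels = vcv(tree)
    x = align_trait(traits, labels)
    if np.ptp(x) == 0:
        raise EstimationError("constant trait: permutation test undefined")
    observed = _k_statistic(x, C)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += _k_statistic(rng.permutation(x), C) >= observed
    p = (1 + exceed) / (n_perm + 1)
    return KResult(k=observed, p_perm=float(p), n_perm=n_perm, seed=seed)


def phylo_signal_report(tree, traits: dict[str, float], n_perm: int = 999,
                        seed: int = 0) -> dict:
    """Lambda fit + K with permutation test, as a JSON-ready dict."""
    fit = fit_lambda(tree, traits)
    kres = k_permutation_p(tree, traits, n_perm=n_perm, seed=seed)
    return {
        "lambda_hat": fit.lambda_hat,
        "sigma2_hat": fit.sigma2_hat,
        "root_hat": fit.root_hat,
        "logl_max": fit.logl_max,
        "logl_lambda0": fit.logl_lambda0,
        "logl_lambda1": fit.logl_lambda1,
        "p_vs_lambda0": fit.p_vs_lambda0,
        "p_vs_lambda1": fit.p_vs_lambda1,
        "K": kres.k,
        "p_perm": kres.p_perm,
        "n_perm": kres.n_perm,
        "seed": kres.seed,
    }
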