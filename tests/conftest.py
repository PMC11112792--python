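"""Shared helpers: seeded random chronograms and reference oracles.

All stochastic tests draw their seeds from SEED = 1234 so the suite is
fully deterministic.
"""

import numpy as np
import pytest

from latdiv.simulate import simulate_bd_tree
from latdiv.niche import _prune_to

SEED = 1234


def random_yule_tree(seed, min_tips=4, max_tips=300, lam=0.5, crown=8.0):
    tree, _ = simulate_bd_tree(
        lam, 0.0, crown, min_tips=min_tips, max_tips=max_tips, seed=seed
    )
    return tree


def random_bd_tree(seed, lam=0.4, mu=0.15, crown=10.0, min_tips=10, max_tips=500):
    tree, _ = simulate_bd_tree(
        lam, mu, crown, min_tips=min_tips, max_tips=max_tips, seed=seed
    )
    return tree


def prune_to_size(tree, size, seed):
    """Randomly subsample an ultrametric tree to exactly `size` tips."""
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(tree.tip_labels, size=size, replace=False))
    return _prune_to(tree, keep)


def dr_bruteforce(chrono):
    """Independent DR oracle: explicit enumeration of each root-to-tip
    path using edge lengths, summing l_j * 2**-(j-1) term by term."""
    chrono.copy_with_recomputed_edges()
    out = {}
    for leaf in chrono.tree.leaf_node_iter():
        path = []
        nd = leaf
        while nd.parent_node is not None:
            path.append(float(nd.edge.length))
            nd = nd.parent_node
        es = sum(l * 2.0 ** (-j) for j, l in enumerate(path))
        out[leaf.taxon.label] = 1.0 / es
    return out


def gls_ancestral_oracle(chrono, trait):
    """Dense covariance-matrix GLS reconstruction (independent oracle).

    Builds C explicitly from pairwise MRCA ages, inverts it, and computes
    the root as (1'C^-1 1)^-1 1'C^-1 x and each internal node's state as
    the conditional expectation root + c' C^-1 (x - root).
    """
    tips = chrono.tip_labels
    n = len(tips)
    tc = chrono.crown_age
    C = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            C[i, j] = tc if i == j else tc - chrono.divergence_time(a, b)
    x = np.array([trait[t] for t in tips])
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    root = (one @ Ci @ x) / (one @ Ci @ one)
    sigma2 = (x - root) @ Ci @ (x - root) / n
    est, var = {}, {}
    for nd in chrono.tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            est[nd.node_id] = root
            var[nd.node_id] = sigma2 / (one @ Ci @ one)
            continue
        below = {l.taxon.label for l in nd.leaf_iter()}
        ref = next(iter(below))
        cv = np.array(
            [
                tc - nd.age_ma if a in below else tc - chrono.divergence_time(a, ref)
                for a in tips
            ]
        )
        w = cv @ Ci
        h = one @ Ci @ one
        est[nd.node_id] = root + w @ (x - root)
        var[nd.node_id] = sigma2 * ((tc - nd.age_ma) - w @ cv + (1 - w @ one) ** 2 / h)
    return root, sigma2, est, var


def nee_crown_loglik(chrono, lam, mu):
    """Closed-form crown-conditioned constant-rate birth-death
    log-likelihood (f = 1), coded independently of the ODE machinery."""
    r = lam - mu

    def E(t):
        return mu * (1 - np.exp(-r * t)) / (lam - mu * np.exp(-r * t))

    def D(t):
        return np.exp(-r * t) * ((lam - mu) / (lam - mu * np.exp(-r * t))) ** 2

    ll = 0.0
    for nd in chrono.tree.preorder_node_iter():
        if nd.parent_node is not None:
            ll += np.log(D(nd.parent_node.age_ma)) - np.log(D(nd.age_ma))
        if not nd.is_leaf():
            ll += np.log(lam)
    return ll - 2 * np.log(1 - E(chrono.crown_age))
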