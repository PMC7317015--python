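"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive — dense matrices, explicit loops,
closed-form conditional Gaussians — and shares no code with the package
implementation it checks.
"""

import numpy as np
import pandas as pd


def naive_kinship(genotypes: np.ndarray, p: np.ndarray):
    """Kinship by explicit double loop over varieties and markers."""
    n, L = genotypes.shape
    b = sum(p[l] * (1 - p[l]) for l in range(L))
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = sum((genotypes[i, l] - p[l]) * (genotypes[j, l] - p[l])
                          for l in range(L)) / b
    return K, b


def heading_day_loop(P, SLDL, tmean, dl, t_base=0.0, tt_e=120.0, hs_flag=4.0,
                     dl_sat=15.0, l_min=8.0, l_max=24.0, k_head=2.5):
    """Day-by-day accumulation loop for the phenology model."""
    tt = 0.0
    dl_star = None
    lf = None
    for d in range(len(tmean)):
        tt += max(0.0, tmean[d] - t_base)
        hs = (tt - tt_e) / P
        if dl_star is None and hs >= hs_flag:
            dl_star = dl[d]
            lf = min(max(l_min + SLDL * max(0.0, dl_sat - dl_star), l_min), l_max)
        if lf is not None and hs >= lf + k_head:
            return d + 1
    raise RuntimeError("heading not reached")


def dense_gei(met_records, test_cells, spec, K, Kids, Sigma_full, Wids,
              g_g, g_ge, sigma2_e, hd_scaling=None):
    """Dense-V GLS / conditional-Gaussian evaluation of a GEI model at
    fixed variance ratios.

    Returns loglik (REML), fixed-effect estimates, BLUPs of G for the
    training varieties, and predictions for ``test_cells``
    (variety_id, env_id, hd, plus alpha/beta overrides for new envs via
    columns 'alpha_new'/'beta_new').
    """
    rec = met_records
    env_ids = list(pd.unique(rec["env_id"]))
    var_ids = [v for v in Kids if v in set(rec["variety_id"])]
    kmap = {v: i for i, v in enumerate(Kids)}
    emap_w = {e: i for i, e in enumerate(Wids)} if Wids is not None else None
    vmap = {v: i for i, v in enumerate(var_ids)}
    emap = {e: i for i, e in enumerate(env_ids)}
    N = len(rec)
    vi = rec["variety_id"].map(vmap).to_numpy()
    ei = rec["env_id"].map(emap).to_numpy()
    y = rec["gy"].to_numpy(float)
    E = len(env_ids)

    # fixed design
    if spec.hd_covariate != "none":
        h, h2 = hd_scaling.transform(rec["hd"].to_numpy(float))
    cols = [np.zeros((N, E))]
    cols[0][np.arange(N), ei] = 1.0
    if spec.hd_covariate != "none":
        Z = np.zeros((N, E)); Z[np.arange(N), ei] = h
        cols.append(Z)
    if spec.hd_covariate == "quadratic":
        Z = np.zeros((N, E)); Z[np.arange(N), ei] = h2
        cols.append(Z)
    X = np.column_stack(cols)
    p = X.shape[1]

    Ksub = K[np.ix_([kmap[v] for v in var_ids], [kmap[v] for v in var_ids])]

    def sig(a, b):
        v = g_g * Ksub[vi[a], vi[b]]
        if spec.has_ge:
            e_a = emap_w[env_ids[ei[a]]] if emap_w else ei[a]
            e_b = emap_w[env_ids[ei[b]]] if emap_w else ei[b]
            v += g_ge * Ksub[vi[a], vi[b]] * Sigma_full[e_a, e_b]
        return v

    V = np.zeros((N, N))
    for a in range(N):
        for b in range(N):
            V[a, b] = sig(a, b)
    V = sigma2_e * (V + np.eye(N))
    Vi = np.linalg.inv(V)
    Cxx = X.T @ Vi @ X
    bhat = np.linalg.solve(Cxx, X.T @ Vi @ y)
    r = y - X @ bhat
    _, ldV = np.linalg.slogdet(V)
    _, ldC = np.linalg.slogdet(Cxx)
    loglik = -0.5 * (ldV + ldC + r @ Vi @ r + (N - p) * np.log(2 * np.pi))

    air = Vi @ r
    # G BLUP for training varieties
    G = np.zeros(len(var_ids))
    for i in range(len(var_ids)):
        cov = g_g * sigma2_e * Ksub[i, vi]
        G[i] = cov @ air

    preds = []
    for _, row in test_cells.iterrows():
        iv = kmap[row["variety_id"]]
        env = row["env_id"]
        if env in emap:
            j = emap[env]
            fixed = bhat[j]
            a_j = bhat[E + j] if spec.hd_covariate != "none" else 0.0
            b_j = bhat[2 * E + j] if spec.hd_covariate == "quadratic" else 0.0
        else:
            fixed = bhat[:E].mean()
            a_j = row.get("alpha_new", 0.0)
            b_j = row.get("beta_new", 0.0)
        if spec.hd_covariate != "none":
            ht, h2t = hd_scaling.transform(np.array([float(row["hd"])]))
            fixed = fixed + a_j * ht[0]
            if spec.hd_covariate == "quadratic":
                fixed = fixed + b_j * h2t[0]
        # conditional expectation of the random part
        cov = np.zeros(N)
        for a in range(N):
            c = g_g * K[iv, kmap[var_ids[vi[a]]]]
            if spec.has_ge:
                e_t = emap_w[env] if emap_w else (emap[env] if env in emap else None)
                e_a = emap_w[env_ids[ei[a]]] if emap_w else ei[a]
                if e_t is not None:
                    c += g_ge * K[iv, kmap[var_ids[vi[a]]]] * Sigma_full[e_t, e_a]
            cov[a] = sigma2_e * c
        preds.append(fixed + cov @ air)
    return {"loglik": loglik, "bhat": bhat, "G": G, "preds": np.array(preds),
            "var_ids": var_ids, "env_ids": env_ids}


def exhaustive_best_subset(y, X_all: pd.DataFrame, candidates, k):
    """Best subset of the screened candidates under
    crit = n log(RSS/n) + k p (p counts coefficients incl. intercept)."""
    from itertools import combinations

    n = len(y)
    best = (np.inf, ())
    for size in range(len(candidates) + 1):
        for sub in combinations(candidates, size):
            X = np.column_stack([np.ones(n)] +
                                ([X_all[list(sub)].to_numpy()] if sub else []))
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            crit = n * np.log(max(rss, 1e-300) / n) + k * (size + 1)
            if crit < best[0] - 1e-12:
                best = (crit, tuple(sorted(sub)))
    return best


def founder_panel(n, L, n_founders=10, n_breaks=2, seed=0):
    """Haplotype-mosaic marker panel with strong LD (elite-program
    style): each line copies segments from a small founder set."""
    rng = np.random.default_rng(seed)
    founders = (rng.random((n_founders, L)) < rng.uniform(0.1, 0.5, L)).astype(float)
    g = np.empty((n, L))
    for i in range(n):
        bps = np.sort(rng.integers(1, L, size=n_breaks))
        for seg in np.split(np.arange(L), bps):
            g[i, seg] = founders[rng.integers(n_founders), seg]
    return g
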