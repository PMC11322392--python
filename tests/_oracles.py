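"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the statistical quantities through explicit
projection matrices and cell-mean arithmetic, sharing no code with the
package implementation.
"""

import numpy as np


def _sum_code(labels):
    """Sum-to-zero coding built from one-hot columns (independent
    construction from the implementation's)."""
    levels = sorted(set(labels))
    onehot = np.stack([np.asarray(labels) == lev for lev in levels], axis=1)
    onehot = onehot.astype(float)
    return onehot[:, :-1] - onehot[:, -1:]


def _rss_proj(X, y):
    P = X @ np.linalg.pinv(X)
    r = y - P @ y
    return float(r @ r)


def brute_force_mixed(Y, g, s=None):
    """Split-plot group x within ANOVA by explicit projections.

    Returns dict effect -> (ss_effect, df1, ss_error, df2) matching the
    Type III / effect-coded estimands of the split-plot model with an
    optional additive sex factor.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    m = Y.mean(axis=1)
    one = np.ones((n, 1))
    Xg = _sum_code(g)
    blocks = {"group": Xg}
    if s is not None and len(set(s)) > 1:
        blocks["sex"] = _sum_code(s)
    X_full = np.hstack([one] + list(blocks.values()))
    rss_full = _rss_proj(X_full, m)
    df_be = n - X_full.shape[1]
    out = {}
    for name in blocks:
        X_red = np.hstack([one] + [b for nm, b in blocks.items() if nm != name])
        out[name] = ((_rss_proj(X_red, m) - rss_full) * k,
                     blocks[name].shape[1], rss_full * k, df_be)

    D = (Y - m[:, None]).ravel()
    mus = np.tile(np.arange(k), n)
    g_long = np.repeat(np.asarray(g), k)
    Xm = _sum_code(mus)
    Xgl = _sum_code(g_long)
    Xgm = np.concatenate([Xgl[:, [i]] * Xm for i in range(Xgl.shape[1])], axis=1)
    n_groups = len(set(g))
    full = np.hstack([Xm, Xgm])
    rss_w = _rss_proj(full, D)
    df_we = (k - 1) * (n - n_groups)
    out["muscle"] = (_rss_proj(Xgm, D) - rss_w, k - 1, rss_w, df_we)
    out["muscle x group"] = (_rss_proj(Xm, D) - rss_w,
                             (k - 1) * (n_groups - 1), rss_w, df_we)
    return out


def brute_force_two_way_rm(Y):
    """Two-way fully-within ANOVA (subject x A x B) from cell means.

    ``Y`` has shape (n, a, b). Returns dict effect -> (ss, df1, ss_err, df2).
    """
    Y = np.asarray(Y, dtype=float)
    n, a, b = Y.shape
    out = {}
    # effect SS from marginal means; error SS from subject-by-effect cells
    for name, axes_eff, axes_err in (("timepoint", 2, 2),
                                     ("muscle", 1, 1)):
        eff_means = Y.mean(axis=(0, axes_eff))
        ss_eff = n * Y.shape[axes_eff] * np.sum((eff_means - Y.mean()) ** 2)
        cells = Y.mean(axis=axes_err)  # (n, levels)
        resid = (cells - cells.mean(axis=0, keepdims=True)
                 - cells.mean(axis=1, keepdims=True) + Y.mean())
        ss_err = Y.shape[axes_eff] * np.sum(resid ** 2)
        df1 = cells.shape[1] - 1
        out[name] = (ss_eff, df1, ss_err, (n - 1) * df1)
    # interaction via full decomposition remainder
    ab = Y.mean(axis=0)
    ta = Y.mean(axis=(0, 2))
    tb = Y.mean(axis=(0, 1))
    ss_ab = n * np.sum((ab - ta[:, None] - tb[None, :] + Y.mean()) ** 2)
    ss_total = np.sum((Y - Y.mean()) ** 2)
    subj = Y.mean(axis=(1, 2))
    ss_subj = a * b * np.sum((subj - Y.mean()) ** 2)
    known = (ss_subj + out["timepoint"][0] + out["timepoint"][2]
             + out["muscle"][0] + out["muscle"][2] + ss_ab)
    ss_abs = ss_total - known
    out["timepoint x muscle"] = (ss_ab, (a - 1) * (b - 1), ss_abs,
                                 (n - 1) * (a - 1) * (b - 1))
    return out


def fine_grid_split_areas(times, values, n_grid=100_000):
    """Area above/below the zero line of a piecewise-linear curve by dense
    resampling, with crossings refined by bracketed root finding."""
    from scipy.optimize import brentq

    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    grid = np.linspace(t[0], t[-1], n_grid)
    yg = np.interp(grid, t, y)
    sign_change = yg[:-1] * yg[1:] < 0
    roots = [brentq(lambda x: np.interp(x, t, y), grid[i], grid[i + 1],
                    xtol=1e-14)
             for i in np.flatnonzero(sign_change)]
    ga = np.sort(np.concatenate([grid, roots, t]))
    ya = np.interp(ga, t, y)
    above = np.trapezoid(np.maximum(ya, 0.0), ga)
    below = -np.trapezoid(np.minimum(ya, 0.0), ga)
    return float(above), float(below)
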