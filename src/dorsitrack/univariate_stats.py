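"""Mixed-design repeated-measures ANOVA for the muscle-deformation study.

Three designs are covered: (1) group (WAD vs control) x muscle (five
within levels) at baseline, adjusted by sex; (2) the same between-group
design with the WAD follow-up data; (3) the within-subject timepoint x
muscle design in the WAD group. Sphericity is checked with Mauchly's test
and, when violated (p < 0.05), within-subject degrees of freedom are
scaled by the Greenhouse-Geisser epsilon. Effect sizes are partial
eta-squared, SS_effect / (SS_effect + SS_error). Post-hoc contrasts
collapse the five muscles to three anatomical levels (superficial =
TR + SP, middle = Scap, deep = Scerv + MF) and Bonferroni-correct the
three pairwise level-by-group interaction tests.

Sums of squares are computed by least-squares model comparison with
effect-coded factors (Type III), split into the between-subject stratum
(on subject means) and the within-subject stratum (on deviations from
subject means) — the strata are orthogonal because every subject has all
within levels. "Adjusted by sex" enters sex as an additive
between-subject factor with no interactions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MUSCLE_LEVELS, MUSCLES

logger = logging.getLogger(__name__)


class UnbalancedDesignError(ValueError):
    """A subject is missing one or more within-factor cells."""


@dataclass
class AnovaResult:
    """One effect of a repeated-measures ANOVA."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    epsilon_gg: float = 1.0
    mauchly_w: float = np.nan
    mauchly_p: float = np.nan
    corrected: bool = False

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ContrastResult:
    """One Bonferroni-corrected post-hoc level-by-group contrast."""

    contrast: tuple[str, str]
    F: float
    df1: float
    df2: float
    p_raw: float
    p_bonferroni: float
    eta_p2: float


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _effect_code(labels: np.ndarray) -> np.ndarray:
    """Effect (sum-to-zero) coding; (n, levels-1) columns."""
    levels = sorted(set(labels))
    n, k = len(labels), len(levels)
    X = np.zeros((n, k - 1))
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == levels[-1], :] = -1.0
    return X


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _pivot_wide(table: pd.DataFrame, dv: str, within: str = "muscle",
                within_levels: tuple = MUSCLES) -> tuple[np.ndarray, pd.DataFrame]:
    """Subjects x within-levels response matrix from a feature table.

    For ``within='muscle'`` the columns ``{m}_{dv}`` are used; subjects
    with any missing value raise :class:`UnbalancedDesignError`.
    """
    cols = [f"{m}_{dv}" for m in within_levels]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks columns {missing}")
    if table["subject"].duplicated().any():
        raise UnbalancedDesignError(
            "duplicate subject rows; filter to one timepoint/direction first")
    Y = table[cols].to_numpy(dtype=float)
    if not np.isfinite(Y).all():
        raise UnbalancedDesignError("missing cells in the within factor")
    return Y, table


def _sphericity(Y_resid: np.ndarray, df_e: int) -> tuple[float, float, float]:
    """(Mauchly W, Mauchly p, Greenhouse-Geisser epsilon) from residuals.

    ``Y_resid`` are within-subject responses with cell means removed,
    shape (n, k); ``df_e`` the residual degrees of freedom used for the
    covariance estimate.
    """
    n, k = Y_resid.shape
    if k == 2:
        return 1.0, 1.0, 1.0
    # orthonormal contrast basis (Helmert, normalized)
    C = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0][:, 1:]
    Z = Y_resid @ C
    S = Z.T @ Z / df_e
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.mean()
    if mean_eig <= 0:
        return 1.0, 1.0, 1.0
    W = float(np.prod(eig / mean_eig))
    d = k - 1
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * df_e)
    chi2 = -f * df_e * np.log(max(W, np.finfo(float).tiny))
    df_chi = d * (d + 1) / 2 - 1
    p = float(stats.chi2.sf(chi2, df_chi))
    eps = float(eig.sum() ** 2 / (d * (eig**2).sum()))
    eps = min(1.0, max(eps, 1.0 / d))
    return W, p, eps


def mauchly(Y: np.ndarray, groups: np.ndarray | None = None) -> tuple[float, float]:
    """Mauchly's sphericity test for a subjects x levels response matrix.

    Cell means (per between-group cell, if given) are removed before
    estimating the contrast covariance. With two within levels sphericity
    holds trivially (W = 1, p = 1).
    """
    Y = np.asarray(Y, dtype=float)
    resid, df_e = _remove_cell_means(Y, groups)
    w, p, _ = _sphericity(resid, df_e)
    return w, p


def greenhouse_geisser(Y: np.ndarray, groups: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser epsilon estimate; in [1/(k-1), 1]."""
    Y = np.asarray(Y, dtype=float)
    resid, df_e = _remove_cell_means(Y, groups)
    return _sphericity(resid, df_e)[2]


def _remove_cell_means(Y: np.ndarray, groups: np.ndarray | None):
    if groups is None:
        return Y - Y.mean(axis=0), Y.shape[0] - 1
    groups = np.asarray(groups)
    resid = Y.astype(float).copy()
    n_cells = 0
    for g in np.unique(groups):
        m = groups == g
        resid[m] -= Y[m].mean(axis=0)
        n_cells += 1
    return resid, Y.shape[0] - n_cells


def _guarded_f(ss_eff: float, df1: float, ss_err: float, df2: float,
               scale: float = 0.0):
    """F, p and partial eta-squared with the 0/0 case mapped to F = 0.

    ``scale`` is the total SS of the data; sums of squares below
    1e-12 * scale are numerical noise and treated as exact zeros.
    """
    tol = max(1e-12 * scale, 1e-300)
    ss_eff = max(ss_eff, 0.0)
    if ss_eff <= tol and ss_err <= tol:
        return 0.0, 1.0, 0.0
    if ss_err <= tol:
        return np.inf, 0.0, 1.0
    F = (ss_eff / df1) / (ss_err / df2)
    p = float(stats.f.sf(F, df1, df2))
    eta = ss_eff / (ss_eff + ss_err)
    return float(F), p, float(eta)


# --------------------------------------------------------------------------
# the group x muscle mixed model
# --------------------------------------------------------------------------

def mixed_anova(table: pd.DataFrame, dv: str = "total",
                between: str = "group", adjust: str | None = "sex",
                within_levels: tuple = MUSCLES) -> list[AnovaResult]:
    """Mixed-design ANOVA: between-subject group, within-subject muscle.

    ``table`` is a feature table filtered to one timepoint and direction
    (one row per subject). Returns results for the between effect, the
    adjustment factor (if any), the within (muscle) effect and the
    muscle x group interaction. Greenhouse-Geisser correction is applied
    to the within-stratum effects when Mauchly's p < 0.05.
    """
    Y, table = _pivot_wide(table, dv, within_levels=within_levels)
    n, k = Y.shape
    g = table[between].to_numpy()
    if len(np.unique(g)) < 2:
        raise UnbalancedDesignError(f"need >= 2 levels of {between}")
    counts = pd.Series(g).value_counts()
    if counts.min() < 2:
        raise UnbalancedDesignError("need >= 2 subjects per group")
    s = table[adjust].to_numpy() if adjust else None
    ss_scale = float(np.sum((Y - Y.mean()) ** 2))

    # ---- between-subject stratum: subject means ------------------------
    m = Y.mean(axis=1)
    one = np.ones((n, 1))
    Xg = _effect_code(g)
    blocks = [one, Xg]
    labels = [between]
    if s is not None and len(np.unique(s)) > 1:
        Xs = _effect_code(s)
        blocks.append(Xs)
        labels.append(adjust)
    X_full = np.hstack(blocks)
    rss_full = _rss(X_full, m)
    df_between_err = n - X_full.shape[1]
    ss_between_err = rss_full * k

    results = []
    for name in labels:
        keep = [b for lab, b in zip(labels, blocks[1:]) if lab != name]
        X_red = np.hstack([one] + keep)
        ss = (_rss(X_red, m) - rss_full) * k
        df1 = blocks[labels.index(name) + 1].shape[1]
        F, p, eta = _guarded_f(ss, df1, ss_between_err, df_between_err,
                               scale=ss_scale)
        results.append(AnovaResult(name, F, df1, df_between_err, p, eta))

    # ---- within-subject stratum: deviations from subject means ---------
    D = (Y - m[:, None]).ravel()  # long, subject-major
    mus = np.tile(np.arange(k), n)
    g_long = np.repeat(g, k)
    Xm = _effect_code(mus)
    Xg_long = _effect_code(g_long)
    Xgm = np.einsum("ni,nj->nij", Xg_long, Xm).reshape(len(D), -1)
    X_w_full = np.hstack([Xm, Xgm])
    rss_w_full = _rss(X_w_full, D)
    n_groups = len(np.unique(g))
    df_w_err = (k - 1) * (n - n_groups)
    # the long residual contains the subject-mean constraint exactly
    ss_w_err = rss_w_full

    w_stat, w_p, eps = np.nan, np.nan, 1.0
    resid_cells, df_e = _remove_cell_means(Y, g)
    w_stat, w_p, eps = _sphericity(resid_cells, df_e)
    corrected = w_p < 0.05 if np.isfinite(w_p) else False

    for name, X_red, df1 in (
            ("muscle", Xgm, k - 1),
            (f"muscle x {between}", Xm, (k - 1) * (n_groups - 1))):
        ss = _rss(X_red, D) - rss_w_full
        use_eps = eps if corrected else 1.0
        F, p, eta = _guarded_f(ss, df1, ss_w_err, df_w_err, scale=ss_scale)
        if corrected:
            p = float(stats.f.sf(F, df1 * use_eps, df_w_err * use_eps)) \
                if np.isfinite(F) else p
        results.append(AnovaResult(
            name, F, df1 * use_eps, df_w_err * use_eps, p, eta,
            epsilon_gg=eps, mauchly_w=w_stat, mauchly_p=w_p,
            corrected=corrected))
    return results


# --------------------------------------------------------------------------
# post-hoc level contrasts
# --------------------------------------------------------------------------

def level_means(table: pd.DataFrame, dv: str = "total") -> pd.DataFrame:
    """Collapse the five muscles to the three anatomical level means."""
    out = table[["subject", "group", "sex"]].copy()
    for level, members in MUSCLE_LEVELS.items():
        out[level] = table[[f"{m}_{dv}" for m in members]].mean(axis=1)
    return out


def posthoc_level_contrasts(table: pd.DataFrame, dv: str = "total",
                            between: str = "group",
                            adjust: str | None = "sex") -> list[ContrastResult]:
    """Level x group interaction tests for the three pairwise level
    contrasts, Bonferroni-corrected over the family of three.

    Each contrast reduces to a between-group comparison of the
    within-subject difference score (level A minus level B); the F test
    comes from the effect-coded OLS model difference ~ group (+ sex).
    """
    lm = level_means(table, dv)
    g = lm[between].to_numpy()
    pairs = list(itertools.combinations(MUSCLE_LEVELS.keys(), 2))
    out = []
    for a, b in pairs:
        diff = (lm[a] - lm[b]).to_numpy(dtype=float)
        one = np.ones((len(diff), 1))
        blocks = [one, _effect_code(g)]
        if adjust and len(np.unique(lm[adjust])) > 1:
            blocks.append(_effect_code(lm[adjust].to_numpy()))
        X_full = np.hstack(blocks)
        rss_full = _rss(X_full, diff)
        X_red = np.hstack([one] + blocks[2:])
        ss = _rss(X_red, diff) - rss_full
        df2 = len(diff) - X_full.shape[1]
        F, p, eta = _guarded_f(ss, 1, rss_full, df2,
                               scale=float(np.sum((diff - diff.mean()) ** 2)))
        out.append(ContrastResult((a, b), F, 1, df2, p,
                                  min(1.0, len(pairs) * p), eta))
    return out


# --------------------------------------------------------------------------
# within-subject timepoint x muscle model
# --------------------------------------------------------------------------

def within_subject_anova(table: pd.DataFrame, dv: str = "total",
                         timepoints: tuple[str, str] = ("baseline", "followup"),
                         within_levels: tuple = MUSCLES) -> list[AnovaResult]:
    """Two-way repeated-measures ANOVA: timepoint x muscle, one group.

    ``table`` holds one row per subject per timepoint (single direction).
    Subjects without both timepoints are dropped with a log entry. Each
    within effect is tested against its own subject-by-effect interaction;
    Greenhouse-Geisser is applied per effect when its Mauchly p < 0.05.
    """
    t0, t1 = timepoints
    wide = {}
    for tp in timepoints:
        sub = table[table["timepoint"] == tp]
        Y, sub = _pivot_wide(sub.reset_index(drop=True), dv,
                             within_levels=within_levels)
        wide[tp] = pd.DataFrame(Y, index=sub["subject"].to_numpy())
    common = wide[t0].index.intersection(wide[t1].index)
    dropped = set(wide[t0].index).symmetric_difference(wide[t1].index)
    if dropped:
        logger.warning("dropping unpaired subjects: %s", sorted(dropped))
    if len(common) < 2:
        raise UnbalancedDesignError("need >= 2 paired subjects")
    Y = np.stack([wide[t0].loc[common].to_numpy(),
                  wide[t1].loc[common].to_numpy()], axis=1)  # (n, 2, k)
    n, t, k = Y.shape

    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    tp_mean = Y.mean(axis=(0, 2))
    mu_mean = Y.mean(axis=(0, 1))
    tm_mean = Y.mean(axis=0)

    ss_t = n * k * np.sum((tp_mean - grand) ** 2)
    ss_m = n * t * np.sum((mu_mean - grand) ** 2)
    ss_tm = n * np.sum((tm_mean - tp_mean[:, None] - mu_mean[None, :] + grand) ** 2)

    st_mean = Y.mean(axis=2)  # (n, t)
    sm_mean = Y.mean(axis=1)  # (n, k)
    ss_st = k * np.sum((st_mean - subj[:, None] - tp_mean[None, :] + grand) ** 2)
    ss_sm = t * np.sum((sm_mean - subj[:, None] - mu_mean[None, :] + grand) ** 2)
    resid = (Y - tm_mean[None] - st_mean[:, :, None] - sm_mean[:, None, :]
             + subj[:, None, None] + tp_mean[None, :, None]
             + mu_mean[None, None, :] - grand)
    ss_stm = np.sum(resid ** 2)

    results = []
    specs = [
        ("timepoint", ss_t, t - 1, ss_st, (n - 1) * (t - 1), st_mean),
        ("muscle", ss_m, k - 1, ss_sm, (n - 1) * (k - 1), sm_mean),
        ("timepoint x muscle", ss_tm, (t - 1) * (k - 1), ss_stm,
         (n - 1) * (t - 1) * (k - 1), None),
    ]
    ss_scale = float(np.sum((Y - grand) ** 2))
    for name, ss_eff, df1, ss_err, df2, cell in specs:
        w_stat, w_p, eps = np.nan, np.nan, 1.0
        if cell is not None and cell.shape[1] > 2:
            w_stat, w_p, eps = _sphericity(cell - cell.mean(axis=0),
                                           cell.shape[0] - 1)
        corrected = np.isfinite(w_p) and w_p < 0.05
        use_eps = eps if corrected else 1.0
        F, p, eta = _guarded_f(ss_eff, df1, ss_err, df2, scale=ss_scale)
        if corrected and np.isfinite(F):
            p = float(stats.f.sf(F, df1 * use_eps, df2 * use_eps))
        results.append(AnovaResult(name, F, df1 * use_eps, df2 * use_eps,
                                   p, eta, epsilon_gg=eps, mauchly_w=w_stat,
                                   mauchly_p=w_p, corrected=corrected))
    return results


def results_frame(results: list[AnovaResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of ANOVA results."""
    return pd.DataFrame([r.as_dict() for r in results])
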