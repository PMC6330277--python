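"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package:
the ANOVA oracle builds one explicit full design matrix and computes
Type III sums of squares by projection algebra on the long data; the
Mann-Whitney oracle enumerates rank-sum assignments; the Spearman oracle
applies the mid-rank Pearson formula directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import rankdata


def _codes(idx: np.ndarray, k: int) -> np.ndarray:
    C = np.zeros((idx.size, k - 1))
    for j in range(k - 1):
        C[idx == j, j] = 1.0
    C[idx == k - 1] = -1.0
    return C


def _proj_rss(X: np.ndarray, y: np.ndarray) -> float:
    P = X @ np.linalg.pinv(X)
    r = y - P @ y
    return float(r @ r)


def glm_mixed_anova(Y: np.ndarray, gidx: np.ndarray) -> dict:
    """Split-plot Type III F and p via one full design matrix.

    Columns: intercept, group (effect coded), subjects (sum-to-zero
    within group), time, group x time.  Each effect's SS is the RSS
    increase from deleting its columns from the full model; Group is
    tested against subjects-within-groups (computed directly), Time and
    the interaction against the full-model residual.
    """
    Y = np.asarray(Y, float)
    N, k = Y.shape
    y = Y.ravel()
    gcode = np.where(gidx == 0, 1.0, -1.0)

    subj_blocks = []
    for g in (0, 1):
        members = np.flatnonzero(gidx == g)
        C = _codes(np.arange(members.size), members.size)  # (n_g, n_g - 1)
        block = np.zeros((N, members.size - 1))
        block[members] = C
        subj_blocks.append(block)
    S = np.hstack(subj_blocks)

    lev = np.tile(np.arange(k), N)
    T = _codes(lev, k)
    ones = np.ones((N * k, 1))
    Grow = np.repeat(gcode, k)[:, None]
    Srow = np.repeat(S, k, axis=0)
    GT = Grow * T

    full = np.hstack([ones, Grow, Srow, T, GT])
    rss_full = _proj_rss(full, y)

    def drop(*blocks):
        keep = [b for b in (ones, Grow, Srow, T, GT) if not any(b is d for d in blocks)]
        return _proj_rss(np.hstack(keep), y) - rss_full

    ss_g, ss_t, ss_gt = drop(Grow), drop(T), drop(GT)
    subj_means = Y.mean(axis=1)
    gm = np.array([subj_means[gidx == g].mean() for g in (0, 1)])
    ss_subj = k * float(np.sum((subj_means - gm[gidx]) ** 2))

    df_s, df_w = N - 2, (N - 2) * (k - 1)
    out = {}
    for name, ss, df1, ss_e, df2 in [
        ("Group", ss_g, 1, ss_subj, df_s),
        ("Time", ss_t, k - 1, rss_full, df_w),
        ("Group x Time", ss_gt, k - 1, rss_full, df_w),
    ]:
        F = (ss / df1) / (ss_e / df2)
        out[name] = {"ss": ss, "F": F, "p": float(f_dist.sf(F, df1, df2))}
    return out


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """U (pairs a<b plus half-ties, via rank sums) and exact two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)

    def u_of(idx_set):
        r1 = ranks[list(idx_set)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0  # pairs a > b plus half-ties
        return n1 * n2 - u1  # pairs a < b plus half-ties

    obs = u_of(range(n1))
    mu = n1 * n2 / 2.0
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(obs - mu) - 1e-12:
            hits += 1
    return obs, hits / total


def spearman_direct(x, y) -> float:
    """Pearson correlation of mid-ranks, written out."""
    rx, ry = rankdata(x), rankdata(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
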