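"""Mixed-design inference for pre/post tool-use experiments.

The central object is the univariate split-plot (mixed repeated
measures) ANOVA with one between-subject factor (Group: patients vs
controls) and one within-subject factor (Time: experimental sessions),
built from its sums-of-squares decomposition:

* the between stratum tests Group against subjects-within-groups,
* the within stratum tests Time and Group x Time against
  Time x subjects-within-groups.

Sums of squares are Type III (each effect adjusted for all others via
model comparison with sum-to-zero coding), which matters because group
sizes are unbalanced; estimated marginal means are therefore unweighted
cell means.  Partial eta squared is SS_effect / (SS_effect + SS_error)
with the error term of the effect's own stratum.

Also provided: the age-covariate ANCOVA variant with adjusted means,
Bonferroni-corrected simple-effect comparisons for the 2 x 2 design,
Spearman rank correlations, an exact-capable Mann-Whitney U test,
printed-style descriptives, and two-sample t power via the noncentral
t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MixedAnovaResult",
    "EmmComparison",
    "CorrelationResult",
    "RankTestResult",
    "mixed_anova",
    "mixed_anova_arrays",
    "emm_simple_effects",
    "ancova_mixed",
    "spearman_rho",
    "mann_whitney_u",
    "describe",
    "power_two_sample",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MixedAnovaResult:
    """Effect table plus everything post hoc comparisons need."""

    table: pd.DataFrame  # index: effect; columns: ss, df1, df2, F, p, partial_eta_sq
    groups: list
    levels: list
    group_sizes: dict
    cell_means: pd.DataFrame  # groups x levels, unweighted (adjusted if covariate)
    ms_subject: float
    df_subject: int
    ms_within: float
    df_within: int
    has_covariate: bool = False
    covariate_group_means: dict | None = None
    covariate_sxx: float | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MixedAnovaResult(\n{self.table.round(4)}\n)"


@dataclass(frozen=True)
class EmmComparison:
    contrast: str
    estimate: float
    se: float
    df: float
    t: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p: float


@dataclass(frozen=True)
class RankTestResult:
    U: float
    n1: int
    n2: int
    p: float
    method: str  # "exact" or "normal"


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _effect_codes(idx: np.ndarray, k: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: (n, k-1)."""
    C = np.zeros((idx.size, k - 1))
    for j in range(k - 1):
        C[idx == j, j] = 1.0
    C[idx == k - 1, :] = -1.0
    return C


# ---------------------------------------------------------------------------
# mixed ANOVA / ANCOVA core on arrays


def mixed_anova_arrays(
    Y: np.ndarray,
    group_idx: np.ndarray,
    covariate: np.ndarray | None = None,
    gg_correction: bool = False,
) -> dict:
    """Split-plot decomposition on a wide response matrix.

    Y is (N subjects, k within-levels), ``group_idx`` holds 0/1 group
    membership, ``covariate`` one value per subject.  Returns the raw
    decomposition; the DataFrame front end wraps it.
    """
    Y = np.asarray(Y, dtype=float)
    group_idx = np.asarray(group_idx)
    N, k = Y.shape
    if N != group_idx.size:
        raise ValueError("group_idx length must match Y rows")
    counts = np.bincount(group_idx, minlength=2)
    if counts.min() < 2 or counts.size != 2:
        raise ValueError("need two groups with >= 2 subjects each")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells are not allowed (no imputation)")

    gcode = np.where(group_idx == 0, 1.0, -1.0)
    subj_means = Y.mean(axis=1)
    ones = np.ones((N, 1))

    # --- between stratum (on subject means, SS rescaled by k)
    if covariate is None:
        Xb = np.column_stack([ones, gcode])
        rss_full = _rss(Xb, subj_means)
        ss_group = k * (_rss(ones, subj_means) - rss_full)
        ss_cov = None
        df_subject = N - 2
    else:
        x = np.asarray(covariate, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("covariate is constant")
        xc = x - x.mean()
        Xb = np.column_stack([ones, gcode, xc])
        rss_full = _rss(Xb, subj_means)
        ss_group = k * (_rss(np.column_stack([ones, xc]), subj_means) - rss_full)
        ss_cov = k * (_rss(np.column_stack([ones, gcode]), subj_means) - rss_full)
        df_subject = N - 3
    ss_subject = k * rss_full

    # --- within stratum (subject-centered responses)
    yc = (Y - subj_means[:, None]).ravel()
    lev = np.tile(np.arange(k), N)
    XT = _effect_codes(lev, k)
    grow = np.repeat(gcode, k)[:, None]
    XGT = grow * XT
    if covariate is None:
        blocks = [XT, XGT]
        df_within = (N - 2) * (k - 1)
    else:
        xrow = np.repeat(xc, k)[:, None]
        blocks = [XT, XGT, xrow * XT]
        df_within = (N - 3) * (k - 1)
    Xw_full = np.hstack(blocks)
    rss_w = _rss(Xw_full, yc)

    def drop(i: int) -> float:
        Xr = np.hstack([b for j, b in enumerate(blocks) if j != i])
        return _rss(Xr, yc) - rss_w

    ss_time = drop(0)
    ss_inter = drop(1)
    ss_covt = drop(2) if covariate is not None else None

    eps = 1.0
    if gg_correction and k > 2:
        # Greenhouse-Geisser epsilon from the pooled within-group covariance
        dev = Y.copy()
        for g in (0, 1):
            dev[group_idx == g] -= Y[group_idx == g].mean(axis=0)
        S = dev.T @ dev / (N - 2)
        A = (
            S
            - S.mean(axis=0, keepdims=True)
            - S.mean(axis=1, keepdims=True)
            + S.mean()
        )
        eps = float(np.trace(A) ** 2 / ((k - 1) * np.trace(A @ A)))
        eps = min(1.0, max(eps, 1.0 / (k - 1)))

    out = {
        "k": k,
        "N": N,
        "counts": counts,
        "epsilon": eps,
        "ss": {"Group": ss_group, "Time": ss_time, "Group x Time": ss_inter},
        "ss_subject": ss_subject,
        "df_subject": df_subject,
        "ss_within": rss_w,
        "df_within": df_within,
    }
    if covariate is not None:
        out["ss"]["Age"] = ss_cov
        out["ss"]["Age x Time"] = ss_covt
    return out


def _assemble_result(
    dec: dict,
    groups: list,
    levels: list,
    cell_means: pd.DataFrame,
    has_covariate: bool,
    cov_info: tuple | None = None,
) -> MixedAnovaResult:
    k = dec["k"]
    eps = dec["epsilon"]
    ms_s = dec["ss_subject"] / dec["df_subject"]
    ms_w = dec["ss_within"] / dec["df_within"]
    rows = {}
    tiny = 1e-12 * max(
        1e-300, dec["ss_subject"], dec["ss_within"], *dec["ss"].values()
    )
    for eff, ss in dec["ss"].items():
        between = eff in ("Group", "Age")
        if between:
            df1, ss_err, df2 = 1, dec["ss_subject"], dec["df_subject"]
        else:
            df1, ss_err, df2 = k - 1, dec["ss_within"], dec["df_within"]
        if ss_err <= tiny:  # degenerate stratum (e.g. all-constant data)
            F, p = (0.0, 1.0) if ss <= tiny else (float("inf"), 0.0)
        else:
            F = (ss / df1) / (ss_err / df2)
            if between:
                p = float(sps.f.sf(F, df1, df2))
            else:  # GG epsilon rescales both dfs, F unchanged
                p = float(sps.f.sf(F, df1 * eps, df2 * eps))
        rows[eff] = {
            "ss": ss,
            "df1": df1,
            "df2": df2,
            "F": F,
            "p": p,
            "partial_eta_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
        }
    order = [e for e in ("Group", "Age", "Time", "Group x Time", "Age x Time") if e in rows]
    table = pd.DataFrame([rows[e] for e in order], index=order)
    res = MixedAnovaResult(
        table=table,
        groups=list(groups),
        levels=list(levels),
        group_sizes={g: int(n) for g, n in zip(groups, dec["counts"])},
        cell_means=cell_means,
        ms_subject=ms_s,
        df_subject=dec["df_subject"],
        ms_within=ms_w,
        df_within=dec["df_within"],
        has_covariate=has_covariate,
    )
    if cov_info is not None:
        res.covariate_group_means, res.covariate_sxx = cov_info
    return res


def _pivot(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> tuple[np.ndarray, np.ndarray, list, list, pd.Series]:
    levels = list(pd.unique(data[within]))
    groups = list(pd.unique(data[between]))
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    wide = wide.reindex(columns=levels)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing cells for subjects {bad}; no imputation is done")
    subj_group = data.drop_duplicates(subject).set_index(subject)[between]
    subj_group = subj_group.loc[wide.index]
    gidx = subj_group.map({groups[0]: 0, groups[1]: 1}).to_numpy()
    return wide.to_numpy(float), gidx, groups, levels, subj_group


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "session",
    between: str = "group",
    subject: str = "participant_id",
    gg_correction: bool = False,
) -> MixedAnovaResult:
    """Mixed Time x Group RM-ANOVA from a long-format table.

    Within levels and group order follow first appearance in ``data``.
    Every subject must have a response at every within level.
    """
    Y, gidx, groups, levels, _ = _pivot(data, dv, within, between, subject)
    dec = mixed_anova_arrays(Y, gidx, gg_correction=gg_correction)
    cells = pd.DataFrame(
        [Y[gidx == 0].mean(axis=0), Y[gidx == 1].mean(axis=0)],
        index=groups,
        columns=levels,
    )
    return _assemble_result(dec, groups, levels, cells, has_covariate=False)


def ancova_mixed(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "session",
    between: str = "group",
    subject: str = "participant_id",
    covariate: str = "age",
    gg_correction: bool = False,
) -> MixedAnovaResult:
    """Mixed ANOVA with a once-per-subject covariate (e.g. age).

    The covariate main effect is partialled from the between stratum and
    its interaction with Time from the within stratum.  Cell means are
    adjusted to the grand covariate mean.
    """
    Y, gidx, groups, levels, subj_group = _pivot(data, dv, within, between, subject)
    cov = (
        data.drop_duplicates(subject)
        .set_index(subject)[covariate]
        .loc[subj_group.index]
        .to_numpy(float)
    )
    if np.isnan(cov).any():
        raise ValueError("covariate contains missing values")
    dec = mixed_anova_arrays(Y, gidx, covariate=cov, gg_correction=gg_correction)

    # adjusted means at the grand covariate mean
    N, k = Y.shape
    xc = cov - cov.mean()
    gcode = np.where(gidx == 0, 1.0, -1.0)
    bb = _coef(np.column_stack([np.ones(N), gcode, xc]), Y.mean(axis=1))
    adj_group = {0: bb[0] + bb[1], 1: bb[0] - bb[1]}
    yc = (Y - Y.mean(axis=1)[:, None]).ravel()
    lev = np.tile(np.arange(k), N)
    XT = _effect_codes(lev, k)
    XGT = np.repeat(gcode, k)[:, None] * XT
    XcT = np.repeat(xc, k)[:, None] * XT
    bw = _coef(np.hstack([XT, XGT, XcT]), yc)
    bT, bGT = bw[: k - 1], bw[k - 1 : 2 * (k - 1)]
    cells = np.zeros((2, k))
    for j in range(k):
        tj = _effect_codes(np.array([j]), k)[0]
        for gi, code in ((0, 1.0), (1, -1.0)):
            cells[gi, j] = adj_group[gi] + tj @ bT + code * (tj @ bGT)
    cell_means = pd.DataFrame(cells, index=groups, columns=levels)
    sxx = sum(float(np.sum((cov[gidx == g] - cov[gidx == g].mean()) ** 2)) for g in (0, 1))
    cov_means = {groups[0]: float(cov[gidx == 0].mean()), groups[1]: float(cov[gidx == 1].mean())}
    return _assemble_result(
        dec, groups, levels, cell_means, has_covariate=True, cov_info=(cov_means, sxx)
    )


# ---------------------------------------------------------------------------
# estimated-marginal-mean simple effects (2 x 2 designs)


def emm_simple_effects(result: MixedAnovaResult, family: int = 4) -> list[EmmComparison]:
    """Bonferroni-corrected simple effects for a 2 (Group) x 2 (Time) design.

    Four contrasts: Time within each group (tested on the within-stratum
    error) and Group within each time (tested on the Winer combined mean
    square (MS_subject + MS_within)/2 with Satterthwaite degrees of
    freedom).  Raw p values are multiplied by ``family`` and capped at 1.
    """
    if len(result.levels) != 2:
        raise ValueError("simple effects are defined for 2-level within factors")
    g0, g1 = result.groups
    l0, l1 = result.levels
    m = result.cell_means
    n0, n1 = result.group_sizes[g0], result.group_sizes[g1]
    out = []

    for g, n in ((g0, n0), (g1, n1)):
        est = float(m.loc[g, l1] - m.loc[g, l0])
        se = math.sqrt(2.0 * result.ms_within / n)
        out.append(_emm(f"{l1} - {l0} | {g}", est, se, result.df_within, family))

    msc = (result.ms_subject + result.ms_within) / 2.0
    df_sat = (result.ms_subject + result.ms_within) ** 2 / (
        result.ms_subject**2 / result.df_subject + result.ms_within**2 / result.df_within
    )
    mult = 1.0 / n0 + 1.0 / n1
    if result.has_covariate and result.covariate_sxx:
        dx = result.covariate_group_means[g0] - result.covariate_group_means[g1]
        mult += dx**2 / result.covariate_sxx
    for lev in (l0, l1):
        est = float(m.loc[g0, lev] - m.loc[g1, lev])
        se = math.sqrt(msc * mult)
        out.append(_emm(f"{g0} - {g1} | {lev}", est, se, df_sat, family))
    return out


def _emm(label: str, est: float, se: float, df: float, family: int) -> EmmComparison:
    if se > 0:
        t = est / se
    else:
        t = 0.0 if abs(est) <= 1e-300 else math.copysign(float("inf"), est)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return EmmComparison(
        contrast=label, estimate=est, se=se, df=df, t=t, p_raw=p,
        p_adjusted=min(1.0, family * p),
    )


# ---------------------------------------------------------------------------
# rank statistics


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman's rank correlation with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), n=int(x.size), p=float(p))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Pairs with a_i < b_j, plus half-ties."""
    return float(np.sum(a[:, None] < b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))


def mann_whitney_u(a, b, exact: bool | None = None) -> RankTestResult:
    """Mann-Whitney U with exact enumeration for small samples.

    Reported statistic is ``min(U, n1*n2 - U)``.  The exact two-sided p
    enumerates all group assignments (used when ``n1 + n2 <= 16`` unless
    overridden) and is valid under ties; otherwise a tie-corrected
    normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    u_report = min(u_obs, n1 * n2 - u_obs)
    mu = n1 * n2 / 2.0
    if exact is None:
        exact = (n1 + n2) <= 16
    if exact:
        pooled = np.concatenate([a, b])
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return RankTestResult(U=u_report, n1=n1, n2=n2, p=hits / total, method="exact")
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(U=u_report, n1=n1, n2=n2, p=1.0, method="normal")
    z = (u_obs - mu) / math.sqrt(var)
    return RankTestResult(
        U=u_report, n1=n1, n2=n2, p=2.0 * float(sps.norm.sf(abs(z))), method="normal"
    )


# ---------------------------------------------------------------------------
# descriptives and power


def _round_half_away(x: float, ndigits: int) -> float:
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def describe(values, mode: str = "round", ndigits: int = 0) -> tuple[float, float]:
    """Mean and n-1 SD formatted the way result tables print them.

    ``mode='round'`` rounds half away from zero; ``mode='truncate'``
    drops the fractional part (how some printed table footers behave).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    if mode == "round":
        fmt = lambda x: _round_half_away(x, ndigits)
    elif mode == "truncate":
        scale = 10.0**ndigits
        fmt = lambda x: math.trunc(x * scale) / scale
    else:
        raise ValueError("mode must be 'round' or 'truncate'")
    out = (fmt(mean), fmt(sd))
    return (int(out[0]), int(out[1])) if ndigits == 0 else out


def power_two_sample(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test via the noncentral t."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    tc = sps.t.ppf(1 - alpha / 2, df)
    upper = float(sps.nct.sf(tc, df, ncp))
    lower = float(sps.nct.cdf(-tc, df, ncp))
    if math.isnan(lower):  # underflows for large noncentrality
        lower = 0.0
    return upper + lower
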