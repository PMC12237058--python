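"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written along a different algebraic or
algorithmic route than the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sl
from scipy import stats as sps


def brute_force_ranks(table_df):
    """Exhaustive pairwise-comparison ranking at every lap index.

    A team's rank at lap l is 1 + the number of teams that beat it,
    where "beats" is decided by the full ordering rules: teams that
    reached lap l compare on cumulative time there; a team that reached
    beats one that did not; teams that both did not compare on (total
    laps desc, total time asc); all ties fall back to team id.
    """
    teams = sorted(table_df["team_id"].unique())
    cum = {}
    for team in teams:
        t = table_df[table_df["team_id"] == team].sort_values("lap_index")
        cum[team] = np.cumsum(t["lap_time_s"].to_numpy())
    lmax = max(len(c) for c in cum.values())

    def key(team, l):
        c = cum[team]
        if len(c) >= l:
            return (0, c[l - 1], 0.0, team)
        return (1, -len(c), c[-1], team)

    ranks = {}
    for l in range(1, lmax + 1):
        for team in teams:
            beat_by = sum(
                1 for other in teams if other != team and key(other, l) < key(team, l)
            )
            ranks[(team, l)] = beat_by + 1
    return ranks, lmax


def brute_force_final(table_df):
    """Final ranks via explicit pairwise counting."""
    teams = sorted(table_df["team_id"].unique())
    stats = {}
    for team in teams:
        t = table_df[table_df["team_id"] == team]
        stats[team] = (-len(t), t["lap_time_s"].sum(), team)
    return {
        team: 1 + sum(1 for o in teams if o != team and stats[o] < stats[team])
        for team in teams
    }


def ats_oracle(X, fa, fb):
    """Rank-based ATS via contrast matrices and pseudo-inverse.

    Independent route: effects are expressed as difference-contrast
    matrices C and projected with ``C'(CC')^+ C`` instead of Kronecker
    products of idempotent operators; loops instead of vectorization.
    """
    X = np.asarray(X, dtype=float)
    n, t = X.shape
    la, lb = np.unique(fa), np.unique(fb)
    a, b = len(la), len(lb)
    R = sps.rankdata(X.ravel()).reshape(n, t)
    q = (R - 0.5) / (n * t)
    p = []
    blocks = []
    for ia in la:
        for ib in lb:
            cell = q[(fa == ia) & (fb == ib)]
            p.extend(cell.mean(axis=0))
            blocks.append(np.cov(cell.T, ddof=1) / len(cell))
    p = np.array(p)
    V = sl.block_diag(*blocks)

    def diff(k):
        return np.hstack([np.eye(k - 1), -np.ones((k - 1, 1))])

    def avg(k):
        return np.ones((1, k)) / k

    contrasts = {
        "size": np.kron(np.kron(diff(a), avg(b)), avg(t)),
        "perf": np.kron(np.kron(avg(a), diff(b)), avg(t)),
        "time": np.kron(np.kron(avg(a), avg(b)), diff(t)),
        "size:perf": np.kron(np.kron(diff(a), diff(b)), avg(t)),
        "size:time": np.kron(np.kron(diff(a), avg(b)), diff(t)),
        "perf:time": np.kron(np.kron(avg(a), diff(b)), diff(t)),
        "size:perf:time": np.kron(np.kron(diff(a), diff(b)), diff(t)),
    }
    out = {}
    for name, C in contrasts.items():
        T = C.T @ np.linalg.pinv(C @ C.T) @ C
        tr = np.trace(T @ V)
        ats = float(p @ T @ p) / tr
        df = tr**2 / np.trace(T @ V @ T @ V)
        out[name] = (ats, float(df), float(sps.chi2.sf(ats * df, df)))
    return out


def welch_oracle(groups):
    """Welch's F from the textbook formula, written out longhand."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    num = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    den = 1 + 2 * (k - 2) * lam / (k**2 - 1)
    F = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def games_howell_oracle(groups):
    """Per-pair Games-Howell statistic/df/p from first principles."""
    k = len(groups)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            x, y = np.asarray(groups[i], float), np.asarray(groups[j], float)
            nx, ny = len(x), len(y)
            vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
            se = np.sqrt(vx / nx + vy / ny)
            tval = (np.mean(x) - np.mean(y)) / se
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
            p = float(sps.studentized_range.sf(abs(tval) * np.sqrt(2), k, df))
            out[(i, j)] = (float(tval), float(df), p)
    return out


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by complete enumeration.

    Enumerates every assignment of the pooled (tie-free) values to the
    first sample and counts assignments whose U is at least as extreme
    (in |U - n1 n2 / 2|) as the observed one.
    """
    from itertools import combinations

    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    n1 = len(x)

    def u_of(sample_a, rest):
        return sum(1 for a in sample_a for b in rest if a > b)

    u_obs = u_of(x, y)
    center = n1 * len(y) / 2
    extreme = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_of(sa, sb)
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
        total += 1
    return u_obs, extreme / total
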