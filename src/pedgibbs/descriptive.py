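"""Prevalence tables, multinomial-logit factor screening and gait GLM.

Prevalence counts records (not animals).  The factor screen fits a
baseline-category multinomial logit by Newton's method and reports
per-factor likelihood-ratio tests; gait scores get a one-way fixed-effects
model with Tukey–Kramer pairwise comparisons and a compact letter display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .posterior import round_half_up
from .simulate import FACTOR_LEVELS, FACTORS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# prevalence


def prevalence_table(records: pd.DataFrame, traits=None, ndigits: int = 2) -> pd.DataFrame:
    """Per-trait record counts and percentages for classes 0/1/2 and 1+2.

    Missing scores are excluded from N; traits with zero scored records
    are omitted with a warning.  Percentages are rounded half-up.
    """
    if traits is None:
        reserved = {"record_id", "animal", "walk", "trot", *FACTORS}
        traits = [c for c in records.columns if c not in reserved]
    rows = []
    for trait in traits:
        scores = pd.to_numeric(records[trait], errors="coerce").dropna()
        if scores.empty:
            warnings.warn(f"trait {trait!r} has no scored records; omitted")
            continue
        bad = set(scores.unique()) - {0, 1, 2}
        if bad:
            raise ValueError(f"trait {trait!r} has scores outside 0/1/2: {sorted(bad)}")
        n = len(scores)
        counts = [int((scores == c).sum()) for c in (0, 1, 2)]
        pct = [round_half_up(100.0 * c / n, ndigits) for c in counts]
        n12 = counts[1] + counts[2]
        rows.append(
            {
                "trait": trait,
                "N": n,
                "n0": counts[0],
                "pct0": pct[0],
                "n1": counts[1],
                "pct1": pct[1],
                "n2": counts[2],
                "pct2": pct[2],
                # the combined percentage is the sum of the rounded per-class
                # percentages (how the source tables tally), not a re-division
                "n12": n12,
                "pct12": round_half_up(pct[1] + pct[2], ndigits),
            }
        )
    return pd.DataFrame(rows)


def prevalence_by_factor(
    records: pd.DataFrame, factor: str, traits=None, ndigits: int = 2
) -> dict[int, pd.DataFrame]:
    """One prevalence table per level of a stratifying factor."""
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    out = {}
    for level, group in records.groupby(factor):
        out[int(level)] = prevalence_table(group, traits=traits, ndigits=ndigits)
    return out


# ---------------------------------------------------------------------------
# baseline-category multinomial logit


def _softmax_probs(eta: np.ndarray) -> np.ndarray:
    # eta: (n, C-1) linear predictors vs baseline class 0
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=1, keepdims=True)


def _fit_multinomial(
    X: np.ndarray, y: np.ndarray, n_classes: int, ridge: float = 0.0,
    max_iter: int = 100, tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """Newton fit of a baseline-category logit; returns (B, loglik, converged).

    ``B`` is (k, C-1).  ``ridge`` adds an L2 penalty to stabilize fits
    under (quasi-)separation; the returned log-likelihood is unpenalized.
    """
    n, k = X.shape
    cm1 = n_classes - 1
    Y = np.zeros((n, cm1))
    for c in range(1, n_classes):
        Y[:, c - 1] = y == c
    B = np.zeros((k, cm1))
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        P = _softmax_probs(X @ B)
        ll = float(np.sum(np.log(np.clip(P[np.arange(n), y], 1e-300, None))))
        grad = (X.T @ (Y - P[:, 1:])).ravel(order="F") - ridge * B.ravel(order="F")
        H = np.zeros((k * cm1, k * cm1))
        for a in range(cm1):
            for b_ in range(a, cm1):
                w = P[:, a + 1] * ((a == b_) - P[:, b_ + 1])
                blk = X.T @ (X * w[:, None])
                H[a * k:(a + 1) * k, b_ * k:(b_ + 1) * k] = blk
                if a != b_:
                    H[b_ * k:(b_ + 1) * k, a * k:(a + 1) * k] = blk
        H += ridge * np.eye(k * cm1)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k * cm1), grad)
        except np.linalg.LinAlgError:
            return B, ll, False
        # halving for monotone likelihood
        lam = 1.0
        for _ in range(30):
            Bn = B + lam * step.reshape((k, cm1), order="F")
            Pn = _softmax_probs(X @ Bn)
            lln = float(np.sum(np.log(np.clip(Pn[np.arange(n), y], 1e-300, None))))
            if lln >= ll - 1e-12:
                break
            lam *= 0.5
        B = Bn
        if abs(lln - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = lln
            break
        ll_old = lln
    return B, ll_old, converged


def _factor_dummies(df: pd.DataFrame, factors) -> tuple[np.ndarray, dict[str, list[int]]]:
    n = len(df)
    cols = [np.ones(n)]
    owner: dict[str, list[int]] = {}
    for f in factors:
        lev = df[f].to_numpy()
        observed = np.unique(lev)
        owner[f] = []
        for v in observed[1:]:
            owner[f].append(len(cols))
            cols.append((lev == v).astype(float))
    return np.column_stack(cols), owner


def fit_multinomial_logit(
    records: pd.DataFrame, trait: str, factors=FACTORS
) -> pd.DataFrame:
    """Per-factor likelihood-ratio screen of an ordinal trait's classes.

    Fits the full baseline-category model, then drops one factor at a
    time; p-values are chi-square with df = (levels−1) × (classes−1).
    Levels with a single outcome class trigger a separation warning and a
    ridge-stabilized refit.
    """
    df = records.dropna(subset=[trait]).copy()
    y_raw = df[trait].astype(int).to_numpy()
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError(f"trait {trait!r} has fewer than 2 observed classes")
    if len(classes) < 3:
        warnings.warn(
            f"trait {trait!r}: classes {sorted(set((0, 1, 2)) - set(classes))} absent; "
            "outcome collapsed"
        )
    remap = {c: i for i, c in enumerate(classes)}
    y = np.array([remap[v] for v in y_raw])
    n_classes = len(classes)

    separation = False
    for f in factors:
        tab = pd.crosstab(df[f], y)
        if (tab.astype(bool).sum(axis=1) == 1).any():
            separation = True
    ridge = 1e-6 * len(df) if separation else 0.0
    if separation:
        warnings.warn(f"possible separation for trait {trait!r}; ridge-stabilized fit")

    X_full, owner = _factor_dummies(df, factors)
    _, ll_full, conv = _fit_multinomial(X_full, y, n_classes, ridge=ridge)
    if not conv and not separation:
        ridge = 1e-6 * len(df)
        warnings.warn(f"full model for {trait!r} did not converge; retrying with ridge")
        _, ll_full, conv = _fit_multinomial(X_full, y, n_classes, ridge=ridge)

    rows = []
    for f in factors:
        keep = [j for j in range(X_full.shape[1]) if j not in owner[f]]
        _, ll_red, _ = _fit_multinomial(X_full[:, keep], y, n_classes, ridge=ridge)
        lr = max(0.0, 2.0 * (ll_full - ll_red))
        dof = len(owner[f]) * (n_classes - 1)
        p = float(stats.chi2.sf(lr, dof)) if dof > 0 else float("nan")
        rows.append(
            {
                "factor": f,
                "lr_stat": lr,
                "df": dof,
                "p_value": p,
                "separation": separation,
            }
        )
    return pd.DataFrame(rows)


def multinomial_logit_coefficients(
    records: pd.DataFrame, trait: str, factors=FACTORS
) -> np.ndarray:
    """Full-model coefficient matrix (k, classes−1); for oracle checks."""
    df = records.dropna(subset=[trait]).copy()
    y_raw = df[trait].astype(int).to_numpy()
    classes = np.unique(y_raw)
    remap = {c: i for i, c in enumerate(classes)}
    y = np.array([remap[v] for v in y_raw])
    X, _ = _factor_dummies(df, factors)
    B, _, _ = _fit_multinomial(X, y, len(classes))
    return B


# ---------------------------------------------------------------------------
# gait GLM with Tukey–Kramer letters


@dataclass
class GaitComparison:
    trait: str
    gait: str
    table: pd.DataFrame  # class, n, mean, letters
    f_stat: float
    f_pvalue: float
    pairwise: pd.DataFrame  # class_i, class_j, p_value


def _compact_letters(levels: list, sig: set[frozenset]) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig`` holds pairs that must NOT share a letter.
    """
    letters: list[set] = [set()]
    groups: list[set] = [set(levels)]
    for a, b in [tuple(sorted(p)) for p in sorted(sig, key=lambda s: tuple(sorted(s)))]:
        for gi in range(len(groups)):
            g = groups[gi]
            if a in g and b in g:
                g1 = g - {b}
                g2 = g - {a}
                groups[gi] = g1
                groups.append(g2)
        # absorb duplicates / subsets
        uniq = []
        for g in groups:
            if g and not any(g < h for h in groups) and g not in uniq:
                uniq.append(g)
        groups = uniq
    groups.sort(key=lambda g: min(levels.index(x) for x in g) if g else 0)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, g in zip(alphabet, groups):
        for lv in g:
            out[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in out.items()}


def fit_gait_glm(
    records: pd.DataFrame, trait: str, gait: str, alpha: float = 0.05
) -> GaitComparison:
    """One-way model of a gait score on defect class with Tukey–Kramer.

    Classes with fewer than 2 records are reported with mean only and
    excluded from the pairwise tests.  Letters: classes sharing no letter
    differ at ``alpha``.
    """
    if gait not in ("walk", "trot"):
        raise ValueError("gait must be 'walk' or 'trot'")
    df = records.dropna(subset=[trait, gait])
    y = df[gait].to_numpy(dtype=float)
    g = df[trait].astype(int).to_numpy()
    all_levels = sorted(np.unique(g))
    info = {lv: y[g == lv] for lv in all_levels}
    tested = [lv for lv in all_levels if len(info[lv]) >= 2]

    k = len(tested)
    n_tot = sum(len(info[lv]) for lv in tested)
    dfe = n_tot - k
    if k >= 2 and dfe > 0:
        means = {lv: info[lv].mean() for lv in tested}
        sse = sum(((info[lv] - means[lv]) ** 2).sum() for lv in tested)
        grand = np.concatenate([info[lv] for lv in tested]).mean()
        ssb = sum(len(info[lv]) * (means[lv] - grand) ** 2 for lv in tested)
        mse = sse / dfe
        if mse <= 0:
            f_stat, f_p = 0.0, 1.0
            mse = 0.0
        else:
            f_stat = (ssb / (k - 1)) / mse
            f_p = float(stats.f.sf(f_stat, k - 1, dfe))
        pairs = []
        sig = set()
        for ii in range(k):
            for jj in range(ii + 1, k):
                a, b = tested[ii], tested[jj]
                if mse == 0.0:
                    p = 1.0 if means[a] == means[b] else 0.0
                else:
                    qs = abs(means[a] - means[b]) / np.sqrt(
                        mse / 2.0 * (1.0 / len(info[a]) + 1.0 / len(info[b]))
                    )
                    p = float(stats.studentized_range.sf(qs, k, dfe))
                pairs.append({"class_i": a, "class_j": b, "p_value": p})
                if p < alpha:
                    sig.add(frozenset((a, b)))
        letters = _compact_letters(tested, sig)
        pairwise = pd.DataFrame(pairs)
    else:
        f_stat, f_p = float("nan"), float("nan")
        letters = {lv: "a" for lv in tested}
        pairwise = pd.DataFrame(columns=["class_i", "class_j", "p_value"])

    table = pd.DataFrame(
        {
            "class": all_levels,
            "n": [len(info[lv]) for lv in all_levels],
            "mean": [float(info[lv].mean()) for lv in all_levels],
            "letters": [letters.get(lv, "") for lv in all_levels],
        }
    )
    return GaitComparison(
        trait=trait, gait=gait, table=table, f_stat=f_stat, f_pvalue=f_p, pairwise=pairwise
    )
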