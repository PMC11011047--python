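"""Posterior summaries and convergence diagnostics.

Transforms covariance-component draws to heritabilities and genetic
correlations (always draw-wise, never on posterior means), and provides
Geweke's Z, a batch-means Monte Carlo standard error and
highest-posterior-density intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PosteriorSamples


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal-style rounding, .5 always away from zero."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def point_heritability(sigma_pe: float, sigma_u: float, sigma_e: float) -> float:
    """h² from point (e.g. posterior-mean) variance components."""
    return sigma_u / (sigma_pe + sigma_u + sigma_e)


def _summary(draws: np.ndarray, mass: float = 0.95) -> dict:
    return {
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0,
        "median": float(np.median(draws)),
        "hpd95": hpd_interval(draws, mass) if len(draws) >= 100 else (float("nan"),) * 2,
    }


def heritability_samples(samples: PosteriorSamples, trait: str) -> tuple[np.ndarray, dict]:
    """Draw-wise h² = σu² / (σu² + σpe² + σe²) for one trait."""
    if samples.n_saved == 0:
        raise ValueError("zero-length chain")
    i = samples.trait_index(trait)
    su = samples.sigma_u[:, i, i]
    spe = samples.sigma_pe[:, i, i]
    se = samples.sigma_e[:, i, i]
    h2 = su / (su + spe + se)
    return h2, _summary(h2)


def genetic_correlation_samples(
    samples: PosteriorSamples, trait_i: str, trait_j: str
) -> tuple[np.ndarray, dict]:
    """Draw-wise genetic correlation between two traits of one run."""
    if samples.n_saved == 0:
        raise ValueError("zero-length chain")
    i = samples.trait_index(trait_i)
    j = samples.trait_index(trait_j)
    su = samples.sigma_u
    rg = su[:, i, j] / np.sqrt(su[:, i, i] * su[:, j, j])
    out = _summary(rg)
    lo, hi = out["hpd95"]
    out["significant"] = bool(lo > 0 or hi < 0) if np.isfinite(lo) else False
    return rg, out


def _spectral_variance(x: np.ndarray) -> float:
    """Spectral density at zero via a Bartlett (Newey–West) window."""
    n = len(x)
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    if gamma0 == 0.0:
        return 0.0
    lag = min(n - 1, int(round(4 * (n / 100.0) ** (2.0 / 9.0))))
    s = gamma0
    for k in range(1, lag + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (lag + 1.0)) * gk
    return max(s, 0.0)


def geweke_z(chain: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke's convergence Z: early vs late segment means.

    ``Z = (m_first - m_last) / sqrt(S_f/n_f + S_l/n_l)`` with
    spectral-density-at-zero variance estimates per segment.  A constant
    chain returns 0 with a warning.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for Geweke diagnostic (need >= 100)")
    a = x[: int(first_frac * n)]
    b = x[n - int(last_frac * n):]
    va = _spectral_variance(a)
    vb = _spectral_variance(b)
    denom = va / len(a) + vb / len(b)
    if denom == 0.0:
        warnings.warn("degenerate (constant) chain; Geweke Z defined as 0")
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(denom))


def mc_standard_error(chain: np.ndarray) -> float:
    """Batch-means Monte Carlo standard error with ⌊√n⌋ batches."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for MCse (need >= 100)")
    nb = int(math.isqrt(n))
    m = n // nb
    means = x[: nb * m].reshape(nb, m).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(nb))


def hpd_interval(chain: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (sliding window)."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(chain, dtype=float))
    n = len(x)
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


@dataclass
class GeneticParameterReport:
    """Per-trait heritabilities and components, pairwise correlations,
    and chain diagnostics for every monitored scalar."""

    heritability: pd.DataFrame
    components: pd.DataFrame
    correlations: pd.DataFrame
    diagnostics: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def flagged(self) -> pd.DataFrame:
        return self.diagnostics[self.diagnostics["flagged"]]

    def to_text(self) -> str:
        lines = ["Genetic parameter report", "=" * 26, "", "Heritabilities:"]
        lines.append(self.heritability.to_string(index=False))
        if len(self.correlations):
            lines += ["", "Genetic correlations:", self.correlations.to_string(index=False)]
        lines += ["", "Diagnostics:", self.diagnostics.to_string(index=False)]
        nflag = int(self.diagnostics["flagged"].sum())
        lines += ["", f"{nflag} monitored scalar(s) flagged for convergence."]
        return "\n".join(lines)


def summarize_run(
    samples: PosteriorSamples,
    mcse_threshold: float = 0.001,
    z_threshold: float = 1.96,
    ndigits: int = 2,
) -> GeneticParameterReport:
    """Assemble the full report for one completed run.

    Monitored scalars (each variance component and each trait's h²) are
    flagged when |Geweke Z| exceeds ``z_threshold`` or the batch-means
    MCse exceeds ``mcse_threshold``.
    """
    her_rows, comp_rows, diag_rows, corr_rows = [], [], [], []

    def _diag(name: str, chain: np.ndarray) -> None:
        if len(chain) >= 100:
            z = geweke_z(chain)
            mcse = mc_standard_error(chain)
            short = False
        else:
            z, mcse, short = float("nan"), float("nan"), True
        diag_rows.append(
            {
                "scalar": name,
                "geweke_z": z,
                "mcse": mcse,
                "flagged": bool(short or abs(z) > z_threshold or mcse > mcse_threshold),
            }
        )

    for trait in samples.traits:
        i = samples.trait_index(trait)
        h2, s = heritability_samples(samples, trait)
        her_rows.append(
            {
                "trait": trait,
                "h2_mean": round_half_up(s["mean"], ndigits),
                "h2_sd": s["sd"],
                "h2_median": s["median"],
                "hpd95_low": s["hpd95"][0],
                "hpd95_high": s["hpd95"][1],
            }
        )
        _diag(f"h2[{trait}]", h2)
        for comp, arr in (
            ("sigma_pe", samples.sigma_pe),
            ("sigma_u", samples.sigma_u),
            ("sigma_e", samples.sigma_e),
        ):
            chain = arr[:, i, i]
            cs = _summary(chain)
            comp_rows.append(
                {
                    "trait": trait,
                    "component": comp,
                    "mean": cs["mean"],
                    "median": cs["median"],
                    "hpd95_low": cs["hpd95"][0],
                    "hpd95_high": cs["hpd95"][1],
                }
            )
            _diag(f"{comp}[{trait}]", chain)

    for a in range(len(samples.traits)):
        for b in range(a + 1, len(samples.traits)):
            ti, tj = samples.traits[a], samples.traits[b]
            rg, s = genetic_correlation_samples(samples, ti, tj)
            corr_rows.append(
                {
                    "trait_i": ti,
                    "trait_j": tj,
                    "rg_mean": round_half_up(s["mean"], ndigits),
                    "rg_sd": s["sd"],
                    "significant": s["significant"],
                }
            )
            _diag(f"rg[{ti},{tj}]", rg)

    return GeneticParameterReport(
        heritability=pd.DataFrame(her_rows),
        components=pd.DataFrame(comp_rows),
        correlations=pd.DataFrame(
            corr_rows, columns=["trait_i", "trait_j", "rg_mean", "rg_sd", "significant"]
        ),
        diagnostics=pd.DataFrame(diag_rows),
        meta=dict(samples.meta),
    )
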