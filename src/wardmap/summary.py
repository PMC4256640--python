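"""Posterior reporting: means, 95% credible regions, exceedance classes.

The reporting surface of a disease-mapping fit is (i) a table of posterior
means with 95% credible regions for the fixed effects and (ii) a per-ward
three-way classification of the spatial effect at a nominal level (default
80%): *positive* if the central 80% credible interval lies entirely above
zero, *negative* if entirely below, *null* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import WardGraph
from .sampler import ChainSet

__all__ = [
    "PosteriorSummary",
    "summarize",
    "classify_at_level",
    "spatial_summary",
    "fixed_effect_summaries",
    "convergence_report",
    "effective_sample_size",
]


@dataclass(frozen=True)
class PosteriorSummary:
    name: str
    posterior_mean: float
    lower95: float
    upper95: float
    prob_positive: float
    class80: str  # "positive" | "negative" | "null"


def _check_draws(draws) -> np.ndarray:
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 draws to summarize")
    return draws


def classify_at_level(draws, nominal: float = 0.80) -> str:
    """Three-way class from the central credible interval at ``nominal`` level."""
    if not 0.0 < nominal < 1.0:
        raise ValueError("nominal level must lie in (0, 1)")
    draws = _check_draws(draws)
    alpha = (1.0 - nominal) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "null"


def summarize(draws, name: str, nominal: float = 0.80) -> PosteriorSummary:
    """Posterior mean, 95% credible region (empirical percentiles, linear
    interpolation), exceedance probability and the nominal-level class."""
    draws = _check_draws(draws)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PosteriorSummary(
        name=name,
        posterior_mean=float(np.mean(draws)),
        lower95=float(lo),
        upper95=float(hi),
        prob_positive=float(np.mean(draws > 0)),
        class80=classify_at_level(draws, nominal),
    )


def fixed_effect_summaries(chains: ChainSet, nominal: float = 0.80) -> list[PosteriorSummary]:
    """Effect-table rows: the constant first, then each fixed effect."""
    out = []
    if "intercept" in chains.draws:
        out.append(summarize(chains.draws["intercept"], "constant", nominal))
    for j, name in enumerate(chains.fixed_names):
        out.append(summarize(chains.draws["fixed"][:, j], name, nominal))
    return out


def spatial_summary(
    chains: ChainSet, graph: WardGraph, nominal: float = 0.80
) -> list[PosteriorSummary]:
    """Per-ward summaries of the spatial effect, in graph order."""
    if "spatial" not in chains.draws:
        raise ValueError("chains contain no spatial draws")
    spat = chains.draws["spatial"]
    if spat.shape[1] != graph.n_nodes:
        raise ValueError(
            f"chains have {spat.shape[1]} spatial columns but graph has {graph.n_nodes} wards"
        )
    cols = {wid: i for i, wid in enumerate(chains.ward_ids)}
    out = []
    for wid in graph.node_ids:
        if wid not in cols:
            raise ValueError(f"graph ward {wid!r} missing from chains")
        out.append(summarize(spat[:, cols[wid]], wid, nominal))
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    """Autocorrelation at all lags via FFT."""
    n = len(x)
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.r_[1.0, np.zeros(n - 1)]
    return acov / acov[0]


def effective_sample_size(x) -> float:
    """ESS via Geyer's initial-positive-sequence estimator.

    Sums of adjacent autocorrelation pairs of a reversible chain are
    positive; the integrated autocorrelation time is estimated by summing
    pairs until the first non-positive one.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 draws for an ESS estimate")
    if np.var(x) == 0:
        return float("nan")
    rho = _autocorrelations(x)
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(n / tau)


def lag1_autocorrelation(x) -> float:
    x = np.asarray(x, dtype=float).ravel()
    if np.var(x) == 0:
        return float("nan")
    return float(_autocorrelations(x)[1])


def convergence_report(chains: ChainSet) -> dict[str, dict[str, float]]:
    """Per-quantity ESS and lag-1 autocorrelation for the run log.

    Vector quantities report the minimum ESS / maximum |lag-1| across their
    components.  Degenerate (constant) chains report NaN rather than a
    number.
    """
    if chains.n_retained < 50:
        raise ValueError("need at least 50 retained draws for diagnostics")
    report: dict[str, dict[str, float]] = {}
    for name, arr in chains.draws.items():
        mat = arr[:, None] if arr.ndim == 1 else arr
        ess_vals, ac_vals = [], []
        for j in range(mat.shape[1]):
            col = mat[:, j]
            if np.var(col) == 0:
                ess_vals.append(float("nan"))
                ac_vals.append(float("nan"))
            else:
                ess_vals.append(effective_sample_size(col))
                ac_vals.append(lag1_autocorrelation(col))
        ess_arr = np.asarray(ess_vals)
        ac_arr = np.asarray(ac_vals)
        report[name] = {
            "ess": float(np.nanmin(ess_arr)) if not np.all(np.isnan(ess_arr)) else float("nan"),
            "lag1_autocorr": float(np.nanmax(np.abs(ac_arr)))
            if not np.all(np.isnan(ac_arr))
            else float("nan"),
        }
    return report
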