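"""Posterior functionals: risk maps, exceedance probabilities, effect tables, R².

All operations consume :class:`~lgcpmap.lgcpfit.PosteriorSamples` — a
matrix of joint draws — so every summary is a plain Monte-Carlo
functional and the same code serves LGCP and BYM fits.

Medians use the mean-of-central-pair convention for even draw counts
(numpy's default), and the spatial relative risk is exp{Z(s)}: the
multiplicative deviation of local risk from the national level after
standardisation for population, age and year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RiskMap",
    "ExceedanceMap",
    "R2Summary",
    "rr_map",
    "exceedance_map",
    "fixed_effects_table",
    "bayesian_r2",
    "render_map",
]


@dataclass
class RiskMap:
    """Cellwise posterior median relative risk with its range over cells."""

    rr: np.ndarray
    rr_min: float
    rr_max: float
    rr_median: float   # median over cells of the cellwise medians
    kind: str = "spatial"  # spatial exp(Z) | total exp(Xb - mean + Z)

    def to_csv(self, path: str | Path, centroids: np.ndarray | None = None) -> None:
        df = pd.DataFrame({"k": np.arange(self.rr.size), "rr": self.rr})
        if centroids is not None:
            df.insert(1, "x_km", centroids[:, 0])
            df.insert(2, "y_km", centroids[:, 1])
        df.to_csv(path, index=False)


@dataclass
class ExceedanceMap:
    """Posterior probability per cell that the relative risk exceeds a threshold."""

    prob: np.ndarray
    threshold: float = 1.0
    highlight: float = 0.80

    def to_csv(self, path: str | Path, centroids: np.ndarray | None = None) -> None:
        df = pd.DataFrame({"k": np.arange(self.prob.size), "prob": self.prob})
        if centroids is not None:
            df.insert(1, "x_km", centroids[:, 0])
            df.insert(2, "y_km", centroids[:, 1])
        df.to_csv(path, index=False)


@dataclass
class R2Summary:
    """Posterior draws of explained spatial variance V(Xb)/(V(Xb)+V(Z))."""

    draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n_degenerate: int = 0  # draws where both variances were zero (ratio set to 0)


def rr_map(samples, include_covariates: bool = False) -> RiskMap:
    """Cellwise posterior median of the relative-risk surface.

    By default maps the spatial field exp{Z(s)} only; with
    ``include_covariates`` the centred covariate contribution is added,
    giving a total predicted-risk map exp{Xb - mean(Xb) + Z}.
    """
    if len(samples) == 0:
        raise ValueError("no posterior draws supplied")
    log_rr = samples.z_cells
    if include_covariates:
        xb = samples.beta @ samples.design.T          # (n, K)
        log_rr = log_rr + xb - xb.mean(axis=1, keepdims=True)
    rr = np.exp(np.median(log_rr, axis=0))
    return RiskMap(
        rr=rr, rr_min=float(rr.min()), rr_max=float(rr.max()),
        rr_median=float(np.median(rr)),
        kind="total" if include_covariates else "spatial",
    )


def exceedance_map(samples, threshold: float = 1.0,
                   highlight: float = 0.80) -> ExceedanceMap:
    """Per cell, the fraction of draws with exp(Z) strictly above the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(samples) == 0:
        raise ValueError("no posterior draws supplied")
    prob = np.mean(np.exp(samples.z_cells) > threshold, axis=0)
    return ExceedanceMap(prob=prob, threshold=threshold, highlight=highlight)


def fixed_effects_table(samples) -> pd.DataFrame:
    """Posterior median RR = exp(beta_i) with equal-tailed 95% CI per coefficient.

    Continuous covariates are SD-scaled upstream, so their RR is the
    multiplicative change in risk per 1 SD increase; indicators are
    contrasts against their reference level.
    """
    if len(samples) == 0:
        raise ValueError("no posterior draws supplied")
    # summarised on the log scale then exponentiated: quantiles commute
    # exactly with the monotone map this way
    med = np.exp(np.median(samples.beta, axis=0))
    lo, hi = np.exp(np.percentile(samples.beta, [2.5, 97.5], axis=0))
    return pd.DataFrame({
        "covariate": samples.columns,
        "rr_median": med, "rr_lo": lo, "rr_hi": hi,
    })


def bayesian_r2(samples) -> R2Summary:
    """Explained spatial variance, draw by draw.

    R² = V(Xβ) / (V(Xβ) + V(Z)) with V(·) the variance over the K
    spatial units; the posterior of R² is summarised by its median and
    equal-tailed 95% interval.  Draws where both variances vanish are
    defined as 0 and counted.
    """
    if len(samples) == 0:
        raise ValueError("no posterior draws supplied")
    xb = samples.beta @ samples.design.T
    v_fix = xb.var(axis=1)
    v_z = samples.z_cells.var(axis=1)
    denom = v_fix + v_z
    degenerate = denom == 0
    with np.errstate(invalid="ignore"):
        draws = np.where(degenerate, 0.0, v_fix / np.where(degenerate, 1.0, denom))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return R2Summary(
        draws=draws, median=float(np.median(draws)),
        ci_low=float(lo), ci_high=float(hi),
        n_degenerate=int(degenerate.sum()),
    )


def render_map(values: np.ndarray, centroids: np.ndarray, path: str | Path,
               title: str = "", highlight_above: float | None = None) -> None:
    """Render a cell-level surface to an image file.

    For exceedance maps pass ``highlight_above=0.80`` to outline cells
    whose posterior exceedance probability is above the display
    threshold.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(centroids[:, 0], centroids[:, 1], c=values, s=8,
                    marker="s", cmap="viridis")
    if highlight_above is not None:
        hot = values > highlight_above
        if hot.any():
            ax.scatter(centroids[hot, 0], centroids[hot, 1], s=10,
                       facecolors="none", edgecolors="red", marker="s",
                       linewidths=0.5)
    fig.colorbar(sc, ax=ax)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
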