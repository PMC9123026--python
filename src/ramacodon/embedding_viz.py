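"""Uncertainty-aware MDS and the publication plots.

Two visual devices summarize the pairwise comparisons:

* An MDS variant in which each codon c is represented not by a point but
  by an isotropic 2-D normal N(mu_c, sigma_c^2 I).  The self-distance of a
  codon is pure estimation noise; since the expected squared distance
  between two draws from N(mu_c, sigma_c^2 I) is 4 sigma_c^2, the scale is
  read off the diagonal as sigma_c = 0.5 * d(c, c).  The expected squared
  cross distance is ||mu_c - mu_c'||^2 + 0.5 (d(c,c)^2 + d(c',c')^2), so
  classical (Torgerson) MDS is run on the noise-corrected target distances
  delta(c,c')^2 = d(c,c')^2 - 0.5 (d(c,c)^2 + d(c',c')^2), clamped at zero.

* Ramachandran contour plots with bootstrap confidence bands: the
  lambda-super-level sets of the bootstrap-averaged KDE are drawn as mean
  contours, and the per-bootstrap binary super-level images are averaged;
  the region where that average lies strictly between alpha and 1 - alpha
  is the [alpha, 1-alpha] confidence band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .density import (
    DEFAULT_BANDWIDTH,
    DEFAULT_GRID_SIZE,
    estimate_density,
    grid_axis,
    level_threshold,
)

__all__ = [
    "EmbeddingLayout",
    "ContourSet",
    "uncertainty_mds",
    "confidence_contours",
    "plot_ramachandran",
    "plot_pvalue_bh_curve",
    "plot_distance_matrix",
    "plot_mds",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.1, 0.5, 0.9)


@dataclass
class EmbeddingLayout:
    """Per-codon 2-D location and uncertainty radius."""

    locations: np.ndarray  # (n, 2), mean-centered
    scales: np.ndarray  # (n,), sigma_c = 0.5 * d(c, c)


@dataclass
class ContourSet:
    """Mean super-level masks and bootstrap confidence bands per level."""

    levels: tuple
    mean_density: np.ndarray
    mean_masks: dict  # level -> bool grid mask of the averaged density
    band_masks: dict  # level -> bool grid mask (alpha < mean binary < 1-alpha)
    avg_binary: dict  # level -> float grid (mean of per-bootstrap masks)
    grid_size: int


def uncertainty_mds(raw_distances, literal_formula: bool = False) -> EmbeddingLayout:
    """Embed a distance matrix with self-distances as 2-D points + radii.

    ``raw_distances`` is the square matrix of bootstrap-mean L1 distances
    including the diagonal self-distances.  ``literal_formula`` switches
    the subtracted average inside the target distance from the
    derivation-consistent 0.5*(d(c,c)^2 + d(c',c')^2) to
    0.5*(d(c,c)^2 + d(c,c')^2).
    """
    d = np.asarray(raw_distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    d2 = np.square(d)
    diag2 = np.diag(d2)
    scales = 0.5 * np.sqrt(diag2)
    if literal_formula:
        delta2 = d2 - 0.5 * (diag2[:, None] + d2)
    else:
        delta2 = d2 - 0.5 * (diag2[:, None] + diag2[None, :])
    n_clamped = int(np.sum(delta2 < 0) - np.sum(np.diag(delta2) < 0))
    if n_clamped:
        logger.info("clamped %d negative squared target distances", n_clamped)
    delta2 = np.clip(delta2, 0.0, None)
    np.fill_diagonal(delta2, 0.0)
    delta2 = 0.5 * (delta2 + delta2.T)  # symmetrize fp noise

    # classical MDS: double-center, eigendecompose, keep the top plane
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ delta2 @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:2]
    w_top = np.clip(w[idx], 0.0, None)
    locations = v[:, idx] * np.sqrt(w_top)
    locations = locations - locations.mean(axis=0)
    return EmbeddingLayout(locations, scales)


def confidence_contours(
    samples,
    levels=DEFAULT_LEVELS,
    alpha: float = 0.1,
    B: int = 1000,
    n_max: int = 200,
    seed=None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ContourSet:
    """Bootstrap mean contours and confidence bands of a dihedral sample.

    B bootstrap samples of size min(N, n_max) are drawn with replacement;
    each yields a KDE and, per level lambda, a binary super-level image.
    The mean contours are the lambda-super-level masks of the averaged
    density; the bands are where the averaged binary image lies strictly
    between alpha and 1 - alpha.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("cannot plot an empty sample")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n = min(len(samples), n_max)
    levels = tuple(levels)
    sum_density = np.zeros((grid_size, grid_size))
    sum_binary = {lam: np.zeros((grid_size, grid_size)) for lam in levels}
    for _ in range(B):
        boot = samples[rng.integers(len(samples), size=n)]
        f = estimate_density(boot, bandwidth, grid_size)
        sum_density += f.values
        for lam in levels:
            tau_b = level_threshold(f, lam)
            sum_binary[lam] += f.values >= tau_b
    mean_density = sum_density / B
    mean_density /= mean_density.sum()
    from .density import TorusDensity

    mean_f = TorusDensity(mean_density, bandwidth, grid_size)
    mean_masks = {}
    band_masks = {}
    avg_binary = {}
    for lam in levels:
        tau = level_threshold(mean_f, lam)
        mean_masks[lam] = mean_density >= tau
        avg = sum_binary[lam] / B
        avg_binary[lam] = avg
        band_masks[lam] = (avg > alpha) & (avg < 1.0 - alpha)
    return ContourSet(levels, mean_density, mean_masks, band_masks,
                      avg_binary, grid_size)


def _extent():
    return (-180, 180, -180, 180)


def plot_ramachandran(contour_sets: dict, output_path) -> None:
    """Contour plots with confidence bands, one panel per codon.

    ``contour_sets`` maps codon label -> ContourSet.  Mean contours are
    drawn for every level; the shaded regions are the bootstrap bands.
    """
    if not contour_sets:
        raise ValueError("no contour sets to plot")
    n = len(contour_sets)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (label, cs) in zip(axes[0], sorted(contour_sets.items())):
        ax_vals = grid_axis(cs.grid_size)
        for lam in cs.levels:
            band = cs.band_masks[lam].T.astype(float)
            ax.contourf(ax_vals, ax_vals, band, levels=[0.5, 1.5],
                        colors=["#77aadd"], alpha=0.35)
            mask = cs.mean_masks[lam].T.astype(float)
            ax.contour(ax_vals, ax_vals, mask, levels=[0.5],
                       colors="k", linewidths=0.8)
        ax.set_xlim(-180, 180)
        ax.set_ylim(-180, 180)
        ax.set_xlabel(r"$\varphi$ [deg]")
        ax.set_ylabel(r"$\psi$ [deg]")
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)


def plot_pvalue_bh_curve(p_values, q: float, output_path, decision=None) -> None:
    """Sorted p-values against rank with the q*i/M rejection curve."""
    ps = np.sort(np.asarray([p for _, p in p_values], dtype=float))
    m = len(ps)
    ranks = np.arange(1, m + 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    rejected_mask = np.zeros(m, dtype=bool)
    if decision is not None and decision.alpha_M is not None:
        rejected_mask = ps < decision.alpha_M
    ax.semilogy(ranks[~rejected_mask], ps[~rejected_mask], "o", mfc="none",
                color="gray", label="not rejected")
    if rejected_mask.any():
        ax.semilogy(ranks[rejected_mask], ps[rejected_mask], "o",
                    color="green", label="rejected")
    ax.semilogy(ranks, q * ranks / m, "r-", label=f"q·i/M (q={q})")
    ax.set_xlabel("rank i")
    ax.set_ylabel("p-value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)


def plot_distance_matrix(normalized, labels, output_path) -> None:
    """Heatmap of the normalized distance matrix (self-distance = 1)."""
    mat = np.asarray(normalized, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(mat, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90)
    ax.set_yticks(range(len(labels)), labels)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)


def plot_mds(layout: EmbeddingLayout, labels, output_path) -> None:
    """Scatter of MDS locations with uncertainty circles of radius sigma."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for (x, y), r, lab in zip(layout.locations, layout.scales, labels):
        ax.plot(x, y, "o", color="C0")
        ax.add_patch(plt.Circle((x, y), r, fill=False, color="C0", alpha=0.6))
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_aspect("equal")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)
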