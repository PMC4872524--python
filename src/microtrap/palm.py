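"""Synthetic single-molecule localization data and its estimators.

Photoactivated localization microscopy (PALM) reconstructs structures far
below the diffraction limit by localizing sparse subsets of photoactivated
fluorophores over thousands of frames; each detection is the true emitter
position plus an isotropic Gaussian localization error of standard
deviation σ_loc.  This module provides

* a generator of synthetic localization tables emulating clustered
  emitters (centromere-like foci of ~200 nm) imaged over many frames,
  with simple on/off photophysics and uniform false localizations;
* a nearest-neighbour estimator of the localization precision: the same
  emitter localized in adjacent frames yields a displacement that is the
  difference of two independent Gaussian errors, so the pair distances
  follow a Rayleigh law of scale √2·σ_loc on top of a linear-in-r
  false-pair background;
* a density-based cluster finder with a Gaussian-equivalent diameter
  estimate, corrected for the localization error in quadrature;
* a simple renderer (2-D histogram with optional Gaussian blur).

All coordinates are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.neighbors import radius_neighbors_graph


class EstimationError(RuntimeError):
    """Too little data to estimate the requested quantity."""


@dataclass(frozen=True)
class EmitterModel:
    """Clustered-emitter model for synthetic PALM acquisitions.

    Emitters are placed uniformly inside disks of ``cluster_diameter``
    around the cluster centres.  Photophysics is a two-state Markov
    chain per emitter and frame: an off emitter switches on with
    probability ``activation_probability``; an on emitter stays on with
    probability ``on_persistence`` (on-runs of a few frames are what
    make adjacent-frame pairing informative).  Every on-frame yields one
    localization with isotropic Gaussian error ``sigma_true``; false
    localizations appear uniformly over the field of view at
    ``background_density`` per μm² per frame.
    """

    n_clusters: int = 8
    cluster_diameter: float = 200.0       # nm
    emitters_per_cluster: int = 50
    frames: int = 5000
    activation_probability: float = 0.002  # off -> on, per frame
    on_persistence: float = 0.6            # on -> on, per frame
    sigma_true: float = 12.0               # nm
    background_density: float = 0.01       # μm⁻² per frame
    fov: tuple[float, float] = (4000.0, 4000.0)   # nm
    cluster_centers: Optional[np.ndarray] = None
    min_cluster_separation: float = 600.0  # nm

    def __post_init__(self) -> None:
        if self.sigma_true < 0 or min(self.n_clusters, self.emitters_per_cluster) < 0:
            raise ValueError("counts and sigma_true must be non-negative")
        if not (0 <= self.activation_probability <= 1 and 0 <= self.on_persistence <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def _draw_centers(model: EmitterModel, rng: np.random.Generator) -> np.ndarray:
    if model.cluster_centers is not None:
        return np.asarray(model.cluster_centers, dtype=float)
    w, h = model.fov
    margin = model.cluster_diameter
    centers: list[np.ndarray] = []
    for _ in range(10_000):
        if len(centers) == model.n_clusters:
            break
        c = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(c - e)) >= model.min_cluster_separation for e in centers):
            centers.append(c)
    else:
        raise ValueError("could not place clusters with the requested separation")
    return np.array(centers)


def simulate_localizations(model: EmitterModel, rng_seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a localization table (frame, x_nm, y_nm, truth_id).

    ``truth_id`` is the global emitter index, or -1 for background false
    localizations.  With ``activation_probability`` = 1 every emitter is
    active in every frame.
    """
    rng = np.random.default_rng(rng_seed)
    centers = _draw_centers(model, rng)
    n_em = model.n_clusters * model.emitters_per_cluster
    if n_em:
        # uniform positions in each cluster disk
        r = 0.5 * model.cluster_diameter * np.sqrt(rng.random(n_em))
        th = rng.uniform(0, 2 * np.pi, n_em)
        emitters = np.repeat(centers, model.emitters_per_cluster, axis=0) + \
            np.column_stack([r * np.cos(th), r * np.sin(th)])
    else:
        emitters = np.empty((0, 2))

    # Markov on/off chain, vectorized over emitters: fresh activation is
    # drawn every frame; an emitter active in the previous frame may in
    # addition persist, so P(on|prev on) = 1-(1-q)(1-p), P(on|prev off) = p.
    p_act, q_on = model.activation_probability, model.on_persistence
    p_stay = q_on + p_act - q_on * p_act
    on = np.zeros(n_em, dtype=bool)
    frames_out, ids_out = [], []
    for f in range(model.frames):
        u01 = rng.random(n_em)
        on = np.where(on, u01 < p_stay, u01 < p_act)
        idx = np.nonzero(on)[0]
        if idx.size:
            frames_out.append(np.full(idx.size, f))
            ids_out.append(idx)
    if frames_out:
        frame = np.concatenate(frames_out)
        emitter_id = np.concatenate(ids_out)
        xy = emitters[emitter_id] + rng.normal(0.0, model.sigma_true, (frame.size, 2)) \
            if model.sigma_true > 0 else emitters[emitter_id].astype(float)
    else:
        frame = np.empty(0, int)
        emitter_id = np.empty(0, int)
        xy = np.empty((0, 2))

    # uniform background false localizations
    area_um2 = model.fov[0] * model.fov[1] * 1e-6
    lam = model.background_density * area_um2
    n_bg = rng.poisson(lam, model.frames) if lam > 0 else np.zeros(model.frames, int)
    tot_bg = int(n_bg.sum())
    if tot_bg:
        bg_frames = np.repeat(np.arange(model.frames), n_bg)
        bg_xy = rng.uniform([0, 0], list(model.fov), (tot_bg, 2))
        frame = np.concatenate([frame, bg_frames])
        xy = np.vstack([xy, bg_xy])
        emitter_id = np.concatenate([emitter_id, np.full(tot_bg, -1)])

    order = np.argsort(frame, kind="stable")
    return pd.DataFrame({
        "frame": frame[order].astype(int),
        "x_nm": xy[order, 0],
        "y_nm": xy[order, 1],
        "truth_id": emitter_id[order].astype(int),
    })


# ---------------------------------------------------------------------------
# Localization-table IO
# ---------------------------------------------------------------------------

def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV with header frame,x_nm,y_nm[,truth_id]."""
    df = pd.read_csv(path)
    missing = {"frame", "x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    if (df["frame"] < 0).any():
        raise ValueError("frame indices must be non-negative")
    if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy()).all():
        raise ValueError("coordinates must be finite")
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("frame", "x_nm", "y_nm", "truth_id") if c in df.columns]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Nearest-neighbour localization precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionEstimate:
    sigma_loc: float            # nm
    ci_low: float
    ci_high: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.sigma_loc <= self.ci_high):
            raise ValueError("confidence interval must contain the estimate")


def _adjacent_frame_distances(df: pd.DataFrame, max_pair_distance: float) -> np.ndarray:
    frames = df["frame"].to_numpy()
    xy = df[["x_nm", "y_nm"]].to_numpy()
    order = np.argsort(frames, kind="stable")
    frames, xy = frames[order], xy[order]
    uniq, starts = np.unique(frames, return_index=True)
    bounds = dict(zip(uniq, zip(starts, np.append(starts[1:], len(frames)))))
    dists = []
    for f in uniq:
        if f + 1 not in bounds:
            continue
        a0, a1 = bounds[f]
        b0, b1 = bounds[f + 1]
        tree = cKDTree(xy[b0:b1])
        d, _ = tree.query(xy[a0:a1], k=1, distance_upper_bound=max_pair_distance)
        dists.append(d[np.isfinite(d)])
    return np.concatenate(dists) if dists else np.empty(0)


def _fit_rayleigh_plus_linear(dists: np.ndarray, rmax: float, bin_width: float):
    bins = np.arange(0.0, rmax + bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=bins)
    r = 0.5 * (edges[:-1] + edges[1:])

    def model(rr, amp, s, bg):
        return amp * (rr / s**2) * np.exp(-rr**2 / (2 * s**2)) + bg * rr

    s0 = max(np.median(dists) / 1.18, bin_width)   # Rayleigh median = s·√(2 ln 2)
    amp0 = counts.max() * s0 * np.e**0.5 if counts.max() > 0 else 1.0
    try:
        popt, _ = optimize.curve_fit(
            model, r, counts, p0=[amp0, s0, 0.0],
            bounds=([0.0, 1e-3, 0.0], [np.inf, rmax, np.inf]), maxfev=20_000,
        )
    except RuntimeError as exc:
        raise EstimationError(f"Rayleigh fit did not converge: {exc}") from exc
    return popt[1]


def nn_precision(
    table: pd.DataFrame,
    max_pair_distance: float = 100.0,
    bin_width: float = 2.0,
    n_bootstrap: int = 200,
    rng_seed: Optional[int] = None,
) -> PrecisionEstimate:
    """Estimate σ_loc from nearest-neighbour distances in adjacent frames.

    For every localization, its nearest neighbour in the following frame
    within ``max_pair_distance`` is collected; same-emitter pairs follow
    a Rayleigh distribution of scale √2·σ_loc, false pairs a linear
    background.  Both are fitted to the binned distances and σ_loc
    returned with a bootstrap percentile confidence interval.
    """
    if table["frame"].nunique() < 2:
        raise EstimationError("need localizations in at least two frames")
    dists = _adjacent_frame_distances(table, max_pair_distance)
    if dists.size < 100:
        raise EstimationError(f"only {dists.size} candidate pairs (need >= 100)")
    s = _fit_rayleigh_plus_linear(dists, max_pair_distance, bin_width)
    sigma = s / np.sqrt(2.0)
    rng = np.random.default_rng(rng_seed)
    boot = []
    for _ in range(n_bootstrap):
        sample = rng.choice(dists, dists.size, replace=True)
        try:
            boot.append(_fit_rayleigh_plus_linear(sample, max_pair_distance, bin_width))
        except EstimationError:
            continue
    if boot:
        lo, hi = np.percentile(np.asarray(boot) / np.sqrt(2.0), [2.5, 97.5])
        lo, hi = min(lo, sigma), max(hi, sigma)
    else:
        lo = hi = sigma
    return PrecisionEstimate(sigma_loc=float(sigma), ci_low=float(lo),
                             ci_high=float(hi), n_pairs=int(dists.size))


# ---------------------------------------------------------------------------
# Cluster identification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterReport:
    n_clusters: int
    centroids: np.ndarray           # (k, 2) nm
    counts: np.ndarray              # localizations per cluster
    diameters: np.ndarray           # Gaussian-equivalent full widths, nm

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_nm": self.centroids[:, 0], "y_nm": self.centroids[:, 1],
            "n_localizations": self.counts, "diameter_nm": self.diameters,
        })


def cluster_centromeres(
    table: pd.DataFrame,
    radius: float = 50.0,
    min_points: int = 10,
    sigma_loc: float = 0.0,
) -> ClusterReport:
    """Find localization clusters by single-linkage connectivity.

    Two localizations are connected when within ``radius`` nm; clusters
    are connected components with at least ``min_points`` members.  The
    diameter estimate is 2√2 × the RMS distance to the centroid (the
    full width of the uniform disk with the same second moment), with
    ``sigma_loc`` subtracted in quadrature to remove the blur of the
    localization error.
    """
    xy = table[["x_nm", "y_nm"]].to_numpy()
    if len(xy) == 0:
        empty = np.empty(0)
        return ClusterReport(0, np.empty((0, 2)), empty.astype(int), empty)
    graph = radius_neighbors_graph(xy, radius=radius, mode="connectivity",
                                   include_self=False)
    n_comp, labels = connected_components(graph, directed=False)
    cents, counts, diams = [], [], []
    for k in range(n_comp):
        members = xy[labels == k]
        if len(members) < min_points:
            continue
        c = members.mean(axis=0)
        ms = ((members - c) ** 2).sum(axis=1).mean()
        ms = max(ms - 2 * sigma_loc**2, 0.0)   # subtract isotropic error variance
        cents.append(c)
        counts.append(len(members))
        diams.append(2.0 * np.sqrt(2.0 * ms))
    if not cents:
        empty = np.empty(0)
        return ClusterReport(0, np.empty((0, 2)), empty.astype(int), empty)
    return ClusterReport(
        n_clusters=len(cents), centroids=np.array(cents),
        counts=np.array(counts, dtype=int), diameters=np.array(diams),
    )


def render_map(
    table: pd.DataFrame,
    pixel: float = 10.0,
    blur_sigma: float = 0.0,
    extent: Optional[tuple[float, float, float, float]] = None,
) -> np.ndarray:
    """Rasterize localizations to an intensity grid (counts per pixel).

    ``pixel`` is the pixel size in nm, ``blur_sigma`` an optional
    Gaussian blur in pixels.  Row index corresponds to y.
    """
    if pixel <= 0:
        raise ValueError("pixel size must be positive")
    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    if extent is None:
        extent = (x.min(), x.max() + pixel, y.min(), y.max() + pixel)
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / pixel)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel)), 1)
    img, _, _ = np.histogram2d(y, x, bins=[ny, nx],
                               range=[[y0, y0 + ny * pixel], [x0, x0 + nx * pixel]])
    if blur_sigma > 0:
        # pad so the kernel never runs off the grid (blur conserves counts)
        pad = int(np.ceil(4 * blur_sigma)) + 1
        img = np.pad(img, pad)
        img = ndimage.gaussian_filter(img, blur_sigma, mode="constant")
    return img
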