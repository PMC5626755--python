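"""Weighted-histogram (WHAM) reconstruction of 1D/2D potentials of mean force
from umbrella-sampling windows.

The estimator is the standard self-consistent WHAM iteration: with per-window
histograms h_k(b), sample counts N_k and bias energies U_k(x_b), the unbiased
probability and window free-energy offsets are iterated,

    p(b)  = sum_k h_k(b) / sum_k N_k exp[(f_k - U_k(x_b)) / kT]
    f_k   = -kT ln sum_b p(b) exp[-U_k(x_b) / kT]

until the largest offset change falls below the tolerance.  The PMF is
-kT ln p, anchored so its minimum over defined bins is exactly zero.  The
harmonic bias is (1/2) k (x - x0)^2 with k the elastic constant as given
(a convention toggle for the k (x-x0)^2 form used by some codes is provided).

For 2D profiles the second coordinate is unbiased ("added with zero force
constant"): the window offsets converge on the biased-axis marginal and the
2D unbiased density is assembled from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL_MOL_K
from .trajio import AtomSelection, Structure, Trajectory

logger = logging.getLogger("stardynet")

__all__ = [
    "UmbrellaWindow",
    "UmbrellaDataset",
    "PmfProfile",
    "reaction_coordinate",
    "wham_1d",
    "wham_2d",
    "bootstrap_errors",
    "write_umbrella_dataset",
    "read_umbrella_dataset",
]


@dataclass
class UmbrellaWindow:
    """One harmonic umbrella window: bias parameters plus sampled series.

    ``center`` in Angstrom, ``force_constant`` in kcal/mol/A^2, ``samples_x``
    the reaction-coordinate series after equilibration discard; ``samples_y``
    an optional unbiased auxiliary coordinate sampled alongside x.
    """

    center: float
    force_constant: float
    samples_x: np.ndarray
    samples_y: np.ndarray | None = None
    burn_in_discarded: bool = True

    def __post_init__(self) -> None:
        self.samples_x = np.asarray(self.samples_x, dtype=float).ravel()
        if self.samples_y is not None:
            self.samples_y = np.asarray(self.samples_y, dtype=float).ravel()
            if len(self.samples_y) != len(self.samples_x):
                raise ValueError("samples_y length must match samples_x")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if len(self.samples_x) == 0:
            raise ValueError(f"empty umbrella window at center {self.center}")


@dataclass
class UmbrellaDataset:
    """Umbrella windows plus the sampling temperature (K)."""

    windows: list[UmbrellaWindow]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("dataset has no windows")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        self._check_overlap()

    def _check_overlap(self) -> None:
        ws = sorted(self.windows, key=lambda w: w.center)
        for a, b in zip(ws, ws[1:]):
            if a.samples_x.max() < b.samples_x.min():
                logger.warning(
                    "umbrella windows at %.3f and %.3f have no histogram "
                    "overlap", a.center, b.center,
                )

    @property
    def kt(self) -> float:
        return KB_KCAL_MOL_K * self.temperature


@dataclass
class PmfProfile:
    """A reconstructed free-energy profile.

    ``bin_centers`` is a 1D array (1D PMF) or an (x_centers, y_centers) tuple
    (2D); ``free_energy`` in kcal/mol with NaN marking bins that received no
    samples (reported as undefined, never interpolated); minimum over defined
    bins is anchored to 0.
    """

    bin_centers: object
    free_energy: np.ndarray
    n_samples: np.ndarray
    temperature: float
    errors: np.ndarray | None = None
    n_iterations: int = 0
    window_offsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def reaction_coordinate(
    traj: Trajectory, group_a: AtomSelection, group_b: AtomSelection
) -> np.ndarray:
    """Per-frame distance between mass-weighted centers of the two groups."""
    ia, ib = group_a.resolved_ids, group_b.resolved_ids
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("reaction-coordinate groups must be non-empty")
    ma = traj.topology.masses[ia]
    mb = traj.topology.masses[ib]
    com_a = np.einsum("fij,i->fj", traj.frames[:, ia], ma) / ma.sum()
    com_b = np.einsum("fij,i->fj", traj.frames[:, ib], mb) / mb.sum()
    return np.linalg.norm(com_a - com_b, axis=1)


def _bias_matrix(
    data: UmbrellaDataset, x: np.ndarray, bias_convention: str
) -> np.ndarray:
    """U_k(x_b) for every window k and bin center x_b, kcal/mol."""
    centers = np.array([w.center for w in data.windows])
    ks = np.array([w.force_constant for w in data.windows])
    dx2 = (x[None, :] - centers[:, None]) ** 2
    if bias_convention == "half_k_x2":
        return 0.5 * ks[:, None] * dx2
    if bias_convention == "k_x2":
        return ks[:, None] * dx2
    raise ValueError(f"unknown bias convention {bias_convention!r}")


def _wham_offsets(
    hist: np.ndarray,
    bias: np.ndarray,
    kt: float,
    tolerance: float,
    max_iter: int,
):
    """Self-consistent solve for window offsets f_k; returns (p, f, n_iter).

    ``hist`` is (K, B) counts, ``bias`` is (K, B) energies.  p is the
    unnormalised unbiased bin probability.
    """
    n_k = hist.sum(axis=1)
    h_sum = hist.sum(axis=0)
    f = np.zeros(len(n_k))
    boltz = np.exp(-bias / kt)  # (K, B); underflow to 0 is fine
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        for it in range(1, max_iter + 1):
            denom = (n_k * np.exp(f / kt)) @ boltz  # (B,)
            p = np.where(denom > 0, h_sum / np.maximum(denom, 1e-300), 0.0)
            p /= p.sum()
            z = boltz @ p  # (K,)
            f_new = -kt * np.log(z)
            f_new -= f_new[0]
            delta = np.max(np.abs(f_new - f))
            f = f_new
            if delta < tolerance:
                return p, f, it
    raise RuntimeError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(residual {delta:.3g} kcal/mol)"
    )


def _bin_edges(data: UmbrellaDataset, n_bins: int, bin_range):
    if bin_range is None:
        lo = min(w.samples_x.min() for w in data.windows)
        hi = max(w.samples_x.max() for w in data.windows)
    else:
        lo, hi = bin_range
    if hi <= lo:
        raise ValueError("empty reaction-coordinate range")
    return np.linspace(lo, hi, n_bins + 1)


def wham_1d(
    data: UmbrellaDataset,
    n_bins: int = 1000,
    tolerance: float = 1e-4,
    max_iter: int = 100000,
    bin_range: tuple[float, float] | None = None,
    bias_convention: str = "half_k_x2",
) -> PmfProfile:
    """Reconstruct the 1D PMF along the biased reaction coordinate.

    Defaults follow the analysis protocol for the KH-QUA2/mRNA system: 1000
    bins, offset tolerance 1e-4 kcal/mol, 300 K dataset temperature.  Bins
    with no samples are reported NaN; the defined minimum is anchored to 0.
    """
    edges = _bin_edges(data, n_bins, bin_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.stack(
        [np.histogram(w.samples_x, bins=edges)[0] for w in data.windows]
    ).astype(float)
    _warn_gaps(hist, centers)
    bias = _bias_matrix(data, centers, bias_convention)
    p, f, n_iter = _wham_offsets(hist, bias, data.kt, tolerance, max_iter)
    counts = hist.sum(axis=0)
    with np.errstate(divide="ignore"):
        pmf = np.where(counts > 0, -data.kt * np.log(np.maximum(p, 1e-300)),
                       np.nan)
    pmf -= np.nanmin(pmf)
    logger.info("WHAM 1D converged in %d iterations", n_iter)
    return PmfProfile(
        bin_centers=centers,
        free_energy=pmf,
        n_samples=counts,
        temperature=data.temperature,
        n_iterations=n_iter,
        window_offsets=f,
    )


def _warn_gaps(hist: np.ndarray, centers: np.ndarray) -> None:
    total = hist.sum(axis=0)
    occupied = np.flatnonzero(total > 0)
    if len(occupied) == 0:
        raise ValueError("no samples fall inside the binning range")
    interior = total[occupied[0]: occupied[-1] + 1]
    empty = interior == 0
    # single empty bins at fine resolution are normal; warn on contiguous gaps
    run, best, best_end = 0, 0, 0
    for k, e in enumerate(empty):
        run = run + 1 if e else 0
        if run > best:
            best, best_end = run, k
    if best > max(2, len(interior) // 50):
        lo = centers[occupied[0] + best_end - best + 1]
        hi = centers[occupied[0] + best_end]
        logger.warning(
            "empty histogram region between %.3f and %.3f A: adjacent "
            "windows may not overlap", lo, hi,
        )


def wham_2d(
    data: UmbrellaDataset,
    n_bins: int = 500,
    tolerance: float = 1e-4,
    n_bins_y: int = 100,
    max_iter: int = 100000,
    bin_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    bias_convention: str = "half_k_x2",
) -> PmfProfile:
    """2D PMF over (biased coordinate x, unbiased auxiliary coordinate y).

    ``n_bins`` counts bins along the biased axis (the headline "500 bins");
    the y-axis bin count is independent.  The bias depends on x only, so the
    window offsets are converged on the x-marginal and reused to unbias the
    2D histogram.
    """
    for w in data.windows:
        if w.samples_y is None:
            raise ValueError(
                f"window at center {w.center} has no auxiliary samples_y"
            )
    x_edges = _bin_edges(data, n_bins, bin_range)
    x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    if y_range is None:
        y_lo = min(w.samples_y.min() for w in data.windows)
        y_hi = max(w.samples_y.max() for w in data.windows)
    else:
        y_lo, y_hi = y_range
    y_edges = np.linspace(y_lo, y_hi, n_bins_y + 1)
    y_centers = 0.5 * (y_edges[:-1] + y_edges[1:])

    hist_x = np.stack(
        [np.histogram(w.samples_x, bins=x_edges)[0] for w in data.windows]
    ).astype(float)
    bias = _bias_matrix(data, x_centers, bias_convention)
    _, f, n_iter = _wham_offsets(hist_x, bias, data.kt, tolerance, max_iter)

    n_k = hist_x.sum(axis=1)
    with np.errstate(under="ignore"):
        denom = (n_k * np.exp(f / data.kt)) @ np.exp(-bias / data.kt)  # (B_x,)
    hist_xy = np.zeros((n_bins, n_bins_y))
    for w in data.windows:
        h, _, _ = np.histogram2d(w.samples_x, w.samples_y,
                                 bins=(x_edges, y_edges))
        hist_xy += h
    with np.errstate(divide="ignore", invalid="ignore"):
        p_xy = hist_xy / denom[:, None]
    p_xy = np.where(hist_xy > 0, p_xy, np.nan)
    total = np.nansum(p_xy)
    p_xy /= total
    with np.errstate(divide="ignore", invalid="ignore"):
        pmf = -data.kt * np.log(p_xy)
    pmf -= np.nanmin(pmf)
    logger.info("WHAM 2D: offsets converged in %d iterations", n_iter)
    return PmfProfile(
        bin_centers=(x_centers, y_centers),
        free_energy=pmf,
        n_samples=hist_xy,
        temperature=data.temperature,
        n_iterations=n_iter,
        window_offsets=f,
    )


def marginalize_y(profile: PmfProfile) -> PmfProfile:
    """Boltzmann-marginalize a 2D PMF over y: F(x) = -kT ln sum_y e^{-F/kT}."""
    if not isinstance(profile.bin_centers, tuple):
        raise ValueError("marginalize_y requires a 2D profile")
    kt = KB_KCAL_MOL_K * profile.temperature
    with np.errstate(under="ignore"):
        weights = np.nansum(np.exp(-np.nan_to_num(profile.free_energy,
                                                  nan=np.inf) / kt), axis=1)
    with np.errstate(divide="ignore"):
        fx = np.where(weights > 0, -kt * np.log(np.maximum(weights, 1e-300)),
                      np.nan)
    fx -= np.nanmin(fx)
    return PmfProfile(
        bin_centers=profile.bin_centers[0],
        free_energy=fx,
        n_samples=profile.n_samples.sum(axis=1),
        temperature=profile.temperature,
        n_iterations=profile.n_iterations,
        window_offsets=profile.window_offsets,
    )


def _block_resample(rng: np.random.Generator, x: np.ndarray,
                    block_length: int) -> np.ndarray:
    """Moving-block bootstrap resample of a series, preserving its length."""
    n = len(x)
    length = min(max(1, block_length), n)
    if length == n:
        return x.copy()
    n_blocks = int(np.ceil(n / length))
    starts = rng.integers(0, n - length + 1, size=n_blocks)
    out = np.concatenate([x[s: s + length] for s in starts])
    return out[:n]


def bootstrap_errors(
    data: UmbrellaDataset,
    n_replicates: int = 20,
    seed: int = 0,
    block_length: int | None = None,
    **wham_kwargs,
) -> PmfProfile:
    """Monte Carlo bootstrap errors for the 1D PMF.

    Within each window the reaction-coordinate series is block-resampled with
    replacement (block length defaults to sqrt(n) per window, to respect
    autocorrelation), WHAM rerun per replicate on the shared binning, and the
    per-bin error taken as the standard deviation across replicates after
    re-anchoring each replicate at its own minimum.  Returns the base profile
    with ``errors`` filled in.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if "bin_range" not in wham_kwargs or wham_kwargs["bin_range"] is None:
        lo = min(w.samples_x.min() for w in data.windows)
        hi = max(w.samples_x.max() for w in data.windows)
        wham_kwargs["bin_range"] = (lo, hi)
    base = wham_1d(data, **wham_kwargs)
    rng = np.random.default_rng(seed)
    replicates = np.full((n_replicates, len(base.free_energy)), np.nan)
    quiet = logging.getLogger("stardynet")
    level = quiet.level
    quiet.setLevel(logging.ERROR)  # replicates repeat the base-run warnings
    for r in range(n_replicates):
        windows = []
        for w in data.windows:
            bl = (block_length if block_length is not None
                  else max(1, int(np.sqrt(len(w.samples_x)))))
            windows.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    samples_x=_block_resample(rng, w.samples_x, bl),
                )
            )
        rep = wham_1d(
            UmbrellaDataset(windows, temperature=data.temperature),
            **wham_kwargs,
        )
        replicates[r] = rep.free_energy
    quiet.setLevel(level)
    import warnings

    n_finite = np.sum(np.isfinite(replicates), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        errors = np.nanstd(replicates, axis=0, ddof=1)
    errors[(n_finite < 2) | ~base.defined] = np.nan
    base.errors = errors
    return base


# --------------------------------------------------------------------------
# Plain-text window manifest IO
# --------------------------------------------------------------------------

def write_umbrella_dataset(data: UmbrellaDataset, directory,
                           timestep: float = 2.0) -> str:
    """Write windows as two/three-column text (time_ps, x[, y]) plus a YAML
    manifest listing per-window file, center and force constant.  Returns the
    manifest path."""
    import os

    import yaml

    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, w in enumerate(data.windows):
        fname = f"window_{i:02d}.dat"
        cols = [np.arange(len(w.samples_x)) * timestep, w.samples_x]
        if w.samples_y is not None:
            cols.append(w.samples_y)
        np.savetxt(os.path.join(directory, fname), np.column_stack(cols),
                   fmt="%.6f")
        entries.append({
            "file": fname,
            "center": float(w.center),
            "force_constant": float(w.force_constant),
        })
    manifest = os.path.join(directory, "windows.yaml")
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {"temperature": float(data.temperature), "windows": entries},
            fh, sort_keys=False,
        )
    return manifest


def read_umbrella_dataset(manifest_path) -> UmbrellaDataset:
    """Read a window manifest written by :func:`write_umbrella_dataset`."""
    import os

    import yaml

    with open(manifest_path) as fh:
        meta = yaml.safe_load(fh)
    base = os.path.dirname(str(manifest_path))
    windows = []
    for entry in meta["windows"]:
        table = np.loadtxt(os.path.join(base, entry["file"]), ndmin=2)
        windows.append(
            UmbrellaWindow(
                center=float(entry["center"]),
                force_constant=float(entry["force_constant"]),
                samples_x=table[:, 1],
                samples_y=table[:, 2] if table.shape[1] > 2 else None,
            )
        )
    return UmbrellaDataset(windows, temperature=float(meta["temperature"]))
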