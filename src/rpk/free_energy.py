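"""Free-energy profiles from umbrella-sampling windows.

The weighted histogram analysis method (WHAM) merges the biased window
histograms by iterating the self-consistency pair

    P(ξ_b) = Σ_i n_i(ξ_b) / Σ_i N_i exp[(f_i − w_i(ξ_b)) / RT]
    f_i    = −RT ln Σ_b P(ξ_b) exp[−w_i(ξ_b) / RT]

with harmonic biases w_i(ξ) = ½ k_i (ξ − ξ_i)², until the largest change in
any window offset f_i drops below tolerance. F(ξ) = −RT ln P, shifted so the
global minimum is zero. Equilibration is judged by time-block histogram
overlap (Bhattacharyya coefficient against the pooled histogram).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import T_DEFAULT, rt
from .io_formats import TimeSeries, UmbrellaMetadata, ValidationError, read_timeseries

log = logging.getLogger("rpk.free_energy")


class ConvergenceError(RuntimeError):
    pass


class DisconnectedSupportError(ValueError):
    pass


class FeatureError(ValueError):
    pass


@dataclass
class UmbrellaWindow:
    """One biased simulation: its CV series plus the restraint parameters."""

    cv_series: TimeSeries
    bias_center: float
    force_constant: float              # kcal mol⁻¹ Å⁻²
    discard_fraction: float = 0.2      # leading equilibration fraction dropped

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValidationError("force_constant must be > 0")
        if not 0 <= self.discard_fraction < 1:
            raise ValidationError("discard_fraction must be in [0, 1)")

    @property
    def retained(self) -> np.ndarray:
        n = len(self.cv_series)
        return self.cv_series.values[int(self.discard_fraction * n):]


def load_windows(metadata: UmbrellaMetadata,
                 discard_fraction: float = 0.2) -> list:
    """Materialise UmbrellaWindows from a metadata inventory; a missing
    series file surfaces here as an I/O error naming the entry."""
    windows = []
    for path, center, k in metadata.entries:
        try:
            series = read_timeseries(path)
        except OSError as exc:
            raise OSError(f"umbrella metadata entry {path!r}: {exc}") from exc
        windows.append(UmbrellaWindow(series, center, k, discard_fraction))
    return windows


@dataclass
class FreeEnergyProfile:
    xi: np.ndarray                      # bin centres, Å
    f: np.ndarray                       # kcal mol⁻¹, min = 0
    temperature: float
    window_offsets: np.ndarray
    iterations: int
    residual: float
    error: np.ndarray | None = None     # optional bootstrap band


@dataclass
class ProfileFeatures:
    barrier: float
    delta_g: float
    xi_reactant: float
    xi_ts: float
    xi_product: float


def _bhattacharyya(p, q):
    return float(np.sum(np.sqrt(p * q)))


def time_block_check(window: UmbrellaWindow, n_blocks: int = 4,
                     overlap_min: float = 0.9, n_bins: int = 30):
    """Split the retained series into equal time blocks and compare each
    block's histogram with the pooled one. Equilibrated iff every
    Bhattacharyya coefficient ≥ overlap_min."""
    data = window.retained
    if data.size < n_blocks * 10:
        raise ValidationError(
            f"retained series too short ({data.size}) for {n_blocks} blocks")
    edges = np.histogram_bin_edges(data, bins=n_bins)
    pooled, _ = np.histogram(data, bins=edges, density=False)
    pooled = pooled / pooled.sum()
    blocks = np.array_split(data, n_blocks)
    coeffs = []
    for b in blocks:
        h, _ = np.histogram(b, bins=edges)
        h = h / h.sum()
        coeffs.append(_bhattacharyya(h, pooled))
    coeffs = np.asarray(coeffs)
    return bool(np.all(coeffs >= overlap_min)), coeffs


def wham_solve(windows, bin_width: float = 0.05,
               temperature: float = T_DEFAULT, tol: float = 1e-7,
               max_iter: int = 100_000) -> FreeEnergyProfile:
    """Self-consistent WHAM solution on a uniform ξ grid.

    Empty interior bins are treated as missing (no infinite F) with a
    warning; empty terminal bins are truncated. Adjacent windows without
    histogram overlap trigger a warning naming the gap; a fully
    disconnected chain is an error.
    """
    if len(windows) < 2:
        raise ValidationError("WHAM needs at least 2 windows")
    kT = rt(temperature)
    data = [np.asarray(w.retained, dtype=float) for w in windows]
    lo = min(d.min() for d in data)
    hi = max(d.max() for d in data)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_win = len(windows)
    counts = np.stack([np.histogram(d, bins=edges)[0] for d in data])
    n_samples = counts.sum(axis=1).astype(float)

    # overlap diagnostics between center-adjacent windows
    order = np.argsort([w.bias_center for w in windows])
    occupied = counts > 0
    connected = False
    for a, b in zip(order[:-1], order[1:]):
        if np.any(occupied[a] & occupied[b]):
            connected = True
        else:
            warnings.warn(
                f"no histogram overlap between windows centred at "
                f"{windows[a].bias_center:.3f} and {windows[b].bias_center:.3f}")
    if not connected:
        raise DisconnectedSupportError("umbrella windows share no support")

    centers_w = np.array([w.bias_center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    bias = 0.5 * ks[:, None] * (centers[None, :] - centers_w[:, None]) ** 2
    exp_neg_bias = np.exp(-bias / kT)

    total_counts = counts.sum(axis=0).astype(float)
    nonempty = total_counts > 0
    f_i = np.zeros(n_win)
    residual = np.inf
    for it in range(1, max_iter + 1):
        denom = np.sum(n_samples[:, None] * np.exp(f_i[:, None] / kT)
                       * exp_neg_bias, axis=0)
        p = np.where(nonempty, total_counts / np.maximum(denom, 1e-300), 0.0)
        z = np.sum(p[None, :] * exp_neg_bias, axis=1)
        f_new = -kT * np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f_i)))
        f_i = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})")

    # truncate empty terminal bins; warn about interior gaps
    occ_idx = np.where(nonempty)[0]
    first, last = occ_idx[0], occ_idx[-1]
    keep = slice(first, last + 1)
    interior_empty = ~nonempty[keep]
    if interior_empty.any():
        warnings.warn(f"{int(interior_empty.sum())} empty interior bins "
                      "treated as missing")
    p = p[keep]
    centers = centers[keep]
    mask = p > 0
    f = np.full(p.shape, np.nan)
    f[mask] = -kT * np.log(p[mask])
    f -= np.nanmin(f)
    log.info("WHAM converged in %d iterations (residual %.2e)", it, residual)
    return FreeEnergyProfile(centers, f, temperature, f_i, it, residual)


def profile_features(profile: FreeEnergyProfile, reactant_range,
                     product_range) -> ProfileFeatures:
    """Reactant/product minima inside the stated ξ ranges, transition state
    as the interior maximum between them."""
    xi, f = profile.xi, profile.f
    ok = np.isfinite(f)

    def _min_in(rng):
        m = ok & (xi >= rng[0]) & (xi <= rng[1])
        if not m.any():
            raise FeatureError(f"no profile support in range {rng}")
        i = np.where(m)[0][np.argmin(f[m])]
        return i

    i_r = _min_in(reactant_range)
    i_p = _min_in(product_range)
    a, b = sorted((i_r, i_p))
    seg = slice(a + 1, b)
    if seg.start >= seg.stop:
        raise FeatureError("no interior points between the two minima")
    interior = np.where(ok[seg])[0]
    if interior.size == 0:
        raise FeatureError("no occupied interior bins between minima")
    i_ts = seg.start + interior[np.argmax(f[seg][interior])]
    if f[i_ts] <= max(f[i_r], f[i_p]):
        raise FeatureError("no interior maximum between the minima "
                           "(monotone profile)")
    return ProfileFeatures(
        barrier=float(f[i_ts] - f[i_r]),
        delta_g=float(f[i_p] - f[i_r]),
        xi_reactant=float(xi[i_r]),
        xi_ts=float(xi[i_ts]),
        xi_product=float(xi[i_p]),
    )


def bootstrap_error(windows, bin_width: float = 0.05,
                    temperature: float = T_DEFAULT, n_resamples: int = 50,
                    block_size: int = 50, seed: int = 0,
                    tol: float = 1e-6) -> FreeEnergyProfile:
    """Advisory error band by block bootstrap over retained samples: the
    profile is re-solved on resampled windows and the per-bin standard
    deviation attached to the point estimate."""
    base = wham_solve(windows, bin_width, temperature, tol=tol)
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_resamples):
        resampled = []
        for w in windows:
            d = w.retained
            n_blocks = max(1, d.size // block_size)
            blocks = np.array_split(d, n_blocks)
            pick = rng.integers(0, len(blocks), len(blocks))
            vals = np.concatenate([blocks[i] for i in pick])
            ts = TimeSeries(w.cv_series.name, np.arange(vals.size, dtype=float),
                            vals)
            resampled.append(UmbrellaWindow(ts, w.bias_center,
                                            w.force_constant, 0.0))
        try:
            prof = wham_solve(resampled, bin_width, temperature, tol=tol)
        except (ConvergenceError, DisconnectedSupportError):
            continue
        profiles.append(np.interp(base.xi, prof.xi, prof.f,
                                  left=np.nan, right=np.nan))
    if profiles:
        base.error = np.nanstd(np.stack(profiles), axis=0)
    return base
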