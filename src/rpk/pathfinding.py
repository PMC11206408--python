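"""Minimum-energy paths by climbing-image nudged elastic band (CI-NEB).

A chain of images between two minima is relaxed under the NEB force —
the true force component perpendicular to the path plus a spring force
along it (improved/upwind tangent to avoid kinks). Once the band is
roughly converged the highest image starts climbing: it feels the true
force with the parallel component inverted and no spring force, so it
converges to the saddle point. Relaxation uses FIRE-style damped dynamics.

Surfaces are analytic objects exposing ``energy(x)`` and ``gradient(x)``
on arbitrary-dimension coordinate vectors; molecular forces are out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import TimeSeries, ValidationError


@dataclass
class NebPath:
    images: np.ndarray        # (n_images, ndim)
    energies: np.ndarray
    spring_constant: float
    converged: bool
    max_perp_force: float
    n_steps: int

    @property
    def climbing_index(self) -> int:
        return int(np.argmax(self.energies))


@dataclass
class SaddleReport:
    location: np.ndarray
    energy: float
    gradient_norm: float
    eigenvalues: np.ndarray   # two smallest Hessian eigenvalues
    is_first_order_saddle: bool


def _energies_gradients(surface, images):
    e = np.empty(len(images))
    g = np.empty_like(images)
    for i, x in enumerate(images):
        try:
            e[i] = surface.energy(x if x.size > 1 else float(x[0]))
            gi = surface.gradient(x if x.size > 1 else float(x[0]))
        except Exception as exc:
            raise RuntimeError(f"gradient evaluation failed at image {i}") from exc
        g[i] = np.atleast_1d(gi)
    return e, g


def _tangents(images, energies):
    """Upwind (improved) tangent of Henkelman & Jónsson."""
    n = len(images)
    t = np.zeros_like(images)
    for i in range(1, n - 1):
        dplus = images[i + 1] - images[i]
        dminus = images[i] - images[i - 1]
        e0, e1, e2 = energies[i - 1], energies[i], energies[i + 1]
        if e2 > e1 > e0:
            tau = dplus
        elif e2 < e1 < e0:
            tau = dminus
        else:
            dmax = max(abs(e2 - e1), abs(e0 - e1))
            dmin = min(abs(e2 - e1), abs(e0 - e1))
            tau = dplus * dmax + dminus * dmin if e2 > e0 \
                else dplus * dmin + dminus * dmax
        norm = np.linalg.norm(tau)
        t[i] = tau / norm if norm > 0 else tau
    return t


def neb_optimize(surface, start, end, n_images: int = 16,
                 spring_k: float = 5.0, max_steps: int = 5000,
                 f_tol: float = 1e-4, dt_init: float = 0.05) -> NebPath:
    """Relax an image chain between two minima; returns the band with the
    climbing image at the saddle when converged (converged flag otherwise
    False — non-convergence is reported, not raised).

    The climbing image activates once the maximum NEB force drops below
    10·f_tol; it then feels the inverted-parallel true force only.
    """
    start = np.atleast_1d(np.asarray(start, dtype=float))
    end = np.atleast_1d(np.asarray(end, dtype=float))
    if n_images < 5:
        raise ValidationError("need at least 5 images")
    frac = np.linspace(0.0, 1.0, n_images)[:, None]
    images = start[None, :] * (1 - frac) + end[None, :] * frac

    # FIRE parameters (standard values)
    dt, dt_max = dt_init, 10 * dt_init
    alpha, alpha0 = 0.1, 0.1
    n_pos = 0
    v = np.zeros_like(images)
    climbing = False
    max_f = np.inf
    for step in range(1, max_steps + 1):
        e, g = _energies_gradients(surface, images)
        tang = _tangents(images, e)
        forces = np.zeros_like(images)
        i_max = int(np.argmax(e[1:-1])) + 1
        for i in range(1, n_images - 1):
            f_true = -g[i]
            f_par = np.dot(f_true, tang[i]) * tang[i]
            if climbing and i == i_max:
                forces[i] = f_true - 2.0 * f_par
            else:
                spring = spring_k * (np.linalg.norm(images[i + 1] - images[i])
                                     - np.linalg.norm(images[i] - images[i - 1]))
                forces[i] = (f_true - f_par) + spring * tang[i]
        max_f = float(np.max(np.linalg.norm(forces[1:-1], axis=1)))
        if max_f < f_tol and climbing:
            e, _ = _energies_gradients(surface, images)
            return NebPath(images, e, spring_k, True, max_f, step)
        if not climbing and max_f < 10 * f_tol:
            climbing = True
            v[:] = 0.0

        # FIRE update (endpoints pinned: their force/velocity stay zero)
        p = float(np.sum(forces * v))
        if p > 0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            n_pos = 0
            dt *= 0.5
            alpha = alpha0
            v[:] = 0.0
        v += dt * forces
        fn = np.linalg.norm(forces)
        if fn > 0:
            v = (1 - alpha) * v + alpha * fn ** -1 * np.linalg.norm(v) * forces
        images = images + dt * v
    e, _ = _energies_gradients(surface, images)
    return NebPath(images, e, spring_k, False, max_f, max_steps)


def finite_difference_hessian(surface, point, fd_step: float = 1e-4):
    """Central-difference Hessian from analytic gradients."""
    x = np.atleast_1d(np.asarray(point, dtype=float))
    n = x.size

    def grad(p):
        return np.atleast_1d(surface.gradient(p if p.size > 1 else float(p[0])))

    h = np.empty((n, n))
    for j in range(n):
        dx = np.zeros(n)
        dx[j] = fd_step
        h[:, j] = (grad(x + dx) - grad(x - dx)) / (2 * fd_step)
    return 0.5 * (h + h.T)


def verify_saddle(surface, point, fd_step: float = 1e-4,
                  f_tol: float = 1e-3) -> SaddleReport:
    """First-order saddle check: small gradient and exactly one negative
    Hessian eigenvalue (the single imaginary mode of a transition state)."""
    x = np.atleast_1d(np.asarray(point, dtype=float))
    g = np.atleast_1d(surface.gradient(x if x.size > 1 else float(x[0])))
    e = surface.energy(x if x.size > 1 else float(x[0]))
    hess = finite_difference_hessian(surface, x, fd_step)
    eig = np.sort(np.linalg.eigvalsh(hess))
    n_neg = int(np.sum(eig < 0))
    ok = bool(np.linalg.norm(g) < f_tol and n_neg == 1)
    return SaddleReport(x, float(e), float(np.linalg.norm(g)),
                        eig[:2] if eig.size >= 2 else eig, ok)


def project_path(path: NebPath, cv_functions) -> list:
    """Evaluate collective variables (e.g. sums of bond distances) along
    the image chain; paired with image energies for minimum-energy-profile
    plots. Returns one TimeSeries per CV, indexed by image number."""
    idx = np.arange(len(path.images), dtype=float)
    out = []
    for name, fn in (cv_functions.items() if isinstance(cv_functions, dict)
                     else enumerate(cv_functions)):
        vals = np.array([float(fn(img)) for img in path.images])
        out.append(TimeSeries(str(name), idx, vals, unit="A"))
    return out


def grid_stationary_points(surface, bounds, n_grid: int = 201):
    """Independent stationary-point oracle: scan a dense grid for cells
    where both gradient components change sign, polish each candidate with
    a gradient root solve, and classify by Hessian index. Returns
    (minima, saddles) as lists of (location, energy), deduplicated."""
    from scipy.optimize import root

    (x0, x1), (y0, y1) = bounds
    xs = np.linspace(x0, x1, n_grid)
    ys = np.linspace(y0, y1, n_grid)
    gx = np.empty((n_grid, n_grid))
    gy = np.empty((n_grid, n_grid))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            gx[i, j], gy[i, j] = surface.gradient(np.array([x, y]))

    minima, saddles = [], []

    def _push(bucket, p, e):
        for q, _ in bucket:
            if np.linalg.norm(q - p) < 1e-3:
                return
        bucket.append((p, e))

    for i in range(n_grid - 1):
        for j in range(n_grid - 1):
            sx = gx[i: i + 2, j: j + 2]
            sy = gy[i: i + 2, j: j + 2]
            if sx.min() < 0 < sx.max() and sy.min() < 0 < sy.max():
                guess = np.array([0.5 * (xs[i] + xs[i + 1]),
                                  0.5 * (ys[j] + ys[j + 1])])
                sol = root(lambda p: surface.gradient(p), guess, tol=1e-12)
                if not sol.success:
                    continue
                p = sol.x
                if not (x0 <= p[0] <= x1 and y0 <= p[1] <= y1):
                    continue
                eig = np.linalg.eigvalsh(finite_difference_hessian(surface, p))
                n_neg = int(np.sum(eig < 0))
                if n_neg == 0:
                    _push(minima, p, float(surface.energy(p)))
                elif n_neg == 1:
                    _push(saddles, p, float(surface.energy(p)))
    return minima, saddles
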