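"""Fuzzy C-means primitives on grayscale images.

The image model is one-dimensional: each pixel is characterised by its gray
level alone, and the distance between pixel ``x_j`` and class center ``c_i``
is the absolute intensity difference ``d_ij = |c_i - x_j|``.  The classical
algorithm alternates two closed-form updates that monotonically reduce the
cost

    J = sum_i sum_j u_ij^m d_ij^2,

where ``u_ij`` is the degree of membership of pixel ``j`` in cluster ``i``
(every pixel's memberships sum to 1) and ``m > 1`` is the fuzzifier.

A spatial variant is also provided: each membership is combined with the
summed memberships of a square neighbourhood around the pixel, which
suppresses isolated noise labels at the price of blurring thin structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from .errors import DegenerateClusterError, DegeneratePixelError

__all__ = [
    "FCMParams",
    "FCMResult",
    "update_memberships",
    "update_centers",
    "compute_cost",
    "spatial_function",
    "spatial_membership",
    "fitness_burst",
    "fcm_run",
]

GENE_RANGE = (0.0, 255.0)


@dataclass(frozen=True)
class FCMParams:
    """Parameters of the (spatial) fuzzy C-means inner loop.

    Attributes
    ----------
    n_clusters : int
        Number of intensity classes ``C``.
    m : float
        Fuzzifier, strictly greater than 1.  ``m -> 1`` approaches crisp
        nearest-center assignment; larger values smooth the memberships.
        Default 2, the standard choice.
    max_iter : int
        Cap on alternating iterations.
    tol : float
        Convergence threshold: stop when ``|J_t - J_{t-1}|`` falls below
        ``tol`` times the first recorded cost.
    spatial_enabled : bool
        Apply the neighbourhood-membership combination after each
        membership update.
    p, q : float
        Exponents weighing the plain membership (``p``) against the
        neighbourhood sum (``q``) in the spatial combination.
    window : int
        Odd side length of the square neighbourhood; truncated at borders.
    """

    n_clusters: int = 6
    m: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    spatial_enabled: bool = False
    p: float = 1.0
    q: float = 1.0
    window: int = 5

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if not self.m > 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol < 0:
            raise ValueError(f"tol must be >= 0, got {self.tol}")
        if self.p < 0 or self.q < 0:
            raise ValueError(f"spatial exponents must be >= 0, got p={self.p}, q={self.q}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")


@dataclass
class FCMResult:
    """Outcome of an alternating-update run.

    ``cost_trace`` holds one cost value per completed iteration and is
    non-increasing for the plain (non-spatial) updates.
    """

    centers: np.ndarray
    memberships: np.ndarray
    cost_trace: np.ndarray
    iterations_run: int


def _as_pixel_vector(image) -> np.ndarray:
    x = np.asarray(image, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("image must contain at least one pixel")
    if not np.all(np.isfinite(x)):
        raise ValueError("image intensities must be finite")
    return x


def _as_centers(centers) -> np.ndarray:
    c = np.asarray(centers, dtype=float).ravel()
    if c.size < 1:
        raise ValueError("centers must be non-empty")
    if not np.all(np.isfinite(c)):
        raise ValueError("centers must be finite")
    return c


def update_memberships(image, centers, m: float = 2.0) -> np.ndarray:
    """Membership update: ``u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1))``.

    Pixels coinciding exactly with a center get membership 1 in the
    lowest-indexed coincident cluster and 0 elsewhere (the zero-distance
    singularity of the closed form).

    Returns a ``(C, N)`` matrix whose columns sum to 1.
    """
    x = _as_pixel_vector(image)
    c = _as_centers(centers)
    if not m > 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")

    d = np.abs(c[:, None] - x[None, :])
    # normalising by the per-pixel minimum distance keeps the exponentials
    # in (0, 1] and avoids overflow for m close to 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d.min(axis=0) / d
        if m == 2.0:
            w = ratio * ratio
        else:
            w = ratio ** (2.0 / (m - 1.0))
        u = w / w.sum(axis=0)

    zero_cols = np.nonzero((d == 0).any(axis=0))[0]
    if zero_cols.size:
        u[:, zero_cols] = 0.0
        winners = np.argmax(d[:, zero_cols] == 0, axis=0)
        u[winners, zero_cols] = 1.0
    return u


def update_centers(image, u, m: float = 2.0) -> np.ndarray:
    """Center update: ``c_i = sum_j u_ij^m x_j / sum_j u_ij^m``.

    Raises
    ------
    DegenerateClusterError
        If some cluster carries zero total membership mass; the caller
        decides whether to re-seed.
    """
    x = _as_pixel_vector(image)
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != x.size:
        raise ValueError(f"membership matrix shape {u.shape} does not match {x.size} pixels")
    um = u * u if m == 2.0 else u**m
    mass = um.sum(axis=1)
    dead = np.nonzero(mass == 0)[0]
    if dead.size:
        raise DegenerateClusterError(dead)
    return (um @ x) / mass


def compute_cost(image, centers, u, m: float = 2.0) -> float:
    """Clustering cost ``J = sum_ij u_ij^m |c_i - x_j|^2`` (non-negative)."""
    x = _as_pixel_vector(image)
    c = _as_centers(centers)
    u = np.asarray(u, dtype=float)
    if u.shape != (c.size, x.size):
        raise ValueError(
            f"membership matrix shape {u.shape} inconsistent with "
            f"{c.size} centers and {x.size} pixels"
        )
    d = c[:, None] - x[None, :]
    um = u * u if m == 2.0 else u**m
    return float(np.sum(um * d * d))


def spatial_function(u, shape, window: int) -> np.ndarray:
    """Neighbourhood membership sum ``h_ij = sum_{k in NB(x_j)} u_ik``.

    ``NB(x_j)`` is the square ``window x window`` patch centered on pixel
    ``j``; at image borders the window is truncated (no padding values are
    invented).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    u = np.asarray(u, dtype=float)
    height, width = shape
    if u.ndim != 2 or u.shape[1] != height * width:
        raise ValueError(f"membership matrix shape {u.shape} not reshapeable to {shape}")
    cube = u.reshape(u.shape[0], height, width)
    kernel = np.ones((1, window, window))
    # constant-zero padding followed by summation == truncated-window sum
    h = ndimage.correlate(cube, kernel, mode="constant", cval=0.0)
    return h.reshape(u.shape)


def spatial_membership(u, h, p: float = 1.0, q: float = 1.0) -> np.ndarray:
    """Combine memberships with their neighbourhood sums.

    ``u'_ij = u_ij^p h_ij^q / sum_k u_kj^p h_kj^q``, with ``0^0 == 1``.
    """
    u = np.asarray(u, dtype=float)
    h = np.asarray(h, dtype=float)
    if u.shape != h.shape:
        raise ValueError(f"u shape {u.shape} != h shape {h.shape}")
    if p < 0 or q < 0:
        raise ValueError(f"exponents must be >= 0, got p={p}, q={q}")
    num = u**p * h**q
    den = num.sum(axis=0)
    if np.any(den == 0):
        raise DegeneratePixelError(
            f"{int(np.count_nonzero(den == 0))} pixel(s) have all-zero combined weights"
        )
    return num / den


@njit(cache=True)
def _fitness_burst(x, centers0, m, inner):  # pragma: no cover - jitted
    """Fused membership+centroid burst with final cost, pixel by pixel.

    Identical math (float64) to chaining ``update_memberships`` /
    ``update_centers`` / ``compute_cost``, but in a single streaming pass
    per iteration, which matters when a genetic algorithm evaluates tens of
    thousands of chromosomes on full-size images.  Returns
    ``(cost, new_centers, ok)``; ``ok`` is False when a cluster lost all
    membership mass (cost is +inf in that case).
    """
    n_clusters = centers0.size
    n_pixels = x.size
    centers = centers0.copy()
    prev = centers0.copy()
    expo = 2.0 / (m - 1.0)
    u = np.empty(n_clusters)
    d = np.empty(n_clusters)

    for _ in range(inner):
        prev = centers.copy()
        num = np.zeros(n_clusters)
        den = np.zeros(n_clusters)
        for j in range(n_pixels):
            xj = x[j]
            zero_at = -1
            for i in range(n_clusters):
                d[i] = abs(prev[i] - xj)
                if d[i] == 0.0 and zero_at < 0:
                    zero_at = i
            if zero_at >= 0:
                for i in range(n_clusters):
                    u[i] = 0.0
                u[zero_at] = 1.0
            else:
                dmin = d[0]
                for i in range(1, n_clusters):
                    if d[i] < dmin:
                        dmin = d[i]
                s = 0.0
                for i in range(n_clusters):
                    r = dmin / d[i]
                    u[i] = r * r if m == 2.0 else r**expo
                    s += u[i]
                for i in range(n_clusters):
                    u[i] /= s
            for i in range(n_clusters):
                um = u[i] * u[i] if m == 2.0 else u[i] ** m
                num[i] += um * xj
                den[i] += um
        for i in range(n_clusters):
            if den[i] == 0.0:
                return np.inf, centers, False
        centers = num / den

    cost = 0.0
    for j in range(n_pixels):
        xj = x[j]
        zero_at = -1
        for i in range(n_clusters):
            d[i] = abs(prev[i] - xj)
            if d[i] == 0.0 and zero_at < 0:
                zero_at = i
        if zero_at >= 0:
            for i in range(n_clusters):
                u[i] = 0.0
            u[zero_at] = 1.0
        else:
            dmin = d[0]
            for i in range(1, n_clusters):
                if d[i] < dmin:
                    dmin = d[i]
            s = 0.0
            for i in range(n_clusters):
                r = dmin / d[i]
                u[i] = r * r if m == 2.0 else r**expo
                s += u[i]
            for i in range(n_clusters):
                u[i] /= s
        for i in range(n_clusters):
            um = u[i] * u[i] if m == 2.0 else u[i] ** m
            diff = centers[i] - xj
            cost += um * diff * diff
    return cost, centers, True


def fitness_burst(image, centers, m: float = 2.0, inner_iterations: int = 1):
    """Cost after a short burst of FCM updates from the given centers.

    Equivalent to ``inner_iterations`` rounds of
    ``update_memberships``/``update_centers`` followed by ``compute_cost``
    on the updated state, evaluated in one fused pass.  Returns
    ``(cost, new_centers)``; a degenerate cluster yields ``(inf, centers)``.
    """
    x = _as_pixel_vector(image)
    c = _as_centers(centers)
    if not m > 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    if inner_iterations < 1:
        raise ValueError(f"inner_iterations must be >= 1, got {inner_iterations}")
    cost, new_centers, ok = _fitness_burst(x, c, float(m), inner_iterations)
    return (cost if ok else np.inf), new_centers


def fcm_run(image, init, params: FCMParams, rng=None) -> FCMResult:
    """Alternate membership and center updates until the cost stabilises.

    The loop stops when the absolute cost change drops below
    ``params.tol`` relative to the first recorded cost, or after
    ``params.max_iter`` iterations.  A cluster that loses all membership
    mass is re-seeded once to a uniform-random intensity; a second
    degeneracy raises.

    Parameters
    ----------
    image : array_like
        2D raster or flat pixel vector.
    init : array_like
        Initial class centers, length ``params.n_clusters``.
    rng : numpy.random.Generator, optional
        Stream used only for the re-seed fallback.
    """
    shape = np.asarray(image).shape
    x = _as_pixel_vector(image)
    centers = _as_centers(init)
    if centers.size != params.n_clusters:
        raise ValueError(
            f"init has {centers.size} centers but params.n_clusters={params.n_clusters}"
        )
    if rng is None:
        rng = np.random.default_rng(0)

    trace: list[float] = []
    reseeded = False
    u = None
    iterations = 0
    for _ in range(params.max_iter):
        iterations += 1
        u = update_memberships(x, centers, params.m)
        if params.spatial_enabled:
            if len(shape) != 2:
                raise ValueError("spatial variant requires a 2D image")
            h = spatial_function(u, shape, params.window)
            u = spatial_membership(u, h, params.p, params.q)
        try:
            centers = update_centers(x, u, params.m)
        except DegenerateClusterError:
            if reseeded:
                raise
            reseeded = True
            centers = centers.copy()
            dead = np.nonzero((u * u if params.m == 2.0 else u**params.m).sum(axis=1) == 0)[0]
            centers[dead] = rng.uniform(*GENE_RANGE, size=dead.size)
            continue
        trace.append(compute_cost(x, centers, u, params.m))
        if not np.isfinite(params.tol):
            break
        scale = max(trace[0], np.finfo(float).tiny)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < params.tol * scale:
            break
        if trace[0] == 0.0:
            break
    return FCMResult(
        centers=centers,
        memberships=u,
        cost_trace=np.asarray(trace),
        iterations_run=iterations,
    )
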