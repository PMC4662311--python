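"""Spatially explicit capture-recapture (SECR) with half-normal detection.

Transects are cut into fixed-length sections whose midpoints act as
binary proximity detectors: an individual is either recorded or not at
each detector on each search occasion.  Each animal has a latent
activity center x; the probability it is recorded at detector j on one
occasion is the half-normal g(d) = g0 * exp(-d^2 / (2 sigma^2)), with d
the detector-to-center distance.  Activity centers follow a homogeneous
Poisson process with density D over a discretized habitat mask, and the
likelihood integrates over the mask:

    log L = -D * sum_x p.(x) a
            + sum_i log( D * sum_x Pr(omega_i | x) a )

where p.(x) is the probability an animal centered at x is detected at
least once and a is the mask cell area.  D, g0 and sigma are estimated
on link scales (log, logit, log) by quasi-Newton search; abundance is
N = D * A with a delta-method standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.prepared import prep

from .dtypes import ConfigError, ValidationError

HA_PER_M2 = 1e-4


# ---------------------------------------------------------------- detectors

@dataclass
class DetectorArray:
    ids: list[int]
    coords: np.ndarray  # (J, 2) meters
    transect_index: np.ndarray  # (J,) parent polyline
    section_length: float

    def __len__(self) -> int:
        return len(self.ids)


def segment_transects(
    polylines: Sequence[LineString], section_length: float = 200.0
) -> DetectorArray:
    """Cut each polyline into consecutive sections and place a detector
    at each section's along-path midpoint.

    A final remainder longer than half the section length becomes its
    own section; a shorter one is merged into the previous section.
    Zero-length polylines are skipped with a warning.
    """
    if section_length <= 0:
        raise ConfigError("section_length must be positive")
    coords, tidx = [], []
    for t_i, line in enumerate(polylines):
        L = line.length
        if L <= 0:
            warnings.warn(f"transect {t_i} has zero length; skipped")
            continue
        n_full = int(L // section_length)
        rem = L - n_full * section_length
        lengths = [section_length] * n_full
        if rem > 1e-9:
            if rem > section_length / 2 or n_full == 0:
                lengths.append(rem)
            else:
                lengths[-1] += rem
        start = 0.0
        for slen in lengths:
            mid = line.interpolate(start + slen / 2.0)
            coords.append((mid.x, mid.y))
            tidx.append(t_i)
            start += slen
    if not coords:
        raise ValidationError("no usable transects")
    arr = np.asarray(coords, dtype=float)
    return DetectorArray(
        ids=list(range(len(arr))),
        coords=arr,
        transect_index=np.asarray(tidx, dtype=int),
        section_length=float(section_length),
    )


# ---------------------------------------------------------------- mask

@dataclass
class HabitatMask:
    points: np.ndarray  # (M, 2) cell centers, meters
    cell_area_ha: float

    @property
    def total_area_ha(self) -> float:
        return self.cell_area_ha * len(self.points)

    def __len__(self) -> int:
        return len(self.points)


def build_mask(
    habitat: Optional[Polygon | MultiPolygon],
    detectors: Optional[DetectorArray] = None,
    resolution: float = 250.0,
    buffer: float = 3000.0,
) -> HabitatMask:
    """Discretize the habitat into mask cells of side ``resolution`` m.

    With a habitat polygon, cells whose centers fall inside it are
    kept.  Without one, a rectangular buffer around the detector array
    is used (buffer should exceed ~4 sigma so that animals outside have
    negligible detection probability).
    """
    if resolution <= 0:
        raise ConfigError("mask resolution must be positive")
    if habitat is not None:
        minx, miny, maxx, maxy = habitat.bounds
        xs = np.arange(minx + resolution / 2, maxx, resolution)
        ys = np.arange(miny + resolution / 2, maxy, resolution)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        prepared = prep(habitat)
        keep = np.fromiter(
            (prepared.contains(Point(x, y)) for x, y in pts), dtype=bool, count=len(pts)
        )
        pts = pts[keep]
    elif detectors is not None:
        minx, miny = detectors.coords.min(axis=0) - buffer
        maxx, maxy = detectors.coords.max(axis=0) + buffer
        xs = np.arange(minx + resolution / 2, maxx, resolution)
        ys = np.arange(miny + resolution / 2, maxy, resolution)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
    else:
        raise ConfigError("need a habitat polygon or a detector array")
    if len(pts) == 0:
        raise ValidationError("empty habitat mask")
    return HabitatMask(points=pts, cell_area_ha=resolution**2 * HA_PER_M2)


# ---------------------------------------------------------------- histories

@dataclass
class CaptureHistory:
    individuals: list[str]
    omega: np.ndarray  # (n, J, K) binary
    n_occasions: int

    @property
    def n(self) -> int:
        return len(self.individuals)


def assign_detections(
    detections: pd.DataFrame,
    detectors: DetectorArray,
    individuals_map: Mapping[str, str],
    n_occasions: Optional[int] = None,
    max_snap: float = 500.0,
) -> CaptureHistory:
    """Snap identified scats to their nearest detector and build the
    binary individual x detector x occasion history.

    Ties go to the lowest detector id; scats farther than ``max_snap``
    from every detector are dropped with a warning; repeated scats of
    one individual at one detector and occasion collapse to a single 1.
    """
    det = detections[detections["scat_id"].astype(str).isin(individuals_map)].copy()
    inds = sorted(set(individuals_map[s] for s in det["scat_id"].astype(str)))
    K = int(n_occasions or (det["occasion"].max() if len(det) else 1))
    J = len(detectors)
    omega = np.zeros((len(inds), J, K), dtype=np.int8)
    ind_index = {ind: i for i, ind in enumerate(inds)}
    dropped = 0
    for _, row in det.iterrows():
        xy = np.array([row["x"], row["y"]], dtype=float)
        d = np.hypot(*(detectors.coords - xy).T)
        j = int(np.argmin(d))  # argmin returns the first (lowest id) on ties
        if d[j] > max_snap:
            dropped += 1
            continue
        k = int(row["occasion"]) - 1
        if k >= K:
            raise ValidationError(f"occasion {k + 1} exceeds n_occasions={K}")
        omega[ind_index[individuals_map[str(row["scat_id"])]], j, k] = 1
    if dropped:
        warnings.warn(f"{dropped} detection(s) farther than {max_snap} m from any detector; dropped")
    keep = omega.reshape(len(inds), -1).any(axis=1)
    return CaptureHistory(
        individuals=[ind for ind, k in zip(inds, keep) if k],
        omega=omega[keep],
        n_occasions=K,
    )


# ---------------------------------------------------------------- likelihood

def halfnormal_detect(d, g0: float, sigma: float):
    """Half-normal per-occasion detection probability g0*exp(-d^2/(2 sigma^2))."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 < g0 < 1:
        raise ValueError("g0 must lie in (0, 1)")
    out = g0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def _distances(mask: HabitatMask, detectors: DetectorArray) -> np.ndarray:
    dx = mask.points[:, 0][:, None] - detectors.coords[:, 0][None, :]
    dy = mask.points[:, 1][:, None] - detectors.coords[:, 1][None, :]
    return np.hypot(dx, dy)


def secr_loglik(
    params: Sequence[float],
    history: CaptureHistory,
    detectors: DetectorArray,
    mask: HabitatMask,
    dist: Optional[np.ndarray] = None,
) -> float:
    """Homogeneous-Poisson SECR log-likelihood at (D, g0, sigma).

    D in animals/ha, sigma in meters.  The integral over activity
    centers is a sum over mask cells.
    """
    D, g0, sigma = (float(v) for v in params)
    if D <= 0 or sigma <= 0 or not 0 < g0 < 1:
        return -math.inf
    if dist is None:
        dist = _distances(mask, detectors)
    a = mask.cell_area_ha
    K = history.n_occasions
    p = g0 * np.exp(-(dist**2) / (2.0 * sigma**2))  # (M, J), per occasion
    p = np.clip(p, 1e-15, 1.0 - 1e-12)
    log_p = np.log(p)
    log_q = np.log1p(-p)
    # p.(x): detected at least once over all detectors and occasions
    log_pdot_c = K * log_q.sum(axis=1)  # log P(never detected | x)
    pdot = -np.expm1(log_pdot_c)
    term1 = -D * a * float(pdot.sum())
    # per-individual: counts over occasions collapse because p is
    # occasion-constant: Pr(omega_i|x) = prod_j p^c_ij (1-p)^(K-c_ij)
    C = history.omega.sum(axis=2).astype(float)  # (n, J)
    log_pr = C @ log_p.T + (K - C) @ log_q.T  # (n, M)
    term2 = float(np.sum(logsumexp(log_pr, axis=1) + math.log(D * a)))
    return term1 + term2


# ---------------------------------------------------------------- fitting

@dataclass
class SecrFit:
    density: float  # animals / ha
    g0: float
    sigma: float  # meters
    n_hat: float  # density * mask area
    se_density: float
    se_g0: float
    se_sigma: float
    se_n: float
    ci_density: tuple[float, float]
    ci_g0: tuple[float, float]
    ci_sigma: tuple[float, float]
    ci_n: tuple[float, float]
    loglik: float
    converged: bool
    n_detected: int
    mask_area_ha: float
    beta: np.ndarray = field(repr=False, default=None)
    beta_cov: np.ndarray = field(repr=False, default=None)


def _start_values(
    history: CaptureHistory, detectors: DetectorArray, mask: HabitatMask
) -> np.ndarray:
    # sigma: half the mean distance between a detected animal's detectors
    dists = []
    for i in range(history.n):
        js = np.flatnonzero(history.omega[i].any(axis=1))
        for a_i in range(len(js)):
            for b_i in range(a_i + 1, len(js)):
                dists.append(
                    float(np.hypot(*(detectors.coords[js[a_i]] - detectors.coords[js[b_i]])))
                )
    sigma0 = 0.5 * float(np.mean(dists)) if dists else 5 * detectors.section_length
    sigma0 = max(sigma0, detectors.section_length / 2)
    d0 = max(history.n / mask.total_area_ha, 1e-8)
    return np.array([math.log(d0), 0.0, math.log(sigma0)])  # logit(0.1) ~ set below


def _unpack(beta: np.ndarray) -> tuple[float, float, float]:
    return math.exp(beta[0]), float(expit(beta[1])), math.exp(beta[2])


def fit_secr(
    history: CaptureHistory,
    detectors: DetectorArray,
    mask: HabitatMask,
    start: Optional[Sequence[float]] = None,
) -> SecrFit:
    """Maximize the SECR likelihood on link scales (log D, logit g0, log sigma).

    Standard errors come from the inverse numerical Hessian at the
    optimum; 95% CIs are Wald intervals on the link scale,
    back-transformed.  N = D * A uses the delta method (A fixed).
    """
    if history.n < 1:
        raise ValidationError("need at least one detected individual")
    if history.n < 2:
        warnings.warn("fewer than 2 detected individuals; estimates will be unstable")
    dist = _distances(mask, detectors)
    if start is not None:
        beta0 = np.array(
            [math.log(start[0]), math.log(start[1] / (1 - start[1])), math.log(start[2])]
        )
    else:
        beta0 = _start_values(history, detectors, mask)
        beta0[1] = math.log(0.1 / 0.9)  # g0 start 0.1

    def neg(beta):
        if np.any(np.abs(beta) > 50):
            return 1e10
        ll = secr_loglik(_unpack(beta), history, detectors, mask, dist=dist)
        return 1e10 if not math.isfinite(ll) else -ll

    res = minimize(neg, beta0, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-10})
    if not res.success or res.fun >= 1e9:
        # restart from a perturbed point before giving up
        res2 = minimize(neg, beta0 + 0.5, method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        if res2.fun < res.fun:
            res = res2
    beta = res.x
    ll = -res.fun

    # central-difference Hessian on link scale
    h = 1e-4
    p_dim = 3
    H = np.zeros((p_dim, p_dim))
    f0 = neg(beta)
    for i in range(p_dim):
        for j in range(i, p_dim):
            ei = np.zeros(p_dim); ei[i] = h
            ej = np.zeros(p_dim); ej[j] = h
            fpp = neg(beta + ei + ej)
            fpm = neg(beta + ei - ej)
            fmp = neg(beta - ei + ej)
            fmm = neg(beta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
        se_beta = np.sqrt(np.diag(cov))
        cov_ok = True
    except np.linalg.LinAlgError:
        cov = np.full((p_dim, p_dim), np.nan)
        se_beta = np.full(p_dim, np.nan)
        cov_ok = False

    D, g0, sigma = _unpack(beta)
    A = mask.total_area_ha
    z = 1.959963984540054
    # delta-method SEs on natural scales
    se_D = D * se_beta[0]
    se_g0 = g0 * (1 - g0) * se_beta[1]
    se_sigma = sigma * se_beta[2]
    ci_D = (D * math.exp(-z * se_beta[0]), D * math.exp(z * se_beta[0])) if cov_ok else (math.nan, math.nan)
    ci_g0 = (
        (float(expit(beta[1] - z * se_beta[1])), float(expit(beta[1] + z * se_beta[1])))
        if cov_ok else (math.nan, math.nan)
    )
    ci_sigma = (
        (sigma * math.exp(-z * se_beta[2]), sigma * math.exp(z * se_beta[2]))
        if cov_ok else (math.nan, math.nan)
    )
    return SecrFit(
        density=D,
        g0=g0,
        sigma=sigma,
        n_hat=D * A,
        se_density=se_D,
        se_g0=se_g0,
        se_sigma=se_sigma,
        se_n=se_D * A,
        ci_density=ci_D,
        ci_g0=ci_g0,
        ci_sigma=ci_sigma,
        ci_n=(ci_D[0] * A, ci_D[1] * A),
        loglik=ll,
        converged=bool(res.success and cov_ok),
        n_detected=history.n,
        mask_area_ha=A,
        beta=beta,
        beta_cov=cov,
    )
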