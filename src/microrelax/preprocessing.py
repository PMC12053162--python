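"""Preparation of multi-echo magnitude volumes for voxel-wise fitting.

The pipeline mirrors a standard quantitative-MRI workflow: repetitions are
harmonized (per-voxel affine mapping onto the first repetition), the
concatenated series is denoised with Marchenko-Pastur PCA, the Rician noise
floor estimated from background voxels is subtracted, and SNR maps are
computed from the signal and the noise-variance map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import EchoSchedule

__all__ = [
    "MultiEchoVolume",
    "NoiseFloorEstimate",
    "harmonize_repetitions",
    "mppca_denoise",
    "estimate_noise_floor",
    "subtract_floor",
    "compute_snr",
]


@dataclass
class MultiEchoVolume:
    """A 4-D multi-echo magnitude volume.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, n_echoes)
        Non-negative magnitudes.  When repetitions are concatenated the
        last axis holds ``n_echoes_per_rep * n_repetitions`` frames.
    sched : EchoSchedule
        Echo times matching the last axis (tiled across repetitions).
    sigma_map : ndarray or None
        Optional per-voxel noise standard deviation, shape (x, y, z).
    """

    data: np.ndarray
    sched: EchoSchedule
    sigma_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, echo)")
        if np.any(self.data < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.data.shape[-1] != self.sched.n_echoes:
            raise ValueError(
                f"echo axis length {self.data.shape[-1]} does not match "
                f"schedule length {self.sched.n_echoes}"
            )
        if self.sigma_map is not None:
            self.sigma_map = np.asarray(self.sigma_map, dtype=float)
            if self.sigma_map.shape != self.data.shape[:3]:
                raise ValueError("sigma_map must match the spatial grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_repetitions(self) -> int:
        return self.sched.n_repetitions


@dataclass(frozen=True)
class NoiseFloorEstimate:
    """Maximum-likelihood Rician fit to background intensities.

    ``noncentrality`` (nu) is the residual coherent signal in the
    background, ``sigma`` the underlying complex-noise standard deviation.
    """

    noncentrality: float
    sigma: float
    n_background: int

    def __post_init__(self) -> None:
        if self.noncentrality < 0:
            raise ValueError("noncentrality must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def harmonize_repetitions(volumes: list[MultiEchoVolume]) -> MultiEchoVolume:
    """Map repetitions 2..n voxel-wise onto repetition 1 and concatenate.

    Per voxel, each later repetition is regressed onto the first with an
    affine model ``S_1 ~ a * S_r + b`` (ordinary least squares over echoes),
    removing scaling and additive offsets between repetitions (receive-field
    changes, baseline drifts).  Repetition 1 is the reference and passes
    through unchanged.

    Returns a volume whose echo axis is the concatenation of the harmonized
    repetitions, with the echo schedule tiled accordingly.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two repetitions to harmonize")
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape:
            raise ValueError("repetition grids/echo counts do not match")
        if not np.allclose(v.sched.echo_times, ref.sched.echo_times):
            raise ValueError("repetition echo schedules do not match")

    n_echo = ref.sched.n_echoes
    out = [ref.data]
    s1 = ref.data.reshape(-1, n_echo)
    for v in volumes[1:]:
        sr = v.data.reshape(-1, n_echo)
        # closed-form per-voxel OLS of s1 on sr: slope a, intercept b
        mr = sr.mean(axis=1, keepdims=True)
        m1 = s1.mean(axis=1, keepdims=True)
        cov = ((sr - mr) * (s1 - m1)).mean(axis=1, keepdims=True)
        var = ((sr - mr) ** 2).mean(axis=1, keepdims=True)
        a = np.divide(cov, var, out=np.ones_like(cov), where=var > 0)
        b = m1 - a * mr
        harmonized = (a * sr + b).reshape(ref.data.shape)
        out.append(np.clip(harmonized, 0.0, None))

    data = np.concatenate(out, axis=-1)
    sched = ref.sched.tiled(len(volumes))
    return MultiEchoVolume(data=data, sched=sched)


def _mp_denoise_patch(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Denoise one patch matrix X (n_voxels, n_echoes); return (Xd, sigma2).

    Eigenvalues of the echo-direction covariance below the Marchenko-Pastur
    bulk edge of pure noise are classified as noise and suppressed; the
    noise variance is the mean of the suppressed eigenvalues.
    """
    m, n = X.shape
    # SVD on the thin side; eigenvalues of X^T X / m, descending
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    lam = (s**2) / m
    r = lam.size
    sigma2 = 0.0
    p_signal = r
    for p in range(r):
        lam_noise = lam[p:]
        nn = lam_noise.size
        sig2 = lam_noise.mean()
        gamma = nn / m
        # all remaining eigenvalues fit under the MP bulk of width 4*sig2*sqrt(gamma)
        if lam[p] - lam[-1] < 4.0 * sig2 * np.sqrt(gamma):
            sigma2 = sig2
            p_signal = p
            break
    s_d = s.copy()
    s_d[p_signal:] = 0.0
    Xd = (u * s_d) @ vt
    return Xd, sigma2


def mppca_denoise(vol: MultiEchoVolume, patch_edge: int = 5,
                  ) -> tuple[MultiEchoVolume, np.ndarray]:
    """Marchenko-Pastur PCA denoising over sliding cubic patches.

    Parameters
    ----------
    vol : MultiEchoVolume
        Input magnitudes; the echo axis (repetitions concatenated) is the
        PCA direction.
    patch_edge : int
        Edge length of the cubic patch in voxels (default 5).

    Returns
    -------
    (denoised_volume, sigma_map)
        Overlapping patch estimates are averaged per voxel.  ``sigma_map``
        holds the per-voxel noise standard deviation estimated from the
        suppressed eigenvalues; it is also attached to the returned volume.
    """
    data = vol.data
    nx, ny, nz, ne = data.shape
    if patch_edge > min(nx, ny, nz):
        raise ValueError(
            f"patch edge {patch_edge} exceeds volume extent {min(nx, ny, nz)}"
        )
    if ne < 2:
        raise ValueError("need at least two echoes for PCA denoising")

    accum = np.zeros_like(data)
    var_accum = np.zeros((nx, ny, nz))
    counts = np.zeros((nx, ny, nz))
    e = patch_edge
    for i0 in range(0, nx - e + 1):
        for j0 in range(0, ny - e + 1):
            for k0 in range(0, nz - e + 1):
                patch = data[i0:i0 + e, j0:j0 + e, k0:k0 + e, :]
                X = patch.reshape(-1, ne)
                Xd, sigma2 = _mp_denoise_patch(X)
                accum[i0:i0 + e, j0:j0 + e, k0:k0 + e, :] += Xd.reshape(patch.shape)
                var_accum[i0:i0 + e, j0:j0 + e, k0:k0 + e] += sigma2
                counts[i0:i0 + e, j0:j0 + e, k0:k0 + e] += 1.0

    counts4 = counts[..., None]
    denoised = accum / counts4
    sigma_map = np.sqrt(var_accum / counts)
    out = MultiEchoVolume(
        data=np.clip(denoised, 0.0, None), sched=vol.sched, sigma_map=sigma_map
    )
    return out, sigma_map


def estimate_noise_floor(background_samples: np.ndarray) -> NoiseFloorEstimate:
    """Fit a Rician distribution to background magnitudes by ML.

    A method-of-moments initialization seeds the likelihood optimization
    (scipy's ``rice`` with location fixed at zero).  The noncentrality
    ``nu = b * sigma`` is the coherent floor later subtracted from the
    images.
    """
    x = np.asarray(background_samples, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 background samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate background samples (all equal)")

    # Moments of the Rician: E[X^2] = nu^2 + 2 sigma^2, Var related via E[X].
    m2 = np.mean(x**2)
    v = np.var(x)
    nu2 = max(m2 - 2.0 * v, 0.0)  # crude but adequate as a seed
    sigma0 = np.sqrt(max((m2 - nu2) / 2.0, 1e-12))
    b0 = np.sqrt(nu2) / sigma0

    b, loc, scale = stats.rice.fit(x, b0 if b0 > 0 else 0.1,
                                   floc=0.0, scale=sigma0)
    return NoiseFloorEstimate(
        noncentrality=float(b * scale), sigma=float(scale), n_background=x.size
    )


def subtract_floor(data: np.ndarray, floor: NoiseFloorEstimate | float) -> np.ndarray:
    """Subtract the Rician noncentrality floor: ``S <- max(S - nu, 0)``."""
    nu = floor.noncentrality if isinstance(floor, NoiseFloorEstimate) else float(floor)
    return np.clip(np.asarray(data, dtype=float) - nu, 0.0, None)


def compute_snr(vol: MultiEchoVolume) -> np.ndarray:
    """Per-echo SNR map: data / sigma_map, broadcast over the echo axis.

    Voxels with zero estimated noise are returned as ``inf`` (flagged, to be
    excluded from summaries).
    """
    if vol.sigma_map is None:
        raise ValueError("volume has no sigma_map; run mppca_denoise first "
                         "or attach one")
    sigma = vol.sigma_map[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sigma > 0, vol.data / np.where(sigma > 0, sigma, 1.0),
                       np.inf)
    return snr
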