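"""Noise channels for distances and dihedral cosines.

Three ways measurement imprecision can enter the features:

* Gaussian noise of std ``eta1`` (Angstrom) on the pairwise distances of
  an atom quadruple.  A noisy distance matrix generally stops being
  realizable in 3-D; it is repaired by projecting its double-centered
  Gram matrix onto the PSD cone (classical-MDS projection), which also
  protects the distance-only dihedral formula from vanishing
  denominators.
* Gaussian noise of std ``eta2`` (dimensionless) directly on dihedral
  cosines, clamped back to [-1, 1].  This is the channel used by the
  classifier robustness experiments.
* Gaussian noise on the three trihedron face angles (radians), an
  alternative channel kept for completeness; it is not part of the main
  pipeline.

A Monte-Carlo routine translates cosine noise into an angular error on
omega, reporting both the mean absolute and the root-mean-square error in
degrees per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import QuadDistances

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of (squared or plain) distances."""

    values: np.ndarray
    squared: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("distance matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NoiseConfig:
    """Noise amplitudes and Monte-Carlo settings."""

    eta1: float = 0.0       # Angstrom, distance noise std
    eta2: float = 0.0       # dimensionless, cosine noise std
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta1 < 0 or self.eta2 < 0:
            raise ValidationError("noise amplitudes must be non-negative")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


def psd_project(D: DistanceMatrix) -> DistanceMatrix:
    """Project a noisy distance matrix onto the set of Euclidean ones.

    Operates on squared distances: double-center G = -1/2 J S J with
    J = I - (1/n) 1 1^T, clip negative eigenvalues of G to zero giving a
    PSD Gram matrix E, and rebuild S_ij = E_ii + E_jj - 2 E_ij.  If the
    input holds plain distances they are squared on entry and un-squared
    on return.  Idempotent, and the identity on valid squared EDMs.
    """
    S = D.values ** 2 if not D.squared else D.values.copy()
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ S @ J
    G = 0.5 * (G + G.T)  # guard symmetry for eigh
    w, V = np.linalg.eigh(G)
    E = (V * np.maximum(w, 0.0)) @ V.T
    diag = np.diag(E)
    S_proj = diag[:, None] + diag[None, :] - 2.0 * E
    S_proj = np.maximum(0.5 * (S_proj + S_proj.T), 0.0)
    np.fill_diagonal(S_proj, 0.0)
    out = S_proj if D.squared else np.sqrt(S_proj)
    return DistanceMatrix(values=out, squared=D.squared)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def perturb_distances(
    q: QuadDistances, eta1: float, seed: int | np.random.Generator = 0
) -> QuadDistances:
    """Add Gaussian noise (std eta1) to the quadruple's distance matrix
    and repair it with the PSD projection."""
    if eta1 < 0:
        raise ValidationError("eta1 must be non-negative")
    rng = _as_rng(seed)
    D = q.to_matrix()
    noise = np.zeros((4, 4))
    iu = np.triu_indices(4, k=1)
    noise[iu] = rng.normal(0.0, eta1, size=len(iu[0])) if eta1 > 0 else 0.0
    noise = noise + noise.T
    noisy = np.abs(D + noise)  # distances stay non-negative before squaring
    np.fill_diagonal(noisy, 0.0)
    projected = psd_project(DistanceMatrix(values=noisy, squared=False))
    return QuadDistances.from_matrix(projected.values)


def perturb_cos(
    c,
    eta2: float,
    seed: int | np.random.Generator = 0,
    mask=None,
):
    """Add i.i.d. Gaussian noise of std eta2 to cosine values, clamped to
    [-1, 1].  Entries where ``mask`` is False are left untouched."""
    if eta2 < 0:
        raise ValidationError("eta2 must be non-negative")
    c = np.asarray(c, dtype=float)
    if eta2 == 0:
        return c.copy()
    rng = _as_rng(seed)
    noisy = np.clip(c + rng.normal(0.0, eta2, size=c.shape), -1.0, 1.0)
    if mask is not None:
        noisy = np.where(np.asarray(mask, dtype=bool), noisy, c)
    return noisy


def perturb_trihedron_angles(
    angles_rad, eta: float, seed: int | np.random.Generator = 0
):
    """Alternative channel: Gaussian noise (std in radians) on the three
    trihedron face angles themselves."""
    if eta < 0:
        raise ValidationError("eta must be non-negative")
    rng = _as_rng(seed)
    a = np.asarray(angles_rad, dtype=float)
    return a + rng.normal(0.0, eta, size=a.shape)


def monte_carlo_omega_error(
    config: NoiseConfig, omega_grid_deg
) -> pd.DataFrame:
    """Monte-Carlo angular error on omega induced by cosine noise.

    For each omega in the grid (degrees, strictly inside (0, 180)):
    draw ``n_trials`` perturbations cos(omega) + N(0, eta2), clamp to
    [-1, 1], take arccos, and accumulate |omega' - omega|.  Returns a
    DataFrame with columns ``omega_deg``, ``eta2``, ``mean_abs_deg``
    (mean absolute error) and ``rms_deg`` (root mean square error).

    Near omega = 0 or 180 the arccos is badly conditioned and the error
    inflates; such grid points trigger a warning but are still computed.
    """
    import warnings

    rng = np.random.default_rng(config.seed)
    rows = []
    for omega in np.atleast_1d(np.asarray(omega_grid_deg, dtype=float)):
        if not 0.0 < omega < 180.0:
            raise ValidationError("omega grid must lie strictly inside (0, 180)")
        if omega < 5.0 or omega > 175.0:
            warnings.warn(
                f"omega={omega} deg is near the arccos boundary; "
                "the estimated error is inflated",
                stacklevel=2,
            )
        c = np.cos(np.radians(omega))
        cp = np.clip(c + rng.normal(0.0, config.eta2, size=config.n_trials), -1.0, 1.0)
        err = np.abs(np.degrees(np.arccos(cp)) - omega)
        rows.append(
            {
                "omega_deg": float(omega),
                "eta2": config.eta2,
                "mean_abs_deg": float(err.mean()),
                "rms_deg": float(np.sqrt((err ** 2).mean())),
            }
        )
    return pd.DataFrame(rows)


def omega_error_table(
    eta2_levels=(0.05, 0.1),
    omega_grid_deg=(30.0, 60.0, 90.0, 120.0, 150.0),
    n_trials: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Error table across noise levels: one row per (omega, eta2)."""
    frames = []
    for i, eta2 in enumerate(eta2_levels):
        cfg = NoiseConfig(eta2=eta2, n_trials=n_trials, seed=seed + i)
        frames.append(monte_carlo_omega_error(cfg, omega_grid_deg))
    return pd.concat(frames, ignore_index=True)
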