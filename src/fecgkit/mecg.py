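"""Maternal ECG cancellation by blind source separation.

The abdominal channels are modeled as an instantaneous linear mixture
x(k) = A s(k) of statistically independent sources (maternal ECG, fetal
ECG). After centering and whitening, the JADE algorithm — joint approximate
diagonalization of fourth-order cumulant matrices by Jacobi rotations —
recovers an unmixing matrix W and independent components Y = W x. JADE has
no random initialization, so separation is fully deterministic.

Components are labeled maternal by peak coincidence with the maternal QRS
annotation: a component whose own detected peaks fall within the matching
window of the known maternal beats at least 80% of the time is maternal.
The maternal ECG estimate is the back-projection of only those components;
subtracting it from the input leaves fetal-dominant residual channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BeatAnnotation, MultichannelRecording, PipelineConfig
from .mqrs import adt_detect, peak_transform

__all__ = [
    "SeparationResult",
    "center_and_whiten",
    "jade_rotation",
    "jade_separate",
    "identify_maternal_components",
    "subtract_mecg",
    "cancel_mecg",
]


@dataclass
class SeparationResult:
    """Whitening + rotation and the separated components.

    ``components[i] = (unmixing @ (x - mean))[i]``; ``back_projection`` maps
    component space back to sensor space (the pseudo-inverse of the total
    unmixing transform, i.e. the estimated mixing matrix).
    """

    mean: np.ndarray                 # (n_channels,)
    whitening_matrix: np.ndarray     # (n_comp, n_channels)
    rotation: np.ndarray             # (n_comp, n_comp) orthogonal
    components: np.ndarray           # (n_comp, n_samples)
    maternal_component_idx: list[int] = field(default_factory=list)
    mecg_estimate: np.ndarray | None = None
    residual: np.ndarray | None = None

    @property
    def unmixing_matrix(self) -> np.ndarray:
        return self.rotation @ self.whitening_matrix

    @property
    def back_projection(self) -> np.ndarray:
        """Estimated mixing matrix (n_channels, n_comp)."""
        return np.linalg.pinv(self.unmixing_matrix)


def center_and_whiten(
    observations: np.ndarray, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove the channel means and decorrelate to unit covariance.

    Eigen-decomposition of the sample covariance gives the whitening matrix
    D^{-1/2} E^T. Eigenvalues below ``rank_tol`` times the largest are
    dropped (rank-deficient input reduces dimension rather than failing).

    Returns ``(whitened, whitening_matrix, mean)`` with
    ``whitened = whitening_matrix @ (observations - mean[:, None])``.
    """
    x = np.atleast_2d(np.asarray(observations, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("whitening needs at least 2 channels")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    cov = (xc @ xc.T) / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * max(evals[0], rank_tol)
    evals, evecs = evals[keep], evecs[:, keep]
    whitening = (evecs / np.sqrt(evals)).T
    return whitening @ xc, whitening, mean


def _cumulant_matrices(z: np.ndarray) -> np.ndarray:
    """Parallel set of fourth-order cumulant matrices of whitened data.

    For whitened zero-mean z, the cumulant matrix associated with the pair
    (p, q) is Q_pq = E[z_p z_q z z^T] - delta_pq I - e_p e_q^T - e_q e_p^T.
    Only the m(m+1)/2 symmetric pairs are needed.
    """
    m, T = z.shape
    eye = np.eye(m)
    mats = []
    for p in range(m):
        for q in range(p + 1):
            w = z[p] * z[q]
            Q = (z * w) @ z.T / T
            Q -= eye if p == q else 0.0
            Q[p, q] -= 1.0
            Q[q, p] -= 1.0
            mats.append(Q)
    return np.array(mats)


def jade_rotation(
    z: np.ndarray, max_sweeps: int = 100, tol: float | None = None
) -> np.ndarray:
    """Orthogonal rotation jointly diagonalizing the cumulant matrices.

    Jacobi sweeps over all index pairs (p, q); for each pair the optimal
    Givens angle has the closed form of the dominant eigenvector of a 2x2
    accumulation of the matrices' (p,q)-plane entries. Sweeps stop when
    every rotation in a sweep is below ``tol`` (default scales with 1/sqrt
    of the sample count). Raises on non-convergence.
    """
    m, T = z.shape
    if m == 1:
        return np.eye(1)
    if tol is None:
        tol = 1e-6 / np.sqrt(T)
    mats = _cumulant_matrices(z)
    V = np.eye(m)
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                g1 = mats[:, p, p] - mats[:, q, q]
                g2 = mats[:, p, q] + mats[:, q, p]
                gg11 = g1 @ g1
                gg22 = g2 @ g2
                gg12 = g1 @ g2
                ton = gg11 - gg22
                toff = 2.0 * gg12
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                if abs(np.sin(theta)) <= tol:
                    continue
                rotated = True
                c, s = np.cos(theta), np.sin(theta)
                G = np.eye(m)
                G[p, p] = G[q, q] = c
                G[p, q], G[q, p] = -s, s
                V = V @ G
                mats = np.einsum("ip,kpq,qj->kij", G.T, mats, G)
        if not rotated:
            return V.T
    raise RuntimeError(
        f"JADE joint diagonalization did not converge in {max_sweeps} sweeps")


def jade_separate(observations: np.ndarray) -> SeparationResult:
    """Full JADE separation: center, whiten, jointly diagonalize.

    Deterministic given the input. Components are ordered by decreasing
    energy of their back-projection onto the sensors (strongest source
    first) with a sign convention making each component's largest-magnitude
    back-projection coefficient positive.
    """
    whitened, whitening, mean = center_and_whiten(observations)
    rotation = jade_rotation(whitened)
    components = rotation @ whitened

    # order by back-projected sensor-space energy, strongest first
    A = np.linalg.pinv(rotation @ whitening)
    energy = np.sum(A ** 2, axis=0)  # components are unit-variance
    order = np.argsort(energy)[::-1]
    rotation = rotation[order]
    components = components[order]
    A = A[:, order]
    # sign convention
    for i in range(rotation.shape[0]):
        j = np.argmax(np.abs(A[:, i]))
        if A[j, i] < 0:
            rotation[i] *= -1.0
            components[i] *= -1.0
    return SeparationResult(
        mean=mean, whitening_matrix=whitening, rotation=rotation,
        components=components)


def identify_maternal_components(
    result: SeparationResult,
    mqrs: BeatAnnotation,
    fs: float,
    config: PipelineConfig | None = None,
    min_match_fraction: float = 0.8,
) -> list[int]:
    """Label components maternal by peak coincidence with the mQRS beats.

    Each component gets its own peak detection (peak transform + ADT on the
    component); a component is maternal when at least ``min_match_fraction``
    of its detected peaks lie within the matching window of an mQRS index.
    At least one component is always labeled: if none crosses the fraction,
    the best-matching one is taken.
    """
    if len(mqrs) == 0:
        raise ValueError("maternal annotation must be non-empty")
    if config is None:
        config = PipelineConfig()
    window = config.match_window_ms * fs / 1000.0
    fractions = []
    for comp in result.components:
        try:
            env = peak_transform(comp, fs, config)
            ann, _ = adt_detect(env, fs, config)
            det = ann.indices
        except (RuntimeError, ValueError):
            det = np.array([], dtype=np.int64)
        if det.size == 0:
            fractions.append(0.0)
            continue
        ref = mqrs.indices
        pos = np.searchsorted(ref, det)
        left = np.abs(det - ref[np.clip(pos - 1, 0, ref.size - 1)])
        right = np.abs(ref[np.clip(pos, 0, ref.size - 1)] - det)
        fractions.append(float(np.mean(np.minimum(left, right) <= window)))
    fractions = np.asarray(fractions)
    idx = [int(i) for i in np.flatnonzero(fractions >= min_match_fraction)]
    if not idx:
        idx = [int(np.argmax(fractions))]
    return idx


def subtract_mecg(
    rec: MultichannelRecording,
    result: SeparationResult,
    maternal_idx: list[int] | None = None,
) -> tuple[MultichannelRecording, SeparationResult]:
    """Back-project the maternal components and subtract them.

    ``mecg_estimate = A[:, maternal] @ Y[maternal]`` with A the estimated
    mixing matrix, plus the maternal share of the removed channel means
    (the means resolved onto the mixing columns); ``residual = x -
    mecg_estimate``, so residual + estimate reconstructs the input exactly.
    """
    if maternal_idx is None:
        maternal_idx = result.maternal_component_idx
    if not maternal_idx:
        raise ValueError("maternal component index set is empty")
    A = result.back_projection
    est = A[:, maternal_idx] @ result.components[maternal_idx]
    mean_coef = np.linalg.pinv(A) @ result.mean
    est = est + (A[:, maternal_idx] @ mean_coef[maternal_idx])[:, None]
    residual = rec.data - est
    result.maternal_component_idx = list(maternal_idx)
    result.mecg_estimate = est
    result.residual = residual
    import dataclasses as _dc
    return _dc.replace(rec, data=residual), result


def cancel_mecg(
    rec: MultichannelRecording,
    mqrs: BeatAnnotation,
    config: PipelineConfig | None = None,
) -> tuple[MultichannelRecording, SeparationResult]:
    """Convenience wrapper: separate, identify, subtract."""
    result = jade_separate(rec.data)
    idx = identify_maternal_components(result, mqrs, rec.fs, config)
    return subtract_mecg(rec, result, idx)
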