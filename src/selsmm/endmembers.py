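"""Candidate endmember extraction: MNF transform and Pixel Purity Index.

The minimum noise fraction (MNF) transform is a noise-whitened principal
components rotation: with the image covariance S and a noise covariance N
estimated from horizontal neighbor differences, it solves the generalized
eigenproblem S v = lambda N v and orders components by descending
noise-adjusted eigenvalue (signal-to-noise).  The Pixel Purity Index (PPI)
then projects the component-space pixels onto random unit "skewers" and
counts, per pixel, how often it is extreme; pure-material pixels sit at the
vertices of the data simplex and collect the highest counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .io import ImageCube, SpectralLibrary

__all__ = ["MnfResult", "PpiScoreMap", "mnf_transform", "ppi_scores",
           "extract_candidate_endmembers"]

_RIDGE = 1e-10


@dataclass
class MnfResult:
    """MNF-transformed image plus the linear map that produced it.

    ``components`` is (rows, cols, k) with NaN on masked pixels;
    ``forward_transform`` W maps centered band space to component space,
    component = (spectrum - mean) @ W.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    forward_transform: np.ndarray
    mean: np.ndarray
    mask: np.ndarray

    def inverse_transform(self) -> np.ndarray:
        """Map components back to band space, (rows, cols, m).

        Exact only when all components were retained."""
        rows, cols, _ = self.components.shape
        flat = self.components.reshape(rows * cols, -1)
        back = flat @ np.linalg.pinv(self.forward_transform) + self.mean
        return back.reshape(rows, cols, -1)


@dataclass
class PpiScoreMap:
    """Per-pixel extremeness counts from random skewer projections."""

    counts: np.ndarray
    n_skewers: int
    seed: int
    mask: np.ndarray


def _noise_covariance(cube: ImageCube) -> np.ndarray:
    """Noise covariance from horizontal shift differencing.

    For spatially smooth signal, the difference of column neighbors is
    dominated by noise with covariance 2N; halve the difference covariance.
    """
    left = cube.data[:, :-1, :]
    right = cube.data[:, 1:, :]
    valid = ~cube.mask[:, :-1] & ~cube.mask[:, 1:]
    if valid.sum() < cube.n_bands:
        raise ValueError("too few unmasked neighbor pairs to estimate noise")
    d = (right - left)[valid]
    cov = np.cov(d, rowvar=False) / 2.0
    cov = np.atleast_2d(cov)
    # absolute floor keeps the matrix invertible even for noiseless input
    ridge = _RIDGE * max(np.trace(cov), 1.0)
    return cov + ridge * np.eye(cov.shape[0])


def mnf_transform(cube: ImageCube, n_components: int | None = None) -> MnfResult:
    """Minimum noise fraction transform of an image cube.

    Components are ordered by descending noise-adjusted eigenvalue
    (variance ratio against the estimated noise); retaining all m components
    makes the transform invertible.
    """
    X = cube.unmasked_spectra()
    m = cube.n_bands
    if X.shape[0] < m:
        raise ValueError("need at least as many unmasked pixels as bands")
    k = m if n_components is None else int(n_components)
    if not 1 <= k <= m:
        raise ValueError(f"n_components must be in [1, {m}]")

    N = _noise_covariance(cube)
    mean = X.mean(axis=0)
    S = np.atleast_2d(np.cov(X, rowvar=False))
    S = S + _RIDGE * np.trace(S) * np.eye(m)
    try:
        evals, evecs = eigh(S, N)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular noise covariance") from exc
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    W = evecs[:, order]

    rows, cols, _ = cube.shape
    comps = np.full((rows, cols, k), np.nan)
    comps[~cube.mask] = (X - mean) @ W
    return MnfResult(components=comps, eigenvalues=evals, forward_transform=W,
                     mean=mean, mask=cube.mask.copy())


def ppi_scores(mnf: MnfResult, n_skewers: int = 10_000,
               extreme_tol: float = 0.01, seed: int = 0) -> PpiScoreMap:
    """Pixel Purity Index over random unit skewers in component space.

    For each skewer, pixels whose projection lies within
    ``extreme_tol * projection range`` of the minimum or of the maximum are
    each incremented (so a pixel can gain up to 2 per skewer).  Deterministic
    for a given seed.
    """
    if n_skewers < 1:
        raise ValueError("n_skewers must be >= 1")
    if extreme_tol < 0:
        raise ValueError("extreme_tol must be non-negative")
    rng = np.random.default_rng(seed)
    valid = ~mnf.mask
    P = mnf.components[valid]          # (npix, k)
    npix, k = P.shape
    counts_flat = np.zeros(npix, dtype=np.int64)

    block = 256
    for start in range(0, n_skewers, block):
        nb = min(block, n_skewers - start)
        skewers = rng.standard_normal((nb, k))
        skewers /= np.linalg.norm(skewers, axis=1, keepdims=True)
        proj = P @ skewers.T           # (npix, nb)
        lo = proj.min(axis=0)
        hi = proj.max(axis=0)
        tol = extreme_tol * (hi - lo)
        counts_flat += (proj <= lo + tol).sum(axis=1)
        counts_flat += (proj >= hi - tol).sum(axis=1)

    counts = np.zeros(mnf.mask.shape, dtype=np.int64)
    counts[valid] = counts_flat
    return PpiScoreMap(counts=counts, n_skewers=n_skewers, seed=seed,
                       mask=mnf.mask.copy())


def extract_candidate_endmembers(cube: ImageCube, scores: PpiScoreMap,
                                 top_k: int,
                                 min_separation_corr: float = 0.995
                                 ) -> SpectralLibrary:
    """Pick the spectra of the top-scoring pure pixels as candidates.

    Candidates are visited in descending count order (ties broken by
    row-major pixel order) and greedily kept unless their response
    coefficient with an already-kept candidate exceeds
    ``min_separation_corr``.  Classes are left as "other" for the user to
    assign V-I-S labels.
    """
    from .selsmm_model import UndefinedResponseError, response_coefficient

    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if scores.counts.shape != cube.mask.shape:
        raise ValueError("score map and cube shapes differ")
    valid = (~cube.mask) & (scores.counts > 0)
    rr, cc = np.nonzero(valid)
    if rr.size == 0:
        raise ValueError("no pixels with positive purity counts")
    # stable sort on -count keeps row-major order among ties
    order = np.argsort(-scores.counts[rr, cc], kind="stable")

    kept_spectra: list[np.ndarray] = []
    kept_pos: list[tuple[int, int]] = []
    for idx in order:
        if len(kept_spectra) == top_k:
            break
        r, c = int(rr[idx]), int(cc[idx])
        spec = cube.data[r, c]
        dup = False
        for prev in kept_spectra:
            try:
                if response_coefficient(spec, prev) > min_separation_corr:
                    dup = True
                    break
            except UndefinedResponseError:
                # flat spectrum: correlation undefined, keep as distinct
                continue
        if not dup:
            kept_spectra.append(spec.copy())
            kept_pos.append((r, c))
    if len(kept_spectra) < top_k:
        warnings.warn(
            f"only {len(kept_spectra)} distinct candidates available "
            f"(requested {top_k})", stacklevel=2)
    names = [f"candidate_{i + 1}_r{r}c{c}"
             for i, (r, c) in enumerate(kept_pos)]
    return SpectralLibrary(names=names,
                           vis_class=["other"] * len(names),
                           spectra=np.vstack(kept_spectra),
                           band_names=list(cube.band_names))
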