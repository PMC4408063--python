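"""Fully constrained linear spectral mixture model (FCLS / LSMM).

A mixed pixel's spectrum R (length m) is modelled as a convex combination of
endmember spectra C (m x n):

    R_L = sum_j C_Lj * alpha_j + eps_L,   alpha_j >= 0,  sum_j alpha_j = 1

Abundances are estimated by least squares under both constraints.  The
sum-to-one constraint is enforced with the Heinz-Chang construction: the
design matrix is augmented with a constant row weighted delta >> reflectance
scale and the augmented problem is solved by non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .io import ImageCube, SpectralLibrary

__all__ = ["AbundanceMap", "fcls_solve", "unmix_image_lsmm"]

# Weight of the sum-to-one row relative to the largest endmember reflectance.
# 1e4 keeps the residual-induced drift of sum(a) from 1 below ~1e-8 while the
# augmented system stays well conditioned in double precision.
_DELTA_FACTOR = 1e4
_SUM_TOL = 1e-6


@dataclass
class AbundanceMap:
    """Per-pixel endmember fractions plus unmixing metadata.

    ``fractions`` is (rows, cols, n); NaN on masked pixels.  ``selected_mask``
    records which endmembers participated in each pixel's unmixing (all True
    for plain LSMM; per-pixel subsets for SELSMM).  ``residual_rms`` is the
    RMS over bands of the model residual.
    """

    fractions: np.ndarray
    endmember_names: list[str]
    residual_rms: np.ndarray
    selected_mask: np.ndarray
    mask: np.ndarray
    geotransform: tuple | None = None

    def __post_init__(self) -> None:
        rows, cols, n = self.fractions.shape
        if len(self.endmember_names) != n:
            raise ValueError("endmember_names must match fraction planes")
        if self.residual_rms.shape != (rows, cols):
            raise ValueError("residual_rms shape mismatch")
        if self.selected_mask.shape != (rows, cols, n):
            raise ValueError("selected_mask shape mismatch")
        if self.mask.shape != (rows, cols):
            raise ValueError("mask shape mismatch")

    @property
    def n_endmembers(self) -> int:
        return self.fractions.shape[2]


def fcls_solve(spectrum: np.ndarray, endmembers: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Solve one pixel: min ||R - C a||^2 s.t. a >= 0, sum(a) = 1.

    Parameters
    ----------
    spectrum : (m,) pixel spectrum R.
    endmembers : (m, n) endmember matrix C, one column per endmember.

    Returns
    -------
    abundances : (n,) estimated fractions.
    residual : (m,) R - C @ abundances.
    """
    R = np.asarray(spectrum, dtype=float)
    C = np.atleast_2d(np.asarray(endmembers, dtype=float))
    if C.shape[1] == 0:
        raise ValueError("need at least one endmember")
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(C))):
        raise ValueError("non-finite spectrum or endmembers")
    if R.shape[0] != C.shape[0]:
        raise ValueError("band count mismatch between spectrum and endmembers")
    m, n = C.shape
    if n > m + 1:
        warnings.warn(f"underdetermined unmixing: {n} endmembers, {m} bands",
                      stacklevel=2)
    if not np.any(R):
        # Flat-zero spectrum carries no information; any simplex point fits
        # equally badly, return the uninformative uniform solution.
        warnings.warn("all-zero spectrum: returning uniform abundances",
                      stacklevel=2)
        a = np.full(n, 1.0 / n)
        return a, R - C @ a

    delta = _DELTA_FACTOR * max(np.abs(C).max(), 1e-12)
    A = np.vstack([C, np.full((1, n), delta)])
    b = np.concatenate([R, [delta]])
    a, _ = nnls(A, b)
    total = a.sum()
    if abs(total - 1.0) <= _SUM_TOL and total > 0:
        a = a / total
    else:
        warnings.warn(
            f"FCLS sum-to-one violated beyond tolerance (sum={total:.3g})",
            stacklevel=2)
    return a, R - C @ a


def unmix_image_lsmm(cube: ImageCube, library: SpectralLibrary) -> AbundanceMap:
    """Unmix every unmasked pixel with the FULL endmember library.

    Every endmember participates in every pixel (selected_mask all True on
    unmasked pixels); this is the baseline against which per-pixel selective
    unmixing is compared.
    """
    if cube.n_bands != library.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands but library has {library.n_bands}")
    C = library.endmember_matrix()
    rows, cols, _ = cube.shape
    n = library.n_endmembers
    fractions = np.full((rows, cols, n), np.nan)
    residual_rms = np.full((rows, cols), np.nan)
    selected = np.zeros((rows, cols, n), dtype=bool)
    for r, c in zip(*np.nonzero(~cube.mask)):
        a, res = fcls_solve(cube.data[r, c], C)
        fractions[r, c] = a
        residual_rms[r, c] = np.sqrt(np.mean(res ** 2))
        selected[r, c] = True
    return AbundanceMap(fractions=fractions,
                        endmember_names=list(library.names),
                        residual_rms=residual_rms,
                        selected_mask=selected,
                        mask=cube.mask.copy(),
                        geotransform=cube.geotransform)
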