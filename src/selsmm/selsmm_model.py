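"""Selective-endmember linear spectral mixture model (SELSMM).

Plain LSMM unmixes every pixel against the full endmember library, but most
moderate-resolution mixed pixels contain only a few of the scene's
components.  SELSMM therefore selects, per pixel, the endmember subset that
actually contributes, then runs fully constrained least squares on that
subset only.

Selection iterates on the pixel's residual spectrum.  At each step the
response coefficient (the Pearson correlation across bands) between the
current residual and every not-yet-selected endmember is computed; the
best-responding endmember A_max is chosen (each endmember at most once per
pixel), its normalized contribution is

    X_max = r_max / sum_j max(r_j, 0)        (over all n endmembers)

and a damped share of it is subtracted from the residual:

    R_re <- R_re - eta * X_max * A_max,      0 < eta < 1.

The adjustment coefficient eta controls how many endmembers a pixel keeps:
large eta strips the residual quickly, triggering a stop after few picks,
while small eta shaves it so gently that nearly all endmembers end up
participating.  Iteration stops when a residual component turns negative,
when the residual change ||dR||_inf falls below a tolerance, when no
candidate responds positively, or when candidates run out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ImageCube, SpectralLibrary
from .lsmm import AbundanceMap, fcls_solve

__all__ = [
    "UndefinedResponseError",
    "SelsmmConfig",
    "IterationRecord",
    "SelectionTrace",
    "response_coefficient",
    "select_endmembers",
    "unmix_image_selsmm",
]

STOP_REASONS = ("negative_component", "small_delta", "candidates_exhausted",
                "no_positive_response")


class UndefinedResponseError(ValueError):
    """Raised when a response coefficient is requested for a zero-variance
    spectrum (Pearson correlation undefined)."""


def response_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral response coefficient of two spectra: their Pearson
    correlation across bands.  Symmetric; in [-1, 1].

    Raises
    ------
    UndefinedResponseError
        if either spectrum has zero variance across bands.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("spectra must be 1-D vectors of equal length >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite spectra")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        raise UndefinedResponseError("zero-variance spectrum")
    r = float(np.dot(da, db) / (na * nb))
    return min(1.0, max(-1.0, r))


@dataclass
class SelsmmConfig:
    """Tuning of the selective-endmember iteration.

    eta : damping of the subtracted endmember contribution, in (0, 1).
        0.35 suits 6-band TM-like imagery, 0.65 4-band HJ-1B-like imagery.
    delta_tol : stop when the max-abs residual change drops below this
        (reflectance units).
    include_final_endmember : keep the endmember chosen in the iteration
        that triggers the stop (it was judged most similar before the
        subtraction was applied).
    max_iterations : hard cap on iterations; None means the library size
        (the natural bound, since each endmember is chosen at most once).
    """

    eta: float = 0.35
    delta_tol: float = 1e-4
    include_final_endmember: bool = True
    max_iterations: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie strictly between 0 and 1")
        if self.delta_tol <= 0:
            raise ValueError("delta_tol must be positive")


@dataclass
class IterationRecord:
    k: int
    endmember: int
    r_max: float
    x_max: float
    residual_after: np.ndarray


@dataclass
class SelectionTrace:
    """Log of one pixel's endmember-selection loop."""

    iterations: list[IterationRecord]
    stop_reason: str
    selected: list[int]
    fallback_full_library: bool = False

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _responses(residual: np.ndarray, dC: np.ndarray, nC: np.ndarray
               ) -> np.ndarray:
    """Pearson correlation of ``residual`` with every endmember column.

    ``dC``/``nC`` are the precentered endmember matrix and its column norms.
    Returns NaN for zero-variance endmember columns.  Raises
    UndefinedResponseError if the residual itself has zero variance.
    """
    dr = residual - residual.mean()
    nr = np.sqrt(np.sum(dr * dr))
    if nr == 0.0:
        raise UndefinedResponseError("zero-variance residual")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dr @ dC) / (nr * nC)
    return np.clip(r, -1.0, 1.0)


def select_endmembers(spectrum: np.ndarray, library: SpectralLibrary,
                      config: SelsmmConfig | None = None) -> SelectionTrace:
    """Run the selective-endmember iteration for one pixel.

    Starting from the pixel spectrum as residual, repeatedly choose the
    best-responding endmember among those not yet selected (negatives
    clamped to zero for the normalization), subtract eta * X_max * A_max,
    and stop on a negative residual component, a small residual change, no
    remaining positive response, or exhaustion of candidates.  A flat
    (zero-variance) pixel has no defined response and falls back to the
    full library.
    """
    if config is None:
        config = SelsmmConfig()
    R = np.asarray(spectrum, dtype=float)
    C = library.endmember_matrix()
    if R.shape[0] != C.shape[0]:
        raise ValueError("band count mismatch between spectrum and library")
    n = library.n_endmembers
    max_iter = config.max_iterations if config.max_iterations is not None else n

    if np.ptp(R) == 0.0:
        return SelectionTrace(iterations=[], stop_reason="no_positive_response",
                              selected=list(range(n)),
                              fallback_full_library=True)

    dC = C - C.mean(axis=0, keepdims=True)
    nC = np.sqrt(np.sum(dC * dC, axis=0))
    residual = R.copy()
    candidates = np.arange(n)
    iterations: list[IterationRecord] = []
    selected: list[int] = []
    stop_reason = None
    stop_on_this_choice = False

    for k in range(max_iter):
        if candidates.size == 0:
            break
        try:
            # responses vs the full library: the normalization denominator
            # runs over every endmember's (clamped) response, so the damped
            # step does not inflate as the candidate pool shrinks
            r_all = _responses(residual, dC, nC)
        except UndefinedResponseError:
            stop_reason = "no_positive_response"
            break
        pos_all = np.where(np.isnan(r_all), 0.0, np.clip(r_all, 0.0, None))
        r = r_all[candidates]
        if not np.any(np.nan_to_num(r, nan=-1.0) > 0.0):
            stop_reason = "no_positive_response"
            break
        # candidates ascend, so argmax breaks r_max ties by lowest index
        best = int(np.nanargmax(np.where(np.isnan(r), -np.inf, r)))
        j = int(candidates[best])
        r_max = float(r[best])
        x_max = float(pos_all[j] / pos_all.sum())
        delta = config.eta * x_max * C[:, j]
        residual = residual - delta
        iterations.append(IterationRecord(k=k, endmember=j, r_max=r_max,
                                          x_max=x_max,
                                          residual_after=residual.copy()))
        selected.append(j)
        candidates = candidates[candidates != j]
        if np.any(residual < 0.0):
            stop_reason = "negative_component"
            stop_on_this_choice = True
            break
        if np.max(np.abs(delta)) < config.delta_tol:
            stop_reason = "small_delta"
            stop_on_this_choice = True
            break
    else:
        if candidates.size > 0:
            warnings.warn("SELSMM selection hit max_iterations", stacklevel=2)
        stop_reason = "candidates_exhausted"
    if stop_reason is None:
        stop_reason = "candidates_exhausted"

    if (stop_on_this_choice and not config.include_final_endmember
            and len(selected) > 1):
        selected = selected[:-1]
    if not selected:
        # nothing positively responded at all: no basis for a subset
        return SelectionTrace(iterations=iterations, stop_reason=stop_reason,
                              selected=list(range(n)),
                              fallback_full_library=True)
    return SelectionTrace(iterations=iterations, stop_reason=stop_reason,
                          selected=selected)


def unmix_image_selsmm(cube: ImageCube, library: SpectralLibrary,
                       config: SelsmmConfig | None = None,
                       keep_traces: bool = False
                       ) -> tuple[AbundanceMap, "SelectionSummary"]:
    """Per-pixel selective unmixing: select an endmember subset, then FCLS
    restricted to that subset.  Unselected endmembers get abundance 0."""
    if cube.n_bands != library.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands but library has {library.n_bands}")
    if config is None:
        config = SelsmmConfig()
    C = library.endmember_matrix()
    rows, cols, _ = cube.shape
    n = library.n_endmembers
    fractions = np.full((rows, cols, n), np.nan)
    residual_rms = np.full((rows, cols), np.nan)
    selected_mask = np.zeros((rows, cols, n), dtype=bool)
    n_selected = np.zeros((rows, cols), dtype=np.int32)
    stop_codes = np.full((rows, cols), -1, dtype=np.int8)
    fallback = np.zeros((rows, cols), dtype=bool)
    traces: dict[tuple[int, int], SelectionTrace] = {}

    for r, c in zip(*np.nonzero(~cube.mask)):
        trace = select_endmembers(cube.data[r, c], library, config)
        sel = sorted(trace.selected)
        a_sub, res = fcls_solve(cube.data[r, c], C[:, sel])
        a = np.zeros(n)
        a[sel] = a_sub
        fractions[r, c] = a
        residual_rms[r, c] = np.sqrt(np.mean(res ** 2))
        selected_mask[r, c, sel] = True
        n_selected[r, c] = len(sel)
        stop_codes[r, c] = STOP_REASONS.index(trace.stop_reason)
        fallback[r, c] = trace.fallback_full_library
        if keep_traces:
            traces[(r, c)] = trace

    abund = AbundanceMap(fractions=fractions,
                         endmember_names=list(library.names),
                         residual_rms=residual_rms,
                         selected_mask=selected_mask,
                         mask=cube.mask.copy(),
                         geotransform=cube.geotransform)
    summary = SelectionSummary(n_selected=n_selected, stop_codes=stop_codes,
                               fallback_full_library=fallback,
                               mask=cube.mask.copy(),
                               traces=traces if keep_traces else None)
    return abund, summary


@dataclass
class SelectionSummary:
    """Per-pixel summary of the selection loop over a whole image.

    ``stop_codes`` indexes into STOP_REASONS (-1 on masked pixels).
    ``traces`` holds full per-pixel traces when requested.
    """

    n_selected: np.ndarray
    stop_codes: np.ndarray
    fallback_full_library: np.ndarray
    mask: np.ndarray
    traces: dict[tuple[int, int], SelectionTrace] | None = None

    def mean_selected(self) -> float:
        """Mean selected-set size over unmasked pixels."""
        return float(self.n_selected[~self.mask].mean())

    def trace_records(self) -> list[dict]:
        """Flatten stored traces to row dicts (for a trace CSV)."""
        if self.traces is None:
            raise ValueError("traces were not kept; pass keep_traces=True")
        out = []
        for (r, c), tr in self.traces.items():
            for it in tr.iterations:
                out.append({"row": r, "col": c, "iteration": it.k,
                            "endmember": it.endmember, "r_max": it.r_max,
                            "x_max": it.x_max, "stop_reason": tr.stop_reason})
        return out
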