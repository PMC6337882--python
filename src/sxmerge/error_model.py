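"""Two-parameter intensity error model and the ISa statistic.

The model inflates the reported counting sigmas to match the scatter that
repeated observations of the same unique reflection actually show:

    σ_adj²(I) = a · (σ_raw² + b · I²)

``a`` rescales the counting estimate and ``b`` adds a fractional systematic
term.  ISa = 1/sqrt(a·b) is the asymptotic signal-to-noise an infinitely
strong reflection could reach; datasets dominated by systematic error score
low ISa regardless of counting statistics, which is what makes it a useful
per-dataset rejection criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = ["ErrorModel", "fit_error_model"]

_FLOOR = 1e-8  # positivity floor for a and b
MIN_GROUPS = 30
MIN_MULTIPLICITY = 3


@dataclass(frozen=True)
class ErrorModel:
    """Fitted (a, b) of one dataset; ``defined`` is False when the fit failed."""

    dataset_id: str
    a: float
    b: float
    isa: float
    n_groups_used: int
    defined: bool = True
    reason: str = ""

    @staticmethod
    def undefined(dataset_id: str, reason: str) -> "ErrorModel":
        return ErrorModel(dataset_id, np.nan, np.nan, np.nan, 0, defined=False, reason=reason)


def fit_error_model(
    intensity: np.ndarray,
    sigma: np.ndarray,
    group_codes: np.ndarray,
    dataset_id: str = "",
    group_means: np.ndarray | None = None,
    group_sizes: np.ndarray | None = None,
    n_bins: int = 10,
    min_groups: int = MIN_GROUPS,
) -> ErrorModel:
    """Fit σ_adj² = a·(σ_raw² + b·I²) to the observed merging residuals.

    ``group_codes`` assigns each observation to its unique reflection.  By
    default the group mean ⟨I⟩ and multiplicity come from the observations
    themselves; when the observations are one dataset's share of a larger
    merged ensemble, pass the ensemble's ``group_means``/``group_sizes``
    (indexed by group code) instead.

    Residuals δ = (I − ⟨I⟩)·sqrt(n/(n−1)); observations are pooled into
    ``n_bins`` equal-count intensity bins keyed on the group mean ⟨I⟩ (the
    best estimate of the true intensity — binning on the noisy observation
    itself washes the I² term out when the errors are large), and the
    bin-wise mean squared residual is regressed on (⟨σ_raw²⟩, ⟨I²⟩) with
    both coefficients kept non-negative.  A degenerate design (e.g.
    constant intensity) yields an undefined model, never an exception.
    """
    intensity = np.asarray(intensity, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    group_codes = np.asarray(group_codes)
    if group_codes.dtype.kind not in "iu":
        _, group_codes = np.unique(group_codes, return_inverse=True)
    n_groups = int(group_codes.max()) + 1 if len(group_codes) else 0
    if group_sizes is None:
        group_sizes = np.bincount(group_codes, minlength=n_groups)
    if group_means is None:
        sums = np.bincount(group_codes, weights=intensity, minlength=n_groups)
        with np.errstate(invalid="ignore"):
            group_means = np.where(group_sizes > 0, sums / np.maximum(group_sizes, 1), np.nan)

    n_h = np.asarray(group_sizes)[group_codes]
    usable = n_h >= MIN_MULTIPLICITY
    n_used = len(np.unique(group_codes[usable])) if usable.any() else 0
    if n_used < min_groups:
        return ErrorModel.undefined(
            dataset_id, f"only {n_used} groups with multiplicity ≥ {MIN_MULTIPLICITY}"
        )

    inten = intensity[usable]
    sig = sigma[usable]
    delta = (inten - np.asarray(group_means)[group_codes[usable]]) * np.sqrt(
        n_h[usable] / (n_h[usable] - 1.0)
    )

    best_i = np.asarray(group_means)[group_codes[usable]]
    order = np.argsort(best_i, kind="stable")
    nb = max(2, min(n_bins, len(inten) // 3))
    bins = (np.arange(len(inten)) * nb) // len(inten)
    counts = np.bincount(bins)
    rms2 = np.bincount(bins, weights=delta[order] ** 2) / counts
    mean_sig2 = np.bincount(bins, weights=sig[order] ** 2) / counts
    mean_i2 = np.bincount(bins, weights=best_i[order] ** 2) / counts

    design = np.column_stack([mean_sig2, mean_i2])
    if not np.all(np.isfinite(design)) or not np.all(np.isfinite(rms2)):
        return ErrorModel.undefined(dataset_id, "non-finite fit inputs")
    good = rms2 > 0
    if good.sum() < 2:
        return ErrorModel.undefined(dataset_id, "degenerate residuals")
    # the sampling variance of a mean-square estimate scales with its square,
    # so weight bins by n/RMS⁴ — a relative-error fit; otherwise the strongest
    # bin dominates and the two nearly collinear columns cannot be separated
    w = np.sqrt(counts[good]) / rms2[good]
    try:
        coef, _ = nnls(design[good] * w[:, None], rms2[good] * w)
    except Exception:
        return ErrorModel.undefined(dataset_id, "singular fit")
    a = max(float(coef[0]), _FLOOR)
    b = max(float(coef[1]) / a, _FLOOR)
    if not np.isfinite(a) or not np.isfinite(b):
        return ErrorModel.undefined(dataset_id, "singular fit")
    isa = 1.0 / np.sqrt(a * b)
    return ErrorModel(dataset_id, a, b, float(isa), n_used)
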