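"""Post-run statistics: blocking error bars, efficiency, wavefunction RMSE.

Correlated FCIQMC time series need blocking (recursive pairwise averaging)
to obtain an honest standard error of the mean; the efficiency
eta = 1 / (Var(E_proj) * t) measures variance reduction per wall-clock
second and is the figure of merit for comparing dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import CISpace, s_squared_expectation

__all__ = [
    "BlockingResult",
    "blocking_analysis",
    "efficiency",
    "wavefunction_rmse",
    "spin_report",
]


@dataclass
class BlockingResult:
    """Standard-error estimates per blocking level and the chosen plateau."""

    block_sizes: np.ndarray
    error_estimates: np.ndarray  # sigma of the mean at each level
    error_of_errors: np.ndarray
    plateau_estimate: float
    plateau_block: int


def blocking_analysis(
    series: np.ndarray, min_blocks: int = 4, plateau_block: int | None = None
) -> BlockingResult:
    """Flyvbjerg-Petersen blocking of a correlated scalar time series.

    Successive levels halve the series by pairwise averaging; each level's
    estimate is sqrt(var(blocks) / n_blocks).  The plateau is the first level
    whose estimate lies within one estimated-error of the next level's (last
    level as fallback); a manual block size can override via
    ``plateau_block``.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 32:
        raise ValueError("series too short for blocking (need >= 32 points)")
    sizes, errs, err_errs = [], [], []
    block = 1
    while len(x) >= min_blocks:
        n = len(x)
        est = float(np.sqrt(np.var(x, ddof=1) / n))
        sizes.append(block)
        errs.append(est)
        err_errs.append(est / np.sqrt(2.0 * (n - 1)))
        if n % 2 == 1:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
        block *= 2
    sizes_a = np.array(sizes)
    errs_a = np.array(errs)
    err_errs_a = np.array(err_errs)
    if plateau_block is not None:
        matches = np.flatnonzero(sizes_a == plateau_block)
        if not len(matches):
            raise ValueError(f"no blocking level with block size {plateau_block}")
        plateau_idx = int(matches[0])
    else:
        plateau_idx = len(errs_a) - 1
        for i in range(len(errs_a) - 1):
            if errs_a[i + 1] - errs_a[i] <= err_errs_a[i]:
                plateau_idx = i
                break
    return BlockingResult(
        sizes_a, errs_a, err_errs_a, float(errs_a[plateau_idx]), int(sizes_a[plateau_idx])
    )


def efficiency(series: np.ndarray, wallclock: float) -> float:
    """eta = (Var(E_proj) * t)^-1 with the blocking-corrected variance.

    Uses the plateau variance of the mean; a zero variance is reported as
    infinity.
    """
    if wallclock <= 0:
        raise ValueError("wallclock must be positive")
    sigma = blocking_analysis(series).plateau_estimate
    var = sigma * sigma
    if var == 0.0:
        return float("inf")
    return 1.0 / (var * wallclock)


def wavefunction_rmse(
    coeffs: np.ndarray,
    ref_coeffs: np.ndarray,
    p_mask: np.ndarray | None = None,
) -> dict[str, object]:
    """RMSE of a CI vector against a reference over the same ordered space.

    Both vectors are L2-normalized and sign-aligned by maximal overlap before
    comparison.  With a P-membership mask the per-configuration deviations
    are additionally split into P- and Q-space contributions.
    """
    c = np.asarray(coeffs, dtype=float)
    r = np.asarray(ref_coeffs, dtype=float)
    if c.shape != r.shape:
        raise ValueError(f"dimension mismatch: {c.shape} vs {r.shape}")
    c = c / np.linalg.norm(c)
    r = r / np.linalg.norm(r)
    if float(c @ r) < 0.0:
        c = -c
    dev = c - r
    out: dict[str, object] = {
        "rmse": float(np.sqrt(np.mean(dev**2))),
        "deviations": dev,
    }
    if p_mask is not None:
        p_mask = np.asarray(p_mask, dtype=bool)
        out["rmse_p"] = float(np.sqrt(np.mean(dev[p_mask] ** 2))) if p_mask.any() else 0.0
        out["rmse_q"] = float(np.sqrt(np.mean(dev[~p_mask] ** 2))) if (~p_mask).any() else 0.0
    return out


def spin_report(coeffs: np.ndarray, space: CISpace, s_value: float | None = None) -> dict[str, float]:
    """<S^2> of a determinant-basis vector and its deviation from S(S+1).

    Without an explicit target spin the nearest S consistent with the space's
    spin projection is used.
    """
    s2 = s_squared_expectation(coeffs, space)
    d0 = space.determinants[0]
    ms = 0.5 * abs(d0.n_alpha - d0.n_beta)
    if s_value is None:
        # nearest S >= |Ms| with S(S+1) closest to the measured value
        best, best_dev = ms, float("inf")
        s = ms
        for _ in range(20):
            dev = abs(s2 - s * (s + 1.0))
            if dev < best_dev:
                best, best_dev = s, dev
            s += 1.0
        s_value = best
    return {
        "s_squared": float(s2),
        "s_value": float(s_value),
        "deviation": float(s2 - s_value * (s_value + 1.0)),
    }
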