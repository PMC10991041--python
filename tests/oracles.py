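"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: extrema come from
scipy.signal.argrelextrema, envelopes use endpoint-anchored splines rather
than mirror extension, and the CEEMDAN loop is written from the published
algorithm description.  Agreement between package and oracle is therefore a
genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


# ---------------------------------------------------------------------------
# EMD / CEEMDAN
# ---------------------------------------------------------------------------


def _oracle_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Spline through extrema with the signal endpoints as extra anchors."""
    n = len(x)
    knots = list(idx)
    if 0 not in knots:
        knots = [0] + knots
    if n - 1 not in knots:
        knots = knots + [n - 1]
    knots = np.array(knots)
    if len(knots) < 4:
        return np.interp(np.arange(n), knots, x[knots])
    return CubicSpline(knots, x[knots])(np.arange(n))


def oracle_sift_once(x: np.ndarray, max_iter: int = 60, tol: float = 0.2):
    """Extract one IMF, or None when the signal cannot be sifted."""
    h = x.copy()
    for _ in range(max_iter):
        maxima = argrelextrema(h, np.greater)[0]
        minima = argrelextrema(h, np.less)[0]
        if len(maxima) < 2 or len(minima) < 2:
            return None if np.array_equal(h, x) else h
        mean_env = 0.5 * (_oracle_envelope(h, maxima) + _oracle_envelope(h, minima))
        h_new = h - mean_env
        denom = np.sum(h**2)
        if denom > 0 and np.sum(mean_env**2) / denom < tol:
            return h_new
        h = h_new
    return h


def oracle_emd(x: np.ndarray, max_imfs: int = 9) -> list[np.ndarray]:
    imfs = []
    residual = x.astype(float).copy()
    while len(imfs) < max_imfs:
        imf = oracle_sift_once(residual)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return imfs


def oracle_ceemdan(
    x: np.ndarray, noise_std: float = 0.2, ensemble_size: int = 50, seed: int = 0, max_imfs: int = 9
) -> list[np.ndarray]:
    """Complete-ensemble EMD with adaptive noise, written from the algorithm.

    Stage k perturbs the running residual with the k-th EMD mode of each
    noise realization (scaled to noise_std * std(residual)), extracts one
    mode from each perturbed residual, and averages.
    """
    rng = np.random.default_rng(seed)
    n = len(x)
    noise_modes = []
    for _ in range(ensemble_size):
        modes = oracle_emd(rng.standard_normal(n), max_imfs=max_imfs)
        noise_modes.append([m / m.std() if m.std() > 0 else m for m in modes])
    imfs = []
    residual = x.astype(float).copy()
    for k in range(max_imfs):
        if len(argrelextrema(residual, np.greater)[0]) < 2:
            break
        beta = noise_std * residual.std()
        acc = np.zeros(n)
        for modes in noise_modes:
            perturbed = residual + beta * modes[k] if k < len(modes) else residual
            imf = oracle_sift_once(perturbed)
            acc += imf if imf is not None else np.zeros(n)
        mode = acc / ensemble_size
        imfs.append(mode)
        residual = residual - mode
    return imfs


# ---------------------------------------------------------------------------
# Tracking: exhaustive spatial cross-correlation localization
# ---------------------------------------------------------------------------


def oracle_displacement(ref_patch: np.ndarray, frame: np.ndarray, top_left: tuple[int, int], max_shift: int) -> tuple[int, int]:
    """Best (dy, dx) by brute-force normalized cross-correlation search."""
    h, w = ref_patch.shape
    y0, x0 = top_left
    ref = ref_patch - ref_patch.mean()
    best, best_val = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            y, x = y0 + dy, x0 + dx
            if y < 0 or x < 0 or y + h > frame.shape[0] or x + w > frame.shape[1]:
                continue
            cand = frame[y : y + h, x : x + w]
            cand = cand - cand.mean()
            denom = np.linalg.norm(ref) * np.linalg.norm(cand)
            if denom == 0:
                continue
            val = float(np.sum(ref * cand)) / denom
            if val > best_val:
                best_val, best = val, (dy, dx)
    return best


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def ks_statistic_brute(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| evaluated at every sample point."""
    pts = np.concatenate([a, b])
    d = 0.0
    for p in pts:
        d = max(d, abs(np.mean(a <= p) - np.mean(b <= p)))
    return d


def ks_permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation p-value for the two-sample KS statistic."""
    rng = np.random.default_rng(seed)
    observed = ks_statistic_brute(a, b)
    pooled = np.concatenate([a, b])
    na = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if ks_statistic_brute(perm[:na], perm[na:]) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def interval_filter_brute(raw: list[float], frac: float = 0.25) -> list[float]:
    """Literal application of the +/-frac-around-the-raw-mean rule."""
    mu = sum(raw) / len(raw)
    return [r for r in raw if (1 - frac) * mu <= r <= (1 + frac) * mu]


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation formula."""
    mx, my = np.mean(x), np.mean(y)
    num = np.sum((x - mx) * (y - my))
    den = np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return float(num / den)
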