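"""Shared numerical utilities: knee detection and bimodal histogram fits.

Every knee point in the package (PC selection, archetype-number selection)
goes through the same max-distance-to-chord rule so behavior is uniform.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """A least-squares distribution fit failed or was degenerate."""


def knee_point(y: np.ndarray, x: np.ndarray | None = None) -> int:
    """Index of the knee of a curve by maximum perpendicular distance to the
    chord joining its endpoints.

    Parameters
    ----------
    y : array of curve values (e.g. cumulative explained variance).
    x : optional abscissae; defaults to 0..len(y)-1.

    Returns
    -------
    Index into ``y`` of the knee. Raises ``FitError`` if the curve is flat
    (chord rule undefined).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise FitError("need >= 3 points to locate a knee")
    if x is None:
        x = np.arange(y.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    # normalize both axes so the chord distance is scale-free
    xs = (x - x[0]) / (x[-1] - x[0]) if x[-1] != x[0] else x - x[0]
    rng_y = y[-1] - y[0]
    if abs(rng_y) < 1e-12:
        raise FitError("flat curve: knee undefined")
    ys = (y - y[0]) / rng_y
    # perpendicular distance to the chord from (0,0) to (1,1)
    d = np.abs(ys - xs) / np.sqrt(2.0)
    return int(np.argmax(d))


def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    g1 = a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
    g2 = a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)
    return g1 + g2


def fit_bimodal(
    values: np.ndarray,
    n_bins: int = 50,
    init_quantiles: tuple[float, float] = (0.25, 0.75),
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit a two-Gaussian model to the histogram of ``values`` by least squares.

    Returns ((mu1, sd1), (mu2, sd2)) ordered by ascending mean, so the
    "second" component is the larger-mean one. Raises FitError when the data
    are degenerate or the optimizer cannot separate two components.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise FitError("too few values for a bimodal fit")
    spread = values.max() - values.min()
    if spread <= 0 or np.std(values) == 0:
        raise FitError("degenerate (constant) distribution")

    hist, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    q1, q2 = np.quantile(values, init_quantiles)
    s0 = max(np.std(values) / 4.0, spread / (4.0 * n_bins))
    p0 = [hist.max(), q1, s0, hist.max(), q2, s0]
    lo = [0.0, values.min() - spread, 1e-12, 0.0, values.min() - spread, 1e-12]
    hi = [np.inf, values.max() + spread, spread * 2, np.inf, values.max() + spread, spread * 2]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _two_gaussians, centers, hist, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
        raise FitError(f"bimodal fit did not converge: {exc}") from exc
    a1, m1, s1, a2, m2, s2 = popt
    if a1 <= 0 or a2 <= 0:
        raise FitError("bimodal fit collapsed to a single component")
    comps = sorted([(m1, s1), (m2, s2)], key=lambda p: p[0])
    if abs(comps[1][0] - comps[0][0]) < 1e-6 * max(1.0, spread):
        raise FitError("bimodal fit components coincide")
    return (comps[0][0], abs(comps[0][1])), (comps[1][0], abs(comps[1][1]))


def check_random_state(seed) -> np.random.Generator:
    """Coerce an int seed or Generator into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
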