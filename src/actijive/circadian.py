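"""Circadian-rhythm features: cosinor, nonparametric metrics, diurnal fPCA.

Fourteen features per subject:

* Mesor, Amp, Acro — single-harmonic (24 h) cosinor fit of minute counts,
  ``x(t) = M + A cos(omega (t - t_peak))``.  The acrophase is reported in
  negative radians, ``Acro = -2 pi t_peak / 24`` in (-2 pi, 0], so a 2 PM
  peak corresponds to roughly -3.67.
* IV, IS — intradaily variability and interdaily stability on hourly-binned
  counts (the field's standard first-difference and 24-hour-pattern ratios).
* L5, M10, L5Time, M10Time, RA — mean counts in the least-active 5 h and
  most-active 10 h wrap-around windows of the average (diurnal) day, the
  clock hours of the window midpoints, and the relative amplitude
  ``RA = (M10 - L5) / (M10 + L5)``.
* fPC1-fPC4 — subject scores on the leading principal components of the
  smoothed, column-centered log-scale diurnal profiles (a discretized
  functional PCA via SVD).
"""

from __future__ import annotations

import numpy as np

OMEGA = 2.0 * np.pi / 24.0  # rad per hour


def cosinor_fit(t_hours: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Least-squares cosinor fit; returns (Mesor, Amp, Acro).

    ``t_hours`` are clock times in hours (any real values; only t mod 24
    matters).  Constant input yields ``Amp = 0`` and ``Acro = nan``.
    """
    t = np.asarray(t_hours, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size != x.size or t.size < 3:
        raise ValueError("need matched t/x with at least 3 points")
    design = np.column_stack([np.ones_like(t), np.cos(OMEGA * t), np.sin(OMEGA * t)])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    mesor, bc, bs = (float(b) for b in beta)
    amp = float(np.hypot(bc, bs))
    if amp < 1e-12:
        return mesor, 0.0, float("nan")
    t_peak = (np.arctan2(bs, bc) / OMEGA) % 24.0
    acro = -2.0 * np.pi * t_peak / 24.0  # in (-2 pi, 0]
    return mesor, amp, float(acro)


def iv_is(hourly: np.ndarray, clock_hour: np.ndarray) -> tuple[float, float]:
    """Intradaily variability and interdaily stability from hourly means.

    ``hourly`` is the chronological sequence of hourly mean counts (N >= 48)
    and ``clock_hour`` the clock hour (0-23) of each bin.  First differences
    are taken between chronologically adjacent bins.  A constant series has
    undefined IV/IS (nan).
    """
    x = np.asarray(hourly, dtype=float)
    h = np.asarray(clock_hour)
    if x.size != h.size or x.size < 48:
        raise ValueError("need at least 48 hourly values")
    n = x.size
    dev = x - x.mean()
    ss = float(np.sum(dev**2))
    if ss <= 0:
        return float("nan"), float("nan")
    iv = n * float(np.sum(np.diff(x) ** 2)) / ((n - 1) * ss)
    hour_means = np.array([x[h == hh].mean() for hh in range(24) if np.any(h == hh)])
    is_ = n * float(np.sum((hour_means - x.mean()) ** 2)) / (24.0 * ss)
    return iv, is_


def _window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Mean of every wrap-around window of ``width`` minutes; index = start."""
    p = np.asarray(profile, dtype=float)
    ext = np.concatenate([p, p[: width - 1]])
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return (c[width:] - c[:-width])[: p.size] / width


def l5_m10(profile: np.ndarray) -> dict[str, float]:
    """L5/M10 window statistics of a 1440-minute diurnal profile (count scale).

    The profile grid is clock time: index 0 is midnight.  M10 is the maximum
    mean over 600-minute wrap-around windows, L5 the minimum over 300-minute
    windows; times are window-midpoint clock hours in [0, 24).  Ties pick
    the earliest window start.  An all-zero profile has undefined RA.
    """
    p = np.asarray(profile, dtype=float)
    if p.size != 1440:
        raise ValueError("profile must have 1440 minutes")
    m10_means = _window_means(p, 600)
    l5_means = _window_means(p, 300)
    i_m10 = int(np.argmax(m10_means))
    i_l5 = int(np.argmin(l5_means))
    m10 = float(m10_means[i_m10])
    l5 = float(l5_means[i_l5])
    ra = (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else float("nan")
    return {
        "L5": l5,
        "M10": m10,
        "L5Time": ((i_l5 + 150) / 60.0) % 24.0,
        "M10Time": ((i_m10 + 300) / 60.0) % 24.0,
        "RA": ra,
    }


def _smooth_circular(profiles: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return profiles
    kernel = np.ones(width) / width
    n = profiles.shape[1]
    ext = np.concatenate([profiles[:, -(width // 2):], profiles,
                          profiles[:, : width - 1 - width // 2]], axis=1)
    out = np.empty_like(profiles)
    for i in range(profiles.shape[0]):
        out[i] = np.convolve(ext[i], kernel, mode="valid")[:n]
    return out


def diurnal_fpca(
    profiles: np.ndarray, k: int = 4, *, smooth_width: int = 21
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discretized functional PCA of diurnal (log-scale) profiles.

    ``profiles`` is subjects x 1440 on a shared clock grid.  Profiles are
    circularly smoothed with a moving average, column-centered across
    subjects and decomposed by SVD.  Returns ``(scores, components, shares)``
    where ``scores`` is subjects x k (projections, mean 0 per column),
    ``components`` is 1440 x k unit-norm loading curves and ``shares`` the
    fraction of total variance carried by each component.

    Sign rule for determinism: each component curve is flipped so its
    integral over 10:00-14:00 is positive (falls back to the largest-
    magnitude element when that integral is zero).
    """
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 subjects")
    Xs = _smooth_circular(X, smooth_width)
    Xc = Xs - Xs.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] < 1e-10 * max(1.0, float(np.linalg.norm(Xs))):
        # all profiles identical: every score is zero by centering
        return (np.zeros((n, k)), np.zeros((X.shape[1], k)), np.zeros(k))
    if np.count_nonzero(s > s[0] * 1e-12) < k:
        raise ValueError(f"profiles have rank < {k}")
    comps = vt[:k].T.copy()  # 1440 x k
    scores = u[:, :k] * s[:k]
    midday = slice(600, 840)  # 10:00-14:00
    for j in range(k):
        integral = comps[midday, j].sum()
        flip = integral < 0 if abs(integral) > 1e-12 else (
            comps[np.argmax(np.abs(comps[:, j])), j] < 0)
        if flip:
            comps[:, j] *= -1.0
            scores[:, j] *= -1.0
    total = float(np.sum(s**2))
    shares = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, comps, shares
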