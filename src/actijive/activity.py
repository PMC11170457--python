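"""Physical-activity features: volume, intensity composition, fragmentation.

Seven features per subject, each a mean over valid days:

* TAC — total activity counts per day; TLAC — total log(1+count).
* TST / LiPA / MVPA — minutes classified sedentary (< ``theta_sed``), light
  ([``theta_sed``, ``theta_mvpa``)) and moderate-to-vigorous
  (>= ``theta_mvpa``).  The classification spans the full 24-hour day, so
  sleep minutes count as sedentary and the three classes partition the worn
  minutes exactly.
* SATP / ASTP — per-minute sedentary-to-active and active-to-sedentary
  transition probabilities: transitions divided by minutes in the source
  state.  Up to edge effects these are the reciprocals of the mean
  sedentary and active bout durations.  The final minute of a day has no
  outgoing transition but still contributes to the denominator.

Count thresholds are device- and scale-dependent; the defaults (50, 1000
counts/min) match the scale of the bundled synthetic generator and are
configurable everywhere.
"""

from __future__ import annotations

import numpy as np


def pa_volume(counts: np.ndarray, wear: np.ndarray | None = None) -> tuple[float, float]:
    """Total activity counts (TAC) and total log counts (TLAC) over worn minutes."""
    counts = np.asarray(counts, dtype=float)
    wear = np.ones_like(counts, bool) if wear is None else np.asarray(wear, bool)
    worn = counts[wear]
    return float(worn.sum()), float(np.log1p(worn).sum())


def pa_composition(
    counts: np.ndarray,
    wear: np.ndarray | None = None,
    *,
    theta_sed: float = 50.0,
    theta_mvpa: float = 1000.0,
) -> tuple[float, float, float]:
    """Minutes in sedentary / light / MVPA intensity classes over worn minutes."""
    if not 0 < theta_sed < theta_mvpa:
        raise ValueError("need 0 < theta_sed < theta_mvpa")
    counts = np.asarray(counts, dtype=float)
    wear = np.ones_like(counts, bool) if wear is None else np.asarray(wear, bool)
    worn = counts[wear]
    tst = int(np.count_nonzero(worn < theta_sed))
    mvpa = int(np.count_nonzero(worn >= theta_mvpa))
    lipa = worn.size - tst - mvpa
    return float(tst), float(lipa), float(mvpa)


def pa_fragmentation(
    counts: np.ndarray,
    wear: np.ndarray | None = None,
    *,
    theta_sed: float = 50.0,
    include: np.ndarray | None = None,
) -> tuple[float, float]:
    """Sedentary->active (SATP) and active->sedentary (ASTP) transition probabilities.

    Transitions are counted between time-adjacent minutes that are both worn
    (and both in ``include``, when given — e.g. a wake-time mask).  Returns
    ``(nan, nan)`` when either state is absent.
    """
    counts = np.asarray(counts, dtype=float)
    wear = np.ones_like(counts, bool) if wear is None else np.asarray(wear, bool)
    use = wear if include is None else wear & np.asarray(include, bool)
    sed = counts < theta_sed
    n_sed = int(np.count_nonzero(sed & use))
    n_act = int(np.count_nonzero(~sed & use))
    if n_sed == 0 or n_act == 0:
        return float("nan"), float("nan")
    pair = use[:-1] & use[1:]
    s0, s1 = sed[:-1], sed[1:]
    n_sa = int(np.count_nonzero(pair & s0 & ~s1))
    n_as = int(np.count_nonzero(pair & ~s0 & s1))
    return n_sa / n_sed, n_as / n_act


def pa_day_features(
    counts: np.ndarray,
    wear: np.ndarray | None = None,
    *,
    theta_sed: float = 50.0,
    theta_mvpa: float = 1000.0,
    frag_include: np.ndarray | None = None,
) -> dict[str, float]:
    """All seven PA features for a single day grid."""
    tac, tlac = pa_volume(counts, wear)
    tst, lipa, mvpa = pa_composition(counts, wear, theta_sed=theta_sed,
                                     theta_mvpa=theta_mvpa)
    satp, astp = pa_fragmentation(counts, wear, theta_sed=theta_sed,
                                  include=frag_include)
    return {"TAC": tac, "TLAC": tlac, "TST": tst, "LiPA": lipa, "MVPA": mvpa,
            "SATP": satp, "ASTP": astp}
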