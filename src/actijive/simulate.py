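"""Synthetic cohorts with planted ground truth, at two tiers.

Feature tier
    Draws the three feature blocks directly from the latent model
    ``X_k = U C_k W_k' + U_k D_k V_k' + E_k`` with independent standard
    Gaussian joint (``U``) and block-individual (``U_k``) factors,
    orthonormal loading frames and component/noise scales solved so the
    expected joint/individual/residual energy split per block hits the
    requested variance-explained targets.  A binary depression outcome is
    drawn from a logistic model on the standardized planted factors, with
    per-SD log odds ratios from the plan; covariates (age, sex, BMI,
    anxiety, SUD, medication) are drawn near the reference cohort marginals
    and are independent of the latents by default.  Feature columns are
    mapped onto the reference means/SDs so the table lives on a realistic
    physical scale.

Epoch tier
    Simulates ~2 weeks of minute-level counts per subject from planted
    per-subject parameters: a nightly sleep period around a planted
    onset/wakeup with occasional >= 5-minute wake bouts, a two-state
    sedentary/active Markov chain (transition probabilities ``p_sa``,
    ``p_as``) governing wake minutes, and positive count laws whose
    expectation follows the subject's 24-hour cosinor envelope
    ``lambda(t) = M + A cos(omega (t - t_peak))``.  Sleep minutes use a
    burst mixture (mostly near-still minutes plus sparse movement bursts)
    whose mean equals the envelope, so the cosinor is recoverable without
    bias; wake minutes split the envelope between a bounded sedentary law
    (counts in [10, 30), always below the sedentary threshold and above the
    sleep threshold) and an active law shifted above the sedentary
    threshold, so intensity classes are separated by construction.  Near
    the sleep edges the envelope can fall below the smallest achievable
    wake mean; the wake mean is then floored (documented limitation).

Every generated cohort carries its ground truth; regeneration from the
same (plan, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import reference
from .blocks import BLOCKS, FeatureBlocks
from .epoch import EpochSeries, MINUTES_PER_DAY

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------- feature tier

@dataclass
class FeaturePlan:
    """Plan for the feature-tier generator (defaults emulate the reference
    cohort: n, ranks, variance partition, outcome odds ratios)."""

    n_subjects: int = 2317
    r_joint: int = 3
    r_indiv: tuple[int, int, int] = (1, 2, 3)  # SL, PA, CR
    varexp: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(reference.VAREXP_REFERENCE))
    joint_weights: tuple[float, ...] = (0.5, 0.3, 0.2)  # energy split, joint comps
    outcome_logor: dict[str, float] = field(
        default_factory=lambda: {k: float(np.log(v))
                                 for k, v in reference.LIFETIME_OR_REFERENCE.items()})
    lifetime_prevalence: float = 1153 / 2317
    current_given_lifetime: float = 185 / 1153
    noise_scale: float = 1.0  # 0 switches the residual term off

    def __post_init__(self) -> None:
        for k, v in self.varexp.items():
            if not (0 <= min(v) and sum(v) <= 1.0 + 1e-9):
                raise ValueError(f"infeasible variance targets for block {k}: {v}")


def _orthonormal(rng: np.random.Generator, p: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((p, r)))
    return q


def _balanced_frames(rng, p: int, scales: list[np.ndarray], n_iter: int = 200):
    """Orthonormal loading frames whose combined scaled rows have equal norm.

    With random frames the planted columns have unequal variance, and the
    pipeline's per-column z-scoring would then tilt the block's
    joint/individual/residual energy split away from the plan.  Alternating
    row-flattening with polar re-orthonormalisation yields frames for which
    every feature carries (nearly) the same structural variance, so the
    planned split survives z-scoring."""
    parts = [_orthonormal(rng, p, s.size) if s.size else np.zeros((p, 0))
             for s in scales]
    for _ in range(n_iter):
        L = np.hstack([P * s for P, s in zip(parts, scales)])
        if L.size == 0:
            break
        rn = np.sqrt((L ** 2).sum(axis=1))
        target = np.sqrt((L ** 2).sum() / p)
        fac = target / np.maximum(rn, 1e-12)
        new_parts = []
        for P, s in zip(parts, scales):
            if s.size == 0:
                new_parts.append(P)
                continue
            M = (P * s) * fac[:, None]
            u, _, vt = np.linalg.svd(M * s, full_matrices=False)
            new_parts.append(u @ vt)
        if all(np.allclose(a, b, atol=1e-12) for a, b in zip(parts, new_parts)):
            parts = new_parts
            break
        parts = new_parts
    return parts


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_feature_cohort(plan: FeaturePlan, seed: int = 0):
    """Generate (FeatureBlocks, covariate table, ground truth dict)."""
    rng = np.random.default_rng(seed)
    n = plan.n_subjects
    names = list(BLOCKS)
    p_k = {k: len(BLOCKS[k]) for k in names}
    r = plan.r_joint
    r_k = dict(zip(names, plan.r_indiv))
    w = np.asarray(plan.joint_weights[:r], dtype=float)
    w = w / w.sum() if r else w
    U = rng.standard_normal((n, r))
    truth_scores = {}
    X_blocks, joint_parts, indiv_parts = {}, {}, {}
    for k in names:
        fJ, fI, fR = plan.varexp[k]
        c = np.sqrt(fJ * w) if r else np.zeros(0)
        wi = np.asarray(plan.joint_weights[: r_k[k]], dtype=float)
        wi = wi / wi.sum() if r_k[k] else wi
        d = np.sqrt(fI * wi)
        W, V = _balanced_frames(rng, p_k[k], [c, d])
        Uk = rng.standard_normal((n, r_k[k]))
        J = (U * c) @ W.T
        A = (Uk * d) @ V.T
        # per-column noise variance tops every feature up to the same total,
        # so the block's columns are exchangeable in variance and the
        # pipeline's z-scoring leaves the energy split intact
        struct = (W * c) ** 2 @ np.ones(r) if r else np.zeros(p_k[k])
        struct = struct + ((V * d) ** 2 @ np.ones(r_k[k]) if r_k[k] else 0.0)
        sigma2 = np.maximum((struct.sum() + fR) / p_k[k] - struct, 0.0)
        if sigma2.sum() > 0 and fR > 0:
            sigma2 *= fR / sigma2.sum()
        sigma = plan.noise_scale * np.sqrt(sigma2)
        E = rng.standard_normal((n, p_k[k])) * sigma
        X_blocks[k] = J + A + E
        joint_parts[k], indiv_parts[k] = J, A
        for j in range(r_k[k]):
            truth_scores[f"{k}-{j + 1}"] = Uk[:, j]
    for j in range(r):
        truth_scores[f"Joint-{j + 1}"] = U[:, j]
    score_df = pd.DataFrame(truth_scores)
    score_df = (score_df - score_df.mean()) / score_df.std(ddof=1)
    eta = np.zeros(n)
    for col, logor in plan.outcome_logor.items():
        if col in score_df:
            eta += logor * score_df[col].to_numpy()
    alpha = _solve_intercept(eta, plan.lifetime_prevalence)
    p_life = 1.0 / (1.0 + np.exp(-(alpha + eta)))
    lifetime = rng.random(n) < p_life
    current = lifetime & (rng.random(n) < plan.current_given_lifetime)
    group = np.where(current, "current", np.where(lifetime, "remitted", "none"))
    subjects = [f"S{i:04d}" for i in range(n)]
    n_tot = sum(reference.GROUP_N.values())
    covariates = pd.DataFrame({
        "age": np.clip(rng.normal(61.79, 9.97, n), 35, 90),
        "sex": np.where(rng.random(n) < 0.5442, "female", "male"),
        "bmi": np.clip(rng.normal(26.35, 4.75, n), 15, 50),
        "group": group,
        "anxiety": rng.random(n) < sum(reference.ANXIETY_N.values()) / n_tot,
        "sud": rng.random(n) < sum(reference.SUD_N.values()) / n_tot,
        "medication": rng.random(n) < sum(reference.MEDICATION_N.values()) / n_tot,
    }, index=pd.Index(subjects, name="subject"))
    # map z-space columns onto the reference physical scale
    frames = []
    for k in names:
        cols = BLOCKS[k]
        Z = X_blocks[k]
        mu = np.array([reference.FEATURE_REFERENCE[c][0] for c in cols])
        sd = np.array([reference.FEATURE_REFERENCE[c][1] for c in cols])
        col_sd = Z.std(axis=0, ddof=1)
        col_sd[col_sd == 0] = 1.0
        frames.append(pd.DataFrame(
            mu + sd * (Z - Z.mean(axis=0)) / col_sd,
            index=subjects, columns=cols))
    features = pd.concat(frames, axis=1)
    features.index.name = "subject"
    score_df.index = pd.Index(subjects, name="subject")
    truth = {
        "scores": score_df,
        "joint_parts": joint_parts,
        "indiv_parts": indiv_parts,
        "z_blocks": X_blocks,
        "lifetime_prob": p_life,
        "intercept": alpha,
        "plan": asdict(plan),
        "seed": seed,
    }
    return FeatureBlocks(features), covariates, truth


# ------------------------------------------------------------------ epoch tier

@dataclass
class EpochPlan:
    """Plan for the epoch-tier generator (defaults emulate the reference
    cohort: ~2-week wear, onset ~23.5 h, SATP 0.07 / ASTP 0.25 wake
    dynamics, acrophase -3.65 rad)."""

    n_subjects: int = 200
    n_days: int = 14
    start: str = "2017-01-02 12:00"
    # sleep timing (hours on the 12-36 noon-to-noon axis)
    onset_mean: float = 23.5
    onset_sd: float = 1.0  # between subjects
    onset_night_sd: float = 0.3  # night-to-night jitter
    wakeup_mean: float = 31.25
    wakeup_sd: float = 0.9
    wakeup_night_sd: float = 0.3
    # wake-time two-state Markov dynamics (per-minute probabilities)
    p_sa: float = 0.07
    p_as: float = 0.25
    p_sa_sd: float = 0.015
    p_as_sd: float = 0.04
    # cosinor envelope population (count scale; acrophase in radians).
    # Amplitude is drawn as a ratio of the mesor so the relative amplitude
    # of the rest-activity rhythm stays in the realistic ~0.8 band.
    mesor_mean: float = 29.57
    mesor_sd: float = 9.48
    amp_ratio_mean: float = 0.83
    amp_ratio_sd: float = 0.06
    acro_mean: float = -3.65
    acro_sd: float = 0.32
    # nightly wake bouts
    bouts_per_night: float = 1.5
    bout_extra_mean: float = 3.0  # duration = 5 + Geometric minutes
    bout_count_mean: float = 30.0
    # count laws
    sed_low: float = 10.0
    sed_high_max: float = 30.0
    active_floor: float = 51.0
    active_shape: float = 2.0
    # occasional vigorous minutes (count ~ vigorous_mean) keep the MVPA
    # feature non-degenerate; drawn only where the active mean has headroom
    # and compensated in the regular active mean, so the envelope holds
    vigorous_prob: float = 0.04
    vigorous_mean: float = 1200.0
    vigorous_min_mu: float = 120.0
    sleep_base_mean: float = 2.0
    sleep_burst_enter: float = 0.055  # per-minute chance a movement run starts
    sleep_burst_exit: float = 0.5  # per-minute chance it ends
    theta_sed: float = 50.0  # the class boundary the laws respect
    # structural switches (used by tests; defaults are the full model)
    with_sleep: bool = True
    with_bouts: bool = True
    deterministic: bool = False  # counts equal the envelope exactly
    # planted low-wear days: first `dropout_subjects` subjects get
    # `dropout_days` days with < 16 h wear
    dropout_subjects: int = 0
    dropout_days: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_sa < 1 and 0 < self.p_as < 1):
            raise ValueError("transition probabilities must lie in (0, 1)")
        if self.n_days < 1:
            raise ValueError("need at least one day")


def _wake_means(lam_w: np.ndarray, pi_act: float, plan: "EpochPlan"):
    """Sedentary-mean and active-mean laws splitting the envelope at wake.

    Returns (mu_act, m_sed, floored): the active gamma mean, the sedentary
    uniform mean, and where the class floors bind (envelope unreachable)."""
    sed_full = 0.5 * (plan.sed_low + plan.sed_high_max)
    mu_act = (lam_w - (1 - pi_act) * sed_full) / pi_act
    floored = mu_act < plan.active_floor
    mu_act = np.maximum(mu_act, plan.active_floor)
    m_sed = np.where(
        floored,
        np.clip((lam_w - pi_act * plan.active_floor) / (1 - pi_act),
                plan.sed_low, sed_full),
        sed_full)
    return mu_act, m_sed, floored


def _cosinor_correction(lam_day, asleep_day, pi_act, plan, bout_excess,
                        t_hours):
    """Additive correction (1440 clock-minute array) to the expected wake
    count so the daily profile's cosinor projection equals the planted
    envelope exactly.

    Near the sleep edges the intensity-class floors (sedentary counts above
    the sleep threshold, active counts above the sedentary threshold) push
    the expected wake count above the envelope; left alone this biases the
    recovered acrophase late.  The excess is re-projected onto the cosinor
    basis and removed from the mid-day active mean, where the floors leave
    room, so the planted (Mesor, Amp, Acro) stay identifiable."""
    mu_act, m_sed, floored = _wake_means(lam_day[~asleep_day], pi_act, plan)
    E0 = lam_day + bout_excess
    wake_idx = np.flatnonzero(~asleep_day)
    E0[wake_idx] = (1 - pi_act) * m_sed + pi_act * mu_act
    excess = E0 - lam_day
    # only the two harmonic components matter for (Amp, Acro); the mean
    # level (Mesor) is left to float, which keeps the system well posed on
    # the midday-only support
    B = np.column_stack([np.cos(TWO_PI * t_hours / 24.0),
                         np.sin(TWO_PI * t_hours / 24.0)])
    adjustable = np.zeros(1440, dtype=bool)
    adjustable[wake_idx[~floored]] = True
    headroom = np.zeros(1440)
    headroom[wake_idx] = pi_act * (mu_act - plan.active_floor)
    target = -(B.T @ excess)
    # headroom-weighted projection: the correction is h(t) * (B theta), so
    # minutes close to the floor move little; |B theta| <= 1 keeps the
    # corrected active mean above the floor
    g = np.zeros(1440)
    for _ in range(6):
        if adjustable.sum() < 30:
            break
        h = np.where(adjustable, headroom, 0.0)
        Bw = B * h[:, None]
        try:
            theta = np.linalg.solve(B.T @ Bw, target)
        except np.linalg.LinAlgError:
            break
        scale = B @ theta
        if np.max(np.abs(scale[adjustable])) > 3.0:
            # full correction infeasible (deeply floored subject); apply the
            # best partial correction the floors allow
            g = h * np.clip(scale, -1.0, 3.0)
            break
        viol = adjustable & (scale < -1.0)
        if not viol.any():
            g = h * scale
            break
        g = h * np.clip(scale, -1.0, 3.0)
        adjustable &= ~viol
    return g


def _markov_states(rng, length: int, p_sa: float, p_as: float) -> np.ndarray:
    """Two-state chain (False=sedentary, True=active) via geometric run
    lengths, started from the stationary law."""
    if length <= 0:
        return np.zeros(0, dtype=bool)
    pi_act = p_sa / (p_sa + p_as)
    state = bool(rng.random() < pi_act)
    out = np.empty(length, dtype=bool)
    pos = 0
    while pos < length:
        run = int(rng.geometric(p_as if state else p_sa))
        stop = min(pos + run, length)
        out[pos:stop] = state
        pos = stop
        state = not state
    return out


def generate_epoch_cohort(plan: EpochPlan, seed: int = 0):
    """Generate (list of EpochSeries, per-night annotation table, ground truth)."""
    rng = np.random.default_rng(seed)
    n, nd = plan.n_subjects, plan.n_days
    total = nd * MINUTES_PER_DAY
    start = pd.Timestamp(plan.start)
    # per-subject planted parameters
    onset_i = rng.normal(plan.onset_mean, plan.onset_sd, n)
    wake_i = rng.normal(plan.wakeup_mean, plan.wakeup_sd, n)
    wake_i = np.maximum(wake_i, onset_i + 4.0)
    p_sa_i = np.clip(rng.normal(plan.p_sa, plan.p_sa_sd, n), 0.01, 0.5)
    p_as_i = np.clip(rng.normal(plan.p_as, plan.p_as_sd, n), 0.05, 0.8)
    mesor_i = np.clip(rng.normal(plan.mesor_mean, plan.mesor_sd, n), 5.0, None)
    amp_i = mesor_i * np.clip(
        rng.normal(plan.amp_ratio_mean, plan.amp_ratio_sd, n), 0.2, 0.98)
    acro_i = rng.normal(plan.acro_mean, plan.acro_sd, n)
    tpeak_i = -acro_i * 24.0 / TWO_PI
    start_clock = start.hour + start.minute / 60.0
    hours = start_clock + np.arange(total) / 60.0  # continuous; cos is periodic
    series_list: list[EpochSeries] = []
    ann_rows = []
    night_truth = []
    for i in range(n):
        sid = f"S{i:04d}"
        lam = mesor_i[i] + amp_i[i] * np.cos(TWO_PI * (hours - tpeak_i[i]) / 24.0)
        lam = np.clip(lam, 0.5, None)
        if plan.deterministic:
            counts = lam.copy()
            wear = np.ones(total, dtype=bool)
            series_list.append(EpochSeries(sid, start, counts, wear))
            continue
        asleep = np.zeros(total, dtype=bool)
        bout = np.zeros(total, dtype=bool)
        if plan.with_sleep:
            for d in range(nd):
                o_h = np.clip(onset_i[i] + rng.normal(0, plan.onset_night_sd),
                              12.5, 33.0)
                w_h = np.clip(wake_i[i] + rng.normal(0, plan.wakeup_night_sd),
                              o_h + 3.0, 35.5)
                o_idx = d * MINUTES_PER_DAY + int(round((o_h - 12.0) * 60))
                w_idx = d * MINUTES_PER_DAY + int(round((w_h - 12.0) * 60))
                w_idx = min(w_idx, total)
                asleep[o_idx:w_idx] = True
                if plan.with_bouts:
                    for _ in range(rng.poisson(plan.bouts_per_night)):
                        dur = 5 + int(rng.geometric(1.0 / (1.0 + plan.bout_extra_mean))) - 1
                        lo, hi = o_idx + 15, w_idx - dur - 15
                        if hi > lo:
                            s0 = int(rng.integers(lo, hi))
                            bout[s0:s0 + dur] = True
                ann_rows.append({
                    "subject": sid,
                    "date": (start + pd.Timedelta(days=d)).date().isoformat(),
                    "onset_hhmm": f"{int(o_h % 24):02d}:{int(round((o_h % 1) * 60)) % 60:02d}",
                    "wakeup_hhmm": f"{int(w_h % 24):02d}:{int(round((w_h % 1) * 60)) % 60:02d}",
                })
                night_truth.append({"subject": sid, "day": d,
                                    "onset": o_h, "wakeup": w_h})
        sleeping = asleep & ~bout
        wake = ~asleep
        counts = np.empty(total)
        # sleep minutes: near-still baseline plus clustered movement bursts
        # (two-state run process); the stationary mean equals the envelope
        idx_s = np.flatnonzero(sleeping)
        if idx_s.size:
            q = plan.sleep_burst_enter / (plan.sleep_burst_enter
                                          + plan.sleep_burst_exit)
            lam_s = lam[idx_s]
            burst = _markov_states(rng, idx_s.size, plan.sleep_burst_enter,
                                   plan.sleep_burst_exit)
            burst_mean = np.clip((lam_s - (1 - q) * plan.sleep_base_mean) / q,
                                 0.1, None)
            mean_s = np.where(burst, burst_mean, plan.sleep_base_mean)
            counts[idx_s] = rng.exponential(mean_s)
        # wake bouts inside the sleep period
        idx_b = np.flatnonzero(bout)
        if idx_b.size:
            counts[idx_b] = rng.gamma(3.0, plan.bout_count_mean / 3.0, idx_b.size)
        # wake minutes: Markov sedentary/active split of the envelope, with
        # a cosinor-orthogonalizing correction of the active mean so the
        # planted (Mesor, Amp, Acro) stay identifiable despite class floors
        idx_w = np.flatnonzero(wake)
        if idx_w.size:
            pi_act = p_sa_i[i] / (p_sa_i[i] + p_as_i[i])
            canonical_asleep = np.zeros(MINUTES_PER_DAY, dtype=bool)
            o_c = int(round((np.clip(onset_i[i], 12.5, 33.0) - 12.0) * 60))
            w_c = int(round((np.clip(wake_i[i], 15.5, 35.5) - 12.0) * 60))
            canonical_asleep[o_c:w_c] = True
            lam_canon = lam[:MINUTES_PER_DAY]  # first day starts at noon
            bout_excess = np.zeros(MINUTES_PER_DAY)
            if plan.with_bouts and w_c > o_c:
                rate = plan.bouts_per_night * (5.0 + plan.bout_extra_mean) \
                    / (w_c - o_c)
                bout_excess[o_c:w_c] = rate * (plan.bout_count_mean
                                               - lam_canon[o_c:w_c])
            g = _cosinor_correction(lam_canon, canonical_asleep, pi_act,
                                    plan, bout_excess,
                                    hours[:MINUTES_PER_DAY])
            segments = np.split(idx_w, np.flatnonzero(np.diff(idx_w) > 1) + 1)
            active = np.concatenate([
                _markov_states(rng, seg.size, p_sa_i[i], p_as_i[i])
                for seg in segments])
            lam_w = lam[idx_w]
            mu_act, m_s, _ = _wake_means(lam_w, pi_act, plan)
            mu_act = np.maximum(
                mu_act + g[idx_w % MINUTES_PER_DAY] / pi_act,
                plan.active_floor)
            sed_high = 2.0 * m_s - plan.sed_low
            i_sed = idx_w[~active]
            counts[i_sed] = rng.uniform(plan.sed_low, sed_high[~active])
            i_act = idx_w[active]
            mu_a = mu_act[active]
            vig = (mu_a >= plan.vigorous_min_mu) \
                & (rng.random(i_act.size) < plan.vigorous_prob)
            mu_reg = np.where(
                mu_a >= plan.vigorous_min_mu,
                np.maximum((mu_a - plan.vigorous_prob * plan.vigorous_mean)
                           / (1.0 - plan.vigorous_prob), plan.active_floor),
                mu_a)
            shape = plan.active_shape
            scale = (mu_reg - (plan.active_floor - 1.0)) / shape
            act_counts = (plan.active_floor - 1.0) + rng.gamma(
                shape, np.maximum(scale, 1e-6))
            act_counts[vig] = rng.gamma(3.0, plan.vigorous_mean / 3.0,
                                        int(vig.sum()))
            counts[i_act] = act_counts
        wear = np.ones(total, dtype=bool)
        if i < plan.dropout_subjects and plan.dropout_days > 0:
            for d in range(nd - plan.dropout_days, nd):
                lo = d * MINUTES_PER_DAY + 60
                wear[lo:lo + 560] = False
                counts[lo:lo + 560] = 0.0
        series_list.append(EpochSeries(sid, start, counts, wear))
    annotations = pd.DataFrame(ann_rows)
    truth = {
        "subjects": [s.subject_id for s in series_list],
        "onset": onset_i, "wakeup": wake_i,
        "p_sa": p_sa_i, "p_as": p_as_i,
        "mesor": mesor_i, "amp": amp_i, "acro": acro_i,
        "nights": pd.DataFrame(night_truth) if night_truth else pd.DataFrame(),
        "plan": asdict(plan),
        "seed": seed,
        "planned_valid_days": {
            s.subject_id: (nd - plan.dropout_days if i < plan.dropout_subjects
                           else nd)
            for i, s in enumerate(series_list)},
    }
    return series_list, annotations, truth
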