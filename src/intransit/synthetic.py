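"""Synthetic three-group cohorts with the statistical structure of a
clinical choice-consistency study.

The generator emulates a cohort of medial-temporal-lobe epilepsy patients
(MTL, n = 31), extratemporal-lobe epilepsy patients (ETL, n = 30) and
healthy controls (CON, n = 30), each completing two complete-pairwise
two-alternative forced-choice sessions over 20 items (190 trials each):

* a *preference* task, simulated with the random-utility noise model — each
  subject draws a noise fraction α from a truncated normal around their
  group's level, with a slow mean-reverting drift in item utilities across
  the session (which makes widely-spaced triples more likely to be
  inconsistent, the signature of preference instability over time);
* a *number* comparison task where the larger item code is objectively
  correct, and responses lapse independently with a per-subject rate drawn
  from a Gamma distribution around the group rate.  Under i.i.d. lapses λ,
  the per-triple cycle probability is exactly λ(1−λ), which is how group
  rates are inverted analytically from target intransitivity percentages.

Response times are lognormal with an involvement-linked slowdown (trials
participating in intransitive triples are slower) and a subject-level MTL
shift.  A random subset of MTL subjects carries left/right hippocampal
volumes constructed so the lateral damage index is a noisy monotone
(scaled-logistic) function of the subject's true α.

Default group parameters are calibrated so the generated preference-task
group means *and standard deviations* match the study regime the package
targets (means ≈ 2.75 / 3.37 / 6.07%, SDs ≈ 1.41 / 2.16 / 5.02% for
CON / ETL / MTL; control-task means 0.14 / 1.00 / 0.50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import expit, ndtr

from .choice_data import ChoiceDataset
from .rum import REFERENCE_UTILITY_SCALE
from .transitivity import enumerate_pairs, triplet_table

__all__ = [
    "GroupParams",
    "CohortSpec",
    "Cohort",
    "lapse_for_control_pct",
    "generate_cohort",
    "generate_null_cohort",
    "null_spec",
    "calibrate_alpha_params",
]


def lapse_for_control_pct(pct: float) -> float:
    """Invert the closed-form λ(1−λ) cycle rate for the number task.

    A triple of objectively ordered comparisons becomes cyclic iff exactly
    one of two specific flip patterns occurs, with total probability
    λ(1−λ); solving for the smaller root gives the lapse rate producing a
    target intransitivity percentage.
    """
    p = pct / 100.0
    if not 0 <= p <= 0.25:
        raise ValueError(f"control intransitivity must be in [0%, 25%], got {pct}")
    return 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * p))


@dataclass(frozen=True)
class GroupParams:
    """Per-group behavioral parameters.

    ``alpha`` and ``alpha_sd`` define the truncated-normal distribution of
    subject noise fractions; ``lapse`` is the mean control-task lapse rate
    and ``lapse_shape`` the Gamma shape of its between-subject distribution
    (smaller shape → heavier tail; ``inf`` → identical lapse for everyone).
    """

    alpha: float
    alpha_sd: float
    lapse: float
    lapse_shape: float

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.alpha_sd < 0 or not 0 <= self.lapse <= 0.5:
            raise ValueError("alpha_sd must be >= 0 and lapse in [0, 0.5]")


# Calibrated against the target regime: preference-task mean (SD) percentages
# 2.75 (1.41) / 3.37 (2.16) / 6.07 (5.02) and control-task means
# 0.14 / 1.00 / 0.50 with SDs 0.20 / 2.54 / 0.53 for CON / ETL / MTL.
_DEFAULT_GROUPS = {
    "CON": GroupParams(alpha=0.240, alpha_sd=0.146, lapse=lapse_for_control_pct(0.14),
                       lapse_shape=0.7),
    "ETL": GroupParams(alpha=0.295, alpha_sd=0.169, lapse=lapse_for_control_pct(1.00),
                       lapse_shape=0.16),
    "MTL": GroupParams(alpha=0.442, alpha_sd=0.234, lapse=lapse_for_control_pct(0.50),
                       lapse_shape=1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Full configuration of a synthetic cohort.

    Utility drift is a stationary mean-reverting (AR(1)) perturbation of
    each item's utility across trial slots, with stationary SD ``drift_sd``
    (utility units) and autocorrelation time ``drift_timescale`` (trials);
    choices far apart in the session see decorrelated utilities, which is
    the generative source of the spacing (trial-index-variance) effect.  RT
    parameters are on the log-seconds scale.  The lesion link maps a
    subject's true α to an expected lateral damage index through a scaled
    logistic centered at ``ldi_midpoint``.
    """

    n_con: int = 30
    n_etl: int = 30
    n_mtl: int = 31
    n_items: int = 20
    u_scale: float = REFERENCE_UTILITY_SCALE
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )
    shuffle_item_assignment: bool = True
    trait_coupling: float = 0.6  # Gaussian-copula correlation between a
    # subject's preference-noise and lapse-rate quantiles (a general
    # "consistency" trait shared across tasks); marginals are unchanged
    drift_sd: float = 1.2  # stationary SD of the AR(1) utility drift
    drift_timescale: float = 60.0  # AR(1) time constant, in trials
    rt_log_mean: float = float(np.log(1.5))  # median 1.5 s
    rt_log_sd: float = 0.4
    rt_involvement_slowdown: float = 0.15  # log-units added to involved trials
    rt_mtl_shift: float = 0.2  # log-units added to every MTL subject
    ldi_scale: float = 0.8
    ldi_steepness: float = 6.0
    ldi_midpoint: float = 0.45  # ≈ mean subject α of the default MTL group
    ldi_noise_sd: float = 0.12
    n_lesion: int = 16
    total_volume_mean: float = 6.0  # arbitrary consistent unit; only the
    total_volume_sd: float = 0.5   # left/right ratio matters downstream
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_con, self.n_etl, self.n_mtl) < 1:
            raise ValueError("group sizes must be >= 1")
        if set(self.groups) != {"CON", "ETL", "MTL"}:
            raise ValueError("groups must be exactly CON, ETL, MTL")
        if self.n_lesion > self.n_mtl:
            raise ValueError("n_lesion cannot exceed n_mtl")
        if self.rt_log_sd <= 0 or self.drift_sd < 0:
            raise ValueError("rt_log_sd must be > 0 and drift_sd >= 0")


@dataclass
class Cohort:
    """A generated cohort: trials, subject table and MTL lesion records."""

    dataset: ChoiceDataset
    subjects: pd.DataFrame  # subject_id, group, alpha, lapse
    lesions: pd.DataFrame  # subject_id, vol_left, vol_right, ldi, side
    spec: CohortSpec


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def _truncnorm_ppf(q: float, center: float, sd: float) -> float:
    """Quantile of the normal(center, sd) truncated to [0, 1]."""
    if sd == 0:
        return center
    a, b = (0.0 - center) / sd, (1.0 - center) / sd
    return float(scipy.stats.truncnorm.ppf(q, a, b, loc=center, scale=sd))


def _subject_traits(
    rng: np.random.Generator, params: GroupParams, coupling: float
) -> tuple[float, float]:
    """Draw (alpha, lapse) for one subject via a Gaussian copula.

    ``coupling`` correlates the quantiles of the two marginals — a general
    consistency trait shared across tasks — without changing either
    marginal distribution.
    """
    z0, z1 = rng.standard_normal(2)
    q_alpha = ndtr(z0)
    q_lapse = ndtr(coupling * z0 + np.sqrt(1.0 - coupling**2) * z1)
    alpha = _truncnorm_ppf(q_alpha, params.alpha, params.alpha_sd)
    if np.isinf(params.lapse_shape) or params.lapse == 0:
        lapse = params.lapse
    else:
        lapse = float(
            min(
                scipy.stats.gamma.ppf(
                    q_lapse,
                    params.lapse_shape,
                    scale=params.lapse / params.lapse_shape,
                ),
                0.5,
            )
        )
    return alpha, lapse


def _drift_paths(
    rng: np.random.Generator, n_steps: int, n_items: int, sd: float, timescale: float
) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein-Uhlenbeck) drift per item.

    Each item's utility perturbation has stationary standard deviation
    ``sd`` and autocorrelation exp(−lag/timescale); perturbations of trials
    far apart in the session are nearly independent, those of adjacent
    trials nearly identical.
    """
    phi = float(np.exp(-1.0 / timescale))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = rng.standard_normal((n_steps, n_items))
    x = np.empty((n_steps, n_items))
    x[0] = sd * e[0]
    for t in range(1, n_steps):
        x[t] = phi * x[t - 1] + innov_sd * e[t]
    return x


def _preference_wins(
    rng: np.random.Generator,
    u: np.ndarray,
    alpha: float,
    drift_sd: float,
    drift_timescale: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one preference session; returns (pair order, first-item wins).

    ``pair_slots[t]`` is the 0-based item pair presented at trial t; wins are
    drawn from the logistic noise model on drift-perturbed utilities.
    """
    pairs = np.asarray(enumerate_pairs(len(u)), dtype=np.intp) - 1
    n_pairs = len(pairs)
    perm = rng.permutation(n_pairs)
    pair_slots = pairs[perm]
    u_a = u[pair_slots[:, 0]].astype(float)
    u_b = u[pair_slots[:, 1]].astype(float)
    if drift_sd > 0:
        x = _drift_paths(rng, n_pairs, len(u), drift_sd, drift_timescale)
        t = np.arange(n_pairs)
        u_a = u_a + x[t, pair_slots[:, 0]]
        u_b = u_b + x[t, pair_slots[:, 1]]
    eps = rng.standard_normal((n_pairs, 2))
    delta = (1.0 - alpha) * (u_a - u_b) + alpha * (eps[:, 0] - eps[:, 1])
    win_first = rng.random(n_pairs) < expit(delta)
    return pair_slots, win_first


def _number_task(
    rng: np.random.Generator, n_items: int, lapse: float
) -> tuple[np.ndarray, np.ndarray]:
    """Number-comparison session: larger code correct, i.i.d. lapses."""
    pairs = np.asarray(enumerate_pairs(n_items), dtype=np.intp) - 1
    n_pairs = len(pairs)
    perm = rng.permutation(n_pairs)
    pair_slots = pairs[perm]
    flipped = rng.random(n_pairs) < lapse
    win_first = flipped  # correct answer is the larger (second) item
    return pair_slots, win_first


def _session_frame(
    subject_id: str,
    group: str,
    task: str,
    pair_slots: np.ndarray,
    win_first: np.ndarray,
) -> pd.DataFrame:
    chosen = np.where(win_first, pair_slots[:, 0], pair_slots[:, 1]) + 1
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "task": task,
            "trial_index": np.arange(1, len(pair_slots) + 1, dtype=np.int64),
            "item_a": pair_slots[:, 0] + 1,
            "item_b": pair_slots[:, 1] + 1,
            "choice": chosen.astype(float),
            "rt": np.nan,
        }
    )


def _attach_rts(cohort_trials: pd.DataFrame, spec: CohortSpec, ds: ChoiceDataset,
                subjects: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw lognormal RTs with involvement-linked slowdown per subject×task."""
    trips = triplet_table(ds)
    cyc = trips[trips["is_intransitive"]]
    involved_keys: set[tuple[str, str, int]] = set()
    for col in ("t_ij", "t_jk", "t_ik"):
        involved_keys.update(
            zip(cyc["subject_id"], cyc["task"], cyc[col].astype(int))
        )
    rng = _rng(seed, 901)
    mu_map = {
        row.subject_id: spec.rt_log_mean
        + (spec.rt_mtl_shift if row.group == "MTL" else 0.0)
        for row in subjects.itertuples()
    }
    mu = cohort_trials["subject_id"].map(mu_map).to_numpy()
    involved = np.fromiter(
        (
            (s, t, int(ti)) in involved_keys
            for s, t, ti in zip(
                cohort_trials["subject_id"],
                cohort_trials["task"],
                cohort_trials["trial_index"],
            )
        ),
        dtype=bool,
        count=len(cohort_trials),
    )
    z = rng.standard_normal(len(cohort_trials))
    out = cohort_trials.copy()
    out["rt"] = np.exp(
        mu + spec.rt_involvement_slowdown * involved + spec.rt_log_sd * z
    )
    return out


def _lesion_table(
    spec: CohortSpec, subjects: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Volumes for a random MTL subset; LDI is a noisy logistic of true α."""
    rng = _rng(seed, 902)
    mtl = subjects[subjects["group"] == "MTL"]
    chosen = rng.choice(mtl["subject_id"].to_numpy(), size=spec.n_lesion, replace=False)
    rows = []
    for sid in sorted(chosen):
        alpha = float(mtl.loc[mtl["subject_id"] == sid, "alpha"].iloc[0])
        ldi_mean = spec.ldi_scale * expit(
            spec.ldi_steepness * (alpha - spec.ldi_midpoint)
        )
        ldi = float(np.clip(ldi_mean + rng.normal(0.0, spec.ldi_noise_sd), 0.0, 0.999))
        total = max(rng.normal(spec.total_volume_mean, spec.total_volume_sd), 0.5)
        side = rng.choice(["left", "right"])  # which side is atrophied
        small, large = total * (1 - ldi) / 2, total * (1 + ldi) / 2
        vol_left, vol_right = (small, large) if side == "left" else (large, small)
        rows.append(
            {
                "subject_id": sid,
                "vol_left": vol_left,
                "vol_right": vol_right,
                "ldi": ldi,
                "side": side,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> Cohort:
    """Generate a complete synthetic cohort (both tasks, RTs, lesion subset).

    Every subject×task is pair-complete; the output always passes
    :func:`intransit.choice_data.validate_design`.  Identical ``(spec, seed)``
    give bitwise-identical cohorts.
    """
    spec = spec or CohortSpec()
    master = spec.seed if seed is None else seed
    u_base = np.linspace(0.0, spec.u_scale, spec.n_items)

    frames: list[pd.DataFrame] = []
    subject_rows = []
    sizes = {"CON": spec.n_con, "ETL": spec.n_etl, "MTL": spec.n_mtl}
    for g_idx, group in enumerate(("CON", "ETL", "MTL")):
        params = spec.groups[group]
        for s_idx in range(sizes[group]):
            sid = f"{group}{s_idx + 1:02d}"
            rng = _rng(master, g_idx, s_idx)
            alpha, lapse = _subject_traits(rng, params, spec.trait_coupling)
            u = u_base[rng.permutation(spec.n_items)] if spec.shuffle_item_assignment else u_base
            slots, wins = _preference_wins(rng, u, alpha, spec.drift_sd,
                                           spec.drift_timescale)
            frames.append(_session_frame(sid, group, "preference", slots, wins))
            slots, wins = _number_task(rng, spec.n_items, lapse)
            frames.append(_session_frame(sid, group, "number", slots, wins))
            subject_rows.append(
                {"subject_id": sid, "group": group, "alpha": alpha, "lapse": lapse}
            )
    trials = pd.concat(frames, ignore_index=True)
    subjects = pd.DataFrame(subject_rows)
    ds = ChoiceDataset(trials=trials, n_items=spec.n_items)
    ds.trials = _attach_rts(ds.trials, spec, ds, subjects, master)
    lesions = _lesion_table(spec, subjects, master)
    return Cohort(dataset=ds, subjects=subjects, lesions=lesions, spec=spec)


def null_spec(base: CohortSpec | None = None, alpha: float = 0.3,
              alpha_sd: float = 0.05, lapse: float = 0.005) -> CohortSpec:
    """A group-exchangeable spec: identical behavioral parameters everywhere.

    Also switches off the utility drift and the MTL response-time shift, so
    group contrasts, spacing effects and item effects are all null by
    construction (item assignment shuffling keeps items exchangeable).
    """
    base = base or CohortSpec()
    shared = GroupParams(alpha=alpha, alpha_sd=alpha_sd, lapse=lapse,
                         lapse_shape=float("inf"))
    return replace(
        base,
        groups={g: shared for g in ("CON", "ETL", "MTL")},
        drift_sd=0.0,
        rt_mtl_shift=0.0,
        shuffle_item_assignment=True,
    )


def generate_null_cohort(
    spec: CohortSpec | None = None, seed: int | None = None
) -> Cohort:
    """Generate a cohort with no group, spacing or item effects."""
    return generate_cohort(null_spec(spec), seed=seed)


def calibrate_alpha_params(
    target_mean: float,
    target_sd: float,
    spec: CohortSpec | None = None,
    n_subjects: int = 400,
    n_iter: int = 12,
    seed: int = 0,
) -> GroupParams:
    """Find (alpha, alpha_sd) whose simulated cohort matches a target
    mean and SD of preference-task intransitivity percentage.

    Iterative moment matching under the full subject model (drift, item
    shuffling, truncation): at each step, ``n_subjects`` subjects are
    simulated and the center/spread are nudged proportionally to the
    mismatch.  Used once to fix the shipped defaults; exposed so users can
    recalibrate after changing the utility or drift configuration.
    """
    from .transitivity import count_cycles_from_wins

    spec = spec or CohortSpec()
    u_base = np.linspace(0.0, spec.u_scale, spec.n_items)
    n = spec.n_items
    total = n * (n - 1) * (n - 2) // 6

    def cohort_moments(center: float, sd: float, it: int) -> tuple[float, float]:
        pcts = np.empty(n_subjects)
        for i in range(n_subjects):
            rng = _rng(seed, it, i)
            a = _truncnorm_ppf(rng.random(), center, sd)
            u = u_base[rng.permutation(n)] if spec.shuffle_item_assignment else u_base
            slots, wins = _preference_wins(rng, u, a, spec.drift_sd,
                                           spec.drift_timescale)
            # slots are a shuffled view of the canonical pair list; restore
            # canonical order before the degree-identity count
            order = np.lexsort((slots[:, 1], slots[:, 0]))
            pcts[i] = 100.0 * count_cycles_from_wins(wins[order], n) / total
        return float(pcts.mean()), float(pcts.std(ddof=1))

    center, sd = 0.3, 0.15
    for it in range(n_iter):
        m, s = cohort_moments(center, sd, it)
        center = float(np.clip(center + 0.012 * (target_mean - m), 0.0, 1.0))
        sd = float(np.clip(sd * (target_sd / max(s, 1e-9)) ** 0.5, 0.0, 0.6))
    return GroupParams(alpha=center, alpha_sd=sd, lapse=0.0, lapse_shape=np.inf)
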