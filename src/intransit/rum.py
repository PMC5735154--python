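"""Random-utility choice simulator with a tunable noise fraction.

The model: in a choice between A and B, each option's effective utility is a
convex combination of its deterministic utility and a fresh random error,
(1−α)·u + α·ε, and the probability of choosing A is a logistic function of
the effective-utility difference:

    p(A) = 1 / (1 + exp[((1−α)u(B) + α·ε_B) − ((1−α)u(A) + α·ε_A)])

α ∈ [0, 1] is the noise fraction — the proportion of the effective utility
attributable to random error.  At α = 0 choices follow the deterministic
utilities (up to the logistic response); at α = 1 each pairwise choice is an
independent fair coin, and the expected proportion of intransitive triples is
exactly 25%.

Two stochastic stages per trial, by construction: the errors ε_A, ε_B are
realized first, then the binary choice is drawn from the resulting logistic
probability.  ε is drawn independently per option per trial; a shared-ε
variant (in which the error cancels algebraically and only attenuates the
utilities) is available behind ``shared_epsilon=True`` for documentation
purposes.

:func:`sweep_alpha` maps a grid of α values to mean intransitivity
percentages by Monte-Carlo simulation, and :func:`invert_alpha` inverts an
observed percentage back to an α estimate through the monotone (isotonic)
fit of that curve.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.special import expit

from .choice_data import ChoiceDataset
from .transitivity import count_cycles_from_wins, enumerate_pairs

__all__ = [
    "REFERENCE_UTILITY_SCALE",
    "SimulationConfig",
    "SweepResult",
    "AlphaEstimate",
    "reference_utilities",
    "choice_probability",
    "simulate_subject",
    "simulate_pct",
    "sweep_alpha",
    "invert_alpha",
]

#: Spread of the reference evenly-spaced utilities (logit units between the
#: extreme items).  Calibrated once so that, with standard-normal errors, the
#: α ↔ intransitivity curve spans ~1% at α = 0 to 25% at α = 1 with the
#: single-digit percentages clinical cohorts produce lying on its steep
#: lower branch, where inversion is well conditioned.  See docs/methods.md.
REFERENCE_UTILITY_SCALE = 16.0

_ERROR_FAMILIES = ("normal", "logistic", "uniform")


def reference_utilities(n_items: int = 20, scale: float = REFERENCE_UTILITY_SCALE) -> np.ndarray:
    """Evenly spaced utilities on [0, scale] for ``n_items`` items."""
    return np.linspace(0.0, scale, n_items)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated subject's choice process.

    ``error_spec`` is the zero-mean error family ("normal", "logistic" or
    "uniform") with ``error_scale`` its standard deviation.
    """

    n_items: int = 20
    utilities: tuple[float, ...] | None = None  # None → reference configuration
    alpha: float = 0.0
    error_spec: str = "normal"
    error_scale: float = 1.0
    shared_epsilon: bool = False
    seed: int = 0
    n_replicates: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_items < 2:
            raise ValueError("need at least two items")
        if self.error_spec not in _ERROR_FAMILIES:
            raise ValueError(
                f"error_spec must be one of {_ERROR_FAMILIES}, got {self.error_spec!r}"
            )
        if self.utilities is not None:
            u = np.asarray(self.utilities, dtype=float)
            if len(u) != self.n_items:
                raise ValueError("utilities length must equal n_items")
            if not np.all(np.isfinite(u)):
                raise ValueError("utilities must be finite")

    def utility_vector(self) -> np.ndarray:
        if self.utilities is None:
            return reference_utilities(self.n_items)
        return np.asarray(self.utilities, dtype=float)

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "utilities": None if self.utilities is None
            else [float(u) for u in self.utilities],
            "alpha": self.alpha,
            "error_spec": self.error_spec,
            "error_scale": self.error_scale,
            "shared_epsilon": self.shared_epsilon,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class SweepResult:
    """Mean ± SE intransitivity percentage over a grid of noise fractions."""

    alpha_grid: np.ndarray
    mean_pct: np.ndarray
    se_pct: np.ndarray
    n_replicates: int
    config: SimulationConfig

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("alpha grid is empty")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("alpha grid must be strictly increasing")
        if grid.min() < 0 or grid.max() > 1:
            raise ValueError("alpha grid must lie within [0, 1]")

    def isotonic_mean(self) -> np.ndarray:
        """Non-decreasing (isotonic) fit of the mean curve over the grid."""
        return isotonic_regression(self.mean_pct).x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha_grid,
                "mean_pct": self.mean_pct,
                "se_pct": self.se_pct,
                "n_replicates": self.n_replicates,
            }
        )


@dataclass(frozen=True)
class AlphaEstimate:
    """Inverted noise fraction with an SE-propagated uncertainty interval."""

    alpha: float
    lo: float
    hi: float
    flag: str = ""  # "" | "below_curve"


def _draw_errors(rng: np.random.Generator, spec: str, scale: float, size) -> np.ndarray:
    """Zero-mean error draws with standard deviation ``scale``."""
    if spec == "normal":
        return rng.normal(0.0, scale, size)
    if spec == "logistic":
        # logistic sd = s·π/√3
        return rng.logistic(0.0, scale * np.sqrt(3.0) / np.pi, size)
    if spec == "uniform":
        return rng.uniform(-scale * np.sqrt(3.0), scale * np.sqrt(3.0), size)
    raise ValueError(f"unknown error family {spec!r}")


def choice_probability(
    u_a: float,
    u_b: float,
    alpha: float,
    eps_a: float,
    eps_b: float,
    shared_epsilon: bool = False,
) -> float:
    """Probability of choosing A given realized utilities and errors.

    Computed as expit(((1−α)u_A + α·ε_A) − ((1−α)u_B + α·ε_B)); numerically
    stable for arbitrarily large exponents.  With ``shared_epsilon`` the same
    error enters both options and cancels, leaving expit((1−α)(u_A − u_B)).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if shared_epsilon:
        eps_b = eps_a
    delta = (1.0 - alpha) * (np.asarray(u_a) - np.asarray(u_b)) + alpha * (
        np.asarray(eps_a) - np.asarray(eps_b)
    )
    return expit(delta)


def _subject_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic sub-stream keyed by integers, independent of call order.

    Keys enter the seed sequence entropy directly, so adding grid points or
    replicates never perturbs the streams of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def _simulate_wins(
    rng: np.random.Generator, u: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """Simulate all pairwise outcomes once; True where the smaller item won."""
    pairs = np.array(enumerate_pairs(len(u)), dtype=np.intp) - 1
    n_pairs = len(pairs)
    eps = _draw_errors(rng, cfg.error_spec, cfg.error_scale, (n_pairs, 2))
    if cfg.shared_epsilon:
        eps[:, 1] = eps[:, 0]
    p_first = choice_probability(
        u[pairs[:, 0]], u[pairs[:, 1]], cfg.alpha, eps[:, 0], eps[:, 1]
    )
    return rng.random(n_pairs) < p_first


def simulate_pct(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    """One simulated subject's intransitivity percentage (fast path)."""
    u = cfg.utility_vector()
    wins = _simulate_wins(rng, u, cfg)
    n = cfg.n_items
    total = n * (n - 1) * (n - 2) // 6
    return 100.0 * count_cycles_from_wins(wins, n) / total


def simulate_subject(
    cfg: SimulationConfig, subject_id: str = "sim", seed: int | None = None
) -> ChoiceDataset:
    """Simulate one subject's complete pairwise session as a dataset.

    Every unordered pair is presented exactly once; the trial order is a
    seeded random permutation.  Fully reproducible given (seed, subject_id).
    """
    master = cfg.seed if seed is None else seed
    sid_key = int.from_bytes(hashlib.sha256(subject_id.encode()).digest()[:4], "big")
    rng = _subject_rng(master, sid_key)
    u = cfg.utility_vector()
    wins = _simulate_wins(rng, u, cfg)
    pairs = np.array(enumerate_pairs(cfg.n_items), dtype=np.int64)
    choice = np.where(wins, pairs[:, 0], pairs[:, 1]).astype(float)
    order = rng.permutation(len(pairs))
    trials = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": "SIM",
            "task": "preference",
            "trial_index": np.empty(len(pairs), dtype=np.int64),
            "item_a": pairs[:, 0],
            "item_b": pairs[:, 1],
            "choice": choice,
            "rt": np.nan,
        }
    )
    trials.loc[order, "trial_index"] = np.arange(1, len(pairs) + 1)
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    return ChoiceDataset(trials=trials, n_items=cfg.n_items)


def sweep_alpha(
    cfg_base: SimulationConfig,
    alpha_grid,
    n_replicates: int,
    simulate_fn: Callable[[SimulationConfig, np.random.Generator], float] | None = None,
) -> SweepResult:
    """Monte-Carlo sweep of mean intransitivity percentage over an α grid.

    Per grid point, ``n_replicates`` independent subjects are simulated and
    scored; sub-streams are keyed by (seed, α in fixed-point, replicate), so
    results at one grid point are unaffected by the rest of the grid.
    ``simulate_fn`` defaults to the reference subject simulator and may be
    replaced (e.g. by a cohort generator's subject model) for calibration.
    """
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    sim = simulate_fn or simulate_pct
    means = np.empty(grid.size)
    ses = np.empty(grid.size)
    for gi, alpha in enumerate(grid):
        cfg = replace(cfg_base, alpha=float(alpha), n_replicates=n_replicates)
        alpha_key = int(round(alpha * 10**9))
        pcts = np.array(
            [
                sim(cfg, _subject_rng(cfg_base.seed, alpha_key, rep))
                for rep in range(n_replicates)
            ]
        )
        means[gi] = pcts.mean()
        ses[gi] = pcts.std(ddof=1) / np.sqrt(n_replicates)
    return SweepResult(
        alpha_grid=grid,
        mean_pct=means,
        se_pct=ses,
        n_replicates=n_replicates,
        config=replace(cfg_base, n_replicates=n_replicates),
    )


def _invert_on_curve(observed: float, curve: np.ndarray, grid: np.ndarray) -> float:
    """Interpolate α at ``observed`` on a non-decreasing curve."""
    keep = np.concatenate([[True], np.diff(curve) > 0])
    return float(np.interp(observed, curve[keep], grid[keep]))


def invert_alpha(observed_pct: float, sweep: SweepResult) -> AlphaEstimate:
    """Map an observed intransitivity percentage to a noise-fraction estimate.

    The point estimate interpolates the isotonic fit of the sweep's mean
    curve; the interval comes from interpolating the mean ± SE curves.  An
    observation below the curve's minimum returns the grid minimum flagged
    ``below_curve``; one above its maximum is not bracketed and raises.
    """
    grid = np.asarray(sweep.alpha_grid, dtype=float)
    mean_iso = sweep.isotonic_mean()
    if observed_pct > mean_iso.max():
        raise ValueError(
            f"observed {observed_pct:.3f}% exceeds the sweep maximum "
            f"{mean_iso.max():.3f}%; extend the α grid or add replicates"
        )
    if observed_pct < mean_iso.min():
        return AlphaEstimate(
            alpha=float(grid[0]), lo=float(grid[0]), hi=float(grid[0]),
            flag="below_curve",
        )
    alpha = _invert_on_curve(observed_pct, mean_iso, grid)
    upper_curve = isotonic_regression(sweep.mean_pct + sweep.se_pct).x
    lower_curve = isotonic_regression(sweep.mean_pct - sweep.se_pct).x
    # higher curve at a given α → smaller inverted α for the same observation
    lo = _invert_on_curve(min(observed_pct, upper_curve.max()), upper_curve, grid)
    hi = _invert_on_curve(min(observed_pct, lower_curve.max()), lower_curve, grid)
    lo, hi = min(lo, hi, alpha), max(lo, hi, alpha)
    return AlphaEstimate(alpha=alpha, lo=lo, hi=hi)
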