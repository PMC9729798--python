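"""A priori power analysis for repeated-measures ANOVA designs.

The study sized its cohorts with three simplified scenarios: a
within-subjects repeated-measures ANOVA for the time effect (alpha 0.05,
effect size f = 0.35, m = 5 measurements, repeated-measures correlation
rho = 0.8), a within-between interaction for time x diet (f = 0.25, m = 5,
rho = 0.8, 2 groups), and a within-between interaction folding time and
area together (f = 0.15, m = 5 x 4 = 20, rho = 0.8, 2 groups).

Power follows the classical noncentral-F formulation with the
repeated-measures correlation correction,

    lambda = f^2 * N * m * eps / (1 - rho),

numerator df (m - 1) * eps for within designs and
(groups - 1) * (m - 1) * eps for interaction designs, denominator df
(N - groups) * (m - 1) * eps, with nonsphericity eps = 1 by default.
The alternative convention where f is already correlation-adjusted (the
source tool supports both) is selectable with ``corr_adjusted_f=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_N = 10_000


@dataclass(frozen=True)
class PowerScenario:
    """One repeated-measures power scenario."""

    design: str  # "within" | "within_between_interaction"
    alpha: float = 0.05
    effect_size_f: float = 0.35
    n_groups: int = 1
    n_measurements: int = 5
    correlation: float = 0.8
    nonsphericity: float = 1.0
    target_power: float = 0.80
    corr_adjusted_f: bool = False

    def __post_init__(self) -> None:
        if self.design not in ("within", "within_between_interaction"):
            raise ValueError(f"unknown design {self.design!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_size_f < 0:
            raise ValueError("effect size f must be >= 0")
        if self.n_measurements < 2:
            raise ValueError("need at least 2 repeated measurements")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must be in [0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target power must be in (0, 1)")
        if self.design == "within_between_interaction" and self.n_groups < 2:
            raise ValueError("interaction designs need >= 2 groups")


#: the three scenarios stated for the study design
PAPER_SCENARIOS: tuple[PowerScenario, ...] = (
    PowerScenario("within", effect_size_f=0.35, n_measurements=5, correlation=0.8),
    PowerScenario("within_between_interaction", effect_size_f=0.25, n_groups=2,
                  n_measurements=5, correlation=0.8),
    PowerScenario("within_between_interaction", effect_size_f=0.15, n_groups=2,
                  n_measurements=20, correlation=0.8),
)


def rm_anova_power(scenario: PowerScenario, n_per_group: int) -> float:
    """Analytic power of the scenario's F test at ``n_per_group`` subjects/group."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    m = scenario.n_measurements
    g = scenario.n_groups if scenario.design == "within_between_interaction" else 1
    N = n_per_group * g
    eps = scenario.nonsphericity
    f2 = scenario.effect_size_f**2
    corr_factor = 1.0 if scenario.corr_adjusted_f else 1.0 / (1.0 - scenario.correlation)
    lam = f2 * N * m * eps * corr_factor
    if scenario.design == "within":
        df1 = (m - 1) * eps
    else:
        df1 = (g - 1) * (m - 1) * eps
    df2 = (N - g) * (m - 1) * eps
    if df2 <= 0:
        raise ValueError("design leaves no residual degrees of freedom")
    fcrit = stats.f.isf(scenario.alpha, df1, df2)
    if lam == 0:  # ncf degenerates to the central F at zero noncentrality
        return float(stats.f.sf(fcrit, df1, df2))
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def solve_n(scenario: PowerScenario) -> int:
    """Smallest n per group whose analytic power reaches the target."""
    for n in range(2, MAX_N + 1):
        if rm_anova_power(scenario, n) >= scenario.target_power:
            return n
    raise RuntimeError(f"target power {scenario.target_power} not reached by n = {MAX_N}")


def consensus_n(scenarios: list[PowerScenario] | tuple[PowerScenario, ...]) -> int:
    """Consensus sample size: the maximum of the per-scenario solutions."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    return max(solve_n(s) for s in scenarios)


def simulate_rm_anova_power(
    scenario: PowerScenario,
    n_per_group: int,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of the repeated-measures F test (simulation oracle).

    Data follow the compound-symmetric model y_ij = mu_j + s_i + e_ij with
    Var(s) = rho, Var(e) = 1 - rho (unit total variance) and cell means
    scaled so that sd(mu) = f; the classical (sphericity-assumed,
    eps = 1) F statistic is formed each replicate.
    """
    rng = np.random.default_rng(seed)
    m = scenario.n_measurements
    g = scenario.n_groups if scenario.design == "within_between_interaction" else 1
    n = n_per_group
    N = n * g
    rho = scenario.correlation
    f = scenario.effect_size_f
    if scenario.corr_adjusted_f:
        f = f / np.sqrt(1.0 - rho)  # undo the adjustment for simulation on raw scale

    if scenario.design == "within":
        mu = np.sin(2 * np.pi * np.arange(m) / m)
        mu = mu - mu.mean()
        mu = mu / np.sqrt(np.mean(mu**2)) * f if f > 0 else np.zeros(m)
        df1, df2 = m - 1, (N - 1) * (m - 1)
        fcrit = stats.f.isf(scenario.alpha, df1, df2)
        hits = 0
        for _ in range(n_reps):
            subj = rng.normal(0.0, np.sqrt(rho), (N, 1))
            err = rng.normal(0.0, np.sqrt(1 - rho), (N, m))
            y = mu[np.newaxis, :] + subj + err
            ybar_t = y.mean(axis=0)
            grand = y.mean()
            ss_time = N * ((ybar_t - grand) ** 2).sum()
            resid = y - y.mean(axis=1, keepdims=True) - ybar_t[np.newaxis, :] + grand
            ss_err = (resid**2).sum()
            F = (ss_time / df1) / (ss_err / df2)
            hits += F > fcrit
        return hits / n_reps

    # group x time interaction pattern with interaction rms = f
    inter = np.outer(np.linspace(-1, 1, g), np.sin(2 * np.pi * np.arange(m) / m))
    inter = inter - inter.mean(axis=0, keepdims=True)
    inter = inter - inter.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(inter**2))
    inter = inter / rms * f if f > 0 and rms > 0 else np.zeros_like(inter)
    df1, df2 = (g - 1) * (m - 1), (N - g) * (m - 1)
    fcrit = stats.f.isf(scenario.alpha, df1, df2)
    hits = 0
    for _ in range(n_reps):
        y = np.empty((N, m))
        for gi in range(g):
            subj = rng.normal(0.0, np.sqrt(rho), (n, 1))
            err = rng.normal(0.0, np.sqrt(1 - rho), (n, m))
            y[gi * n : (gi + 1) * n] = inter[gi][np.newaxis, :] + subj + err
        groups = np.repeat(np.arange(g), n)
        grand = y.mean()
        cell = np.stack([y[groups == gi].mean(axis=0) for gi in range(g)])
        gmean = cell.mean(axis=1, keepdims=True)
        tmean = cell.mean(axis=0, keepdims=True)
        ss_inter = n * ((cell - gmean - tmean + grand) ** 2).sum()
        subj_mean = y.mean(axis=1, keepdims=True)
        resid = y - subj_mean - cell[groups] + gmean[groups]
        ss_err = (resid**2).sum()
        F = (ss_inter / df1) / (ss_err / df2)
        hits += F > fcrit
    return hits / n_reps
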