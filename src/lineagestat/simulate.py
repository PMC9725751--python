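"""Branching-process simulator with gamma generation times and random cell
removal.

Cells divide into two daughters after a gamma(k, θ) generation time; with the
calibration θ = 2^(1/k) − 1 the Euler–Lotka relation 2(1 + Λθ)^(−k) = 1
fixes the asymptotic growth rate at Λ = 1 for every shape k.  A fitness
perturbation of strength ε removes each newborn daughter independently with
probability 1 − 2^(−ε), damping every lineage's fitness from d·ln2 to
(1−ε)·d·ln2.

Mother–daughter generation-time correlations r are produced by a conditional
gamma kernel with shape (r·τ_m/θ + k(1−r))/(1−r²) and scale (1−r²)θ, whose
stationary law keeps the gamma(k, θ) mean kθ and variance kθ² exactly and
has lag-1 autocorrelation r.

The protocol has two stages.  A pre-run grows single newborn cells (with
removal) until every surviving lineage passes T_max and exports the residual
time to each lineage's next division; the pooled residuals are the
first-division times of the main run, so main-run progenitors start from the
quasi-stationary age distribution.  The main run grows one progenitor per
cycle and records the division count of every lineage surviving to T_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treeio import LineageEnsemble, LineageRecord

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "euler_lotka_growth_rate",
    "draw_generation_time",
    "prerun_first_division_times",
    "simulate_main",
    "sim_growth_and_fitness",
    "to_ensemble",
    "removal_sweep",
]

LN2 = float(np.log(2.0))


def euler_lotka_growth_rate(shape: float, scale: float) -> float:
    """Asymptotic growth rate for uncorrelated gamma(k, θ) generation times.

    Λ solves 2 E[e^(−Λ T)] = 1, i.e. 2 (1 + Λθ)^(−k) = 1, giving
    Λ = (2^(1/k) − 1)/θ.  Used as an independent oracle in tests.
    """
    return (2.0 ** (1.0 / shape) - 1.0) / scale


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one removal-perturbation simulation.

    ``scale=None`` applies the growth-rate-one calibration θ = 2^(1/k) − 1.
    ``fixed_generation_time`` replaces the gamma draws by a constant
    (degenerate k → ∞ mode used in tests).
    """

    shape: float
    scale: float | None = None
    corr: float = 0.0
    eps: float = 0.0
    t_max: float = 8.0
    n_prerun: int = 1000
    n_main: int = 1000
    seed: int = 0
    fixed_generation_time: float | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape k must be > 0")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("gamma scale θ must be > 0")
        if not 0.0 <= self.corr < 1.0:
            raise ValueError("mother-daughter correlation r must lie in [0, 1)")
        if self.t_max <= 0:
            raise ValueError("T_max must be > 0")
        if self.eps < 0:
            raise ValueError("perturbation strength ε must be >= 0")

    @property
    def theta(self) -> float:
        return self.scale if self.scale is not None else 2.0 ** (1.0 / self.shape) - 1.0

    @property
    def survival_probability(self) -> float:
        """Probability 2^(−ε) that a newborn daughter escapes removal."""
        return 2.0 ** (-self.eps)

    def rng(self) -> np.random.Generator:
        # counter-based stream: deterministic and cheap to fast-forward
        return np.random.Generator(np.random.Philox(np.random.SeedSequence(self.seed)))


def draw_generation_time(
    shape: float,
    scale: float,
    corr: float,
    tau_mother: float | np.ndarray | None,
    rng: np.random.Generator,
) -> float | np.ndarray:
    """One generation time; conditional on the mother's when corr > 0.

    With corr = 0 (or no mother) this is a plain gamma(k, θ) draw.  The
    correlated kernel keeps the stationary first and second moments at kθ
    and kθ² and the lag-1 correlation at r.
    """
    if not 0.0 <= corr < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    if corr == 0.0 or tau_mother is None:
        size = None if np.ndim(tau_mother) == 0 else np.shape(tau_mother)
        return rng.gamma(shape, scale, size=size)
    tau_m = np.asarray(tau_mother, dtype=float)
    cond_shape = (corr * tau_m / scale + shape * (1.0 - corr)) / (1.0 - corr ** 2)
    cond_scale = (1.0 - corr ** 2) * scale
    out = rng.gamma(cond_shape, cond_scale)
    return float(out) if np.ndim(tau_mother) == 0 else out


@dataclass(frozen=True)
class SimulationResult:
    """Surviving lineages of a main run (division counts tagged by cycle)."""

    division_counts: np.ndarray
    run_ids: np.ndarray
    n_main: int
    t_max: float
    eps: float
    config: SimulationConfig = field(compare=False)
    first_division_pool: np.ndarray = field(compare=False, repr=False, default=None)

    @property
    def n_survivors(self) -> int:
        return int(self.division_counts.size)


def _draw_taus(cfg: SimulationConfig, tau_m: np.ndarray | None,
               rng: np.random.Generator, size: int) -> np.ndarray:
    if cfg.fixed_generation_time is not None:
        return np.full(size, cfg.fixed_generation_time)
    if cfg.corr == 0.0 or tau_m is None:
        return rng.gamma(cfg.shape, cfg.theta, size=size)
    return np.asarray(draw_generation_time(cfg.shape, cfg.theta, cfg.corr, tau_m, rng))


def _grow(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    run_id: np.ndarray,
    t_next: np.ndarray,
    tau_cur: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow all cycles at once until every lineage passes T_max.

    Returns (run_id, divisions, residual next-division time − T_max) of the
    surviving lineages.  Removal happens at birth with probability
    1 − 2^(−ε); a cycle whose lineages are all removed goes extinct and
    contributes nothing.
    """
    keep_p = cfg.survival_probability
    d = np.zeros(run_id.size, dtype=np.int64)
    out_run, out_d, out_res = [], [], []
    while run_id.size:
        done = t_next > cfg.t_max
        if done.any():
            out_run.append(run_id[done])
            out_d.append(d[done])
            out_res.append(t_next[done] - cfg.t_max)
        act = ~done
        run_id, t_next, tau_cur, d = run_id[act], t_next[act], tau_cur[act], d[act]
        if not run_id.size:
            break
        # each active cell divides: two daughters, independent removal
        run_id = np.repeat(run_id, 2)
        t_birth = np.repeat(t_next, 2)
        tau_m = np.repeat(tau_cur, 2)
        d = np.repeat(d + 1, 2)
        if keep_p < 1.0:
            kept = rng.random(run_id.size) < keep_p
            run_id, t_birth, tau_m, d = run_id[kept], t_birth[kept], tau_m[kept], d[kept]
        tau_cur = _draw_taus(cfg, tau_m, rng, run_id.size)
        t_next = t_birth + tau_cur
    if not out_run:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    return np.concatenate(out_run), np.concatenate(out_d), np.concatenate(out_res)


def prerun_first_division_times(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Pool of first-division times for the main run.

    Each of n_prerun cycles starts from one newborn cell; when every
    surviving lineage has passed T_max, the residual time to its next
    division is exported.  Removal operates in the pre-run exactly as in
    the main run.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_prerun
    run_id = np.arange(n, dtype=np.int64)
    tau0 = _draw_taus(config, None, rng, n)
    _, _, residuals = _grow(config, rng, run_id, tau0.copy(), tau0)
    if residuals.size == 0:
        warnings.warn("pre-run pool is empty: every cycle went extinct", stacklevel=2)
    return residuals


def simulate_main(
    config: SimulationConfig, pool: np.ndarray | None = None
) -> SimulationResult:
    """Main run: n_main progenitors with pooled first-division times.

    Each progenitor founds one cycle; its first division occurs at a time
    drawn from the pre-run pool, daughters are removed with probability
    1 − 2^(−ε), survivors draw fresh generation times, and lineages stop
    branching past T_max.  Division counts of surviving lineages are
    recorded per cycle.
    """
    rng = config.rng()
    if pool is None:
        pool = prerun_first_division_times(config, rng)
    if pool.size == 0:
        raise ValueError("empty first-division pool; cannot start the main run")
    n = config.n_main
    run_id = np.arange(n, dtype=np.int64)
    t_first = rng.choice(pool, size=n)
    # the pooled residual doubles as the correlation anchor for the first
    # daughters (a fresh progenitor has no recorded mother)
    run_out, d_out, _ = _grow(config, rng, run_id, t_first.copy(), t_first.copy())
    order = np.argsort(run_out, kind="stable")
    return SimulationResult(
        division_counts=d_out[order],
        run_ids=run_out[order],
        n_main=n,
        t_max=config.t_max,
        eps=config.eps,
        config=config,
        first_division_pool=pool,
    )


def sim_growth_and_fitness(result: SimulationResult) -> tuple[float, float, float]:
    """(Λ(ε), ⟨h̃⟩_cl, ⟨h̃⟩_rs) from a main run.

    Λ(ε) = (1/T_max) ln(N/n_main).  The mean-fitness formulas assume the
    unperturbed (ε = 0) run, where Σ 2^(−D) = n_main makes the chronological
    weights exact.
    """
    n = result.n_survivors
    if n == 0:
        raise ValueError("no lineage survived; growth rate undefined")
    d = result.division_counts.astype(float)
    lam = np.log(n / result.n_main) / result.t_max
    h_cl = float(np.sum(d * LN2 * np.exp2(-d)) / result.n_main)
    h_rs = float(np.sum(d * LN2) / n)
    return float(lam), h_cl, h_rs


def to_ensemble(result: SimulationResult, mode: str = "tree") -> LineageEnsemble:
    """Bridge a simulation into the analysis modules.

    Tree mode requires ε = 0 (complete trees; conservation holds per cycle).
    Chronological export is allowed for any ε but is approximate: survivors
    of removal are not an unbiased chronological sample.
    """
    records = [
        LineageRecord(f"c{run}.{i}", int(d))
        for i, (run, d) in enumerate(zip(result.run_ids, result.division_counts))
    ]
    if mode == "tree":
        if result.eps != 0:
            raise ValueError(
                "tree-mode export requires ε = 0: removal leaves incomplete trees"
            )
        return LineageEnsemble(
            "tree", records, float(result.n_main), 0.0, result.t_max,
            n_tau=float(len(records)),
        )
    if mode == "chronological":
        return LineageEnsemble(
            "chronological", records, float(len(records)), 0.0, result.t_max
        )
    raise ValueError(f"unknown export mode {mode!r}")


def fit_response_slope(df: pd.DataFrame) -> tuple[float, float]:
    """Measured initial response slope from a removal sweep.

    ΔΛ/Λ = aε + bε² + O(ε³): the quadratic term is part of the exact
    response K_D(1−ε), so the initial slope is estimated as the linear
    coefficient of a two-term least-squares fit; returns (a, b).
    """
    x = df["eps"].to_numpy()
    y = df["dll"].to_numpy()
    design = np.column_stack([x, x ** 2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def division_count_pair(divisions: np.ndarray, n0: float, tau: float):
    """Binned division-count distribution pair straight from a D array.

    Array-only fast path for very large simulated populations (equivalent
    to exporting a tree-mode ensemble and binning it, without building the
    per-lineage records).
    """
    from .distributions import TraitDistributionPair

    d = np.asarray(divisions)
    n_tau = float(d.size)
    counts_rs = np.bincount(d)
    counts_cl = np.bincount(d, weights=np.exp2(-d.astype(float)))
    occ = counts_rs > 0
    centers = np.arange(counts_rs.size, dtype=float)[occ]
    q_cl = counts_cl[occ] / counts_cl[occ].sum()
    q_rs = counts_rs[occ] / n_tau
    return TraitDistributionPair(
        "D", centers, q_cl, q_rs / q_rs.sum(), tau, float(n0), n_tau, 1.0,
        {"binning_kind": "integer", "mode": "tree"},
    )


def removal_sweep(
    shape: float,
    eps_grid: np.ndarray | list[float],
    n_main: int = 1000,
    n_prerun: int = 1000,
    seed: int = 0,
    corr: float = 0.0,
    t_max: float = 8.0,
    scale: float | None = None,
) -> pd.DataFrame:
    """Λ(ε) over a perturbation sweep plus the three theory reference lines.

    Returns one row per ε with the simulated relative growth change and the
    predictions −ε, −(⟨h̃⟩_cl/τΛ)ε and −(1 + S_KL2[D]/τΛ)ε; the theory
    coefficients come from the unperturbed (ε = 0) run only.
    """
    from .selection import selection_strengths

    eps_grid = np.asarray(list(eps_grid), dtype=float)
    if eps_grid[0] != 0.0:
        eps_grid = np.concatenate([[0.0], eps_grid])
    seeds = np.random.SeedSequence(seed).generate_state(len(eps_grid)) % (2 ** 31)

    rows = []
    lam0 = None
    theory = {}
    for eps, s in zip(eps_grid, seeds):
        cfg = SimulationConfig(
            shape=shape, scale=scale, corr=corr, eps=float(eps), t_max=t_max,
            n_prerun=n_prerun, n_main=n_main, seed=int(s),
        )
        res = simulate_main(cfg)
        lam = np.log(res.n_survivors / n_main) / t_max if res.n_survivors else np.nan
        if eps == 0.0:
            lam0, h_cl, h_rs = sim_growth_and_fitness(res)
            pair = division_count_pair(res.division_counts, n_main, t_max)
            _, s_kl1, s_kl2 = selection_strengths(pair)
            tau_lambda = pair.tau_lambda
            theory = {
                "slope_uniform": -1.0,
                "slope_chronological": -h_cl / tau_lambda,
                "slope_retrospective": -(1.0 + s_kl2 / tau_lambda),
                "s_kl1": s_kl1,
                "s_kl2": s_kl2,
                "tau_lambda": tau_lambda,
            }
        rows.append({"eps": eps, "n_survivors": res.n_survivors, "lam": lam})
    df = pd.DataFrame(rows)
    df["dll"] = (df["lam"] - lam0) / lam0
    for key, val in theory.items():
        df.attrs[key] = float(val)
    return df
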