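"""Programmatic fixtures: small exactly-solvable ensembles and simulated data.

Every fixture ships with a manifest of its exact expected statistics,
computed here by direct-from-definition sums over lineages (independent of
the distributions/selection modules) so the manifests can serve as oracles
in tests and documentation.

Fixture catalogue
-----------------
``T1``
    The worked micro-tree: one founder, D = (1, 2, 2) over a unit window.
``uniform(d, n0)``
    n0 founders, every lineage divides exactly d times — no heterogeneity,
    all selection strengths zero.
``two_root``
    Two founders, D-multisets {0} and {1, 1}.
``skewed_regrowth(p0, dmax, n)``
    Chronological-mode lineage list mimicking regrowth from deep dormancy:
    fraction p0 of lineages never divide, the rest spread over 3..dmax
    divisions — a strongly right-skewed Q_cl(d).
``gamma_sim(k, theta, r)``
    An unperturbed branching-process run exported as a tree-mode ensemble.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .simulate import SimulationConfig, simulate_main, to_ensemble
from .treeio import (
    CellRecord,
    LineageEnsemble,
    LineageRecord,
    parse_cell_table,
    write_cell_table,
    write_lineage_table,
)

__all__ = [
    "t1_cell_table",
    "build_t1",
    "build_uniform",
    "build_two_root",
    "build_skewed_regrowth",
    "build_gamma_sim",
    "random_tree_ensemble",
    "generate_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("T1", "uniform", "two_root", "skewed_regrowth", "gamma_sim")


def t1_cell_table() -> list[CellRecord]:
    """The 3-lineage micro-tree: root divides at 0.3, one daughter at 0.6."""
    return [
        CellRecord("A", None, 0.0, 0.3, "divided"),
        CellRecord("A1", "A", 0.3, 1.0, "alive_at_end"),
        CellRecord("B", "A", 0.3, 0.6, "divided"),
        CellRecord("B1", "B", 0.6, 1.0, "alive_at_end"),
        CellRecord("B2", "B", 0.6, 1.0, "alive_at_end"),
    ]


def _manifest_from_divisions(
    divisions: np.ndarray, n0: float, mode: str = "tree"
) -> dict:
    """Exact statistics by direct substitution into the definitions."""
    d = np.asarray(divisions, dtype=float)
    if mode == "tree":
        n_tau = float(d.size)
        p_cl = np.exp2(-d) / n0
        p_rs = np.full(d.size, 1.0 / n_tau)
    else:
        n_tau = float(np.exp2(d).sum())
        p_cl = np.full(d.size, 1.0 / n0)
        p_rs = np.exp2(d) / np.exp2(d).sum()
    tau_lambda = math.log(n_tau / n0)
    support = np.unique(d)
    q_cl = np.array([p_cl[d == v].sum() for v in support])
    q_rs = np.array([p_rs[d == v].sum() for v in support])
    h = tau_lambda + np.log(q_rs / q_cl)
    s_kl1 = float(q_cl @ np.log(q_cl / q_rs))
    s_kl2 = float(q_rs @ np.log(q_rs / q_cl))
    m_cl = float(h @ q_cl)
    kappa2 = float((h - m_cl) ** 2 @ q_cl)
    return {
        "mode": mode,
        "N0": n0,
        "Ntau": n_tau,
        "tau_lambda": tau_lambda,
        "support": support.tolist(),
        "landscape": {float(v): float(hv) for v, hv in zip(support, h)},
        "S_KL1": s_kl1,
        "S_KL2": s_kl2,
        "S_JF": s_kl1 + s_kl2,
        "mean_fitness_cl": m_cl,
        "kappa2": kappa2,
        "W1": m_cl / tau_lambda if tau_lambda else None,
        "skewed_right": s_kl2 > s_kl1,
    }


def build_t1() -> tuple[LineageEnsemble, dict]:
    ens = parse_cell_table(t1_cell_table(), 0.0, 1.0)
    return ens, _manifest_from_divisions(ens.divisions, 1.0)


def build_uniform(d: int = 3, n0: int = 2) -> tuple[LineageEnsemble, dict]:
    """Deterministic tree: every founder yields 2^d lineages of D = d."""
    records = [
        LineageRecord(f"u{i}.{j}", d) for i in range(n0) for j in range(2 ** d)
    ]
    ens = LineageEnsemble("tree", records, float(n0), 0.0, 1.0,
                          n_tau=float(len(records)))
    return ens, _manifest_from_divisions(ens.divisions, float(n0))


def build_two_root() -> tuple[LineageEnsemble, dict]:
    records = [LineageRecord("a", 0), LineageRecord("b1", 1), LineageRecord("b2", 1)]
    ens = LineageEnsemble("tree", records, 2.0, 0.0, 1.0, n_tau=3.0)
    return ens, _manifest_from_divisions(ens.divisions, 2.0)


def build_skewed_regrowth(
    p0: float = 0.9, dmax: int = 6, n: int = 500
) -> tuple[LineageEnsemble, dict]:
    """Late-stationary-like regrowth: most lineages dormant, a few prolific.

    Built as a chronological-mode lineage list (division counts assigned
    deterministically from the rounded target fractions, so the fixture is
    reproducible without a seed).
    """
    n_zero = int(round(p0 * n))
    rest = n - n_zero
    counts = [0] * n_zero
    d_values = list(range(3, dmax + 1))
    for i in range(rest):
        counts.append(d_values[i % len(d_values)])
    records = [LineageRecord(f"s{i}", c) for i, c in enumerate(counts)]
    ens = LineageEnsemble("chronological", records, float(n), 0.0, 1.0)
    return ens, _manifest_from_divisions(ens.divisions, float(n), mode="chronological")


def build_gamma_sim(
    shape: float = 2.0,
    theta: float | None = None,
    corr: float = 0.0,
    seed: int = 0,
    n_main: int = 50,
    n_prerun: int = 50,
    t_max: float = 8.0,
) -> tuple[LineageEnsemble, dict]:
    cfg = SimulationConfig(shape=shape, scale=theta, corr=corr, eps=0.0,
                           t_max=t_max, n_prerun=n_prerun, n_main=n_main, seed=seed)
    res = simulate_main(cfg)
    ens = to_ensemble(res, "tree")
    return ens, _manifest_from_divisions(ens.divisions, float(n_main))


def random_tree_ensemble(
    rng: np.random.Generator,
    n_roots: int | None = None,
    max_lineages: int = 200,
    n_traits: int = 0,
) -> LineageEnsemble:
    """A random complete tree-mode ensemble for fuzz/property tests.

    Built by repeatedly splitting random leaves of a genuine forest, so the
    dyadic conservation law holds by construction.  Optional continuous
    traits are noisy monotone functions of D (so trait and fitness
    correlate, as in real data).
    """
    n_roots = int(rng.integers(1, 5)) if n_roots is None else n_roots
    depths = [0] * n_roots
    target = int(rng.integers(n_roots + 1, max(n_roots + 2, max_lineages)))
    while len(depths) < target:
        i = int(rng.integers(len(depths)))
        d = depths.pop(i)
        depths.extend([d + 1, d + 1])
    records = []
    for i, d in enumerate(depths):
        traits = {}
        for t in range(n_traits):
            traits[f"x{t}"] = float(d + rng.normal(0.0, 1.0 + t))
        records.append(LineageRecord(f"r{i}", d, traits))
    tau = float(rng.uniform(1.0, 10.0))
    return LineageEnsemble("tree", records, float(n_roots), 0.0, tau,
                           n_tau=float(len(records)))


def generate_fixture(
    name: str, outdir: str | Path, params: dict | None = None, seed: int = 0
) -> dict:
    """Write a fixture to disk (cell/lineage tables + JSON manifest).

    Returns the manifest.  ``name`` is one of FIXTURE_NAMES; ``params`` are
    forwarded to the matching builder.
    """
    params = dict(params or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "T1":
        ens, manifest = build_t1()
        write_cell_table(t1_cell_table(), outdir / "T1_cells.tsv")
    elif name == "uniform":
        ens, manifest = build_uniform(**params)
    elif name == "two_root":
        ens, manifest = build_two_root()
    elif name == "skewed_regrowth":
        ens, manifest = build_skewed_regrowth(**params)
    elif name == "gamma_sim":
        ens, manifest = build_gamma_sim(seed=seed, **params)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    write_lineage_table(ens, outdir / f"{name}_lineages.tsv")
    (outdir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
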