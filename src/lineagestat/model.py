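"""Model/Results interface over the lineage-statistics estimators.

`LineageSelectionModel` holds the data (a :class:`~lineagestat.treeio.LineageEnsemble`
plus the trait and binning to analyse); :meth:`~LineageSelectionModel.fit`
returns a :class:`LineageSelectionResults` carrying the point estimates,
bootstrap uncertainties, cumulant diagnostics, and a ``summary()`` table,
in the style of the fitted-model objects of the statistical-modelling
ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgf import (
    CGFCurve,
    CumulantSeries,
    MeasureDifference,
    cumulants as _cumulants,
    kprime_curve as _kprime_curve,
    measure_difference as _measure_difference,
    perturbed_growth as _perturbed_growth,
    response_slope as _response_slope,
)
from .distributions import BinningSpec, TraitDistributionPair, trait_distribution_pair
from .resample import ResampleSpec, UncertaintySummary, bootstrap
from .selection import SelectionSummary, selection_summary
from .treeio import DIVISION_TRAIT, LineageEnsemble, LineageRecord

__all__ = ["LineageSelectionModel", "LineageSelectionResults"]

_BOOT_STATISTICS = (
    "tau_lambda",
    "mean_fitness_cl",
    "mean_fitness_rs",
    "S_KL1",
    "S_KL2",
    "S_JF",
    "W1",
    "W2",
    "S_rel",
)


def _stat_fn(stat: str, trait: str, binning: BinningSpec | None):
    """Ensemble -> scalar statistic used inside bootstrap replicates."""

    def fn(ens: LineageEnsemble) -> float:
        summ = selection_summary(ens, trait, binning)
        if stat == "tau_lambda":
            return summ.tau_lambda
        if stat == "mean_fitness_cl":
            return summ.mean_fitness_cl
        if stat == "mean_fitness_rs":
            return summ.mean_fitness_rs
        if stat == "S_KL1":
            return summ.s_kl1
        if stat == "S_KL2":
            return summ.s_kl2
        if stat == "S_JF":
            return summ.s_jf
        if stat == "S_rel":
            return np.nan if summ.s_rel is None else summ.s_rel
        if stat in ("W1", "W2"):
            # cheap closed forms: W1 = <h>_cl/τΛ, W2 adds Var[h]_cl/2
            if summ.tau_lambda == 0:
                return np.nan
            num = summ.mean_fitness_cl
            if stat == "W2":
                num += 0.5 * summ.var_fitness_cl
            return num / summ.tau_lambda
        raise KeyError(stat)

    return fn


class LineageSelectionModel:
    """Selection-on-lineages model for one trait of a lineage ensemble.

    Parameters
    ----------
    ensemble:
        The lineage data (tree or chronological mode).
    trait:
        Trait to analyse; the reserved name ``"D"`` is the division count.
    binning:
        Optional binning override; division counts default to integer bins,
        continuous traits to the 0.4·IQR width rule.
    """

    def __init__(
        self,
        ensemble: LineageEnsemble,
        trait: str = DIVISION_TRAIT,
        binning: BinningSpec | None = None,
    ) -> None:
        self.ensemble = ensemble
        self.trait = trait
        self.binning = binning

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        mode: str = "chronological",
        trait: str = DIVISION_TRAIT,
        n0: float | None = None,
        n_tau: float | None = None,
        t_start: float = 0.0,
        t_end: float = 1.0,
        binning: BinningSpec | None = None,
    ) -> "LineageSelectionModel":
        """Build from a lineage table with columns lineage_id/division_count
        plus optional trait columns."""
        trait_cols = [c for c in data.columns if c not in ("lineage_id", "division_count")]
        records = [
            LineageRecord(
                str(r.lineage_id),
                int(r.division_count),
                {t: float(getattr(r, t)) for t in trait_cols if not pd.isna(getattr(r, t))},
            )
            for r in data.itertuples(index=False)
        ]
        if mode == "chronological":
            n0 = float(len(records)) if n0 is None else n0
        elif n0 is None:
            raise ValueError("tree mode requires the observed founder count n0")
        ens = LineageEnsemble(mode, records, float(n0), t_start, t_end,
                              n_tau=n_tau)
        return cls(ens, trait=trait, binning=binning)

    def fit(
        self,
        n_max: int = 20,
        n_boot: int = 0,
        seed: int | None = None,
    ) -> "LineageSelectionResults":
        """Estimate the landscape, selection strengths and cumulant series.

        ``n_boot > 0`` adds lineage-bootstrap uncertainties (colony scheme
        for tree-mode data, chronological scheme otherwise).
        """
        pair = trait_distribution_pair(self.ensemble, self.trait, self.binning)
        summary = selection_summary(self.ensemble, self.trait, self.binning)
        series = _cumulants(pair, n_max=n_max)
        uncertainties: dict[str, UncertaintySummary] = {}
        if n_boot > 0:
            scheme = "colony" if self.ensemble.mode == "tree" else "chronological"
            spec = ResampleSpec(n_boot, 0 if seed is None else seed, scheme)
            for stat in _BOOT_STATISTICS:
                if stat == "S_rel" and self.trait == DIVISION_TRAIT:
                    continue
                uncertainties[stat] = bootstrap(
                    self.ensemble, spec, _stat_fn(stat, self.trait, self.binning),
                    name=stat,
                )
        return LineageSelectionResults(self, pair, summary, series, uncertainties)


@dataclass
class LineageSelectionResults:
    """Fitted lineage-selection estimates with diagnostics.

    Scalar estimates are exposed as attributes (``tau_lambda``, ``s_kl1``,
    ``s_kl2``, ``s_jf``, ``s_rel``, ``w`` …); ``summary()`` renders a text
    table; curve/perturbation evaluators and plots hang off this object.
    """

    model: LineageSelectionModel
    pair: TraitDistributionPair
    selection: SelectionSummary
    cumulant_series: CumulantSeries
    uncertainties: dict[str, UncertaintySummary] = field(default_factory=dict)

    # -- scalar views -----------------------------------------------------

    @property
    def tau_lambda(self) -> float:
        return self.selection.tau_lambda

    @property
    def growth_rate(self) -> float:
        return self.selection.growth_rate

    @property
    def landscape(self) -> pd.Series:
        return pd.Series(self.selection.landscape, index=self.selection.bin_centers,
                         name="h")

    @property
    def s_jf(self) -> float:
        return self.selection.s_jf

    @property
    def s_kl1(self) -> float:
        return self.selection.s_kl1

    @property
    def s_kl2(self) -> float:
        return self.selection.s_kl2

    @property
    def s_rel(self) -> float | None:
        return self.selection.s_rel

    @property
    def w(self) -> np.ndarray:
        """Cumulative cumulant contributions W_1..W_n_max."""
        return self.cumulant_series.w

    @property
    def gain_fraction(self) -> float:
        """S_KL1/τΛ: share of population growth contributed by selection."""
        return self.s_kl1 / self.tau_lambda

    # -- derived curves ---------------------------------------------------

    def kprime_curve(self, step: float = 0.01) -> CGFCurve:
        return _kprime_curve(self.pair, step=step)

    def perturbed_growth(self, eps) -> float | np.ndarray:
        return _perturbed_growth(self.pair, eps,
                                     allow_generic=self.model.trait != DIVISION_TRAIT)

    def response_slope(self) -> tuple[float, float]:
        return _response_slope(self.pair,
                                   allow_generic=self.model.trait != DIVISION_TRAIT)

    def measure_difference(self, n_max: int | None = None) -> MeasureDifference:
        return _measure_difference(
            self.pair, n_max=n_max or self.cumulant_series.n_max
        )

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        s = self.selection
        ser = self.cumulant_series
        lines = [
            "Lineage selection analysis",
            "=" * 60,
            f"trait: {s.trait_name:<22} mode: {self.model.ensemble.mode}",
            f"lineages: {self.model.ensemble.n_lineages:<19} window tau: {s.tau:g} h",
            f"N0: {self.model.ensemble.n0:<25} Ntau: {self.pair.n_tau:g}",
            "-" * 60,
            f"tau*Lambda          {s.tau_lambda: .6f} nats",
            f"Lambda              {s.growth_rate: .6f} /h",
            f"<h>_cl              {s.mean_fitness_cl: .6f} nats",
            f"<h>_rs              {s.mean_fitness_rs: .6f} nats",
            f"Var[h]_cl           {s.var_fitness_cl: .6f} nats^2",
            f"Var[h]_rs           {s.var_fitness_rs: .6f} nats^2",
            f"S_KL1               {s.s_kl1: .6f} nats   (gain fraction {s.s_kl1 / s.tau_lambda:.4f})"
            if s.tau_lambda else f"S_KL1               {s.s_kl1: .6f} nats",
            f"S_KL2               {s.s_kl2: .6f} nats",
            f"S_JF                {s.s_jf: .6f} nats",
        ]
        if s.s_rel is not None:
            lines.append(f"S_rel               {s.s_rel: .6f}")
        lines += [
            f"W1                  {ser.w[0]: .6f}",
            f"W2                  {ser.w[1]: .6f}",
            f"skewness(h)_cl      {ser.skewness: .6f}",
            f"cumulant series converged at n={ser.n_max}: {ser.converged}",
        ]
        if self.uncertainties:
            lines += ["-" * 60, f"{'statistic':<16}{'point':>12}{'boot mean':>12}{'boot sd':>12}"]
            for u in self.uncertainties.values():
                lines.append(f"{u.name:<16}{u.point:>12.5f}{u.boot_mean:>12.5f}{u.boot_sd:>12.5f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # keep the notebook view short
        return (
            f"<LineageSelectionResults trait={self.selection.trait_name!r} "
            f"tauL={self.tau_lambda:.4f} S_KL1={self.s_kl1:.4f} S_KL2={self.s_kl2:.4f}>"
        )

    # -- plotting (optional matplotlib) -----------------------------------

    def plot_kprime(self, ax=None, step: float = 0.01):
        """K′(ξ) on [0, 1] with the ⟨h⟩_cl and ⟨h⟩_rs reference levels."""
        import matplotlib.pyplot as plt

        curve = self.kprime_curve(step)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.xi, curve.kprime, label="K'(xi)")
        ax.axhline(self.selection.mean_fitness_cl, ls="--", c="gray", label="<h>_cl")
        ax.axhline(self.selection.mean_fitness_rs, ls=":", c="gray", label="<h>_rs")
        ax.set_xlabel("xi")
        ax.set_ylabel("K' (nats)")
        ax.legend()
        return ax

    def plot_landscape(self, ax=None, per_time: bool = False):
        """Fitness landscape h(x) (or h(x)/τ) over the trait bins."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.selection.landscape / (self.selection.tau if per_time else 1.0)
        ax.plot(self.selection.bin_centers, h, "o-")
        ax.set_xlabel(self.selection.trait_name)
        ax.set_ylabel("h/tau (1/h)" if per_time else "h (nats)")
        return ax
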