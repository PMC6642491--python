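"""Model/Results façades over the functional pipeline.

Three estimator classes follow the familiar fit-then-inspect pattern:
construct a model from data, call :meth:`fit`, and read estimates,
diagnostics and a ``summary()`` table off the returned Results object.

* :class:`OutputPCA` — principal-component aggregation of the output
  indicators with KMO/Bartlett adequacy diagnostics.
* :class:`EfficiencyModel` — static SBM / super-SBM efficiency per period.
* :class:`MalmquistModel` — adjacent-period productivity decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dea import evaluate_cross_section
from .malmquist import aggregate_mpi, mpi_all_periods
from .panel import PanelDataset
from .pca import (AdequacyStats, CorrelationMatrix, PCAResult,
                  bartlett_sphericity, component_scores, eigendecompose, kmo,
                  pearson_correlation, zstandardize)

__all__ = ["OutputPCA", "PCAResults", "EfficiencyModel", "EfficiencyResults",
           "MalmquistModel", "MalmquistResults"]


def _fmt(df: pd.DataFrame, title: str) -> str:
    bar = "=" * max(len(title), 40)
    return f"{bar}\n{title}\n{bar}\n{df.to_string(float_format=lambda v: f'{v:10.4f}')}\n"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class OutputPCA:
    """PCA aggregation model for an observation × variable block.

    Parameters
    ----------
    data : ndarray or DataFrame
        Pooled observations (rows) by indicators (columns). Already
        z-standardized data are accepted via ``standardize=False``.
    labels : list of str, optional
        Column labels (taken from the DataFrame if omitted).
    """

    def __init__(self, data, labels=None, standardize: bool = True):
        if isinstance(data, pd.DataFrame):
            labels = labels or [str(c) for c in data.columns]
            data = data.to_numpy(float)
        self.raw = np.asarray(data, float)
        self.labels = labels or [f"V{j + 1}" for j in range(self.raw.shape[1])]
        self.standardize = standardize

    @classmethod
    def from_panel(cls, dataset: PanelDataset) -> "OutputPCA":
        """Pool all (dmu, period) observations of the panel's outputs."""
        codes = dataset.indicator_codes
        yi = [codes.index(c) for c in dataset.output_codes]
        n, T = dataset.n_dmus, dataset.n_periods
        return cls(dataset.values[:, :, yi].reshape(n * T, len(yi)),
                   labels=dataset.output_codes)

    def fit(self, n_components: int | str = "kaiser") -> "PCAResults":
        Z = zstandardize(self.raw) if self.standardize else self.raw
        R = pearson_correlation(Z, labels=self.labels)
        decomp = eigendecompose(R)
        k = decomp.n_selected if n_components == "kaiser" else int(n_components)
        k = max(k, 1)
        scores = component_scores(Z, decomp, k=k)
        adequacy = bartlett_sphericity(R, n_obs=Z.shape[0])
        return PCAResults(self, R, decomp, kmo(R), adequacy, scores, k)


class PCAResults:
    """Fitted PCA aggregation: spectrum, loadings, adequacy, scores."""

    def __init__(self, model: OutputPCA, correlation: CorrelationMatrix,
                 decomposition: PCAResult, kmo_value: float,
                 bartlett: AdequacyStats, scores: np.ndarray, k: int):
        self.model = model
        self.correlation = correlation
        self.decomposition = decomposition
        self.kmo = kmo_value
        self.bartlett = bartlett
        self.scores = scores
        self.n_components = k

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.decomposition.eigenvalues

    @property
    def loadings(self) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(d.loadings[:, :self.n_components], index=list(d.labels),
                            columns=[f"PC{c + 1}" for c in range(self.n_components)])

    def summary(self) -> str:
        tab = self.decomposition.variance_table()
        head = (f"KMO sampling adequacy : {self.kmo:8.3f}\n"
                f"Bartlett chi2 (df={self.bartlett.df:d}) : "
                f"{self.bartlett.chi2:10.3f}  (p={self.bartlett.p_value:.3g}, "
                f"n={self.bartlett.n_obs})\n"
                f"Components retained (Kaiser) : {self.n_components}\n")
        return head + _fmt(tab, "Total variance explained") \
            + _fmt(self.loadings, "Component loadings")


# ---------------------------------------------------------------------------
# Static efficiency
# ---------------------------------------------------------------------------

class EfficiencyModel:
    """Static SBM / super-SBM efficiency over a panel's cross-sections.

    Parameters
    ----------
    dataset : PanelDataset
        Strictly positive, normalized panel.
    rts : {"vrs", "crs"}
    super_efficiency : bool
        Re-score SBM-efficient DMUs with super-SBM so they rank above 1.
    """

    def __init__(self, dataset: PanelDataset, rts: str = "vrs",
                 super_efficiency: bool = True):
        self.dataset = dataset
        self.rts = rts
        self.super_efficiency = super_efficiency

    def fit(self, periods=None) -> "EfficiencyResults":
        periods = list(periods) if periods is not None else self.dataset.periods
        frames = [evaluate_cross_section(self.dataset, p, rts=self.rts,
                                         super_efficiency=self.super_efficiency)
                  for p in periods]
        return EfficiencyResults(self, pd.concat(frames, ignore_index=True))


class EfficiencyResults:
    """Per-DMU-per-period efficiency scores with slacks and solver status."""

    def __init__(self, model: EfficiencyModel, scores: pd.DataFrame):
        self.model = model
        self.scores = scores

    def table(self) -> pd.DataFrame:
        """DMU × period score matrix with a DMU-average column."""
        t = self.scores.pivot_table(index="dmu", columns="period",
                                    values="score", sort=False)
        t["Average"] = t.mean(axis=1)
        return t

    def annual_average(self) -> pd.Series:
        return self.scores.groupby("period", sort=True)["score"].mean()

    def regional_average(self) -> pd.DataFrame:
        from .reporting import regional_averages
        return regional_averages(self.scores, self.model.dataset.regions, "static")

    def summary(self) -> str:
        tab = self.table()
        mean = self.scores["score"].mean()
        head = (f"Model: {'super-SBM' if self.model.super_efficiency else 'SBM'}"
                f"-{self.model.rts.upper()}   DMUs: {self.model.dataset.n_dmus}"
                f"   periods: {len(set(self.scores['period']))}\n"
                f"Grand mean efficiency : {mean:.3f}\n")
        return head + _fmt(tab, "Efficiency scores (DMU x period)")


# ---------------------------------------------------------------------------
# Malmquist
# ---------------------------------------------------------------------------

class MalmquistModel:
    """Adjacent-period Malmquist productivity decomposition over a panel."""

    def __init__(self, dataset: PanelDataset):
        self.dataset = dataset

    def fit(self) -> "MalmquistResults":
        return MalmquistResults(self, mpi_all_periods(self.dataset))


class MalmquistResults:
    """tfpch = effch × techch = (pech × sech) × techch per DMU-pair."""

    def __init__(self, model: MalmquistModel, components: pd.DataFrame):
        self.model = model
        self.components = components

    def by_dmu(self) -> pd.DataFrame:
        return aggregate_mpi(self.components, "by-dmu")

    def by_period(self) -> pd.DataFrame:
        return aggregate_mpi(self.components, "by-period")

    def by_region(self) -> pd.DataFrame:
        return aggregate_mpi(self.components, "by-region",
                             regions=self.model.dataset.regions)

    def overall(self) -> pd.Series:
        return aggregate_mpi(self.components, "overall").iloc[0]

    def summary(self) -> str:
        ov = self.overall()
        head = ("Malmquist productivity decomposition "
                "(geometric means, input-oriented CRS distances)\n"
                + "".join(f"  {c:7s}: {ov[c]:.4f}\n"
                          for c in ("effch", "techch", "pech", "sech", "tfpch")))
        return head + _fmt(self.by_dmu().set_index("dmu"),
                           "Average components by DMU")
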