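"""Adjacent-period Malmquist productivity index and its decomposition.

Total factor productivity change between periods t and t+1 is measured by
the geometric-mean Malmquist index built from input-oriented Farrell
distances θ evaluated within and across the two periods' technologies:

    tfpch = [ θᵗ(t+1)/θᵗ(t) · θᵗ⁺¹(t+1)/θᵗ⁺¹(t) ]^{1/2}

where θˢ(r) is the distance of a DMU's period-r data to the period-s
frontier. It decomposes multiplicatively as

    tfpch = effch × techch = (pech × sech) × techch

with effch = θᵗ⁺¹(t+1)/θᵗ(t) under CRS (catching-up), pech the same ratio
under VRS (pure efficiency change), sech = effch/pech (scale efficiency
change), and techch = tfpch/effch (frontier shift). All components are
reported so that values above 1 mean improvement. Cross-period VRS
programs can be infeasible; affected DMU-pairs are flagged incomplete and
excluded from aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea import DEATechnology, radial_distance

__all__ = ["DistanceValue", "MPIResult", "distance", "mpi_adjacent",
           "mpi_all_periods", "aggregate_mpi"]

_COMPONENTS = ["effch", "techch", "pech", "sech", "tfpch"]


@dataclass(frozen=True)
class DistanceValue:
    """One Farrell distance θ of (data_period point) to (tech_period frontier)."""

    value: float
    data_period: int
    technology_period: int
    rts: str
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal" and np.isfinite(self.value) and self.value > 0


@dataclass(frozen=True)
class MPIResult:
    """Malmquist components for one DMU over one adjacent period pair."""

    dmu: str
    period_pair: tuple[int, int]
    effch: float
    techch: float
    pech: float
    sech: float
    tfpch: float
    complete: bool = True

    def as_dict(self) -> dict:
        d = {"dmu": self.dmu, "period_from": self.period_pair[0],
             "period_to": self.period_pair[1], "complete": self.complete}
        for c in _COMPONENTS:
            d[c] = getattr(self, c)
        return d


def _technology(dataset, period: int, rts: str) -> DEATechnology:
    X, Y = dataset.input_output(period)
    return DEATechnology(X, Y, rts=rts, dmu_ids=tuple(dataset.dmu_ids))


def distance(dmu: int, data_period: int, tech_period: int, dataset,
             rts: str = "crs",
             tech: DEATechnology | None = None) -> DistanceValue:
    """θ of one DMU's ``data_period`` point against ``tech_period``'s frontier.

    ``tech`` may carry a prebuilt technology for ``tech_period`` to avoid
    rebuilding it per DMU.
    """
    if tech is None:
        tech = _technology(dataset, tech_period, rts)
    ti = dataset.period_index(data_period)
    codes = dataset.indicator_codes
    xi = [codes.index(c) for c in dataset.input_codes]
    yi = [codes.index(c) for c in dataset.output_codes]
    x0 = dataset.values[dmu, ti, xi]
    y0 = dataset.values[dmu, ti, yi]
    res = radial_distance(x0, y0, tech)
    return DistanceValue(res.score, data_period, tech_period, rts, res.status)


def mpi_adjacent(dataset, t: int, t_next: int) -> list[MPIResult]:
    """Malmquist components for every DMU between two adjacent periods.

    CRS distances drive tfpch/effch/techch; VRS within-period distances
    provide pech, and sech = effch/pech. A DMU whose required distances
    include an infeasible or degenerate program is returned with NaN
    components and ``complete=False``.
    """
    techs = {(p, r): _technology(dataset, p, r)
             for p in (t, t_next) for r in ("crs", "vrs")}
    out = []
    for k, dmu in enumerate(dataset.dmu_ids):
        d = {(dp, tp): distance(k, dp, tp, dataset, "crs", techs[(tp, "crs")])
             for dp in (t, t_next) for tp in (t, t_next)}
        v_own = {p: distance(k, p, p, dataset, "vrs", techs[(p, "vrs")])
                 for p in (t, t_next)}
        needed = list(d.values()) + list(v_own.values())
        if not all(dv.ok for dv in needed):
            out.append(MPIResult(dmu, (t, t_next), *([np.nan] * 5), complete=False))
            continue
        th = {key: dv.value for key, dv in d.items()}
        effch = th[(t_next, t_next)] / th[(t, t)]
        tfpch = float(np.sqrt((th[(t_next, t)] / th[(t, t)])
                              * (th[(t_next, t_next)] / th[(t, t_next)])))
        techch = tfpch / effch
        pech = v_own[t_next].value / v_own[t].value
        sech = effch / pech
        out.append(MPIResult(dmu, (t, t_next), effch, techch, pech, sech, tfpch))
    return out


def mpi_all_periods(dataset) -> pd.DataFrame:
    """Components for every DMU and every adjacent period pair, as a frame."""
    rows = []
    for t, t_next in zip(dataset.periods[:-1], dataset.periods[1:]):
        rows.extend(r.as_dict() for r in mpi_adjacent(dataset, t, t_next))
    return pd.DataFrame(rows)


def _gmean(a: np.ndarray) -> float:
    a = np.asarray(a, float)
    return float(np.exp(np.mean(np.log(a))))


def aggregate_mpi(results, grouping: str = "by-dmu",
                  regions: dict[str, str] | None = None,
                  mean: str = "geometric") -> pd.DataFrame:
    """Aggregate Malmquist components by geometric (default) means.

    ``results`` is a list of :class:`MPIResult` or the frame produced by
    :func:`mpi_all_periods`. Geometric means preserve the multiplicative
    decomposition identities in every aggregate row; arithmetic means are
    available for table replication but do not. Incomplete rows are
    dropped. ``grouping`` is one of ``by-dmu``, ``by-period``,
    ``by-region`` (requires ``regions``) or ``overall``.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.as_dict() for r in results])
    if results.empty:
        raise ValueError("no MPI results to aggregate")
    df = results[results["complete"]].copy()
    if df.empty:
        raise ValueError("no complete MPI results to aggregate")
    if grouping == "by-dmu":
        keys = ["dmu"]
    elif grouping == "by-period":
        keys = ["period_from", "period_to"]
    elif grouping == "by-region":
        if regions is None:
            raise ValueError("by-region aggregation needs a region map")
        unmapped = sorted(set(df["dmu"]) - set(regions))
        if unmapped:
            raise ValueError(f"DMUs without region label: {unmapped}")
        df["region"] = df["dmu"].map(regions)
        keys = ["region", "period_from", "period_to"]
    elif grouping == "overall":
        keys = []
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    agg = _gmean if mean == "geometric" else np.mean
    if mean not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown mean {mean!r}")
    if not keys:
        row = {c: agg(df[c].to_numpy()) for c in _COMPONENTS}
        row["n_obs"] = len(df)
        return pd.DataFrame([row])
    grouped = df.groupby(keys, sort=True)
    out = grouped[_COMPONENTS].agg(lambda s: agg(s.to_numpy()))
    out["n_obs"] = grouped.size()
    return out.reset_index()
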