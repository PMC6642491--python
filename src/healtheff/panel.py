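"""Panel data model for DMU × period × indicator efficiency studies.

A :class:`PanelDataset` holds a dense, fully observed block of indicator
values for ``n`` decision-making units (DMUs, e.g. provinces) over ``T``
periods (years), together with an indicator registry assigning each column
an input or output role, and a region label per DMU. The module also
implements indicator derivation from raw counts (ratio indicators, per-1000
rates and percentage rates) and the pooled min–max rescaling that makes the
data strictly positive as required by DEA models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorSpec",
    "PanelDataset",
    "PanelSchemaError",
    "PanelIntegrityError",
    "read_panel_csv",
    "write_panel_csv",
    "derive_indicators",
    "normalize_minmax",
    "REGION_CODES",
]

REGION_CODES = frozenset({"E", "NE", "C", "W"})

#: float formatting used for all CSV output (12 significant digits keeps
#: round-trips lossless for values printed at that precision)
_FLOAT_FMT = "%.12g"


class PanelSchemaError(ValueError):
    """Raised when a CSV file does not match the declared panel schema."""


class PanelIntegrityError(ValueError):
    """Raised on duplicate or missing (dmu, period, indicator) cells."""


@dataclass(frozen=True)
class IndicatorSpec:
    """One input or output indicator.

    Parameters
    ----------
    code : str
        Short unique identifier (e.g. ``"PPP"``).
    name : str
        Free-text description.
    role : {"input", "output"}
        Whether the indicator enters the DEA technology as an input or
        an output.
    category : str
        Thematic grouping (expenditure, health-institution, ...).
    formula : str
        Textual definition (numerator / denominator / scale).
    """

    code: str
    name: str = ""
    role: str = "output"
    category: str = ""
    formula: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("input", "output"):
            raise ValueError(f"role must be 'input' or 'output', got {self.role!r}")


#: Registry for the rural health-expenditure application: two expenditure
#: inputs and eleven service-capacity / utilization outputs.
DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("PPP", "Healthcare expenditure per capita (yuan)", "input",
                  "expenditure", "total rural health expenditure / rural population"),
    IndicatorSpec("EXP", "Total expenditure on health (% GDP)", "input",
                  "expenditure", "total rural health expenditure / GDP x 100%"),
    IndicatorSpec("NC", "Village clinics per 1000 rural population", "output",
                  "health-institution", "village clinics / rural population x 1000"),
    IndicatorSpec("NTHC", "Township health centers per 1000 rural population", "output",
                  "health-institution", "township health centers / rural population x 1000"),
    IndicatorSpec("DA", "Village doctors and assistants per 1000 rural population", "output",
                  "health-personnel", "village doctors and assistants / rural population x 1000"),
    IndicatorSpec("DTH", "Doctors of township health centers per 1000 rural population", "output",
                  "health-personnel", "THC doctors / rural population x 1000"),
    IndicatorSpec("LDT", "Licensed (assistant) doctors of THCs per 1000 rural population", "output",
                  "health-personnel", "THC licensed doctors / rural population x 1000"),
    IndicatorSpec("RNT", "Registered nurses of THCs per 1000 rural population", "output",
                  "health-personnel", "THC registered nurses / rural population x 1000"),
    IndicatorSpec("BED", "Beds per 1000 rural population", "output",
                  "health-facility", "beds of medical institutions / rural population x 1000"),
    IndicatorSpec("NV", "Outpatients per 1000 rural population", "output",
                  "utilization", "THC outpatients / rural population x 1000"),
    IndicatorSpec("NI", "Inpatients per 1000 rural population", "output",
                  "utilization", "THC inpatients / rural population x 1000"),
    IndicatorSpec("UB", "Utilization rate of beds (%)", "output",
                  "utilization", "actual bed-days used / actual available bed-days x 100%"),
    IndicatorSpec("ADH", "Average duration of hospitalization (days)", "output",
                  "utilization", "bed-days of discharged persons / discharged persons"),
)


@dataclass
class PanelDataset:
    """Dense (dmu, period, indicator) panel with roles and region labels.

    Attributes
    ----------
    dmu_ids : list of str
        Ordered DMU labels; defines the row order of every derived matrix.
    periods : list of int
        Strictly increasing period labels (years).
    indicators : list of IndicatorSpec
        Column registry; codes must be unique.
    values : ndarray, shape (n_dmus, n_periods, n_indicators)
        Fully observed value block.
    regions : dict
        DMU label -> region code in {E, NE, C, W}.
    """

    dmu_ids: list[str]
    periods: list[int]
    indicators: list[IndicatorSpec]
    values: np.ndarray
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, T, p = len(self.dmu_ids), len(self.periods), len(self.indicators)
        if self.values.shape != (n, T, p):
            raise PanelIntegrityError(
                f"values shape {self.values.shape} != ({n}, {T}, {p})")
        if len(set(self.dmu_ids)) != n:
            raise PanelIntegrityError("duplicate DMU labels")
        codes = [s.code for s in self.indicators]
        if len(set(codes)) != p:
            raise PanelIntegrityError("duplicate indicator codes")
        if list(self.periods) != sorted(set(self.periods)):
            raise PanelIntegrityError("periods must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise PanelIntegrityError("missing or non-finite cells in panel")
        bad = set(self.regions.values()) - REGION_CODES
        if bad:
            raise PanelIntegrityError(
                f"invalid region codes {sorted(bad)}; allowed: E, NE, C, W")

    # -- basic introspection -------------------------------------------------

    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def indicator_codes(self) -> list[str]:
        return [s.code for s in self.indicators]

    @property
    def input_codes(self) -> list[str]:
        return [s.code for s in self.indicators if s.role == "input"]

    @property
    def output_codes(self) -> list[str]:
        return [s.code for s in self.indicators if s.role == "output"]

    def column(self, code: str) -> np.ndarray:
        """Values of one indicator, shape (n_dmus, n_periods)."""
        return self.values[:, :, self.indicator_codes.index(code)]

    def period_index(self, period: int) -> int:
        try:
            return self.periods.index(period)
        except ValueError:
            raise KeyError(f"period {period!r} not in panel") from None

    def input_output(self, period: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) for one period: m×n inputs and q×n outputs."""
        t = self.period_index(period)
        codes = self.indicator_codes
        xi = [codes.index(c) for c in self.input_codes]
        yi = [codes.index(c) for c in self.output_codes]
        sect = self.values[:, t, :]
        return sect[:, xi].T.copy(), sect[:, yi].T.copy()

    def region_of(self, dmu: str) -> str:
        if dmu not in self.regions:
            raise KeyError(f"no region label for DMU {dmu!r}")
        return self.regions[dmu]

    # -- frames --------------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with columns dmu, region, period, indicator, value."""
        n, T, p = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.dmu_ids, self.periods, self.indicator_codes],
            names=["dmu", "period", "indicator"])
        df = pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()
        df.insert(1, "region", df["dmu"].map(self.regions))
        return df

    def to_wide(self) -> pd.DataFrame:
        """Wide frame: one row per (dmu, period), one column per indicator."""
        long = self.to_long()
        wide = long.pivot_table(index=["dmu", "region", "period"], columns="indicator",
                                values="value", sort=False).reset_index()
        wide.columns.name = None
        return wide[["dmu", "region", "period"] + self.indicator_codes]

    @classmethod
    def from_arrays(cls, X: np.ndarray, Y: np.ndarray,
                    dmu_ids: list[str] | None = None,
                    periods: list[int] | None = None,
                    regions: dict[str, str] | None = None) -> "PanelDataset":
        """Build a panel from raw input/output arrays.

        Parameters
        ----------
        X : ndarray, shape (n, T, m)
        Y : ndarray, shape (n, T, q)
        """
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if X.shape[:2] != Y.shape[:2]:
            raise PanelIntegrityError("X and Y disagree on (n_dmus, n_periods)")
        n, T, m = X.shape
        q = Y.shape[2]
        dmu_ids = dmu_ids or [f"DMU{i + 1:02d}" for i in range(n)]
        periods = periods or list(range(1, T + 1))
        specs = ([IndicatorSpec(f"X{i + 1}", role="input") for i in range(m)]
                 + [IndicatorSpec(f"Y{r + 1}", role="output") for r in range(q)])
        values = np.concatenate([X, Y], axis=2)
        return cls(dmu_ids, list(periods), specs, values, regions or {})


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_LONG_COLS = ["dmu", "region", "period", "indicator", "value"]


import re

_INPUT_CODE = re.compile(r"^X\d+$")  # from_arrays / synthetic input convention


def _specs_for(codes: list[str], roles: dict[str, str] | None) -> list[IndicatorSpec]:
    known = {s.code: s for s in DEFAULT_INDICATORS}
    specs = []
    for c in codes:
        if roles and c in roles:
            specs.append(IndicatorSpec(c, role=roles[c]))
        elif c in known:
            specs.append(known[c])
        elif _INPUT_CODE.match(c):
            specs.append(IndicatorSpec(c, role="input"))
        else:
            specs.append(IndicatorSpec(c, role="output"))
    return specs


def read_panel_csv(path, schema: str = "wide",
                   roles: dict[str, str] | None = None) -> PanelDataset:
    """Read a panel CSV in ``long`` or ``wide`` dialect.

    Long schema columns: dmu, region, period, indicator, value.
    Wide schema columns: dmu, region, period, then one column per indicator.

    Indicator roles are taken from ``roles`` (code -> "input"/"output"),
    falling back to the default rural-health registry for known codes and
    to "output" otherwise.
    """
    if schema not in ("long", "wide"):
        raise PanelSchemaError(f"schema must be 'long' or 'wide', got {schema!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise PanelSchemaError(f"{path}: empty file") from None
    if schema == "long":
        missing = [c for c in _LONG_COLS if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"{path}: missing columns {missing}")
        long = df[_LONG_COLS].copy()
    else:
        for c in ("dmu", "region", "period"):
            if c not in df.columns:
                raise PanelSchemaError(f"{path}: missing column {c!r}")
        ind_cols = [c for c in df.columns if c not in ("dmu", "region", "period")]
        if not ind_cols:
            raise PanelSchemaError(f"{path}: no indicator columns")
        long = df.melt(id_vars=["dmu", "region", "period"], value_vars=ind_cols,
                       var_name="indicator", value_name="value")

    long["value"] = pd.to_numeric(long["value"], errors="raise")
    long["period"] = long["period"].astype(int)
    dup = long.duplicated(["dmu", "period", "indicator"])
    if dup.any():
        first = long.loc[dup.idxmax(), ["dmu", "period", "indicator"]].tolist()
        raise PanelIntegrityError(f"{path}: duplicate cell {tuple(first)}")

    dmu_ids = list(pd.unique(long["dmu"]))
    periods = sorted(long["period"].unique().tolist())
    codes = list(pd.unique(long["indicator"]))
    regions = (long.drop_duplicates("dmu").set_index("dmu")["region"]
               .dropna().astype(str).to_dict())

    cube = long.pivot_table(index="dmu", columns=["period", "indicator"],
                            values="value", sort=False)
    full = pd.MultiIndex.from_product([periods, codes])
    if cube.isna().any().any() or not full.isin(cube.columns).all():
        raise PanelIntegrityError(f"{path}: missing cells in panel")
    cube = cube.reindex(index=dmu_ids, columns=full)
    values = cube.values.reshape(len(dmu_ids), len(periods), len(codes))
    return PanelDataset(dmu_ids, periods, _specs_for(codes, roles), values, regions)


def write_panel_csv(dataset: PanelDataset, path, schema: str = "wide") -> None:
    """Write a panel to CSV in the requested dialect (12 significant digits)."""
    if schema not in ("long", "wide"):
        raise PanelSchemaError(f"schema must be 'long' or 'wide', got {schema!r}")
    frame = dataset.to_long() if schema == "long" else dataset.to_wide()
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Indicator derivation from raw counts
# ---------------------------------------------------------------------------

#: indicator -> (numerator column, denominator column, scale factor)
_DERIVATIONS = {
    "PPP": ("health_expenditure", "rural_population", 1.0),
    "EXP": ("health_expenditure", "gdp", 100.0),
    "NC": ("village_clinics", "rural_population", 1000.0),
    "NTHC": ("township_health_centers", "rural_population", 1000.0),
    "DA": ("village_doctors", "rural_population", 1000.0),
    "DTH": ("thc_doctors", "rural_population", 1000.0),
    "LDT": ("thc_licensed_doctors", "rural_population", 1000.0),
    "RNT": ("thc_registered_nurses", "rural_population", 1000.0),
    "BED": ("beds", "rural_population", 1000.0),
    "NV": ("outpatients", "rural_population", 1000.0),
    "NI": ("inpatients", "rural_population", 1000.0),
    "UB": ("bed_days_used", "bed_days_available", 100.0),
    "ADH": ("discharge_bed_days", "discharged_persons", 1.0),
}


def derive_indicators(raw: pd.DataFrame) -> PanelDataset:
    """Compute the registry indicators from a raw-counts table.

    ``raw`` has one row per (dmu, period) with columns ``dmu``, ``region``,
    ``period`` and the raw numerators/denominators named in the derivation
    table (expenditure, population, facility and personnel counts, bed-day
    tallies). Per-1000 indicators are scaled by 1000, the bed utilization
    rate by 100 (%), and simple ratios left unscaled.
    """
    needed = {c for num_den in _DERIVATIONS.values() for c in num_den[:2]}
    missing = sorted(needed - set(raw.columns))
    if missing:
        raise PanelSchemaError(f"raw table missing columns {missing}")
    out = raw[["dmu", "region", "period"]].copy()
    for code, (num, den, scale) in _DERIVATIONS.items():
        d = raw[den].to_numpy(float)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise ValueError(
                f"zero/negative denominator {den!r} for DMU "
                f"{raw['dmu'].iloc[i]!r}, period {raw['period'].iloc[i]!r}")
        out[code] = raw[num].to_numpy(float) / d * scale
    import io

    buf = io.StringIO()
    out.to_csv(buf, index=False)
    buf.seek(0)
    return read_panel_csv(buf, schema="wide")


# ---------------------------------------------------------------------------
# Min–max normalization
# ---------------------------------------------------------------------------

def normalize_minmax(dataset: PanelDataset, lower: float = 0.1,
                     upper: float = 1.0) -> PanelDataset:
    """Affinely rescale each indicator to [lower, upper], pooled over the panel.

    Min and max are taken over all DMUs and periods jointly so that
    cross-period distance functions compare commensurable data. Constant
    columns map to ``upper``. ``lower`` must be strictly positive because
    the SBM objective divides by the evaluated DMU's data.
    """
    if not (upper > lower > 0):
        raise ValueError(f"need upper > lower > 0, got [{lower}, {upper}]")
    vals = dataset.values.copy()
    for j in range(vals.shape[2]):
        col = vals[:, :, j]
        lo, hi = col.min(), col.max()
        if hi - lo < 1e-300:
            vals[:, :, j] = upper
        else:
            vals[:, :, j] = lower + (col - lo) * (upper - lower) / (hi - lo)
    return replace(dataset, values=vals)
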