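"""Synthetic efficiency panels with known frontier, inefficiency and drift.

The generator emulates the statistical structure the analysis pipeline
assumes: a balanced panel of DMUs observed over several periods, strictly
positive inputs, a Cobb–Douglas production frontier with Hicks-neutral
technical change, DMU-specific half-normal inefficiency, and a block of
correlated output indicators driven by a small number of latent factors
(the first of which is the aggregate frontier output), so that Kaiser
selection on the indicator correlation matrix recovers the latent factor
count.

The data-generating process for DMU j in period t is

    y*_jt = A_t · Π_i x_ijt^{β_i} · exp(−u_jt),   A_{t+1} = (1 + γ) A_t,
    u_jt ~ |N(0, σ_u²)|  (u = 0 for at least one DMU per period),

with inputs drawn log-uniformly. Observable indicators are softplus
transforms of latent-factor combinations plus Gaussian noise: positive,
monotone in their factor, and correlated within factor blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import IndicatorSpec, PanelDataset

__all__ = ["SyntheticConfig", "SyntheticPanel", "generate_panel", "known_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating parameters; ``seed`` is mandatory.

    Defaults mirror the target application's panel shape: 31 DMUs × 10
    periods, 2 inputs, 11 output indicators driven by 4 latent factors.
    ``beta`` are the Cobb–Douglas exponents (Σβ < 1 gives a strictly
    concave, VRS-consistent frontier; Σβ = 1 gives CRS); ``sigma_u`` the
    half-normal inefficiency scale; ``sigma_e`` indicator measurement
    noise; ``gamma`` the per-period Hicks-neutral technical-change rate.
    """

    seed: int
    n_dmus: int = 31
    n_periods: int = 10
    n_inputs: int = 2
    n_output_indicators: int = 11
    n_latent_factors: int = 4
    beta: tuple[float, ...] | None = None
    sigma_u: float = 0.3
    sigma_e: float = 0.5
    gamma: float = 0.03
    input_range: tuple[float, float] = (1.0, 10.0)
    A0: float = 1.0
    ensure_frontier_dmu: bool = True

    def __post_init__(self) -> None:
        if self.beta is None:
            object.__setattr__(self, "beta",
                               tuple([0.8 / self.n_inputs] * self.n_inputs))
        if len(self.beta) != self.n_inputs:
            raise ValueError("beta length must equal n_inputs")
        if any(b <= 0 for b in self.beta):
            raise ValueError("frontier exponents must be positive")
        if min(self.sigma_u, self.sigma_e) < 0 or self.gamma < -1:
            raise ValueError("scales must be >= 0 and gamma > -1")
        if self.n_latent_factors > self.n_output_indicators:
            raise ValueError("more latent factors than indicators")


@dataclass
class SyntheticPanel:
    """A generated panel together with its ground truth."""

    dataset: PanelDataset
    inputs: np.ndarray  # (n, T, m)
    aggregate_output: np.ndarray  # (n, T) frontier output y*
    true_efficiency: np.ndarray  # (n, T) exp(-u) in (0, 1]
    frontier_levels: np.ndarray  # (T,) A_t
    beta: tuple[float, ...]
    factor_loadings: np.ndarray  # (p_out, n_factors)
    config: SyntheticConfig

    def aggregate_dataset(self) -> PanelDataset:
        """Panel with the true aggregate output y* as the single output
        (the noise-free design used for frontier-recovery checks)."""
        return PanelDataset.from_arrays(
            self.inputs, self.aggregate_output[:, :, None],
            dmu_ids=self.dataset.dmu_ids, periods=self.dataset.periods,
            regions=self.dataset.regions)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _block_loadings(p_out: int, n_factors: int, rng: np.random.Generator) -> np.ndarray:
    """Each indicator loads 1.0 on its block's factor (blocks as equal as
    possible), plus a small cross-loading to keep the structure realistic."""
    L = np.zeros((p_out, n_factors))
    blocks = np.array_split(np.arange(p_out), n_factors)
    for f, idx in enumerate(blocks):
        L[idx, f] = 1.0
    L += rng.uniform(-0.1, 0.1, size=L.shape) * (L == 0)
    return L


def generate_panel(config: SyntheticConfig) -> SyntheticPanel:
    """Draw one synthetic panel; identical seeds give identical panels."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T, m = cfg.n_dmus, cfg.n_periods, cfg.n_inputs
    p_out, F = cfg.n_output_indicators, cfg.n_latent_factors

    lo, hi = cfg.input_range
    X = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, T, m)))
    u = np.abs(rng.normal(0.0, cfg.sigma_u, size=(n, T))) if cfg.sigma_u > 0 \
        else np.zeros((n, T))
    if cfg.ensure_frontier_dmu:
        u[np.argmin(u, axis=0), np.arange(T)] = 0.0

    A = cfg.A0 * (1.0 + cfg.gamma) ** np.arange(T)
    frontier = A[None, :] * np.prod(X ** np.asarray(cfg.beta)[None, None, :], axis=2)
    y_star = frontier * np.exp(-u)

    # latent factors per (dmu, period) observation; factor 0 tracks y*
    log_y = np.log(y_star).reshape(-1)
    f0 = (log_y - log_y.mean()) / (log_y.std() or 1.0)
    factors = np.column_stack(
        [f0] + [rng.normal(size=n * T) for _ in range(F - 1)])
    loadings = _block_loadings(p_out, F, rng)
    lin = 2.0 + factors @ loadings.T
    if cfg.sigma_e > 0:
        lin = lin + rng.normal(0.0, cfg.sigma_e, size=lin.shape)
    indicators = _softplus(lin).reshape(n, T, p_out)

    dmu_ids = [f"DMU{i + 1:02d}" for i in range(n)]
    periods = list(range(1, T + 1))
    regions = {d: code for d, code in
               zip(dmu_ids, np.tile(["E", "NE", "C", "W"], n)[:n])}
    specs = ([IndicatorSpec(f"X{i + 1}", role="input") for i in range(m)]
             + [IndicatorSpec(f"O{r + 1:02d}", role="output") for r in range(p_out)])
    values = np.concatenate([X, indicators], axis=2)
    dataset = PanelDataset(dmu_ids, periods, specs, values, regions)
    return SyntheticPanel(dataset, X, y_star, np.exp(-u), A, cfg.beta,
                          loadings, cfg)


def known_truth(panel: SyntheticPanel) -> dict:
    """Ground-truth quantities the estimators should recover.

    ``true_efficiency`` is exp(−u); ``expected_techch`` is 1 + γ, the
    frontier-shift factor any CRS Malmquist run on the noise-free
    aggregate output should attribute to techch.
    """
    return {
        "true_efficiency": panel.true_efficiency,
        "expected_techch": 1.0 + panel.config.gamma,
        "frontier_levels": panel.frontier_levels,
        "beta": panel.beta,
    }
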