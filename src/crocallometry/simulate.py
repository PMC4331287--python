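"""Synthetic calibration panels with the statistical structure the chain assumes.

Real calibration data for the estimation chain are (a) an ontogenetic series
of a single broad-snouted caiman species measured for skull length,
snout-vent length and total length, and (b) a cross-species panel of extant
crocodilians measured for total length, body mass and bite force. The
generators here emulate those panels statistically — power-law relationships
``log10 y = a + b log10 x + Normal(0, noise_sd)`` with log-uniformly sampled
predictors over realistic crocodilian size ranges — without reproducing any
actual measurement. They exist so every pipeline stage (file I/O, fitting,
bootstrap, chaining) is testable end-to-end with known ground truth.

Defaults: generating coefficients equal the published chain coefficients;
log10 residual sd 0.05; skull lengths spanning 20-700 mm, the extant range —
so a 1400 mm fossil skull is, as in the real analysis, an extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import PUBLISHED_COEFFICIENTS, STAGES
from .io import CalibrationTable, MeasurementRecord

__all__ = ["PanelSpec", "simulate_relationship", "simulate_crocodilian_panel"]

#: Default log10 residual standard deviation of generated relationships.
DEFAULT_NOISE_SD = 0.05
#: Extant-range skull lengths (mm) spanned by the single-species series.
DEFAULT_DCL_RANGE = (20.0, 700.0)
#: Total-length range (cm) spanned by the cross-species panel.
DEFAULT_TTL_RANGE = (30.0, 600.0)


@dataclass(frozen=True)
class PanelSpec:
    """Generating recipe for one synthetic power-law relationship.

    ``true_a``/``true_b`` are the generating log10 intercept and slope;
    ``noise_sd`` the log10 residual sd; ``x_range`` the natural-scale
    predictor range sampled log-uniformly; ``missing_rate`` the fraction of
    response cells blanked when the relationship is embedded in a table.
    """

    n: int
    true_a: float
    true_b: float
    noise_sd: float = DEFAULT_NOISE_SD
    x_range: tuple[float, float] = DEFAULT_DCL_RANGE
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.x_range
        if not 0 < lo < hi:
            raise ValueError("x_range must satisfy 0 < min < max")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_relationship(spec: PanelSpec) -> np.ndarray:
    """Draw ``(x, y)`` pairs from the spec's power law; shape ``(n, 2)``.

    ``x`` is log-uniform over ``x_range`` so leverage is spread evenly across
    the size range on the scale the regression is fitted on; ``log10 y`` adds
    Normal(0, noise_sd) scatter about the generating line. Deterministic per
    seed; all outputs strictly positive by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.x_range
    log_x = rng.uniform(np.log10(lo), np.log10(hi), size=spec.n)
    log_y = spec.true_a + spec.true_b * log_x
    if spec.noise_sd > 0:
        log_y = log_y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return np.column_stack([10.0**log_x, 10.0**log_y])


def _chain_columns(
    rng: np.random.Generator,
    n: int,
    start_role: str,
    x_range: tuple[float, float],
    noise_sd: float,
) -> dict[str, np.ndarray]:
    """Columns for consecutive chain roles, each generated from the last."""
    log_x = rng.uniform(np.log10(x_range[0]), np.log10(x_range[1]), size=n)
    columns = {start_role: 10.0**log_x}
    stage_map = dict(STAGES)
    role = start_role
    while role in stage_map:
        y_role = stage_map[role]
        c = PUBLISHED_COEFFICIENTS[(role, y_role)]
        log_y = (
            c["intercept"]
            + c["slope"] * log_x
            + rng.normal(0.0, noise_sd, size=n)
        )
        columns[y_role] = 10.0**log_y
        log_x, role = log_y, y_role
    return columns


def _blank_cells(
    rng: np.random.Generator,
    columns: dict[str, np.ndarray],
    keep_role: str,
    missing_rate: float,
) -> list[MeasurementRecord]:
    n = len(next(iter(columns.values())))
    records = []
    for i in range(n):
        kwargs: dict[str, object] = {"specimen_id": f"SYN{i + 1:03d}"}
        for role, values in columns.items():
            if (
                role != keep_role
                and missing_rate > 0
                and rng.random() < missing_rate
            ):
                continue
            kwargs[role] = float(values[i])
        records.append(MeasurementRecord(**kwargs))  # type: ignore[arg-type]
    return records


def simulate_crocodilian_panel(
    seed: int = 0,
    n_svl: int = 30,
    n_body: int = 23,
    noise_sd: float = DEFAULT_NOISE_SD,
    missing_rate: float = 0.0,
) -> tuple[CalibrationTable, CalibrationTable]:
    """Generate the two default calibration tables.

    Returns ``(svl_table, body_table)``: the first emulates a single-species
    ontogenetic series with (dcl, svl, ttl) over skull lengths 20-700 mm;
    the second a 23-row cross-species panel with (ttl, bm, bf). Downstream
    columns are generated through the chain so that within-table
    relationships carry the published coefficients with lognormal scatter.
    """
    rng = np.random.default_rng(seed)
    truncate = {"dcl", "svl", "ttl"}
    svl_cols = {
        role: values
        for role, values in _chain_columns(
            rng, n_svl, "dcl", DEFAULT_DCL_RANGE, noise_sd
        ).items()
        if role in truncate
    }
    body_cols = _chain_columns(rng, n_body, "ttl", DEFAULT_TTL_RANGE, noise_sd)
    svl_table = CalibrationTable(
        _blank_cells(rng, svl_cols, "dcl", missing_rate),
        source_label=f"synthetic single-species series (seed={seed})",
    )
    body_table = CalibrationTable(
        _blank_cells(rng, body_cols, "ttl", missing_rate),
        source_label=f"synthetic cross-species panel (seed={seed})",
    )
    return svl_table, body_table
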