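"""Synthetic dose-response generator with known monotherapy curves, an
injectable interaction effect and Gaussian replicate noise.

Expectations are built on the inhibition fraction scale: margins follow the
two monotherapy logistics exactly, combination cells follow the chosen
reference-model expectation plus ``delta`` (clipped to [0, 1] *before*
noise; noisy observations are not clipped, mirroring how raw screening
data retain out-of-range values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import MonotherapyCurve
from .io_data import (
    CrossDesignRecord,
    DoseResponseMatrix,
    ResponseRecord,
    build_matrix,
    extract_cross,
)

INTERACTION_MODELS = ("bliss", "hsa", "loewe")

#: replicate noise sd on the inhibition fraction scale (typical matrix-screen
#: replicate variability of ~6.6% inhibition)
DEFAULT_NOISE_SD = 0.066


def logistic_curve(a: float, b: float, c: float,
                   conc_range: tuple[float, float] = (-2.0, 2.0)) -> MonotherapyCurve:
    """Construct a monotherapy curve from known parameters (no fitting)."""
    return MonotherapyCurve(a=a, b=b, c=c, conc_range=conc_range)


def _default_grid() -> tuple[float, ...]:
    """Zero dose plus 9 log-spaced concentrations spanning 1e-2 .. 1e2.

    An odd count keeps the default IC50 (concentration 1) on the grid, so
    the cross extraction anchors exactly instead of tie-breaking.
    """
    return (0.0,) + tuple(np.logspace(-2, 2, 9))


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated drug-pair block."""

    mono1: tuple[float, float, float] = (0.8, 1.0, 0.0)   # (a, b, c)
    mono2: tuple[float, float, float] = (0.8, 1.0, 0.0)
    grid1: tuple[float, ...] = field(default_factory=_default_grid)
    grid2: tuple[float, ...] = field(default_factory=_default_grid)
    interaction_model: str = "bliss"
    delta: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 4
    seed: int = 0
    block_id: str = "sim-1"
    drug_row: str = "drug1"
    drug_col: str = "drug2"
    cell_line: str = "sim-cell"

    def __post_init__(self):
        if self.interaction_model not in INTERACTION_MODELS:
            raise ValueError(f"unknown interaction model {self.interaction_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if tuple(sorted(self.grid1)) != tuple(self.grid1) or \
           tuple(sorted(self.grid2)) != tuple(self.grid2):
            raise ValueError("grids must be sorted ascending")

    def curves(self) -> tuple[MonotherapyCurve, MonotherapyCurve]:
        pos1 = [c for c in self.grid1 if c > 0]
        pos2 = [c for c in self.grid2 if c > 0]
        r1 = (np.log10(min(pos1)), np.log10(max(pos1)))
        r2 = (np.log10(min(pos2)), np.log10(max(pos2)))
        return (logistic_curve(*self.mono1, conc_range=r1),
                logistic_curve(*self.mono2, conc_range=r2))


def _mono_fraction(curve: MonotherapyCurve, conc: float) -> float:
    return 0.0 if conc == 0 else float(curve.predict_conc(conc))


def expected_inhibition(spec: SimSpec) -> np.ndarray:
    """Noise-free expectation grid (fractions), rows = grid1, cols = grid2."""
    curve1, curve2 = spec.curves()
    n1, n2 = len(spec.grid1), len(spec.grid2)
    grid = np.zeros((n1, n2))
    for i, x1 in enumerate(spec.grid1):
        for j, x2 in enumerate(spec.grid2):
            y1 = _mono_fraction(curve1, x1)
            y2 = _mono_fraction(curve2, x2)
            if x1 == 0 and x2 == 0:
                y = 0.0
            elif x2 == 0:
                y = y1
            elif x1 == 0:
                y = y2
            else:
                if spec.interaction_model == "bliss":
                    base = y1 + y2 - y1 * y2
                elif spec.interaction_model == "hsa":
                    base = max(y1, y2)
                else:  # loewe: mean evaluation of the summed dose
                    base = 0.5 * (float(curve1.predict_conc(x1 + x2))
                                  + float(curve2.predict_conc(x1 + x2)))
                y = float(np.clip(base + spec.delta, 0.0, 1.0))
            grid[i, j] = y
    return grid


def simulate_matrix(spec: SimSpec) -> list[ResponseRecord]:
    """Long-format records for the full factorial grid with replicates.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    expect = expected_inhibition(spec)
    records = []
    for i, x1 in enumerate(spec.grid1):
        for j, x2 in enumerate(spec.grid2):
            for rep in range(1, spec.n_replicates + 1):
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                records.append(ResponseRecord(
                    block_id=spec.block_id,
                    drug_row=spec.drug_row,
                    drug_col=spec.drug_col,
                    conc_row=float(x1),
                    conc_col=float(x2),
                    response=100.0 * (expect[i, j] + noise),
                    cell_line=spec.cell_line,
                    replicate=rep,
                ))
    return records


def simulate_matrix_grid(spec: SimSpec) -> DoseResponseMatrix:
    """Convenience: simulate and average replicates into a matrix."""
    return build_matrix(simulate_matrix(spec))


def simulate_cross(spec: SimSpec) -> CrossDesignRecord:
    """Simulate the full matrix, then extract the cross at the true IC50s
    (``10**c`` of each generating monotherapy curve)."""
    matrix = simulate_matrix_grid(spec)
    ic50_1 = 10.0 ** spec.mono1[2]
    ic50_2 = 10.0 ** spec.mono2[2]
    return extract_cross(matrix, ic50_1, ic50_2)


def replicate_spec(spec: SimSpec, seed: int) -> SimSpec:
    """The same block regenerated under a different random seed."""
    return replace(spec, seed=seed, block_id=f"{spec.block_id}-s{seed}")
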