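"""Synthetic scratch-wound data with known ground truth.

The generators reproduce the statistical shape of scratch-assay data —
not the cell biology — so every downstream stage can be validated
against known truth:

* closure curves: gap percent pinned to 100 at t = 0, declining linearly
  at a phase-1 rate and, for biphasic courses, switching to a faster
  phase-2 rate at a breakpoint on the sampling grid. Default parameter
  ranges mirror corneal epithelial cultures (phase-1 rates of roughly
  3-6 %/h, phase-2 rates of 14-17 %/h, 3-h sampling). Measurement noise
  is additive Gaussian on the percent scale, clipped at 0; its default
  SD of 2 percentage points is a stipulation, exposed as a parameter.
* cell fields: uniformly seeded monolayer flanking a central cell-free
  gap, with marker positivity probability that depends on whether the
  cell lies within a fixed band of the nearest wound edge.
* debridement geometries: straight original-edge / front pairs whose
  separation is drawn from a zero-truncated Gaussian, so measured
  migration equals the drawn displacement exactly per cornea.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.stats

from .edge_band import CellRecord, EdgeGeometry
from .errors import InvalidInputError, ParameterizationError
from .kinetics import ClosureSeries

__all__ = [
    "SyntheticTruth",
    "simulate_closure",
    "simulate_cell_field",
    "simulate_debridement",
]

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a simulated closure experiment.

    ``k1``/``k2`` are decline rates in delta-percent per hour; ``k2`` and
    ``breakpoint_h`` are present together (biphasic) or absent together
    (monophasic). ``noise_sd`` is in percentage points. The default 3-h
    sampling over 24 h matches routine time-lapse scratch assays.
    """

    k1: float
    k2: Optional[float] = None
    breakpoint_h: Optional[float] = None
    noise_sd: float = 2.0
    dt_h: float = 3.0
    t_max_h: float = 24.0
    floor_pct: float = 2.0
    n_replicates: int = 3
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ParameterizationError("k1 must be positive for a closing wound")
        if (self.k2 is None) != (self.breakpoint_h is None):
            raise ParameterizationError("k2 and breakpoint_h must be set together")
        if self.noise_sd < 0:
            raise ParameterizationError("noise_sd must be >= 0")
        if self.dt_h <= 0 or self.t_max_h < self.dt_h:
            raise ParameterizationError("need 0 < dt_h <= t_max_h")
        if self.n_replicates < 1:
            raise ParameterizationError("n_replicates must be >= 1")
        if self.breakpoint_h is not None:
            ratio = self.breakpoint_h / self.dt_h
            if abs(ratio - round(ratio)) > _GRID_TOL:
                raise ParameterizationError("breakpoint_h must lie on the sampling grid")
            if self.k2 is not None and self.k2 <= 0:
                raise ParameterizationError("k2 must be positive")

    def noiseless(self, times: np.ndarray) -> np.ndarray:
        """The generative hinge curve (no noise, no clipping)."""
        t = np.asarray(times, dtype=float)
        y = 100.0 - self.k1 * t
        if self.breakpoint_h is not None:
            tb = self.breakpoint_h
            y = np.where(t > tb, 100.0 - self.k1 * tb - self.k2 * (t - tb), y)
        return y


def simulate_closure(truth: SyntheticTruth) -> List[ClosureSeries]:
    """Simulate replicate closure curves under ``truth``.

    Sampling runs at 0, dt, 2 dt, ... and stops at ``t_max_h`` or at the
    first grid time where the noiseless curve has reached 0 (that closure
    sample is kept, clipped to 0). Gaussian noise of SD ``noise_sd`` is
    added to every point, values are clipped below at 0, and the t = 0
    point is re-pinned to exactly 100, mirroring the normalization
    convention of the assay.
    """
    n_grid = int(np.floor(truth.t_max_h / truth.dt_h + _GRID_TOL)) + 1
    grid = np.arange(n_grid) * truth.dt_h
    clean = truth.noiseless(grid)
    if clean[1] < 0:
        raise ParameterizationError(
            "rates drive the gap negative before the first sample"
        )
    closed = np.nonzero(clean <= 0)[0]
    end = int(closed[0]) + 1 if closed.size else n_grid
    times = grid[:end]
    clean = clean[:end]
    rng = np.random.default_rng(truth.seed)
    out = []
    for r in range(truth.n_replicates):
        noise = rng.normal(0.0, truth.noise_sd, size=times.size) if truth.noise_sd else 0.0
        pct = np.clip(clean + noise, 0.0, None)
        pct[0] = 100.0
        out.append(
            ClosureSeries(
                condition=truth.condition,
                replicate=f"r{r + 1}",
                times=times.copy(),
                gap_pct=pct,
            )
        )
    return out


def simulate_cell_field(
    n_cells: int,
    gap_halfwidth_um: float,
    p_in_band: float,
    p_out_band: float,
    seed: int,
    band_um: float = 100.0,
    field_width_um: float = 1200.0,
    field_height_um: float = 900.0,
    image_id: str = "field",
    marker: str = "EdU",
) -> Tuple[List[CellRecord], List[EdgeGeometry], Dict[str, float]]:
    """Simulate a wounded monolayer with edge-dependent marker positivity.

    Cells are uniform over the two monolayer slabs flanking a central
    vertical cell-free gap of half-width ``gap_halfwidth_um``; the two
    gap borders become front polylines. A cell is marker-positive with
    probability ``p_in_band`` when within ``band_um`` of the nearest
    edge, else ``p_out_band``. Returns the cells, the two edges, and the
    realized truth (counts and fractions actually drawn).
    """
    if n_cells < 1:
        raise InvalidInputError("n_cells must be positive")
    for name, p in (("p_in_band", p_in_band), ("p_out_band", p_out_band)):
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"{name} must be in [0, 1]")
    half_w = field_width_um / 2.0
    slab = half_w - gap_halfwidth_um
    if gap_halfwidth_um < 0 or slab <= 0:
        raise InvalidInputError("gap must be narrower than the field")
    if band_um >= slab:
        raise ParameterizationError("band is wider than the monolayer slab")
    x_left_edge = half_w - gap_halfwidth_um
    x_right_edge = half_w + gap_halfwidth_um
    rng = np.random.default_rng(seed)
    side = rng.integers(0, 2, size=n_cells)  # 0 = left slab, 1 = right slab
    u = rng.uniform(0.0, slab, size=n_cells)
    x = np.where(side == 0, x_left_edge - u, x_right_edge + u)
    y = rng.uniform(0.0, field_height_um, size=n_cells)
    # nearest-edge distance is the perpendicular offset into the slab
    dist = u
    in_band = dist <= band_um
    p = np.where(in_band, p_in_band, p_out_band)
    positive = rng.uniform(size=n_cells) < p
    cells = [
        CellRecord(
            image_id=image_id,
            x=float(x[i]),
            y=float(y[i]),
            marker=marker,
            positive=bool(positive[i]),
        )
        for i in range(n_cells)
    ]
    edges = [
        EdgeGeometry(
            image_id=image_id,
            edge_type="front",
            vertices=np.array([[xe, 0.0], [xe, field_height_um]]),
        )
        for xe in (x_left_edge, x_right_edge)
    ]
    n_in = int(in_band.sum())
    truth = {
        "p_in_band": p_in_band,
        "p_out_band": p_out_band,
        "band_um": band_um,
        "n_in_band": n_in,
        "n_positive_in_band": int(positive[in_band].sum()),
        "fraction_in_band": float(positive[in_band].mean()) if n_in else float("nan"),
        "n_out_band": int(n_cells - n_in),
        "fraction_out_band": float(positive[~in_band].mean())
        if n_in < n_cells
        else float("nan"),
    }
    return cells, edges, truth


def simulate_debridement(
    front_mean_um: float,
    front_sd_um: float,
    n_corneas: int,
    seed: int,
    edge_length_um: float = 300.0,
    image_prefix: str = "cornea",
) -> Tuple[List[Tuple[EdgeGeometry, EdgeGeometry]], np.ndarray]:
    """Simulate original-edge / wound-front pairs for debrided corneas.

    Each cornea gets a straight vertical original edge at x = 0 and a
    parallel front displaced by a zero-truncated Gaussian draw
    (mean ``front_mean_um``, SD ``front_sd_um``), so the measured
    migration distance recovers the drawn displacement exactly. Returns
    the (original, front) pairs and the true displacements.
    """
    if front_mean_um < 0:
        raise InvalidInputError("front_mean_um must be >= 0")
    if front_sd_um < 0:
        raise InvalidInputError("front_sd_um must be >= 0")
    if n_corneas < 1:
        raise InvalidInputError("n_corneas must be >= 1")
    rng = np.random.default_rng(seed)
    if front_sd_um == 0.0:
        d = np.full(n_corneas, float(front_mean_um))
    else:
        a = (0.0 - front_mean_um) / front_sd_um
        d = scipy.stats.truncnorm.rvs(
            a, np.inf, loc=front_mean_um, scale=front_sd_um,
            size=n_corneas, random_state=rng,
        )
    pairs = []
    for i in range(n_corneas):
        image_id = f"{image_prefix}{i + 1}"
        original = EdgeGeometry(
            image_id=image_id,
            edge_type="original",
            vertices=np.array([[0.0, 0.0], [0.0, edge_length_um]]),
        )
        front = EdgeGeometry(
            image_id=image_id,
            edge_type="front",
            vertices=np.array([[d[i], 0.0], [d[i], edge_length_um]]),
        )
        pairs.append((original, front))
    return pairs, d
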