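"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of (parameters, seed) and returns truth
labels alongside the data so downstream recovery tests are closed-loop.

The "paper-matched" measurement preset encodes the study conditions: n = 3
animals per age and sex, group-mean dermis volumes of 0.18 cm³ at P2 and
2.32 cm³ at P50 (male/female average), and a total-density ratio of
2**1.3128 / (2.32/0.18) ≈ 0.19275 between P50 and P2, so the zero-noise
tables reproduce the division-number estimate exactly.  Absolute densities
are free, order-of-magnitude-plausible parameters (the source reports them
only graphically); only the ratio is pinned algebraically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import morphometry

# --- paper-matched constants -------------------------------------------------
DV_P2_CM3 = 0.18
DV_P50_CM3 = 2.32
N_DIVISIONS = 1.3128
VOLUME_RATIO = DV_P50_CM3 / DV_P2_CM3
CELL_RATIO = 2.0**N_DIVISIONS
DENSITY_RATIO = CELL_RATIO / VOLUME_RATIO  # ≈ 0.19275

# plausible trunk dimensions (cm); depths back-solved from the target volumes
P2_LENGTH_CM, P2_WIDTH_CM = 2.5, 1.2
P50M_LENGTH_CM, P50M_WIDTH_CM, P50M_DV_CM3 = 6.2, 3.0, 2.45
P50F_LENGTH_CM, P50F_WIDTH_CM, P50F_DV_CM3 = 5.8, 2.8, 2.19

P2_DERMIS_DEPTH_CM = morphometry.depth_for_volume(
    P2_WIDTH_CM / 2.0, P2_LENGTH_CM, DV_P2_CM3
)
P50M_DERMIS_DEPTH_CM = morphometry.depth_for_volume(
    P50M_WIDTH_CM / 2.0, P50M_LENGTH_CM, P50M_DV_CM3
)
P50F_DERMIS_DEPTH_CM = morphometry.depth_for_volume(
    P50F_WIDTH_CM / 2.0, P50F_LENGTH_CM, P50F_DV_CM3
)

# free absolute density scale (cells/mm² of 60 µm section, total dermis at P2)
RHO_P2_TOTAL_PER_MM2 = 1200.0
LAYER_FRACTIONS = {"papillary": 0.45, "reticular": 0.35, "DWAT": 0.20}
N_REGIONS_SCORED = 30  # inter-HF regions per biological replicate


def gen_measurements(
    preset: str = "paper-matched",
    noise_cv: float = 0.0,
    seed: int = 0,
    n_animals: int = 3,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Body-measurement and density tables for ages {2, 50} x sex, n animals each.

    Multiplicative Gaussian noise with coefficient of variation ``noise_cv``
    is applied per animal and per field; at zero noise the group means hit the
    paper-matched targets exactly.  Returns (measurements, densities, truth).
    """
    if preset != "paper-matched":
        raise ValueError(f"unknown preset {preset!r}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)

    groups = [
        (2, "male", P2_LENGTH_CM, P2_WIDTH_CM, P2_DERMIS_DEPTH_CM),
        (2, "female", P2_LENGTH_CM, P2_WIDTH_CM, P2_DERMIS_DEPTH_CM),
        (50, "male", P50M_LENGTH_CM, P50M_WIDTH_CM, P50M_DERMIS_DEPTH_CM),
        (50, "female", P50F_LENGTH_CM, P50F_WIDTH_CM, P50F_DERMIS_DEPTH_CM),
    ]

    def jitter(base: float) -> float:
        if noise_cv == 0:
            return base
        return base * max(0.05, 1.0 + noise_cv * rng.standard_normal())

    meas_rows = []
    for age, sex, length, width, depth in groups:
        for _ in range(n_animals):
            meas_rows.append(
                {
                    "age_days": age,
                    "sex": sex,
                    "length_cm": jitter(length),
                    "width_cm": jitter(width),
                    "dermis_depth_cm": jitter(depth),
                }
            )
    measurements = pd.DataFrame(meas_rows)

    rho = {2: RHO_P2_TOTAL_PER_MM2, 50: RHO_P2_TOTAL_PER_MM2 * DENSITY_RATIO}
    dens_rows = []
    for age in (2, 50):
        for layer, frac in [("total", 1.0)] + list(LAYER_FRACTIONS.items()):
            for _ in range(n_animals):
                dens_rows.append(
                    {
                        "age_days": age,
                        "layer": layer,
                        "rho_per_mm2": jitter(rho[age] * frac),
                        "n_regions": N_REGIONS_SCORED,
                    }
                )
    densities = pd.DataFrame(dens_rows)

    truth = {
        "dv_p2_cm3": DV_P2_CM3,
        "dv_p50_cm3": DV_P50_CM3,
        "volume_ratio": VOLUME_RATIO,
        "density_ratio": DENSITY_RATIO,
        "n_divisions": N_DIVISIONS,
        "noise_cv": noise_cv,
        "seed": seed,
    }
    return measurements, densities, truth


@dataclass(frozen=True)
class CloneSpec:
    """Labelled-clone layout for a synthetic whole-mount.

    cells_per_clone may be an int or an inclusive (lo, hi) range; spread_um is
    the Gaussian sd of member xy-offsets around the founder (0 = co-located
    young tissue, large = dispersed expanded tissue).  Founders are placed with
    a minimum mutual separation (rejection sampling), emulating the sparse
    one-founder-per-inter-HF-region labelling design; set
    min_founder_separation_um=0 for fully random founders.
    """

    n_clones: int = 10
    cells_per_clone: Tuple[int, int] | int = (4, 8)
    spread_um: float = 30.0
    min_founder_separation_um: float = 300.0
    marker_probs: Tuple[Tuple[str, float], ...] = (
        ("ki67", 0.02),
        ("ccasp3", 0.005),
        ("topgfp", 0.10),
    )

    def __post_init__(self) -> None:
        if self.n_clones < 0 or self.spread_um < 0:
            raise ValueError("n_clones and spread_um must be non-negative")
        if self.min_founder_separation_um < 0:
            raise ValueError("min_founder_separation_um must be non-negative")
        for name, p in self.marker_probs:
            if not 0 <= p <= 1:
                raise ValueError(f"marker {name!r} probability outside [0, 1]")


def gen_wholemount(
    density_per_mm2: Dict[str, float],
    clones: CloneSpec,
    lx_um: float = 2000.0,
    ly_um: float = 2000.0,
    layer_bounds_um: Sequence[Tuple[str, float, float]] = (
        ("papillary", 0.0, 60.0),
        ("reticular", 60.0, 140.0),
        ("DWAT", 140.0, 200.0),
    ),
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Synthetic whole-mount cell table: Poisson background + labelled clones.

    Background cells are a homogeneous Poisson process per layer; clone
    members sit at founder + Gaussian(sd=spread_um) xy-offsets with z uniform
    over the full dermis (clones span the layers).  All cells carry Bernoulli
    marker states.  Returns (cells, truth) with true clone sizes and
    probabilities in ``truth``.
    """
    rng = np.random.default_rng(seed)
    area_mm2 = lx_um * ly_um / 1e6
    depth = layer_bounds_um[-1][2]
    rows = []
    next_id = 0

    for layer, z0, z1 in layer_bounds_um:
        rho = density_per_mm2.get(layer, 0.0)
        n = int(rng.poisson(rho * area_mm2))
        if n == 0:
            continue
        x = rng.uniform(0, lx_um, n)
        y = rng.uniform(0, ly_um, n)
        z = rng.uniform(z0, z1, n)
        for k in range(n):
            rows.append((next_id + k, x[k], y[k], z[k], layer, False, next_id + k))
        next_id += n

    clone_sizes = {}
    names = [b[0] for b in layer_bounds_um]
    edges = np.asarray([b[2] for b in layer_bounds_um])
    founders_xy: list = []
    for _ in range(clones.n_clones):
        if isinstance(clones.cells_per_clone, int):
            size = clones.cells_per_clone
        else:
            lo, hi = clones.cells_per_clone
            size = int(rng.integers(lo, hi + 1))
        if size <= 0:
            continue
        sep = clones.min_founder_separation_um
        for _attempt in range(200):
            fx, fy = rng.uniform(0, lx_um), rng.uniform(0, ly_um)
            if sep == 0 or all(
                (fx - px) ** 2 + (fy - py) ** 2 >= sep**2 for px, py in founders_xy
            ):
                break
        else:
            warnings.warn(
                "could not place a founder at the requested separation; "
                "placing it uniformly",
                stacklevel=2,
            )
        founders_xy.append((fx, fy))
        founder_id = next_id
        clone_sizes[founder_id] = size
        for k in range(size):
            if k == 0 or clones.spread_um == 0:
                x, y = fx, fy
            else:
                x = fx + clones.spread_um * rng.standard_normal()
                y = fy + clones.spread_um * rng.standard_normal()
            z = float(rng.uniform(0, depth))
            layer = names[min(int(np.searchsorted(edges, z, side="right")), len(names) - 1)]
            rows.append((next_id, x, y, z, layer, True, founder_id))
            next_id += 1

    cells = pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "z_um", "layer", "labelled", "clone_id"]
    )
    for name, p in clones.marker_probs:
        cells[name] = rng.random(len(cells)) < p

    truth = {
        "clone_sizes": clone_sizes,
        "marker_probs": dict(clones.marker_probs),
        "density_per_mm2": dict(density_per_mm2),
        "area_mm2": area_mm2,
        "seed": seed,
    }
    return cells, truth


def gen_wound_sections(
    n_wounds: int = 4,
    sections_per_wound: int = 8,
    mean_hfs: float = 5.0,
    seed: int = 0,
    section_thickness_um: float = 60.0,
) -> Tuple[pd.DataFrame, dict]:
    """New-HF counts per wound-bed section, drawn Poisson(mean_hfs).

    The default mean of five echoes the neonatal wound phenotype; eight 60 µm
    sections per wound is the scoring protocol minimum.
    """
    if sections_per_wound < 1:
        raise ValueError("sections_per_wound must be >= 1")
    if mean_hfs < 0:
        raise ValueError("mean_hfs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(n_wounds):
        counts = rng.poisson(mean_hfs, sections_per_wound)
        for s, c in enumerate(counts):
            rows.append(
                {
                    "wound_id": w,
                    "section_id": s,
                    "section_thickness_um": section_thickness_um,
                    "n_new_hfs": int(c),
                }
            )
    records = pd.DataFrame(rows)
    truth = {"mean_hfs": mean_hfs, "seed": seed}
    return records, truth
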