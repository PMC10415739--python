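"""Droplet generation: sizes, copy numbers, mixing ratios and pool partitioning.

Water-in-oil droplets are produced at a flow-focusing junction fed by two
aqueous stocks — solution A (invader, optionally pre-equilibrated with a
random pool, plus the reference dye) and solution B (reporter complex).  The
volume fraction xi = V_A / (V_A + V_B) of solution A sets the in-droplet
concentrations

    [A] = xi * [A]_stock,     [B] = (1 - xi) * [B]_stock,

so [A]/[A]_stock + [B]/[B]_stock = 1 exactly.  Opposing sinusoidal pressure
programs on the two inlets sweep xi at constant total pressure (constant
droplet size); molecule counts follow N = N_Avogadro * c * (4 pi / 3) r^3.

Individual random-pool sequences are present at low per-sequence copy
numbers, so each droplet samples the pool: per-sequence occupancy is drawn
independently Poisson, and the sampled composition sets a per-droplet
effective rate factor via :mod:`tmsdrop.pool_thermo`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro

from .errors import ConfigError, InputError
from .pool_thermo import (
    EnergyModel,
    PoolInteraction,
    calibrate_rate_factors,
    effective_rate_factor,
)
from .seeding import substream

__all__ = [
    "EmulsionConfig",
    "PressureProgram",
    "DropletSpec",
    "sphere_volume",
    "copy_number",
    "mixing_ratio_series",
    "droplet_concentrations",
    "sample_pool_partition",
    "generate_emulsion",
    "emulsion_to_frame",
]


@dataclass(frozen=True)
class PressureProgram:
    """Sinusoidal inlet-pressure program driving the mixing ratio.

    The achieved mixing ratio of droplet i generated at time
    t_i = i * droplet_interval is

        xi_i = 0.5 + 0.5 * amplitude * sin(2 pi t_i / period + phase),

    i.e. symmetric about 0.5 with range [(1-amplitude)/2, (1+amplitude)/2].
    amplitude = 0 reproduces a balanced (fixed 50:50) program.
    """

    period: float = 1.0  # s; experimental range 0.1 - 5 s
    phase: float = 0.0  # rad
    amplitude: float = 1.0  # fraction of the half-range
    droplet_interval: float = 0.01  # s between consecutive droplets

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ConfigError("period must be positive")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ConfigError("amplitude must lie in [0, 1]")
        if self.droplet_interval <= 0:
            raise ConfigError("droplet_interval must be positive")


@dataclass(frozen=True)
class EmulsionConfig:
    """Stock compositions and droplet-population parameters.

    Defaults are the experimental conditions: 500 nM invader stock, 400 nM
    reporter stock, an optional 5 uM random pool (10-fold invader excess) on
    the invader side represented by ``pool_size`` distinct sequences, and
    radii 10-30 um with CV up to ~6%.
    """

    n_droplets: int
    radius_mean: float = 15.0  # um
    radius_cv: float = 0.03
    stock_A: float = 500e-9  # M, invader side
    stock_B: float = 400e-9  # M, reporter side
    pool_stock: float = 0.0  # M total pool on the invader side (5e-6 when present)
    pool_size: int = 10_000  # distinct pool sequences in the surrogate pool
    mixing_mode: str = "fixed"  # "fixed" or "sinusoidal"
    xi_fixed: float = 0.5  # mixing ratio in fixed mode
    xi_jitter_sd: float = 0.0  # production noise on xi (both modes)

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ConfigError("n_droplets must be >= 1")
        if not (0.0 <= self.radius_cv < 1.0):
            raise ConfigError("radius_cv must lie in [0, 1)")
        if self.stock_A <= 0 or self.stock_B <= 0:
            raise ConfigError("stock concentrations must be positive")
        if self.pool_stock < 0:
            raise ConfigError("pool_stock must be >= 0")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")
        if self.mixing_mode not in ("fixed", "sinusoidal"):
            raise ConfigError(f"unknown mixing_mode {self.mixing_mode!r}")
        if not (0.0 <= self.xi_fixed <= 1.0):
            raise ConfigError("xi_fixed must lie in [0, 1]")


@dataclass(frozen=True)
class DropletSpec:
    """One compartment, fully specified for trace simulation."""

    id: str
    radius_um: float
    volume_l: float
    xi: float
    conc_invader: float  # M
    conc_reporter: float  # M
    copies_invader: float  # expected count (real-valued)
    copies_reporter: float
    rate_factor: float  # f in k_eff = f * k0
    pool_copies: np.ndarray | None = None  # per-sequence sampled counts


def sphere_volume(radius_um: float) -> float:
    """Volume of a spherical droplet of radius r um, in litres."""
    if radius_um <= 0:
        raise InputError("radius must be positive")
    return (4.0 * np.pi / 3.0) * (radius_um * 1e-6) ** 3 * 1e3


def copy_number(conc: float, radius_um: float) -> float:
    """Expected molecule count N = N_A * c * (4 pi/3) r^3 (real-valued)."""
    if conc < 0:
        raise InputError("concentration must be >= 0")
    return Avogadro * conc * sphere_volume(radius_um)


def mixing_ratio_series(n: int, program: PressureProgram) -> np.ndarray:
    """Mixing ratios xi_i for n consecutively generated droplets."""
    if n < 1:
        raise InputError("n must be >= 1")
    t = np.arange(n) * program.droplet_interval
    xi = 0.5 + 0.5 * program.amplitude * np.sin(
        2.0 * np.pi * t / program.period + program.phase
    )
    return np.clip(xi, 0.0, 1.0)


def droplet_concentrations(
    xi: float, stock_A: float, stock_B: float
) -> tuple[float, float]:
    """In-droplet concentrations ([A], [B]) = (xi*[A]_stock, (1-xi)*[B]_stock)."""
    if not (0.0 <= xi <= 1.0):
        raise InputError("xi must lie in [0, 1]")
    return xi * stock_A, (1.0 - xi) * stock_B


def sample_pool_partition(
    pool_stock: float,
    pool_size: int,
    volume_l: float,
    xi: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Per-sequence copy counts encapsulated in one droplet.

    Each of the ``pool_size`` distinct sequences is drawn independently
    Poisson with mean xi * (pool_stock/pool_size) * N_A * V — the standard
    low-occupancy encapsulation model.
    """
    if pool_size < 1:
        raise InputError("pool_size must be >= 1")
    if volume_l <= 0:
        raise InputError("volume must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = substream(int(rng), "partition")
    mean = xi * (pool_stock / pool_size) * Avogadro * volume_l
    if mean == 0.0:
        return np.zeros(pool_size, dtype=np.int64)
    return rng.poisson(mean, size=pool_size)


def _pool_ddg_array(
    pool: Sequence[PoolInteraction] | np.ndarray | None,
) -> np.ndarray | None:
    if pool is None:
        return None
    if isinstance(pool, np.ndarray):
        return pool.astype(float)
    if len(pool) and isinstance(pool[0], PoolInteraction):
        return np.array([it.ddG for it in pool], dtype=float)
    return np.asarray(pool, dtype=float)


def generate_emulsion(
    config: EmulsionConfig,
    program: PressureProgram | None = None,
    pool: Sequence[PoolInteraction] | np.ndarray | None = None,
    seed: int = 0,
    model: EnergyModel | None = None,
    calibration: float | None = None,
    store_pool_copies: bool = False,
) -> list[DropletSpec]:
    """Generate a droplet population from stocks and a pressure program.

    Radii are truncated-normal (resampled while non-positive) with the
    configured mean and CV; xi comes from the pressure program (sinusoidal
    mode) or ``xi_fixed`` (fixed mode), plus optional production jitter; pool
    occupancies are Poisson-partitioned and mapped to per-droplet rate
    factors.  ``pool`` supplies the surrogate pool's interaction energies
    (PoolInteraction list or a plain ddG array of length ``pool_size``); when
    absent or ``pool_stock`` is 0, every rate factor is 1.  ``calibration``
    rescales the population-mean rate factor (e.g. to a measured
    pool-to-clean rate-constant ratio).
    """
    model = model or EnergyModel()
    ddgs = _pool_ddg_array(pool)
    has_pool = config.pool_stock > 0 and ddgs is not None
    if has_pool and ddgs.size != config.pool_size:
        raise ConfigError(
            f"pool has {ddgs.size} interactions but pool_size={config.pool_size}"
        )

    rng_radii = substream(seed, "radii")
    rng_xi = substream(seed, "xi")
    rng_part = substream(seed, "partition")

    radii = rng_radii.normal(
        config.radius_mean, config.radius_cv * config.radius_mean, config.n_droplets
    )
    while np.any(radii <= 0):  # truncate at zero by resampling
        bad = radii <= 0
        radii[bad] = rng_radii.normal(
            config.radius_mean, config.radius_cv * config.radius_mean, bad.sum()
        )

    if config.mixing_mode == "sinusoidal":
        xi = mixing_ratio_series(config.n_droplets, program or PressureProgram())
    else:
        xi = np.full(config.n_droplets, config.xi_fixed)
    if config.xi_jitter_sd > 0:
        xi = np.clip(xi + rng_xi.normal(0.0, config.xi_jitter_sd, xi.size), 0.0, 1.0)

    width = len(str(config.n_droplets - 1))
    droplets: list[DropletSpec] = []
    raw_factors = np.ones(config.n_droplets)
    kept_copies: list[np.ndarray | None] = []
    volumes = np.array([sphere_volume(r) for r in radii])

    for i in range(config.n_droplets):
        counts = None
        if has_pool:
            counts = sample_pool_partition(
                config.pool_stock, config.pool_size, volumes[i], xi[i], rng_part
            )
            conc_a = xi[i] * config.stock_A
            if conc_a > 0:
                seq_concs = counts / (Avogadro * volumes[i])
                raw_factors[i] = effective_rate_factor(
                    ddgs, seq_concs, conc_a, model
                )
        kept_copies.append(counts if store_pool_copies else None)

    if has_pool and calibration is not None:
        factors = calibrate_rate_factors(raw_factors, calibration)
    else:
        factors = raw_factors

    for i in range(config.n_droplets):
        conc_a, conc_b = droplet_concentrations(
            float(xi[i]), config.stock_A, config.stock_B
        )
        droplets.append(
            DropletSpec(
                id=f"d{i:0{width}d}",
                radius_um=float(radii[i]),
                volume_l=float(volumes[i]),
                xi=float(xi[i]),
                conc_invader=conc_a,
                conc_reporter=conc_b,
                copies_invader=copy_number(conc_a, float(radii[i])),
                copies_reporter=copy_number(conc_b, float(radii[i])),
                rate_factor=float(factors[i]),
                pool_copies=kept_copies[i],
            )
        )
    return droplets


def emulsion_to_frame(droplets: Sequence[DropletSpec]):
    """Emulsion summary as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "droplet_id": [d.id for d in droplets],
            "radius_um": [d.radius_um for d in droplets],
            "xi": [d.xi for d in droplets],
            "conc_invader_nM": [d.conc_invader * 1e9 for d in droplets],
            "conc_reporter_nM": [d.conc_reporter * 1e9 for d in droplets],
            "rate_factor": [d.rate_factor for d in droplets],
        }
    )
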