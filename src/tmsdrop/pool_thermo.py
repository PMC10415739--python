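"""Equilibrium interaction of an invader strand with a random-sequence DNA pool.

A free invader strand in a background of random oligonucleotides (here
25-mers, "N25") is transiently sequestered by partial hybridization to pool
members.  This module quantifies that sequestration:

* ``interaction_ddG`` — hybridization free-energy difference
  ddG = dG_AB - (dG_A + dG_B) for one invader/pool-strand pair, from a
  unified nearest-neighbor stack model over the best ungapped antiparallel
  alignment (the default backend treats the isolated strands as unstructured,
  dG_A = dG_B = 0; an ``external`` backend delegates to a full secondary-
  structure engine supplied by the caller).
* ``boltzmann_bound_probabilities`` — the probability p(n) that the invader
  sits in a complex with pool member n, p(n) = exp(-ddG_n/kT)/Q.
* ``two_state_bound_fraction`` — the fraction theta of invader bound to a
  single pool species under the two-state equilibrium A + R <=> C at given
  total concentrations.
* ``pool_sequestration_mu`` — mu, the mean theta over the strongest-binding
  top decile of the pool: the scalar summary of how much invader the pool
  soaks up.
* ``effective_rate_factor`` — maps a droplet's sampled pool composition to a
  multiplicative factor f in (0, 1] on the strand-displacement rate constant,
  k_eff = f * k0.

Thermodynamics are evaluated at 302.15 K (the 29 degC of the droplet
experiments), kT = R*T ~ 0.6005 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, InputError
from .seeding import substream

__all__ = [
    "DNAStrand",
    "EnergyModel",
    "PoolInteraction",
    "PoolEquilibrium",
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "sequence_space_size",
    "generate_random_pool",
    "interaction_ddG",
    "pool_ddGs",
    "boltzmann_bound_probabilities",
    "two_state_bound_fraction",
    "compute_pool_equilibrium",
    "pool_sequestration_mu",
    "effective_rate_factor",
    "calibrate_rate_factors",
]

R_KCAL_PER_MOL_K = 1.987204258640832e-3  # gas constant, kcal / (mol K)
DEFAULT_TEMPERATURE_K = 302.15  # 29 degC, the droplet-experiment temperature

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}  # A=0 C=1 G=2 T=3; complement = 3 - code
RATE_FACTOR_FLOOR = 0.01


@dataclass(frozen=True)
class DNAStrand:
    """A DNA sequence over {A,C,G,T}, written 5'->3'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("DNA sequence must be non-empty")
        if any(b not in _CODE for b in self.sequence):
            raise InputError(
                f"strand {self.id!r}: sequence may only contain A, C, G, T"
            )

    def __len__(self) -> int:
        return len(self.sequence)


ExternalEnergyFn = Callable[[str, str], tuple[float, float, float]]


@dataclass(frozen=True)
class EnergyModel:
    """Free-energy backend and thermodynamic context.

    backend
        ``"nearest_neighbor"`` (default): unified stack table over the best
        ungapped antiparallel alignment, isolated-strand folding energies
        taken as zero.
        ``"external"``: ``external_fn(seq_a, seq_b) -> (dG_A, dG_B, dG_AB)``
        supplies all three free energies (kcal/mol), e.g. from a partition-
        function engine.
    temperature
        Kelvin; sets kT for Boltzmann weights and equilibrium constants.
    salt
        Descriptive only (the stack table is not salt-corrected).
    """

    backend: str = "nearest_neighbor"
    temperature: float = DEFAULT_TEMPERATURE_K
    salt: str = "1x TE, 100 mM NaCl, 12.5 mM MgCl2"
    external_fn: ExternalEnergyFn | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive (kelvin)")
        if self.backend not in ("nearest_neighbor", "external"):
            raise ConfigError(f"unknown energy backend {self.backend!r}")
        if self.backend == "external" and self.external_fn is None:
            raise ConfigError("external backend requires external_fn")

    @property
    def kT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return R_KCAL_PER_MOL_K * self.temperature


@dataclass(frozen=True)
class PoolInteraction:
    """One pool member's equilibrium interaction with the invader."""

    strand: DNAStrand
    ddG: float  # kcal/mol, <= 0 by convention
    p_bound: float  # Boltzmann probability p(n) within the pool
    theta: float  # two-state bound fraction of invader at pool conditions

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bound <= 1.0):
            raise InputError("p_bound must lie in [0, 1]")
        if not (0.0 <= self.theta <= 1.0):
            raise InputError("theta must lie in [0, 1]")


@dataclass(frozen=True)
class PoolEquilibrium:
    """Pool-wide equilibrium summary.

    ``mu`` is the mean bound fraction over the ``M = round(top_fraction*N)``
    strongest binders (lowest ddG) — the sequestration statistic.
    """

    interactions: tuple[PoolInteraction, ...]
    partition_sum: float  # Q = sum_j exp(-ddG_j / kT)
    mu: float
    top_fraction: float = 0.10
    M: int = field(default=0)
    N: int = field(default=0)


def _load_stack_table() -> tuple[np.ndarray, float]:
    """Read the shipped nearest-neighbor table into a 4x4 matrix + initiation."""
    table = np.zeros((4, 4))
    init = 0.0
    text = resources.files("tmsdrop.data").joinpath("nn_stacks_v1.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split()
        if key == "INIT":
            init = float(value)
        else:
            table[_CODE[key[0]], _CODE[key[1]]] = float(value)
    return table, init


_STACK_DG37, _DUPLEX_INIT = _load_stack_table()


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in sequence), dtype=np.int8, count=len(sequence))


def sequence_space_size(length: int) -> int:
    """Number of distinct DNA sequences of the given length, 4**length."""
    if length < 1:
        raise InputError("length must be >= 1")
    return 4 ** length


def generate_random_pool(n: int, length: int, seed: int) -> list[DNAStrand]:
    """Draw ``n`` uniform-random strands of ``length`` nt (i.i.d. letters)."""
    if n < 1 or length < 1:
        raise InputError("n and length must be >= 1")
    rng = substream(seed, "pool")
    codes = rng.integers(0, 4, size=(n, length), dtype=np.int8)
    letters = np.array(list(_ALPHABET))
    width = len(str(n - 1))
    return [
        DNAStrand(id=f"pool_{i:0{width}d}", sequence="".join(letters[row]))
        for i, row in enumerate(codes)
    ]


def _nn_pool_ddGs(invader_codes: np.ndarray, pool_codes: np.ndarray) -> np.ndarray:
    """Vectorized nearest-neighbor ddG of one invader against a code matrix.

    For each ungapped antiparallel alignment offset, positions where the
    invader base Watson-Crick-pairs the pool base score the stack energy of
    each adjacent paired dinucleotide; the best (most negative) alignment
    total plus one initiation penalty gives dG_AB, clamped at 0.
    """
    l1 = invader_codes.size
    pool_rc = 3 - pool_codes[:, ::-1]  # reverse complement, 5'->3' along invader
    l2 = pool_rc.shape[1]
    best = np.zeros(pool_rc.shape[0])
    for s in range(-(l1 - 1), l2):
        i0 = max(0, -s)
        i1 = min(l1, l2 - s)
        if i1 - i0 < 2:
            continue
        seg = invader_codes[i0:i1]
        match = seg[None, :] == pool_rc[:, i0 + s : i1 + s]
        stack_e = _STACK_DG37[seg[:-1], seg[1:]]
        score = ((match[:, :-1] & match[:, 1:]) * stack_e).sum(axis=1)
        np.minimum(best, score, out=best)
    ddg = np.where(best < 0.0, np.minimum(best + _DUPLEX_INIT, 0.0), 0.0)
    return ddg


def pool_ddGs(
    invader: DNAStrand,
    strands: Sequence[DNAStrand],
    model: EnergyModel | None = None,
) -> np.ndarray:
    """ddG (kcal/mol) of the invader against each pool strand (vectorized)."""
    model = model or EnergyModel()
    if model.backend == "external":
        out = np.empty(len(strands))
        for i, strand in enumerate(strands):
            dg_a, dg_b, dg_ab = model.external_fn(invader.sequence, strand.sequence)
            out[i] = min(dg_ab - (dg_a + dg_b), 0.0)
        return out
    lengths = {len(s) for s in strands}
    inv = _encode(invader.sequence)
    out = np.empty(len(strands))
    for length in lengths:
        idx = [i for i, s in enumerate(strands) if len(s) == length]
        codes = np.stack([_encode(strands[i].sequence) for i in idx])
        out[idx] = _nn_pool_ddGs(inv, codes)
    return out


def interaction_ddG(
    invader: DNAStrand, strand: DNAStrand, model: EnergyModel | None = None
) -> float:
    """Hybridization free-energy difference ddG = dG_AB - (dG_A + dG_B).

    Non-positive by convention: a pair whose best duplex is unfavourable is
    clamped to 0 (no stable complex).
    """
    return float(pool_ddGs(invader, [strand], model)[0])


def boltzmann_bound_probabilities(
    ddGs: Sequence[float] | np.ndarray, model: EnergyModel | None = None
) -> np.ndarray:
    """Boltzmann probabilities p(n) = exp(-ddG_n/kT) / Q over a pool.

    Probabilities sum to 1 and decrease strictly with increasing ddG.
    """
    ddGs = np.asarray(ddGs, dtype=float)
    if ddGs.size == 0:
        raise InputError("ddG list must be non-empty")
    model = model or EnergyModel()
    # shift by the minimum so the largest weight is exp(0)
    w = np.exp(-(ddGs - ddGs.min()) / model.kT)
    return w / w.sum()


def two_state_bound_fraction(
    ddG: float,
    invader_conc: float,
    strand_conc: float,
    model: EnergyModel | None = None,
) -> float:
    """Fraction theta of invader bound under A + R <=> C at equilibrium.

    K_eq = exp(-ddG/kT) M^-1 (1 M standard state); theta = [C]/A_tot from the
    exact quadratic mass balance, evaluated in a cancellation-free form.
    """
    if invader_conc <= 0 or strand_conc <= 0:
        raise InputError("concentrations must be positive")
    model = model or EnergyModel()
    k_eq = np.exp(min(-ddG / model.kT, 700.0))  # M^-1; cap avoids overflow
    return _theta_quadratic(k_eq, invader_conc, strand_conc)


def _theta_quadratic(k_eq: float, a_tot: float, r_tot: float) -> float:
    # C solves K(A-C)(R-C) = C; stable root: C = 2AR / (b + sqrt(b^2 - 4AR))
    b = a_tot + r_tot + 1.0 / k_eq
    disc = b * b - 4.0 * a_tot * r_tot
    c = 2.0 * a_tot * r_tot / (b + np.sqrt(max(disc, 0.0)))
    return float(min(max(c / a_tot, 0.0), 1.0))


def two_state_bound_fraction_oracle(
    ddG: float,
    invader_conc: float,
    strand_conc: float,
    model: EnergyModel | None = None,
) -> float:
    """Independent root-finding solution of the same mass balance (for checks)."""
    model = model or EnergyModel()
    k_eq = np.exp(min(-ddG / model.kT, 700.0))

    def residual(c: float) -> float:
        return k_eq * (invader_conc - c) * (strand_conc - c) - c

    upper = min(invader_conc, strand_conc)
    c = brentq(residual, 0.0, upper, xtol=1e-30, rtol=4 * np.finfo(float).eps)
    return c / invader_conc


def _rank_by_energy(interactions: Sequence[PoolInteraction]) -> list[PoolInteraction]:
    # stable sort by (ddG, id): ties between equal energies break by strand id
    return sorted(interactions, key=lambda it: (it.ddG, it.strand.id))


def _top_m(n: int, top_fraction: float) -> int:
    if not (0.0 < top_fraction <= 1.0):
        raise InputError("top_fraction must lie in (0, 1]")
    # round half up, at least one strand
    return max(1, int(np.floor(top_fraction * n + 0.5)))


def pool_sequestration_mu(
    interactions: Sequence[PoolInteraction], top_fraction: float = 0.10
) -> float:
    """mu: mean bound fraction theta over the strongest-binding top decile.

    Selects the M = round(top_fraction*N) interactions with lowest ddG
    (stable tie-break on strand id) and averages their theta.
    """
    if not interactions:
        raise InputError("interactions must be non-empty")
    ranked = _rank_by_energy(interactions)
    m = _top_m(len(ranked), top_fraction)
    return float(np.mean([it.theta for it in ranked[:m]]))


def compute_pool_equilibrium(
    invader: DNAStrand,
    strands: Sequence[DNAStrand],
    invader_conc: float,
    strand_conc: float,
    model: EnergyModel | None = None,
    top_fraction: float = 0.10,
) -> PoolEquilibrium:
    """Full pool summary: ddG, p(n) and theta per strand, plus Q and mu.

    ``strand_conc`` is the total concentration of each individual pool
    species (pool_stock / pool_size for an equimolar pool).
    """
    model = model or EnergyModel()
    ddgs = pool_ddGs(invader, strands, model)
    probs = boltzmann_bound_probabilities(ddgs, model)
    interactions = tuple(
        PoolInteraction(
            strand=s,
            ddG=float(g),
            p_bound=float(p),
            theta=two_state_bound_fraction(float(g), invader_conc, strand_conc, model),
        )
        for s, g, p in zip(strands, ddgs, probs)
    )
    mu = pool_sequestration_mu(interactions, top_fraction)
    q = float(np.exp(-ddgs / model.kT).sum())
    return PoolEquilibrium(
        interactions=interactions,
        partition_sum=q,
        mu=mu,
        top_fraction=top_fraction,
        M=_top_m(len(strands), top_fraction),
        N=len(strands),
    )


def effective_rate_factor(
    ddGs: Sequence[float] | np.ndarray,
    strand_concs: Sequence[float] | np.ndarray,
    invader_conc: float,
    model: EnergyModel | None = None,
    floor: float = RATE_FACTOR_FLOOR,
) -> float:
    """Rate factor f for one droplet: k_eff = f * k0, f = 1 - mu_droplet.

    mu_droplet is the equilibrium bound fraction of invader against the
    droplet's sampled pool, computed by collapsing the sample onto a single
    effective ligand (total concentration = sum of per-sequence
    concentrations, binding constant = concentration-weighted mean K).  An
    empty sample gives f = 1; full sequestration is clamped at ``floor`` so
    no droplet is assigned a zero rate.
    """
    if invader_conc <= 0:
        raise InputError("invader_conc must be positive")
    model = model or EnergyModel()
    ddGs = np.asarray(ddGs, dtype=float)
    concs = np.asarray(strand_concs, dtype=float)
    if ddGs.size != concs.size:
        raise InputError("ddGs and strand_concs must have equal length")
    present = concs > 0
    if ddGs.size == 0 or not present.any():
        return 1.0
    ddGs, concs = ddGs[present], concs[present]
    k = np.exp(np.minimum(-ddGs / model.kT, 700.0))
    r_tot = concs.sum()
    k_bar = float((concs * k).sum() / r_tot)
    mu_droplet = _theta_quadratic(k_bar, invader_conc, float(r_tot))
    return float(min(max(1.0 - mu_droplet, floor), 1.0))


def calibrate_rate_factors(
    factors: Sequence[float] | np.ndarray,
    calibration: float,
    floor: float = RATE_FACTOR_FLOOR,
) -> np.ndarray:
    """Rescale a population of rate factors so its mean equals ``calibration``.

    Used when an independently measured clean-vs-pool rate-constant ratio
    (e.g. 2.7e4 / 3.2e4) anchors the population mean while the droplet-to-
    droplet spread comes from the sampled pool compositions.  Values are
    clipped to [floor, 1]; if clipping engages, the scale is re-solved so the
    clipped mean still matches.
    """
    if not (0.0 < calibration <= 1.0):
        raise ConfigError("calibration must lie in (0, 1]")
    f = np.asarray(factors, dtype=float)
    if f.size == 0:
        raise InputError("factors must be non-empty")

    def clipped_mean(scale: float) -> float:
        return float(np.clip(f * scale, floor, 1.0).mean())

    # mean(clip(f*scale)) is monotone non-decreasing in scale: bisect
    lo, hi = 0.0, 1.0
    while clipped_mean(hi) < calibration and hi < 1e12:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if clipped_mean(mid) < calibration:
            lo = mid
        else:
            hi = mid
    return np.clip(f * hi, floor, 1.0)
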