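"""Juxtacrine Notch GRN models on a 1-D cell lattice.

Notochord precursor cells are coin-shaped and stacked one after another, so
each cell signals to exactly its two neighbors.  Three circuit variants are
implemented as right-hand-side (RHS) functions for the per-cell ODE system:

``induction``
    The ligand activates Notch (NICD release, species ``S``) in the
    neighboring cell, and NICD activates ligand (``L``) expression in its own
    cell.  Positive feedback through neighbors propagates the same fate and
    produces a homogeneous pattern.

``inhibition``
    NICD activates a transcriptional repressor (``R``, the Her-type factor)
    which shuts off ligand production, so high-Notch cells silence their own
    ligand — the classical lateral-inhibition circuit producing alternating
    fates.

``cistrans``
    A reduced mutual-inactivation model with an explicit Notch receptor
    (``N``).  Receptor and ligand inactivate each other both within a cell
    (cis, rate constant ``K_cis``) and between neighboring cells (trans, rate
    constant ``K_trans``); only trans complexes release signal ``S``, which
    represses ligand production through a single Hill step (the Her repressor
    folded into the ``S -| L`` arm).  Larger ``K_cis``/``K_trans`` means
    stronger interaction.

Species order in all state matrices follows the documented convention
(N, L, S, R), restricted to the species a model carries:
``induction`` -> (L, S); ``inhibition`` -> (L, S, R); ``cistrans`` -> (N, L, S).

Neighbor coupling uses the *mean* of the two neighbor values so that periodic
and reflecting lattices share parameter scales.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable

import numpy as np

__all__ = [
    "CellLattice",
    "InductionParams",
    "InhibitionParams",
    "CisTransParams",
    "neighbor_average",
    "rhs_induction",
    "rhs_inhibition",
    "rhs_cistrans",
    "MODELS",
    "get_model",
]

BOUNDARIES = ("periodic", "reflecting")


class InvalidLatticeError(ValueError):
    """Raised when a lattice violates its structural invariants."""


def _check_positive(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class InductionParams:
    """Lateral-induction circuit: S activates L in its own cell."""

    beta_L: float = 10.0     # max ligand production rate
    gamma_L: float = 1.0     # ligand degradation rate
    gamma_S: float = 1.0     # signal degradation rate
    k_trans_act: float = 1.0  # trans-activation rate of S by neighbor ligand
    K_act: float = 0.5       # half-max of S -> L activation
    h_act: float = 2.0       # Hill exponent of the activation

    def __post_init__(self):
        _check_positive(self)

    species = ("L", "S")


@dataclass(frozen=True)
class InhibitionParams:
    """Lateral-inhibition circuit: S activates repressor R, R represses L."""

    beta_L: float = 10.0
    beta_R: float = 10.0
    gamma_L: float = 1.0
    gamma_R: float = 1.0
    gamma_S: float = 1.0
    k_trans_act: float = 1.0
    K_R_act: float = 1.0     # half-max of S -> R activation
    K_L_rep: float = 1.0     # half-max of R -| L repression
    h: float = 2.0           # shared Hill exponent

    def __post_init__(self):
        _check_positive(self)

    species = ("L", "S", "R")


@dataclass(frozen=True)
class CisTransParams:
    """Cis/trans mutual-inactivation circuit with explicit receptor.

    ``K_cis`` and ``K_trans`` are mass-action rate constants (per
    concentration per time); larger values mean stronger interactions, so
    "cis stronger than trans" reads directly as ``K_cis > K_trans``.
    ``h`` is the cooperativity of the S -| L repression; ``h = 1`` is the
    non-cooperative case.  Production rates and interaction constants may be
    zero (the term is simply absent); degradation rates and ``K_S`` must be
    strictly positive.
    """

    beta_N: float = 10.0
    beta_L: float = 10.0
    gamma: float = 1.0       # receptor and ligand degradation rate
    gamma_S: float = 1.0
    K_cis: float = 1.0
    K_trans: float = 1.0
    K_S: float = 1.0         # half-max of S -| L repression
    h: float = 1.0

    def __post_init__(self):
        for name in ("beta_N", "beta_L", "K_cis", "K_trans"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"CisTransParams.{name} must be finite and >= 0, got {v!r}")
        for name in ("gamma", "gamma_S", "K_S"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"CisTransParams.{name} must be finite and > 0, got {v!r}")
        if self.h < 1:
            raise ValueError(f"CisTransParams.h must be >= 1, got {self.h}")

    species = ("N", "L", "S")


@dataclass
class CellLattice:
    """A 1-D array of cells with per-species concentrations.

    ``state`` has shape (n_cells, n_species); all concentrations must be
    nonnegative and ``n_cells >= 2`` (a single cell has no neighbor).
    """

    n_cells: int
    boundary: str
    species_names: tuple
    state: np.ndarray

    def __post_init__(self):
        self.species_names = tuple(self.species_names)
        self.state = np.asarray(self.state, dtype=float)
        if self.n_cells < 2:
            raise InvalidLatticeError(f"n_cells must be >= 2, got {self.n_cells}")
        if self.boundary not in BOUNDARIES:
            raise InvalidLatticeError(f"boundary must be one of {BOUNDARIES}, got {self.boundary!r}")
        if self.state.shape != (self.n_cells, len(self.species_names)):
            raise InvalidLatticeError(
                f"state shape {self.state.shape} != ({self.n_cells}, {len(self.species_names)})"
            )
        if not np.all(np.isfinite(self.state)):
            raise InvalidLatticeError("state contains non-finite values")
        if np.any(self.state < 0):
            raise InvalidLatticeError("concentrations must be nonnegative")

    @classmethod
    def homogeneous(cls, n_cells: int, boundary: str, species_names, values) -> "CellLattice":
        values = np.asarray(values, dtype=float)
        state = np.tile(values, (n_cells, 1))
        return cls(n_cells=n_cells, boundary=boundary, species_names=tuple(species_names), state=state)


def neighbor_average(field: np.ndarray, boundary: str) -> np.ndarray:
    """Mean of the neighbor values for every cell of a 1-D lattice.

    Periodic lattices close the ring (cells 0 and n-1 are neighbors);
    reflecting lattices give end cells their single interior neighbor.
    Operates column-wise on 2-D input (cells x species).
    """
    field = np.asarray(field, dtype=float)
    n = field.shape[0]
    if n < 2:
        raise InvalidLatticeError(f"need at least 2 cells, got {n}")
    if boundary == "periodic":
        return 0.5 * (np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0))
    if boundary == "reflecting":
        out = np.empty_like(field)
        out[1:-1] = 0.5 * (field[:-2] + field[2:])
        out[0] = field[1]
        out[-1] = field[-2]
        return out
    raise InvalidLatticeError(f"unknown boundary {boundary!r}")


def _hill_act(x, K, h):
    # x^h / (K^h + x^h); 0^h -> 0 for h >= 1
    xh = np.power(x, h)
    return xh / (K**h + xh)


def _hill_rep(x, K, h):
    # K^h / (K^h + x^h)
    Kh = K**h
    return Kh / (Kh + np.power(x, h))


def _check_state(lattice: CellLattice, expected_species) -> np.ndarray:
    if tuple(lattice.species_names) != tuple(expected_species):
        raise InvalidLatticeError(
            f"lattice species {lattice.species_names} != expected {tuple(expected_species)}"
        )
    if np.any(lattice.state < 0):
        raise InvalidLatticeError("concentrations must be nonnegative")
    return lattice.state


def rhs_induction(lattice: CellLattice, params: InductionParams) -> np.ndarray:
    """Time derivatives for the lateral-induction circuit.

    dS_i/dt = k_trans_act * <L>_i - gamma_S * S_i
    dL_i/dt = beta_L * S_i^h / (K_act^h + S_i^h) - gamma_L * L_i
    """
    state = _check_state(lattice, InductionParams.species)
    L, S = state[:, 0], state[:, 1]
    Lbar = neighbor_average(L, lattice.boundary)
    dL = params.beta_L * _hill_act(S, params.K_act, params.h_act) - params.gamma_L * L
    dS = params.k_trans_act * Lbar - params.gamma_S * S
    return np.column_stack([dL, dS])


def rhs_inhibition(lattice: CellLattice, params: InhibitionParams) -> np.ndarray:
    """Time derivatives for the lateral-inhibition circuit.

    dS_i/dt = k_trans_act * <L>_i - gamma_S * S_i
    dR_i/dt = beta_R * S_i^h / (K_R_act^h + S_i^h) - gamma_R * R_i
    dL_i/dt = beta_L * K_L_rep^h / (K_L_rep^h + R_i^h) - gamma_L * L_i
    """
    state = _check_state(lattice, InhibitionParams.species)
    L, S, R = state[:, 0], state[:, 1], state[:, 2]
    Lbar = neighbor_average(L, lattice.boundary)
    dL = params.beta_L * _hill_rep(R, params.K_L_rep, params.h) - params.gamma_L * L
    dS = params.k_trans_act * Lbar - params.gamma_S * S
    dR = params.beta_R * _hill_act(S, params.K_R_act, params.h) - params.gamma_R * R
    return np.column_stack([dL, dS, dR])


def rhs_cistrans(lattice: CellLattice, params: CisTransParams) -> np.ndarray:
    """Time derivatives for the cis/trans mutual-inactivation circuit.

    dN_i/dt = beta_N - gamma*N_i - K_cis*N_i*L_i - K_trans*N_i*<L>_i
    dL_i/dt = beta_L*K_S^h/(K_S^h + S_i^h) - gamma*L_i - K_cis*L_i*N_i
              - K_trans*L_i*<N>_i
    dS_i/dt = K_trans*N_i*<L>_i - gamma_S*S_i

    Cis and trans binding are irreversible inactivation sinks on both
    partners; only trans binding releases signal.
    """
    state = _check_state(lattice, CisTransParams.species)
    N, L, S = state[:, 0], state[:, 1], state[:, 2]
    Nbar = neighbor_average(N, lattice.boundary)
    Lbar = neighbor_average(L, lattice.boundary)
    dN = params.beta_N - params.gamma * N - params.K_cis * N * L - params.K_trans * N * Lbar
    dL = (
        params.beta_L * _hill_rep(S, params.K_S, params.h)
        - params.gamma * L
        - params.K_cis * L * N
        - params.K_trans * L * Nbar
    )
    dS = params.K_trans * N * Lbar - params.gamma_S * S
    return np.column_stack([dN, dL, dS])


@dataclass(frozen=True)
class Model:
    """A named GRN variant: species order, RHS and parameter class."""

    name: str
    species: tuple
    rhs: Callable[[CellLattice, object], np.ndarray]
    params_cls: type


MODELS = {
    "induction": Model("induction", InductionParams.species, rhs_induction, InductionParams),
    "inhibition": Model("inhibition", InhibitionParams.species, rhs_inhibition, InhibitionParams),
    "cistrans": Model("cistrans", CisTransParams.species, rhs_cistrans, CisTransParams),
}


def get_model(name: str) -> Model:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None
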