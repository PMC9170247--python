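"""Linear stability analysis of the homogeneous steady state (HSS).

The HSS is the fixed point at which every cell carries identical species
concentrations.  On a periodic lattice, the linearization around the HSS is
block-circulant and diagonalizes into per-mode blocks ``J_intra + m * J_nbr``
with coupling factor ``m = cos(2*pi*k/n) in [-1, 1]``; ``m = -1`` is the
period-2 alternating mode.  The Maximal Lyapunov Exponent (MLE) is the
largest real eigenvalue part over all modes: it measures the escape rate
from the homogeneous state, and a positive MLE means the homogeneous state
is unstable and patterning ensues.

Scanning the MLE over a (K_cis, K_trans) grid produces the phase diagram of
the mutual-inactivation model: without cooperativity (h = 1) patterning is
confined to the region where cis-interactions are stronger than trans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import root

from .grn_models import (
    CellLattice,
    CisTransParams,
    InductionParams,
    InhibitionParams,
    get_model,
)

__all__ = [
    "HomogeneousState",
    "JacobianBlocks",
    "StabilityResult",
    "PhaseDiagram",
    "ConvergenceError",
    "find_hss",
    "jacobian_blocks",
    "mode_mle",
    "default_modes",
    "phase_diagram",
    "phase_diagram_to_frame",
    "plot_phase_diagram",
]

logger = logging.getLogger(__name__)

HSS_TOL = 1e-10
N_STARTS = 64  # multi-start root finding: 8 x 8 log-spaced grid


class ConvergenceError(RuntimeError):
    """No steady-state root found; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float = np.inf):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class HomogeneousState:
    """Per-species HSS concentrations shared by all cells."""

    concentrations: np.ndarray
    residual: float

    def __post_init__(self):
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, dtype=float))


@dataclass(frozen=True)
class JacobianBlocks:
    """Linearization split into own-cell and neighbor-average blocks."""

    J_intra: np.ndarray
    J_nbr: np.ndarray

    def __post_init__(self):
        Ji = np.asarray(self.J_intra, dtype=float)
        Jn = np.asarray(self.J_nbr, dtype=float)
        if not (np.all(np.isfinite(Ji)) and np.all(np.isfinite(Jn))):
            raise ValueError("Jacobian blocks contain non-finite entries")
        object.__setattr__(self, "J_intra", Ji)
        object.__setattr__(self, "J_nbr", Jn)


@dataclass(frozen=True)
class StabilityResult:
    hss: HomogeneousState
    mle: float
    argmax_mode: float
    per_mode: np.ndarray  # (n_modes, 2): coupling factor m, spectral abscissa

    @property
    def patterning(self) -> bool:
        return self.mle > 0


def _homogeneous_rhs(model_name: str, params) -> callable:
    """RHS restricted to the homogeneous subspace (2-cell periodic lattice)."""
    model = get_model(model_name)

    def fun(x):
        x = np.asarray(x, dtype=float)
        lat = CellLattice.homogeneous(2, "periodic", model.species, np.abs(x))
        return model.rhs(lat, params)[0]

    return fun


def _start_grid(model_name: str, params, n_starts: int) -> np.ndarray:
    """Log-spaced multi-start grid over the two leading species."""
    model = get_model(model_name)
    s = len(model.species)
    side = max(2, int(round(np.sqrt(n_starts))))
    vals = np.logspace(-3, 2, side)
    starts = []
    for a in vals:
        for b in vals:
            x0 = np.full(s, b)
            x0[0] = a
            if s > 1:
                x0[1] = b
            if model_name == "cistrans":
                # seed S at its quasi-steady value for the (N, L) guess
                x0[2] = max(params.K_trans * a * b / params.gamma_S, 1e-8)
            starts.append(x0)
    return np.array(starts)


def find_hss(model_name: str, params, tol: float = HSS_TOL, n_starts: int = N_STARTS) -> HomogeneousState:
    """Locate the homogeneous steady state by multi-start root finding.

    Roots are polished with a hybrid Powell solver from ``n_starts``
    log-spaced starting points.  When several roots exist, the
    componentwise-positive root with the largest ligand concentration is
    returned (documented tie-break; mutual-inactivation circuits can be
    multistable).
    """
    fun = _homogeneous_rhs(model_name, params)
    model = get_model(model_name)
    lig = model.species.index("L")
    best_res = np.inf
    candidates = []
    for x0 in _start_grid(model_name, params, n_starts):
        sol = root(fun, x0, method="hybr")
        x = np.abs(sol.x)
        res = float(np.max(np.abs(fun(x))))
        best_res = min(best_res, res)
        if res < tol and np.all(np.isfinite(x)):
            candidates.append((x, res))
    if not candidates:
        raise ConvergenceError(
            f"no HSS found for model {model_name!r} (best residual {best_res:.3e})",
            best_residual=best_res,
        )
    arr = np.array([c[0] for c in candidates])
    res_arr = np.array([c[1] for c in candidates])
    positive = np.all(arr > 0, axis=1)
    if np.any(positive):
        arr, res_arr = arr[positive], res_arr[positive]
    k = int(np.argmax(arr[:, lig]))
    return HomogeneousState(concentrations=arr[k], residual=float(res_arr[k]))


def _polish(model_name: str, params, x0: np.ndarray, tol: float) -> HomogeneousState | None:
    """Single-start polish used for warm-started grid sweeps."""
    fun = _homogeneous_rhs(model_name, params)
    sol = root(fun, x0, method="hybr")
    x = np.abs(sol.x)
    res = float(np.max(np.abs(fun(x))))
    if res < tol and np.all(np.isfinite(x)):
        return HomogeneousState(concentrations=x, residual=res)
    return None


def jacobian_blocks(model_name: str, params, hss: HomogeneousState) -> JacobianBlocks:
    """Analytic Jacobian of the RHS at the HSS, split by own-cell vs
    neighbor-average dependence."""
    if hss.residual >= 1e-8:
        raise ValueError(f"hss residual {hss.residual:.3e} too large for linearization")
    x = hss.concentrations
    if model_name == "induction":
        p: InductionParams = params
        L, S = x
        dact = _hill_act_deriv(S, p.K_act, p.h_act) * p.beta_L
        Ji = np.array([[-p.gamma_L, dact], [0.0, -p.gamma_S]])
        Jn = np.array([[0.0, 0.0], [p.k_trans_act, 0.0]])
    elif model_name == "inhibition":
        p: InhibitionParams = params
        L, S, R = x
        dLR = -p.beta_L * _hill_rep_deriv(R, p.K_L_rep, p.h)
        dRS = p.beta_R * _hill_act_deriv(S, p.K_R_act, p.h)
        Ji = np.array(
            [
                [-p.gamma_L, 0.0, dLR],
                [0.0, -p.gamma_S, 0.0],
                [0.0, dRS, -p.gamma_R],
            ]
        )
        Jn = np.zeros((3, 3))
        Jn[1, 0] = p.k_trans_act
    elif model_name == "cistrans":
        p: CisTransParams = params
        N, L, S = x
        # at the HSS the neighbor average equals the own-cell value
        dLS = -p.beta_L * _hill_rep_deriv(S, p.K_S, p.h)
        Ji = np.array(
            [
                [-p.gamma - p.K_cis * L - p.K_trans * L, -p.K_cis * N, 0.0],
                [-p.K_cis * L, -p.gamma - p.K_cis * N - p.K_trans * N, dLS],
                [p.K_trans * L, 0.0, -p.gamma_S],
            ]
        )
        Jn = np.array(
            [
                [0.0, -p.K_trans * N, 0.0],
                [-p.K_trans * L, 0.0, 0.0],
                [0.0, p.K_trans * N, 0.0],
            ]
        )
    else:
        raise KeyError(f"unknown model {model_name!r}")
    return JacobianBlocks(J_intra=Ji, J_nbr=Jn)


def _hill_act_deriv(x, K, h):
    # d/dx [x^h / (K^h + x^h)] = h K^h x^(h-1) / (K^h + x^h)^2
    # np.power(0., 0.) == 1.0 handles the h == 1, x == 0 corner correctly
    return h * K**h * np.power(x, h - 1) / (K**h + np.power(x, h)) ** 2


def _hill_rep_deriv(x, K, h):
    # |d/dx [K^h / (K^h + x^h)]|
    return h * K**h * np.power(x, h - 1) / (K**h + np.power(x, h)) ** 2


def default_modes(n_cells: int | None = None, n_envelope: int = 201) -> np.ndarray:
    """Coupling factors: lattice modes cos(2*pi*k/n) plus a continuum
    envelope sampled uniformly on [-1, 1]."""
    modes = np.linspace(-1.0, 1.0, n_envelope)
    if n_cells is not None:
        lattice_modes = np.cos(2 * np.pi * np.arange(n_cells) / n_cells)
        modes = np.union1d(np.round(lattice_modes, 15), modes)
    return modes


def mode_mle(blocks: JacobianBlocks, modes: Sequence[float], hss: HomogeneousState | None = None) -> StabilityResult:
    """Spectral abscissa of ``J_intra + m * J_nbr`` for each coupling factor.

    The MLE is the maximum over the supplied modes; ``m = -1`` corresponds to
    the period-2 alternating pattern on an even periodic lattice.
    """
    modes = np.asarray(modes, dtype=float)
    if modes.size == 0:
        raise ValueError("mode set must be nonempty")
    if np.any(np.abs(modes) > 1 + 1e-12):
        raise ValueError("coupling factors must lie in [-1, 1]")
    stack = blocks.J_intra[None, :, :] + modes[:, None, None] * blocks.J_nbr[None, :, :]
    eigs = np.linalg.eigvals(stack)
    abscissa = eigs.real.max(axis=1)
    k = int(np.argmax(abscissa))
    return StabilityResult(
        hss=hss if hss is not None else HomogeneousState(np.array([]), 0.0),
        mle=float(abscissa[k]),
        argmax_mode=float(modes[k]),
        per_mode=np.column_stack([modes, abscissa]),
    )


def analyze(model_name: str, params, modes: Sequence[float] | None = None, n_cells: int | None = None) -> StabilityResult:
    """find_hss -> jacobian_blocks -> mode_mle in one call."""
    hss = find_hss(model_name, params)
    blocks = jacobian_blocks(model_name, params, hss)
    if modes is None:
        modes = default_modes(n_cells)
    return mode_mle(blocks, modes, hss=hss)


@dataclass(frozen=True)
class PhaseDiagram:
    """MLE over a (K_cis, K_trans) grid at otherwise fixed parameters.

    ``mle_matrix[i, j]`` is the MLE at ``(kcis_grid[i], ktrans_grid[j])``;
    grid points where the HSS search failed carry NaN and are listed in
    ``failures`` as (i, j) index pairs.
    """

    kcis_grid: np.ndarray
    ktrans_grid: np.ndarray
    mle_matrix: np.ndarray
    params: CisTransParams
    failures: tuple = ()


def phase_diagram(
    params: CisTransParams,
    kcis_grid: Sequence[float],
    ktrans_grid: Sequence[float],
    modes: Sequence[float] | None = None,
) -> PhaseDiagram:
    """Sweep the MLE over a log grid of cis and trans interaction strengths.

    The HSS search warm-starts from the neighboring grid point and falls
    back to the full multi-start search when the polish step fails.
    """
    kcis_grid = np.asarray(kcis_grid, dtype=float)
    ktrans_grid = np.asarray(ktrans_grid, dtype=float)
    for g, name in ((kcis_grid, "kcis_grid"), (ktrans_grid, "ktrans_grid")):
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly increasing and positive")
    if modes is None:
        modes = default_modes()
    M = np.full((kcis_grid.size, ktrans_grid.size), np.nan)
    failures = []
    prev_row_hss = [None] * ktrans_grid.size
    for i, kc in enumerate(kcis_grid):
        prev = None
        for j, kt in enumerate(ktrans_grid):
            p = replace(params, K_cis=float(kc), K_trans=float(kt))
            hss = None
            for guess in (prev, prev_row_hss[j]):
                if guess is not None:
                    hss = _polish("cistrans", p, guess.concentrations, HSS_TOL)
                    if hss is not None:
                        break
            if hss is None:
                try:
                    hss = find_hss("cistrans", p)
                except ConvergenceError:
                    failures.append((i, j))
                    logger.warning("HSS search failed at K_cis=%g, K_trans=%g", kc, kt)
                    prev = None
                    continue
            blocks = jacobian_blocks("cistrans", p, hss)
            M[i, j] = mode_mle(blocks, modes).mle
            prev = prev_row_hss[j] = hss
    return PhaseDiagram(
        kcis_grid=kcis_grid,
        ktrans_grid=ktrans_grid,
        mle_matrix=M,
        params=params,
        failures=tuple(failures),
    )


def phase_diagram_to_frame(pd_: PhaseDiagram):
    """Long-format table (k_cis, k_trans, mle) for CSV export."""
    import pandas as pd

    kc, kt = np.meshgrid(pd_.kcis_grid, pd_.ktrans_grid, indexing="ij")
    return pd.DataFrame(
        {"k_cis": kc.ravel(), "k_trans": kt.ravel(), "mle": pd_.mle_matrix.ravel()}
    )


def plot_phase_diagram(pd_: PhaseDiagram, ax=None):
    """Signed-colormap rendering: red = MLE > 0 (patterning), blue = stable."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vmax = np.nanmax(np.abs(pd_.mle_matrix)) or 1.0
    mesh = ax.pcolormesh(
        pd_.ktrans_grid,
        pd_.kcis_grid,
        pd_.mle_matrix,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        shading="nearest",
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("K_trans")
    ax.set_ylabel("K_cis")
    ax.figure.colorbar(mesh, ax=ax, label="MLE (1/time)")
    return ax
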