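"""Auxin-PIN-CUC dynamics on the margin grid.

Each cell i carries auxin a_i; each directed membrane (edge i->j) carries a
PIN allocation P_ij with sum_j P_ij = P_tot.  Auxin obeys

    da_i/dt = sigma_src*1(source) + sigma_bg - mu_a*a_i
              + D * sum_j (a_j - a_i) - sum_j J_ij

with carrier-mediated flux J_ij = T*(eff_i*P_ij*a_i - eff_j*P_ji*a_j)
(antisymmetric, so transport and diffusion conserve mass on the closed
tissue).  PIN allocations relax at rate rho toward per-cell targets set by
the polarization rule:

* up-the-gradient (UTG): membrane weight softmax(kappa * a_j) — PIN goes to
  membranes facing auxin-rich neighbors;
* with-the-flux (WTF): membrane weight proportional to
  max(F_ij, 0)**wtf_exponent + beta, where F_ij is the total net efflux
  (diffusive + carrier) across that membrane — PIN reinforces membranes the
  auxin already leaves through.

Static patterned CUC sets the phosphorylated PIN fraction
phi_i = cuc^h / (K_c^h + cuc^h) (quasi-equilibrium Hill).  The two model
variants read phi differently:

* PMM (polarization modulation): targets are the phi-weighted mix
  (1-phi)*UTG + phi*WTF; transport efficiency is unchanged.
* EMM (efficiency modulation): targets are pure UTG, but phosphorylated PIN
  transports more efficiently, eff_i = 1 + (epsilon-1)*phi_i applied to the
  effluxing cell's own term.
* utg_only: the CUC-blind control (pure UTG, eff = 1).

Integration is explicit fixed-step Euler with a stability guard checked at
parameter construction; steady state is declared when max_i |da_i/dt| falls
below ``tol_ss``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from scipy import sparse

from .tissue import MarginTissue, ScenarioTemplate

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "SimulationState",
    "SimulationResult",
    "phospho_fraction",
    "utg_weights",
    "wtf_weights",
    "edge_flux",
    "target_allocation",
    "initial_state",
    "step",
    "run_to_steady_state",
]

_VARIANTS = ("pmm", "emm", "utg_only")


@dataclasses.dataclass
class ModelParams:
    """Kinetic, allocation and numerical parameters.

    The defaults are the package's baseline calibration: they reproduce the
    qualitative wild-type sequence (distal convergence at the source,
    CUC-band repolarization, emergent proximal convergence and auxin
    maximum) on the default 20x5 template.  They are NOT a published
    parameter set; every value can be overridden, e.g. from a YAML file.

    Units are arbitrary concentration units (a.u.) and an arbitrary time
    unit t; rates are per t.
    """

    sigma_src: float = 2.0      # auxin production at the source cell (a.u./t)
    sigma_bg: float = 0.01      # background auxin production (a.u./t)
    mu_a: float = 0.02          # auxin turnover (1/t)
    D: float = 0.35             # passive cell-to-cell diffusion (1/t)
    T: float = 0.45             # transport rate per PIN unit (1/t)
    P_tot: float = 1.0          # total PIN per cell (PIN units)
    kappa: float = 12.0         # UTG sensitivity (relative-contrast units)
    wtf_exponent: float = 2.0   # flux-response exponent
    beta: float = 0.01          # baseline membrane affinity in the WTF rule
    K_c: float = 0.4            # CUC half-saturation of PIN phosphorylation (a.u.)
    h_c: float = 3.0            # Hill coefficient
    epsilon: float = 4.0        # efficiency multiplier of phospho-PIN (EMM)
    rho: float = 1.5            # PIN reallocation relaxation rate (1/t)
    mu_sink: float = 0.0        # extra turnover on the proximal boundary row
                                # (basipetal drainage toward the midvein/petiole)
    utg_relative: bool = True   # UTG senses relative (mean-normalized) auxin
    dt: float = 0.1             # integration step (t)
    tol_ss: float = 1e-6        # steady-state residual threshold (a.u./t)
    t_max: float = 4000.0       # integration horizon (t)
    variant: str = "pmm"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS} (got {self.variant!r})")
        for name in ("sigma_src", "sigma_bg", "mu_a", "mu_sink", "D", "T", "P_tot",
                     "kappa", "wtf_exponent", "rho", "tol_ss", "t_max", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (got {getattr(self, name)})")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0 (got {self.beta})")
        if self.K_c <= 0:
            raise ValueError(f"K_c must be > 0 (got {self.K_c})")
        if self.h_c < 1:
            raise ValueError(f"h_c must be >= 1 (got {self.h_c})")
        if self.epsilon < 1:
            raise ValueError(f"epsilon must be >= 1 (got {self.epsilon})")
        guard = self.dt * (
            self.mu_a + self.mu_sink + 4 * self.D
            + 4 * self.T * self.P_tot * max(1.0, self.epsilon)
        )
        if guard >= 1:
            raise ValueError(
                f"explicit-scheme stability guard violated: "
                f"dt*(mu_a + 4D + 4*T*P_tot*max(1,epsilon)) = {guard:.3f} >= 1"
            )

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class SimulationState:
    """Per-cell auxin, per-directed-edge PIN, phospho fraction, and time."""

    auxin: np.ndarray
    pin: np.ndarray
    phospho_fraction: np.ndarray
    t: float = 0.0

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.auxin.copy(), self.pin.copy(), self.phospho_fraction.copy(), self.t
        )


@dataclasses.dataclass
class SimulationResult:
    final_state: SimulationState
    converged: bool
    residual: float
    trajectory: Optional[list[SimulationState]] = None
    n_clamps: int = 0


def phospho_fraction(cuc, K_c: float, h_c: float):
    """Phosphorylated PIN fraction: Hill response to the local CUC level.

    phi = cuc^h / (K_c^h + cuc^h); phi(0) = 0, phi(K_c) = 1/2.
    """
    if K_c <= 0:
        raise ValueError(f"K_c must be > 0 (got {K_c})")
    cuc = np.asarray(cuc, dtype=float)
    if np.any(cuc < 0):
        raise ValueError("cuc must be >= 0")
    ch = cuc**h_c
    out = ch / (K_c**h_c + ch)
    return float(out) if out.ndim == 0 else out


def utg_weights(neighbor_auxin, kappa: float, relative: bool = False) -> np.ndarray:
    """Up-the-gradient membrane weights: softmax(kappa * neighbor auxin).

    With ``relative=True`` (the form the simulation uses) the neighbor
    auxin is first normalized by its mean, making the weights scale
    invariant: polarization then responds to relative contrast, so cells
    far from the source stay polarized even where absolute auxin is low.
    """
    a = np.asarray(neighbor_auxin, dtype=float)
    if a.size == 0:
        raise ValueError("utg_weights requires at least one neighbor")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0 (got {kappa})")
    if relative:
        a = a / max(a.mean(), 1e-12)
    z = kappa * a
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def wtf_weights(edge_fluxes, wtf_exponent: float = 2.0, beta: float = 0.01) -> np.ndarray:
    """With-the-flux membrane weights: rectified power law plus baseline.

    w_j = (max(J_j, 0)**wtf_exponent + beta) / sum_k (...); all-negative
    fluxes fall back to the uniform beta-only limit.
    """
    J = np.asarray(edge_fluxes, dtype=float)
    if J.size == 0:
        raise ValueError("wtf_weights requires at least one edge")
    if beta <= 0:
        raise ValueError(f"beta must be > 0 (got {beta})")
    g = np.maximum(J, 0.0) ** wtf_exponent + beta
    return g / g.sum()


def edge_flux(a_i, a_j, P_ij, P_ji, T: float, eff_i=1.0, eff_j=1.0):
    """Net carrier-mediated flux i->j: J_ij = T*(eff_i*P_ij*a_i - eff_j*P_ji*a_j)."""
    return T * (eff_i * np.asarray(P_ij) * a_i - eff_j * np.asarray(P_ji) * a_j)


# ---------------------------------------------------------------------------
# vectorized internals

class _Workspace:
    """Precomputed sparse incidence operators for one tissue."""

    def __init__(self, tissue: MarginTissue):
        E = tissue.n_edges
        n = tissue.n_cells
        ones = np.ones(E)
        self.by_src = sparse.csr_matrix(
            (ones, (tissue.edge_src, np.arange(E))), shape=(n, E)
        )
        self.src = tissue.edge_src
        self.dst = tissue.edge_dst
        self.rev = tissue.edge_rev
        self.sink_mask = (tissue.rows == tissue.n_rows).astype(float)

    def cell_sum(self, edge_vals: np.ndarray) -> np.ndarray:
        return self.by_src @ edge_vals


def _efficiency(phi: np.ndarray, params: ModelParams) -> np.ndarray:
    if params.variant == "emm":
        return 1.0 + (params.epsilon - 1.0) * phi
    return np.ones_like(phi)


def _edge_targets(
    a: np.ndarray,
    pin: np.ndarray,
    phi: np.ndarray,
    ws: _Workspace,
    params: ModelParams,
) -> np.ndarray:
    """Per-edge PIN allocation targets (sum to P_tot in every cell)."""
    a_dst = a[ws.dst]
    if params.utg_relative:
        # scale-invariant sensing: neighbor auxin normalized by its local mean
        deg = ws.cell_sum(np.ones_like(a_dst))
        nbr_mean = ws.cell_sum(a_dst) / deg
        a_dst = a_dst / np.maximum(nbr_mean[ws.src], 1e-12)
    z = params.kappa * a_dst
    z = z - z.max()
    w = np.exp(z)
    utg = w / ws.cell_sum(w)[ws.src]
    if params.variant != "pmm":
        return params.P_tot * utg
    # WTF senses the total net efflux (diffusive + carrier) across the membrane,
    # normalized by the cell's transport scale so beta is dimensionless
    J = params.T * (pin * a[ws.src] - pin[ws.rev] * a[ws.dst])
    F = J + params.D * (a[ws.src] - a[ws.dst])
    scale = params.T * params.P_tot * np.maximum(a[ws.src], 1e-12)
    g = np.maximum(F / scale, 0.0) ** params.wtf_exponent + params.beta
    wtf = g / ws.cell_sum(g)[ws.src]
    mix = (1.0 - phi[ws.src]) * utg + phi[ws.src] * wtf
    return params.P_tot * mix


def _dadt(
    a: np.ndarray,
    pin: np.ndarray,
    eff: np.ndarray,
    source_mask: np.ndarray,
    ws: _Workspace,
    params: ModelParams,
) -> np.ndarray:
    J = params.T * (eff[ws.src] * pin * a[ws.src] - eff[ws.dst] * pin[ws.rev] * a[ws.dst])
    exchange = ws.cell_sum(params.D * (a[ws.dst] - a[ws.src]) - J)
    return (
        params.sigma_src * source_mask
        + params.sigma_bg
        - (params.mu_a + params.mu_sink * ws.sink_mask) * a
        + exchange
    )


def target_allocation(cell: int, state: SimulationState, tissue: MarginTissue,
                      params: ModelParams) -> np.ndarray:
    """PIN allocation targets for one cell's directed edges (in edge order).

    PMM mixes UTG and WTF targets by the cell's phospho fraction; EMM and
    utg_only allocate purely up-the-gradient.  Targets sum to P_tot exactly.
    """
    ws = _Workspace(tissue)
    targets = _edge_targets(state.auxin, state.pin, state.phospho_fraction, ws, params)
    return targets[tissue.edge_src == cell]


def initial_state(template: ScenarioTemplate, params: ModelParams) -> SimulationState:
    """Initial condition: uniform auxin baseline and the template's PIN rule."""
    tissue = template.tissue
    n, E = tissue.n_cells, tissue.n_edges
    a = np.broadcast_to(np.asarray(template.initial_auxin, dtype=float), (n,)).copy()
    deg = tissue.degree
    if template.initial_pin_allocation == "apical":
        pin = np.zeros(E)
        up = tissue.edge_uy > 0
        pin[up] = params.P_tot
        has_up = np.zeros(n, dtype=bool)
        has_up[tissue.edge_src[up]] = True
        fallback = ~has_up[tissue.edge_src]
        pin[fallback] = params.P_tot / deg[tissue.edge_src[fallback]]
    else:
        pin = params.P_tot / deg[tissue.edge_src].astype(float)
    phi = phospho_fraction(tissue.cuc, params.K_c, params.h_c)
    return SimulationState(auxin=a, pin=pin, phospho_fraction=np.asarray(phi), t=0.0)


def step(state: SimulationState, tissue: MarginTissue, params: ModelParams) -> SimulationState:
    """One explicit Euler step (returns a new state; the input is untouched)."""
    ws = _Workspace(tissue)
    eff = _efficiency(state.phospho_fraction, params)
    dadt = _dadt(state.auxin, state.pin, eff, tissue.source_mask.astype(float), ws, params)
    targets = _edge_targets(state.auxin, state.pin, state.phospho_fraction, ws, params)
    a = state.auxin + params.dt * dadt
    n_clamps = int(np.count_nonzero(a < 0))
    if n_clamps:
        logger.warning("clamped %d negative auxin values at t=%.3f", n_clamps, state.t)
        a = np.maximum(a, 0.0)
    pin = state.pin + params.dt * params.rho * (targets - state.pin)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(pin))):
        raise FloatingPointError(
            f"non-finite state at t={state.t + params.dt:.3f}; "
            f"max|a|={np.nanmax(np.abs(a)):.3g}"
        )
    return SimulationState(a, pin, state.phospho_fraction.copy(), state.t + params.dt)


def run_to_steady_state(
    template: ScenarioTemplate,
    params: ModelParams,
    *,
    noise=None,
    rng: Optional[np.random.Generator] = None,
    record_every: Optional[int] = None,
) -> SimulationResult:
    """Integrate the template until steady state (or the horizon ``t_max``).

    Noise-free runs are fully deterministic.  ``noise`` is a
    :class:`~leafmargin.patterns.NoiseSpec`; CUC noise perturbs the static
    CUC field once before integration, auxin noise perturbs the initial
    condition and, under the ``resample_every`` schedule, is re-injected
    every ``tau`` time units (such runs integrate the full horizon and do
    not early-stop).
    """
    tissue = template.tissue
    cuc = tissue.cuc.copy()

    resample_steps = 0
    last_noise_step = None
    amplitude = 0.0
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        if noise.target == "cuc":
            cuc = cuc * (1.0 + noise.amplitude * rng.uniform(-1.0, 1.0, cuc.size))
        elif noise.target == "auxin":
            amplitude = noise.amplitude
            if noise.schedule == "resample_every":
                resample_steps = max(1, int(round(noise.tau / params.dt)))
                # score the pattern, not the noise phase: no injections in
                # the final settling window
                settle = getattr(noise, "settle_time", 0.0)
                last_noise_step = int((params.t_max - settle) / params.dt)

    state = initial_state(template, params)
    state.phospho_fraction = np.asarray(phospho_fraction(cuc, params.K_c, params.h_c))
    if noise is not None and noise.target == "auxin":
        state.auxin = state.auxin * (
            1.0 + noise.amplitude * rng.uniform(-1.0, 1.0, state.auxin.size)
        )

    ws = _Workspace(tissue)
    eff = _efficiency(state.phospho_fraction, params)
    source = tissue.source_mask.astype(float)
    a, pin = state.auxin, state.pin
    n_steps = int(np.ceil(params.t_max / params.dt))
    trajectory = [] if record_every else None
    n_clamps = 0
    converged = False
    residual = np.inf
    dt = params.dt

    for k in range(n_steps):
        if (resample_steps and k > 0 and k % resample_steps == 0
                and (last_noise_step is None or k <= last_noise_step)):
            a = a * (1.0 + amplitude * rng.uniform(-1.0, 1.0, a.size))
        dadt = _dadt(a, pin, eff, source, ws, params)
        targets = _edge_targets(a, pin, state.phospho_fraction, ws, params)
        a = a + dt * dadt
        neg = a < 0
        if neg.any():
            n_clamps += int(np.count_nonzero(neg))
            a = np.maximum(a, 0.0)
        pin = pin + dt * params.rho * (targets - pin)
        if record_every and (k + 1) % record_every == 0:
            trajectory.append(
                SimulationState(a.copy(), pin.copy(), state.phospho_fraction.copy(),
                                (k + 1) * dt)
            )
        if (k + 1) % 25 == 0 or k == n_steps - 1:
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(
                    f"non-finite auxin at t={(k + 1) * dt:.2f} "
                    f"(variant={params.variant}); last residual {residual:.3g}"
                )
            # steady state of the full system: auxin AND PIN reallocation at rest
            residual = max(
                float(np.max(np.abs(dadt))),
                float(params.rho * np.max(np.abs(targets - pin))),
            )
            if residual < params.tol_ss and not resample_steps:
                converged = True
                break

    if n_clamps:
        logger.warning("run clamped %d negative auxin values in total", n_clamps)
    final = SimulationState(a, pin, state.phospho_fraction, (k + 1) * dt)
    if not converged:
        residual = max(
            float(np.max(np.abs(_dadt(a, pin, eff, source, ws, params)))),
            float(params.rho * np.max(np.abs(
                _edge_targets(a, pin, state.phospho_fraction, ws, params) - pin
            ))),
        )
    return SimulationResult(
        final_state=final,
        converged=converged,
        residual=residual,
        trajectory=trajectory,
        n_clamps=n_clamps,
    )
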