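"""Mass-action ODE model of redox-coupled γD-crystallin aggregation.

The network tracks a native monomer N that transiently misfolds
(N ⇌ I_red), is trapped by an internal disulfide through exchange with
the glutathione couple (I_red + GSSG ⇌-ish I_ox + 2 GSH), dimerizes
through the rate-limiting bimolecular step (2 I_ox → D, inhibited by
myo-inositol), and polymerizes into short extended chains that coalesce
into globules and eventually settle.  Extended aggregates are tracked
by two moments: particle number P0 and monomer mass P1 (mean chain
length = P1/P0).  Solution turbidity is a weighted sum of aggregated
mass; settled material remains visible to the vertically oriented
plate-reader optics.

Conserved quantities along every trajectory:

* total protein monomer-equivalents  N + I_red + I_ox + D + D_red + P1 + G1 + S1
* total glutathione                  GSH + 2·GSSG
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .containers import AdditionEvent, TurbidityTrace, WellCondition
from .params import ParameterError, RateParams

__all__ = [
    "SystemState",
    "Trajectory",
    "AggregationModel",
    "SimulationError",
    "inhibition_factor",
    "build_rhs",
    "simulate",
    "turbidity_observable",
    "soluble_thiol_distribution",
    "apply_event",
]

#: conversion from a μM/s protein flux to the mM/s it moves on the
#: glutathione pool
_UM_TO_MM = 1.0e-3

#: integrator tolerances; negativity beyond this is treated as failure
_NEG_TOL = 1.0e-9


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails or produces negative states."""


def inhibition_factor(inositol_mM: float, K_I: float) -> float:
    """Noncompetitive inhibition factor 1/(1 + [inositol]/K_I) ∈ (0, 1].

    Applied multiplicatively to the bimolecular dimerization constant.
    """
    if inositol_mM < 0:
        raise ParameterError(f"inositol must be >= 0, got {inositol_mM!r}")
    if K_I <= 0:
        raise ParameterError(f"K_I must be > 0, got {K_I!r}")
    return 1.0 / (1.0 + inositol_mM / K_I)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous composition of a reaction well.

    Protein pools are μM monomer-equivalents; the transient dimer D is
    counted as 2 monomer-equivalents per particle.  P0 is the number
    concentration of extended chains on the same μM scale.
    """

    N: float = 0.0        # native monomer
    I_red: float = 0.0    # misfolded, reduced
    I_ox: float = 0.0     # misfolded, disulfide-locked precursor
    D: float = 0.0        # transient dimer of locked precursors (monomer-equiv.)
    D_red: float = 0.0    # transient dimer of reduced misfolded monomers
    P0: float = 0.0       # extended-chain number concentration
    P1: float = 0.0       # monomer mass in extended chains
    G1: float = 0.0       # monomer mass in suspended globules
    S1: float = 0.0       # monomer mass in settled globules
    GSH: float = 0.0      # mM
    GSSG: float = 0.0     # mM
    inositol: float = 0.0  # mM
    volume: float = 100.0  # μL

    _FIELDS = ("N", "I_red", "I_ox", "D", "D_red", "P0", "P1", "G1", "S1",
               "GSH", "GSSG", "inositol", "volume")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            if getattr(self, name) < 0:
                raise ParameterError(f"state field {name} must be >= 0")

    # -- vector interface -------------------------------------------------
    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if np.any(y < -_NEG_TOL):
            bad = [cls._FIELDS[i] for i in np.nonzero(y < -_NEG_TOL)[0]]
            raise SimulationError(f"negative concentrations in {bad}")
        y = np.clip(y, 0.0, None)
        return cls(**dict(zip(cls._FIELDS, y)))

    # -- convenience constructors -----------------------------------------
    @classmethod
    def initial(
        cls,
        protein_uM: float,
        gsh_mM: float = 0.0,
        gssg_mM: float = 0.5,
        inositol_mM: float = 0.0,
        volume_uL: float = 100.0,
    ) -> "SystemState":
        """All protein native; glutathione and inositol as dosed."""
        return cls(N=protein_uM, GSH=gsh_mM, GSSG=gssg_mM,
                   inositol=inositol_mM, volume=volume_uL)

    @classmethod
    def from_condition(cls, cond: WellCondition, volume_uL: float = 100.0) -> "SystemState":
        from .redox import speciate

        if cond.total_glutathione_mM > 0:
            gsh, gssg = speciate(cond.oxd, cond.total_glutathione_mM)
        else:
            gsh = gssg = 0.0
        return cls.initial(cond.protein_uM, gsh, gssg, cond.inositol_mM, volume_uL)

    # -- derived quantities -----------------------------------------------
    @property
    def total_protein(self) -> float:
        """Total monomer-equivalents (μM); conserved under reaction dynamics."""
        return (self.N + self.I_red + self.I_ox + self.D + self.D_red
                + self.P1 + self.G1 + self.S1)

    @property
    def total_glutathione(self) -> float:
        """GSH + 2·GSSG (mM); conserved under reaction dynamics."""
        return self.GSH + 2.0 * self.GSSG

    @property
    def aggregated_mass(self) -> float:
        return self.P1 + self.G1 + self.S1


def build_rhs(params: RateParams):
    """Return dy/dt for the mass-action network as a function f(t, y).

    The derivative conserves total monomer-equivalents and GSH + 2·GSSG
    exactly (term-by-term stoichiometry), for any state.
    """
    p = params

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        (N, I_red, I_ox, D, D_red, P0, P1, G1, S1, GSH, GSSG, ino, vol) = y
        # negative excursions within solver tolerance: use clipped values
        N = max(N, 0.0); I_red = max(I_red, 0.0); I_ox = max(I_ox, 0.0)
        D = max(D, 0.0); D_red = max(D_red, 0.0); P0 = max(P0, 0.0); P1 = max(P1, 0.0)
        G1 = max(G1, 0.0); GSH = max(GSH, 0.0); GSSG = max(GSSG, 0.0)

        f_ino = inhibition_factor(ino, p.K_I)
        k_coal = p.k_coal * (f_ino if p.inhibit_coal else 1.0)

        r_mis = p.k_mis * N
        r_fold = p.k_fold * I_red
        r_ox = p.k_ox * I_red * GSSG          # μM/s, I_red + GSSG -> I_ox + 2 GSH
        r_red = p.k_red * I_ox * GSH          # μM/s, I_ox + 2 GSH -> I_red + GSSG
        r_dim = p.k_dim * f_ino * I_ox ** 2   # dimer-formation events, μM/s
        r_diss = p.k_diss * 0.5 * D           # dimer-dissociation events
        r_nuc = p.k_elong * 0.5 * D * I_ox    # chain births: D + I_ox -> trimer chain
        r_elg = p.k_elong * P0 * I_ox         # chain growth, μM mass/s
        r_pp = k_coal * P0 * P0               # chain-chain coalescence events
        r_pp_mass = 2.0 * k_coal * P0 * P1    # mass moved by chain-chain events
        r_pg_num = k_coal * P0 * G1           # chain captured by a globule
        r_pg_mass = k_coal * G1 * P1
        r_set = p.k_settle * G1

        dN = -r_mis + r_fold
        dI_red = r_mis - r_fold - r_ox + r_red
        dI_ox = r_ox - r_red - 2.0 * r_dim + 2.0 * r_diss - r_nuc - r_elg
        dD = 2.0 * r_dim - 2.0 * r_diss - 2.0 * r_nuc
        dP0 = r_nuc - 2.0 * r_pp - r_pg_num
        dP1 = 3.0 * r_nuc + r_elg - r_pp_mass - r_pg_mass
        dG1 = r_pp_mass + r_pg_mass - r_set
        dS1 = r_set
        dGSH = (2.0 * r_ox - 2.0 * r_red) * _UM_TO_MM
        dGSSG = (-r_ox + r_red) * _UM_TO_MM

        dD_red = 0.0
        if p.dim_oxidizes:
            # misfolding-before-oxidation ordering: 2 I_red -> D_red,
            # then D_red + GSSG -> I_ox + I_red + 2 GSH; the reduced dimer
            # dissociates back to reduced monomers
            r_dim2 = p.k_dim * f_ino * I_red ** 2
            r_diss2 = p.k_diss * 0.5 * D_red
            r_dox = p.k_ox * 0.5 * D_red * GSSG
            dI_red += -2.0 * r_dim2 + 2.0 * r_diss2 + r_dox
            dI_ox += r_dox
            dD_red += 2.0 * r_dim2 - 2.0 * r_diss2 - 2.0 * r_dox
            dGSH += 2.0 * r_dox * _UM_TO_MM
            dGSSG += -r_dox * _UM_TO_MM

        return np.array([dN, dI_red, dI_ox, dD, dD_red, dP0, dP1, dG1, dS1,
                         dGSH, dGSSG, 0.0, 0.0])

    return rhs


@dataclass
class Trajectory:
    """Integrated species trajectories on a fixed output grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_fields), columns per SystemState._FIELDS
    params: RateParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_array(self.states[i])

    @property
    def final_state(self) -> SystemState:
        return self.state_at(-1)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SystemState._FIELDS.index(name)]

    # -- diagnostics -------------------------------------------------------
    def conservation_error(self) -> dict:
        """Max relative drift of the two conserved totals along the run."""
        prot_idx = [SystemState._FIELDS.index(n)
                    for n in ("N", "I_red", "I_ox", "D", "D_red", "P1", "G1", "S1")]
        prot = self.states[:, prot_idx].sum(axis=1)
        glut = self.species("GSH") + 2.0 * self.species("GSSG")
        out = {}
        for key, tot in (("protein", prot), ("glutathione", glut)):
            if tot[0] > 0:
                out[key] = float(np.max(np.abs(tot - tot[0])) / tot[0])
            else:
                out[key] = float(np.max(np.abs(tot - tot[0])))
        return out

    def turbidity(self, w_P: float | None = None, w_G: float | None = None,
                  well: str = "sim", condition: WellCondition | None = None) -> TurbidityTrace:
        return turbidity_observable(self, w_P, w_G, well=well, condition=condition)

    def to_frame(self):
        """Long-format table (time_s, species, value, units)."""
        import pandas as pd

        rows = []
        for j, name in enumerate(SystemState._FIELDS):
            units = "mM" if name in ("GSH", "GSSG", "inositol") else (
                "uL" if name == "volume" else "uM")
            rows.append(pd.DataFrame({
                "time_s": self.times,
                "species": name,
                "value": self.states[:, j],
                "units": units,
            }))
        return pd.concat(rows, ignore_index=True)

    def plot(self, ax=None, species=("N", "I_ox", "P1", "G1", "S1")):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in species:
            ax.plot(self.times / 3600.0, self.species(name), label=name)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (μM monomer-equiv.)")
        ax.legend()
        return ax


def simulate(params: RateParams, initial: SystemState, t_grid: np.ndarray) -> Trajectory:
    """Integrate the network on a fixed output grid with a stiff solver.

    Tolerances (rtol 1e-8, atol 1e-12 μM) keep relative conservation
    error of both invariants at or below 1e-6; states more negative
    than −1e-9 raise :class:`SimulationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ParameterError("t_grid must be a strictly increasing 1-D array")
    y0 = initial.to_array()
    rhs = build_rhs(params)
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA",
        t_eval=t_grid, rtol=1.0e-8, atol=1.0e-12,
    )
    if not sol.success:
        raise SimulationError(
            f"stiff integration failed on [{t_grid[0]}, {t_grid[-1]}] s: {sol.message}")
    y = sol.y.T
    if np.any(y < -_NEG_TOL):
        i, j = np.unravel_index(np.argmin(y), y.shape)
        raise SimulationError(
            f"negative concentration {y[i, j]:.3e} in {SystemState._FIELDS[j]} "
            f"at t={t_grid[i]:.0f} s")
    return Trajectory(times=t_grid, states=np.clip(y, 0.0, None), params=params)


def turbidity_observable(
    traj: Trajectory,
    w_P: float | None = None,
    w_G: float | None = None,
    well: str = "sim",
    condition: WellCondition | None = None,
) -> TurbidityTrace:
    """Turbidity τ(t) = w_P·P1 + w_G·(G1 + S1).

    Settled mass stays visible (vertically oriented optics).  With
    w_P = w_G the observable is strictly proportional to total
    aggregated mass; w_G > w_P lets late coalescence produce a second
    rise (biphasic trace).
    """
    w_P = traj.params.w_P if w_P is None else w_P
    w_G = traj.params.w_G if w_G is None else w_G
    if w_P < 0 or w_G < 0:
        raise ParameterError("turbidity weights must be >= 0")
    tau = w_P * traj.species("P1") + w_G * (traj.species("G1") + traj.species("S1"))
    if condition is None:
        s0 = traj.state_at(0)
        condition = WellCondition(
            protein_uM=s0.total_protein,
            inositol_mM=s0.inositol,
            oxd=(2 * s0.GSSG / s0.total_glutathione) if s0.total_glutathione > 0 else 0.0,
            total_glutathione_mM=s0.total_glutathione,
        )
    return TurbidityTrace(well=well, condition=condition, times=traj.times, turbidity=tau)


def soluble_thiol_distribution(state: SystemState, n_cys: int = 4) -> dict[int, float]:
    """Fractions of the soluble protein pool by free-thiol count.

    Fully reduced soluble species (N, I_red) carry n_cys free thiols;
    the disulfide-locked precursor and the transient dimer carry
    n_cys − 2.  Aggregated mass (P1, G1) is excluded: aggregates
    contain no fully reduced protein, and settled material (S1) is not
    sampled when pipetting from bulk solution.
    """
    if n_cys not in (4, 6):
        raise ParameterError("n_cys must be 4 or 6")
    reduced = state.N + state.I_red + state.D_red
    locked = state.I_ox + state.D
    soluble = reduced + locked
    if soluble <= 0:
        raise ParameterError("no soluble protein")
    out = {n_cys: reduced / soluble, n_cys - 2: locked / soluble}
    return {k: v for k, v in out.items() if v > 0 or k == n_cys}


def apply_event(state: SystemState, event: AdditionEvent) -> SystemState:
    """Apply a late-addition/dilution event instantaneously.

    All solution species are diluted by V_old/(V_old+V_add); inositol is
    set to the volume-weighted mixture; a fraction of extended-chain
    mass is returned to the disulfide-locked monomer pool (fragile
    early aggregates), with particle number rescaled proportionally.
    """
    v_old = state.volume
    v_new = v_old + event.added_volume_uL
    dil = v_old / v_new if v_new > 0 else 1.0
    y = {f: getattr(state, f) * dil for f in SystemState._FIELDS
         if f not in ("inositol", "volume")}
    ino = (state.inositol * v_old + event.added_inositol_mM * event.added_volume_uL) / v_new
    frac = event.disruption_fraction
    if frac > 0:
        y["I_ox"] += frac * y["P1"]
        y["P0"] *= (1.0 - frac)
        y["P1"] *= (1.0 - frac)
    return SystemState(inositol=ino, volume=v_new, **y)


class AggregationModel:
    """Mechanistic aggregation model for one well condition.

    statsmodels-style entry point: build the model from a condition
    (or an explicit initial state) and rate parameters, then call
    :meth:`simulate` to obtain a :class:`Trajectory` results object.

    Parameters
    ----------
    params : RateParams
        Rate constants; ``crystagg.default_params()`` gives the shipped
        calibrated set.
    initial : SystemState, optional
        Explicit initial composition; alternatively use
        :meth:`from_condition`.
    """

    def __init__(self, params: RateParams, initial: SystemState):
        self.params = params
        self.initial = initial

    @classmethod
    def from_condition(cls, params: RateParams, condition: WellCondition,
                       volume_uL: float = 100.0) -> "AggregationModel":
        return cls(params, SystemState.from_condition(condition, volume_uL))

    def simulate(self, duration_s: float = 16200.0, read_interval_s: float = 90.0,
                 t_grid: np.ndarray | None = None) -> Trajectory:
        """Integrate over the incubation (default 4.5 h read every 90 s)."""
        if t_grid is None:
            t_grid = np.arange(0.0, duration_s + 0.5 * read_interval_s, read_interval_s)
        if self.initial.total_protein == 0:
            # degenerate input: no protein, flat zero trajectory
            states = np.tile(self.initial.to_array(), (len(t_grid), 1))
            return Trajectory(times=np.asarray(t_grid, float), states=states,
                              params=self.params)
        return simulate(self.params, self.initial, t_grid)

    def simulate_with_events(
        self,
        events: tuple[AdditionEvent, ...],
        duration_s: float = 16200.0,
        read_interval_s: float = 90.0,
    ) -> Trajectory:
        """Piecewise integration with instantaneous addition events.

        The output grid is the regular read grid; the reading that
        falls inside each event's dead time (one read interval) is kept
        in the grid and reflects the post-event state.
        """
        events = tuple(sorted(events, key=lambda e: e.time_s))
        for e in events:
            if not 0.0 <= e.time_s <= duration_s:
                raise ParameterError("event time must lie within the incubation")
        full_grid = np.arange(0.0, duration_s + 0.5 * read_interval_s, read_interval_s)
        state = self.initial
        pieces: list[np.ndarray] = []
        seg_start = 0.0
        first = True
        for e in list(events) + [None]:
            seg_end = duration_s if e is None else e.time_s
            if first:
                mask = (full_grid >= seg_start) & (full_grid <= seg_end)
            else:
                mask = (full_grid > seg_start) & (full_grid <= seg_end)
            seg_t = full_grid[mask]
            inner = np.unique(np.concatenate([[seg_start], seg_t, [seg_end]]))
            if inner.size >= 2 and state.total_protein > 0 and seg_end > seg_start:
                traj = simulate(self.params, state, inner)
                keep = np.isin(inner, seg_t)
                pieces.append(traj.states[keep])
                state = traj.final_state
            else:
                pieces.append(np.tile(state.to_array(), (seg_t.size, 1)))
            if e is not None:
                state = apply_event(state, e)
                seg_start = seg_end
                first = False
        states = np.vstack(pieces) if pieces else np.empty((0, len(SystemState._FIELDS)))
        if states.shape[0] != full_grid.size:
            raise SimulationError("event segmentation lost grid points")
        return Trajectory(times=full_grid, states=states, params=self.params)
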