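"""Deterministic mass-action integration, settle-time detection, decoding.

Concentrations are in nM and time in s.  The solver is an implicit
stiff-capable method (BDF) with an analytic Jacobian assembled from the
bilinear mass-action structure; defaults (rtol 1e-8, atol 1e-6 nM) resolve
benchmark-scale networks of a few hundred species in seconds.

The settle criterion is a sustained band: the settle time is the earliest
grid time after which every tracked output stays within ``epsilon``
(default 5%) of its final value.  Decoding compares the two fluorescence
plateaus per output wire as a ratio, because absolute fluorescence scales
with the circuit concentration unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .compiler import CRN
from .errors import DecodingError, DomainCodeError, SimulationError
from .gates import fluorescence_name


def build_ode(crn: CRN):
    """Vectorised RHS and Jacobian for a compiled CRN.

    Returns ``(rhs, jac, y0, names)``.  Unimolecular reactions use a
    sentinel index pointing at a constant 1.0 slot appended to the state.
    """
    n_s = len(crn.species)
    n_r = len(crn.reactions)
    index = {sp.structure: i for i, sp in enumerate(crn.species)}
    y0 = np.array([sp.init_conc for sp in crn.species], dtype=float)
    names = [sp.name for sp in crn.species]

    ra = np.empty(n_r, dtype=int)
    rb = np.empty(n_r, dtype=int)   # n_s == sentinel (constant 1)
    rates = np.empty(n_r, dtype=float)
    rows, cols, vals = [], [], []
    for r, rxn in enumerate(crn.reactions):
        rates[r] = rxn.rate
        ri = [index[sp.structure] for sp in rxn.reactants]
        ra[r] = ri[0]
        rb[r] = ri[1] if len(ri) == 2 else n_s
        net: dict[int, int] = {}
        for sp in rxn.reactants:
            net[index[sp.structure]] = net.get(index[sp.structure], 0) - 1
        for sp in rxn.products:
            net[index[sp.structure]] = net.get(index[sp.structure], 0) + 1
        for i, delta in net.items():
            if delta:
                rows.append(i)
                cols.append(r)
                vals.append(float(delta))
    stoich = sparse.csr_matrix((vals, (rows, cols)), shape=(n_s, n_r))

    bi = rb < n_s

    def rhs(t, y):
        y_ext = np.append(y, 1.0)
        v = rates * y_ext[ra] * y_ext[rb]
        return stoich @ v

    r_idx = np.arange(n_r)

    def jac(t, y):
        y_ext = np.append(y, 1.0)
        # dv_r/dy: wrt first reactant -> k * y[rb]; wrt second -> k * y[ra]
        data = np.concatenate([rates * y_ext[rb], (rates * y_ext[ra])[bi]])
        jrows = np.concatenate([r_idx, r_idx[bi]])
        jcols = np.concatenate([ra, rb[bi]])
        dv = sparse.csr_matrix((data, (jrows, jcols)), shape=(n_r, n_s))
        return (stoich @ dv).toarray()

    return rhs, jac, y0, names


@dataclass
class Trajectory:
    """Time-resolved concentrations on a fixed output grid."""

    t: np.ndarray
    conc: np.ndarray            # shape (n_times, n_species)
    names: list[str]
    crn: Optional[CRN] = None
    rtol: float = 1e-8
    atol: float = 1e-6
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {name: i for i, name in enumerate(self.names)}

    def series(self, name: str) -> np.ndarray:
        try:
            return self.conc[:, self.index[name]]
        except KeyError:
            raise DomainCodeError(f"species {name!r} not in trajectory") from None

    def final(self, name: str) -> float:
        return float(self.series(name)[-1])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def fluorescence_names(self) -> list[str]:
        if self.crn is None:
            return []
        return [sp.name for sp in self.crn.species if sp.role == "fluorescence"]

    def to_dataframe(self, species: Optional[Sequence[str]] = None) -> pd.DataFrame:
        names = list(species) if species is not None else self.names
        data = {"time_s": self.t}
        for name in names:
            data[name] = self.series(name)
        return pd.DataFrame(data)

    def write_csv(self, path, species: Optional[Sequence[str]] = None) -> None:
        self.to_dataframe(species).to_csv(path, index=False,
                                          float_format="%.10g")


def simulate(
    crn: CRN,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    grid_dt: Optional[float] = None,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the CRN ODEs deterministically to ``t_end`` seconds.

    The output grid is 0.1 s, coarsened automatically so that no more than
    ~20 000 points are stored; pass ``grid_dt`` to fix it.
    """
    if t_end <= 0:
        raise SimulationError("t_end must be positive")
    if not crn.species:
        t = np.array([0.0, t_end])
        return Trajectory(t=t, conc=np.zeros((2, 0)), names=[], crn=crn,
                          rtol=rtol, atol=atol)
    dt = grid_dt if grid_dt is not None else max(0.1, t_end / 20000.0)
    t_eval = np.arange(0.0, t_end + dt / 2, dt)
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    rhs, jac, y0, names = build_ode(crn)
    if not crn.reactions:
        conc = np.tile(y0, (len(t_eval), 1))
        return Trajectory(t=t_eval, conc=conc, names=names, crn=crn,
                          rtol=rtol, atol=atol)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol, jac=jac)
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed for CRN with {len(crn.species)} species "
            f"at t_end={t_end}: {sol.message}"
        )
    return Trajectory(t=sol.t, conc=sol.y.T, names=names, crn=crn,
                      rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# Settle-time detection


@dataclass
class SettleReport:
    settle_time: float
    epsilon: float
    t_end: float
    plateaus: dict[str, float]


def settle_time(
    traj: Trajectory,
    outputs: Optional[Sequence[str]] = None,
    epsilon: float = 0.05,
    abs_floor: float = 1e-3,
) -> SettleReport:
    """Earliest time after which every output stays within ``epsilon`` of
    its final value.

    The band is ``epsilon * |final| + abs_floor`` (the floor, in nM, keeps
    identically-zero outputs from tripping on solver noise).  ``outputs``
    defaults to all fluorescence species.
    """
    names = list(outputs) if outputs is not None else traj.fluorescence_names()
    if not names:
        raise DomainCodeError("no outputs to measure settle time on")
    ok = np.ones(len(traj.t), dtype=bool)
    plateaus = {}
    for name in names:
        y = traj.series(name)
        final = float(y[-1])
        plateaus[name] = final
        ok &= np.abs(y - final) <= epsilon * abs(final) + abs_floor
    not_ok = np.flatnonzero(~ok)
    settle = 0.0 if not_ok.size == 0 else float(traj.t[min(not_ok[-1] + 1,
                                                           len(traj.t) - 1)])
    return SettleReport(settle_time=settle, epsilon=epsilon,
                        t_end=traj.t_end, plateaus=plateaus)


# ---------------------------------------------------------------------------
# Logic decoding


@dataclass
class LogicOutcome:
    """A decoded output word (MSB = highest-indexed wire, leftmost)."""

    word: str
    bits: tuple[int, ...]
    decimal: int
    plateaus: dict[str, tuple[float, float]]   # wire -> (Y_x1, Y_x2) in nM


def decode_word(
    traj: Trajectory,
    wires: Sequence[str],
    ratio_threshold: float = 10.0,
    min_signal: float = 1.0,
) -> LogicOutcome:
    """Decode reporter plateaus into a logic word.

    ``wires`` are the reporter input wires, MSB first.  A bit reads 1 when
    the logic-1 fluorescence plateau exceeds ``ratio_threshold`` times the
    logic-0 plateau, and symmetrically for 0; anything else (including both
    channels below ``min_signal`` nM) raises :class:`DecodingError` rather
    than guessing, since it indicates a malfunctioning circuit.
    """
    bits = []
    plateaus: dict[str, tuple[float, float]] = {}
    for wire in wires:
        y1 = traj.final(fluorescence_name(wire, 0))
        y2 = traj.final(fluorescence_name(wire, 1))
        plateaus[wire] = (y1, y2)
        if max(y1, y2) < min_signal:
            raise DecodingError(
                f"wire {wire!r}: both fluorescence channels below "
                f"{min_signal} nM (Y1={y1:.3g}, Y2={y2:.3g})"
            )
        if y2 >= ratio_threshold * y1:
            bits.append(1)
        elif y1 >= ratio_threshold * y2:
            bits.append(0)
        else:
            raise DecodingError(
                f"wire {wire!r}: ambiguous plateau ratio "
                f"(Y1={y1:.4g} nM, Y2={y2:.4g} nM, threshold {ratio_threshold})"
            )
    word = "".join(str(b) for b in bits)
    return LogicOutcome(word=word, bits=tuple(bits), decimal=int(word, 2),
                        plateaus=plateaus)


def plot_trajectory(traj: Trajectory, species: Optional[Sequence[str]] = None,
                    path: Optional[str] = None):
    """Quick fluorescence/trajectory plot (matplotlib, Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(species) if species is not None else traj.fluorescence_names()
    fig, ax = plt.subplots(figsize=(7, 4))
    for name in names:
        ax.plot(traj.t, traj.series(name), label=name)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("concentration (nM)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
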