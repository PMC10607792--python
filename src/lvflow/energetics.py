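"""Hemodynamic quantities computed from flow states.

All definitions follow the intraventricular-flow conventions:

* kinetic-energy density ``KE = 1/2 rho |v|^2`` (J/m^3) and its spatial
  average over the lumen;
* vorticity ``Omega = curl v`` (1/s): the out-of-plane component in 2D; its
  *magnitude* average uses ``|Omega_z|`` (the signed average measures the
  rotational balance of the lumen flow and vanishes for mirror-symmetric
  vortex pairs);
* hemodynamic force ``F = \\int_S sigma . n dS`` over the lumen wall (IO
  excluded), ``sigma = -p I + mu (grad v + grad v^T)``, with ``n`` outward
  from the fluid; F is the force the moving blood and pressure field exert
  through the wall interface.  Its component along the base-apex axis (+y in
  2D, +z in 3D, positive toward the base) is reported as the HDF;
* IO flow rate ``Q = \\int_IO v . n dA`` (outflow positive; mL/s in 3D, the
  2D analog Q' is an area flux in mm^2/s);
* IO kinetic power ``P = \\int_IO KE (v . n) dA`` (mW; positive when kinetic
  energy leaves the lumen);
* stroke volume ``SV = V_ED - V_ES``, cross-checked against the systolic
  time integral of Q.

Geometry passed around is the solver's (SI); outputs use the units above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fem import FemSpace

__all__ = ["HemoSeries", "ke_density", "ke_average", "vorticity",
           "vorticity_averages", "hemodynamic_force", "flow_rate",
           "stroke_volume", "io_power", "compute_series"]


def _sync(space: FemSpace, state) -> None:
    if not np.shares_memory(space.verts, state.verts) and \
            not np.array_equal(space.verts, state.verts):
        space.set_coords(state.verts)


def ke_density(state, props) -> np.ndarray:
    """Pointwise kinetic-energy density 1/2 rho |v|^2 at velocity nodes (J/m^3)."""
    return 0.5 * props.density * np.sum(np.asarray(state.v) ** 2, axis=1)


def ke_average(space: FemSpace, state, props) -> float:
    """Lumen-averaged kinetic-energy density (J/m^3)."""
    _sync(space, state)
    meas = space.measure()
    if meas <= 0:
        raise ValueError("zero-measure domain")
    vq = space.interp_vel(state.v)
    ke = 0.5 * props.density * np.sum(vq ** 2, axis=2)
    return space.integrate(ke) / meas


def vorticity(space: FemSpace, state):
    """Vorticity at quadrature points: (E, q) scalar Omega_z in 2D,
    (E, q, 3) vector in 3D."""
    _sync(space, state)
    g = space.grad_vel(state.v)            # (E, q, comp, dx)
    if space.dim == 2:
        return g[..., 1, 0] - g[..., 0, 1]
    return np.stack([g[..., 2, 1] - g[..., 1, 2],
                     g[..., 0, 2] - g[..., 2, 0],
                     g[..., 1, 0] - g[..., 0, 1]], axis=-1)


def vorticity_averages(space: FemSpace, state) -> tuple[float, float]:
    """(magnitude average, signed average), both 1/s.

    2D: area averages of |Omega_z| and Omega_z.  3D: volume average of
    ||Omega|| and of the axial (base-apex) component Omega_z.
    """
    _sync(space, state)
    om = vorticity(space, state)
    meas = space.measure()
    if meas <= 0:
        raise ValueError("zero-measure domain")
    if space.dim == 2:
        return (space.integrate(np.abs(om)) / meas,
                space.integrate(om) / meas)
    mag = np.linalg.norm(om, axis=-1)
    return (space.integrate(mag) / meas,
            space.integrate(om[..., 2]) / meas)


def _axis_vec(dim: int) -> np.ndarray:
    e = np.zeros(dim)
    e[dim - 1] = 1.0     # +y (2D) / +z (3D) toward the base
    return e


def hemodynamic_force(space: FemSpace, state, props, tag: str = "wall"):
    """Traction integral F = int_S sigma.n dS over the tagged boundary.

    Returns ``(F, HDF)``: the force vector (N; per meter depth in 2D) and its
    base-apex component.  ``n`` is outward from the fluid, so for still fluid
    at uniform pressure over a closed boundary F = 0.
    """
    _sync(space, state)
    mu = props.dynamic_viscosity
    F = np.zeros(space.dim)
    found = False
    for fd in space.facet_data(tag):
        found = True
        vloc = state.v[fd["vconn"]]                # (nloc, dim)
        ploc = state.p[fd["pconn"]]
        g = np.einsum("qnd,nc->qcd", fd["veldN"], vloc)
        pq = fd["pN"] @ ploc
        sig = mu * (g + np.swapaxes(g, 1, 2))
        sig[:, range(space.dim), range(space.dim)] -= pq[:, None]
        tr = np.einsum("qcd,qd->qc", sig, fd["normal"])
        F += np.einsum("qc,q->c", tr, fd["w"])
    if not found:
        raise ValueError(f"no boundary facets tagged '{tag}'")
    return F, float(F @ _axis_vec(space.dim))


def flow_rate(space: FemSpace, state) -> float:
    """IO flux int_IO v.n (outflow positive): mL/s in 3D, mm^2/s in 2D."""
    _sync(space, state)
    q = 0.0
    found = False
    for fd in space.facet_data("io"):
        found = True
        vq = np.einsum("qn,nc->qc", fd["velN"], state.v[fd["vconn"]])
        q += np.einsum("qc,qc,q->", vq, fd["normal"], fd["w"])
    if not found:
        raise ValueError("no boundary facets tagged 'io'")
    return q * 1e6   # m^3/s -> mL/s, or m^2/s -> mm^2/s


def io_power(space: FemSpace, state, props) -> float:
    """Kinetic power through IO: int_IO KE (v.n) dA in mW (2D: mW per m depth)."""
    _sync(space, state)
    p = 0.0
    found = False
    for fd in space.facet_data("io"):
        found = True
        vq = np.einsum("qn,nc->qc", fd["velN"], state.v[fd["vconn"]])
        ke = 0.5 * props.density * np.sum(vq ** 2, axis=1)
        p += np.einsum("q,qc,qc,q->", ke, vq, fd["normal"], fd["w"])
    if not found:
        raise ValueError("no boundary facets tagged 'io'")
    return p * 1e3   # W -> mW


def stroke_volume(v_ed_ml: float, v_es_ml: float, q_ml_s=None, t_s=None,
                  systole_span=None):
    """SV = V_ED - V_ES (mL) with an optional systolic flux cross-check.

    When a flow-rate series is given (``q_ml_s`` over times ``t_s`` with the
    systolic window ``systole_span = (t_start, t_end)``), also returns the
    time integral of Q over systole and the relative discrepancy.
    """
    import warnings
    if v_ed_ml < v_es_ml:
        warnings.warn("V_ED < V_ES: negative stroke volume")
    sv = v_ed_ml - v_es_ml
    if q_ml_s is None:
        return sv
    q = np.asarray(q_ml_s, float)
    t = np.asarray(t_s, float)
    if systole_span is not None:
        sel = (t >= systole_span[0] - 1e-12) & (t <= systole_span[1] + 1e-12)
        q, t = q[sel], t[sel]
    # right-endpoint rule: with implicit stepping, Q at t_{i} accounts for
    # the interval [t_{i-1}, t_i] (exact for the piecewise-constant flux of
    # linear-in-time wall motion)
    sv_flux = float(np.sum(q[1:] * np.diff(t)))
    rel = abs(sv_flux - sv) / max(abs(sv), 1e-14)
    return sv, sv_flux, rel


# ------------------------------------------------------------------ series

@dataclass
class HemoSeries:
    """Cycle time series of the hemodynamic metrics (tidy DataFrame inside).

    Columns (units): T [-], t [s], measure [mm^2 or mm^3], Q [mm^2/s or mL/s],
    dmeasure_dt (finite-difference cross-check, same units as Q), ke_avg
    [J/m^3], vort_mag_avg [1/s], vort_avg [1/s], F_x..F_z [N; per m depth in
    2D], hdf [N], hdf_reaction [N], power [mW].
    """

    frame: pd.DataFrame
    dim: int
    stroke_volume: float | None = None      # mL (3D) / mm^2 (2D area change)
    stroke_volume_flux: float | None = None
    meta: dict = field(default_factory=dict)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @property
    def mass_conservation_error(self) -> float:
        """max |Q + dV/dt| / max |Q| over the cycle (finite-difference dV/dt).

        The initial rest state is excluded: its flow state predates any mesh
        motion so no volume derivative is attributable to it.
        """
        q = self.frame["Q"].to_numpy()[1:]
        dv = self.frame["dmeasure_dt"].to_numpy()[1:]
        ok = ~np.isnan(dv)
        return float(np.max(np.abs(q[ok] + dv[ok])) /
                     max(np.max(np.abs(q)), 1e-14))


def compute_series(result, systole_fraction: float = 0.4) -> HemoSeries:
    """Evaluate all hemodynamic metrics for every state of a solved cycle."""
    space, props = result.space, result.props
    rows = []
    for st in result.states:
        space.set_coords(st.verts)
        meas_si = space.measure()
        scale_meas = 1e6 if space.dim == 2 else 1e9   # m^2->mm^2 / m^3->mm^3
        F, hdf = hemodynamic_force(space, st, props)
        row = {
            "T": st.T, "t": st.t,
            "measure": meas_si * scale_meas,
            "Q": flow_rate(space, st),
            "ke_avg": ke_average(space, st, props),
            "power": io_power(space, st, props),
            "hdf": hdf,
        }
        vm, va = vorticity_averages(space, st)
        row["vort_mag_avg"], row["vort_avg"] = vm, va
        for c, name in enumerate("xyz"[:space.dim]):
            row[f"F_{name}"] = F[c]
        # the residual-based reaction carries the same convention as Eq. F:
        # sum of momentum residuals at wall dofs = int_wall sigma.n dS
        row["hdf_reaction"] = (st.wall_reaction[space.dim - 1]
                               if st.wall_reaction is not None else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)

    # backward-difference d(measure)/dt on the flux scale (mm^3->mL in 3D):
    # consistent with the implicit stepping, where Q at t_{n+1} responds to
    # the mesh motion over [t_n, t_{n+1}]
    meas = df["measure"].to_numpy()
    t = df["t"].to_numpy()
    flux_scale = 1e-3 if space.dim == 3 else 1.0     # mm^3/s -> mL/s
    dmdt = np.full_like(meas, np.nan)
    dmdt[1:] = np.diff(meas) / np.diff(t) * flux_scale
    df["dmeasure_dt"] = dmdt

    sv = sv_flux = None
    Ts = df["T"].to_numpy()
    ed_idx = np.where(np.isclose(Ts, 0.0))[0]
    es_idx = np.where(np.isclose(Ts, systole_fraction, atol=1e-9))[0]
    if len(ed_idx) >= 1 and len(es_idx) >= 1:
        # ED/ES of the last cycle that contains a complete systole
        i_es = es_idx[-1]
        cycle_dur = _steps_per_cycle(result) * result.dt
        conv = 1e-3 if space.dim == 3 else 1.0       # mm^3 -> mL
        v_ed, v_es = meas[ed_idx[0]] * conv, meas[i_es] * conv
        t_es = t[i_es]
        t0 = t_es - systole_fraction * cycle_dur
        sv, sv_flux, _ = stroke_volume(v_ed, v_es, df["Q"].to_numpy(), t,
                                       systole_span=(t0, t_es))
    return HemoSeries(frame=df, dim=space.dim, stroke_volume=sv,
                      stroke_volume_flux=sv_flux,
                      meta={"systole_fraction": systole_fraction})


def _steps_per_cycle(result) -> int:
    # states wrap T at cycle ends; infer from the first return to T = 0
    Ts = [s.T for s in result.states[1:]]
    for i, T in enumerate(Ts):
        if np.isclose(T, 0.0):
            return i + 1
    return len(Ts)
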