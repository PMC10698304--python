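"""Vectorised Lagrangian tracking engine behind :func:`aerowalk.cases.run_case`.

All suspended particles are stepped together; each particle owns an
independent random stream derived from (master seed, particle index), so
changing the particle count never reshuffles existing trajectories.  The
timestep of a particle is limited by the remaining time of its current
eddy interaction (the minimum of the remaining lifetime and the crossing
time, both evaluated at eddy birth), by a geometric bound on wall-normal
travel, and by a global cap.  Velocity and position updates use the exact
exponential solution of the linear-drag balance over two half-steps with
the drag factor refreshed at each half-step, matching the adaptive scalar
integrator in :mod:`aerowalk.particle_dynamics` to its tolerance for the
step sizes used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deposition import DepositionTally, RegionMap
from .eim import CorrectionConfig, matida_damping, timescale_array
from .particle_dynamics import _piecewise_drag

__all__ = ["RunResult", "track"]

_DT_MIN = 1e-9  # s; protects against degenerate zero-length steps


@dataclass
class RunResult:
    """Outcome of one tracked injection."""

    tally: DepositionTally
    per_bin: pd.DataFrame     # per-diameter released/deposited/DE table
    stats: dict = field(default_factory=dict)

    @property
    def deposition_by_region(self) -> dict:
        return dict(self.tally.deposited)


def _batch_half_steps(pos, vel, uf, g_eff, taup, dp, rho, mu, dt):
    """Two exact exponential half-steps with the drag factor refreshed."""
    for _ in range(2):
        h = dt / 2.0
        slip = np.linalg.norm(uf - vel, axis=1)
        rep = rho * slip * dp / mu
        f = _piecewise_drag(rep)
        tau = taup / f
        v_inf = uf + g_eff * tau[:, None]
        e = np.exp(-h / tau)
        pos = pos + v_inf * h[:, None] + (tau * (1.0 - e))[:, None] * (vel - v_inf)
        vel = v_inf + e[:, None] * (vel - v_inf)
    return pos, vel


def track(
    field_,
    particles,
    config: CorrectionConfig,
    region_map: RegionMap,
    seed: int,
    gravity=(0.0, 0.0, 0.0),
    yplus_limits=None,
    dt_max: float | None = None,
    max_residence: float | None = None,
    bin_diameters=None,
    trace_hits: list | None = None,
    trace_particle: int | None = None,
    trace_log: list | None = None,
) -> RunResult:
    """Track every particle to a terminal fate and build the tally.

    ``yplus_limits`` is the resolved per-wall-region array of y+ limits
    (symbolic settings such as ``"correlated"`` must already be resolved).
    ``max_residence`` defaults to 20 domain flow-through times.
    """
    n = len(particles)
    if n == 0:
        raise ValueError("no particles to track")
    pos = np.array([p.position for p in particles], dtype=float)
    vel = np.array([p.velocity for p in particles], dtype=float)
    dp = np.array([p.diameter for p in particles], dtype=float)
    rp = dp / 2.0
    taup = np.array([p.relaxation_time for p in particles], dtype=float)
    dens = np.array([p.density for p in particles], dtype=float)
    mass = np.array([p.mass_weight for p in particles], dtype=float)
    bins = np.array([p.bin_index for p in particles], dtype=int)

    rho = field_.fluid.density
    mu = field_.fluid.viscosity
    nu = mu / rho
    g = np.asarray(gravity, dtype=float)
    g_eff = g[None, :] * ((dens - rho) / dens)[:, None]

    n_wall = len(region_map.regions)
    if yplus_limits is None:
        yplus_limits = np.array(
            [config.yplus_limit_for(r.name) for r in region_map.regions]
        )
    else:
        yplus_limits = np.asarray(yplus_limits, dtype=float)
    trap_codes = region_map.behavior_codes()

    path_end = region_map.path_end
    if dt_max is None:
        bulk = getattr(field_, "bulk_velocity", None)
        dt_max = (path_end / bulk) / 200.0 if bulk else 1e-4
    if max_residence is None:
        bulk = getattr(field_, "bulk_velocity", 1.0)
        max_residence = 20.0 * path_end / max(bulk, 1e-12)

    # per-particle independent streams
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(n)
    ]

    # eddy state
    G = np.zeros((n, 3))
    t_int = np.zeros(n)          # remaining interaction time
    Le = np.zeros(n)
    tl = np.full(n, np.inf)      # current Lagrangian timescale
    drift = np.zeros((n, 3))

    t = np.zeros(n)
    status = np.zeros(n, dtype=np.int8)   # 0 susp, 1 trapped, 2 escaped, 3 unfinished
    fate_region = np.full(n, -1, dtype=int)
    s0, _, _, _ = field_.local_coords(pos)
    max_region = region_map.region_index(s0)

    min_tl_plus = np.inf
    n_eddies = 0
    n_steps = 0
    u_star_ref = getattr(field_, "friction_velocity", None)

    max_iter = 2_000_000
    it = 0
    active = np.flatnonzero(status == 0)
    while active.size and it < max_iter:
        it += 1
        p = pos[active]
        smp = field_.sample_batch(p)
        uf_mean = smp["mean_velocity"]
        tke = smp["tke"]
        sdr = smp["sdr"]
        yw = smp["wall_distance"]
        normal = smp["wall_normal"]
        u_star = smp["friction_velocity"]
        sigma = np.sqrt(2.0 * tke / 3.0)
        yplus = yw * u_star * rho / mu
        s_here, _, _, _ = field_.local_coords(p)
        reg_here = region_map.region_index(s_here)

        if config.dispersion:
            renew = t_int[active] <= 1e-15
            if np.any(renew):
                ridx = active[renew]
                tl_new = timescale_array(sdr[renew], u_star[renew], nu, config)
                for j, i in enumerate(ridx):
                    G[i] = streams[i].standard_normal(3)
                tl[ridx] = tl_new
                te = 2.0 * tl_new
                Le[ridx] = np.linalg.norm(G[ridx] * sigma[renew, None], axis=1) * te
                drift[ridx] = 0.0
                t_int[ridx] = te  # provisional; capped by crossing time below
                n_eddies += ridx.size
                us = u_star[renew] if u_star_ref is None else np.full(
                    ridx.size, u_star_ref
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    tlp = tl_new * us**2 / nu
                tlp = tlp[np.isfinite(tlp)]
                if tlp.size:
                    min_tl_plus = min(min_tl_plus, float(tlp.min()))

            # fluctuation velocity (vectorised eim.fluctuation_velocity)
            u_fluct = G[active] * sigma[:, None]
            limit = yplus_limits[reg_here]
            damp_mask = (limit > 0) & (yplus < limit)
            if np.any(damp_mask):
                gn = np.einsum("ij,ij->i", G[active][damp_mask], normal[damp_mask])
                un = gn * matida_damping(yplus[damp_mask]) * sigma[damp_mask]
                un_iso = np.einsum(
                    "ij,ij->i", u_fluct[damp_mask], normal[damp_mask]
                )
                u_fluct[damp_mask] += (un - un_iso)[:, None] * normal[damp_mask]
            uf = uf_mean + u_fluct
            if config.drift_correction:
                uf = uf + drift[active]
            if config.nw_limit > 0.0:
                nw = yw < config.nw_limit
                if np.any(nw):
                    if config.nw_zero_mean:
                        un_tot = np.einsum("ij,ij->i", uf[nw], normal[nw])
                        uf[nw] -= un_tot[:, None] * normal[nw]
                    else:
                        un_fl = np.einsum(
                            "ij,ij->i", u_fluct[nw], normal[nw]
                        )
                        uf[nw] -= un_fl[:, None] * normal[nw]

            # crossing time for freshly spawned eddies, using current slip
            if np.any(renew):
                slip = np.linalg.norm(uf[renew] - vel[active][renew], axis=1)
                tp = taup[active][renew]
                le_r = Le[active][renew]
                arg = 1.0 - le_r / np.maximum(tp * slip, 1e-300)
                cross = np.where(
                    (slip > 0) & (arg > 0) & (le_r > 0),
                    -tp * np.log(np.maximum(arg, 1e-300)),
                    np.inf,
                )
                t_int[active[renew]] = np.minimum(t_int[active[renew]], cross)
        else:
            uf = uf_mean

        # timestep: remaining interaction, wall-normal geometric bound, cap
        v_n = np.abs(np.einsum("ij,ij->i", vel[active], normal))
        u_n = np.abs(np.einsum("ij,ij->i", uf, normal))
        v_norm = np.maximum(v_n, u_n)
        dt_geo = 0.5 * np.maximum(yw, rp[active]) / np.maximum(v_norm, 1e-12)
        dt = np.minimum(dt_geo, dt_max)
        dt = np.maximum(dt, _DT_MIN)
        if config.dispersion:
            # zero-length eddies carry no fluctuation, so they never
            # constrain the step (keeps k=0 runs identical to no-dispersion)
            live = Le[active] > 0
            dt = np.where(
                live,
                np.minimum(dt, np.maximum(t_int[active], _DT_MIN)),
                dt,
            )

        if trace_particle is not None and trace_log is not None:
            w = np.flatnonzero(active == trace_particle)
            if w.size:
                kk = int(w[0])
                trace_log.append(
                    dict(
                        yw=float(yw[kk]),
                        vn=float(np.dot(vel[trace_particle], normal[kk])),
                        un=float(np.dot(uf[kk], normal[kk])),
                        dr=float(np.dot(drift[trace_particle], normal[kk])),
                        sig=float(sigma[kk]),
                        dt=float(dt[kk]) if np.ndim(dt) else float(dt),
                        tint=float(t_int[trace_particle]),
                    )
                )
        if config.dispersion and config.drift_correction:
            # the incremented mean fluctuation acts during the current step
            # (otherwise single-step eddies would never feel the correction)
            stk = taup[active] / tl[active]
            incr = (
                sigma[:, None] * smp["sigma_gradient"]
                * (dt / (1.0 + stk))[:, None]
            )
            drift[active] += incr
            if config.nw_limit > 0.0:
                nw_i = yw < config.nw_limit
                if np.any(nw_i):
                    incr_n = np.einsum("ij,ij->i", incr[nw_i], normal[nw_i])
                    incr[nw_i] -= incr_n[:, None] * normal[nw_i]
            uf = uf + incr

        new_pos, new_vel = _batch_half_steps(
            pos[active], vel[active], uf, g_eff[active],
            taup[active], dp[active], rho, mu, dt,
        )
        pos[active] = new_pos
        vel[active] = new_vel
        t[active] += dt
        if config.dispersion:
            t_int[active] -= dt
        n_steps += active.size

        # fates
        s_new, yw_new, n_new, _ = field_.local_coords(new_pos)
        reg_new = region_map.region_index(s_new)
        max_region[active] = np.maximum(max_region[active], reg_new)

        escaped = s_new > path_end
        hit = (yw_new <= rp[active]) & ~escaped
        if np.any(hit):
            hit_idx = active[hit]
            hit_reg = reg_new[hit]
            if trace_hits is not None:
                vn0 = np.einsum("ij,ij->i", vel[active], normal)
                un0 = np.einsum("ij,ij->i", uf, normal)
                for kk in np.flatnonzero(hit):
                    trace_hits.append(
                        dict(yw0=float(yw[kk]), yw1=float(yw_new[kk]),
                             vn0=float(vn0[kk]), un0=float(un0[kk]),
                             dt=float(dt[kk]))
                    )
            traps = trap_codes[hit_reg] == 1
            tr = hit_idx[traps]
            status[tr] = 1
            fate_region[tr] = hit_reg[traps]
            # reflect walls: mirror position about the contact plane and
            # flip the wall-ward normal velocity component (magnitude kept)
            rf = hit_idx[~traps]
            if rf.size:
                nvec = n_new[hit][~traps]
                gap = rp[rf] - yw_new[hit][~traps]
                pos[rf] += (2.0 * gap)[:, None] * nvec
                vn = np.einsum("ij,ij->i", vel[rf], nvec)
                going_in = vn < 0
                vel[rf] -= (2.0 * vn * going_in)[:, None] * nvec
        status[active[escaped]] = 2
        overdue = (t[active] > max_residence) & (status[active] == 0)
        status[active[overdue]] = 3

        active = np.flatnonzero(status == 0)

    if active.size:  # iteration cap hit: report rather than loop forever
        status[active] = 3

    # ---- tally -----------------------------------------------------------
    tally = DepositionTally(region_map.names, region_map.terminal)
    tally.add_release(float(mass.sum()))
    for r in range(n_wall):
        tally.add_entry(
            region_map.regions[r].name, float(mass[max_region >= r].sum())
        )
        trapped_here = (status == 1) & (fate_region == r)
        tally.add_deposit(region_map.regions[r].name, float(mass[trapped_here].sum()))
    tally.book_escaped(float(mass[status == 2].sum()))
    tally.add_unfinished(float(mass[status == 3].sum()))

    # ---- per-bin table ---------------------------------------------------
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        released = float(mass[sel].sum())
        dep = float(mass[sel & (status == 1)].sum())
        rows.append(
            {
                "bin": int(b),
                "diameter": (
                    float(bin_diameters[b]) if bin_diameters is not None
                    else float(dp[sel][0])
                ),
                "mass_released": released,
                "mass_deposited": dep,
                "DE_percent": 100.0 * dep / released if released > 0 else np.nan,
            }
        )
    per_bin = pd.DataFrame(rows).set_index("bin")

    stats = {
        "n_particles": n,
        "n_steps": int(n_steps),
        "n_eddies": int(n_eddies),
        "n_unfinished": int(np.sum(status == 3)),
        "min_tl_plus": float(min_tl_plus) if np.isfinite(min_tl_plus) else None,
        "iterations": it,
    }
    return RunResult(tally=tally, per_bin=per_bin, stats=stats)
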