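"""Numba kernels for the embodied foraging trial.

Everything here operates on plain numpy arrays so that one compiled function
(`run_trial`) can advance a whole 12,000-tick trial, while the same pieces
(`transition_code`, `diffuse_evaporate`, `step`) back the step-level Python
API in :mod:`swarmevo.arena`.  All randomness enters through the
pre-generated per-robot noise matrix, which makes trials bit-reproducible
and prefix-stable in the number of ticks.
"""

from __future__ import annotations

import math
from collections import namedtuple

import numpy as np
from numba import njit

#: scalar parameters of one trial, flattened for numba
KernelParams = namedtuple(
    "KernelParams",
    [
        "width", "length", "robot_r", "speed",
        "food_cx", "food_cy", "food_r", "light_r",
        "nest_cx", "nest_cy", "nest_r",
        "cell", "ny", "nx", "diff", "evap", "deposit", "thresh",
        "sigma", "stay_steps", "leave_dist",
        "sensor_off", "sensor_ang", "turn", "lost_max", "cone", "sigma_motor",
    ],
)


def make_params(arena, pheromone, behavior) -> KernelParams:
    """Flatten config dataclasses into a :class:`KernelParams`."""
    ny = int(math.ceil(arena.field_length_mm / pheromone.grid_cell_mm))
    nx = int(math.ceil(arena.field_width_mm / pheromone.grid_cell_mm))
    return KernelParams(
        width=float(arena.field_width_mm),
        length=float(arena.field_length_mm),
        robot_r=float(arena.robot_diameter_mm) / 2.0,
        speed=float(arena.robot_max_speed_mm_s) * float(arena.dt_s),
        food_cx=float(arena.food_center[0]),
        food_cy=float(arena.food_center[1]),
        food_r=float(arena.food_diameter_mm) / 2.0,
        light_r=float(arena.food_light_radius_mm),
        nest_cx=float(arena.nest_center[0]),
        nest_cy=float(arena.nest_center[1]),
        nest_r=float(arena.nest_diameter_mm) / 2.0,
        cell=float(pheromone.grid_cell_mm),
        ny=ny,
        nx=nx,
        diff=float(pheromone.diffusion_coeff),
        evap=float(pheromone.evaporation_coeff),
        deposit=float(pheromone.deposit_amount_per_step),
        thresh=float(pheromone.detection_threshold),
        sigma=float(behavior.heading_sigma_rad),
        stay_steps=int(round(behavior.stay_duration_s / arena.dt_s)),
        leave_dist=float(behavior.leave_distance_mm),
        sensor_off=float(behavior.sensor_offset_mm),
        sensor_ang=float(behavior.sensor_angle_rad),
        turn=float(behavior.s3_turn_rad),
        lost_max=int(behavior.trail_lost_steps),
        cone=float(behavior.s3_outbound_cone_rad),
        sigma_motor=float(behavior.motor_noise_rad),
    )


@njit(cache=True)
def cell_index(x, y, cell, ny, nx):
    ix = int(x / cell)
    iy = int(y / cell)
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    return iy, ix


@njit(cache=True)
def field_at(field, x, y, cell, ny, nx):
    iy, ix = cell_index(x, y, cell, ny, nx)
    return field[iy, ix]


@njit(cache=True)
def diffuse_evaporate(field, buf, diff, evap):
    """One tick of mass-conserving 4-neighbour diffusion, then evaporation.

    Neumann (no-flux) walls: diffusion is a sum of antisymmetric pairwise
    exchanges, so total mass is conserved exactly before the multiplicative
    evaporation factor is applied.
    """
    ny, nx = field.shape
    for i in range(ny):
        for j in range(nx):
            buf[i, j] = field[i, j]
    for i in range(ny):
        for j in range(nx):
            c = field[i, j]
            if j + 1 < nx:
                d = diff * (field[i, j + 1] - c)
                buf[i, j] += d
                buf[i, j + 1] -= d
            if i + 1 < ny:
                d = diff * (field[i + 1, j] - c)
                buf[i, j] += d
                buf[i + 1, j] -= d
    keep = 1.0 - evap
    for i in range(ny):
        for j in range(nx):
            v = buf[i, j] * keep
            field[i, j] = v if v > 0.0 else 0.0


@njit(cache=True)
def transition_code(state, at_food, at_nest, detect, lost, lost_max):
    """Pure state-machine step.  Returns (new_state, bout_increment).

    ``detect`` must already combine the p allele with the local pheromone
    reading, so state 3 is unreachable whenever p = 0.
    Unknown states return (-1, 0) and are rejected by the Python wrapper.
    """
    if state == 1:
        if at_food:
            return 2, 0
        if detect and not at_nest:
            return 3, 0
        return 1, 0
    if state == 2:
        if at_nest:
            if detect:
                return 3, 1
            return 1, 1
        return 2, 0
    if state == 3:
        if at_food:
            return 2, 0
        if lost >= lost_max:
            return 1, 0
        return 3, 0
    return -1, 0


@njit(cache=True)
def _resolve_overlaps(pos, stay, robot_r, width, length):
    """Iteratively push overlapping bodies apart and keep them inside walls.

    Robots frozen by an active Stay timer are never displaced; their moving
    partner takes the whole correction (equal split if, defensively, both
    are frozen).
    """
    n = pos.shape[0]
    # separate to a small positive clearance so persistent pushing breaks
    # and remakes contact (each remake is a countable collision event)
    two_r = 2.0 * robot_r + 1.0
    lim = 2.0 * robot_r - 1e-7
    for _ in range(16):
        moved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                d2 = dx * dx + dy * dy
                if d2 < lim * lim:
                    d = math.sqrt(d2)
                    if d < 1e-9:
                        dx, dy, d = 1.0, 0.0, 1.0
                    overlap = two_r - d
                    ux = dx / d
                    uy = dy / d
                    wi = 0.0 if stay[i] > 0 else 1.0
                    wj = 0.0 if stay[j] > 0 else 1.0
                    tot = wi + wj
                    if tot == 0.0:
                        wi = wj = 0.5
                        tot = 1.0
                    pos[i, 0] -= ux * overlap * wi / tot
                    pos[i, 1] -= uy * overlap * wi / tot
                    pos[j, 0] += ux * overlap * wj / tot
                    pos[j, 1] += uy * overlap * wj / tot
                    moved = True
        for i in range(n):
            if stay[i] > 0:
                continue
            if pos[i, 0] < robot_r:
                pos[i, 0] = robot_r
            elif pos[i, 0] > width - robot_r:
                pos[i, 0] = width - robot_r
            if pos[i, 1] < robot_r:
                pos[i, 1] = robot_r
            elif pos[i, 1] > length - robot_r:
                pos[i, 1] = length - robot_r
        if not moved:
            break


@njit(cache=True)
def step(pos, heading, state, stay, leave, lost, contact, field, buf,
         noise, gt, pm, pher_active):
    """One synchronous world tick.

    Order: per-robot motion -> wall containment -> collision detection and
    reactions -> overlap resolution -> pheromone deposit/diffuse/evaporate
    -> state transitions (bouts counted here).  Returns
    (bouts, collisions, s1_steps, s2_steps, s3_steps, pher_active).
    """
    n = pos.shape[0]
    c1 = 0
    c2 = 0
    c3 = 0
    for i in range(n):
        if state[i] == 1:
            c1 += 1
        elif state[i] == 2:
            c2 += 1
        else:
            c3 += 1

    # --- motion ---------------------------------------------------------
    for i in range(n):
        if state[i] == 1:
            heading[i] += pm.sigma * noise[i]
        else:  # small motor noise on goal-directed motion
            heading[i] += pm.sigma_motor * noise[i]
        if stay[i] > 0:
            stay[i] -= 1
            continue
        if leave[i] > 0.0:
            d = pm.speed if pm.speed < leave[i] else leave[i]
            x0 = pos[i, 0]
            y0 = pos[i, 1]
            x1 = x0 - math.cos(heading[i]) * d
            y1 = y0 - math.sin(heading[i]) * d
            if x1 < pm.robot_r:
                x1 = pm.robot_r
            elif x1 > pm.width - pm.robot_r:
                x1 = pm.width - pm.robot_r
            if y1 < pm.robot_r:
                y1 = pm.robot_r
            elif y1 > pm.length - pm.robot_r:
                y1 = pm.length - pm.robot_r
            actual = math.hypot(x1 - x0, y1 - y0)
            pos[i, 0] = x1
            pos[i, 1] = y1
            if actual + 1e-9 < d:
                leave[i] = 0.0  # stuck against a wall: abandon the retreat
            else:
                leave[i] -= d
                if leave[i] < 1e-9:
                    leave[i] = 0.0
            continue
        # steering by state
        if state[i] == 1:
            dfx = pm.food_cx - pos[i, 0]
            dfy = pm.food_cy - pos[i, 1]
            if dfx * dfx + dfy * dfy <= pm.light_r * pm.light_r:
                heading[i] = math.atan2(dfy, dfx)
        elif state[i] == 2:
            heading[i] = math.atan2(pm.nest_cy - pos[i, 1], pm.nest_cx - pos[i, 0])
        else:  # S3 trail following with two forward sensors
            dfx = pm.food_cx - pos[i, 0]
            dfy = pm.food_cy - pos[i, 1]
            if dfx * dfx + dfy * dfy <= pm.light_r * pm.light_r:
                heading[i] = math.atan2(dfy, dfx)
                lost[i] = 0
            else:
                hl = heading[i] + pm.sensor_ang
                hr = heading[i] - pm.sensor_ang
                lv = field_at(field, pos[i, 0] + pm.sensor_off * math.cos(hl),
                              pos[i, 1] + pm.sensor_off * math.sin(hl),
                              pm.cell, pm.ny, pm.nx)
                rv = field_at(field, pos[i, 0] + pm.sensor_off * math.cos(hr),
                              pos[i, 1] + pm.sensor_off * math.sin(hr),
                              pm.cell, pm.ny, pm.nx)
                if lv < pm.thresh and rv < pm.thresh:
                    lost[i] += 1
                else:
                    lost[i] = 0
                # outbound enforcement first: trail-following is toward the
                # food, i.e. away from the nest beacon the robots can always
                # sense.  Outside the outbound cone the restoring turn takes
                # priority; inside it the two-sensor comparison steers.
                away = math.atan2(pos[i, 1] - pm.nest_cy, pos[i, 0] - pm.nest_cx)
                diff = away - heading[i]
                while diff > math.pi:
                    diff -= 2.0 * math.pi
                while diff < -math.pi:
                    diff += 2.0 * math.pi
                if diff > pm.cone or diff < -pm.cone:
                    if diff > pm.turn:
                        diff = pm.turn
                    elif diff < -pm.turn:
                        diff = -pm.turn
                    heading[i] += diff
                elif lv >= pm.thresh or rv >= pm.thresh:
                    if lv > rv:
                        heading[i] += pm.turn
                    elif rv > lv:
                        heading[i] -= pm.turn
                    # constant right-hand bias shifts the tracking
                    # equilibrium to the trail's right edge, so outbound
                    # traffic self-separates from inbound carriers
                    heading[i] -= 0.5 * pm.turn
        # forward move with reflective walls (searchers turn away)
        x1 = pos[i, 0] + math.cos(heading[i]) * pm.speed
        y1 = pos[i, 1] + math.sin(heading[i]) * pm.speed
        hit_x = False
        hit_y = False
        if x1 < pm.robot_r:
            x1 = pm.robot_r
            hit_x = True
        elif x1 > pm.width - pm.robot_r:
            x1 = pm.width - pm.robot_r
            hit_x = True
        if y1 < pm.robot_r:
            y1 = pm.robot_r
            hit_y = True
        elif y1 > pm.length - pm.robot_r:
            y1 = pm.length - pm.robot_r
            hit_y = True
        pos[i, 0] = x1
        pos[i, 1] = y1
        if state[i] != 2:  # searchers and trail followers turn away from walls
            if hit_x:
                heading[i] = math.pi - heading[i]
            if hit_y:
                heading[i] = -heading[i]

    # --- collisions -----------------------------------------------------
    bouts = 0
    colls = 0
    two_r = 2.0 * pm.robot_r
    touch = two_r + 1e-9
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            in_contact = dx * dx + dy * dy <= touch * touch
            if in_contact and contact[i, j] == 0:
                colls += 1
                if stay[i] == 0 and leave[i] == 0.0:
                    if gt[state[i] - 1] == 0:
                        stay[i] = pm.stay_steps
                    else:
                        leave[i] = pm.leave_dist
                if stay[j] == 0 and leave[j] == 0.0:
                    if gt[state[j] - 1] == 0:
                        stay[j] = pm.stay_steps
                    else:
                        leave[j] = pm.leave_dist
            contact[i, j] = 1 if in_contact else 0
            contact[j, i] = contact[i, j]
    _resolve_overlaps(pos, stay, pm.robot_r, pm.width, pm.length)

    # --- pheromone ------------------------------------------------------
    for i in range(n):
        if state[i] == 2:
            iy, ix = cell_index(pos[i, 0], pos[i, 1], pm.cell, pm.ny, pm.nx)
            field[iy, ix] += pm.deposit
            pher_active = True
    if pher_active:
        diffuse_evaporate(field, buf, pm.diff, pm.evap)

    # --- state transitions ---------------------------------------------
    for i in range(n):
        dfx = pm.food_cx - pos[i, 0]
        dfy = pm.food_cy - pos[i, 1]
        # state change on body contact with the food-disk boundary
        food_reach = pm.food_r + pm.robot_r
        at_food = dfx * dfx + dfy * dfy <= food_reach * food_reach
        dnx = pm.nest_cx - pos[i, 0]
        dny = pm.nest_cy - pos[i, 1]
        at_nest = dnx * dnx + dny * dny <= pm.nest_r * pm.nest_r
        detect = False
        if gt[3] == 1:
            conc = field_at(field, pos[i, 0], pos[i, 1], pm.cell, pm.ny, pm.nx)
            detect = conc >= pm.thresh
        new_state, bout = transition_code(state[i], at_food, at_nest, detect,
                                          lost[i], pm.lost_max)
        bouts += bout
        if new_state == 3 and state[i] != 3:
            lost[i] = 0
            # enter the trail pointing outbound (away from the nest beacon)
            heading[i] = math.atan2(pos[i, 1] - pm.nest_cy, pos[i, 0] - pm.nest_cx)
        state[i] = new_state
    return bouts, colls, c1, c2, c3, pher_active


@njit(cache=True)
def run_trial(pos, heading, state, stay, leave, lost, contact, field, buf,
              noise, gt, pm, n_steps, budgets):
    """Advance ``n_steps`` ticks; returns (bouts, collisions)."""
    bouts = 0
    colls = 0
    pher_active = False
    for t in range(n_steps):
        b, c, c1, c2, c3, pher_active = step(
            pos, heading, state, stay, leave, lost, contact, field, buf,
            noise[t], gt, pm, pher_active)
        bouts += b
        colls += c
        budgets[0] += c1
        budgets[1] += c2
        budgets[2] += c3
    return bouts, colls
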