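"""Compiled Monte Carlo / Langevin kernels over the packed potential family.

The kernels operate on plain float arrays produced by
``Potential1D.pack`` so that million-step chains run in milliseconds.
Per-state parameters are pre-interpolated to the window's lambda; the
lambda-derivative needs both the interpolated parameters and the raw
endpoint differences, so both are passed in.

Array shapes (S = number of end states, D = dimensions, G = Gaussians):
  quad   (S, D, 3)    rows (k, x0, c) at the current lambda
  dquad  (S, D, 3)    endpoint differences (lam=1 minus lam=0)
  gauss  (S, D, G, 3) rows (a, m, s) at the current lambda
  dgauss (S, D, G, 3) endpoint differences
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _state_energy(x, quad, gauss):
    """Potential energy of one end state at configuration x (D,)."""
    u = 0.0
    for d in range(quad.shape[0]):
        dx = x[d] - quad[d, 1]
        u += 0.5 * quad[d, 0] * dx * dx + quad[d, 2]
        for g in range(gauss.shape[1]):
            a = gauss[d, g, 0]
            if a != 0.0:
                dm = x[d] - gauss[d, g, 1]
                s = gauss[d, g, 2]
                u += a * np.exp(-dm * dm / (2.0 * s * s))
    return u


@njit(cache=True)
def _state_dlambda(x, quad, gauss, dquad, dgauss):
    """d(potential)/d(lambda) of one end state at configuration x."""
    out = 0.0
    for d in range(quad.shape[0]):
        dx = x[d] - quad[d, 1]
        out += 0.5 * dquad[d, 0] * dx * dx - quad[d, 0] * dx * dquad[d, 1] + dquad[d, 2]
        for g in range(gauss.shape[1]):
            a = gauss[d, g, 0]
            da = dgauss[d, g, 0]
            if a != 0.0 or da != 0.0:
                m = gauss[d, g, 1]
                s = gauss[d, g, 2]
                dm = x[d] - m
                gv = np.exp(-dm * dm / (2.0 * s * s))
                out += da * gv + a * gv * (
                    dm * dgauss[d, g, 1] / (s * s) + dm * dm * dgauss[d, g, 2] / s**3
                )
    return out


@njit(cache=True)
def _state_gradient(x, quad, gauss, grad):
    for d in range(quad.shape[0]):
        dx = x[d] - quad[d, 1]
        g_d = quad[d, 0] * dx
        for g in range(gauss.shape[1]):
            a = gauss[d, g, 0]
            if a != 0.0:
                m = gauss[d, g, 1]
                s = gauss[d, g, 2]
                dm = x[d] - m
                g_d += -a * np.exp(-dm * dm / (2.0 * s * s)) * dm / (s * s)
        grad[d] = g_d


@njit(cache=True)
def _reference_point(x, quad, gauss, offs, RT, e_min, e_max, H, w):
    """Fill H and w; return (e_r, e_star, slope)."""
    n_states = quad.shape[0]
    for i in range(n_states):
        H[i] = _state_energy(x, quad[i], gauss[i])
    zmax = -1e300
    for i in range(n_states):
        z = -(H[i] - offs[i]) / RT
        if z > zmax:
            zmax = z
    ssum = 0.0
    for i in range(n_states):
        w[i] = np.exp(-(H[i] - offs[i]) / RT - zmax)
        ssum += w[i]
    for i in range(n_states):
        w[i] /= ssum
    e_r = -RT * (zmax + np.log(ssum))
    # harmonic boost
    span = e_max - e_min
    if span <= 0.0 or e_r <= e_min:
        return e_r, e_r, 1.0
    if e_r >= e_max:
        return e_r, 0.5 * (e_min + e_max), 0.0
    dd = e_r - e_min
    return e_r, e_r - dd * dd / (2.0 * span), 1.0 - dd / span


@njit(cache=True)
def _restraint(x, anchor, k_lam, dk):
    r2 = 0.0
    for d in range(x.shape[0]):
        dx = x[d] - anchor[d]
        r2 += dx * dx
    return 0.5 * k_lam * r2, 0.5 * dk * r2


@njit(cache=True)
def metropolis_chain(
    x0,
    n_steps,
    burn_in,
    sigma,
    tune,
    save_every,
    quad,
    dquad,
    gauss,
    dgauss,
    offs,
    offs_slope,
    RT,
    e_min,
    e_max,
    rest_anchor,
    rest_k,
    rest_dk,
    x_lo,
    x_hi,
    seed,
):
    """Metropolis chain sampling exp(-(E_R* + V_rest)/RT) on [x_lo, x_hi]^D.

    Proposals leaving the box are rejected (hard walls), which keeps
    detailed balance and makes the stationary density match quadrature
    oracles integrated over the same domain.

    Returns (xs, H, e_r, e_star, v_rest, dhdl_states, dhdl_aeds,
    n_accept, n_prod, sigma_final, x_final).
    """
    np.random.seed(seed)
    n_states = quad.shape[0]
    ndim = quad.shape[1]
    n_save = n_steps // save_every
    xs = np.empty((n_save, ndim))
    H = np.empty((n_save, n_states))
    e_r_out = np.empty(n_save)
    e_star_out = np.empty(n_save)
    v_rest_out = np.empty(n_save)
    dhdl_states = np.empty((n_save, n_states))
    dhdl_aeds = np.empty(n_save)

    x = x0.copy()
    x_new = x0.copy()
    h_buf = np.empty(n_states)
    w_buf = np.empty(n_states)
    e_r, e_star, slope = _reference_point(
        x, quad, gauss, offs, RT, e_min, e_max, h_buf, w_buf
    )
    v_rest, _ = _restraint(x, rest_anchor, rest_k, rest_dk)
    e_tot = e_star + v_rest

    n_accept = 0
    win_accept = 0
    k_save = 0
    for step in range(burn_in + n_steps):
        inside = True
        for d in range(ndim):
            x_new[d] = x[d] + sigma * np.random.normal()
            if x_new[d] < x_lo or x_new[d] > x_hi:
                inside = False
        e_r_n = 0.0
        e_star_n = 0.0
        if not inside:
            e_tot_n = np.inf
        else:
            e_r_n, e_star_n, slope_n = _reference_point(
                x_new, quad, gauss, offs, RT, e_min, e_max, h_buf, w_buf
            )
            v_rest_n, _ = _restraint(x_new, rest_anchor, rest_k, rest_dk)
            e_tot_n = e_star_n + v_rest_n
        if e_tot_n <= e_tot or np.random.random() < np.exp(-(e_tot_n - e_tot) / RT):
            for d in range(ndim):
                x[d] = x_new[d]
            e_r, e_star, e_tot = e_r_n, e_star_n, e_tot_n
            if step >= burn_in:
                n_accept += 1
            else:
                win_accept += 1
        if tune and step < burn_in and (step + 1) % 100 == 0:
            acc = win_accept / 100.0
            if acc < 0.3:
                sigma *= 0.8
            elif acc > 0.5:
                sigma *= 1.2
            win_accept = 0
        if step >= burn_in and (step - burn_in + 1) % save_every == 0:
            e_r_s, e_star_s, slope_s = _reference_point(
                x, quad, gauss, offs, RT, e_min, e_max, h_buf, w_buf
            )
            v_r, dv_r = _restraint(x, rest_anchor, rest_k, rest_dk)
            acc_dhdl = 0.0
            for i in range(n_states):
                dl = _state_dlambda(x, quad[i], gauss[i], dquad[i], dgauss[i])
                dhdl_states[k_save, i] = dl
                acc_dhdl += w_buf[i] * (dl - offs_slope[i])
            xs[k_save] = x
            H[k_save] = h_buf
            e_r_out[k_save] = e_r_s
            e_star_out[k_save] = e_star_s
            v_rest_out[k_save] = v_r
            dhdl_aeds[k_save] = slope_s * acc_dhdl + dv_r
            k_save += 1
    return (
        xs[:k_save],
        H[:k_save],
        e_r_out[:k_save],
        e_star_out[:k_save],
        v_rest_out[:k_save],
        dhdl_states[:k_save],
        dhdl_aeds[:k_save],
        n_accept,
        n_steps,
        sigma,
        x,
    )


@njit(cache=True)
def langevin_chain(
    x0,
    n_steps,
    burn_in,
    dt,
    diffusion,
    save_every,
    quad,
    dquad,
    gauss,
    dgauss,
    offs,
    offs_slope,
    RT,
    e_min,
    e_max,
    rest_anchor,
    rest_k,
    rest_dk,
    x_lo,
    x_hi,
    seed,
):
    """Overdamped Euler-Maruyama chain on the boosted reference surface.

    x' = x - (D/RT) grad(E_R* + V_rest) dt + sqrt(2 D dt) xi.
    Carries the documented first-order discretization bias; intended for
    time-series realism (state lifetimes), not exact free energies.
    """
    np.random.seed(seed)
    n_states = quad.shape[0]
    ndim = quad.shape[1]
    n_save = n_steps // save_every
    xs = np.empty((n_save, ndim))
    H = np.empty((n_save, n_states))
    e_r_out = np.empty(n_save)
    e_star_out = np.empty(n_save)
    v_rest_out = np.empty(n_save)
    dhdl_states = np.empty((n_save, n_states))
    dhdl_aeds = np.empty(n_save)

    x = x0.copy()
    h_buf = np.empty(n_states)
    w_buf = np.empty(n_states)
    grad_i = np.empty(ndim)
    grad = np.empty(ndim)
    noise_pref = np.sqrt(2.0 * diffusion * dt)
    k_save = 0
    for step in range(burn_in + n_steps):
        e_r, e_star, slope = _reference_point(
            x, quad, gauss, offs, RT, e_min, e_max, h_buf, w_buf
        )
        for d in range(ndim):
            grad[d] = 0.0
        for i in range(n_states):
            _state_gradient(x, quad[i], gauss[i], grad_i)
            for d in range(ndim):
                grad[d] += w_buf[i] * grad_i[d]
        for d in range(ndim):
            grad[d] = slope * grad[d] + rest_k * (x[d] - rest_anchor[d])
        if step >= burn_in and (step - burn_in + 1) % save_every == 0:
            v_r, dv_r = _restraint(x, rest_anchor, rest_k, rest_dk)
            acc_dhdl = 0.0
            for i in range(n_states):
                dl = _state_dlambda(x, quad[i], gauss[i], dquad[i], dgauss[i])
                dhdl_states[k_save, i] = dl
                acc_dhdl += w_buf[i] * (dl - offs_slope[i])
            xs[k_save] = x
            H[k_save] = h_buf
            e_r_out[k_save] = e_r
            e_star_out[k_save] = e_star
            v_rest_out[k_save] = v_r
            dhdl_aeds[k_save] = slope * acc_dhdl + dv_r
            k_save += 1
        for d in range(ndim):
            x[d] = x[d] - diffusion / RT * grad[d] * dt + noise_pref * np.random.normal()
            # reflecting walls keep the chain on the oracle domain
            if x[d] < x_lo:
                x[d] = 2.0 * x_lo - x[d]
            elif x[d] > x_hi:
                x[d] = 2.0 * x_hi - x[d]
    return (
        xs[:k_save],
        H[:k_save],
        e_r_out[:k_save],
        e_star_out[:k_save],
        v_rest_out[:k_save],
        dhdl_states[:k_save],
        dhdl_aeds[:k_save],
        0,
        n_steps,
        dt,
        x,
    )
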