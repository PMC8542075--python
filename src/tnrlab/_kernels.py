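"""Numba kernels for the sample-by-sample recursions.

Everything here operates on raw float64 arrays; the wrappers in
:mod:`tnrlab.tnr` and :mod:`tnrlab.frontend` handle calibration and types.
Levels inside the kernels are dB re full-scale power; thresholds are
relative, so the absolute reference cancels.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def one_pole_power(power, coeff, init, floor_p):
    """Symmetric one-pole smoother of instantaneous power."""
    n = power.shape[0]
    out = np.empty(n)
    s = init if init > floor_p else floor_p
    for i in range(n):
        s += coeff * (power[i] - s)
        if s < floor_p:
            s = floor_p
        out[i] = s
    return out


@njit(cache=True)
def asym_one_pole_power(power, a_attack, a_release, init, floor_p):
    """Attack/release power detector: fast coefficient when the input is
    above the state (attack), slow when below (release)."""
    n = power.shape[0]
    out = np.empty(n)
    s = init if init > floor_p else floor_p
    for i in range(n):
        x = power[i]
        if x > s:
            s += a_attack * (x - s)
        else:
            s += a_release * (x - s)
        if s < floor_p:
            s = floor_p
        out[i] = s
    return out


@njit(cache=True)
def tnr_gain_loop(
    power,
    fs,
    env_coeff,
    bg_coeff,
    slope_win,
    slope_thr_db_per_ms,
    amp_thr_db,
    amp_floor_db,
    attack_coeff,
    release_coeff,
    fixed_atten_db,
    prop_lo_db,
    prop_hi_db,
    prop_range_db,
    scale_atten,
    max_atten_db,
    floor_db,
    refractory_n,
):
    """Transient detector + gain computer, feed-forward and causal.

    The envelope (one-pole smoothed power, in dB) is monitored for slope
    (over ``slope_win`` samples) and amplitude above a slowly tracked
    background.  The background is a one-pole power average (so it sits at
    the rms of the stationary bed rather than at the dB-mean of the spiky
    envelope) and is only updated while the envelope is within half the
    amplitude threshold of it, so transients do not inflate their own
    reference.  A transient must additionally be loud in absolute terms
    (envelope above ``amp_floor_db``, dB re full-scale power): the
    algorithm targets high-intensity transients, not every small
    fluctuation in an otherwise quiet band.  While all conditions hold the
    gain attacks toward the event's target attenuation; otherwise it
    releases exponentially toward unity.

    ``fixed_atten_db >= 0`` selects the broadband rule (constant base
    attenuation); a negative value selects the amplitude-proportional map
    from ``prop_lo_db`` (threshold-level excess) to ``prop_hi_db``
    (threshold + ``prop_range_db``).

    Returns (gains_db, event_onsets, event_peaks_db, event_atten_db).
    """
    n = power.shape[0]
    gains_db = np.empty(n)
    max_ev = n // (refractory_n if refractory_n > 1 else 1) + 2
    ev_onset = np.empty(max_ev, np.int64)
    ev_peak = np.empty(max_ev)
    ev_atten = np.empty(max_ev)
    n_ev = 0

    floor_p = 10.0 ** (floor_db / 10.0)
    init_n = int(fs * 0.050)
    if init_n < 1:
        init_n = 1
    if init_n > n:
        init_n = n
    acc = 0.0
    for i in range(init_n):
        acc += power[i]
    bg_p = acc / init_n
    if bg_p < floor_p:
        bg_p = floor_p
    env_p = power[0] if power[0] > floor_p else floor_p
    env_db = 10.0 * np.log10(env_p)
    bg_db = 10.0 * np.log10(bg_p)
    hist = np.full(slope_win, env_db)
    hpos = 0
    g_db = 0.0
    ms_span = slope_win * 1000.0 / fs
    in_run = False
    cur_ev = -1
    last_onset = -refractory_n

    for i in range(n):
        env_p += env_coeff * (power[i] - env_p)
        if env_p < floor_p:
            env_p = floor_p
        env_db = 10.0 * np.log10(env_p)
        old = hist[hpos]
        hist[hpos] = env_db
        hpos += 1
        if hpos == slope_win:
            hpos = 0
        slope = (env_db - old) / ms_span

        cond = (
            (slope >= slope_thr_db_per_ms)
            and (env_db >= bg_db + amp_thr_db)
            and (env_db >= amp_floor_db)
        )
        if cond:
            excess = env_db - bg_db
            if fixed_atten_db >= 0.0:
                base = fixed_atten_db
            else:
                base = prop_lo_db + (excess - amp_thr_db) * (
                    prop_hi_db - prop_lo_db
                ) / prop_range_db
                if base < prop_lo_db:
                    base = prop_lo_db
                elif base > prop_hi_db:
                    base = prop_hi_db
            target = base * scale_atten
            if target > max_atten_db:
                target = max_atten_db
            tgt_db = -target
            if tgt_db < g_db:
                g_db += attack_coeff * (tgt_db - g_db)
            # gain deeper than target: hold until the condition clears
            if not in_run:
                in_run = True
                if i - last_onset >= refractory_n:
                    cur_ev = n_ev
                    ev_onset[cur_ev] = i
                    ev_peak[cur_ev] = env_db
                    ev_atten[cur_ev] = target
                    n_ev += 1
                    last_onset = i
            if cur_ev >= 0:
                if env_db > ev_peak[cur_ev]:
                    ev_peak[cur_ev] = env_db
                if target > ev_atten[cur_ev]:
                    ev_atten[cur_ev] = target
        else:
            in_run = False
            g_db += release_coeff * (0.0 - g_db)
        if env_db < bg_db + 0.5 * amp_thr_db:
            bg_p += bg_coeff * (env_p - bg_p)
            if bg_p < floor_p:
                bg_p = floor_p
            bg_db = 10.0 * np.log10(bg_p)
        gains_db[i] = g_db

    return gains_db, ev_onset[:n_ev], ev_peak[:n_ev], ev_atten[:n_ev]
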