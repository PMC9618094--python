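"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain Python ``math`` with explicit loops,
deliberately sharing no code with the package implementation.
"""

import cmath
import math


def wrap(a):
    while a <= -180.0:
        a += 360.0
    while a > 180.0:
        a -= 360.0
    return a


def brute_bearing(fx, fz, tx, tz):
    return wrap(math.degrees(math.atan2(tz - fz, tx - fx)))


def trial_points(trial):
    return [(s.pos.x, s.pos.z) for s in trial.samples]


def brute_placement_error(trial, env):
    true = env.chest_locations[trial.object_id]
    return math.hypot(trial.placement.x - true.x, trial.placement.z - true.z)


def brute_path_length(trial, threshold=0.2):
    pts = trial_points(trial)
    n = 0
    for (x0, z0), (x1, z1) in zip(pts, pts[1:]):
        if math.hypot(x1 - x0, z1 - z0) >= threshold:
            n += 1
    return n


def brute_deviations(trial, env, threshold=0.2):
    """Signed facing-vs-instantaneous-bearing deviations per movement step."""
    true = env.chest_locations[trial.object_id]
    pts = trial_points(trial)
    devs = []
    for i in range(len(pts) - 1):
        x0, z0 = pts[i]
        x1, z1 = pts[i + 1]
        if math.hypot(x1 - x0, z1 - z0) < threshold:
            continue
        if x0 == true.x and z0 == true.z:
            continue
        ref = brute_bearing(x0, z0, true.x, true.z)
        devs.append(wrap(trial.samples[i].heading_deg - ref))
    return devs


def brute_header_direction(trial, env):
    d = brute_deviations(trial, env)
    return abs(sum(d) / len(d))


def brute_cumulative_error(trial, env):
    return sum(abs(x) for x in brute_deviations(trial, env))


def brute_initial_orientation(trial, env):
    d = brute_deviations(trial, env)[:5]
    return abs(sum(d) / len(d))


def brute_dwell(trial, env, radius):
    true = env.chest_locations[trial.object_id]
    inside = 0
    for x, z in trial_points(trial):
        if math.hypot(x - true.x, z - true.z) <= radius:
            inside += 1
    return inside / len(trial.samples)


def brute_approach_angle(trial, target, k=5, radius=3.0, threshold=0.2):
    """Circular mean of the last-k movement bearings before the anchor
    sample (terminal placement for test trials)."""
    pts = trial_points(trial)
    dists = [math.hypot(x - target.x, z - target.z) for x, z in pts]
    if min(dists) > radius:
        return None
    if trial.is_test and trial.samples[-1].event == "place_chest":
        anchor = len(pts) - 1
    else:
        anchor = None
        for i, s in enumerate(trial.samples):
            if s.event == "open_chest" and dists[i] <= radius:
                anchor = i
                break
        if anchor is None:
            anchor = dists.index(min(dists))
    bearings = []
    for i in range(anchor):
        x0, z0 = pts[i]
        x1, z1 = pts[i + 1]
        if math.hypot(x1 - x0, z1 - z0) >= threshold:
            bearings.append(brute_bearing(x0, z0, x1, z1))
    if not bearings:
        return None
    v = sum(cmath.exp(1j * math.radians(b)) for b in bearings[-k:])
    return wrap(math.degrees(cmath.phase(v)))


def brute_rm_2x2(values):
    """Textbook 2x2 fully-within ANOVA from cell and marginal means.

    ``values``: dict (a_level, b_level) -> list of per-subject values, all in
    the same subject order. Returns {effect: (F, df1, df2, ss_eff, ss_err)}.
    """
    a_levels = sorted({a for a, _ in values})
    b_levels = sorted({b for _, b in values})
    n = len(next(iter(values.values())))
    grand = sum(sum(v) for v in values.values()) / (4 * n)
    sub_mean = [
        sum(values[(a, b)][i] for a in a_levels for b in b_levels) / 4.0
        for i in range(n)
    ]
    a_mean = {a: sum(sum(values[(a, b)]) for b in b_levels) / (2 * n)
              for a in a_levels}
    b_mean = {b: sum(sum(values[(a, b)]) for a in a_levels) / (2 * n)
              for b in b_levels}
    cell_mean = {k: sum(v) / n for k, v in values.items()}

    ss_a = 2 * n * sum((a_mean[a] - grand) ** 2 for a in a_levels)
    ss_b = 2 * n * sum((b_mean[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (cell_mean[(a, b)] - a_mean[a] - b_mean[b] + grand) ** 2
        for a in a_levels for b in b_levels
    )
    # error terms: subject x effect interactions
    ss_as = 0.0
    for i in range(n):
        for a in a_levels:
            m_ai = sum(values[(a, b)][i] for b in b_levels) / 2.0
            ss_as += 2 * (m_ai - a_mean[a] - sub_mean[i] + grand) ** 2
    ss_bs = 0.0
    for i in range(n):
        for b in b_levels:
            m_bi = sum(values[(a, b)][i] for a in a_levels) / 2.0
            ss_bs += 2 * (m_bi - b_mean[b] - sub_mean[i] + grand) ** 2
    ss_abs = 0.0
    for i in range(n):
        for a in a_levels:
            for b in b_levels:
                m_abi = values[(a, b)][i]
                m_ai = sum(values[(a, bb)][i] for bb in b_levels) / 2.0
                m_bi = sum(values[(aa, b)][i] for aa in a_levels) / 2.0
                e = (m_abi - cell_mean[(a, b)] - m_ai - m_bi
                     + a_mean[a] + b_mean[b] + sub_mean[i] - grand)
                ss_abs += e ** 2
    dfe = n - 1
    out = {}
    for name, ss_eff, ss_err in (("A", ss_a, ss_as), ("B", ss_b, ss_bs),
                                 ("A x B", ss_ab, ss_abs)):
        F = (ss_eff / 1.0) / (ss_err / dfe) if ss_err > 0 else float("nan")
        out[name] = (F, 1, dfe, ss_eff, ss_err)
    return out
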