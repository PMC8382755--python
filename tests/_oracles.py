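"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive results from first principles (literal
interval-by-interval application of the preprocessing rules; explicit
enumeration of rank permutations) and share no code with the package paths
they check.
"""

from itertools import permutations
from math import sqrt

import numpy as np

EYES = ("left_eye", "right_eye")


# ---------------------------------------------------------------------------
# rivalry preprocessing oracle


def _merge_adjacent(segs):
    out = []
    for s, e, lab in segs:
        if out and out[-1][2] == lab:
            out[-1][1] = e
        else:
            out.append([s, e, lab])
    return out


def oracle_segment(events, duration, cw_eye):
    """events: list of (time, state). Returns [start, end, label] segments."""
    if not events:
        return []
    lab = {
        "cw": "left_eye" if cw_eye == "left" else "right_eye",
        "ccw": "right_eye" if cw_eye == "left" else "left_eye",
        "mixed": "mixed",
        "none": "missing",
    }
    segs = []
    for i, (t, s) in enumerate(events):
        end = events[i + 1][0] if i + 1 < len(events) else duration
        segs.append([t, end, lab[s]])
    if events[0][0] > 0:
        segs.insert(0, [0.0, events[0][0], "missing"])
    return _merge_adjacent(segs)


def oracle_preprocess(events, duration, cw_eye, min_dur=0.2):
    """Literal application of the three preprocessing rules.

    Returns (eye_segments, mixed_time, missing_time) where eye_segments is a
    list of (start, end, label, censored) and censored means the segment is
    truncated by the run end.
    """
    segs = oracle_segment(events, duration, cw_eye)
    if not segs:
        return [], 0.0, 0.0

    # rule (a): missing data before a percept is assigned to that percept
    changed = True
    while changed:
        changed = False
        for i in range(len(segs) - 1):
            if segs[i][2] == "missing" and segs[i + 1][2] != "missing":
                segs[i + 1][0] = segs[i][0]
                del segs[i]
                changed = True
                break
        segs = _merge_adjacent(segs)

    # rule (b): eye responses shorter than min_dur are removed
    while True:
        target = next(
            (
                i
                for i, (s, e, lab) in enumerate(segs)
                if lab in EYES and e - s < min_dur
            ),
            None,
        )
        if target is None:
            break
        i = target
        prev = segs[i - 1] if i > 0 else None
        nxt = segs[i + 1] if i + 1 < len(segs) else None
        if prev is not None and nxt is not None and prev[2] == nxt[2]:
            prev[1] = nxt[1]
            del segs[i : i + 2]
        elif nxt is not None:
            nxt[0] = segs[i][0]
            del segs[i]
        else:
            segs[i][2] = "missing"
            segs = _merge_adjacent(segs)

    eye = [
        (s, e, lab, abs(e - duration) < 1e-12)
        for s, e, lab in segs
        if lab in EYES
    ]
    mixed_time = sum(e - s for s, e, lab in segs if lab == "mixed")
    missing_time = sum(e - s for s, e, lab in segs if lab == "missing")
    return eye, mixed_time, missing_time


# ---------------------------------------------------------------------------
# Spearman enumeration oracle


def _ranks(v):
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    r = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            r[order[k]] = avg
        i = j + 1
    return r


def _corr(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sqrt(sum((x - ma) ** 2 for x in a))
    db = sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def oracle_spearman(x, y, tol=1e-12):
    """(r, two-sided exact p) by full enumeration of all n! orderings of y."""
    rx = _ranks(list(x))
    ry = _ranks(list(y))
    r_obs = _corr(rx, ry)
    hits = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(_corr(rx, list(perm))) >= abs(r_obs) - tol:
            hits += 1
    return r_obs, hits / total


def oracle_spearman_null_r(n):
    """All n! rank-correlation values of 1..n against its permutations."""
    rx = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(permutations(rx)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    return (pc @ rxc) / np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
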