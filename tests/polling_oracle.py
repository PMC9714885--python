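"""Independent brute-force oracle for the polling estimator.

Pure-Python dictionary counting over explicit record loops — deliberately
naive and independent of the package's vectorised implementation, so the
two can be compared cell-for-cell and rank-for-rank.
"""

from __future__ import annotations


def oracle_joint(records, subset, threshold=-2.0):
    """records: iterable of dicts with keys haz, weight and covariate names.

    Returns (cells, counts): {(g, values): mass} and {(g, values): n}.
    Skips records with missing HAZ or any missing subset value.
    """
    cells: dict = {}
    counts: dict = {}
    for r in records:
        haz = r.get("haz")
        if haz is None or haz != haz:
            continue
        values = []
        ok = True
        for v in subset:
            val = r.get(v)
            if val is None or val != val:
                ok = False
                break
            values.append(val)
        if not ok:
            continue
        g = 1 if haz < threshold else 0
        key = (g, tuple(values))
        cells[key] = cells.get(key, 0.0) + r["weight"]
        counts[key] = counts.get(key, 0) + 1
    return cells, counts


def oracle_poll(cells, counts, g=1, convention="coverage-rank", min_cell=25):
    """Winner / runner-up / coverage / edge by exhaustive enumeration.

    Returns None when fewer than two profiles qualify (the implementation
    raises in that case).
    """
    group = {c: m for (gg, c), m in cells.items() if gg == g}
    m_g = 0.0
    for (gg, _), m in cells.items():  # record insertion order, like the impl's data
        if gg == g:
            m_g += m
    eligible = [c for c in group if counts[(g, c)] >= min_cell]
    if len(eligible) < 2:
        return None
    if convention == "coverage-rank":
        scores = {c: group[c] for c in eligible}
    else:
        scores = {}
        for c in eligible:
            denom = cells.get((0, c), 0.0) + cells.get((1, c), 0.0)
            scores[c] = group[c] / denom
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    (c_win, s_win), (c_run, s_run) = ranked[0], ranked[1]
    tied = abs(s_win - s_run) <= 1e-12 * max(abs(s_win), abs(s_run))
    return {
        "winner": c_win,
        "runner_up": c_run,
        "coverage": group[c_win] / m_g,
        "edge": 1.0 if tied else s_win / s_run,
        "tied": tied,
    }
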