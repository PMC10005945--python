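"""Independent brute-force re-derivation of CWD bookkeeping (test oracle)."""

def brute_force_cwd(et, p_in, runaway_days=5 * 365):
    """Independent day-by-day re-derivation of CWD, events and runaway flags."""
    n = len(et)
    cwd = [0.0] * n
    eid = [-1] * n
    events = []  # (start, end, max, day_of_max)
    i = 0
    while i < n:
        d = et[i] - p_in[i]
        if d <= 0:
            i += 1
            continue
        start = i
        running = 0.0
        best, best_day = -1.0, -1
        while i < n:
            running += et[i] - p_in[i]
            if running <= 0:
                cwd[i] = 0.0
                eid[i] = len(events)
                i += 1
                break
            cwd[i] = running
            eid[i] = len(events)
            if running > best:
                best, best_day = running, i
            i += 1
        end = i
        events.append((start, end, best, best_day, (end - start) > runaway_days))
    return cwd, eid, events


def brute_force_mask(cwd, events, fraction=0.9):
    masked = [False] * len(cwd)
    for start, end, ev_max, day_max, _ in events:
        hit = False
        for i in range(day_max + 1, end):
            if hit or cwd[i] < fraction * ev_max:
                hit = True
                masked[i] = True
    return masked
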