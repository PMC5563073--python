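"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def dock_windows_bruteforce(t, s, diameter=1.0, min_dur=10.0):
    """Exhaustive window enumeration for dock detection.

    For every window start, every window end is checked in full against the
    definition (all positions within half a diameter of the window mean);
    leftmost maximal valid windows meeting the duration criterion are kept,
    non-overlapping.
    """
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    tol = diameter / 2.0
    docks = []
    i, n = 0, len(t)
    while i < n:
        best = None
        for j in range(i, n):
            w = s[i : j + 1]
            if np.all(np.abs(w - w.mean()) <= tol + 1e-12):
                best = j
        if best is not None and t[best] - t[i] >= min_dur - 1e-6:
            docks.append((float(t[i]), float(t[best])))
            i = best + 1
        else:
            i += 1
    return docks
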