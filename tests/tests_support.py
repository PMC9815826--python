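"""Independent brute-force oracles shared by the validation suite.

These deliberately use plain Python loops and textbook formulas, independent
of the vectorised implementations they check.
"""

import numpy as np


def brute_pearson_all(X: np.ndarray, w: int) -> np.ndarray:
    """Loop-based sliding pairwise Pearson over causal windows of w samples."""
    n_ch, n_t = X.shape
    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    out = np.full((n_t - w + 1, len(pairs)), np.nan)
    for k, end in enumerate(range(w - 1, n_t)):
        for p, (a, b) in enumerate(pairs):
            x = X[a, end - w + 1 : end + 1]
            y = X[b, end - w + 1 : end + 1]
            xm, ym = x - x.mean(), y - y.mean()
            den = np.sqrt((xm**2).sum() * (ym**2).sum())
            if den > 0:
                out[k, p] = (xm * ym).sum() / den
    return out


def brute_cofluct(R: np.ndarray, C: float) -> np.ndarray:
    out = np.full(R.shape[0], np.nan)
    for t in range(R.shape[0]):
        n_def = n_above = 0
        for v in R[t]:
            if not np.isnan(v):
                n_def += 1
                if v > C:
                    n_above += 1
        if n_def:
            out[t] = 100.0 * n_above / n_def
    return out


def brute_events(values, T):
    """State-machine oracle over defined samples; timestamps are 1, 2, ..."""
    t = np.arange(1.0, len(values) + 1.0)
    intervals = []
    state = None
    start = None
    for k, v in enumerate(values):
        if np.isnan(v):
            continue
        above = v >= T
        if state is None:
            state = above
        elif above and not state:
            start = t[k]
            state = True
        elif not above and state:
            if start is not None:
                intervals.append((start, t[k]))
                start = None
            state = False
    if start is not None:
        defined_t = t[~np.isnan(np.asarray(values, float))]
        intervals.append((start, defined_t[-1]))
    return intervals
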