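"""Independent brute-force references used to cross-check the package.

Everything here is written as a literal transcription of the intended
behaviour (nested loops, pairwise counts) and stays independent of the
implementation modules it checks.
"""

import numpy as np

WINDOW_FACTORS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def odd(w):
    w = int(round(w))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def brute_cma(values, window):
    h = (window - 1) // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = sum(values[lo:hi]) / (hi - lo)
    return out


def brute_partial_peaks(values, window):
    """Literal re-scan: argmax of every maximal run strictly above the CMA."""
    cma = brute_cma(values, window)
    n = len(values)
    labels = set()
    i = 0
    while i < n:
        if values[i] > cma[i]:
            j = i
            while j + 1 < n and values[j + 1] > cma[j + 1]:
                j += 1
            best = i
            for k in range(i, j + 1):
                if values[k] > values[best]:
                    best = k
            labels.add(best)
            i = j + 1
        else:
            i += 1
    return labels


def brute_label_sets(values, sf):
    return [brute_partial_peaks(values, odd(f * sf)) for f in WINDOW_FACTORS]


def brute_detect_peaks(values, sf, min_sep_s=0.4):
    """Six-window intersection plus the literal pairwise 400 ms rule."""
    sets = brute_label_sets(values, sf)
    candidates = sorted(set.intersection(*sets))
    changed = True
    while changed:
        changed = False
        for k in range(len(candidates) - 1):
            a, b = candidates[k], candidates[k + 1]
            if (b - a) / sf < min_sep_s:
                drop = a if values[a] < values[b] else b
                candidates.remove(drop)
                changed = True
                break
    return np.array(candidates, dtype=int)


def pairwise_auc(scores, labels):
    """Concordant-pair (Mann-Whitney) AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    count = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                count += 1.0
            elif p == q:
                count += 0.5
    return count / (len(pos) * len(neg))


def dense_template_extrema(template, n_grid=2400):
    """Phases of the second-derivative extrema of a beat template."""
    g = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    d2 = np.gradient(np.gradient(template(g)))
    i = d2[1:-1]
    mask = ((i > d2[:-2]) & (i > d2[2:])) | ((i < d2[:-2]) & (i < d2[2:]))
    return g[np.where(mask)[0] + 1], d2[np.where(mask)[0] + 1]
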