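"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, density-reachability closure) without touching the package
implementations they are used to check.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_best_stump_error(X, y, w):
    """Minimal weighted 0/1 error over every axis-aligned stump.

    Considers every split position on every feature (including cuts
    outside the data range) and both polarities, counting errors
    directly.
    """
    best = np.inf
    for j in range(X.shape[1]):
        vals = np.sort(np.unique(X[:, j]))
        cuts = np.concatenate(
            [[vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2, [vals[-1] + 1.0]]
        )
        for thr in cuts:
            for pol in (1, -1):
                pred = np.where(pol * (X[:, j] - thr) >= 0, 1, -1)
                best = min(best, float(np.sum(w[pred != y])))
    return best


def dbscan_closure(pts, eps, minpts):
    """Density-reachability closure by explicit set expansion.

    Returns (core mask, labels over core points with -1 elsewhere,
    border candidate clusters per non-core point).  Border points that
    are eps-close to cores of several clusters are ambiguous by
    definition, so their admissible clusters are returned as a set.
    """
    n = len(pts)
    D = cdist(pts, pts)
    neigh = [np.flatnonzero(D[i] <= eps) for i in range(n)]
    core = np.array([nb.size >= minpts for nb in neigh])
    labels = np.full(n, -1)
    cid = 0
    for i in np.flatnonzero(core):
        if labels[i] != -1:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            u = stack.pop()
            for v in neigh[u]:
                if core[v] and labels[v] == -1:
                    labels[v] = cid
                    stack.append(v)
        cid += 1
    border = {}
    for i in range(n):
        if not core[i]:
            cands = {labels[c] for c in neigh[i] if core[c]}
            cands.discard(-1)
            if cands:
                border[i] = cands
    return core, labels, border


def check_dbscan_equivalence(pts, eps, minpts, labels, noise_mask):
    """Assert an implementation's labeling matches the closure oracle."""
    core, oracle_labels, border = dbscan_closure(pts, eps, minpts)
    n = len(pts)
    for i in range(n):
        if core[i]:
            assert not noise_mask[i], f"core point {i} marked noise"
        elif i in border:
            assert not noise_mask[i], f"border point {i} marked noise"
        else:
            assert noise_mask[i], f"unreachable point {i} not marked noise"
    # cluster structure over core points must agree up to relabeling
    mapping = {}
    for i in np.flatnonzero(core):
        ours = labels[i]
        theirs = oracle_labels[i]
        assert mapping.setdefault(theirs, ours) == ours, "core partition differs"
    assert len(set(mapping.values())) == len(mapping), "core clusters merged"
    # border points must sit in one of their admissible clusters
    for i, cands in border.items():
        assert labels[i] in {mapping[c] for c in cands}, f"border point {i} misassigned"
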