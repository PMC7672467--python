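"""A second, loop-coded implementation of the SAMME.R stump-boosting
recurrence, independent of the package's vectorized one, used as the oracle
for predicted probabilities.

Same published recurrence and the same deterministic conventions (midpoint
thresholds between consecutive distinct sorted values; ties broken by lower
feature index then lower threshold; leaf probabilities clipped to
[1e-15, 1 - 1e-15]; weight update exponent -lr/2 * (log p_true - log p_other)
for two classes), but written entirely with plain Python loops.
"""

from __future__ import annotations

import math

EPS = 1e-15


def _gini_of_split(rows, weights, labels, feature, threshold):
    wl = wl1 = wr = wr1 = 0.0
    for x, w, y in zip(rows, weights, labels):
        if x[feature] <= threshold:
            wl += w
            wl1 += w * y
        else:
            wr += w
            wr1 += w * y
    total = 0.0
    for wside, w1 in ((wl, wl1), (wr, wr1)):
        if wside > 0:
            p1 = w1 / wside
            p0 = (wside - w1) / wside
            total += wside * (1.0 - p1 * p1 - p0 * p0)
    return total, wl, wl1, wr, wr1


def _parent_gini(weights, labels):
    wsum = sum(weights)
    w1 = sum(w for w, y in zip(weights, labels) if y == 1)
    p1 = w1 / wsum
    p0 = 1.0 - p1
    return wsum * (1.0 - p1 * p1 - p0 * p0)


def _best_stump(rows, weights, labels):
    n_features = len(rows[0])
    best = None  # (impurity, feature, threshold)
    for f in range(n_features):
        values = sorted(set(x[f] for x in rows))
        for lo, hi in zip(values, values[1:]):
            thr = 0.5 * (lo + hi)
            imp, *_ = _gini_of_split(rows, weights, labels, f, thr)
            if best is None or imp < best[0]:
                best = (imp, f, thr)
    return best


def _clip(p):
    return min(max(p, EPS), 1.0 - EPS)


def fit_reference(rows, labels, n_estimators, learning_rate):
    """Fit the reference ensemble; returns a list of stump dicts."""
    n = len(rows)
    weights = [1.0 / n] * n
    stumps = []
    for _ in range(n_estimators):
        parent = _parent_gini(weights, labels)
        found = _best_stump(rows, weights, labels)
        if found is None or found[0] >= parent - 1e-12:
            break
        _, f, thr = found
        _, wl, wl1, wr, wr1 = _gini_of_split(rows, weights, labels, f, thr)
        p1_left = _clip(wl1 / wl) if wl > 0 else 0.5
        p1_right = _clip(wr1 / wr) if wr > 0 else 0.5
        stump = {"feature": f, "threshold": thr,
                 "left": (1.0 - p1_left, p1_left),
                 "right": (1.0 - p1_right, p1_right)}

        # weighted 0/1 error of the stump's argmax prediction
        err = 0.0
        for x, w, y in zip(rows, weights, labels):
            p1 = p1_left if x[f] <= thr else p1_right
            pred = 1 if p1 >= 1.0 - p1 else 0
            if pred != y:
                err += w
        if err > 0.5:
            break
        stumps.append(stump)

        pure = min(stump["left"]) <= 2 * EPS and min(stump["right"]) <= 2 * EPS
        if pure:
            break

        new_weights = []
        for x, w, y in zip(rows, weights, labels):
            p0, p1 = stump["left"] if x[f] <= thr else stump["right"]
            margin = (math.log(p1) - math.log(p0)) if y == 1 else (
                math.log(p0) - math.log(p1)
            )
            new_weights.append(w * math.exp(-0.5 * learning_rate * margin))
        z = sum(new_weights)
        weights = [w / z for w in new_weights]
        assert abs(sum(weights) - 1.0) < 1e-12
    return stumps


def predict_reference(stumps, rows, prior1=0.5):
    """Class-1 probability via softmax of the summed votes."""
    out = []
    for x in rows:
        F = 0.0
        for s in stumps:
            p0, p1 = s["left"] if x[s["feature"]] <= s["threshold"] else s["right"]
            F += 0.5 * (math.log(p1) - math.log(p0))
        if not stumps:
            out.append(prior1)
        else:
            out.append(1.0 / (1.0 + math.exp(-2.0 * F)))
    return out
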