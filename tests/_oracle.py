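"""Independent brute-force simplex-projection oracle.

Deliberately naive: pure-Python loops, an explicit full distance list per
target, and a plain sort.  Shares no code with phytoedm.edm; used only to
cross-check the vectorized implementation on small series.
"""
import math


def brute_force_simplex(values, E, tau=1, tp=1):
    """Return [(target_time, observed, predicted), ...] for one series.

    Contract mirrored independently: delay vectors (x_t, x_{t-tau}, ...,
    x_{t-(E-1)tau}) at every t where all coordinates are observed; targets
    and library both require x_{t+tp} observed; E+1 nearest neighbors by
    Euclidean distance (ties by earlier time), exp(-d/d_min) weights; all
    zero-distance duplicates join with weight 1.
    """
    n = len(values)

    def ok(v):
        return not math.isnan(v)

    pts = []
    for t in range((E - 1) * tau, n):
        vec = [values[t - j * tau] for j in range(E)]
        if all(ok(v) for v in vec) and t + tp < n and ok(values[t + tp]):
            pts.append((t, vec))

    out = []
    for t, vec in pts:
        cand = []
        for s, other in pts:
            if s == t:
                continue
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(vec, other)))
            cand.append((d, s))
        if not cand:
            continue
        cand.sort()
        k = min(E + 1, len(cand))
        sel = cand[:k]
        d_min = sel[0][0]
        if d_min > 0:
            weighted = [(math.exp(-d / d_min), s) for d, s in sel]
        else:
            zeros = [(1.0, s) for d, s in cand if d == 0]
            nonzero = [(d, s) for d, s in sel if d > 0]
            weighted = list(zeros)
            if nonzero:
                d_tilde = min(d for d, _ in nonzero)
                weighted += [(math.exp(-d / d_tilde), s) for d, s in nonzero]
        num = sum(w * values[s + tp] for w, s in weighted)
        den = sum(w for w, _ in weighted)
        out.append((t + tp, values[t + tp], num / den))
    return out
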