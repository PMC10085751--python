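"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: plain string
slicing, per-position arithmetic, and dict group-bys, so agreement with the
implementation is meaningful.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_revcomp(s):
    return "".join(_COMP[c] for c in reversed(s))


def brute_side(ori, ter, length, position):
    off = (position - ori) % length
    toff = (ter - ori) % length
    return "right" if off < toff else "left"


def brute_key_left(k):
    return k // 2 if k % 2 == 1 else k // 2 - 1


def brute_windows(seq, circular, k):
    """Yield (0-based key coordinate, window string)."""
    L = len(seq)
    left = brute_key_left(k)
    right = k - 1 - left
    if circular:
        ext = seq + seq
        for c in range(L):
            start = (c - left) % L
            yield c, ext[start : start + k]
    else:
        for c in range(left, L - right):
            yield c, seq[c - left : c - left + k]


def brute_count(seq, circular, k, frame=None, region="genome", strand="reference"):
    """Naive context count: returns (counts dict, n_skipped)."""
    counts, skipped = {}, 0
    for c, w in brute_windows(seq, circular, k):
        if region != "genome":
            side = brute_side(frame.ori, frame.ter, len(seq), c + 1)
            if (region == "right_replichore") != (side == "right"):
                continue
        if "N" in w:
            skipped += 1
            continue
        if strand == "complement":
            w = brute_revcomp(w)
        counts[w] = counts.get(w, 0) + 1
    return counts, skipped


def brute_context(seq, circular, position, ori, ter, convention):
    """Naive oriented triplet for a 1-based position; None if unavailable."""
    L = len(seq)
    i = position - 1
    if circular:
        up, down = seq[(i - 1) % L], seq[(i + 1) % L]
    else:
        if i == 0 or i == L - 1:
            return None
        up, down = seq[i - 1], seq[i + 1]
    trip = up + seq[i] + down
    if "N" in trip:
        return None
    side = brute_side(ori, ter, L, position)
    if convention == "lagging_template_revcomp" and side == "right":
        trip = brute_revcomp(trip)
    return trip, side


def brute_bin(position, ori, length, n_bins):
    offset = (position - ori) % length
    return int(offset // (length / n_bins)) + 1


def brute_rate_groupby(entries):
    """Aggregate a 192-entry dict {(u,r,a,d): RateEntry} to triplets by
    explicit looping."""
    out = {}
    for (u, r, a, d), e in entries.items():
        t = u + r + d
        m, rate, any_rate = out.get(t, (0, 0.0, False))
        m += e.M
        if e.rate is not None:
            rate += e.rate
            any_rate = True
        out[t] = (m, rate, any_rate)
    return {t: (m, rate if any_rate else None) for t, (m, rate, any_rate) in out.items()}
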