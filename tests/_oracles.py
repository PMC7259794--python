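"""Independent brute-force reference implementations used only by tests."""

_ALLOWED = [set("AG"), set("G"), set("GT"), set("T"), set("C"), set("A")]
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_drs(seq, tol):
    """Enumerate every (start, end, type, strand, mismatches) direct-repeat
    window within tolerance, testing each (offset, spacer, strand) triple
    independently of the production scanner."""
    seq = seq.upper()
    n = len(seq)
    hits = set()
    for strand in "+-":
        s = seq if strand == "+" else "".join(_RC[b] for b in reversed(seq))
        for spacer, name in ((1, "DR1"), (2, "DR2"), (5, "DR5")):
            width = 12 + spacer
            for off in range(n - width + 1):
                window = s[off:off + width]
                mm = 0
                for i in range(6):
                    if window[i] not in _ALLOWED[i]:
                        mm += 1
                    if window[6 + spacer + i] not in _ALLOWED[i]:
                        mm += 1
                if mm <= tol:
                    start = off if strand == "+" else n - off - width
                    hits.add((start, start + width, name, strand, mm))
    return hits


def bh_step_up(pvals):
    """Textbook step-up: sort, scale by n/rank, enforce monotonicity from
    the largest rank down, restore input order."""
    n = len(pvals)
    indexed = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = indexed[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adjusted[i] = running
    return adjusted
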