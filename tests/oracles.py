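"""Independent brute-force oracles shared by the test modules."""


def oracle_scan(probe, target, min_len=3, exclude=None):
    """Enumerate every (i, j, L) substring pair, keep maximal matches, drop
    those overlapping ``exclude`` (1-based closed), then collapse
    overlapping target intervals to one locus (longest wins, ties to
    smallest target then probe start). Returns sorted tuples
    (target_start, length, probe_start, sequence), all 1-based."""
    matches = []
    for i in range(len(probe)):
        for j in range(len(target)):
            max_l = min(len(probe) - i, len(target) - j)
            for L in range(min_len, max_l + 1):
                if probe[i : i + L] != target[j : j + L]:
                    continue
                left_max = i == 0 or j == 0 or probe[i - 1] != target[j - 1]
                right_max = (
                    i + L == len(probe)
                    or j + L == len(target)
                    or probe[i + L] != target[j + L]
                )
                if left_max and right_max:
                    matches.append((j, L, i))
    if exclude is not None:
        xs, xe = exclude
        matches = [
            (j, L, i) for (j, L, i) in matches if not (j + 1 <= xe and xs <= j + L)
        ]
    matches.sort()
    clusters = []
    for m in matches:
        if clusters and m[0] <= clusters[-1][1]:
            clusters[-1][1] = max(clusters[-1][1], m[0] + m[1] - 1)
            clusters[-1][2].append(m)
        else:
            clusters.append([m[0], m[0] + m[1] - 1, [m]])
    out = []
    for _, _, ms in clusters:
        j, L, i = min(ms, key=lambda m: (-m[1], m[0], m[2]))
        out.append((j + 1, L, i + 1, target[j : j + L]))
    return sorted(out)
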