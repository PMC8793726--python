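"""Independent brute-force recomputations of the statistics and interpolation.

Everything here works on plain Python structures with explicit loops and no
calls into retrolink internals, so agreement with the package is a genuine
dual-route check, not a tautology.

Conventions mirrored from the package contracts: maps are per-chromosome
(bp, cM) marker lists; a chromosome with fewer than two markers is unmapped
(intrachromosomal distance 0); positions clamp to terminal markers;
interchromosomal distance is 0.5 Morgans; gene points are floor midpoints of
0-based half-open spans.
"""


def naive_point(start0, end0):
    return (start0 + end0) // 2


def naive_genetic_position(markers, bp):
    """Linear interpolation by explicit segment search; cM in, Morgans out."""
    pos = [m[0] for m in markers]
    cm = [m[1] for m in markers]
    if bp <= pos[0]:
        return cm[0] / 100.0
    if bp >= pos[-1]:
        return cm[-1] / 100.0
    for k in range(len(pos) - 1):
        if pos[k] <= bp <= pos[k + 1]:
            frac = (bp - pos[k]) / (pos[k + 1] - pos[k])
            return (cm[k] + frac * (cm[k + 1] - cm[k])) / 100.0
    raise AssertionError("unreachable")


def naive_dist(chrom_a, bp_a, chrom_b, bp_b, maps, cap_half=False):
    if chrom_a != chrom_b:
        return 0.5
    markers = maps.get(chrom_a, [])
    if len(markers) < 2:
        return 0.0
    d = abs(naive_genetic_position(markers, bp_a) - naive_genetic_position(markers, bp_b))
    return min(d, 0.5) if cap_half else d


def naive_x1(rows, x_name):
    """rows: (parent_chrom, parent_bp, retro_chrom, retro_bp, status); retrogenes only."""
    return sum(
        1 for pc, _, rc, _, st in rows if st == "retrogene" and pc == x_name and rc != x_name
    )


def naive_filter_out_of_x(rows, x_name):
    return [r for r in rows if r[0] != x_name]


def naive_x2(rows, maps, cap_half=False):
    retro = [r for r in rows if r[4] == "retrogene"]
    return sum(naive_dist(pc, pp, rc, rp, maps, cap_half) for pc, pp, rc, rp, _ in retro) / len(retro)


def naive_x3(grouped_rows, maps, cap_half=False):
    """grouped_rows: list of per-parent lists of rows; empty groups skipped."""
    per_parent = []
    for group in grouped_rows:
        retro = [r for r in group if r[4] == "retrogene"]
        if not retro:
            continue
        dsum = sum(naive_dist(pc, pp, rc, rp, maps, cap_half) for pc, pp, rc, rp, _ in retro)
        per_parent.append(dsum / len(retro))
    return sum(per_parent) / len(per_parent)


def naive_x4(retro_rows, candidate_sets, maps, cap_half=False):
    """retro_rows: (retro_chrom, retro_bp); candidate_sets: per-retro list of (chrom, bp)."""
    total = 0.0
    for (rc, rp), cands in zip(retro_rows, candidate_sets):
        total += min(naive_dist(rc, rp, cc, cp, maps, cap_half) for cc, cp in cands)
    return total / len(retro_rows)
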