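"""Independent brute-force oracles for the bundling and family algorithms.

These deliberately share no code with the package: bundling is checked by
exhaustive enumeration of all contiguous partitions, families by a
hand-rolled union-find over the exhaustive pairwise distance matrix.
"""

from itertools import combinations


def _contiguous_partitions(items):
    """Every way to split a sequence into contiguous non-empty blocks."""
    n = len(items)
    for mask in range(1 << max(n - 1, 0)):
        blocks = [[items[0]]]
        for i in range(1, n):
            if (mask >> (i - 1)) & 1:
                blocks.append([items[i]])
            else:
                blocks[-1].append(items[i])
        yield blocks


def unique_gap_partition(ordinals, gap):
    """The unique partition where within-block gaps <= gap and block
    boundaries have gaps > gap; asserts uniqueness by full enumeration."""
    valid = []
    for blocks in _contiguous_partitions(list(ordinals)):
        ok = all(y - x - 1 <= gap for b in blocks for x, y in zip(b, b[1:]))
        ok = ok and all(b2[0] - b1[-1] - 1 > gap for b1, b2 in zip(blocks, blocks[1:]))
        if ok:
            valid.append(blocks)
    assert len(valid) == 1, f"gap partition not unique: {len(valid)} candidates"
    return valid[0]


def brute_force_two_stage(ordinals, g1, g2, min_core):
    """Reference result of stage 1 (+min_core) then stage 2, as ordinal tuples."""
    ordinals = sorted(ordinals)
    if not ordinals:
        return []
    stage1 = [b for b in unique_gap_partition(ordinals, g1) if len(b) >= min_core]
    if not stage1:
        return []
    valid = []
    k = len(stage1)
    for mask in range(1 << (k - 1)):
        groups = [[stage1[0]]]
        for i in range(1, k):
            if (mask >> (i - 1)) & 1:
                groups.append([stage1[i]])
            else:
                groups[-1].append(stage1[i])
        ok = all(
            c2[0] - c1[-1] - 1 <= g2 for g in groups for c1, c2 in zip(g, g[1:])
        )
        ok = ok and all(
            gb[0][0] - ga[-1][-1] - 1 > g2 for ga, gb in zip(groups, groups[1:])
        )
        if ok:
            valid.append(groups)
    assert len(valid) == 1, "merge grouping not unique"
    return [tuple(o for c in g for o in c) for g in valid[0]]


def brute_force_families(signatures, threshold):
    """Union-find families over all pairwise 1-Jaccard distances.

    ``signatures`` maps bundle_id -> frozenset of domains.  Returns a set
    of frozensets of bundle_ids.
    """
    parent = {b: b for b in signatures}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(sorted(signatures), 2):
        sa, sb = signatures[a], signatures[b]
        jac = len(sa & sb) / len(sa | sb)
        if 1.0 - jac <= threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups = {}
    for b in signatures:
        groups.setdefault(find(b), set()).add(b)
    return {frozenset(g) for g in groups.values()}
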