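"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops, set arithmetic,
direct double sums — and shares no code path with the package, so
agreement is evidence of correctness rather than self-confirmation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------- region grow


def region_grow_bfs(img, seed, tolerance, connectivity=8):
    """FIFO breadth-first region growing with a running-mean predicate,
    neighbors visited in row-major order."""
    rows, cols = img.shape
    if connectivity == 4:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    else:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                   (1, -1), (1, 0), (1, 1)]
    member = [[False] * cols for _ in range(rows)]
    r0, c0 = seed
    member[r0][c0] = True
    queue = [(r0, c0)]
    total = float(img[r0][c0])
    count = 1
    head = 0
    while head < len(queue):
        r, c = queue[head]
        head += 1
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and not member[nr][nc]:
                if abs(float(img[nr][nc]) - total / count) <= tolerance:
                    member[nr][nc] = True
                    total += float(img[nr][nc])
                    count += 1
                    queue.append((nr, nc))
    return np.array(member, dtype=np.uint8)


# ------------------------------------------------------------------- filtering


def _reflect_index(i, n):
    """Half-sample symmetric ('reflect including edge') index folding."""
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def correlate2d_reflect(img, kernel):
    """Direct nested-loop correlation with reflect (symmetric) padding."""
    rows, cols = img.shape
    kr, kc = kernel.shape
    ar, ac = kr // 2, kc // 2
    out = np.zeros_like(img, dtype=float)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for i in range(kr):
                for j in range(kc):
                    rr = _reflect_index(r + i - ar, rows)
                    cc = _reflect_index(c + j - ac, cols)
                    acc += kernel[i, j] * img[rr, cc]
            out[r, c] = acc
    return out


def local_mean_threshold(img, block, offset):
    """Sliding-window mean threshold with reflect padding."""
    rows, cols = img.shape
    half = block // 2
    out = np.zeros(img.shape, dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for i in range(-half, half + 1):
                for j in range(-half, half + 1):
                    acc += img[_reflect_index(r + i, rows),
                               _reflect_index(c + j, cols)]
            mean = acc / (block * block)
            out[r, c] = 1 if img[r, c] > mean + offset else 0
    return out


# ------------------------------------------------------------------ morphology


def se_offsets(footprint):
    k = footprint.shape[0] // 2
    return [(i - k, j - k)
            for i in range(footprint.shape[0])
            for j in range(footprint.shape[1]) if footprint[i, j]]


def erode_shifts(mask, footprint):
    """Set-definition erosion: a pixel survives iff every SE offset lands
    on a foreground pixel (outside the image counts as background)."""
    rows, cols = mask.shape
    out = np.zeros(mask.shape, dtype=np.uint8)
    offs = se_offsets(footprint)
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = 1 if ok else 0
    return out


def dilate_shifts(mask, footprint):
    """Set-definition dilation: union of the mask shifted by every SE offset."""
    rows, cols = mask.shape
    out = np.zeros(mask.shape, dtype=np.uint8)
    offs = se_offsets(footprint)
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        out[rr, cc] = 1
    return out


# ----------------------------------------------------------------- wavelets/DCT


def dwt1d(x, filt):
    """One analysis channel: half-sample symmetric extension, true
    convolution, dyadic downsampling."""
    x = np.asarray(x, dtype=float)
    L = len(filt)
    pad = np.concatenate([x[:L - 1][::-1], x, x[-(L - 1):][::-1]])
    out_len = (len(x) + L - 1) // 2
    return np.convolve(pad, filt)[L::2][:out_len]


def dwpt2_separable(img, lo, hi, depth):
    """Separable 2-D packet decomposition: 1-D pass over rows then
    columns, recursively on every node; natural order."""
    def one_level(a):
        # natural order LL, LH, HL, HH: the first letter is the filter
        # applied down the columns (axis 0), the second along the rows
        row_lo = np.apply_along_axis(dwt1d, 1, a, lo)
        row_hi = np.apply_along_axis(dwt1d, 1, a, hi)
        ll = np.apply_along_axis(dwt1d, 0, row_lo, lo)
        lh = np.apply_along_axis(dwt1d, 0, row_lo, hi)
        hl = np.apply_along_axis(dwt1d, 0, row_hi, lo)
        hh = np.apply_along_axis(dwt1d, 0, row_hi, hi)
        return [ll, lh, hl, hh]

    nodes = [np.asarray(img, dtype=float)]
    for _ in range(depth):
        nodes = [band for node in nodes for band in one_level(node)]
    return nodes


def dct2_direct(img):
    """Orthonormal 2-D DCT-II by the defining double cosine sum."""
    img = np.asarray(img, dtype=float)
    n, m = img.shape
    out = np.zeros((n, m))
    for u in range(n):
        for v in range(m):
            s = 0.0
            for r in range(n):
                for c in range(m):
                    s += (img[r, c]
                          * math.cos(math.pi * (2 * r + 1) * u / (2 * n))
                          * math.cos(math.pi * (2 * c + 1) * v / (2 * m)))
            au = math.sqrt((1 if u == 0 else 2) / n)
            av = math.sqrt((1 if v == 0 else 2) / m)
            out[u, v] = au * av * s
    return out


# ------------------------------------------------------------------ rough sets


def blocks_pairwise(rows):
    """Equivalence classes by O(n^2) pairwise comparison of value tuples.

    ``rows`` maps object id -> tuple of attribute values.
    """
    ids = list(rows)
    out = []
    assigned = set()
    for i, x in enumerate(ids):
        if x in assigned:
            continue
        block = {x}
        for y in ids[i + 1:]:
            if rows[x] == rows[y]:
                block.add(y)
        assigned |= block
        out.append(frozenset(block))
    return out


def approximations_enum(rows, labels, concept):
    """Lower/upper approximation by enumerating all blocks."""
    concept_set = frozenset(x for x in rows if labels[x] == concept)
    lower, upper = set(), set()
    for block in blocks_pairwise(rows):
        if block <= concept_set:
            lower |= block
        if block & concept_set:
            upper |= block
    return frozenset(lower), frozenset(upper)


def minimal_certain_complexes(rows, labels, concept, attrs):
    """All minimal conjunctions of attribute-value pairs whose matching
    set is nonempty and lies inside the concept's lower approximation,
    found by exhaustive search over condition subsets."""
    lower, _ = approximations_enum(rows, labels, concept)
    pairs = sorted({(a, rows[x][i]) for x in rows
                    for i, a in enumerate(attrs)})

    def block_of(conds):
        out = set(rows)
        for a, v in conds:
            i = attrs.index(a)
            out &= {x for x in rows if rows[x][i] == v}
        return frozenset(out)

    certain = []
    for k in range(1, len(attrs) + 1):
        for conds in itertools.combinations(pairs, k):
            if len({a for a, _ in conds}) < len(conds):
                continue  # one attribute per conjunction
            blk = block_of(conds)
            if blk and blk <= lower:
                certain.append((frozenset(conds), blk))
    minimal = []
    for conds, blk in certain:
        if not any(other < conds for other, _ in certain):
            minimal.append((conds, blk))
    return minimal, lower
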