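"""Independent brute-force reference implementations used only by tests.

Everything here is written from the operation definitions with plain
Python loops, deliberately sharing no code with the package: per-column
statistics are recounted by hand, sliding windows enumerate every
placement, DBSCAN follows the textbook definition via breadth-first
search, and patristic distances are summed over explicit tree paths.
"""

from __future__ import annotations

import random


# ---------------------------------------------------------------- cleaning


def column_gap_fraction(rows: list[str], col: int) -> float:
    return sum(1 for r in rows if r[col] == "-") / len(rows)


def column_base_counts(rows: list[str], col: int) -> dict[str, int]:
    counts = {b: 0 for b in "ACGT"}
    for r in rows:
        if r[col] in counts:
            counts[r[col]] += 1
    return counts


def remove_gap_columns_oracle(
    rows: list[str],
    hard_gap: float = 0.80,
    min_nuc: int = 5,
    soft_low: float = 0.40,
    soft_high: float = 0.80,
    soft_pred: float = 0.70,
) -> list[int]:
    """Removed column indices from a per-column re-evaluation of both
    passes."""
    width = len(rows[0])
    removed = []
    survivors = []
    for c in range(width):
        gap = column_gap_fraction(rows, c)
        nongap = sum(1 for r in rows if r[c] != "-")
        if gap > hard_gap or nongap < min_nuc:
            removed.append(c)
        else:
            survivors.append(c)
    for c in survivors:
        gap = column_gap_fraction(rows, c)
        counts = column_base_counts(rows, c)
        total = sum(counts.values())
        pred = max(counts.values()) / total if total else 0.0
        if soft_low < gap <= soft_high and pred < soft_pred:
            removed.append(c)
    return sorted(removed)


def proportion_matrix_oracle(rows: list[str]) -> list[list[float]]:
    width = len(rows[0])
    out = [[0.0] * width for _ in rows]
    for c in range(width):
        counts = column_base_counts(rows, c)
        nongap = sum(1 for r in rows if r[c] != "-")
        total = sum(counts.values())
        if nongap < 5 or total == 0:
            continue
        for ri, r in enumerate(rows):
            if r[c] in counts:
                out[ri][c] = counts[r[c]] / total
    return out


def crop_row_oracle(
    values: list[float], window: int, threshold: float, stop: str
) -> tuple[int, int] | None:
    """Kept span per the window definition, enumerating every placement.

    ``stop`` is ``"ge"`` (mean >= threshold) or ``"lt"`` (mean < threshold).
    None when no placement qualifies (the row is fully cropped).
    """
    width = len(values)
    w = min(window, width)
    placements = list(range(width - w + 1))
    means = [sum(values[s : s + w]) / w for s in placements]

    def ok(m: float) -> bool:
        return m >= threshold if stop == "ge" else m < threshold

    left = next((s for s in placements if ok(means[s])), None)
    if left is None:
        return None
    right = next((s for s in reversed(placements) if ok(means[s])), None)
    return (left, right + w)


def crop_end_by_gap_oracle(
    rows: list[str], window: int = 250, threshold: float = 0.1
) -> tuple[list[str], list[int]]:
    out, counts = [], []
    for row in rows:
        gaps = [1.0 if ch == "-" else 0.0 for ch in row]
        span = crop_row_oracle(gaps, window, threshold, "lt")
        if span is None:
            out.append("-" * len(row))
            counts.append(len(row))
        else:
            lo, hi = span
            out.append("-" * lo + row[lo:hi] + "-" * (len(row) - hi))
            counts.append(lo + len(row) - hi)
    return out, counts


def crop_end_by_divergence_oracle(
    rows: list[str],
    window: int = 40,
    threshold: float = 0.7,
    polish_window: int = 4,
    polish_threshold: float = 1.0,
) -> tuple[list[str], list[int]]:
    counts = [0] * len(rows)
    current = list(rows)
    for w, thr in ((window, threshold), (polish_window, polish_threshold)):
        prop = proportion_matrix_oracle(current)
        nxt = []
        for ri, row in enumerate(current):
            span = crop_row_oracle(prop[ri], w, thr, "ge")
            if span is None:
                nxt.append("-" * len(row))
                counts[ri] = len(row)
            else:
                lo, hi = span
                nxt.append("-" * lo + row[lo:hi] + "-" * (len(row) - hi))
                counts[ri] = lo + len(row) - hi
        current = nxt
    return current, counts


# ---------------------------------------------------------------- clustering


def dbscan_oracle(d, eps: float, min_samples: int) -> list[int]:
    """Textbook DBSCAN over a precomputed distance matrix (labels; -1 =
    noise), deterministic in index order."""
    n = len(d)
    neighbors = [
        [j for j in range(n) if d[i][j] <= eps] for i in range(n)
    ]  # includes self
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = [None] * n
    cluster = 0
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            p = queue.pop(0)
            if not core[p]:
                continue
            for q in neighbors[p]:
                if labels[q] is None:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    return [lab if lab is not None else -1 for lab in labels]


def random_additive_matrix(n: int, rng: random.Random):
    """Random binary tree with random branch lengths and its exact
    path-length (additive) distance matrix."""
    nodes = {i: None for i in range(n)}  # leaf ids
    # adjacency with branch lengths
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    next_id = n

    def link(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    pool = list(range(n))
    while len(pool) > 2:
        a = pool.pop(rng.randrange(len(pool)))
        b = pool.pop(rng.randrange(len(pool)))
        parent = next_id
        next_id += 1
        link(a, parent, rng.uniform(0.1, 2.0))
        link(b, parent, rng.uniform(0.1, 2.0))
        pool.append(parent)
    if len(pool) == 2:
        link(pool[0], pool[1], rng.uniform(0.1, 2.0))

    def path_lengths(src):
        dist = {src: 0.0}
        queue = [src]
        while queue:
            p = queue.pop()
            for q, w in adj[p]:
                if q not in dist:
                    dist[q] = dist[p] + w
                    queue.append(q)
        return dist

    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        dist = path_lengths(i)
        for j in range(i + 1, n):
            out[i][j] = out[j][i] = dist[j]  # mirrored: exactly symmetric
    return out


# ---------------------------------------------------------------- helpers


def random_msa_rows(rng: random.Random, n_rows: int, width: int, gap_p: float = 0.25):
    alphabet = "ACGT-"
    weights = [(1 - gap_p) / 4] * 4 + [gap_p]
    return [
        "".join(rng.choices(alphabet, weights=weights, k=width)) for _ in range(n_rows)
    ]
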