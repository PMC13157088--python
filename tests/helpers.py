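"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: pair enumeration is an
exhaustive O(n^2) loop, half-sphere exposure is a literal re-count with
numpy dot products, and the rank/t/U statistics are textbook formulas.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_pairs(sites, max_distance: float):
    """All unordered site pairs with resolved SG strictly closer than the cut."""
    out = []
    usable = [s for s in sites if s.has_resolved_sg and not s.modified]
    for a, b in itertools.combinations(usable, 2):
        d = float(np.linalg.norm(a.sg.coords - b.sg.coords))
        if 0.0 < d < max_distance:
            key = tuple(sorted([a.key, b.key]))
            out.append((key, d))
    return sorted(out)


def brute_force_hse(site, structure, radius: float):
    """Re-count neighbours against the CA->CB plane (pseudo-CB not needed:
    fixtures used with this oracle always have a CB)."""
    u = site.cb.coords - site.ca.coords
    u = u / np.linalg.norm(u)
    up = down = 0
    for r in structure.residues():
        if not r.polymer or r.key == site.key:
            continue
        ca = r.atom("CA")
        if ca is None:
            continue
        d = ca.coords - site.ca.coords
        if np.linalg.norm(d) >= radius:
            continue
        if float(np.dot(d, u)) > 0.0:
            up += 1
        else:
            down += 1
    return up, down


def average_ranks(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def welch_oracle(a, b) -> tuple[float, float]:
    """Welch's t with Welch-Satterthwaite df, two-sided p via scipy's CDF."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p


def mwu_oracle(a, b) -> tuple[float, float]:
    """U statistic of the first sample; z from the tie-corrected normal
    approximation, no continuity correction; two-sided p."""
    from scipy.stats import norm

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = average_ranks(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u1 - mu) / sigma
    p = 2.0 * norm.sf(abs(z))
    return u1, min(p, 1.0)


def auc_from_scores(pos, neg) -> float:
    """Rank-based AUC (probability a positive outscores a negative)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = average_ranks(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
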