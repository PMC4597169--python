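"""Independent brute-force oracles used to check the package's implementations.

Everything here is written from first principles on plain dicts and lists,
deliberately sharing no code path with the package.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations


# -- naive neighbour-edge collaborative filtering --------------------------


def naive_predict(
    edges: dict[tuple[str, str], float],
    h_i: str,
    p_x: str,
    mode: str = "literal",
    eps: float = 1e-12,
    ul: float = 1.5,
):
    """From-scratch evaluation of the two-sided neighbour-edge predictor.

    ``edges`` maps (hla, peptide) -> weight in {1, 2}.  The queried pair's
    own edge is excluded everywhere.  Returns (F, call, side_h, side_p),
    with None sides when undefined; F falls back to the global training mean
    when neither side is defined.
    """
    E = {k: v for k, v in edges.items() if k != (h_i, p_x)}
    hlas = sorted({h for h, _ in E})
    peps = sorted({p for _, p in E})

    def mean_h(h):
        ws = [v for (hh, _), v in E.items() if hh == h]
        return sum(ws) / len(ws) if ws else None

    def mean_p(p):
        ws = [v for (_, pp), v in E.items() if pp == p]
        return sum(ws) / len(ws) if ws else None

    def pearson(profile_a, mean_a, profile_b, mean_b):
        shared = sorted(set(profile_a) & set(profile_b))
        if not shared:
            return 0.0
        num = sum((profile_a[s] - mean_a) * (profile_b[s] - mean_b) for s in shared)
        da = sum((profile_a[s] - mean_a) ** 2 for s in shared)
        db = sum((profile_b[s] - mean_b) ** 2 for s in shared)
        if da == 0 or db == 0:
            return 0.0
        return num / (da * db) ** 0.5

    def hla_profile(h):
        return {p: E[(h, p)] for p in peps if (h, p) in E}

    def pep_profile(p):
        return {h: E[(h, p)] for h in hlas if (h, p) in E}

    # HLA side
    mh = mean_h(h_i)
    if mh is None:
        side_h = None
    else:
        J = [h for h in hlas if h != h_i and (h, p_x) in E]
        S = {j: pearson(hla_profile(h_i), mh, hla_profile(j), mean_h(j)) for j in J}
        D = sum(abs(s) for s in S.values()) if mode == "absolute" else sum(S.values())
        if abs(D) < eps:
            side_h = mh
        else:
            side_h = mh + sum((E[(j, p_x)] - mean_h(j)) * S[j] for j in J) / D

    # peptide side
    mp = mean_p(p_x)
    if mp is None:
        side_p = None
    else:
        K = [p for p in peps if p != p_x and (h_i, p) in E]
        S = {k: pearson(pep_profile(p_x), mp, pep_profile(k), mean_p(k)) for k in K}
        D = sum(abs(s) for s in S.values()) if mode == "absolute" else sum(S.values())
        if abs(D) < eps:
            side_p = mp
        else:
            side_p = mp + sum((E[(h_i, k)] - mean_p(k)) * S[k] for k in K) / D

    if side_h is not None and side_p is not None:
        F = (side_h + side_p) / 2.0
    elif side_h is not None:
        F = side_h
    elif side_p is not None:
        F = side_p
    else:
        F = sum(E.values()) / len(E)
    call = "positive" if F >= ul else "negative"
    return F, call, side_h, side_p


# -- repeated single-node deletion (bipartite k-core) ----------------------


def brute_force_core(edges, min_count=2, rng=None):
    """Repeatedly delete ONE deficient node at a time (random order when an
    rng is given) until all degrees are >= min_count."""
    cur = set(edges)
    while True:
        du = Counter(u for u, _ in cur)
        dv = Counter(v for _, v in cur)
        bad_u = [u for u, d in du.items() if d < min_count]
        bad_v = [v for v, d in dv.items() if d < min_count]
        candidates = [("u", u) for u in sorted(bad_u)] + [("v", v) for v in sorted(bad_v)]
        if not candidates:
            return cur
        side, node = candidates[rng.integers(0, len(candidates))] if rng is not None else candidates[0]
        if side == "u":
            cur = {(u, v) for u, v in cur if u != node}
        else:
            cur = {(u, v) for u, v in cur if v != node}


# -- exhaustive modularity optimisation ------------------------------------


def modularity_oracle(edges, assignment):
    """Newman-Girvan Q written independently with explicit loops."""
    m = sum(w for _, _, w in edges)
    comms = set(assignment.values())
    q = 0.0
    for c in comms:
        inside = sum(w for u, v, w in edges if assignment[u] == c and assignment[v] == c)
        deg = sum(
            w * ((assignment[u] == c) + (assignment[v] == c)) for u, v, w in edges
        )
        q += inside / m - (deg / (2 * m)) ** 2
    return q


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_best_partition(edges):
    """Maximum-modularity partition by enumerating all set partitions
    (feasible for graphs of about 10 nodes)."""
    nodes = sorted({x for u, v, _ in edges for x in (u, v)})
    best_q, best_assignment = float("-inf"), None
    for blocks in _set_partitions(nodes):
        assignment = {}
        for cid, block in enumerate(blocks):
            for node in block:
                assignment[node] = cid
        q = modularity_oracle(edges, assignment)
        if q > best_q:
            best_q, best_assignment = q, assignment
    return best_assignment, best_q


# -- AUC by exhaustive pair counting ---------------------------------------


def auc_pair_counting(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(tie) over all positive x negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


# -- misc -------------------------------------------------------------------


def random_bipartite_edges(rng, max_h=6, max_p=6):
    """Random small weighted bipartite edge dict for oracle comparisons."""
    nh = int(rng.integers(2, max_h + 1))
    np_ = int(rng.integers(2, max_p + 1))
    edges = {}
    for i in range(nh):
        for j in range(np_):
            if rng.random() < 0.55:
                edges[(f"H{i}", f"pep{j}")] = float(rng.integers(1, 3))
    return edges


def partition_agreement(assignment, truth):
    """True iff the found partition equals the planted one up to relabeling."""
    forward = {}
    backward = {}
    for node, found in assignment.items():
        planted = truth[node]
        if forward.setdefault(found, planted) != planted:
            return False
        if backward.setdefault(planted, found) != found:
            return False
    return True
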