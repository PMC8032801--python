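"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the aligner oracle is a
plain-Python dynamic program, and the Dollo oracle enumerates every
single-gain ancestral labeling.  They are slow and simple on purpose.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_BLOSUM.alphabet)
GAP_OPEN = -10.0
GAP_EXTEND = -1.0
NEG = float("-inf")


def _s(a: str, b: str) -> float:
    ia = _ALPHA.index(a) if a in _ALPHA else _ALPHA.index("X")
    ib = _ALPHA.index(b) if b in _ALPHA else _ALPHA.index("X")
    return float(_BLOSUM[ia, ib])


def align_oracle(a: str, b: str) -> tuple[float, float]:
    """Semi-global affine-gap alignment: returns (score, percent identity).

    Same scoring and tie-break conventions as the package aligner
    (diagonal > up > left; ties inside the gap states prefer opening),
    implemented as an independent plain-Python quadratic DP.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    pH = [[0] * (m + 1) for _ in range(n + 1)]
    pE = [[0] * (m + 1) for _ in range(n + 1)]
    pF = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo, ee = H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND
            E[i][j], pE[i][j] = (eo, 0) if eo >= ee else (ee, 1)
            fo, fe = H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND
            F[i][j], pF[i][j] = (fo, 0) if fo >= fe else (fe, 1)
            best, ptr = H[i - 1][j - 1] + _s(a[i - 1], b[j - 1]), 0
            if F[i][j] > best:
                best, ptr = F[i][j], 1
            if E[i][j] > best:
                best, ptr = E[i][j], 2
            H[i][j], pH[i][j] = best, ptr
    bi, bj, score = n, m, H[n][m]
    for i in range(n + 1):
        if H[i][m] > score:
            bi, bj, score = i, m, H[i][m]
    for j in range(m + 1):
        if H[n][j] > score:
            bi, bj, score = n, j, H[n][j]

    ra, rb = [], []
    for i in range(n, bi, -1):
        ra.append(a[i - 1])
        rb.append("-")
    for j in range(m, bj, -1):
        ra.append("-")
        rb.append(b[j - 1])
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            if pH[i][j] == 0:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i, j = i - 1, j - 1
            else:
                state = pH[i][j]
        elif state == 1:
            ra.append(a[i - 1])
            rb.append("-")
            state = 0 if pF[i][j] == 0 else 1
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            state = 0 if pE[i][j] == 0 else 2
            j -= 1
    while i > 0:
        ra.append(a[i - 1])
        rb.append("-")
        i -= 1
    while j > 0:
        ra.append("-")
        rb.append(b[j - 1])
        j -= 1
    ra, rb = "".join(reversed(ra)), "".join(reversed(rb))

    core_a = [k for k, c in enumerate(ra) if c != "-"]
    core_b = [k for k, c in enumerate(rb) if c != "-"]
    lo, hi = max(core_a[0], core_b[0]), min(core_a[-1], core_b[-1])
    if hi < lo:
        return score, 0.0
    matches = sum(1 for k in range(lo, hi + 1) if ra[k] == rb[k] and ra[k] != "-")
    return score, 100.0 * matches / (hi - lo + 1)


# -- Dollo brute force ----------------------------------------------------


class SimpleNode:
    def __init__(self, name=None, children=()):
        self.name = name
        self.children = list(children)

    def nodes(self):
        yield self
        for c in self.children:
            yield from c.nodes()

    def leaves(self):
        return [n for n in self.nodes() if not n.children]

    def to_newick(self) -> str:
        if not self.children:
            return self.name
        return "(" + ",".join(c.to_newick() for c in self.children) + ")"


def dollo_bruteforce(root: SimpleNode, presence: dict[str, bool]) -> int | None:
    """Minimum losses over all single-gain histories, by full enumeration.

    States are enumerated over internal nodes (leaves fixed by the data);
    a history is valid iff it has exactly one 0->1 edge transition, or the
    root is present and no other 0->1 transition exists.  Returns None if
    no present leaf exists (no valid single-gain history is required).
    """
    internals = [n for n in root.nodes() if n.children]
    if not any(presence.values()):
        return None
    best = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, states)}
        for leaf in root.leaves():
            st[id(leaf)] = 1 if presence[leaf.name] else 0
        gains = losses = 0
        stack = [root]
        while stack:
            node = stack.pop()
            for c in node.children:
                if st[id(node)] == 0 and st[id(c)] == 1:
                    gains += 1
                elif st[id(node)] == 1 and st[id(c)] == 0:
                    losses += 1
                stack.append(c)
        total_gains = gains + st[id(root)]  # root presence counts as the gain
        if total_gains != 1:
            continue
        if best is None or losses < best:
            best = losses
    return best


def all_topologies(leaves: list[str]) -> list[SimpleNode]:
    """Every rooted binary topology on the given labeled leaves."""
    if len(leaves) == 1:
        return [SimpleNode(name=leaves[0])]
    out = []
    first, rest = leaves[0], leaves[1:]
    # split rest into the part grouped with `first` vs the sister clade
    for k in range(0, len(rest)):
        for left_rest in itertools.combinations(rest, k):
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in all_topologies([first, *left_rest]):
                for rt in all_topologies(right):
                    out.append(SimpleNode(children=[lt, rt]))
    return out


def random_topology(leaves: list[str], rng) -> SimpleNode:
    nodes = [SimpleNode(name=x) for x in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = SimpleNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]
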