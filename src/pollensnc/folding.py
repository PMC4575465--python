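"""RNA secondary-structure folding and MFE-significance scoring.

Folding delegates to the ViennaRNA nearest-neighbor energy model (the RNAfold
engine); everything layered on top — pair tables, dinucleotide-preserving
shuffles, and the Gumbel calibration of an observed MFE against shuffled
nulls — is engine-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import RNA

_EULER_GAMMA = 0.5772156649015329
VALID_BASES = set("ACGU")


def fold(sequence: str) -> tuple[str, float]:
    """Minimum-free-energy structure (dot-bracket) and MFE in kcal/mol.

    T is mapped to U; any other non-ACGU character is an error.  The returned
    structure is pseudoknot-free and its MFE is <= 0.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid bases for folding: {sorted(bad)}")
    structure, mfe = RNA.fold(seq)
    return structure, float(mfe)


def pair_table(structure: str) -> list[int | None]:
    """Partner index per position (None = unpaired) from dot-bracket."""
    stack: list[int] = []
    table: list[int | None] = [None] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    return table


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random permutation of a sequence preserving dinucleotide counts.

    Uses the Eulerian-path construction: the sequence is a walk on the graph
    whose vertices are bases and whose edges are the observed dinucleotides;
    a uniform random Eulerian walk with the same start and end realizes a
    dinucleotide-preserving shuffle.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        return seq
    # adjacency: vertex -> multiset of successors
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    vertices = sorted(adj.keys() | {seq[-1]})
    last = seq[-1]

    # choose, for every vertex except the terminal one, a "last exit" edge
    # forming an arborescence toward the terminal vertex (Altschul-Erickson)
    for _attempt in range(100):
        last_exit: dict[str, str] = {}
        for v in vertices:
            if v == last or v not in adj:
                continue
            last_exit[v] = adj[v][rng.integers(len(adj[v]))]
        # check connectivity: following last-exit edges must reach `last`
        ok = True
        for v in last_exit:
            seen = {v}
            cur = v
            while cur != last:
                if cur not in last_exit:
                    ok = False
                    break
                cur = last_exit[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:
        return seq  # graph too constrained; give the input back unchanged

    # shuffle the remaining edges, appending the designated last exits
    walk_adj: dict[str, list[str]] = {}
    for v, edges in adj.items():
        pool = list(edges)
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        walk_adj[v] = pool

    out = [seq[0]]
    ptr = {v: 0 for v in walk_adj}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_adj[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class MfeSignificance:
    mfe: float
    p_value: float
    score: float          # -log10(p)
    location: float       # Gumbel mu of the shuffled -MFE distribution
    scale: float          # Gumbel beta
    n_shuffles: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def score_precursor(sequence: str, n_shuffles: int = 100,
                    seed: int | np.random.Generator = 0) -> MfeSignificance:
    """Calibrate a precursor's MFE against dinucleotide-shuffled nulls.

    Shuffled copies are folded; a Gumbel distribution is fitted by moments to
    their negated MFEs and the p-value is the Gumbel upper-tail probability
    of a stability at least as extreme as observed.  Score = -log10(p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    _, mfe = fold(sequence)
    shuffles = [dinucleotide_shuffle(sequence, rng) for _ in range(n_shuffles)]
    if len(set(shuffles)) < 2 or len(sequence) < 10:
        return MfeSignificance(mfe, 1.0, 0.0, 0.0, 0.0, n_shuffles,
                               degenerate=True)
    null = np.array([fold(s)[1] for s in shuffles])
    x = -null  # stability as a maximum
    sd = x.std(ddof=1)
    if sd == 0:
        degenerate = True
        p = 1.0 if -mfe <= x[0] else 1.0 / (n_shuffles + 1)
        return MfeSignificance(mfe, p, -math.log10(max(p, 1e-300)),
                               float(x[0]), 0.0, n_shuffles, degenerate)
    beta = sd * math.sqrt(6.0) / math.pi
    mu = x.mean() - _EULER_GAMMA * beta
    z = (-mfe - mu) / beta
    # upper tail of the Gumbel max distribution
    p = float(1.0 - math.exp(-math.exp(-z)))
    p = min(max(p, 1e-300), 1.0)
    return MfeSignificance(mfe, p, -math.log10(p), mu, beta, n_shuffles)
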