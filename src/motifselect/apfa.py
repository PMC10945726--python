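"""Acyclic probabilistic finite automata over fixed-length DNA sequences.

An APFA organises states in levels 0..l plus a final state; every
nucleotide edge goes from level k to level k+1 and every level-l state
emits an end-of-sequence edge to the final state.  The probability of a
sequence is the product of edge probabilities along its unique path,
which lets the automaton encode dependence between positions that a PWM
cannot express (a state at level k remembers which prefix led to it).

Learning starts from the sample's prefix tree and folds together states
whose futures look alike, level by level:

* two states are *similar* when the L1 distance between their smoothed
  next-symbol conditional distributions is at most ``mu`` (the L1 range
  is [0, 2], so ``mu = 2`` always merges);
* only states with arrival count >= ``m0`` carry enough evidence to be
  compared; a state below ``m0`` is folded into the most similar
  eligible state unconditionally, or kept if the level has none;
* edge probabilities are smoothed with pseudocount ``gamma`` per
  nucleotide: p = (count + gamma) / (arrivals + 4 * gamma).

Because all sample sequences share one length l, end-of-sequence mass
is meaningful only at level l, where it is 1 from every state; interior
smoothing is therefore over the 4 nucleotides only and the final factor
of every sequence probability is 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import ALPHABET, NullModel, TFBSSample, encode_sequences

#: Default hyperparameter grid searched by the nested cross-validation.
DEFAULT_MU_GRID = (0.1, 0.3, 0.6, 1.0)
DEFAULT_M0_GRID = (2, 5, 10)
DEFAULT_GAMMA_GRID = (0.1, 0.5, 1.0)


@dataclass(frozen=True)
class LearnApfaHyperparams:
    """Hyperparameters of the APFA learning algorithm.

    mu : similarity threshold on the L1 distance between next-symbol
        conditionals, in [0, 2]; larger means more merging.
    m0 : minimum arrival count for a state to count as statistical
        evidence in a similarity comparison.
    gamma : additive smoothing pseudocount per nucleotide edge.
    """

    mu: float
    m0: float
    gamma: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.m0 < 0:
            raise ValueError("m0 must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def default_grid() -> tuple[LearnApfaHyperparams, ...]:
    return tuple(
        LearnApfaHyperparams(mu, m0, g)
        for mu, m0, g in itertools.product(
            DEFAULT_MU_GRID, DEFAULT_M0_GRID, DEFAULT_GAMMA_GRID
        )
    )


@dataclass
class APFA:
    """Leveled automaton in array form.

    For each level k in 0..l-1: ``counts[k]`` and ``probs[k]`` are
    (n_states_k, 4) arrays of training counts and edge probabilities,
    ``trans[k]`` the (n_states_k, 4) destination state index at level
    k+1 (-1 for a missing, zero-probability edge), ``arrivals[k]`` the
    per-state arrival counts and ``prefixes[k]`` a canonical
    (lexicographically smallest) arriving prefix per state.  Level l
    states all emit end-of-sequence with probability 1.
    """

    l: int  # noqa: E741
    counts: list[np.ndarray]
    probs: list[np.ndarray]
    trans: list[np.ndarray]
    arrivals: list[np.ndarray]
    prefixes: list[list[str]]
    hp: LearnApfaHyperparams | None = None
    threshold: float | None = None

    @property
    def level_sizes(self) -> list[int]:
        return [len(a) for a in self.arrivals]

    @property
    def n_states(self) -> int:
        # +1 for the final state reached by the EOS edges
        return sum(self.level_sizes) + 1


def _prefix_tree_arrays(mat: np.ndarray):
    """Level-wise count/transition arrays of the sample's prefix tree."""
    n, l = mat.shape
    # state ids per level; sequences enter state 0 at level 0
    state = np.zeros(n, dtype=np.intp)
    counts, trans, arrivals, prefixes = [], [], [], []
    level_prefixes = [""]
    for k in range(l):
        n_states = len(level_prefixes)
        cnt = np.zeros((n_states, 4), dtype=np.int64)
        np.add.at(cnt, (state, mat[:, k]), 1)
        tr = np.full((n_states, 4), -1, dtype=np.intp)
        next_prefixes = []
        nxt_id = 0
        occupied = np.argwhere(cnt > 0)
        for s_id, sym in occupied:
            tr[s_id, sym] = nxt_id
            next_prefixes.append(level_prefixes[s_id] + ALPHABET[sym])
            nxt_id += 1
        counts.append(cnt)
        trans.append(tr)
        arrivals.append(cnt.sum(axis=1))
        prefixes.append(level_prefixes)
        state = tr[state, mat[:, k]]
        level_prefixes = next_prefixes
    arrivals.append(np.bincount(state, minlength=len(level_prefixes)).astype(np.int64))
    prefixes.append(level_prefixes)
    return counts, trans, arrivals, prefixes


def build_prefix_tree(sample: TFBSSample) -> APFA:
    """Prefix tree of the sample with raw-count edge probabilities.

    Edge probabilities are the unsmoothed conditionals count/arrivals;
    missing edges keep probability 0 (and destination -1), so the tree
    reproduces the empirical sequence distribution exactly.
    """
    mat = sample.matrix()
    counts, trans, arrivals, prefixes = _prefix_tree_arrays(mat)
    probs = [c / a[:, None] for c, a in zip(counts, arrivals)]
    return APFA(
        l=sample.l,
        counts=counts,
        probs=probs,
        trans=trans,
        arrivals=arrivals,
        prefixes=prefixes,
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller index as root for determinism
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _collapse(uf: _UnionFind, n: int):
    """Mapping old id -> new compact id, grouping by union-find root."""
    roots = [uf.find(i) for i in range(n)]
    order: dict[int, int] = {}
    mapping = np.empty(n, dtype=np.intp)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        mapping[i] = order[r]
    return mapping, len(order)


def _merge_level(cnt, tr, prefixes, mapping, n_new, next_uf):
    """Apply a state-id mapping to one level, fusing rows and children."""
    new_cnt = np.zeros((n_new, 4), dtype=cnt.dtype)
    np.add.at(new_cnt, mapping, cnt)
    new_tr = np.full((n_new, 4), -1, dtype=np.intp)
    new_prefixes = [None] * n_new
    for old in range(len(cnt)):
        new = mapping[old]
        p = prefixes[old]
        if new_prefixes[new] is None or p < new_prefixes[new]:
            new_prefixes[new] = p
        if tr is None:
            continue
        for sym in range(4):
            dest = tr[old, sym]
            if dest < 0:
                continue
            if new_tr[new, sym] < 0:
                new_tr[new, sym] = dest
            elif next_uf is not None:
                # two subtrees reached by the same symbol fold together
                next_uf.union(int(new_tr[new, sym]), int(dest))
    return new_cnt, new_tr, new_prefixes


def learn_apfa(sample: TFBSSample, hp: LearnApfaHyperparams) -> APFA:
    """Learn an APFA by level-wise folding of the sample's prefix tree.

    Within each level, eligible states (arrival count >= m0) whose
    smoothed next-symbol conditionals are within L1 distance mu are
    merged, transitively; states below m0 fold into their most similar
    eligible state.  Merging two states also merges, per symbol, the
    subtrees they lead to.  Examination order is deterministic: arrival
    count descending, ties broken by the lexicographically smallest
    arriving prefix.  After folding, probabilities are gamma-smoothed
    over the 4 nucleotides and every missing edge is pointed at the
    heaviest state of the next level so no sequence gets probability 0.
    """
    mat = sample.matrix()
    l = sample.l
    counts, trans, arrivals, prefixes = _prefix_tree_arrays(mat)

    pending: _UnionFind | None = None
    for k in range(1, l + 1):
        cnt = counts[k] if k < l else np.zeros((len(arrivals[k]), 4), dtype=np.int64)
        tr = trans[k] if k < l else None
        n_k = len(arrivals[k])
        next_uf = _UnionFind(len(arrivals[k + 1])) if k < l else None

        # 1. collapse groups forced by merges at level k-1
        if pending is not None:
            mapping, n_k = _collapse(pending, n_k)
            cnt, tr, prefixes[k] = _merge_level(
                cnt, tr, prefixes[k], mapping, n_k, next_uf
            )
            trans[k - 1] = np.where(trans[k - 1] >= 0, mapping[trans[k - 1]], -1)

        arr = cnt.sum(axis=1) if k < l else _arrivals_from_parent(trans[k - 1], counts[k - 1], n_k)

        # 2. similarity clustering within the level
        if k < l and n_k > 1:
            cond = (cnt + hp.gamma) / (arr + 4 * hp.gamma)[:, None]
            order = sorted(range(n_k), key=lambda i: (-arr[i], prefixes[k][i]))
            eligible = [i for i in order if arr[i] >= hp.m0]
            uf = _UnionFind(n_k)
            if eligible:
                e = np.array(eligible)
                d = np.abs(cond[e][:, None, :] - cond[e][None, :, :]).sum(axis=2)
                for a in range(len(e)):
                    for b in range(a + 1, len(e)):
                        if d[a, b] <= hp.mu:
                            uf.union(int(e[a]), int(e[b]))
                for i in order:
                    if arr[i] < hp.m0:
                        dist = np.abs(cond[e] - cond[i]).sum(axis=1)
                        uf.union(int(e[int(np.argmin(dist))]), i)
            mapping, n_new = _collapse(uf, n_k)
            if n_new < n_k:
                cnt, tr, prefixes[k] = _merge_level(
                    cnt, tr, prefixes[k], mapping, n_new, next_uf
                )
                trans[k - 1] = np.where(trans[k - 1] >= 0, mapping[trans[k - 1]], -1)
                arr = cnt.sum(axis=1)
                n_k = n_new
        elif k == l and n_k > 1:
            # all level-l states behave identically (EOS with prob 1): fuse
            uf = _UnionFind(n_k)
            for i in range(1, n_k):
                uf.union(0, i)
            mapping, n_k = _collapse(uf, n_k)
            cnt, tr, prefixes[k] = _merge_level(cnt, None, prefixes[k], mapping, n_k, None)
            trans[k - 1] = np.where(trans[k - 1] >= 0, mapping[trans[k - 1]], -1)
            arr = _arrivals_from_parent(trans[k - 1], counts[k - 1], n_k)

        if k < l:
            counts[k] = cnt
            trans[k] = tr
        arrivals[k] = arr
        pending = next_uf

    # 3. smooth and complete: every interior state gets 4 positive edges
    probs = []
    for k in range(l):
        arr = arrivals[k].astype(float)
        probs.append((counts[k] + hp.gamma) / (arr + 4 * hp.gamma)[:, None])
        heaviest = int(np.lexsort((prefixes[k + 1], -arrivals[k + 1]))[0])
        trans[k] = np.where(trans[k] >= 0, trans[k], heaviest)
    return APFA(
        l=l,
        counts=counts[:l],
        probs=probs,
        trans=trans[:l],
        arrivals=arrivals,
        prefixes=prefixes,
        hp=hp,
    )


def _arrivals_from_parent(parent_trans, parent_counts, n_states):
    arr = np.zeros(n_states, dtype=np.int64)
    valid = parent_trans >= 0
    np.add.at(arr, parent_trans[valid], parent_counts[valid])
    return arr


def apfa_prob(a: APFA, s: str) -> float:
    """Probability the automaton assigns to sequence ``s`` (length l)."""
    if len(s) != a.l:
        raise ValueError(f"sequence length {len(s)} != automaton length {a.l}")
    return float(apfa_prob_many(a, encode_sequences([s]))[0])


def apfa_prob_many(a: APFA, mat: np.ndarray) -> np.ndarray:
    """Vectorised path probabilities for an (n, l) encoded matrix."""
    if mat.shape[1] != a.l:
        raise ValueError(f"matrix width {mat.shape[1]} != automaton length {a.l}")
    n = mat.shape[0]
    state = np.zeros(n, dtype=np.intp)
    prob = np.ones(n, dtype=float)
    for k in range(a.l):
        sym = mat[:, k]
        prob *= a.probs[k][state, sym]
        nxt = a.trans[k][state, sym]
        state = np.where(nxt >= 0, nxt, 0)
    return prob


def score_apfa(a: APFA, s: str, null: NullModel) -> float:
    """Log-odds score in bits: log2 P_A(s) - sum_i log2 q(s_i).

    Returns -inf when the automaton assigns probability 0 (possible only
    for unsmoothed prefix trees).
    """
    if len(s) != a.l:
        raise ValueError(f"sequence length {len(s)} != automaton length {a.l}")
    return float(score_apfa_many(a, encode_sequences([s]), null)[0])


def score_apfa_many(a: APFA, mat: np.ndarray, null: NullModel) -> np.ndarray:
    p = apfa_prob_many(a, mat)
    logq = np.log2(null.as_array())
    with np.errstate(divide="ignore"):
        return np.log2(p) - logq[mat].sum(axis=1)


MAX_ENUMERATION_LENGTH = 8


def enumerate_distribution(a: APFA) -> dict[str, float]:
    """Exhaustive sequence -> probability map over all 4**l sequences.

    Refuses l > 8 to guard against combinatorial blow-up.  For any
    smoothed automaton the values sum to 1.
    """
    if a.l > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"enumeration refused for l={a.l} > {MAX_ENUMERATION_LENGTH}"
        )
    seqs = ["".join(p) for p in itertools.product(ALPHABET, repeat=a.l)]
    probs = apfa_prob_many(a, encode_sequences(seqs))
    return dict(zip(seqs, probs.tolist()))


def save_apfa(a: APFA, path) -> None:
    """Line-oriented text format: header, then one line per edge."""
    with open(path, "w") as fh:
        if a.hp is None:
            fh.write(f"#apfa l={a.l} hp=none\n")
        else:
            fh.write(
                f"#apfa l={a.l} hp=mu:{a.hp.mu!r},m0:{a.hp.m0!r},gamma:{a.hp.gamma!r}\n"
            )
        fh.write("#source_id\tlevel\tsymbol\tdest_id\tprobability\n")
        for k in range(a.l):
            for s_id in range(len(a.probs[k])):
                for sym in range(4):
                    dest = a.trans[k][s_id, sym]
                    p = a.probs[k][s_id, sym]
                    if dest < 0 and p == 0.0:
                        continue
                    fh.write(f"{s_id}\t{k}\t{ALPHABET[sym]}\t{dest}\t{float(p)!r}\n")
        for s_id in range(len(a.arrivals[a.l])):
            fh.write(f"{s_id}\t{a.l}\tEOS\t0\t1.0\n")


def load_apfa(path) -> APFA:
    sym_code = {c: i for i, c in enumerate(ALPHABET)}
    with open(path) as fh:
        header = fh.readline().split()
        l = int(header[1].split("=", 1)[1])
        hp_field = header[2].split("=", 1)[1]
        hp = None
        if hp_field != "none":
            vals = dict(tok.split(":") for tok in hp_field.split(","))
            hp = LearnApfaHyperparams(
                float(vals["mu"]), float(vals["m0"]), float(vals["gamma"])
            )
        fh.readline()
        edges = [line.split("\t") for line in fh if line.strip()]
    sizes = [0] * (l + 1)
    for src, level, sym, dest, p in edges:
        k = int(level)
        sizes[k] = max(sizes[k], int(src) + 1)
        if sym != "EOS":
            sizes[k + 1] = max(sizes[k + 1], int(dest) + 1)
    probs = [np.zeros((sizes[k], 4)) for k in range(l)]
    trans = [np.full((sizes[k], 4), -1, dtype=np.intp) for k in range(l)]
    for src, level, sym, dest, p in edges:
        k = int(level)
        if sym == "EOS":
            continue
        probs[k][int(src), sym_code[sym]] = float(p)
        trans[k][int(src), sym_code[sym]] = int(dest)
    arrivals = [np.zeros(sizes[k], dtype=np.int64) for k in range(l + 1)]
    prefixes = [[""] * sizes[k] for k in range(l + 1)]
    return APFA(
        l=l,
        counts=[np.zeros_like(p) for p in probs],
        probs=probs,
        trans=trans,
        arrivals=arrivals,
        prefixes=prefixes,
        hp=hp,
    )
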