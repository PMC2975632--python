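"""Two-state splice HMM over match/mismatch emissions with quality bins.

The model describes the alignment of a whole read laid on the genome at the
placement of one of its halves.  State 1 is "still aligned": a base matches
the genome with a probability that rises with its Phred quality.  State 2 is
"past the splice": matches are coincidental, at roughly the genomic base
composition, independent of quality.  A string either transitions from
State 1 to State 2 exactly once (a junction-spanning read) or never (the read
aligns end to end); State 2 never returns to State 1.

Because at most one transition can occur, the hidden path is fully described
by the split index k = the last position emitted in State 1.  The model is a
mixture over split points: with probability ``p12`` the string contains a
transition, at a position taken to be a priori uniform; with probability
``1 - p12`` it stays in State 1 throughout (k = L).  Training (Baum-Welch /
EM over this exact posterior) then drives ``p12`` to the fraction of strings
that span a junction, and decoding picks the posterior-maximal split point.
Quality scores are binned into five levels so each emission parameter sees
enough training data even when the quality distribution is lumpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

N_BINS = 5
#: default Phred cut points: bins [0-9], [10-19], [20-26], [27-33], [34+]
DEFAULT_BIN_EDGES: tuple[int, ...] = (10, 20, 27, 34)

_PROB_FLOOR = 1e-4
_TIE_TOL = 1e-12  # log-units within which split probabilities count as equal


def bin_quality(q, edges: Sequence[int] = DEFAULT_BIN_EDGES):
    """Map Phred scores to bin indices 0 (low) .. 4 (high).

    Monotone non-decreasing in q; exactly five bins with the default edges.
    Accepts scalars or arrays.
    """
    edges = np.asarray(edges)
    if edges.size != N_BINS - 1:
        raise ValueError(f"need {N_BINS - 1} bin edges, got {edges.size}")
    b = np.searchsorted(edges, q, side="right")
    return int(b) if np.isscalar(q) else b.astype(np.int8)


@dataclass
class MatchString:
    """Per-position match flags and quality bins for one whole-read placement."""

    matches: np.ndarray  # bool, length = read length
    bins: np.ndarray     # int in 0..4, same length

    def __post_init__(self) -> None:
        self.matches = np.asarray(self.matches, dtype=bool)
        self.bins = np.asarray(self.bins, dtype=np.int8)
        if self.matches.shape != self.bins.shape:
            raise ValueError("matches and bins length mismatch")
        if self.bins.size and (self.bins.min() < 0 or self.bins.max() >= N_BINS):
            raise ValueError("quality bin out of range")

    def __len__(self) -> int:
        return self.matches.size


@dataclass
class SplitCall:
    """Decoded splice position: k is the last read position in State 1 (1-based)."""

    split: int
    log_prob: float
    tied: bool = False


@dataclass
class SpliceHMM:
    """Trained two-state model: transition p12 and per-bin match probabilities."""

    p12: float
    m1: np.ndarray  # P(match | State 1, bin b), b = 0 (low) .. 4 (high)
    m2: np.ndarray  # P(match | State 2, bin b)
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if self.m1.size != N_BINS or self.m2.size != N_BINS:
            raise ValueError("emission vectors must have 5 entries")
        for p in (self.p12, *self.m1, *self.m2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    #: State 2 never returns to State 1 (structural, never re-estimated)
    @property
    def p21(self) -> float:
        return 0.0

    @classmethod
    def initial_uniform(cls, bin_edges=DEFAULT_BIN_EDGES) -> "SpliceHMM":
        """Completely uninformative start: everything at 0.5."""
        return cls(0.5, np.full(N_BINS, 0.5), np.full(N_BINS, 0.5), tuple(bin_edges))

    @classmethod
    def initial_informed(cls, bin_edges=DEFAULT_BIN_EDGES) -> "SpliceHMM":
        """Start near typical trained values (the default initialisation)."""
        return cls(
            0.5,
            np.array([0.4, 0.5, 0.7, 0.7, 0.7]),
            np.full(N_BINS, 0.3),
            tuple(bin_edges),
        )

    def params(self) -> np.ndarray:
        return np.concatenate([[self.p12], self.m1, self.m2])

    # -- persistence (small key=value text file) ----------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"p12={float(self.p12)!r}\n")
            for i in range(N_BINS):
                fh.write(f"m1_{i}={float(self.m1[i])!r}\n")
            for i in range(N_BINS):
                fh.write(f"m2_{i}={float(self.m2[i])!r}\n")
            fh.write("bin_edges=" + ",".join(str(e) for e in self.bin_edges) + "\n")

    @classmethod
    def load(cls, path) -> "SpliceHMM":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if "=" in line:
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        return cls(
            float(kv["p12"]),
            np.array([float(kv[f"m1_{i}"]) for i in range(N_BINS)]),
            np.array([float(kv[f"m2_{i}"]) for i in range(N_BINS)]),
            tuple(int(x) for x in kv["bin_edges"].split(",")),
        )


@dataclass
class TrainingInfo:
    """Bookkeeping from a Baum-Welch run."""

    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    undertrained_bins: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# core probability machinery
# ---------------------------------------------------------------------------

def _log_emissions(hmm: SpliceHMM, M: np.ndarray, B: np.ndarray):
    eps = 1e-12
    m1 = np.clip(hmm.m1, eps, 1 - eps)
    m2 = np.clip(hmm.m2, eps, 1 - eps)
    e1 = np.where(M, np.log(m1)[B], np.log1p(-m1)[B])
    e2 = np.where(M, np.log(m2)[B], np.log1p(-m2)[B])
    return e1, e2


def split_log_probs(hmm: SpliceHMM, M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Log joint probability of (string, split at k) for every k = 1..L.

    ``M``/``B`` are (n, L) stacked match flags and bins.  Column k-1 holds the
    split-at-k path: positions 1..k in State 1, then (for k < L) a single
    transition and positions k+1..L in State 2, weighted by p12 and the
    uniform prior 1/(L-1) over transition positions.  k = L is the
    no-transition path, weighted by 1 - p12.  The prior factor never changes
    which split point wins, but it does arbitrate split-vs-no-split, which is
    what lets EM recover the splice fraction.
    """
    M = np.atleast_2d(M)
    B = np.atleast_2d(B)
    e1, e2 = _log_emissions(hmm, M, B)
    eps = 1e-9
    p12 = min(max(hmm.p12, eps), 1 - eps)
    lp = np.cumsum(e1, axis=1)
    L = M.shape[1]
    if L > 1:
        tail2 = np.cumsum(e2[:, ::-1], axis=1)[:, ::-1]  # sum over t..L-1
        lp[:, : L - 1] += tail2[:, 1:] + np.log(p12) - np.log(L - 1)
    lp[:, L - 1] += np.log1p(-p12)
    return lp


def decode_split_batch(hmm: SpliceHMM, M: np.ndarray, B: np.ndarray):
    """Vectorised decoding of many equal-length strings.

    Returns (splits, log_probs, tied): among split points whose log
    probability is within ``1e-12`` of the maximum, the largest k (shortest
    second piece) wins.
    """
    lp = split_log_probs(hmm, M, B)
    best = lp.max(axis=1, keepdims=True)
    ok = lp >= best - _TIE_TOL
    L = lp.shape[1]
    splits = L - np.argmax(ok[:, ::-1], axis=1)
    tied = ok.sum(axis=1) > 1
    return splits, best[:, 0], tied


def decode_split(hmm: SpliceHMM, ms: MatchString) -> SplitCall:
    """Most probable splice position within one match string."""
    splits, lps, tied = decode_split_batch(hmm, ms.matches[None, :], ms.bins[None, :])
    return SplitCall(int(splits[0]), float(lps[0]), bool(tied[0]))


def _stack_by_length(strings: Iterable[MatchString]):
    groups: dict[int, list[MatchString]] = {}
    for ms in strings:
        groups.setdefault(len(ms), []).append(ms)
    out = []
    for L, mss in sorted(groups.items()):
        M = np.stack([ms.matches for ms in mss])
        B = np.stack([ms.bins for ms in mss])
        out.append((M, B))
    return out


def train_baum_welch(
    match_strings: Sequence[MatchString],
    init: SpliceHMM | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> tuple[SpliceHMM, TrainingInfo]:
    """Fit the splice HMM by expectation-maximisation.

    The E-step computes the exact posterior over the split point of each
    string (the path space is the L split points because State 2 is
    absorbing); the M-step re-estimates ``p12`` and the per-bin match
    probabilities from posterior state occupancies.  The start state and the
    State 2 -> State 1 transition stay clamped.  A quality bin absent from
    the training data keeps its initial value and is flagged.
    """
    strings = list(match_strings)
    if not strings:
        raise ValueError("empty training set")
    if init is None:
        init = SpliceHMM.initial_informed()
    groups = _stack_by_length(strings)
    cur = SpliceHMM(init.p12, init.m1.copy(), init.m2.copy(), init.bin_edges)
    info = TrainingInfo()
    for it in range(max_iter):
        n1m = np.zeros(N_BINS)
        n1 = np.zeros(N_BINS)
        n2m = np.zeros(N_BINS)
        n2 = np.zeros(N_BINS)
        ntrans = 0.0
        nstr = 0
        ll = 0.0
        for M, B in groups:
            lp = split_log_probs(cur, M, B)
            mx = lp.max(axis=1, keepdims=True)
            w = np.exp(lp - mx)
            Z = w.sum(axis=1, keepdims=True)
            w /= Z
            ll += float(np.log(Z).sum() + mx.sum())
            # P(position t+1 in State 1) = P(split >= t+1)
            occ1 = w[:, ::-1].cumsum(axis=1)[:, ::-1]
            occ2 = 1.0 - occ1
            for b in range(N_BINS):
                mask = B == b
                mm = mask & M
                n1m[b] += float((occ1 * mm).sum())
                n1[b] += float((occ1 * mask).sum())
                n2m[b] += float((occ2 * mm).sum())
                n2[b] += float((occ2 * mask).sum())
            ntrans += float((1.0 - w[:, -1]).sum())
            nstr += M.shape[0]
        info.log_likelihood.append(ll)
        p12 = ntrans / nstr
        m1 = cur.m1.copy()
        m2 = cur.m2.copy()
        for b in range(N_BINS):
            if n1[b] > 1e-9:
                m1[b] = n1m[b] / n1[b]
            elif (1, b) not in info.undertrained_bins:
                info.undertrained_bins.append((1, b))
            if n2[b] > 1e-9:
                m2[b] = n2m[b] / n2[b]
            elif (2, b) not in info.undertrained_bins:
                info.undertrained_bins.append((2, b))
        p12 = float(np.clip(p12, _PROB_FLOOR, 1 - _PROB_FLOOR))
        m1 = np.clip(m1, _PROB_FLOOR, 1 - _PROB_FLOOR)
        m2 = np.clip(m2, _PROB_FLOOR, 1 - _PROB_FLOOR)
        delta = float(
            np.max(np.abs(np.concatenate([[p12 - cur.p12], m1 - cur.m1, m2 - cur.m2])))
        )
        cur = SpliceHMM(p12, m1, m2, cur.bin_edges)
        info.n_iter = it + 1
        if delta < tol:
            info.converged = True
            break
    return cur, info


def sample_training_set(population: Sequence, n: int, seed) -> list:
    """Uniform sample without replacement (everything if the population is small)."""
    items = list(population)
    if not items:
        raise ValueError("empty population")
    if len(items) <= n:
        return items
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(items), size=n, replace=False)
    return [items[i] for i in sorted(idx)]
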