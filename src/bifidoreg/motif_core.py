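"""Position weight matrices with palindromic symmetry, and motif discovery.

A TF-binding site model is a symmetrized L x 4 count matrix (columns ordered
A, C, G, T) with derived positional weights

    w(b, j) = ln(N(b, j) + 0.5) - (1/4) * sum_b' ln(N(b', j) + 0.5)

so every weight column sums to zero and the score of a sequence equals the
score of its reverse complement whenever the count matrix equals its own
reverse-complement mirror.  Most bacterial LacI/TetR/ROK-family operators are
(near-)palindromes bound by homodimers, which is what the symmetrization
encodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
#: index of the complementary base for A,C,G,T
_COMP_IDX = np.array([3, 2, 1, 0])

PSEUDOCOUNT = 0.5
#: weak threshold as a fraction of the strong one, mirroring a 4.75/5 ratio
DEFAULT_WEAK_RATIO = 0.95
#: laxer preset for a global-regulon scan (4.75/5 strong, 4.5/4.75 weak)
GLOBAL_REGULON_PRESET = {"strong_fraction": 0.95, "weak_ratio": 4.5 / 4.75}

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0,C=1,G=2,T=3, else -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_IDX[codes[::-1]]


class InsufficientDataError(ValueError):
    """Raised when too few regions/sites are supplied for motif work."""


@dataclass(frozen=True)
class Site:
    """One training site: a fixed-length sequence at a known location."""

    genome_id: str
    gene_id: str
    sequence: str
    strand: str = "+"
    offset: int = 0


@dataclass
class SiteAlignment:
    """A gapless alignment of equal-length sites over {A,C,G,T}; L is even."""

    sites: list[Site]
    length: int

    def __post_init__(self) -> None:
        if self.length % 2 != 0:
            raise ValueError("motif length must be even")
        for s in self.sites:
            if len(s.sequence) != self.length:
                raise ValueError(f"site {s.gene_id}: length "
                                 f"{len(s.sequence)} != {self.length}")
            if (encode(s.sequence) < 0).any():
                raise ValueError(f"site {s.gene_id}: non-ACGT base")

    def count_matrix(self) -> np.ndarray:
        """Raw (unsymmetrized) L x 4 count matrix."""
        counts = np.zeros((self.length, 4))
        for s in self.sites:
            codes = encode(s.sequence)
            counts[np.arange(self.length), codes] += 1.0
        return counts


# ---------------------------------------------------------------------------
# matrix algebra


def symmetrize_counts(counts: np.ndarray) -> np.ndarray:
    """Average a count matrix with its reverse-complement mirror.

    N'(b, j) = (N(b, j) + N(complement(b), L-1-j)) / 2.  The result equals
    its own mirror (exact palindromic symmetry) and column sums are
    preserved.  Idempotent.  L must be even.
    """
    counts = np.asarray(counts, dtype=float)
    L = counts.shape[0]
    if L % 2 != 0:
        raise ValueError("palindromic symmetrization requires even L")
    if counts.shape[1] != 4 or (counts < 0).any():
        raise ValueError("counts must be a non-negative L x 4 matrix")
    mirrored = counts[::-1][:, _COMP_IDX]
    return (counts + mirrored) / 2.0


def is_palindromic(counts: np.ndarray, tol: float = 1e-9) -> bool:
    mirrored = np.asarray(counts)[::-1][:, _COMP_IDX]
    return bool(np.allclose(counts, mirrored, atol=tol))


def build_weights(counts: np.ndarray,
                  pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """Zero-sum log-count weights: w = ln(N + pc) - column mean of the same."""
    logs = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)


def information_content(counts: np.ndarray,
                        pseudocount: float = PSEUDOCOUNT) -> float:
    """Total information content in bits vs. a uniform background.

    IC = sum_j sum_b f(b,j) * log2(f(b,j) / 0.25), with f from
    pseudocounted frequencies; bounded by 2 bits per column.
    """
    counts = np.asarray(counts, dtype=float)
    f = counts + pseudocount
    f /= f.sum(axis=1, keepdims=True)
    return float((f * np.log2(f / 0.25)).sum())


# ---------------------------------------------------------------------------
# the motif model


@dataclass
class MotifModel:
    """A named palindromic binding-site model with calibrated thresholds."""

    name: str
    counts: np.ndarray            # symmetrized L x 4
    weights: np.ndarray = field(init=False)
    training_sites: SiteAlignment | None = None
    strong_threshold: float = float("nan")
    weak_threshold: float = float("nan")
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = symmetrize_counts(self.counts)
        self.weights = build_weights(self.counts, self.pseudocount)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def ic_bits(self) -> float:
        return information_content(self.counts, self.pseudocount)

    @property
    def max_score(self) -> float:
        """Score of the (a) consensus sequence."""
        return float(self.weights.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return decode(self.weights.argmax(axis=1))

    def score_codes(self, codes: np.ndarray) -> float:
        if (codes < 0).any():
            return float("nan")
        return float(self.weights[np.arange(self.length), codes].sum())

    def score(self, seq: str) -> float:
        """PWM score of one L-length sequence; NaN on ambiguous bases."""
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != motif "
                             f"length {self.length}")
        return self.score_codes(encode(seq))

    def score_windows(self, codes: np.ndarray) -> np.ndarray:
        """Scores of all L-windows of an encoded sequence (one strand;
        the palindromic model makes the reverse strand identical).
        Windows containing a non-ACGT base score -inf."""
        L = self.length
        n = codes.size - L + 1
        if n <= 0:
            return np.zeros(0)
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        bad = (win < 0).any(axis=1)
        safe = np.where(win < 0, 0, win)
        scores = self.weights[np.arange(L), safe].sum(axis=1)
        scores[bad] = -np.inf
        return scores


def from_sites(name: str, alignment: SiteAlignment,
               pseudocount: float = PSEUDOCOUNT) -> MotifModel:
    """Build a symmetrized model from a training-site alignment."""
    model = MotifModel(name, alignment.count_matrix(),
                       pseudocount=pseudocount)
    model.training_sites = alignment
    return model


def calibrate_thresholds(model: MotifModel,
                         strong_fraction: float = 1.0,
                         weak_ratio: float = DEFAULT_WEAK_RATIO
                         ) -> tuple[float, float]:
    """Set strong/weak score thresholds from the training sites.

    strong = ``strong_fraction`` x (minimum training-site score);
    weak = ``weak_ratio`` x strong.  ``GLOBAL_REGULON_PRESET`` reproduces a
    laxer setting for a large, diffuse regulon scan.  With a single training
    site both thresholds collapse to that site's score (a warning is logged).
    """
    if model.training_sites is None or not model.training_sites.sites:
        raise InsufficientDataError("model has no training sites")
    scores = [model.score(s.sequence) for s in model.training_sites.sites]
    if len(scores) == 1:
        logger.warning("motif %s: single training site; thresholds "
                       "degenerate to its score", model.name)
        strong = weak = scores[0]
    else:
        strong = strong_fraction * min(scores)
        weak = weak_ratio * strong
    model.strong_threshold = strong
    model.weak_threshold = weak
    return strong, weak


# ---------------------------------------------------------------------------
# de novo discovery


def _region_seqs(regions) -> list[str]:
    return [r if isinstance(r, str) else r.seq for r in regions]


def _palindromicity(codes: np.ndarray, L: int) -> np.ndarray:
    """Per-window count of self-complementary base pairs (max L/2).

    A window w is a perfect palindrome when w[j] complements w[L-1-j] for
    every j; this scores the first L/2 of those pairings for every window.
    Windows containing a non-ACGT base score -1.
    """
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    if win.shape[0] == 0:
        return np.zeros(0, dtype=int)
    half = L // 2
    left = win[:, :half]
    right = win[:, L - 1:half - 1:-1]
    ok = (left >= 0) & (right >= 0)
    matches = ((left == _COMP_IDX_ARR[np.where(right < 0, 0, right)]) & ok)
    score = matches.sum(axis=1)
    score[(win < 0).any(axis=1)] = -1
    return score


_COMP_IDX_ARR = _COMP_IDX  # alias used in vectorized code above


def _seed_pool(coded: list[np.ndarray], L: int) -> list[tuple[int, int]]:
    """Candidate seed windows: near-perfect palindromes anywhere in the
    regions.  Palindromic operators are self-complementary, so these are the
    highest-prior starting points for the greedy search."""
    pool: list[tuple[int, int]] = []
    half = L // 2
    for ri, c in enumerate(coded):
        pal = _palindromicity(c, L)
        for p in np.nonzero(pal >= half - 1)[0]:
            pool.append((ri, int(p)))
    return pool


def discover_palindromic_motif(regions, length: int,
                               n_restarts: int = 20,
                               seed: int | None = None,
                               max_iter: int = 50,
                               name: str = "motif") -> MotifModel:
    """Greedy seeded search for the best shared palindromic motif.

    Restarts are seeded preferentially from near-perfect palindromic
    L-windows (the object of the search), falling back to random L-mers;
    each seed matrix is the one-hot L-mer plus its reverse complement.  A
    restart then iterates: score every L-window of every region (one strand
    suffices for a palindromic model), take each region's best window,
    rebuild the symmetrized count matrix, recompute weights — until the
    chosen site set is stable or ``max_iter`` iterations.  The restart
    maximizing IC x (fraction of regions whose best site scores >= 75% of
    the consensus score) wins.  Zero-or-one site per region; deterministic
    given ``seed``.
    """
    seqs = _region_seqs(regions)
    if len(seqs) < 4:
        raise InsufficientDataError(
            f"need >= 4 regions for motif discovery, got {len(seqs)}")
    if length % 2 != 0:
        raise ValueError("motif length must be even")
    rng = np.random.default_rng(seed)
    coded = [encode(s) for s in seqs]
    usable = [c for c in coded if c.size >= length]
    if len(usable) < 4:
        raise InsufficientDataError("fewer than 4 regions reach motif length")

    pool = _seed_pool(usable, length)
    rng.shuffle(pool)
    # seed from the palindromic pool first, then random L-mers
    seeds: list[tuple[int, int]] = pool[:n_restarts]
    while len(seeds) < n_restarts:
        ri = int(rng.integers(len(usable)))
        p = int(rng.integers(usable[ri].size - length + 1))
        if (usable[ri][p:p + length] >= 0).all():
            seeds.append((ri, p))

    best: tuple[float, np.ndarray, list[int], list[bool]] | None = None
    for ri, p in seeds[:n_restarts]:
        counts, positions, included = _one_restart(
            usable, length, usable[ri][p:p + length], max_iter)
        model = MotifModel(name, counts)
        thr = OBJECTIVE_SCORE_FRACTION * model.max_score
        frac = np.mean([model.score_codes(c[q:q + length]) >= thr
                        for c, q in zip(usable, positions)])
        objective = model.ic_bits * float(frac)
        if best is None or objective > best[0]:
            best = (objective, counts, positions, included)

    assert best is not None
    _, counts, positions, included = best
    model = MotifModel(name, counts)
    sites = [Site("", f"region_{i}",
                  decode(np.where(c[q:q + length] < 0, 0, c[q:q + length])),
                  "+", int(q))
             for i, (c, q, inc) in enumerate(zip(usable, positions, included))
             if inc]
    model.training_sites = SiteAlignment(sites, length)
    calibrate_thresholds(model)
    return model


def discover_best_length(regions, lengths=(14, 16, 18, 20, 22),
                         n_restarts: int = 20, seed: int | None = None,
                         name: str = "motif") -> MotifModel:
    """Run discovery at several motif lengths; best IC-per-column wins.

    Near-ties (within 1e-6 bits/column, e.g. a fully conserved motif and
    its fully conserved sub-window) break toward the longer motif, which
    carries more total information."""
    rng = np.random.default_rng(seed)
    best: MotifModel | None = None
    for L in lengths:
        model = discover_palindromic_motif(
            regions, L, n_restarts=n_restarts,
            seed=int(rng.integers(2**31)), name=name)
        if best is None:
            best = model
            continue
        per_col, best_per_col = (model.ic_bits / model.length,
                                 best.ic_bits / best.length)
        if per_col > best_per_col + 1e-6 or \
                (abs(per_col - best_per_col) <= 1e-6
                 and model.length > best.length):
            best = model
    assert best is not None
    return best


#: a region contributes its best window to the next count matrix only when
#: that window reaches this fraction of the consensus score (the "zero" of
#: zero-or-one sites per region); keeps mixed target/non-target region sets
#: from diluting the motif with background windows
INCLUDE_SCORE_FRACTION = 0.6
OBJECTIVE_SCORE_FRACTION = 0.75
_MIN_INCLUDED = 4


def _one_restart(coded: list[np.ndarray], L: int, seed_kmer: np.ndarray,
                 max_iter: int
                 ) -> tuple[np.ndarray, list[int], list[bool]]:
    counts = np.zeros((L, 4))
    counts[np.arange(L), seed_kmer] += 1.0
    # adding the mirrored copy == symmetrizing the doubled one-hot counts
    counts = symmetrize_counts(counts * 2.0)

    state: tuple[list[int], list[bool]] | None = None
    model = MotifModel("_iter", counts)
    for _ in range(max_iter):
        best_scores = []
        positions = []
        for c in coded:
            scores = model.score_windows(c)
            positions.append(int(scores.argmax()))
            best_scores.append(float(scores.max()))
        cut = INCLUDE_SCORE_FRACTION * model.max_score
        included = [s >= cut for s in best_scores]
        if sum(included) < _MIN_INCLUDED:
            order = np.argsort(best_scores)[::-1][:_MIN_INCLUDED]
            included = [i in set(order.tolist())
                        for i in range(len(coded))]
        new_state = (positions, included)
        if new_state == state:
            break
        state = new_state
        counts = np.zeros((L, 4))
        for c, p, inc in zip(coded, positions, included):
            if not inc:
                continue
            kmer = c[p:p + L]
            clean = kmer >= 0
            counts[np.arange(L)[clean], kmer[clean]] += 1.0
        model = MotifModel("_iter", counts)
    assert state is not None
    return model.counts, state[0], state[1]


def empirical_ic_null(regions, length: int, n_shuffles: int = 20,
                      seed: int | None = None,
                      n_restarts: int = 5) -> np.ndarray:
    """IC values of motifs discovered in per-region shuffled sequences.

    Shuffling preserves each region's base composition while destroying any
    shared signal; the returned distribution is the empirical null for
    judging whether a discovered motif is significant.
    """
    seqs = _region_seqs(regions)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        shuffled = ["".join(rng.permutation(list(s))) for s in seqs]
        model = discover_palindromic_motif(
            shuffled, length, n_restarts=n_restarts,
            seed=int(rng.integers(2**31)))
        out.append(model.ic_bits)
    return np.array(out)


def is_significant(model: MotifModel, regions, n_shuffles: int = 20,
                   seed: int | None = None, quantile: float = 0.95) -> bool:
    """True when the model's IC exceeds the chosen quantile of the
    shuffled-region null; otherwise the motif is reported as not
    significant."""
    null = empirical_ic_null(regions, model.length, n_shuffles, seed)
    return model.ic_bits > float(np.quantile(null, quantile))


# ---------------------------------------------------------------------------
# serialization


def write_transfac(model: MotifModel, path) -> None:
    """Plain-text TRANSFAC-like count matrix."""
    with open(path, "w") as fh:
        fh.write(f"ID {model.name}\nBF synthetic\nP0 A C G T\n")
        for j in range(model.length):
            row = " ".join(f"{model.counts[j, b]:.2f}" for b in range(4))
            fh.write(f"{j + 1:02d} {row} {model.consensus[j]}\n")
        fh.write("XX\n//\n")


def write_sites_fasta(model: MotifModel, path) -> None:
    if model.training_sites is None:
        raise ValueError("model has no training sites")
    with open(path, "w") as fh:
        for s in model.training_sites.sites:
            fh.write(f">{s.genome_id}|{s.gene_id}|{s.offset}\n{s.sequence}\n")
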