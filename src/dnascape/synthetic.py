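"""Synthetic genomes with known ground truth.

Stands in for real chromosome downloads: multi-chromosome genomes with
controllable base composition, embedded tandem-repeat arrays, transposon-like
insertions of fixed consensus composition, and anchor annotations whose
flanks carry programmable dinucleotide enrichment.  Every random element is
recorded in a machine-readable truth record, so downstream stages (maps,
profiles, peaks, influences) can be validated against exact expectations.

Determinism: each operation derives its own RNG stream from the given seed
via the operation name (see :mod:`dnascape._rng`), so identical seeds yield
byte-identical genomes, intervals, and truth records, and stages can be
regenerated independently.

Insertions overwrite the existing sequence rather than splicing, so
chromosome lengths and all previously recorded coordinates stay stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import derive_rng
from ._seq import BASES, DINUCLEOTIDES, decode, encode
from .genome import Genome
from .maps import Interval

__all__ = [
    "GenomeSpec", "RepeatInsertionSpec", "AnchorFlankSpec", "RepeatInsertion",
    "generate_genome", "insert_repeats", "place_anchors",
    "ALU_LIKE_CONSENSUS", "L1_LIKE_CONSENSUS",
]

#: G+C- and AG-rich consensus emulating a SINE/Alu-family element (synthetic,
#: modelled on the composition of the Alu left-arm consensus).
ALU_LIKE_CONSENSUS = (
    "GGCCGGGAGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCAGGAGGA"
    "TCGCTTGAGCCCAGGAGTTCGAGACCAGCCTGGGCAGCATAGCGAGACCCAGTCTCTACA"
)

#: A+T-rich consensus emulating a LINE-1-family element (synthetic).
L1_LIKE_CONSENSUS = (
    "AATAACTTTAAATCAAAAGAATAGTATTTGGTTTACATGAAAACTTTAAAGCATTAAAAT"
    "ATTTATAAGAAATGTTTTCATTAAATTTCAAAACAATTTTAAGTAAACATAAAGAAATCA"
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Background genome: chromosome lengths plus base composition.

    Composition is either i.i.d. base frequencies (4-vector) or a 4x4
    row-stochastic first-order transition matrix.
    """

    lengths: dict[str, int]
    base_frequencies: Sequence[float] | None = (0.25, 0.25, 0.25, 0.25)
    transition: np.ndarray | None = None
    seed: int = 0
    resolution: int = 1000

    def __post_init__(self) -> None:
        for name, L in self.lengths.items():
            if L < 10 * self.resolution:
                raise ValueError(
                    f"chromosome {name!r} length {L} < 10 x resolution "
                    f"({self.resolution})")
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or np.any(t < 0) or \
                    np.any(np.abs(t.sum(axis=1) - 1) > 1e-9):
                raise ValueError("transition must be 4x4 row-stochastic")
            self.transition = t
        else:
            f = np.asarray(self.base_frequencies, dtype=float)
            if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
                raise ValueError("base frequencies must be 4 nonnegative "
                                 "values summing to 1")
            self.base_frequencies = f

    def stationary_base_frequencies(self) -> np.ndarray:
        if self.transition is None:
            return np.asarray(self.base_frequencies, dtype=float)
        # left eigenvector of the transition matrix for eigenvalue 1
        vals, vecs = np.linalg.eig(self.transition.T)
        k = int(np.argmin(np.abs(vals - 1)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class RepeatInsertionSpec:
    """A batch of repeat insertions of one class.

    Exactly one of ``unit`` (tandem repeat, 1-6 bp) or ``consensus``
    (transposon-like element) must be given.  ``length`` is a fixed bp length
    or a (lo, hi) uniform range; tandem-repeat insertions must total at least
    4 bp (two units).  Placement is uniform, or biased toward anchor flanks
    by ``enrichment_factor`` within ``flank_width`` bp of anchor centers.
    """

    label: str
    unit: str | None = None
    consensus: str | None = None
    copies: int = 0
    length: int | tuple[int, int] | None = None
    placement: str = "uniform"
    enrichment_factor: float = 1.0
    flank_width: int | None = None
    allow_anchor_overlap: bool = False

    def __post_init__(self) -> None:
        if (self.unit is None) == (self.consensus is None):
            raise ValueError("give exactly one of unit or consensus")
        if self.unit is not None:
            if not 1 <= len(self.unit) <= 6:
                raise ValueError("tandem-repeat unit length must be 1..6 bp")
            self.unit = self.unit.upper()
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
        if self.placement not in ("uniform", "anchor_biased"):
            raise ValueError("placement must be 'uniform' or 'anchor_biased'")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")

    @property
    def kind(self) -> str:
        return "tandem_repeat" if self.unit is not None else "transposon"

    def draw_length(self, rng: np.random.Generator) -> int:
        if self.length is None:
            if self.consensus is not None:
                return len(self.consensus)
            raise ValueError("tandem-repeat insertions need a length")
        if isinstance(self.length, tuple):
            lo, hi = self.length
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(self.length)
        if self.unit is not None:
            n = max(n - n % len(self.unit), 2 * len(self.unit))
            if n < 4:
                raise ValueError("inserted tandem repeat must total >= 4 bp")
        return n

    def build(self, length: int) -> np.ndarray:
        if self.unit is not None:
            reps = -(-length // len(self.unit))
            return encode((self.unit * reps)[:length])
        cons = encode(self.consensus)
        reps = -(-length // cons.size)
        return np.tile(cons, reps)[:length]


@dataclass
class AnchorFlankSpec:
    """Anchors with programmable flank dinucleotide enrichment.

    ``enrichment`` maps dinucleotides to multiplicative factors over the
    background joint distribution at the anchor center; alternatively
    ``nucleotide_enrichment`` maps single bases to factors, producing the
    rank-1 dinucleotide enrichment g_XY = g_X * g_Y (a pure composition
    gradient).  The factor decays over the support ``W`` following ``shape``
    ("triangular" by default, or "flat").
    """

    n_anchors: int
    anchor_length: int
    support: int
    enrichment: dict[str, float] = field(default_factory=dict)
    nucleotide_enrichment: dict[str, float] = field(default_factory=dict)
    shape: str = "triangular"

    def __post_init__(self) -> None:
        if self.n_anchors < 1:
            raise ValueError("need at least one anchor")
        if self.support < 1:
            raise ValueError("support must be positive")
        if self.shape not in ("triangular", "flat"):
            raise ValueError("shape must be 'triangular' or 'flat'")
        for v in (*self.enrichment.values(), *self.nucleotide_enrichment.values()):
            if v <= 0:
                raise ValueError("enrichment factors must be > 0")
        if self.enrichment and self.nucleotide_enrichment:
            raise ValueError("give dinucleotide or nucleotide enrichment, not both")

    def center_factors(self) -> np.ndarray:
        """4x4 matrix of dinucleotide enrichment factors at distance 0."""
        f = np.ones((4, 4))
        if self.nucleotide_enrichment:
            g = np.array([self.nucleotide_enrichment.get(b, 1.0) for b in BASES])
            f = np.outer(g, g)
        for xy, v in self.enrichment.items():
            i = DINUCLEOTIDES.index(xy.upper())
            f[i // 4, i % 4] = v
        return f

    def factor_at(self, offset: int) -> np.ndarray:
        """Dinucleotide enrichment at a signed bp offset from the center."""
        if self.shape == "flat":
            s = 1.0 if abs(offset) < self.support else 0.0
        else:
            s = max(0.0, 1.0 - abs(offset) / self.support)
        return 1.0 + (self.center_factors() - 1.0) * s


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _sample_iid(rng: np.random.Generator, length: int, freqs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=freqs).astype(np.uint8)


def _sample_markov(rng: np.random.Generator, length: int, transition: np.ndarray,
                   start: np.ndarray) -> np.ndarray:
    out = np.empty(length, dtype=np.uint8)
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    out[0] = rng.choice(4, p=start)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    return out


def generate_genome(spec: GenomeSpec) -> tuple[Genome, dict]:
    """Generate a background genome from a spec; deterministic given the seed."""
    rng = derive_rng(spec.seed, "generate_genome")
    chroms: dict[str, np.ndarray] = {}
    for name in spec.lengths:
        L = spec.lengths[name]
        if spec.transition is not None:
            chroms[name] = _sample_markov(rng, L, spec.transition,
                                          spec.stationary_base_frequencies())
        else:
            chroms[name] = _sample_iid(rng, L, np.asarray(spec.base_frequencies))
    truth = {
        "seed": spec.seed,
        "chromosomes": {n: {"length": int(L)} for n, L in spec.lengths.items()},
        "base_frequencies": spec.stationary_base_frequencies().tolist(),
        "order": 1 if spec.transition is not None else 0,
    }
    return Genome(chroms), truth


# ---------------------------------------------------------------------------
# repeat insertion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatInsertion:
    chrom: str
    start: int
    end: int
    label: str
    kind: str

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


def _overlaps(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in intervals)


def insert_repeats(genome: Genome, spec: RepeatInsertionSpec, seed: int,
                   anchors: Sequence[Interval] | None = None,
                   avoid: Sequence[Interval] | None = None,
                   ) -> tuple[Genome, list[RepeatInsertion]]:
    """Overwrite the genome with repeat copies; returns the new genome and
    the recorded insertion intervals (coordinates unchanged by construction).

    Insertions never overlap each other, the given anchors, or ``avoid``
    intervals.  With ``placement='anchor_biased'`` candidate positions whose
    midpoint falls within ``flank_width`` of an anchor center are accepted
    preferentially by the spec's enrichment factor (rejection sampling).
    """
    rng = derive_rng(seed, "insert_repeats")
    out = genome.copy()
    insertions: list[RepeatInsertion] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in out.names}
    blocked = list(avoid or [])
    if not spec.allow_anchor_overlap:
        blocked += list(anchors or [])
    for iv in blocked:
        occupied.setdefault(iv.chrom, []).append((iv.start, iv.end))

    if spec.placement == "anchor_biased":
        if not anchors:
            raise ValueError("anchor-biased placement needs anchors")
        if spec.flank_width is None:
            raise ValueError("anchor-biased placement needs flank_width")
        centers = {n: np.array(sorted((iv.start + iv.end) // 2
                                      for iv in anchors if iv.chrom == n))
                   for n in out.names}

    names = out.names
    lengths = np.array([out.length(n) for n in names], dtype=float)
    p_chrom = lengths / lengths.sum()

    for _ in range(spec.copies):
        ins_len = spec.draw_length(rng)
        if all(ins_len > out.length(n) for n in names):
            raise ValueError(f"insertion of {ins_len} bp exceeds every chromosome")
        placed = False
        for _attempt in range(1000):
            chrom = names[int(rng.choice(len(names), p=p_chrom))]
            L = out.length(chrom)
            if ins_len > L:
                continue
            start = int(rng.integers(0, L - ins_len + 1))
            if _overlaps(start, start + ins_len, occupied.get(chrom, [])):
                continue
            if spec.placement == "anchor_biased":
                mid = start + ins_len // 2
                cs = centers[chrom]
                near = cs.size and np.min(np.abs(cs - mid)) <= spec.flank_width
                weight = spec.enrichment_factor if near else 1.0
                if rng.random() > weight / max(spec.enrichment_factor, 1.0):
                    continue
            placed = True
            break
        if not placed:
            raise ValueError("could not place repeat without overlap after 1000 tries")
        out.chromosomes[chrom][start:start + ins_len] = spec.build(ins_len)
        occupied.setdefault(chrom, []).append((start, start + ins_len))
        insertions.append(RepeatInsertion(chrom, start, start + ins_len,
                                          spec.label, spec.kind))
    insertions.sort(key=lambda r: (r.chrom, r.start))
    return out, insertions


# ---------------------------------------------------------------------------
# anchors with enriched flanks
# ---------------------------------------------------------------------------

def _flank_transitions(spec: AnchorFlankSpec, background: np.ndarray,
                       offsets: np.ndarray) -> np.ndarray:
    """Per-offset transition matrices realizing the enriched dinucleotide
    target; shape (n_offsets, 4, 4)."""
    pi_joint = np.outer(background, background)
    T = np.empty((offsets.size, 4, 4))
    center = spec.center_factors()
    for k, o in enumerate(offsets):
        if spec.shape == "flat":
            s = 1.0 if abs(int(o)) < spec.support else 0.0
        else:
            s = max(0.0, 1.0 - abs(int(o)) / spec.support)
        q = pi_joint * (1.0 + (center - 1.0) * s)
        rows = q.sum(axis=1, keepdims=True)
        T[k] = np.where(rows > 0, q / np.where(rows > 0, rows, 1), 0.25)
    return T


def place_anchors(genome: Genome, spec: AnchorFlankSpec, seed: int,
                  truth_resolution: int = 1000,
                  ) -> tuple[Genome, list[Interval], dict]:
    """Place anchors and resample their flanks with enriched dinucleotide
    content; returns the modified genome, anchor intervals, and the analytic
    truth (expected dinucleotide frequencies per distance bin).

    The flank window [center - W, center + W) of every anchor is resampled
    from a local first-order Markov chain whose per-position transition
    matrix is the conditional of the enrichment-scaled background joint
    distribution; all anchors share one window model, so the expected
    dinucleotide profile is computed exactly by evolving the chain's
    marginal.  Anchor windows never overlap each other.
    """
    if spec.anchor_length <= 0:
        raise ValueError("anchor length must be positive")
    W = spec.support
    for name in genome.names:
        if W >= genome.length(name) / 4:
            raise ValueError(f"support {W} too large for chromosome {name!r}")
    rng = derive_rng(seed, "place_anchors")
    out = genome.copy()

    # sample non-overlapping windows by drawing uniformly from the remaining
    # feasible center positions (exact, never fails while space remains)
    names = genome.names
    free: dict[str, list[tuple[int, int]]] = {
        n: [(W, genome.length(n) - W)] for n in names}
    anchors: list[Interval] = []
    for _ in range(spec.n_anchors):
        sizes = {n: sum(hi - lo for lo, hi in free[n]) for n in names}
        total = sum(sizes.values())
        if total <= 0:
            raise ValueError("could not place anchors without overlapping flanks")
        pick = int(rng.integers(0, total))
        for chrom in names:
            if pick < sizes[chrom]:
                break
            pick -= sizes[chrom]
        segments = free[chrom]
        for lo, hi in segments:
            if pick < hi - lo:
                c = lo + pick
                break
            pick -= hi - lo
        new_segments = []
        for lo, hi in segments:
            if hi <= c - 2 * W or lo >= c + 2 * W:
                new_segments.append((lo, hi))
            else:
                if lo < c - 2 * W:
                    new_segments.append((lo, c - 2 * W))
                if hi > c + 2 * W:
                    new_segments.append((c + 2 * W, hi))
        free[chrom] = new_segments
        half = spec.anchor_length // 2
        anchors.append(Interval(chrom, c - half, c - half + spec.anchor_length))
    anchors.sort(key=lambda iv: (iv.chrom, iv.start))

    # resample all windows in parallel, one position at a time
    background = np.full(4, 0.25)
    # estimate background from the genome itself so insertions/bias are honored
    counts = np.zeros(4)
    for n in names:
        c = genome.chromosomes[n]
        counts += np.bincount(c[c < 4], minlength=4)
    background = counts / counts.sum()

    offsets = np.arange(-W, W)
    T = _flank_transitions(spec, background, offsets)
    centers = np.array([(iv.start + iv.end) // 2 for iv in anchors])
    chrom_of = [iv.chrom for iv in anchors]
    n_anchor = len(anchors)
    prev = rng.choice(4, size=n_anchor, p=background).astype(np.uint8)
    window = np.empty((n_anchor, offsets.size), dtype=np.uint8)
    window[:, 0] = prev
    mu = background.copy()
    expected = np.zeros((offsets.size - 1, 16))
    u = rng.random((n_anchor, offsets.size))
    for k in range(1, offsets.size):
        Tk = T[k - 1]        # step from offset k-1 to k
        cum = np.cumsum(Tk, axis=1)
        nxt = (u[:, k][:, None] > cum[prev]).sum(axis=1).astype(np.uint8)
        window[:, k] = nxt
        expected[k - 1] = (mu[:, None] * Tk).reshape(16)
        mu = mu @ Tk
        prev = nxt
    for i in range(n_anchor):
        seq = out.chromosomes[chrom_of[i]]
        seq[centers[i] - W:centers[i] + W] = window[i]

    # aggregate expected per-step dinucleotide probabilities into distance bins
    step_offsets = offsets[:-1]  # left position of each dinucleotide step
    bin_idx = (step_offsets + W) // truth_resolution
    n_bins_truth = int(bin_idx.max()) + 1
    per_bin = np.zeros((n_bins_truth, 16))
    np.add.at(per_bin, bin_idx, expected)
    counts_per_bin = np.bincount(bin_idx, minlength=n_bins_truth)[:, None]
    truth = {
        "anchors": [{"chrom": iv.chrom, "start": int(iv.start), "end": int(iv.end)}
                    for iv in anchors],
        "support": int(W),
        "anchor_length": int(spec.anchor_length),
        "background_base_frequencies": background.tolist(),
        "truth_resolution": int(truth_resolution),
        "bin_start_offsets": (np.unique(bin_idx) * truth_resolution - W).tolist(),
        "expected_dinucleotide_frequencies": (per_bin / counts_per_bin).tolist(),
        "background_dinucleotide_frequencies":
            np.outer(background, background).reshape(16).tolist(),
    }
    return out, anchors, truth
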