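"""Position weight matrices and genome scanning.

A PWM is stored as a 4 x m matrix of log2 likelihood-ratio scores over the
alphabet A, C, G, T.  The score of an m-bp window is the sum of the per-column
scores of its bases (``w`` in the occupancy model); the reverse strand is
scored on the reverse complement.  Scores are in bits throughout — the
specificity factor lambda that divides the score inside the Boltzmann weight
absorbs any change of log base, so the convention only matters when quoting
lambda values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
# anything not ACGT (N, lowercase handled upstream) -> 4
_LUT = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3, other=4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


@dataclass(frozen=True)
class PWM:
    """Log2 likelihood-ratio scoring matrix for a TF binding motif.

    Attributes
    ----------
    matrix : (4, m) array of per-position log2(f_b / bg_b) scores.
    frequencies : (4, m) array of the pseudo-count-regularised base
        frequencies the scores were derived from (columns sum to 1).
    background : length-4 base composition, strictly positive, sums to 1.
    pseudo_count : total pseudo-count added per column (split across bases
        in proportion to the background).
    """

    matrix: np.ndarray
    frequencies: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudo_count: float = 1.0
    name: str = "pwm"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PWM matrix must be 4 x m with m >= 1, got {m.shape}")
        if f.shape != m.shape:
            raise ValueError("frequencies must have the same shape as the score matrix")
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 strictly positive frequencies summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.length

    @property
    def max_score(self) -> float:
        """Score of the consensus word."""
        return float(self.matrix.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        """Score of the anti-consensus word."""
        return float(self.matrix.min(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse complement strand at the same coordinates."""
        return replace(
            self,
            matrix=self.matrix[::-1, ::-1],
            frequencies=self.frequencies[::-1, ::-1],
            name=f"{self.name}_rc",
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))


@dataclass
class ScoredSites:
    """Candidate binding sites: m-bp windows with their PWM scores.

    Positions are 0-based window starts; the same start can appear once per
    strand (both strands are scanned and kept as distinct sites).  Arrays are
    ordered with all '+' sites first, then all '-' sites, each block sorted by
    position.
    """

    chrom: str
    positions: np.ndarray
    strands: np.ndarray
    scores: np.ndarray
    width: int
    threshold_fraction: float | None = None
    # score range of the originating scan (kept through filtering so the
    # relative threshold stays anchored to the scanned region)
    score_min: float | None = None
    score_max: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.positions)
        if len(self.strands) != n or len(self.scores) != n:
            raise ValueError("positions, strands and scores must have equal length")
        for strand in "+-":
            pos = self.positions[self.strands == strand]
            if len(pos) > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on strand {strand} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centers(self) -> np.ndarray:
        """Midpoint of each site, used to anchor the coverage kernel."""
        return self.positions + self.width // 2


def build_pwm(
    counts,
    pseudo_count: float = 1.0,
    background=None,
    name: str = "pwm",
) -> PWM:
    """Build a log2 likelihood-ratio PWM from a 4 x m base-count matrix.

    A total pseudo-count is added to every column, split across the four
    bases in proportion to the background (an equal 0.25 share each under a
    uniform background), before normalising to frequencies:

        f[b, i] = (counts[b, i] + pseudo_count * bg[b]) / (total_i + pseudo_count)
        score[b, i] = log2(f[b, i] / bg[b])

    With ``pseudo_count == 0`` a base absent from a column receives a -inf
    score; a fully empty column is rejected.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError(f"counts must be a 4 x m matrix, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be >= 0")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, dtype=float)
    totals = counts.sum(axis=0)
    if pseudo_count == 0 and np.any(totals == 0):
        raise ValueError("all-zero count column with pseudo_count = 0 gives undefined scores")
    freqs = (counts + pseudo_count * bg[:, None]) / (totals + pseudo_count)
    with np.errstate(divide="ignore"):
        matrix = np.log2(freqs / bg[:, None])
    return PWM(matrix=matrix, frequencies=freqs, background=bg, pseudo_count=pseudo_count, name=name)


def information_content(pwm: PWM) -> float:
    """Total information content of the motif in bits.

    IC = sum over positions and bases of f * log2(f / background); zero when
    every column equals the background, and bounded by 2 bits per column for
    a uniform background.  Zero frequencies contribute zero (lim f->0).
    """
    f = pwm.frequencies
    bg = pwm.background[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / bg), 0.0)
    return float(terms.sum())


def score_sequence(pwm: PWM, sequence: str, chrom: str = "chr") -> ScoredSites:
    """Score every m-bp window of ``sequence`` on both strands.

    Windows containing a non-ACGT base are masked (excluded from the output);
    they still occupy genomic slots and are treated as zero-weight by the
    occupancy model.  The reverse strand is scored on the reverse complement
    at the same window coordinates.
    """
    m = pwm.length
    L = len(sequence)
    if L < m:
        raise ValueError(f"sequence length {L} shorter than motif length {m}")
    codes = encode_sequence(sequence)
    valid = codes < 4
    n_win = L - m + 1

    # window is valid iff all m bases are ACGT
    ok = np.ones(n_win, dtype=bool)
    if not valid.all():
        cum = np.concatenate(([0], np.cumsum(valid)))
        ok = (cum[m:] - cum[:-m]) == m

    safe = np.where(valid, codes, 0)

    # forward: score[i] = sum_k M[code[i+k], k]; reverse strand scored with the
    # reverse-complement matrix at the same window coordinates
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    M = pwm.matrix
    Mrc = pwm.reverse_complement().matrix
    for k in range(m):
        col = safe[k : k + n_win]
        fwd += M[col, k]
        rev += Mrc[col, k]

    pos = np.arange(n_win, dtype=np.int64)[ok]
    positions = np.concatenate([pos, pos])
    strands = np.concatenate([np.full(len(pos), "+"), np.full(len(pos), "-")])
    scores = np.concatenate([fwd[ok], rev[ok]])
    smin = float(scores.min()) if len(scores) else None
    smax = float(scores.max()) if len(scores) else None
    return ScoredSites(chrom=chrom, positions=positions, strands=strands,
                       scores=scores, width=m, score_min=smin, score_max=smax)


def relative_score_threshold(
    scores: np.ndarray, fraction: float, mode: str = "absolute_range"
) -> float:
    """Score cutoff for the relative-score filter.

    ``absolute_range`` applies the published rule literally:
    ``threshold = fraction * (max - min)``.  ``offset_from_min`` anchors the
    band at the weakest site: ``threshold = min + fraction * (max - min)``.
    The literal rule degenerates (threshold above the maximum, empty result)
    whenever ``min < -(1 - fraction)/fraction * max``; see the methods note.
    """
    lo, hi = float(np.min(scores)), float(np.max(scores))
    if mode == "absolute_range":
        return fraction * (hi - lo)
    if mode == "offset_from_min":
        return lo + fraction * (hi - lo)
    raise ValueError(f"unknown threshold mode {mode!r}")


def filter_by_relative_score(
    sites: ScoredSites,
    fraction: float = 0.7,
    mode: str = "absolute_range",
) -> ScoredSites:
    """Keep sites whose score clears the relative threshold.

    The max/min defining the threshold come from the score range of the
    originating scan (``score_min`` / ``score_max``, falling back to the
    scores at hand), and are propagated to the output — filtering is
    therefore idempotent and the threshold reflects the whole scanned
    region, not the surviving subset.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if len(sites) == 0:
        warnings.warn("filter_by_relative_score called on empty site set", stacklevel=2)
        return ScoredSites(
            chrom=sites.chrom,
            positions=np.array([], dtype=np.int64),
            strands=np.array([], dtype="U1"),
            scores=np.array([]),
            width=sites.width,
            threshold_fraction=fraction,
            score_min=sites.score_min,
            score_max=sites.score_max,
        )
    smin = sites.score_min if sites.score_min is not None else float(sites.scores.min())
    smax = sites.score_max if sites.score_max is not None else float(sites.scores.max())
    threshold = relative_score_threshold(np.array([smin, smax]), fraction, mode)
    keep = sites.scores >= threshold
    return ScoredSites(
        chrom=sites.chrom,
        positions=sites.positions[keep],
        strands=sites.strands[keep],
        scores=sites.scores[keep],
        width=sites.width,
        threshold_fraction=fraction,
        score_min=smin,
        score_max=smax,
    )
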