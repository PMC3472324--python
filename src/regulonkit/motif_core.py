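"""TFBS motif machinery: probability matrices, log-odds scoring, exact
p-value thresholds and double-strand scanning.

Scores are log-odds in bits (base-2) of motif vs background.  The score
distribution of a random background word is computed exactly by dynamic
programming over a discretized score lattice (default granularity
1/1000 bit); the same lattice maps hit scores to p-values, so thresholds
and reported p-values are mutually consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .sequence_io import ParseError, reverse_complement

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BASE_INDEX["N"] = 4

DEFAULT_GRANULARITY = 1e-3  # bits per score bin
DEFAULT_CUTOFF_PVALUE = 1e-5


def encode(seq: str) -> np.ndarray:
    """Encode DNA to integer indices (A=0..T=3, N=4)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    out = lut[arr]
    if (out == 255).any():
        pos = int(np.argmax(out == 255))
        raise ValueError(f"illegal DNA character {seq[pos]!r} at position {pos}")
    return out.astype(np.intp)


@dataclass
class Background:
    """Zeroth-order background base composition."""

    freqs: np.ndarray  # A, C, G, T

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("background needs exactly 4 frequencies")
        if (self.freqs <= 0).any():
            raise ValueError("background frequencies must be > 0")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], pseudocount: float = 1.0) -> "Background":
        counts = np.full(4, pseudocount, dtype=float)
        for s in seqs:
            e = encode(s)
            counts += np.bincount(e[e < 4], minlength=4)
        return cls(counts / counts.sum())

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for b, f in zip(BASES, self.freqs):
                fh.write(f"{b} {f:.6f}\n")

    @classmethod
    def from_file(cls, path) -> "Background":
        freqs = np.full(4, np.nan)
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 2 and parts[0] in BASE_INDEX:
                    freqs[BASE_INDEX[parts[0]]] = float(parts[1])
        if np.isnan(freqs).any():
            raise ParseError(f"{path}: incomplete background file")
        return cls(freqs / freqs.sum())


@dataclass
class PSPM:
    """Position-specific probability matrix: row j = base probabilities at
    motif position j."""

    matrix: np.ndarray  # (width, 4)
    site_count: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PSPM matrix must be (width, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PSPM entries must be >= 0")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("PSPM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PSPM":
        return PSPM(self.matrix[::-1, ::-1].copy(), self.site_count)


@dataclass
class PWM:
    """Log-odds (bits) scoring matrix derived from a PSPM and background."""

    matrix: np.ndarray  # (width, 4)
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        self.min_score = float(self.matrix.min(axis=1).sum())
        self.max_score = float(self.matrix.max(axis=1).sum())

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def score_word(self, word: str) -> float:
        """Real-valued score of one word; N positions contribute 0."""
        e = encode(word)
        if len(e) != self.width:
            raise ValueError("word length != PWM width")
        ext = np.hstack([self.matrix, np.zeros((self.width, 1))])
        return float(ext[np.arange(self.width), e].sum())


def build_pspm(sites: Sequence[str], pseudocount: float = 0.0) -> PSPM:
    """Count matrix from aligned equal-length sites, with additive smoothing:
    p(j,b) = (count + pseudocount) / (n_sites + 4*pseudocount)."""
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites have unequal lengths")
    counts = np.zeros((w, 4))
    for s in sites:
        e = encode(s.upper())
        if (e >= 4).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[np.arange(w), e] += 1
    n = len(sites)
    return PSPM((counts + pseudocount) / (n + 4 * pseudocount), site_count=n)


def pspm_to_pwm(pspm: PSPM, bg: Background, pseudocount: float = 0.01) -> PWM:
    """Convert probabilities to base-2 log-odds against the background.

    Probabilities are regularized toward the background:
    p' = (p + pseudocount * bg_b) / (1 + pseudocount), which keeps rows
    normalized and forbids -inf entries.  With pseudocount 0 a zero
    probability is an error.
    """
    p = pspm.matrix
    if pseudocount == 0.0:
        if (p == 0).any():
            raise ValueError("zero probability requires pseudocount > 0")
        reg = p
    else:
        reg = (p + pseudocount * bg.freqs[None, :]) / (1.0 + pseudocount)
    return PWM(np.log2(reg / bg.freqs[None, :]))


def information_content(pspm: PSPM, bg: Background) -> tuple[np.ndarray, float]:
    """Per-position relative entropy (bits) vs background, and the total."""
    p = pspm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg.freqs[None, :]), 0.0)
    per_col = terms.sum(axis=1)
    return per_col, float(per_col.sum())


class ScoreDistribution:
    """Exact distribution of PWM scores of random background words on a
    discretized lattice of ``granularity`` bits per bin."""

    def __init__(self, pwm: PWM, bg: Background,
                 granularity: float = DEFAULT_GRANULARITY):
        self.granularity = float(granularity)
        self.int_matrix = np.rint(pwm.matrix / self.granularity).astype(np.int64)
        lo = self.int_matrix.min(axis=1)
        hi = self.int_matrix.max(axis=1)
        self.min_int = int(lo.sum())
        self.max_int = int(hi.sum())
        dist = np.ones(1)
        offset = 0  # dist[k] = P(sum == k + offset)
        for j in range(pwm.width):
            width_j = int(hi[j] - lo[j])
            new = np.zeros(len(dist) + width_j)
            for b in range(4):
                sh = int(self.int_matrix[j, b] - lo[j])
                new[sh : sh + len(dist)] += dist * bg.freqs[b]
            dist = new
            offset += int(lo[j])
        self.dist = dist
        self.offset = offset
        # survival[k] = P(score_int >= k + offset)
        self.survival = dist[::-1].cumsum()[::-1]

    def word_int_score(self, encoded: np.ndarray) -> int:
        ext = np.hstack(
            [self.int_matrix, np.zeros((self.int_matrix.shape[0], 1), dtype=np.int64)]
        )
        return int(ext[np.arange(len(encoded)), encoded].sum())

    def pvalue(self, int_score: int) -> float:
        k = int_score - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.survival):
            return 0.0
        return float(min(1.0, self.survival[k]))

    def threshold_int(self, pvalue: float) -> int:
        """Smallest achievable score t with P(score >= t) <= pvalue.

        When even the maximal score carries more mass than ``pvalue`` the
        returned threshold exceeds every achievable score (nothing passes).
        """
        if pvalue <= 0:
            raise ValueError("pvalue must be > 0")
        if pvalue >= 1:
            return self.min_int
        idx = int(np.searchsorted(-self.survival, -pvalue, side="left"))
        nz = np.nonzero(self.dist[idx:] > 0)[0]
        if len(nz) == 0:
            return self.max_int + 1
        return idx + int(nz[0]) + self.offset


def score_threshold(pwm: PWM, pvalue: float, bg: Background,
                    granularity: float = DEFAULT_GRANULARITY) -> float:
    """Score cutoff whose background tail mass does not exceed ``pvalue``.

    Computed exactly by dynamic programming over the discretized score
    distribution; the returned threshold is conservative at the stated
    granularity.
    """
    sd = ScoreDistribution(pwm, bg, granularity)
    return sd.threshold_int(pvalue) * sd.granularity


@dataclass
class TFBSLibraryEntry:
    """A named TFBS motif with its scanning cutoff."""

    tf_name: str
    organism: str
    pspm: PSPM
    pwm: PWM
    cutoff_pvalue: float
    cutoff_score: float
    granularity: float = DEFAULT_GRANULARITY

    @property
    def width(self) -> int:
        return self.pspm.width


def make_library_entry(
    tf_name: str,
    sites_or_pspm,
    bg: Background,
    organism: str = "",
    cutoff_pvalue: float = DEFAULT_CUTOFF_PVALUE,
    pseudocount: float = 0.01,
    granularity: float = DEFAULT_GRANULARITY,
    enforce_width: bool = True,
) -> TFBSLibraryEntry:
    """Build a library entry from aligned sites (or a ready PSPM)."""
    if isinstance(sites_or_pspm, PSPM):
        pspm = sites_or_pspm
    else:
        pspm = build_pspm(list(sites_or_pspm), pseudocount=0.0)
    if enforce_width and not (6 <= pspm.width <= 18):
        raise ValueError(
            f"{tf_name}: library motif width {pspm.width} outside [6, 18]"
        )
    pwm = pspm_to_pwm(pspm, bg, pseudocount=pseudocount)
    cutoff = score_threshold(pwm, cutoff_pvalue, bg, granularity)
    return TFBSLibraryEntry(
        tf_name=tf_name,
        organism=organism,
        pspm=pspm,
        pwm=pwm,
        cutoff_pvalue=cutoff_pvalue,
        cutoff_score=cutoff,
        granularity=granularity,
    )


@dataclass
class MotifHit:
    """One scored motif occurrence (coordinates local to the scanned
    sequence unless the caller maps them to the genome)."""

    tf_name: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    matched_seq: str


def _window_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Sum matrix[j, base] over sliding windows; N (index 4) scores 0."""
    w = matrix.shape[0]
    ext = np.hstack([matrix, np.zeros((w, 1), dtype=matrix.dtype)])
    wins = np.lib.stride_tricks.sliding_window_view(enc, w)
    return ext[np.arange(w)[None, :], wins].sum(axis=1)


def scan(
    seq: str,
    entry: TFBSLibraryEntry,
    bg: Background,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Report every window scoring at or above the entry's cutoff.

    Scores are compared on the same discretized lattice used for the
    threshold, and each hit carries the exact background p-value of its
    score.  Hits are sorted by position; overlaps are all kept.  For
    minus-strand hits ``matched_seq`` is given in motif orientation.
    """
    w = entry.width
    if len(seq) < w:
        return []
    sd = ScoreDistribution(entry.pwm, bg, entry.granularity)
    cutoff_int = sd.threshold_int(entry.cutoff_pvalue)
    enc = encode(seq.upper())
    hits: list[MotifHit] = []

    def one_strand(matrix_int: np.ndarray, matrix_real: np.ndarray, strand: str):
        ints = _window_scores(enc, matrix_int)
        reals = _window_scores(enc, matrix_real)
        for i in np.nonzero(ints >= cutoff_int)[0]:
            word = seq[i : i + w].upper()
            hits.append(
                MotifHit(
                    tf_name=entry.tf_name,
                    start=int(i),
                    end=int(i + w),
                    strand=strand,
                    score=float(reals[i]),
                    pvalue=sd.pvalue(int(ints[i])),
                    matched_seq=word if strand == "+" else reverse_complement(word),
                )
            )

    one_strand(sd.int_matrix, entry.pwm.matrix, "+")
    if both_strands:
        # scoring the reverse complement of each window == scoring the
        # forward window with the reverse-complemented matrix
        one_strand(sd.int_matrix[::-1, ::-1], entry.pwm.matrix[::-1, ::-1], "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# MEME-minimal motif library format


def write_motif_library(entries: Sequence[TFBSLibraryEntry], path,
                        bg: Optional[Background] = None) -> None:
    """Write entries in MEME-minimal text format.

    The per-entry scanning cutoff is carried on a comment-line extension
    (``# cutoff_pvalue=``) immediately after the MOTIF line.
    """
    bg = bg or Background.uniform()
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg.freqs)),
        "",
    ]
    for e in entries:
        name = e.tf_name if not e.organism else f"{e.tf_name} {e.organism}"
        lines.append(f"MOTIF {name}")
        lines.append(f"# cutoff_pvalue= {e.cutoff_pvalue:.6g}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {e.pspm.width} "
            f"nsites= {e.pspm.site_count} E= 0"
        )
        for row in e.pspm.matrix:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_motif_library(path, cutoff_pvalue: float = DEFAULT_CUTOFF_PVALUE,
                       granularity: float = DEFAULT_GRANULARITY,
                       pseudocount: float = 0.01) -> list[TFBSLibraryEntry]:
    """Read a MEME-minimal motif file into library entries.

    Matrix rows off unity by <= 1e-3 are renormalized (with a warning when
    the deviation exceeds rounding noise); larger deviations are errors.
    The file's background frequencies are used to rebuild PWMs and score
    cutoffs; a ``# cutoff_pvalue=`` comment overrides the default per motif.
    """
    bg = Background.uniform()
    entries: list[TFBSLibraryEntry] = []
    name = organism = None
    cur_pvalue = cutoff_pvalue
    rows: list[list[float]] = []
    expect = 0
    nsites = 0
    matrix_line = 0

    def flush():
        nonlocal rows
        if name is None:
            return
        if expect and len(rows) != expect:
            raise ParseError(
                f"{path}:{matrix_line}: motif {name} declares w= {expect} "
                f"but has {len(rows)} rows"
            )
        mat = np.asarray(rows, dtype=float)
        sums = mat.sum(axis=1)
        dev = np.abs(sums - 1.0)
        if dev.max() > 1e-3:
            raise ParseError(
                f"{path}: motif {name} row sums deviate from 1 by {dev.max():.2g}"
            )
        if dev.max() > 1e-5:
            warnings.warn(
                f"motif {name}: renormalizing rows off unity by {dev.max():.2g}"
            )
        mat = mat / sums[:, None]
        pspm = PSPM(mat, site_count=nsites)
        entries.append(
            make_library_entry(
                name, pspm, bg, organism=organism or "",
                cutoff_pvalue=cur_pvalue, pseudocount=pseudocount,
                granularity=granularity, enforce_width=False,
            )
        )
        rows = []

    with open(path) as fh:
        in_bg = False
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("Background letter frequencies"):
                in_bg = True
                continue
            if in_bg and line:
                parts = line.split()
                freqs = np.full(4, 0.25)
                try:
                    for b, f in zip(parts[0::2], parts[1::2]):
                        freqs[BASE_INDEX[b]] = float(f)
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{ln}: bad background line") from exc
                bg = Background(freqs / freqs.sum())
                in_bg = False
                continue
            if line.startswith("MOTIF"):
                flush()
                parts = line.split(maxsplit=2)
                name = parts[1] if len(parts) > 1 else f"motif_{len(entries)}"
                organism = parts[2] if len(parts) > 2 else None
                cur_pvalue = cutoff_pvalue
                expect = 0
                nsites = 0
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("cutoff_pvalue="):
                    cur_pvalue = float(body.split("=", 1)[1])
                continue
            if line.startswith("letter-probability matrix"):
                matrix_line = ln
                toks = line.split()
                for key, val in zip(toks, toks[1:]):
                    if key == "w=":
                        expect = int(val)
                    elif key == "nsites=":
                        nsites = int(val)
                continue
            if line and name is not None and line[0] in "0123456789.":
                vals = line.split()
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}:{ln}: matrix row must have 4 values"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: malformed matrix row") from exc
    flush()
    return entries
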