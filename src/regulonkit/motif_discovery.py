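"""De-novo discovery of overrepresented motifs in upstream regions.

A ZOOPS (zero-or-one-occurrence-per-sequence) mixture model is fitted by
expectation-maximization, MEME-style: each input sequence either carries
one motif occurrence at an unknown offset (and strand) or is pure
background.  Seeding is deterministic — EM is restarted from the most
frequent exact words of each width — so a run is reproducible without
seed sweeps.

Significance is summarized by ``evalue_like``, a BIC-penalized
likelihood-ratio surrogate (lower = stronger).  It ranks motifs across
widths within this package and is not numerically comparable to MEME's
E-values.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .motif_core import (
    PSPM,
    Background,
    TFBSLibraryEntry,
    build_pspm,
    encode,
)
from .sequence_io import reverse_complement

LN2 = math.log(2.0)


@dataclass
class DiscoveryConfig:
    width_min: int = 6
    width_max: int = 18
    model: str = "ZOOPS"
    max_iters: int = 200
    tol: float = 1e-4
    n_seeds: int = 5
    both_strands: bool = True
    rng_seed: int = 0
    pseudocount: float = 0.25  # EM count smoothing, fraction of a site

    def __post_init__(self) -> None:
        if not (1 <= self.width_min <= self.width_max):
            raise ValueError("need 1 <= width_min <= width_max")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.model not in ("ZOOPS", "OOPS"):
            raise ValueError("model must be ZOOPS or OOPS")


@dataclass
class DiscoveredMotif:
    pspm: PSPM
    sites: list[tuple[int, int, str]]  # (sequence index, offset, strand)
    log_likelihood_ratio: float  # nats, vs all-background model
    evalue_like: float
    ll_trace: list[float] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pspm.width

    def consensus(self) -> str:
        return self.pspm.consensus()


class _WidthData:
    """Per-width window tables for a set of sequences."""

    def __init__(self, seqs: Sequence[str], w: int, bg: Background,
                 both_strands: bool):
        self.w = w
        self.windows: list[np.ndarray] = []  # (n_options, w) base indices
        self.strands: list[np.ndarray] = []
        self.offsets: list[np.ndarray] = []
        logbg = np.log(np.append(bg.freqs, 1.0))  # N contributes log 1 = 0
        self.log_bg: list[np.ndarray] = []
        for s in seqs:
            enc = encode(s.upper())
            m = len(enc) - w + 1
            if m <= 0:
                self.windows.append(np.zeros((0, w), dtype=np.intp))
                self.strands.append(np.zeros(0, dtype=np.intp))
                self.offsets.append(np.zeros(0, dtype=np.intp))
                self.log_bg.append(np.zeros(0))
                continue
            fwd = np.lib.stride_tricks.sliding_window_view(enc, w)
            if both_strands:
                rc_enc = encode(reverse_complement(s.upper()))
                rc = np.lib.stride_tricks.sliding_window_view(rc_enc, w)
                wins = np.vstack([fwd, rc])
                strands = np.concatenate(
                    [np.zeros(m, dtype=np.intp), np.ones(m, dtype=np.intp)]
                )
                # rc window at index j covers forward offset len - w - j
                offs = np.concatenate(
                    [np.arange(m), (m - 1) - np.arange(m)]
                )
            else:
                wins, strands, offs = fwd, np.zeros(m, dtype=np.intp), np.arange(m)
            self.windows.append(np.ascontiguousarray(wins))
            self.strands.append(strands)
            self.offsets.append(offs)
            self.log_bg.append(logbg[wins].sum(axis=1))

    def n_seqs(self) -> int:
        return len(self.windows)


def _log_motif(windows: np.ndarray, log_theta: np.ndarray) -> np.ndarray:
    w = log_theta.shape[0]
    return log_theta[np.arange(w)[None, :], windows].sum(axis=1)


def _em(data: _WidthData, bg: Background, theta0: np.ndarray, cfg: DiscoveryConfig):
    """Run EM to convergence; returns (theta, gamma, llr, trace)."""
    w = data.w
    n = data.n_seqs()
    theta = theta0.copy()
    gamma = 1.0 if cfg.model == "OOPS" else 0.5
    trace: list[float] = []
    bgf = bg.freqs
    prev = -np.inf
    for _ in range(cfg.max_iters):
        # log_theta with a 5th column for N scoring as background-neutral
        log_theta = np.log(np.hstack([theta, np.ones((w, 1))]))
        llr = 0.0
        counts = np.zeros((w, 4))
        q_sum = 0.0
        n_used = 0
        for i in range(n):
            wins = data.windows[i]
            if len(wins) == 0:
                continue
            n_used += 1
            S = len(wins)
            lr = _log_motif(wins, log_theta) - data.log_bg[i]
            m = max(float(lr.max()), 0.0)
            ex = np.exp(lr - m)
            if cfg.model == "OOPS":
                denom = (1.0 / S) * ex.sum()
                z = ex / (S * denom)
                llr += m + math.log((1.0 / S) * ex.sum())
            else:
                denom = (1.0 - gamma) * math.exp(-m) + (gamma / S) * ex.sum()
                z = (gamma / S) * ex / denom
                llr += m + math.log(denom)
            q_sum += float(z.sum())
            for j in range(w):
                np.add.at(counts[j], wins[:, j], z)
        trace.append(llr)
        # M-step
        counts += cfg.pseudocount * bgf[None, :]
        theta = counts / counts.sum(axis=1, keepdims=True)
        if cfg.model == "ZOOPS" and n_used:
            gamma = min(max(q_sum / n_used, 1e-6), 1.0 - 1e-6)
        if llr - prev < cfg.tol and len(trace) > 1:
            break
        prev = llr
    return theta, gamma, trace[-1], trace


def _hard_sites(data: _WidthData, theta: np.ndarray, gamma: float,
                cfg: DiscoveryConfig) -> list[tuple[int, int, str]]:
    w = data.w
    log_theta = np.log(np.hstack([theta, np.ones((w, 1))]))
    sites = []
    best_global = None
    for i in range(data.n_seqs()):
        wins = data.windows[i]
        if len(wins) == 0:
            continue
        S = len(wins)
        lr = _log_motif(wins, log_theta) - data.log_bg[i]
        m = max(float(lr.max()), 0.0)
        ex = np.exp(lr - m)
        k = int(lr.argmax())
        if cfg.model == "OOPS":
            q = 1.0
        else:
            denom = (1.0 - gamma) * math.exp(-m) + (gamma / S) * ex.sum()
            q = float((gamma / S) * ex.sum() / denom)
        strand = "+" if data.strands[i][k] == 0 else "-"
        cand = (i, int(data.offsets[i][k]), strand)
        if best_global is None or lr[k] > best_global[0]:
            best_global = (float(lr[k]), cand)
        if q >= 0.5:
            sites.append(cand)
    if not sites and best_global is not None:
        sites.append(best_global[1])
    return sites


def _seed_words(seqs: Sequence[str], w: int, n_seeds: int) -> list[str]:
    """Most frequent exact w-mers (ties lexicographic) — deterministic seeds."""
    counter: Counter[str] = Counter()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - w + 1):
            word = s[i : i + w]
            if "N" not in word:
                counter[word] += 1
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return [word for word, _ in ranked[:n_seeds]]


def _theta_from_seed(word: str, match_p: float = 0.7) -> np.ndarray:
    enc = encode(word)
    theta = np.full((len(word), 4), (1.0 - match_p) / 3.0)
    theta[np.arange(len(word)), enc] = match_p
    return theta


def discover(regions: Sequence[str], bg: Background,
             cfg: Optional[DiscoveryConfig] = None) -> list[DiscoveredMotif]:
    """Find overrepresented motifs of each width in ``regions`` and rank
    them across widths by ``evalue_like``.

    For each width the EM is restarted from ``n_seeds`` deterministic
    seed words and the best-likelihood fit kept; the returned site list
    is the hard (posterior >= 0.5) assignment and the reported PSPM is
    rebuilt from those sites, so sites and matrix agree by construction.
    """
    cfg = cfg or DiscoveryConfig()
    seqs = [r.upper() for r in regions]
    if len(seqs) < 2:
        raise ValueError("need at least 2 regions")
    if all(len(s) < cfg.width_min for s in seqs):
        raise ValueError("all regions shorter than width_min")
    total_len = sum(len(s) for s in seqs)
    results: list[DiscoveredMotif] = []
    for w in range(cfg.width_min, cfg.width_max + 1):
        if all(len(s) < w for s in seqs):
            continue
        data = _WidthData(seqs, w, bg, cfg.both_strands)
        best = None
        for word in _seed_words(seqs, w, cfg.n_seeds):
            theta, gamma, llr, trace = _em(data, bg, _theta_from_seed(word), cfg)
            if best is None or llr > best[2]:
                best = (theta, gamma, llr, trace)
        if best is None:
            continue
        theta, gamma, llr, trace = best
        sites = _hard_sites(data, theta, gamma, cfg)
        words = []
        for i, off, strand in sites:
            word = seqs[i][off : off + w]
            words.append(word if strand == "+" else reverse_complement(word))
        words = [wd for wd in words if "N" not in wd]
        pspm = (
            build_pspm(words, pseudocount=0.0)
            if words
            else PSPM(np.tile(bg.freqs, (w, 1)))
        )
        # BIC-style penalty: 3 free parameters per column, n = total input size
        penalty = 1.5 * w * math.log(max(total_len, 2))
        log_e = -(llr - penalty)
        evalue_like = math.exp(min(max(log_e, -700.0), 700.0))
        results.append(
            DiscoveredMotif(
                pspm=pspm,
                sites=sites,
                log_likelihood_ratio=llr,
                evalue_like=evalue_like,
                ll_trace=trace,
            )
        )
    results.sort(key=lambda m: (m.evalue_like, -m.log_likelihood_ratio))
    return results


# ---------------------------------------------------------------------------
# matrix similarity and library refinement


def pspm_similarity(a: PSPM, b: PSPM, min_overlap: int = 4
                    ) -> tuple[float, int, str]:
    """Best mean per-column Pearson correlation over all ungapped
    alignments of two PSPMs, both strands.

    Returns (similarity in [-1, 1], column offset of b relative to a,
    strand of b).  Columns with zero variance correlate as 0.
    """

    def col_corr(x: np.ndarray, y: np.ndarray) -> float:
        xc = x - x.mean()
        yc = y - y.mean()
        d = math.sqrt((xc @ xc) * (yc @ yc))
        return float(xc @ yc / d) if d > 0 else 0.0

    def best_offset(ma: np.ndarray, mb: np.ndarray) -> tuple[float, int]:
        wa, wb = ma.shape[0], mb.shape[0]
        best_s, best_o = -2.0, 0
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            cols = [
                col_corr(ma[j], mb[j - off])
                for j in range(max(0, off), min(wa, wb + off))
            ]
            if len(cols) < min_overlap:
                continue
            s = float(np.mean(cols))
            if s > best_s:
                best_s, best_o = s, off
        return best_s, best_o

    s_fwd, o_fwd = best_offset(a.matrix, b.matrix)
    s_rev, o_rev = best_offset(a.matrix, b.reverse_complement().matrix)
    if s_rev > s_fwd:
        return s_rev, o_rev, "-"
    return s_fwd, o_fwd, "+"


@dataclass
class RefinementResult:
    motif: DiscoveredMotif
    similarity: float
    offset: int
    strand: str


def refine_library_entry(candidate_sites: Sequence[str],
                         reference: TFBSLibraryEntry,
                         bg: Background,
                         cfg: Optional[DiscoveryConfig] = None
                         ) -> RefinementResult:
    """Discover motifs in candidate regions and score each against a known
    library entry; the mechanized stand-in for curating discovered motifs
    against experimentally verified sites.
    """
    cfg = cfg or DiscoveryConfig()
    motifs = discover(candidate_sites, bg, cfg)
    best: Optional[RefinementResult] = None
    for m in motifs:
        sim, off, strand = pspm_similarity(reference.pspm, m.pspm)
        if best is None or sim > best.similarity:
            best = RefinementResult(motif=m, similarity=sim, offset=off,
                                    strand=strand)
    assert best is not None
    return best
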