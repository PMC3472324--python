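"""Sigma70-type promoter prediction, ribosome-binding-site detection with
start adjustment, and simplified rho-independent terminator calling.

The promoter model pairs two 6-bp box PWMs (-35, consensus TTGACA; -10
Pribnow box, consensus TATAAT).  The boxes are scanned independently at
a permissive per-box p-value and then paired: a pairing counts as a
complete promoter only when the spacer between the boxes is 16-18 nt.
Box hits that enter no valid pairing are reported as incomplete
promoters.  The TSS is placed 10 nt downstream of the -10 box start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .motif_core import (
    Background,
    MotifHit,
    ScoreDistribution,
    TFBSLibraryEntry,
    build_pspm,
    make_library_entry,
    pspm_to_pwm,
    scan,
)
from .sequence_io import (
    START_CODONS,
    STOP_CODONS,
    GeneFeature,
    GenomeRecord,
    IntergenicRegion,
    reverse_complement,
)

BOX_WIDTH = 6
DEFAULT_BOX_PVALUE = 1e-3
TSS_OFFSET = 10  # nt from -10 box start to transcription start


def _load_sites(filename: str) -> list[str]:
    text = resources.files("regulonkit.data").joinpath(filename).read_text()
    return [ln.strip().upper() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


@dataclass
class PromoterModel:
    """Two-box promoter model with a spacer-window duration constraint."""

    minus35: TFBSLibraryEntry
    minus10: TFBSLibraryEntry
    spacer_min: int = 16
    spacer_max: int = 18
    box_pvalue: float = DEFAULT_BOX_PVALUE
    gram: str = "positive"

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if self.minus35.width != BOX_WIDTH or self.minus10.width != BOX_WIDTH:
            raise ValueError("promoter boxes must be 6 bp wide")


def default_promoter_model(gram: str = "positive",
                           bg: Optional[Background] = None,
                           box_pvalue: float = DEFAULT_BOX_PVALUE,
                           spacer_min: int = 16,
                           spacer_max: int = 18) -> PromoterModel:
    """Promoter model built from the packaged -35/-10 site collections.

    ``gram`` selects the Gram-positive or Gram-negative collection; both
    are centred on the TTGACA / TATAAT consensus.
    """
    if gram not in ("positive", "negative"):
        raise ValueError("gram must be 'positive' or 'negative'")
    bg = bg or Background.uniform()
    m35 = make_library_entry(
        "minus35", _load_sites(f"sigma70_minus35_gram{gram}.synthetic_sites.txt"),
        bg, cutoff_pvalue=box_pvalue,
    )
    m10 = make_library_entry(
        "minus10", _load_sites(f"sigma70_minus10_gram{gram}.synthetic_sites.txt"),
        bg, cutoff_pvalue=box_pvalue,
    )
    return PromoterModel(minus35=m35, minus10=m10, box_pvalue=box_pvalue,
                         gram=gram, spacer_min=spacer_min, spacer_max=spacer_max)


@dataclass
class PromoterCall:
    """A (possibly incomplete) promoter: paired -35/-10 box hits.

    Hit coordinates are offsets into the scanned region (5'->3' toward
    the gene); ``strand`` records the genomic strand of that region.
    """

    minus35_hit: Optional[MotifHit]
    minus10_hit: Optional[MotifHit]
    spacer_nt: Optional[int]
    complete: bool
    combined_score: float
    tss: Optional[int]
    strand: str = "+"

    def __post_init__(self) -> None:
        both = self.minus35_hit is not None and self.minus10_hit is not None
        if self.complete != (both and self.spacer_nt is not None):
            raise ValueError("complete flag inconsistent with hits")
        if not self.complete and both:
            raise ValueError("incomplete call cannot carry both boxes")
        if self.tss is not None and self.minus10_hit is None:
            raise ValueError("TSS requires a -10 hit")

    @property
    def start(self) -> int:
        return min(h.start for h in (self.minus35_hit, self.minus10_hit) if h)

    @property
    def end(self) -> int:
        return max(h.end for h in (self.minus35_hit, self.minus10_hit) if h)


def find_promoters(region: Union[IntergenicRegion, str], model: PromoterModel,
                   bg: Optional[Background] = None) -> list[PromoterCall]:
    """Scan a 5'->3' oriented region for promoters.

    Both boxes are scanned independently on the region's own strand;
    every (-35, -10) combination with an in-range spacer becomes a
    complete call (overlapping calls are all kept), remaining box hits
    become incomplete calls.  Calls are sorted by combined score.
    """
    bg = bg or Background.uniform()
    if isinstance(region, IntergenicRegion):
        seq, strand = region.sequence, region.strand
    else:
        seq, strand = str(region), "+"
    h35 = scan(seq, model.minus35, bg, both_strands=False)
    h10 = scan(seq, model.minus10, bg, both_strands=False)
    calls: list[PromoterCall] = []
    paired35: set[int] = set()
    paired10: set[int] = set()
    for i, a in enumerate(h35):
        for j, b in enumerate(h10):
            spacer = b.start - a.end
            if model.spacer_min <= spacer <= model.spacer_max:
                paired35.add(i)
                paired10.add(j)
                calls.append(
                    PromoterCall(
                        minus35_hit=a, minus10_hit=b, spacer_nt=spacer,
                        complete=True, combined_score=a.score + b.score,
                        tss=b.start + TSS_OFFSET, strand=strand,
                    )
                )
    for i, a in enumerate(h35):
        if i not in paired35:
            calls.append(PromoterCall(a, None, None, False, a.score, None, strand))
    for j, b in enumerate(h10):
        if j not in paired10:
            calls.append(
                PromoterCall(None, b, None, False, b.score,
                             b.start + TSS_OFFSET, strand)
            )
    calls.sort(key=lambda c: (-c.combined_score, c.start))
    return calls


def predict_tss(call: PromoterCall) -> int:
    """Transcription start: 10 nt downstream of the -10 box start
    (4 nt past the hexamer's end), in region coordinates."""
    if call.minus10_hit is None:
        raise ValueError("TSS prediction requires a -10 box hit")
    return call.minus10_hit.start + TSS_OFFSET


# ---------------------------------------------------------------------------
# ribosome binding sites

RBS_WIDTH = 6
RBS_SPACING_MIN = 4
RBS_SPACING_MAX = 15
DEFAULT_MIN_RBS_SCORE = 5.0  # bits


@dataclass
class RBSCall:
    start: int
    end: int
    matched_seq: str
    score: float
    spacing_to_start: int
    strand: str = "+"


_rbs_entry_cache: dict[tuple, TFBSLibraryEntry] = {}


def _rbs_entry(bg: Background) -> TFBSLibraryEntry:
    key = tuple(np.round(bg.freqs, 9))
    if key not in _rbs_entry_cache:
        _rbs_entry_cache[key] = make_library_entry(
            "RBS", _load_sites("rbs_shine_dalgarno.synthetic_sites.txt"),
            bg, cutoff_pvalue=1.0,
        )
    return _rbs_entry_cache[key]


def find_rbs(region: Union[IntergenicRegion, str],
             start_codon_offset: Optional[int] = None,
             bg: Optional[Background] = None,
             min_score: float = DEFAULT_MIN_RBS_SCORE) -> Optional[RBSCall]:
    """Best Shine-Dalgarno-like window 4-15 nt upstream of the start codon.

    ``start_codon_offset`` is the region offset of the first start-codon
    base; for an IntergenicRegion it defaults to the start of the gene
    prefix.  Ties in score are broken toward the window nearest the
    start.  Returns None when no window reaches ``min_score`` bits.
    """
    bg = bg or Background.uniform()
    if isinstance(region, IntergenicRegion):
        seq = region.sequence
        strand = region.strand
        if start_codon_offset is None:
            start_codon_offset = region.upstream_flank_len
    else:
        seq = str(region)
        strand = "+"
        if start_codon_offset is None:
            raise ValueError("start_codon_offset required for a bare sequence")
    entry = _rbs_entry(bg)
    best: Optional[RBSCall] = None
    for spacing in range(RBS_SPACING_MIN, RBS_SPACING_MAX + 1):
        s = start_codon_offset - spacing - RBS_WIDTH
        if s < 0:
            break
        word = seq[s : s + RBS_WIDTH].upper()
        score = entry.pwm.score_word(word)
        if score < min_score:
            continue
        if best is None or score > best.score:
            best = RBSCall(start=s, end=s + RBS_WIDTH, matched_seq=word,
                           score=score, spacing_to_start=spacing, strand=strand)
    return best


def adjust_start(gene: GeneFeature, genome: GenomeRecord,
                 window_nt: int = 30,
                 bg: Optional[Background] = None,
                 min_score: float = DEFAULT_MIN_RBS_SCORE) -> GeneFeature:
    """Move a de-novo ORF call's start codon to the best-supported RBS.

    Considers in-frame ATG/GTG/TTG starts within +-``window_nt`` of the
    called start (without crossing a stop codon) and keeps the start
    whose upstream window carries the strongest RBS; annotated genes
    (anything not flagged by the naive ORF caller) are returned
    unchanged, as are genes where no alternative beats the current one.
    """
    if gene.product != "naive_orf_caller":
        return gene
    bg = bg or Background.uniform()
    n = len(genome)

    def gene_seq_start(pos: int) -> str:
        """Codon at distance `pos` (gene-local nt, may be negative=upstream)."""
        if gene.strand == "+":
            s = gene.start + pos
            return genome.sequence[s : s + 3] if 0 <= s <= n - 3 else ""
        e = gene.end - pos
        return (
            reverse_complement(genome.sequence[e - 3 : e]) if 3 <= e <= n else ""
        )

    def rbs_score_at(pos: int) -> float:
        # 25 nt upstream of the candidate start, in gene orientation
        if gene.strand == "+":
            s0 = gene.start + pos
            up = genome.sequence[max(0, s0 - 25) : s0]
        else:
            e0 = gene.end - pos
            up = reverse_complement(genome.sequence[e0 : min(n, e0 + 25)])
        call = find_rbs(up, start_codon_offset=len(up), bg=bg,
                        min_score=min_score)
        return call.score if call else -math.inf

    candidates = [0]
    # upstream in-frame extensions until a stop (or window edge)
    pos = -3
    while pos >= -window_nt:
        codon = gene_seq_start(pos)
        if len(codon) < 3 or codon in STOP_CODONS:
            break
        if codon in START_CODONS:
            candidates.append(pos)
        pos -= 3
    # downstream in-frame alternatives
    pos = 3
    while pos <= window_nt and pos < len(gene) - 3:
        codon = gene_seq_start(pos)
        if codon in STOP_CODONS:
            break
        if codon in START_CODONS:
            candidates.append(pos)
        pos += 3

    current_score = rbs_score_at(0)
    best_pos, best_score = 0, current_score
    for pos in candidates:
        s = rbs_score_at(pos)
        if s > best_score:
            best_pos, best_score = pos, s
    if best_pos == 0:
        return gene
    if gene.strand == "+":
        new_start, new_end = gene.start + best_pos, gene.end
    else:
        new_start, new_end = gene.start, gene.end - best_pos
    nt = genome.sequence[new_start:new_end]
    if gene.strand == "-":
        nt = reverse_complement(nt)
    from Bio.Seq import Seq

    aa = str(Seq(nt).translate(table=11))
    aa = aa[:-1] if aa.endswith("*") else aa
    return GeneFeature(
        feature_id=gene.feature_id, locus_tag=gene.locus_tag,
        start=new_start, end=new_end, strand=gene.strand,
        gene_name=gene.gene_name, product=gene.product,
        translation=aa or None,
    )


# ---------------------------------------------------------------------------
# rho-independent terminators

PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,  # GU wobble, penalized by low score
}
STEM_MIN, STEM_MAX = 4, 12
LOOP_MIN, LOOP_MAX = 3, 9
TAIL_LEN = 8
DEFAULT_MIN_TERMINATOR_SCORE = 12.0


@dataclass
class TerminatorCall:
    start: int
    end: int
    strand: str
    stem_len: int
    loop_len: int
    hairpin_score: float
    tail_score: float
    total_score: float

    def __post_init__(self) -> None:
        if self.stem_len < STEM_MIN:
            raise ValueError("stem too short")
        if not (LOOP_MIN <= self.loop_len <= LOOP_MAX):
            raise ValueError("loop length out of range")
        if abs(self.total_score - (self.hairpin_score + self.tail_score)) > 1e-9:
            raise ValueError("total_score must equal hairpin + tail")


def tail_t_score(tail: str) -> float:
    """Position-weighted T-richness of the 8 nt following the stem
    (weight 1 - i/8 for position i, so proximal Ts count most)."""
    return sum(
        (1.0 - i / TAIL_LEN) for i, b in enumerate(tail[:TAIL_LEN]) if b == "T"
    )


def find_terminators(seq: str, strand: str = "+",
                     min_total_score: float = DEFAULT_MIN_TERMINATOR_SCORE
                     ) -> list[TerminatorCall]:
    """Simplified rho-independent terminator scan: maximal stem-loops
    (stem 4-12 bp, Watson-Crick + GU, no mismatches; loop 3-9 nt) scored
    as sum of pair scores minus the loop length, plus the weighted
    T-richness of the 8 nt 3' tail.

    For ``strand="-"`` the reverse complement is scanned and coordinates
    are mirrored back onto the given sequence.
    """
    work = seq.upper() if strand == "+" else reverse_complement(seq.upper())
    n = len(work)
    # per hairpin interval keep the best-scoring stem/loop decomposition
    best: dict[tuple[int, int], TerminatorCall] = {}
    for loop_start in range(1, n):
        for loop_len in range(LOOP_MIN, LOOP_MAX + 1):
            i = loop_start - 1  # last base of 5' stem arm
            j = loop_start + loop_len  # first base of 3' stem arm
            stem = 0
            score = 0.0
            while (
                stem < STEM_MAX and i - stem >= 0 and j + stem < n
                and (work[i - stem], work[j + stem]) in PAIR_SCORES
            ):
                score += PAIR_SCORES[(work[i - stem], work[j + stem])]
                stem += 1
            if stem < STEM_MIN:
                continue
            hp_start = i - stem + 1
            hp_end = j + stem
            hairpin = score - float(loop_len)
            tail = tail_t_score(work[hp_end : hp_end + TAIL_LEN])
            total = hairpin + tail
            if total < min_total_score:
                continue
            if strand == "+":
                s, e = hp_start, hp_end
            else:
                s, e = n - hp_end, n - hp_start
            prev = best.get((s, e))
            if prev is None or total > prev.total_score:
                best[(s, e)] = TerminatorCall(
                    start=s, end=e, strand=strand, stem_len=stem,
                    loop_len=loop_len, hairpin_score=hairpin,
                    tail_score=tail, total_score=total,
                )
    calls = sorted(best.values(), key=lambda c: (c.start, -c.total_score))
    return calls
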