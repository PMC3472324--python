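"""Protein similarity search and regulon ortholog mapping.

Local (Smith-Waterman) alignment with affine gaps stands in for a full
BLAST: hits get an analytic Karlin-Altschul E-value
E = K * m * n * exp(-lambda * S) with parameters appropriate for
BLOSUM62 with gap open 11 / extend 1.  The gap model charges
``gap_open`` for the first gapped residue and ``gap_extend`` for each
additional one.  Seeding heuristics and composition-based statistics are
deliberately not reproduced; searches are exact all-vs-all alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"

# Gapped Karlin-Altschul parameters for BLOSUM62, open 11 / extend 1
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

DEFAULT_TIER_BANDS = {"strong": 1e-50, "moderate": 1e-20, "weak": 1e-5}


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and E-value parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = KARLIN_LAMBDA
    karlin_K: float = KARLIN_K
    matrix: object = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def pair_score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = self.matrix
        al.open_gap_score = -float(self.gap_open)
        al.extend_gap_score = -float(self.gap_extend)
        return al


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity_fraction: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def _validate(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"{name}: illegal residues {sorted(bad)}")
    return seq


def evalue(raw_score: float, m: int, n: int,
           scheme: Optional[ScoringScheme] = None) -> float:
    """Karlin-Altschul expected hit count: E = K * m * n * exp(-lambda*S)."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    scheme = scheme or ScoringScheme()
    return scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * raw_score)


def bit_score(raw_score: float, scheme: Optional[ScoringScheme] = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_K)) / math.log(2)


def local_align(query: str, subject: str,
                scheme: Optional[ScoringScheme] = None,
                query_id: str = "query", subject_id: str = "subject",
                db_len: Optional[int] = None) -> AlignmentHit:
    """Optimal Smith-Waterman alignment of two proteins.

    ``db_len`` (default: the subject length) is the database size used in
    the E-value; search() passes the whole proteome's residue count.
    """
    scheme = scheme or ScoringScheme()
    q = _validate(query, query_id)
    s = _validate(subject, subject_id)
    al = scheme.aligner()
    score = float(al.score(q, s))
    if score <= 0:
        return AlignmentHit(
            query_id=query_id, subject_id=subject_id, raw_score=0.0,
            bit_score=bit_score(0.0, scheme),
            evalue=evalue(0.0, len(q), db_len or len(s), scheme),
            identity_fraction=0.0, query_span=(0, 0), subject_span=(0, 0),
        )
    aln = al.align(q, s)[0]
    qa, sa = aln.aligned
    ident = 0
    cols = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        for k in range(qe - qs):
            cols += 1
            if q[qs + k] == s[ss + k]:
                ident += 1
    # count gap columns inside the local alignment footprint
    qspan = (int(qa[0][0]), int(qa[-1][1]))
    sspan = (int(sa[0][0]), int(sa[-1][1]))
    gap_cols = (qspan[1] - qspan[0] - cols) + (sspan[1] - sspan[0] - cols)
    aln_len = cols + gap_cols
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id, raw_score=score,
        bit_score=bit_score(score, scheme),
        evalue=evalue(score, len(q), db_len or len(s), scheme),
        identity_fraction=ident / aln_len if aln_len else 0.0,
        query_span=qspan, subject_span=sspan,
    )


def search(queries: Sequence[tuple[str, str]],
           proteome: Sequence[tuple[str, str]],
           cutoff_evalue: float = 1e-5,
           scheme: Optional[ScoringScheme] = None
           ) -> dict[str, Optional[AlignmentHit]]:
    """Best proteome hit per query at ``cutoff_evalue``.

    Sequences are (id, sequence) pairs.  The database length in the
    E-value is the total residue count of the proteome.  Ties are broken
    by higher raw score, then lexicographic subject id, so results do not
    depend on proteome order.
    """
    if not proteome:
        raise ValueError("empty proteome")
    scheme = scheme or ScoringScheme()
    db_len = sum(len(s) for _, s in proteome)
    out: dict[str, Optional[AlignmentHit]] = {}
    for qid, qseq in queries:
        best: Optional[AlignmentHit] = None
        for sid, sseq in sorted(proteome, key=lambda p: p[0]):
            hit = local_align(qseq, sseq, scheme, query_id=qid,
                              subject_id=sid, db_len=db_len)
            if hit.evalue > cutoff_evalue:
                continue
            if (
                best is None
                or hit.evalue < best.evalue
                or (hit.evalue == best.evalue and hit.raw_score > best.raw_score)
            ):
                best = hit
        out[qid] = best
    return out


@dataclass
class OrthologMap:
    """Per-regulon-member best hits in a target proteome, tiered by E-value."""

    hits: dict[str, Optional[AlignmentHit]]
    tiers: dict[str, str]
    tier_bands: dict[str, float]

    def members(self) -> list[str]:
        return list(self.hits)


def assign_tier(e: Optional[float], bands: dict[str, float]) -> str:
    if e is None:
        return "absent"
    for tier in ("strong", "moderate", "weak"):
        if e <= bands[tier]:
            return tier
    return "absent"


def map_regulon(regulon_members: Sequence[tuple[str, str]],
                target_proteome: Sequence[tuple[str, str]],
                tier_bands: Optional[dict[str, float]] = None,
                scheme: Optional[ScoringScheme] = None) -> OrthologMap:
    """Tiered homology map of regulon members onto a target proteome.

    Default bands: strong <= 1e-50 < moderate <= 1e-20 < weak <= 1e-5,
    anchored to the conventional 'high similarity' cutoff of 1e-20.
    """
    bands = dict(tier_bands or DEFAULT_TIER_BANDS)
    if not regulon_members:
        return OrthologMap(hits={}, tiers={}, tier_bands=bands)
    hits = search(regulon_members, target_proteome,
                  cutoff_evalue=bands["weak"], scheme=scheme)
    tiers = {
        mid: assign_tier(h.evalue if h else None, bands)
        for mid, h in hits.items()
    }
    return OrthologMap(hits=hits, tiers=tiers, tier_bands=bands)


def hits_table(hits: Sequence[AlignmentHit]):
    """BLAST-tabular-style DataFrame of alignment hits."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query": h.query_id,
                "subject": h.subject_id,
                "identity": round(100 * h.identity_fraction, 2),
                "q_start": h.query_span[0] + 1,
                "q_end": h.query_span[1],
                "s_start": h.subject_span[0] + 1,
                "s_end": h.subject_span[1],
                "evalue": h.evalue,
                "bitscore": round(h.bit_score, 1),
            }
            for h in hits
        ]
    )
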