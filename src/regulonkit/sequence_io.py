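"""Genome and annotation I/O plus intergenic-region extraction.

Internal coordinates are 0-based half-open on the forward strand
throughout the package; all file formats (GenBank in, GFF3 out) use
their native 1-based inclusive convention and are converted at the
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class GeneFeature:
    """A stranded gene (CDS) on a genome.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``strand`` is "+" or "-".
    """

    feature_id: str
    locus_tag: str
    start: int
    end: int
    strand: str
    gene_name: Optional[str] = None
    product: Optional[str] = None
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")
        if self.translation is not None:
            if len(self.translation) < 1:
                raise ValueError(f"{self.feature_id}: empty translation")
            bad = set(self.translation) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.feature_id}: illegal amino acids {sorted(bad)}"
                )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A genome sequence with its ordered gene features."""

    accession: str
    sequence: str
    topology: str = "linear"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.accession}: topology must be linear|circular")
        self.features.sort(key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"{f.feature_id}: end {f.end} beyond genome length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_id(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def slice(self, start: int, end: int) -> str:
        """Forward-strand slice; on circular genomes end may wrap past the origin."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError(f"slice [{start}, {end}) outside linear genome of {n}")
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]


@dataclass
class IntergenicRegion:
    """Upstream region of a gene/operon, oriented 5'->3' toward the gene start.

    ``sequence`` already reads in transcription direction (minus-strand
    targets are reverse-complemented).  ``genome_start``/``genome_end``
    keep the forward-strand footprint so hits can be mapped back.
    """

    sequence: str
    anchor_gene: str
    operon_members: list[str]
    upstream_flank_len: int
    gene_prefix_len: int
    strand: str = "+"
    genome_start: int = 0
    genome_end: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != self.upstream_flank_len + self.gene_prefix_len:
            raise ValueError(
                "region length != upstream_flank_len + gene_prefix_len"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genome_coords(self, offset: int, width: int) -> tuple[int, int]:
        """Map a window [offset, offset+width) of ``sequence`` to forward coords."""
        if self.strand == "+":
            return self.genome_start + offset, self.genome_start + offset + width
        return self.genome_end - offset - width, self.genome_end - offset


@dataclass
class OperonModel:
    """Run of co-directional genes treated as one transcription unit."""

    members: list[str]
    lead_gene: str
    strand: str

    def __post_init__(self) -> None:
        if self.lead_gene not in self.members:
            raise ValueError("lead_gene must be a member")


# ---------------------------------------------------------------------------
# readers


def _feature_from_seqfeature(sf, idx: int, genome_seq: str) -> GeneFeature:
    loc = sf.location
    start = int(loc.start)
    end = int(loc.end)
    strand = "+" if loc.strand in (1, None) else "-"
    quals = sf.qualifiers
    locus = quals.get("locus_tag", [f"cds_{idx:04d}"])[0]
    gene = quals.get("gene", [None])[0]
    product = quals.get("product", [None])[0]
    translation = quals.get("translation", [None])[0]
    if translation is None:
        nt = genome_seq[start:end]
        if strand == "-":
            nt = reverse_complement(nt)
        # bacterial translation table; drop the stop codon if present
        aa = str(Seq(nt[: len(nt) // 3 * 3]).translate(table=11))
        translation = aa[:-1] if aa.endswith("*") else aa
        translation = translation.replace("*", "X") or None
    return GeneFeature(
        feature_id=locus,
        locus_tag=locus,
        start=start,
        end=end,
        strand=strand,
        gene_name=gene,
        product=product,
        translation=translation,
    )


def read_genbank(path) -> list[GenomeRecord]:
    """Read a GenBank flat file into one GenomeRecord per LOCUS.

    CDS features become :class:`GeneFeature`; coordinates are converted
    from GenBank's 1-based inclusive to 0-based half-open.  Translations
    are taken from ``/translation`` or computed with the bacterial code.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if not seq or set(seq) == {"N"} and len(seq) == 0:
            raise ParseError(f"record {rec.id}: missing ORIGIN sequence")
        try:
            seq[0]
        except Exception as exc:  # pragma: no cover - defensive
            raise ParseError(f"record {rec.id}: missing ORIGIN sequence") from exc
        topology = rec.annotations.get("topology", "linear")
        feats = []
        i = 0
        for sf in rec.features:
            if sf.type != "CDS":
                continue
            if len(sf.location.parts) > 1 and topology == "linear":
                first, last = sf.location.parts[0], sf.location.parts[-1]
                if int(first.start) > int(last.start):
                    raise ParseError(
                        f"record {rec.id}: CDS join() spans the origin of a "
                        "linear record"
                    )
            feats.append(_feature_from_seqfeature(sf, i, seq))
            i += 1
        records.append(
            GenomeRecord(accession=rec.id, sequence=seq, topology=topology,
                         features=feats)
        )
    if not records:
        raise ParseError(f"{path}: no GenBank records found (missing ORIGIN?)")
    return records


def read_fasta(path) -> list[GenomeRecord]:
    """Read FASTA DNA records; sequences are upper-cased and validated."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = [i for i, c in enumerate(seq) if c not in DNA_ALPHABET]
        if bad:
            shown = ", ".join(str(i) for i in bad[:10])
            raise ParseError(
                f"record {rec.id}: non-ACGTN characters at positions {shown}"
                + ("..." if len(bad) > 10 else "")
            )
        records.append(GenomeRecord(accession=rec.id, sequence=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# naive ORF calling

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def _orfs_in_frame(seq: str, frame: int, min_aa: int):
    """Maximal ORFs (longest start per stop) in one forward frame."""
    n = len(seq)
    out = []
    start = None
    i = frame
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if start is None:
            if codon in START_CODONS:
                start = i
        elif codon in STOP_CODONS:
            if (i + 3 - start) // 3 - 1 >= min_aa:
                out.append((start, i + 3))
            start = None
        i += 3
    return out


def call_orfs(genome: GenomeRecord, min_aa: int = 50) -> list[GeneFeature]:
    """Naive 6-frame ORF caller (stand-in for a real gene finder).

    Reports maximal ORFs with start in ATG/GTG/TTG, stop in TAA/TAG/TGA
    and >= ``min_aa`` codons before the stop.  Within one strand+frame the
    longest ORF per stop wins.  Output is flagged ``naive_orf_caller``.
    """
    if genome.features:
        raise ValueError("call_orfs expects an un-annotated genome")
    seq = genome.sequence
    n = len(seq)
    feats = []
    k = 0
    for frame in range(3):
        for s, e in _orfs_in_frame(seq, frame, min_aa):
            feats.append((s, e, "+"))
    rc = reverse_complement(seq)
    for frame in range(3):
        for s, e in _orfs_in_frame(rc, frame, min_aa):
            feats.append((n - e, n - s, "-"))
    out = []
    for s, e, strand in sorted(feats):
        nt = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
        aa = str(Seq(nt).translate(table=11))
        aa = aa[:-1] if aa.endswith("*") else aa
        out.append(
            GeneFeature(
                feature_id=f"orf_{k:04d}",
                locus_tag=f"orf_{k:04d}",
                start=s,
                end=e,
                strand=strand,
                product="naive_orf_caller",
                translation=aa or None,
            )
        )
        k += 1
    return out


# ---------------------------------------------------------------------------
# operons and upstream regions


def group_operons(genome: GenomeRecord, max_gap_nt: int = 50) -> list[OperonModel]:
    """Group consecutive same-strand genes with gaps <= ``max_gap_nt``.

    The lead gene is the 5'-most member in transcription direction.
    """
    operons: list[OperonModel] = []
    run: list[GeneFeature] = []

    def flush():
        if not run:
            return
        strand = run[0].strand
        members = [f.feature_id for f in run]
        lead = members[0] if strand == "+" else members[-1]
        operons.append(OperonModel(members=members, lead_gene=lead, strand=strand))

    for f in genome.features:
        if run and (f.strand != run[-1].strand or f.start - run[-1].end > max_gap_nt):
            flush()
            run = []
        run.append(f)
    flush()
    return operons


def extract_upstream(
    genome: GenomeRecord,
    target: OperonModel | GeneFeature,
    max_upstream_nt: int = 300,
    gene_prefix_nt: int = 20,
) -> IntergenicRegion:
    """Extract the upstream region of a gene/operon plus the first bases of
    the gene, oriented toward the start codon.

    The flank is truncated at the nearest annotated feature boundary
    (any strand).  Circular genomes wrap across the origin.
    """
    if isinstance(target, OperonModel):
        lead = genome.feature_by_id(target.lead_gene)
        members = list(target.members)
    else:
        lead = target
        members = [target.feature_id]
    n = len(genome)
    member_set = set(members)
    others = [f for f in genome.features if f.feature_id not in member_set]

    if lead.strand == "+":
        if genome.topology == "linear":
            prev_end = max(
                (f.end for f in others if f.end <= lead.start), default=0
            )
        else:
            # nearest feature end walking backwards around the circle;
            # with no other features the gene's own end bounds the wrap
            prev_end = max(
                (f.end if f.end <= lead.start else f.end - n for f in others),
                default=lead.end - n,
            )
        flank = min(max_upstream_nt, lead.start - prev_end)
        flank = max(flank, 0)
        prefix = min(gene_prefix_nt, len(lead))
        if flank + prefix == 0:
            raise ValueError(f"{lead.feature_id}: empty upstream region")
        gstart, gend = lead.start - flank, lead.start + prefix
        seq = genome.slice(gstart, gend)
        strand = "+"
    else:
        if genome.topology == "linear":
            nxt = min(
                (f.start for f in others if f.start >= lead.end), default=n
            )
        else:
            nxt = min(
                (f.start if f.start >= lead.end else f.start + n for f in others),
                default=lead.start + n,
            )
        flank = min(max_upstream_nt, nxt - lead.end)
        flank = max(flank, 0)
        prefix = min(gene_prefix_nt, len(lead))
        if flank + prefix == 0:
            raise ValueError(f"{lead.feature_id}: empty upstream region")
        gstart, gend = lead.end - prefix, lead.end + flank
        seq = reverse_complement(genome.slice(gstart, gend))
        strand = "-"
    return IntergenicRegion(
        sequence=seq,
        anchor_gene=lead.feature_id,
        operon_members=members,
        upstream_flank_len=flank,
        gene_prefix_len=prefix,
        strand=strand,
        # raw coordinates: may extend past [0, n) on circular genomes, in
        # which case callers take them modulo the genome length
        genome_start=gstart,
        genome_end=gend,
    )


# ---------------------------------------------------------------------------
# GFF3


def _gff_fields(ann, genome_len: Optional[int]):
    """Return (source, type, start0, end0, score, strand, attrs) for an annotation."""
    # imported lazily to avoid circular imports
    from . import motif_core, promoter_elements

    if isinstance(ann, GeneFeature):
        attrs = {"ID": ann.feature_id, "locus_tag": ann.locus_tag}
        if ann.gene_name:
            attrs["Name"] = ann.gene_name
        src = "naive_orf_caller" if ann.product == "naive_orf_caller" else "annotation"
        return src, "gene", ann.start, ann.end, ".", ann.strand, attrs
    if isinstance(ann, motif_core.MotifHit):
        attrs = {
            "Name": ann.tf_name,
            "pvalue": f"{ann.pvalue:.1e}",
            "matched_seq": ann.matched_seq,
        }
        return "tfbs_scan", "TFBS", ann.start, ann.end, f"{ann.score:.3f}", ann.strand, attrs
    if isinstance(ann, promoter_elements.PromoterCall):
        attrs = {"complete": "yes" if ann.complete else "no"}
        if ann.spacer_nt is not None:
            attrs["spacer"] = str(ann.spacer_nt)
        if ann.tss is not None:
            attrs["tss"] = str(ann.tss + 1)
        s = min(
            x.start for x in (ann.minus35_hit, ann.minus10_hit) if x is not None
        )
        e = max(x.end for x in (ann.minus35_hit, ann.minus10_hit) if x is not None)
        typ = "promoter" if ann.complete else (
            "minus35" if ann.minus10_hit is None else "minus10"
        )
        return "promoter_scan", typ, s, e, f"{ann.combined_score:.3f}", ann.strand, attrs
    if isinstance(ann, promoter_elements.RBSCall):
        attrs = {
            "matched_seq": ann.matched_seq,
            "spacing_to_start": str(ann.spacing_to_start),
        }
        return "rbs_scan", "RBS", ann.start, ann.end, f"{ann.score:.3f}", ann.strand, attrs
    if isinstance(ann, promoter_elements.TerminatorCall):
        attrs = {
            "stem_len": str(ann.stem_len),
            "loop_len": str(ann.loop_len),
            "tail_score": f"{ann.tail_score:.3f}",
        }
        return (
            "simplified-transterm",
            "terminator",
            ann.start,
            ann.end,
            f"{ann.total_score:.3f}",
            ann.strand,
            attrs,
        )
    raise TypeError(f"cannot write {type(ann).__name__} to GFF")


def write_gff(annotations: Iterable, path, seqid: str = "genome",
              genome_len: Optional[int] = None) -> None:
    """Write annotations as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for ann in annotations:
        src, typ, s0, e0, score, strand, attrs = _gff_fields(ann, genome_len)
        if s0 < 0 or (genome_len is not None and e0 > genome_len):
            raise ValueError(f"annotation [{s0},{e0}) outside genome")
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
        lines.append(
            "\t".join(
                [seqid, src, typ, str(s0 + 1), str(e0), str(score), strand, ".", attr_s]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff(path) -> list[dict]:
    """Parse a GFF3 file back into dicts with 0-based half-open coordinates."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GFF columns")
            attrs = {}
            if parts[8] != ".":
                for kv in parts[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            out.append(
                {
                    "seqid": parts[0],
                    "source": parts[1],
                    "type": parts[2],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "score": None if parts[5] == "." else float(parts[5]),
                    "strand": parts[6],
                    "attributes": attrs,
                }
            )
    return out
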