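"""The all-in-one mining flow: homology channel + TFBS channel, de-novo
motif refinement, and full intergenic annotation.

Candidate transcription units are gathered through two independent
evidence channels — protein homology of known regulon members against
the target proteome (pool Ia) and hits of the known TFBS in upstream
regions (pool Ib).  The pooled candidates' upstream regions then go
through motif discovery, and only units carrying a site of the refined
motif survive into the final predicted regulon (pool II), which is
annotated with promoters, RBSs and terminators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from . import homology, motif_core, motif_discovery, promoter_elements
from .motif_core import Background, MotifHit, TFBSLibraryEntry, make_library_entry, scan
from .motif_discovery import DiscoveredMotif, DiscoveryConfig, discover
from .promoter_elements import (
    PromoterCall,
    RBSCall,
    TerminatorCall,
    default_promoter_model,
    find_promoters,
    find_rbs,
    find_terminators,
)
from .sequence_io import (
    GenomeRecord,
    IntergenicRegion,
    OperonModel,
    extract_upstream,
    group_operons,
    write_gff,
)
from .simulate import (  # noqa: F401  (re-exported surface)
    SimulatedGenome,
    SimulatedGenomeSpec,
    simulate_genome,
)


@dataclass
class RegulonDefinition:
    """A known regulon: its TF, member proteins, and (optionally) the TFBS."""

    tf_name: str
    source_organism: str
    member_proteins: list[tuple[str, str]]  # (id, aa sequence)
    tfbs: Optional[TFBSLibraryEntry] = None

    def __post_init__(self) -> None:
        if not self.member_proteins:
            raise ValueError("regulon needs at least one member protein")
        if self.tfbs is not None and not (6 <= self.tfbs.width <= 18):
            raise ValueError("TFBS width must be within [6, 18]")


@dataclass
class PipelineConfig:
    homology_cutoff: float = 1e-20
    tfbs_pvalue: float = 1e-5
    refined_motif_pvalue: float = 1e-5
    max_upstream_nt: int = 300
    gene_prefix_nt: int = 20
    operon_gap_nt: int = 50
    pool_mode: str = "union"  # or "intersection"
    gram: str = "positive"
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    annotate_pool_II: bool = True

    def __post_init__(self) -> None:
        if self.pool_mode not in ("union", "intersection"):
            raise ValueError("pool_mode must be union|intersection")


@dataclass
class RegulonPrediction:
    target_genome: str
    pool_Ia: list[str]  # operon ids (lead-gene feature ids) with homology evidence
    pool_Ib: list[str]  # operon ids with TFBS evidence
    pool_II: list[str]  # final operon ids
    pool_II_genes: list[str]  # member genes of pool_II operons
    refined_motif: Optional[DiscoveredMotif]
    evidence: pd.DataFrame  # one row per candidate operon
    annotations: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set(self.pool_Ia) | set(self.pool_Ib)
        if not set(self.pool_II) <= allowed:
            raise ValueError("pool_II must be a subset of pool_Ia | pool_Ib")


def _operon_regions(genome: GenomeRecord, operons: Sequence[OperonModel],
                    cfg: PipelineConfig) -> dict[str, IntergenicRegion]:
    regions = {}
    for op in operons:
        try:
            regions[op.lead_gene] = extract_upstream(
                genome, op, cfg.max_upstream_nt, cfg.gene_prefix_nt
            )
        except ValueError:
            continue  # no upstream room: unit skipped from scanning
    return regions


def intergenic_background(regions: Sequence[IntergenicRegion]) -> Background:
    """Background base composition estimated from upstream regions, the
    mining analogue of an all-intergenic-regions background model."""
    return Background.from_sequences([r.sequence for r in regions])


def mine_regulon(regulon: RegulonDefinition, target: GenomeRecord,
                 cfg: Optional[PipelineConfig] = None) -> RegulonPrediction:
    """Transfer a known regulon onto a target genome.

    Pool Ia: operons with a member-protein homology hit at the cutoff.
    Pool Ib: operons whose upstream region carries the known TFBS.
    The pooled regions feed motif discovery; pool II keeps the operons
    whose region carries a site of the refined motif at the gate
    p-value, annotated with promoter/RBS/terminator calls.
    """
    cfg = cfg or PipelineConfig()
    if not target.features:
        raise ValueError("target genome has no gene features")
    operons = group_operons(target, cfg.operon_gap_nt)
    regions = _operon_regions(target, operons, cfg)
    bg = intergenic_background(list(regions.values()))

    gene_to_operon = {
        gid: op.lead_gene for op in operons for gid in op.members
    }
    proteome = [
        (f.feature_id, f.translation)
        for f in target.features
        if f.translation
    ]

    # --- channel Ia: protein homology
    hits = homology.search(regulon.member_proteins, proteome,
                           cutoff_evalue=cfg.homology_cutoff)
    pool_Ia: set[str] = set()
    member_hits: dict[str, list] = {}
    for mid, hit in hits.items():
        if hit is None:
            continue
        opid = gene_to_operon.get(hit.subject_id)
        if opid is not None:
            pool_Ia.add(opid)
            member_hits.setdefault(opid, []).append(hit)

    if regulon.tfbs is None and not pool_Ia:
        raise ValueError(
            "no evidence channels: regulon lacks a TFBS and no homology hits"
        )

    # --- channel Ib: known-TFBS scan
    pool_Ib: set[str] = set()
    tfbs_hits: dict[str, list[MotifHit]] = {}
    if regulon.tfbs is not None:
        entry = regulon.tfbs
        if cfg.tfbs_pvalue != entry.cutoff_pvalue:
            entry = make_library_entry(
                entry.tf_name, entry.pspm, bg, organism=entry.organism,
                cutoff_pvalue=cfg.tfbs_pvalue, enforce_width=False,
            )
        for opid, region in regions.items():
            h = scan(region.sequence, entry, bg, both_strands=True)
            if h:
                pool_Ib.add(opid)
                tfbs_hits[opid] = h

    if cfg.pool_mode == "union":
        candidates = sorted(pool_Ia | pool_Ib)
    else:
        candidates = sorted(pool_Ia & pool_Ib)

    # --- motif refinement over candidate upstream regions
    refined: Optional[DiscoveredMotif] = None
    pool_II: list[str] = []
    refined_hits: dict[str, list[MotifHit]] = {}
    cand_regions = [(c, regions[c]) for c in candidates if c in regions]
    if len(cand_regions) >= 2:
        dcfg = cfg.discovery
        if regulon.tfbs is not None:
            w = regulon.tfbs.width
            dcfg = replace(dcfg, width_min=max(dcfg.width_min, w - 2),
                           width_max=min(dcfg.width_max, w + 2))
        found = discover([r.sequence for _, r in cand_regions], bg, dcfg)
        if found:
            refined = found[0]
            entry = make_library_entry(
                f"{regulon.tf_name}_refined", refined.pspm, bg,
                cutoff_pvalue=cfg.refined_motif_pvalue, enforce_width=False,
            )
            for opid, region in cand_regions:
                h = scan(region.sequence, entry, bg, both_strands=True)
                if h:
                    pool_II.append(opid)
                    refined_hits[opid] = h
    elif len(cand_regions) == 1:
        # too few regions for discovery: fall back to the known-TFBS gate
        opid = cand_regions[0][0]
        if opid in tfbs_hits or regulon.tfbs is None:
            pool_II = [opid]

    # --- annotate final members
    annotations: dict[str, list] = {}
    if cfg.annotate_pool_II and pool_II:
        model = default_promoter_model(cfg.gram, bg)
        for opid in pool_II:
            region = regions[opid]
            anns: list = []
            anns.extend(find_promoters(region, model, bg))
            rbs = find_rbs(region, bg=bg)
            if rbs:
                anns.append(rbs)
            anns.extend(find_terminators(region.sequence, "+"))
            annotations[opid] = anns

    op_by_lead = {op.lead_gene: op for op in operons}
    pool_II_genes = sorted(
        gid for opid in pool_II for gid in op_by_lead[opid].members
    )
    rows = []
    for opid in candidates:
        best_hit = min(
            (h for h in member_hits.get(opid, [])), key=lambda h: h.evalue,
            default=None,
        )
        best_tfbs = min(
            (h for h in tfbs_hits.get(opid, [])), key=lambda h: h.pvalue,
            default=None,
        )
        best_ref = min(
            (h for h in refined_hits.get(opid, [])), key=lambda h: h.pvalue,
            default=None,
        )
        rows.append(
            {
                "operon": opid,
                "members": ",".join(op_by_lead[opid].members),
                "homology_evalue": best_hit.evalue if best_hit else None,
                "tfbs_pvalue": best_tfbs.pvalue if best_tfbs else None,
                "refined_motif_pvalue": best_ref.pvalue if best_ref else None,
                "in_pool_Ia": opid in pool_Ia,
                "in_pool_Ib": opid in pool_Ib,
                "in_pool_II": opid in pool_II,
            }
        )
    evidence = pd.DataFrame(
        rows,
        columns=["operon", "members", "homology_evalue", "tfbs_pvalue",
                 "refined_motif_pvalue", "in_pool_Ia", "in_pool_Ib",
                 "in_pool_II"],
    )
    return RegulonPrediction(
        target_genome=target.accession,
        pool_Ia=sorted(pool_Ia),
        pool_Ib=sorted(pool_Ib),
        pool_II=sorted(pool_II),
        pool_II_genes=pool_II_genes,
        refined_motif=refined,
        evidence=evidence,
        annotations=annotations,
    )


def mine_multi(regulon: RegulonDefinition,
               targets: Sequence[GenomeRecord],
               tier_bands: Optional[dict[str, float]] = None
               ) -> pd.DataFrame:
    """Tiered member-by-genome ortholog matrix across several targets.

    Rows are regulon members, one column pair per genome: the homology
    tier and the best-hit gene id — the tabular twin of a regulon
    conservation heat-grid.
    """
    if not targets:
        raise ValueError("need at least one target genome")
    data: dict[str, list] = {}
    index = [mid for mid, _ in regulon.member_proteins]
    for g in targets:
        proteome = [
            (f.feature_id, f.translation) for f in g.features if f.translation
        ]
        omap = homology.map_regulon(regulon.member_proteins, proteome,
                                    tier_bands=tier_bands)
        data[f"{g.accession}:tier"] = [omap.tiers[m] for m in index]
        data[f"{g.accession}:best_hit"] = [
            omap.hits[m].subject_id if omap.hits[m] else None for m in index
        ]
    return pd.DataFrame(data, index=index)


@dataclass
class GenomeAnnotation:
    """Genome-forward annotations of all upstream regions."""

    genome: str
    genome_len: int
    tfbs: list[MotifHit]
    promoters: list[PromoterCall]
    rbs: list[RBSCall]
    terminators: list[TerminatorCall]

    def all_records(self) -> list:
        return [*self.tfbs, *self.promoters, *self.rbs, *self.terminators]

    def to_gff(self, path) -> None:
        write_gff(self.all_records(), path, seqid=self.genome)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for h in self.tfbs:
            rows.append({"type": "TFBS", "name": h.tf_name, "start": h.start,
                         "end": h.end, "strand": h.strand, "score": h.score,
                         "pvalue": h.pvalue})
        for p in self.promoters:
            rows.append({"type": "promoter" if p.complete else "promoter_partial",
                         "name": "sigma70", "start": p.start, "end": p.end,
                         "strand": p.strand, "score": p.combined_score,
                         "pvalue": None})
        for r in self.rbs:
            rows.append({"type": "RBS", "name": r.matched_seq, "start": r.start,
                         "end": r.end, "strand": r.strand, "score": r.score,
                         "pvalue": None})
        for t in self.terminators:
            rows.append({"type": "terminator", "name": f"stem{t.stem_len}",
                         "start": t.start, "end": t.end, "strand": t.strand,
                         "score": t.total_score, "pvalue": None})
        return pd.DataFrame(
            rows, columns=["type", "name", "start", "end", "strand", "score",
                           "pvalue"],
        )


def _map_hit(region: IntergenicRegion, start: int, end: int, strand: str,
             n: int) -> tuple[int, int, str]:
    gs, ge = region.to_genome_coords(start, end - start)
    gs %= n
    ge = gs + (end - start)
    if strand == "-":
        out_strand = "-" if region.strand == "+" else "+"
    else:
        out_strand = region.strand
    return gs, ge, out_strand


def annotate_intergenic(genome: GenomeRecord,
                        library: Sequence[TFBSLibraryEntry],
                        cfg: Optional[PipelineConfig] = None
                        ) -> GenomeAnnotation:
    """Annotate every operon's upstream region with library TFBS hits,
    promoter calls, RBSs and terminators, mapped to forward coordinates."""
    cfg = cfg or PipelineConfig()
    operons = group_operons(genome, cfg.operon_gap_nt)
    regions = _operon_regions(genome, operons, cfg)
    n = len(genome)
    if regions:
        bg = intergenic_background(list(regions.values()))
    else:
        bg = Background.uniform()
    model = default_promoter_model(cfg.gram, bg)
    out_tfbs: list[MotifHit] = []
    out_prom: list[PromoterCall] = []
    out_rbs: list[RBSCall] = []
    out_term: list[TerminatorCall] = []
    for region in regions.values():
        for entry in library:
            for h in scan(region.sequence, entry, bg, both_strands=True):
                gs, ge, st = _map_hit(region, h.start, h.end, h.strand, n)
                out_tfbs.append(
                    MotifHit(h.tf_name, gs, ge, st, h.score, h.pvalue,
                             h.matched_seq)
                )
        for p in find_promoters(region, model, bg):
            def remap(hit):
                if hit is None:
                    return None
                gs, ge, st = _map_hit(region, hit.start, hit.end, "+", n)
                return MotifHit(hit.tf_name, gs, ge, st, hit.score,
                                hit.pvalue, hit.matched_seq)
            tss = None
            if p.tss is not None:
                tss = _map_hit(region, p.tss, p.tss + 1, "+", n)[0]
            out_prom.append(
                PromoterCall(
                    minus35_hit=remap(p.minus35_hit),
                    minus10_hit=remap(p.minus10_hit),
                    spacer_nt=p.spacer_nt, complete=p.complete,
                    combined_score=p.combined_score, tss=tss,
                    strand=region.strand,
                )
            )
        r = find_rbs(region, bg=bg)
        if r is not None:
            gs, ge, st = _map_hit(region, r.start, r.end, "+", n)
            out_rbs.append(
                RBSCall(gs, ge, r.matched_seq, r.score, r.spacing_to_start, st)
            )
        for t in find_terminators(region.sequence, "+"):
            gs, ge, st = _map_hit(region, t.start, t.end, "+", n)
            out_term.append(
                TerminatorCall(gs, ge, st, t.stem_len, t.loop_len,
                               t.hairpin_score, t.tail_score, t.total_score)
            )
    return GenomeAnnotation(
        genome=genome.accession, genome_len=n, tfbs=out_tfbs,
        promoters=out_prom, rbs=out_rbs, terminators=out_term,
    )
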