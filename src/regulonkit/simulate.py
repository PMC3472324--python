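"""Synthetic bacterial genome generator with planted ground truth.

Emulates, at desk scale, the structures the mining pipeline consumes: a
circular genome of transcription units on both strands, occasional
two-gene operons, a regulon protein family diverged from a common
ancestor, TFBS instances sampled from a motif and planted upstream of
the regulon genes, and optional sigma70 promoter boxes and
Shine-Dalgarno sites.  Every planted element is recorded in truth
tables, and the whole construction is a pure function of ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .motif_core import PSPM, Background, TFBSLibraryEntry, make_library_entry
from .sequence_io import GeneFeature, GenomeRecord, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

# CodY-box-like degenerate consensus used as the default planted motif
DEFAULT_TFBS_CONSENSUS = "AATTTTCAGAAAATT"


def default_planted_pspm() -> PSPM:
    """Sharp 15-bp motif with one 50/50 degenerate position (position 7),
    mimicking a W in an otherwise fixed consensus."""
    w = len(DEFAULT_TFBS_CONSENSUS)
    mat = np.zeros((w, 4))
    for j, b in enumerate(DEFAULT_TFBS_CONSENSUS):
        mat[j, BASES.index(b)] = 1.0
    mat[7] = [0.5, 0.0, 0.0, 0.5]  # A/T
    return PSPM(mat, site_count=0)


@dataclass
class SimulatedGenomeSpec:
    n_genes: int = 50
    mean_gene_len: int = 360  # nt, ~120 codons
    mean_intergenic_len: int = 200
    regulon_size: int = 8
    planted_tfbs: PSPM = field(default_factory=default_planted_pspm)
    tfbs_mutation_rate: float = 0.05  # per planted-site position
    plant_promoters: bool = True
    plant_rbs: bool = True
    homolog_divergence: float = 0.2  # aa substitutions per site
    operon_fraction: float = 0.2  # chance a unit carries a second gene
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.regulon_size > self.n_genes:
            raise ValueError("regulon_size cannot exceed n_genes")
        for r in (self.tfbs_mutation_rate, self.homolog_divergence,
                  self.operon_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SimulatedGenome:
    genome: GenomeRecord
    regulon_members: list[str]  # feature ids of planted regulon genes
    tfbs_truth: pd.DataFrame  # feature_id, start, end, strand, site
    promoter_truth: pd.DataFrame  # feature_id, m35_start, m10_start, tss, strand
    source_regulon_proteins: list[tuple[str, str]]
    tfbs_entry: TFBSLibraryEntry


def _back_table() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    back: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        back.setdefault(aa, []).append(codon)
    for aa in back:
        back[aa].sort()
    return back


_BACK = _back_table()
_STOPS = sorted(CodonTable.unambiguous_dna_by_id[11].stop_codons)


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(rng.choice(list(AA20), size=n_aa))


def _mutate_protein(rng: np.random.Generator, prot: str, rate: float) -> str:
    out = []
    for aa in prot:
        if rng.random() < rate:
            alt = AA20.replace(aa, "")
            out.append(alt[rng.integers(len(alt))])
        else:
            out.append(aa)
    return "".join(out)


def _back_translate(rng: np.random.Generator, prot: str) -> str:
    codons = [ _BACK[aa][rng.integers(len(_BACK[aa]))] for aa in prot ]
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(codons) + stop


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _sample_site(rng: np.random.Generator, pspm: PSPM, mut_rate: float) -> str:
    site = []
    for row in pspm.matrix:
        b = BASES[rng.choice(4, p=row / row.sum())]
        if rng.random() < mut_rate:
            alt = BASES.replace(b, "")
            b = alt[rng.integers(3)]
        site.append(b)
    return "".join(site)


def simulate_genome(spec: SimulatedGenomeSpec) -> SimulatedGenome:
    """Build a circular genome with planted regulon, TFBS, promoter and RBS
    elements, plus the matching source-organism regulon definition."""
    rng = np.random.default_rng(spec.rng_seed)
    w_tfbs = spec.planted_tfbs.width

    ancestor = _random_protein(rng, max(50, spec.mean_gene_len // 3 - 1))

    # which genes belong to the regulon (each as its own transcription unit)
    regulon_idx = set(
        rng.choice(spec.n_genes, size=spec.regulon_size, replace=False).tolist()
    )

    parts: list[str] = []
    pos = 0
    features: list[GeneFeature] = []
    regulon_ids: list[str] = []
    tfbs_rows = []
    prom_rows = []

    gi = 0
    while gi < spec.n_genes:
        is_reg = gi in regulon_idx
        strand = "+" if rng.random() < 0.5 else "-"
        n_in_unit = (
            2 if (not is_reg and gi + 1 < spec.n_genes
                  and gi + 1 not in regulon_idx
                  and rng.random() < spec.operon_fraction)
            else 1
        )
        # the floor keeps every planted element inside its own unit's
        # upstream scan window and out of the neighbouring unit's
        flank_len = max(190, int(rng.normal(spec.mean_intergenic_len, 20)))
        flank = list(_random_dna(rng, flank_len))

        planted: dict[str, tuple] = {}
        if spec.plant_rbs:
            # Shine-Dalgarno 7 nt before the start codon
            s = flank_len - 7 - 6
            flank[s : s + 6] = "AGGAGG"
        if is_reg:
            site = _sample_site(rng, spec.planted_tfbs, spec.tfbs_mutation_rate)
            s = flank_len - 45 - w_tfbs
            flank[s : s + w_tfbs] = site
            planted["tfbs"] = (s, site)
        if spec.plant_promoters:
            m10 = flank_len - 75
            m35 = m10 - 17 - 6
            flank[m35 : m35 + 6] = "TTGACA"
            flank[m10 : m10 + 6] = "TATAAT"
            planted["promoter"] = (m35, m10)

        genes_nt: list[tuple[str, str, bool]] = []  # (nt, protein, is_regulon)
        for k in range(n_in_unit):
            if is_reg:
                prot = _mutate_protein(rng, ancestor, spec.homolog_divergence)
            else:
                n_aa = max(50, int(rng.normal(spec.mean_gene_len / 3, 15)))
                prot = _random_protein(rng, n_aa)
            genes_nt.append((_back_translate(rng, prot), prot, is_reg))

        unit = "".join(flank)
        gene_local: list[tuple[int, int, str, bool]] = []
        cursor = len(unit)
        for k, (nt, prot, reg_flag) in enumerate(genes_nt):
            if k > 0:
                gap = _random_dna(rng, 20)
                unit += gap
                cursor += 20
            unit += nt
            gene_local.append((cursor, cursor + len(nt), prot, reg_flag))
            cursor += len(nt)
        U = len(unit)
        if strand == "-":
            unit_seq = reverse_complement(unit)
        else:
            unit_seq = unit

        def fwd(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return pos + a, pos + b
            return pos + U - b, pos + U - a

        for (gs, ge, prot, reg_flag) in gene_local:
            fid = f"gene_{gi:04d}"
            s, e = fwd(gs, ge)
            features.append(
                GeneFeature(feature_id=fid, locus_tag=fid, start=s, end=e,
                            strand=strand, translation=prot)
            )
            if reg_flag:
                regulon_ids.append(fid)
            gi += 1
        lead_id = f"gene_{gi - n_in_unit:04d}"
        if "tfbs" in planted:
            s_loc, site = planted["tfbs"]
            s, e = fwd(s_loc, s_loc + w_tfbs)
            tfbs_rows.append(
                {"feature_id": lead_id, "start": s, "end": e,
                 "strand": strand, "site": site}
            )
        if "promoter" in planted:
            m35_loc, m10_loc = planted["promoter"]
            m35_s, _ = fwd(m35_loc, m35_loc + 6)
            m10_s, _ = fwd(m10_loc, m10_loc + 6)
            tss_loc = m10_loc + 10
            tss_s, _ = fwd(tss_loc, tss_loc + 1)
            prom_rows.append(
                {"feature_id": lead_id, "m35_start": m35_s,
                 "m10_start": m10_s, "tss": tss_s, "strand": strand}
            )
        parts.append(unit_seq)
        pos += U

    # closing intergenic stretch so the last gene does not touch the origin
    parts.append(_random_dna(rng, max(120, spec.mean_intergenic_len)))
    sequence = "".join(parts)
    genome = GenomeRecord(
        accession=f"SIM_{spec.rng_seed:08d}", sequence=sequence,
        topology="circular", features=features,
    )

    source = [
        (f"src_{i:03d}", _mutate_protein(rng, ancestor, spec.homolog_divergence))
        for i in range(spec.regulon_size)
    ]
    entry = make_library_entry(
        "SimTF",
        [_sample_site(rng, spec.planted_tfbs, spec.tfbs_mutation_rate)
         for _ in range(20)],
        Background.uniform(),
        organism="synthetic",
    )
    return SimulatedGenome(
        genome=genome,
        regulon_members=sorted(set(regulon_ids)),
        tfbs_truth=pd.DataFrame(
            tfbs_rows, columns=["feature_id", "start", "end", "strand", "site"]
        ),
        promoter_truth=pd.DataFrame(
            prom_rows,
            columns=["feature_id", "m35_start", "m10_start", "tss", "strand"],
        ),
        source_regulon_proteins=source,
        tfbs_entry=entry,
    )
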