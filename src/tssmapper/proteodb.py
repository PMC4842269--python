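"""TSS-guided proteogenomic search-database construction.

A protein search database built only from the reference annotation misses
proteins whose genes were mis-annotated or never annotated.  Guided by the
TSS map, this module emits, alongside every annotated protein:

* shorter N-terminal variants starting at internal in-frame start codons
  that have a supporting TSS at most 200 nt upstream,
* longer N-terminal variants starting at upstream in-frame start codons
  (no intervening stop) present in an alternate annotation or supported by
  a TSS,
* novel ORFs present only in the alternate annotation, and
* in-silico translations downstream of internal TSSs: from every start
  codon whose first base lies within 200 nt of the iTSS, in any reading
  frame, to the next stop codon.

Duplicate amino-acid sequences are collapsed with provenance retained in
the FASTA header.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Data import CodonTable

from .categorizer import UtrConfig, categorize
from .io_formats import GeneModel, Replicon
from .promoter import revcomp

logger = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_MAP = dict(_TABLE11.forward_table)
STOP_CODONS = frozenset(_TABLE11.stop_codons)
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
ITSS_DOWNSTREAM_MAX = 200  # nt from iTSS to the first base of a start codon


@dataclass
class ProteoConfig:
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    itss_downstream_max: int = ITSS_DOWNSTREAM_MAX
    tss_upstream_max: int = 200   # TSS support window for shorter/longer variants
    min_protein_length: int = 10  # aa, applied to iTSS translations only


@dataclass
class ProteinEntry:
    """One database entry with genomic provenance."""

    id: str
    source_class: str            # annotated | shorter | longer | novel | itss_orf
    source: str                  # locus_tag or TSS id
    replicon_id: str
    strand: str
    start: int                   # 1-based inclusive, genomic
    end: int
    sequence: str                # amino acids, initiator always M, no stop
    extra_provenance: list[str] = field(default_factory=list)

    def header(self) -> str:
        head = (f"{self.id}|{self.source_class}|{self.source}|"
                f"{self.replicon_id}:{self.start}-{self.end}({self.strand})")
        if self.extra_provenance:
            head += " " + ";".join(self.extra_provenance)
        return head


def translate_orf(nt: str, *, initiator_met: bool = True) -> str:
    """Translate an in-frame nucleotide sequence, stopping at the first stop.

    Bacterial initiator codons (ATG/GTG/TTG and any codon the caller deems a
    start) are rendered as M, matching proteomic N-terminus conventions.
    """
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        if codon in STOP_CODONS:
            break
        aa.append(_CODON_MAP.get(codon, "X"))
    if aa and initiator_met:
        aa[0] = "M"
    return "".join(aa)


def _gene_nt(rep: Replicon, start: int, end: int, strand: str) -> str:
    seq = rep.sequence[start - 1:end]
    return seq if strand == "+" else revcomp(seq)


def _codon_at(rep: Replicon, pos: int, strand: str) -> str | None:
    """Codon whose first base (in transcription direction) is at `pos`."""
    if strand == "+":
        if pos + 2 > rep.length:
            return None
        return rep.sequence[pos - 1:pos + 2]
    if pos - 2 < 1:
        return None
    return revcomp(rep.sequence[pos - 3:pos])


def _translate_from(rep: Replicon, pos: int, strand: str) -> tuple[str, int]:
    """Translate from a start-codon position to the next stop (or the edge).

    Returns (protein, genomic coordinate of the last included base).
    """
    aa = []
    p = pos
    while True:
        codon = _codon_at(rep, p, strand)
        if codon is None or codon in STOP_CODONS:
            break
        aa.append(_CODON_MAP.get(codon, "X"))
        p = p + 3 if strand == "+" else p - 3
    if aa:
        aa[0] = "M"
    last = p - 1 if strand == "+" else p + 1
    return "".join(aa), last


def _tss_supported(pos: int, strand: str, tss_positions: list[int],
                   max_upstream: int) -> bool:
    """Is there a same-strand TSS 0..max_upstream nt upstream of `pos`?"""
    for t in tss_positions:
        d = pos - t if strand == "+" else t - pos
        if 0 <= d <= max_upstream:
            return True
    return False


def build_search_db(replicons: dict[str, Replicon], genes: Sequence[GeneModel],
                    tss_list: Sequence, alt_genes: Sequence[GeneModel] = (),
                    config: ProteoConfig | None = None) -> list[ProteinEntry]:
    """Assemble the extended protein search database.

    ``tss_list`` records need position/strand/replicon_id/id; categories are
    recomputed locally where needed, so the list may come straight from the
    SVM stage.  Entries with identical sequences are collapsed; provenance of
    the collapsed duplicates is kept on the surviving entry.
    """
    cfg = config or ProteoConfig()
    entries: list[ProteinEntry] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"prot_{counter}"

    tss_by_strand: dict[tuple[str, str], list[int]] = {}
    for t in tss_list:
        tss_by_strand.setdefault((t.replicon_id, t.strand), []).append(t.position)

    gene_keys = {(g.replicon_id, g.strand, g.start, g.end) for g in genes}

    def check_bounds(g: GeneModel) -> None:
        rep = replicons.get(g.replicon_id)
        if rep is None:
            raise ValueError(f"gene {g.locus_tag}: unknown replicon {g.replicon_id!r}")
        if g.end > rep.length:
            raise ValueError(f"gene {g.locus_tag}: beyond replicon end")

    # (a) annotated proteins, (b) shorter variants, (c) longer variants
    for g in genes:
        if g.kind != "CDS":
            continue
        check_bounds(g)
        rep = replicons[g.replicon_id]
        nt = _gene_nt(rep, g.start, g.end, g.strand)
        prot = translate_orf(nt)
        if "*" in prot:
            raise AssertionError("translate_orf must stop at the first stop codon")
        if 3 * (len(prot) + 1) < len(nt):  # internal stop before the annotated end
            logger.warning("gene %s: internal stop codon, emitting truncated protein",
                           g.locus_tag)
        if prot:
            last = (g.start + 3 * len(prot) - 1 if g.strand == "+"
                    else g.end - 3 * len(prot) + 1)
            entries.append(ProteinEntry(new_id(), "annotated", g.locus_tag,
                                        g.replicon_id, g.strand,
                                        g.start if g.strand == "+" else last,
                                        last if g.strand == "+" else g.end, prot))
        tss_here = tss_by_strand.get((g.replicon_id, g.strand), [])

        # shorter: internal in-frame starts with TSS support
        n_codons = len(nt) // 3
        for ci in range(1, n_codons - 1):
            codon = nt[3 * ci:3 * ci + 3]
            if codon in STOP_CODONS:
                break  # annotated frame ended early; no shorter forms past a stop
            if codon not in cfg.start_codons:
                continue
            gpos = g.start + 3 * ci if g.strand == "+" else g.end - 3 * ci
            if not _tss_supported(gpos, g.strand, tss_here, cfg.tss_upstream_max):
                continue
            prot_s = translate_orf(nt[3 * ci:])
            if not prot_s:
                continue
            s, e = ((gpos, g.end) if g.strand == "+" else (g.start, gpos))
            entries.append(ProteinEntry(new_id(), "shorter", g.locus_tag,
                                        g.replicon_id, g.strand, s, e, prot_s))

        # longer: upstream in-frame starts, no intervening stop, supported by
        # the alternate annotation or by a TSS
        alt_starts = {(a.start if a.strand == "+" else a.end)
                      for a in alt_genes
                      if a.replicon_id == g.replicon_id and a.strand == g.strand
                      and a.three_prime == g.three_prime}
        p = g.five_prime
        while True:
            p = p - 3 if g.strand == "+" else p + 3
            codon = _codon_at(replicons[g.replicon_id], p, g.strand)
            if codon is None or codon in STOP_CODONS:
                break
            if codon in cfg.start_codons:
                supported = (p in alt_starts or
                             _tss_supported(p, g.strand, tss_here, cfg.tss_upstream_max))
                if supported:
                    if g.strand == "+":
                        nt_long = _gene_nt(rep, p, g.end, "+")
                        s, e = p, g.end
                    else:
                        nt_long = _gene_nt(rep, g.start, p, "-")
                        s, e = g.start, p
                    prot_l = translate_orf(nt_long)
                    if prot_l:
                        entries.append(ProteinEntry(new_id(), "longer", g.locus_tag,
                                                    g.replicon_id, g.strand,
                                                    s, e, prot_l))

    # (d) novel ORFs from the alternate annotation only
    for a in alt_genes:
        if a.kind != "CDS":
            continue
        if (a.replicon_id, a.strand, a.start, a.end) in gene_keys:
            continue
        check_bounds(a)
        rep = replicons[a.replicon_id]
        prot = translate_orf(_gene_nt(rep, a.start, a.end, a.strand))
        if prot:
            entries.append(ProteinEntry(new_id(), "novel", a.locus_tag,
                                        a.replicon_id, a.strand, a.start, a.end, prot))

    # (e) iTSS translations: every start codon within 200 nt downstream,
    # any reading frame, translated to the next stop
    utr_cfg = UtrConfig()
    for t in tss_list:
        rep = replicons[t.replicon_id]
        cats = categorize(t.position, t.strand, genes, utr_cfg, t.replicon_id)
        if not any(a.category == "iTSS" for a in cats):
            continue
        seen_starts: set[int] = set()
        for d in range(0, cfg.itss_downstream_max + 1):
            pos = t.position + d if t.strand == "+" else t.position - d
            if pos < 1 or pos > rep.length or pos in seen_starts:
                continue
            codon = _codon_at(rep, pos, t.strand)
            if codon is None or codon not in cfg.start_codons:
                continue
            seen_starts.add(pos)
            prot, last = _translate_from(rep, pos, t.strand)
            if len(prot) < cfg.min_protein_length:
                continue
            s, e = (pos, last) if t.strand == "+" else (last, pos)
            entries.append(ProteinEntry(new_id(), "itss_orf", t.id or f"tss@{t.position}",
                                        t.replicon_id, t.strand, s, e, prot))

    return collapse_duplicates(entries)


def collapse_duplicates(entries: list[ProteinEntry]) -> list[ProteinEntry]:
    """Collapse entries with identical sequences, keeping all provenance."""
    by_seq: dict[str, ProteinEntry] = {}
    order: list[str] = []
    for e in entries:
        if e.sequence not in by_seq:
            by_seq[e.sequence] = e
            order.append(e.sequence)
        else:
            keeper = by_seq[e.sequence]
            keeper.extra_provenance.append(
                f"{e.source_class}|{e.source}|{e.replicon_id}:{e.start}-{e.end}({e.strand})")
    return [by_seq[s] for s in order]


def write_fasta_db(entries: Sequence[ProteinEntry], path: str | os.PathLike,
                   contaminants_fasta: str | None = None, width: int = 60) -> None:
    """Write the database as FASTA; optionally append a contaminant FASTA."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.header()}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i:i + width] + "\n")
        if contaminants_fasta:
            with open(contaminants_fasta) as cf:
                fh.write(cf.read())
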