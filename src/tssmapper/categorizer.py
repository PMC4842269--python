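"""Genomic-context categorization of TSSs.

Every mapped TSS is placed in one or more of six categories relative to the
annotation:

  gTSS    gene TSS: 0..utr5_max bp upstream of a same-strand gene start
          (riboswitch-preceded genes are allowed a longer leader)
  iTSS    internal TSS: inside a same-strand gene, downstream of its start
  aTSS_5  antisense TSS in the 5'-UTR window of an opposite-strand gene
  aTSS_i  antisense TSS inside an opposite-strand gene
  aTSS_3  antisense TSS in the 3'-UTR window of an opposite-strand gene
  oTSS    orphan: none of the above

5'- and 3'-UTR windows of adjacent genes may overlap, so a TSS can hold
several assignments simultaneously; oTSS only ever appears alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GeneModel, Operon

CATEGORIES = ("gTSS", "iTSS", "aTSS_5", "aTSS_i", "aTSS_3", "oTSS")


@dataclass
class UtrConfig:
    """UTR length caps (bp) used for categorization.

    Defaults: leaders rarely exceed 200 nt and antisense TSSs cluster within
    ~100 nt of stop codons in rhizobial dRNA-seq data; leaderless mRNAs start
    within 10 nt of the start codon.  Riboswitch-preceded genes are allowed
    an extended leader cap (500 nt by default) since their regulatory leaders
    are known to exceed the ordinary 200 nt limit.
    """

    utr5_max: int = 200
    utr3_max: int = 100
    leaderless_max: int = 10
    riboswitch_utr5_max: int = 500

    def __post_init__(self) -> None:
        if min(self.utr5_max, self.utr3_max, self.leaderless_max,
               self.riboswitch_utr5_max) < 0:
            raise ValueError("UTR lengths must be >= 0")
        if self.leaderless_max > self.utr5_max:
            raise ValueError("leaderless_max must not exceed utr5_max")


@dataclass(frozen=True)
class CategoryAssignment:
    """One (TSS, gene, category) link.

    ``distance`` is the signed distance in transcription direction of the
    gene: for gTSS it is the 5'-UTR length (0 = leaderless exact case, TSS at
    the first base of the start codon); for iTSS it is the offset into the
    gene; for antisense categories it is the offset from the relevant gene
    boundary.  ``gene`` is None only for oTSS.
    """

    category: str
    gene: str | None
    distance: int | None


def categorize(position: int, strand: str, genes: Sequence[GeneModel],
               cfg: UtrConfig, replicon_id: str | None = None) -> list[CategoryAssignment]:
    """All category assignments for one TSS against a gene annotation.

    Genes on other replicons are ignored when ``replicon_id`` is given; an
    annotation with no gene on that replicon still yields an oTSS.
    """
    out: list[CategoryAssignment] = []
    for g in genes:
        if replicon_id is not None and g.replicon_id != replicon_id:
            continue
        if g.strand == strand:
            cap = cfg.riboswitch_utr5_max if g.riboswitch_preceded else cfg.utr5_max
            if strand == "+":
                d5 = g.start - position
                internal = g.start < position <= g.end
                into = position - g.start
            else:
                d5 = position - g.end
                internal = g.start <= position < g.end
                into = g.end - position
            if 0 <= d5 <= cap:
                out.append(CategoryAssignment("gTSS", g.locus_tag, d5))
            if internal:
                out.append(CategoryAssignment("iTSS", g.locus_tag, into))
        else:
            # antisense: windows are defined in the *gene's* frame of reference
            if g.strand == "+":
                in_utr5 = g.start - cfg.utr5_max <= position <= g.start - 1
                in_gene = g.start <= position <= g.end
                in_utr3 = g.end + 1 <= position <= g.end + cfg.utr3_max
                d5 = g.start - position
                d3 = position - g.end
                into = position - g.start
            else:
                in_utr5 = g.end + 1 <= position <= g.end + cfg.utr5_max
                in_gene = g.start <= position <= g.end
                in_utr3 = g.start - cfg.utr3_max <= position <= g.start - 1
                d5 = position - g.end
                d3 = g.start - position
                into = g.end - position
            if in_utr5:
                out.append(CategoryAssignment("aTSS_5", g.locus_tag, d5))
            if in_gene:
                out.append(CategoryAssignment("aTSS_i", g.locus_tag, into))
            if in_utr3:
                out.append(CategoryAssignment("aTSS_3", g.locus_tag, d3))
    if not out:
        out.append(CategoryAssignment("oTSS", None, None))
    return out


def flag_leaderless(assignments: Iterable[CategoryAssignment],
                    cfg: UtrConfig) -> tuple[bool, int | None]:
    """Leaderless call for a TSS with >= 1 gTSS assignment.

    Returns (is_leaderless, min gTSS distance); distance 0 means the TSS
    coincides with the first base of the start codon.
    """
    dists = [a.distance for a in assignments if a.category == "gTSS"]
    if not dists:
        return False, None
    d = min(dists)
    return d <= cfg.leaderless_max, d


def categorize_tss_list(tss_list: Sequence, genes: Sequence[GeneModel],
                        cfg: UtrConfig | None = None) -> None:
    """Fill ``categories`` and ``leaderless`` in place on ScoredTSS records."""
    cfg = cfg or UtrConfig()
    known_replicons = {g.replicon_id for g in genes}
    for t in tss_list:
        if genes and t.replicon_id not in known_replicons:
            raise ValueError(f"TSS {t.id}: unknown replicon {t.replicon_id!r}")
        t.categories = categorize(t.position, t.strand, genes, cfg, t.replicon_id)
        t.leaderless, _ = flag_leaderless(t.categories, cfg)


def expressed_gene_fraction(tss_list: Sequence, genes: Sequence[GeneModel],
                            operons: Sequence[Operon]) -> tuple[float, float]:
    """Fraction of genes with expression evidence, directly and via operons.

    direct:     genes carrying >= 1 gTSS / all genes.
    propagated: additionally counts every operon member downstream (in
                transcription direction) of a gTSS-bearing member, and every
                member downstream of an iTSS-bearing member -- polycistronic
                transcription carries expression past the first gene.
    """
    if not genes:
        raise ValueError("empty annotation")
    by_tag = {g.locus_tag: g for g in genes}
    gtss_genes: set[str] = set()
    itss_genes: set[str] = set()
    for t in tss_list:
        for a in (t.categories or []):
            if a.gene is None:
                continue
            if a.gene not in by_tag:
                raise ValueError(f"assignment references unknown gene {a.gene!r}")
            if a.category == "gTSS":
                gtss_genes.add(a.gene)
            elif a.category == "iTSS":
                itss_genes.add(a.gene)
    direct = len(gtss_genes) / len(genes)

    expressed = set(gtss_genes)
    for op in operons:
        for tag in op.locus_tags:
            if tag not in by_tag:
                raise ValueError(f"operon {op.id} references unknown gene {tag!r}")
        for i, tag in enumerate(op.locus_tags):
            if tag in gtss_genes:
                expressed.update(op.locus_tags[i:])
                break
        for i, tag in enumerate(op.locus_tags):
            if tag in itss_genes:
                expressed.update(op.locus_tags[i + 1:])
    propagated = len(expressed) / len(genes)
    return direct, propagated
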