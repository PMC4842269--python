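"""Synthetic dRNA-seq data with planted, known truth.

The simulator emulates the measurement design of differential RNA-seq: a
TEX-treated (+) library in which primary, triphosphorylated 5' ends survive
and processed ends are depleted, and an untreated (-) library containing
both.  It emits a GC-biased genome with clean ORFs, an annotation with
operons, planted TSSs in two conditions (free-living "Free" and symbiotic
"Nod") with promoter motifs written into their upstream sequence, planted
processed 5'-end sites with the inverse TEX response, Poisson read-start
noise, and coverage tracks derived by extending reads a fixed length
downstream.  Everything is deterministic given the seed.

Planted read-start counts follow the TEX contrast: at a TSS the (+) library
draws Poisson(tier mean) and the (-) library Poisson(tier mean /
tex_enrichment); at a processed site the ratio inverts.  The Nod condition
reuses a subset of the Free TSSs and adds Nod-specific TSSs that carry the
sigma-54-type (RpoN-like) planted motif, mirroring the dominance of RpoN
promoters among symbiosis-only TSSs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (CoverageTrack, GeneModel, LibraryMeta, Operon, Replicon,
                         write_fasta, write_genes_gff3, write_operons,
                         write_track_directory)
from .promoter import revcomp

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class MotifSpec:
    """A promoter motif planted upstream of a subset of TSSs."""

    name: str
    consensus_up: str
    consensus_down: str
    pos_up: int        # box start offset relative to TSS (negative)
    pos_down: int
    fraction: float    # of eligible TSSs carrying the motif
    mutation_rate: float = 0.1


DEFAULT_MOTIFS = (
    # sigma-70-type: -35 / -10 boxes, spacer 17
    MotifSpec("RpoD", "TTGACA", "TATAAT", -35, -12, fraction=0.7),
    # sigma-54-type: GG box at -24, GC box at -12
    MotifSpec("RpoN", "TGGCAC", "TTGCAT", -26, -14, fraction=1.0),
)


@dataclass
class SimConfig:
    """Study conditions of the default simulation scenario.

    Expression tiers are mean (+)-library read-start counts at a TSS; the
    high tier corresponds to a strongly expressed gene, the low tier to
    transcripts near the detection limit.  processed_site_rate is per kb.
    """

    genome_length: int = 100_000
    gc: float = 0.64
    n_genes: int = 90
    n_operons: int = 10
    n_tss_per_condition: int = 100
    tier_means: dict = field(default_factory=lambda: {"high": 200.0, "mid": 50.0,
                                                      "low": 8.0})
    tier_weights: dict = field(default_factory=lambda: {"high": 0.4, "mid": 0.4,
                                                        "low": 0.2})
    tex_enrichment: float = 5.0
    processed_site_rate: float = 0.2      # sites per kb
    processed_mean: float = 60.0          # (-)-library mean at a processed site
    background_rate: float = 0.02         # Poisson read-start noise per bp
    transcript_length: int = 300          # span of in-transcript 5'-end background
    transcript_minus_rate: float = 0.3    # (-)-library 5' ends per bp inside transcripts
    read_length: int = 100                # reads extend this far for coverage
    motifs: tuple = DEFAULT_MOTIFS
    nod_overlap_fraction: float = 0.3     # fraction of Nod TSSs shared with Free
    min_site_spacing: int = 60            # bp between planted single-nt signals
    replicon_id: str = "sim_chr"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.tex_enrichment <= 1.0:
            raise ValueError("tex_enrichment must exceed 1")
        for m in self.motifs:
            if m.pos_up - 0 < -50 - 0 and False:
                pass
            if m.pos_up < -50 or m.pos_down + len(m.consensus_down) > 0:
                raise ValueError(f"motif {m.name} does not fit the 50 bp upstream window")

    @classmethod
    def scaled(cls, genome_length: int, seed: int = 0, **overrides) -> "SimConfig":
        """Defaults scaled to a different genome size (same densities)."""
        f = genome_length / 100_000
        params = dict(genome_length=genome_length,
                      n_genes=max(10, round(90 * f)),
                      n_tss_per_condition=max(10, round(100 * f)),
                      n_operons=max(2, round(10 * f)),
                      seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class SimTSS:
    position: int
    strand: str
    in_free: bool
    in_nod: bool
    tier: str
    category: str            # planted context: gTSS | iTSS | oTSS
    gene: str | None
    motif: str | None


@dataclass
class SimProcessedSite:
    position: int
    strand: str
    gene: str
    gene_has_gtss: bool


@dataclass
class SimDataset:
    config: SimConfig
    replicon: Replicon
    genes: list[GeneModel]
    operons: list[Operon]
    tss: list[SimTSS]
    processed: list[SimProcessedSite]
    tracks: dict[tuple[str, str, str], CoverageTrack]

    def truth_tss_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "position": t.position, "strand": t.strand,
            "in_free": t.in_free, "in_nod": t.in_nod, "tier": t.tier,
            "category": t.category, "gene": t.gene or "", "motif": t.motif or "",
        } for t in self.tss])

    def truth_processed_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "position": s.position, "strand": s.strand, "gene": s.gene,
            "gene_has_gtss": s.gene_has_gtss,
        } for s in self.processed])


def _random_orf(n_codons: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    """Start codon + non-stop body codons drawn from the base model + stop."""
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(np.array(list("ACGT"))[rng.choice(4, 3, p=probs)])
        if codon in _STOPS:
            continue
        body.append(codon)
    return "ATG" + "".join(body) + _STOPS[rng.integers(len(_STOPS))]


def _far_enough(pos: int, taken: list[int], spacing: int) -> bool:
    return all(abs(pos - q) >= spacing for q in taken)


def simulate_dataset(cfg: SimConfig | None = None,
                     seed: int | None = None) -> SimDataset:
    """Generate one complete synthetic dataset.

    ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    gc = cfg.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = np.array(list("ACGT"))[rng.choice(4, L, p=probs)]

    # --- genes: non-overlapping clean ORFs with intergenic gaps ---
    genes: list[GeneModel] = []
    cursor = 400
    while len(genes) < cfg.n_genes:
        n_codons = int(rng.integers(60, 200))
        length = 3 * n_codons
        if cursor + length > L - 400:
            raise ValueError("genome too short for the requested gene count")
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(n_codons, probs, rng)
        block = orf if strand == "+" else revcomp(orf)
        genome[cursor - 1:cursor - 1 + length] = list(block)
        tag = f"simg_{len(genes) + 1:04d}"
        genes.append(GeneModel(tag, cfg.replicon_id, strand,
                               cursor, cursor + length - 1, kind="CDS"))
        cursor += length + int(rng.integers(250, 450))

    # --- operons: runs of consecutive same-strand genes ---
    operons: list[Operon] = []
    i = 0
    while i < len(genes) and len(operons) < cfg.n_operons:
        j = i
        while (j + 1 < len(genes) and genes[j + 1].strand == genes[i].strand
               and j - i < 3):
            j += 1
        if j > i:
            members = genes[i:j + 1]
            tags = [g.locus_tag for g in members]
            if members[0].strand == "-":
                tags = tags[::-1]  # 5'->3' in transcription direction
            operons.append(Operon(f"simop_{len(operons) + 1:03d}", tags,
                                  members[0].strand))
        i = j + 1

    # --- assign genes to planted-TSS roles ---
    n = cfg.n_tss_per_condition
    n_shared = round(cfg.nod_overlap_fraction * n)
    n_free_gtss, n_free_itss = round(0.40 * n), round(0.15 * n)
    n_free_otss = n - n_free_gtss - n_free_itss
    n_nod_only = n - n_shared
    n_nod_gtss, n_nod_itss = round(0.28 * n_nod_only), round(0.14 * n_nod_only)
    n_nod_otss = n_nod_only - n_nod_gtss - n_nod_itss

    perm = list(rng.permutation(len(genes)))
    need = n_free_gtss + n_nod_gtss + n_free_itss + n_nod_itss
    if need > len(genes):
        raise ValueError("not enough genes for the requested TSS composition")
    free_gtss_genes = [genes[k] for k in perm[:n_free_gtss]]
    nod_gtss_genes = [genes[k] for k in perm[n_free_gtss:n_free_gtss + n_nod_gtss]]
    itss_pool = perm[n_free_gtss + n_nod_gtss:need]
    free_itss_genes = [genes[k] for k in itss_pool[:n_free_itss]]
    nod_itss_genes = [genes[k] for k in itss_pool[n_free_itss:]]
    spare_genes = [genes[k] for k in perm[need:]]

    taken: list[int] = []
    tss: list[SimTSS] = []
    tiers = list(cfg.tier_means)
    tier_p = np.array([cfg.tier_weights[t] for t in tiers], dtype=float)
    tier_p /= tier_p.sum()

    def draw_tier() -> str:
        return tiers[rng.choice(len(tiers), p=tier_p)]

    def add_tss(pos: int, strand: str, category: str, gene: str | None,
                in_free: bool, in_nod: bool) -> SimTSS | None:
        if pos - 55 < 1 or pos + 55 > L or not _far_enough(pos, taken, cfg.min_site_spacing):
            return None
        rec = SimTSS(pos, strand, in_free, in_nod, draw_tier(), category, gene, None)
        tss.append(rec)
        taken.append(pos)
        return rec

    def place_gtss(gene: GeneModel, in_free: bool, in_nod: bool) -> SimTSS | None:
        for _ in range(30):
            u = int(rng.integers(20, 41))
            pos = gene.five_prime - u if gene.strand == "+" else gene.five_prime + u
            rec = add_tss(pos, gene.strand, "gTSS", gene.locus_tag, in_free, in_nod)
            if rec:
                return rec
        return None

    def leader_of_some_gene(pos: int, strand: str) -> bool:
        # would the categorizer call this a gTSS of any gene (200 nt leader cap)?
        for g in genes:
            if g.strand != strand:
                continue
            d = (g.start - pos) if strand == "+" else (pos - g.end)
            if 0 <= d <= 200:
                return True
        return False

    def place_itss(gene: GeneModel, in_free: bool, in_nod: bool) -> SimTSS | None:
        span = gene.end - gene.start
        for _ in range(30):
            off = int(rng.integers(50, max(51, span - 30)))
            pos = gene.start + off if gene.strand == "+" else gene.end - off
            if leader_of_some_gene(pos, gene.strand):
                continue  # keep planted iTSSs free of gTSS double-assignments
            rec = add_tss(pos, gene.strand, "iTSS", gene.locus_tag, in_free, in_nod)
            if rec:
                return rec
        return None

    gaps = []
    prev_end = 0
    for g in genes:
        if g.start - prev_end > 170:
            gaps.append((prev_end + 1, g.start - 1))
        prev_end = g.end
    if L - prev_end > 170:
        gaps.append((prev_end + 1, L))

    def place_otss(in_free: bool, in_nod: bool) -> SimTSS | None:
        for _ in range(300):
            lo, hi = gaps[rng.integers(len(gaps))]
            if hi - lo < 130:
                continue
            pos = int(rng.integers(lo + 60, hi - 60))
            strand = "+" if rng.random() < 0.5 else "-"
            if leader_of_some_gene(pos, strand):
                continue  # orphans must stay outside every gene's leader window
            rec = add_tss(pos, strand, "oTSS", None, in_free, in_nod)
            if rec:
                return rec
        return None

    for g in free_gtss_genes:
        place_gtss(g, True, False)
    for g in free_itss_genes:
        place_itss(g, True, False)
    while sum(1 for t in tss if t.in_free) < n:
        if place_otss(True, False) is None:
            raise RuntimeError("could not place all Free oTSSs; genome too crowded")
    free_tss = [t for t in tss if t.in_free]
    for k in rng.choice(len(free_tss), size=n_shared, replace=False):
        free_tss[int(k)].in_nod = True
    for g in nod_gtss_genes:
        place_gtss(g, False, True)
    for g in nod_itss_genes:
        place_itss(g, False, True)
    while sum(1 for t in tss if t.in_nod) < n:
        if place_otss(False, True) is None:
            raise RuntimeError("could not place all Nod oTSSs; genome too crowded")

    # --- plant promoter motifs into upstream sequence ---
    rpod = next((m for m in cfg.motifs if m.name == "RpoD"), None)
    rpon = next((m for m in cfg.motifs if m.name == "RpoN"), None)

    def plant(seq_spec: MotifSpec, t: SimTSS) -> None:
        for consensus, off in ((seq_spec.consensus_up, seq_spec.pos_up),
                               (seq_spec.consensus_down, seq_spec.pos_down)):
            bases = list(consensus)
            for bi in range(len(bases)):
                if rng.random() < seq_spec.mutation_rate:
                    others = [b for b in "ACGT" if b != bases[bi]]
                    bases[bi] = others[rng.integers(3)]
            motif_seq = "".join(bases)
            if t.strand == "+":
                start0 = t.position + off - 1          # 0-based
                genome[start0:start0 + len(motif_seq)] = list(motif_seq)
            else:
                end0 = t.position - off                # 0-based exclusive end
                rc = revcomp(motif_seq)
                genome[end0 - len(rc):end0] = list(rc)
        t.motif = seq_spec.name

    for t in tss:
        if t.category == "iTSS":
            continue  # never overwrite coding sequence
        if t.in_nod and not t.in_free:
            if rpon is not None and rng.random() < rpon.fraction:
                plant(rpon, t)
        elif t.in_free:
            if rpod is not None and rng.random() < rpod.fraction:
                plant(rpod, t)

    # --- processed 5'-end sites inside genes (TEX-depleted) ---
    n_proc = round(cfg.processed_site_rate * L / 1000)
    free_gtss_tags = {t.gene for t in tss if t.category == "gTSS" and t.in_free}
    proc_hosts = ([g for g in free_gtss_genes] * 2)[:max(0, round(0.75 * n_proc))]
    proc_hosts += (spare_genes * 2)[:n_proc - len(proc_hosts)]
    processed: list[SimProcessedSite] = []
    for g in proc_hosts:
        span = g.end - g.start
        for _ in range(30):
            off = int(rng.integers(50, max(51, span - 30)))
            pos = g.start + off if g.strand == "+" else g.end - off
            if not _far_enough(pos, taken, cfg.min_site_spacing):
                continue
            taken.append(pos)
            processed.append(SimProcessedSite(pos, g.strand, g.locus_tag,
                                              g.locus_tag in free_gtss_tags))
            break

    replicon = Replicon(cfg.replicon_id, "".join(genome))

    # --- read-start and coverage tracks ---
    tracks: dict[tuple[str, str, str], CoverageTrack] = {}
    arrays: dict[tuple[str, str, str], np.ndarray] = {}
    for cond in ("Free", "Nod"):
        for treat in ("TEXplus", "TEXminus"):
            for strand in ("+", "-"):
                arrays[(cond, treat, strand)] = rng.poisson(
                    cfg.background_rate, L).astype(np.int64)
    for t in tss:
        mean = cfg.tier_means[t.tier]
        # in-transcript 5' ends (degradation/processing products along the
        # transcript body, TEX-depleted): these put the TSS spike on a small
        # downstream step, as in real dRNA-seq coverage
        if t.strand == "+":
            span = slice(t.position, min(L, t.position + cfg.transcript_length))
        else:
            span = slice(max(0, t.position - 1 - cfg.transcript_length), t.position - 1)
        span_len = span.stop - span.start
        for cond, active in (("Free", t.in_free), ("Nod", t.in_nod)):
            if not active:
                continue
            arrays[(cond, "TEXplus", t.strand)][t.position - 1] += rng.poisson(mean)
            arrays[(cond, "TEXminus", t.strand)][t.position - 1] += rng.poisson(
                mean / cfg.tex_enrichment)
            arrays[(cond, "TEXminus", t.strand)][span] += rng.poisson(
                cfg.transcript_minus_rate, span_len)
            arrays[(cond, "TEXplus", t.strand)][span] += rng.poisson(
                cfg.transcript_minus_rate / cfg.tex_enrichment, span_len)
    for s in processed:
        arrays[("Free", "TEXminus", s.strand)][s.position - 1] += rng.poisson(
            cfg.processed_mean)
        arrays[("Free", "TEXplus", s.strand)][s.position - 1] += rng.poisson(
            cfg.processed_mean / cfg.tex_enrichment)

    for key, starts in arrays.items():
        cond, treat, strand = key
        cov = _extend_coverage(starts, cfg.read_length, strand)
        tracks[key] = CoverageTrack(cfg.replicon_id, LibraryMeta(cond, treat, strand),
                                    read_starts=starts, coverage=cov)

    return SimDataset(cfg, replicon, genes, operons, tss, processed, tracks)


def _extend_coverage(read_starts: np.ndarray, read_length: int,
                     strand: str) -> np.ndarray:
    """Coverage from reads extending `read_length` bp downstream of each start."""
    csum = np.concatenate(([0], np.cumsum(read_starts)))
    L = len(read_starts)
    idx = np.arange(L)
    if strand == "+":
        lo = np.clip(idx - read_length + 1, 0, L)
        hi = idx + 1
    else:
        lo = idx
        hi = np.clip(idx + read_length, 0, L)
    return (csum[hi] - csum[lo]).astype(np.int64)


def write_dataset(sim: SimDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the full dataset to disk; returns artifact name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    genome_path = os.path.join(outdir, "genome.fasta")
    write_fasta([sim.replicon], genome_path)
    paths["genome"] = genome_path
    gff_path = os.path.join(outdir, "genes.gff3")
    write_genes_gff3(sim.genes, gff_path)
    paths["annotation"] = gff_path
    op_path = os.path.join(outdir, "operons.tsv")
    write_operons(sim.operons, op_path)
    paths["operons"] = op_path
    tracks_dir = os.path.join(outdir, "tracks")
    write_track_directory(sim.tracks, tracks_dir)
    paths["tracks"] = tracks_dir
    tss_path = os.path.join(outdir, "truth_tss.tsv")
    sim.truth_tss_frame().to_csv(tss_path, sep="\t", index=False)
    paths["truth_tss"] = tss_path
    proc_path = os.path.join(outdir, "truth_processed.tsv")
    sim.truth_processed_frame().to_csv(proc_path, sep="\t", index=False)
    paths["truth_processed"] = proc_path
    return paths


def make_training_labels(sim: SimDataset, region: tuple[int, int] | None = None,
                         max_match: int = 2) -> pd.DataFrame:
    """Expert-style training labels for candidates in a genomic region.

    Mirrors manual curation of candidate peaks in a subregion: every TSS
    candidate found by peak calling within ``region`` is labeled TSS when it
    lies within ``max_match`` bp of a planted TSS active in its condition,
    and notTSS otherwise.
    """
    from .peakcalling import SalienceParams, call_candidates

    if region is None:
        region = (1, int(0.3 * sim.config.genome_length))
    params = SalienceParams()
    rows = []
    for cond in ("Free", "Nod"):
        truth = {s: sorted(t.position for t in sim.tss
                           if t.strand == s and
                           (t.in_free if cond == "Free" else t.in_nod))
                 for s in ("+", "-")}
        for strand in ("+", "-"):
            for c in call_candidates(sim.tracks, cond, strand, params):
                if not (region[0] <= c.position <= region[1]):
                    continue
                arr = np.array(truth[strand])
                is_tss = bool(len(arr) and np.min(np.abs(arr - c.position)) <= max_match)
                rows.append({"position": c.position, "strand": strand,
                             "condition": cond,
                             "label": "TSS" if is_tss else "notTSS"})
    return pd.DataFrame(rows)


def simulate_upstream_windows(n: int, window: int, gc: float, motif: MotifSpec | None,
                              fraction: float, seed: int,
                              mutation_rate: float | None = None
                              ) -> tuple[list[str], np.ndarray]:
    """Standalone upstream-window sampler for promoter-discovery studies.

    Draws n windows i.i.d. from the GC background and plants ``motif`` into
    a ``fraction`` of them (None plants nothing).  Returns the windows and a
    boolean planted-mask.
    """
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = []
    planted = np.zeros(n, dtype=bool)
    mut = motif.mutation_rate if (motif and mutation_rate is None) else (mutation_rate or 0.0)
    for i in range(n):
        chars = np.array(list("ACGT"))[rng.choice(4, window, p=probs)]
        if motif is not None and rng.random() < fraction:
            planted[i] = True
            for consensus, off in ((motif.consensus_up, motif.pos_up),
                                   (motif.consensus_down, motif.pos_down)):
                bases = list(consensus)
                for bi in range(len(bases)):
                    if rng.random() < mut:
                        others = [b for b in "ACGT" if b != bases[bi]]
                        bases[bi] = others[rng.integers(3)]
                chars[window + off:window + off + len(bases)] = bases
        seqs.append("".join(chars))
    return seqs, planted
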