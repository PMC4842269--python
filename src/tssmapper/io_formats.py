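"""Readers and writers for the formats the toolkit consumes and emits.

All genomic coordinates handled by this package are 1-based inclusive, the
convention used for printed genomic positions in bacterial annotation.
bedGraph input/output converts from/to 0-based half-open intervals at the
boundary, and nowhere else.

Minus-strand coverage tracks are stored in genome coordinates (never
reversed); any strand-aware logic (e.g. what "downstream" means) lives in
the consumers of these arrays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONDITIONS = ("Free", "Nod")
TREATMENTS = ("TEXplus", "TEXminus")
STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Replicon:
    """A replicon sequence (chromosome or plasmid), uppercase over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"replicon {self.id}: unexpected characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        """GC content over unambiguous bases."""
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        return (s.count("G") + s.count("C")) / acgt


@dataclass
class LibraryMeta:
    """Identifies one sequencing library track: condition x TEX treatment x strand."""

    condition: str
    treatment: str
    strand: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class CoverageTrack:
    """Per-position read-start counts (and optional coverage) for one library.

    ``read_starts[i]`` counts read 5' ends mapped at 1-based position ``i+1``;
    ``coverage[i]`` counts reads overlapping that position.  Arrays span the
    full replicon.
    """

    replicon_id: str
    meta: LibraryMeta
    read_starts: np.ndarray
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.read_starts = np.asarray(self.read_starts)
        if np.any(self.read_starts < 0):
            raise ValueError("read_starts must be non-negative")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage)
            if len(self.coverage) != len(self.read_starts):
                raise ValueError("coverage and read_starts length mismatch")
            if np.any(self.coverage < 0):
                raise ValueError("coverage must be non-negative")

    @property
    def length(self) -> int:
        return len(self.read_starts)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene (CDS, ncRNA or other feature) on a replicon."""

    locus_tag: str
    replicon_id: str
    strand: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: str = "CDS"
    riboswitch_preceded: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.locus_tag}: invalid interval {self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.locus_tag}: invalid strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the first base in transcription direction."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class Operon:
    """Ordered run of co-transcribed genes, 5'->3' in transcription direction."""

    id: str
    locus_tags: list[str]
    strand: str


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, Replicon]:
    """Load all replicons from a FASTA file, keyed by record id."""
    out: dict[str, Replicon] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = Replicon(rec.id, str(rec.seq))
    return out


def write_fasta(replicons: Iterable[Replicon], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in replicons]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_coverage(path: str | os.PathLike, replicon: Replicon,
                  meta: LibraryMeta, *, what: str = "read_starts") -> CoverageTrack:
    """Read a bedGraph file into a dense per-position track.

    Intervals must be 0-based half-open, non-overlapping and within the
    replicon; uncovered positions are 0.
    """
    dense = read_bedgraph_array(path, replicon.length, replicon_id=replicon.id)
    if what == "read_starts":
        return CoverageTrack(replicon.id, meta, read_starts=dense)
    elif what == "coverage":
        return CoverageTrack(replicon.id, meta,
                             read_starts=np.zeros(replicon.length, dtype=dense.dtype),
                             coverage=dense)
    raise ValueError(f"what must be 'read_starts' or 'coverage', got {what!r}")


def read_bedgraph_array(path: str | os.PathLike, length: int,
                        replicon_id: str | None = None) -> np.ndarray:
    """Parse a bedGraph into a dense array of the given length.

    Raises on overlapping intervals or intervals extending past the replicon.
    """
    dense = np.zeros(length, dtype=np.int64)
    seen_end = {}  # per-chrom running max end, to detect overlaps
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if replicon_id is not None and chrom != replicon_id:
                raise ValueError(f"{path}:{lineno}: chrom {chrom!r} does not match "
                                 f"replicon {replicon_id!r}")
            if s < 0 or e > length:
                raise ValueError(f"{path}:{lineno}: interval {chrom}:{s}-{e} outside "
                                 f"replicon of length {length}")
            if e <= s:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval {s}-{e}")
            prev_end = seen_end.get(chrom, -1)
            if s < prev_end:
                raise ValueError(f"{path}:{lineno}: interval {chrom}:{s}-{e} overlaps "
                                 f"a previous interval")
            seen_end[chrom] = max(prev_end, e)
            iv = int(v)
            if iv != v:
                dense = dense.astype(float) if dense.dtype == np.int64 else dense
                dense[s:e] = v
            else:
                dense[s:e] = iv
    return dense


def write_bedgraph(array: np.ndarray, replicon_id: str,
                   path: str | os.PathLike, *, skip_zero: bool = True) -> None:
    """Write a dense array as bedGraph (0-based half-open, run-length encoded)."""
    array = np.asarray(array)
    n = len(array)
    with open(path, "w") as fh:
        if n == 0:
            return
        # boundaries of constant runs
        change = np.flatnonzero(np.diff(array)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for s, e in zip(starts, ends):
            v = array[s]
            if skip_zero and v == 0:
                continue
            val = int(v) if float(v).is_integer() else float(v)
            fh.write(f"{replicon_id}\t{s}\t{e}\t{val}\n")


def track_filename(meta: LibraryMeta, what: str) -> str:
    """Canonical file name: ``<cond>_<treatment>_<strand>.<what>.bedgraph``."""
    strand = "plus" if meta.strand == "+" else "minus"
    return f"{meta.condition}_{meta.treatment}_{strand}.{what}.bedgraph"


def read_track_directory(directory: str | os.PathLike,
                         replicon: Replicon) -> dict[tuple[str, str, str], CoverageTrack]:
    """Load all library tracks from a directory following the canonical naming.

    Returns a dict keyed by (condition, treatment, strand).  read_starts files
    are required for every library present; coverage files are attached when
    available.
    """
    tracks: dict[tuple[str, str, str], CoverageTrack] = {}
    for cond in CONDITIONS:
        for treat in TREATMENTS:
            for strand in STRANDS:
                meta = LibraryMeta(cond, treat, strand)
                rs_path = os.path.join(directory, track_filename(meta, "readstarts"))
                if not os.path.exists(rs_path):
                    continue
                rs = read_bedgraph_array(rs_path, replicon.length, replicon.id)
                cov_path = os.path.join(directory, track_filename(meta, "coverage"))
                cov = None
                if os.path.exists(cov_path):
                    cov = read_bedgraph_array(cov_path, replicon.length, replicon.id)
                tracks[(cond, treat, strand)] = CoverageTrack(
                    replicon.id, meta, read_starts=rs, coverage=cov)
    return tracks


def write_track_directory(tracks: dict[tuple[str, str, str], CoverageTrack],
                          directory: str | os.PathLike) -> list[str]:
    os.makedirs(directory, exist_ok=True)
    written = []
    for (_, _, _), track in sorted(tracks.items()):
        rs_name = track_filename(track.meta, "readstarts")
        write_bedgraph(track.read_starts, track.replicon_id,
                       os.path.join(directory, rs_name))
        written.append(rs_name)
        if track.coverage is not None:
            cov_name = track_filename(track.meta, "coverage")
            write_bedgraph(track.coverage, track.replicon_id,
                           os.path.join(directory, cov_name))
            written.append(cov_name)
    return written


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

_GENE_KINDS = {"CDS": "CDS", "ncRNA": "ncRNA"}


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3 (CDS, ncRNA and gene features)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "ncRNA", "gene"):
            continue
        tag = (feat.attributes.get("locus_tag", [None])[0]
               or feat.attributes.get("ID", [feat.id])[0])
        if tag in seen:
            continue
        seen.add(tag)
        kind = _GENE_KINDS.get(feat.featuretype, "other")
        if feat.featuretype == "gene":
            kind = "CDS"
        ribo = feat.attributes.get("riboswitch_preceded", ["false"])[0].lower() == "true"
        genes.append(GeneModel(locus_tag=tag, replicon_id=feat.seqid,
                               strand=feat.strand, start=feat.start, end=feat.end,
                               kind=kind, riboswitch_preceded=ribo))
    return genes


def write_genes_gff3(genes: Sequence[GeneModel], path: str | os.PathLike,
                     source: str = "tssmapper") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = g.kind if g.kind in ("CDS", "ncRNA") else "gene"
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.riboswitch_preceded:
                attrs += ";riboswitch_preceded=true"
            fh.write(f"{g.replicon_id}\t{source}\t{ftype}\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# TSS GFF3 export (round-trippable)
# ---------------------------------------------------------------------------

def _fmt_score(x: float | None) -> str:
    return "" if x is None else f"{x:.6g}"


def write_tss_gff3(tss_list: Sequence, promoter_hits: Sequence, path: str | os.PathLike,
                   source: str = "tssmapper") -> None:
    """Write TSS and promoter features to a GFF3 file.

    Each TSS becomes a single-base ``TSS`` feature carrying its scores,
    condition flags, categories and confidence class as attributes; each
    promoter hit becomes a ``promoter`` feature spanning its two boxes.
    Scores that are NA (TSS not scored in that condition) are omitted from
    the attributes rather than encoded as sentinels.
    """
    ids = [t.id for t in tss_list]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate TSS ids: {dupes[:5]}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tss_list:
            attrs = [f"ID={t.id}", f"detected_in={','.join(sorted(t.detected_in))}"]
            if t.score_free is not None:
                attrs.append(f"score_free={_fmt_score(t.score_free)}")
            if t.score_nod is not None:
                attrs.append(f"score_nod={_fmt_score(t.score_nod)}")
            if t.peak_free is not None:
                attrs.append(f"peak_free={t.peak_free:g}")
            if t.peak_nod is not None:
                attrs.append(f"peak_nod={t.peak_nod:g}")
            if t.ratio_free is not None:
                attrs.append(f"ratio_free={_fmt_score(t.ratio_free)}")
            if t.ratio_nod is not None:
                attrs.append(f"ratio_nod={_fmt_score(t.ratio_nod)}")
            if t.confidence is not None:
                attrs.append(f"confidence={t.confidence}")
            if t.categories:
                cat_str = ",".join(
                    f"{a.category}:{a.gene or '.'}:{'.' if a.distance is None else a.distance}"
                    for a in t.categories)
                attrs.append(f"categories={cat_str}")
            if t.leaderless is not None:
                attrs.append(f"leaderless={'true' if t.leaderless else 'false'}")
            fh.write(f"{t.replicon_id}\t{source}\tTSS\t{t.position}\t{t.position}\t.\t"
                     f"{t.strand}\t.\t{';'.join(attrs)}\n")
        for h in promoter_hits:
            start = min(h.box_up_start, h.box_down_start)
            end = max(h.box_up_end, h.box_down_end)
            attrs = (f"ID=prom_{h.tss_id}_{h.motif_id};tss_id={h.tss_id};"
                     f"motif_id={h.motif_id};score={h.score:.4f};"
                     f"box_up={h.box_up_start}-{h.box_up_end};"
                     f"box_down={h.box_down_start}-{h.box_down_end}")
            fh.write(f"{h.replicon_id}\t{source}\tpromoter\t{start}\t{end}\t"
                     f"{h.score:.4f}\t{h.strand}\t.\t{attrs}\n")


def read_tss_gff3(path: str | os.PathLike) -> list:
    """Read TSS features written by :func:`write_tss_gff3` back into records."""
    from .tss_svm import ScoredTSS
    from .categorizer import CategoryAssignment

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "TSS":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            cats = []
            for item in attrs.get("categories", "").split(","):
                if not item:
                    continue
                cat, gene, dist = item.split(":")
                cats.append(CategoryAssignment(
                    category=cat, gene=None if gene == "." else gene,
                    distance=None if dist == "." else int(dist)))
            def _f(key):
                return float(attrs[key]) if key in attrs else None
            leaderless = None
            if "leaderless" in attrs:
                leaderless = attrs["leaderless"] == "true"
            out.append(ScoredTSS(
                id=attrs["ID"], replicon_id=cols[0], strand=cols[6],
                position=int(cols[3]),
                score_free=_f("score_free"), score_nod=_f("score_nod"),
                peak_free=_f("peak_free"), peak_nod=_f("peak_nod"),
                ratio_free=_f("ratio_free"), ratio_nod=_f("ratio_nod"),
                detected_in=set(attrs["detected_in"].split(",")),
                confidence=attrs.get("confidence"),
                categories=cats, leaderless=leaderless))
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_training_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Training labels: columns position, strand, condition, label in {TSS, notTSS}."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "strand", "condition", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"training label file missing columns: {sorted(missing)}")
    bad = set(df["label"]) - {"TSS", "notTSS"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return df


def write_training_labels(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_operons(path: str | os.PathLike, genes: Sequence[GeneModel]) -> list[Operon]:
    """Operon TSV: columns operon_id, locus_tags (comma-joined, 5'->3')."""
    by_tag = {g.locus_tag: g for g in genes}
    df = pd.read_csv(path, sep="\t")
    operons = []
    for _, row in df.iterrows():
        tags = [t for t in str(row["locus_tags"]).split(",") if t]
        unknown = [t for t in tags if t not in by_tag]
        if unknown:
            raise ValueError(f"operon {row['operon_id']}: unknown genes {unknown}")
        strands = {by_tag[t].strand for t in tags}
        if len(strands) != 1:
            raise ValueError(f"operon {row['operon_id']}: genes on mixed strands")
        operons.append(Operon(str(row["operon_id"]), tags, strands.pop()))
    return operons


def write_operons(operons: Sequence[Operon], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tlocus_tags\n")
        for op in operons:
            fh.write(f"{op.id}\t{','.join(op.locus_tags)}\n")


def write_tss_table(tss_list: Sequence, path: str | os.PathLike) -> None:
    """TSS TSV export: id, position, strand, categories, scores, peaks, confidence."""
    rows = []
    for t in tss_list:
        rows.append({
            "id": t.id, "replicon": t.replicon_id, "position": t.position,
            "strand": t.strand,
            "categories": ",".join(sorted({a.category for a in t.categories}))
                          if t.categories else "",
            "detected_in": ",".join(sorted(t.detected_in)),
            "score_free": "" if t.score_free is None else f"{t.score_free:.6g}",
            "score_nod": "" if t.score_nod is None else f"{t.score_nod:.6g}",
            "peak_free": "" if t.peak_free is None else f"{t.peak_free:g}",
            "peak_nod": "" if t.peak_nod is None else f"{t.peak_nod:g}",
            "confidence": t.confidence or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
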