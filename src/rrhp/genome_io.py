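"""Genome FASTA / GFF3 input and the strand-specific CCGG site catalogue.

RRHP libraries measure 5-hydroxymethylcytosine at MspI recognition sites
(CCGG), so everything downstream is anchored on a catalogue of strand-specific
CCGG positions.  Because the motif is palindromic, every occurrence on the
plus strand is simultaneously an occurrence on the minus strand: one
measurable cytosine per strand per occurrence.

Coordinate conventions used throughout the package:

* positions are 1-based; intervals are closed (GFF3 style);
* a site's ``position`` is the first C of the motif as read 5'->3' on the
  site's own strand.  A plus-strand occurrence whose first C is at ``p``
  therefore yields the plus site ``(chrom, p, '+')`` and the minus site
  ``(chrom, p + 3, '-')``;
* any BED output is converted to 0-based half-open on the way out.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeSequence",
    "CcggSite",
    "TranscriptModel",
    "GenomeAnnotation",
    "read_fasta",
    "write_fasta",
    "catalog_ccgg_sites",
    "read_gff3",
    "write_site_catalog_tsv",
    "write_site_catalog_bed",
    "read_site_catalog_tsv",
]

_ALPHABET = frozenset("ACGTN")
_MOTIF = re.compile(r"(?=CCGG)")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: an uppercased sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("genome record with empty name")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.name!r}: invalid characters {sorted(bad)!r} "
                "(expected A/C/G/T/N after uppercasing)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class CcggSite(NamedTuple):
    """A strand-specific CCGG position; the unit of 5hmC measurement.

    ``position`` is the 1-based coordinate of the first C of the motif as
    read 5'->3' on ``strand``.
    """

    chrom: str
    position: int
    strand: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.position}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "CcggSite":
        chrom, pos, strand = key.rsplit(":", 2)
        return cls(chrom, int(pos), strand)


@dataclass
class TranscriptModel:
    """A transcript reduced to what feature annotation needs.

    ``tss``/``tes`` are genome coordinates of the transcription start/end in
    transcript orientation (for a minus-strand transcript ``tss > tes``).
    ``exons`` are 1-based closed genome intervals ordered 5'->3' in transcript
    orientation (each interval still has start <= end in genome coordinates).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]]
    description: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"transcript {self.transcript_id}: exon {start}>{end}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (min, max) over all exons."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in transcript orientation (genome start <= end)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


@dataclass
class GenomeAnnotation:
    """Transcript collection plus per-chromosome indexes for fast lookup."""

    transcripts: list[TranscriptModel]
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)
        self._tss: dict[str, np.ndarray] = {}
        self._tss_order: dict[str, list[TranscriptModel]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for chrom, txs in self._by_chrom.items():
            order = sorted(txs, key=lambda t: (t.tss, t.gene_id, t.transcript_id))
            self._tss_order[chrom] = order
            self._tss[chrom] = np.array([t.tss for t in order], dtype=np.int64)
            tree = IntervalTree()
            for t in txs:
                lo, hi = t.span
                tree[lo : hi + 1] = t  # half-open on 1-based closed interval
            self._trees[chrom] = tree

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def transcripts_on(self, chrom: str) -> list[TranscriptModel]:
        return self._by_chrom.get(chrom, [])

    def overlapping(self, chrom: str, position: int) -> list[TranscriptModel]:
        """Transcripts whose genomic span contains ``position``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[position]]
        return sorted(hits, key=lambda t: (t.gene_id, t.transcript_id))

    def nearest_by_tss(self, chrom: str, position: int) -> TranscriptModel | None:
        """Transcript minimizing |position - tss|; ties -> smaller gene_id.

        Distance magnitude is strand-independent, so nearest-by-absolute
        signed TSS distance reduces to nearest TSS coordinate.
        """
        tss = self._tss.get(chrom)
        if tss is None or len(tss) == 0:
            return None
        order = self._tss_order[chrom]
        i = int(np.searchsorted(tss, position))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d = abs(position - int(tss[j]))
                if best is None or d < best:
                    best = d
        # collect all transcripts at the minimal absolute distance
        ties: list[TranscriptModel] = []
        j = i - 1
        while j >= 0 and abs(position - int(tss[j])) == best:
            ties.append(order[j])
            j -= 1
        j = i
        while j < len(tss) and abs(position - int(tss[j])) == best:
            ties.append(order[j])
            j += 1
        return min(ties, key=lambda t: (t.gene_id, t.transcript_id))


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased; record order is preserved.  Raises ``ValueError``
    naming the offending record on empty sequences or duplicate names, and on
    files with content but no parseable record.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, seq))
    if not records and path.stat().st_size > 0:
        raise ValueError(f"{path}: no FASTA records found (malformed header?)")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def catalog_ccgg_sites(
    genome: Sequence[GenomeSequence],
    chrom_subset: Sequence[str] | None = None,
) -> list[CcggSite]:
    """Catalogue every strand-specific CCGG site in the genome.

    The motif is palindromic, so each plus-strand occurrence at ``p`` yields
    two sites: ``(p, '+')`` and ``(p + 3, '-')``.  Overlapping occurrences are
    each counted (lookahead scan).  Output is sorted by (chrom, position,
    strand); '+' orders before '-'.
    """
    if not genome:
        raise ValueError("empty genome")
    by_name = {g.name: g for g in genome}
    if chrom_subset is not None:
        missing = [c for c in chrom_subset if c not in by_name]
        if missing:
            raise KeyError(f"chromosomes not in genome: {missing}")
        selected = [by_name[c] for c in chrom_subset]
    else:
        selected = list(genome)
    sites: list[CcggSite] = []
    for rec in sorted(selected, key=lambda g: g.name):
        chrom_sites: list[CcggSite] = []
        for m in _MOTIF.finditer(rec.sequence):
            p = m.start() + 1  # 1-based first C of the plus-strand motif
            chrom_sites.append(CcggSite(rec.name, p, "+"))
            chrom_sites.append(CcggSite(rec.name, p + 3, "-"))
        chrom_sites.sort(key=lambda s: (s.position, s.strand))
        sites.extend(chrom_sites)
    return sites


def write_site_catalog_tsv(sites: Iterable[CcggSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.strand}\n")


def read_site_catalog_tsv(path: str | Path) -> list[CcggSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"{path}: expected 'chrom\\tposition\\tstrand' header")
        for line in fh:
            chrom, pos, strand = line.rstrip("\n").split("\t")
            sites.append(CcggSite(chrom, int(pos), strand))
    return sites


def write_site_catalog_bed(sites: Iterable[CcggSite], path: str | Path) -> None:
    """BED6 output: 0-based half-open single-base intervals."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position - 1}\t{s.position}\t{s.key}\t0\t{s.strand}\n")


def _attr_first(feature, *names: str) -> str:
    for name in names:
        vals = feature.attributes.get(name)
        if vals:
            return vals[0]
    return ""


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse gene/mRNA/exon features into transcript models.

    One ``TranscriptModel`` per mRNA; genes with no mRNA children produce one
    model from the gene itself (using its direct exon children, or the gene
    span as a single exon).  Exons whose Parent cannot be resolved are skipped
    with a warning and counted in the parse report.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = set()
    for ftype in ("gene", "mRNA"):
        for f in db.features_of_type(ftype):
            known_ids.add(f.id)
    exons_by_parent: dict[str, list] = {}
    n_orphan_exons = 0
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        resolved = [p for p in parents if p in known_ids]
        if not resolved:
            n_orphan_exons += 1
            continue
        for p in resolved:
            exons_by_parent.setdefault(p, []).append(exon)
    if n_orphan_exons:
        warnings.warn(f"{path}: skipped {n_orphan_exons} exon(s) without a resolvable parent")

    transcripts: list[TranscriptModel] = []
    genes_with_mrna: set[str] = set()

    def build(feature, gene_id: str, description: str) -> TranscriptModel:
        exon_feats = exons_by_parent.get(feature.id, [])
        if exon_feats:
            ivals = sorted((e.start, e.end) for e in exon_feats)
        else:
            ivals = [(feature.start, feature.end)]
        if feature.strand == "-":
            tss, tes = max(e for _, e in ivals), min(s for s, _ in ivals)
            ivals = ivals[::-1]
        else:
            tss, tes = min(s for s, _ in ivals), max(e for _, e in ivals)
        return TranscriptModel(
            gene_id=gene_id,
            transcript_id=feature.id,
            chrom=feature.seqid,
            strand=feature.strand,
            tss=tss,
            tes=tes,
            exons=ivals,
            description=description,
        )

    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else _attr_first(mrna, "gene") or mrna.id
        genes_with_mrna.add(gene_id)
        desc = _attr_first(mrna, "description", "product")
        if not desc:
            try:
                desc = _attr_first(db[gene_id], "description", "product")
            except Exception:
                desc = ""
        transcripts.append(build(mrna, gene_id, desc))
    for gene in db.features_of_type("gene"):
        if gene.id in genes_with_mrna:
            continue
        transcripts.append(build(gene, gene.id, _attr_first(gene, "description", "product")))

    report = {
        "n_transcripts": len(transcripts),
        "n_orphan_exons_skipped": n_orphan_exons,
    }
    return GenomeAnnotation(transcripts=transcripts, parse_report=report)
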