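"""Reference-genome handling, cytosine context annotation, and gene/interval input.

Coordinates are 0-based half-open everywhere in memory and in BED output; the
per-cytosine text report written by :mod:`mcseq.io` uses 1-based positions.

A cytosine *site* is any reference position carrying a C on the Watson (+)
strand or a G on the Watson strand (i.e. a C on the Crick (−) strand). ``pos``
is always the Watson-forward coordinate of that base. The context (CG, CHG,
CHH; H = A, C or T) is read from the two bases 3' of the cytosine on its own
strand; sites whose context bases run off the contig or include N are labelled
CNN, except that a C immediately followed by G is always CG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import A, C, G, N, T, seq_to_array

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH", "CNN")

_VALID = frozenset("ACGTN")


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered contig → uppercase sequence.

    ``mask`` holds soft-masked (lowercase in the source FASTA) intervals per
    contig; ``mito_contig`` optionally names the unmethylated control contig
    used to estimate the bisulfite error rate.
    """

    contigs: dict[str, str]
    mito_contig: str | None = None
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"contig {name!r} contains invalid bases {sorted(bad)}")
        if self.mito_contig is not None and self.mito_contig not in self.contigs:
            raise ValueError(f"mito_contig {self.mito_contig!r} is not a contig")

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class GeneModel:
    """A gene with exon structure; ``tss``/``tts`` follow the strand."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if self.strand == "-":
            # 5'→3' order on the minus strand runs right to left
            self.exons = self.exons[::-1]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def read_fasta(path: str | Path, mito_contig: str | None = None) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; runs of lowercase (soft-masked) bases are kept
    as intervals in ``genome.mask``. Duplicate contig names and text before
    the first header are errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:30]!r}")
            break
    contigs: dict[str, str] = {}
    mask: dict[str, list[tuple[int, int]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
        raw = str(rec.seq)
        contigs[rec.id] = raw.upper()
        lower = np.frombuffer(raw.encode("ascii"), dtype=np.uint8) >= ord("a")
        if lower.any():
            edges = np.flatnonzero(np.diff(np.concatenate(([0], lower.view(np.int8), [0]))))
            mask[rec.id] = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeSequence(contigs=contigs, mito_contig=mito_contig, mask=mask)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def annotate_contexts(genome: GenomeSequence) -> pd.DataFrame:
    """Annotate every cytosine site on both strands.

    Returns a DataFrame with columns ``contig, pos, strand, context`` sorted by
    contig (in genome order) then position; both strands are interleaved.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    frames = []
    for name, seq in genome.contigs.items():
        arr = seq_to_array(seq)
        pad = np.full(2, N, dtype=np.uint8)
        ext = np.concatenate((pad, arr, pad))  # shift by +2
        # Watson: C at i, context = bases i+1, i+2
        wpos = np.flatnonzero(arr == C)
        n1, n2 = ext[wpos + 3], ext[wpos + 4]
        wctx = _context_codes(n1 == G, n2 == G, _is_h(n1), _is_h(n2))
        # Crick: G at i is a C on the minus strand; 3' bases are complements
        # of arr[i-1], arr[i-2]; complement == G iff base == C, H iff base in {A,G,T}
        cpos = np.flatnonzero(arr == G)
        p1, p2 = ext[cpos + 1], ext[cpos]
        cctx = _context_codes(p1 == C, p2 == C, _is_h_comp(p1), _is_h_comp(p2))
        df = pd.DataFrame(
            {
                "contig": name,
                "pos": np.concatenate((wpos, cpos)),
                "strand": np.repeat(["+", "-"], [len(wpos), len(cpos)]),
                "context": pd.Categorical.from_codes(
                    np.concatenate((wctx, cctx)), categories=list(CONTEXTS)
                ),
            }
        )
        df = df.sort_values(["pos", "strand"], kind="stable")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out


def _is_h(b: np.ndarray) -> np.ndarray:
    return (b == A) | (b == C) | (b == T)


def _is_h_comp(b: np.ndarray) -> np.ndarray:
    # complement of b is H (A/C/T) iff b is T/G/A
    return (b == T) | (b == G) | (b == A)


def _context_codes(nxt_is_g, far_is_g, nxt_is_h, far_is_h) -> np.ndarray:
    codes = np.full(len(nxt_is_g), 3, dtype=np.int8)  # CNN default
    codes[nxt_is_g] = 0  # CG regardless of the second base
    codes[nxt_is_h & far_is_g] = 1  # CHG
    codes[nxt_is_h & far_is_h] = 2  # CHH
    return codes


def cg_dyads(sites: pd.DataFrame) -> pd.DataFrame:
    """Pair the two strand sites of each CpG dyad.

    Returns columns ``contig, pos`` (Watson C coordinate), ``idx_plus``,
    ``idx_minus`` (row positions into ``sites``; −1 where one strand site is
    missing, e.g. a CpG at a contig edge).
    """
    cg = sites[sites["context"] == "CG"]
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"]
    pl = pd.DataFrame(
        {"contig": plus["contig"], "pos": plus["pos"], "idx_plus": plus.index}
    )
    mi = pd.DataFrame(
        {"contig": minus["contig"], "pos": minus["pos"] - 1, "idx_minus": minus.index}
    )
    dy = pl.merge(mi, on=["contig", "pos"], how="outer")
    dy["idx_plus"] = dy["idx_plus"].fillna(-1).astype(np.int64)
    dy["idx_minus"] = dy["idx_minus"].fillna(-1).astype(np.int64)
    return dy.sort_values(["contig", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation input


def read_gtf(path: str | Path, genome: GenomeSequence | None = None) -> list[GeneModel]:
    """Read gene models from a GTF (1-based closed coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        rec = by_gene.setdefault(gid, {"contig": feat.seqid, "strand": feat.strand, "exons": []})
        rec["exons"].append((feat.start - 1, feat.end))
    return _build_genes(by_gene, genome)


def read_bed12(path: str | Path, genome: GenomeSequence | None = None) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons)."""
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            by_gene[name] = {"contig": chrom, "strand": strand, "exons": exons}
    return _build_genes(by_gene, genome)


def _build_genes(by_gene: dict[str, dict], genome: GenomeSequence | None) -> list[GeneModel]:
    genes: list[GeneModel] = []
    skipped = 0
    for gid, rec in by_gene.items():
        if genome is not None and rec["contig"] not in genome.contigs:
            skipped += 1
            continue
        exons = sorted(rec["exons"])
        start, end = exons[0][0], exons[-1][1]
        if any(s < start or e > end for s, e in exons):
            raise ValueError(f"gene {gid}: exon outside gene span")
        tss, tts = (start, end) if rec["strand"] == "+" else (end, start)
        genes.append(
            GeneModel(gene_id=gid, contig=rec["contig"], strand=rec["strand"], exons=exons, tss=tss, tts=tts)
        )
    if skipped:
        logger.warning("read_annotations: skipped %d gene(s) on unknown contigs", skipped)
    return genes


def read_bed6(path: str | Path, genome: GenomeSequence | None = None) -> pd.DataFrame:
    """Read intervals (e.g. repeats) from BED; returns contig/start/end/label."""
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            contig, start, end = f[0], int(f[1]), int(f[2])
            if genome is not None and contig not in genome.contigs:
                skipped += 1
                continue
            label = f[3] if len(f) > 3 else "."
            rows.append((contig, start, end, label))
    if skipped:
        logger.warning("read_bed6: skipped %d interval(s) on unknown contigs", skipped)
    return pd.DataFrame(rows, columns=["contig", "start", "end", "label"])


def read_annotations(
    gene_path: str | Path,
    *interval_paths: str | Path,
    genome: GenomeSequence | None = None,
) -> tuple[list[GeneModel], dict[str, pd.DataFrame]]:
    """Read gene models (GTF or BED12 by extension) plus labelled BED interval sets."""
    gene_path = Path(gene_path)
    if gene_path.suffix.lower() in {".gtf", ".gff"}:
        genes = read_gtf(gene_path, genome)
    else:
        genes = read_bed12(gene_path, genome)
    intervals = {Path(p).stem: read_bed6(p, genome) for p in interval_paths}
    return genes, intervals
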