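"""Bisulfite read pre-processing, three-letter alignment, dedup and pileup.

The protocol mirrors standard MethylC-seq processing: reads with more than
three cytosines in a non-CG (read-internal) context are discarded as
non-converted; the remainder are aligned, after three-letter conversion, to
the two computationally converted reference strands; ambiguous and
wrong-strand placements are dropped; clonal reads (same library and 5'
position) are collapsed to the first seen; and surviving alignments are piled
up into per-cytosine (m, n) counts.

The built-in aligner is an ungapped seed-and-verify search meant for toy-scale
genomes (a few Mb); genome-scale data should be aligned externally and
imported via :func:`alignments_from_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .util import A, C, G, T, contig_bounds, revcomp, seq_to_array

logger = logging.getLogger(__name__)

_C2T = bytes.maketrans(b"C", b"T")
_G2A = bytes.maketrans(b"G", b"A")


def convert_three_letter(sequence: str, mode: str) -> str:
    """Apply the bisulfite reference conversion: ``C2T`` or ``G2A``."""
    if mode == "C2T":
        return sequence.translate(_C2T)
    if mode == "G2A":
        return sequence.translate(_G2A)
    raise ValueError(f"mode must be C2T or G2A, got {mode!r}")


def count_non_cg_cytosines(sequence: str, richness: str = "T-rich") -> int:
    """Cytosines whose read-internal next base is not G (trailing C counts).

    For A-rich reads the rule is applied to the reverse complement.
    """
    if richness == "A-rich":
        sequence = revcomp(sequence)
    # every CG occurrence accounts for exactly one CG-context cytosine
    return sequence.count("C") - sequence.count("CG")


def filter_nonconverted(sequence: str, richness: str = "T-rich", max_non_cg: int = 3) -> bool:
    """True if the read is kept (at most ``max_non_cg`` non-CG cytosines)."""
    return count_non_cg_cytosines(sequence, richness) <= max_non_cg


def filter_reads(reads: pd.DataFrame, max_non_cg: int = 3) -> pd.DataFrame:
    keep = [
        filter_nonconverted(row.sequence, row.richness, max_non_cg)
        for row in reads.itertuples(index=False)
    ]
    kept = reads[np.asarray(keep)].reset_index(drop=True)
    logger.info("filter_nonconverted: kept %d/%d reads", len(kept), len(reads))
    return kept


def read_fastq(path, library_id: str = "L1", richness: str = "auto") -> pd.DataFrame:
    """Read single-end FASTQ into a read table.

    Richness is taken from a ``richness=`` tag in the description when
    present; with ``richness='auto'`` and no tag it is inferred from base
    composition (fewer C than G → T-rich).
    """
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        lib = library_id
        rich = richness
        for tok in rec.description.split():
            if tok.startswith("lib="):
                lib = tok[4:]
            elif tok.startswith("richness="):
                rich = tok[9:]
        if rich == "auto":
            rich = "T-rich" if seq.count("C") <= seq.count("G") else "A-rich"
        rows.append((rec.id, seq, lib, rich))
    return pd.DataFrame(rows, columns=["read_id", "sequence", "library_id", "richness"])


# ---------------------------------------------------------------------------
# alignment


class BisulfiteAligner:
    """Ungapped seed-and-verify aligner against the converted references.

    Both converted references are indexed: ``R1`` = Watson with C→T and
    ``R2`` = Watson with G→A (the Crick bisulfite strand in Watson
    coordinates). Three non-overlapping seeds per query guarantee that every
    placement with at most two mismatches is found (pigeonhole), so ambiguity
    detection is exact for the default mismatch cap.
    """

    def __init__(self, genome: GenomeSequence, seed_len: int = 20, max_mismatches: int = 2):
        if len(genome) == 0 or all(len(s) == 0 for s in genome.contigs.values()):
            raise ValueError("empty genome")
        self.genome = genome
        self.seed_len = seed_len
        self.max_mismatches = max_mismatches
        self.contig_names = list(genome.contigs)
        self.refs: dict[str, dict[str, np.ndarray]] = {"R1": {}, "R2": {}}
        self.index: dict[str, dict[bytes, list[tuple[str, int]]]] = {"R1": {}, "R2": {}}
        for name, seq in genome.contigs.items():
            for ref_id, mode in (("R1", "C2T"), ("R2", "G2A")):
                conv = convert_three_letter(seq, mode)
                self.refs[ref_id][name] = seq_to_array(conv)
                idx = self.index[ref_id]
                b = conv.encode("ascii")
                for i in range(0, len(b) - seed_len + 1):
                    idx.setdefault(b[i : i + seed_len], []).append((name, i))

    def _candidates(self, query: bytes, ref_id: str) -> set[tuple[str, int]]:
        k, L = self.seed_len, len(query)
        offsets = sorted({0, max((L - k) // 2, 0), max(L - k, 0)})
        cands: set[tuple[str, int]] = set()
        for off in offsets:
            for name, pos in self.index[ref_id].get(query[off : off + k], ()):
                start = pos - off
                if 0 <= start <= len(self.refs[ref_id][name]) - L:
                    cands.add((name, start))
        return cands

    def align_read(self, sequence: str, richness: str):
        """Best unique placement of one read, or (None, reason)."""
        sequence = sequence.upper()
        if richness == "T-rich":
            modes = [
                ("R1", convert_three_letter(sequence, "C2T"), "Watson", False),
                ("R2", convert_three_letter(revcomp(sequence), "G2A"), "Crick", True),
            ]
        else:
            modes = [
                ("R2", convert_three_letter(sequence, "G2A"), "Crick", False),
                ("R1", convert_three_letter(revcomp(sequence), "C2T"), "Watson", True),
            ]
        hits = []
        for ref_id, query, target, reversed_ in modes:
            q = seq_to_array(query)
            for name, start in self._candidates(query.encode("ascii"), ref_id):
                ref = self.refs[ref_id][name]
                mm = int(np.count_nonzero(ref[start : start + len(q)] != q))
                if mm <= self.max_mismatches:
                    hits.append((mm, name, start, target, reversed_))
        if not hits:
            return None, "unmapped"
        best = min(h[0] for h in hits)
        top = [h for h in hits if h[0] == best]
        if len(top) > 1:
            return None, "ambiguous"
        return top[0], None


@dataclass
class Alignment:
    read_id: str
    library_id: str
    contig: str
    start: int
    target_strand: str
    five_prime: int
    n_mismatches: int
    watson_seq: str


def align_bisulfite_reads(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    max_mismatches: int = 2,
    seed_len: int = 20,
    aligner: BisulfiteAligner | None = None,
) -> pd.DataFrame:
    """Align reads; only unique, strand-consistent placements are returned.

    The result carries, per alignment, the read sequence re-oriented to Watson
    forward coordinates (``watson_seq``) for pileup, and the 5' position used
    for clonal dedup. Drop reasons are tallied in ``result.attrs['drops']``.
    """
    if aligner is None:
        aligner = BisulfiteAligner(genome, seed_len=seed_len, max_mismatches=max_mismatches)
    rows = []
    drops = {"unmapped": 0, "ambiguous": 0}
    for row in reads.itertuples(index=False):
        hit, reason = aligner.align_read(row.sequence, row.richness)
        if hit is None:
            drops[reason] += 1
            continue
        mm, contig, start, target, reversed_ = hit
        wseq = revcomp(row.sequence) if reversed_ else row.sequence
        L = len(row.sequence)
        # the stored sequence's first base is the read's 5' end
        five_prime = start if not reversed_ else start + L - 1
        rows.append(
            (row.read_id, row.library_id, contig, start, target, five_prime, mm, wseq)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "read_id", "library_id", "contig", "start",
            "target_strand", "five_prime", "n_mismatches", "watson_seq",
        ],
    )
    out.attrs["drops"] = drops
    logger.info(
        "align_bisulfite_reads: %d unique, %d unmapped, %d ambiguous",
        len(out), drops["unmapped"], drops["ambiguous"],
    )
    return out


def alignments_from_sam(path, genome: GenomeSequence, library_id: str = "L1") -> pd.DataFrame:
    """Import externally produced ungapped bisulfite alignments from SAM.

    Reverse-strand records (FLAG 0x10) are treated as Crick-target placements
    of T-rich reads; pysam reports SEQ already on forward coordinates, which
    is what the pileup expects.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            if rec.reference_name not in genome.contigs:
                continue
            target = "Crick" if rec.is_reverse else "Watson"
            start = rec.reference_start
            L = len(rec.query_sequence)
            five_prime = start + L - 1 if rec.is_reverse else start
            rows.append(
                (rec.query_name, library_id, rec.reference_name, start, target,
                 five_prime, int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                 rec.query_sequence.upper())
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "library_id", "contig", "start",
            "target_strand", "five_prime", "n_mismatches", "watson_seq",
        ],
    )


def deduplicate_clonal(alignments: pd.DataFrame) -> pd.DataFrame:
    """Drop clonal reads: same library, contig, strand and 5' position; the
    first read in input order survives."""
    out = alignments.drop_duplicates(
        subset=["library_id", "contig", "target_strand", "five_prime"], keep="first"
    ).reset_index(drop=True)
    out.attrs = dict(alignments.attrs)
    logger.info("deduplicate_clonal: %d -> %d alignments", len(alignments), len(out))
    return out


def pileup_counts(
    alignments: pd.DataFrame,
    genome: GenomeSequence,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Pile unique, deduplicated alignments into per-site (m, n) counts.

    Watson sites count C (methylated) and T (unmethylated) read bases from
    Watson-target alignments; Crick sites count G and A (Watson-coordinate
    appearance) from Crick-target alignments. Any other base at a site is
    uninformative and excluded from n. Overhang past a contig end is ignored.
    """
    bounds = contig_bounds(sites)
    m_arr = np.zeros(len(sites), dtype=np.int64)
    n_arr = np.zeros(len(sites), dtype=np.int64)
    row_of: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, (lo, hi) in bounds.items():
        L = genome.length(contig)
        wrow = np.full(L, -1, dtype=np.int64)
        crow = np.full(L, -1, dtype=np.int64)
        sub = sites.iloc[lo:hi]
        pos = sub["pos"].to_numpy()
        plus = sub["strand"].to_numpy() == "+"
        wrow[pos[plus]] = np.arange(lo, hi)[plus]
        crow[pos[~plus]] = np.arange(lo, hi)[~plus]
        row_of[contig] = (wrow, crow)

    for row in alignments.itertuples(index=False):
        if row.contig not in row_of:
            continue
        wrow, crow = row_of[row.contig]
        L = len(row.watson_seq)
        end = min(row.start + L, len(wrow))
        if row.start >= end:
            continue
        seq = seq_to_array(row.watson_seq)[: end - row.start]
        rows_at = (wrow if row.target_strand == "Watson" else crow)[row.start : end]
        covered = rows_at >= 0
        b = seq[covered]
        r = rows_at[covered]
        if row.target_strand == "Watson":
            meth, unmeth = b == C, b == T
        else:
            meth, unmeth = b == G, b == A
        np.add.at(m_arr, r[meth], 1)
        np.add.at(n_arr, r[meth | unmeth], 1)
    return pd.DataFrame({"m": m_arr, "n": n_arr})


@dataclass
class LibraryStats:
    """Table-1-style per-sample statistics."""

    cpg_coverage_fraction: float
    conversion_rate: float | None
    mean_depth: float
    reads_in: int | None = None
    reads_after_filter: int | None = None
    reads_unique: int | None = None
    reads_post_processed: int | None = None


def library_stats(
    counts: pd.DataFrame,
    sites: pd.DataFrame,
    genome: GenomeSequence,
    chain_counts: dict[str, int] | None = None,
) -> LibraryStats:
    """CpG coverage, bisulfite conversion rate (from the mito control) and
    mean depth, plus the read-count chain when supplied."""
    cg = (sites["context"] == "CG").to_numpy()
    n = counts["n"].to_numpy()
    m = counts["m"].to_numpy()
    coverage = float((n[cg] >= 1).mean()) if cg.any() else 0.0
    conversion = None
    if genome.mito_contig is not None:
        mito = (sites["contig"] == genome.mito_contig).to_numpy()
        tot = n[mito].sum()
        if tot > 0:
            conversion = float((n[mito] - m[mito]).sum() / tot)
    chain = chain_counts or {}
    stats = LibraryStats(
        cpg_coverage_fraction=coverage,
        conversion_rate=conversion,
        mean_depth=float(n.mean()) if len(n) else 0.0,
        reads_in=chain.get("reads_in"),
        reads_after_filter=chain.get("reads_after_filter"),
        reads_unique=chain.get("reads_unique"),
        reads_post_processed=chain.get("reads_post_processed"),
    )
    vals = [v for v in (stats.reads_in, stats.reads_after_filter, stats.reads_unique,
                        stats.reads_post_processed) if v is not None]
    if any(a < b for a, b in zip(vals, vals[1:])):
        raise ValueError("read counts must be non-increasing along the processing chain")
    return stats
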