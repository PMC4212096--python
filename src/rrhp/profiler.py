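"""Strand-specific per-site counting of CCGG-tagged reads.

A read whose first four sequenced bases are the reconstituted CCGG tag reports one
5hmC event at the junction it starts from: a forward-strand read starting exactly at
a cataloged site's first C counts toward that site's forward strand, and a
reverse-strand read whose rightmost aligned base is the site's last G counts toward
the reverse strand.  Everything else (untagged, off-junction, unmapped) is tallied
but contributes no site signal.

Input can be SAM/BAM alignments (via pysam) or raw FASTQ matched with the built-in
exact junction aligner, which indexes the expected junction-anchored sequence of
every retained fragment.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Iterable, Iterator, Sequence

import pysam

from .digest import FragmentCatalog, SiteCatalog
from .io import read_fastq
from .simulate import junction_read_sequence, revcomp

__all__ = [
    "AlignedRead",
    "SiteCounts",
    "LibrarySummary",
    "has_tag",
    "assign_to_site",
    "builtin_junction_align",
    "profile",
]

logger = logging.getLogger(__name__)

TAG = "CCGG"


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read; ``seq`` is in sequencing orientation, ``pos``/``ref_end``
    delimit the reference span 0-based half-open."""

    name: str
    contig: str
    pos: int
    strand: str  # '+' or '-'
    seq: str
    ref_end: int


class SiteCounts:
    """Per-site forward/reverse CCGG-tagged read counts."""

    def __init__(self, counts: dict[tuple[str, int], list[int]] | None = None):
        # (contig, pos) -> [fwd_reads, rev_reads]
        self._counts: dict[tuple[str, int], list[int]] = counts or {}

    def add(self, contig: str, pos: int, strand: str, n: int = 1) -> None:
        pair = self._counts.setdefault((contig, pos), [0, 0])
        pair[0 if strand == "+" else 1] += n

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._counts

    def get(self, contig: str, pos: int) -> tuple[int, int]:
        fwd, rev = self._counts.get((contig, pos), (0, 0))
        return fwd, rev

    def total(self, contig: str, pos: int) -> int:
        fwd, rev = self.get(contig, pos)
        return fwd + rev

    def sites(self) -> set[tuple[str, int]]:
        return set(self._counts)

    def items(self) -> Iterator[tuple[tuple[str, int], tuple[int, int]]]:
        for key in sorted(self._counts):
            fwd, rev = self._counts[key]
            yield key, (fwd, rev)

    def totals(self) -> dict[tuple[str, int], int]:
        return {k: v[0] + v[1] for k, v in self._counts.items()}

    def n_detected(self) -> int:
        return sum(1 for v in self._counts.values() if v[0] + v[1] >= 1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\tfwd_reads\trev_reads\ttotal\n")
            for (contig, pos), (fwd, rev) in self.items():
                fh.write(f"{contig}\t{pos}\t{fwd}\t{rev}\t{fwd + rev}\n")

    @classmethod
    def from_tsv(cls, path) -> "SiteCounts":
        counts: dict[tuple[str, int], list[int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["contig", "pos", "fwd_reads", "rev_reads"]:
                raise ValueError(f"unexpected site-counts header in {path}: {header}")
            for line in fh:
                contig, pos, fwd, rev, *_ = line.rstrip("\n").split("\t")
                counts[(contig, int(pos))] = [int(fwd), int(rev)]
        return cls(counts)


@dataclass
class LibrarySummary:
    """Library-level statistics: read totals, mapping and tagging rates, site count."""

    total_reads: int
    mapped_reads: int
    mappability_pct: float
    tagged_reads: int
    tagged_pct: float
    n_sites: int
    off_junction_reads: int = 0  # tagged but not starting at a cataloged junction

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def has_tag(read_sequence: str) -> bool:
    """True iff the read's first four bases are exactly CCGG (case-insensitive)."""
    if len(read_sequence) < 4:
        raise ValueError("read shorter than the 4 bp CCGG tag")
    return read_sequence[:4].upper() == TAG


def assign_to_site(read: AlignedRead, sites: SiteCatalog):
    """Map a tagged read to the (site, strand) junction it starts from, or None.

    A '+' read is assigned when its leftmost position is the site's first C and the
    site is forward-detectable; a '-' read when its rightmost base is the site's
    last G (position + 3) and the site is reverse-detectable.
    """
    if read.strand == "+":
        entry = sites.get(read.contig, read.pos)
        if entry is not None and entry.fwd_detectable:
            return entry.site, "+"
    else:
        entry = sites.get(read.contig, read.ref_end - 4)
        if entry is not None and entry.rev_detectable:
            return entry.site, "-"
    return None


def builtin_junction_align(
    reads: Iterable[tuple[str, str]] | str | os.PathLike,
    fragments: FragmentCatalog,
    max_mismatches: int = 0,
) -> tuple[list[AlignedRead], int]:
    """Exact/near-exact matcher of reads against fragment junction sequences.

    Each retained fragment contributes up to two junction-anchored reference
    sequences (forward from its left junction, reverse-complement from its right
    junction).  A read maps iff exactly one junction sequence agrees with it over
    the read's full length within ``max_mismatches`` substitutions; ambiguous or
    failed reads stay unmapped.  Returns (alignments, total read count).

    This is a desk-scale stand-in for an external genome aligner, adequate because
    library reads are junction-anchored by construction.
    """
    if not fragments.fragments:
        raise ValueError("empty fragment catalog")
    genome = fragments.genome

    # (expected_seq, contig, leftmost pos of a full-length read, strand)
    junctions: list[tuple[str, str, int, str]] = []
    for frag in fragments:
        if frag.left_site is not None:
            seq = junction_read_sequence(genome, frag, "+", frag.length + 4)
            junctions.append((seq, frag.contig, frag.left_site.pos, "+"))
        if frag.right_site is not None:
            seq = junction_read_sequence(genome, frag, "-", frag.length + 4)
            junctions.append((seq, frag.contig, frag.right_site.pos, "-"))

    # exact-prefix index for the mismatch-free fast path
    k = min(len(s) for s, *_ in junctions)
    index: dict[str, list[int]] = {}
    for j, (seq, *_rest) in enumerate(junctions):
        index.setdefault(seq[:k], []).append(j)

    if isinstance(reads, (str, os.PathLike)):
        reads = read_fastq(reads)

    aligned: list[AlignedRead] = []
    n_total = 0
    for name, seq in reads:
        n_total += 1
        seq = seq.upper()
        if len(seq) < 4:
            continue
        matches: list[int] = []
        if max_mismatches == 0 and len(seq) >= k:
            for j in index.get(seq[:k], []):
                ref = junctions[j][0]
                if len(ref) >= len(seq) and ref[: len(seq)] == seq:
                    matches.append(j)
        else:
            for j, (ref, *_rest) in enumerate(junctions):
                if len(ref) < len(seq):
                    continue
                mm = sum(a != b for a, b in zip(seq, ref))
                if mm <= max_mismatches:
                    matches.append(j)
        if len(matches) != 1:
            continue  # unmapped: no hit, or ambiguous placement
        _, contig, site_pos, strand = junctions[matches[0]]
        if strand == "+":
            pos = site_pos
            ref_end = pos + len(seq)
        else:
            ref_end = site_pos + 4
            pos = ref_end - len(seq)
        aligned.append(AlignedRead(name, contig, pos, strand, seq, ref_end))
    return aligned, n_total


def _iter_sam(path: str | os.PathLike) -> Iterator[tuple[AlignedRead | None, bool]]:
    """Yield (aligned read or None, counted-as-total) from a SAM/BAM file.

    Unmapped records yield (None, True); malformed records are skipped with a
    warning and still counted in the total.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(os.fspath(path), mode, check_sq=False) as fh:
        for rec in fh:
            try:
                if rec.is_unmapped or rec.reference_name is None:
                    yield None, True
                    continue
                seq = rec.query_sequence
                if seq is None or rec.reference_end is None:
                    logger.warning("skipping malformed SAM record %s", rec.query_name)
                    yield None, True
                    continue
                strand = "-" if rec.is_reverse else "+"
                # SAM stores '-' reads reference-forward; restore sequencing orientation
                if rec.is_reverse:
                    seq = revcomp(seq)
                yield AlignedRead(
                    rec.query_name, rec.reference_name, rec.reference_start,
                    strand, seq, rec.reference_end,
                ), True
            except (ValueError, AttributeError) as exc:
                logger.warning("skipping malformed SAM record: %s", exc)
                yield None, True


def profile(
    reads,
    sites: SiteCatalog,
    fragments: FragmentCatalog | None = None,
    max_mismatches: int = 0,
) -> tuple[SiteCounts, LibrarySummary]:
    """Count CCGG-tagged reads per (site, strand).

    ``reads`` may be a SAM/BAM path, a list of :class:`AlignedRead`, or — when
    ``fragments`` is given — a FASTQ path or (name, sequence) iterable routed
    through :func:`builtin_junction_align`.  Every tagged read assigned to a
    detectable junction is counted once; untagged and off-junction reads appear
    only in the summary tallies.
    """
    is_path = isinstance(reads, (str, os.PathLike))
    if is_path and str(reads).endswith((".sam", ".bam")):
        aligned = []
        n_total = 0
        for rec, _ in _iter_sam(reads):
            n_total += 1
            if rec is not None:
                aligned.append(rec)
        n_mapped = len(aligned)
        stream: Sequence[AlignedRead] = aligned
    elif fragments is not None:
        aligned, n_total = builtin_junction_align(reads, fragments, max_mismatches)
        n_mapped = len(aligned)
        stream = aligned
    elif is_path:
        raise ValueError("a FASTQ input requires a FragmentCatalog for the built-in matcher")
    else:
        stream = list(reads)
        n_total = n_mapped = len(stream)

    counts = SiteCounts()
    tagged = 0
    off_junction = 0
    for read in stream:
        if len(read.seq) < 4 or not has_tag(read.seq):
            continue
        tagged += 1
        assignment = assign_to_site(read, sites)
        if assignment is None:
            off_junction += 1
            continue
        site, strand = assignment
        counts.add(site.contig, site.pos, strand)

    summary = LibrarySummary(
        total_reads=n_total,
        mapped_reads=n_mapped,
        mappability_pct=100.0 * n_mapped / n_total if n_total else 0.0,
        tagged_reads=tagged,
        tagged_pct=100.0 * tagged / n_mapped if n_mapped else 0.0,
        n_sites=counts.n_detected(),
        off_junction_reads=off_junction,
    )
    return counts, summary
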