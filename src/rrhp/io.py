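"""File plumbing: FASTA, BED6, FASTQ and the TSV dialects used across the tool."""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

from .digest import CutSite, Fragment, FragmentCatalog, Genome, SiteCatalog, SiteEntry


def read_fasta(path: str | os.PathLike) -> Genome:
    """Load a (multi-record, possibly line-wrapped) FASTA file as a Genome."""
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- BED6 ---------------------------------------------------------------

def write_fragments_bed(catalog: FragmentCatalog, path: str | os.PathLike) -> None:
    """One BED6 line per fragment (strand '.', name frag<i>, score 0)."""
    with open(path, "w") as fh:
        for i, frag in enumerate(catalog.fragments):
            fh.write(f"{frag.contig}\t{frag.start}\t{frag.end}\tfrag{i}\t0\t.\n")


def write_sites_bed(sites: SiteCatalog, path: str | os.PathLike) -> None:
    """One BED6 line per detectable strand of each site, spanning the CCGG 4-mer."""
    with open(path, "w") as fh:
        for e in sites:
            if e.fwd_detectable:
                fh.write(f"{e.site.contig}\t{e.site.pos}\t{e.site.pos + 4}\t.\t0\t+\n")
            if e.rev_detectable:
                fh.write(f"{e.site.contig}\t{e.site.pos}\t{e.site.pos + 4}\t.\t0\t-\n")


def read_sites_bed(path: str | os.PathLike) -> SiteCatalog:
    """Inverse of :func:`write_sites_bed`; strand rows for a site are merged."""
    flags: dict[tuple[str, int], list[bool]] = {}
    order: list[tuple[str, int]] = []
    for line_no, line in enumerate(open(path), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{line_no}: expected BED6, got {len(parts)} columns")
        contig, start, _end, _name, _score, strand = parts[:6]
        key = (contig, int(start))
        if key not in flags:
            flags[key] = [False, False]
            order.append(key)
        if strand == "+":
            flags[key][0] = True
        elif strand == "-":
            flags[key][1] = True
        else:
            raise ValueError(f"{path}:{line_no}: site strand must be + or -")
    entries = [
        SiteEntry(CutSite(contig, pos), fwd, rev)
        for (contig, pos), (fwd, rev) in ((k, flags[k]) for k in order)
    ]
    return SiteCatalog(entries)


def read_bed_intervals(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read BED records as (contig, start, end, name); name defaults to ''.

    Used for category-labelled annotation tracks (column 4 is the category).
    """
    out: list[tuple[str, int, int, str]] = []
    for line_no, line in enumerate(open(path), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: expected >=3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: non-integer coordinates") from exc
        if end <= start:
            raise ValueError(f"{path}:{line_no}: empty or inverted interval")
        name = parts[3] if len(parts) > 3 else ""
        out.append((parts[0], start, end, name))
    return out


def read_fragments_bed(path: str | os.PathLike, genome: Genome) -> FragmentCatalog:
    """Rebuild a FragmentCatalog from a fragments BED plus its genome.

    Junction sites are re-derived by checking for the CCGG motif around each
    fragment boundary, so the result round-trips with :func:`write_fragments_bed`
    for catalogs produced by digestion.
    """
    fragments: list[Fragment] = []
    for contig, start, end, _name in read_bed_intervals(path):
        seq = genome[contig]
        left = None
        if start >= 1 and seq[start - 1 : start + 3] == "CCGG":
            left = CutSite(contig, start - 1)
        right = None
        if seq[end - 1 : end + 3] == "CCGG":
            right = CutSite(contig, end - 1)
        fragments.append(Fragment(contig, start, end, left, right))
    return FragmentCatalog(genome=genome, fragments=fragments, size_range=None)


# --- FASTQ --------------------------------------------------------------

def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike,
                quality_char: str = "I") -> int:
    """Write (name, sequence) pairs as 4-line FASTQ records with constant quality."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a 4-line-record FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            if len(qual.rstrip('\n')) != len(seq):
                raise ValueError(f"quality/sequence length mismatch for {header!r}")
            yield header[1:].split()[0].rstrip("\n"), seq
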