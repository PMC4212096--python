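"""In silico restriction digestion and the catalog of detectable CCGG junction sites.

MspI cleaves C^CGG irrespective of CpG methylation or hydroxymethylation, so an
exhaustive scan of a reference genome for the CCGG motif predicts every fragment a
reduced-representation 5hmC library can contain.  After size selection, each retained
fragment exposes up to two adapter junctions; the CpG cytosines at those junctions
(forward strand at ``pos + 1``, reverse strand at ``pos + 2`` of the motif) are the
only positions the assay can interrogate.  This module computes the fragment catalog
and the per-strand detectability flags that every downstream stage keys on.

Coordinates are 0-based half-open throughout; a site is keyed by the position of the
first C of its forward-strand CCGG occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MSPI_MOTIF",
    "DEFAULT_MIN_INSERT",
    "DEFAULT_MAX_INSERT",
    "Genome",
    "CutSite",
    "Fragment",
    "FragmentCatalog",
    "SiteEntry",
    "SiteCatalog",
    "find_sites",
    "digest",
    "size_select",
    "detectable_sites",
]

MSPI_MOTIF = "CCGG"

# Insert-space analogue of the 110-500 bp gel window (adapters contribute ~70 bp).
DEFAULT_MIN_INSERT = 40
DEFAULT_MAX_INSERT = 430

_VALID_BASES = frozenset("ACGTN")


class Genome:
    """An ordered collection of named contigs.

    Input sequences are normalized to upper case; only A/C/G/T/N are accepted.
    Contig order is preserved so digestion output is deterministic.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        normalized: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if name in normalized:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            normalized[name] = seq
        self._contigs = normalized

    @property
    def contigs(self) -> dict[str, str]:
        return dict(self._contigs)

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        total = sum(len(s) for s in self._contigs.values())
        return f"Genome({len(self._contigs)} contigs, {total} bp)"


@dataclass(frozen=True, order=True)
class CutSite:
    """A forward-strand CCGG occurrence; ``pos`` indexes its first C."""

    contig: str
    pos: int


@dataclass(frozen=True)
class Fragment:
    """A digestion product as a top-strand interval ``[start, end)``.

    ``left_site``/``right_site`` are the cut sites bounding the fragment, or None at
    a contig boundary (boundary ends carry no reconstituted junction).  Lengths are
    measured between consecutive top-strand cut coordinates, so fragments tile the
    contig and the 2-nt 5'-CG overhang is not double-counted.
    """

    contig: str
    start: int
    end: int
    left_site: CutSite | None
    right_site: CutSite | None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentCatalog:
    """MspI fragments of a genome, optionally restricted to a size window."""

    genome: Genome
    fragments: list[Fragment]
    size_range: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def fragment_sequence(self, frag: Fragment) -> str:
        return self.genome[frag.contig][frag.start : frag.end]


@dataclass(frozen=True)
class SiteEntry:
    """A cut site with per-strand detectability.

    ``fwd_detectable``: some retained fragment begins at this site, so a read can
    interrogate the forward-strand CpG cytosine at ``pos + 1``.
    ``rev_detectable``: some retained fragment ends here, interrogating the
    reverse-strand cytosine at ``pos + 2``.
    """

    site: CutSite
    fwd_detectable: bool
    rev_detectable: bool


@dataclass
class SiteCatalog:
    """Detectable junction sites of a (size-selected) fragment catalog."""

    entries: list[SiteEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {(e.site.contig, e.site.pos): e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SiteEntry]:
        return iter(self.entries)

    def get(self, contig: str, pos: int) -> SiteEntry | None:
        return self._index.get((contig, pos))

    def positions(self) -> set[tuple[str, int]]:
        return set(self._index)

    def strand_pairs(self) -> list[tuple[str, int, str]]:
        """All detectable (contig, pos, strand) triples, in catalog order."""
        out: list[tuple[str, int, str]] = []
        for e in self.entries:
            if e.fwd_detectable:
                out.append((e.site.contig, e.site.pos, "+"))
            if e.rev_detectable:
                out.append((e.site.contig, e.site.pos, "-"))
        return out


def find_sites(genome: Genome, motif: str = MSPI_MOTIF) -> list[CutSite]:
    """Locate every forward-strand occurrence of ``motif`` (default CCGG).

    Overlapping occurrences are each reported; any occurrence containing N is
    excluded.  Sites come back sorted by (contig order, position).
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be a non-empty A/C/G/T string, got {motif!r}")
    sites: list[CutSite] = []
    k = len(motif)
    for name in genome:
        seq = genome[name]
        start = 0
        while True:
            i = seq.find(motif, start)
            if i == -1:
                break
            sites.append(CutSite(name, i))
            start = i + 1  # step 1 so overlapping motifs are all seen
        _ = k
    return sites


def digest(genome: Genome, motif: str = MSPI_MOTIF, cut_offset: int = 1) -> FragmentCatalog:
    """Digest a genome at every motif occurrence.

    The cut coordinate for a site at ``pos`` is ``pos + cut_offset`` (MspI cuts
    between the first C and CGG on the top strand, offset 1).  Fragments are the
    intervals between consecutive cut coordinates plus the contig ends, so per
    contig they tile ``[0, length)`` and number ``sites + 1``.
    """
    sites = find_sites(genome, motif)
    by_contig: dict[str, list[CutSite]] = {name: [] for name in genome}
    for s in sites:
        by_contig[s.contig].append(s)

    fragments: list[Fragment] = []
    for name in genome:
        length = len(genome[name])
        contig_sites = by_contig[name]
        cuts = [s.pos + cut_offset for s in contig_sites]
        bounds = [0] + cuts + [length]
        left: list[CutSite | None] = [None] + list(contig_sites)
        right: list[CutSite | None] = list(contig_sites) + [None]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            fragments.append(Fragment(name, start, end, left[i], right[i]))
    return FragmentCatalog(genome=genome, fragments=fragments, size_range=None)


def size_select(
    catalog: FragmentCatalog,
    min_len: int = DEFAULT_MIN_INSERT,
    max_len: int = DEFAULT_MAX_INSERT,
) -> FragmentCatalog:
    """Retain fragments with ``min_len <= length <= max_len`` (inclusive)."""
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid size range [{min_len}, {max_len}]")
    kept = [f for f in catalog.fragments if min_len <= f.length <= max_len]
    return FragmentCatalog(genome=catalog.genome, fragments=kept, size_range=(min_len, max_len))


def detectable_sites(catalog: FragmentCatalog) -> SiteCatalog:
    """Flag each cut site bordering a retained fragment by detectable strand.

    A site is forward-detectable iff it is the left junction of a retained
    fragment, reverse-detectable iff it is the right junction; a site interior to
    two retained fragments gets both flags.  Contig-boundary fragment ends have no
    site and contribute nothing.
    """
    fwd: set[CutSite] = set()
    rev: set[CutSite] = set()
    for frag in catalog.fragments:
        if frag.left_site is not None:
            fwd.add(frag.left_site)
        if frag.right_site is not None:
            rev.add(frag.right_site)
    order = {name: i for i, name in enumerate(catalog.genome)}
    entries = [
        SiteEntry(site, site in fwd, site in rev)
        for site in sorted(fwd | rev, key=lambda s: (order[s.contig], s.pos))
    ]
    return SiteCatalog(entries)
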