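"""Molecule-level simulation of the positive-display 5hmC library workflow.

The simulated chemistry follows the assay: a genome is digested with MspI, the
size-selected fragments are adapterized (only hetero-adapterized molecules with the
junction-reconstituting adapter at a genuine CCGG junction can amplify), 5hmC at the
adapter junction is optionally glucosylated by beta-glucosyltransferase, and a second
digestion with MspI (blocked only by glucosyl-5hmC) or HpaII (blocked by 5mC, 5hmC,
or glucosyl-5hmC) destroys unprotected molecules.  Survivors are PCR-duplicated and
emit single-end reads starting with the reconstituted CCGG tag.

Randomness is driven by a single numpy Generator seeded from the config, so the same
inputs always produce byte-identical FASTQ and truth output.  The stochastic draws
(adapter orientation, junction cytosine state, digestion-escape uniform) are made in
:func:`enumerate_molecules` independently of the enzyme setting; the survival rule in
:func:`apply_second_digestion` is deterministic, which lets callers compare enzyme
chemistries on exactly the same molecule population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digest import (
    DEFAULT_MAX_INSERT,
    DEFAULT_MIN_INSERT,
    Fragment,
    FragmentCatalog,
    Genome,
    SiteCatalog,
    detectable_sites,
    digest,
    find_sites,
    size_select,
)

__all__ = [
    "EpiProfile",
    "LibraryConfig",
    "Molecule",
    "TruthTable",
    "make_genome",
    "make_profile",
    "enumerate_molecules",
    "apply_second_digestion",
    "simulate_library",
    "junction_read_sequence",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# cytosine states at the junction CpG
UNMODIFIED = "u"
MC = "m"
HMC = "h"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class EpiProfile:
    """Per (site, strand) ground-truth 5hmC and 5mC fractions.

    Keys are (contig, site position, strand); values satisfy
    ``0 <= hmc, 0 <= mc, hmc + mc <= 1``.  A valid profile covers exactly the
    detectable (site, strand) pairs of a SiteCatalog.
    """

    def __init__(self, fractions: dict[tuple[str, int, str], tuple[float, float]]):
        clean: dict[tuple[str, int, str], tuple[float, float]] = {}
        for key, (hmc, mc) in fractions.items():
            if not (0.0 <= hmc <= 1.0 and 0.0 <= mc <= 1.0 and hmc + mc <= 1.0 + 1e-9):
                raise ValueError(f"invalid fractions at {key}: hmc={hmc}, mc={mc}")
            if hmc + mc > 1.0:  # round-trip rounding at the simplex boundary
                mc = 1.0 - hmc
            clean[key] = (hmc, mc)
        self._fractions = clean

    def __len__(self) -> int:
        return len(self._fractions)

    def __getitem__(self, key: tuple[str, int, str]) -> tuple[float, float]:
        return self._fractions[key]

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._fractions

    def keys(self):
        return self._fractions.keys()

    def items(self):
        return self._fractions.items()

    def check_matches(self, sites: SiteCatalog) -> None:
        expected = set(sites.strand_pairs())
        got = set(self._fractions)
        if expected != got:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"profile does not cover the detectable (site, strand) pairs: "
                f"{len(missing)} missing, {len(extra)} extra"
            )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\tstrand\thmc_fraction\tmc_fraction\n")
            for (contig, pos, strand), (hmc, mc) in self._fractions.items():
                fh.write(f"{contig}\t{pos}\t{strand}\t{hmc:.10g}\t{mc:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "EpiProfile":
        df = pd.read_csv(path, sep="\t")
        fractions = {
            (str(r.contig), int(r.pos), str(r.strand)): (float(r.hmc_fraction), float(r.mc_fraction))
            for r in df.itertuples()
        }
        return cls(fractions)


@dataclass
class LibraryConfig:
    """Tunable parameters of one simulated library preparation."""

    n_molecules_per_fragment: int = 100
    beta_gt: bool = True
    second_enzyme: str = "MspI"  # "MspI" or "HpaII"
    digestion_failure_rate: float = 0.0
    hetero_adapter_prob: float = 0.5
    insert_range: tuple[int, int] = (DEFAULT_MIN_INSERT, DEFAULT_MAX_INSERT)
    read_length: int = 50
    seq_error_rate: float = 0.0
    pcr_duplicate_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.second_enzyme not in ("MspI", "HpaII"):
            raise ValueError(f"second_enzyme must be 'MspI' or 'HpaII', got {self.second_enzyme!r}")
        for name in ("digestion_failure_rate", "hetero_adapter_prob", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 4:
            raise ValueError("read_length must be >= 4 (the read must contain the CCGG tag)")
        if self.pcr_duplicate_mean < 1.0:
            raise ValueError("pcr_duplicate_mean must be >= 1")
        if self.n_molecules_per_fragment < 1:
            raise ValueError("n_molecules_per_fragment must be >= 1")


@dataclass(frozen=True)
class Molecule:
    """One hetero-adapterized molecule with its junction state and escape draw."""

    fragment_index: int
    contig: str
    site_pos: int
    strand: str  # '+' = P5 at the left junction, '-' = P5 at the right junction
    state: str  # UNMODIFIED / MC / HMC at the P5-junction CpG cytosine
    escape_u: float  # pre-drawn uniform deciding incomplete-digestion escape
    molecule_id: int


class TruthTable:
    """Ground truth per detectable (site, strand): fractions, molecule and read fates."""

    COLUMNS = ["contig", "pos", "strand", "hmc_true", "mc_true", "drawn", "surviving", "reads"]

    def __init__(self, rows: dict[tuple[str, int, str], dict]):
        self.rows = rows

    def __getitem__(self, key: tuple[str, int, str]) -> dict:
        return self.rows[key]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"contig": c, "pos": p, "strand": s, **vals}
            for (c, p, s), vals in self.rows.items()
        ]
        df = pd.DataFrame(records, columns=self.COLUMNS)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        rows = {
            (str(r.contig), int(r.pos), str(r.strand)): {
                "hmc_true": float(r.hmc_true),
                "mc_true": float(r.mc_true),
                "drawn": int(r.drawn),
                "surviving": int(r.surviving),
                "reads": int(r.reads),
            }
            for r in df.itertuples()
        }
        return cls(rows)


def make_genome(
    n_contigs: int,
    contig_length: int,
    target_site_count: int,
    seed: int,
) -> Genome:
    """Random test genome with at least ``target_site_count`` CCGG sites per contig.

    The background sequence is uniform A/C/G/T; the target count is guaranteed by
    planting non-overlapping CCGG motifs at jittered regular spacing (chance
    occurrences in the background can only add sites).
    """
    if n_contigs < 1 or contig_length < 4 or target_site_count < 0:
        raise ValueError("n_contigs >= 1, contig_length >= 4, target_site_count >= 0 required")
    if target_site_count > 0 and (contig_length - 4) // target_site_count < 4:
        raise ValueError(
            f"cannot fit {target_site_count} CCGG sites in a {contig_length} bp contig"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    contigs: dict[str, str] = {}
    for c in range(n_contigs):
        arr = rng.integers(0, 4, size=contig_length)
        seq = list(bases[arr])
        if target_site_count > 0:
            step = (contig_length - 4) // target_site_count
            for i in range(target_site_count):
                jitter = int(rng.integers(0, step - 3)) if step > 4 else 0
                pos = i * step + jitter
                seq[pos : pos + 4] = list("CCGG")
        contigs[f"contig{c + 1}"] = "".join(seq)
    return Genome(contigs)


def make_profile(
    sites: SiteCatalog,
    hmc_beta_params: tuple[float, float] = (2.0, 5.0),
    mc_beta_params: tuple[float, float] = (2.0, 2.0),
    zero_hmc_fraction: float = 0.0,
    seed: int = 0,
) -> EpiProfile:
    """Draw a ground-truth profile: Beta-distributed fractions per (site, strand).

    With probability ``zero_hmc_fraction`` a (site, strand) gets exactly zero 5hmC (a
    point mass emulating the large unhydroxymethylated background of real genomes);
    otherwise hmc ~ Beta(hmc_beta_params).  mc ~ Beta(mc_beta_params) independently,
    clipped so hmc + mc <= 1.
    """
    for a, b in (hmc_beta_params, mc_beta_params):
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
    if not 0.0 <= zero_hmc_fraction <= 1.0:
        raise ValueError("zero_hmc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fractions: dict[tuple[str, int, str], tuple[float, float]] = {}
    for key in sites.strand_pairs():
        if rng.random() < zero_hmc_fraction:
            hmc = 0.0
        else:
            hmc = float(rng.beta(*hmc_beta_params))
        mc = float(rng.beta(*mc_beta_params))
        if hmc + mc > 1.0:
            mc = 1.0 - hmc
        fractions[key] = (hmc, mc)
    return EpiProfile(fractions)


def enumerate_molecules(
    catalog: FragmentCatalog,
    profile: EpiProfile,
    config: LibraryConfig,
    rng: np.random.Generator,
) -> list[Molecule]:
    """Draw the stochastic fate of every adapterized molecule, enzyme-agnostically.

    For each retained fragment, ``n_molecules_per_fragment`` ligation events are
    attempted.  A molecule contributes only if it is hetero-adapterized (probability
    ``hetero_adapter_prob``; homo-adapterized molecules hairpin and never amplify)
    and the end carrying the junction-reconstituting adapter is a true CCGG junction
    rather than a contig boundary.  The junction cytosine state is drawn from the
    profile on the strand the junction interrogates.  An escape uniform is drawn for
    every molecule so that downstream survival rules for different enzymes consume
    identical randomness.
    """
    molecules: list[Molecule] = []
    mol_id = 0
    for frag_idx, frag in enumerate(catalog.fragments):
        for _ in range(config.n_molecules_per_fragment):
            hetero = rng.random() < config.hetero_adapter_prob
            left_p5 = rng.random() < 0.5
            u_state = rng.random()
            u_escape = rng.random()
            mol_id += 1
            if not hetero:
                continue
            site = frag.left_site if left_p5 else frag.right_site
            if site is None:
                continue  # boundary end: no reconstituted junction, nothing amplifies
            strand = "+" if left_p5 else "-"
            hmc, mc = profile[(frag.contig, site.pos, strand)]
            if u_state < hmc:
                state = HMC
            elif u_state < hmc + mc:
                state = MC
            else:
                state = UNMODIFIED
            molecules.append(
                Molecule(frag_idx, frag.contig, site.pos, strand, state, u_escape, mol_id)
            )
    return molecules


def survives_second_digestion(
    state: str, escape_u: float, enzyme: str, beta_gt: bool, failure_rate: float
) -> bool:
    """Deterministic survival rule for one molecule.

    MspI cleaves any junction except glucosyl-5hmC; HpaII is additionally blocked by
    5mC and (glucosylated or not) 5hmC.  A cleavable molecule still escapes when its
    pre-drawn uniform falls below the incomplete-digestion rate.
    """
    if enzyme == "MspI":
        protected = beta_gt and state == HMC
    else:  # HpaII
        protected = state in (MC, HMC)
    return protected or escape_u < failure_rate


def apply_second_digestion(
    molecules: Iterable[Molecule],
    enzyme: str,
    beta_gt: bool,
    failure_rate: float,
) -> list[Molecule]:
    return [
        m
        for m in molecules
        if survives_second_digestion(m.state, m.escape_u, enzyme, beta_gt, failure_rate)
    ]


def junction_read_sequence(
    genome: Genome, frag: Fragment, strand: str, read_length: int
) -> str:
    """The error-free read a junction emits: CCGG tag plus fragment sequence.

    Forward reads run along the top strand from the site's first C (the adapter
    restores that C, and CGG is the fragment's overhang); reverse reads are the
    reverse complement ending at the last G of the site 4-mer.  Reads are truncated
    at ``read_length`` or at the sequenced strand's far end, whichever comes first
    (the bottom strand stops two bases short of the far cut because of the 5'-CG
    overhangs).
    """
    seq = genome[frag.contig]
    if strand == "+":
        if frag.left_site is None:
            raise ValueError("fragment has no left junction")
        start = frag.left_site.pos
        return seq[start : min(start + read_length, frag.end)]
    elif strand == "-":
        if frag.right_site is None:
            raise ValueError("fragment has no right junction")
        end = frag.right_site.pos + 4
        limit = frag.start + 2 if frag.left_site is not None else frag.start
        return revcomp(seq[max(end - read_length, limit) : end])
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACGT"}
    for i in hits:
        chars[i] = others[chars[i]][rng.integers(0, len(others[chars[i]]))]
    return "".join(chars)


def simulate_library(
    genome: Genome,
    profile: EpiProfile,
    config: LibraryConfig,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Run the full library workflow; return FASTQ records and the truth table.

    Returns a list of ``(read_name, sequence)`` pairs (write with
    :func:`rrhp.io.write_fastq`) and a :class:`TruthTable` keyed by
    (contig, site position, strand).  Read names encode
    ``contig|sitepos|strand|m<molecule>|c<copy>`` for truth matching.
    """
    catalog = size_select(digest(genome), *config.insert_range)
    sites = detectable_sites(catalog)
    profile.check_matches(sites)

    rng = np.random.default_rng(config.seed)
    molecules = enumerate_molecules(catalog, profile, config, rng)
    survivors = apply_second_digestion(
        molecules, config.second_enzyme, config.beta_gt, config.digestion_failure_rate
    )
    surviving_ids = {m.molecule_id for m in survivors}

    rows: dict[tuple[str, int, str], dict] = {}
    for contig, pos, strand in sites.strand_pairs():
        hmc, mc = profile[(contig, pos, strand)]
        rows[(contig, pos, strand)] = {
            "hmc_true": hmc,
            "mc_true": mc,
            "drawn": 0,
            "surviving": 0,
            "reads": 0,
        }
    for m in molecules:
        row = rows[(m.contig, m.site_pos, m.strand)]
        row["drawn"] += 1
        if m.molecule_id in surviving_ids:
            row["surviving"] += 1

    reads: list[tuple[str, str]] = []
    for m in survivors:
        frag = catalog.fragments[m.fragment_index]
        template = junction_read_sequence(genome, frag, m.strand, config.read_length)
        if config.pcr_duplicate_mean > 1.0:
            copies = int(rng.geometric(1.0 / config.pcr_duplicate_mean))
        else:
            copies = 1
        for c in range(copies):
            seq = _apply_errors(template, config.seq_error_rate, rng)
            name = f"{m.contig}|{m.site_pos}|{m.strand}|m{m.molecule_id}|c{c}"
            reads.append((name, seq))
        rows[(m.contig, m.site_pos, m.strand)]["reads"] += copies

    return reads, TruthTable(rows)
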