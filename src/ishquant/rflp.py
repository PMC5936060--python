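"""In-silico PCR and restriction-digest (RFLP) genotyping.

Zebrafish point mutants and small indels are routinely genotyped by
amplifying the locus and digesting with a restriction enzyme whose
recognition site is destroyed by the mutation: the wild-type allele cuts
into two bands, the mutant allele stays as one, and a heterozygote shows
all three. This module performs that assay in silico — locating
(possibly IUPAC-degenerate) recognition sites, predicting fragment
lengths for a linear amplicon, deriving the expected band pattern per
genotype, and calling a genotype from an observed band set with a
gel-resolution tolerance.

Only top-strand cut coordinates are used: gel band sizes do not resolve
sticky-end overhangs. Amplicons are treated as linear molecules;
circular templates are unsupported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "NucleotideSequence",
    "RestrictionEnzyme",
    "PrimerPair",
    "DigestResult",
    "GenotypeCall",
    "ENZYMES",
    "InvalidPatternError",
    "NoAmpliconError",
    "UninformativeAssayError",
    "match_iupac",
    "find_sites",
    "digest",
    "find_amplicon",
    "expected_band_patterns",
    "call_genotype",
    "read_fasta",
    "write_fasta",
    "read_band_table",
    "enzyme_from_config",
]

# Degeneracy sets for IUPAC nucleotide codes. N in the *sequence* never
# matches any code (conservative: unknown bases must not create sites).
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_VALID_BASES = frozenset("ACGTN")


class InvalidPatternError(ValueError):
    """Recognition pattern contains a non-IUPAC character."""


class NoAmpliconError(ValueError):
    """Primer pair does not define a unique amplicon on the template."""


class UninformativeAssayError(ValueError):
    """Wild-type and mutant alleles produce identical band patterns."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A, C, G, T, N}, stored uppercase."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise ValueError("sequence must be non-empty")
        bad = set(bases) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in {self.name!r}: {sorted(bad)}")
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        rc = str(Seq(self.bases).reverse_complement())
        return NucleotideSequence(f"{self.name}_rc", rc)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset.

    ``cut_offset`` is the 0-based position within the site after which the
    top strand is cut (0..len(site)).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        bad = set(site) - set(IUPAC_CODES)
        if bad:
            raise InvalidPatternError(
                f"{self.name}: non-IUPAC characters in site: {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.name}: cut_offset outside 0..{len(site)}")
        object.__setattr__(self, "site", site)


# REBASE top-strand conventions: HaeII RGCGC^Y, SacII CCGC^GG.
ENZYMES: Mapping[str, RestrictionEnzyme] = {
    "HaeII": RestrictionEnzyme("HaeII", "RGCGCY", 5),
    "SacII": RestrictionEnzyme("SacII", "CCGCGG", 4),
}


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3'."""

    forward: NucleotideSequence
    reverse: NucleotideSequence

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError(f"primer {p.name!r} shorter than 10 bases")


@dataclass(frozen=True)
class DigestResult:
    """Predicted fragment lengths (descending) of a complete linear digest."""

    fragment_lengths: tuple[int, ...]
    n_sites: int

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")
        if len(self.fragment_lengths) != self.n_sites + 1:
            raise ValueError("fragment count must equal n_sites + 1")

    @property
    def bands(self) -> tuple[int, ...]:
        """Distinct band lengths as resolved on a gel (descending)."""
        return tuple(sorted(set(self.fragment_lengths), reverse=True))


@dataclass(frozen=True)
class GenotypeCall:
    """A WT / HET / MUT call, or UNKNOWN when no pattern matches."""

    call: str

    VALID = ("WT", "HET", "MUT", "UNKNOWN")

    def __post_init__(self) -> None:
        if self.call not in self.VALID:
            raise ValueError(f"invalid genotype call {self.call!r}")


def match_iupac(pattern: str, window: str) -> bool:
    """True iff ``window`` matches the IUPAC ``pattern`` base by base.

    An N in the *window* never matches (unknown bases are not allowed to
    create phantom sites); an N in the pattern matches any concrete base.
    """
    if len(window) != len(pattern):
        raise ValueError("window and pattern lengths differ")
    for code, base in zip(pattern.upper(), window.upper()):
        allowed = IUPAC_CODES.get(code)
        if allowed is None:
            raise InvalidPatternError(f"unknown IUPAC code {code!r}")
        if base not in allowed:  # N in window is not in any set's singleton
            return False
    return True


def find_sites(seq: NucleotideSequence | str, enzyme: RestrictionEnzyme) -> list[int]:
    """All top-strand cut positions of ``enzyme`` on a linear sequence.

    A cut position p means the backbone is cut between bases p-1 and p
    (0-based). Overlapping site occurrences are all reported.
    """
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq.upper()
    site, off = enzyme.site, enzyme.cut_offset
    w = len(site)
    cuts = [
        m + off
        for m in range(len(bases) - w + 1)
        if match_iupac(site, bases[m : m + w])
    ]
    return sorted(set(cuts))


def digest(seq: NucleotideSequence | str, enzyme: RestrictionEnzyme) -> DigestResult:
    """Complete digest of a linear molecule: all sites cut simultaneously.

    Fragment lengths are differences between consecutive interior cut
    positions; cuts falling exactly at either molecule end produce no
    fragment and are not counted.
    """
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq.upper()
    n = len(bases)
    cuts = [c for c in find_sites(bases, enzyme) if 0 < c < n]
    bounds = [0, *cuts, n]
    frags = sorted(
        (b - a for a, b in zip(bounds[:-1], bounds[1:])), reverse=True
    )
    return DigestResult(tuple(frags), n_sites=len(cuts))


def _exact_hits(template: str, probe: str) -> list[int]:
    """Start positions of exact occurrences of probe (overlaps allowed)."""
    return [m.start() for m in re.finditer(f"(?={re.escape(probe)})", template)]


def find_amplicon(
    template: NucleotideSequence, primers: PrimerPair
) -> NucleotideSequence:
    """In-silico PCR: the template span bounded by a unique primer pair.

    The forward primer must occur exactly once on the top strand and the
    reverse-complement of the reverse primer exactly once downstream of it;
    the amplicon runs from the forward start to the end of the reverse
    binding site, inclusive.
    """
    fwd_hits = _exact_hits(template.bases, primers.forward.bases)
    if len(fwd_hits) != 1:
        raise NoAmpliconError(
            f"forward primer binds {len(fwd_hits)} times (need exactly 1)"
        )
    rev_site = primers.reverse.reverse_complement().bases
    rev_hits = [
        h for h in _exact_hits(template.bases, rev_site) if h >= fwd_hits[0]
    ]
    if len(rev_hits) != 1:
        raise NoAmpliconError(
            f"reverse primer binds {len(rev_hits)} times downstream (need 1)"
        )
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_site)
    return NucleotideSequence(
        f"{template.name}_amplicon", template.bases[start:end]
    )


def expected_band_patterns(
    wt: NucleotideSequence,
    mut: NucleotideSequence,
    enzyme: RestrictionEnzyme,
) -> dict[str, tuple[int, ...]]:
    """Expected gel band pattern for each genotype.

    WT and MUT show their allele's digest bands; a heterozygote carries
    both alleles so its lane shows the union of the distinct band lengths.
    """
    wt_bands = digest(wt, enzyme).bands
    mut_bands = digest(mut, enzyme).bands
    if wt_bands == mut_bands:
        raise UninformativeAssayError(
            f"{enzyme.name} digest cannot distinguish the alleles: "
            f"both give bands {wt_bands}"
        )
    het_bands = tuple(sorted(set(wt_bands) | set(mut_bands), reverse=True))
    return {"WT": wt_bands, "HET": het_bands, "MUT": mut_bands}


def _merge_close(bands: Sequence[int], tolerance: int) -> list[int]:
    """Merge bands closer than the gel tolerance into one (their mean)."""
    if not bands:
        return []
    out: list[list[int]] = [[]]
    for b in sorted(bands):
        if out[-1] and b - out[-1][-1] >= tolerance:
            out.append([])
        out[-1].append(b)
    return sorted((round(sum(g) / len(g)) for g in out), reverse=True)


def call_genotype(
    observed: Iterable[int],
    patterns: Mapping[str, Sequence[int]],
    tolerance: int = 5,
) -> GenotypeCall:
    """Call a genotype from observed band lengths.

    Bands closer than ``tolerance`` (default 5 bp, about the resolving
    power of a 2% agarose gel) are first merged; a pattern matches when
    band counts agree and each observed band is within the tolerance of
    its expected counterpart. Zero or multiple matching patterns give
    UNKNOWN.
    """
    obs = _merge_close([int(b) for b in observed], tolerance)
    if any(b <= 0 for b in obs):
        raise ValueError("band lengths must be positive")
    matches = []
    for genotype, expected in patterns.items():
        exp = sorted(expected, reverse=True)
        if len(obs) == len(exp) and all(
            abs(o - e) <= tolerance for o, e in zip(obs, exp)
        ):
            matches.append(genotype)
    if len(matches) == 1:
        return GenotypeCall(matches[0])
    return GenotypeCall("UNKNOWN")


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Read a gel band table: columns sample_id, band_lengths (';'-separated).

    Malformed band lists are kept as empty lists so the caller can report
    them as UNKNOWN rather than aborting the whole table.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "band_lengths": str})
    if not {"sample_id", "band_lengths"} <= set(df.columns):
        raise ValueError("band table needs columns: sample_id, band_lengths")

    def parse(cell: object) -> list[int]:
        if pd.isna(cell) or str(cell).strip() == "":
            return []
        try:
            return [int(tok) for tok in str(cell).split(";") if tok.strip()]
        except ValueError:
            return []

    df["bands"] = df["band_lengths"].map(parse)
    return df[["sample_id", "bands"]]


def enzyme_from_config(cfg: Mapping[str, object]) -> RestrictionEnzyme:
    """Build an enzyme from a config mapping {name, site, cut_offset}."""
    return RestrictionEnzyme(
        str(cfg["name"]), str(cfg["site"]), int(cfg["cut_offset"])
    )
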