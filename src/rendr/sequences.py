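"""Construct modelling for split splicing-ribozyme RNA sensors.

A splicing ribozyme (a group I intron) is inserted inside an output gene so
that translation of the intact protein requires the splicing reaction: the
intron excises itself and ligates the flanking exons.  The 5' splice site of
this intron family lies immediately after a uracil, which constrains where
the ribozyme may be inserted.  Splitting the ribozyme into two fragments and
appending RNA guides (reverse complements of windows on an RNA input) turns
splicing into an input-templated reaction: the input co-localises the two
fragments, restoring the ribozyme and hence output expression.

All public operations take and return :class:`NucSeq` objects and use
1-based coordinates, matching how split sites are labelled in the field
(e.g. "split site 15" = the cut between ribozyme nucleotides 15 and 16).
DNA input (containing T) is transcribed to the RNA alphabet on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NucSeq",
    "RibozymeConstruct",
    "GuidePair",
    "SplitDesign",
    "InsertionSiteReport",
    "SpliceSiteError",
    "reverse_complement",
    "enumerate_split_sites",
    "validate_insertion_site",
    "insert_ribozyme",
    "splice",
    "split_ribozyme",
    "design_guides",
    "introduce_mismatches",
    "design_inhibitor",
    "build_modular_construct",
]

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")
#: Watson-Crick pairs plus GU wobble; used when picking mismatch substitutions
#: so that a "mismatch" cannot silently form a wobble pair with the input.
_PAIRS_WITH = {
    "A": {"U"},
    "C": {"G"},
    "G": {"C", "U"},
    "U": {"A", "G"},
}


class SpliceSiteError(ValueError):
    """Raised when the 5' splice-site rule (exon1 must end in U) is violated."""


@dataclass(frozen=True)
class NucSeq:
    """An RNA sequence over {A, C, G, U} with an identifier.

    DNA input is accepted and transcribed (T -> U); case is normalised to
    upper.  Empty sequences are permitted only with ``allow_empty=True``
    (zero-length guides are a legitimate negative control).
    """

    residues: str
    name: str = ""

    def __init__(self, residues: str, name: str = "", *, allow_empty: bool = False):
        residues = residues.upper().replace("T", "U")
        if not residues and not allow_empty:
            raise ValueError(f"empty sequence not allowed for {name!r}")
        bad = set(residues) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-nucleotide characters {sorted(bad)} in {name!r}")
        object.__setattr__(self, "residues", residues)
        object.__setattr__(self, "name", name)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def slice1(self, start: int, stop: int) -> str:
        """Residues at 1-based half-open interval [start, stop)."""
        if not (1 <= start <= stop <= len(self) + 1):
            raise IndexError(f"interval [{start}, {stop}) out of bounds for length {len(self)}")
        return self.residues[start - 1 : stop - 1]

    def reverse_complement(self, name: str | None = None) -> "NucSeq":
        rc = self.residues.translate(_COMPLEMENT)[::-1]
        return NucSeq(rc, name if name is not None else f"{self.name}_rc", allow_empty=True)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a raw RNA string."""
    return seq.upper().replace("T", "U").translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionSiteReport:
    """Outcome of checking a candidate ribozyme insertion site in a CDS."""

    position: int          # 1-based index of the last exon-1 nucleotide
    base: str              # the base at that position
    valid: bool            # True iff base == "U" (5' splice-site rule)
    codon_number: int      # 1-based codon index containing the position
    codon: str             # the codon sequence (may be partial at CDS end)
    codon_phase: int       # 1..3: position of the base within its codon
    reason: str = ""


@dataclass(frozen=True)
class RibozymeConstruct:
    """An output gene carrying an inserted splicing ribozyme.

    ``exon1 + intron + exon2`` is the pre-mRNA.  ``insertion_site`` is the
    1-based CDS position of the last exon-1 nucleotide.  ``mode`` is
    ``"in_cds"`` for insertion inside a coding sequence or ``"modular"``
    when the ribozyme sits between the RBS and the CDS (exon1 is then the
    5'-UTR segment downstream of the RBS and exon2 the untouched CDS).
    """

    exon1: NucSeq
    intron: NucSeq
    exon2: NucSeq
    insertion_site: int
    mode: str = "in_cds"

    def __post_init__(self):
        if self.mode not in ("in_cds", "modular"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def pre_mrna(self) -> NucSeq:
        return NucSeq(
            self.exon1.residues + self.intron.residues + self.exon2.residues,
            name=f"{self.exon1.name}_pre_mrna",
            allow_empty=True,
        )


@dataclass(frozen=True)
class GuidePair:
    """Two RNA guides, each the reverse complement of a window on the input.

    Windows are half-open 1-based intervals on the RNA input.  Mismatch
    positions are 1-based over the concatenated guide1+guide2 interaction
    (positions <= len(guide1) lie in guide1).
    """

    guide1: NucSeq
    guide2: NucSeq
    input_window1: tuple[int, int]
    input_window2: tuple[int, int]
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self):
        for w, g in ((self.input_window1, self.guide1), (self.input_window2, self.guide2)):
            if w[1] - w[0] != len(g):
                raise ValueError(f"window {w} length != guide length {len(g)}")
        a, b = sorted([self.input_window1, self.input_window2])
        if a[1] > b[0]:
            raise ValueError("guide windows overlap on the input")

    @property
    def interaction_length(self) -> int:
        """Total designed guide:input interaction length in nucleotides."""
        return len(self.guide1) + len(self.guide2)

    def mismatches_in(self, which: int) -> tuple[int, ...]:
        """Mismatch positions local to guide 1 or 2 (1-based)."""
        n1 = len(self.guide1)
        if which == 1:
            return tuple(p for p in self.mismatch_positions if p <= n1)
        return tuple(p - n1 for p in self.mismatch_positions if p > n1)


@dataclass(frozen=True)
class SplitDesign:
    """A split ribozyme: cut site plus the two guide-bearing fragments.

    ``split_index`` = s means the cut lies between ribozyme positions s and
    s+1.  guide1 is appended at the 3' end of the 5' fragment and guide2 at
    the 5' end of the 3' fragment, so both guides face the RNA input between
    the fragments.
    """

    split_index: int
    fragment5: NucSeq
    fragment3: NucSeq
    guides: GuidePair

    def core5(self) -> str:
        """5'-fragment sequence with its guide removed."""
        n = len(self.guides.guide1)
        return self.fragment5.residues[: len(self.fragment5) - n]

    def core3(self) -> str:
        """3'-fragment sequence with its guide removed."""
        return self.fragment3.residues[len(self.guides.guide2):]


# ---------------------------------------------------------------------------
# operations


def enumerate_split_sites(ribozyme: NucSeq) -> list[int]:
    """All candidate split sites of a ribozyme: cuts between adjacent bases.

    Returns ``[1, ..., L-1]`` for a ribozyme of length L (empty for L < 2).
    """
    return list(range(1, len(ribozyme)))


def validate_insertion_site(cds: NucSeq, position: int) -> InsertionSiteReport:
    """Check the 5' splice-site rule at a candidate insertion position.

    The ribozyme must be inserted immediately downstream of a uracil, so the
    site is valid iff the CDS base at ``position`` (1-based) is U.  The
    report also records the codon and codon phase, which is what one reads
    off a construct map (e.g. "after the first nucleotide of codon 66").
    """
    if not (1 <= position <= len(cds)):
        raise IndexError(f"position {position} out of range 1..{len(cds)}")
    base = cds[position - 1]
    codon_number = (position - 1) // 3 + 1
    phase = (position - 1) % 3 + 1
    codon = cds[(codon_number - 1) * 3 : codon_number * 3]
    valid = base == "U"
    reason = "" if valid else f"base at position {position} is {base}, not U"
    return InsertionSiteReport(position, base, valid, codon_number, codon, phase, reason)


def insert_ribozyme(cds: NucSeq, position: int, ribozyme: NucSeq, mode: str = "in_cds") -> RibozymeConstruct:
    """Insert a splicing ribozyme after ``position`` (1-based) in a CDS.

    The insertion site must satisfy :func:`validate_insertion_site`; the
    resulting construct has ``exon1 = cds[1..position]``, ``intron`` the
    ribozyme and ``exon2`` the CDS remainder.  Insertion at the last
    position leaves exon2 empty (degenerate, warned).
    """
    report = validate_insertion_site(cds, position)
    if not report.valid:
        raise SpliceSiteError(f"invalid insertion site: {report.reason}")
    exon1 = NucSeq(cds[:position], name=f"{cds.name}_exon1")
    exon2 = NucSeq(cds[position:], name=f"{cds.name}_exon2", allow_empty=True)
    if len(exon2) == 0:
        warnings.warn(f"insertion at last CDS position {position}: exon2 is empty", stacklevel=2)
    return RibozymeConstruct(exon1, ribozyme, exon2, insertion_site=position, mode=mode)


def splice(construct: RibozymeConstruct) -> tuple[NucSeq, NucSeq]:
    """In-silico splicing: excise the intron, ligate the exons.

    Returns ``(spliced_mrna, excised_intron)``.  Raises
    :class:`SpliceSiteError` if exon1 does not end in U (the 5' splice site
    of this intron family requires a uracil just upstream of the intron).
    """
    if not construct.exon1.residues.endswith("U"):
        raise SpliceSiteError(
            f"exon1 of {construct.exon1.name!r} ends in {construct.exon1.residues[-1]!r}; "
            "the 5' splice site requires a terminal U"
        )
    ligated = NucSeq(
        construct.exon1.residues + construct.exon2.residues,
        name=f"{construct.exon1.name}_spliced",
    )
    return ligated, construct.intron


def split_ribozyme(ribozyme: NucSeq, s: int, guides: GuidePair) -> SplitDesign:
    """Split a ribozyme between positions s and s+1 and append the guides.

    The 5' fragment is ``ribozyme[1..s]`` with guide1 at its 3' end; the 3'
    fragment is guide2 followed by ``ribozyme[s+1..L]``.  Removing the
    guides and re-joining the fragment cores reproduces the ribozyme.
    """
    L = len(ribozyme)
    if not (1 <= s <= L - 1):
        raise IndexError(f"split index {s} out of range 1..{L - 1}")
    frag5 = NucSeq(ribozyme[:s] + guides.guide1.residues, name=f"{ribozyme.name}_frag5_s{s}")
    frag3 = NucSeq(guides.guide2.residues + ribozyme[s:], name=f"{ribozyme.name}_frag3_s{s}")
    return SplitDesign(split_index=s, fragment5=frag5, fragment3=frag3, guides=guides)


def design_guides(
    input_rna: NucSeq,
    window1: tuple[int, int],
    window2: tuple[int, int],
) -> GuidePair:
    """Design a guide pair as reverse complements of two input windows.

    Windows are half-open 1-based intervals on the RNA input; they must be
    in bounds and non-overlapping.  Zero-length windows yield empty guides
    (the no-guide negative control).
    """
    for w in (window1, window2):
        if not (1 <= w[0] <= w[1] <= len(input_rna) + 1):
            raise IndexError(f"window {w} out of bounds for input of length {len(input_rna)}")
    g1 = NucSeq(reverse_complement(input_rna.slice1(*window1)), name="guide1", allow_empty=True)
    g2 = NucSeq(reverse_complement(input_rna.slice1(*window2)), name="guide2", allow_empty=True)
    return GuidePair(g1, g2, tuple(window1), tuple(window2))


def _noncomplementary_base(current: str, window_base: str, rng: np.random.Generator) -> str:
    """A base differing from ``current`` that cannot pair ``window_base``."""
    options = [b for b in "ACGU" if b != current and window_base not in _PAIRS_WITH[b]]
    return options[int(rng.integers(len(options)))]


def introduce_mismatches(guides: GuidePair, fraction: float, seed: int) -> GuidePair:
    """Substitute a fraction of guide positions with non-complementary bases.

    ``round(fraction * interaction_length)`` positions are drawn uniformly
    without replacement (seeded) over the concatenated guide1+guide2
    interaction and replaced with bases that can pair neither canonically
    nor by GU wobble with the corresponding input base.  Deterministic for
    a fixed seed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"mismatch fraction {fraction} outside [0, 1]")
    n = guides.interaction_length
    k = int(round(fraction * n))
    if k == 0:
        return replace(guides, mismatch_positions=())
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(n, size=k, replace=False)) + 1  # 1-based
    n1 = len(guides.guide1)
    g1 = list(guides.guide1.residues)
    g2 = list(guides.guide2.residues)
    for p in positions:
        if p <= n1:
            i = p - 1
            window_base = reverse_complement(guides.guide1.residues)[i]  # original partner
            g1[i] = _noncomplementary_base(g1[i], window_base, rng)
        else:
            i = p - n1 - 1
            window_base = reverse_complement(guides.guide2.residues)[i]
            g2[i] = _noncomplementary_base(g2[i], window_base, rng)
    return GuidePair(
        NucSeq("".join(g1), name=guides.guide1.name, allow_empty=True),
        NucSeq("".join(g2), name=guides.guide2.name, allow_empty=True),
        guides.input_window1,
        guides.input_window2,
        tuple(int(p) for p in positions),
    )


def design_inhibitor(guide: NucSeq, toehold_len: int, flank: NucSeq | None = None) -> NucSeq:
    """Design an RNA inhibitor against a guide, with a toehold extension.

    The inhibitor is the reverse complement of the guide, extended by the
    reverse complement of ``toehold_len`` bases of the guide's 3' flanking
    context, so that an invading strand (the RNA input) can initiate
    displacement at the toehold.  ``toehold_len = 0`` returns the plain
    reverse complement.
    """
    if toehold_len < 0:
        raise ValueError("toehold length must be >= 0")
    flank_res = flank.residues if flank is not None else ""
    if toehold_len > len(flank_res):
        raise ValueError(
            f"toehold length {toehold_len} exceeds available flank ({len(flank_res)} nt)"
        )
    extended = guide.residues + flank_res[:toehold_len]
    return NucSeq(reverse_complement(extended), name=f"{guide.name}_inhibitor", allow_empty=True)


def build_modular_construct(utr5: NucSeq, split: SplitDesign, cds: NucSeq) -> RibozymeConstruct:
    """Build a modular-output construct: ribozyme between the RBS and CDS.

    Here exon1 is the 5'-UTR segment downstream of the RBS (it must end in
    U, as the splice-site rule applies to the 5' exon) and exon2 is the
    untouched CDS, so splicing yields ``utr5 + cds`` and the protein output
    can be exchanged without redesigning the split or the guides.
    """
    if not utr5.residues.endswith("U"):
        raise SpliceSiteError(f"5'-UTR {utr5.name!r} must end in U for the modular design")
    intron = NucSeq(split.core5() + split.core3(), name=f"{split.fragment5.name}_rejoined")
    return RibozymeConstruct(
        exon1=utr5, intron=intron, exon2=cds, insertion_site=len(utr5), mode="modular"
    )
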