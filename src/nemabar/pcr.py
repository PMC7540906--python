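"""In-silico PCR over IUPAC-degenerate primers.

Locates primer pairs on full-length small-subunit (18S) rRNA gene sequences,
excises the primer-trimmed insert of each amplified region, and concatenates
regional inserts into artificial long sequences.  Coordinates are 0-based
half-open on the source sequence and always refer to the insert only (primer
sites excluded), matching the convention of primer-trimmed amplicon reads.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "IUPAC",
    "PrimerSet",
    "DEFAULT_PRIMERS",
    "RegionSeq",
    "match_degenerate",
    "reverse_complement",
    "extract_region",
    "extract_all_regions",
    "concatenate_regions",
    "concatenate_for_species",
    "IncompleteRegionError",
]

# IUPAC nucleotide degeneracy classes.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN-", "TGCAYRWSMKVHDBN-")


class IncompleteRegionError(ValueError):
    """A requested region is absent or incomplete on the source sequence."""


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair defining one PCR target region.

    The reverse primer is written 5'->3' on the antisense strand, per
    convention; matching is done against its reverse complement on the
    sense strand.
    """

    region_id: int
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"{name} primer of region {self.region_id} contains "
                    f"non-IUPAC characters: {sorted(bad)}"
                )


#: Primer pairs for the four 18S SSU target regions (sequencing-adapter tail
#: sequences excluded).  Regions are numbered 5'->3' along the gene; the
#: region 3 and region 4 amplicons overlap on the sense strand.
DEFAULT_PRIMERS: dict[int, PrimerSet] = {
    1: PrimerSet(1, "GCTTRTCTCAAAGATTAAGCCATGCATG", "GCCTGCTGCCTTCCTTGGA"),
    2: PrimerSet(2, "AGCAGCCGCGGTAATTCCAGCTC", "AAGACATTCTTGGCAAATGCTTTCG"),
    3: PrimerSet(3, "GTTCGAAGGCGATYAGATACCGCC", "TCGYTCGTTATCGGAATWAACCAGAC"),
    4: PrimerSet(4, "GGTGGTGCATGGCCGTTCTTAGTT", "GGTGTGTACAAAKSGCAGGGACGTA"),
}


@dataclass
class RegionSeq:
    """A primer-trimmed regional insert cut from a source sequence."""

    species_id: str
    region_id: int
    sequence: str
    start: int = 0
    end: int = 0
    complete: bool = True


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    return seq


def match_degenerate(seq: str, pattern: str) -> list[int]:
    """Return all 0-based start positions where ``pattern`` matches ``seq``.

    Position p is reported iff every sequence character at p..p+len(pattern)-1
    lies in the IUPAC class of the corresponding pattern character.  ``N`` in
    the sequence matches nothing (an unknown base cannot be confirmed to lie
    in any class).  Overlapping matches are all reported.
    """
    if not seq or not pattern:
        raise ValueError("sequence and pattern must be non-empty")
    seq = _validate_seq(seq)
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"pattern contains non-IUPAC characters: {sorted(bad)}")
    regex = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern
    )
    return [m.start() for m in re.finditer(f"(?={regex})", seq)]


def _match_with_mismatches(seq: str, pattern: str, max_mismatch: int) -> list[int]:
    """Degenerate matching allowing up to ``max_mismatch`` failures at
    non-degenerate pattern positions (degenerate positions must still match)."""
    seq = _validate_seq(seq)
    pattern = pattern.upper()
    classes = [IUPAC[c] for c in pattern]
    degenerate = [len(c) > 1 for c in classes]
    hits = []
    m = len(pattern)
    for p in range(len(seq) - m + 1):
        mism = 0
        ok = True
        for k in range(m):
            if seq[p + k] not in classes[k]:
                if degenerate[k]:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            hits.append(p)
    return hits


def extract_region(
    source: str,
    primers: PrimerSet,
    species_id: str = "",
    max_mismatch: int = 0,
) -> RegionSeq:
    """Excise the insert between a primer pair on the sense strand.

    The forward primer is matched directly; the reverse primer is matched as
    its reverse complement downstream of the forward site.  The returned
    sequence is the insert BETWEEN the primer matches (primer sites removed).
    The leftmost forward match and the nearest valid downstream reverse match
    are used; when several non-nested pairings exist a warning is emitted and
    the leftmost pair is returned.  When no valid pair exists the result has
    ``complete=False`` and an empty sequence.
    """
    if not source:
        raise ValueError("source sequence must be non-empty")
    source = _validate_seq(source)
    rc_rev = reverse_complement(primers.reverse)
    if max_mismatch == 0:
        fwd_hits = match_degenerate(source, primers.forward)
        rev_hits = match_degenerate(source, rc_rev)
    else:
        fwd_hits = _match_with_mismatches(source, primers.forward, max_mismatch)
        rev_hits = _match_with_mismatches(source, rc_rev, max_mismatch)

    flen = len(primers.forward)
    incomplete = RegionSeq(species_id, primers.region_id, "", 0, 0, complete=False)
    if not fwd_hits:
        return incomplete
    valid_pairs = [
        (f, r) for f in fwd_hits for r in rev_hits if r >= f + flen
    ]
    if not valid_pairs:
        return incomplete
    fwd = min(f for f, _ in valid_pairs)
    rev = min(r for f, r in valid_pairs if f == fwd)
    n_pairs = len({f for f, _ in valid_pairs})
    if n_pairs > 1:
        warnings.warn(
            f"region {primers.region_id}: {n_pairs} candidate forward sites on "
            f"{species_id or 'sequence'}; using leftmost pair",
            stacklevel=2,
        )
    start, end = fwd + flen, rev
    return RegionSeq(species_id, primers.region_id, source[start:end], start, end, True)


def extract_all_regions(
    source: str,
    species_id: str = "",
    primers: dict[int, PrimerSet] | None = None,
    max_mismatch: int = 0,
) -> dict[int, RegionSeq]:
    """Extract every region of ``primers`` (default: the four shipped pairs)."""
    primers = primers or DEFAULT_PRIMERS
    return {
        rid: extract_region(source, pset, species_id, max_mismatch)
        for rid, pset in sorted(primers.items())
    }


def concatenate_regions(regions: dict[int, RegionSeq], order: list[int]) -> str:
    """Concatenate regional inserts in the stated numeric order.

    Raises :class:`IncompleteRegionError` when a requested region is missing
    or incomplete; batch callers exclude such species and report them.
    """
    parts = []
    for rid in order:
        reg = regions.get(rid)
        if reg is None or not reg.complete:
            raise IncompleteRegionError(
                f"region {rid} missing or incomplete"
                + (f" for {reg.species_id}" if reg is not None else "")
            )
        parts.append(reg.sequence)
    return "".join(parts)


def concatenate_for_species(
    per_species: dict[str, dict[int, RegionSeq]], order: list[int]
) -> tuple[dict[str, str], list[str]]:
    """Concatenate a region set for many species, excluding incomplete ones.

    Returns (species -> concatenated sequence, sorted list of excluded
    species ids).  Exclusion mirrors the treatment of taxa that lack one of
    the requested amplicons: they are dropped from that concatenation set and
    reported rather than padded.
    """
    out: dict[str, str] = {}
    excluded: list[str] = []
    for sp in sorted(per_species):
        try:
            out[sp] = concatenate_regions(per_species[sp], order)
        except IncompleteRegionError:
            excluded.append(sp)
    return out, excluded
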