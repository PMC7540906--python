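"""Per-sample SV resolution: major/minor ranking and minor-SV classification.

Within one retained sample and one region, the most abundant nematode-derived
SV (major) is taken as the specimen's sequence; each remaining nematode SV
above the minor-abundance floor is classified as a polymorphic allele (same
order, few edits — a second rDNA-repeat haplotype), a second nematode
(different order — predation or contamination), or ambiguous.  Cross-sample
recurrence of a major/minor pair is recorded as supporting evidence for
allelic status but is not required: genuine alleles can appear in a single
sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd

__all__ = [
    "AlleleCall",
    "IsolateProfile",
    "edit_distance_and_summary",
    "rank_svs",
    "classify_minor",
    "build_isolate_profiles",
    "flag_ambiguous_isolates",
]

POLYMORPHIC = "polymorphic_allele"
SECOND_NEMATODE = "second_nematode"
AMBIGUOUS = "ambiguous"


@dataclass
class AlleleCall:
    sample_id: str
    region_id: int
    major_sv: str
    minor_sv: str
    edit_distance: int
    edit_summary: str
    n_cooccurring_samples: int
    classification: str
    minor_order: str = "NA"


@dataclass
class IsolateProfile:
    """One specimen's per-region major SV plus classified minor SVs."""

    sample_id: str
    majors: dict[int, str] = field(default_factory=dict)  # region -> sv_id
    calls: list[AlleleCall] = field(default_factory=list)
    multi_nematode: bool = False
    ambiguous_excluded: bool = False


def _parse_cigar(cigar: str):
    n = ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            yield int(n), c
            n = ""


def edit_distance_and_summary(major: str, minor: str) -> tuple[int, str]:
    """Levenshtein distance and a human-readable difference summary.

    Substitutions are written major-base/minor-base ("A/G"); identical
    substitution pairs are grouped ("T/C (4 sites)"); insertions and
    deletions are stated relative to the major sequence ("GG insertion",
    "C deletion").  Substitution groups come first (in order of first
    occurrence), then indels in positional order.
    """
    res = edlib.align(minor, major, task="path", mode="NW")
    dist = res["editDistance"]
    subs: list[tuple[str, str]] = []
    indels: list[str] = []
    qi = ti = 0  # minor, major cursors
    for n, op in _parse_cigar(res["cigar"] or ""):
        if op == "=":
            qi += n
            ti += n
        elif op == "X":
            for k in range(n):
                subs.append((major[ti + k], minor[qi + k]))
            qi += n
            ti += n
        elif op == "I":  # bases present in minor, absent from major
            indels.append(f"{minor[qi:qi + n]} insertion")
            qi += n
        elif op == "D":  # bases present in major, absent from minor
            indels.append(f"{major[ti:ti + n]} deletion")
            ti += n
    groups = Counter(subs)
    parts = []
    seen = set()
    for pair in subs:
        if pair in seen:
            continue
        seen.add(pair)
        a, b = pair
        k = groups[pair]
        parts.append(f"{a}/{b}" if k == 1 else f"{a}/{b} ({k} sites)")
    parts.extend(indels)
    return dist, ", ".join(parts)


def rank_svs(
    table: pd.DataFrame,
    sample_id: str,
    minor_floor: float = 0.07,
) -> tuple[pd.Series | None, pd.DataFrame]:
    """Major nematode SV and ordered minor SVs for one sample in one region.

    The major SV is the highest-count nematode SV (count ties broken
    lexicographically by sequence); minors are the remaining nematode SVs
    whose relative abundance within the sample's nematode fraction exceeds
    ``minor_floor``.  Returns (major row or None, minors frame ordered by
    descending count).
    """
    grp = table[(table["sample_id"] == sample_id)
                & (table["phylum"] == "Nematoda")]
    if grp.empty:
        return None, grp
    grp = grp.sort_values(["count", "sequence"],
                          ascending=[False, True], kind="stable")
    major = grp.iloc[0]
    rest = grp.iloc[1:]
    nem_total = grp["count"].sum()
    minors = rest[rest["count"] / nem_total > minor_floor]
    return major, minors


def classify_minor(
    major: pd.Series,
    minor: pd.Series,
    n_cooccurring: int = 0,
    max_allele_edits: int = 5,
) -> AlleleCall:
    """Classify one minor nematode SV against its sample's major SV.

    Different order labels -> second nematode; otherwise a polymorphic
    allele when the Levenshtein distance is within ``max_allele_edits``;
    otherwise ambiguous.
    """
    dist, summary = edit_distance_and_summary(major["sequence"],
                                              minor["sequence"])
    maj_order, min_order = major.get("order", "NA"), minor.get("order", "NA")
    if (maj_order != min_order and maj_order not in ("NA", None)
            and min_order not in ("NA", None)):
        cls = SECOND_NEMATODE
    elif dist <= max_allele_edits:
        cls = POLYMORPHIC
    else:
        cls = AMBIGUOUS
    return AlleleCall(
        sample_id=str(major["sample_id"]),
        region_id=int(major["region"]),
        major_sv=str(major["sv_id"]),
        minor_sv=str(minor["sv_id"]),
        edit_distance=dist,
        edit_summary=summary,
        n_cooccurring_samples=n_cooccurring,
        classification=cls,
        minor_order=str(min_order),
    )


def build_isolate_profiles(
    tables: dict[int, pd.DataFrame],
    retained: dict[int, list[str]],
    minor_floor: float = 0.07,
    max_allele_edits: int = 5,
) -> list[IsolateProfile]:
    """Resolve major/minor SVs for every retained sample across regions.

    ``retained`` maps region id -> QC-passing sample ids for that region.
    A first pass collects each sample's (major, minor) pairs to build the
    cross-sample co-occurrence index; the second pass classifies.
    """
    ranked: dict[tuple[str, int], tuple[pd.Series, pd.DataFrame]] = {}
    pair_counts: Counter = Counter()
    all_samples: set[str] = set()
    for rid, table in sorted(tables.items()):
        for sample in retained.get(rid, []):
            major, minors = rank_svs(table, sample, minor_floor)
            if major is None:
                continue
            ranked[(sample, rid)] = (major, minors)
            all_samples.add(sample)
            for _, minor in minors.iterrows():
                pair_counts[(rid, major["sv_id"], minor["sv_id"])] += 1

    profiles: dict[str, IsolateProfile] = {
        s: IsolateProfile(s) for s in sorted(all_samples)
    }
    for (sample, rid), (major, minors) in sorted(ranked.items()):
        prof = profiles[sample]
        prof.majors[rid] = str(major["sv_id"])
        for _, minor in minors.iterrows():
            call = classify_minor(
                major, minor,
                n_cooccurring=pair_counts[(rid, major["sv_id"], minor["sv_id"])],
                max_allele_edits=max_allele_edits,
            )
            prof.calls.append(call)
            if call.classification == SECOND_NEMATODE:
                prof.multi_nematode = True
    return list(profiles.values())


def flag_ambiguous_isolates(
    profiles: list[IsolateProfile],
    max_allele_edits: int = 5,
) -> list[str]:
    """Exclude isolates whose same-order minor SVs cannot be explained as one
    allele family.

    A sample is excluded when, in any region, it holds two or more
    same-order minors beyond the allele edit limit, or three or more
    distinct same-order SVs (major included) that do not form a single
    polymorphic-allele family.  Two-nematode samples (different orders) are
    retained with the ``multi_nematode`` flag; their major SVs remain usable.
    """
    excluded = []
    for prof in profiles:
        bad = False
        for rid in sorted(prof.majors):
            same = [c for c in prof.calls
                    if c.region_id == rid
                    and c.classification != SECOND_NEMATODE]
            n_far = sum(c.edit_distance > max_allele_edits for c in same)
            family = all(c.classification == POLYMORPHIC for c in same)
            if n_far >= 2 or (1 + len(same) >= 3 and not family):
                bad = True
        if bad:
            prof.ambiguous_excluded = True
            excluded.append(prof.sample_id)
    return sorted(excluded)


def allele_calls_table(profiles: list[IsolateProfile]) -> pd.DataFrame:
    """Flat report of every minor-SV classification."""
    rows = [
        (c.sample_id, c.region_id, c.major_sv, c.minor_sv, c.edit_distance,
         c.edit_summary, c.n_cooccurring_samples, c.classification)
        for p in profiles for c in p.calls
    ]
    return pd.DataFrame(rows, columns=[
        "sample_id", "region", "major_sv", "minor_sv", "edit_distance",
        "edit_summary", "n_cooccurring_samples", "classification",
    ])
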