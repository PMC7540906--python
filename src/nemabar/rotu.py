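"""Cross-region rOTU clustering and composition summaries.

Isolates (individual specimens) sharing identical major SVs in every region
where both have data — and sharing at least one region — are merged into one
ribosomal-RNA-gene-derived OTU (rOTU).  Agreement in some regions combined
with disagreement in another is a conflict and blocks merging, including
through intermediate isolates.  rOTUs are ranked by descending member count
(ties by smallest member sample number) and named with a configurable
experiment code, e.g. ``Z01rOTU01``; each region's defining SV is the
regional rOTU, and polymorphic-allele SVs attach with letter suffixes
(``_R1a``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .alleles import POLYMORPHIC, IsolateProfile
from .qc import round_half_up

__all__ = [
    "ROTU",
    "cluster_isolates",
    "summarize_orders",
    "summarize_feeding",
    "feeding_category",
    "rotu_table",
]


@dataclass
class ROTU:
    rotu_id: str
    members: list[str]                       # sample ids, sorted
    regional: dict[int, str]                 # region -> defining SV id
    polymorphic: dict[str, str] = field(default_factory=dict)
    # suffixed regional id (e.g. "Z01rOTU01_R1a") -> allele SV id
    order: str | None = None
    feeding_code: str | None = None

    @property
    def n_isolates(self) -> int:
        return len(self.members)


def _sample_number(sample_id: str) -> tuple[int, str]:
    m = re.search(r"(\d+)\s*$", sample_id)
    return (int(m.group(1)) if m else 1 << 30, sample_id)


def _compatible(a: IsolateProfile, b: IsolateProfile) -> tuple[bool, bool]:
    """(share at least one region with equal SVs and no unequal shared
    region, any shared region disagrees)."""
    shared = set(a.majors) & set(b.majors)
    if not shared:
        return False, False
    conflict = any(a.majors[r] != b.majors[r] for r in shared)
    return not conflict, conflict


def cluster_isolates(
    profiles: list[IsolateProfile],
    experiment_code: str = "Z01",
) -> list[ROTU]:
    """Partition isolates into rOTUs by identical shared-region major SVs.

    Compatibility edges are closed transitively, but two clusters are merged
    only if no cross-pair conflicts (a conflict edge blocks a merge even
    when an intermediate isolate is compatible with both sides).  Isolates
    flagged ambiguous are excluded; every remaining isolate lands in exactly
    one rOTU.
    """
    kept = [p for p in profiles if not p.ambiguous_excluded and p.majors]
    kept.sort(key=lambda p: _sample_number(p.sample_id))
    n = len(kept)
    clusters: list[list[int]] = [[i] for i in range(n)]
    where = list(range(n))

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            ok, _ = _compatible(kept[i], kept[j])
            if ok:
                edges.append((i, j))
    for i, j in edges:
        ci, cj = where[i], where[j]
        if ci == cj:
            continue
        merged_ok = all(
            not _compatible(kept[a], kept[b])[1]
            for a in clusters[ci] for b in clusters[cj]
        )
        if not merged_ok:
            continue
        lo, hi = min(ci, cj), max(ci, cj)
        clusters[lo].extend(clusters[hi])
        for idx in clusters[hi]:
            where[idx] = lo
        clusters[hi] = []

    groups = [sorted(c) for c in clusters if c]
    groups.sort(key=lambda g: (-len(g),
                               min(_sample_number(kept[i].sample_id) for i in g)))

    width = max(2, len(str(len(groups))))
    rotus: list[ROTU] = []
    for rank, g in enumerate(groups, start=1):
        members = sorted((kept[i].sample_id for i in g), key=_sample_number)
        regional: dict[int, str] = {}
        for i in g:
            for rid, sv in kept[i].majors.items():
                regional.setdefault(rid, sv)
        rotu_id = f"{experiment_code}rOTU{rank:0{width}d}"
        rotu = ROTU(rotu_id, members, dict(sorted(regional.items())))
        # Polymorphic attachments: distinct allele SVs per region, lettered
        # in discovery order (member order, then call order).
        for rid in sorted(regional):
            seen: list[str] = []
            for i in g:
                for call in kept[i].calls:
                    if (call.region_id == rid
                            and call.classification == POLYMORPHIC
                            and call.minor_sv not in seen):
                        seen.append(call.minor_sv)
            for k, sv in enumerate(seen):
                suffix = chr(ord("a") + k)
                rotu.polymorphic[f"{rotu_id}_R{rid}{suffix}"] = sv
        rotus.append(rotu)
    return rotus


def summarize_orders(rotus: list[ROTU]) -> pd.DataFrame:
    """Per-order isolate counts and percentages (1-decimal, half-up).
    rOTUs without an assigned order count under ``"NA"``."""
    counts: dict[str, int] = {}
    for r in rotus:
        counts[r.order or "NA"] = counts.get(r.order or "NA", 0) + r.n_isolates
    total = sum(counts.values())
    rows = [(o, c, round_half_up(c, total, scale=100))
            for o, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["order", "n_isolates", "pct"])


#: Yeates-style feeding-code families -> trophic category.
_CATEGORY = {
    "1": "plant feeder",
    "2": "fungivore",
    "3": "bacterivore",
    "5": "predator/omnivore",
    "8": "predator/omnivore",
}


def feeding_category(code: str | None) -> str:
    """Collapse a feeding code (possibly uncertain, e.g. ``"3?"``, or
    alternative, e.g. ``"5,8"``) to its trophic category via the first
    code's family; unknown codes map to ``"other"``."""
    if not code or code == "NA":
        return "other"
    first = code.split(",")[0].strip().rstrip("?")
    return _CATEGORY.get(first[:1] if first[:1] == "1" else first, "other")


def summarize_feeding(
    rotus: list[ROTU],
    feeding_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-trophic-category isolate counts and percentages.

    ``feeding_map`` (rOTU id -> code) overrides codes stored on the rOTUs.
    """
    counts: dict[str, int] = {}
    for r in rotus:
        code = (feeding_map or {}).get(r.rotu_id, r.feeding_code)
        cat = feeding_category(code)
        counts[cat] = counts.get(cat, 0) + r.n_isolates
    total = sum(counts.values())
    rows = [(cat, c, round_half_up(c, total, scale=100))
            for cat, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["feeding_category", "n_isolates", "pct"])


def rotu_table(rotus: list[ROTU]) -> pd.DataFrame:
    """Long-format rOTU report: one row per regional (or polymorphic
    regional) rOTU, mirroring the regional-SV / allele layout."""
    rows = []
    for r in rotus:
        for rid, sv in r.regional.items():
            rows.append((r.rotu_id, f"{r.rotu_id}_R{rid}", sv, "",
                         r.n_isolates, ",".join(r.members),
                         r.order or "NA", r.feeding_code or "NA"))
        for reg_id, sv in r.polymorphic.items():
            rows.append((r.rotu_id, reg_id, sv, "allele",
                         r.n_isolates, ",".join(r.members),
                         r.order or "NA", r.feeding_code or "NA"))
    return pd.DataFrame(rows, columns=[
        "rotu", "regional_rotu", "regional_sv", "allele",
        "n_isolates", "sample_ids", "order", "feeding_code",
    ])
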