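"""Synthetic reference species and per-sample SV count tables with ground truth.

Emulates the data structure of an individual-specimen amplicon-barcoding
experiment: each sample holds one dominant nematode-derived sequence variant
(SV) per amplified region, sometimes accompanied by a polymorphic allele pair
(a second rDNA-repeat haplotype differing by a few edits, recurring across
samples of the same species), non-nematode contaminant SVs, rarely a second
nematode of a different order (predation/contamination), and occasional
failed amplifications yielding under a thousand reads.

Reference sequences carry the four primer-site blocks of the shipped primer
pairs separated by order-specific variable blocks, so the in-silico PCR
module recovers all four regional inserts at known coordinates.  Sequence
evolution uses substitutions only (within variable blocks, along a simple
order -> species hierarchy); indels occur only between designated allele
pairs.  All sequences of a region therefore have equal insert length and are
trivially aligned, which lets the phylogeny stage run without an external
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .pcr import DEFAULT_PRIMERS, reverse_complement

__all__ = [
    "SimulationConfig",
    "ReferenceSpecies",
    "TruthBundle",
    "simulate_reference_set",
    "simulate_sv_tables",
    "simulate_all",
    "ORDER_POOL",
]

#: Nematode orders used to name synthetic clades, most common soil orders first.
ORDER_POOL = [
    "Dorylaimida", "Rhabditida", "Triplonchida", "Plectida",
    "Enoplida", "Mononchida", "Monhysterida", "Chromadorida",
    "Araeolaimida", "Desmodorida", "Strongylida", "Trichinellida",
]

#: Yeates-style feeding code assigned to each synthetic order, cycled.
_FEEDING_CYCLE = ["2", "1d", "3", "8", "5", "1b", "1e", "3?"]

_CONTAMINANT_PHYLA = ["Ascomycota", "Chordata", "Basidiomycota"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration cannot be realized."""


@dataclass
class SimulationConfig:
    """Study-scale defaults: 96 specimens, four regions, ~26% failed PCRs,
    ~28% contaminated samples, ~7% two-nematode samples, and roughly a third
    of species carrying a polymorphic allele pair."""

    n_orders: int = 6
    species_per_order: int = 5
    seq_length: int = 1600
    n_samples: int = 96
    polymorphism_rate: float = 0.3
    allele_edit_count: int = 1
    contamination_rate: float = 0.28
    predation_rate: float = 0.07
    fail_rate: float = 0.25
    depth_mean: float = 20000.0
    truncate_fraction: float = 0.0
    n_community_species: int = 12
    specimen_divergence: float = 0.008
    between_order_div: float = 0.12
    within_order_div: float = 0.015
    outgroup_div: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("polymorphism_rate", "contamination_rate",
                     "predation_rate", "fail_rate", "truncate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_orders < 1 or self.species_per_order < 1 or self.n_samples < 1:
            raise ConfigurationError("counts must be positive")
        if self.allele_edit_count < 1:
            raise ConfigurationError("allele_edit_count must be >= 1")


@dataclass
class ReferenceSpecies:
    species_id: str
    order: str
    sequence: str
    feeding_code: str
    truncated: bool = False
    is_outgroup: bool = False


@dataclass
class TruthBundle:
    """Ground truth mapping every generated artifact to its source."""

    region_coords: dict = field(default_factory=dict)   # species -> {region: (start, end)}
    species_order: dict = field(default_factory=dict)   # species -> order
    species_feeding: dict = field(default_factory=dict)  # species -> code
    allele_inserts: dict = field(default_factory=dict)  # species -> {region: minor insert}
    var_positions: "np.ndarray | None" = None           # mutable site coordinates
    specimen_seqs: dict = field(default_factory=dict)   # community species -> haplotype
    sample_species: dict = field(default_factory=dict)  # sample -> species
    sample_class: dict = field(default_factory=dict)    # sample -> ok|failed|contaminated|predation
    sample_prey: dict = field(default_factory=dict)     # sample -> prey species
    depths: dict = field(default_factory=dict)          # (sample, region) -> drawn depth
    allele_pairs: pd.DataFrame | None = None            # sample, region, major_sv, minor_sv
    second_nematode: pd.DataFrame | None = None         # sample, region, major_sv, minor_sv

    @property
    def n_predation_samples(self) -> int:
        return sum(1 for c in self.sample_class.values() if c == "predation")


# ---------------------------------------------------------------------------
# Reference set


def _layout(config: SimulationConfig) -> dict:
    """Block layout of a full-length synthetic gene.

    pad5 F1 v1 rcR1 gap12 F2 v2 rcR2 gap23 F3 v3 F4 ov rcR3 v4 rcR4 pad3
    The region 3 and 4 inserts share the ``ov`` block (their designed
    sense-strand overlap), and region 3's insert contains the region 4
    forward-primer site, as on the real gene.
    """
    p = DEFAULT_PRIMERS
    fixed = {
        "pad5": 60, "gap12": 80, "gap23": 40, "ov": 63, "pad3_min": 20,
        "F1": len(p[1].forward), "rcR1": len(p[1].reverse),
        "F2": len(p[2].forward), "rcR2": len(p[2].reverse),
        "F3": len(p[3].forward), "rcR3": len(p[3].reverse),
        "F4": len(p[4].forward), "rcR4": len(p[4].reverse),
    }
    overhead = (fixed["pad5"] + fixed["gap12"] + fixed["gap23"] + fixed["ov"]
                + fixed["pad3_min"]
                + sum(fixed[k] for k in ("F1", "rcR1", "F2", "rcR2",
                                         "F3", "rcR3", "F4", "rcR4")))
    leftover = config.seq_length - overhead
    weights = {"v1": 0.30, "v2": 0.30, "v3": 0.22, "v4": 0.18}
    vsizes = {k: int(leftover * w) for k, w in weights.items()}
    if leftover < 120 or min(vsizes.values()) < 30:
        raise ConfigurationError(
            f"seq_length={config.seq_length} too short to place the four "
            "primer pairs with usable variable blocks"
        )
    fixed.update(vsizes)
    fixed["pad3"] = fixed["pad3_min"] + leftover - sum(vsizes.values())

    blocks = ["pad5", "F1", "v1", "rcR1", "gap12", "F2", "v2", "rcR2",
              "gap23", "F3", "v3", "F4", "ov", "rcR3", "v4", "rcR4", "pad3"]
    pos, spans = 0, {}
    for b in blocks:
        spans[b] = (pos, pos + fixed[b])
        pos += fixed[b]
    assert pos == config.seq_length
    # Insert coordinates (primer sites excluded).
    coords = {
        1: (spans["F1"][1], spans["rcR1"][0]),
        2: (spans["F2"][1], spans["rcR2"][0]),
        3: (spans["F3"][1], spans["rcR3"][0]),
        4: (spans["F4"][1], spans["rcR4"][0]),
    }
    return {"spans": spans, "coords": coords, "blocks": blocks}


def _realize_primer(pattern: str, rng: np.random.Generator) -> str:
    """Realize one concrete base at each degenerate primer position."""
    from .pcr import IUPAC
    out = []
    for c in pattern:
        opts = IUPAC[c]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def _mutate(seq: np.ndarray, positions: np.ndarray, rate: float,
            rng: np.random.Generator) -> None:
    """Substitute bases in-place at `positions` with per-site probability."""
    hit = positions[rng.random(len(positions)) < rate]
    for p in hit:
        cur = seq[p]
        choices = [b for b in b"ACGT" if b != cur]
        seq[p] = choices[rng.integers(3)]


def simulate_reference_set(
    config: SimulationConfig,
) -> tuple[list[ReferenceSpecies], TruthBundle]:
    """Generate a reference species set plus a designated outgroup.

    Each sequence carries all eight primer-site blocks (one realization of
    each degenerate position), separated by variable blocks evolved along a
    two-level order/species hierarchy so that within-order divergence is
    well below between-order divergence.  Optionally a fraction of species
    is 5'-truncated (losing the region-1 forward primer site); such species
    are flagged and prefixed ``Q_``.
    """
    rng = np.random.default_rng(config.seed)
    lay = _layout(config)
    spans = lay["spans"]
    L = config.seq_length

    var_blocks = ["v1", "v2", "v3", "ov", "v4"]
    var_pos = np.concatenate(
        [np.arange(*spans[b]) for b in var_blocks]
    )

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    root = lut[rng.integers(0, 4, size=L)]

    p = DEFAULT_PRIMERS
    primer_blocks = {
        "F1": p[1].forward, "rcR1": reverse_complement(p[1].reverse),
        "F2": p[2].forward, "rcR2": reverse_complement(p[2].reverse),
        "F3": p[3].forward, "rcR3": reverse_complement(p[3].reverse),
        "F4": p[4].forward, "rcR4": reverse_complement(p[4].reverse),
    }

    orders = [ORDER_POOL[i] if i < len(ORDER_POOL) else f"Order{i + 1:02d}"
              for i in range(config.n_orders)]
    truth = TruthBundle()
    truth.var_positions = var_pos
    references: list[ReferenceSpecies] = []

    def finish_sequence(base: np.ndarray) -> str:
        seq = base.copy()
        for block, pat in primer_blocks.items():
            s, e = spans[block]
            realized = _realize_primer(pat, rng)
            seq[s:e] = np.frombuffer(realized.encode(), dtype=np.uint8)
        return seq.tobytes().decode()

    n_total = config.n_orders * config.species_per_order
    n_trunc = int(round(config.truncate_fraction * n_total))
    trunc_ids: set[str] = set()

    for oi, order in enumerate(orders):
        ancestor = root.copy()
        _mutate(ancestor, var_pos, config.between_order_div, rng)
        feeding = _FEEDING_CYCLE[oi % len(_FEEDING_CYCLE)]
        for si in range(config.species_per_order):
            sp = ancestor.copy()
            _mutate(sp, var_pos, config.within_order_div, rng)
            species_id = f"{order}_sp{si + 1:02d}"
            seq = finish_sequence(sp)
            references.append(
                ReferenceSpecies(species_id, order, seq, feeding)
            )
            truth.species_order[species_id] = order
            truth.species_feeding[species_id] = feeding
            truth.region_coords[species_id] = dict(lay["coords"])

    # Outgroup: far from every ingroup order.
    og = root.copy()
    _mutate(og, var_pos, config.outgroup_div, rng)
    og_id = "Tardigrada_outgroup"
    references.append(
        ReferenceSpecies(og_id, "outgroup", finish_sequence(og), "NA",
                         is_outgroup=True)
    )
    truth.species_order[og_id] = "outgroup"
    truth.region_coords[og_id] = dict(lay["coords"])

    # 5'-truncation: cut inside the region-1 forward primer site so region 1
    # becomes unrecoverable while regions 2-4 stay intact.
    if n_trunc:
        ingroup = [r for r in references if not r.is_outgroup]
        cut = spans["F1"][0] + (spans["F1"][1] - spans["F1"][0]) // 2
        for ref in ingroup[:n_trunc]:
            ref.sequence = ref.sequence[cut:]
            ref.truncated = True
            ref.species_id = f"Q_{ref.species_id}"
            trunc_ids.add(ref.species_id)
            old = ref.species_id[2:]
            for d in (truth.species_order, truth.species_feeding):
                d[ref.species_id] = d.pop(old)
            coords = truth.region_coords.pop(old)
            truth.region_coords[ref.species_id] = {
                rid: (s - cut, e - cut) for rid, (s, e) in coords.items()
                if rid != 1
            }

    # Polymorphic allele pairs: a species-level second rDNA haplotype in a
    # random non-empty subset of regions, differing from the major insert by
    # exactly `allele_edit_count` edit operations (verified).
    for ref in references:
        if ref.is_outgroup or ref.truncated:
            continue
        if rng.random() >= config.polymorphism_rate:
            continue
        mask = rng.random(4) < 0.5
        if not mask.any():
            mask[rng.integers(4)] = True
        alleles = {}
        for rid in (np.flatnonzero(mask) + 1):
            rid = int(rid)
            s, e = truth.region_coords[ref.species_id][rid]
            insert = ref.sequence[s:e]
            alleles[rid] = _make_allele(insert, config.allele_edit_count, rng)
        truth.allele_inserts[ref.species_id] = alleles

    return references, truth


def _make_allele(insert: str, n_edits: int, rng: np.random.Generator) -> str:
    """Substitute `n_edits` distinct positions; verify the Levenshtein
    distance to the original is exactly `n_edits` (resampling on the rare
    compositions where edits collapse)."""
    arr = np.frombuffer(insert.encode(), dtype=np.uint8)
    for _ in range(50):
        out = arr.copy()
        pos = rng.choice(len(arr), size=n_edits, replace=False)
        for p in pos:
            cur = out[p]
            choices = [b for b in b"ACGT" if b != cur]
            out[p] = choices[rng.integers(3)]
        cand = out.tobytes().decode()
        if edlib.align(insert, cand, task="distance")["editDistance"] == n_edits:
            return cand
    raise RuntimeError("could not realize allele at requested edit distance")


# ---------------------------------------------------------------------------
# SV tables


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_sv_tables(
    config: SimulationConfig,
    references: list[ReferenceSpecies],
    truth: TruthBundle,
) -> tuple[dict[int, pd.DataFrame], TruthBundle]:
    """Draw per-sample, per-region SV count tables.

    Returns a feature table per region (columns: sample_id, sv_id, region,
    count, sequence, phylum, order) and the truth bundle completed with
    sample classes, allele pairs and second-nematode records resolved to the
    assigned SV ids.
    """
    rng = np.random.default_rng(config.seed + 1)
    candidates = [r for r in references if not r.is_outgroup and not r.truncated]
    if not candidates:
        raise ConfigurationError("no usable (untruncated, ingroup) species")

    # The sampled community is a subset of the reference species pool (a real
    # survey samples far fewer taxa than its reference set covers), and each
    # community species carries a slightly diverged local haplotype relative
    # to its reference sequence.  Samples of the same species share that
    # haplotype, so major/minor SV pairs recur across samples.
    n_comm = min(config.n_community_species, len(candidates))
    comm_idx = sorted(rng.choice(len(candidates), size=n_comm, replace=False))
    community = [candidates[i] for i in comm_idx]
    for ref in community:
        arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8).copy()
        if config.specimen_divergence > 0 and truth.var_positions is not None:
            _mutate(arr, truth.var_positions, config.specimen_divergence, rng)
        hap = arr.tobytes().decode()
        truth.specimen_seqs[ref.species_id] = hap
        if ref.species_id in truth.allele_inserts:
            # Re-anchor the allele haplotype on the specimen sequence so the
            # pair differs by exactly the configured edit count.
            for rid in sorted(truth.allele_inserts[ref.species_id]):
                s, e = truth.region_coords[ref.species_id][rid]
                truth.allele_inserts[ref.species_id][rid] = _make_allele(
                    hap[s:e], config.allele_edit_count, rng)

    width = max(2, len(str(config.n_samples)))
    samples = [f"S{i + 1:0{width}d}" for i in range(config.n_samples)]

    sigma = 0.5
    mu = np.log(config.depth_mean) - sigma ** 2 / 2

    # Per-region row accumulators: (sample, sequence, count, phylum, order)
    rows: dict[int, list[tuple]] = {1: [], 2: [], 3: [], 4: []}
    allele_rec, prey_rec = [], []

    for sample in samples:
        spec = community[rng.integers(len(community))]
        truth.sample_species[sample] = spec.species_id

        failed = rng.random() < config.fail_rate
        contaminated = (not failed) and rng.random() < config.contamination_rate
        predation = (not failed and not contaminated
                     and rng.random() < config.predation_rate)
        truth.sample_class[sample] = (
            "failed" if failed else
            "contaminated" if contaminated else
            "predation" if predation else "ok"
        )

        prey = None
        if predation:
            others = [r for r in community if r.order != spec.order]
            if others:
                prey = others[rng.integers(len(others))]
                truth.sample_prey[sample] = prey.species_id
            else:
                truth.sample_class[sample] = "ok"

        if contaminated:
            nem_frac = rng.uniform(0.10, 0.50)
        else:
            nem_frac = 1.0 - (rng.uniform(0.0, 0.05) if rng.random() < 0.5 else 0.0)
        prey_frac = rng.uniform(0.10, 0.30) if prey is not None else 0.0
        n_contam = int(rng.integers(1, 4)) if nem_frac < 0.999 else 0

        for rid in (1, 2, 3, 4):
            depth = (int(rng.integers(50, 900)) if failed
                     else int(np.rint(rng.lognormal(mu, sigma))))
            truth.depths[(sample, rid)] = depth

            s, e = truth.region_coords[spec.species_id][rid]
            major = truth.specimen_seqs[spec.species_id][s:e]
            comps: list[tuple[str, float, str, str, str]] = []
            # (sequence, fraction, phylum, order, role)
            allele = truth.allele_inserts.get(spec.species_id, {}).get(rid)
            af = rng.uniform(0.10, 0.45) if allele else 0.0
            pf = prey_frac
            comps.append((major, nem_frac * (1 - af - pf), "Nematoda",
                          spec.order, "major"))
            if allele:
                comps.append((allele, nem_frac * af, "Nematoda",
                              spec.order, "allele"))
            if prey is not None:
                ps, pe = truth.region_coords[prey.species_id][rid]
                prey_hap = truth.specimen_seqs[prey.species_id]
                comps.append((prey_hap[ps:pe], nem_frac * pf, "Nematoda",
                              prey.order, "prey"))
            contam_frac = 1.0 - nem_frac
            for _ in range(n_contam):
                phylum = _CONTAMINANT_PHYLA[rng.integers(len(_CONTAMINANT_PHYLA))]
                comps.append((_random_seq(e - s, rng), contam_frac / max(n_contam, 1),
                              phylum, "NA", "contaminant"))

            fracs = np.array([c[1] for c in comps])
            fracs = fracs / fracs.sum()
            counts = rng.multinomial(depth, fracs)
            for (seq, _, phylum, order, role), cnt in zip(comps, counts):
                if cnt == 0:
                    continue
                rows[rid].append((sample, seq, int(cnt), phylum, order))
                if role == "allele":
                    allele_rec.append((sample, rid, major, seq))
                elif role == "prey":
                    prey_rec.append((sample, rid, major, seq))

    tables: dict[int, pd.DataFrame] = {}
    seq_to_sv: dict[int, dict[str, str]] = {}
    for rid in (1, 2, 3, 4):
        df = pd.DataFrame(rows[rid], columns=["sample_id", "sequence", "count",
                                              "phylum", "order"])
        # Collapse duplicate (sample, sequence) rows (e.g. a contaminant drawn
        # equal to another), then rank SVs by total abundance like a denoiser.
        df = (df.groupby(["sample_id", "sequence", "phylum", "order"],
                         as_index=False)["count"].sum())
        totals = (df.groupby("sequence")["count"].sum()
                  .sort_values(ascending=False))
        ranked = sorted(totals.index, key=lambda s: (-totals[s], s))
        mapping = {seq: f"R{rid}_SV_{i + 1}" for i, seq in enumerate(ranked)}
        seq_to_sv[rid] = mapping
        df["sv_id"] = df["sequence"].map(mapping)
        df["region"] = rid
        df["_rank"] = df["sv_id"].str.rsplit("_", n=1).str[-1].astype(int)
        df = (df.sort_values(["sample_id", "_rank"])
              .drop(columns="_rank")
              .reset_index(drop=True))
        tables[rid] = df[["sample_id", "sv_id", "region", "count",
                          "sequence", "phylum", "order"]]

    truth.allele_pairs = pd.DataFrame(
        [(s, r, seq_to_sv[r][ma], seq_to_sv[r][mi])
         for s, r, ma, mi in allele_rec],
        columns=["sample_id", "region", "major_sv", "minor_sv"],
    )
    truth.second_nematode = pd.DataFrame(
        [(s, r, seq_to_sv[r][ma], seq_to_sv[r][mi])
         for s, r, ma, mi in prey_rec],
        columns=["sample_id", "region", "major_sv", "minor_sv"],
    )
    return tables, truth


def simulate_all(
    config: SimulationConfig,
) -> tuple[list[ReferenceSpecies], dict[int, pd.DataFrame], TruthBundle]:
    """Convenience wrapper: reference set + SV tables + completed truth."""
    references, truth = simulate_reference_set(config)
    tables, truth = simulate_sv_tables(config, references, truth)
    return references, tables, truth
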