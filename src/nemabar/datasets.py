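"""Packaged worked-example data.

A published individual-specimen barcoding survey of 68 soil nematodes from a
Japanese copse: each retained isolate's major SV identity in each of the
four 18S regions, plus the per-isolate order and Yeates-style feeding code
determined in that survey.  One isolate lacks a region-3 amplicon; three
distinct rOTUs share a region-3 SV while differing elsewhere, which
exercises the conflict rule of the clustering stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .alleles import IsolateProfile

__all__ = ["load_copse_profiles", "load_copse_annotations"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("nemabar.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def load_copse_profiles() -> list[IsolateProfile]:
    """Isolate profiles (per-region major SV ids) for the 68-isolate survey."""
    df = _read("copse68_regional_svs.tsv")
    profiles: dict[str, IsolateProfile] = {}
    for row in df.itertuples():
        prof = profiles.setdefault(row.sample_id,
                                   IsolateProfile(row.sample_id))
        prof.majors[int(row.region)] = row.sv_id
    return [profiles[s] for s in sorted(profiles)]


def load_copse_annotations() -> pd.DataFrame:
    """Per-isolate order and feeding code (columns: sample_id, order,
    feeding_code)."""
    return _read("copse68_isolate_annotations.tsv")
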