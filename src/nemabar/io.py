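"""Plain-text readers and writers: FASTA, TSV tables, newick trees.

Every writer has a matching reader so that each pipeline intermediate can be
re-read by the stage that consumes it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .pcr import PrimerSet
from .synthetic import ReferenceSpecies

FEATURE_COLUMNS = ["sample_id", "sv_id", "region", "count",
                   "sequence", "phylum", "order"]


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    # "NA" is a meaningful taxonomy label (unassigned), not missing data
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                       keep_default_na=False, na_values=[""], **kwargs)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[FEATURE_COLUMNS]


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def write_references(refs: list[ReferenceSpecies], fasta: str | Path,
                     annotations: str | Path) -> None:
    write_fasta({r.species_id: r.sequence for r in refs}, fasta)
    df = pd.DataFrame(
        [(r.species_id, r.order, r.feeding_code, r.truncated, r.is_outgroup)
         for r in refs],
        columns=["species_id", "order", "feeding_code", "truncated",
                 "is_outgroup"],
    )
    write_table(df, annotations)


def read_references(fasta: str | Path,
                    annotations: str | Path) -> list[ReferenceSpecies]:
    seqs = read_fasta(fasta)
    ann = pd.read_csv(annotations, sep="\t")
    refs = []
    for row in ann.itertuples():
        refs.append(ReferenceSpecies(
            species_id=row.species_id, order=row.order,
            sequence=seqs[row.species_id], feeding_code=str(row.feeding_code),
            truncated=bool(row.truncated), is_outgroup=bool(row.is_outgroup),
        ))
    return refs


def write_primers(primers: dict[int, PrimerSet], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.region_id, p.forward, p.reverse) for p in primers.values()],
        columns=["region", "forward", "reverse"],
    )
    write_table(df, path)


def read_primers(path: str | Path) -> dict[int, PrimerSet]:
    df = pd.read_csv(path, sep="\t")
    return {int(r.region): PrimerSet(int(r.region), r.forward, r.reverse)
            for r in df.itertuples()}
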