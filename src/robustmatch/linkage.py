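"""Genetic-linkage grouping from genome coordinates.

Two genes are "genetically linked" when they are adjacent in genomic order,
on the same strand (colinear) and separated by an intergenic gap strictly
smaller than a threshold (default 100 bp).  Maximal runs of pairwise-linked
genes form linkage groups (an operon-like proxy); genes with no linked
neighbour are singleton groups.  Coordinates follow the GFF3 convention:
1-based, inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneModel",
    "LinkageGroup",
    "read_gene_models",
    "intergenic_spacing",
    "find_linked_groups",
    "annotate_signature",
    "groups_to_frame",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    start: int   # 1-based inclusive
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class LinkageGroup:
    group_id: str
    contig: str
    strand: str
    gene_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_gene_models(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models from a GFF3 file (seqid, start, end, strand, ID)."""
    import gffutils

    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError as err:
        raise ValueError(f"no features in {path}") from err
    out = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        out.append(GeneModel(gene_id=gid, contig=feat.seqid,
                             start=feat.start, end=feat.end, strand=feat.strand))
    if not out:
        raise ValueError(f"no {feature_type!r} features in {path}")
    return out


def intergenic_spacing(a: GeneModel, b: GeneModel) -> int:
    """Gap in bp between two genes with ``a`` preceding ``b`` in genomic order.

    ``b.start - a.end - 1``: 0 for directly abutting genes, negative
    (<= -1) for overlapping genes, which count as zero distance for linkage.
    """
    if a.contig != b.contig:
        raise ValueError(f"{a.gene_id} and {b.gene_id} lie on different contigs")
    return b.start - a.end - 1


def find_linked_groups(genes, max_spacing: int = 100) -> list[LinkageGroup]:
    """Partition genes into maximal linked runs.

    Genes are sorted internally per contig by start coordinate, so input
    order does not matter.  A run extends while the next gene shares the
    contig and strand and the intergenic spacing is strictly below
    ``max_spacing`` (overlaps always qualify).
    """
    ordered = sorted(genes, key=lambda g: (g.contig, g.start, g.end, g.gene_id))
    groups: list[LinkageGroup] = []
    run: list[GeneModel] = []

    def flush() -> None:
        if run:
            groups.append(LinkageGroup(
                group_id=f"LG{len(groups) + 1:04d}",
                contig=run[0].contig, strand=run[0].strand,
                gene_ids=tuple(g.gene_id for g in run),
            ))

    for g in ordered:
        if run:
            prev = run[-1]
            linked = (g.contig == prev.contig and g.strand == prev.strand
                      and intergenic_spacing(prev, g) < max_spacing)
            if not linked:
                flush()
                run = []
        run.append(g)
    flush()
    return groups


def annotate_signature(sig, groups) -> pd.DataFrame:
    """Label each signature gene with its linkage group and co-members.

    Co-members are the other signature genes in the same group.  Signature
    genes absent from the annotation are flagged (``in_annotation=False``)
    rather than dropped.
    """
    gene_to_group = {g: grp for grp in groups for g in grp.gene_ids}
    sig_ids = list(sig.gene_ids)
    sig_set = set(sig_ids)
    rows = []
    for gid in sig_ids:
        grp = gene_to_group.get(gid)
        if grp is None:
            rows.append((gid, None, "", False))
        else:
            co = [g for g in grp.gene_ids if g != gid and g in sig_set]
            rows.append((gid, grp.group_id, ",".join(co), True))
    return pd.DataFrame(
        rows, columns=["gene_id", "group_id", "co_members", "in_annotation"]
    )


def groups_to_frame(groups) -> pd.DataFrame:
    """Linkage groups as a tidy table (one row per group)."""
    return pd.DataFrame(
        [(g.group_id, g.contig, g.strand, ",".join(g.gene_ids)) for g in groups],
        columns=["group_id", "contig", "strand", "gene_ids"],
    )
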