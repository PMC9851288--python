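"""Multi-omics network integration: cis proximity, trans concatenation, custom tables.

Three integration styles decorate or extend a gene-regulatory network with a
second modality:

* **cis** (soft/late): elements of a non-focal modality (e.g. ChIP peaks)
  whose coordinates fall within a strand-aware window upstream/downstream of
  a focal node's interval are attached as annotation nodes.
* **trans** (complete/early): two expression matrices over identical samples
  are row-concatenated before joint inference, with per-feature modality tags
  preserved so nodes can be coloured by source.  No re-normalisation is
  performed: tree-ensemble inference standardises each feature, which absorbs
  scale differences between modalities.
* **custom**: externally curated regulator -> target interactions are added
  as annotation nodes/edges wherever the target exists in the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .grn import Network
from .matrixio import ExpressionMatrix, GenomicInterval, InteractionTable, MatrixIOError

__all__ = ["CisAnnotation", "cis_annotate", "trans_integrate", "custom_annotate"]

log = logging.getLogger(__name__)


@dataclass
class CisAnnotation:
    """Per-focal-node record of attached cis elements."""

    window_bp: int
    side: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: focal_id, element_id, chrom, start, end, relation, distance_bp
    skipped_nodes: list[str] = field(default_factory=list)


def _extension(iv: GenomicInterval, window_bp: int, side: str) -> tuple[int, int]:
    """Extended [start, end) per requested side, resolved by strand.

    Upstream of a + feature is towards lower coordinates; for - features the
    sides flip.  Unknown strand is treated as + (logged by the caller).
    """
    strand = iv.strand if iv.strand in ("+", "-") else "+"
    lo, hi = iv.start, iv.end
    extend_left = (side == "both"
                   or (side == "upstream" and strand == "+")
                   or (side == "downstream" and strand == "-"))
    extend_right = (side == "both"
                    or (side == "downstream" and strand == "+")
                    or (side == "upstream" and strand == "-"))
    if extend_left:
        lo = max(0, lo - window_bp)
    if extend_right:
        hi = hi + window_bp
    return lo, hi


def _relation(focal: GenomicInterval, elem: GenomicInterval) -> tuple[str, int]:
    """(upstream/downstream/overlapping, gap in bp) of element vs focal body."""
    if focal.overlaps(elem):
        return "overlapping", 0
    strand = focal.strand if focal.strand in ("+", "-") else "+"
    if elem.end <= focal.start:
        gap = focal.start - elem.end
        return ("upstream" if strand == "+" else "downstream"), gap
    gap = elem.start - focal.end
    return ("downstream" if strand == "+" else "upstream"), gap


def cis_annotate(
    net: Network,
    focal_coords: dict[str, GenomicInterval],
    non_focal: list[tuple[str, GenomicInterval]],
    window_bp: int = 1000,
    side: str = "both",
    element_modality: str = "cis",
    tss_mode: bool = False,
) -> tuple[Network, CisAnnotation]:
    """Attach non-focal elements within a genomic window of focal nodes.

    An element is attached to a focal node iff its interval intersects the
    node's interval extended by ``window_bp`` on the requested side(s)
    (strand-aware; unknown strand treated as +, logged).  Attached elements
    become annotation nodes linked by unweighted edges labelled with their
    relation (upstream / downstream / overlapping) for colour-coded display.
    Nodes without coordinates are skipped with a warning.

    With ``tss_mode`` the focal interval is collapsed to the 1-bp
    transcription start (strand-aware 5' end) before extension.
    """
    if window_bp < 0:
        raise MatrixIOError("window_bp must be non-negative")
    if side not in ("upstream", "downstream", "both"):
        raise MatrixIOError(f"unknown side {side!r}")

    trees: dict[str, IntervalTree] = {}
    for eid, iv in non_focal:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (eid, iv))

    out = net.copy()
    rows = []
    skipped = []
    for node in sorted(net.g.nodes):
        if net.g.nodes[node].get("annotation_source"):
            continue
        iv = focal_coords.get(node)
        if iv is None:
            skipped.append(node)
            continue
        if iv.strand not in ("+", "-"):
            log.info("cis_annotate: node %s has unknown strand, treated as +", node)
        body = iv
        if tss_mode:
            tss = iv.start if iv.strand != "-" else iv.end - 1
            body = GenomicInterval(iv.chrom, tss, tss + 1, iv.strand)
        lo, hi = _extension(body, window_bp, side)
        for hit in sorted(trees.get(iv.chrom, IntervalTree()).overlap(lo, hi),
                          key=lambda h: (h.begin, h.end, h.data[0])):
            eid, eiv = hit.data
            relation, gap = _relation(body, eiv)
            out.add_node(eid, modality=element_modality, annotation_source=element_modality)
            if eid != node:
                out.add_edge(eid, node, weight=0.0, kind="annotation", relation=relation)
            rows.append((node, eid, eiv.chrom, eiv.start, eiv.end, relation, gap))
    if skipped:
        log.warning("cis_annotate: %d node(s) without coordinates skipped", len(skipped))
    records = pd.DataFrame(
        rows, columns=["focal_id", "element_id", "chrom", "start", "end", "relation", "distance_bp"]
    )
    return out, CisAnnotation(window_bp=window_bp, side=side, records=records, skipped_nodes=skipped)


def trans_integrate(m1: ExpressionMatrix, m2: ExpressionMatrix) -> ExpressionMatrix:
    """Row-concatenate two modality matrices over identical samples.

    ``m2`` columns are harmonised to ``m1``'s order first; a sample-set
    mismatch is an error listing the difference.  Colliding feature ids are
    suffixed with their modality tag.  Per-feature modality tags are stored
    so downstream networks can colour nodes by source.
    """
    s1, s2 = set(m1.sample_ids), set(m2.sample_ids)
    if s1 != s2:
        raise MatrixIOError(
            f"sample sets differ: only in first {sorted(s1 - s2)}, only in second {sorted(s2 - s1)}"
        )
    d1, d2 = m1.data.copy(), m2.data[m1.sample_ids].copy()

    collide = set(d1.index) & set(d2.index)
    if collide:
        d1.index = [f"{fid}_{m1.modality_tag}" if fid in collide else fid for fid in d1.index]
        d2.index = [f"{fid}_{m2.modality_tag}" if fid in collide else fid for fid in d2.index]

    tags1 = (m1.feature_modalities.to_numpy() if m1.feature_modalities is not None
             else [m1.modality_tag] * m1.n_features)
    tags2 = (m2.feature_modalities.to_numpy() if m2.feature_modalities is not None
             else [m2.modality_tag] * m2.n_features)
    data = pd.concat([d1, d2], axis=0)
    tags = pd.Series(list(tags1) + list(tags2), index=data.index)

    state = m1.state if m1.state == m2.state else "raw"
    tag = m1.modality_tag if m1.modality_tag == m2.modality_tag else f"{m1.modality_tag}+{m2.modality_tag}"
    return ExpressionMatrix(data, state=state, modality_tag=tag, feature_modalities=tags)


def custom_annotate(net: Network, tbl: InteractionTable) -> tuple[Network, dict[str, int]]:
    """Attach external regulator -> target interactions to existing targets.

    Rows whose target is a node of the network add the regulator as an
    annotation node with an unweighted edge; duplicate rows collapse to one
    edge; rows with absent targets are skipped and counted.  Idempotent.
    """
    out = net.copy()
    added, skipped = 0, 0
    seen: set[tuple[str, str]] = set()
    for regulator, target, source in tbl.rows():
        if target not in net.g or (regulator, target) in seen:
            if target not in net.g:
                skipped += 1
            continue
        seen.add((regulator, target))
        if regulator == target:
            skipped += 1
            continue
        out.add_node(regulator, modality=source, annotation_source=source)
        if not out.g.has_edge(regulator, target):
            out.add_edge(regulator, target, weight=0.0, kind="annotation")
            added += 1
    return out, {"edges_added": added, "rows_skipped": skipped}
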